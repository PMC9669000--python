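"""Exact Pólya-Gamma PG(1, z) sampling (Devroye-style alternating series).

PG augmentation turns Bernoulli-logit likelihoods into conditionally
Gaussian ones: with omega_i ~ PG(1, psi_i), the logistic regression
coefficients have a closed-form multivariate-normal full conditional.
The sampler below is the standard O(1) rejection scheme: a mixture of a
truncated inverse-Gaussian (left of t = 0.64) and a truncated exponential
(right of t) proposal for J*(1, z), accepted against the alternating
series expansion of the density; PG(1, z) = J*(1, z) / 4.

Everything is numba-compiled and driven by numba's internal RNG; seed it
through :func:`seed_rng` before a chain for reproducibility.
"""

import math

import numpy as np
from numba import njit

_TRUNC = 0.64


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def _norm_cdf(x):
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


@njit(cache=True)
def _mass_texpon(z):
    # P(proposal comes from the exponential piece right of _TRUNC)
    t = _TRUNC
    fz = 0.125 * math.pi * math.pi + 0.5 * z * z
    b = math.sqrt(1.0 / t) * (t * z - 1.0)
    a = -math.sqrt(1.0 / t) * (t * z + 1.0)
    x0 = math.log(fz) + fz * t
    cb = _norm_cdf(b)
    ca = _norm_cdf(a)
    xb = x0 - z + (math.log(cb) if cb > 0.0 else -745.0)
    xa = x0 + z + (math.log(ca) if ca > 0.0 else -745.0)
    qdivp = 4.0 / math.pi * (math.exp(xb) + math.exp(xa))
    return 1.0 / (1.0 + qdivp)


@njit(cache=True)
def _rtigauss(z):
    # inverse-Gaussian(mu=1/z, lambda=1) truncated to (0, _TRUNC)
    t = _TRUNC
    x = t + 1.0
    if z < 1.0 / t:  # mu > t: rejection from the x^{-3/2} tail kernel
        alpha = 0.0
        while np.random.random() > alpha:
            e1 = np.random.exponential()
            e2 = np.random.exponential()
            while e1 * e1 > 2.0 * e2 / t:
                e1 = np.random.exponential()
                e2 = np.random.exponential()
            x = t / ((1.0 + t * e1) * (1.0 + t * e1))
            alpha = math.exp(-0.5 * z * z * x)
    else:
        mu = 1.0 / z
        while x > t:
            y = np.random.normal()
            y = y * y
            muy = mu * y
            x = mu + 0.5 * mu * muy - 0.5 * mu * math.sqrt(4.0 * muy + muy * muy)
            if np.random.random() > mu / (mu + x):
                x = mu * mu / x
    return x


@njit(cache=True)
def _a_coef(n, x):
    # n-th term of the alternating series for the J*(1) density at x
    npl = n + 0.5
    if x > _TRUNC:
        return math.pi * npl * math.exp(-0.5 * npl * npl * math.pi * math.pi * x)
    return math.pi * npl * math.pow(2.0 / (math.pi * x), 1.5) * math.exp(-2.0 * npl * npl / x)


@njit(cache=True)
def sample_pg1(zin):
    """One draw from PG(1, zin)."""
    z = 0.5 * abs(zin)
    fz = 0.125 * math.pi * math.pi + 0.5 * z * z
    p_right = _mass_texpon(z)
    while True:
        if np.random.random() < p_right:
            x = _TRUNC + np.random.exponential() / fz
        else:
            x = _rtigauss(z)
        s = _a_coef(0, x)
        y = np.random.random() * s
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    return 0.25 * x
            else:
                s += _a_coef(n, x)
                if y > s:
                    break


@njit(cache=True)
def pg_draws(psi):
    """Vector of independent PG(1, psi_i) draws."""
    out = np.empty(psi.size)
    for i in range(psi.size):
        out[i] = sample_pg1(psi[i])
    return out


def pg_mean(z):
    """E[PG(1, z)] = tanh(z/2) / (2z), with the z -> 0 limit 1/4."""
    z = np.asarray(z, dtype=float)
    small = np.abs(z) < 1e-8
    safe = np.where(small, 1.0, z)
    return np.where(small, 0.25, np.tanh(safe / 2.0) / (2.0 * safe))


def pg_var(z):
    """Var[PG(1, z)] = (sinh(z) - z) * sech^2(z/2) / (4 z^3), limit 1/24."""
    z = np.asarray(z, dtype=float)
    small = np.abs(z) < 1e-4
    safe = np.where(small, 1.0, z)
    v = (np.sinh(safe) - safe) / (4.0 * safe**3) / np.cosh(safe / 2.0) ** 2
    return np.where(small, 1.0 / 24.0, v)
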
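"""Posterior summaries: HDI, probability of direction, ROPE, Bayes factors.

Every reported coefficient gets the same reporting line: posterior median,
95% highest-density interval, probability of direction, percentage of the
posterior inside the region of practical equivalence, a Savage–Dickey
point-null Bayes factor, a ROPE Bayes factor, and the odds ratio
exp(median).  The default ROPE half-width 0.013 on the log-odds scale is
the image of a negligible effect size d = 0.007 on the stay probability
(logistic sd = pi/sqrt(3)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ..errors import InputError

BF_CAP = 1e4


def hdi(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` posterior mass.

    Sorted-window algorithm; ties broken toward the lower interval start
    (``argmin`` takes the first minimum).
    """
    if not (0.0 < mass < 1.0):
        raise InputError("mass must be in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 100:
        raise InputError(f"need >= 100 samples for an HDI, got {n}")
    m = int(math.ceil(mass * n))
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def pd_direction(samples) -> float:
    """Probability of direction, in percent: 100 x max(P(s>0), P(s<0))."""
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 100:
        raise InputError(f"need >= 100 samples, got {x.size}")
    p_pos = float(np.mean(x > 0))
    p_neg = float(np.mean(x < 0))
    return max(100.0 * max(p_pos, p_neg), 50.0)


def rope_summary(samples, rope: tuple[float, float]) -> float:
    """Percentage of samples inside the closed ROPE interval."""
    lo, hi = rope
    if not lo < hi:
        raise InputError("rope.low must be < rope.high")
    x = np.asarray(samples, dtype=float).ravel()
    return float(100.0 * np.mean((x >= lo) & (x <= hi)))


def rope_from_d(d: float) -> float:
    """Log-odds ROPE half-width for a Cohen's d on the probability scale.

    A standard-logistic latent variable has sd pi/sqrt(3), so a negligible
    d maps to d * pi/sqrt(3) log-odds units (rounded to 3 decimals).
    """
    if d < 0:
        raise InputError("d must be >= 0")
    return round(d * math.pi / math.sqrt(3.0), 3)


def _posterior_density_at(samples: np.ndarray, x0: float) -> float:
    kde = stats.gaussian_kde(samples, bw_method="silverman")
    return float(kde(x0)[0])


def bf_savage_dickey(samples, prior_density_at_0: float):
    """Point-null BF10 = prior density at 0 / posterior density at 0.

    Returns ``(bf10, capped)``; when the kernel estimate of the posterior
    density at 0 underflows, the BF is reported at the cap and flagged.
    """
    if prior_density_at_0 <= 0:
        raise InputError("prior density at 0 must be positive")
    x = np.asarray(samples, dtype=float).ravel()
    post0 = _posterior_density_at(x, 0.0)
    if post0 <= prior_density_at_0 / BF_CAP:
        return BF_CAP, True
    return prior_density_at_0 / post0, False


def bf_rope(samples, prior: stats.rv_continuous | object, rope: tuple[float, float]):
    """ROPE Bayes factor: posterior vs prior odds of being outside the ROPE.

    ``prior`` is a frozen scipy distribution (its CDF supplies the prior
    mass inside the ROPE).  Returns ``(bf, capped)``.
    """
    lo, hi = rope
    if not lo < hi:
        raise InputError("rope.low must be < rope.high")
    x = np.asarray(samples, dtype=float).ravel()
    post_in = float(np.mean((x >= lo) & (x <= hi)))
    prior_in = float(prior.cdf(hi) - prior.cdf(lo))
    if not (0.0 < prior_in < 1.0):
        raise InputError("prior must place mass both inside and outside the ROPE")
    prior_odds_out = (1.0 - prior_in) / prior_in
    if post_in <= 1.0 / (BF_CAP * prior_odds_out):
        return BF_CAP, True
    post_odds_out = (1.0 - post_in) / post_in
    return post_odds_out / prior_odds_out, False


@dataclass
class PosteriorSummary:
    """One coefficient's reporting line."""

    name: str
    median: float
    hdi_low: float
    hdi_high: float
    pd: float
    pct_in_rope: float | None = None
    bf10_point: float | None = None
    bf_rope: float | None = None
    odds_ratio: float | None = None
    bf_capped: bool = False

    def __post_init__(self) -> None:
        if not (self.hdi_low <= self.median <= self.hdi_high):
            raise InputError("summary violates hdi_low <= median <= hdi_high")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "median": self.median,
            "hdi_low": self.hdi_low,
            "hdi_high": self.hdi_high,
            "pd": self.pd,
            "pct_in_rope": self.pct_in_rope,
            "bf10_point": self.bf10_point,
            "bf_rope": self.bf_rope,
            "odds_ratio": self.odds_ratio,
            "bf_capped": self.bf_capped,
        }

    def report_line(self) -> str:
        parts = [
            f"median {self.median:.2f}",
            f"HDI95% [{self.hdi_low:.2f}, {self.hdi_high:.2f}]",
            f"pd {self.pd:.0f}%",
        ]
        if self.pct_in_rope is not None:
            parts.append(f"{self.pct_in_rope:.0f}% in ROPE")
        if self.bf10_point is not None:
            parts.append(f"BF10 {self.bf10_point:.2f}{'+' if self.bf_capped else ''}")
        if self.bf_rope is not None:
            parts.append(f"BF-ROPE {self.bf_rope:.2f}")
        if self.odds_ratio is not None:
            parts.append(f"OR {self.odds_ratio:.2f}")
        return ", ".join(parts)


def summarize_coefficient(
    name: str,
    samples,
    rope: tuple[float, float] = (-0.013, 0.013),
    hdi_mass: float = 0.95,
    prior_sd: float | None = 1.0,
) -> PosteriorSummary:
    """Full reporting line for one coefficient's posterior samples."""
    x = np.asarray(samples, dtype=float).ravel()
    lo, hi = hdi(x, hdi_mass)
    med = float(np.median(x))
    summary = PosteriorSummary(
        name=name,
        median=med,
        hdi_low=lo,
        hdi_high=hi,
        pd=pd_direction(x),
        pct_in_rope=rope_summary(x, rope),
        odds_ratio=float(np.exp(med)),
    )
    if prior_sd is not None:
        prior = stats.norm(0.0, prior_sd)
        bf10, cap1 = bf_savage_dickey(x, prior.pdf(0.0))
        bfr, cap2 = bf_rope(x, prior, rope)
        summary.bf10_point = bf10
        summary.bf_rope = bfr
        summary.bf_capped = cap1 or cap2
    return summary


def marginal_means(draws, at=(0, 1), hdi_mass: float = 0.95) -> dict[int, dict]:
    """Predicted stay probability per previous-outcome level.

    Other covariates sit at 0 (their standardized centre) and random
    effects at 0, so the prediction is the typical-subject probability
    logit^-1(intercept + beta_prev * (level - 1/2)) per posterior draw.
    """
    b0 = draws.samples("intercept")
    b1 = draws.samples("prev_outcome")
    out = {}
    for level in at:
        psi = b0 + b1 * (float(level) - 0.5)
        prob = 1.0 / (1.0 + np.exp(-psi))
        lo, hi = hdi(prob, hdi_mass)
        out[int(level)] = {"median": float(np.median(prob)), "hdi_low": lo, "hdi_high": hi}
    return out
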
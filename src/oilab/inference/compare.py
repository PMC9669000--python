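"""PSIS-LOO model comparison with stacking weights."""

from __future__ import annotations

from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

from ..errors import DataError
from .gibbs import Draws


@dataclass
class StackingWeights:
    """Per-model expected log predictive density and stacking weight."""

    names: list[str]
    elpd: dict[str, float]
    elpd_se: dict[str, float]
    weights: dict[str, float]
    pareto_k_high_frac: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "names": self.names,
            "elpd": self.elpd,
            "elpd_se": self.elpd_se,
            "weights": self.weights,
            "pareto_k_high_frac": self.pareto_k_high_frac,
        }


def loo_stacking(draws_map: dict[str, Draws]) -> StackingWeights:
    """Compare fitted models by PSIS-LOO and return stacking weights.

    All models must be fitted to the identical observation set (the
    sampler stores pointwise log-likelihoods in a fixed subject-sorted
    order, so fits from the same stay table line up).  Weights maximize
    the leave-one-out log score over the simplex; the fraction of
    Pareto-k diagnostics above 0.7 is reported per model.
    """
    if not draws_map:
        raise DataError("no models to compare")
    names = list(draws_map)
    n_obs = {name: d.n_obs for name, d in draws_map.items()}
    if len(set(n_obs.values())) != 1:
        raise DataError(f"models were fit to different observation sets: {n_obs}")
    k_frac = {}
    idatas = {}
    for name, d in draws_map.items():
        idata = d.to_idata()
        idatas[name] = idata
        loo = az.loo(idata, pointwise=True)
        k_frac[name] = float(np.mean(loo.pareto_k.to_numpy() > 0.7))
    if len(names) == 1:
        only = names[0]
        loo = az.loo(idatas[only])
        return StackingWeights(
            names=names,
            elpd={only: float(loo.elpd_loo)},
            elpd_se={only: float(loo.se)},
            weights={only: 1.0},
            pareto_k_high_frac=k_frac,
        )
    table: pd.DataFrame = az.compare(idatas, ic="loo", method="stacking")
    weights = {name: float(table.loc[name, "weight"]) for name in names}
    total = sum(weights.values())
    weights = {k: v / total for k, v in weights.items()}
    return StackingWeights(
        names=names,
        elpd={name: float(table.loc[name, "elpd_loo"]) for name in names},
        elpd_se={name: float(table.loc[name, "se"]) for name in names},
        weights=weights,
        pareto_k_high_frac=k_frac,
    )
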
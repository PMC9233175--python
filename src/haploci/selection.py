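"""WAIC model comparison and finite-population variance decomposition.

WAIC estimates out-of-sample predictive accuracy from the pointwise
posterior log-likelihood matrix:

    lppd   = sum_i log mean_s exp(loglik_si)      (log-sum-exp, stable)
    p_waic = sum_i var_s(loglik_si)               (sample variance, ddof 1)
    waic   = -2 (lppd - p_waic)
    se     = sqrt(n * var_i(-2 (lppd_i - p_i)))

Lower WAIC is better.  To compare the explanatory impact of model terms,
the finite-population standard deviation of each term's realized per-level
effects is computed per posterior draw: the term's coefficients with the
treatment-coding reference level included as 0, centered, SD with a J-1
denominator.  The day group uses the realized day intercepts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .core_data import BroodRecord
from .inference import McmcSettings, ModelSpec, Posterior, fit_model

__all__ = [
    "WaicResult",
    "waic",
    "compare_models",
    "finite_population_sd",
    "group_sd",
]


@dataclass(frozen=True)
class WaicResult:
    lppd: float
    p_waic: float
    waic: float
    se: float
    n_obs: int
    pointwise: np.ndarray  # -2 * (lppd_i - p_i) per observation


def waic(posterior: Posterior | np.ndarray) -> WaicResult:
    """Widely applicable information criterion from pointwise log-likelihoods.

    Accepts a fitted posterior or a raw (draws x observations) log-likelihood
    matrix.  Requires at least two draws (the effective-parameter term is a
    sample variance over draws).
    """
    ll = posterior.pointwise_loglik if isinstance(posterior, Posterior) else np.asarray(
        posterior, dtype=float
    )
    if ll.ndim != 2:
        raise ValueError("pointwise log-likelihood must be draws x observations")
    n_draws, n_obs = ll.shape
    if n_draws < 2:
        raise ValueError("WAIC needs at least 2 posterior draws")
    lppd_i = logsumexp(ll, axis=0) - np.log(n_draws)
    p_i = np.var(ll, axis=0, ddof=1)
    pointwise = -2.0 * (lppd_i - p_i)
    total = float(pointwise.sum())
    se = float(np.sqrt(n_obs * np.var(pointwise, ddof=1))) if n_obs > 1 else 0.0
    return WaicResult(
        lppd=float(lppd_i.sum()),
        p_waic=float(p_i.sum()),
        waic=total,
        se=se,
        n_obs=n_obs,
        pointwise=pointwise,
    )


def compare_models(
    records: Sequence[BroodRecord],
    specs: Sequence[ModelSpec],
    settings: McmcSettings | None = None,
) -> tuple[pd.DataFrame, dict[str, Posterior]]:
    """Fit each spec on identical retained rows and rank them by WAIC.

    All specs must model the same response (which also guarantees the same
    zero-denominator filtering).  The table is sorted by WAIC ascending and
    carries the difference to the best model and the standard error of that
    difference (from the paired pointwise contributions).
    """
    responses = {s.response for s in specs}
    if len(specs) < 2:
        raise ValueError("need at least two model specs to compare")
    if len(responses) != 1:
        raise ValueError(f"specs disagree on the response: {responses}")
    posteriors: dict[str, Posterior] = {}
    results: dict[str, WaicResult] = {}
    for spec in specs:
        name = spec.fixed_terms
        k = 2
        while name in posteriors:  # duplicated specs stay distinguishable
            name = f"{spec.fixed_terms}#{k}"
            k += 1
        posteriors[name] = fit_model(records, spec, settings)
        results[name] = waic(posteriors[name])
    best = min(results, key=lambda k: results[k].waic)
    rows = []
    for name, res in results.items():
        diff = res.pointwise - results[best].pointwise
        d_se = float(np.sqrt(res.n_obs * np.var(diff, ddof=1))) if res.n_obs > 1 else 0.0
        rows.append(
            {
                "model": name,
                "waic": res.waic,
                "se": res.se,
                "p_waic": res.p_waic,
                "lppd": res.lppd,
                "d_waic": res.waic - results[best].waic,
                "d_se": d_se,
            }
        )
    table = pd.DataFrame(rows).sort_values("waic", ignore_index=True)
    return table, posteriors


def group_sd(effects: np.ndarray) -> np.ndarray:
    """Finite-population SD of per-level effects, per draw.

    ``effects`` is (draws x levels); each row is centered and its SD taken
    with a J-1 denominator, J the number of levels.
    """
    effects = np.atleast_2d(np.asarray(effects, dtype=float))
    if effects.shape[1] < 2:
        raise ValueError("a group needs at least two levels")
    centered = effects - effects.mean(axis=1, keepdims=True)
    return np.sqrt((centered**2).sum(axis=1) / (effects.shape[1] - 1))


def finite_population_sd(
    posterior: Posterior,
    grouping: dict[str, list[str]] | None = None,
) -> dict[str, np.ndarray]:
    """Per-draw finite-population SD of each coefficient group.

    By default every fixed-effect term of the model forms one group (its
    coefficients plus the reference level's implicit 0) and the day random
    intercepts form a ``day`` group.  A custom ``grouping`` must map every
    non-intercept fixed-effect parameter to exactly one group.
    """
    design = posterior.design
    if grouping is None:
        grouping = {
            ":".join(term): [design.colnames[j] for j in cols]
            for term, cols in design.term_columns().items()
        }
    fixed = set(design.colnames) - {"Intercept"}
    mapped: list[str] = [p for ps in grouping.values() for p in ps]
    if len(mapped) != len(set(mapped)):
        raise ValueError("a parameter is mapped to more than one group")
    unmapped = fixed - set(mapped)
    if unmapped:
        raise ValueError(f"parameters not mapped to any group: {sorted(unmapped)}")
    unknown = set(mapped) - fixed
    if unknown:
        raise ValueError(f"unknown parameters in grouping: {sorted(unknown)}")

    out: dict[str, np.ndarray] = {}
    flat = posterior.flat
    for label, params in grouping.items():
        cols = [posterior.param_names.index(p) for p in params]
        effects = np.concatenate(
            [np.zeros((flat.shape[0], 1)), flat[:, cols]], axis=1
        )
        out[label] = group_sd(effects)
    if posterior.spec.day_intercepts and len(posterior.day_levels) >= 2:
        out["day"] = group_sd(posterior.day_effects())
    return out


def group_sd_summary(sds: dict[str, np.ndarray]) -> pd.DataFrame:
    """Posterior mean/median and 0.09/0.91 percentiles per group, sorted."""
    rows = []
    for label, draws in sds.items():
        q09, q50, q91 = np.quantile(draws, (0.09, 0.5, 0.91))
        rows.append(
            {"group": label, "mean": float(np.mean(draws)), "q09": float(q09),
             "q50": float(q50), "q91": float(q91)}
        )
    return pd.DataFrame(rows).sort_values("q50", ascending=False, ignore_index=True)
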
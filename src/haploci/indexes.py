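"""Corrected CI strength and phenotype indexes.

Raw brood proportions confound CI with nuclear and temporal effects, so
each incompatible cross is paired with the compatible control of the same
female x male genotype pair and three corrected indexes are computed:

    CI_corr = 1 - F_obs / F_c
    MD_corr = (MD_obs - MD_c) / (1 - MD_c)
    FM_corr = (FM_obs * (1 - MD_corr) - FM_c) / (1 - FM_c)

where the ``obs`` quantities are estimated in the incompatible cross and
the ``c`` quantities in its compatible control.  The indexes are computed
per posterior draw and summarized afterwards (mean and the 0.09/0.50/0.91
percentiles), never from summarized proportions, so that uncertainty
propagates through the ratios.  Values below 0 are legal and reported
unclipped.  A plug-in variant substitutes pooled raw proportions into the
same formulas and serves as the non-Bayesian oracle at large sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import BroodRecord, CrossClass, CrossType, Genotype
from .inference import McmcSettings, ModelSpec, Posterior, fit_model, predict_proportion

__all__ = [
    "CIIndexDraws",
    "ci_corr",
    "md_corr",
    "fm_corr",
    "plugin_indexes",
    "posterior_indexes",
    "diallel_index_analysis",
    "summarize_indexes",
]

QUANTILES = (0.09, 0.50, 0.91)


def _aligned(*arrays: np.ndarray) -> list[np.ndarray]:
    out = [np.asarray(a, dtype=float) for a in arrays]
    lengths = {a.shape for a in out}
    if len(lengths) != 1:
        raise ValueError(f"draw vectors are not sample-aligned: shapes {lengths}")
    return out


def ci_corr(f_obs_draws, f_c_draws, cross: str = "") -> np.ndarray:
    """Corrected CI strength, 1 - F_obs/F_c, per draw."""
    f_obs, f_c = _aligned(f_obs_draws, f_c_draws)
    if np.any(f_c == 0):
        raise ValueError(
            f"degenerate compatible cross {cross or ''}: F_c draw equal to 0"
        )
    return 1.0 - f_obs / f_c


def md_corr(md_obs_draws, md_c_draws, cross: str = "") -> np.ndarray:
    """Corrected male-development phenotype, (MD_obs - MD_c)/(1 - MD_c)."""
    md_obs, md_c = _aligned(md_obs_draws, md_c_draws)
    if np.any(md_c == 1):
        raise ValueError(
            f"all-male compatible brood {cross or ''}: MD_c draw equal to 1"
        )
    return (md_obs - md_c) / (1.0 - md_c)


def fm_corr(fm_obs_draws, fm_c_draws, md_corr_draws, cross: str = "") -> np.ndarray:
    """Corrected female-mortality phenotype.

    Consumes the MD_corr draws (positionally aligned) because the observed
    failure fraction must be discounted by the share of CI-affected eggs
    that became males instead of dying.
    """
    fm_obs, fm_c, md = _aligned(fm_obs_draws, fm_c_draws, md_corr_draws)
    if np.any(fm_c == 1):
        raise ValueError(
            f"fully failing compatible cross {cross or ''}: FM_c draw equal to 1"
        )
    return (fm_obs * (1.0 - md) - fm_c) / (1.0 - fm_c)


@dataclass
class CIIndexDraws:
    """Sample-aligned index draws for one female x male genotype pair."""

    female: str
    male: str
    ci: np.ndarray
    md: np.ndarray
    fm: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.ci) == len(self.md) == len(self.fm)):
            raise ValueError("index draw vectors must be sample-aligned")

    def summary(self) -> list[dict]:
        rows = []
        for name, draws in (("CI_corr", self.ci), ("MD_corr", self.md),
                            ("FM_corr", self.fm)):
            q09, q50, q91 = np.quantile(draws, QUANTILES)
            rows.append(
                {
                    "female": self.female,
                    "male": self.male,
                    "index": name,
                    "mean": float(np.mean(draws)),
                    "q09": float(q09),
                    "q50": float(q50),
                    "q91": float(q91),
                }
            )
        return rows


def _pooled_proportions(records: Sequence[BroodRecord]) -> tuple[float, float, float]:
    eggs = sum(r.eggs for r in records)
    females = sum(r.adult_females for r in records)
    males = sum(r.adult_males for r in records)
    if eggs == 0:
        raise ValueError("pooled egg count is zero")
    fm_den = eggs - males
    if fm_den == 0:
        raise ValueError("pooled FM denominator is zero (all eggs became males)")
    failed = eggs - females - males
    return females / eggs, males / eggs, failed / fm_den


def plugin_indexes(
    records: Sequence[BroodRecord], pair: tuple[str, str]
) -> tuple[float, float, float]:
    """Point-estimate indexes from pooled raw counts for one genotype pair.

    ``pair`` is (female_genotype, male_genotype).  Pools all incompatible
    and all compatible-control replicates of the pair and substitutes the
    pooled proportions into the three index formulas.  Serves as the
    brute-force oracle for the Bayesian pipeline at large n.
    """
    female, male = pair
    inc = [r for r in records if r.cross_type.pair == pair
           and r.cross_type.cross_class == CrossClass.INCOMPATIBLE]
    comp = [r for r in records if r.cross_type.pair == pair
            and r.cross_type.cross_class == CrossClass.COMPATIBLE_CONTROL]
    if not inc or not comp:
        raise ValueError(f"empty cross cell for pair {female} x {male}")
    f_obs, md_obs, fm_obs = _pooled_proportions(inc)
    f_c, md_c, fm_c = _pooled_proportions(comp)
    label = f"{female} x {male}"
    ci = float(ci_corr(np.array([f_obs]), np.array([f_c]), label)[0])
    md = float(md_corr(np.array([md_obs]), np.array([md_c]), label)[0])
    fm = float(
        fm_corr(np.array([fm_obs]), np.array([fm_c]), np.array([md]), label)[0]
    )
    return ci, md, fm


def _paired_cross_types(posterior: Posterior) -> list[tuple[str, str]]:
    obs = posterior.observations
    pairs = []
    for (f, m), grp in obs.groupby(["fgeno", "mgeno"], sort=True):
        if grp["inf"].nunique() == 2:
            pairs.append((f, m))
    return pairs


def posterior_indexes(
    post_f: Posterior,
    post_md: Posterior,
    post_fm: Posterior,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> list[CIIndexDraws]:
    """Corrected-index draws per genotype pair from the three fitted models.

    The pairing of each incompatible cross with its own compatible control
    is constructed here from the genotype pair, so a mismatch is impossible.
    The three posteriors must hold the same number of draws; draws are
    coupled positionally (FM_corr consumes the MD_corr draws).
    """
    sizes = {post_f.flat.shape[0], post_md.flat.shape[0], post_fm.flat.shape[0]}
    if len(sizes) != 1:
        raise ValueError(f"posteriors hold different draw counts: {sizes}")
    if pairs is None:
        pairs = _paired_cross_types(post_f)
    out = []
    for female, male in pairs:
        inc = CrossType(Genotype(female), Genotype(male), male_infected=True)
        comp = CrossType(Genotype(female), Genotype(male), male_infected=False)
        label = f"{female} x {male}"
        ci = ci_corr(
            predict_proportion(post_f, inc), predict_proportion(post_f, comp), label
        )
        md = md_corr(
            predict_proportion(post_md, inc), predict_proportion(post_md, comp), label
        )
        fm = fm_corr(
            predict_proportion(post_fm, inc), predict_proportion(post_fm, comp),
            md, label,
        )
        out.append(CIIndexDraws(female=female, male=male, ci=ci, md=md, fm=fm))
    return out


def summarize_indexes(index_draws: Sequence[CIIndexDraws]) -> pd.DataFrame:
    """One row per genotype pair x index with mean and percentiles."""
    rows = [row for d in index_draws for row in d.summary()]
    return pd.DataFrame(rows)


def diallel_index_analysis(
    records: Sequence[BroodRecord],
    settings: McmcSettings | None = None,
    fixed_terms: str = "inf*mgeno*fgeno",
    day_intercepts: bool = True,
) -> tuple[list[CIIndexDraws], dict[str, Posterior]]:
    """Fit the F, MD and FM models and compute all corrected indexes."""
    posteriors = {}
    for response in ("F", "MD", "FM"):
        spec = ModelSpec(response=response, fixed_terms=fixed_terms,
                         day_intercepts=day_intercepts)
        posteriors[response] = fit_model(records, spec, settings)
    draws = posterior_indexes(posteriors["F"], posteriors["MD"], posteriors["FM"])
    return draws, posteriors
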
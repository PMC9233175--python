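"""Generative simulators of haplodiploid CI brood counts with known truth.

The generative chain for one brood mirrors haplodiploid biology.  Each egg
is fertilized with probability ``fert``; unfertilized (haploid) eggs are
candidate males.  In an incompatible cross a fertilized egg is CI-affected
with probability ``theta`` (the CI penetrance); an affected egg loses the
paternal genome and develops as a haploid candidate male with probability
``phi`` (the male-development fraction) and dies otherwise.  Unaffected
fertilized eggs are candidate females.  Every candidate adult survives with
probability ``1 - base_mort``.  Rescue crosses (infected females) behave as
compatible: CI is ablated.

In the zero-mortality limit the expected brood proportions are

    F_obs  = f (1 - theta)                 F_c  = f
    MD_obs = (1 - f) + f theta phi         MD_c = 1 - f
    FM_obs = theta (1 - phi) / (1 - theta phi)   FM_c = 0

and substituting these into the corrected indexes makes the fertilization
rate f cancel, leaving

    CI_corr = theta,  MD_corr = theta phi,  FM_corr = theta (1 - phi),

the closed form exposed by :func:`closed_form_indexes` and used as the
ground-truth oracle throughout the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, logit

from .core_data import BroodRecord, CrossClass, CrossType, Genotype, enumerate_diallel

__all__ = [
    "DiallelSimParams",
    "InheritanceSimParams",
    "simulate_diallel",
    "simulate_inheritance",
    "closed_form_indexes",
    "DEFAULT_PANEL",
]

#: The five near-isogenic nuclear backgrounds of the default panel.
DEFAULT_PANEL = tuple(Genotype(g) for g in ("Beis", "LonX", "Scp", "Stt", "Temp"))

PairMap = Mapping[tuple[str, str], float]


def _check_prob(name: str, value: float, lo: float = 0.0, hi: float = 1.0,
                lo_open: bool = False, hi_open: bool = False) -> None:
    ok = (value > lo if lo_open else value >= lo) and (
        value < hi if hi_open else value <= hi
    )
    if not ok:
        lo_b = "(" if lo_open else "["
        hi_b = ")" if hi_open else "]"
        raise ValueError(f"{name}={value} outside {lo_b}{lo}, {hi}{hi_b}")


def _per_pair(value: float | PairMap, genotypes: Sequence[Genotype],
              name: str, **bounds) -> dict[tuple[str, str], float]:
    """Expand a scalar or (male, female)-keyed mapping to the full pair grid."""
    labels = [g.label for g in genotypes]
    if isinstance(value, Mapping):
        table = dict(value)
        missing = [(m, f) for m in labels for f in labels if (m, f) not in table]
        if missing:
            raise ValueError(f"{name} missing entries for pairs {missing[:5]}")
    else:
        table = {(m, f): float(value) for m in labels for f in labels}
    for pair, v in table.items():
        _check_prob(f"{name}[{pair}]", v, **bounds)
    return table


@dataclass
class DiallelSimParams:
    """Parameters of the diallel brood-count simulator.

    theta and phi may be scalars or mappings keyed by
    (male_genotype, female_genotype) label pairs, so CI penetrance and the
    MD fraction can vary with either parent and their interaction.
    """

    genotypes: Sequence[Genotype] = DEFAULT_PANEL
    theta: float | PairMap = 0.7
    phi: float | PairMap = 0.1
    fert: float | PairMap = 0.9
    base_mort: float = 0.05
    day_sd: float = 0.3
    n_days: int = 5
    replicates_per_cross: int | tuple[int, int] = (8, 11)
    eggs_mean: float = 80.0
    eggs_dispersion: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.genotypes:
            raise ValueError("need at least one genotype")
        self.theta = _per_pair(self.theta, self.genotypes, "theta")
        self.phi = _per_pair(self.phi, self.genotypes, "phi")
        self.fert = _per_pair(self.fert, self.genotypes, "fert", lo_open=True)
        _check_prob("base_mort", self.base_mort, hi_open=True)
        if self.day_sd < 0:
            raise ValueError("day_sd must be >= 0")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.eggs_mean <= 0 or self.eggs_dispersion <= 0:
            raise ValueError("eggs_mean and eggs_dispersion must be > 0")
        if isinstance(self.replicates_per_cross, int):
            self.replicates_per_cross = (
                self.replicates_per_cross,
                self.replicates_per_cross,
            )
        lo, hi = self.replicates_per_cross
        if lo < 1 or hi < lo:
            raise ValueError("replicates_per_cross must be a positive count or range")


def _draw_eggs(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    # negative binomial with mean `mean` and shape `dispersion`
    # (variance = mean + mean^2 / dispersion)
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _shifted(p: float, shift: float) -> float:
    """Shift probability p by `shift` on the logit scale; 0 and 1 are fixed points."""
    if p <= 0.0 or p >= 1.0:
        return p
    return float(expit(logit(p) + shift))


def _simulate_brood(
    rng: np.random.Generator,
    eggs: int,
    fert_p: float,
    theta: float,
    phi: float,
    survival: float,
) -> tuple[int, int]:
    """Run the generative chain for one brood; returns (females, males)."""
    fertilized = rng.binomial(eggs, fert_p)
    unfertilized = eggs - fertilized
    affected = rng.binomial(fertilized, theta) if theta > 0 else 0
    md_males = rng.binomial(affected, phi) if affected else 0
    cand_females = fertilized - affected
    cand_males = unfertilized + md_males
    females = rng.binomial(cand_females, survival)
    males = rng.binomial(cand_males, survival)
    return int(females), int(males)


def simulate_diallel(
    params: DiallelSimParams,
    cross_types: Sequence[CrossType] | None = None,
) -> list[BroodRecord]:
    """Simulate brood counts for a full diallel (or any given cross types).

    Day cohorts share a logit-scale random effect that perturbs both the
    fertilization rate and candidate survival, creating recoverable
    temporal structure.  Rescue and rescue-control crosses behave as
    compatible (CI ablated).  Fully reproducible from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    if cross_types is None:
        cross_types = enumerate_diallel(list(params.genotypes))
    day_effects = rng.normal(0.0, params.day_sd, size=params.n_days)
    lo, hi = params.replicates_per_cross
    records = []
    for ct in cross_types:
        pair = (ct.male_genotype.label, ct.female_genotype.label)
        theta = params.theta[pair] if ct.cross_class == CrossClass.INCOMPATIBLE else 0.0
        phi = params.phi[pair]
        n_rep = int(rng.integers(lo, hi + 1))
        for rep in range(n_rep):
            day = int(rng.integers(params.n_days))
            shift = day_effects[day]
            fert_p = _shifted(params.fert[pair], shift)
            survival = _shifted(1.0 - params.base_mort, shift)
            eggs = _draw_eggs(rng, params.eggs_mean, params.eggs_dispersion)
            females, males = _simulate_brood(rng, eggs, fert_p, theta, phi, survival)
            records.append(
                BroodRecord(
                    cross_type=ct,
                    day=f"d{day + 1}",
                    replicate=f"r{rep + 1}",
                    eggs=eggs,
                    adult_females=females,
                    adult_males=males,
                )
            )
    return records


def closed_form_indexes(theta: float, phi: float) -> tuple[float, float, float]:
    """Corrected indexes implied by the generative model at zero mortality.

    Substituting the generative expectations into the corrected-index
    formulas (see module docstring) cancels the fertilization rate and
    yields (theta, theta*phi, theta*(1-phi)); note the additivity
    CI_corr = MD_corr + FM_corr.
    """
    _check_prob("theta", theta)
    _check_prob("phi", phi)
    return theta, theta * phi, theta * (1.0 - phi)


@dataclass
class InheritanceSimParams:
    """Parameters of the F1/F2 maternal-modifier inheritance simulator.

    A maternal modifier of the CI phenotype is carried by ``modifier_line``
    (recessive, ``k_loci`` unlinked loci all required homozygous).  Females
    homozygous at every locus express the high MD fraction ``phi_high``;
    all other females express ``phi_low``.  F1 females are heterozygous;
    each F2 backcross female (F1 female x modifier-line male) is homozygous
    at each locus independently with probability 1/2, so the expected
    fraction of high-MD F2 females is ``0.5 ** k_loci``.
    """

    k_loci: int = 1
    phi_high: float = 0.7
    phi_low: float = 0.05
    theta: float = 0.7
    fert: float = 0.9
    base_mort: float = 0.05
    eggs_mean: float = 40.0
    eggs_dispersion: float = 20.0
    n_parental: int = 8
    n_f1: int = 8
    n_f2: int = 30
    n_f2_control: int = 10
    modifier_line: str = "LonX"
    other_line: str = "Scp"
    male_line: str = "Scp"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_loci < 1:
            raise ValueError("k_loci must be >= 1")
        _check_prob("phi_high", self.phi_high)
        _check_prob("phi_low", self.phi_low)
        if not self.phi_low < self.phi_high:
            raise ValueError("need phi_low < phi_high")
        _check_prob("theta", self.theta)
        _check_prob("fert", self.fert, lo_open=True)
        _check_prob("base_mort", self.base_mort, hi_open=True)
        if self.eggs_mean <= 0 or self.eggs_dispersion <= 0:
            raise ValueError("eggs_mean and eggs_dispersion must be > 0")
        for name in ("n_parental", "n_f1", "n_f2", "n_f2_control"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def simulate_inheritance(params: InheritanceSimParams) -> list[BroodRecord]:
    """Simulate the parental, F1 and F2-backcross inheritance experiment.

    Emits single-female broods annotated with ``generation``,
    ``maternal_origin`` and ``modifier_genotype`` extras; incompatible
    broods express CI with penetrance theta, compatible broods none.  Day
    effects are absent by design (the real experiment could not estimate
    them).
    """
    rng = np.random.default_rng(params.seed)
    survival = 1.0 - params.base_mort
    records = []

    def brood(female_label, generation, origin, modifier, compatible, rep):
        theta = 0.0 if compatible else params.theta
        phi = params.phi_high if modifier == "homozygous" else params.phi_low
        eggs = _draw_eggs(rng, params.eggs_mean, params.eggs_dispersion)
        females, males = _simulate_brood(
            rng, eggs, params.fert, theta, phi, survival
        )
        ct = CrossType(
            female_genotype=Genotype(female_label),
            male_genotype=Genotype(params.male_line),
            male_infected=not compatible,
        )
        return BroodRecord(
            cross_type=ct,
            day="d1",
            replicate=f"{generation}-{origin}-{'c' if compatible else 'i'}-{rep}",
            eggs=eggs,
            adult_females=females,
            adult_males=males,
            extra={
                "generation": generation,
                "maternal_origin": origin,
                "modifier_genotype": modifier,
            },
        )

    # parental lines: modifier line is homozygous, the other line is not
    for line, modifier in (
        (params.modifier_line, "homozygous"),
        (params.other_line, "heterozygous"),
    ):
        for compatible in (False, True):
            for rep in range(params.n_parental):
                records.append(brood(line, "P", line, modifier, compatible, rep + 1))

    # F1 reciprocal heterozygotes: recessive modifier is masked
    for origin in (params.modifier_line, params.other_line):
        for compatible in (False, True):
            for rep in range(params.n_f1):
                records.append(
                    brood(f"F1({origin})", "F1", origin, "heterozygous",
                          compatible, rep + 1)
                )

    # F2 backcross females: homozygous at each locus independently w.p. 1/2
    for origin in (params.modifier_line, params.other_line):
        for compatible, n in ((False, params.n_f2), (True, params.n_f2_control)):
            for rep in range(n):
                hom = bool(np.all(rng.random(params.k_loci) < 0.5))
                records.append(
                    brood(
                        f"F2({origin})", "F2", origin,
                        "homozygous" if hom else "heterozygous",
                        compatible, rep + 1,
                    )
                )
    return records
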
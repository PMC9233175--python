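"""Ordered two-binomial mixture for F2 segregation of the MD phenotype.

In the backcross design each F2 female is homozygous for a recessive
maternal modifier at one locus with probability 1/2, so under a monogenic
recessive model half the F2 broods should express the extreme (high-MD)
phenotype; with k jointly required loci the expected fraction is 0.5^k.
The brood male counts are therefore modeled as a mixture of two binomials,

    md_num_i ~ w * Bin(md_den_i, p_hi) + (1 - w) * Bin(md_den_i, p_lo),

with the ordering p_lo < p_hi enforced by construction (the high component
is parameterized as the low one plus a positive logit-scale increment), so
the weight w always refers to the high-MD component and label switching is
impossible.  Priors: w ~ Uniform(0, 1); the base logit and the
log-increment are Normal(0, 1.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit, gammaln, log_expit, logit

import emcee

from .core_data import BroodRecord, derive_responses
from .inference import Diagnostics, McmcSettings, rhat_ess

__all__ = [
    "MixtureFit",
    "fit_binomial_mixture",
    "expected_extreme_fraction",
    "test_monogenic",
]

_PARAM_NAMES = ["w", "p_lo", "p_hi"]


@dataclass
class MixtureFit:
    """Posterior draws of the ordered two-binomial mixture."""

    w: np.ndarray
    p_lo: np.ndarray
    p_hi: np.ndarray
    pointwise_loglik: np.ndarray
    diagnostics: Diagnostics
    identifiable: bool
    n_broods: int

    def __post_init__(self) -> None:
        if np.any(self.p_lo >= self.p_hi):
            raise ValueError("ordering p_lo < p_hi violated")
        if np.any((self.w < 0) | (self.w > 1)):
            raise ValueError("w outside [0, 1]")

    def w_summary(self) -> dict[str, float]:
        q09, q50, q91 = np.quantile(self.w, (0.09, 0.5, 0.91))
        return {
            "mean": float(np.mean(self.w)),
            "q09": float(q09),
            "q50": float(q50),
            "q91": float(q91),
        }


class _MixtureLogPost:
    def __init__(self, num: np.ndarray, den: np.ndarray, prior_scale: float):
        self.num = num
        self.den = den
        self.prior_scale = prior_scale
        self.const = gammaln(den + 1) - gammaln(num + 1) - gammaln(den - num + 1)

    def _components(self, theta: np.ndarray):
        u, a, b = theta[:, 0], theta[:, 1], theta[:, 2]
        eta_lo = a
        eta_hi = a + np.exp(b)
        return u, a, b, eta_lo, eta_hi

    def pointwise(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        u, _, _, eta_lo, eta_hi = self._components(theta)

        def binom_ll(eta):
            e = eta[:, None]
            return self.const + self.num * log_expit(e) + (
                self.den - self.num
            ) * log_expit(-e)

        log_w = log_expit(u)[:, None]
        log_1mw = log_expit(-u)[:, None]
        return np.logaddexp(log_w + binom_ll(eta_hi), log_1mw + binom_ll(eta_lo))

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        u, a, b, _, _ = self._components(theta)
        # uniform prior on w via the logit transform Jacobian
        lp = log_expit(u) + log_expit(-u)
        lp = lp - 0.5 * (a / self.prior_scale) ** 2
        lp = lp - 0.5 * (b / self.prior_scale) ** 2
        return self.pointwise(theta).sum(axis=1) + lp


def fit_binomial_mixture(
    broods: Sequence[BroodRecord],
    prior_scale: float = 1.5,
    settings: McmcSettings | None = None,
    seed: int | None = None,
) -> MixtureFit:
    """Fit the ordered two-binomial mixture to per-brood male counts.

    Broods with zero MD denominator are dropped; at least five informative
    broods are required.  If every brood shows the identical male
    proportion the mixture weight is unconstrained and the fit is flagged
    non-identifiable (``identifiable=False``).
    """
    settings = settings or McmcSettings()
    if seed is not None:
        settings = McmcSettings(
            chains=settings.chains, iterations=settings.iterations,
            warmup=settings.warmup, walkers=settings.walkers,
            target_draws=settings.target_draws, seed=seed,
        )
    triples = [derive_responses(b) for b in broods]
    counts = [(t.md_num, t.md_den) for t in triples if t.md_den > 0]
    if len(counts) < 5:
        raise ValueError(f"need >= 5 broods with eggs, got {len(counts)}")
    num = np.array([c[0] for c in counts], dtype=float)
    den = np.array([c[1] for c in counts], dtype=float)
    props = num / den
    identifiable = bool(np.ptp(props) > 0)

    logpost = _MixtureLogPost(num, den, prior_scale)
    rng = np.random.default_rng(settings.seed)
    n_walkers = settings.walkers or 16

    # data-informed starting point: split the proportions at their median
    lo0 = logit(np.clip(np.quantile(props, 0.25), 0.02, 0.98))
    hi0 = logit(np.clip(np.quantile(props, 0.75), 0.02, 0.98))
    b0 = np.log(max(hi0 - lo0, 0.3))
    center = np.array([0.0, lo0, b0])

    post_steps = settings.iterations - settings.warmup
    keep_steps = max(min(post_steps,
                         settings.target_draws // (settings.chains * n_walkers)), 1)
    thin = max(post_steps // keep_steps, 1)

    chains = []
    for _ in range(settings.chains):
        sampler = emcee.EnsembleSampler(n_walkers, 3, logpost, vectorize=True)
        p0 = center + 0.5 * rng.standard_normal((n_walkers, 3))
        state = sampler.run_mcmc(p0, settings.warmup, skip_initial_state_check=True)
        sampler.reset()
        sampler.run_mcmc(state, post_steps, skip_initial_state_check=True)
        chains.append(sampler.get_chain(thin=thin).transpose(1, 0, 2))
    raw = np.concatenate(chains, axis=0)  # (chains, steps, 3)

    # transform to the natural scale, preserving the chain structure
    w3 = expit(raw[:, :, 0])
    p_lo3 = expit(raw[:, :, 1])
    p_hi3 = expit(raw[:, :, 1] + np.exp(raw[:, :, 2]))
    rhats, esss = {}, {}
    for name, arr in zip(_PARAM_NAMES, (w3, p_lo3, p_hi3)):
        rhats[name], esss[name] = rhat_ess(arr)
    diagnostics = Diagnostics(rhats, esss)

    flat = raw.reshape(-1, 3)
    return MixtureFit(
        w=w3.reshape(-1),
        p_lo=p_lo3.reshape(-1),
        p_hi=p_hi3.reshape(-1),
        pointwise_loglik=logpost.pointwise(flat),
        diagnostics=diagnostics,
        identifiable=identifiable,
        n_broods=len(counts),
    )


def expected_extreme_fraction(k_loci: int) -> float:
    """Expected fraction of extreme-phenotype F2 backcross females.

    Each recessive locus is homozygous with probability 1/2 in the
    backcross, and all k loci are jointly required: 0.5 ** k.  k = 0 means
    no modifier locus, so every female is extreme.
    """
    if k_loci < 0:
        raise ValueError("k_loci must be >= 0")
    return 0.5**k_loci


def test_monogenic(
    fit: MixtureFit, k_max: int = 4, band: float = 0.05
) -> dict:
    """Rank Mendelian hypotheses for the high-MD mixture weight.

    Reports the posterior summary of w, whether the monogenic expectation
    0.5 lies inside the q09-q91 interval, the posterior mass within
    ``band`` of each candidate fraction 0.5^k, and the candidate closest to
    the posterior median.  A non-identifiable fit declines to rank.
    """
    summary = fit.w_summary()
    report: dict = {
        "identifiable": fit.identifiable,
        "w_mean": summary["mean"],
        "w_q09": summary["q09"],
        "w_median": summary["q50"],
        "w_q91": summary["q91"],
        "covers_monogenic": bool(summary["q09"] <= 0.5 <= summary["q91"]),
        "candidates": None,
        "closest_k": None,
    }
    if not fit.identifiable:
        return report
    candidates = {}
    for k in range(1, k_max + 1):
        target = expected_extreme_fraction(k)
        candidates[k] = {
            "expected_fraction": target,
            "posterior_mass_within_band": float(
                np.mean(np.abs(fit.w - target) <= band)
            ),
        }
    report["candidates"] = candidates
    report["closest_k"] = min(
        candidates,
        key=lambda k: abs(summary["q50"] - candidates[k]["expected_fraction"]),
    )
    return report
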
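"""Bayesian binomial regression with a logit link for brood proportions.

Each brood contributes a binomial observation: the response numerator out
of its denominator (F: adult females / eggs, MD: adult males / eggs,
FM: failed eggs / eggs that did not become adult males).  The linear
predictor combines treatment-coded fixed effects for the male infection
state (``inf``), male genotype (``mgeno``) and female genotype (``fgeno``)
with, optionally, zero-mean day-cohort random intercepts whose scale is
estimated (centered parameterization, half-normal hyperprior on the scale).

Sampling uses Hamiltonian Monte Carlo with analytic gradients: the chain
starts at the posterior mode (L-BFGS), uses the mode's Hessian as a
constant mass matrix, and adapts its step size by dual averaging during
warmup.  Independent chains feed the rank-normalized split R-hat and ESS
diagnostics (computed through arviz).

Priors default to weakly-regularizing normals on the logit scale:
coefficients ~ N(0, 1.5), intercept ~ N(0, 3), day-intercept scale ~
half-N(0, 1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln, log_expit

import arviz as az

from .core_data import BroodRecord, CrossType, derive_responses

__all__ = [
    "ModelSpec",
    "McmcSettings",
    "Posterior",
    "Diagnostics",
    "fit_model",
    "predict_proportion",
    "diagnose",
    "MODEL_VARIANTS",
]

_FACTOR_ORDER = ("inf", "mgeno", "fgeno")

#: The four fixed-effect structures compared in the diallel analysis; all
#: retain the male-infection effect.
MODEL_VARIANTS = ("inf", "inf*mgeno", "inf*fgeno", "inf*mgeno*fgeno")


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure and priors for one binomial response model.

    ``fixed_terms`` uses full-factorial star notation: ``"inf*mgeno"``
    expands to inf + mgeno + inf:mgeno.  The male-infection state is always
    included.
    """

    response: str
    fixed_terms: str = "inf*mgeno*fgeno"
    day_intercepts: bool = True
    coef_scale: float = 1.5
    intercept_scale: float = 3.0
    day_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.response not in ("F", "MD", "FM"):
            raise ValueError(f"unknown response {self.response!r}")
        factors = self.factors()
        if "inf" not in factors:
            raise ValueError("the male infection state 'inf' must be included")
        unknown = [f for f in factors if f not in _FACTOR_ORDER]
        if unknown:
            raise ValueError(f"unknown factors {unknown}")

    def factors(self) -> tuple[str, ...]:
        fs = tuple(f.strip() for f in self.fixed_terms.split("*") if f.strip())
        return tuple(f for f in _FACTOR_ORDER if f in fs)

    def terms(self) -> list[tuple[str, ...]]:
        """All non-empty factor subsets, main effects before interactions."""
        factors = self.factors()
        out: list[tuple[str, ...]] = []
        for order in range(1, len(factors) + 1):
            out.extend(itertools.combinations(factors, order))
        return out


@dataclass(frozen=True)
class McmcSettings:
    """Sampler settings; defaults are 2 chains x 5000 iterations with 1000
    warmup.  ``walkers`` only applies to ensemble-sampled models (the
    segregation mixture)."""

    chains: int = 2
    iterations: int = 5000
    warmup: int = 1000
    walkers: int | None = None
    target_draws: int = 4000  # retained draws across all chains (thinning)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ValueError("chains must be >= 1")
        if not 0 <= self.warmup < self.iterations:
            raise ValueError("need 0 <= warmup < iterations")


class Design:
    """Treatment-coded design matrix for the diallel fixed effects.

    The first (alphabetical) genotype is the reference level for mgeno and
    fgeno; uninfected is the reference for inf.  Column names follow the
    ``term[level]`` convention, e.g. ``inf:mgeno[LonX]``.
    """

    def __init__(self, spec: ModelSpec, mgeno_levels: Sequence[str],
                 fgeno_levels: Sequence[str]):
        self.spec = spec
        self.levels = {
            "inf": [False, True],
            "mgeno": sorted(mgeno_levels),
            "fgeno": sorted(fgeno_levels),
        }
        self.colnames: list[str] = ["Intercept"]
        self._cols: list[tuple[tuple[str, object], ...]] = [()]
        for term in spec.terms():
            # non-reference levels per factor: inf -> [True], genotypes -> [1:]
            per_factor = [
                [(f, lvl) for lvl in (self.levels[f][1:])] for f in term
            ]
            for combo in itertools.product(*per_factor):
                self._cols.append(combo)
                self.colnames.append(
                    ":".join(
                        f if f == "inf" else f"{f}[{lvl}]" for f, lvl in combo
                    )
                )

    @property
    def n_params(self) -> int:
        return len(self.colnames)

    def _indicators(self, ct: CrossType) -> dict[tuple[str, object], float]:
        vals: dict[tuple[str, object], float] = {("inf", True): float(ct.male_infected)}
        for f, label in (("mgeno", ct.male_genotype.label),
                         ("fgeno", ct.female_genotype.label)):
            if f in self.spec.factors() and label not in self.levels[f]:
                raise ValueError(f"unknown {f} level {label!r}")
            for lvl in self.levels[f][1:]:
                vals[(f, lvl)] = float(label == lvl)
        return vals

    def row(self, ct: CrossType) -> np.ndarray:
        ind = self._indicators(ct)
        return np.array(
            [np.prod([ind[key] for key in combo]) if combo else 1.0
             for combo in self._cols]
        )

    def matrix(self, cross_types: Sequence[CrossType]) -> np.ndarray:
        return np.vstack([self.row(ct) for ct in cross_types])

    def term_columns(self) -> dict[tuple[str, ...], list[int]]:
        """Map each fixed-effect term to the indexes of its columns."""
        out: dict[tuple[str, ...], list[int]] = {}
        for j, combo in enumerate(self._cols):
            if not combo:
                continue
            term = tuple(f for f, _ in combo)
            out.setdefault(term, []).append(j)
        return out


@dataclass
class Diagnostics:
    """Convergence summaries per sampled parameter."""

    rhat: dict[str, float]
    ess: dict[str, float]
    rhat_threshold: float = 1.01
    ess_threshold: float = 400.0

    @property
    def flagged(self) -> list[str]:
        bad = []
        for name in self.rhat:
            r, e = self.rhat[name], self.ess[name]
            if (np.isfinite(r) and r >= self.rhat_threshold) or e < self.ess_threshold:
                bad.append(name)
        return bad

    @property
    def ok(self) -> bool:
        return not self.flagged and all(np.isfinite(v) for v in self.rhat.values())


@dataclass
class Posterior:
    """Post-warmup draws of a fitted binomial model.

    ``draws`` has shape (chains, steps, params) where the chains are the
    ensemble walkers of all independent runs; ``flat`` is the chain-major
    flattening used for prediction and index computation, and
    ``pointwise_loglik`` (draws x observations) is aligned with it.
    """

    param_names: list[str]
    draws: np.ndarray
    pointwise_loglik: np.ndarray
    spec: ModelSpec
    design: Design
    day_levels: list[str]
    settings: McmcSettings
    seed: int
    observations: pd.DataFrame
    diagnostics: Diagnostics | None = None
    accept_rates: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.draws)):
            raise ValueError("non-finite posterior draws")

    @property
    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    @property
    def n_fixed(self) -> int:
        return self.design.n_params

    @property
    def converged(self) -> bool:
        return self.diagnostics is not None and self.diagnostics.ok

    def param(self, name: str) -> np.ndarray:
        return self.flat[:, self.param_names.index(name)]

    def day_sigma(self) -> np.ndarray:
        """Draws of the day-intercept scale (requires day intercepts)."""
        return np.exp(self.param("log_day_sigma"))

    def day_effects(self) -> np.ndarray:
        """Draws x days matrix of the day intercepts."""
        idx = [self.param_names.index(f"day[{d}]") for d in self.day_levels]
        return self.flat[:, idx]

    def to_tidy(self) -> pd.DataFrame:
        """Tidy (chain, sample, parameter, value) table of the draws."""
        n_chain, n_step, ndim = self.draws.shape
        chain = np.repeat(np.arange(n_chain), n_step * ndim)
        sample = np.tile(np.repeat(np.arange(n_step), ndim), n_chain)
        names = np.tile(np.array(self.param_names, dtype=object), n_chain * n_step)
        return pd.DataFrame(
            {"chain": chain, "sample": sample, "parameter": names,
             "value": self.draws.reshape(-1)}
        )


def _response_frame(records: Sequence[BroodRecord], response: str) -> pd.DataFrame:
    rows = []
    for r in records:
        t = derive_responses(r)
        num, den = {
            "F": (t.f_num, t.f_den),
            "MD": (t.md_num, t.md_den),
            "FM": (t.fm_num, t.fm_den),
        }[response]
        rows.append(
            {
                "num": num,
                "den": den,
                "day": r.day,
                "mgeno": r.cross_type.male_genotype.label,
                "fgeno": r.cross_type.female_genotype.label,
                "inf": r.cross_type.male_infected,
                "cross_type": r.cross_type,
            }
        )
    return pd.DataFrame(rows)


class _LogPosterior:
    """Vectorized log posterior (and gradient) of the binomial GLM."""

    def __init__(self, y, n, X, day_idx, n_days, spec: ModelSpec):
        self.y = y
        self.n = n
        self.X = X
        self.day_idx = day_idx
        self.n_days = n_days if day_idx is not None else 0
        self.p = X.shape[1]
        self.ndim = self.p + (self.n_days + 1 if day_idx is not None else 0)
        scales = np.full(self.p, spec.coef_scale)
        scales[0] = spec.intercept_scale
        self.prior_scale = scales
        self.day_scale = spec.day_scale
        self.binom_const = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)

    def _eta(self, theta: np.ndarray) -> np.ndarray:
        # theta: (draws, ndim); day intercepts are centered: eta += d[day]
        eta = theta[:, : self.p] @ self.X.T
        if self.day_idx is not None:
            d = theta[:, self.p : self.p + self.n_days]
            eta = eta + d[:, self.day_idx]
        return eta

    def pointwise(self, theta: np.ndarray) -> np.ndarray:
        """Per-draw, per-observation binomial log-likelihood."""
        eta = self._eta(np.atleast_2d(theta))
        return (
            self.binom_const
            + self.y * log_expit(eta)
            + (self.n - self.y) * log_expit(-eta)
        )

    def log_prior(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        beta = theta[:, : self.p]
        lp = -0.5 * np.sum((beta / self.prior_scale) ** 2, axis=1)
        if self.day_idx is not None:
            d = theta[:, self.p : self.p + self.n_days]
            t = theta[:, -1]
            sigma = np.exp(t)
            # d | sigma ~ N(0, sigma), including the sigma-dependent norm
            lp = lp - 0.5 * np.sum(d**2, axis=1) / sigma**2 - self.n_days * t
            # half-normal on sigma with the log-transform Jacobian
            lp = lp - 0.5 * (sigma / self.day_scale) ** 2 + t
        return lp

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        ll = self.pointwise(theta).sum(axis=1)
        return ll + self.log_prior(theta)

    def neg_with_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        theta2 = np.atleast_2d(theta)
        eta = self._eta(theta2)[0]
        p = expit(eta)
        resid = self.y - self.n * p
        grad = np.empty(self.ndim)
        grad[: self.p] = self.X.T @ resid - theta[: self.p] / self.prior_scale**2
        if self.day_idx is not None:
            d = theta[self.p : self.p + self.n_days]
            t = theta[-1]
            sigma = np.exp(t)
            rday = np.bincount(self.day_idx, weights=resid, minlength=self.n_days)
            grad[self.p : self.p + self.n_days] = rday - d / sigma**2
            grad[-1] = (
                float(d @ d) / sigma**2
                - self.n_days
                - (sigma / self.day_scale) ** 2
                + 1.0
            )
        val = float(self(theta)[0])
        return -val, -grad


def _cond_logf_t(logpost: _LogPosterior, d: np.ndarray):
    """Log conditional of t = log(day sigma) given the day intercepts.

    Collects every t-dependent term of the joint log posterior: the
    N(0, sigma) prior of the intercepts (with its normalizing constant),
    the half-normal prior on sigma and the log-transform Jacobian.
    """
    ssq = float(d @ d)
    n_days = logpost.n_days
    scale = logpost.day_scale

    def logf(t: float) -> float:
        s2 = np.exp(2.0 * t)
        return -0.5 * ssq / s2 - (n_days - 1) * t - 0.5 * s2 / scale**2

    return logf


def _map_estimate(logpost: _LogPosterior) -> np.ndarray:
    """Posterior mode of the fixed effects and day intercepts.

    With day intercepts the mode is profiled: (beta, d) are optimized at
    fixed t and t at fixed d, alternating (the joint density is unbounded
    as sigma -> 0, so a joint mode does not exist)."""
    if logpost.day_idx is None:
        res = minimize(logpost.neg_with_grad, np.zeros(logpost.ndim), jac=True,
                       method="L-BFGS-B", options={"maxiter": 1000})
        return res.x if np.all(np.isfinite(res.x)) else np.zeros(logpost.ndim)

    nb = logpost.ndim - 1
    xb = np.zeros(nb)
    t = np.log(0.3)
    for _ in range(4):
        def neg_cond(xb_):
            v, g = logpost.neg_with_grad(np.append(xb_, t))
            return v, g[:nb]

        res = minimize(neg_cond, xb, jac=True, method="L-BFGS-B",
                       options={"maxiter": 1000})
        if np.all(np.isfinite(res.x)):
            xb = res.x
        logf = _cond_logf_t(logpost, xb[logpost.p :])
        grid = np.linspace(-6.0, 2.0, 400)
        t = float(grid[np.argmax([logf(g) for g in grid])])
    return np.append(xb, t)


def _hessian(grad_fn, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Hessian by central differences of an analytic gradient function."""
    ndim = x.shape[0]
    H = np.empty((ndim, ndim))
    for j in range(ndim):
        step = np.zeros(ndim)
        step[j] = eps
        H[:, j] = (grad_fn(x + step) - grad_fn(x - step)) / (2 * eps)
    return 0.5 * (H + H.T)


def _slice_update(logf, x0: float, logf0: float, rng: np.random.Generator,
                  width: float = 1.0, max_steps: int = 50) -> tuple[float, float]:
    """One univariate slice-sampling update (stepping out + shrinkage)."""
    logy = logf0 + np.log(rng.random())
    lo = x0 - width * rng.random()
    hi = lo + width
    for _ in range(max_steps):
        if logf(lo) <= logy:
            break
        lo -= width
    for _ in range(max_steps):
        if logf(hi) <= logy:
            break
        hi += width
    for _ in range(100):
        x1 = lo + rng.random() * (hi - lo)
        f1 = logf(x1)
        if f1 > logy:
            return x1, f1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0, logf0


def _spd_factor(H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cholesky factor of H and of its inverse, regularizing to SPD."""
    ndim = H.shape[0]
    jitter = 1e-8 * max(1.0, float(np.trace(H)) / ndim)
    for _ in range(8):
        try:
            L = np.linalg.cholesky(H + jitter * np.eye(ndim))
            L_inv_cov = np.linalg.cholesky(np.linalg.inv(H + jitter * np.eye(ndim)))
            return L, L_inv_cov
        except np.linalg.LinAlgError:
            jitter *= 100
    return np.eye(ndim), np.eye(ndim)


def _hmc_chain(
    logpost: _LogPosterior,
    x0: np.ndarray,
    mass_chol: np.ndarray,
    mass_inv: np.ndarray,
    n_iter: int,
    warmup: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    leapfrog_range: tuple[int, int] = (8, 32),
) -> tuple[np.ndarray, float]:
    """One MCMC chain: HMC over (coefficients, day intercepts) with a slice
    update of the day-scale parameter between trajectories.

    The HMC block uses the conditional posterior-mode Hessian as a constant
    mass matrix (so the preconditioned target is nearly unit-Gaussian and
    short jittered trajectories suffice) and adapts its step size by dual
    averaging during warmup.  log(day sigma), whose joint density is
    unbounded as sigma -> 0, is instead updated by univariate slice
    sampling from its exact conditional given the intercepts.  Returns
    (post-warmup draws, mean HMC acceptance probability).
    """
    has_t = logpost.day_idx is not None
    ndim = logpost.ndim
    nb = ndim - 1 if has_t else ndim
    xb = x0[:nb].copy()
    t = float(x0[-1]) if has_t else 0.0

    def val_grad(xb_):
        full = np.append(xb_, t) if has_t else xb_
        v, g = logpost.neg_with_grad(full)
        return -v, -g[:nb]

    logp, grad = val_grad(xb)

    step = 0.5
    mu = np.log(10 * step)
    log_step_bar, h_bar = np.log(step), 0.0
    gamma, t0_da, kappa = 0.05, 10.0, 0.75

    draws = np.empty((n_iter - warmup, ndim))
    acc_sum, acc_n = 0.0, 0
    for i in range(n_iter):
        z = rng.standard_normal(nb)
        p = mass_chol @ z
        kin0 = 0.5 * float(z @ z)  # p^T M^-1 p with p = L z
        x_new, grad_new, logp_new = xb, grad, logp
        p_new = p
        n_leap = int(rng.integers(leapfrog_range[0], leapfrog_range[1] + 1))
        diverged = False
        for _ in range(n_leap):
            p_new = p_new + 0.5 * step * grad_new
            x_new = x_new + step * (mass_inv @ p_new)
            logp_new, grad_new = val_grad(x_new)
            if not np.all(np.isfinite(grad_new)) or not np.isfinite(logp_new):
                diverged = True
                break
            p_new = p_new + 0.5 * step * grad_new
        if diverged:
            alpha = 0.0
        else:
            kin1 = 0.5 * float(p_new @ (mass_inv @ p_new))
            log_alpha = (logp_new - kin1) - (logp - kin0)
            alpha = min(1.0, float(np.exp(min(log_alpha, 0.0))))
        if rng.random() < alpha:
            xb, logp, grad = x_new, logp_new, grad_new

        if has_t:
            logf = _cond_logf_t(logpost, xb[logpost.p :])
            t, _ = _slice_update(logf, t, logf(t), rng)
            logp, grad = val_grad(xb)

        if i < warmup:
            m = i + 1
            h_bar = (1 - 1 / (m + t0_da)) * h_bar + (target_accept - alpha) / (m + t0_da)
            log_step = mu - np.sqrt(m) / gamma * h_bar
            eta = m**-kappa
            log_step_bar = eta * log_step + (1 - eta) * log_step_bar
            step = float(np.exp(log_step))
            if i == warmup - 1:
                step = float(np.exp(log_step_bar))
        else:
            draws[i - warmup] = np.append(xb, t) if has_t else xb
            acc_sum += alpha
            acc_n += 1
    return draws, acc_sum / max(acc_n, 1)


def fit_model(
    records: Sequence[BroodRecord],
    spec: ModelSpec,
    settings: McmcSettings | None = None,
    seed: int | None = None,
) -> Posterior:
    """Fit a binomial logit model by ensemble MCMC and return its posterior.

    Rows whose denominator for the chosen response is zero carry no
    likelihood information and are dropped for this fit only.  The returned
    posterior holds post-warmup draws, the pointwise log-likelihood matrix
    (for WAIC) and convergence diagnostics.
    """
    settings = settings or McmcSettings()
    if seed is not None:
        settings = replace(settings, seed=seed)
    frame = _response_frame(records, spec.response)
    frame = frame[frame["den"] > 0].reset_index(drop=True)
    if frame.empty:
        raise ValueError(
            f"no records with positive {spec.response} denominator to fit"
        )
    design = Design(spec, frame["mgeno"].unique(), frame["fgeno"].unique())
    X = design.matrix(list(frame["cross_type"]))
    y = frame["num"].to_numpy(float)
    n = frame["den"].to_numpy(float)
    if spec.day_intercepts:
        day_levels = sorted(frame["day"].unique())
        day_idx = frame["day"].map({d: i for i, d in enumerate(day_levels)}).to_numpy()
    else:
        day_levels, day_idx = [], None
    logpost = _LogPosterior(y, n, X, day_idx, len(day_levels), spec)

    ndim = logpost.ndim
    has_t = spec.day_intercepts
    nb = ndim - 1 if has_t else ndim
    x_map = _map_estimate(logpost)
    t_map = float(x_map[-1]) if has_t else 0.0

    def block_grad(xb):
        full = np.append(xb, t_map) if has_t else xb
        return logpost.neg_with_grad(full)[1][:nb]

    mass = _hessian(block_grad, x_map[:nb])
    mass_chol, cov_chol = _spd_factor(mass)
    mass_inv = np.linalg.inv(mass + 1e-8 * np.eye(nb))

    post_steps = settings.iterations - settings.warmup
    keep = max(settings.target_draws // settings.chains, 1)
    thin = max(post_steps // keep, 1)

    chains, accept_rates = [], []
    for c in range(settings.chains):
        rng = np.random.default_rng([settings.seed, c])
        # overdispersed start: a draw from the Laplace approximation
        x0 = x_map.copy()
        x0[:nb] = x0[:nb] + cov_chol @ rng.standard_normal(nb)
        samples, acc = _hmc_chain(
            logpost, x0, mass_chol, mass_inv,
            settings.iterations, settings.warmup, rng,
        )
        chains.append(samples[::thin])
        accept_rates.append(acc)
    draws = np.stack(chains, axis=0)

    param_names = list(design.colnames)
    if spec.day_intercepts:
        param_names += [f"day[{d}]" for d in day_levels] + ["log_day_sigma"]

    flat = draws.reshape(-1, ndim)
    pointwise = logpost.pointwise(flat)

    posterior = Posterior(
        param_names=param_names,
        draws=draws,
        pointwise_loglik=pointwise,
        spec=spec,
        design=design,
        day_levels=day_levels,
        settings=settings,
        seed=settings.seed,
        observations=frame.drop(columns="cross_type"),
        accept_rates=accept_rates,
    )
    posterior.diagnostics = diagnose(posterior)
    return posterior


def predict_proportion(
    posterior: Posterior,
    cross_type: CrossType,
    response: str | None = None,
) -> np.ndarray:
    """Population-level posterior draws of the response proportion at a cross.

    Day intercepts are excluded (prediction for an average day); draws are
    aligned by sample index across cross types so index ratios can be taken
    within draws.
    """
    if response is not None and response != posterior.spec.response:
        raise ValueError(
            f"posterior models {posterior.spec.response}, not {response}"
        )
    x = posterior.design.row(cross_type)
    return expit(posterior.flat[:, : posterior.n_fixed] @ x)


def rhat_ess(draws: np.ndarray) -> tuple[float, float]:
    """Rank-normalized split R-hat and bulk ESS for one parameter.

    ``draws`` has shape (chains, steps).  With a single chain R-hat is
    undefined and returned as NaN.
    """
    data = az.convert_to_dataset(np.asarray(draws))
    ess = float(np.asarray(az.ess(data)["x"]).item())
    if draws.shape[0] < 2:
        return float("nan"), ess
    rhat = float(np.asarray(az.rhat(data)["x"]).item())
    return rhat, ess


def diagnose(posterior: Posterior, rhat_threshold: float = 1.01,
             ess_threshold: float = 400.0) -> Diagnostics:
    """Compute split-R-hat and ESS for every sampled parameter."""
    rhats, esss = {}, {}
    for j, name in enumerate(posterior.param_names):
        r, e = rhat_ess(posterior.draws[:, :, j])
        rhats[name], esss[name] = r, e
    return Diagnostics(rhats, esss, rhat_threshold, ess_threshold)
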
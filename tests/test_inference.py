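import numpy as np
import pytest
from scipy.special import expit, logit
from scipy.stats import binom

from haploci import (
    BroodRecord,
    CrossType,
    DiallelSimParams,
    Genotype,
    McmcSettings,
    ModelSpec,
    fit_model,
    predict_proportion,
    simulate_diallel,
)
from haploci.inference import Diagnostics, rhat_ess


def _cross(inf, female="A", male="A"):
    return CrossType(Genotype(female), Genotype(male), male_infected=inf)


def _brood(eggs, females, males, inf=False, day="d1", rep="r1", **kw):
    return BroodRecord(cross_type=_cross(inf, **kw), day=day, replicate=rep,
                       eggs=eggs, adult_females=females, adult_males=males)


class TestModelSpec:
    def test_star_notation_expands_to_all_subsets(self):
        spec = ModelSpec(response="F", fixed_terms="inf*mgeno*fgeno")
        assert spec.terms() == [
            ("inf",), ("mgeno",), ("fgeno",),
            ("inf", "mgeno"), ("inf", "fgeno"), ("mgeno", "fgeno"),
            ("inf", "mgeno", "fgeno"),
        ]

    def test_infection_state_is_mandatory(self):
        with pytest.raises(ValueError, match="inf"):
            ModelSpec(response="F", fixed_terms="mgeno")

    def test_unknown_response_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(response="G")


class TestFitModel:
    def test_posterior_matches_conjugate_beta_binomial(self, fast_settings):
        """With flat-ish priors and pooled counts, the posterior proportion
        must agree with the conjugate Beta-Binomial oracle."""
        params = DiallelSimParams(
            genotypes=[Genotype("A")], theta=0.0, phi=0.1, fert=0.7,
            base_mort=0.0, day_sd=0.0, replicates_per_cross=30,
            eggs_mean=100.0, seed=21,
        )
        records = simulate_diallel(params)
        spec = ModelSpec(response="F", fixed_terms="inf", day_intercepts=False)
        post = fit_model(records, spec, fast_settings)
        comp = [r for r in records if not r.cross_type.male_infected]
        successes = sum(r.adult_females for r in comp)
        trials = sum(r.eggs for r in comp)
        oracle = (successes + 1) / (trials + 2)  # Beta(1,1) posterior mean
        p = predict_proportion(post, _cross(False))
        assert p.mean() == pytest.approx(oracle, abs=0.01)

    def test_single_observation_posterior_is_symmetric_around_half(
        self, fast_settings
    ):
        records = [_brood(10, 5, 0)]
        spec = ModelSpec(response="F", fixed_terms="inf", day_intercepts=False)
        post = fit_model(records, spec, fast_settings)
        p = predict_proportion(post, _cross(False))
        assert p.mean() == pytest.approx(0.5, abs=0.05)
        assert np.median(p) == pytest.approx(0.5, abs=0.05)

    def test_pointwise_loglik_equals_direct_binomial_logpmf(self, fast_settings):
        records = [_brood(20, 8, 6), _brood(30, 10, 5, inf=True, rep="r2")]
        spec = ModelSpec(response="F", fixed_terms="inf", day_intercepts=False)
        post = fit_model(records, spec, fast_settings)
        X = post.design.matrix(
            [_cross(False), _cross(True)]
        )
        p = expit(post.flat @ X.T)  # (draws, obs)
        direct = binom.logpmf([8, 10], [20, 30], p)
        assert np.allclose(post.pointwise_loglik, direct, atol=1e-10)

    def test_ground_truth_theta_ordering_is_recovered(self, fast_settings):
        """Males with stronger CI penetrance must be predicted to sire fewer
        females in incompatible crosses."""
        gs = [Genotype(g) for g in ("A", "B", "C")]
        theta = {(m, f): t for m, t in (("A", 0.9), ("B", 0.5), ("C", 0.1))
                 for f in "ABC"}
        params = DiallelSimParams(
            genotypes=gs, theta=theta, phi=0.1, fert=0.9, base_mort=0.05,
            day_sd=0.2, replicates_per_cross=10, eggs_mean=80.0, seed=17,
        )
        records = simulate_diallel(params)
        spec = ModelSpec(response="F", fixed_terms="inf*mgeno*fgeno")
        post = fit_model(records, spec, fast_settings)
        means = [
            predict_proportion(post, _cross(True, female="A", male=m)).mean()
            for m in ("A", "B", "C")
        ]
        assert means[0] < means[1] < means[2]

    def test_zero_denominator_rows_dropped_per_response(self, fast_settings):
        records = [
            _brood(20, 8, 6),
            _brood(10, 0, 10, rep="r2"),  # FM denominator is zero here
            _brood(25, 9, 7, inf=True, rep="r3"),
        ]
        spec = ModelSpec(response="FM", fixed_terms="inf", day_intercepts=False)
        post = fit_model(records, spec, fast_settings)
        assert post.pointwise_loglik.shape[1] == 2
        spec_f = ModelSpec(response="F", fixed_terms="inf", day_intercepts=False)
        assert fit_model(records, spec_f, fast_settings).pointwise_loglik.shape[1] == 3

    def test_empty_data_after_filtering_is_an_error(self, fast_settings):
        records = [_brood(0, 0, 0)]
        spec = ModelSpec(response="F", fixed_terms="inf", day_intercepts=False)
        with pytest.raises(ValueError, match="denominator"):
            fit_model(records, spec, fast_settings)


@pytest.fixture(scope="module")
def posterior(fast_settings):
    params = DiallelSimParams(
        genotypes=[Genotype("A"), Genotype("B")], theta=0.5, phi=0.2,
        fert=0.9, base_mort=0.05, day_sd=0.2, replicates_per_cross=6,
        eggs_mean=60.0, seed=23,
    )
    spec = ModelSpec(response="F", fixed_terms="inf*mgeno*fgeno")
    return fit_model(simulate_diallel(params), spec, fast_settings)


class TestPredictProportion:
    def test_reference_cross_equals_inverse_logit_of_intercept(self, posterior):
        p = predict_proportion(posterior, _cross(False, "A", "A"))
        assert np.allclose(p, expit(posterior.param("Intercept")))

    def test_inf_contrast_equals_coefficient_on_logit_scale(self, posterior):
        p0 = predict_proportion(posterior, _cross(False, "A", "A"))
        p1 = predict_proportion(posterior, _cross(True, "A", "A"))
        assert np.allclose(logit(p1) - logit(p0), posterior.param("inf"))

    def test_day_intercepts_are_excluded_from_prediction(self, posterior):
        # population-level: the same cross type always predicts identically
        a = predict_proportion(posterior, _cross(True, "B", "A"))
        b = predict_proportion(posterior, _cross(True, "B", "A"))
        assert np.array_equal(a, b)
        assert "log_day_sigma" in posterior.param_names  # day block was sampled

    def test_unknown_genotype_level_is_an_error(self, posterior):
        with pytest.raises(ValueError, match="unknown"):
            predict_proportion(posterior, _cross(True, "Z", "A"))

    def test_response_mismatch_is_an_error(self, posterior):
        with pytest.raises(ValueError, match="models F"):
            predict_proportion(posterior, _cross(True, "A", "A"), response="MD")


class TestDiagnostics:
    def test_iid_chains_pass(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal((2, 1000))
        rhat, ess = rhat_ess(draws)
        assert rhat == pytest.approx(1.0, abs=0.01)
        assert ess > 400

    def test_separated_chains_are_flagged(self):
        rng = np.random.default_rng(1)
        draws = np.stack([rng.normal(-5, 1, 800), rng.normal(5, 1, 800)])
        rhat, _ = rhat_ess(draws)
        assert rhat > 1.1

    def test_constant_chain_has_minimal_ess(self):
        draws = np.vstack([np.linspace(0, 1e-8, 500)] * 2)
        _, ess = rhat_ess(draws)
        assert ess < 400

    def test_single_chain_rhat_undefined(self):
        draws = np.random.default_rng(2).standard_normal((1, 500))
        rhat, ess = rhat_ess(draws)
        assert np.isnan(rhat) and ess > 0

    def test_flagging_logic(self):
        good = Diagnostics(rhat={"a": 1.001}, ess={"a": 1200.0})
        assert good.ok and good.flagged == []
        bad = Diagnostics(rhat={"a": 1.05, "b": 1.0}, ess={"a": 900.0, "b": 100.0})
        assert set(bad.flagged) == {"a", "b"} and not bad.ok


class TestCalibration:
    def test_posterior_intervals_cover_generating_proportion(self):
        """Scaled-down recovery check: over 20 seeded simulations the 95%
        posterior interval of the incompatible-cross F proportion covers
        the generative truth in at least 90% of runs."""
        theta, fert = 0.6, 0.9
        truth = fert * (1 - theta)
        settings = lambda s: McmcSettings(chains=2, iterations=1200,
                                          warmup=400, seed=s)
        spec = ModelSpec(response="F", fixed_terms="inf", day_intercepts=False)
        covered = 0
        for rep in range(20):
            params = DiallelSimParams(
                genotypes=[Genotype("A")], theta=theta, phi=0.0, fert=fert,
                base_mort=0.0, day_sd=0.0, replicates_per_cross=10,
                eggs_mean=80.0, seed=1000 + rep,
            )
            post = fit_model(simulate_diallel(params), spec, settings(rep))
            lo, hi = np.quantile(predict_proportion(post, _cross(True)),
                                 (0.025, 0.975))
            covered += lo <= truth <= hi
        assert covered >= 18
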
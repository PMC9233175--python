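import math

import numpy as np
import pandas as pd
import pytest

from haploci import (
    DiallelSimParams,
    Genotype,
    McmcSettings,
    ModelSpec,
    compare_models,
    finite_population_sd,
    fit_model,
    group_sd,
    simulate_diallel,
    waic,
)


class TestWaic:
    def test_hand_computed_two_by_two_matrix(self):
        """WAIC on a 2-draw x 2-observation log-likelihood matrix must equal
        the formulas evaluated by hand."""
        ll = np.log(np.array([[0.5, 0.25], [0.5, 0.5]]))
        res = waic(ll)
        lppd = math.log(0.5) + math.log((0.25 + 0.5) / 2)
        # draw-variances: first column constant, second has ddof-1 variance
        p2 = (
            (math.log(0.25) - (math.log(0.25) + math.log(0.5)) / 2) ** 2
            + (math.log(0.5) - (math.log(0.25) + math.log(0.5)) / 2) ** 2
        )
        assert res.lppd == pytest.approx(lppd, abs=1e-12)
        assert res.p_waic == pytest.approx(p2, abs=1e-12)
        assert res.waic == pytest.approx(-2 * (lppd - p2), abs=1e-12)

    def test_constant_draws_give_zero_effective_parameters(self):
        ll = np.tile(np.log([0.3, 0.6, 0.9]), (5, 1))
        res = waic(ll)
        assert res.p_waic == pytest.approx(0.0, abs=1e-14)
        assert res.waic == pytest.approx(-2 * ll[0].sum(), abs=1e-12)

    def test_invariant_to_draw_permutation(self):
        rng = np.random.default_rng(4)
        ll = rng.normal(-2, 0.5, size=(200, 30))
        shuffled = ll[rng.permutation(200)]
        assert waic(shuffled).waic == pytest.approx(waic(ll).waic, abs=1e-10)

    def test_needs_two_draws(self):
        with pytest.raises(ValueError, match="2 posterior draws"):
            waic(np.array([[-1.0, -2.0]]))

    def test_agrees_with_arviz_reference_implementation(self):
        """Independent cross-check of the WAIC formulas against arviz."""
        import arviz as az
        import xarray as xr

        rng = np.random.default_rng(8)
        ll = rng.normal(-3, 0.4, size=(400, 25))
        idata = az.from_dict(
            log_likelihood={"y": ll[None, :, :]}  # (chain, draw, obs)
        )
        ref = az.waic(idata, scale="deviance")
        res = waic(ll)
        # arviz takes the draw variance with ddof=0; this package uses the
        # ddof=1 sample variance, an O(1/S) difference
        s = ll.shape[0]
        p_ref = float(ref.p_waic) * s / (s - 1)
        assert res.p_waic == pytest.approx(p_ref, rel=1e-10)
        assert res.waic == pytest.approx(
            float(ref.elpd_waic) + 2 * (p_ref - float(ref.p_waic)), rel=1e-10
        )


class TestGroupSd:
    def test_two_level_group_hand_value(self):
        """Effects {0, c}: centered to {-c/2, c/2}, ddof-1 SD = |c|/sqrt(2)."""
        for c in (1.0, -3.0, 0.25):
            sd = group_sd(np.array([[0.0, c]]))
            assert sd[0] == pytest.approx(abs(c) / math.sqrt(2), abs=1e-14)

    def test_constant_group_has_zero_sd(self):
        assert group_sd(np.array([[2.0, 2.0, 2.0]]))[0] == pytest.approx(0.0)

    def test_matches_numpy_std_with_ddof(self):
        rng = np.random.default_rng(1)
        effects = rng.normal(size=(50, 6))
        assert np.allclose(group_sd(effects), effects.std(axis=1, ddof=1))


@pytest.fixture(scope="module")
def male_driven_posterior():
    gs = [Genotype(g) for g in ("A", "B", "C")]
    theta = {(m, f): t for m, t in (("A", 0.9), ("B", 0.45), ("C", 0.1))
             for f in "ABC"}
    params = DiallelSimParams(
        genotypes=gs, theta=theta, phi=0.1, fert=0.9, base_mort=0.05,
        day_sd=0.2, replicates_per_cross=8, eggs_mean=80.0, seed=19,
    )
    spec = ModelSpec(response="F")
    settings = McmcSettings(chains=2, iterations=2500, warmup=800, seed=3)
    return fit_model(simulate_diallel(params), spec, settings)


class TestFinitePopulationSd:
    def test_groups_cover_all_terms_plus_day(self, male_driven_posterior):
        sds = finite_population_sd(male_driven_posterior)
        assert set(sds) == {
            "inf", "mgeno", "fgeno", "inf:mgeno", "inf:fgeno",
            "mgeno:fgeno", "inf:mgeno:fgeno", "day",
        }
        for draws in sds.values():
            assert np.all(draws >= 0)

    def test_male_genotype_interaction_dominates_female(
        self, male_driven_posterior
    ):
        """CI penetrance varies only with the male genotype, so the
        inf:mgeno group must carry far more variation than inf:fgeno."""
        sds = finite_population_sd(male_driven_posterior)
        assert np.median(sds["inf:mgeno"]) > 2 * np.median(sds["inf:fgeno"])

    def test_unmapped_parameter_is_an_error(self, male_driven_posterior):
        with pytest.raises(ValueError, match="not mapped"):
            finite_population_sd(male_driven_posterior, {"inf": ["inf"]})

    def test_doubly_mapped_parameter_is_an_error(self, male_driven_posterior):
        grouping = {
            ":".join(t): [male_driven_posterior.design.colnames[j] for j in cols]
            for t, cols in male_driven_posterior.design.term_columns().items()
        }
        grouping["dup"] = ["inf"]
        with pytest.raises(ValueError, match="more than one group"):
            finite_population_sd(male_driven_posterior, grouping)


class TestCompareModels:
    def test_specs_must_share_the_response(self, fast_settings):
        records = simulate_diallel(DiallelSimParams(
            genotypes=[Genotype("A")], replicates_per_cross=4, seed=1))
        specs = [ModelSpec(response="F", fixed_terms="inf"),
                 ModelSpec(response="MD", fixed_terms="inf")]
        with pytest.raises(ValueError, match="disagree"):
            compare_models(records, specs, fast_settings)

    def test_duplicate_specs_tie_up_to_mcmc_noise(self, fast_settings):
        records = simulate_diallel(DiallelSimParams(
            genotypes=[Genotype("A")], theta=0.5, replicates_per_cross=10,
            day_sd=0.0, seed=2))
        specs = [ModelSpec(response="F", fixed_terms="inf", day_intercepts=False)] * 2
        table, _ = compare_models(records, specs, fast_settings)
        assert len(table) == 2
        assert table["d_waic"].iloc[1] == pytest.approx(0.0, abs=1.0)

    def test_structure_in_male_genotype_prefers_mgeno_model(self):
        """Data generated with male-genotype-driven CI must rank the
        inf*mgeno model above the infection-only model."""
        gs = [Genotype(g) for g in ("A", "B")]
        theta = {("A", f): 0.9 for f in "AB"} | {("B", f): 0.1 for f in "AB"}
        params = DiallelSimParams(
            genotypes=gs, theta=theta, phi=0.1, fert=0.9, base_mort=0.05,
            day_sd=0.0, replicates_per_cross=10, eggs_mean=80.0, seed=29,
        )
        records = simulate_diallel(params)
        settings = McmcSettings(chains=2, iterations=2000, warmup=600, seed=5)
        specs = [
            ModelSpec(response="F", fixed_terms="inf", day_intercepts=False),
            ModelSpec(response="F", fixed_terms="inf*mgeno", day_intercepts=False),
        ]
        table, _ = compare_models(records, specs, settings)
        assert table["model"].iloc[0] == "inf*mgeno"
        ranked = table.set_index("model")
        assert ranked.loc["inf", "d_waic"] > ranked.loc["inf", "d_se"]
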
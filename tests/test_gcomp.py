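"""The g-computation engine against closed-form and Monte Carlo oracles."""

import numpy as np
import pandas as pd
import pytest

from bgcomp.datamodel import (
    DerivedOutcomeSpec,
    EstimandSpec,
    PopulationSpec,
    PosteriorDraws,
)
from bgcomp.derive import toy_spec
from bgcomp.gcomp import (
    conditional_outcome_prob,
    draw_population_params,
    expected_outcome,
    gcompute,
    make_source_bank,
    sample_sources,
)

TOY = {"zeta": 0.4, "muZ1A": 0.5, "muZ2A": 1.7, "muZ1B": 1.5, "muZ2B": 1.8,
       "sigZ1": 1.0, "sigZ2": 0.8, "rho": 0.3}


def _toy_draws(M=1):
    return PosteriorDraws(params=pd.DataFrame([TOY] * M), model="toy")


TWO_POPS = [PopulationSpec(index=1, conditioning={"X": 0}),
            PopulationSpec(index=2, conditioning={"X": 1})]


class TestSampleSources:
    def test_population_conditioning_sets_group_means(self, rng):
        s = sample_sources("toy", TOY, {}, TWO_POPS[1], 20000, rng)
        assert abs(s["Z1"].mean() - TOY["muZ1B"]) < 4 * TOY["sigZ1"] / np.sqrt(20000)

    def test_sample_covariance_matches_model(self, rng):
        S = 100_000
        s = sample_sources("toy", TOY, {}, TWO_POPS[0], S, rng)
        cov = np.cov(s["Z1"], s["Z2"])
        want = np.array([
            [TOY["sigZ1"] ** 2, TOY["rho"] * TOY["sigZ1"] * TOY["sigZ2"]],
            [TOY["rho"] * TOY["sigZ1"] * TOY["sigZ2"], TOY["sigZ2"] ** 2],
        ])
        assert np.abs(cov - want).max() < 3.0 / np.sqrt(S) * want.max() * 3
    def test_unregistered_model_errors(self, rng):
        with pytest.raises(ValueError, match="simulator"):
            sample_sources("nope", TOY, {}, TWO_POPS[0], 10, rng)


class TestExpectedOutcome:
    def test_mean_of_f(self):
        samples = pd.DataFrame({"Z1": [1.0, 3.0], "Z2": [2.0, 4.0]})
        val, se = expected_outcome(samples, toy_spec())
        assert val == pytest.approx(5.0)
        assert se == pytest.approx(np.std([3.0, 7.0], ddof=1) / np.sqrt(2))

    def test_binary_outcome_in_unit_interval(self, rng):
        spec = DerivedOutcomeSpec(lambda a, b: (a > b).astype(float), ("Z1", "Z2"), "binary")
        samples = pd.DataFrame({"Z1": rng.normal(size=500), "Z2": rng.normal(size=500)})
        val, _ = expected_outcome(samples, spec)
        assert 0.0 <= val <= 1.0


class TestGcompute:
    def test_constant_outcome(self):
        spec = DerivedOutcomeSpec(lambda a, b: np.full_like(a, 7.5), ("Z1", "Z2"))
        ed = gcompute(_toy_draws(5), [PopulationSpec(index=1)], EstimandSpec.identity(),
                      spec, S=50, seed=0)
        np.testing.assert_allclose(ed.theta, 7.5)

    def test_matches_closed_form_group_expectations(self):
        """E(Y|X=x) from g-computation equals μZ1 + μZ2 of the group."""
        ed = gcompute(_toy_draws(40), TWO_POPS, EstimandSpec.difference(),
                      toy_spec(), S=2000, seed=1)
        want = (TOY["muZ1B"] + TOY["muZ2B"]) - (TOY["muZ1A"] + TOY["muZ2A"])
        # fixed params: spread is pure inner MC noise
        assert abs(ed.theta.mean() - want) < 4 * ed.mc_se
        assert ed.mc_se > 0

    def test_reproducible(self):
        a = gcompute(_toy_draws(10), TWO_POPS, EstimandSpec.difference(),
                     toy_spec(), S=200, seed=7)
        b = gcompute(_toy_draws(10), TWO_POPS, EstimandSpec.difference(),
                     toy_spec(), S=200, seed=7)
        np.testing.assert_array_equal(a.theta, b.theta)

    def test_inner_mc_error_shrinks_with_S(self):
        """Median variability across seeds decays like 1/S."""
        variances = []
        for S in (100, 1600):
            meds = [
                np.median(gcompute(_toy_draws(20), TWO_POPS, EstimandSpec.difference(),
                                   toy_spec(), S=S, seed=s).theta)
                for s in range(12)
            ]
            variances.append(np.var(meds))
        assert variances[1] < variances[0] / 4  # expected factor 16

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            gcompute(_toy_draws(2), TWO_POPS, EstimandSpec.difference(), toy_spec(), S=0)


class TestPopulationParams:
    def test_empty_gamma_spec(self, rng):
        assert draw_population_params(_toy_draws(3), PopulationSpec(index=1), 0, rng) == {}

    def test_gamma_read_off_parameter_record(self, rng):
        pop = PopulationSpec(index=1, gamma_spec={
            "muB_sum": lambda rec, table, rng: rec["muZ1B"] + rec["muZ2B"],
        })
        out = draw_population_params(_toy_draws(3), pop, 1, rng)
        assert out == {"muB_sum": pytest.approx(TOY["muZ1B"] + TOY["muZ2B"])}

    def test_unknown_quantity_errors(self, rng):
        pop = PopulationSpec(index=1, gamma_spec={
            "bad": lambda rec, table, rng: rec["nonexistent"],
        })
        with pytest.raises(ValueError, match="unknown quantity"):
            draw_population_params(_toy_draws(3), pop, 0, rng)


class TestConditionalRisk:
    def test_empty_condition_equals_unconditional_mean(self):
        draws = _toy_draws(5)
        bank = make_source_bank(draws, TWO_POPS[0], S=3000, seed=3)
        out = conditional_outcome_prob(draws, bank, {}, {}, toy_spec(), min_matches=1)
        for m, b in enumerate(bank):
            assert out.p_hat[m] == pytest.approx(expected_outcome(b, toy_spec())[0])
            assert out.G[m] == len(b)

    def test_matches_conditional_gaussian_oracle(self):
        """ε-matching on Z2 reproduces E(Z1+Z2 | Z2≈v) of the bivariate Normal."""
        draws = _toy_draws(8)
        v, eps, S = 1.2, 0.1, 40000
        bank = make_source_bank(draws, TWO_POPS[0], S=S, seed=5)
        out = conditional_outcome_prob(draws, bank, {"Z2": v}, {"Z2": eps},
                                       toy_spec(), min_matches=20)
        cond_mean = (TOY["muZ1A"]
                     + TOY["rho"] * TOY["sigZ1"] / TOY["sigZ2"] * (v - TOY["muZ2A"]) + v)
        csd = TOY["sigZ1"] * np.sqrt(1 - TOY["rho"] ** 2)
        for m in range(8):
            assert out.G[m] > 1000
            assert abs(out.p_hat[m] - cond_mean) < 4 * csd / np.sqrt(out.G[m]) + 0.01

    def test_no_match_flags_and_warns(self):
        draws = _toy_draws(3)
        bank = make_source_bank(draws, TWO_POPS[0], S=200, seed=1)
        with pytest.warns(UserWarning, match="increase S"):
            out = conditional_outcome_prob(draws, bank, {"Z2": 99.0}, {"Z2": 0.01},
                                           toy_spec())
        assert np.isnan(out.p_hat).all()
        assert out.flagged.all()

    def test_condition_validation(self):
        draws = _toy_draws(2)
        bank = make_source_bank(draws, TWO_POPS[0], S=50, seed=0)
        with pytest.raises(ValueError, match="not among"):
            conditional_outcome_prob(draws, bank, {"W": 1.0}, {}, toy_spec())
        with pytest.raises(ValueError, match="unconditioned"):
            conditional_outcome_prob(draws, bank, {"Z1": 0.0, "Z2": 0.0}, {}, toy_spec())
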
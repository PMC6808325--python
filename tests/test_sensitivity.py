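"""Distribution fitting, tornado analysis, PSA and CEAC."""

import numpy as np
import pytest

from dialysis_cea import run_scenario
from dialysis_cea.parameters import ParamRange, ValidationError
from dialysis_cea.sensitivity import (
    ceac,
    default_threshold_grid,
    fit_distribution,
    one_way_tornado,
    parameter_distributions,
    run_psa,
)


class TestFitDistribution:
    def test_symmetric_beta_by_moments(self, rng):
        # mean 0.5, 95% range (0.25, 0.75) -> SD 0.1276, alpha = beta ~ 14.86
        spec = fit_distribution("beta", 0.5, 0.25, 0.75)
        alpha, beta = spec.params
        assert alpha == pytest.approx(beta)
        sd = 0.5 / 3.92
        expected_nu = 0.25 / (sd * sd) - 1.0
        assert alpha == pytest.approx(0.5 * expected_nu)
        sample = spec.sample(rng, 200_000)
        assert sample.mean() == pytest.approx(0.5, abs=2e-3)
        assert sample.std() == pytest.approx(sd, rel=0.02)

    def test_gamma_preserves_mean(self, rng):
        spec = fit_distribution("gamma", 887.28, 0.0, 18171.19)
        shape, rate = spec.params
        assert shape / rate == pytest.approx(887.28, rel=1e-9)
        sample = spec.sample(rng, 500_000)
        assert sample.mean() == pytest.approx(887.28, rel=0.01)

    def test_degenerate_range_is_point_mass(self, rng):
        spec = fit_distribution("gamma", 5.0, 5.0, 5.0)
        assert spec.family == "degenerate"
        assert np.all(spec.sample(rng, 10) == 5.0)

    def test_infeasible_beta_rejected(self):
        # variance from a full-width range exceeds mean(1-mean) near 0
        with pytest.raises(ValidationError, match="infeasible"):
            fit_distribution("beta", 0.01, 0.0, 1.0)

    def test_alternative_range_width_flag(self):
        wide = fit_distribution("gamma", 100.0, 50.0, 150.0, z=3.92)
        narrow = fit_distribution("gamma", 100.0, 50.0, 150.0, z=4.0)
        # z = 4 means a smaller SD, hence larger shape
        assert narrow.params[0] > wide.params[0]

    def test_every_model_input_gets_a_distribution(self, params):
        specs = parameter_distributions(params)
        assert set(specs) == set(params.labelled_inputs())
        families = {lab: s.family for lab, s in specs.items()}
        assert families["cHD_staffing"] == "gamma"
        assert families["uHD"] == "beta"
        assert families["pCAPD_death"] == "beta"


@pytest.fixture(scope="module")
def entries(params):
    return one_way_tornado(params)


@pytest.fixture(scope="module")
def psa(params):
    return run_psa(params, n_iterations=200, seed=42)


class TestTornado:
    def test_sorted_by_descending_bar_width(self, entries):
        widths = [e.bar_width for e in entries]
        assert widths == sorted(widths, reverse=True)

    def test_one_entry_per_uncertain_input(self, params, entries):
        assert {e.label for e in entries} == set(params.labelled_inputs())

    def test_utilities_and_hospitalization_dominate_uncertainty(self, entries):
        # top predictors: health utilities, then hospitalization and
        # outpatient cost components of both modalities
        top6 = {e.label for e in entries[:6]}
        assert {"uHD", "uCAPD"} <= top6
        assert {"cHD_hosp", "cCAPD_hosp"} <= top6

    def test_degenerate_range_ranks_last(self, params):
        import dataclasses as dc

        pinned = dc.replace(
            params,
            rates=dc.replace(
                params.rates, HD_CAPD=ParamRange(0.007, 0.007, 0.007)
            ),
        )
        entries = one_way_tornado(pinned)
        assert entries[-1].label == "pHD_CAPD"
        assert entries[-1].bar_width == pytest.approx(0.0, abs=1e-9)

    def test_perturbation_is_local(self, params):
        """Widening one input's range changes only that input's bar."""
        import dataclasses as dc

        profile = params.costs["HD"]
        comps = dict(profile.components)
        old = comps["equipment"]
        comps["equipment"] = ParamRange(old.mean, old.low / 2, old.high * 2)
        widened = dc.replace(
            params,
            costs={**params.costs,
                   "HD": dc.replace(profile, components=comps)},
        )
        base = {e.label: e for e in one_way_tornado(params)}
        wide = {e.label: e for e in one_way_tornado(widened)}
        assert wide["cHD_equipment"].bar_width > base["cHD_equipment"].bar_width
        for label in base:
            if label != "cHD_equipment":
                assert wide[label].nmb_at_low == pytest.approx(
                    base[label].nmb_at_low
                )

    def test_deterministic(self, params, entries):
        again = one_way_tornado(params)
        assert again == entries


class TestPsa:
    def test_reproducible_under_same_seed(self, params, psa):
        again = run_psa(params, n_iterations=200, seed=42)
        assert again.parameters.equals(psa.parameters)
        assert again.outcomes.equals(psa.outcomes)

    def test_different_seed_differs(self, params, psa):
        other = run_psa(params, n_iterations=200, seed=43)
        assert not other.parameters.equals(psa.parameters)

    def test_sampled_costs_centred_on_deterministic(self, params, psa):
        _, det = run_scenario(params, "base_case")
        cost, _ = psa.scenario_outcomes("base_case")
        se = cost.std(ddof=1) / np.sqrt(len(cost))
        assert abs(cost.mean() - det.disc_cost) <= 4 * se + 0.02 * det.disc_cost

    def test_all_scenarios_sampled_per_iteration(self, params, psa):
        counts = psa.outcomes.groupby("iteration")["scenario"].nunique()
        assert (counts == len(params.scenarios)).all()

    def test_degenerate_distributions_reproduce_deterministic_run(self, params):
        doc = params.to_dict()
        for section in ("utilities", "transition_rates"):
            for entry in doc[section].values():
                entry["low"] = entry["high"] = entry["mean"]
        for modality in ("HD", "CAPD"):
            for entry in doc["costs"][modality]["components"].values():
                entry["low"] = entry["high"] = entry["mean"]
            total = doc["costs"][modality]["total"]
            total["low"] = total["high"] = total["mean"]
        from dialysis_cea import load_parameters

        degenerate = load_parameters(doc)
        psa = run_psa(degenerate, n_iterations=5, seed=0)
        _, det = run_scenario(degenerate, "base_case")
        cost, qaly = psa.scenario_outcomes("base_case")
        assert np.all(cost == det.disc_cost)
        assert np.all(qaly == det.disc_qaly)


class TestCeac:
    def test_probabilities_sum_to_one_everywhere(self, params):
        psa = run_psa(params, n_iterations=100, seed=7)
        curve = ceac(psa)
        sums = curve.probabilities.sum(axis=1).to_numpy()
        assert np.allclose(sums, 1.0, atol=1e-12)
        assert np.all((curve.probabilities.to_numpy() >= 0)
                      & (curve.probabilities.to_numpy() <= 1))

    def test_single_iteration_gives_indicator_curve(self, params):
        psa = run_psa(params, n_iterations=1, seed=3)
        curve = ceac(psa)
        values = curve.probabilities.to_numpy()
        assert np.all(np.isin(values, [0.0, 1.0]))

    def test_identical_strategies_split_ties_equally(self, params):
        import dataclasses as dc

        twin_scenarios = {
            "x": dc.replace(params.scenario("base_case"), name="x"),
            "y": dc.replace(params.scenario("base_case"), name="y"),
        }
        twin = dc.replace(params, scenarios=twin_scenarios)
        psa = run_psa(twin, n_iterations=20, seed=1)
        curve = ceac(psa)
        assert np.allclose(curve.probabilities.to_numpy(), 0.5)

    def test_default_grid_covers_gdp_thresholds(self):
        grid = default_threshold_grid()
        assert grid[0] == 0.0 and grid[-1] == 200_000.0
        assert 40_000.0 in grid and 120_000.0 in grid

    def test_same_seed_identical_curves(self, params):
        c1 = ceac(run_psa(params, n_iterations=50, seed=9))
        c2 = ceac(run_psa(params, n_iterations=50, seed=9))
        assert c1.probabilities.equals(c2.probabilities)
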
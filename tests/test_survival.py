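"""Kaplan-Meier estimation, restricted-mean survival, and annual rates."""

import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines import KaplanMeierFitter

from dialysis_cea import (
    GeneratorConfig,
    annual_event_rate,
    generate_registry,
    km_estimate,
    rate_to_probability,
    restricted_mean_survival,
)
from dialysis_cea.survival import KMCurve

from conftest import make_record


def km_oracle(durations, observed, t):
    """Direct enumeration of the product-limit formula (events before
    censorings at ties)."""
    s = 1.0
    for ti in sorted({d for d, o in zip(durations, observed) if o}):
        if ti > t:
            break
        n_i = sum(1 for d in durations if d >= ti)
        d_i = sum(1 for d, o in zip(durations, observed) if o and d == ti)
        s *= 1.0 - d_i / n_i
    return s


class TestKaplanMeier:
    def test_hand_worked_three_patient_curve(self):
        records = [
            make_record("a", months=1, event="death"),
            make_record("b", months=2, event="lost_to_follow_up"),
            make_record("c", months=3, event="death"),
        ]
        curve = km_estimate(records)
        assert curve.survival == pytest.approx([1.0, 2 / 3, 2 / 3, 0.0])
        assert curve.at_risk == pytest.approx([3, 3, 2, 1])
        assert curve.times == pytest.approx([0, 1, 2, 3], abs=0.05)

    def test_all_censored_is_flat_at_one(self):
        records = [make_record(str(i), months=i + 1, event="transplant") for i in range(4)]
        with pytest.warns(UserWarning, match="censored"):
            curve = km_estimate(records)
        assert np.all(curve.survival == 1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            km_estimate([])

    def test_overlapping_event_sets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            km_estimate([make_record()], {"death"}, {"death", "transplant"})

    @given(
        data=st.lists(
            st.tuples(st.floats(0.5, 60.0), st.booleans()), min_size=1, max_size=20
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_oracle(self, data):
        records = [
            make_record(
                f"p{i}", months=m, event="death" if ev else "administrative_censor"
            )
            for i, (m, ev) in enumerate(data)
        ]
        durations = [r.followup_months for r in records]
        observed = [r.terminal_event == "death" for r in records]
        if not any(observed):
            return
        curve = km_estimate(records)
        for t in list(curve.times) + [0.25, 10.0, 100.0]:
            assert curve.survival_at(t) == pytest.approx(
                km_oracle(durations, observed, t), abs=1e-12
            )

    def test_matches_lifelines_fitter(self):
        records = generate_registry(GeneratorConfig(n_patients=300, seed=5))
        curve = km_estimate(records)
        kmf = KaplanMeierFitter().fit(
            [r.followup_months for r in records],
            [r.terminal_event == "death" for r in records],
        )
        for t in (6.0, 12.0, 24.0, 48.0):
            assert curve.survival_at(t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-10
            )

    def test_extra_censored_record_leaves_earlier_curve_unchanged(self):
        base = [
            make_record("a", months=3, event="death"),
            make_record("b", months=9, event="death"),
        ]
        extra = base + [make_record("c", months=6, event="transplant")]
        c1, c2 = km_estimate(base), km_estimate(extra)
        for t in (0.0, 1.0, 2.9):
            assert c2.survival_at(t) == pytest.approx(c1.survival_at(t))

    def test_itt_death_after_switch_counts_for_first_modality(self):
        start = dt.date(2012, 1, 1)
        rec = make_record(
            "s", modality="CAPD", months=24, event="death",
            switch_date=start + dt.timedelta(days=180), final_modality="HD",
        )
        curve = km_estimate([rec])
        assert rec.first_modality == "CAPD"
        assert curve.survival[-1] == pytest.approx(0.0)

    def test_greenwood_ci_covers_exponential_truth(self):
        cfg = GeneratorConfig(
            n_patients=1000,
            death_hazard={"HD": 0.125, "CAPD": 0.125},
            switch_hazard={"HD": 0.0, "CAPD": 0.0},
            censor_hazards={"transplant": 0.0, "recovery": 0.0,
                            "lost_to_follow_up": 0.0},
            seed=11,
        )
        curve = km_estimate(generate_registry(cfg))
        idx = int(np.searchsorted(curve.times, 12.0, side="right")) - 1
        s, se = curve.survival[idx], curve.std_err[idx]
        assert abs(s - math.exp(-0.125)) <= 1.96 * se


class TestRestrictedMean:
    def test_flat_curve_gives_full_horizon(self):
        curve = KMCurve([0.0, 60.0], [1.0, 1.0], [10, 10], [0.0, 0.0])
        assert restricted_mean_survival(curve, 5.0) == pytest.approx(5.0)

    def test_unit_rectangle(self):
        # S drops to 0 at exactly one year
        curve = KMCurve([0.0, 12.0], [1.0, 0.0], [5, 5], [0.0, 0.1])
        assert restricted_mean_survival(curve, 5.0) == pytest.approx(1.0)

    def test_horizon_beyond_followup_warns_and_extends(self):
        curve = KMCurve([0.0, 12.0], [1.0, 0.5], [4, 2], [0.0, 0.25])
        with pytest.warns(UserWarning, match="horizon"):
            value = restricted_mean_survival(curve, 3.0)
        assert value == pytest.approx(1.0 + 2 * 0.5)

    def test_exponential_cohort_matches_closed_form(self):
        cfg = GeneratorConfig(
            n_patients=5000,
            death_hazard={"HD": 0.25, "CAPD": 0.25},
            switch_hazard={"HD": 0.0, "CAPD": 0.0},
            censor_hazards={"transplant": 0.0, "recovery": 0.0,
                            "lost_to_follow_up": 0.0},
            seed=7,
        )
        curve = km_estimate(generate_registry(cfg))
        rmst = restricted_mean_survival(curve, 5.0)
        closed_form = (1 - math.exp(-0.25 * 5)) / 0.25
        assert rmst == pytest.approx(closed_form, rel=0.02)

    def test_nonpositive_horizon_rejected(self):
        curve = KMCurve([0.0], [1.0], [1], [0.0])
        with pytest.raises(ValueError):
            restricted_mean_survival(curve, 0.0)


class TestAnnualRates:
    def test_simple_quotient(self):
        est = annual_event_rate(100, 800)
        assert est.rate == pytest.approx(0.125)

    def test_zero_events(self):
        assert annual_event_rate(0, 500).rate == 0.0

    def test_multi_year_equal_weight_mean(self):
        est = annual_event_rate(
            [12, 13, 12, 13, 12.5],
            [100, 100, 100, 100, 100],
            years=range(2011, 2016),
        )
        assert est.rate == pytest.approx(0.125)
        assert len(est.per_year_breakdown) == 5

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            annual_event_rate(3, 0)


class TestRateToProbability:
    @pytest.mark.parametrize(
        "rate, expected",
        [
            (0.0, 0.0),
            (0.125, 1 - math.exp(-0.125)),
            (0.134, 1 - math.exp(-0.134)),
            (0.007, 1 - math.exp(-0.007)),
        ],
    )
    def test_formula(self, rate, expected):
        assert rate_to_probability(rate, 1.0) == pytest.approx(expected, abs=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            rate_to_probability(-0.1, 1.0)

    @given(st.floats(1e-8, 1e-3))
    @settings(max_examples=50, deadline=None)
    def test_small_rate_linearization(self, rate):
        p = rate_to_probability(rate, 1.0)
        assert p == pytest.approx(rate, rel=1e-3)

    @given(st.floats(0.0, 2.0), st.floats(0.0, 2.0))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_rate(self, r1, r2):
        lo, hi = sorted((r1, r2))
        assert rate_to_probability(lo, 1.0) <= rate_to_probability(hi, 1.0)
        assert 0.0 <= rate_to_probability(hi, 1.0) < 1.0
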
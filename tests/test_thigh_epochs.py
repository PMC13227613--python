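import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from consenslab.activity_scheme import EXCLUDED, Activity
from consenslab.cadence import CadenceThresholds
from consenslab.thigh_epochs import (
    assign_epoch_label,
    classify_stepping_intensity,
    derive_durations,
    exclusion_rate,
    label_epochs,
)

THR = CadenceThresholds(90.0, 130.0)


def oracle_label(seconds, steps, thresholds, majority=30.0):
    """Literal brute-force application of the epoch rule, independent of the
    implementation: derive all six competing durations and pick the one
    strictly exceeding the majority boundary."""
    get = lambda k: float(seconds.get(k, 0.0))
    durations = {
        "lying": get("lying_primary_s") + get("lying_secondary_s"),
        "sitting_not_in_transport": max(0.0, get("sedentary_s") - get("sitting_transport_s")),
        "sitting_in_transport": get("sitting_transport_s"),
        "standing": max(
            0.0, get("upright_s") - get("stepping_s") - get("cycling_s")
        ),
        "stepping": get("stepping_s"),
        "cycling": get("cycling_s"),
    }
    winners = [k for k, v in durations.items() if v > majority]
    if not winners:
        return EXCLUDED
    assert len(winners) == 1
    key = winners[0]
    if key == "stepping":
        if steps < thresholds.theta_lm:
            return Activity.LOW_STEPPING
        if thresholds.theta_mv is not None and steps >= thresholds.theta_mv:
            return Activity.VIGOROUS_STEPPING
        return Activity.MODERATE_STEPPING
    return {
        "lying": Activity.LYING,
        "sitting_not_in_transport": Activity.SITTING_NOT_IN_TRANSPORT,
        "sitting_in_transport": Activity.SITTING_IN_TRANSPORT,
        "standing": Activity.STANDING,
        "cycling": Activity.CYCLING,
    }[key]


def random_composition(rng):
    """Random integer-second composition over the six derived leaves,
    re-expressed in the raw export columns."""
    parts = rng.multinomial(60, rng.dirichlet(np.ones(6) * rng.uniform(0.2, 2.0)))
    lying, snt, sit_t, standing, stepping, cycling = (float(p) for p in parts)
    return {
        "lying_primary_s": lying,
        "lying_secondary_s": 0.0,
        "sedentary_s": snt + sit_t,
        "sitting_transport_s": sit_t,
        "upright_s": standing + stepping + cycling,
        "stepping_s": stepping,
        "cycling_s": cycling,
    }


class TestDeriveDurations:
    def test_full_transport_minute(self):
        d = derive_durations({"sedentary_s": 60, "sitting_transport_s": 60})
        assert d["sitting_not_in_transport"] == 0

    def test_lying_aggregation(self):
        d = derive_durations({"lying_primary_s": 20, "lying_secondary_s": 25})
        assert d["lying"] == 45

    def test_standing_subtraction(self):
        d = derive_durations({"upright_s": 60, "stepping_s": 20, "cycling_s": 10})
        assert d["standing"] == 30

    def test_small_negative_clamped(self):
        d = derive_durations({"sedentary_s": 30, "sitting_transport_s": 30.5})
        assert d["sitting_not_in_transport"] == 0.0

    def test_large_negative_invalid(self):
        with pytest.raises(ValueError, match="invalid"):
            derive_durations({"sedentary_s": 20, "sitting_transport_s": 25})


class TestAssignEpochLabel:
    def test_standing_wins_at_31(self):
        label, basis = assign_epoch_label(
            {"upright_s": 31, "sedentary_s": 29}, thresholds=THR
        )
        assert label is Activity.STANDING
        assert basis == 31

    def test_exact_30_30_split_excluded(self):
        label, basis = assign_epoch_label(
            {"sedentary_s": 30, "upright_s": 30}, thresholds=THR
        )
        assert label == EXCLUDED
        assert basis == 0.0

    def test_stepping_needs_thresholds(self):
        with pytest.raises(ValueError, match="thresholds"):
            assign_epoch_label({"upright_s": 60, "stepping_s": 40}, steps=100)

    def test_stepping_refined(self):
        label, _ = assign_epoch_label(
            {"upright_s": 60, "stepping_s": 40}, steps=100, thresholds=THR
        )
        assert label is Activity.MODERATE_STEPPING

    def test_oracle_equivalence_10k(self):
        rng = np.random.default_rng(1234)
        for _ in range(10_000):
            comp = random_composition(rng)
            steps = float(rng.integers(0, 180))
            expected = oracle_label(comp, steps, THR)
            got, _ = assign_epoch_label(comp, steps=steps, thresholds=THR)
            assert got == expected


class TestClassifyStepping:
    def test_between_thresholds(self):
        # 96 steps/min with thresholds (90, 130)
        assert classify_stepping_intensity(96, THR) is Activity.MODERATE_STEPPING

    def test_no_vigorous_threshold(self):
        thr = CadenceThresholds(80.0, None)
        assert classify_stepping_intensity(85, thr) is Activity.MODERATE_STEPPING
        assert classify_stepping_intensity(170, thr) is Activity.MODERATE_STEPPING

    def test_boundary_goes_up(self):
        assert classify_stepping_intensity(90, THR) is Activity.MODERATE_STEPPING
        assert classify_stepping_intensity(130, THR) is Activity.VIGOROUS_STEPPING

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_stepping_intensity(-1, THR)

    def test_threshold_monotonicity(self):
        # raising theta_lm never moves a minute from Low to a higher class
        rng = np.random.default_rng(0)
        order = {Activity.LOW_STEPPING: 0, Activity.MODERATE_STEPPING: 1, Activity.VIGOROUS_STEPPING: 2}
        for _ in range(200):
            steps = float(rng.uniform(0, 200))
            lo = classify_stepping_intensity(steps, CadenceThresholds(80.0, 130.0))
            hi = classify_stepping_intensity(steps, CadenceThresholds(95.0, 130.0))
            assert order[hi] <= order[lo]


@st.composite
def compositions(draw):
    parts = draw(
        st.lists(st.integers(min_value=0, max_value=60), min_size=6, max_size=6).filter(
            lambda p: sum(p) <= 60
        )
    )
    lying, snt, sit_t, standing, stepping, cycling = (float(p) for p in parts)
    return {
        "lying_primary_s": lying,
        "sedentary_s": snt + sit_t,
        "sitting_transport_s": sit_t,
        "upright_s": standing + stepping + cycling,
        "stepping_s": stepping,
        "cycling_s": cycling,
    }


class TestInvariants:
    @given(compositions())
    @settings(max_examples=300)
    def test_at_most_one_majority(self, comp):
        derived = derive_durations(comp)
        competing = [
            derived[k]
            for k in (
                "lying",
                "sitting_not_in_transport",
                "sitting_in_transport",
                "standing",
                "stepping",
                "cycling",
            )
        ]
        assert sum(1 for v in competing if v > 30) <= 1

    @given(compositions())
    @settings(max_examples=300)
    def test_conservation(self, comp):
        derived = derive_durations(comp)
        total_derived = (
            derived["lying"]
            + derived["sitting_not_in_transport"]
            + derived["sitting_in_transport"]
            + derived["standing"]
            + derived["stepping"]
            + derived["cycling"]
        )
        total_raw = (
            comp.get("lying_primary_s", 0)
            + comp.get("sedentary_s", 0)
            + comp.get("upright_s", 0)
        )
        assert abs(total_derived - total_raw) <= 1.0


class TestLabelEpochs:
    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(7)
        rows = []
        for i in range(500):
            comp = random_composition(rng)
            rows.append(
                {
                    "participant_id": "P1",
                    "minute_start": pd.Timestamp("2023-05-01") + pd.Timedelta(minutes=i),
                    **comp,
                    "steps": int(rng.integers(0, 180)),
                    "met": 1.5,
                }
            )
        df = pd.DataFrame(rows)
        out = label_epochs(df, {"P1": THR})
        for row, got in zip(rows, out["label"]):
            comp = {k: v for k, v in row.items() if k.endswith("_s")}
            expected, _ = assign_epoch_label(comp, steps=row["steps"], thresholds=THR)
            assert got == (expected if expected == EXCLUDED else expected.value)

    def test_basis_seconds_exceed_majority(self):
        rng = np.random.default_rng(8)
        rows = [
            {
                "participant_id": "P1",
                "minute_start": pd.Timestamp("2023-05-01") + pd.Timedelta(minutes=i),
                **random_composition(rng),
                "steps": 0,
                "met": 1.0,
            }
            for i in range(200)
        ]
        out = label_epochs(pd.DataFrame(rows), {"P1": THR})
        labeled = out[out["label"] != EXCLUDED]
        assert (labeled["basis_seconds"] > 30).all()


class TestExclusionRate:
    def test_all_valid(self):
        assert exclusion_rate(["Lying", "Standing"]) == 0.0

    def test_half(self):
        assert exclusion_rate(["Lying", EXCLUDED]) == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            exclusion_rate([])

    def test_synthetic_alternation_rate(self, default_bundle, default_result):
        # three-way uniform-Dirichlet split minutes are excluded w.p. 1/4
        rate = exclusion_rate(default_result.labeled_epochs["label"])
        n_three = sum(tb["n_three_way"] for tb in default_bundle.book["thigh"].values())
        analytic = 0.25 * n_three / len(default_bundle.thigh)
        assert abs(rate - analytic) < 0.003
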
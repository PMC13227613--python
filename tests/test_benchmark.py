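import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from consenslab.activity_scheme import EXCLUDED, Activity
from consenslab.benchmark import (
    auc,
    binarize_truth,
    compare_sources,
    error_crosstab,
    evaluate,
    roc,
    youden_optimal,
)

T = pd.Timestamp


# --- independent oracles ----------------------------------------------------

def auc_oracle(conf, truth):
    """Mann-Whitney pairwise comparison with half credit for ties."""
    conf = np.asarray(conf, dtype=float)
    truth = np.asarray(truth)
    pos = conf[truth == 1]
    neg = conf[truth == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def youden_oracle(conf, truth):
    """Exhaustive grid over all candidate thresholds (the distinct
    confidence values); ties broken toward the highest threshold."""
    conf = np.asarray(conf, dtype=float)
    truth = np.asarray(truth)
    n_pos = truth.sum()
    n_neg = len(truth) - n_pos
    best = None
    for t in sorted(set(conf), reverse=True):
        pred = conf >= t
        tpr = (pred & (truth == 1)).sum() / n_pos
        fpr = (pred & (truth == 0)).sum() / n_neg
        j = tpr - fpr
        if best is None or j > best[1] + 1e-12:
            best = (t, j)
    return best


def roc_oracle(conf, truth):
    """Per-threshold (FPR, TPR) sweep over distinct confidences, descending,
    with the (0, 0) start point."""
    conf = np.asarray(conf, dtype=float)
    truth = np.asarray(truth)
    n_pos = truth.sum()
    n_neg = len(truth) - n_pos
    points = [(0.0, 0.0)]
    for t in sorted(set(conf), reverse=True):
        pred = conf >= t
        points.append(
            (
                (pred & (truth == 0)).sum() / n_neg,
                (pred & (truth == 1)).sum() / n_pos,
            )
        )
    return points


def random_instance(rng, n=60, ties=True):
    truth = rng.integers(0, 2, size=n)
    while truth.min() == truth.max():
        truth = rng.integers(0, 2, size=n)
    if ties:
        conf = rng.integers(0, 20, size=n).astype(float) * 5
    else:
        conf = rng.random(n) * 100
    conf[truth == 1] += rng.random(n)[truth == 1] * 30  # some signal
    return conf, truth


class TestRoc:
    def test_perfect_separation_through_0_1(self):
        fpr, tpr, _ = roc([90, 80, 30, 20], [1, 1, 0, 0])
        assert any(f == 0 and t == 1 for f, t in zip(fpr, tpr))

    def test_all_equal_diagonal(self):
        fpr, tpr, _ = roc([50, 50, 50, 50], [1, 0, 1, 0])
        pts = set(zip(fpr, tpr))
        assert pts == {(0.0, 0.0), (1.0, 1.0)}

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            roc([1, 2, 3], [1, 1, 1])

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            conf, truth = random_instance(rng, n=200)
            fpr, tpr, _ = roc(conf, truth)
            assert [(f, t) for f, t in zip(fpr, tpr)] == pytest.approx(
                roc_oracle(conf, truth)
            )

    def test_monotone_with_endpoints(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            conf, truth = random_instance(rng)
            fpr, tpr, _ = roc(conf, truth)
            assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()
            assert (fpr[0], tpr[0]) == (0.0, 0.0)
            assert (fpr[-1], tpr[-1]) == (1.0, 1.0)


class TestYouden:
    def test_perfect_split_tiebreak(self):
        fpr, tpr, thr = roc([90, 80, 30, 20], [1, 1, 0, 0])
        t, j = youden_optimal(fpr, tpr, thr)
        assert j == 1.0
        assert t == 80.0  # highest threshold attaining J=1

    def test_all_equal_j_zero(self):
        fpr, tpr, thr = roc([50, 50, 50, 50], [1, 0, 1, 0])
        _, j = youden_optimal(fpr, tpr, thr)
        assert j == 0.0

    def test_matches_grid_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            conf, truth = random_instance(rng)
            fpr, tpr, thr = roc(conf, truth)
            t, j = youden_optimal(fpr, tpr, thr)
            t_o, j_o = youden_oracle(conf, truth)
            assert j == pytest.approx(j_o, abs=1e-12)
            assert t == t_o


class TestAuc:
    def test_perfect_ranking(self):
        assert auc([90, 80, 30, 20], [1, 1, 0, 0]) == 1.0

    def test_inverted_ranking(self):
        assert auc([20, 30, 80, 90], [1, 1, 0, 0]) == 0.0

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            conf, truth = random_instance(rng)
            assert auc(conf, truth) == pytest.approx(auc_oracle(conf, truth), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 2], [0, 0])

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        conf, truth = random_instance(rng)
        base = auc(conf, truth)
        assert auc(np.exp(conf / 25.0), truth) == pytest.approx(base, abs=1e-12)
        assert auc(3 * conf + 7, truth) == pytest.approx(base, abs=1e-12)


def tiny_frames(rows):
    """rows: (thigh, verbal_set, consensus, confidences dict)"""
    out = []
    for i, (t_lab, v_set, c_lab, conf) in enumerate(rows):
        out.append(
            {
                "participant_id": "P1",
                "minute_start": T("2023-05-01 10:00") + pd.Timedelta(minutes=i),
                "worn": True,
                "thigh_label": t_lab,
                "verbal_labels": frozenset(v_set),
                "consensus_label": c_lab,
                "api_confidences": conf,
            }
        )
    return pd.DataFrame(out)


class TestBinarizeTruth:
    def test_consensus_direct_map(self):
        f = tiny_frames([("VigorousStepping", {Activity.VIGOROUS_STEPPING},
                          "VigorousStepping", {"RUNNING": 90.0})])
        assert binarize_truth(f, "RUNNING", "consensus").tolist() == [1]

    def test_still_excludes_transport(self):
        f = tiny_frames([("SittingInTransport", {Activity.SITTING_IN_TRANSPORT},
                          "SittingInTransport", {"STILL": 90.0})])
        assert binarize_truth(f, "STILL", "consensus").tolist() == [0]

    def test_verbal_set_membership(self):
        f = tiny_frames([("Standing", {Activity.STANDING, Activity.LOW_STEPPING},
                          EXCLUDED, {"WALKING": 70.0})])
        assert binarize_truth(f, "WALKING", "verbal").tolist() == [1]

    def test_unmapped_class_rejected(self):
        f = tiny_frames([("Standing", {Activity.STANDING}, "Standing", {})])
        with pytest.raises(ValueError, match="TILTING"):
            binarize_truth(f, "TILTING", "consensus")

    def test_unlabeled_minutes_omitted(self):
        f = tiny_frames(
            [
                ("Standing", {Activity.STANDING}, "Standing", {"STILL": 90.0}),
                (EXCLUDED, set(), EXCLUDED, {"STILL": 10.0}),
            ]
        )
        assert len(binarize_truth(f, "STILL", "thigh")) == 1
        assert len(binarize_truth(f, "STILL", "verbal")) == 1
        assert len(binarize_truth(f, "STILL", "consensus")) == 1


class TestCompareSources:
    def test_noise_free_world_all_ones(self, zero_noise_small):
        _, result = zero_noise_small
        table = compare_sources(result.frames)
        values = table[["thigh", "verbal", "consensus"]].to_numpy()
        assert np.nanmin(values) == 1.0

    def test_shuffled_confidences_near_half(self, zero_noise_small):
        bundle, result = zero_noise_small
        frames = result.frames.copy()
        rng = np.random.default_rng(0)
        conf = frames["api_confidences"].to_numpy().copy()
        rng.shuffle(conf)
        frames["api_confidences"] = conf
        curve = evaluate(frames, "STILL", "consensus")
        n = min(curve.n_pos, curve.n_neg)
        assert abs(curve.auc - 0.5) < 5.0 / np.sqrt(n)

    def test_n_counts_reported(self, default_result):
        table = compare_sources(default_result.frames, api_classes=("RUNNING",))
        row = table.loc["RUNNING"]
        for src in ("thigh", "verbal", "consensus"):
            assert row[f"{src}_n_pos"] > 0 and row[f"{src}_n_neg"] > 0


class TestErrorCrosstab:
    def test_fp_cell_semantics(self):
        # one stepping minute detected as IN_VEHICLE lands in the FP cell
        f = tiny_frames(
            [
                ("LowStepping", {Activity.LOW_STEPPING}, "LowStepping", {"IN_VEHICLE": 95.0}),
                ("SittingInTransport", {Activity.SITTING_IN_TRANSPORT},
                 "SittingInTransport", {"IN_VEHICLE": 90.0}),
                ("Standing", {Activity.STANDING}, "Standing", {"IN_VEHICLE": 5.0}),
            ]
        )
        ct = error_crosstab(f, api_classes=("IN_VEHICLE",), thresholds={"IN_VEHICLE": 50.0})
        assert ct.loc["LowStepping", "IN_VEHICLE_detected"] == 1
        assert ct.loc["Standing", "IN_VEHICLE_not_detected"] == 1

    def test_marginals_conserved(self, default_result):
        f = default_result.frames
        ct = error_crosstab(f)
        evaluated = (
            (f["consensus_label"] != EXCLUDED)
            & f["api_confidences"].map(lambda c: isinstance(c, dict))
        ).sum()
        for cls in ("IN_VEHICLE", "STILL"):
            assert ct[f"{cls}_detected"].sum() + ct[f"{cls}_not_detected"].sum() == evaluated

    def test_empty_cohort_all_zero(self):
        f = tiny_frames([(EXCLUDED, set(), EXCLUDED, {"STILL": 50.0})])
        ct = error_crosstab(f)
        assert (ct.to_numpy() == 0).all()
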
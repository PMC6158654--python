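"""Confusion-matrix metrics and the stratified cross-validation harness.

sklearn.metrics serves as the independent oracle for the hand-written
metric formulas; it is never the implementation.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idaod import (
    ConfusionCounts,
    SimulationConfig,
    compute_metrics,
    resolve_config,
    run_cv_pipeline,
    simulate_dataset,
    stratified_kfold,
)
from idaod.errors import StratificationError, ValidationError

counts_strategy = st.tuples(
    st.integers(0, 200), st.integers(0, 200),
    st.integers(0, 200), st.integers(0, 200),
).filter(lambda t: sum(t) > 0)


class TestComputeMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(TP=1, FP=0, TN=1, FN=0))
        assert (m.sn, m.sp, m.acc, m.precision, m.f1, m.mcc) == (
            1, 1, 1, 1, 1, 1
        )
        assert not m.undefined

    def test_no_association(self):
        m = compute_metrics(ConfusionCounts(TP=25, FP=25, TN=25, FN=25))
        assert m.acc == 0.5
        assert m.mcc == 0.0

    def test_worked_confusion_table(self):
        m = compute_metrics(ConfusionCounts(TP=90, FP=60, TN=140, FN=10))
        assert m.sn == pytest.approx(0.9, abs=1e-12)
        assert m.sp == pytest.approx(0.7, abs=1e-12)
        assert m.precision == pytest.approx(0.6, abs=1e-12)
        assert m.f1 == pytest.approx(0.72, abs=1e-12)
        assert m.acc == pytest.approx(230 / 300, abs=1e-12)
        assert m.mcc == pytest.approx(
            12000 / math.sqrt(100 * 150 * 200 * 150), abs=1e-12
        )

    def test_zero_denominators_reported_undefined(self):
        m = compute_metrics(ConfusionCounts(TP=0, FP=0, TN=5, FN=0))
        assert m.precision is None and m.sn is None
        assert {"Sn", "precision", "F1", "MCC"} <= m.undefined
        assert m.sp == 1.0 and m.acc == 1.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            compute_metrics(ConfusionCounts(TP=0, FP=0, TN=0, FN=0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            ConfusionCounts(TP=-1, FP=0, TN=0, FN=1)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(counts=counts_strategy)
    def test_matches_sklearn_oracle(self, counts):
        tp, fp, tn, fn = counts
        from sklearn.metrics import (
            accuracy_score,
            f1_score,
            matthews_corrcoef,
            precision_score,
            recall_score,
        )

        y_true = np.array([1] * tp + [0] * fp + [0] * tn + [1] * fn)
        y_pred = np.array([1] * tp + [1] * fp + [0] * tn + [0] * fn)
        m = compute_metrics(ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn))
        assert m.acc == pytest.approx(
            accuracy_score(y_true, y_pred), abs=1e-12
        )
        if m.sn is not None:
            assert m.sn == pytest.approx(
                recall_score(y_true, y_pred, zero_division=np.nan), abs=1e-12
            )
        if m.precision is not None:
            assert m.precision == pytest.approx(
                precision_score(y_true, y_pred, zero_division=np.nan),
                abs=1e-12,
            )
        if m.f1 is not None:
            assert m.f1 == pytest.approx(
                f1_score(y_true, y_pred), abs=1e-12
            )
            # harmonic-mean identity
            assert m.f1 == pytest.approx(
                2 * m.precision * m.sn / (m.precision + m.sn), abs=1e-12
            )
        if m.mcc is not None and len(set(y_true)) == 2 and len(set(y_pred)) == 2:
            assert m.mcc == pytest.approx(
                matthews_corrcoef(y_true, y_pred), abs=1e-12
            )
            assert -1 - 1e-12 <= m.mcc <= 1 + 1e-12

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(counts=counts_strategy)
    def test_label_swap_symmetry(self, counts):
        tp, fp, tn, fn = counts
        m = compute_metrics(ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn))
        s = compute_metrics(ConfusionCounts(TP=tn, FP=fn, TN=tp, FN=fp))
        assert m.acc == s.acc
        assert m.sn == s.sp and m.sp == s.sn
        if m.mcc is not None and s.mcc is not None:
            assert abs(m.mcc) == pytest.approx(abs(s.mcc), abs=1e-12)


class TestStratifiedKFold:
    def test_balanced_20_into_10(self):
        labels = np.array([0, 1] * 10)
        folds = stratified_kfold(labels, 10, seed=3)
        assert all(len(f) == 2 for f in folds)
        assert all(labels[f].sum() == 1 for f in folds)

    def test_acceptance_scale_stratification(self):
        labels = np.array([1] * 50 + [0] * 300)
        folds = stratified_kfold(labels, 10, seed=0)
        for f in folds:
            assert labels[f].sum() == 5
            assert len(f) == 35

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        n_pos=st.integers(3, 40),
        n_neg=st.integers(3, 40),
        k=st.integers(2, 3),
        seed=st.integers(0, 100),
    )
    def test_partition_property(self, n_pos, n_neg, k, seed):
        labels = np.array([1] * n_pos + [0] * n_neg)
        folds = stratified_kfold(labels, k, seed)
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(n_pos + n_neg))
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1
        pos_counts = [int(labels[f].sum()) for f in folds]
        assert max(pos_counts) - min(pos_counts) <= 1

    def test_class_smaller_than_k(self):
        labels = np.array([1] * 3 + [0] * 50)
        with pytest.raises(StratificationError):
            stratified_kfold(labels, 10, seed=0)

    def test_deterministic(self):
        labels = np.array([1] * 20 + [0] * 40)
        a = stratified_kfold(labels, 5, seed=9)
        b = stratified_kfold(labels, 5, seed=9)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)


@pytest.fixture(scope="module")
def quick_cv_setup():
    sim = simulate_dataset(
        SimulationConfig(n_positive=20, n_negative=60,
                         length_range=(50, 150), bias_strength=8.0, seed=17)
    )
    config = resolve_config({
        "autoencoder": {"epochs": 2},
        "fine_tune": {"epochs": 5},
        "tsne": {"perplexity": 10, "n_iter": 250},
    })
    return sim, config


class TestRunCvPipeline:
    def test_pooled_counts_equal_fold_sums(self, quick_cv_setup):
        sim, config = quick_cv_setup
        res = run_cv_pipeline(sim.records, sim.labels, config, k=5, seed=2)
        total = sum(
            (r.counts for r in res.per_fold),
            ConfusionCounts(0, 0, 0, 0),
        )
        assert total == res.pooled.counts
        assert res.pooled.counts.total == len(sim.records)

    def test_seeded_reruns_identical(self, quick_cv_setup):
        sim, config = quick_cv_setup
        r1 = run_cv_pipeline(sim.records, sim.labels, config, k=5, seed=4)
        r2 = run_cv_pipeline(sim.records, sim.labels, config, k=5, seed=4)
        assert r1.pooled.as_dict() == r2.pooled.as_dict()
        for e1, e2 in zip(r1.embeddings, r2.embeddings):
            np.testing.assert_array_equal(e1.coordinates, e2.coordinates)

    def test_missing_label_named(self, quick_cv_setup):
        sim, config = quick_cv_setup
        labels = dict(sim.label_map)
        victim = sim.records[0].id
        del labels[victim]
        with pytest.raises(ValidationError, match=victim):
            run_cv_pipeline(sim.records, labels, config, k=5, seed=1)
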
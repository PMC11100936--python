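"""Metrics, stratification, and the method-comparison harness."""

import numpy as np
import pytest

from ehrharmonize.evaluate import (
    compare_methods,
    compute_metrics,
    evaluate_scores,
    stratify_by_missingness,
)
from ehrharmonize.models import ModelConfig
from ehrharmonize.records import HarmonizedSequence

from oracles import concordant_pair_auc


class TestComputeMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics([1, 1, 0, 0], [1, 1, 0, 0])
        assert m.auc == 1.0 and m.f1 == 1.0

    def test_inverted_classifier(self):
        m = compute_metrics([0, 0, 1, 1], [1, 1, 0, 0])
        assert m.auc == 0.0

    def test_toy_pair_enumeration(self):
        # 4 pos/neg pairs: (0.9,0.6)+, (0.9,0.2)+, (0.4,0.6)-, (0.4,0.2)+
        m = compute_metrics([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0])
        assert m.auc == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_concordant_pair_fraction(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.uniform(size=n), 2)  # rounding forces ties
        m = compute_metrics(scores, labels)
        assert m.auc == pytest.approx(concordant_pair_auc(scores, labels),
                                      abs=1e-12)

    def test_roc_monotone(self):
        rng = np.random.default_rng(3)
        m = compute_metrics(rng.uniform(size=50), rng.integers(0, 2, size=50))
        pts = np.array(m.roc_points)
        assert np.all(np.diff(pts[:, 0]) >= 0)
        assert np.all(np.diff(pts[:, 1]) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([0.1, 0.9], [1, 1])


class TestStratify:
    def test_boundary_goes_to_more_missing_stratum(self):
        parts = stratify_by_missingness([0.0, 0.25, 0.5, 0.75])
        assert parts["lt50"].tolist() == [0, 1]
        assert parts["ge50"].tolist() == [2, 3]

    def test_all_observed_leaves_ge50_empty(self):
        parts = stratify_by_missingness([0.0, 0.25])
        assert parts["ge50"].size == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_partition_exhaustive_and_disjoint(self, seed):
        fr = np.random.default_rng(seed).uniform(size=30)
        parts = stratify_by_missingness(fr)
        combined = np.concatenate([parts["lt50"], parts["ge50"]])
        assert sorted(combined.tolist()) == list(range(30))

    def test_stratified_confusion_matrices_recombine(self):
        rng = np.random.default_rng(7)
        n = 120
        scores = rng.uniform(size=n)
        labels = rng.integers(0, 2, size=n)
        fr = rng.choice([0.0, 0.25, 0.5, 0.75], size=n)
        report = evaluate_scores(scores, labels, fr)

        def confusion(idx):
            pred = (scores[idx] >= 0.5).astype(int)
            return np.array([[(pred[labels[idx] == a] == b).sum()
                              for b in (0, 1)] for a in (0, 1)])

        parts = stratify_by_missingness(fr)
        pooled = confusion(np.arange(n))
        assert np.array_equal(
            pooled, confusion(parts["lt50"]) + confusion(parts["ge50"]))
        assert report.strata["lt50"].n + report.strata["ge50"].n == n


def _toy_sequences(n, d=4, seed=0):
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, size=n)
    seqs = []
    for i in range(n):
        vec = rng.normal(size=(4, d)) + labels[i] * 2.0
        seqs.append(HarmonizedSequence(f"p{i}", vec, ["observed"] * 4,
                                       float(rng.choice([0.0, 0.5]))))
    return seqs, labels


@pytest.fixture(scope="module")
def result():
    seqs, labels = _toy_sequences(60)
    cfg = ModelConfig(arch="bilstm", input_dim=4, hidden_dim=4,
                      epochs=2, seed=0)
    return compare_methods(
        {"a": seqs, "b": seqs}, labels, archs=("bilstm", "transformer"),
        split_seed=1, model_config=cfg,
    )


class TestCompareMethods:

    def test_one_row_per_method_arch_cell(self, result):
        _, table = result
        assert len(table) == 4
        assert set(zip(table["method"], table["arch"])) == {
            ("a", "bilstm"), ("a", "transformer"),
            ("b", "bilstm"), ("b", "transformer")}

    def test_split_shared_across_cells(self, result):
        _, table = result
        assert table["n_test"].nunique() == 1
        # identical methods + shared split => identical metrics
        a = table[table["method"] == "a"].drop(columns="method")
        b = table[table["method"] == "b"].drop(columns="method")
        assert a.reset_index(drop=True).equals(b.reset_index(drop=True))

    def test_seeded_reproducibility(self):
        seqs, labels = _toy_sequences(50, seed=3)
        cfg = ModelConfig(arch="bilstm", input_dim=4, hidden_dim=4,
                          epochs=2, seed=0)
        t1 = compare_methods({"m": seqs}, labels, ("bilstm",), split_seed=5,
                             model_config=cfg)[1]
        t2 = compare_methods({"m": seqs}, labels, ("bilstm",), split_seed=5,
                             model_config=cfg)[1]
        assert t1.equals(t2)
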
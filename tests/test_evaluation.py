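import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from steinermark import (
    ClassificationResult,
    ExpressionDataset,
    evaluate_features,
    known_marker_coverage,
    paired_run_comparison,
)
from steinermark.synthetic_data import generate_expression


def make_result(aucs, **kw):
    return ClassificationResult(
        auc_runs=tuple(aucs),
        mean_auc=float(np.mean(aucs)),
        n_repetitions=len(aucs),
        n_folds=kw.get("n_folds", 10),
        classifier=kw.get("classifier", "logistic"),
        features_used=frozenset({"g"}),
        features_missing=frozenset(),
    )


@pytest.fixture
def separable_dataset():
    """One feature equal to the label: perfectly separable."""
    n = 40
    labels = pd.Series([0] * (n // 2) + [1] * (n // 2), index=[f"S{i}" for i in range(n)])
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        {
            "perfect": labels.to_numpy().astype(float),
            "noise": rng.normal(size=n),
        }
    ).T
    values.columns = labels.index
    return ExpressionDataset(values=values, labels=labels)


class TestEvaluateFeatures:
    def test_perfect_feature_reaches_auc_one(self, separable_dataset):
        res = evaluate_features(separable_dataset, {"perfect"}, n_repetitions=5, n_folds=5, seed=0)
        assert res.auc_runs == tuple([1.0] * 5)
        assert res.mean_auc == 1.0

    def test_missing_features_recorded(self, separable_dataset):
        res = evaluate_features(
            separable_dataset, {"perfect", "ghost"}, n_repetitions=2, n_folds=5, seed=0
        )
        assert res.features_used == {"perfect"}
        assert res.features_missing == {"ghost"}

    def test_no_mapped_feature_errors(self, separable_dataset):
        with pytest.raises(ValueError, match="no feature maps"):
            evaluate_features(separable_dataset, {"ghost"}, n_folds=5)

    def test_class_size_precondition(self, separable_dataset):
        with pytest.raises(ValueError, match="n_folds"):
            evaluate_features(separable_dataset, {"perfect"}, n_folds=25)

    def test_deterministic_given_seed(self, small_scenario):
        data = small_scenario.expression
        # noise features: AUC depends on the fold split, exposing the seed
        feats = sorted(set(data.genes) - small_scenario.de_genes)[:10]
        r1 = evaluate_features(data, feats, n_repetitions=3, n_folds=5, seed=5)
        r2 = evaluate_features(data, feats, n_repetitions=3, n_folds=5, seed=5)
        assert r1.auc_runs == r2.auc_runs
        r3 = evaluate_features(data, feats, n_repetitions=3, n_folds=5, seed=6)
        assert r1.auc_runs != r3.auc_runs

    def test_signal_features_beat_noise_features(self, small_scenario):
        data = small_scenario.expression
        signal = evaluate_features(
            data, small_scenario.de_genes, n_repetitions=3, n_folds=5, seed=1
        )
        noise_feats = sorted(set(data.genes) - small_scenario.de_genes)[:20]
        noise = evaluate_features(data, noise_feats, n_repetitions=3, n_folds=5, seed=1)
        assert signal.mean_auc > 0.9
        assert noise.mean_auc < signal.mean_auc

    def test_noise_features_do_not_wash_out_signal(self, small_scenario):
        # regression guard: diluting an informative set with noise genes must
        # stay within the CV noise band, not collapse the AUC
        data = small_scenario.expression
        noise_feats = sorted(set(data.genes) - small_scenario.de_genes)[:30]
        pure = evaluate_features(data, small_scenario.de_genes, n_repetitions=5, n_folds=5, seed=2)
        diluted = evaluate_features(
            data, set(small_scenario.de_genes) | set(noise_feats), n_repetitions=5, n_folds=5, seed=2
        )
        assert abs(pure.mean_auc - diluted.mean_auc) < 0.1

    def test_svm_classifier_accepted(self, separable_dataset):
        res = evaluate_features(
            separable_dataset, {"perfect"}, classifier="svm", n_repetitions=2, n_folds=5, seed=0
        )
        assert res.mean_auc == 1.0

    def test_unknown_classifier_rejected(self, separable_dataset):
        with pytest.raises(ValueError, match="classifier"):
            evaluate_features(separable_dataset, {"perfect"}, classifier="forest", n_folds=5)


class TestAucRankInvariance:
    @given(st.lists(st.integers(-10**6, 10**6), min_size=6, max_size=30, unique=True), st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_transform_preserves_auc(self, scores, data):
        y = data.draw(
            st.lists(st.integers(0, 1), min_size=len(scores), max_size=len(scores)).filter(
                lambda ls: 0 < sum(ls) < len(ls)
            )
        )
        s = np.asarray(scores, dtype=float) / 1000.0  # spacing keeps the transform injective
        a1 = roc_auc_score(y, s)
        a2 = roc_auc_score(y, np.exp(s / 25.0))  # strictly monotone transform
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestPairedRunComparison:
    def test_identical_runs_degenerate(self):
        a = make_result([0.7, 0.8, 0.75])
        wins, p = paired_run_comparison(a, a)
        assert wins == 0
        assert p == 1.0

    def test_constant_shift_wins_everywhere(self):
        rng = np.random.default_rng(1)
        base = 0.6 + 0.05 * rng.standard_normal(100)
        a = make_result(base + 0.01)
        b = make_result(base)
        wins, p = paired_run_comparison(a, b)
        assert wins == 100
        assert p < 1e-10

    def test_mismatched_lengths_error(self):
        with pytest.raises(ValueError):
            paired_run_comparison(make_result([0.5, 0.6]), make_result([0.5, 0.6, 0.7]))

    def test_type_one_error_rate_under_null(self):
        rng = np.random.default_rng(12)
        rejections = 0
        n_pairs = 1000
        for _ in range(n_pairs):
            a = make_result(0.5 + 0.05 * rng.standard_normal(20))
            b = make_result(0.5 + 0.05 * rng.standard_normal(20))
            _, p = paired_run_comparison(a, b)
            rejections += p < 0.05
        assert rejections / n_pairs <= 0.07


class TestKnownMarkerCoverage:
    def test_superset_covers_everything(self):
        cov = known_marker_coverage({"a", "b", "c", "d"}, {"a", "b"}, N=100)
        assert cov.coverage_percent == 100.0
        assert cov.n_covered == 2

    def test_disjoint_sets_are_null(self):
        cov = known_marker_coverage({"a", "b"}, {"x", "y"}, N=100)
        assert cov.coverage_percent == 0.0
        assert cov.overlap.p_value == 1.0

    def test_planted_fixture_counts(self, small_scenario):
        known = set(list(small_scenario.planted_connectors)[:4]) | {"zzz1", "zzz2"}
        stms = set(small_scenario.planted_connectors)
        cov = known_marker_coverage(stms, known, N=small_scenario.network.number_of_nodes())
        assert cov.n_covered == 4
        assert cov.coverage_percent == pytest.approx(100 * 4 / 6)

    def test_empty_known_list_errors(self):
        with pytest.raises(ValueError):
            known_marker_coverage({"a"}, set(), N=10)


class TestExpressionDataset:
    def test_tsv_round_trip(self, tmp_path):
        data = generate_expression([f"g{i}" for i in range(5)], ["g0"], n_samples=20, seed=0)
        e, l = tmp_path / "expr.tsv", tmp_path / "labels.tsv"
        data.to_tsv(e, l)
        again = ExpressionDataset.from_tsv(e, l)
        assert again.genes == data.genes
        assert again.samples == data.samples
        assert np.allclose(again.values.to_numpy(), data.values.to_numpy())
        assert (again.labels == data.labels).all()

    def test_single_class_rejected(self):
        values = pd.DataFrame(np.zeros((2, 4)), index=["a", "b"], columns=list("wxyz"))
        labels = pd.Series([1, 1, 1, 1], index=list("wxyz"))
        with pytest.raises(ValueError, match="both outcome classes"):
            ExpressionDataset(values=values, labels=labels)
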
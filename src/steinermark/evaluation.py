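"""Classification evaluation of marker gene sets and known-marker coverage.

Feature sets (STMs, DE genes, their union) are scored by repeated stratified
k-fold cross-validation of a logistic-regression or linear-SVM classifier on
a two-class expression matrix; performance is AUC on the pooled out-of-fold
decision scores of each repetition. In cross-dataset use the feature set is
selected on one cohort and the cross-validation runs entirely within the
other cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.svm import SVC

from .overlap_stats import OverlapResult, overlap_result

PathLike = Union[str, Path]

CLASSIFIERS = ("logistic", "svm")


@dataclass
class ExpressionDataset:
    """Genes-by-samples expression matrix with a binary outcome per sample.

    ``values`` is a DataFrame indexed by gene identifier with one column per
    sample; ``labels`` is a 0/1 Series over the same samples (1 = event, e.g.
    metastasis within five years).
    """

    values: pd.DataFrame
    labels: pd.Series

    def __post_init__(self):
        if list(self.values.columns) != list(self.labels.index):
            raise ValueError("label index must match the sample columns of the matrix")
        uniq = set(pd.unique(self.labels))
        if not uniq <= {0, 1}:
            raise ValueError(f"labels must be 0/1, got {sorted(uniq)}")
        if len(uniq) < 2:
            raise ValueError("both outcome classes must be present")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene identifiers in expression matrix")

    @property
    def genes(self) -> list:
        return list(self.values.index)

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    @classmethod
    def from_tsv(cls, expression_path: PathLike, labels_path: PathLike) -> "ExpressionDataset":
        """Read a TSV matrix (first column gene ID, header of sample IDs) and a
        two-column (sample, label) TSV."""
        values = pd.read_csv(expression_path, sep="\t", index_col=0)
        lab = pd.read_csv(labels_path, sep="\t", index_col=0, header=None).iloc[:, 0]
        lab.index = lab.index.astype(str)
        values.columns = values.columns.astype(str)
        missing = [s for s in values.columns if s not in lab.index]
        if missing:
            raise ValueError(f"samples without labels: {missing[:5]}")
        return cls(values=values, labels=lab.loc[values.columns].astype(int))

    def to_tsv(self, expression_path: PathLike, labels_path: PathLike) -> None:
        self.values.to_csv(expression_path, sep="\t")
        self.labels.to_csv(labels_path, sep="\t", header=False)


@dataclass(frozen=True)
class ClassificationResult:
    auc_runs: tuple
    mean_auc: float
    n_repetitions: int
    n_folds: int
    classifier: str
    features_used: frozenset
    features_missing: frozenset

    def __post_init__(self):
        if len(self.auc_runs) != self.n_repetitions:
            raise ValueError("one AUC per repetition required")


def _make_classifier(name: str):
    if name == "logistic":
        # default regularization, generous iteration cap for convergence only
        return LogisticRegression(max_iter=5000)
    if name == "svm":
        return SVC(kernel="linear")
    raise ValueError(f"classifier must be one of {CLASSIFIERS}, got {name!r}")


def evaluate_features(
    data: ExpressionDataset,
    features: Iterable[str],
    classifier: str = "logistic",
    n_repetitions: int = 100,
    n_folds: int = 10,
    seed: int = 0,
) -> ClassificationResult:
    """Repeated stratified k-fold CV AUC of one feature set on one dataset.

    The matrix is restricted to the features present in the data (the rest are
    recorded in ``features_missing``). Each repetition reshuffles the
    stratified fold assignment from a seed-derived stream, fits the classifier
    with default hyperparameters on each training split, and pools the
    out-of-fold decision scores into a single AUC.
    """
    feats = frozenset(features)
    present = [g for g in data.genes if g in feats]
    if not present:
        raise ValueError("no feature maps to the expression matrix")
    missing = feats - set(present)
    y = data.labels.to_numpy()
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_folds:
        raise ValueError(
            f"each class needs >= n_folds={n_folds} samples, got class counts {counts.tolist()}"
        )
    X = data.values.loc[present].to_numpy().T
    rng = np.random.default_rng(np.random.SeedSequence([seed, 915]))
    fold_seeds = rng.integers(0, 2**31 - 1, size=n_repetitions)
    aucs = []
    for rs in fold_seeds:
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(rs))
        scores = cross_val_predict(_make_classifier(classifier), X, y, cv=cv, method="decision_function")
        aucs.append(float(roc_auc_score(y, scores)))
    return ClassificationResult(
        auc_runs=tuple(aucs),
        mean_auc=float(np.mean(aucs)),
        n_repetitions=n_repetitions,
        n_folds=n_folds,
        classifier=classifier,
        features_used=frozenset(present),
        features_missing=missing,
    )


def paired_run_comparison(a: ClassificationResult, b: ClassificationResult) -> tuple:
    """Per-run wins of ``a`` over ``b`` and a paired t-test on the AUC differences.

    Runs must be index-matched (same repetition count and fold seeds). Ties
    count as non-wins. A zero-variance difference vector is degenerate for the
    t statistic: p is reported as 1.0 when the mean difference is also zero,
    and 0.0 otherwise (the limit of the test as the variance vanishes).
    """
    if a.n_repetitions != b.n_repetitions:
        raise ValueError("results have different numbers of repetitions")
    xa = np.asarray(a.auc_runs)
    xb = np.asarray(b.auc_runs)
    wins_a = int(np.sum(xa > xb))
    diff = xa - xb
    if np.allclose(diff.std(), 0.0):
        p = 1.0 if np.allclose(diff.mean(), 0.0) else 0.0
    else:
        p = float(stats.ttest_rel(xa, xb).pvalue)
    return wins_a, p


@dataclass(frozen=True)
class MarkerCoverage:
    """Fraction of a known-marker list recovered by a candidate set, with significance."""

    n_known: int
    n_covered: int
    coverage_percent: float
    overlap: OverlapResult


def known_marker_coverage(stms: Iterable[str], known: Iterable[str], N: int) -> MarkerCoverage:
    """Coverage of a curated marker list by the STM set against background N."""
    stm_set = frozenset(stms)
    known_set = frozenset(known)
    if not known_set:
        raise ValueError("known-marker list is empty")
    covered = stm_set & known_set
    ov = overlap_result(N, len(stm_set), len(known_set), len(covered))
    return MarkerCoverage(
        n_known=len(known_set),
        n_covered=len(covered),
        coverage_percent=100.0 * len(covered) / len(known_set),
        overlap=ov,
    )
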
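"""Cohort-level statistics and classification.

Two-sample comparisons of per-cell quantities (droplet volume, dry mass,
birefringent volume, ...) use the two-sided Wilcoxon rank-sum test: exact
by enumeration of all rank assignments for small pooled samples (total
n <= 12 by default, where enumeration is cheap and handles ties by
midranks), and the tie-corrected normal approximation otherwise.

Classification emulates the birefringence-based separation of healthy and
cancer cohorts: per-cell feature vectors (quantification fields and/or
birefringence-histogram bin counts) are z-scored, projected on the top
principal components, and classified with a linear discriminant under
leave-one-out cross-validation.  A nearest-centroid alternative is
provided.  PC signs follow the convention that the largest-|loading|
element of each component is positive, making reports reproducible under
feature reordering up to column permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import NearestCentroid

from .birefringence import BirefringenceHistogram
from .segment_quantify import LDQuantification

__all__ = [
    "CohortTable",
    "ClassificationReport",
    "wilcoxon_rank_sum",
    "build_features",
    "pca_classify",
]


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact p by full enumeration of rank assignments.

    Midranks handle ties, so the null distribution is computed on the
    observed pooled multiset itself (a permutation test on the rank-sum
    statistic).
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n, na = len(pooled), len(a)
    w_obs = ranks[:na].sum()
    mu = na * (n + 1) / 2.0
    dev = abs(w_obs - mu)
    total = comb(n, na)
    hits = 0
    for idx in combinations(range(n), na):
        if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-9:
            hits += 1
    return hits / total


def wilcoxon_rank_sum(
    a: Sequence[float],
    b: Sequence[float],
    mode: str = "auto",
    exact_cutoff: int = 12,
) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    ``mode``: 'exact' enumerates all rank assignments; 'approx' uses the
    tie-corrected normal approximation; 'auto' picks exact when the pooled
    sample size is at most ``exact_cutoff``.  Degenerate all-tied input
    yields p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all observations tied: rank-sum test degenerate, p = 1")
        return 1.0
    if mode not in ("auto", "exact", "approx"):
        raise ValueError("mode must be 'auto', 'exact' or 'approx'")
    if mode == "exact" or (mode == "auto" and len(pooled) <= exact_cutoff):
        return _exact_rank_sum_p(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortTable:
    """Rectangular per-cell feature matrix with labels and provenance."""

    features: pd.DataFrame  # rows = cells, z-scored columns
    labels: pd.Series
    raw: pd.DataFrame  # pre-standardization values

    def __post_init__(self):
        if self.labels.isna().any():
            raise ValueError("missing labels")
        if len(self.features) != len(self.labels):
            raise ValueError("labels must match the feature rows")


def build_features(
    cells: Sequence[Tuple[LDQuantification, Optional[BirefringenceHistogram]]],
    labels: Sequence[str],
    feature_set: Sequence[str] = ("quant", "histogram"),
    cell_ids: Optional[Sequence[str]] = None,
) -> CohortTable:
    """Standardized (z-scored) per-cell feature matrix.

    ``feature_set`` may include 'quant' (the quantification fields) and/or
    'histogram' (birefringence-histogram bin counts; binning must be
    consistent across cells).  Constant columns are left at zero.
    """
    if len(cells) != len(labels):
        raise ValueError("one label per cell required")
    rows: List[Dict[str, float]] = []
    ref_edges = None
    for quant, hist in cells:
        row: Dict[str, float] = {}
        if "quant" in feature_set:
            row.update(quant.as_dict())
        if "histogram" in feature_set:
            if hist is None:
                raise ValueError("histogram features requested but a cell has no histogram")
            if ref_edges is None:
                ref_edges = hist.edges
            elif not np.array_equal(ref_edges, hist.edges):
                raise ValueError("inconsistent histogram binning across cells")
            for i, c in enumerate(hist.counts):
                row[f"biref_bin_{i:03d}"] = float(c)
        rows.append(row)
    if not rows or not rows[0]:
        raise ValueError("empty feature set")
    raw = pd.DataFrame(rows, index=cell_ids)
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0, ddof=0)
    z = (raw - mean).div(sd.where(sd > 0, 1.0), axis=1)
    return CohortTable(features=z, labels=pd.Series(list(labels), index=raw.index), raw=raw)


# ---------------------------------------------------------------------------
# PCA + classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassificationReport:
    scores: np.ndarray  # (cells, k) PC scores from the full-data fit
    loadings: np.ndarray  # (k, features)
    explained_variance_ratio: np.ndarray
    accuracy: float
    confusion: pd.DataFrame  # rows = true label, cols = predicted
    classifier: str

    def __post_init__(self):
        if not (0.0 <= self.accuracy <= 1.0):
            raise ValueError("accuracy must lie in [0, 1]")
        if self.explained_variance_ratio.sum() > 1.0 + 1e-9:
            raise ValueError("explained-variance fractions must sum to <= 1")


def _fix_signs(components: np.ndarray, scores: np.ndarray):
    for i in range(components.shape[0]):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] *= -1
            scores[:, i] *= -1
    return components, scores


def pca_classify(
    table: CohortTable,
    k: int = 2,
    seed: int = 0,
    classifier: str = "lda",
) -> ClassificationReport:
    """PCA on the standardized features, then a linear classifier on the
    top-``k`` PC scores with leave-one-out cross-validation.

    Deterministic given the input row order (the seed only feeds solvers
    that would otherwise randomize; the default solvers are deterministic).
    """
    X = table.features.to_numpy(dtype=float)
    y = table.labels.to_numpy()
    classes = np.unique(y)
    if len(X) < 4:
        raise ValueError("need at least 4 cells")
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    if k > rank:
        warnings.warn(f"k={k} exceeds feature rank {rank}; reduced")
        k = max(rank, 1)

    def make_clf():
        if classifier == "lda":
            # uniform priors: with frequency priors, leave-one-out makes the
            # held-out class the training minority, so an uninformative
            # discriminant systematically predicts the wrong class
            return LinearDiscriminantAnalysis(priors=np.full(2, 0.5))
        if classifier == "nearest_centroid":
            return NearestCentroid()
        raise ValueError("classifier must be 'lda' or 'nearest_centroid'")

    # leave-one-out: PCA and classifier are refit without the held-out cell
    preds = []
    for i in range(len(X)):
        train = np.ones(len(X), dtype=bool)
        train[i] = False
        if len(np.unique(y[train])) < 2:
            raise ValueError("a class has a single member; LOO undefined")
        pca = PCA(n_components=k, svd_solver="full", random_state=seed)
        s_train = pca.fit_transform(X[train])
        clf = make_clf().fit(s_train, y[train])
        preds.append(clf.predict(pca.transform(X[i : i + 1]))[0])
    preds = np.asarray(preds)
    accuracy = float(np.mean(preds == y))
    confusion = pd.DataFrame(
        [[int(np.sum((y == t) & (preds == p))) for p in classes] for t in classes],
        index=classes,
        columns=classes,
    )

    pca = PCA(n_components=k, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(X)
    components, scores = _fix_signs(pca.components_.copy(), scores)
    return ClassificationReport(
        scores=scores,
        loadings=components,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        accuracy=accuracy,
        confusion=confusion,
        classifier=classifier,
    )


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment for a family of comparisons."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj
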
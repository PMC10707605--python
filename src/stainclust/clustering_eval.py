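"""Internal cluster-validity indices, optimum selection and vote aggregation.

Because the clustering is unsupervised, the number of clusters is chosen
by *internal* validation: score a clustering from the data alone, for
every candidate cluster count, with six classical indices —

* Xie-Beni (lower better): within-cluster compactness over minimal
  centroid separation;
* Calinski-Harabasz (higher better): ratio of between- to
  within-cluster scatter, each scaled by its degrees of freedom;
* C index (lower better, in [0, 1]): within-cluster pair-distance sum
  ranked against the best and worst possible sums of as many pairs;
* Hartigan (higher better): log of the between/within sum-of-squares
  ratio;
* Dunn (higher better): smallest between-cluster point distance over
  largest within-cluster point distance;
* McClain-Rao (lower better): mean within-cluster over mean
  between-cluster pair distance.

Each index nominates an optimum per dataset; the final cluster count is
the mode of those nominations across all index x dataset columns.

All indices use Euclidean distance; a centroid is the arithmetic mean
of its member points. Every index raises on K < 2 or an empty cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

__all__ = [
    "ClusteredPoints",
    "ValidityTable",
    "INDEX_DIRECTIONS",
    "xie_beni",
    "calinski_harabasz",
    "c_index",
    "hartigan",
    "dunn",
    "mclain_rao",
    "validity_scores",
    "select_optimal",
    "vote",
    "agreement",
    "reference_table",
]

#: Optimization direction of each index.
INDEX_DIRECTIONS: dict[str, str] = {
    "xie_beni": "min",
    "calinski_harabasz": "max",
    "c_index": "min",
    "hartigan": "max",
    "dunn": "max",
    "mclain_rao": "min",
}


@dataclass
class ClusteredPoints:
    """An (N, D) feature matrix with hard labels and optional soft assignments."""

    X: np.ndarray
    labels: np.ndarray
    soft: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be (N, D)")
        if len(self.labels) != len(self.X):
            raise ValueError("labels and X lengths differ")
        k = self.n_clusters
        if k < 2:
            raise ValueError("need at least 2 clusters")
        counts = np.bincount(self.labels, minlength=k)
        if (counts == 0).any():
            raise ValueError(f"empty cluster(s): {np.flatnonzero(counts == 0).tolist()}")

    @property
    def n_clusters(self) -> int:
        if len(self.labels) == 0:
            raise ValueError("no points")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        return int(self.labels.max()) + 1

    def centroids(self) -> np.ndarray:
        k = self.n_clusters
        return np.stack([self.X[self.labels == i].mean(axis=0) for i in range(k)])


def _scatter(cp: ClusteredPoints) -> tuple[float, float]:
    """(between, within) sums of squares around centroids / grand mean."""
    v = cp.centroids()
    grand = cp.X.mean(axis=0)
    counts = np.bincount(cp.labels, minlength=cp.n_clusters)
    ssb = float((counts * ((v - grand) ** 2).sum(axis=1)).sum())
    ssw = float(((cp.X - v[cp.labels]) ** 2).sum())
    return ssb, ssw


def _pair_masks(cp: ClusteredPoints) -> tuple[np.ndarray, np.ndarray]:
    """Condensed pairwise distances and the within-cluster pair mask."""
    d = pdist(cp.X)
    eq = cp.labels[:, None] == cp.labels[None, :]
    same = squareform(eq, checks=False).astype(bool)
    return d, same


def xie_beni(cp: ClusteredPoints, use_soft: bool = False) -> float:
    """Compactness over minimal squared centroid separation (lower better).

    The crisp form divides the within-cluster sum of squared distances
    by N times the smallest squared distance between two centroids.
    With ``use_soft`` and soft assignments present, the fuzzy form
    weights each point-centroid term by its squared membership.
    """
    v = cp.centroids()
    sep = pdist(v) ** 2
    if sep.min() <= 0:
        raise ValueError("coincident centroids: zero separation")
    n = len(cp.X)
    if use_soft:
        if cp.soft is None:
            raise ValueError("no soft assignments available")
        u2 = np.asarray(cp.soft, dtype=float) ** 2  # (N, K)
        d2 = ((cp.X[:, None, :] - v[None, :, :]) ** 2).sum(axis=2)  # (N, K)
        compact = float((u2 * d2).sum())
    else:
        compact = float(((cp.X - v[cp.labels]) ** 2).sum())
    return compact / (n * float(sep.min()))


def calinski_harabasz(cp: ClusteredPoints) -> float:
    """Between/within scatter ratio scaled by degrees of freedom (higher better)."""
    ssb, ssw = _scatter(cp)
    n, k = len(cp.X), cp.n_clusters
    if ssw <= 0:
        raise ValueError("zero within-cluster scatter")
    if n <= k:
        raise ValueError("need more points than clusters")
    return (ssb / (k - 1)) / (ssw / (n - k))


def c_index(cp: ClusteredPoints) -> float:
    """Normalized within-cluster pair-distance sum, in [0, 1] (lower better)."""
    d, same = _pair_masks(cp)
    n_w = int(same.sum())
    if n_w == 0:
        raise ValueError("no within-cluster pairs (all clusters singletons)")
    s = float(d[same].sum())
    d_sorted = np.sort(d)
    s_min = float(d_sorted[:n_w].sum())
    s_max = float(d_sorted[-n_w:].sum())
    if s_max == s_min:
        raise ValueError("degenerate distances: all pairs equal")
    return (s - s_min) / (s_max - s_min)


def hartigan(cp: ClusteredPoints) -> float:
    """Natural log of the between/within sum-of-squares ratio (higher better)."""
    ssb, ssw = _scatter(cp)
    if ssw <= 0:
        raise ValueError("zero within-cluster scatter")
    if ssb <= 0:
        raise ValueError("zero between-cluster scatter")
    return float(np.log(ssb / ssw))


def dunn(cp: ClusteredPoints) -> float:
    """Min between-cluster point distance over max within-cluster one (higher better)."""
    d, same = _pair_masks(cp)
    if not same.any():
        raise ValueError("no within-cluster pairs (all clusters singletons)")
    max_intra = float(d[same].max())
    if max_intra == 0:
        raise ValueError("zero within-cluster diameter")
    return float(d[~same].min()) / max_intra


def mclain_rao(cp: ClusteredPoints) -> float:
    """Mean within-cluster over mean between-cluster pair distance (lower better)."""
    d, same = _pair_masks(cp)
    if not same.any() or same.all():
        raise ValueError("need both within- and between-cluster pairs")
    return float(d[same].mean()) / float(d[~same].mean())


_INDEX_FUNCS = {
    "xie_beni": xie_beni,
    "calinski_harabasz": calinski_harabasz,
    "c_index": c_index,
    "hartigan": hartigan,
    "dunn": dunn,
    "mclain_rao": mclain_rao,
}


def validity_scores(
    X: np.ndarray,
    labels: np.ndarray,
    soft: np.ndarray | None = None,
    subsample: int | None = None,
    seed: int = 0,
) -> dict[str, float]:
    """All six indices for one clustering; optionally on a recorded subsample."""
    X = np.asarray(X)
    labels = np.asarray(labels)
    if subsample is not None and subsample < len(X):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(X), size=subsample, replace=False)
        X, labels = X[idx], labels[idx]
        soft = soft[idx] if soft is not None else None
    cp = ClusteredPoints(X, labels, soft)
    return {name: fn(cp) for name, fn in _INDEX_FUNCS.items()}


@dataclass
class ValidityTable:
    """(cluster count, index:dataset) score grid with per-index directions.

    Columns are named ``<index>`` or ``<index>:<dataset tag>``; the part
    before the colon must be one of the six index names, which fixes the
    column's optimization direction.
    """

    df: pd.DataFrame

    def __post_init__(self):
        for col in self.df.columns:
            if self._index_name(col) not in INDEX_DIRECTIONS:
                raise ValueError(f"unknown index in column {col!r}")

    @staticmethod
    def _index_name(col: str) -> str:
        return str(col).split(":")[0]

    def direction(self, col: str) -> str:
        return INDEX_DIRECTIONS[self._index_name(col)]

    @classmethod
    def from_scores(cls, scores: dict[int, dict[str, float]], tag: str | None = None) -> "ValidityTable":
        """Build from {cluster_count: {index: score}} for one dataset."""
        df = pd.DataFrame(scores).T.sort_index()
        if tag:
            df.columns = [f"{c}:{tag}" for c in df.columns]
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index_label="n_clusters")

    @classmethod
    def read_csv(cls, path: str | Path) -> "ValidityTable":
        return cls(pd.read_csv(path, index_col="n_clusters"))

    def join(self, other: "ValidityTable") -> "ValidityTable":
        return ValidityTable(self.df.join(other.df))


def select_optimal(table: ValidityTable) -> pd.DataFrame:
    """Per-column optimal cluster count (argmin or argmax by direction).

    Ties go to the smallest cluster count and are flagged in the
    ``tied`` column.
    """
    rows = []
    for col in table.df.columns:
        s = table.df[col].dropna()
        if s.empty:
            raise ValueError(f"column {col!r} has no scores")
        best = s.min() if table.direction(col) == "min" else s.max()
        hits = s.index[s == best]
        rows.append(
            {
                "column": col,
                "optimum": int(hits.min()),
                "direction": table.direction(col),
                "tied": len(hits) > 1,
            }
        )
    return pd.DataFrame(rows).set_index("column")


def vote(optima: pd.DataFrame) -> tuple[int, dict[int, int]]:
    """Modal cluster count across columns, plus the full vote histogram.

    Ties in the mode go to the smallest cluster count; callers can see
    the tie in the returned histogram.
    """
    counts = optima["optimum"].value_counts().to_dict()
    counts = {int(k): int(v) for k, v in counts.items()}
    top = max(counts.values())
    mode = min(k for k, v in counts.items() if v == top)
    return mode, counts


def agreement(labels: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """Adjusted Rand index and normalized mutual information against truth."""
    return (
        float(adjusted_rand_score(truth, labels)),
        float(normalized_mutual_info_score(truth, labels)),
    )


def reference_table() -> ValidityTable:
    """The published index grid for cluster counts 8-18 on the two patch sizes.

    Shipped as package data; used to exercise the selection and vote
    logic against a known outcome (the 14-cluster mode).
    """
    with resources.files("stainclust.data").joinpath("reference_validity_table.csv").open() as f:
        return ValidityTable(pd.read_csv(f, index_col="n_clusters"))
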
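"""Fold-change binning, one-vs-all confusion metrics, spherical k-means and
the adjusted Rand index.

Signed fold changes are binned into seven levels {-4, -2, -1.5, 0, +1.5, +2,
+4} whose boundaries partition the signed line as (-inf,-3.0], (-3.0,-2.0],
(-2.0,-1.5], (-1.5,+1.5), [+1.5,+2.0), [+2.0,+3.0), [+3.0,inf).  Method
performance is scored one level vs the rest (sensitivity, specificity,
precision) plus multiclass overall accuracy; agreement of a clustering with
the design assignment is measured by the adjusted Rand index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from .diffexpr import GroupDesign
from .normalization import NormalizedMatrix

__all__ = [
    "BIN_LEVELS",
    "ConfusionCounts",
    "PerformanceTable",
    "Partition",
    "bin_signed_fc",
    "one_vs_all_metrics",
    "log_ratio_profiles",
    "kmeans_cosine",
    "adjusted_rand_index",
]

#: the seven bin levels in increasing order of the underlying fold change
BIN_LEVELS = (-4.0, -2.0, -1.5, 0.0, 1.5, 2.0, 4.0)

# breakpoints between consecutive levels; side encodes which bin owns each
_BREAKS = (-3.0, -2.0, -1.5, 1.5, 2.0, 3.0)


def bin_signed_fc(fc):
    """Map signed fold change(s) to their bin level.

    Negative breakpoints close on the right ((-3,-2] -> -2, etc.), positive
    breakpoints close on the left ([+1.5,+2) -> +1.5), so every finite value
    lands in exactly one bin.
    """
    arr = np.asarray(fc, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("NaN fold change cannot be binned")
    conditions = [
        arr <= -3.0,
        (arr > -3.0) & (arr <= -2.0),
        (arr > -2.0) & (arr <= -1.5),
        (arr > -1.5) & (arr < 1.5),
        (arr >= 1.5) & (arr < 2.0),
        (arr >= 2.0) & (arr < 3.0),
        arr >= 3.0,
    ]
    out = np.select(conditions, BIN_LEVELS)
    if np.isscalar(fc) or arr.ndim == 0:
        return float(out)
    if isinstance(fc, pd.Series):
        return pd.Series(out, index=fc.index)
    return out


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-all confusion counts for a single bin level."""

    level: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class PerformanceTable:
    """Per-level one-vs-all metrics plus overall accuracy for one method.

    ``table`` is indexed by bin level with columns sensitivity, specificity,
    precision, tp, fp, tn, fn.  Undefined ratios (zero denominators) are NaN.
    """

    method: str
    table: pd.DataFrame
    overall_accuracy: float

    def counts(self, level: float) -> ConfusionCounts:
        row = self.table.loc[level]
        return ConfusionCounts(
            level, int(row["tp"]), int(row["fp"]), int(row["tn"]), int(row["fn"])
        )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def one_vs_all_metrics(
    true_bins: pd.Series,
    predicted_bins: pd.Series,
    method: str = "",
    levels=BIN_LEVELS,
    accuracy: str = "multiclass",
) -> PerformanceTable:
    """Score predicted vs true bin levels, one level against all others.

    Per level: sensitivity = TP/(TP+FN), specificity = TN/(FP+TN), precision
    = TP/(TP+FP); zero denominators yield NaN.  Overall accuracy is the
    multiclass proportion correct by default; ``accuracy='binary_aggregate'``
    instead pools TP/TN/FP/FN over all levels (the literal binary formula).
    """
    t = pd.Series(true_bins)
    p = pd.Series(predicted_bins)
    if set(t.index) != set(p.index):
        raise ValueError("true and predicted bins cover different gene sets")
    p = p.reindex(t.index)
    n = len(t)
    rows = {}
    agg = dict(tp=0, tn=0, fp=0, fn=0)
    for level in levels:
        tp = int(((t == level) & (p == level)).sum())
        fn = int(((t == level) & (p != level)).sum())
        fp = int(((t != level) & (p == level)).sum())
        tn = n - tp - fn - fp
        rows[level] = {
            "sensitivity": _ratio(tp, tp + fn),
            "specificity": _ratio(tn, fp + tn),
            "precision": _ratio(tp, tp + fp),
            "tp": tp,
            "fp": fp,
            "tn": tn,
            "fn": fn,
        }
        agg["tp"] += tp
        agg["tn"] += tn
        agg["fp"] += fp
        agg["fn"] += fn
    if accuracy == "multiclass":
        overall = float((t.to_numpy() == p.to_numpy()).mean())
    elif accuracy == "binary_aggregate":
        overall = (agg["tp"] + agg["tn"]) / (agg["tp"] + agg["tn"] + agg["fp"] + agg["fn"])
    else:
        raise ValueError("accuracy must be 'multiclass' or 'binary_aggregate'")
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "level"
    return PerformanceTable(method=method, table=table, overall_accuracy=overall)


def log_ratio_profiles(
    norm: NormalizedMatrix | pd.DataFrame,
    design: GroupDesign,
    offset: float = 1.0,
) -> pd.DataFrame:
    """Per-gene log2 ratios of each treated sample to the untreated mean.

    out[g, t] = log2((x_gt + offset) / (mean over untreated of x_g. + offset))
    """
    if offset <= 0:
        raise ValueError("offset must be > 0")
    vals = norm.values if isinstance(norm, NormalizedMatrix) else pd.DataFrame(norm)
    unt = vals[design.members("untreated")]
    trt = vals[design.members("treated")]
    baseline = unt.mean(axis=1) + offset
    return np.log2(trt.add(offset).div(baseline, axis=0))


# ---------------------------------------------------------------------------
# clustering and agreement
# ---------------------------------------------------------------------------


@dataclass
class Partition:
    """A hard partition of objects into classes."""

    labels: pd.Series
    flagged: tuple = ()

    @property
    def n(self) -> int:
        return len(self.labels)

    @classmethod
    def from_labels(cls, labels, index=None) -> "Partition":
        if isinstance(labels, pd.Series):
            return cls(labels.copy())
        return cls(pd.Series(np.asarray(labels), index=index))


def _spherical_kmeans_once(
    X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100
) -> tuple[np.ndarray, float]:
    n = X.shape[0]
    # random-partition init: a balanced random assignment so no cluster starts empty
    labels = rng.permutation(np.arange(n) % k)
    for _ in range(max_iter):
        centroids = np.zeros((k, X.shape[1]))
        for j in range(k):
            members = labels == j
            if members.any():
                centroids[j] = X[members].mean(axis=0)
        norms = np.linalg.norm(centroids, axis=1)
        degenerate = norms == 0
        if degenerate.any():
            # re-seed collapsed centroids from the currently worst-fit points
            sims_tmp = X @ centroids[~degenerate].T if (~degenerate).any() else np.zeros((n, 1))
            worst = np.argsort(sims_tmp.max(axis=1))
            for idx, j in zip(worst, np.flatnonzero(degenerate)):
                centroids[j] = X[idx]
            norms = np.linalg.norm(centroids, axis=1)
        centroids /= norms[:, None]
        sims = X @ centroids.T
        new_labels = np.argmax(sims, axis=1)
        # an empty cluster is re-seeded from the farthest (least similar) point
        for j in range(k):
            if not (new_labels == j).any():
                far = int(np.argmin(sims[np.arange(n), new_labels]))
                new_labels[far] = j
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    objective = float(np.sum(1.0 - sims[np.arange(n), labels]))
    return labels, objective


def kmeans_cosine(
    profiles: pd.DataFrame,
    k: int,
    n_restarts: int = 50,
    seed: int = 0,
) -> Partition:
    """Spherical k-means under cosine dissimilarity, best of ``n_restarts``.

    Rows are scaled to unit length and clustered with centroid-based k-means
    on the unit sphere; the restart with the lowest total cosine
    dissimilarity wins.  Zero-norm rows cannot be placed on the sphere; they
    are assigned to the centroid nearest the zero vector in Euclidean
    distance (all unit centroids tie, broken by lowest index) and flagged.
    """
    df = pd.DataFrame(profiles)
    X = df.to_numpy(dtype=float)
    norms = np.linalg.norm(X, axis=1)
    nonzero = norms > 0
    Xu = X[nonzero] / norms[nonzero, None]
    n_distinct = np.unique(np.round(Xu, 12), axis=0).shape[0] if Xu.size else 0
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_distinct:
        raise ValueError(
            f"k={k} exceeds the {n_distinct} distinct non-zero profiles"
        )
    rng = np.random.default_rng(seed)
    best_labels, best_obj = None, np.inf
    for _ in range(n_restarts):
        labels, obj = _spherical_kmeans_once(Xu, k, rng)
        if obj < best_obj - 1e-12:
            best_labels, best_obj = labels, obj
    full = np.zeros(len(df), dtype=int)
    full[nonzero] = best_labels
    # zero-norm rows: Euclidean distance from the origin to every unit
    # centroid is 1, so the tie-break lands on cluster 0
    full[~nonzero] = 0
    flagged = tuple(df.index[~nonzero])
    return Partition(pd.Series(full, index=df.index), flagged=flagged)


def adjusted_rand_index(u, v) -> float:
    """Chance-corrected pair-counting agreement between two partitions.

    With contingency counts n_ij (class i of u, class j of v), row/column
    sums n_i., n_.j and n objects:

        ARI = [sum_ij C(n_ij,2) - E] / [(a + b)/2 - E],
        a = sum_i C(n_i.,2), b = sum_j C(n_.j,2), E = a*b / C(n,2).

    1 for identical partitions; ~0 for chance agreement (can be negative).
    """
    lu = u.labels if isinstance(u, Partition) else pd.Series(u)
    lv = v.labels if isinstance(v, Partition) else pd.Series(v)
    if set(lu.index) != set(lv.index):
        raise ValueError("partitions cover different object sets")
    lv = lv.reindex(lu.index)
    n = len(lu)
    cont = pd.crosstab(lu.to_numpy(), lv.to_numpy()).to_numpy()
    sum_ij = sum(comb(int(x), 2) for x in cont.ravel())
    a = sum(comb(int(x), 2) for x in cont.sum(axis=1))
    b = sum(comb(int(x), 2) for x in cont.sum(axis=0))
    expected = a * b / comb(n, 2)
    max_index = (a + b) / 2.0
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))
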
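"""Seven between-sample normalizations for targeted RNA-seq count matrices.

Within-sample methods rescale each column directly: total counts (TC), counts
per million (CPM), per-sample median scaling, and quantile normalization.
Factor methods first compute a per-sample scaling factor — upper quartile
(UQ), weighted trimmed mean of M-values (TMM), and the median-of-ratios size
factor — and then adjust the library size before per-million scaling (UQ/TMM)
or divide by the size factor directly (median-of-ratios).

UQ and TMM factors are normalized to geometric mean 1 so that they are
depth-neutral; this convention is recorded in the ScalingFactors provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix

__all__ = [
    "ScalingFactors",
    "NormalizedMatrix",
    "normalize_total_count",
    "normalize_cpm",
    "normalize_median",
    "quantile_normalize",
    "upper_quartile_factors",
    "tmm_factors",
    "median_of_ratios_factors",
    "apply_factors",
    "log2_offset",
    "normalize",
    "METHODS",
]


@dataclass
class ScalingFactors:
    """Per-sample scaling factors and the effective library sizes they imply.

    For factor methods (uq, tmm): effective_library_sizes = library_sizes *
    factors, with factors geomean-1.  For median-of-ratios: the size factor
    itself is the effective size (counts are divided by it directly).
    """

    method: str
    factors: pd.Series
    effective_library_sizes: pd.Series

    def __post_init__(self) -> None:
        if (self.factors <= 0).any() or (self.effective_library_sizes <= 0).any():
            raise ValueError("scaling factors and effective sizes must be positive")


@dataclass
class NormalizedMatrix:
    """Genes × samples non-negative reals plus how they were produced."""

    values: pd.DataFrame
    method: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("normalized values must be finite and >= 0")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def _as_counts(counts: CountMatrix | pd.DataFrame) -> CountMatrix:
    if isinstance(counts, CountMatrix):
        return counts
    return CountMatrix(pd.DataFrame(counts))


def _geomean(x: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(x))))


# ---------------------------------------------------------------------------
# within-sample methods
# ---------------------------------------------------------------------------


def normalize_total_count(counts: CountMatrix | pd.DataFrame) -> NormalizedMatrix:
    """Divide each sample by its library size, multiply by the mean library size."""
    counts = _as_counts(counts)
    libs = counts.library_sizes
    zero = libs[libs == 0]
    if len(zero):
        raise ValueError(f"zero library size in sample {zero.index[0]!r}")
    out = counts.values / libs * libs.mean()
    return NormalizedMatrix(out, "tc", {"library_sizes": libs, "target": float(libs.mean())})


def normalize_cpm(
    counts: CountMatrix | pd.DataFrame,
    effective_sizes: pd.Series | None = None,
) -> NormalizedMatrix:
    """Counts per million: counts / (effective) library size * 1e6."""
    counts = _as_counts(counts)
    sizes = counts.library_sizes if effective_sizes is None else effective_sizes
    sizes = pd.Series(sizes).reindex(counts.sample_ids)
    if sizes.isna().any() or (sizes <= 0).any():
        bad = sizes.index[(sizes.isna()) | (sizes <= 0)][0]
        raise ValueError(f"non-positive library size in sample {bad!r}")
    out = counts.values / sizes * 1e6
    return NormalizedMatrix(out, "cpm", {"sizes": sizes})


def normalize_median(counts: CountMatrix | pd.DataFrame) -> NormalizedMatrix:
    """Divide each sample by the median of its gene counts, multiply by 1e6."""
    counts = _as_counts(counts)
    med = counts.values.median(axis=0)
    zero = med[med == 0]
    if len(zero):
        raise ValueError(f"zero median count in sample {zero.index[0]!r}")
    out = counts.values / med * 1e6
    return NormalizedMatrix(out, "median", {"medians": med})


def quantile_normalize(counts: CountMatrix | pd.DataFrame) -> NormalizedMatrix:
    """Force every sample onto the mean distribution of order statistics.

    The reference is the across-sample mean of sorted columns; each column's
    values are replaced by the reference value at their rank.  Tied entries in
    a column receive the arithmetic mean of the reference quantiles over their
    tied rank span, so after normalization all columns share the same
    multiset of values up to tie-averaging.
    """
    counts = _as_counts(counts)
    if counts.n_samples < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    X = counts.values.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(n_samples):
        order = np.argsort(X[:, j], kind="stable")
        col_sorted = X[order, j]
        assigned = reference.copy()
        # average the reference over runs of tied values
        start = 0
        for end in range(1, n_genes + 1):
            if end == n_genes or col_sorted[end] != col_sorted[start]:
                if end - start > 1:
                    assigned[start:end] = reference[start:end].mean()
                start = end
        out[order, j] = assigned
    df = pd.DataFrame(out, index=counts.gene_ids, columns=counts.sample_ids)
    return NormalizedMatrix(df, "quantile", {"reference": reference})


# ---------------------------------------------------------------------------
# factor methods
# ---------------------------------------------------------------------------


def upper_quartile_factors(counts: CountMatrix | pd.DataFrame) -> ScalingFactors:
    """Upper-quartile scaling factors, geomean-normalized.

    The 75th percentile (linear interpolation) of each sample's counts over
    genes expressed in at least one sample, divided by the library size;
    factors are rescaled to geometric mean 1.
    """
    counts = _as_counts(counts).drop_allzero_genes()
    libs = counts.library_sizes.to_numpy(dtype=float)
    q75 = np.quantile(counts.values.to_numpy(dtype=float), 0.75, axis=0)
    if np.any(q75 == 0):
        bad = counts.sample_ids[np.argmax(q75 == 0)]
        raise ValueError(f"zero upper quartile in sample {bad!r}")
    raw = q75 / libs
    factors = raw / _geomean(raw)
    f = pd.Series(factors, index=counts.sample_ids)
    return ScalingFactors("uq", f, pd.Series(libs, index=counts.sample_ids) * f)


def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float) -> float:
    """Weighted TMM factor of one sample against the reference (log2 -> 2**f).

    Doubly trimmed: 30% two-sided on M (log ratios) and 5% two-sided on A
    (average log abundance); weights are inverse delta-method variances.
    """
    keep = (obs > 0) & (ref > 0)
    o = obs[keep] / n_obs
    r = ref[keep] / n_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    var = (n_obs - obs[keep]) / (n_obs * obs[keep]) + (n_ref - ref[keep]) / (n_ref * ref[keep])

    n = m.size
    if n == 0:
        raise ValueError("degenerate trim: no genes shared with the reference")
    # rank-based two-sided trim, ties get average ranks
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    lo_m = np.floor(n * 0.30) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * 0.05) + 1
    hi_a = n + 1 - lo_a
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        raise ValueError("degenerate trim: no genes survive trimming")
    w = 1.0 / var[keep2]
    f = np.sum(w * m[keep2]) / np.sum(w)
    return float(2.0**f)


def tmm_factors(counts: CountMatrix | pd.DataFrame) -> ScalingFactors:
    """Weighted trimmed-mean-of-M-values scaling factors, geomean-normalized.

    The reference sample is the one whose upper-quartile/library-size ratio is
    closest to the mean of that ratio over samples.
    """
    counts = _as_counts(counts).drop_allzero_genes()
    if counts.n_samples < 2:
        raise ValueError("TMM needs >= 2 samples")
    X = counts.values.to_numpy(dtype=float)
    libs = counts.library_sizes.to_numpy(dtype=float)
    f75 = np.quantile(X, 0.75, axis=0) / libs
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.empty(counts.n_samples)
    for j in range(counts.n_samples):
        if j == ref_idx:
            factors[j] = 1.0
        else:
            factors[j] = _tmm_pair_factor(X[:, j], X[:, ref_idx], libs[j], libs[ref_idx])
    factors = factors / _geomean(factors)
    f = pd.Series(factors, index=counts.sample_ids)
    return ScalingFactors("tmm", f, pd.Series(libs, index=counts.sample_ids) * f)


def median_of_ratios_factors(counts: CountMatrix | pd.DataFrame) -> ScalingFactors:
    """Median-of-ratios size factors (DESeq-style).

    Each gene's counts are divided by the gene's across-sample geometric
    mean; a sample's size factor is the median of those ratios over genes
    with strictly positive counts in every sample.
    """
    counts = _as_counts(counts)
    X = counts.values.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_gm = np.log(X).mean(axis=1)
    ok = np.isfinite(log_gm)
    if not ok.any():
        raise ValueError("no gene with positive counts in every sample")
    sizes = np.median(X[ok] / np.exp(log_gm[ok])[:, None], axis=0)
    s = pd.Series(sizes, index=counts.sample_ids)
    return ScalingFactors("mor", s, s)


def apply_factors(
    counts: CountMatrix | pd.DataFrame, sf: ScalingFactors
) -> NormalizedMatrix:
    """Turn scaling factors into normalized expression.

    uq/tmm: CPM computed on effective library sizes (library size × factor);
    mor: counts divided by the size factor directly.
    """
    counts = _as_counts(counts)
    if set(sf.factors.index) != set(counts.sample_ids):
        raise ValueError("scaling factors do not match the sample set")
    if sf.method == "mor":
        sizes = sf.effective_library_sizes.reindex(counts.sample_ids)
        out = counts.values / sizes
        return NormalizedMatrix(out, "mor", {"size_factors": sizes})
    eff = sf.effective_library_sizes.reindex(counts.sample_ids)
    norm = normalize_cpm(counts, effective_sizes=eff)
    return NormalizedMatrix(
        norm.values, sf.method, {"factors": sf.factors, "effective_sizes": eff}
    )


def log2_offset(values: NormalizedMatrix | pd.DataFrame, offset: float = 1.0) -> pd.DataFrame:
    """Elementwise log2(values + offset)."""
    if offset <= 0:
        raise ValueError("offset must be > 0")
    vals = values.values if isinstance(values, NormalizedMatrix) else pd.DataFrame(values)
    return np.log2(vals + offset)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

METHODS = ("tc", "cpm", "median", "quantile", "uq", "tmm", "mor")


def normalize(counts: CountMatrix | pd.DataFrame, method: str) -> NormalizedMatrix:
    """Run one of the seven methods by name (tc, cpm, median, quantile, uq, tmm, mor)."""
    counts = _as_counts(counts)
    if method == "tc":
        return normalize_total_count(counts)
    if method == "cpm":
        return normalize_cpm(counts)
    if method == "median":
        return normalize_median(counts)
    if method == "quantile":
        return quantile_normalize(counts)
    if method == "uq":
        return apply_factors(counts, upper_quartile_factors(counts))
    if method == "tmm":
        return apply_factors(counts, tmm_factors(counts))
    if method == "mor":
        return apply_factors(counts, median_of_ratios_factors(counts))
    raise ValueError(f"unknown normalization method {method!r}; choose from {METHODS}")
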
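"""Negative-binomial simulation of targeted RNA-seq (TempO-Seq-style) count data.

The generative model: a gene ``g`` in sample ``s`` of treatment group ``m``
has read count

    Y_gs ~ NB(mean = mu_gs, var = mu_gs * (1 + mu_gs * theta_g))

with a per-gene dispersion ``theta_g`` shared by all samples and both groups
(theta = 0 degenerates to Poisson).  Relative abundances ``lambda*_g`` set the
expected proportion of reads each gene captures; differential expression is
injected through per-group weights, ``lambda_{g,m} = w_m(g) * lambda*_g``, and
the expected count is the proportion times the sample's sequencing depth:

    mu_gs = lambda_{g,m(s)} / sum_g' lambda_{g',m(s)} * M_s

so that sum_g mu_gs == M_s exactly.  Depths are drawn as M_s = base * U with
U ~ Unif[u_min, u_max] (defaults 1e6 and [0.2, 1.5]).

The default fold-change design has seven gene sets of 50 genes each at signed
fold changes -4, -2, -1.5, +1.5, +2, +4 and 0 (weight pairs (6,1.5), (3,1.5),
(2.25,1.5), (1.5,2.25), (1.5,3), (1.5,6), (1.5,1.5)), with 35 samples per
group — a design in which the majority of the panel is differentially
expressed, as expected for a targeted sentinel-gene platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix

__all__ = [
    "NBGeneParams",
    "PoolProfile",
    "FCSet",
    "FoldChangeDesign",
    "DepthModel",
    "SimulatedDataset",
    "GROUP_UNTREATED",
    "GROUP_TREATED",
    "implied_fc",
    "estimate_nb_params",
    "synthesize_param_pool",
    "simulate_counts",
    "default_design",
]

GROUP_UNTREATED = "untreated"
GROUP_TREATED = "treated"


# ---------------------------------------------------------------------------
# parameter pool
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NBGeneParams:
    """Per-gene negative-binomial parameters.

    ``lambda_star`` is the relative expected abundance (count units at the
    nominal per-gene depth); ``theta`` is the unitless NB dispersion in the
    variance form ``mu * (1 + mu * theta)``, shared across samples and groups.
    """

    gene_id: str
    lambda_star: float
    theta: float

    def __post_init__(self) -> None:
        if not self.lambda_star > 0:
            raise ValueError(f"lambda_star must be > 0 (gene {self.gene_id!r})")
        if self.theta < 0:
            raise ValueError(f"theta must be >= 0 (gene {self.gene_id!r})")


@dataclass(frozen=True)
class PoolProfile:
    """Shape of a synthetic NB parameter pool.

    ``mean_count`` is the target mean expected count per gene at nominal
    depth (500 reads/gene for a down-sampled targeted run).  ``lambda_sigma``
    is the log-normal shape of the abundances; the default 1.0 reflects a
    panel restricted to well-expressed (top-quartile) transcripts.
    Dispersions are log-normal with median ``theta_median`` and shape
    ``theta_sigma``; the defaults put ~82% of the mass below 0.2 with a
    right tail reaching a few units, matching control-well NB fits.
    """

    mean_count: float = 500.0
    lambda_sigma: float = 1.0
    theta_median: float = 0.05
    theta_sigma: float = 1.5

    def __post_init__(self) -> None:
        if not self.mean_count > 0:
            raise ValueError("invalid profile: mean_count must be > 0")
        if not self.lambda_sigma > 0:
            raise ValueError("invalid profile: lambda_sigma must be > 0")
        if self.theta_median < 0 or self.theta_sigma < 0:
            raise ValueError("invalid profile: theta parameters must be >= 0")


def estimate_nb_params(counts: CountMatrix | pd.DataFrame) -> list[NBGeneParams]:
    """Moment-based NB parameter estimates from a real count matrix.

    Counts are first rescaled to a common depth (each sample multiplied by
    mean library size over its own), then per gene the sample mean ``m`` and
    variance ``v`` (ddof=1) invert the NB variance ``v = m * (1 + m*theta)``:

        lambda_star = m,   theta = max(0, (v - m) / m**2)

    All-zero genes are dropped.
    """
    if not isinstance(counts, CountMatrix):
        counts = CountMatrix(pd.DataFrame(counts))
    if counts.n_samples < 2:
        raise ValueError("insufficient replicates: need >= 2 samples")
    counts = counts.drop_allzero_genes()
    libs = counts.library_sizes.to_numpy(dtype=float)
    scaled = counts.values.to_numpy(dtype=float) * (libs.mean() / libs)
    m = scaled.mean(axis=1)
    v = scaled.var(axis=1, ddof=1)
    theta = np.maximum(0.0, (v - m) / m**2)
    return [
        NBGeneParams(gene_id=str(g), lambda_star=float(mi), theta=float(ti))
        for g, mi, ti in zip(counts.gene_ids, m, theta)
    ]


def synthesize_param_pool(
    n_genes: int,
    seed: int,
    profile: PoolProfile | None = None,
) -> list[NBGeneParams]:
    """Draw a synthetic NB parameter pool.

    Abundances are log-normal with mean ``profile.mean_count``; dispersions
    are log-normal with median ``profile.theta_median`` (right-skewed, most
    mass below 0.2 under the default).  Deterministic for a given seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    profile = profile or PoolProfile()
    rng = np.random.default_rng(seed)
    mu_log = math.log(profile.mean_count) - profile.lambda_sigma**2 / 2.0
    lam = rng.lognormal(mean=mu_log, sigma=profile.lambda_sigma, size=n_genes)
    if profile.theta_median > 0:
        theta = rng.lognormal(
            mean=math.log(profile.theta_median),
            sigma=profile.theta_sigma,
            size=n_genes,
        )
    else:
        theta = np.zeros(n_genes)
    return [
        NBGeneParams(gene_id=f"pool_{i + 1:05d}", lambda_star=float(l), theta=float(t))
        for i, (l, t) in enumerate(zip(lam, theta))
    ]


# ---------------------------------------------------------------------------
# fold-change design
# ---------------------------------------------------------------------------


def implied_fc(w1: float, w2: float) -> float:
    """Signed linear fold change encoded by a weight pair (w1, w2).

    The treated/untreated mean ratio is r = w2 / w1; it is reported as +r for
    upregulation, -1/r for downregulation, and 0 for no change (r == 1).
    """
    if not (w1 > 0 and w2 > 0):
        raise ValueError("weights must be positive")
    r = w2 / w1
    if r == 1:
        return 0.0
    return float(r) if r > 1 else float(-1.0 / r)


@dataclass(frozen=True)
class FCSet:
    """One fold-change set: a block of genes sharing group weights (w1, w2)."""

    label: str
    w1: float
    w2: float
    n_genes: int
    signed_fc: float

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError(f"set {self.label!r}: n_genes must be > 0")
        expected = implied_fc(self.w1, self.w2)
        if not math.isclose(expected, self.signed_fc, rel_tol=0, abs_tol=1e-9):
            raise ValueError(
                f"set {self.label!r}: stored signed_fc {self.signed_fc} "
                f"inconsistent with weights (implies {expected})"
            )

    @classmethod
    def from_weights(cls, label: str, w1: float, w2: float, n_genes: int) -> "FCSet":
        return cls(label, w1, w2, n_genes, implied_fc(w1, w2))


@dataclass(frozen=True)
class FoldChangeDesign:
    """Ordered collection of FC sets plus the per-group sample count."""

    sets: tuple[FCSet, ...]
    n_samples_per_group: int = 35

    def __post_init__(self) -> None:
        labels = [s.label for s in self.sets]
        if len(set(labels)) != len(labels):
            raise ValueError("set labels must be unique")
        if self.n_samples_per_group < 1:
            raise ValueError("n_samples_per_group must be >= 1")

    @property
    def n_genes(self) -> int:
        return sum(s.n_genes for s in self.sets)

    @property
    def n_samples(self) -> int:
        return 2 * self.n_samples_per_group

    def signed_fc_of_label(self) -> dict[str, float]:
        return {s.label: s.signed_fc for s in self.sets}


#: weight pairs of the default seven-set design, in set order A..G
_DEFAULT_WEIGHTS = (
    ("A", 6.0, 1.5),
    ("B", 3.0, 1.5),
    ("C", 2.25, 1.5),
    ("D", 1.5, 2.25),
    ("E", 1.5, 3.0),
    ("F", 1.5, 6.0),
    ("G", 1.5, 1.5),
)


def default_design(n_genes_per_set: int = 50, n_samples_per_group: int = 35) -> FoldChangeDesign:
    """The seven-set benchmark design: FC in {-4,-2,-1.5,+1.5,+2,+4,0}."""
    sets = tuple(
        FCSet.from_weights(label, w1, w2, n_genes_per_set)
        for label, w1, w2 in _DEFAULT_WEIGHTS
    )
    return FoldChangeDesign(sets=sets, n_samples_per_group=n_samples_per_group)


# ---------------------------------------------------------------------------
# depth model and simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DepthModel:
    """Per-sample sequencing depth M = base * U, U ~ Unif[u_min, u_max].

    ``draw_scope`` selects whether U is drawn independently per sample
    (default) or once per treatment group.
    """

    base: float = 1e6
    u_min: float = 0.2
    u_max: float = 1.5
    draw_scope: str = "per_sample"

    def __post_init__(self) -> None:
        if not (0 < self.u_min < self.u_max):
            raise ValueError("depth bounds invalid: need 0 < u_min < u_max")
        if self.base <= 0:
            raise ValueError("depth base must be > 0")
        if self.draw_scope not in ("per_sample", "per_group"):
            raise ValueError("draw_scope must be 'per_sample' or 'per_group'")


@dataclass
class SimulatedDataset:
    """A simulated grouped count matrix with full ground truth.

    ``expected_means`` holds the NB means mu_gs (genes × samples), whose
    column sums equal the realized depths exactly.
    """

    counts: CountMatrix
    group_of_sample: dict[str, str]
    set_of_gene: dict[str, str]
    seed: int
    depths: dict[str, float]
    expected_means: pd.DataFrame
    design: FoldChangeDesign | None = None

    @property
    def samples_in_group(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, g in self.group_of_sample.items():
            out.setdefault(g, []).append(s)
        return out

    def true_signed_fc(self) -> pd.Series:
        """Per-gene design fold change (signed linear scale)."""
        if self.design is None:
            raise ValueError("dataset carries no design")
        fc_of = self.design.signed_fc_of_label()
        return pd.Series(
            {g: fc_of[lbl] for g, lbl in self.set_of_gene.items()},
            name="signed_fc",
        ).loc[self.counts.gene_ids]


def simulate_counts(
    pool: list[NBGeneParams],
    design: FoldChangeDesign,
    depth: DepthModel | None = None,
    seed: int = 0,
) -> SimulatedDataset:
    """Simulate a grouped NB count matrix under a fold-change design.

    Genes are drawn from ``pool`` without replacement (seeded) and assigned to
    sets in design order.  For a gene with weights (w1, w2), the group means
    are w_m * lambda*; within each sample means are renormalized to sum to the
    sample's depth.  Counts are NB(mean mu, size 1/theta); theta == 0 draws
    exact Poisson.
    """
    depth = depth or DepthModel()
    total = design.n_genes
    if len(pool) < total:
        raise ValueError(
            f"parameter pool too small: {len(pool)} genes available, "
            f"{total} required by the design"
        )
    rng = np.random.default_rng(seed)

    chosen = rng.choice(len(pool), size=total, replace=False)
    genes = [pool[i] for i in chosen]
    gene_ids = [p.gene_id for p in genes]
    lam_star = np.array([p.lambda_star for p in genes])
    theta = np.array([p.theta for p in genes])

    set_of_gene: dict[str, str] = {}
    w = np.empty((total, 2))
    pos = 0
    for s in design.sets:
        for _ in range(s.n_genes):
            set_of_gene[gene_ids[pos]] = s.label
            w[pos] = (s.w1, s.w2)
            pos += 1

    npg = design.n_samples_per_group
    width = len(str(npg))
    sample_ids = [f"{GROUP_UNTREATED}_{i + 1:0{width}d}" for i in range(npg)] + [
        f"{GROUP_TREATED}_{i + 1:0{width}d}" for i in range(npg)
    ]
    group_idx = np.array([0] * npg + [1] * npg)
    group_of_sample = {
        s: (GROUP_UNTREATED if m == 0 else GROUP_TREATED)
        for s, m in zip(sample_ids, group_idx)
    }

    if depth.draw_scope == "per_sample":
        u = rng.uniform(depth.u_min, depth.u_max, size=2 * npg)
    else:  # per_group: one draw shared by all samples of a group
        ug = rng.uniform(depth.u_min, depth.u_max, size=2)
        u = ug[group_idx]
    depths = depth.base * u

    # per-group expected proportions, then per-sample means summing to M_s
    lam_group = w * lam_star[:, None]  # genes x 2
    props = lam_group / lam_group.sum(axis=0, keepdims=True)
    mu = props[:, group_idx] * depths[None, :]  # genes x samples

    counts = np.empty_like(mu, dtype=np.int64)
    poisson = theta == 0
    if poisson.any():
        counts[poisson] = rng.poisson(mu[poisson])
    if (~poisson).any():
        size = 1.0 / theta[~poisson]
        p = size[:, None] / (size[:, None] + mu[~poisson])
        counts[~poisson] = rng.negative_binomial(size[:, None], p)

    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=sample_ids))
    return SimulatedDataset(
        counts=cm,
        group_of_sample=group_of_sample,
        set_of_gene=set_of_gene,
        seed=seed,
        depths=dict(zip(sample_ids, depths)),
        expected_means=pd.DataFrame(mu, index=gene_ids, columns=sample_ids),
        design=design,
    )
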
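"""End-to-end benchmark: simulate -> normalize (x7) -> log2 -> fold change ->
bin -> one-vs-all metrics -> cosine k-means -> adjusted Rand index.

Everything is a pure function of (config, seed): the run seed is split with
``numpy.random.SeedSequence`` into independent streams for the parameter
pool, the count simulation and the k-means restarts, so stages are
individually reproducible.  A user-supplied dataset (counts + label sidecars)
can replace the simulation for evaluating the same metrics on external data.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .containers import CountMatrix
from .diffexpr import GroupDesign, de_call, two_group_log_fc
from .evaluation import (
    BIN_LEVELS,
    Partition,
    adjusted_rand_index,
    bin_signed_fc,
    kmeans_cosine,
    log_ratio_profiles,
    one_vs_all_metrics,
)
from .normalization import METHODS, log2_offset, normalize
from .synthetic_data import (
    DepthModel,
    FoldChangeDesign,
    PoolProfile,
    SimulatedDataset,
    default_design,
    simulate_counts,
    synthesize_param_pool,
)

__all__ = [
    "BenchmarkConfig",
    "BenchmarkReport",
    "run_benchmark",
    "load_external_dataset",
    "write_dataset",
    "write_report",
    "load_config",
]

logger = logging.getLogger("temponorm")


@dataclass
class BenchmarkConfig:
    """Everything needed to reproduce one benchmark run.

    Defaults reproduce the reference setup: 7 FC sets × 50 genes, 35 samples
    per group, depths 1e6·Unif[0.2, 1.5], log2 offset 1, k = 7 clusters.
    """

    design: FoldChangeDesign = field(default_factory=default_design)
    depth: DepthModel = field(default_factory=DepthModel)
    pool_profile: PoolProfile = field(default_factory=PoolProfile)
    pool_size: int = 2680
    methods: tuple = METHODS
    log_offset: float = 1.0
    profile_offset: float = 1.0
    de_threshold: float = 1.5
    k: int = 7
    n_restarts: int = 50
    cluster: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.methods) - set(METHODS)
        if bad:
            raise ValueError(f"unknown methods {sorted(bad)}; choose from {METHODS}")

    def config_hash(self) -> str:
        payload = yaml.safe_dump(
            {
                "sets": [(s.label, s.w1, s.w2, s.n_genes) for s in self.design.sets],
                "n_per_group": self.design.n_samples_per_group,
                "depth": (self.depth.base, self.depth.u_min, self.depth.u_max, self.depth.draw_scope),
                "pool": (
                    self.pool_profile.mean_count,
                    self.pool_profile.lambda_sigma,
                    self.pool_profile.theta_median,
                    self.pool_profile.theta_sigma,
                ),
                "pool_size": self.pool_size,
                "methods": list(self.methods),
                "offsets": (self.log_offset, self.profile_offset),
                "de_threshold": self.de_threshold,
                "k": self.k,
                "n_restarts": self.n_restarts,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class BenchmarkReport:
    """All benchmark outputs for one dataset."""

    performance: dict  # method -> PerformanceTable
    ari: dict  # method -> float
    call_percentages: pd.DataFrame  # methods x (up, down, no_change), percent
    fc_correlations: pd.DataFrame  # methods x methods Pearson r of log2 FC
    log2_fc: pd.DataFrame  # genes x methods
    predicted_bins: pd.DataFrame  # genes x methods
    true_bins: pd.Series
    metadata: dict


def _derive_seeds(seed: int, n: int) -> list[int]:
    """Split one run seed into n independent integer seeds (< 2**31)."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def run_benchmark(
    config: BenchmarkConfig, dataset: SimulatedDataset | None = None
) -> BenchmarkReport:
    """Run the full benchmark; simulate unless an external dataset is given."""
    pool_seed, sim_seed, cluster_seed = _derive_seeds(config.seed, 3)
    if dataset is None:
        logger.info("simulating: pool of %d genes, %d sets, %d samples/group",
                    config.pool_size, len(config.design.sets),
                    config.design.n_samples_per_group)
        pool = synthesize_param_pool(config.pool_size, pool_seed, config.pool_profile)
        dataset = simulate_counts(pool, config.design, config.depth, sim_seed)
    design = GroupDesign(dataset.group_of_sample)
    true_fc = dataset.true_signed_fc()
    true_bins = bin_signed_fc(true_fc)
    set_partition = Partition(pd.Series(dataset.set_of_gene).loc[dataset.counts.gene_ids])

    performance, ari, calls, lfc_cols, bin_cols = {}, {}, {}, {}, {}
    method_seeds = dict(zip(config.methods, _derive_seeds(cluster_seed, len(config.methods))))
    for method in config.methods:
        try:
            norm = normalize(dataset.counts, method)
            logvals = log2_offset(norm, config.log_offset)
            est = two_group_log_fc(logvals, design)
            pred_bins = bin_signed_fc(est.signed)
            performance[method] = one_vs_all_metrics(true_bins, pred_bins, method=method)
            call = de_call(est.signed, config.de_threshold)
            calls[method] = call.value_counts(normalize=True).reindex(
                ["up", "down", "no_change"], fill_value=0.0
            ) * 100.0
            lfc_cols[method] = est.log2_fc
            bin_cols[method] = pred_bins
            if config.cluster:
                profiles = log_ratio_profiles(norm, design, config.profile_offset)
                part = kmeans_cosine(
                    profiles, config.k, config.n_restarts, method_seeds[method]
                )
                ari[method] = adjusted_rand_index(set_partition, part)
        except Exception as exc:  # surface the failing stage and method
            raise RuntimeError(f"benchmark stage failed for method {method!r}: {exc}") from exc

    log2_fc = pd.DataFrame(lfc_cols)
    corr = log2_fc.corr(method="pearson")
    report = BenchmarkReport(
        performance=performance,
        ari=ari,
        call_percentages=pd.DataFrame(calls).T[["up", "down", "no_change"]],
        fc_correlations=corr,
        log2_fc=log2_fc,
        predicted_bins=pd.DataFrame(bin_cols),
        true_bins=true_bins,
        metadata={
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "n_genes": dataset.counts.n_genes,
            "n_samples": dataset.counts.n_samples,
            "methods": list(config.methods),
        },
    )
    return report


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------


def write_dataset(dataset: SimulatedDataset, prefix: str) -> dict:
    """Write counts + sample/gene label sidecars as TSV; returns the paths."""
    paths = {
        "counts": f"{prefix}_counts.tsv",
        "samples": f"{prefix}_samples.tsv",
        "genes": f"{prefix}_genes.tsv",
    }
    dataset.counts.values.to_csv(paths["counts"], sep="\t", index_label="gene_id")
    pd.DataFrame(
        {
            "sample_id": list(dataset.group_of_sample),
            "group": list(dataset.group_of_sample.values()),
        }
    ).to_csv(paths["samples"], sep="\t", index=False)
    pd.DataFrame(
        {
            "gene_id": list(dataset.set_of_gene),
            "fc_set": list(dataset.set_of_gene.values()),
        }
    ).to_csv(paths["genes"], sep="\t", index=False)
    return paths


def load_external_dataset(
    counts_path: str,
    sample_labels_path: str,
    gene_labels_path: str | None = None,
    design: FoldChangeDesign | None = None,
    column_map: dict | None = None,
    sep: str = "\t",
) -> SimulatedDataset:
    """Load a counts matrix plus label sidecars into a dataset.

    ``counts_path``: TSV/CSV, first column gene ids, header of sample ids,
    integer cells.  ``sample_labels_path``: columns (sample_id, group) with
    group in {untreated, treated}.  ``gene_labels_path`` (optional): columns
    (gene_id, fc_set).  ``column_map`` renames non-standard column headers,
    e.g. {"well": "sample_id", "treatment": "group"}.  ``design`` attaches
    the fold-change design the labels refer to (defaults to the seven-set
    design when gene labels use its A..G labels).
    """
    raw = pd.read_csv(counts_path, sep=sep, index_col=0)
    neg = np.argwhere(raw.to_numpy() < 0)
    if len(neg):
        g, s = neg[0]
        raise ValueError(
            f"negative count at gene {raw.index[g]!r}, sample {raw.columns[s]!r}"
        )
    counts = CountMatrix(raw)

    samples = pd.read_csv(sample_labels_path, sep=sep)
    if column_map:
        samples = samples.rename(columns=column_map)
    missing_cols = {"sample_id", "group"} - set(samples.columns)
    if missing_cols:
        raise ValueError(f"sample label file lacks columns {sorted(missing_cols)}")
    group_of_sample = dict(zip(samples["sample_id"].astype(str), samples["group"]))
    unlabeled = [s for s in counts.sample_ids if str(s) not in group_of_sample]
    if unlabeled:
        raise ValueError(f"samples without a group label: {unlabeled}")
    extra = [s for s in group_of_sample if s not in set(map(str, counts.sample_ids))]
    if extra:
        raise ValueError(f"labels for unknown samples: {extra}")

    set_of_gene: dict[str, str] = {}
    if gene_labels_path is not None:
        genes = pd.read_csv(gene_labels_path, sep=sep)
        if column_map:
            genes = genes.rename(columns=column_map)
        missing_cols = {"gene_id", "fc_set"} - set(genes.columns)
        if missing_cols:
            raise ValueError(f"gene label file lacks columns {sorted(missing_cols)}")
        set_of_gene = dict(zip(genes["gene_id"].astype(str), genes["fc_set"]))
        unlabeled_g = [g for g in counts.gene_ids if str(g) not in set_of_gene]
        if unlabeled_g:
            raise ValueError(f"genes without an FC-set label: {unlabeled_g[:10]}")
        if design is None and set(set_of_gene.values()) <= {
            s.label for s in default_design().sets
        }:
            design = default_design(
                n_genes_per_set=max(
                    pd.Series(set_of_gene).value_counts()
                ),
                n_samples_per_group=sum(
                    1 for g in group_of_sample.values() if g == "untreated"
                ),
            )

    libs = counts.library_sizes
    return SimulatedDataset(
        counts=counts,
        group_of_sample={str(s): group_of_sample[str(s)] for s in counts.sample_ids},
        set_of_gene=set_of_gene,
        seed=-1,
        depths={str(s): float(libs[s]) for s in counts.sample_ids},
        expected_means=counts.values.astype(float),
        design=design,
    )


# ---------------------------------------------------------------------------
# report I/O
# ---------------------------------------------------------------------------


def write_report(report: BenchmarkReport, outdir: str) -> dict:
    """Write the report tables as TSVs under ``outdir``; returns the paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    # performance table shaped metric x level rows, method columns
    rows = []
    for metric in ("sensitivity", "specificity", "precision"):
        for level in BIN_LEVELS:
            row = {"metric": metric, "level": level}
            for method, perf in report.performance.items():
                row[method] = perf.table.loc[level, metric]
            rows.append(row)
    acc = {"metric": "accuracy", "level": "overall"}
    for method, perf in report.performance.items():
        acc[method] = perf.overall_accuracy
    perf_df = pd.DataFrame([acc] + rows)
    paths["performance"] = os.path.join(outdir, "performance.tsv")
    perf_df.to_csv(paths["performance"], sep="\t", index=False)

    if report.ari:
        ari_df = pd.DataFrame(
            {"method": list(report.ari), "ari": list(report.ari.values())}
        )
        paths["ari"] = os.path.join(outdir, "ari.tsv")
        ari_df.to_csv(paths["ari"], sep="\t", index=False)

    paths["calls"] = os.path.join(outdir, "call_percentages.tsv")
    report.call_percentages.to_csv(paths["calls"], sep="\t", index_label="method")

    paths["correlations"] = os.path.join(outdir, "fc_correlations.tsv")
    report.fc_correlations.to_csv(paths["correlations"], sep="\t", index_label="method")

    paths["log2_fc"] = os.path.join(outdir, "log2_fc.tsv")
    report.log2_fc.to_csv(paths["log2_fc"], sep="\t", index_label="gene_id")

    for method, perf in report.performance.items():
        p = os.path.join(outdir, f"confusion_{method}.tsv")
        perf.table[["tp", "fp", "tn", "fn"]].to_csv(p, sep="\t", index_label="level")
        paths[f"confusion_{method}"] = p

    meta = pd.Series(report.metadata, dtype=object)
    paths["metadata"] = os.path.join(outdir, "metadata.tsv")
    meta.to_csv(paths["metadata"], sep="\t", header=False)
    return paths


def load_config(path: str, seed: int | None = None) -> BenchmarkConfig:
    """Build a BenchmarkConfig from a YAML file (all keys optional)."""
    from .synthetic_data import FCSet

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    if "design" in raw:
        d = raw["design"]
        sets = tuple(
            FCSet.from_weights(s["label"], float(s["w1"]), float(s["w2"]), int(s["n_genes"]))
            for s in d.get("sets", [])
        )
        if not sets:
            sets = default_design().sets
        kwargs["design"] = FoldChangeDesign(
            sets=sets, n_samples_per_group=int(d.get("n_samples_per_group", 35))
        )
    if "depth" in raw:
        kwargs["depth"] = DepthModel(**raw["depth"])
    if "pool_profile" in raw:
        kwargs["pool_profile"] = PoolProfile(**raw["pool_profile"])
    for key in (
        "pool_size",
        "methods",
        "log_offset",
        "profile_offset",
        "de_threshold",
        "k",
        "n_restarts",
        "cluster",
        "seed",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    if "methods" in kwargs:
        kwargs["methods"] = tuple(kwargs["methods"])
    if seed is not None:
        kwargs["seed"] = seed
    return BenchmarkConfig(**kwargs)
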
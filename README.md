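# temponorm

Benchmarking between-sample normalization for **targeted RNA-seq count
data** (TempO-Seq-style sentinel-gene panels).

Targeted panels differ from whole-transcriptome RNA-seq in one crucial way:
the panel is designed so that *most* genes respond to a perturbation, which
violates the majority-unchanged assumption behind popular scaling
normalizations (TMM, median-of-ratios). `temponorm` quantifies what that
costs. It simulates grouped count matrices from a negative-binomial model
with known injected fold changes, normalizes them with seven standard
methods implemented from scratch, estimates two-group fold changes, and
scores each method on how well the designed fold-change levels are
recovered.

## Model

A gene *g* in sample *s* of group *m* ∈ {untreated, treated} has count

```
Y_gs ~ NB(mean = μ_gs, var = μ_gs (1 + μ_gs θ_g))
μ_gs = λ_{g,m} / Σ_g' λ_{g',m} · M_s,    λ_{g,m} = w_m(g) · λ*_g
M_s  = base · U_s,  U_s ~ Unif[u_min, u_max]      (defaults 10⁶, [0.2, 1.5])
```

with per-gene dispersion θ_g shared by both groups (θ = 0 is Poisson) and
relative abundances λ\*_g. Differential expression enters through per-set
weight pairs (w₁, w₂); the default design has seven sets of 50 genes at
signed fold changes −4, −2, −1.5, +1.5, +2, +4 and 0 (weights (6, 1.5),
(3, 1.5), (2.25, 1.5), (1.5, 2.25), (1.5, 3), (1.5, 6), (1.5, 1.5)) and 35
samples per group.

Normalizations: total counts (`tc`), counts per million (`cpm`), per-sample
median scaling (`median`), quantile (`quantile`), upper quartile (`uq`),
weighted trimmed mean of M-values (`tmm`), and median-of-ratios size
factors (`mor`). The factor methods are validated against
`edgeR::calcNormFactors` and `DESeq2::estimateSizeFactors` in the test
suite.

Evaluation: the treated−untreated log₂ fold change (the two-group linear
model coefficient) is mapped to the signed linear scale
(L ↦ 2^L for L ≥ 0, −2^(−L) otherwise) and binned into the seven levels via
the partition (−∞,−3], (−3,−2], (−2,−1.5], (−1.5,+1.5), [+1.5,+2), [+2,+3),
[+3,∞). Each method is scored with one-vs-all sensitivity / specificity /
precision per level plus multiclass overall accuracy, and with the adjusted
Rand index between a cosine k-means clustering (k = 7) of per-gene log-ratio
profiles and the true set assignment.

## Worked example

```python
import temponorm as tn

cfg = tn.BenchmarkConfig(seed=7)        # default: 7 sets x 50 genes, 35/group
report = tn.run_benchmark(cfg)
for m, perf in sorted(report.performance.items(),
                      key=lambda kv: -kv[1].overall_accuracy):
    print(f"{m:9s} {perf.overall_accuracy:.3f}   ARI {report.ari[m]:.2f}")
```

prints

```
mor       0.709   ARI 0.31
tc        0.694   ARI 0.28
cpm       0.694   ARI 0.31
uq        0.694   ARI 0.32
median    0.691   ARI 0.28
tmm       0.691   ARI 0.31
quantile  0.666   ARI 0.31
```

Overall accuracy is the fraction of the 350 simulated genes whose estimated
fold change lands in its true bin: roughly 0.7 for every library-size-based
method here, because the narrow ±1.5 bins are intrinsically hard to hit,
while quantile normalization trails the field. ARI ≈ 0.3 says the k-means
clustering of noisy per-sample log-ratio profiles recovers the seven design
sets only partially. Per-level detail sits in
`report.performance[method].table`; e.g. with this seed UQ keeps perfect
sensitivity at the ±4 levels (1.00 / 0.98) but drops to 0.06 at +1.5.

The same run is available from the shell:

```
temponorm benchmark --seed 7 --out results/
temponorm simulate --out-prefix sim --seed 3
temponorm normalize --method uq --in sim_counts.tsv --out uq.tsv --offset 1
```

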
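"""Independent, deliberately naive loop-based oracles for the test suite.

Everything here is written directly from the printed description of each
procedure, with explicit Python loops and no shared code with the package,
so agreement between package and oracle is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# normalizations (rows = genes, cols = samples; plain numpy arrays)
# ---------------------------------------------------------------------------


def naive_tc(x):
    x = np.asarray(x, dtype=float)
    n_samples = x.shape[1]
    totals = [sum(x[:, j]) for j in range(n_samples)]
    mean_total = sum(totals) / n_samples
    out = np.zeros_like(x)
    for g in range(x.shape[0]):
        for j in range(n_samples):
            out[g, j] = x[g, j] / totals[j] * mean_total
    return out


def naive_cpm(x):
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    for j in range(x.shape[1]):
        total = sum(x[:, j])
        for g in range(x.shape[0]):
            out[g, j] = x[g, j] / total * 1e6
    return out


def naive_median(x):
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    for j in range(x.shape[1]):
        med = float(np.median(x[:, j]))
        for g in range(x.shape[0]):
            out[g, j] = x[g, j] / med * 1e6
    return out


def naive_quantile(x):
    x = np.asarray(x, dtype=float)
    n_genes, n_samples = x.shape
    ref = [
        sum(sorted(x[:, j])[r] for j in range(n_samples)) / n_samples
        for r in range(n_genes)
    ]
    out = np.zeros_like(x)
    for j in range(n_samples):
        order = sorted(range(n_genes), key=lambda g: (x[g, j], g))
        # tied values share the mean of the reference over their rank span
        r = 0
        while r < n_genes:
            r2 = r
            while r2 + 1 < n_genes and x[order[r2 + 1], j] == x[order[r], j]:
                r2 += 1
            tie_mean = sum(ref[r : r2 + 1]) / (r2 - r + 1)
            for k in range(r, r2 + 1):
                out[order[k], j] = tie_mean
            r = r2 + 1
    return out


def _naive_geomean(vals):
    return math.exp(sum(math.log(v) for v in vals) / len(vals))


def naive_uq_factors(x):
    x = np.asarray(x, dtype=float)
    expressed = [g for g in range(x.shape[0]) if sum(x[g, :]) > 0]
    raw = []
    for j in range(x.shape[1]):
        q75 = float(np.quantile([x[g, j] for g in expressed], 0.75))
        raw.append(q75 / sum(x[:, j]))
    gm = _naive_geomean(raw)
    return np.array([r / gm for r in raw])


def naive_tmm_factors(x):
    x = np.asarray(x, dtype=float)
    n_genes, n_samples = x.shape
    expressed = [g for g in range(n_genes) if sum(x[g, :]) > 0]
    libs = [sum(x[:, j]) for j in range(n_samples)]
    f75 = [
        float(np.quantile([x[g, j] for g in expressed], 0.75)) / libs[j]
        for j in range(n_samples)
    ]
    mean_f75 = sum(f75) / n_samples
    ref = min(range(n_samples), key=lambda j: abs(f75[j] - mean_f75))

    def rank_avg(vals):
        order = sorted(range(len(vals)), key=lambda i: vals[i])
        ranks = [0.0] * len(vals)
        i = 0
        while i < len(vals):
            j = i
            while j + 1 < len(vals) and vals[order[j + 1]] == vals[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    factors = []
    for k in range(n_samples):
        if k == ref:
            factors.append(1.0)
            continue
        genes = [g for g in expressed if x[g, k] > 0 and x[g, ref] > 0]
        m_vals, a_vals, var = [], [], []
        for g in genes:
            ok, orf = x[g, k] / libs[k], x[g, ref] / libs[ref]
            m_vals.append(math.log2(ok / orf))
            a_vals.append(0.5 * math.log2(ok * orf))
            var.append(
                (libs[k] - x[g, k]) / (libs[k] * x[g, k])
                + (libs[ref] - x[g, ref]) / (libs[ref] * x[g, ref])
            )
        n = len(genes)
        lo_m, hi_m = math.floor(n * 0.30) + 1, n - math.floor(n * 0.30)
        lo_a, hi_a = math.floor(n * 0.05) + 1, n - math.floor(n * 0.05)
        rm, ra = rank_avg(m_vals), rank_avg(a_vals)
        num = den = 0.0
        for i in range(n):
            if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a:
                num += m_vals[i] / var[i]
                den += 1.0 / var[i]
        factors.append(2.0 ** (num / den))
    gm = _naive_geomean(factors)
    return np.array([f / gm for f in factors])


def naive_mor_sizes(x):
    x = np.asarray(x, dtype=float)
    n_genes, n_samples = x.shape
    geomeans = []
    for g in range(n_genes):
        prod = 1.0
        for j in range(n_samples):
            prod *= x[g, j]
        geomeans.append(prod ** (1.0 / n_samples))
    sizes = []
    for j in range(n_samples):
        ratios = [
            x[g, j] / geomeans[g] for g in range(n_genes) if geomeans[g] > 0
        ]
        sizes.append(float(np.median(ratios)))
    return np.array(sizes)


# ---------------------------------------------------------------------------
# NB moment estimation
# ---------------------------------------------------------------------------


def naive_nb_moments(x):
    """Per-gene (lambda_star, theta) by explicit depth scaling and moments."""
    x = np.asarray(x, dtype=float)
    n_genes, n_samples = x.shape
    totals = [sum(x[:, j]) for j in range(n_samples)]
    mean_total = sum(totals) / n_samples
    out = []
    for g in range(n_genes):
        vals = [x[g, j] * mean_total / totals[j] for j in range(n_samples)]
        if sum(x[g, :]) == 0:
            continue
        m = sum(vals) / n_samples
        v = sum((u - m) ** 2 for u in vals) / (n_samples - 1)
        out.append((m, max(0.0, (v - m) / m**2)))
    return out


# ---------------------------------------------------------------------------
# confusion metrics and ARI
# ---------------------------------------------------------------------------


def naive_confusion(true_labels, pred_labels, level):
    tp = fp = tn = fn = 0
    for t, p in zip(true_labels, pred_labels):
        if t == level and p == level:
            tp += 1
        elif t == level and p != level:
            fn += 1
        elif t != level and p == level:
            fp += 1
        else:
            tn += 1
    return tp, fp, tn, fn


def naive_ari_pairs(u, v):
    """ARI from explicit enumeration of all object pairs."""
    u, v = list(u), list(v)
    n = len(u)
    together_u = together_v = together_both = 0
    for i in range(n):
        for j in range(i + 1, n):
            su, sv = u[i] == u[j], v[i] == v[j]
            together_u += su
            together_v += sv
            together_both += su and sv
    total_pairs = n * (n - 1) // 2
    expected = together_u * together_v / total_pairs
    max_index = (together_u + together_v) / 2
    if max_index == expected:
        return 1.0
    return (together_both - expected) / (max_index - expected)


def set_partitions(items):
    """All set partitions of a list, as lists of label assignments."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        n_blocks = max(part, default=-1) + 1
        for b in range(n_blocks + 1):
            yield [b] + part
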
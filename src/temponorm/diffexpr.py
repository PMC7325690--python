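"""Two-group fold-change estimation on log2 normalized expression.

The log2 fold change is the treated-minus-untreated difference of group
means, which is exactly the group coefficient of the two-group linear model
(the moderated-model coefficient equals the ordinary least-squares one; only
the variance, not the coefficient, is shrunk by empirical Bayes, and all
downstream classification here is by fold-change value alone).

Log2 fold changes are mapped to the signed linear scale: a log2 ratio L
becomes 2**L if L >= 0 and -2**(-L) otherwise, so the signed scale excludes
the open interval (-1, +1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalization import NormalizedMatrix

__all__ = [
    "GroupDesign",
    "FCEstimates",
    "two_group_log_fc",
    "signed_fc",
    "coefficient_of_variation",
    "de_call",
]


@dataclass(frozen=True)
class GroupDesign:
    """Assignment of samples to the untreated / treated groups."""

    group_of_sample: dict

    def __post_init__(self) -> None:
        groups = set(self.group_of_sample.values())
        if groups != {"untreated", "treated"}:
            missing = {"untreated", "treated"} - groups
            raise ValueError(f"both groups must be non-empty; missing {sorted(missing)}")

    @property
    def sample_ids(self) -> list:
        return list(self.group_of_sample)

    def members(self, group: str) -> list:
        return [s for s, g in self.group_of_sample.items() if g == group]


@dataclass
class FCEstimates:
    """Per-gene fold-change estimates from a two-group comparison.

    ``log2_fc`` is treated minus untreated in log2 units; ``signed_fc`` the
    corresponding signed linear fold change; ``residual_sd`` the pooled
    within-group standard deviation (NaN when either group has < 2 samples).
    """

    table: pd.DataFrame  # columns: log2_fc, signed_fc, residual_sd

    @property
    def log2_fc(self) -> pd.Series:
        return self.table["log2_fc"]

    @property
    def signed(self) -> pd.Series:
        return self.table["signed_fc"]

    @property
    def residual_sd(self) -> pd.Series:
        return self.table["residual_sd"]


def signed_fc(log2_fc):
    """Map log2 fold change(s) to the signed linear scale.

    2**L for L >= 0, -2**(-L) for L < 0; a strictly monotone odd bijection
    from the reals onto (-inf, -1] U [+1, inf).
    """
    arr = np.asarray(log2_fc, dtype=float)
    out = np.where(arr >= 0, 2.0**arr, -(2.0 ** (-arr)))
    if np.isscalar(log2_fc) or arr.ndim == 0:
        return float(out)
    if isinstance(log2_fc, pd.Series):
        return pd.Series(out, index=log2_fc.index)
    return out


def _split(logvalues: pd.DataFrame, design: GroupDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    missing = [s for s in design.sample_ids if s not in logvalues.columns]
    if missing:
        raise ValueError(f"design samples absent from the matrix: {missing}")
    unt = logvalues[design.members("untreated")]
    trt = logvalues[design.members("treated")]
    return unt, trt


def two_group_log_fc(logvalues: pd.DataFrame, design: GroupDesign) -> FCEstimates:
    """Fold-change estimates for treated vs untreated on log2 data.

    log2_fc is the difference of group means; residual_sd is the square root
    of the pooled within-group variance (denominator n1 + n2 - 2), reported
    as NaN when either group has fewer than 2 samples.
    """
    unt, trt = _split(logvalues, design)
    n1, n2 = unt.shape[1], trt.shape[1]
    lfc = trt.mean(axis=1) - unt.mean(axis=1)
    if n1 >= 2 and n2 >= 2:
        ss = ((unt.sub(unt.mean(axis=1), axis=0)) ** 2).sum(axis=1) + (
            (trt.sub(trt.mean(axis=1), axis=0)) ** 2
        ).sum(axis=1)
        rsd = np.sqrt(ss / (n1 + n2 - 2))
    else:
        rsd = pd.Series(np.nan, index=logvalues.index)
    table = pd.DataFrame(
        {"log2_fc": lfc, "signed_fc": signed_fc(lfc), "residual_sd": rsd}
    )
    return FCEstimates(table)


def coefficient_of_variation(
    values: NormalizedMatrix | pd.DataFrame, design: GroupDesign
) -> pd.DataFrame:
    """Per-gene, per-group CV (sample SD / mean) of unlogged normalized values.

    Genes with zero group mean get NaN (undefined, not infinite).
    """
    vals = values.values if isinstance(values, NormalizedMatrix) else pd.DataFrame(values)
    out = {}
    for group in ("untreated", "treated"):
        cols = design.members(group)
        if len(cols) < 2:
            raise ValueError(f"group {group!r} needs >= 2 samples for a CV")
        sub = vals[cols]
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        cv = sd / mean
        cv[mean == 0] = np.nan
        out[group] = cv
    return pd.DataFrame(out)


def de_call(signed, threshold: float = 1.5):
    """Classify signed fold change(s) as 'up', 'down' or 'no_change'.

    up if fc >= threshold, down if fc <= -threshold (boundaries inclusive,
    matching the closed fold-change bin brackets), else no_change.
    """
    if not abs(threshold) > 1:
        raise ValueError("threshold must exceed 1 on the signed scale")
    arr = np.asarray(signed, dtype=float)
    out = np.where(arr >= threshold, "up", np.where(arr <= -threshold, "down", "no_change"))
    if np.isscalar(signed) or arr.ndim == 0:
        return str(out)
    if isinstance(signed, pd.Series):
        return pd.Series(out, index=signed.index)
    return out
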
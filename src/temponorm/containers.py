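"""Shared count-matrix container used across the simulation and normalization layers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountMatrix"]


@dataclass
class CountMatrix:
    """A genes × samples matrix of non-negative integer read counts.

    Rows are genes, columns are samples.  ``library_sizes`` are the per-sample
    column sums (total mapped reads), recomputed on access so the identity
    ``library_sizes[s] == values[:, s].sum()`` holds by construction.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.values
        if not isinstance(vals, pd.DataFrame):
            vals = pd.DataFrame(vals)
        arr = vals.to_numpy()
        if arr.size == 0:
            raise ValueError("invalid counts: empty matrix")
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("invalid counts: non-numeric entries")
        if np.any(arr < 0):
            g, s = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"invalid counts: negative entry at gene {vals.index[g]!r}, "
                f"sample {vals.columns[s]!r}"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                g, s = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
                raise ValueError(
                    f"invalid counts: non-integer entry at gene {vals.index[g]!r}, "
                    f"sample {vals.columns[s]!r}"
                )
            vals = vals.round().astype(np.int64)
        if vals.index.has_duplicates or vals.columns.has_duplicates:
            raise ValueError("invalid counts: duplicate gene or sample ids")
        self.values = vals

    # -- basic geometry -------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def library_sizes(self) -> pd.Series:
        """Total mapped reads per sample (column sums)."""
        return self.values.sum(axis=0)

    # -- convenience ----------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        values: np.ndarray,
        gene_ids=None,
        sample_ids=None,
    ) -> "CountMatrix":
        values = np.asarray(values)
        n_genes, n_samples = values.shape
        if gene_ids is None:
            gene_ids = [f"gene_{i + 1:04d}" for i in range(n_genes)]
        if sample_ids is None:
            sample_ids = [f"sample_{j + 1:03d}" for j in range(n_samples)]
        return cls(pd.DataFrame(values, index=gene_ids, columns=sample_ids))

    def drop_allzero_genes(self) -> "CountMatrix":
        keep = self.values.sum(axis=1) > 0
        return CountMatrix(self.values.loc[keep])
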
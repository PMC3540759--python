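"""Core data container: the gene-by-sample expression matrix."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix"]


@dataclass(frozen=True)
class ExpressionMatrix:
    """A p-gene by n-sample matrix of continuous expression values.

    Rows are genes, columns are samples, matching the usual orientation of
    processed microarray series matrices.  Values are assumed to already be
    on a log scale; no transformation is applied here.
    """

    values: np.ndarray
    gene_ids: list[str] = field(default=None)
    sample_ids: list[str] = field(default=None)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError(f"values must be 2-D (genes x samples), got shape {v.shape}")
        p, n = v.shape
        if p < 2 or n < 1:
            raise ValueError(f"need at least 2 genes and 1 sample, got {p} x {n}")
        if not np.all(np.isfinite(v)):
            bad = np.argwhere(~np.isfinite(v))
            raise ValueError(
                f"non-finite expression values at (gene, sample) positions "
                f"{bad[:5].tolist()}{'...' if len(bad) > 5 else ''}"
            )
        object.__setattr__(self, "values", v)
        gids = self.gene_ids if self.gene_ids is not None else [f"g{i}" for i in range(p)]
        sids = (
            self.sample_ids
            if self.sample_ids is not None
            else [f"s{j}" for j in range(n)]
        )
        gids, sids = list(map(str, gids)), list(map(str, sids))
        if len(gids) != p:
            raise ValueError(f"{len(gids)} gene ids for {p} genes")
        if len(sids) != n:
            raise ValueError(f"{len(sids)} sample ids for {n} samples")
        if len(set(gids)) != p:
            dup = sorted({g for g in gids if gids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dup}")
        if len(set(sids)) != n:
            raise ValueError("duplicate sample ids")
        object.__setattr__(self, "gene_ids", gids)
        object.__setattr__(self, "sample_ids", sids)

    @property
    def p(self) -> int:
        """Number of genes."""
        return self.values.shape[0]

    @property
    def n(self) -> int:
        """Number of samples."""
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        """Build from a genes-in-rows DataFrame (index = gene ids)."""
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, keep: list[str]) -> "ExpressionMatrix":
        """Restrict to the given gene ids, preserving their matrix order."""
        keep_set = set(keep)
        missing = keep_set - set(self.gene_ids)
        if missing:
            raise KeyError(f"gene ids not in matrix: {sorted(missing)}")
        idx = [i for i, g in enumerate(self.gene_ids) if g in keep_set]
        return ExpressionMatrix(
            self.values[idx], [self.gene_ids[i] for i in idx], self.sample_ids
        )
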
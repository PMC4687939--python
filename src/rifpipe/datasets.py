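"""Core expression container and its tabular I/O.

The pipeline operates on a gene x sample count matrix with per-gene
transcript lengths and a two-group sample design (conventionally group A =
"IB", the purebred Iberian line, and group B = "IBxDU", the Duroc cross).
FPKM values are derived from the counts unless supplied explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class ExpressionDataset:
    """Gene x sample expression data with lengths and a two-group design.

    Parameters
    ----------
    counts
        Integer count matrix, genes in rows, samples in columns.
    gene_length_bp
        Transcript length per gene in base pairs (positive).
    design
        Mapping sample id -> group label; exactly two distinct labels.
    fpkm
        Optional precomputed FPKM matrix; computed from ``counts`` using
        column sums as total mapped reads when omitted.
    is_trf
        Optional boolean flag per gene marking candidate transcription
        regulators (TRFs).
    """

    counts: pd.DataFrame
    gene_length_bp: pd.Series
    design: pd.Series
    fpkm: pd.DataFrame | None = None
    is_trf: pd.Series | None = None
    _groups: tuple[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.gene_length_bp = self.gene_length_bp.reindex(self.counts.index)
        if self.gene_length_bp.isna().any():
            raise ValueError("every gene needs a length")
        if (self.gene_length_bp <= 0).any():
            raise ValueError("gene lengths must be positive")
        self.design = self.design.reindex(self.counts.columns)
        if self.design.isna().any():
            raise ValueError("every sample needs a group label")
        labels = pd.unique(self.design)
        if len(labels) != 2:
            raise ValueError(f"expected exactly two groups, got {list(labels)}")
        # Group A = lexicographically first label, which makes "IB" the
        # reference group against "IBxDU" under the standard naming.
        self._groups = tuple(sorted(labels))
        if self.fpkm is None:
            from rifpipe.expression import compute_fpkm

            self.fpkm = compute_fpkm(self.counts, self.gene_length_bp)
        else:
            if self.fpkm.shape != self.counts.shape:
                raise ValueError("counts and fpkm must share dimensions")
            self.fpkm = self.fpkm.reindex(
                index=self.counts.index, columns=self.counts.columns
            )
        if self.is_trf is not None:
            self.is_trf = self.is_trf.reindex(self.counts.index).fillna(False)

    # ------------------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def groups(self) -> tuple[str, str]:
        """The two group labels, group A first."""
        return self._groups

    def samples_in(self, group: str) -> list[str]:
        return list(self.design.index[self.design == group])

    def trf_ids(self) -> list[str]:
        if self.is_trf is None:
            return []
        return list(self.gene_ids[self.is_trf.astype(bool)])

    def log_fpkm(self, offset: float = 0.25) -> pd.DataFrame:
        """log2(FPKM + offset); the scale used for e, a, d and correlations."""
        if offset <= 0:
            raise ValueError("offset must be positive")
        return np.log2(self.fpkm + offset)

    def group_mean_fpkm(self) -> pd.DataFrame:
        """Mean FPKM per gene within each group (columns = group labels)."""
        return pd.DataFrame(
            {g: self.fpkm[self.samples_in(g)].mean(axis=1) for g in self.groups}
        )

    # ------------------------------------------------------------------
    def to_files(self, prefix: str | Path) -> dict[str, Path]:
        """Write counts/metadata/design TSVs sharing a path prefix."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = {
            "counts": prefix.with_suffix(".counts.tsv"),
            "genes": prefix.with_suffix(".genes.tsv"),
            "design": prefix.with_suffix(".design.tsv"),
        }
        self.counts.rename_axis("gene").to_csv(paths["counts"], sep="\t")
        meta = pd.DataFrame(
            {
                "length_bp": self.gene_length_bp,
                "is_trf": (
                    self.is_trf.astype(bool)
                    if self.is_trf is not None
                    else pd.Series(False, index=self.gene_ids)
                ),
            }
        )
        meta.rename_axis("gene").to_csv(paths["genes"], sep="\t")
        self.design.rename("group").rename_axis("sample").to_csv(
            paths["design"], sep="\t"
        )
        return paths

    @classmethod
    def from_files(
        cls,
        counts_tsv: str | Path,
        genes_tsv: str | Path,
        design_tsv: str | Path,
    ) -> "ExpressionDataset":
        counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
        meta = pd.read_csv(genes_tsv, sep="\t", index_col=0)
        design = pd.read_csv(design_tsv, sep="\t", index_col=0)["group"]
        is_trf = meta["is_trf"].astype(bool) if "is_trf" in meta else None
        return cls(
            counts=counts,
            gene_length_bp=meta["length_bp"],
            design=design,
            is_trf=is_trf,
        )
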
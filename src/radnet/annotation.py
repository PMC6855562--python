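"""Gene annotation: chromosomal coordinates and chromosomal ordering.

Coordinates are stored internally as 0-based half-open intervals
(BED convention); SEG files keep their native 1-based inclusive
coordinates at the I/O boundary (see :mod:`radnet.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_COLUMNS = ["gene_id", "chrom", "start", "end", "order_index"]


def _chrom_sort_key(chrom: pd.Series) -> pd.Series:
    """Natural ordering: numeric chromosomes first, then X, Y, others."""

    def key(c: str) -> tuple:
        c = str(c)
        body = c[3:] if c.lower().startswith("chr") else c
        if body.isdigit():
            return (0, int(body), "")
        special = {"X": 23, "Y": 24, "MT": 25, "M": 25}
        if body.upper() in special:
            return (0, special[body.upper()], "")
        return (1, 0, body)

    return chrom.map(key)


@dataclass
class GeneAnnotation:
    """Ordered gene annotation table.

    The ``table`` has columns gene_id, chrom, start, end (0-based
    half-open) and order_index, sorted by (chrom, start) with
    order_index a permutation of 0..n-1 in that sort.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in _COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if (t["start"] >= t["end"]).any():
            bad = t.loc[t["start"] >= t["end"], "gene_id"].tolist()[:5]
            raise ValueError(f"annotation has start >= end for genes {bad}")
        if t["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids in annotation")
        order = np.sort(t["order_index"].to_numpy())
        if not np.array_equal(order, np.arange(len(t))):
            raise ValueError("order_index is not a permutation of 0..n-1")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GeneAnnotation":
        """Build an annotation from (gene_id, chrom, start, end) rows.

        Rows are sorted by (chrom, start) using natural chromosome order
        and order_index is assigned along that sort.
        """
        t = frame.loc[:, ["gene_id", "chrom", "start", "end"]].copy()
        t["_key"] = _chrom_sort_key(t["chrom"])
        t = t.sort_values(["_key", "start", "end"], kind="mergesort")
        t = t.drop(columns="_key").reset_index(drop=True)
        t["order_index"] = np.arange(len(t))
        return cls(t)

    @property
    def gene_ids(self) -> list[str]:
        return self.table["gene_id"].tolist()

    @property
    def n_genes(self) -> int:
        return len(self.table)

    def __len__(self) -> int:
        return len(self.table)

    def indexed(self) -> pd.DataFrame:
        return self.table.set_index("gene_id")

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))


def read_annotation(path) -> GeneAnnotation:
    """Read a BED-like TSV (chrom, start, end, gene_id) with header."""
    t = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return GeneAnnotation.from_frame(
        t.rename(columns={c: c.strip() for c in t.columns})
    )


def write_annotation(annotation: GeneAnnotation, path) -> None:
    annotation.table.loc[:, ["chrom", "start", "end", "gene_id"]].to_csv(
        path, sep="\t", index=False
    )
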
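"""Core in-memory containers for genomic annotations, peaks and methylation.

All interval containers use BED-style 0-based half-open coordinates.  GTF
input/output converts to/from the 1-based closed convention at the file
boundary (see :mod:`neutronet.io`).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Dict, Optional

import numpy as np
import pandas as pd

__all__ = ["GenomeAnnotation", "PeakSet", "MethylationTrack", "merge_intervals"]


def merge_intervals(df: pd.DataFrame, merge_adjacent: bool = True) -> pd.DataFrame:
    """Merge overlapping (and, by default, book-ended) intervals per chromosome.

    ``df`` needs columns ``chrom``, ``start``, ``end``.  Returns a sorted frame
    with the merged intervals and an ``n_merged`` column counting how many
    input intervals fed each output interval.
    """
    if df.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_merged"])
    out = []
    for chrom, sub in df.sort_values(["chrom", "start", "end"]).groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e, n = starts[0], ends[0], 1
        for s, e in zip(starts[1:], ends[1:]):
            joined = s <= cur_e if merge_adjacent else s < cur_e
            if joined:
                cur_e = max(cur_e, e)
                n += 1
            else:
                out.append((chrom, cur_s, cur_e, n))
                cur_s, cur_e, n = s, e, 1
        out.append((chrom, cur_s, cur_e, n))
    return pd.DataFrame(out, columns=["chrom", "start", "end", "n_merged"])


@dataclasses.dataclass
class GenomeAnnotation:
    """Per-gene coordinates plus chromosome sizes.

    ``genes`` is indexed by gene ID with columns ``chrom``, ``start``, ``end``
    (0-based half-open gene body), ``strand`` ('+'/'-'), ``tss``, ``tes``
    (point coordinates, strand aware) and ``length`` (gene body bp).
    ``exons`` holds one row per exon (``gene_id``, ``chrom``, ``start``,
    ``end``) and may be None when exon structure is unknown.
    """

    genes: pd.DataFrame
    chrom_sizes: Dict[str, int]
    exons: Optional[pd.DataFrame] = None

    @staticmethod
    def from_gene_table(genes: pd.DataFrame, chrom_sizes: Dict[str, int],
                        exons: Optional[pd.DataFrame] = None) -> "GenomeAnnotation":
        """Build from a minimal (chrom, start, end, strand) gene table."""
        g = genes.copy()
        plus = g["strand"] == "+"
        g["tss"] = np.where(plus, g["start"], g["end"] - 1)
        g["tes"] = np.where(plus, g["end"] - 1, g["start"])
        g["length"] = g["end"] - g["start"]
        return GenomeAnnotation(genes=g, chrom_sizes=dict(chrom_sizes), exons=exons)

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "strand", "tss", "tes", "length"}
        missing = required - set(self.genes.columns)
        if missing:
            raise ValueError(f"annotation gene table missing columns: {sorted(missing)}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def promoters(self, flank: int = 3000) -> pd.DataFrame:
        """TSS +/- ``flank`` windows, clipped to chromosome bounds."""
        g = self.genes
        sizes = g["chrom"].map(self.chrom_sizes).to_numpy()
        start = np.maximum(g["tss"].to_numpy() - flank, 0)
        end = np.minimum(g["tss"].to_numpy() + flank, sizes)
        return pd.DataFrame(
            {"chrom": g["chrom"].to_numpy(), "start": start, "end": end,
             "gene_id": g.index.to_numpy(), "strand": g["strand"].to_numpy()})

    def tts_regions(self, flank: int = 1000) -> pd.DataFrame:
        """TES +/- ``flank`` windows (transcription termination sites)."""
        g = self.genes
        sizes = g["chrom"].map(self.chrom_sizes).to_numpy()
        start = np.maximum(g["tes"].to_numpy() - flank, 0)
        end = np.minimum(g["tes"].to_numpy() + flank, sizes)
        return pd.DataFrame(
            {"chrom": g["chrom"].to_numpy(), "start": start, "end": end,
             "gene_id": g.index.to_numpy(), "strand": g["strand"].to_numpy()})


@dataclasses.dataclass
class PeakSet:
    """ATAC peak intervals with optional per-sample read counts.

    ``peaks`` is indexed by peak name with columns ``chrom``, ``start``,
    ``end`` and optional ``summit`` (offset from start, -1 if absent).
    ``counts`` shares the peak index; its columns are sample IDs.
    ``norm`` records the normalisation state: raw | RPK | TMM_CPM.
    """

    peaks: pd.DataFrame
    counts: Optional[pd.DataFrame] = None
    norm: str = "raw"

    def __post_init__(self) -> None:
        if not (self.peaks["start"] < self.peaks["end"]).all():
            raise ValueError("peak intervals must satisfy start < end")
        if self.counts is not None and not self.peaks.index.equals(self.counts.index):
            self.counts = self.counts.reindex(self.peaks.index)
        if not self._is_sorted():
            warnings.warn("peak set was not coordinate-sorted; sorting", stacklevel=2)
            order = self.peaks.sort_values(["chrom", "start", "end"]).index
            self.peaks = self.peaks.loc[order]
            if self.counts is not None:
                self.counts = self.counts.loc[order]

    def _is_sorted(self) -> bool:
        p = self.peaks
        return p.equals(p.sort_values(["chrom", "start", "end"]))

    @property
    def widths(self) -> pd.Series:
        return self.peaks["end"] - self.peaks["start"]

    def __len__(self) -> int:
        return len(self.peaks)


@dataclasses.dataclass
class MethylationTrack:
    """Per-position (or per-region) methylation rates with read coverage."""

    data: pd.DataFrame  # chrom, start, end, rate, coverage

    def __post_init__(self) -> None:
        d = self.data
        if len(d) and not ((d["rate"] >= 0) & (d["rate"] <= 1)).all():
            raise ValueError("methylation rates must lie in [0, 1]")
        self.data = d.sort_values(["chrom", "start"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def mean_rate(self) -> float:
        return float(self.data["rate"].mean())
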
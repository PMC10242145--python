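"""Lowly methylated regions (LMRs) and their enrichment in gene features and
ATAC peaks.

The LMR caller here is a deliberately simple windowed scan (studies of this
kind usually import an externally called LMR set, which the pipeline
equally accepts as a BED file): the genome is tiled in non-overlapping
windows; a window seeds an LMR when it holds at least three sufficiently
covered positions whose mean methylation rate is at or below ``max_rate``;
adjacent seed windows merge.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from .atac import methylation_to_track, signal_metaprofile
from .containers import GenomeAnnotation, MethylationTrack, PeakSet, merge_intervals
from .stats import bh_adjust, fold_enrichment, hypergeom_upper_p

__all__ = [
    "detect_lmr", "feature_overlap_enrichment", "peak_lmr_enrichment",
    "methylation_metaprofile", "gene_feature_regions",
]

log = logging.getLogger(__name__)

FEATURES = ("promoter", "exon", "intron", "TTS", "intergenic")


def detect_lmr(track: MethylationTrack, window: int = 1000, max_rate: float = 0.3,
               min_cov: int = 3, min_positions: int = 3) -> pd.DataFrame:
    """Call LMRs by tiling each chromosome in ``window``-bp windows.

    Windows qualify when they contain >= ``min_positions`` positions with
    coverage >= ``min_cov`` whose mean rate is <= ``max_rate``; adjacent
    qualifying windows are merged.  Returns a sorted, disjoint interval
    frame (chrom, start, end).
    """
    if len(track) == 0:
        raise ValueError("methylation track is empty")
    d = track.data
    covered = d[d["coverage"] >= min_cov]
    seeds = []
    for chrom, sub in covered.groupby("chrom"):
        win = (sub["start"] // window).to_numpy()
        rates = sub["rate"].to_numpy()
        frame = pd.DataFrame({"win": win, "rate": rates})
        agg = frame.groupby("win")["rate"].agg(["mean", "count"])
        ok = agg[(agg["count"] >= min_positions) & (agg["mean"] <= max_rate)]
        for w in ok.index:
            seeds.append((chrom, int(w) * window, (int(w) + 1) * window))
    lmrs = pd.DataFrame(seeds, columns=["chrom", "start", "end"])
    merged = merge_intervals(lmrs, merge_adjacent=True)
    return merged[["chrom", "start", "end"]].reset_index(drop=True)


def gene_feature_regions(ann: GenomeAnnotation, gene: str,
                         promoter_flank: int = 3000, tts_flank: int = 1000,
                         intergenic_span: int = 10000) -> Dict[str, pd.DataFrame]:
    """Per-gene genomic feature regions used for the LMR x feature grid.

    Promoter = TSS +/- 3 kb, TTS = TES +/- 1 kb, exon/intron from the exon
    model, and (a declared convention) intergenic = the flanking space from
    the promoter edge out to ``intergenic_span`` from the TSS plus the
    mirror-image region beyond the TTS.
    """
    g = ann.genes.loc[gene]
    size = ann.chrom_sizes[g["chrom"]]
    tss, tes = int(g["tss"]), int(g["tes"])

    def clip(s, e):
        s, e = max(int(s), 0), min(int(e), size)
        return (s, e) if e > s else None

    out: Dict[str, pd.DataFrame] = {}
    regions = {"promoter": [clip(tss - promoter_flank, tss + promoter_flank)],
               "TTS": [clip(tes - tts_flank, tes + tts_flank)]}
    exons = []
    if ann.exons is not None:
        exons = [(int(r["start"]), int(r["end"]))
                 for _, r in ann.exons[ann.exons["gene_id"] == gene].iterrows()]
    regions["exon"] = [clip(s, e) for s, e in exons]
    body = (int(g["start"]), int(g["end"]))
    introns = []
    cur = body[0]
    for s, e in sorted(exons):
        if s > cur:
            introns.append((cur, s))
        cur = max(cur, e)
    if cur < body[1]:
        introns.append((cur, body[1]))
    regions["intron"] = [clip(s, e) for s, e in introns]
    lo = min(tss, tes)
    hi = max(tss, tes)
    regions["intergenic"] = [clip(lo - intergenic_span, lo - promoter_flank),
                             clip(hi + tts_flank, hi + intergenic_span)]
    for feat, ivals in regions.items():
        ivals = [iv for iv in ivals if iv is not None]
        out[feat] = pd.DataFrame(ivals, columns=["start", "end"]).assign(chrom=g["chrom"])
    return out


def _overlaps_any(intervals: pd.DataFrame, lmrs_by_chrom) -> bool:
    for _, iv in intervals.iterrows():
        sub = lmrs_by_chrom.get(iv["chrom"])
        if sub is None:
            continue
        starts, ends = sub
        i = np.searchsorted(starts, iv["end"], side="left")
        if (ends[:i] > iv["start"]).any():
            return True
    return False


def feature_overlap_enrichment(lmrs: pd.DataFrame, ann: GenomeAnnotation,
                               gene_sets: Dict[str, Iterable[str]],
                               universe: Iterable[str],
                               promoter_flank: int = 3000, tts_flank: int = 1000
                               ) -> pd.DataFrame:
    """Hypergeometric LMR-overlap enrichment per (feature, gene set) cell.

    For each feature row: the universe is the expressed genes with a
    non-empty region of that feature; K of them have an LMR-overlapping
    region; each gene set contributes k of n.  BH is applied across the
    whole grid.
    """
    universe = [g for g in universe if g in ann.genes.index]
    lmrs_by_chrom = {}
    for chrom, sub in lmrs.groupby("chrom"):
        s = sub.sort_values("start")
        lmrs_by_chrom[chrom] = (s["start"].to_numpy(), s["end"].to_numpy())
    has_lmr: Dict[str, Dict[str, bool]] = {f: {} for f in FEATURES}
    empty: Dict[str, int] = {f: 0 for f in FEATURES}
    for g in universe:
        regions = gene_feature_regions(ann, g, promoter_flank, tts_flank)
        for feat in FEATURES:
            df = regions[feat]
            if df.empty:
                empty[feat] += 1
                continue
            has_lmr[feat][g] = _overlaps_any(df, lmrs_by_chrom)
    rows = []
    for feat in FEATURES:
        feat_universe = list(has_lmr[feat])
        N = len(feat_universe)
        K = sum(has_lmr[feat].values())
        if empty[feat]:
            log.info("%d genes excluded from %s row (empty feature region)", empty[feat], feat)
        for set_name, genes in gene_sets.items():
            members = [g for g in genes if g in has_lmr[feat]]
            n = len(members)
            k = sum(has_lmr[feat][g] for g in members)
            expected = n * K / N if N else float("nan")
            p = 1.0 if (N == 0 or n == 0) else hypergeom_upper_p(k, N, K, n)
            rows.append({"feature": feat, "gene_set": set_name, "k": k, "n": n,
                         "K": K, "N": N, "expected": expected,
                         "fold": fold_enrichment(k, n, K, N) if K else (0.0 if k == 0 else float("nan")),
                         "p": p})
    grid = pd.DataFrame(rows)
    grid["q"] = bh_adjust(grid["p"].to_numpy())
    return grid


def _unit_mask(intervals: pd.DataFrame, chrom_units: Dict[str, int], unit: int) -> Dict[str, np.ndarray]:
    masks = {c: np.zeros(n, dtype=bool) for c, n in chrom_units.items()}
    for _, iv in intervals.iterrows():
        m = masks.get(iv["chrom"])
        if m is None:
            continue
        lo = int(iv["start"]) // unit
        hi = -(-int(iv["end"]) // unit)  # ceil: any overlap marks the unit
        m[lo:min(hi, len(m))] = True
    return masks


def peak_lmr_enrichment(lmrs: pd.DataFrame, peaks: PeakSet,
                        chrom_sizes: Dict[str, int], unit: int = 100
                        ) -> Dict[str, float]:
    """Base-level LMR x ATAC-peak overlap enrichment on ``unit``-bp units.

    The genome is discretised into N units; K lie in peaks, n in LMRs and k
    in both.  fold = (k/n)/(K/N), p is the upper-tail hypergeometric.
    """
    if len(lmrs) == 0 or len(peaks) == 0:
        raise ValueError("peak_lmr_enrichment needs non-empty LMRs and peaks")
    chrom_units = {c: -(-s // unit) for c, s in chrom_sizes.items()}
    peak_masks = _unit_mask(peaks.peaks, chrom_units, unit)
    lmr_masks = _unit_mask(lmrs, chrom_units, unit)
    N = int(sum(chrom_units.values()))
    K = int(sum(m.sum() for m in peak_masks.values()))
    n = int(sum(m.sum() for m in lmr_masks.values()))
    k = int(sum((peak_masks[c] & lmr_masks[c]).sum() for c in chrom_units))
    fold = fold_enrichment(k, n, K, N)
    if not np.isfinite(fold):
        raise ValueError("fold undefined (no peak units)")
    return {"overlap_bp": float(k * unit), "k": k, "n": n, "K": K, "N": N,
            "fold": float(fold), "p": hypergeom_upper_p(k, N, K, n)}


def methylation_metaprofile(track: MethylationTrack, anchors: pd.DataFrame,
                            chrom_sizes: Dict[str, int], flank: int = 2000,
                            bins: int = 100) -> Tuple[np.ndarray, np.ndarray]:
    """Mean methylation profile around anchors (TSSs or peak centres)."""
    return signal_metaprofile(methylation_to_track(track), anchors, chrom_sizes,
                              flank=flank, bins=bins)
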
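"""Consensus peaks, feature annotation, TMM/CPM normalisation, promoter
open-chromatin statistics and signal metaprofiles.

Peak counts are standardised as reads per kilobase (RPK), scaled between
samples by trimmed-mean-of-M-values (TMM) factors (30% M-trim, 5% A-trim,
upper-quartile reference) and expressed as counts per million on the
effective library sizes -- the usual edgeR-style treatment, authored here so
the pipeline is self-contained.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .containers import GenomeAnnotation, MethylationTrack, PeakSet, merge_intervals

__all__ = [
    "merge_consensus_peaks", "annotate_peaks", "tmm_factors",
    "normalize_peak_counts", "promoter_ocr_stats",
    "expression_accessibility_correlation", "signal_metaprofile",
]

log = logging.getLogger(__name__)

FEATURE_PRIORITY = ("promoter", "TTS", "exon", "intron", "intergenic")


def merge_consensus_peaks(replicate_peaksets: Sequence[PeakSet]) -> PeakSet:
    """Union-merge peak intervals across replicates into consensus peaks.

    Overlapping or book-ended intervals become one consensus peak whose
    per-sample counts are the sums over the contributing input peaks.
    """
    if len(replicate_peaksets) == 0:
        raise ValueError("need at least one replicate peak set")
    frames, count_frames = [], []
    for ps in replicate_peaksets:
        frames.append(ps.peaks[["chrom", "start", "end"]])
        if ps.counts is not None:
            count_frames.append(ps.counts)
    allp = pd.concat(frames, ignore_index=True)
    merged = merge_intervals(allp, merge_adjacent=True)
    merged["name"] = [f"consensus_{i + 1}" for i in range(len(merged))]
    merged = merged.set_index("name")

    counts = None
    if count_frames:
        samples = sorted({c for df in count_frames for c in df.columns})
        counts = pd.DataFrame(0.0, index=merged.index, columns=samples)
        for ps in replicate_peaksets:
            if ps.counts is None:
                continue
            idx = _assign_to_merged(ps.peaks, merged)
            for sample in ps.counts.columns:
                contrib = pd.Series(ps.counts[sample].to_numpy(), index=idx)
                add = contrib.groupby(level=0).sum()
                counts.loc[add.index, sample] += add
    return PeakSet(peaks=merged[["chrom", "start", "end"]].assign(summit=-1),
                   counts=counts, norm="raw")


def _assign_to_merged(peaks: pd.DataFrame, merged: pd.DataFrame) -> List[str]:
    """Map each input peak to the merged interval containing it."""
    out = []
    by_chrom = {c: sub for c, sub in merged.reset_index().groupby("chrom")}
    for _, row in peaks.iterrows():
        sub = by_chrom[row["chrom"]]
        starts = sub["start"].to_numpy()
        i = int(np.searchsorted(starts, row["start"], side="right") - 1)
        out.append(sub.iloc[i]["name"])
    return out


def _interval_lookup(regions: pd.DataFrame):
    """Build a per-chromosome sorted-interval membership test (any overlap of
    a point).  Regions may overlap each other."""
    by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in regions.groupby("chrom"):
        s = sub.sort_values("start")
        starts = s["start"].to_numpy()
        ends = np.maximum.accumulate(s["end"].to_numpy())
        by_chrom[chrom] = (starts, ends)

    def contains(chrom: str, pos: int) -> bool:
        if chrom not in by_chrom:
            return False
        starts, ends = by_chrom[chrom]
        i = np.searchsorted(starts, pos, side="right") - 1
        return i >= 0 and pos < ends[i]

    return contains


def annotate_peaks(peaks: PeakSet, ann: GenomeAnnotation,
                   promoter_flank: int = 3000, tts_flank: int = 1000
                   ) -> Tuple[pd.Series, pd.DataFrame]:
    """Label each peak by its midpoint with priority
    promoter > TTS > exon > intron > intergenic.

    Promoters are strand-aware TSS +/- ``promoter_flank`` windows; TTS
    regions are TES +/- ``tts_flank``.  Returns the per-peak labels and a
    category-fraction summary table.
    """
    in_promoter = _interval_lookup(ann.promoters(promoter_flank))
    in_tts = _interval_lookup(ann.tts_regions(tts_flank))
    if ann.exons is not None:
        in_exon = _interval_lookup(ann.exons)
    else:
        in_exon = lambda chrom, pos: False  # noqa: E731
    bodies = ann.genes.reset_index()[["chrom", "start", "end"]]
    in_body = _interval_lookup(bodies)
    known = set(ann.chrom_sizes)

    labels = []
    for name, row in peaks.peaks.iterrows():
        chrom = row["chrom"]
        mid = (int(row["start"]) + int(row["end"])) // 2
        if chrom not in known:
            warnings.warn(f"peak {name} on unknown chromosome {chrom!r}; labelled intergenic")
            labels.append("intergenic")
            continue
        if in_promoter(chrom, mid):
            labels.append("promoter")
        elif in_tts(chrom, mid):
            labels.append("TTS")
        elif in_exon(chrom, mid):
            labels.append("exon")
        elif in_body(chrom, mid):
            labels.append("intron")
        else:
            labels.append("intergenic")
    s = pd.Series(labels, index=peaks.peaks.index, name="feature")
    summary = (s.value_counts(normalize=True)
               .reindex(FEATURE_PRIORITY, fill_value=0.0)
               .rename("fraction").rename_axis("feature").reset_index())
    return s, summary


def tmm_factors(rpk: pd.DataFrame, m_trim: float = 0.30, a_trim: float = 0.05) -> pd.Series:
    """TMM scale factors on an RPK matrix (features x samples).

    Reference sample: the one whose 75th percentile of library-scaled values
    is closest to the mean 75th percentile.  For each sample, M (log ratio)
    and A (log abundance) values vs. the reference are computed over features
    with non-zero values in both samples, double-trimmed (30% of M, 5% of A
    from each tail by rank) and the factor is 2**mean(M).  Factors are
    renormalised to have geometric mean 1.
    """
    lib = rpk.sum(axis=0)
    if (lib == 0).any():
        raise ValueError(f"all-zero sample(s): {list(lib.index[lib == 0])}")
    scaled = rpk.div(lib, axis=1)
    q75 = scaled.quantile(0.75, axis=0)
    ref = (q75 - q75.mean()).abs().idxmin()
    yr = rpk[ref].to_numpy(dtype=float)
    lr = float(lib[ref])
    factors = {}
    for sample in rpk.columns:
        if sample == ref:
            factors[sample] = 1.0
            continue
        y = rpk[sample].to_numpy(dtype=float)
        both = (y > 0) & (yr > 0)
        if both.sum() == 0:
            factors[sample] = 1.0
            continue
        m = np.log2((y[both] / lib[sample]) / (yr[both] / lr))
        a = 0.5 * np.log2((y[both] / lib[sample]) * (yr[both] / lr))
        n = len(m)
        lo_m, hi_m = np.floor(n * m_trim), np.ceil(n * (1 - m_trim))
        lo_a, hi_a = np.floor(n * a_trim), np.ceil(n * (1 - a_trim))
        rm = _sps.rankdata(m, method="ordinal")
        ra = _sps.rankdata(a, method="ordinal")
        keep = (rm > lo_m) & (rm <= hi_m) & (ra > lo_a) & (ra <= hi_a)
        factors[sample] = float(2 ** np.mean(m[keep])) if keep.any() else 1.0
    f = pd.Series(factors).reindex(rpk.columns)
    f = f / np.exp(np.mean(np.log(f)))
    return f


def normalize_peak_counts(peaks: PeakSet) -> PeakSet:
    """raw counts -> RPK -> TMM-scaled CPM (norm state ``TMM_CPM``)."""
    if peaks.norm != "raw":
        raise ValueError("normalize_peak_counts expects raw counts")
    if peaks.counts is None or peaks.counts.shape[1] < 1:
        raise ValueError("peak set has no counts to normalize")
    width_kb = (peaks.peaks["end"] - peaks.peaks["start"]) / 1000.0
    rpk = peaks.counts.div(width_kb, axis=0)
    f = tmm_factors(rpk)
    eff_lib = rpk.sum(axis=0) * f
    cpm = rpk.div(eff_lib, axis=1) * 1e6
    return PeakSet(peaks=peaks.peaks.copy(), counts=cpm, norm="TMM_CPM")


def promoter_ocr_stats(peaks: PeakSet, ann: GenomeAnnotation, flank: int = 3000,
                       sample: Optional[str] = None) -> pd.DataFrame:
    """Per-gene promoter open-chromatin intensity, clipped length and peak count.

    A peak contributes to a gene when it overlaps the TSS +/- ``flank``
    window by >= 1 bp; intensity sums its normalized counts (mean across
    samples unless ``sample`` picks one), length sums the clipped overlap
    peak-by-peak, and a peak spanning two promoters counts fully for both.
    Genes without overlap are retained with zeros.
    """
    if peaks.counts is None:
        raise ValueError("promoter_ocr_stats needs peak counts")
    vals = peaks.counts[sample] if sample else peaks.counts.mean(axis=1)
    prom = ann.promoters(flank)
    p = peaks.peaks
    out = pd.DataFrame(0.0, index=ann.genes.index, columns=["intensity", "length", "n_peaks"])
    by_chrom = {c: sub.assign(value=vals.loc[sub.index]) for c, sub in p.groupby("chrom")}
    for _, pr in prom.iterrows():
        sub = by_chrom.get(pr["chrom"])
        if sub is None:
            continue
        ov = (sub["start"] < pr["end"]) & (sub["end"] > pr["start"])
        if not ov.any():
            continue
        hit = sub[ov]
        clip = (np.minimum(hit["end"], pr["end"]) - np.maximum(hit["start"], pr["start"]))
        gid = pr["gene_id"]
        out.loc[gid, "intensity"] = float(hit["value"].sum())
        out.loc[gid, "length"] = float(clip.sum())
        out.loc[gid, "n_peaks"] = float(len(hit))
    out["n_peaks"] = out["n_peaks"].astype(int)
    return out


def expression_accessibility_correlation(stats: pd.DataFrame, expr: pd.Series,
                                         gene_sets: Dict[str, Iterable[str]]
                                         ) -> pd.DataFrame:
    """Pearson r between log2(expression + 1) and log2(promoter OCR stats + 1).

    ``expr`` is a per-gene expression vector (e.g. mean TPM in the assayed
    cell type); each requested gene set gets r/p for intensity and length.
    """
    rows = []
    for name, genes in gene_sets.items():
        genes = [g for g in genes if g in stats.index and g in expr.index]
        if len(genes) < 3:
            raise ValueError(f"gene set {name!r} has fewer than 3 usable genes")
        e = np.log2(expr.loc[genes].to_numpy(dtype=float) + 1.0)
        res = {"gene_set": name, "n": len(genes)}
        for col in ("intensity", "length"):
            x = np.log2(stats.loc[genes, col].to_numpy(dtype=float) + 1.0)
            if np.ptp(x) == 0 or np.ptp(e) == 0:
                res[f"r_{col}"], res[f"p_{col}"] = np.nan, np.nan
            else:
                r, p = _sps.pearsonr(e, x)
                res[f"r_{col}"], res[f"p_{col}"] = float(r), float(p)
        rows.append(res)
    return pd.DataFrame(rows).set_index("gene_set")


def signal_metaprofile(track: pd.DataFrame, anchors: pd.DataFrame,
                       chrom_sizes: Dict[str, int], flank: int = 2000,
                       bins: int = 100, value_col: str = "value"
                       ) -> Tuple[np.ndarray, np.ndarray]:
    """Bin-averaged signal around anchors (deepTools computeMatrix style).

    ``track`` holds sorted, non-overlapping intervals (chrom, start, end,
    value); ``anchors`` has chrom, pos and optional strand.  Each anchor
    contributes one row of ``bins`` means over [pos - flank, pos + flank),
    reversed for '-' strand anchors; base pairs without data are missing and
    ignored by the column-mean profile.  Anchors outside their chromosome
    give all-missing rows with a warning.
    """
    if len(anchors) == 0:
        raise ValueError("anchor list is empty")
    if (2 * flank) % bins != 0:
        raise ValueError("2*flank must be divisible by bins")
    width = 2 * flank
    binsize = width // bins
    by_chrom = {}
    for chrom, sub in track.groupby("chrom"):
        s = sub.sort_values("start")
        by_chrom[chrom] = (s["start"].to_numpy(), s["end"].to_numpy(),
                           s[value_col].to_numpy(dtype=float))
    mat = np.full((len(anchors), bins), np.nan)
    for i, (_, a) in enumerate(anchors.iterrows()):
        chrom, pos = a["chrom"], int(a["pos"])
        size = chrom_sizes.get(chrom)
        if size is None or pos < 0 or pos >= size:
            warnings.warn(f"anchor {chrom}:{pos} outside chromosome bounds")
            continue
        row = np.full(width, np.nan)
        lo, hi = pos - flank, pos + flank
        if chrom in by_chrom:
            starts, ends, vals = by_chrom[chrom]
            j0 = np.searchsorted(ends, lo, side="right")
            j1 = np.searchsorted(starts, hi, side="left")
            for j in range(j0, j1):
                s = max(int(starts[j]), lo, 0)
                e = min(int(ends[j]), hi, size)
                if e > s:
                    row[s - lo:e - lo] = vals[j]
        # positions beyond the chromosome stay missing
        if lo < 0:
            row[:-lo] = np.nan
        if hi > size:
            row[size - hi:] = np.nan
        if str(a.get("strand", "+")) == "-":
            row = row[::-1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            mat[i] = np.nanmean(row.reshape(bins, binsize), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        profile = np.nanmean(mat, axis=0)
    return mat, profile


def methylation_to_track(track: MethylationTrack) -> pd.DataFrame:
    """Adapter: a MethylationTrack as a (chrom, start, end, value) signal."""
    d = track.data
    return pd.DataFrame({"chrom": d["chrom"], "start": d["start"],
                         "end": d["end"], "value": d["rate"]})


def peaks_to_track(peaks: PeakSet, sample: Optional[str] = None) -> pd.DataFrame:
    """Adapter: peak normalized counts as a signal track (0 elsewhere implied)."""
    vals = peaks.counts[sample] if sample else peaks.counts.mean(axis=1)
    p = peaks.peaks
    return pd.DataFrame({"chrom": p["chrom"], "start": p["start"],
                         "end": p["end"], "value": vals.to_numpy(dtype=float)})
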
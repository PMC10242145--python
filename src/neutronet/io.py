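"""Readers and writers for the plain-text genomic formats used by the pipeline.

Conventions
-----------
* FASTA via Biopython.
* GTF is 1-based closed on disk and converted to 0-based half-open on load.
* narrowPeak (BED6+4), bedGraph and chrom.sizes follow their usual BED-style
  0-based half-open conventions.
* A methylation track is written as *two* bedGraph files (rate + coverage)
  because the 4-column format holds a single value per interval.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import GenomeAnnotation, MethylationTrack, PeakSet

__all__ = [
    "write_fasta", "read_fasta", "write_gtf", "read_gtf",
    "write_chrom_sizes", "read_chrom_sizes",
    "write_narrowpeak", "read_narrowpeak",
    "write_counts", "read_counts",
    "write_methylation", "read_methylation",
    "write_bedgraph", "read_bedgraph",
    "write_bed", "read_bed",
    "write_ppi", "read_ppi",
    "write_json", "read_json",
]


# ---------------------------------------------------------------- FASTA

def write_fasta(seqs: Dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ------------------------------------------------------------------ GTF

def write_gtf(ann: GenomeAnnotation, path) -> None:
    """Write gene (and exon, when known) features; 1-based closed coordinates."""
    lines = []
    for gid, row in ann.genes.iterrows():
        attrs = f'gene_id "{gid}";'
        lines.append("\t".join([
            str(row["chrom"]), "neutronet", "gene",
            str(int(row["start"]) + 1), str(int(row["end"])),
            ".", row["strand"], ".", attrs]))
        if ann.exons is not None:
            sub = ann.exons[ann.exons["gene_id"] == gid]
            for i, (_, ex) in enumerate(sub.sort_values("start").iterrows(), start=1):
                attrs = f'gene_id "{gid}"; exon_number "{i}";'
                lines.append("\t".join([
                    str(ex["chrom"]), "neutronet", "exon",
                    str(int(ex["start"]) + 1), str(int(ex["end"])),
                    ".", row["strand"], ".", attrs]))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def _gtf_attr(attrs: str, key: str) -> str:
    for field in attrs.strip().split(";"):
        field = field.strip()
        if field.startswith(key + " "):
            return field.split(" ", 1)[1].strip().strip('"')
    raise ValueError(f"attribute {key!r} not found in GTF attributes: {attrs!r}")


def read_gtf(path, chrom_sizes: Optional[Dict[str, int]] = None) -> GenomeAnnotation:
    genes, exons = [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, feature, start, end, strand, attrs = f[0], f[2], int(f[3]), int(f[4]), f[6], f[8]
            gid = _gtf_attr(attrs, "gene_id")
            if feature == "gene":
                genes.append((gid, chrom, start - 1, end, strand))
            elif feature == "exon":
                exons.append((gid, chrom, start - 1, end))
    gdf = pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end", "strand"])
    gdf = gdf.set_index("gene_id")
    edf = pd.DataFrame(exons, columns=["gene_id", "chrom", "start", "end"]) if exons else None
    if chrom_sizes is None:
        chrom_sizes = {c: int(sub["end"].max()) for c, sub in gdf.groupby("chrom")}
    return GenomeAnnotation.from_gene_table(gdf, chrom_sizes, exons=edf)


# ---------------------------------------------------------- chrom.sizes

def write_chrom_sizes(sizes: Dict[str, int], path) -> None:
    pd.Series(sizes).rename_axis("chrom").to_csv(path, sep="\t", header=False)


def read_chrom_sizes(path) -> Dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


# ------------------------------------------------------------ narrowPeak

_NARROWPEAK_COLS = ["chrom", "start", "end", "name", "score", "strand",
                    "signalValue", "pValue", "qValue", "peak"]


def write_narrowpeak(ps: PeakSet, path) -> None:
    p = ps.peaks
    df = pd.DataFrame({
        "chrom": p["chrom"], "start": p["start"].astype(int), "end": p["end"].astype(int),
        "name": p.index, "score": 0, "strand": ".",
        "signalValue": p.get("signalValue", pd.Series(0.0, index=p.index)),
        "pValue": -1.0, "qValue": -1.0,
        "peak": p.get("summit", pd.Series(-1, index=p.index)).astype(int),
    })
    df.to_csv(path, sep="\t", header=False, index=False)


def read_narrowpeak(path, counts: Optional[pd.DataFrame] = None) -> PeakSet:
    df = pd.read_csv(path, sep="\t", header=None, names=_NARROWPEAK_COLS)
    df["chrom"] = df["chrom"].astype(str)
    peaks = df.set_index("name")[["chrom", "start", "end", "signalValue", "peak"]]
    peaks = peaks.rename(columns={"peak": "summit"})
    return PeakSet(peaks=peaks, counts=counts)


# ------------------------------------------------------------ count TSVs

def write_counts(counts: pd.DataFrame, path, index_name: str = "feature") -> None:
    counts.rename_axis(index_name).to_csv(path, sep="\t")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# -------------------------------------------------------------- bedGraph

def write_bedgraph(df: pd.DataFrame, value_col: str, path) -> None:
    out = df[["chrom", "start", "end", value_col]].copy()
    out["start"] = out["start"].astype(int)
    out["end"] = out["end"].astype(int)
    if out[value_col].dtype.kind == "f":
        # 6 decimals keeps write -> read -> write byte-stable
        out[value_col] = out[value_col].round(6)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path, value_col: str = "value") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", value_col])
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_methylation(track: MethylationTrack, rate_path, coverage_path) -> None:
    write_bedgraph(track.data, "rate", rate_path)
    write_bedgraph(track.data, "coverage", coverage_path)


def read_methylation(rate_path, coverage_path=None) -> MethylationTrack:
    rate = read_bedgraph(rate_path, "rate")
    if coverage_path is not None:
        cov = read_bedgraph(coverage_path, "coverage")
        rate["coverage"] = cov["coverage"].to_numpy()
    else:
        rate["coverage"] = 1
    return MethylationTrack(rate)


# ------------------------------------------------------------------ BED

def write_bed(df: pd.DataFrame, path) -> None:
    out = df[["chrom", "start", "end"]].copy()
    out["start"] = out["start"].astype(int)
    out["end"] = out["end"].astype(int)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"])
    df["chrom"] = df["chrom"].astype(str)
    return df


# ------------------------------------------------------------------ PPI

def write_ppi(edges: pd.DataFrame, path) -> None:
    edges[["gene_a", "gene_b"]].to_csv(path, sep="\t", index=False)


def read_ppi(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["gene_a", "gene_b"]:
        df = df.rename(columns=dict(zip(df.columns[:2], ["gene_a", "gene_b"])))
    return df[["gene_a", "gene_b"]]


# ----------------------------------------------------------------- JSON

def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
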
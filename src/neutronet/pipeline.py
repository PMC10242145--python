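"""End-to-end pipeline driver: configuration, stage execution, manifest.

The pipeline chains: count filtering -> TPM -> group-aware quantile
normalisation -> SEG/HEG calling -> PCIT co-expression network -> clusters
-> NSG/NSTF/MSTF calls -> consensus ATAC peaks -> feature annotation ->
RPK/TMM/CPM normalisation -> promoter OCR statistics -> expression x
accessibility correlations -> motif presence and enrichment -> methylation
LMRs, enrichment grids and metaprofiles -> regulatory network assembly.
Every stage writes its outputs under the configured output directory and is
recorded (with content hashes and timings) in a JSON run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import atac as natac
from . import coexpression as ncoex
from . import expression as nexpr
from . import io as nio
from . import methylation as nmeth
from . import motifs as nmot

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)

_PATH_KEYS = ("expression", "samples", "gene_lengths", "gtf", "chrom_sizes",
              "peaks", "peak_counts", "methylation_rate", "methylation_coverage",
              "pwms", "ppi", "tf_list", "genome")
_OPTIONAL_PATH_KEYS = ("lmr_bed",)


@dataclasses.dataclass
class PipelineConfig:
    """Input paths, thresholds and run parameters.

    All thresholds default to their conventional values: fold change 2, q 0.05,
    co-expression |r| 0.95, HEG fraction 0.25, promoter flank 3 kb,
    metaprofile flank 2 kb, LMR max rate 0.3.
    """

    paths: Dict[str, str]
    outdir: str
    target_cell_type: str = "neutrophil"
    comparator_cell_type: str = "monocyte_dc"
    fc_threshold: float = 2.0
    q_threshold: float = 0.05
    r_threshold: float = 0.95
    heg_fraction: float = 0.25
    min_count: int = 4
    promoter_flank: int = 3000
    metaprofile_flank: int = 2000
    metaprofile_bins: int = 100
    lmr_max_rate: float = 0.3
    lmr_window: int = 1000
    n_clusters: int = 3
    seed: int = 1

    def validate(self) -> None:
        checks = [
            (0 < self.q_threshold <= 1, "q_threshold must be in (0, 1]"),
            (self.fc_threshold >= 1, "fc_threshold must be >= 1"),
            (0 < self.r_threshold <= 1, "r_threshold must be in (0, 1]"),
            (0 < self.heg_fraction <= 1, "heg_fraction must be in (0, 1]"),
            (0 <= self.lmr_max_rate <= 1, "lmr_max_rate must be in [0, 1]"),
            (self.promoter_flank > 0, "promoter_flank must be positive"),
            (self.metaprofile_flank > 0, "metaprofile_flank must be positive"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)
        for key in _PATH_KEYS:
            if key not in self.paths:
                raise ValueError(f"missing input path: {key}")
            if not Path(self.paths[key]).exists():
                raise FileNotFoundError(f"{key}: {self.paths[key]}")

    @staticmethod
    def from_file(path, outdir: Optional[str] = None, **overrides) -> "PipelineConfig":
        """Parse a plain key=value config file (paths + thresholds)."""
        fields = {f.name: f for f in dataclasses.fields(PipelineConfig)}
        paths: Dict[str, str] = {}
        kwargs: Dict[str, object] = {}
        base = Path(path).parent
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key in _PATH_KEYS or key in _OPTIONAL_PATH_KEYS:
                p = Path(value)
                paths[key] = str(p if p.is_absolute() else base / p)
            elif key in fields and key != "paths":
                typ = fields[key].type
                if typ in ("int", int):
                    kwargs[key] = int(value)
                elif typ in ("float", float):
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
            else:
                raise ValueError(f"unknown config key: {key}")
        kwargs.update(overrides)
        if outdir is not None:
            kwargs["outdir"] = outdir
        kwargs.setdefault("outdir", str(base / "results"))
        return PipelineConfig(paths=paths, **kwargs)

    def write(self, path) -> None:
        lines = [f"{k} = {v}" for k, v in sorted(self.paths.items())]
        for f in dataclasses.fields(self):
            if f.name in ("paths", "outdir"):
                continue
            lines.append(f"{f.name} = {getattr(self, f.name)}")
        Path(path).write_text("\n".join(lines) + "\n")


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, config: PipelineConfig):
        self.stages: List[dict] = []
        self.config = config
        self.t0 = time.time()

    def record(self, name: str, outputs: List[str], t_start: float) -> None:
        self.stages.append({
            "stage": name,
            "outputs": [str(o) for o in outputs],
            "sha256": {Path(o).name: _sha256(o) for o in outputs},
            "seconds": round(time.time() - t_start, 3),
        })

    def to_dict(self) -> dict:
        import neutronet
        return {
            "package_version": neutronet.__version__,
            "seed": self.config.seed,
            "input_sha256": {k: _sha256(v) for k, v in sorted(self.config.paths.items())
                             if Path(v).exists()},
            "stages": self.stages,
            "total_seconds": round(time.time() - self.t0, 3),
        }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to run_manifest.json).

    Any stage failure raises with the stage name prepended so partial runs
    are easy to diagnose; outputs written before the failure remain on disk.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config)
    state: Dict[str, object] = {}
    stage_fns = [
        ("load_and_filter", _stage_load_and_filter),
        ("normalize_expression", _stage_normalize),
        ("seg_heg", _stage_seg_heg),
        ("coexpression_network", _stage_network),
        ("clusters", _stage_clusters),
        ("specificity", _stage_specificity),
        ("consensus_peaks", _stage_consensus_peaks),
        ("peak_annotation", _stage_peak_annotation),
        ("peak_normalization", _stage_peak_normalization),
        ("promoter_ocr", _stage_promoter_ocr),
        ("expression_accessibility", _stage_expr_atac_correlation),
        ("motif_presence", _stage_motif_presence),
        ("motif_enrichment", _stage_motif_enrichment),
        ("methylation", _stage_methylation),
        ("network_assembly", _stage_assembly),
    ]
    for name, fn in stage_fns:
        t = time.time()
        try:
            outputs = fn(config, state, out)
        except Exception as exc:  # pragma: no cover - error path
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest.record(name, outputs, t)
    doc = manifest.to_dict()
    nio.write_json(doc, out / "run_manifest.json")
    return doc


# ------------------------------------------------------------------ stages

def _stage_load_and_filter(cfg, state, out):
    counts = nio.read_counts(cfg.paths["expression"])
    samples = pd.read_csv(cfg.paths["samples"], sep="\t", index_col=0)
    lengths = pd.read_csv(cfg.paths["gene_lengths"], sep="\t", index_col=0)["length"]
    m = nexpr.ExpressionMatrix(counts, samples, gene_lengths=lengths, unit="counts")
    state["counts"] = nexpr.filter_low_genes(m, cfg.min_count)
    state["ann"] = nio.read_gtf(cfg.paths["gtf"],
                                nio.read_chrom_sizes(cfg.paths["chrom_sizes"]))
    path = out / "filtered_counts.tsv"
    nio.write_counts(state["counts"].values, path, index_name="gene")
    return [path]

def _stage_normalize(cfg, state, out):
    # TPM feeds the replicate-based contrasts; the group-aware quantile
    # normalisation (which by construction removes within-group variance)
    # feeds the co-expression profiles only.
    state["tpm"] = nexpr.compute_tpm(state["counts"])
    state["norm"] = nexpr.group_quantile_normalize(state["tpm"])
    p1 = out / "tpm.tsv"
    nio.write_counts(state["tpm"].values.round(4), p1, index_name="gene")
    p2 = out / "normalized_tpm.tsv"
    nio.write_counts(state["norm"].values.round(4), p2, index_name="gene")
    return [p1, p2]

def _stage_seg_heg(cfg, state, out):
    e = nexpr.call_enriched_genes(state["tpm"], cfg.fc_threshold, cfg.q_threshold)
    state["heg"] = nexpr.select_heg(e, cfg.heg_fraction)
    state["enrichment"] = e
    path = out / "enrichment.tsv"
    e.table.to_csv(path, sep="\t", index=False)
    return [path]

def _stage_network(cfg, state, out):
    segs = state["enrichment"].seg_genes(cfg.target_cell_type)
    state["segs"] = segs
    if len(segs) < 3:
        raise ValueError(f"only {len(segs)} SEGs in {cfg.target_cell_type}; "
                         "cannot build a co-expression network")
    corr = ncoex.pearson_matrix(state["norm"], segs)
    pcit = ncoex.pcit_prune(corr)
    net = ncoex.build_network(corr, pcit, cfg.r_threshold,
                              enrichment=state["enrichment"], m=state["tpm"],
                              cell_type=cfg.target_cell_type)
    state["corr"], state["net"] = corr, net
    edge_path = out / "coexpression_edges.tsv"
    net.write_edge_tsv(edge_path)
    gml = out / "coexpression_network.graphml"
    net.write_graphml(gml)
    return [edge_path, gml]

def _stage_clusters(cfg, state, out):
    net = state["net"]
    if len(net.edges) == 0:
        labels = pd.Series(dtype=int, name="cluster")
    else:
        k = min(cfg.n_clusters, max(len(net.nodes), 1))
        labels = ncoex.cluster_network(net, state["norm"], k=k)
    state["clusters"] = labels
    path = out / "network_clusters.tsv"
    labels.rename_axis("gene").to_csv(path, sep="\t")
    return [path]

def _stage_specificity(cfg, state, out):
    tf_list = [ln.strip() for ln in Path(cfg.paths["tf_list"]).read_text().splitlines()
               if ln.strip()]
    state["tf_list"] = tf_list
    calls = ncoex.call_specific_genes(
        state["enrichment"], state["net"], state["tpm"], tf_list,
        target=cfg.target_cell_type, comparator=cfg.comparator_cell_type,
        fc_threshold=cfg.fc_threshold, q_threshold=cfg.q_threshold)
    state["specificity"] = calls
    path = out / "specificity_calls.tsv"
    calls.to_csv(path, sep="\t")
    return [path]

def _stage_consensus_peaks(cfg, state, out):
    counts = nio.read_counts(cfg.paths["peak_counts"])
    raw = nio.read_narrowpeak(cfg.paths["peaks"], counts=counts)
    consensus = natac.merge_consensus_peaks([raw])
    state["peaks"] = consensus
    path = out / "consensus_peaks.narrowPeak"
    nio.write_narrowpeak(consensus, path)
    return [path]

def _stage_peak_annotation(cfg, state, out):
    labels, summary = natac.annotate_peaks(state["peaks"], state["ann"],
                                           promoter_flank=cfg.promoter_flank)
    state["peak_labels"] = labels
    p1, p2 = out / "peak_features.tsv", out / "peak_feature_summary.tsv"
    labels.rename_axis("peak").to_csv(p1, sep="\t")
    summary.to_csv(p2, sep="\t", index=False)
    return [p1, p2]

def _stage_peak_normalization(cfg, state, out):
    norm = natac.normalize_peak_counts(state["peaks"])
    state["norm_peaks"] = norm
    path = out / "normalized_peak_counts.tsv"
    nio.write_counts(norm.counts.round(4), path, index_name="peak")
    return [path]

def _stage_promoter_ocr(cfg, state, out):
    stats = natac.promoter_ocr_stats(state["norm_peaks"], state["ann"],
                                     flank=cfg.promoter_flank)
    state["ocr"] = stats
    path = out / "promoter_ocr_stats.tsv"
    stats.rename_axis("gene").to_csv(path, sep="\t")
    return [path]

def _stage_expr_atac_correlation(cfg, state, out):
    tpm = state["tpm"]
    expr = tpm.cell_type_means()[cfg.target_cell_type]
    segs = state["segs"]
    ocr = state["ocr"]
    with_ocr = [g for g in segs if g in ocr.index and ocr.loc[g, "n_peaks"] > 0]
    sets = {"all": list(expr.index), "SEG": segs, "SEG_with_OCR": with_ocr}
    sets = {k: v for k, v in sets.items() if len(v) >= 3}
    table = natac.expression_accessibility_correlation(ocr, expr, sets)
    state["expr_atac"] = table
    path = out / "expression_accessibility_correlation.tsv"
    table.to_csv(path, sep="\t")
    return [path]

def _stage_motif_presence(cfg, state, out):
    genome = nio.read_fasta(cfg.paths["genome"])
    pwms = nmot.read_pwms(cfg.paths["pwms"])
    state["pwms"] = pwms
    ann = state["ann"]
    prom = ann.promoters(cfg.promoter_flank).set_index("gene_id")
    peaks = state["norm_peaks"].peaks
    intervals: Dict[str, list] = {}
    for g, pr in prom.iterrows():
        sub = peaks[(peaks["chrom"] == pr["chrom"]) & (peaks["start"] < pr["end"])
                    & (peaks["end"] > pr["start"])]
        ivals = [(r["chrom"], max(int(r["start"]), int(pr["start"])),
                  min(int(r["end"]), int(pr["end"]))) for _, r in sub.iterrows()]
        if ivals:
            intervals[g] = ivals
    scannable_genes = sorted(intervals)
    presence, scannable = nmot.motif_presence_table(scannable_genes, intervals,
                                                    genome, pwms)
    state["presence"], state["scannable"] = presence, scannable
    state["promoter_peak_intervals"] = intervals
    path = out / "motif_presence.tsv"
    presence.to_csv(path, sep="\t")
    return [path]

def _stage_motif_enrichment(cfg, state, out):
    spec = state["specificity"]
    nsg = sorted(spec.index[spec["nsg"]])
    background = sorted(state["presence"].index[state["scannable"]])
    target = [g for g in nsg if g in background]
    state["nsg"] = nsg
    if target:
        enr = nmot.motif_enrichment(state["presence"], target, background)
    else:
        enr = pd.DataFrame(columns=["k", "n", "K", "N", "fold", "p", "q"])
    state["motif_enrichment"] = enr
    path = out / "motif_enrichment.tsv"
    enr.to_csv(path, sep="\t")
    return [path]

def _stage_methylation(cfg, state, out):
    track = nio.read_methylation(cfg.paths["methylation_rate"],
                                 cfg.paths.get("methylation_coverage"))
    if "lmr_bed" in cfg.paths:
        lmrs = nio.read_bed(cfg.paths["lmr_bed"])
    else:
        lmrs = nmeth.detect_lmr(track, window=cfg.lmr_window,
                                max_rate=cfg.lmr_max_rate)
    state["lmrs"] = lmrs
    ann = state["ann"]
    e = state["enrichment"]
    segs = state["segs"]
    hegs = state["heg"].get(cfg.target_cell_type, [])
    universe = list(state["tpm"].values.index)
    grid = nmeth.feature_overlap_enrichment(lmrs, ann, {"SEG": segs, "HEG": hegs},
                                            universe, promoter_flank=cfg.promoter_flank)
    peak_enr = nmeth.peak_lmr_enrichment(lmrs, state["peaks"], ann.chrom_sizes)
    state["lmr_peak_enrichment"] = peak_enr
    g = ann.genes.loc[[s for s in segs if s in ann.genes.index]]
    anchors = pd.DataFrame({"chrom": g["chrom"], "pos": g["tss"], "strand": g["strand"]})
    _, profile = nmeth.methylation_metaprofile(track, anchors, ann.chrom_sizes,
                                               flank=cfg.metaprofile_flank,
                                               bins=cfg.metaprofile_bins)
    state["meth_profile"] = profile
    p1 = out / "lmrs.bed"
    nio.write_bed(lmrs, p1)
    p2 = out / "lmr_feature_enrichment.tsv"
    grid.to_csv(p2, sep="\t", index=False)
    p3 = out / "lmr_peak_enrichment.tsv"
    pd.DataFrame([peak_enr]).to_csv(p3, sep="\t", index=False)
    p4 = out / "methylation_tss_metaprofile.tsv"
    pd.DataFrame({"bin": np.arange(len(profile)), "mean_rate": profile}).to_csv(
        p4, sep="\t", index=False)
    return [p1, p2, p3, p4]

def _stage_assembly(cfg, state, out):
    spec = state["specificity"]
    nstf = sorted(spec.index[spec["nstf"]])
    presence = state["presence"]
    nsg = [g for g in state["nsg"] if g in presence.index]
    tf_cols = [p.tf for p in state["pwms"] if p.tf in presence.columns]
    sub = presence.loc[nsg, tf_cols] if nsg else presence.loc[[], tf_cols]
    ppi = nio.read_ppi(cfg.paths["ppi"])
    extra_tfs = [t for t in nstf if t not in tf_cols]  # TFs without a PWM
    net, report = nmot.assemble_network(sub, ppi, specificity=spec,
                                        coexpression_edges=None,
                                        extra_tfs=extra_tfs)
    state["regulatory_network"] = net
    state["assembly_report"] = report
    p1 = out / "regulatory_network_edges.tsv"
    net.write_edge_tsv(p1)
    p2 = out / "regulatory_network.graphml"
    net.write_graphml(p2)
    p3 = out / "regulatory_network_report.json"
    nio.write_json(report, p3)
    return [p1, p2, p3]
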
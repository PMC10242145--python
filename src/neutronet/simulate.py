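"""Synthetic multi-omics data with planted ground truth.

The generator emulates the study design the pipeline targets: nine sorted
immune cell types with two RNA-seq replicates each, negative-binomial counts
with cell-type-enriched genes planted at chosen fold changes, TF modules
whose members share a latent cell-type factor (so their profiles co-vary),
ATAC peaks (~1 kb) over the promoters of accessible genes with intensities
that track expected expression, methylation tracks hypomethylated around the
promoters of chosen genes, information-rich PWMs whose consensus strings are
written into target promoters, and a PPI edge list.  Everything is a pure
function of the design seed.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as nio
from .containers import GenomeAnnotation, MethylationTrack, PeakSet
from .expression import ExpressionMatrix
from .motifs import BASES, PositionWeightMatrix, reverse_complement, write_pwms

__all__ = [
    "CELL_TYPES", "SimulationDesign", "GroundTruth", "default_design",
    "generate_genome", "generate_expression", "generate_atac",
    "generate_methylation", "generate_motifs_and_ppi", "simulate_dataset",
]

CELL_TYPES = ("neutrophil", "monocyte_dc", "cd4_t", "cd8_t", "cd4cd8_t",
              "swc6_gd_t", "nk", "cd21p_b", "cd21n_b")

MIN_TSS_SPACING = 8000
PROMOTER_SPAN = 6000          # TSS +/- 3 kb
LMR_HALF_WIDTH = 2000         # hypomethylated span around planted promoters
MOTIF_PLANT_HALF_WIDTH = 200  # planted motifs stay this close to the TSS

# Substream tags: one fixed integer per generator stage so every stage is an
# independent, reproducible function of the design seed.
_SUB_GENOME, _SUB_EXPR, _SUB_ATAC, _SUB_METH, _SUB_MOTIF = 11, 12, 13, 14, 15


class CapacityError(ValueError):
    """Raised when the requested genes cannot be placed on the genome."""


@dataclasses.dataclass
class SimulationDesign:
    """Full specification of one synthetic dataset."""

    n_genes: int = 300
    cell_types: Sequence[str] = CELL_TYPES
    n_replicates_per_type: int = 2
    n_chromosomes: int = 3
    chromosome_length: int = 1_200_000
    enriched_gene_plan: Dict[str, Dict[str, float]] = dataclasses.field(default_factory=dict)
    tf_module_plan: List[Tuple[str, str, List[str]]] = dataclasses.field(default_factory=list)
    accessible_gene_set: List[str] = dataclasses.field(default_factory=list)
    lmr_gene_set: List[str] = dataclasses.field(default_factory=list)
    tf_list: List[str] = dataclasses.field(default_factory=list)
    nb_dispersion: float = 0.005
    base_mean: float = 200.0
    gene_level_sigma: float = 1.0
    planted_base_floor: bool = True
    module_latent_sigma: float = 0.25
    n_background_peaks: int = 300
    n_atac_replicates: int = 2
    motif_length: int = 12
    motif_both_strands: bool = False
    n_ppi_edges: int = 14
    seed: int = 1

    @property
    def gene_ids(self) -> List[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]

    @property
    def n_cell_types(self) -> int:
        return len(self.cell_types)

    def validate(self) -> None:
        if self.chromosome_length < 20 * PROMOTER_SPAN:
            raise CapacityError(
                f"chromosome_length {self.chromosome_length} < {20 * PROMOTER_SPAN}")
        ids = set(self.gene_ids)
        planted = set()
        for ct, plan in self.enriched_gene_plan.items():
            if ct not in self.cell_types:
                raise ValueError(f"unknown cell type in plan: {ct!r}")
            for g, fc in plan.items():
                if fc < 1.0:
                    raise ValueError(f"fold change below 1 for {g}: {fc}")
            planted |= set(plan)
        for tf, _, targets in self.tf_module_plan:
            planted |= {tf, *targets}
        planted |= set(self.accessible_gene_set) | set(self.lmr_gene_set)
        unknown = planted - ids
        if unknown:
            raise ValueError(f"planted genes absent from annotation: {sorted(unknown)[:5]}")
        if self.nb_dispersion <= 0 or self.base_mean <= 0:
            raise ValueError("nb_dispersion and base_mean must be positive")
        per_chrom = math.ceil(self.n_genes / max(self.n_chromosomes, 1))
        margin = 25_000
        if per_chrom and per_chrom * MIN_TSS_SPACING + 2 * margin > self.chromosome_length:
            raise CapacityError(
                f"cannot place {per_chrom} genes per chromosome with "
                f"{MIN_TSS_SPACING} bp TSS spacing on {self.chromosome_length} bp")


@dataclasses.dataclass
class GroundTruth:
    """Planted truth recorded alongside the generated files."""

    true_enriched: Dict[str, List[str]] = dataclasses.field(default_factory=dict)
    true_tf_targets: Dict[str, List[str]] = dataclasses.field(default_factory=dict)
    true_accessible: List[str] = dataclasses.field(default_factory=list)
    true_lmrs: List[Tuple[str, int, int]] = dataclasses.field(default_factory=list)
    motif_placements: Dict[str, Tuple[str, int, str, str]] = dataclasses.field(default_factory=dict)
    expected_mean: Dict[str, float] = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "GroundTruth":
        return GroundTruth(
            true_enriched={k: list(v) for k, v in d.get("true_enriched", {}).items()},
            true_tf_targets={k: list(v) for k, v in d.get("true_tf_targets", {}).items()},
            true_accessible=list(d.get("true_accessible", [])),
            true_lmrs=[tuple(x) for x in d.get("true_lmrs", [])],
            motif_placements={k: tuple(v) for k, v in d.get("motif_placements", {}).items()},
            expected_mean={k: float(v) for k, v in d.get("expected_mean", {}).items()},
        )


def default_design(seed: int = 1, n_genes: int = 300) -> SimulationDesign:
    """The default study-shaped design: two neutrophil TF modules of 12
    targets each, extra neutrophil-enriched genes, a few enriched genes in
    every other cell type, background TFs, and accessibility/hypomethylation
    planted at the neutrophil-enriched promoters."""
    if n_genes < 120:
        raise ValueError("default design needs at least 120 genes")
    ids = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    tf1, tf2 = ids[0], ids[1]
    module1 = ids[2:14]
    module2 = ids[14:26]
    extras = ids[26:40]
    neutro = {g: 10.0 for g in [tf1, tf2, *module1, *module2]}
    neutro.update({g: 6.0 for g in extras})
    plan: Dict[str, Dict[str, float]] = {"neutrophil": neutro}
    cursor = 40
    for ct in CELL_TYPES[1:]:
        plan[ct] = {ids[cursor + j]: 6.0 for j in range(4)}
        cursor += 4
    background_tfs = [ids[40], ids[44], ids[100], ids[101]]
    # Accessibility is widespread, as in real promoter landscapes: all module
    # genes plus ~55% of the remaining genes carry promoter peaks, so the
    # "has at least one promoter OCR" restriction is a genuine subset.
    module_genes = {tf1, tf2, *module1, *module2}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    rest = [g for g in ids if g not in module_genes and g not in extras]
    accessible = sorted(module_genes | {g for g in rest if rng.random() < 0.55})
    return SimulationDesign(
        n_genes=n_genes,
        enriched_gene_plan=plan,
        tf_module_plan=[(tf1, f"PWM_{tf1}", list(module1)),
                        (tf2, f"PWM_{tf2}", list(module2))],
        accessible_gene_set=accessible,
        lmr_gene_set=sorted(neutro),
        tf_list=sorted({tf1, tf2, *background_tfs}),
        seed=seed,
    )


def _rng(design: SimulationDesign, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([design.seed, tag]))


# ------------------------------------------------------------------ genome

def generate_genome(design: SimulationDesign) -> Tuple[Dict[str, np.ndarray], GenomeAnnotation]:
    """Random i.i.d. A/C/G/T chromosomes plus a placed gene annotation.

    Sequences are returned as mutable uint8 arrays (base codes 0..3) so the
    motif stage can plant consensus strings; convert with
    :func:`decode_genome` for FASTA output.  TSSs on a chromosome are at
    least 8 kb apart, strands are drawn 50/50 and gene bodies span 1-20 kb.
    """
    design.validate()
    rng = _rng(design, _SUB_GENOME)
    chroms = [f"chr{i + 1}" for i in range(design.n_chromosomes)]
    seqs = {c: rng.integers(0, 4, size=design.chromosome_length, dtype=np.uint8)
            for c in chroms}
    sizes = {c: design.chromosome_length for c in chroms}
    genes = []
    exons = []
    ids = design.gene_ids
    per_chrom = np.array_split(np.arange(design.n_genes), design.n_chromosomes)
    margin = 25_000
    for c_idx, idx in enumerate(per_chrom):
        k = len(idx)
        if k == 0:
            continue
        span = design.chromosome_length - 2 * margin
        leftover = span - (k - 1) * MIN_TSS_SPACING
        if leftover < 0:
            raise CapacityError("gene placement infeasible")
        extra = np.sort(rng.uniform(0, leftover, size=k))
        tss = (margin + extra + MIN_TSS_SPACING * np.arange(k)).astype(int)
        strands = rng.choice(["+", "-"], size=k)
        lengths = rng.integers(1000, 20001, size=k)
        for g_i, t, strand, L in zip(idx, tss, strands, lengths):
            gid = ids[g_i]
            chrom = chroms[c_idx]
            if strand == "+":
                start, end = t, min(t + int(L), design.chromosome_length)
            else:
                start, end = max(t + 1 - int(L), 0), t + 1
            genes.append((gid, chrom, int(start), int(end), strand))
            n_ex = int(rng.integers(1, 4))
            cuts = np.sort(rng.integers(start + 1, end, size=2 * n_ex - 2)) \
                if n_ex > 1 else np.array([], dtype=int)
            bounds = [start, *cuts.tolist(), end]
            for e_i in range(n_ex):
                s, e = int(bounds[2 * e_i]), int(bounds[2 * e_i + 1])
                if e > s:
                    exons.append((gid, chrom, s, e))
    gdf = pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end", "strand"])
    gdf = gdf.set_index("gene_id").sort_values(["chrom", "start"])
    gdf = gdf.loc[sorted(gdf.index)]  # stable gene-id order
    edf = pd.DataFrame(exons, columns=["gene_id", "chrom", "start", "end"]) if exons else None
    ann = GenomeAnnotation.from_gene_table(gdf, sizes, exons=edf)
    return seqs, ann


def decode_genome(seqs: Dict[str, np.ndarray]) -> Dict[str, str]:
    lut = np.frombuffer(BASES.encode(), dtype=np.uint8)
    return {c: lut[a].tobytes().decode() for c, a in seqs.items()}


# -------------------------------------------------------------- expression

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson negative binomial with variance mean + dispersion*mean^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, np.asarray(mean, dtype=float) * dispersion)
    return rng.poisson(lam)


def generate_expression(design: SimulationDesign, annotation: GenomeAnnotation
                        ) -> Tuple[ExpressionMatrix, GroundTruth]:
    """Negative-binomial count matrix with planted enrichment and TF modules."""
    design.validate()
    rng = _rng(design, _SUB_EXPR)
    genes = list(annotation.genes.index)
    n_g = len(genes)
    cts = list(design.cell_types)
    base = design.base_mean * rng.lognormal(0.0, design.gene_level_sigma, size=n_g)
    gene_pos = {g: i for i, g in enumerate(genes)}
    if design.planted_base_floor:
        # Planted cell-identity genes are robustly expressed: floor their
        # base mean at the cohort-typical level (background genes keep the
        # full lognormal spread).
        planted = {g for plan in design.enriched_gene_plan.values() for g in plan}
        planted |= {g for tf, _, ts in design.tf_module_plan for g in (tf, *ts)}
        for g in planted:
            if g in gene_pos:
                base[gene_pos[g]] = max(base[gene_pos[g]], design.base_mean)
    mean = np.tile(base[:, None], (1, len(cts)))
    for ct, plan in design.enriched_gene_plan.items():
        j = cts.index(ct)
        for g, fc in plan.items():
            mean[gene_pos[g], j] *= fc
    for _, _, targets in design.tf_module_plan:
        latent = rng.normal(0.0, design.module_latent_sigma, size=len(cts))
        factor = np.exp(latent)[None, :]
        rows = [gene_pos[t] for t in targets if t in gene_pos]
        mean[rows, :] *= factor
    cols, data = [], []
    sample_rows = []
    for j, ct in enumerate(cts):
        for rep in range(1, design.n_replicates_per_type + 1):
            cols.append(f"{ct}_r{rep}")
            sample_rows.append((f"{ct}_r{rep}", ct, rep))
            data.append(_nb_draw(rng, mean[:, j], design.nb_dispersion))
    values = pd.DataFrame(np.column_stack(data), index=pd.Index(genes, name="gene"),
                          columns=cols)
    samples = pd.DataFrame(sample_rows, columns=["sample", "cell_type", "replicate"])
    samples = samples.set_index("sample")
    lengths = annotation.genes["length"].astype(float)
    truth = GroundTruth(
        true_enriched={ct: sorted(plan) for ct, plan in design.enriched_gene_plan.items()},
        true_tf_targets={tf: sorted(targets) for tf, _, targets in design.tf_module_plan},
        true_accessible=sorted(design.accessible_gene_set),
        expected_mean={g: float(mean[gene_pos[g], cts.index("neutrophil")])
                       for g in genes} if "neutrophil" in cts else {},
    )
    m = ExpressionMatrix(values, samples, gene_lengths=lengths, unit="counts")
    return m, truth


# -------------------------------------------------------------------- ATAC

def generate_atac(design: SimulationDesign, annotation: GenomeAnnotation,
                  gene_means: Optional[Dict[str, float]] = None) -> PeakSet:
    """Promoter peaks for accessible genes plus intergenic background peaks.

    Peak widths are lognormal with ~1 kb mean (floored at 700 bp so promoter
    peaks always cover the motif-planting window); promoter peak intensity
    follows the gene's expected expression with lognormal noise, keeping
    planted promoter counts at least ~4x background on average.
    """
    design.validate()
    rng = _rng(design, _SUB_ATAC)
    samples = [f"atac_r{i + 1}" for i in range(design.n_atac_replicates)]
    rows, means = [], []
    width_mu = math.log(1000.0) - 0.08  # lognormal mean ~= 1 kb at sigma 0.4
    for g in sorted(design.accessible_gene_set):
        info = annotation.genes.loc[g]
        size = annotation.chrom_sizes[info["chrom"]]
        tss = int(info["tss"])
        center = tss + int(rng.integers(-100, 101))
        width = max(700, int(rng.lognormal(width_mu, 0.4)))
        start = max(center - width // 2, 0)
        end = min(start + width, size)
        expr = (gene_means or {}).get(g, design.base_mean * 10)
        mu = 20.0 * expr ** 0.8 * rng.lognormal(0.0, 0.35)
        rows.append((f"peak_{g}", info["chrom"], start, end, width // 2))
        means.append(mu)
    promoters = annotation.promoters(PROMOTER_SPAN // 2)
    prom_by_chrom = {c: sub[["start", "end"]].to_numpy()
                     for c, sub in promoters.groupby("chrom")}
    chroms = sorted(annotation.chrom_sizes)
    n_bg = design.n_background_peaks
    i = 0
    attempts = 0
    while i < n_bg and attempts < 50 * max(n_bg, 1):
        attempts += 1
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        size = annotation.chrom_sizes[chrom]
        width = max(200, int(rng.lognormal(width_mu, 0.4)))
        start = int(rng.integers(0, max(size - width, 1)))
        end = start + width
        ivals = prom_by_chrom.get(chrom)
        if ivals is not None and ((ivals[:, 0] < end) & (ivals[:, 1] > start)).any():
            continue
        rows.append((f"bg_{i + 1}", chrom, start, end, width // 2))
        means.append(50.0 * rng.lognormal(0.0, 0.5))
        i += 1
    peaks = pd.DataFrame(rows, columns=["name", "chrom", "start", "end", "summit"])
    peaks = peaks.set_index("name").sort_values(["chrom", "start", "end"])
    mean_arr = pd.Series(means, index=[r[0] for r in rows]).loc[peaks.index].to_numpy()
    counts = pd.DataFrame(
        {s: _nb_draw(rng, mean_arr, 0.05) for s in samples}, index=peaks.index)
    return PeakSet(peaks=peaks, counts=counts.astype(float), norm="raw")


# -------------------------------------------------------------- methylation

def generate_methylation(design: SimulationDesign, annotation: GenomeAnnotation,
                         spacing: int = 50) -> Tuple[MethylationTrack, List[Tuple[str, int, int]]]:
    """Beta-distributed methylation rates, hypomethylated at planted promoters.

    Background rates centre at 0.8 (Beta(8, 2)); within TSS +/- 2 kb of each
    ``lmr_gene_set`` gene rates centre at 0.1 (Beta(2, 18)).  Positions are
    every ``spacing`` bp with Poisson(30) coverage.  Returns the track and
    the planted LMR intervals.
    """
    design.validate()
    rng = _rng(design, _SUB_METH)
    frames = []
    planted: List[Tuple[str, int, int]] = []
    low_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for g in sorted(design.lmr_gene_set):
        info = annotation.genes.loc[g]
        size = annotation.chrom_sizes[info["chrom"]]
        lo = max(int(info["tss"]) - LMR_HALF_WIDTH, 0)
        hi = min(int(info["tss"]) + LMR_HALF_WIDTH, size)
        planted.append((str(info["chrom"]), lo, hi))
        low_by_chrom.setdefault(str(info["chrom"]), []).append((lo, hi))
    for chrom in sorted(annotation.chrom_sizes):
        size = annotation.chrom_sizes[chrom]
        pos = np.arange(0, size, spacing)
        rate = rng.beta(8.0, 2.0, size=len(pos))
        lows = np.zeros(len(pos), dtype=bool)
        for lo, hi in low_by_chrom.get(chrom, []):
            lows |= (pos >= lo) & (pos < hi)
        if lows.any():
            rate[lows] = rng.beta(2.0, 18.0, size=int(lows.sum()))
        coverage = rng.poisson(30, size=len(pos))
        frames.append(pd.DataFrame({"chrom": chrom, "start": pos, "end": pos + 1,
                                    "rate": rate, "coverage": coverage}))
    track = MethylationTrack(pd.concat(frames, ignore_index=True))
    return track, planted


# ------------------------------------------------------------- motifs / PPI

def generate_motifs_and_ppi(design: SimulationDesign, genome: Dict[str, np.ndarray],
                            annotation: GenomeAnnotation
                            ) -> Tuple[List[PositionWeightMatrix], pd.DataFrame,
                                       Dict[str, Tuple[str, int, str, str]]]:
    """Build one information-rich PWM per TF module and plant consensus
    strings into target promoters (mutates ``genome`` in place).

    Each PWM gives its consensus base probability 0.9 (rest uniform).  The
    consensus is written within TSS +/- 200 bp of every target, on the +
    strand unless ``motif_both_strands`` randomises the strand.  PPI edges
    are sampled among the planted targets plus a couple of outside partners.
    Returns (pwms, ppi_edges, placements).
    """
    if not design.tf_module_plan:
        raise ValueError("tf_module_plan is empty")
    L = design.motif_length
    if L > PROMOTER_SPAN:
        raise ValueError("motif longer than the promoter span")
    rng = _rng(design, _SUB_MOTIF)
    pwms = []
    placements: Dict[str, Tuple[str, int, str, str]] = {}
    for tf, pwm_id, targets in design.tf_module_plan:
        cons = rng.integers(0, 4, size=L)
        mat = np.full((4, L), 0.1 / 3)
        mat[cons, np.arange(L)] = 0.9
        pwm = PositionWeightMatrix(pwm_id, tf, mat)
        pwms.append(pwm)
        cons_str = "".join(BASES[i] for i in cons)
        for g in targets:
            info = annotation.genes.loc[g]
            chrom = str(info["chrom"])
            size = annotation.chrom_sizes[chrom]
            tss = int(info["tss"])
            off = int(rng.integers(-MOTIF_PLANT_HALF_WIDTH,
                                   MOTIF_PLANT_HALF_WIDTH - L + 1))
            pos = min(max(tss + off, 0), size - L)
            strand = "+"
            planted = cons_str
            if design.motif_both_strands and rng.random() < 0.5:
                strand = "-"
                planted = reverse_complement(cons_str)
            enc = np.frombuffer(planted.encode(), dtype=np.uint8)
            lut = np.zeros(256, dtype=np.uint8)
            for b, i in zip(BASES, range(4)):
                lut[ord(b)] = i
            genome[chrom][pos:pos + L] = lut[enc]
            placements[g] = (chrom, pos, strand, pwm_id)
    all_targets = sorted({t for _, _, ts in design.tf_module_plan for t in ts})
    edges = set()
    guard = 0
    while len(edges) < min(design.n_ppi_edges, len(all_targets) * 2) and guard < 1000:
        guard += 1
        a, b = rng.choice(all_targets, size=2, replace=False)
        edges.add(tuple(sorted((a, b))))
    planted_set = {g for plan in design.enriched_gene_plan.values() for g in plan}
    outsiders = [g for g in design.gene_ids if g not in planted_set][:2]
    for o, t in zip(outsiders, all_targets[:len(outsiders)]):
        edges.add(tuple(sorted((o, t))))
    ppi = pd.DataFrame(sorted(edges), columns=["gene_a", "gene_b"])
    return pwms, ppi, placements


# ------------------------------------------------------------ orchestration

def simulate_dataset(design: SimulationDesign, outdir) -> Dict[str, str]:
    """Generate and write the full dataset; returns the path manifest.

    Stage order matters: the genome is generated first, motifs are planted
    into it, then expression / ATAC / methylation are drawn.  All outputs
    round-trip through :mod:`neutronet.io`.
    """
    outdir = Path(outdir).resolve()
    outdir.mkdir(parents=True, exist_ok=True)
    genome, ann = generate_genome(design)
    truth = GroundTruth()
    pwms, ppi, placements = ([], pd.DataFrame(columns=["gene_a", "gene_b"]), {})
    if design.tf_module_plan:
        pwms, ppi, placements = generate_motifs_and_ppi(design, genome, ann)
    expr, truth = generate_expression(design, ann)
    atac = generate_atac(design, ann, gene_means=truth.expected_mean)
    meth, planted_lmrs = generate_methylation(design, ann)
    truth.true_lmrs = planted_lmrs
    truth.motif_placements = placements

    paths = {
        "genome": str(outdir / "genome.fa"),
        "gtf": str(outdir / "genes.gtf"),
        "chrom_sizes": str(outdir / "chrom.sizes"),
        "expression": str(outdir / "expression_counts.tsv"),
        "samples": str(outdir / "samples.tsv"),
        "gene_lengths": str(outdir / "gene_lengths.tsv"),
        "peaks": str(outdir / "atac_peaks.narrowPeak"),
        "peak_counts": str(outdir / "atac_counts.tsv"),
        "methylation_rate": str(outdir / "methylation.rate.bedGraph"),
        "methylation_coverage": str(outdir / "methylation.cov.bedGraph"),
        "pwms": str(outdir / "motifs.pwm"),
        "ppi": str(outdir / "ppi.tsv"),
        "tf_list": str(outdir / "tf_list.txt"),
        "ground_truth": str(outdir / "ground_truth.json"),
    }
    nio.write_fasta(decode_genome(genome), paths["genome"])
    nio.write_gtf(ann, paths["gtf"])
    nio.write_chrom_sizes(ann.chrom_sizes, paths["chrom_sizes"])
    nio.write_counts(expr.values, paths["expression"], index_name="gene")
    expr.samples.rename_axis("sample").to_csv(paths["samples"], sep="\t")
    expr.gene_lengths.rename("length").rename_axis("gene").to_csv(
        paths["gene_lengths"], sep="\t")
    nio.write_narrowpeak(atac, paths["peaks"])
    nio.write_counts(atac.counts, paths["peak_counts"], index_name="peak")
    nio.write_methylation(meth, paths["methylation_rate"], paths["methylation_coverage"])
    write_pwms(pwms, paths["pwms"])
    nio.write_ppi(ppi, paths["ppi"])
    Path(paths["tf_list"]).write_text("\n".join(design.tf_list) + "\n")
    nio.write_json(truth.to_dict(), paths["ground_truth"])
    return paths
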
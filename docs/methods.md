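# Methods

This note documents the statistical models, parameter defaults and design
choices behind `neutronet`, and what the synthetic benchmark does and does
not demonstrate about real data.

## Study design emulated

The pipeline targets a sorted-immune-cell comparison: nine cell types
(neutrophil, monocyte/DC, three T-cell populations, γδ T, NK, two B-cell
populations), two RNA-seq replicates per type, two ATAC-seq replicates for
the cell type of interest, one whole-genome methylation track, PWMs for the
candidate TFs, and a PPI edge list. All thresholds default to their
conventional values in this kind of analysis: fold change 2, BH q 0.05,
co-expression |r| 0.95, HEG fraction 0.25, promoter = TSS ± 3 kb, TTS ± 1 kb,
metaprofile flank 2 kb, LMR rate ≤ 0.3.

## Enriched-gene model

Counts are filtered (`count > 4` in ≥ 1 sample), converted to TPM, and the
replicates of each cell-type group are quantile-normalised *within group*
(each sample's sorted values replaced by the group's mean sorted vector,
ties averaged). This is a deterministic simplification of smooth
("tissue-aware") quantile normalisation: it preserves between-group
differences exactly, but with n = 2 it makes the two replicates identical
up to gene ordering. For that reason all replicate-based tests run on TPM,
and the normalised matrix feeds only the co-expression profiles and
cluster heatmap ordering, where exchangeable replicates are what you want.

The enrichment contrast is fixed to a two-sided Welch t-test on log2(x+1)
— replicates of the target cell type against all other samples pooled —
with BH adjustment per cell type, because it is reproducible at n = 2 and
needs no fitted dispersion model. The fold change uses the mean of the
*per-cell-type means* of the remaining types (not the pooled samples), so a
large cell type cannot dominate the denominator. The +1 log offset is a
documented constant. HEG selection takes exactly `round(0.25 · n_SEG)`
genes (round-half-even), ties broken by smaller q then gene ID.

Power note: with 2 replicates the Welch statistic has ~1–2 Satterthwaite
degrees of freedom and its p-value floor (≈ 1/t²) sits near the BH
threshold whenever thousands of genes are tested. Calibration experiments
that demand ≥ 90 % sensitivity therefore use 4 replicates per type; the
null-calibration (false-positive) experiments keep the n = 2 design. On
real n = 2 data this test is conservative — it will under-call, not
over-call.

## PCIT

For every unordered gene trio (x, y, z) the three first-order partial
correlations are computed, a trio tolerance
`ε = mean(r_xy.z/r_xy, r_xz.y/r_xz, r_yz.x/r_yz)` is formed (ratio terms
with |r| < 1e−12 are skipped — the zero-correlation guard), and edge (x, y)
is flagged in that trio iff `|r_xy| < |ε·r_xz|` **and** `|r_xy| < |ε·r_yz|`.
An edge flagged in any trio is removed. Note that a weak edge attached to
one weak neighbour often survives PCIT (the second comparison fails); such
edges are eliminated by the |r| > 0.95 network threshold instead. The
vectorised implementation builds the full n×n×n partial-correlation tensor
(capped at 600 genes — ample for SEG-sized networks) and is tested for
exact mask equality against a literal triple-loop evaluation.

Correlation profiles use all samples rather than cell-type means (with two
replicates per type the two options are nearly equivalent; using samples
keeps the n ≥ 3 Pearson precondition comfortable). Network clusters come
from connected components when their number already equals k, otherwise
average-linkage hierarchical clustering on the 1 − |r| profile distance,
with labels canonicalised by cluster size so the partition is independent
of node input order.

NSG (neutrophil-specific gene) = SEG ∧ network member ∧ maximum
per-cell-type mean in the target type ∧ ≥ 2-fold above the monocyte/DC
comparator with BH-adjusted Welch q < 0.05 (BH across the candidate genes
of that contrast). NSTF = NSG ∩ TF list; MSTF = TF with maximum in target
or comparator and ≥ 2-fold (q < 0.05) above each remaining type. Network
membership means any network membership by default; `require_cluster`
restricts it to one cluster when desired.

## ATAC integration

Consensus peaks are the union-merge of replicate peak intervals
(book-ended intervals merge; counts sum across contributing peaks).
Feature annotation is by peak midpoint with priority promoter > TTS > exon
> intron > intergenic, strand-aware. Normalisation is reads-per-kilobase,
then TMM scale factors (30 % M-trim, 5 % A-trim, reference = sample whose
75th percentile of library-scaled values is closest to the mean, zero
counts excluded pairwise), then CPM on the effective library sizes.

Promoter OCR intensity is the sum of normalized counts of peaks
overlapping TSS ± 3 kb by ≥ 1 bp (a peak spanning two promoters counts for
both); OCR length is the *clipped* overlap (peak ∩ promoter), a bounded and
interpretable choice where the full peak width would not be. Feature
annotation deliberately uses the midpoint (categorical summaries) while
quantification uses any-overlap — the two conventions serve different
purposes. Expression–accessibility correlations are Pearson on log2(x+1)
for all genes, SEGs, and SEGs with ≥ 1 promoter peak. Metaprofiles average
the signal in equal-width bins across strand-oriented anchor windows,
ignoring missing data; 2·flank must be divisible by the bin count.

## Methylation

The LMR caller tiles the genome in 1-kb windows and seeds an LMR where ≥ 3
positions with coverage ≥ 3 average a rate ≤ 0.3, merging adjacent seeds.
This is a declared simplification — studies of this kind usually import an
externally called LMR set, and the pipeline accepts an `lmr_bed` input that
bypasses the caller. Enrichment statistics share one hypergeometric kernel:
gene-level for the feature × gene-set grid (universe = expressed genes with
a non-empty region of that feature; per-gene intergenic flank defined as
the 10-kb span beyond the promoter/TTS edges — a documented convention),
and base-level (100-bp units, any overlap marks a unit) for the LMR × peak
overlap. BH is applied across the whole 10-cell grid.

## Synthetic data generator

Everything is a pure function of one seed, split into fixed per-stage
substreams (genome / expression / ATAC / methylation / motifs), so files
are byte-identical across reruns and stages are independently reproducible.

* **Genome & annotation.** I.i.d. uniform A/C/G/T chromosomes; TSSs placed
  with ≥ 8 kb spacing (capacity-checked, explicit error otherwise), strand
  50/50, gene bodies 1–20 kb with 1–3 exons.
* **Expression.** Negative binomial via gamma–Poisson with variance
  `m + φ·m²`. Gene base means are lognormal (σ = 1) around `base_mean`
  (default 200); planted genes are floored at `base_mean`, reflecting that
  cell-identity markers are robustly expressed — and, practically, that an
  n = 2 design cannot recover planted genes whose comparator-side counts
  are tiny. Default dispersion φ = 0.005 emulates technical-quality
  replication of sorted pure populations; it was chosen by a power analysis
  of the fixed Welch contrasts (the binding one is the 2-vs-2 comparator
  contrast, p floor ≈ 1/t²), and real biological replicates are
  substantially more dispersed — see "What passing tests show" below.
  Enriched genes have their cell-type mean multiplied by the planted fold
  change (default 10 for module genes, 6 elsewhere); TF-module members
  share a per-cell-type lognormal latent factor (σ = 0.25) so module
  profiles co-vary beyond the shared enrichment spike.
* **ATAC.** Promoter peaks for accessible genes: width lognormal with ~1 kb
  mean, floored at 700 bp, centred within TSS ± 100 bp — the floor
  guarantees the peak covers the motif-planting window. Peak mean counts
  follow the gene's expected expression (`20·mean^0.8` with lognormal
  noise, ≥ ~4× the background peak mean), so promoter accessibility tracks
  expression as it does in real cells. Background intergenic peaks avoid
  all promoters. In the default design accessibility is widespread (~55 %
  of background genes plus every TF-module gene), matching real promoter
  landscapes where most expressed genes carry a promoter peak; the planted
  non-module enriched genes get no peak, so "SEG with ≥ 1 OCR" is a genuine
  subset and the observed correlation ordering r(SEG with OCR) > r(all)
  emerges for the same reason it does in real data (the all-gene
  correlation is diluted by peakless genes).
* **Methylation.** Positions every 50 bp, background rate Beta(8, 2)
  (mean 0.8), hypomethylated Beta(2, 18) (mean 0.1) within TSS ± 2 kb of
  the chosen genes. The 2-kb half-width keeps the 1-kb-window LMR caller's
  recovery insensitive to tiling alignment.
* **Motifs & PPIs.** One PWM per module TF: consensus probability 0.9 per
  column, length 12, probabilities floored at 1e−3. The consensus string is
  written into TSS ± 200 bp of every target (forward strand by default; a
  flag randomises strands — the scanner handles both regardless). At the
  0.8·max log-odds threshold a length-12 consensus admits no mismatches, so
  background hits require an exact 0.25¹² coincidence. PPI edges are
  sampled among targets plus two outside partners.

## Numerical conventions

Interval containers are 0-based half-open; GTF converts at the file
boundary. bedGraph values are rounded to 6 decimals and PWM probabilities
written at 6 decimals, with the PWM loader accepting columns within 1e−5 of
unity as-is — both choices make write → read → write byte-stable, which the
round-trip tests assert. The methylation writer emits a rate bedGraph plus
a parallel coverage bedGraph, since the 4-column format holds one value.
Hierarchical-cluster labels, HEG ties and PCIT masks all have deterministic
tie-break rules (documented at each function) so reruns and input
permutations reproduce identical outputs; the run manifest records SHA-256
hashes of every stage output to make this checkable.

## What passing tests show — and what they do not

The planted-truth tests demonstrate that each stage implements its stated
rule and that the stages compose: enriched genes are recovered at the
designed rates, PCIT matches its literal definition, planted motifs and
LMRs are found where they were written, and the planted TFs — and only
they — emerge as neutrophil-specific TFs end to end. They do **not** show
that the pipeline would recover biology from two biological replicates of
real sorted cells: the generator's dispersion is optimistic, methylation is
unlinked from CpG context, peaks have no fragment-model noise, and motif
instances are exact consensus strings. With realistic biological dispersion
(φ ≈ 0.05–0.4) the n = 2 Welch contrasts lose most of their power, which is
a property of the design, not of the implementation. The cross-species
Spearman comparison and the external-LMR path are exercised on constructed
vectors/intervals only.

## Problem sizes

Default synthetic runs use 300 genes on 3 × 1.2 Mb chromosomes (~500
peaks, ~72k methylation positions); calibration experiments use 2,000
genes × 9 cell types over 10–20 seeds. These sizes make every documented
property measurable in seconds while keeping all counting statistics
(hypergeometric universes, BH families) far from degenerate.
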
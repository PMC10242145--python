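"""Expression filtering, normalisation and cell-type-enriched gene calling.

The enrichment model: a gene is *significantly enriched* (SEG) in a cell type
when its mean expression there is at least ``fc_threshold`` times the average
of the per-cell-type means of all remaining cell types, and a two-sided Welch
t-test on log2(x + 1) values (replicates of the target type vs. all other
samples pooled) gives a Benjamini-Hochberg adjusted p below ``q_threshold``.
*Highly enriched* genes (HEG) are the top quarter of SEGs by log2 fold change.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .stats import bh_adjust, welch_t_log2

__all__ = [
    "ExpressionMatrix", "EnrichmentResult",
    "filter_low_genes", "compute_tpm", "group_quantile_normalize",
    "call_enriched_genes", "select_heg", "cross_species_spearman",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class ExpressionMatrix:
    """Gene x sample expression values with a sample sheet.

    ``values``: DataFrame indexed by gene ID, columns are sample IDs.
    ``samples``: DataFrame indexed by sample ID with ``cell_type`` and
    ``replicate`` columns. ``unit`` is one of counts | TPM | normalized.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    gene_lengths: Optional[pd.Series] = None
    unit: str = "counts"

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing from sample sheet: {sorted(missing)}")
        self.samples = self.samples.loc[list(self.values.columns)]

    @property
    def cell_types(self) -> List[str]:
        seen: List[str] = []
        for ct in self.samples["cell_type"]:
            if ct not in seen:
                seen.append(ct)
        return seen

    def samples_of(self, cell_type: str) -> List[str]:
        return list(self.samples.index[self.samples["cell_type"] == cell_type])

    def cell_type_means(self) -> pd.DataFrame:
        """Per-cell-type mean expression (genes x cell types)."""
        cols = {ct: self.values[self.samples_of(ct)].mean(axis=1) for ct in self.cell_types}
        return pd.DataFrame(cols)


@dataclasses.dataclass
class EnrichmentResult:
    """Long-format per (gene, cell type) enrichment table.

    Columns: gene, cell_type, fc, log2fc, p, q, seg, heg, untestable.
    """

    table: pd.DataFrame
    fc_threshold: float = 2.0
    q_threshold: float = 0.05

    def seg_genes(self, cell_type: str) -> List[str]:
        t = self.table
        return sorted(t.loc[(t["cell_type"] == cell_type) & t["seg"], "gene"])

    def heg_genes(self, cell_type: str) -> List[str]:
        t = self.table
        return sorted(t.loc[(t["cell_type"] == cell_type) & t["heg"], "gene"])


def filter_low_genes(m: ExpressionMatrix, min_count: int = 4) -> ExpressionMatrix:
    """Keep genes with count > ``min_count`` in at least one sample."""
    if m.unit != "counts":
        raise ValueError("filter_low_genes expects raw counts")
    keep = (m.values > min_count).any(axis=1)
    if not keep.any():
        log.warning("filter_low_genes removed every gene")
    lengths = m.gene_lengths.loc[keep[keep].index] if m.gene_lengths is not None else None
    return ExpressionMatrix(m.values.loc[keep], m.samples.copy(), lengths, unit="counts")


def compute_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Counts -> transcripts per million using gene lengths in bp."""
    if m.unit != "counts":
        raise ValueError("compute_tpm expects raw counts")
    if m.gene_lengths is None:
        raise ValueError("gene lengths are required for TPM")
    lengths = m.gene_lengths.reindex(m.values.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length for TPM")
    rpk = m.values.div(lengths / 1000.0, axis=0)
    totals = rpk.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero total RPK in sample(s): {list(zero.index)}")
    tpm = rpk.div(totals, axis=1) * 1e6
    return ExpressionMatrix(tpm, m.samples.copy(), m.gene_lengths, unit="TPM")


def group_quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalise samples *within* each cell-type group.

    Each sample's sorted values are replaced by the mean sorted vector of its
    group (ties receive the average of their tied quantiles), so replicates of
    a cell type become exchangeable while between-group differences survive.
    Groups of size one pass through unchanged with a warning.
    """
    out = m.values.copy().astype(float)
    for ct in m.cell_types:
        cols = m.samples_of(ct)
        if len(cols) < 2:
            warnings.warn(f"cell type {ct!r} has a single replicate; passthrough")
            continue
        block = m.values[cols].to_numpy(dtype=float)
        mean_sorted = np.sort(block, axis=0).mean(axis=1)
        n = block.shape[0]
        for j in range(block.shape[1]):
            ranks = _sps.rankdata(block[:, j], method="average")  # 1..n, ties averaged
            lo = np.floor(ranks - 1).astype(int)
            hi = np.ceil(ranks - 1).astype(int)
            frac = (ranks - 1) - lo
            vals = mean_sorted[lo] * (1 - frac) + mean_sorted[np.minimum(hi, n - 1)] * frac
            out[cols[j]] = vals
    return ExpressionMatrix(out, m.samples.copy(), m.gene_lengths, unit="normalized")


def call_enriched_genes(m: ExpressionMatrix, fc_threshold: float = 2.0,
                        q_threshold: float = 0.05) -> EnrichmentResult:
    """Call SEGs per cell type (fold change on cell-type means + Welch t)."""
    if m.unit not in ("TPM", "normalized"):
        raise ValueError("call_enriched_genes expects TPM or normalized values")
    cts = m.cell_types
    if len(cts) < 2:
        raise ValueError("at least two cell types are required")
    means = m.cell_type_means()
    rows = []
    for ct in cts:
        own = means[ct].to_numpy()
        other = means.drop(columns=ct).mean(axis=1).to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = np.where(other > 0, own / other, np.where(own > 0, np.inf, np.nan))
            log2fc = np.log2(fc)
        own_cols = m.samples_of(ct)
        other_cols = [c for c in m.values.columns if c not in own_cols]
        untestable = len(own_cols) < 2
        if untestable:
            log.warning("cell type %r has <2 replicates; p undefined, no SEG calls", ct)
            p = np.full(len(means), np.nan)
        else:
            p = welch_t_log2(m.values[own_cols].to_numpy(),
                             m.values[other_cols].to_numpy(), axis=1)
        q = bh_adjust(p)
        seg = (fc >= fc_threshold) & (q < q_threshold)
        seg &= ~np.isnan(q)
        rows.append(pd.DataFrame({
            "gene": means.index, "cell_type": ct, "fc": fc, "log2fc": log2fc,
            "p": p, "q": q, "seg": seg, "heg": False, "untestable": untestable,
        }))
    table = pd.concat(rows, ignore_index=True)
    return EnrichmentResult(table, fc_threshold=fc_threshold, q_threshold=q_threshold)


def select_heg(e: EnrichmentResult, fraction: float = 0.25) -> Dict[str, List[str]]:
    """Mark the top ``fraction`` of SEGs by log2FC per cell type as HEGs.

    Exactly ``round(fraction * n_SEG)`` genes are taken per cell type
    (round-half-even); ties broken by smaller q, then gene ID.  Updates the
    ``heg`` column in place and returns the per-cell-type HEG lists.
    """
    out: Dict[str, List[str]] = {}
    t = e.table
    t["heg"] = False
    for ct, sub in t.groupby("cell_type", sort=False):
        segs = sub[sub["seg"]]
        n = int(round(fraction * len(segs)))
        if n == 0:
            out[ct] = []
            continue
        ordered = segs.sort_values(["log2fc", "q", "gene"],
                                   ascending=[False, True, True])
        chosen = ordered.head(n)
        t.loc[chosen.index, "heg"] = True
        out[ct] = sorted(chosen["gene"])
    return out


_RHO_CATEGORIES = ((0.5, "strong"), (0.3, "moderate"))


def cross_species_spearman(tpm_a, tpm_b):
    """Spearman correlation between matched ortholog expression vectors.

    Returns ``(rho, p, category)`` with category low / moderate / strong at
    the 0.3 and 0.5 cutpoints.
    """
    a = np.asarray(tpm_a, dtype=float)
    b = np.asarray(tpm_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Spearman rho undefined for a constant vector")
    rho, p = _sps.spearmanr(a, b)
    category = "low"
    for cut, name in _RHO_CATEGORIES:
        if rho >= cut:
            category = name
            break
    return float(rho), float(p), category
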
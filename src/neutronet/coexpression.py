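"""PCIT-pruned co-expression networks and cell-specificity calls.

PCIT (partial correlation + information theory) examines every unordered
gene trio (x, y, z).  For a trio it computes the three first-order partial
correlations, e.g.::

    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2) (1 - r_yz^2))

and a trio tolerance ``eps = mean(r_xy.z / r_xy, r_xz.y / r_xz, r_yz.x / r_yz)``.
The edge (x, y) is non-significant *in that trio* when both
``|r_xy| < |eps * r_xz|`` and ``|r_xy| < |eps * r_yz|``; an edge flagged in
any trio is removed.  Ratio terms with |r| < 1e-12 are skipped when forming
``eps`` (documented guard for degenerate inputs).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .expression import EnrichmentResult, ExpressionMatrix
from .network import RegulatoryNetwork
from .stats import bh_adjust, welch_t_log2

__all__ = [
    "CorrelationMatrix", "PcitResult",
    "pearson_matrix", "partial_correlation", "pcit_prune",
    "build_network", "cluster_network", "call_specific_genes",
]

log = logging.getLogger(__name__)

ZERO_R_GUARD = 1e-12


@dataclasses.dataclass
class CorrelationMatrix:
    """Symmetric gene x gene Pearson correlation matrix (diagonal 1)."""

    r: pd.DataFrame
    dropped_constant: List[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        a = self.r.to_numpy()
        if not np.allclose(a, a.T, equal_nan=True):
            raise ValueError("correlation matrix must be symmetric")

    @property
    def genes(self) -> List[str]:
        return list(self.r.index)


@dataclasses.dataclass
class PcitResult:
    """Boolean mask of PCIT-surviving gene pairs (symmetric, False diagonal)."""

    kept: pd.DataFrame


def pearson_matrix(m: ExpressionMatrix, genes: Optional[Iterable[str]] = None) -> CorrelationMatrix:
    """Pairwise Pearson r of expression profiles across all samples.

    Constant-profile genes cannot be correlated; they are dropped with a
    warning and recorded on the result.
    """
    genes = list(genes) if genes is not None else list(m.values.index)
    missing = set(genes) - set(m.values.index)
    if missing:
        raise ValueError(f"genes absent from matrix: {sorted(missing)[:5]}")
    x = m.values.loc[genes]
    if x.shape[1] < 3:
        raise ValueError("need at least 3 profile points per gene")
    sd = x.std(axis=1)
    constant = list(x.index[sd == 0])
    if constant:
        warnings.warn(f"dropping {len(constant)} constant-profile gene(s) from correlation")
        x = x.drop(index=constant)
    r = np.atleast_2d(np.corrcoef(x.to_numpy(dtype=float)))
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(pd.DataFrame(r, index=x.index, columns=x.index),
                             dropped_constant=constant)


def partial_correlation(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation r_xy.z."""
    if abs(r_xz) >= 1.0 or abs(r_yz) >= 1.0:
        raise ValueError("partial correlation undefined when |r_xz| or |r_yz| is 1")
    return (r_xy - r_xz * r_yz) / np.sqrt((1.0 - r_xz ** 2) * (1.0 - r_yz ** 2))


def pcit_prune(c: CorrelationMatrix) -> PcitResult:
    """Vectorised PCIT edge pruning over all gene trios.

    Uses an n x n x n tensor of first-order partials; fine for the network
    sizes this pipeline works at (hundreds of genes).
    """
    R = c.r.to_numpy(dtype=float)
    n = R.shape[0]
    if n < 3:
        raise ValueError("PCIT needs at least 3 genes")
    if np.isnan(R).any():
        raise ValueError("correlation matrix contains undefined entries")
    if n > 600:
        raise ValueError("pcit_prune tensor formulation capped at 600 genes")

    with np.errstate(divide="ignore", invalid="ignore"):
        # P[x, y, z] = r_xy.z
        num = R[:, :, None] - R[:, None, :] * R[None, :, :]
        den = np.sqrt((1.0 - R[:, None, :] ** 2) * (1.0 - R[None, :, :] ** 2))
        P = num / den
        # Ratio term r_xy.z / r_xy, skipped (NaN) under the zero guard.
        Rxy = np.broadcast_to(R[:, :, None], P.shape)
        T = np.where(np.abs(Rxy) >= ZERO_R_GUARD, P / Rxy, np.nan)
        # eps[x, y, z] averages the defined terms of the trio's three ratios.
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            # the trio's three ratio terms at [x, y, z]:
            #   T[x,y,z] = r_xy.z/r_xy, T[x,z,y] = r_xz.y/r_xz, T[y,z,x] = r_yz.x/r_yz
            eps = np.nanmean(np.stack([T, T.transpose(0, 2, 1), T.transpose(2, 0, 1)]), axis=0)
        thr_xz = np.abs(eps * R[:, None, :])   # |eps * r_xz|
        thr_yz = np.abs(eps * R[None, :, :])   # |eps * r_yz|
        absr = np.abs(R)[:, :, None]
        flagged = (absr < thr_xz) & (absr < thr_yz)

    idx = np.arange(n)
    flagged[idx, :, idx] = False   # z == x
    flagged[:, idx, idx] = False   # z == y (NaN comparisons are already False)
    removed = flagged.any(axis=2)
    kept = ~removed
    kept &= np.abs(R) > 0
    np.fill_diagonal(kept, False)
    kept &= kept.T  # the criterion is symmetric; enforce exactly
    return PcitResult(pd.DataFrame(kept, index=c.r.index, columns=c.r.columns))


def build_network(c: CorrelationMatrix, p: PcitResult, r_threshold: float = 0.95,
                  enrichment: Optional[EnrichmentResult] = None,
                  m: Optional[ExpressionMatrix] = None,
                  cell_type: str = "neutrophil") -> RegulatoryNetwork:
    """Keep PCIT-surviving pairs with |r| > ``r_threshold``; drop isolated genes.

    Node annotations (log2FC in ``cell_type``, cell type of maximum
    expression) are attached when an enrichment result / expression matrix
    are supplied, mirroring the usual network-figure export.
    """
    if list(c.r.index) != list(p.kept.index):
        raise ValueError("correlation matrix and PCIT result gene sets differ")
    R = c.r.to_numpy()
    keep = p.kept.to_numpy() & (np.abs(R) > r_threshold)
    genes = np.asarray(c.r.index)
    iu = np.triu_indices(len(genes), k=1)
    sel = keep[iu]
    edges = pd.DataFrame({
        "source": genes[iu[0][sel]],
        "target": genes[iu[1][sel]],
        "edge_type": "coexpression",
        "r": R[iu][sel],
    })
    used = sorted(set(edges["source"]) | set(edges["target"]))
    nodes = pd.DataFrame(index=pd.Index(used, name="gene"))
    nodes["is_tf"] = False
    if m is not None:
        means = m.cell_type_means()
        nodes["max_cell_type"] = means.loc[used].idxmax(axis=1)
    if enrichment is not None:
        sub = enrichment.table
        sub = sub[sub["cell_type"] == cell_type].set_index("gene")
        nodes["log2fc"] = sub["log2fc"].reindex(used)
    return RegulatoryNetwork(nodes=nodes, edges=edges)


def cluster_network(net: RegulatoryNetwork, m: ExpressionMatrix, k: int = 3) -> pd.Series:
    """Partition network nodes into ``k`` clusters, deterministically.

    Connected components are used when their number already equals ``k``;
    otherwise average-linkage hierarchical clustering on the 1 - |r| distance
    of node expression profiles is cut to ``k`` clusters.  Cluster labels are
    canonicalised (1..k by decreasing size, ties by smallest gene ID) so the
    partition is invariant to node input order.
    """
    genes = sorted(net.nodes.index)
    if len(genes) == 0 or len(net.edges) == 0:
        raise ValueError("network has no edges to cluster")
    if k > len(genes):
        raise ValueError(f"k={k} exceeds node count {len(genes)}")
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(genes)
    for _, e in net.edge_view("coexpression").iterrows():
        g.add_edge(e["source"], e["target"])
    comps = sorted((sorted(comp) for comp in nx.connected_components(g)),
                   key=lambda comp: (-len(comp), comp[0]))
    if len(comps) == k:
        raw = {gene: i + 1 for i, comp in enumerate(comps) for gene in comp}
        labels = pd.Series({gene: raw[gene] for gene in genes}, name="cluster")
        return labels
    x = m.values.loc[genes].to_numpy(dtype=float)
    r = np.corrcoef(x)
    d = 1.0 - np.abs(np.clip(r, -1, 1))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    z = linkage(squareform(d, checks=False), method="average")
    raw = fcluster(z, t=k, criterion="maxclust")
    groups = {}
    for gene, lab in zip(genes, raw):
        groups.setdefault(lab, []).append(gene)
    ordered = sorted(groups.values(), key=lambda gg: (-len(gg), gg[0]))
    mapping = {gene: i + 1 for i, gg in enumerate(ordered) for gene in gg}
    return pd.Series({gene: mapping[gene] for gene in genes}, name="cluster")


def call_specific_genes(e: EnrichmentResult, net: RegulatoryNetwork,
                        m: ExpressionMatrix, tf_list: Iterable[str],
                        target: str = "neutrophil", comparator: str = "monocyte_dc",
                        fc_threshold: float = 2.0, q_threshold: float = 0.05,
                        require_cluster: Optional[pd.Series] = None,
                        cluster_id: int = 1) -> pd.DataFrame:
    """Classify genes as NSG / NSTF / MSTF relative to a target cell type.

    NSG: SEG in ``target``, member of the co-expression network, maximum
    per-cell-type mean in ``target``, and >= ``fc_threshold``-fold above the
    ``comparator`` myeloid population with BH-adjusted Welch-t q below
    ``q_threshold``.  NSTF restricts NSGs to the supplied TF list.  MSTF:
    TFs whose maximum is in target or comparator and that are two-fold
    (q < threshold) above *each* remaining cell type.

    ``require_cluster`` optionally restricts network membership to one
    cluster of a :func:`cluster_network` partition.
    """
    tf_set = set(tf_list)
    cts = m.cell_types
    if comparator not in cts:
        raise ValueError(f"comparator cell type {comparator!r} absent from matrix")
    means = m.cell_type_means()
    seg = set(e.seg_genes(target))
    members = set(net.nodes.index)
    if require_cluster is not None:
        members &= set(require_cluster.index[require_cluster == cluster_id])

    genes = list(m.values.index)
    max_ct = means.idxmax(axis=1)
    tcols, ccols = m.samples_of(target), m.samples_of(comparator)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc_cmp = means[target] / means[comparator]
    p_cmp = welch_t_log2(m.values[tcols].to_numpy(), m.values[ccols].to_numpy(), axis=1)
    p_cmp = pd.Series(p_cmp, index=genes)
    # BH over the genes that are actually candidates for the NSG contrast.
    candidates = [g for g in genes if g in seg and g in members and max_ct[g] == target]
    q_cmp = pd.Series(np.nan, index=genes)
    if candidates:
        q_cmp.loc[candidates] = bh_adjust(p_cmp.loc[candidates].to_numpy())

    nsg = pd.Series(False, index=genes)
    for g in candidates:
        nsg[g] = bool(fc_cmp[g] >= fc_threshold and q_cmp[g] < q_threshold)
    nstf = nsg & pd.Series([g in tf_set for g in genes], index=genes)

    # MSTF: myeloid-specific TFs vs each of the remaining cell types.
    mstf = pd.Series(False, index=genes)
    others = [ct for ct in cts if ct not in (target, comparator)]
    tf_candidates = [g for g in genes if g in tf_set and max_ct[g] in (target, comparator)]
    if tf_candidates and others:
        ok = pd.Series(True, index=tf_candidates)
        my_cols = tcols + ccols
        for ct in others:
            oc = m.samples_of(ct)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = means.loc[tf_candidates].max(axis=1) / means.loc[tf_candidates, ct]
            p = welch_t_log2(m.values.loc[tf_candidates, my_cols].to_numpy(),
                             m.values.loc[tf_candidates, oc].to_numpy(), axis=1)
            q = pd.Series(bh_adjust(p), index=tf_candidates)
            ok &= (ratio >= fc_threshold) & (q < q_threshold)
        mstf.loc[tf_candidates] = ok

    label = pd.Series("other", index=genes)
    label[mstf] = "MSTF"
    label[nsg] = "NSG"
    label[nstf] = "NSTF"
    return pd.DataFrame({
        "seg": [g in seg for g in genes],
        "in_network": [g in members for g in genes],
        "max_cell_type": max_ct,
        "fc_vs_comparator": fc_cmp,
        "q_vs_comparator": q_cmp,
        "is_tf": [g in tf_set for g in genes],
        "nsg": nsg, "nstf": nstf, "mstf": mstf, "label": label,
    }, index=pd.Index(genes, name="gene"))
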
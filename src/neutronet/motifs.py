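"""PWM motif scanning over promoter open-chromatin sequence, hypergeometric
motif enrichment, and assembly of the TF -> target + PPI regulatory network.

Scanning scores a window by the summed log2 odds of base probabilities
against the background; both strands are scanned and hits are windows
scoring at least ``threshold_fraction`` (default 0.8) of the maximum
attainable score.  This is a deterministic stand-in for empirically
calibrated motif scanners: thresholds are explicit rather than tuned per
motif.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .network import RegulatoryNetwork
from .stats import bh_adjust, fold_enrichment, hypergeom_upper_p

__all__ = [
    "PositionWeightMatrix", "read_pwms", "write_pwms", "reverse_complement",
    "scan_pwm", "motif_presence_table", "motif_enrichment",
    "multi_tf_audit", "assemble_network",
]

log = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
PROBABILITY_FLOOR = 1e-3


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclasses.dataclass
class PositionWeightMatrix:
    """4 x L base-probability matrix with a log-odds scanning threshold.

    Rows are A, C, G, T.  Probabilities are floored at 1e-3 and renormalised
    per column; the default hit threshold is ``threshold_fraction`` times the
    maximum attainable log-odds score.
    """

    motif_id: str
    tf: str
    matrix: np.ndarray
    background: np.ndarray = dataclasses.field(
        default_factory=lambda: np.full(4, 0.25))
    threshold_fraction: float = 0.8

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape[0] != 4 or m.shape[1] < 2:
            raise ValueError("PWM must be 4 x L with L >= 2")
        m = np.maximum(m, PROBABILITY_FLOOR)
        sums = m.sum(axis=0, keepdims=True)
        # Renormalise counts / off-by-more-than-rounding columns, but accept
        # columns already within write-precision of 1 so that file
        # round-trips are byte-stable.
        off = np.abs(sums - 1.0) > 1e-5
        if off.any():
            m = m / sums
        self.matrix = m

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.matrix / self.background[:, None])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def threshold(self) -> float:
        return self.threshold_fraction * self.max_score

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))

    def information_content(self) -> float:
        """Mean information content per column, in bits."""
        with np.errstate(divide="ignore", invalid="ignore"):
            ic = (self.matrix * np.log2(self.matrix / self.background[:, None])).sum(axis=0)
        return float(ic.mean())


def write_pwms(pwms: Sequence[PositionWeightMatrix], path) -> None:
    """Plain-text PWM set: one '>' header + 4 probability rows per motif."""
    lines = []
    for p in pwms:
        lines.append(f">{p.motif_id} tf={p.tf}")
        for i, base in enumerate(BASES):
            lines.append(base + "\t" + "\t".join(f"{v:.6f}" for v in p.matrix[i]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_pwms(path) -> List[PositionWeightMatrix]:
    """Read the package PWM format; JASPAR-style count rows (``A [ 3 5 .. ]``)
    are also accepted and normalised on load."""
    pwms: List[PositionWeightMatrix] = []
    header: Optional[Tuple[str, str]] = None
    rows: Dict[str, List[float]] = {}

    def flush():
        nonlocal header, rows
        if header is None:
            return
        missing = set(BASES) - set(rows)
        if missing:
            raise ValueError(f"PWM {header[0]} missing rows {sorted(missing)}")
        m = np.array([rows[b] for b in BASES], dtype=float)
        pwms.append(PositionWeightMatrix(header[0], header[1], m))
        header, rows = None, {}

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            parts = line[1:].split()
            mid = parts[0]
            tf = mid
            for tok in parts[1:]:
                if tok.startswith("tf="):
                    tf = tok[3:]
                    break
            else:
                if len(parts) >= 2:
                    tf = parts[1]
            header = (mid, tf)
        else:
            base = line[0].upper()
            if base not in _BASE_INDEX:
                raise ValueError(f"unexpected PWM row: {line!r}")
            body = line[1:].replace(":", " ").replace("[", " ").replace("]", " ")
            rows[base] = [float(tok) for tok in body.split()]
    flush()
    return pwms


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    code = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        code[ord(b)] = i
    return code[arr]


def scan_pwm(seq: str, pwm: PositionWeightMatrix,
             threshold: Optional[float] = None) -> List[Tuple[int, str, float]]:
    """All PWM hits in ``seq`` on both strands.

    Returns (offset, strand, score) triples; offsets always refer to the
    forward sequence.  Windows containing non-ACGT characters are skipped;
    sequences shorter than the motif yield an empty list.
    """
    thr = pwm.threshold if threshold is None else threshold
    L = pwm.length
    hits: List[Tuple[int, str, float]] = []
    if len(seq) < L:
        return hits
    lo = pwm.log_odds
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        enc = _encode(s)
        n_win = len(enc) - L + 1
        scores = np.zeros(n_win)
        valid = np.ones(n_win, dtype=bool)
        for j in range(L):
            col = enc[j:j + n_win]
            valid &= col >= 0
            scores += np.where(col >= 0, lo[np.maximum(col, 0), j], 0.0)
        for off in np.nonzero(valid & (scores >= thr))[0]:
            fwd_off = int(off) if strand == "+" else len(seq) - L - int(off)
            hits.append((fwd_off, strand, float(scores[off])))
    hits.sort()
    return hits


def motif_presence_table(genes: Iterable[str],
                         promoter_peak_intervals: Dict[str, List[Tuple[str, int, int]]],
                         genome: Dict[str, str],
                         pwms: Sequence[PositionWeightMatrix]
                         ) -> Tuple[pd.DataFrame, pd.Series]:
    """Gene x TF boolean motif-presence table over promoter OCR sequence.

    A gene is scannable only if it has at least one promoter peak interval;
    presence means >= 1 hit of the TF's PWM within any peak-by-promoter
    intersection interval of the gene.  Returns (presence, scannable).
    """
    genes = list(genes)
    tfs = [p.tf for p in pwms]
    presence = pd.DataFrame(False, index=pd.Index(genes, name="gene"), columns=tfs)
    scannable = pd.Series(False, index=presence.index, name="scannable")
    for g in genes:
        intervals = promoter_peak_intervals.get(g, [])
        if not intervals:
            continue
        seqs = []
        ok = True
        for chrom, start, end in intervals:
            if chrom not in genome:
                log.warning("no sequence for %s:%d-%d; gene %s unscanned", chrom, start, end, g)
                ok = False
                break
            seqs.append(genome[chrom][max(start, 0):end])
        if not ok:
            continue
        scannable[g] = True
        for p in pwms:
            presence.loc[g, p.tf] = any(len(scan_pwm(s, p)) > 0 for s in seqs)
    return presence, scannable


def motif_enrichment(presence: pd.DataFrame, target_genes: Iterable[str],
                     background_genes: Iterable[str]) -> pd.DataFrame:
    """Per-TF hypergeometric enrichment of motif presence in target vs background.

    ``k`` target genes with a hit out of ``n`` targets, against ``K`` of
    ``N`` background genes; p is the upper tail P(X >= k), fold is
    (k/n)/(K/N), BH across TFs.  K = 0 is reported with fold NaN, p 1 and a
    flag.
    """
    bg = [g for g in background_genes if g in presence.index]
    tg = [g for g in target_genes if g in bg]
    if not set(tg) <= set(bg):
        raise ValueError("target genes must be a subset of the background")
    N, n = len(bg), len(tg)
    rows = []
    for tf in presence.columns:
        K = int(presence.loc[bg, tf].sum())
        k = int(presence.loc[tg, tf].sum())
        undefined = K == 0
        p = 1.0 if undefined else hypergeom_upper_p(k, N, K, n)
        fold = float("nan") if undefined else (0.0 if k == 0 else fold_enrichment(k, n, K, N))
        rows.append({"tf": tf, "k": k, "n": n, "K": K, "N": N,
                     "fold": fold, "p": p, "undefined_fold": undefined})
    df = pd.DataFrame(rows).set_index("tf")
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df


def multi_tf_audit(presence: pd.DataFrame) -> Dict[str, object]:
    """Inclusion-exclusion audit of the per-TF motif gene counts.

    With per-TF counts k_i, the identity
    ``sum(k_i) - |exactly two TFs| - 2 * |exactly three TFs| = |distinct genes|``
    must hold exactly; the audit recomputes both sides from the table.
    """
    per_tf = presence.sum(axis=0).astype(int).to_dict()
    n_parents = presence.sum(axis=1)
    distinct = int((n_parents >= 1).sum())
    exactly2 = int((n_parents == 2).sum())
    exactly3 = int((n_parents == 3).sum())
    multi = int((n_parents >= 2).sum())
    total = int(sum(per_tf.values()))
    return {
        "per_tf_counts": per_tf,
        "distinct_genes": distinct,
        "multi_tf_genes": multi,
        "exactly_two": exactly2,
        "exactly_three": exactly3,
        "identity_holds": total - exactly2 - 2 * exactly3 == distinct,
        "multi_tf_gene_ids": sorted(n_parents.index[n_parents >= 2]),
    }


def assemble_network(presence: pd.DataFrame, ppi_edges: pd.DataFrame,
                     specificity: Optional[pd.DataFrame] = None,
                     coexpression_edges: Optional[pd.DataFrame] = None,
                     extra_tfs: Iterable[str] = ()) -> Tuple[RegulatoryNetwork, Dict[str, object]]:
    """Motif TF -> target edges plus PPI edges touching the network.

    PPI edges are kept when at least one endpoint is already a network node
    (TFs, motif targets, or TFs without a PWM passed via ``extra_tfs``);
    their partners join the node set, mirroring how interacting non-enriched
    genes appear in typical TF-target network figures.  Returns the network and a
    report with per-TF out-degrees and the multi-TF audit.
    """
    tfs = list(presence.columns)
    edges = []
    for tf in tfs:
        for g in presence.index[presence[tf]]:
            edges.append({"source": tf, "target": g, "edge_type": "motif", "r": np.nan})
    core = set(tfs) | {e["target"] for e in edges} | set(extra_tfs)
    for _, row in ppi_edges.iterrows():
        a, b = row["gene_a"], row["gene_b"]
        if a == b:
            continue
        if a in core or b in core:
            s, t = sorted((a, b))
            edges.append({"source": s, "target": t, "edge_type": "ppi", "r": np.nan})
    if coexpression_edges is not None:
        nodeset = core | {e["source"] for e in edges} | {e["target"] for e in edges}
        for _, row in coexpression_edges.iterrows():
            if row["source"] in nodeset and row["target"] in nodeset:
                edges.append({"source": row["source"], "target": row["target"],
                              "edge_type": "coexpression", "r": row.get("r", np.nan)})
    edf = pd.DataFrame(edges, columns=["source", "target", "edge_type", "r"])
    edf = edf.drop_duplicates(subset=["source", "target", "edge_type"]).reset_index(drop=True)
    node_ids = sorted(set(edf["source"]) | set(edf["target"]) | core)
    nodes = pd.DataFrame(index=pd.Index(node_ids, name="gene"))
    nodes["is_tf"] = [g in set(tfs) | set(extra_tfs) for g in node_ids]
    if specificity is not None:
        nodes["label"] = specificity["label"].reindex(node_ids).fillna("other")
    audit = multi_tf_audit(presence)
    report = {
        "per_tf_out_degree": {tf: int(presence[tf].sum()) for tf in tfs},
        "audit": audit,
    }
    return RegulatoryNetwork(nodes=nodes, edges=edf), report
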
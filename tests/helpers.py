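"""Independent oracle implementations and small builders shared by the tests.

The oracles here are deliberately literal (triple loops, exact enumeration)
and independent of the package's vectorised code paths.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from neutronet.containers import GenomeAnnotation
from neutronet.coexpression import partial_correlation


def pcit_oracle(R: np.ndarray) -> np.ndarray:
    """Literal O(n^3) PCIT pruning: for every trio compute the three partial
    correlations and the tolerance, flag the (x, y) edge when it is below
    both tolerance-scaled neighbour correlations, remove edges flagged in
    any trio."""
    n = R.shape[0]
    removed = np.zeros((n, n), dtype=bool)
    for x in range(n):
        for y in range(x + 1, n):
            for z in range(n):
                if z in (x, y):
                    continue
                rxy, rxz, ryz = R[x, y], R[x, z], R[y, z]
                pxy = partial_correlation(rxy, rxz, ryz)
                pxz = partial_correlation(rxz, rxy, ryz)
                pyz = partial_correlation(ryz, rxy, rxz)
                terms = []
                for p_c, r_c in ((pxy, rxy), (pxz, rxz), (pyz, ryz)):
                    if abs(r_c) >= 1e-12:
                        terms.append(p_c / r_c)
                if not terms:
                    continue
                eps = sum(terms) / len(terms)
                if abs(rxy) < abs(eps * rxz) and abs(rxy) < abs(eps * ryz):
                    removed[x, y] = removed[y, x] = True
    kept = ~removed
    kept &= np.abs(R) > 0
    np.fill_diagonal(kept, False)
    return kept


def hypergeom_oracle(k: int, N: int, K: int, n: int) -> float:
    """Exact upper-tail hypergeometric P(X >= k) by term-wise enumeration."""
    total = math.comb(N, n)
    acc = 0
    for i in range(max(k, 0), min(K, n) + 1):
        acc += math.comb(K, i) * math.comb(N - K, n - i)
    return acc / total


def random_correlation_matrix(rng: np.random.Generator, n: int,
                              n_obs: int = 8) -> np.ndarray:
    """Valid correlation matrix from random Gaussian observations."""
    x = rng.normal(size=(n, n_obs))
    r = np.corrcoef(x)
    r = np.clip(r, -0.9999, 0.9999)
    np.fill_diagonal(r, 1.0)
    return r


def toy_annotation(tss_list, chrom="chr1", size=1_000_000, strand="+",
                   body=2000, exons=None) -> GenomeAnnotation:
    """Annotation with one + strand gene per requested TSS."""
    rows = []
    for i, tss in enumerate(tss_list):
        rows.append((f"g{i + 1}", chrom, tss, tss + body, strand))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    return GenomeAnnotation.from_gene_table(genes.set_index("gene_id"),
                                            {chrom: size}, exons=exons)


def spaced_annotation(n_genes: int, spacing: int = 10_000, length: int = 1000,
                      chrom: str = "chr1") -> GenomeAnnotation:
    """Large, cheap annotation (no sequence) for expression-only simulations."""
    rows = [(f"G{i + 1:05d}", chrom, 10_000 + i * spacing,
             10_000 + i * spacing + length, "+") for i in range(n_genes)]
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    size = 20_000 + n_genes * spacing
    return GenomeAnnotation.from_gene_table(genes.set_index("gene_id"), {chrom: size})
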
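"""Pairwise linkage disequilibrium (r-squared) and LD-block construction.

r2 between two biallelic loci is computed from two-locus haplotype
frequencies estimated by EM from unphased genotypes: every genotype pair
except the double heterozygote resolves into known gametes; double
heterozygotes are split between the cis (AB/ab) and trans (Ab/aB)
configurations in proportion to the current frequency estimates, iterating to
a fixed point.  This is the estimator PLINK reports for unphased data.

Blocks of linked markers are connected components of the graph whose edges
join SNP pairs (within a sliding window, same chromosome) with
r2 >= threshold; components of a single SNP form no block.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd

from .types import MISSING, GenotypeMatrix, LDBlock

__all__ = ["two_locus_frequencies", "pairwise_r2", "pairwise_r2_table", "build_blocks"]

# gametes carried by each non-double-het genotype pair (xa, xb) -> list of
# (hapA_allele, hapB_allele); haplotypes indexed h = 2*a + b in {00,01,10,11}
_KNOWN_GAMETES: dict[tuple[int, int], list[int]] = {}
for _xa, _xb in itertools.product((0, 1, 2), repeat=2):
    if _xa == 1 and _xb == 1:
        continue
    a_alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[_xa]
    b_alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[_xb]
    if _xa == 1:  # a het, b hom: pair each a-allele with the b allele
        gametes = [2 * a_alleles[0] + b_alleles[0], 2 * a_alleles[1] + b_alleles[1]]
    elif _xb == 1:
        gametes = [2 * a_alleles[0] + b_alleles[0], 2 * a_alleles[1] + b_alleles[1]]
    else:
        gametes = [2 * a_alleles[0] + b_alleles[0]] * 2
    _KNOWN_GAMETES[(_xa, _xb)] = gametes


def two_locus_frequencies(
    xa: np.ndarray, xb: np.ndarray, max_iter: int = 200, tol: float = 1e-12
) -> tuple[np.ndarray, int]:
    """EM haplotype frequencies (p00, p01, p10, p11) for two loci.

    ``xa``/``xb`` are dosage vectors over the same animals; animals missing
    at either locus are dropped.  Returns the frequencies and the number of
    jointly observed animals.
    """
    xa = np.asarray(xa)
    xb = np.asarray(xb)
    ok = (xa != MISSING) & (xb != MISSING)
    xa, xb = xa[ok], xb[ok]
    n = xa.size
    if n < 2:
        raise ValueError("fewer than 2 animals with both calls non-missing")

    base = np.zeros(4)
    for (ga, gb), gametes in _KNOWN_GAMETES.items():
        count = int(np.sum((xa == ga) & (xb == gb)))
        for h in gametes:
            base[h] += count
    n_dh = int(np.sum((xa == 1) & (xb == 1)))

    freqs = np.full(4, 0.25)
    for _ in range(max_iter):
        cis = freqs[0] * freqs[3]
        trans = freqs[1] * freqs[2]
        w = cis / (cis + trans) if cis + trans > 0 else 0.5
        counts = base + n_dh * np.array([w, 1 - w, 1 - w, w])
        new = counts / (2.0 * n)
        if np.max(np.abs(new - freqs)) < tol:
            freqs = new
            break
        freqs = new
    return freqs, n


def pairwise_r2(g: GenotypeMatrix, snp_a: int, snp_b: int) -> float:
    """EM-based r2 between two SNPs of the same chromosome.

    Returns 0.0 when either locus is monomorphic among the jointly observed
    animals.  Raises if the SNPs sit on different chromosomes or fewer than
    two animals are observed at both.
    """
    if g.chromosome[snp_a] != g.chromosome[snp_b]:
        raise ValueError("r2 is only defined within a chromosome")
    freqs, _ = two_locus_frequencies(g.calls[:, snp_a], g.calls[:, snp_b])
    p_a = freqs[2] + freqs[3]  # allele 1 at locus A
    p_b = freqs[1] + freqs[3]
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom <= 0:
        return 0.0
    d = freqs[3] - p_a * p_b
    return float(min(1.0, d * d / denom))


def pairwise_r2_table(
    g: GenotypeMatrix, window_snps: int = 50
) -> pd.DataFrame:
    """All within-window, within-chromosome r2 values.

    Pairs with fewer than two jointly observed animals get NaN.
    """
    rows = []
    for chrom in dict.fromkeys(g.chromosome):
        idx = np.flatnonzero(g.chromosome == chrom)
        for i, a in enumerate(idx):
            for b in idx[i + 1 : i + 1 + window_snps]:
                try:
                    r2 = pairwise_r2(g, int(a), int(b))
                except ValueError:
                    r2 = float("nan")
                rows.append((g.snp_ids[a], g.snp_ids[b], chrom, int(a), int(b), r2))
    return pd.DataFrame(
        rows, columns=["snp_a", "snp_b", "chromosome", "idx_a", "idx_b", "r2"]
    )


def build_blocks(
    g: GenotypeMatrix,
    r2_threshold: float = 0.8,
    window_snps: int = 50,
    contiguous: bool = False,
) -> list[LDBlock]:
    """Assemble LD blocks as connected components of the thresholded r2 graph.

    ``contiguous=True`` restricts edges to map-adjacent SNP pairs, chaining
    runs of consecutive linked markers instead (sensitivity mode).
    Singleton components are discarded.
    """
    if not 0 < r2_threshold <= 1:
        raise ValueError("r2_threshold must be in (0, 1]")
    if window_snps < 1:
        raise ValueError("window_snps must be >= 1")
    blocks: list[LDBlock] = []
    counter = 0
    for chrom in dict.fromkeys(g.chromosome):
        idx = np.flatnonzero(g.chromosome == chrom)
        graph = nx.Graph()
        graph.add_nodes_from(int(i) for i in idx)
        for i, a in enumerate(idx):
            neighbours = idx[i + 1 : i + 2] if contiguous else idx[i + 1 : i + 1 + window_snps]
            for b in neighbours:
                try:
                    r2 = pairwise_r2(g, int(a), int(b))
                except ValueError:
                    continue
                if r2 >= r2_threshold:
                    graph.add_edge(int(a), int(b))
        for comp in sorted(nx.connected_components(graph), key=min):
            if len(comp) < 2:
                continue
            blocks.append(
                LDBlock(
                    block_id=f"block{counter}",
                    chromosome=str(chrom),
                    snp_indices=tuple(sorted(comp)),
                )
            )
            counter += 1
    return blocks
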
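"""Haplotype phasing within LD blocks by multi-locus EM.

Each block is treated as one multi-allelic locus.  Haplotype (gametic)
frequencies are estimated by expectation-maximisation over unphased
genotypes: the E-step distributes each animal's genotype over its compatible
unordered haplotype pairs in proportion to f_j*f_k (doubled for
heterozygous pairs, the Hardy-Weinberg diplotype probabilities); the M-step
re-estimates frequencies from the expected gamete counts.  Missing calls
inside a block are marginalised by enumerating all compatible alleles; an
animal with every call missing contributes nothing to the likelihood and
receives the population (Hardy-Weinberg) prior as its posterior.

The final E-step weights are the per-animal diplotype posteriors consumed by
the prediction model, both as transmission probabilities and as most-probable
diplotypes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .types import MISSING, GenotypeMatrix, HaplotypeAllele, LDBlock

__all__ = [
    "BlockTooComplexError",
    "BlockPhase",
    "PhasedData",
    "em_phase_block",
    "phase_blocks",
    "carrier_frequency",
    "select_frequent_haplotypes",
    "SelectedHaplotype",
]

#: frequencies below this are pruned after convergence
_PRUNE_FREQ = 1e-9


class BlockTooComplexError(ValueError):
    """Raised when a block's haplotype enumeration exceeds the cap."""


@dataclass
class BlockPhase:
    """Phasing result for one block.

    ``posteriors[i]`` lists ``(j, k, prob)`` with ``j <= k`` indexing
    ``alleles``; probabilities sum to one per animal.
    """

    block_id: str
    alleles: list[HaplotypeAllele]
    posteriors: list[list[tuple[int, int, float]]]
    log_likelihood_trace: list[float] = field(default_factory=list)
    n_iterations: int = 0

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([a.population_frequency for a in self.alleles])

    def carry_probability(self, j: int) -> np.ndarray:
        """P(animal carries >= 1 copy of allele j), per animal."""
        out = np.zeros(len(self.posteriors))
        for i, pairs in enumerate(self.posteriors):
            out[i] = sum(p for a, b, p in pairs if j in (a, b))
        return np.minimum(out, 1.0)

    def expected_dosage(self, j: int) -> np.ndarray:
        """Expected copy count of allele j, per animal."""
        out = np.zeros(len(self.posteriors))
        for i, pairs in enumerate(self.posteriors):
            out[i] = sum(p * ((a == j) + (b == j)) for a, b, p in pairs)
        return out

    def modal_pair(self, i: int) -> tuple[int, int]:
        """Most probable unordered diplotype of animal i (ties: first listed)."""
        pairs = self.posteriors[i]
        return max(pairs, key=lambda t: t[2])[:2]


@dataclass
class PhasedData:
    """Per-block phasing results plus the blocks skipped as too complex."""

    blocks: list[LDBlock]
    phases: dict[str, BlockPhase]
    skipped: list[str] = field(default_factory=list)
    animal_ids: list[str] = field(default_factory=list)


def _compatible_pairs(
    pattern: tuple[int, ...]
) -> list[tuple[bytes, bytes]]:
    """Unordered haplotype pairs consistent with one genotype pattern.

    Pattern entries are dosages 0/1/2 or MISSING.  Homozygous sites fix both
    haplotypes, heterozygous sites split complementarily, missing sites are
    free on both haplotypes independently.
    """
    arr = np.array(pattern)
    het = np.flatnonzero(arr == 1)
    miss = np.flatnonzero(arr == MISSING)
    n_pairs = (2 ** max(len(het) - 1, 0)) * (4 ** len(miss))
    if len(het) + 2 * len(miss) > 40 or n_pairs > 2**22:
        raise BlockTooComplexError("pair enumeration too large for this genotype")
    base = np.where(arr == 2, 1, 0).astype(np.int8)
    seen: set[tuple[bytes, bytes]] = set()
    for het_bits in itertools.product((0, 1), repeat=len(het)):
        h1t = base.copy()
        h2t = base.copy()
        h1t[het] = het_bits
        h2t[het] = 1 - np.array(het_bits, dtype=np.int8)
        for m1 in itertools.product((0, 1), repeat=len(miss)):
            h1 = h1t.copy()
            h1[miss] = m1
            for m2 in itertools.product((0, 1), repeat=len(miss)):
                h2 = h2t.copy()
                h2[miss] = m2
                key = tuple(sorted((h1.tobytes(), h2.tobytes())))
                seen.add(key)
    return sorted(seen)


def em_phase_block(
    g_block: np.ndarray,
    block_id: str = "block",
    max_iter: int = 1000,
    tol: float = 1e-8,
    enumeration_cap: int = 2**20,
) -> BlockPhase:
    """Phase one block of genotype calls (animals x SNPs, dosage/MISSING coded).

    Frequencies start uniform over all observation-compatible haplotypes, so
    the default run is deterministic.  The log-likelihood is checked to be
    non-decreasing at every iteration; convergence is declared when its change
    drops below ``tol``.
    """
    g_block = np.asarray(g_block)
    if g_block.ndim != 2 or g_block.shape[1] < 2:
        raise ValueError("block must be a 2-D matrix with >= 2 SNPs")
    n, length = g_block.shape
    patterns = [tuple(int(v) for v in row) for row in g_block]
    informative = {
        p for p in set(patterns) if any(v != MISSING for v in p)
    }
    if not informative:
        raise ValueError("no animal has a non-missing call in this block")

    # candidate haplotypes and per-pattern compatible pairs
    pattern_pairs: dict[tuple[int, ...], list[tuple[bytes, bytes]]] = {}
    candidates: dict[bytes, int] = {}
    for p in sorted(informative):
        pairs = _compatible_pairs(p)
        pattern_pairs[p] = pairs
        for h1, h2 in pairs:
            for h in (h1, h2):
                if h not in candidates:
                    candidates[h] = len(candidates)
        if len(candidates) > enumeration_cap:
            raise BlockTooComplexError(
                f"{block_id}: candidate haplotypes exceed cap {enumeration_cap}"
            )
    n_hap = len(candidates)
    pattern_idx = {
        p: np.array([(candidates[a], candidates[b]) for a, b in pairs])
        for p, pairs in pattern_pairs.items()
    }
    counts_by_pattern = {p: 0 for p in informative}
    n_informative = 0
    for p in patterns:
        if p in counts_by_pattern:
            counts_by_pattern[p] += 1
            n_informative += 1

    freqs = np.full(n_hap, 1.0 / n_hap)
    ll_trace: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        counts = np.zeros(n_hap)
        ll = 0.0
        for p, cnt in counts_by_pattern.items():
            jk = pattern_idx[p]
            w = freqs[jk[:, 0]] * freqs[jk[:, 1]]
            w = np.where(jk[:, 0] != jk[:, 1], 2.0 * w, w)
            total = w.sum()
            if total <= 0:
                continue
            ll += cnt * np.log(total)
            w = w / total
            np.add.at(counts, jk[:, 0], cnt * w)
            np.add.at(counts, jk[:, 1], cnt * w)
        if ll_trace and ll < ll_trace[-1] - 1e-9:
            raise RuntimeError("EM log-likelihood decreased")
        converged = bool(ll_trace) and abs(ll - ll_trace[-1]) < tol
        ll_trace.append(ll)
        if converged:
            break
        freqs = counts / (2.0 * n_informative)

    # prune vanishing alleles and re-index
    keep = np.flatnonzero(freqs > _PRUNE_FREQ)
    remap = {int(old): new for new, old in enumerate(keep)}
    freqs_kept = freqs[keep]
    freqs_kept = freqs_kept / freqs_kept.sum()
    inv_candidates = {v: k for k, v in candidates.items()}
    alleles = [
        HaplotypeAllele(
            block_id=block_id,
            allele_string="".join(
                str(int(b)) for b in np.frombuffer(inv_candidates[int(old)], dtype=np.int8)
            ),
            population_frequency=float(f),
        )
        for old, f in zip(keep, freqs_kept)
    ]

    # final E-step posteriors on the pruned allele set
    pattern_post: dict[tuple[int, ...], list[tuple[int, int, float]]] = {}
    for p in informative:
        jk = pattern_idx[p]
        ok = np.isin(jk[:, 0], keep) & np.isin(jk[:, 1], keep)
        jk = jk[ok]
        w = freqs[jk[:, 0]] * freqs[jk[:, 1]]
        w = np.where(jk[:, 0] != jk[:, 1], 2.0 * w, w)
        total = w.sum()
        if total <= 0:  # degenerate; fall back to uniform over compatible pairs
            w = np.ones(len(jk))
            total = w.sum()
        w = w / total
        pattern_post[p] = [
            (min(remap[int(a)], remap[int(b)]), max(remap[int(a)], remap[int(b)]), float(pw))
            for (a, b), pw in zip(jk, w)
            if pw > 0
        ]

    # Hardy-Weinberg prior for all-missing animals
    prior_pairs: list[tuple[int, int, float]] = []
    for j in range(len(keep)):
        for k in range(j, len(keep)):
            p_jk = freqs_kept[j] * freqs_kept[k] * (2.0 if j != k else 1.0)
            if p_jk > 0:
                prior_pairs.append((j, k, float(p_jk)))

    posteriors = [
        pattern_post[p] if p in pattern_post else list(prior_pairs) for p in patterns
    ]
    return BlockPhase(
        block_id=block_id,
        alleles=alleles,
        posteriors=posteriors,
        log_likelihood_trace=ll_trace,
        n_iterations=n_iter,
    )


def phase_blocks(
    g: GenotypeMatrix,
    blocks: list[LDBlock],
    max_iter: int = 1000,
    tol: float = 1e-8,
    enumeration_cap: int = 2**20,
) -> PhasedData:
    """Phase every block; blocks exceeding the enumeration cap are skipped."""
    phases: dict[str, BlockPhase] = {}
    kept_blocks: list[LDBlock] = []
    skipped: list[str] = []
    for block in blocks:
        sub = g.calls[:, list(block.snp_indices)]
        try:
            phases[block.block_id] = em_phase_block(
                sub,
                block_id=block.block_id,
                max_iter=max_iter,
                tol=tol,
                enumeration_cap=enumeration_cap,
            )
            kept_blocks.append(block)
        except BlockTooComplexError:
            skipped.append(block.block_id)
    return PhasedData(
        blocks=kept_blocks,
        phases=phases,
        skipped=skipped,
        animal_ids=list(g.animal_ids),
    )


def carrier_frequency(phase: BlockPhase, allele_index: int) -> float:
    """Fraction of animals whose posterior carry probability exceeds 0.5."""
    return float(np.mean(phase.carry_probability(allele_index) > 0.5))


@dataclass(frozen=True)
class SelectedHaplotype:
    """A high-frequency haplotype allele retained for the prediction model."""

    block_id: str
    allele_index: int
    allele_string: str
    population_frequency: float
    carrier_frequency: float
    block_size: int


def select_frequent_haplotypes(
    phased: PhasedData,
    threshold: float = 0.25,
    basis: str = "carrier",
) -> list[SelectedHaplotype]:
    """Keep haplotypes whose frequency strictly exceeds ``threshold``.

    ``basis`` chooses the frequency compared against the threshold:
    ``"carrier"`` (fraction of individuals carrying the allele, the default)
    or ``"population"`` (chromosome frequency).  Order is deterministic:
    block order, then descending selection frequency, ties broken by allele
    string.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    if basis not in ("carrier", "population"):
        raise ValueError("basis must be 'carrier' or 'population'")
    selected: list[SelectedHaplotype] = []
    block_sizes = {b.block_id: b.size for b in phased.blocks}
    for block in phased.blocks:
        phase = phased.phases[block.block_id]
        rows = []
        for j, allele in enumerate(phase.alleles):
            carrier = carrier_frequency(phase, j)
            freq = carrier if basis == "carrier" else allele.population_frequency
            allele.carrier_frequency = carrier
            if freq > threshold:
                rows.append((freq, allele.allele_string, j, allele, carrier))
        rows.sort(key=lambda r: (-r[0], r[1]))
        for freq, string, j, allele, carrier in rows:
            selected.append(
                SelectedHaplotype(
                    block_id=block.block_id,
                    allele_index=j,
                    allele_string=string,
                    population_frequency=allele.population_frequency,
                    carrier_frequency=carrier,
                    block_size=block_sizes[block.block_id],
                )
            )
    return selected
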
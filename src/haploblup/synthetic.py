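"""Synthetic dairy-cattle populations with block-structured haplotypes.

The real data behind this kind of analysis — national-evaluation proofs and
SNP-chip genotypes of progeny-tested bulls — are not public, so every
downstream stage is exercised on populations simulated here.  The generator
emulates the statistical structure the analysis assumes:

* the genome is a set of independent LD blocks, each segregating a small
  number of haplotype alleles whose frequencies follow a symmetric Dirichlet;
* diplotypes are drawn per animal under Hardy-Weinberg equilibrium;
* true breeding values are sums of per-haplotype effects, calibrated so that
  the additive-genetic variance among animals equals the trait's sigma2_g;
* EBVs are TBV plus noise with the prediction-error variance implied by each
  bull's reliability, PEV = sigma2_g * (1 - REL) / REL;
* birth years span a range so a generational train/validation split exists;
* genotype calls go missing independently at a configurable rate.

Blocks are simulated without between-block LD: the downstream model treats
haplotype effects as independent random effects, and within-block LD is
implicit in the finite allele set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import CHROMOSOME_LABELS, MISSING, GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "TruePopulation",
    "simulate_population",
    "inject_missingness",
    "true_dosage_matrix",
]

#: bp spacing of SNPs within a block and gap between blocks on a chromosome.
_SNP_SPACING = 5_000
_BLOCK_GAP = 1_000_000


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated population.

    Defaults describe the study conditions the package targets: 1216
    progeny-tested bulls born 1987-2003, a milk-yield-like trait
    (h2 = 0.33, sigma2_g = 213,490 kg2), proof reliabilities typical of
    progeny-tested sires, and a desk-scale genome of 50 independent blocks.
    """

    n_animals: int = 1216
    n_blocks: int = 50
    block_size_range: tuple[int, int] = (2, 8)
    alleles_per_block: int = 4
    allele_freq_concentration: float = 1.0
    heritability: float = 0.33
    genetic_variance: float = 213_490.0
    reliability_range: tuple[float, float] = (0.60, 0.98)
    birth_year_range: tuple[int, int] = (1987, 2003)
    missing_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        lo, hi = self.block_size_range
        if lo < 2 or hi < lo:
            raise ValueError("block_size_range must satisfy 2 <= min <= max")
        if self.alleles_per_block < 2:
            raise ValueError("alleles_per_block must be >= 2")
        if self.allele_freq_concentration <= 0:
            raise ValueError("allele_freq_concentration must be positive")
        if not 0 < self.heritability <= 1:
            raise ValueError("heritability must be in (0, 1]")
        if self.genetic_variance <= 0:
            raise ValueError("genetic_variance must be positive")
        rlo, rhi = self.reliability_range
        if not (0 < rlo <= rhi <= 1):
            raise ValueError("reliability_range values must be in (0, 1], min <= max")
        ylo, yhi = self.birth_year_range
        if yhi < ylo:
            raise ValueError("birth_year_range must satisfy min <= max")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class TruePopulation:
    """A simulated population together with its generating ground truth.

    ``genotypes`` holds the complete (pre-missingness) calls.  Diplotypes are
    stored ordered (two gametes) but phase of origin is unobservable and all
    comparisons downstream are unordered.
    """

    config: SimulationConfig
    genotypes: GenotypeMatrix
    #: per block: (K, L) 0/1 array, one row per haplotype allele
    block_alleles: list[np.ndarray]
    #: per block: (K,) gametic frequencies used to draw diplotypes
    allele_freqs: list[np.ndarray]
    #: per block: (n_animals, 2) allele indices
    true_diplotypes: list[np.ndarray]
    #: per block: (K,) additive effect of one copy of each allele
    true_effects: list[np.ndarray]
    #: per block: panel column indices of the block's SNPs
    block_columns: list[np.ndarray]
    tbv: np.ndarray
    proofs: pd.DataFrame = field(repr=False)  # animal_id, birth_year, ebv, reliability

    @property
    def n_haplotypes(self) -> int:
        return sum(len(f) for f in self.allele_freqs)

    def analytic_genetic_variance(self) -> float:
        """Variance of TBV over the diplotype distribution, given the drawn
        frequencies and effects: sum over blocks of 2*Var_f(h)."""
        total = 0.0
        for f, h in zip(self.allele_freqs, self.true_effects):
            total += 2.0 * (float(f @ h**2) - float(f @ h) ** 2)
        return total


def _draw_block_alleles(rng: np.random.Generator, k: int, length: int) -> np.ndarray:
    """Draw K distinct binary haplotype alleles of given length such that
    every SNP column segregates (is non-constant across alleles)."""
    for _ in range(1000):
        alleles = rng.integers(0, 2, size=(k, length), dtype=np.int8)
        # resample constant columns until every SNP is polymorphic in the pool
        for _ in range(1000):
            const = np.flatnonzero(np.ptp(alleles, axis=0) == 0)
            if const.size == 0:
                break
            alleles[:, const] = rng.integers(0, 2, size=(k, const.size), dtype=np.int8)
        if len({a.tobytes() for a in alleles}) == k:
            return alleles
    raise RuntimeError("could not draw distinct segregating haplotype alleles")


def simulate_population(config: SimulationConfig) -> TruePopulation:
    """Simulate genotypes, haplotype effects, TBV and proofs from ``config``.

    Fully reproducible from ``config.seed``.  Haplotype effects are drawn from
    the equal-partition prior h_j ~ N(0, sigma2_g / H) and then rescaled once
    so that the analytic genetic variance given the drawn frequencies equals
    sigma2_g exactly; EBV noise is N(0, sigma2_g*(1-REL)/REL) with REL uniform
    on ``reliability_range``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_animals
    k = config.alleles_per_block
    lo, hi = config.block_size_range

    block_alleles: list[np.ndarray] = []
    allele_freqs: list[np.ndarray] = []
    diplotypes: list[np.ndarray] = []
    block_chrom: list[str] = []
    for b in range(config.n_blocks):
        length = int(rng.integers(lo, hi + 1))
        alleles = _draw_block_alleles(rng, k, length)
        freqs = rng.dirichlet(np.full(k, config.allele_freq_concentration))
        dip = rng.choice(k, size=(n, 2), p=freqs)  # Hardy-Weinberg
        block_alleles.append(alleles)
        allele_freqs.append(freqs)
        diplotypes.append(dip)
        block_chrom.append(CHROMOSOME_LABELS[b % len(CHROMOSOME_LABELS)])

    # lay blocks out chromosome by chromosome so MAP order is well defined
    order = [
        b
        for chrom in CHROMOSOME_LABELS
        for b in range(config.n_blocks)
        if block_chrom[b] == chrom
    ]
    snp_ids: list[str] = []
    chromosome: list[str] = []
    position: list[int] = []
    columns: list[np.ndarray] = [np.empty(0, dtype=int)] * config.n_blocks
    geno_cols: list[np.ndarray] = []
    next_pos: dict[str, int] = {}
    for b in order:
        chrom = block_chrom[b]
        length = block_alleles[b].shape[1]
        start = next_pos.get(chrom, _SNP_SPACING)
        cols = np.arange(len(snp_ids), len(snp_ids) + length)
        columns[b] = cols
        for j in range(length):
            snp_ids.append(f"blk{b}_snp{j}")
            chromosome.append(chrom)
            position.append(start + j * _SNP_SPACING)
        next_pos[chrom] = start + length * _SNP_SPACING + _BLOCK_GAP
        geno_cols.append(
            block_alleles[b][diplotypes[b][:, 0]] + block_alleles[b][diplotypes[b][:, 1]]
        )
    calls = np.concatenate(geno_cols, axis=1).astype(np.int8)

    genotypes = GenotypeMatrix(
        animal_ids=[f"bull{i + 1:05d}" for i in range(n)],
        snp_ids=snp_ids,
        chromosome=np.array(chromosome, dtype=object),
        position=np.array(position),
        calls=calls,
    )

    # haplotype effects: equal partition across all H alleles, then calibrated
    # so the realised additive variance equals sigma2_g
    total_h = k * config.n_blocks
    effects = [
        rng.normal(0.0, np.sqrt(config.genetic_variance / total_h), size=k)
        for _ in range(config.n_blocks)
    ]
    # breeding values are deviations from the population mean: centre each
    # block's effects at the frequency-weighted mean (the mean belongs to mu)
    effects = [h - f @ h for f, h in zip(allele_freqs, effects)]
    raw_var = sum(
        2.0 * (float(f @ h**2) - float(f @ h) ** 2)
        for f, h in zip(allele_freqs, effects)
    )
    if raw_var > 0:
        scale = np.sqrt(config.genetic_variance / raw_var)
        effects = [h * scale for h in effects]

    tbv = np.zeros(n)
    for b in range(config.n_blocks):
        tbv += effects[b][diplotypes[b][:, 0]] + effects[b][diplotypes[b][:, 1]]

    rlo, rhi = config.reliability_range
    rel = rng.uniform(rlo, rhi, size=n)
    pev = config.genetic_variance * (1.0 - rel) / rel
    ebv = tbv + rng.normal(0.0, np.sqrt(pev))
    ylo, yhi = config.birth_year_range
    birth_year = rng.integers(ylo, yhi + 1, size=n)

    proofs = pd.DataFrame(
        {
            "animal_id": genotypes.animal_ids,
            "birth_year": birth_year,
            "ebv": ebv,
            "reliability": rel,
        }
    )
    return TruePopulation(
        config=config,
        genotypes=genotypes,
        block_alleles=block_alleles,
        allele_freqs=allele_freqs,
        true_diplotypes=diplotypes,
        true_effects=effects,
        block_columns=columns,
        tbv=tbv,
        proofs=proofs,
    )


def inject_missingness(
    pop: TruePopulation | GenotypeMatrix, rate: float, seed: int
) -> GenotypeMatrix:
    """Set each genotype call to missing independently with probability ``rate``."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    g = pop.genotypes if isinstance(pop, TruePopulation) else pop
    calls = g.calls.copy()
    if rate > 0:
        rng = np.random.default_rng(seed)
        mask = rng.random(calls.shape) < rate
        calls[mask] = MISSING
    return GenotypeMatrix(
        animal_ids=list(g.animal_ids),
        snp_ids=list(g.snp_ids),
        chromosome=g.chromosome.copy(),
        position=g.position.copy(),
        calls=calls,
    )


def true_dosage_matrix(pop: TruePopulation) -> tuple[np.ndarray, np.ndarray]:
    """Exact haplotype dosages from the generating diplotypes.

    Returns ``(dosage, effects)`` where ``dosage`` is an
    ``(n_animals, H)`` array of copy counts (0/1/2) over all simulated
    haplotype alleles, columns ordered block-major, and ``effects`` the
    matching flat vector of true per-copy effects.  Useful for testing the
    prediction model with phasing uncertainty removed.
    """
    cols = []
    for dip, f in zip(pop.true_diplotypes, pop.allele_freqs):
        k = len(f)
        dos = np.zeros((dip.shape[0], k))
        for c in range(2):
            np.add.at(dos, (np.arange(dip.shape[0]), dip[:, c]), 1.0)
        cols.append(dos)
    dosage = np.concatenate(cols, axis=1)
    effects = np.concatenate(pop.true_effects)
    return dosage, effects
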
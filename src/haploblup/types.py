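"""Core in-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Code for a missing genotype call in :class:`GenotypeMatrix.calls`.
MISSING: int = -1

#: Chromosome labels in map order: 29 bovine autosomes followed by the allosome.
CHROMOSOME_LABELS: tuple[str, ...] = tuple(str(c) for c in range(1, 30)) + ("X",)


@dataclass
class GenotypeMatrix:
    """Biallelic genotypes for a panel of animals.

    ``calls`` is an ``(n_animals, n_snps)`` integer array counting copies of
    the B allele (0, 1 or 2), with :data:`MISSING` (-1) for no-calls.  SNPs are
    ordered by chromosome and, within a chromosome, strictly increasing by
    base-pair position — the order of the accompanying PLINK MAP file.
    """

    animal_ids: list[str]
    snp_ids: list[str]
    chromosome: np.ndarray  # (n_snps,) str labels
    position: np.ndarray  # (n_snps,) int base pairs
    calls: np.ndarray  # (n_animals, n_snps) int8

    def __post_init__(self) -> None:
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position = np.asarray(self.position, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D animals x SNPs array")
        n_animals, n_snps = self.calls.shape
        if n_animals != len(self.animal_ids):
            raise ValueError("calls rows do not match animal_ids")
        if n_snps != len(self.snp_ids):
            raise ValueError("calls columns do not match snp_ids")
        if len(self.chromosome) != n_snps or len(self.position) != n_snps:
            raise ValueError("chromosome/position length does not match snp_ids")
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("calls contain codes outside {0,1,2,missing}")
        for chrom in dict.fromkeys(self.chromosome):
            pos = self.position[self.chromosome == chrom]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions on chromosome {chrom} not strictly increasing"
                )

    @property
    def n_animals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to SNP indices ``keep`` (original order)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        keep = np.sort(keep)
        return GenotypeMatrix(
            animal_ids=list(self.animal_ids),
            snp_ids=[self.snp_ids[i] for i in keep],
            chromosome=self.chromosome[keep],
            position=self.position[keep],
            calls=self.calls[:, keep].copy(),
        )


@dataclass(frozen=True)
class LDBlock:
    """An ordered set of linked SNPs on one chromosome.

    ``snp_indices`` index into the QC-passed panel and are strictly
    increasing; they need not be contiguous in map order (blocks are connected
    components of the thresholded r-squared graph).
    """

    block_id: str
    chromosome: str
    snp_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.snp_indices) < 2:
            raise ValueError("a block needs at least 2 SNPs")
        if any(b <= a for a, b in zip(self.snp_indices, self.snp_indices[1:])):
            raise ValueError("snp_indices must be strictly increasing")

    @property
    def size(self) -> int:
        """Haplotype size L: number of SNPs in the block."""
        return len(self.snp_indices)


@dataclass
class HaplotypeAllele:
    """One haplotype allele of a block.

    ``population_frequency`` is the chromosome (gametic) frequency estimated
    by the phaser; ``carrier_frequency`` is the fraction of individuals whose
    posterior probability of carrying at least one copy exceeds one half.
    """

    block_id: str
    allele_string: str  # over {0,1}, length = block size
    population_frequency: float
    carrier_frequency: float = field(default=float("nan"))
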
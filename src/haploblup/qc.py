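"""SNP-level quality control: call-rate (GENO) and minor-allele-frequency filters.

The panel is filtered in two stages mirroring standard PLINK practice: first
SNPs with more than ``max_missing`` missing calls are removed (GENO filter),
then SNPs whose MAF does not exceed ``min_maf`` (strict inequality).  MAF is
computed over non-missing calls only; an all-missing SNP has undefined MAF and
fails both filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeMatrix

__all__ = ["QCReport", "compute_call_rate", "compute_maf", "apply_qc"]


@dataclass
class QCReport:
    """Stage-by-stage bookkeeping of the SNP filters."""

    n_input_snps: int
    n_after_geno: int
    n_after_maf: int
    per_snp: pd.DataFrame  # snp_id, call_rate, maf, pass_geno, pass_maf, kept
    kept_snp_ids: list[str]

    def __post_init__(self) -> None:
        if not (self.n_after_maf <= self.n_after_geno <= self.n_input_snps):
            raise ValueError("filter stages must be nested")


def compute_call_rate(g: GenotypeMatrix) -> np.ndarray:
    """Per-SNP fraction of non-missing calls, in [0, 1]."""
    if g.n_animals == 0:
        raise ValueError("empty genotype matrix")
    return (g.calls != MISSING).mean(axis=0)


def compute_maf(g: GenotypeMatrix) -> np.ndarray:
    """Per-SNP minor allele frequency over non-missing calls.

    Returns NaN for SNPs with no non-missing calls.
    """
    if g.n_animals == 0:
        raise ValueError("empty genotype matrix")
    observed = g.calls != MISSING
    n_obs = observed.sum(axis=0)
    b_count = np.where(observed, g.calls, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_obs > 0, b_count / (2.0 * n_obs), np.nan)
    return np.minimum(p, 1.0 - p)


def apply_qc(
    g: GenotypeMatrix, max_missing: float = 0.10, min_maf: float = 0.01
) -> tuple[GenotypeMatrix, QCReport]:
    """Keep SNPs with call rate >= 1 - max_missing and MAF > min_maf.

    The two criteria are conjunctive, so the kept set is order-independent;
    the report counts them GENO-first.
    """
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must be in [0, 1]")
    if not 0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    call_rate = compute_call_rate(g)
    maf = compute_maf(g)
    pass_geno = call_rate >= 1.0 - max_missing
    # NaN MAF (all-missing SNP) fails: NaN > t is False
    with np.errstate(invalid="ignore"):
        pass_maf = maf > min_maf
    kept = pass_geno & pass_maf
    per_snp = pd.DataFrame(
        {
            "snp_id": g.snp_ids,
            "chromosome": g.chromosome,
            "position": g.position,
            "call_rate": call_rate,
            "maf": maf,
            "pass_geno": pass_geno,
            "pass_maf": pass_maf,
            "kept": kept,
        }
    )
    report = QCReport(
        n_input_snps=g.n_snps,
        n_after_geno=int(pass_geno.sum()),
        n_after_maf=int(kept.sum()),
        per_snp=per_snp,
        kept_snp_ids=[s for s, k in zip(g.snp_ids, kept) if k],
    )
    return g.subset_snps(kept), report
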
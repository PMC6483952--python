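"""The random-haplotype-effect prediction model.

The model is a single-mean linear mixed model

    y = mu + Z h + e,    h_j ~ N(0, sigma2_h_j),    e ~ N(0, R),

with y the deregressed proofs, Z a design matrix over the selected
high-frequency haplotypes and h their random effects.  Four variants arise
from crossing two choices:

* Z kind — ``probability``: Z_ij is the probability that animal i transmits
  haplotype j (expected dosage / 2, from the diplotype posterior);
  ``indicator``: Z_ij is 1 if the most probable diplotype of animal i at j's
  block contains j, else 0.
* variance scheme — ``equal``: sigma2_h_j = sigma2_g / H for all H selected
  haplotypes; ``size_weighted``: sigma2_h_j = sigma2_g * L_j / sum_k L_k with
  L_j the SNP count of j's block, so longer haplotypes absorb more variance.

Both schemes partition the trait's genetic variance exactly.  The mixed model
equations are formed densely and solved by a symmetric positive-definite
factorisation; mu is the fixed effect, h the BLUP.  The direct genomic value
of an animal is DGV_i = sum_j Z_ij h_j (mu excluded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .phasing import PhasedData, SelectedHaplotype

__all__ = [
    "ModelVariant",
    "HaplotypeModelFit",
    "build_design_matrix",
    "partition_variance",
    "solve_model",
    "predict_dgv",
]


@dataclass(frozen=True)
class ModelVariant:
    """One of the four model variants (Z kind x variance scheme)."""

    z_kind: str  # "probability" | "indicator"
    variance_scheme: str  # "equal" | "size_weighted"

    _TABLE = {
        1: ("probability", "equal"),
        2: ("indicator", "equal"),
        3: ("probability", "size_weighted"),
        4: ("indicator", "size_weighted"),
    }

    def __post_init__(self) -> None:
        if (self.z_kind, self.variance_scheme) not in self._TABLE.values():
            raise ValueError("unknown z_kind/variance_scheme combination")

    @property
    def variant_number(self) -> int:
        for num, pair in self._TABLE.items():
            if pair == (self.z_kind, self.variance_scheme):
                return num
        raise AssertionError

    @classmethod
    def from_number(cls, number: int) -> "ModelVariant":
        if number not in cls._TABLE:
            raise ValueError("variant number must be 1, 2, 3 or 4")
        return cls(*cls._TABLE[number])


@dataclass
class HaplotypeModelFit:
    """Solution of the mixed model equations for one variant."""

    mu_hat: float
    effects: np.ndarray  # (H,)
    haplotype_variances: np.ndarray  # (H,)
    error_variance: float
    residuals: np.ndarray  # (n,)
    columns: list[str]  # "block:allele_string" labels aligned with effects


def build_design_matrix(
    phased: PhasedData,
    selected: list[SelectedHaplotype],
    z_kind: str = "probability",
    dosage_mode: str = "transmission",
) -> pd.DataFrame:
    """Z matrix over the selected haplotypes, rows = animals.

    ``probability`` entries are transmission probabilities (expected copy
    count / 2, in [0, 1]); with ``dosage_mode="dosage"`` the raw expected
    copy count (0-2) is used instead.  ``indicator`` entries are 1 when the
    animal's most probable diplotype at the block contains the haplotype.
    Animals whose block posterior is the population prior (all calls missing)
    are handled the same way: expectation under the prior, or the prior's
    modal diplotype.
    """
    if z_kind not in ("probability", "indicator"):
        raise ValueError("z_kind must be 'probability' or 'indicator'")
    if dosage_mode not in ("transmission", "dosage"):
        raise ValueError("dosage_mode must be 'transmission' or 'dosage'")
    n = len(phased.animal_ids)
    cols = {}
    for hap in selected:
        phase = phased.phases[hap.block_id]
        label = f"{hap.block_id}:{hap.allele_string}"
        if z_kind == "probability":
            dos = phase.expected_dosage(hap.allele_index)
            cols[label] = dos if dosage_mode == "dosage" else dos / 2.0
        else:
            entries = np.zeros(n)
            for i in range(n):
                a, b = phase.modal_pair(i)
                entries[i] = 1.0 if hap.allele_index in (a, b) else 0.0
            cols[label] = entries
    return pd.DataFrame(cols, index=list(phased.animal_ids))


def partition_variance(
    selected: list[SelectedHaplotype],
    genetic_variance: float,
    scheme: str = "equal",
) -> np.ndarray:
    """Per-haplotype variances summing exactly to the genetic variance.

    ``equal`` divides sigma2_g by the number of selected haplotypes;
    ``size_weighted`` divides it in proportion to each haplotype's block
    size (SNP count), normalised by the total SNP count over selected
    haplotypes so the partition still sums to sigma2_g.
    """
    if not selected:
        raise ValueError("at least one selected haplotype is required")
    if genetic_variance <= 0:
        raise ValueError("genetic_variance must be positive")
    h = len(selected)
    if scheme == "equal":
        return np.full(h, genetic_variance / h)
    if scheme == "size_weighted":
        sizes = np.array([hap.block_size for hap in selected], dtype=float)
        return genetic_variance * sizes / sizes.sum()
    raise ValueError("scheme must be 'equal' or 'size_weighted'")


def solve_model(
    y: np.ndarray,
    z: np.ndarray | pd.DataFrame,
    haplotype_variances: np.ndarray,
    error_variance: float,
    weights: np.ndarray | None = None,
) -> HaplotypeModelFit:
    """Solve the mixed model equations for (mu, h).

    The coefficient matrix is ``[[1'R^-1 1, 1'R^-1 Z], [Z'R^-1 1,
    Z'R^-1 Z + G^-1]]`` with ``R = diag(1/w_i) * sigma2_e`` (identity weights
    by default) and ``G = diag(sigma2_h_j)``; the right-hand side is
    ``[1'R^-1 y, Z'R^-1 y]``.  Solved by a symmetric factorisation; if the
    system is numerically singular the minimum-norm least-squares solution is
    returned with a warning naming the degenerate columns.
    """
    columns = list(z.columns) if isinstance(z, pd.DataFrame) else [
        f"h{j}" for j in range(np.asarray(z).shape[1])
    ]
    z = np.asarray(z, dtype=float)
    y = np.asarray(y, dtype=float)
    variances = np.asarray(haplotype_variances, dtype=float)
    n, n_hap = z.shape
    if y.shape != (n,):
        raise ValueError("y length does not match Z rows")
    if variances.shape != (n_hap,):
        raise ValueError("one variance per haplotype is required")
    if np.any(variances <= 0) or error_variance <= 0:
        raise ValueError("all variances must be positive")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w <= 0):
        raise ValueError("weights must be positive, one per animal")

    rinv = w / error_variance
    a = np.empty((n_hap + 1, n_hap + 1))
    a[0, 0] = rinv.sum()
    a[0, 1:] = rinv @ z
    a[1:, 0] = a[0, 1:]
    a[1:, 1:] = (z * rinv[:, None]).T @ z
    a[1:, 1:][np.diag_indices(n_hap)] += 1.0 / variances
    rhs = np.empty(n_hap + 1)
    rhs[0] = rinv @ y
    rhs[1:] = z.T @ (rinv * y)

    try:
        sol = scipy.linalg.solve(a, rhs, assume_a="pos")
        if not np.all(np.isfinite(sol)):
            raise np.linalg.LinAlgError("non-finite solution")
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError, ValueError):
        degenerate = [columns[j] for j in range(n_hap) if not z[:, j].any()]
        warnings.warn(
            "singular mixed model equations; returning minimum-norm solution"
            + (f" (zero columns: {', '.join(degenerate)})" if degenerate else ""),
            RuntimeWarning,
            stacklevel=2,
        )
        sol = np.linalg.lstsq(a, rhs, rcond=None)[0]

    mu_hat = float(sol[0])
    effects = sol[1:]
    residuals = y - mu_hat - z @ effects
    return HaplotypeModelFit(
        mu_hat=mu_hat,
        effects=effects,
        haplotype_variances=variances,
        error_variance=float(error_variance),
        residuals=residuals,
        columns=columns,
    )


def predict_dgv(
    z_new: np.ndarray | pd.DataFrame, fit: HaplotypeModelFit
) -> np.ndarray:
    """Direct genomic values DGV_i = sum_j Z_ij h_j (the mean is excluded)."""
    if isinstance(z_new, pd.DataFrame):
        if list(z_new.columns) != fit.columns:
            raise ValueError("Z columns do not align with the fitted effects")
        z_new = z_new.to_numpy(dtype=float)
    z_new = np.asarray(z_new, dtype=float)
    if z_new.shape[1] != len(fit.effects):
        raise ValueError("Z columns do not align with the fitted effects")
    return z_new @ fit.effects
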
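"""Response-variable preparation: the SCS transform and EBV deregression.

Deregressed proofs (DRP) remove the shrinkage of the genetic evaluation from
the EBV so that the marker model sees an (approximately) unregressed
phenotype.  The full mixed-model-equation deregression of national
evaluations needs the evaluation's own system matrices, which are not
available here; the package ships a transparent reliability-scaled deviation
rule behind a pluggable interface:

    drp_i = m + (ebv_i - m) / REL_i,         m = mean EBV of the input set,

with fitting weight w_i = REL_i / (1 - REL_i).  The rule expands deviations
from the mean by exactly the factor the reliability shrank them, and is the
identity at REL = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TraitSpec", "TRAIT_CATALOG", "scs_transform", "deregress"]


@dataclass(frozen=True)
class TraitSpec:
    """A trait's variance components.

    ``error_variance`` defaults to the residual variance implied by the
    heritability on the phenotypic scale, sigma2_g * (1 - h2) / h2.
    """

    name: str
    heritability: float
    genetic_variance: float
    error_variance: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 0 < self.heritability <= 1:
            raise ValueError("heritability must be in (0, 1]")
        if self.genetic_variance <= 0:
            raise ValueError("genetic_variance must be positive")
        if self.error_variance is None:
            object.__setattr__(
                self,
                "error_variance",
                self.genetic_variance * (1.0 - self.heritability) / self.heritability,
            )
        if self.error_variance < 0:
            raise ValueError("error_variance must be non-negative")


#: National-evaluation variance components for the ten routinely evaluated
#: traits: milk/fat/protein yield (kg), stature, overall feet & legs, udder
#: support (points), non-return rate, rest before pregnancy and interval
#: between pregnancies (days), and somatic cell score.
TRAIT_CATALOG: dict[str, TraitSpec] = {
    t.name: t
    for t in (
        TraitSpec("MY", 0.33, 213_490.0),
        TraitSpec("FY", 0.29, 330.10),
        TraitSpec("PY", 0.29, 181.30),
        TraitSpec("STA", 0.54, 5.50),
        TraitSpec("OFL", 0.11, 0.89),
        TraitSpec("USU", 0.20, 0.37),
        TraitSpec("NRK", 0.02, 0.00451),
        TraitSpec("PRP", 0.05, 1171.50),
        TraitSpec("OMC", 0.08, 557.40),
        TraitSpec("SCS", 0.32, 28_737.0),
    )
}


def scs_transform(scc):
    """Somatic cell score from somatic cell count (cells/mL).

    SCS = log2(SCC / 100,000) + 3, so 100,000 cells/mL maps to score 3 and
    each doubling adds one point.
    """
    scc = np.asarray(scc, dtype=float)
    if np.any(scc <= 0):
        raise ValueError("somatic cell count must be positive")
    out = np.log2(scc / 100_000.0) + 3.0
    return float(out) if out.ndim == 0 else out


def deregress(proofs: pd.DataFrame, trait: TraitSpec | None = None) -> pd.DataFrame:
    """Attach deregressed proofs and fitting weights to a proof table.

    ``proofs`` needs columns ``ebv`` and ``reliability`` (in (0, 1]).
    Returns a copy with ``drp`` and ``weight`` columns; ``weight`` is
    REL/(1-REL), infinite at REL = 1.  The ``trait`` argument is accepted so
    alternative deregression rules with trait variance components can be
    plugged in behind the same signature.
    """
    rel = np.asarray(proofs["reliability"], dtype=float)
    if np.any(rel <= 0) or np.any(rel > 1):
        raise ValueError("reliability must be in (0, 1]")
    ebv = np.asarray(proofs["ebv"], dtype=float)
    m = ebv.mean()
    out = proofs.copy()
    out["drp"] = m + (ebv - m) / rel
    with np.errstate(divide="ignore"):
        out["weight"] = np.where(rel < 1, rel / (1.0 - rel), np.inf)
    return out
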
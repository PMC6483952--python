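"""Readers and writers for the pipeline's plain-text interchange formats.

Genotypes travel as PLINK text PED/MAP with a two-letter allele alphabet
(default A = reference, B = alternate; "0 0" marks a missing call).  All
other artifacts are tab-delimited tables with a header row, written so that
identical inputs produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeMatrix

__all__ = [
    "read_ped_map",
    "write_ped_map",
    "read_trait_table",
    "write_trait_table",
    "write_table",
]


def read_ped_map(
    ped_path: str | Path,
    map_path: str | Path,
    ref_allele: str = "A",
    alt_allele: str = "B",
) -> GenotypeMatrix:
    """Parse a PED/MAP pair into a genotype matrix of B-allele dosages.

    MAP rows are ``chromosome, snp_id, genetic_distance, position``; PED rows
    are six pedigree columns followed by two allele columns per SNP.  Allele
    codes outside ``{ref, alt, "0"}`` and ragged rows raise line-numbered
    errors.
    """
    map_path = Path(map_path)
    ped_path = Path(ped_path)
    snp_ids: list[str] = []
    chromosome: list[str] = []
    position: list[int] = []
    for lineno, line in enumerate(map_path.read_text().splitlines(), start=1):
        fields = line.split()
        if not fields:
            continue
        if len(fields) != 4:
            raise ValueError(f"{map_path}:{lineno}: expected 4 MAP columns")
        chromosome.append(fields[0])
        snp_ids.append(fields[1])
        position.append(int(fields[3]))
    n_snps = len(snp_ids)

    code = {
        (ref_allele, ref_allele): 0,
        (ref_allele, alt_allele): 1,
        (alt_allele, ref_allele): 1,
        (alt_allele, alt_allele): 2,
        ("0", "0"): MISSING,
    }
    animal_ids: list[str] = []
    rows: list[np.ndarray] = []
    for lineno, line in enumerate(ped_path.read_text().splitlines(), start=1):
        fields = line.split()
        if not fields:
            continue
        if len(fields) != 6 + 2 * n_snps:
            raise ValueError(
                f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} columns "
                f"for {n_snps} MAP SNPs, found {len(fields)}"
            )
        animal_ids.append(fields[1])
        calls = np.empty(n_snps, dtype=np.int8)
        for s in range(n_snps):
            pair = (fields[6 + 2 * s], fields[7 + 2 * s])
            try:
                calls[s] = code[pair]
            except KeyError:
                raise ValueError(
                    f"{ped_path}:{lineno}: allele pair {pair!r} at SNP "
                    f"{snp_ids[s]} outside alphabet "
                    f"{{{ref_allele},{alt_allele},0}}"
                ) from None
        rows.append(calls)
    return GenotypeMatrix(
        animal_ids=animal_ids,
        snp_ids=snp_ids,
        chromosome=np.array(chromosome, dtype=object),
        position=np.array(position),
        calls=np.vstack(rows) if rows else np.empty((0, n_snps), dtype=np.int8),
    )


def write_ped_map(
    g: GenotypeMatrix,
    ped_path: str | Path,
    map_path: str | Path,
    ref_allele: str = "A",
    alt_allele: str = "B",
) -> None:
    """Write a genotype matrix as a PED/MAP pair (family=id, unknown parents)."""
    pair_of = {
        0: f"{ref_allele} {ref_allele}",
        1: f"{ref_allele} {alt_allele}",
        2: f"{alt_allele} {alt_allele}",
        MISSING: "0 0",
    }
    with open(map_path, "w") as fh:
        for s in range(g.n_snps):
            fh.write(f"{g.chromosome[s]}\t{g.snp_ids[s]}\t0\t{g.position[s]}\n")
    with open(ped_path, "w") as fh:
        for i, animal in enumerate(g.animal_ids):
            genos = " ".join(pair_of[int(c)] for c in g.calls[i])
            fh.write(f"{animal} {animal} 0 0 0 -9 {genos}\n")


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited proof table (animal_id, birth_year, ebv, reliability[, drp])."""
    df = pd.read_csv(path, sep="\t", dtype={"animal_id": str})
    required = {"animal_id", "birth_year", "ebv", "reliability"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_trait_table(df: pd.DataFrame, path: str | Path) -> None:
    write_table(df, path)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write any artifact table as deterministic, header-first TSV."""
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.10g")
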
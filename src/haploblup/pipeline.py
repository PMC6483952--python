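"""End-to-end pipeline: QC -> LD blocks -> phasing -> deregression -> fit -> validation.

A single :class:`PipelineConfig` carries every path, threshold and switch;
``run_pipeline`` executes the stages in order, writes each stage's artifact
as deterministic TSV into the output directory, and keeps a structured log
of every parameter and input/output count (SNPs before/after each filter,
haplotypes before/after the frequency cut), so a run can be audited from its
artifacts alone.  All randomness derives from the single config seed through
named substreams, making re-runs byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, ld, phasing, qc, synthetic, validation
from .deregression import TRAIT_CATALOG, TraitSpec, deregress
from .model import ModelVariant, build_design_matrix, partition_variance, predict_dgv, solve_model

__all__ = ["PipelineConfig", "run_pipeline", "substream_seed"]

logger = logging.getLogger("haploblup")

#: fixed offsets for named random substreams derived from the config seed
_SUBSTREAMS = {"simulate": 0, "missingness": 1}


def substream_seed(seed: int, name: str) -> int:
    """Derive a reproducible per-stage seed (< 2^31) from the config seed."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_SUBSTREAMS[name],))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Every knob of the end-to-end analysis in one place."""

    out_dir: str = "haploblup_out"
    # input paths; if ped is None a population is simulated instead
    ped: str | None = None
    map: str | None = None
    traits: str | None = None
    # simulation settings (used when ped is None)
    n_animals: int = 1216
    n_blocks: int = 50
    block_size_range: tuple[int, int] = (2, 8)
    alleles_per_block: int = 4
    allele_freq_concentration: float = 1.0
    missing_rate: float = 0.02
    reliability_range: tuple[float, float] = (0.60, 0.98)
    birth_year_range: tuple[int, int] = (1987, 2003)
    # trait
    trait_name: str = "MY"
    heritability: float | None = None
    genetic_variance: float | None = None
    error_variance: float | None = None
    # thresholds
    max_missing: float = 0.10
    min_maf: float = 0.01
    r2_threshold: float = 0.8
    window_snps: int = 50
    contiguous_blocks: bool = False
    freq_threshold: float = 0.25
    freq_basis: str = "carrier"
    variance_scale: float = 1.0
    use_drp_weights: bool = False
    train_fraction: float = 0.875
    variants: tuple[int, ...] = (1, 2, 3, 4)
    validation_target: str = "ebv"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        checks = [
            (0 <= self.max_missing <= 1, "max_missing"),
            (0 <= self.min_maf <= 0.5, "min_maf"),
            (0 < self.r2_threshold <= 1, "r2_threshold"),
            (self.window_snps >= 1, "window_snps"),
            (0 <= self.freq_threshold < 1, "freq_threshold"),
            (self.freq_basis in ("carrier", "population"), "freq_basis"),
            (self.variance_scale > 0, "variance_scale"),
            (0 < self.train_fraction < 1, "train_fraction"),
            (all(v in (1, 2, 3, 4) for v in self.variants), "variants"),
            (self.validation_target in ("ebv", "drp", "tbv"), "validation_target"),
            (0 <= self.missing_rate < 1, "missing_rate"),
        ]
        for ok, name in checks:
            if not ok:
                raise ValueError(f"config field {name} out of range")
        self.trait_spec()  # raises if the trait cannot be resolved

    def trait_spec(self) -> TraitSpec:
        if self.heritability is None or self.genetic_variance is None:
            if self.trait_name not in TRAIT_CATALOG:
                raise ValueError(
                    f"unknown trait {self.trait_name!r}; give heritability "
                    "and genetic_variance explicitly"
                )
            base = TRAIT_CATALOG[self.trait_name]
            h2 = self.heritability if self.heritability is not None else base.heritability
            var_g = (
                self.genetic_variance
                if self.genetic_variance is not None
                else base.genetic_variance
            )
        else:
            h2, var_g = self.heritability, self.genetic_variance
        if self.error_variance is not None:
            return TraitSpec(self.trait_name, h2, var_g, self.error_variance)
        return TraitSpec(self.trait_name, h2, var_g)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a YAML config; unknown keys are rejected."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("block_size_range", "reliability_range", "birth_year_range", "variants"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _log_rows(log: list[dict], stage: str, **items) -> None:
    for key, value in items.items():
        log.append({"stage": stage, "key": key, "value": value})
        logger.info("%s: %s = %s", stage, key, value)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and write artifacts under ``config.out_dir``.

    Returns a dict of the in-memory results keyed by stage.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    trait = config.trait_spec()
    _log_rows(
        log,
        "config",
        **{
            f.name: getattr(config, f.name)
            for f in dataclasses.fields(config)
        },
        derived_error_variance=trait.error_variance,
    )

    # --- input: read or simulate ------------------------------------------
    pop = None
    if config.ped is not None:
        if config.map is None or config.traits is None:
            raise ValueError("ped input needs map and traits paths")
        genotypes = io.read_ped_map(config.ped, config.map)
        proofs = io.read_trait_table(config.traits)
    else:
        sim_cfg = synthetic.SimulationConfig(
            n_animals=config.n_animals,
            n_blocks=config.n_blocks,
            block_size_range=config.block_size_range,
            alleles_per_block=config.alleles_per_block,
            allele_freq_concentration=config.allele_freq_concentration,
            heritability=trait.heritability,
            genetic_variance=trait.genetic_variance,
            reliability_range=config.reliability_range,
            birth_year_range=config.birth_year_range,
            missing_rate=config.missing_rate,
            seed=substream_seed(config.seed, "simulate"),
        )
        pop = synthetic.simulate_population(sim_cfg)
        genotypes = synthetic.inject_missingness(
            pop, config.missing_rate, substream_seed(config.seed, "missingness")
        )
        proofs = pop.proofs.copy()
        proofs["tbv"] = pop.tbv
        io.write_ped_map(genotypes, out / "simulated.ped", out / "simulated.map")
        io.write_trait_table(proofs, out / "simulated_traits.tsv")
    _log_rows(log, "input", n_animals=genotypes.n_animals, n_snps=genotypes.n_snps)

    # --- stage 1: QC and LD blocks ----------------------------------------
    filtered, report = qc.apply_qc(genotypes, config.max_missing, config.min_maf)
    io.write_table(report.per_snp, out / "qc_report.tsv")
    io.write_ped_map(filtered, out / "filtered.ped", out / "filtered.map")
    _log_rows(
        log,
        "qc",
        n_input_snps=report.n_input_snps,
        n_after_geno=report.n_after_geno,
        n_after_maf=report.n_after_maf,
    )

    blocks = ld.build_blocks(
        filtered, config.r2_threshold, config.window_snps, config.contiguous_blocks
    )
    io.write_table(
        pd.DataFrame(
            {
                "block_id": [b.block_id for b in blocks],
                "chromosome": [b.chromosome for b in blocks],
                "n_snps": [b.size for b in blocks],
                "snp_ids": [
                    ",".join(filtered.snp_ids[i] for i in b.snp_indices) for b in blocks
                ],
            }
        ),
        out / "blocks.tsv",
    )
    _log_rows(log, "blocks", n_blocks=len(blocks))

    # --- stage 2: phasing and haplotype selection -------------------------
    phased = phasing.phase_blocks(filtered, blocks)
    selected = phasing.select_frequent_haplotypes(
        phased, config.freq_threshold, config.freq_basis
    )
    hap_rows = []
    selected_keys = {(h.block_id, h.allele_string) for h in selected}
    for block in phased.blocks:
        for allele in phased.phases[block.block_id].alleles:
            hap_rows.append(
                {
                    "block_id": block.block_id,
                    "allele_string": allele.allele_string,
                    "population_frequency": allele.population_frequency,
                    "carrier_frequency": allele.carrier_frequency,
                    "selected": (block.block_id, allele.allele_string) in selected_keys,
                }
            )
    io.write_table(pd.DataFrame(hap_rows), out / "haplotypes.tsv")
    post_rows = [
        {
            "animal_id": animal,
            "block_id": block.block_id,
            "allele_a": a,
            "allele_b": b,
            "probability": p,
        }
        for block in phased.blocks
        for i, animal in enumerate(phased.animal_ids)
        for a, b, p in phased.phases[block.block_id].posteriors[i]
    ]
    io.write_table(pd.DataFrame(post_rows), out / "posteriors.tsv")
    _log_rows(
        log,
        "phase",
        n_blocks_phased=len(phased.blocks),
        n_blocks_skipped=len(phased.skipped),
        n_haplotypes=len(hap_rows),
        n_selected_haplotypes=len(selected),
    )
    if not selected:
        raise RuntimeError("no haplotype passed the frequency filter")

    # --- stage 3: response, model fits, validation ------------------------
    proofs = deregress(proofs, trait)
    io.write_trait_table(proofs, out / "traits_drp.tsv")
    train_ids, val_ids = validation.generational_split(
        proofs, validation.SplitSpec(config.train_fraction)
    )
    _log_rows(log, "split", n_train=len(train_ids), n_validation=len(val_ids))

    id_pos = {a: i for i, a in enumerate(phased.animal_ids)}
    proofs_idx = proofs.set_index("animal_id")
    reports = []
    fits = {}
    dgv_tables = {}
    for number in config.variants:
        variant = ModelVariant.from_number(number)
        z_all = build_design_matrix(phased, selected, variant.z_kind)
        variances = (
            partition_variance(selected, trait.genetic_variance, variant.variance_scheme)
            * config.variance_scale
        )
        train_rows = [id_pos[a] for a in train_ids]
        y_train = proofs_idx.loc[train_ids, "drp"].to_numpy(dtype=float)
        weights = None
        if config.use_drp_weights:
            weights = proofs_idx.loc[train_ids, "weight"].to_numpy(dtype=float)
            weights = np.minimum(weights, 1e6)  # REL=1 gives infinite weight
        fit = solve_model(
            y_train,
            z_all.iloc[train_rows],
            variances,
            trait.error_variance,
            weights=weights,
        )
        dgv = pd.Series(predict_dgv(z_all, fit), index=z_all.index)
        fits[number] = fit
        dgv_tables[number] = dgv
        io.write_table(
            pd.DataFrame(
                {
                    "haplotype": fit.columns,
                    "effect": fit.effects,
                    "variance": fit.haplotype_variances,
                }
            ),
            out / f"effects_variant{number}.tsv",
        )
        io.write_table(
            pd.DataFrame({"animal_id": dgv.index, "dgv": dgv.to_numpy()}),
            out / f"dgv_variant{number}.tsv",
        )
        rep = validation.validation_report(
            proofs, dgv, train_ids, val_ids, target=config.validation_target
        )
        rep.insert(0, "variant", number)
        rep.insert(1, "trait", trait.name)
        reports.append(rep)
        _log_rows(
            log,
            f"fit_variant{number}",
            mu_hat=fit.mu_hat,
            train_r=float(rep.loc[rep.subset == "train", "pearson_r"].iloc[0]),
            validation_r=float(rep.loc[rep.subset == "validation", "pearson_r"].iloc[0]),
            validation_slope=float(rep.loc[rep.subset == "validation", "slope"].iloc[0]),
        )
    report_df = pd.concat(reports, ignore_index=True)
    io.write_table(report_df, out / "validation_report.tsv")
    io.write_table(pd.DataFrame(log), out / "pipeline_log.tsv")

    return {
        "population": pop,
        "genotypes": genotypes,
        "filtered": filtered,
        "qc_report": report,
        "blocks": blocks,
        "phased": phased,
        "selected": selected,
        "proofs": proofs,
        "train_ids": train_ids,
        "validation_ids": val_ids,
        "fits": fits,
        "dgv": dgv_tables,
        "report": report_df,
        "log": pd.DataFrame(log),
    }
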
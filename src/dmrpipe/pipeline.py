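"""End-to-end orchestration: tile -> call -> permute -> annotate -> associate.

Every stage is a pure function of (inputs, parameters, seed); a JSON manifest
records parameters, the seed, input checksums, and the stages completed, so a
rerun with the same config is byte-identical for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .annotation import annotate_dmrs
from .association import dmr_gene_enrichment, upregulated_genes
from .calling import DmrParams, call_postnatal, call_tissue_specific, tissue_means
from .permutation import permutation_test
from .simulate import SimConfig, simulate_expression, simulate_methylomes
from .tiling import TilingParams, aggregate_tiles_frame, build_matrix, merge_strands

logger = logging.getLogger("dmrpipe")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "matrix_from_simulation"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Single-file configuration of a full run (YAML-serialisable)."""

    out_dir: str = "dmrpipe_out"
    sample_sheet: str | None = None  # TSV with per-sample coverage paths
    gene_models: str | None = None  # BED12
    expression: str | None = None  # genes x samples TSV
    expression_sheet: str | None = None  # sample sheet for expression columns
    de_table: str | None = None  # precomputed differential-expression TSV
    simulate_preset: str | None = None  # generate inputs instead of reading
    sim_overrides: dict | None = None  # SimConfig field overrides for presets
    cpg_dialect: str = "bismark_cov"
    target_tissue: str = "liver"
    newborn_age: float = 1.0
    adult_age: float = 15.0
    age_filter: float | None = 15.0  # age used for tissue-specific calling
    direction: str = "hypo"
    tiling: TilingParams = field(default_factory=TilingParams)
    dmr: DmrParams = field(default_factory=DmrParams)
    n_perm: int = 10_000
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "tiling" in raw:
            raw["tiling"] = TilingParams(**raw["tiling"])
        if "dmr" in raw:
            raw["dmr"] = DmrParams(**raw["dmr"])
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d


def _checksum(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def matrix_from_simulation(sim, tiling: TilingParams):
    """Tile every simulated sample and assemble the matrix."""
    per_sample = {}
    for s in sim.sheet:
        merged = merge_strands(sim.calls[s.sample_id])
        per_sample[s.sample_id] = aggregate_tiles_frame(merged, tiling)
    return build_matrix(per_sample, sim.sheet)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run all stages; returns the result bundle and writes output files."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "parameters": config.to_dict(),
        "seed": config.seed,
        "inputs": {},
        "stages_completed": [],
    }
    bundle: dict[str, Any] = {}
    stage = "setup"
    try:
        # ---- inputs -------------------------------------------------------
        if config.simulate_preset:
            sim = dataclasses.replace(
                SimConfig.preset(config.simulate_preset, seed=config.seed),
                **(config.sim_overrides or {}),
            )
            simres = simulate_methylomes(sim)
            sheet = simres.sheet
            genes = simres.genes
            chrom_sizes = simres.chrom_sizes
            expr, expr_sheet = simulate_expression(simres.truth, sim)
            de_table = None
            bundle["truth"] = simres.truth
        else:
            if not config.sample_sheet or not config.gene_models:
                raise PipelineError("sample_sheet and gene_models are required")
            manifest["inputs"]["sample_sheet"] = _checksum(config.sample_sheet)
            sheet = mio.read_sample_sheet(config.sample_sheet)
            genes = mio.read_gene_models(config.gene_models, dialect="bed12")
            manifest["inputs"]["gene_models"] = _checksum(config.gene_models)
            chrom_sizes = {
                g.chrom: 0 for g in genes
            }
            for g in genes:
                chrom_sizes[g.chrom] = max(chrom_sizes[g.chrom], g.end + 100_000)
            expr = expr_sheet = de_table = None
            if config.expression:
                expr = mio.read_expression_table(config.expression)
                expr_sheet = mio.read_sample_sheet(config.expression_sheet)
                manifest["inputs"]["expression"] = _checksum(config.expression)
            if config.de_table:
                de_table = pd.read_csv(config.de_table, sep="\t")
                manifest["inputs"]["de_table"] = _checksum(config.de_table)

        # ---- tile ---------------------------------------------------------
        stage = "tile"
        if config.simulate_preset:
            matrix = matrix_from_simulation(simres, config.tiling)
        else:
            per_sample = {}
            for s in sheet:
                if not s.path:
                    raise PipelineError(f"sample {s.sample_id} has no coverage path")
                frame = mio.read_cpg_frame(s.path, config.cpg_dialect)
                manifest["inputs"][s.sample_id] = _checksum(s.path)
                per_sample[s.sample_id] = aggregate_tiles_frame(
                    merge_strands(frame), config.tiling
                )
            matrix = build_matrix(per_sample, sheet)
        matrix.to_tsv(out / "tile_matrix.tsv", out / "tile_counts.tsv")
        bundle["matrix"] = matrix
        manifest["stages_completed"].append("tile")
        logger.info("tile: %d tiles x %d samples", matrix.n_tiles, len(matrix.samples))

        # ---- call ---------------------------------------------------------
        stage = "call"
        tissues_present = {s.tissue for s in matrix.samples}
        if config.target_tissue not in tissues_present:
            raise PipelineError(f"call: unknown target tissue {config.target_tissue!r}")
        means = tissue_means(matrix, age_filter=config.age_filter)
        specific = call_tissue_specific(
            means, config.target_tissue, config.direction, config.dmr, tiles=matrix.tiles
        )
        dmrs = call_postnatal(
            matrix, specific, config.target_tissue,
            newborn_age=config.newborn_age, adult_age=config.adult_age,
            params=config.dmr,
        )
        mio.write_dmr_bed(dmrs, out / "dmrs.bed")
        audit = pd.DataFrame(dmrs)
        audit.to_csv(out / "dmr_audit.tsv", sep="\t", index=False)
        bundle["dmrs"] = dmrs
        manifest["stages_completed"].append("call")
        logger.info("call: %d tissue-specific DMRs", len(dmrs))

        # ---- permute ------------------------------------------------------
        stage = "permute"
        perm = permutation_test(
            matrix, config.target_tissue, config.dmr,
            direction=config.direction, age_filter=config.age_filter,
            n_perm=config.n_perm, rng_seed=config.seed,
        )
        perm.to_frame().to_csv(out / "permutation.tsv", sep="\t", index=False)
        bundle["permutation"] = perm
        manifest["stages_completed"].append("permute")
        logger.info("permute: observed=%d p=%.3g", perm.observed_count, perm.p_value)

        # ---- annotate -----------------------------------------------------
        stage = "annotate"
        annotated = annotate_dmrs(dmrs, genes)
        annotated.to_csv(out / "dmrs_annotated.tsv", sep="\t", index=False)
        bundle["annotation"] = annotated
        manifest["stages_completed"].append("annotate")

        # ---- associate ----------------------------------------------------
        stage = "associate"
        if expr is not None and dmrs:
            up = upregulated_genes(
                expr, expr_sheet, age_from=config.newborn_age,
                age_to=config.adult_age, de_table=de_table,
            )
            assoc = dmr_gene_enrichment(
                dmrs, genes, up, chrom_sizes, rng_seed=config.seed
            )
            assoc.to_frame().to_csv(out / "association.tsv", sep="\t", index=False)
            bundle["association"] = assoc
            manifest["stages_completed"].append("associate")
            logger.info("associate: %.1f%% vs %.1f%% (z=%.2f)",
                        100 * assoc.prop_dmr, 100 * assoc.prop_bg, assoc.z_stat)
    except PipelineError:
        manifest["failed_stage"] = stage
        _write_manifest(manifest, out)
        raise
    except Exception as exc:
        manifest["failed_stage"] = stage
        _write_manifest(manifest, out)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    _write_manifest(manifest, out)
    bundle["manifest"] = manifest
    return bundle


def _write_manifest(manifest: dict, out: Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        return str(o)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=default)
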
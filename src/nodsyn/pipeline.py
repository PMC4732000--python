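"""Pipeline orchestration: simulate -> catalog -> synteny -> expression -> density.

A single top-level ``rng_seed`` drives every stage through stable derived
seeds (a hash of the stage name mixed into a ``SeedSequence``), so a stage
rerun in isolation reproduces its slice of a full run, and identical
configurations yield byte-identical outputs.  Each run writes its stage
TSVs plus a manifest (config hash, seed, completed stages, input checksums)
sufficient to reproduce it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import catalog as cat
from . import density as dens
from . import expression as expr
from . import synteny as syn
from . import synthdata as sd

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "catalog", "synteny", "expression", "density")


@dataclass
class Thresholds:
    evalue_max: float = cat.EVALUE_MAX
    score_min: float = cat.SCORE_MIN
    fc_threshold: float = 2.0
    pseudocount: float = 1.0
    expression_floor: float = 1.0
    max_rank_gap: int = syn.DEFAULT_MAX_RANK_GAP
    min_anchors: int = syn.DEFAULT_MIN_ANCHORS
    alpha: float = 0.05
    n_permutations: int = 1000
    max_z_quantile: float = 0.99


@dataclass
class RunConfig:
    outdir: Path
    simulate: sd.SimConfig | None = None
    input_dir: Path | None = None
    stages: tuple[str, ...] = ALL_STAGES
    thresholds: Thresholds = field(default_factory=Thresholds)
    rng_seed: int = 0
    window_override: dict[str, tuple[int, int]] | None = None

    def validate(self) -> None:
        for s in self.stages:
            if s not in ALL_STAGES:
                raise ValueError(f"unknown stage {s!r}")
        if "simulate" in self.stages and self.simulate is None and self.input_dir is None:
            raise ValueError("simulate stage enabled but no SimConfig given")
        if "simulate" not in self.stages and self.input_dir is None:
            raise ValueError("without the simulate stage an input_dir is required")


@dataclass
class PipelineResult:
    config: RunConfig
    genes_by_species: dict[str, list[cat.GeneModel]] = field(default_factory=dict)
    chrom_lengths: dict[str, dict[str, int]] = field(default_factory=dict)
    hits: list[cat.HomologyHit] = field(default_factory=list)
    seed_mapping: pd.DataFrame | None = None
    truth: sd.GroundTruth | None = None
    expression: pd.DataFrame | None = None
    blocks: list[syn.SyntenicBlock] = field(default_factory=list)
    groups: list[syn.OrthologGroup] = field(default_factory=list)
    calls: dict[str, expr.ExpressionCall] = field(default_factory=dict)
    summaries: list[expr.GroupCallSummary] = field(default_factory=list)
    venns: dict[str, pd.DataFrame] = field(default_factory=dict)
    tracks: list[dens.DensityTrack] = field(default_factory=list)
    enrichments: list[dens.EnrichmentResult] = field(default_factory=list)
    manifest: dict[str, Any] = field(default_factory=dict)


def stage_seed(rng_seed: int, stage: str) -> int:
    """Stable per-stage seed: top-level seed mixed with a stage-name hash."""
    ss = np.random.SeedSequence([int(rng_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _config_hash(config: RunConfig) -> str:
    d = dataclasses.asdict(config)
    d["outdir"] = str(d["outdir"])
    if d.get("input_dir") is not None:
        d["input_dir"] = str(d["input_dir"])
    blob = yaml.safe_dump(d, sort_keys=True, default_flow_style=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig) -> PipelineResult:
    """Execute the enabled stages in order; abort naming a failing stage."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    result = PipelineResult(config=config)
    manifest: dict[str, Any] = {
        "config_hash": _config_hash(config),
        "rng_seed": config.rng_seed,
        "stages_completed": [],
        "stages_skipped": [s for s in ALL_STAGES if s not in config.stages],
        "input_checksums": {},
        "status": "incomplete",
    }
    result.manifest = manifest

    def _write_manifest() -> None:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    seeds_df: pd.DataFrame | None = None
    current_stage = "setup"
    try:
        # --- inputs: simulate or read -------------------------------------
        if "simulate" in config.stages and config.simulate is not None:
            current_stage = "simulate"
            sim_cfg = dataclasses.replace(
                config.simulate, rng_seed=stage_seed(config.rng_seed, "simulate"))
            dataset = sd.simulate(sim_cfg)
            indir = outdir / "inputs"
            dataset.write(indir)
            result.truth = dataset.truth
            result.genes_by_species = dataset.genes_by_species
            result.hits = dataset.hits
            result.expression = dataset.expression
            result.chrom_lengths = {
                sp.name: dict(zip(sp.chromosome_names(), sp.chromosome_lengths))
                for sp in sim_cfg.species}
            seeds_df = dataset.seed_list()
            manifest["stages_completed"].append("simulate")
        else:
            current_stage = "load-inputs"
            indir = Path(config.input_dir)  # type: ignore[arg-type]
            genes, hits, expression, seeds_df, lengths = sd.read_dataset(indir)
            result.genes_by_species = genes
            result.hits = hits
            result.expression = expression
            result.chrom_lengths = lengths
        for p in sorted(Path(indir).rglob("*")):
            if p.is_file():
                manifest["input_checksums"][str(p.relative_to(indir))] = _checksum(p)

        all_genes = [g for genes in result.genes_by_species.values() for g in genes]
        mapped_ids: set[str] = set()

        # --- catalog -------------------------------------------------------
        if "catalog" in config.stages:
            current_stage = "catalog"
            result.seed_mapping = cat.map_seed_genes(
                seeds_df, result.hits,
                evalue_max=th.evalue_max, score_min=th.score_min)
            mapped_ids = set(
                result.seed_mapping.loc[
                    result.seed_mapping.status == "mapped", "mapped_gene_id"])
            for g in all_genes:  # re-annotation: nodulation status from mapping
                g.is_nodulation = g.gene_id in mapped_ids
            result.seed_mapping.to_csv(outdir / "seed_mapping.tsv", sep="\t", index=False)
            manifest["stages_completed"].append("catalog")

        # --- synteny ---------------------------------------------------------
        if "synteny" in config.stages:
            current_stage = "synteny"
            kept = cat.filter_hits(result.hits, th.evalue_max, th.score_min)
            anchors = syn.build_anchor_map(kept, all_genes)
            result.blocks = syn.chain_anchors(
                anchors, all_genes, th.max_rank_gap, th.min_anchors)
            pairs = syn.call_syntelogs(result.blocks)
            result.groups = syn.build_groups(pairs, mapped_ids, all_genes)
            syn.blocks_table(result.blocks).to_csv(
                outdir / "blocks.tsv", sep="\t", index=False)
            syn.groups_table(result.groups).to_csv(
                outdir / "groups.tsv", sep="\t", index=False)
            manifest["stages_completed"].append("synteny")

        # --- expression ------------------------------------------------------
        if "expression" in config.stages:
            current_stage = "expression"
            result.calls = expr.call_genes(
                result.expression, threshold=th.fc_threshold,
                pseudocount=th.pseudocount, floor=th.expression_floor)
            result.summaries = expr.lift_to_groups(result.groups, result.calls)
            expr.calls_table(result.calls).to_csv(
                outdir / "calls.tsv", sep="\t", index=False)
            expr.group_summary_table(result.summaries).to_csv(
                outdir / "group_summary.tsv", sep="\t", index=False)
            species = sorted(result.genes_by_species)
            if len(species) >= 2 and result.summaries:
                for flag, tag in (("rh_induced", "rh"), ("nodule_preferential", "nodule")):
                    vt = expr.venn_table(result.summaries, flag, species)
                    result.venns[flag] = vt
                    vt.to_csv(outdir / f"venn_{tag}.tsv", sep="\t", index=False)
            manifest["stages_completed"].append("expression")

        # --- density ---------------------------------------------------------
        if "density" in config.stages:
            current_stage = "density"
            grouped_by_species: dict[str, set[str]] = {}
            for grp in result.groups:
                for sp, members in grp.members.items():
                    grouped_by_species.setdefault(sp, set()).update(members)
            if not result.groups:  # synteny skipped: fall back to mapped seeds
                for g in all_genes:
                    if g.is_nodulation:
                        grouped_by_species.setdefault(g.species, set()).add(g.gene_id)
            for sp in sorted(result.genes_by_species):
                wc = dens.species_window_params(
                    sp, (config.window_override or {}).get(sp))
                nod_ids = grouped_by_species.get(sp, set())
                by_chrom: dict[str, list[cat.GeneModel]] = {}
                for g in result.genes_by_species[sp]:
                    by_chrom.setdefault(g.chromosome, []).append(g)
                for chrom in sorted(by_chrom):
                    genes_here = by_chrom[chrom]
                    length = result.chrom_lengths.get(sp, {}).get(
                        chrom, max(g.end for g in genes_here))
                    all_pts = np.array([g.midpoint for g in genes_here])
                    nod_pts = np.array(
                        [g.midpoint for g in genes_here if g.gene_id in nod_ids])
                    track = dens.window_counts(
                        nod_pts, length, wc, species=sp, chromosome=chrom)
                    dens.zscore_normalize(track)
                    result.tracks.append(track)
                    result.enrichments.append(dens.call_enrichment(
                        track, all_pts, nod_pts.size,
                        n_permutations=th.n_permutations, alpha=th.alpha,
                        rng_seed=stage_seed(config.rng_seed, f"density:{sp}:{chrom}"),
                        max_z_quantile=th.max_z_quantile))
            dens.tracks_table(result.tracks).to_csv(
                outdir / "density_windows.tsv", sep="\t", index=False)
            dens.enrichment_table(result.enrichments).to_csv(
                outdir / "enrichment.tsv", sep="\t", index=False)
            manifest["stages_completed"].append("density")
    except Exception as e:
        manifest["status"] = f"failed at stage {current_stage}: {e}"
        _write_manifest()
        raise RuntimeError(f"pipeline stage {current_stage!r} failed: {e}") from e

    manifest["status"] = "complete"
    _write_manifest()
    return result


def summarize(result: PipelineResult) -> dict[str, Any]:
    """Headline counts: grouped genes per species, flagged groups, overlaps,
    and the per-species enriched-chromosome tally."""
    summary: dict[str, Any] = {}
    if result.groups:
        per_species, n_groups = syn.count_members_by_species(result.groups)
        summary["n_groups"] = n_groups
        summary["grouped_genes_per_species"] = per_species
    if result.summaries:
        species = sorted(result.genes_by_species)
        for flag, tag in (("rh_induced", "rh_induced"),
                          ("nodule_preferential", "nodule_preferential")):
            totals = expr.flagged_group_counts(result.summaries, flag)
            summary[f"{tag}_groups_per_species"] = totals
            if len(species) >= 2:
                venn = expr.overlap_groups(result.summaries, flag, species)
                shared = venn.get(frozenset(species), 0)
                summary[f"{tag}_shared_all_species"] = shared
                summary[f"{tag}_overlap_percent"] = {
                    sp: expr.overlap_percent(shared, totals[sp])
                    for sp in species if totals.get(sp)}
    if result.enrichments:
        tally: dict[str, str] = {}
        for sp in sorted({r.species for r in result.enrichments}):
            rs = [r for r in result.enrichments if r.species == sp]
            k = sum(r.enriched for r in rs)
            tally[sp] = f"{k} of {len(rs)} chromosomes enriched"
        summary["enrichment"] = tally
    return summary


# ---------------------------------------------------------------------------
# YAML run configuration
# ---------------------------------------------------------------------------

def run_config_from_dict(d: Mapping[str, Any], outdir: str | Path | None = None,
                         rng_seed: int | None = None) -> RunConfig:
    sim = d.get("simulate")
    sim_cfg = None
    if sim == "default":
        sim_cfg = sd.default_config()
    elif isinstance(sim, Mapping):
        sim_cfg = sd.config_from_dict(sim)
    th = Thresholds(**d.get("thresholds", {}))
    wo = d.get("window_override")
    return RunConfig(
        outdir=Path(outdir if outdir is not None else d.get("outdir", "nodsyn_out")),
        simulate=sim_cfg,
        input_dir=Path(d["input_dir"]) if d.get("input_dir") else None,
        stages=tuple(d.get("stages", ALL_STAGES)),
        thresholds=th,
        rng_seed=int(rng_seed if rng_seed is not None else d.get("rng_seed", 0)),
        window_override={k: tuple(v) for k, v in wo.items()} if wo else None,
    )


def run_config_from_yaml(path: str | Path, outdir: str | Path | None = None,
                         rng_seed: int | None = None) -> RunConfig:
    with open(path) as fh:
        return run_config_from_dict(yaml.safe_load(fh) or {}, outdir, rng_seed)
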
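"""Seeded multi-species synthetic data with known ground truth.

Real comparative studies of legume nodulation genes combine genome
annotations from several species (one of which, soybean, carries a recent
whole-genome duplication), BLAST-style homology tables, curated seed-gene
lists and expression atlases.  None of that is redistributable at desk
scale, so this module emulates the study design: it plants

* non-overlapping gene annotations on a configurable set of chromosomes,
* ortholog groups of "nodulation" genes, duplicated (two paralogs on
  distinct chromosomes) in the WGD-flagged species,
* chromosomal clusters holding a configured fraction of the nodulation
  genes inside a short span,
* collinear syntenic blocks around every planted ortholog/paralog pair
  (plus seed-less decoy blocks),
* homology hits that pass the downstream filter for every true pair and
  decoy hits drawn adjacent to the filter thresholds, and
* expression profiles with planted root-hair induction, nodule-preferential
  signal, "broad" reassigned paralogs, and multiplicative log-normal noise.

Everything is deterministic for a fixed ``rng_seed``; the emitted
``GroundTruth`` lets every downstream stage be scored against a known
answer.  At zero noise and zero decoys the whole pipeline recovers the
truth exactly.
"""

from __future__ import annotations

import dataclasses
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .catalog import (
    GeneModel,
    HomologyHit,
    parse_gff3,
    parse_sequence_regions,
    read_hits,
    write_gff3,
    write_hits,
)

# rng stream labels: annotations, homology, expression
_STREAM_ANNOT, _STREAM_HOMOL, _STREAM_EXPR = 0, 1, 2

ATLAS_TISSUES = ("nodule", "flower", "pod", "leaf", "root", "root_tip")
RH_TIMEPOINTS = ("12H", "24H", "48H")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SpeciesSpec:
    name: str
    prefix: str
    chromosome_lengths: tuple[int, ...]
    n_genes: int
    mean_gene_length: int = 3000
    has_recent_wgd: bool = False

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosome_lengths)

    def chromosome_names(self) -> list[str]:
        return [f"{self.prefix}Chr{k:02d}" for k in range(1, self.n_chromosomes + 1)]


@dataclass
class ClusterSpec:
    """Placement of nodulation genes inside planted chromosomal clusters."""

    fraction: float = 10.0 / 12.0
    span_bp: int = 2_000_000


@dataclass
class SyntenySpec:
    """Planted collinear blocks; ``genes_per_block`` includes the anchor pair."""

    genes_per_block: int = 5
    n_decoy_blocks: int = 2
    n_scatter_anchors: int = 0


@dataclass
class ExpressionSpec:
    induced_fc: float = 4.0
    preferential_fc: float = 3.0
    broad_fraction: float = 0.25
    divergence_fraction: float = 0.25
    noise_cv: float = 0.0
    baseline: float = 10.0
    silent_fraction: float = 0.05
    tissues: tuple[str, ...] = ATLAS_TISSUES
    timepoints: tuple[str, ...] = RH_TIMEPOINTS


@dataclass
class SimConfig:
    species: tuple[SpeciesSpec, ...]
    n_seed_groups: int = 12
    cluster: ClusterSpec = field(default_factory=ClusterSpec)
    synteny: SyntenySpec = field(default_factory=SyntenySpec)
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)
    n_decoy_hits: int = 25
    rng_seed: int = 0

    def validate(self) -> None:
        if not self.species:
            raise ValueError("at least one species required")
        if self.n_seed_groups < 0 or self.n_decoy_hits < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.cluster.fraction <= 1.0:
            raise ValueError("cluster fraction must lie in [0, 1]")
        if self.expression.induced_fc <= 1.0 or self.expression.preferential_fc <= 1.0:
            raise ValueError("fold-change magnitudes must exceed 1")
        if self.expression.noise_cv < 0:
            raise ValueError("noise CV must be non-negative")
        for frac in (self.expression.broad_fraction,
                     self.expression.divergence_fraction,
                     self.expression.silent_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        for sp in self.species:
            if any(L <= 0 for L in sp.chromosome_lengths):
                raise ValueError(f"{sp.name}: chromosome lengths must be positive")
            if sp.n_genes < 0:
                raise ValueError(f"{sp.name}: n_genes must be non-negative")
            n_cluster = _n_cluster_genes(self)
            if n_cluster > 0 and self.cluster.span_bp >= min(sp.chromosome_lengths):
                raise ValueError(
                    f"{sp.name}: cluster span must be smaller than every targeted chromosome"
                )
            if sp.has_recent_wgd and n_cluster > 0 and sp.n_chromosomes < 2:
                raise ValueError(f"{sp.name}: WGD species needs >= 2 chromosomes")


def _n_cluster_genes(config: SimConfig) -> int:
    return int(round(config.cluster.fraction * config.n_seed_groups))


def default_config(rng_seed: int = 0) -> SimConfig:
    """Desk-scale emulation of the four-species study design.

    Four species with differing chromosome counts, 40-Mb chromosomes at
    ~200 genes each, 12 planted nodulation ortholog groups with 10 of 12
    genes inside a 2-Mb cluster, and a recent WGD in the soybean stand-in.
    """
    return SimConfig(
        species=(
            SpeciesSpec("G. max", "Gm", (40_000_000,) * 8, 1600, has_recent_wgd=True),
            SpeciesSpec("M. truncatula", "Mt", (40_000_000,) * 5, 1000),
            SpeciesSpec("P. vulgaris", "Pv", (40_000_000,) * 4, 800),
            SpeciesSpec("L. japonicus", "Lj", (40_000_000,) * 3, 600),
        ),
        n_seed_groups=12,
        rng_seed=rng_seed,
    )


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Planted signal: what a perfect analysis should recover."""

    true_groups: dict[str, dict[str, tuple[str, ...]]] = field(default_factory=dict)
    true_induced: set[str] = field(default_factory=set)
    true_preferential: set[str] = field(default_factory=set)
    true_broad: set[str] = field(default_factory=set)
    true_cluster_chromosomes: dict[str, tuple[str, ...]] = field(default_factory=dict)
    true_syntenic_blocks: list[list[tuple[str, str]]] = field(default_factory=list)
    seed_to_gene: dict[str, str] = field(default_factory=dict)
    group_labels: dict[str, str] = field(default_factory=dict)

    def group_members(self, group_id: str) -> set[str]:
        return {g for members in self.true_groups[group_id].values() for g in members}

    def all_group_genes(self) -> set[str]:
        return {g for gid in self.true_groups for g in self.group_members(gid)}

    def genes_of_species(self, species: str) -> set[str]:
        out: set[str] = set()
        for members in self.true_groups.values():
            out.update(members.get(species, ()))
        return out


# ---------------------------------------------------------------------------
# Annotation generation
# ---------------------------------------------------------------------------

class _IntervalPacker:
    """Non-overlapping interval placement on one chromosome (rejection sampling)."""

    def __init__(self, chrom: str, length: int, rng: np.random.Generator):
        self.chrom = chrom
        self.length = length
        self.rng = rng
        self._starts: list[int] = []
        self._ends: list[int] = []
        self._blocked: list[tuple[int, int]] = []

    def block(self, start: int, end: int) -> None:
        """Exclude a region from future ``place`` calls (existing intervals stay)."""
        self._blocked.append((start, end))

    def _overlaps(self, start: int, end: int) -> bool:
        i = bisect_left(self._starts, start)
        if i < len(self._starts) and self._starts[i] < end:
            return True
        if i > 0 and self._ends[i - 1] > start:
            return True
        return False

    def insert(self, start: int, end: int) -> None:
        if start < 0 or end > self.length or self._overlaps(start, end):
            raise ValueError(f"cannot place interval [{start}, {end}) on {self.chrom}")
        i = bisect_left(self._starts, start)
        self._starts.insert(i, start)
        self._ends.insert(i, end)

    def place(self, gene_len: int, lo: int = 0, hi: int | None = None,
              max_tries: int = 10_000) -> tuple[int, int]:
        hi = self.length if hi is None else hi
        if gene_len > hi - lo:
            raise ValueError(
                f"infeasible packing on {self.chrom}: gene of {gene_len} bp "
                f"does not fit in [{lo}, {hi})"
            )
        for _ in range(max_tries):
            start = int(self.rng.integers(lo, hi - gene_len + 1))
            end = start + gene_len
            if self._overlaps(start, end):
                continue
            if any(start < be and bs < end for bs, be in self._blocked):
                continue
            self.insert(start, end)
            return start, end
        raise ValueError(
            f"infeasible packing on {self.chrom}: no room after {max_tries} tries"
        )


def _allocate_counts(total: int, lengths: Sequence[int]) -> list[int]:
    """Largest-remainder proportional allocation of genes to chromosomes."""
    weights = np.asarray(lengths, dtype=float)
    raw = total * weights / weights.sum()
    counts = np.floor(raw).astype(int)
    rest = total - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in range(rest):
        counts[order[i % len(counts)]] += 1
    return counts.tolist()


def _seed_id(prefix: str, group: int, copy: str) -> str:
    return f"SEED_{prefix}_G{group:02d}{copy}"


def generate_annotations(
    config: SimConfig,
) -> tuple[dict[str, list[GeneModel]], GroundTruth]:
    """Place genes on chromosomes and plant the nodulation ortholog groups.

    Returns per-species gene lists (sorted by position) plus a partial
    ``GroundTruth`` (groups, cluster chromosomes, seed ids); homology and
    expression truth are filled in by the later generators.

    Genes never overlap; planted-cluster genes fall inside one configured
    span per cluster chromosome; the WGD species carries every group twice,
    the two paralogs on distinct chromosomes.  Raises ``ValueError`` naming
    the chromosome when the requested genes cannot be packed.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, _STREAM_ANNOT]))
    truth = GroundTruth()
    n_cluster = _n_cluster_genes(config)
    cluster_groups = list(range(n_cluster))
    leftover_groups = list(range(n_cluster, config.n_seed_groups))
    group_ids = [f"grp{g:02d}" for g in range(config.n_seed_groups)]
    for gid in group_ids:
        truth.true_groups[gid] = {}

    genes_by_species: dict[str, list[GeneModel]] = {}
    for sp in config.species:
        chroms = sp.chromosome_names()
        copies = ("a", "b") if sp.has_recent_wgd else ("a",)
        # cluster chromosomes: first chromosome per copy
        cluster_chroms: dict[str, str] = {}
        if n_cluster > 0 and config.n_seed_groups > 0:
            for ci, copy in enumerate(copies):
                cluster_chroms[copy] = chroms[ci]
        truth.true_cluster_chromosomes[sp.name] = tuple(sorted(set(cluster_chroms.values())))

        non_cluster = [c for c in chroms if c not in cluster_chroms.values()]
        # planted (group, copy) -> chromosome; leftover genes deliberately go
        # to distinct non-cluster chromosomes so planted blocks never interact
        planted_on: dict[str, list[tuple[int, str]]] = {c: [] for c in chroms}
        for copy in copies:
            for g in cluster_groups:
                planted_on[cluster_chroms[copy]].append((g, copy))
        if leftover_groups and not non_cluster:
            raise ValueError(f"{sp.name}: no non-cluster chromosome for leftover genes")
        for i, g in enumerate(leftover_groups):
            for k, copy in enumerate(copies):
                if non_cluster:
                    chrom = non_cluster[(i + k * (len(leftover_groups) + 1)) % len(non_cluster)]
                    if len(copies) > 1 and len(non_cluster) > 1:
                        # keep the two paralogs on distinct chromosomes
                        prev = [c for gg, cc, c in
                                [(gg, cc, ch) for ch, items in planted_on.items()
                                 for gg, cc in items] if gg == g]
                        while chrom in prev:
                            chrom = non_cluster[(non_cluster.index(chrom) + 1) % len(non_cluster)]
                    planted_on[chrom].append((g, copy))

        alloc = dict(zip(chroms, _allocate_counts(sp.n_genes, sp.chromosome_lengths)))
        for chrom in chroms:
            if alloc[chrom] < len(planted_on[chrom]):
                alloc[chrom] = len(planted_on[chrom])

        species_genes: list[GeneModel] = []
        member_genes: dict[tuple[int, str], str] = {}
        for ci, chrom in enumerate(chroms):
            L = sp.chromosome_lengths[ci]
            n_here = alloc[chrom]
            mean_len = sp.mean_gene_length
            if n_here * mean_len * 1.4 > L:
                raise ValueError(
                    f"infeasible packing on {chrom}: {n_here} genes of ~{mean_len} bp "
                    f"exceed {L} bp"
                )
            packer = _IntervalPacker(chrom, L, rng)
            placed: list[tuple[int, int, tuple[int, str] | None]] = []

            planted_here = planted_on[chrom]
            cluster_here = [gc for gc in planted_here if gc[0] in cluster_groups]
            single_here = [gc for gc in planted_here if gc[0] not in cluster_groups]

            if cluster_here:
                # one contiguous span holds the cluster, genes in group order
                lens = [int(rng.integers(int(0.6 * mean_len), int(1.4 * mean_len) + 1))
                        for _ in cluster_here]
                span = config.cluster.span_bp
                if sum(lens) > span:
                    raise ValueError(f"infeasible packing on {chrom}: cluster span too small")
                cs = int(rng.integers(0, L - span + 1))
                free = span - sum(lens)
                offs = np.sort(rng.random(len(cluster_here)) * free).astype(int)
                pos = cs
                acc = 0
                for (gc, glen, off) in zip(sorted(cluster_here), lens, offs):
                    start = cs + int(off) + acc
                    packer.insert(start, start + glen)
                    placed.append((start, start + glen, gc))
                    acc += glen
                # the span holds only cluster genes: keeps cluster gene order
                # and rank adjacency identical across species, so planted
                # collinear blocks are unambiguous
                packer.block(cs, cs + span)
            for gc in single_here:
                glen = int(rng.integers(int(0.6 * mean_len), int(1.4 * mean_len) + 1))
                start, end = packer.place(glen)
                placed.append((start, end, gc))
            for _ in range(n_here - len(planted_here)):
                glen = int(rng.integers(int(0.6 * mean_len), int(1.4 * mean_len) + 1))
                start, end = packer.place(glen)
                placed.append((start, end, None))

            placed.sort(key=lambda t: t[0])
            for rank, (start, end, gc) in enumerate(placed, start=1):
                gene_id = f"{sp.prefix}{ci + 1:02d}g{rank * 10:05d}"
                strand = "+" if rng.random() < 0.5 else "-"
                if gc is None:
                    gm = GeneModel(gene_id, sp.name, chrom, start, end, strand)
                else:
                    g, copy = gc
                    gm = GeneModel(
                        gene_id, sp.name, chrom, start, end, strand,
                        legacy_id=_seed_id(sp.prefix, g, copy),
                        is_nodulation=True,
                    )
                    member_genes[gc] = gene_id
                    truth.seed_to_gene[gm.legacy_id] = gene_id
                species_genes.append(gm)

        for g in range(config.n_seed_groups):
            members = [member_genes[(g, copy)] for copy in copies if (g, copy) in member_genes]
            if members:
                truth.true_groups[group_ids[g]][sp.name] = tuple(members)
        genes_by_species[sp.name] = species_genes

    return genes_by_species, truth


# ---------------------------------------------------------------------------
# Homology generation
# ---------------------------------------------------------------------------

def _rank_index(genes_by_species: Mapping[str, Sequence[GeneModel]]):
    by_id: dict[str, GeneModel] = {}
    chrom_genes: dict[tuple[str, str], list[GeneModel]] = {}
    for sp, genes in genes_by_species.items():
        for g in genes:
            by_id[g.gene_id] = g
            chrom_genes.setdefault((sp, g.chromosome), []).append(g)
    rank: dict[str, int] = {}
    for key, glist in chrom_genes.items():
        glist.sort(key=lambda g: (g.start, g.gene_id))
        for i, g in enumerate(glist):
            rank[g.gene_id] = i
    return by_id, chrom_genes, rank


def _passing_hit(rng: np.random.Generator, qid: str, sid: str) -> HomologyHit:
    return HomologyHit(
        query_id=qid,
        subject_id=sid,
        pident=float(np.round(rng.uniform(80, 100), 2)),
        evalue=float(10.0 ** rng.uniform(-60, -20)),
        score=float(np.round(rng.uniform(150, 600), 1)),
    )


def generate_homology(
    genes_by_species: Mapping[str, Sequence[GeneModel]],
    truth: GroundTruth,
    config: SimConfig,
) -> list[HomologyHit]:
    """Emit homology hits: seed-query hits, collinear block anchors, decoys.

    Every true ortholog/paralog pair receives a hit that passes the strict
    filter, embedded in a planted collinear run of ``genes_per_block``
    anchors (flanking anchors connect non-nodulation neighbours at matching
    rank offsets, so planted blocks are perfectly monotone).  Decoy hits are
    drawn adjacent to the filter thresholds and always fail it; the first
    two sit exactly on the boundaries (e-value = 1e-12, score = 100).
    Seed-less decoy blocks exercise the discarding of unanchored syntelog
    components.  Deterministic per seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, _STREAM_HOMOL]))
    by_id, chrom_genes, rank = _rank_index(genes_by_species)
    hits: list[HomologyHit] = []
    truth.true_syntenic_blocks = []

    # 1) seed-query hits (query = published/legacy id, subject = current id)
    for seed_id, gene_id in sorted(truth.seed_to_gene.items()):
        hits.append(_passing_hit(rng, seed_id, gene_id))

    # 2) anchors around every true pair
    flank = max(0, (config.synteny.genes_per_block - 1) // 2)
    emitted_pairs: set[frozenset[str]] = set()
    used_ranks: dict[tuple, tuple[set[int], set[int]]] = {}
    anchored_genes: set[str] = set()

    def _sides(g1: GeneModel, g2: GeneModel):
        s1, s2 = (g1, g2)
        if (s2.species, s2.chromosome, s2.gene_id) < (s1.species, s1.chromosome, s1.gene_id):
            s1, s2 = s2, s1
        return s1, s2

    def _emit_anchor(g1: GeneModel, g2: GeneModel) -> bool:
        key = frozenset((g1.gene_id, g2.gene_id))
        if len(key) < 2 or key in emitted_pairs:
            return False
        a, b = _sides(g1, g2)
        pk = (a.species, a.chromosome, b.species, b.chromosome)
        ranks = used_ranks.setdefault(pk, (set(), set()))
        if rank[a.gene_id] in ranks[0] or rank[b.gene_id] in ranks[1]:
            return False
        ranks[0].add(rank[a.gene_id])
        ranks[1].add(rank[b.gene_id])
        emitted_pairs.add(key)
        anchored_genes.update((a.gene_id, b.gene_id))
        hits.append(_passing_hit(rng, a.gene_id, b.gene_id))
        return True

    pairs_per_group: dict[str, list[tuple[GeneModel, GeneModel]]] = {}
    for gid in sorted(truth.true_groups):
        members = [by_id[m] for sp in sorted(truth.true_groups[gid])
                   for m in truth.true_groups[gid][sp]]
        pairs = [(members[i], members[j])
                 for i in range(len(members)) for j in range(i + 1, len(members))]
        pairs_per_group[gid] = pairs
        for g1, g2 in pairs:  # true pairs claim their ranks first
            _emit_anchor(g1, g2)
    for gid in sorted(truth.true_groups):
        for g1, g2 in pairs_per_group[gid]:
            block = [(g1.gene_id, g2.gene_id)]
            for d in list(range(-flank, 0)) + list(range(1, flank + 1)):
                n1 = _neighbour(chrom_genes, rank, g1, d)
                n2 = _neighbour(chrom_genes, rank, g2, d)
                if n1 is None or n2 is None or n1.is_nodulation or n2.is_nodulation:
                    continue
                if _emit_anchor(n1, n2):
                    block.append((n1.gene_id, n2.gene_id))
            truth.true_syntenic_blocks.append(block)

    # 3) seed-less decoy blocks
    species = sorted(genes_by_species)
    if len(species) >= 2:
        for b in range(config.synteny.n_decoy_blocks):
            sp_a = species[b % len(species)]
            sp_b = species[(b + 1) % len(species)]
            run_a = _free_run(chrom_genes, truth, anchored_genes, sp_a,
                              config.synteny.genes_per_block, rng)
            run_b = _free_run(chrom_genes, truth, anchored_genes, sp_b,
                              config.synteny.genes_per_block, rng)
            if run_a is None or run_b is None:
                continue
            block = []
            for ga, gb in zip(run_a, run_b):
                if _emit_anchor(ga, gb):
                    block.append((ga.gene_id, gb.gene_id))
            truth.true_syntenic_blocks.append(block)

    # 4) scattered single anchors (never chain into blocks)
    all_ids = sorted(by_id)
    for _ in range(config.synteny.n_scatter_anchors):
        for _try in range(100):
            g1 = by_id[all_ids[int(rng.integers(len(all_ids)))]]
            g2 = by_id[all_ids[int(rng.integers(len(all_ids)))]]
            if (g1.species != g2.species and g1.gene_id not in anchored_genes
                    and g2.gene_id not in anchored_genes):
                _emit_anchor(g1, g2)
                break

    # 5) decoy hits failing the filter, drawn adjacent to the thresholds
    seed_ids = sorted(truth.seed_to_gene) or ["SEED_NONE"]
    boundary = [(1e-12, 250.0), (1e-30, 100.0)]  # exactly on each boundary
    for i in range(config.n_decoy_hits):
        qid = seed_ids[int(rng.integers(len(seed_ids)))]
        sid = all_ids[int(rng.integers(len(all_ids)))]
        if i < len(boundary):
            ev, sc = boundary[i]
        else:
            mode = int(rng.integers(3))
            ev = float(10.0 ** rng.uniform(-12, -8)) if mode != 1 else float(10.0 ** rng.uniform(-40, -20))
            sc = float(rng.uniform(50, 100)) if mode != 0 else float(rng.uniform(150, 400))
            if ev < 1e-12 and sc > 100:  # must fail at least one comparison
                sc = 100.0
        hits.append(HomologyHit(qid, sid, float(np.round(rng.uniform(40, 80), 2)), ev, sc))

    return hits


def _neighbour(chrom_genes, rank, gene: GeneModel, d: int) -> GeneModel | None:
    glist = chrom_genes[(gene.species, gene.chromosome)]
    i = rank[gene.gene_id] + d
    if 0 <= i < len(glist):
        return glist[i]
    return None


def _free_run(chrom_genes, truth: GroundTruth, anchored: set[str], species: str,
              n: int, rng: np.random.Generator) -> list[GeneModel] | None:
    cluster = set(truth.true_cluster_chromosomes.get(species, ()))
    keys = sorted(k for k in chrom_genes if k[0] == species and k[1] not in cluster)
    for _ in range(200):
        if not keys:
            return None
        glist = chrom_genes[keys[int(rng.integers(len(keys)))]]
        if len(glist) < n:
            continue
        s = int(rng.integers(0, len(glist) - n + 1))
        run = glist[s:s + n]
        if all(not g.is_nodulation and g.gene_id not in anchored for g in run):
            return run
    return None


# ---------------------------------------------------------------------------
# Expression generation
# ---------------------------------------------------------------------------

def generate_expression(
    genes_by_species: Mapping[str, Sequence[GeneModel]],
    truth: GroundTruth,
    config: SimConfig,
) -> pd.DataFrame:
    """Emit an expression matrix (rows = genes, columns = atlas + time course).

    Planted ortholog groups cycle through three labels — induced + preferential,
    root-hair-induced only, nodule-preferential only — so cross-species
    overlap statistics have structure.  A configured fraction of the WGD
    paralog copies is reassigned a flat "broad" profile (emulating
    sub-functionalization after duplication); a configured fraction of
    background genes is silent.  Before noise, planted contrasts are exact:
    inoculated = baseline x induced_fc, nodule = baseline x preferential_fc.
    Multiplicative log-normal noise with the configured CV is then applied.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, _STREAM_EXPR]))
    ex = config.expression
    labels = ("both", "rh", "nod")
    truth.true_induced = set()
    truth.true_preferential = set()
    truth.true_broad = set()
    truth.group_labels = {}

    wgd_species = [sp.name for sp in config.species if sp.has_recent_wgd]
    dup_copies: list[str] = []
    for gid in sorted(truth.true_groups):
        for sp in wgd_species:
            members = truth.true_groups[gid].get(sp, ())
            if len(members) > 1:
                dup_copies.extend(members[1:])
    n_broad = int(round(ex.broad_fraction * len(dup_copies)))
    if n_broad > 0:
        broad = rng.choice(np.array(sorted(dup_copies)), size=n_broad, replace=False)
        truth.true_broad = set(str(b) for b in broad)

    for i, gid in enumerate(sorted(truth.true_groups)):
        label = labels[i % len(labels)]
        truth.group_labels[gid] = label
        for sp in sorted(truth.true_groups[gid]):
            # expression divergence: a species may have lost the planted
            # effect for this group (partial cross-species conservation)
            keep_rh = rng.random() >= ex.divergence_fraction
            keep_nod = rng.random() >= ex.divergence_fraction
            for m in truth.true_groups[gid][sp]:
                if m in truth.true_broad:
                    continue
                if label in ("both", "rh") and keep_rh:
                    truth.true_induced.add(m)
                if label in ("both", "nod") and keep_nod:
                    truth.true_preferential.add(m)

    columns = list(ex.tissues) + [f"{tp}_{t}" for tp in ex.timepoints for t in ("UN", "IN")]
    rows: list[list[float]] = []
    index: list[str] = []
    for sp in sorted(genes_by_species):
        for g in genes_by_species[sp]:
            index.append(g.gene_id)
            if g.is_nodulation:
                base = ex.baseline
            elif rng.random() < ex.silent_fraction:
                rows.append([0.0] * len(columns))
                continue
            else:
                base = float(np.round(rng.uniform(5.0, 50.0), 3))
            atlas = {t: base for t in ex.tissues}
            if g.gene_id in truth.true_preferential:
                atlas["nodule"] = base * ex.preferential_fc
            induced = g.gene_id in truth.true_induced
            row = [atlas[t] for t in ex.tissues]
            for tp in ex.timepoints:
                row.append(base)                                    # UN
                row.append(base * ex.induced_fc if induced else base)  # IN
            rows.append(row)

    df = pd.DataFrame(rows, index=pd.Index(index, name="gene_id"), columns=columns)
    if ex.noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(ex.noise_cv ** 2)))
        noise = rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma, size=df.shape)
        df = df * noise
    return df


# ---------------------------------------------------------------------------
# Dataset bundle and file IO
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimConfig
    genes_by_species: dict[str, list[GeneModel]]
    truth: GroundTruth
    hits: list[HomologyHit]
    expression: pd.DataFrame

    def chrom_lengths(self, species: str) -> dict[str, int]:
        sp = next(s for s in self.config.species if s.name == species)
        return dict(zip(sp.chromosome_names(), sp.chromosome_lengths))

    def seed_list(self) -> pd.DataFrame:
        rows = []
        for seed_id in sorted(self.truth.seed_to_gene):
            gene = self.truth.seed_to_gene[seed_id]
            sp = next(s.name for s in self.config.species
                      if any(g.gene_id == gene for g in self.genes_by_species[s.name]))
            group = seed_id.split("_G")[-1][:2]
            rows.append((seed_id, sp, f"NOD{group}"))
        return pd.DataFrame(rows, columns=["seed_id", "species", "published_name"])

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sp_name, genes in self.genes_by_species.items():
            write_gff3(genes, outdir / f"{_safe(sp_name)}.gff3",
                       chrom_lengths=self.chrom_lengths(sp_name))
        write_hits(self.hits, outdir / "hits.tsv")
        self.expression.to_csv(outdir / "expression.tsv", sep="\t")
        self.seed_list().to_csv(outdir / "seeds.tsv", sep="\t", index=False)
        write_config(self.config, outdir / "config.yaml")
        tdir = outdir / "truth"
        tdir.mkdir(exist_ok=True)
        write_truth(self.truth, tdir)


def _safe(name: str) -> str:
    return name.replace(" ", "_").replace(".", "")


def simulate(config: SimConfig) -> SimulatedDataset:
    """Run all three generators under one seed."""
    genes, truth = generate_annotations(config)
    hits = generate_homology(genes, truth, config)
    expr = generate_expression(genes, truth, config)
    return SimulatedDataset(config, genes, truth, hits, expr)


def write_truth(truth: GroundTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    rows = [(gid, sp, m) for gid in sorted(truth.true_groups)
            for sp in sorted(truth.true_groups[gid])
            for m in truth.true_groups[gid][sp]]
    pd.DataFrame(rows, columns=["group_id", "species", "gene_id"]).to_csv(
        outdir / "groups.tsv", sep="\t", index=False)
    for name, ids in (("induced", truth.true_induced),
                      ("preferential", truth.true_preferential),
                      ("broad", truth.true_broad)):
        pd.DataFrame({"gene_id": sorted(ids)}).to_csv(
            outdir / f"{name}.tsv", sep="\t", index=False)
    rows = [(sp, c) for sp in sorted(truth.true_cluster_chromosomes)
            for c in truth.true_cluster_chromosomes[sp]]
    pd.DataFrame(rows, columns=["species", "chromosome"]).to_csv(
        outdir / "cluster_chromosomes.tsv", sep="\t", index=False)
    rows = [(i, a, b) for i, block in enumerate(truth.true_syntenic_blocks)
            for a, b in block]
    pd.DataFrame(rows, columns=["block", "gene_a", "gene_b"]).to_csv(
        outdir / "syntenic_blocks.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(truth.seed_to_gene.items()),
                 columns=["seed_id", "gene_id"]).to_csv(
        outdir / "seed_map.tsv", sep="\t", index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id",
                       float_precision="round_trip")


def read_seed_list(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_dataset(indir: str | Path) -> tuple[dict[str, list[GeneModel]], list[HomologyHit], pd.DataFrame, pd.DataFrame, dict[str, dict[str, int]]]:
    """Read back a written dataset: genes, hits, expression, seeds, chrom lengths."""
    indir = Path(indir)
    config = read_config(indir / "config.yaml") if (indir / "config.yaml").exists() else None
    genes: dict[str, list[GeneModel]] = {}
    lengths: dict[str, dict[str, int]] = {}
    if config is not None:
        names = [sp.name for sp in config.species]
    else:
        names = [p.stem.replace("_", " ") for p in sorted(indir.glob("*.gff3"))]
    for name in names:
        path = indir / f"{_safe(name)}.gff3"
        genes[name] = parse_gff3(path, species=name)
        lengths[name] = parse_sequence_regions(path)
    hits = read_hits(indir / "hits.tsv")
    expr = read_expression(indir / "expression.tsv")
    seeds = read_seed_list(indir / "seeds.tsv")
    return genes, hits, expr, seeds, lengths


# --- config (de)serialisation ----------------------------------------------

def config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)

    def _tuples_to_lists(obj):
        if isinstance(obj, dict):
            return {k: _tuples_to_lists(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return [_tuples_to_lists(v) for v in obj]
        return obj

    return _tuples_to_lists(d)


def config_from_dict(d: Mapping) -> SimConfig:
    species = tuple(
        SpeciesSpec(
            name=s["name"], prefix=s["prefix"],
            chromosome_lengths=tuple(s["chromosome_lengths"]),
            n_genes=s["n_genes"],
            mean_gene_length=s.get("mean_gene_length", 3000),
            has_recent_wgd=s.get("has_recent_wgd", False),
        )
        for s in d["species"]
    )
    ex = d.get("expression", {})
    return SimConfig(
        species=species,
        n_seed_groups=d.get("n_seed_groups", 12),
        cluster=ClusterSpec(**d.get("cluster", {})),
        synteny=SyntenySpec(**d.get("synteny", {})),
        expression=ExpressionSpec(
            **{**ex,
               "tissues": tuple(ex.get("tissues", ATLAS_TISSUES)),
               "timepoints": tuple(ex.get("timepoints", RH_TIMEPOINTS))}
        ),
        n_decoy_hits=d.get("n_decoy_hits", 25),
        rng_seed=d.get("rng_seed", 0),
    )


def write_config(config: SimConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def read_config(path: str | Path) -> SimConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
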
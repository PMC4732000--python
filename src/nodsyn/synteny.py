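"""Syntelog detection by anchor chaining and ortholog/paralog group assembly.

Homologous gene pairs (anchors) that sit in conserved gene-order context are
evidence of orthology or ancient paralogy (syntelogs).  This module chains
anchors over gene rank (index in start-coordinate order per chromosome): a
chain extends while consecutive anchors advance by at most ``max_rank_gap``
genes on both genomes and stay monotone on the second genome, the direction
(same/inverted) being locked by the chain's first two anchors.  Chains with
at least ``min_anchors`` anchors become syntenic blocks; only pairs inside a
block are syntelogs.  Rank-space gaps (rather than bp) make the chaining
robust to gene-density differences between genomes.

Syntelog pairs form an undirected graph whose connected components are the
ortholog/paralog groups; within-species pairs contribute paralogy edges
(e.g. WGD pairs), so paralogs and orthologs land in the same group.  Only
components containing at least one functionally characterized seed gene are
kept as groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .catalog import GeneModel, HomologyHit

log = logging.getLogger(__name__)

DEFAULT_MAX_RANK_GAP = 10
DEFAULT_MIN_ANCHORS = 3


@dataclass(frozen=True)
class AnchorPair:
    """A homologous gene pair usable as collinearity evidence."""

    gene_a: GeneModel
    gene_b: GeneModel

    def ids(self) -> tuple[str, str]:
        return (self.gene_a.gene_id, self.gene_b.gene_id)


@dataclass
class SyntenicBlock:
    species_a: str
    chr_a: str
    species_b: str
    chr_b: str
    orientation: str  # "same" | "inverted"
    anchors: list[AnchorPair]

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


@dataclass
class OrthologGroup:
    group_id: str
    members: dict[str, tuple[str, ...]]  # species -> gene ids
    seed_ids: tuple[str, ...]

    def all_members(self) -> set[str]:
        return {g for ms in self.members.values() for g in ms}


def gene_ranks(genes: Iterable[GeneModel]) -> dict[str, int]:
    """Rank of each gene = its index in start-coordinate order per chromosome."""
    per_chrom: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        per_chrom.setdefault((g.species, g.chromosome), []).append(g)
    ranks: dict[str, int] = {}
    for glist in per_chrom.values():
        glist.sort(key=lambda g: (g.start, g.gene_id))
        for i, g in enumerate(glist):
            ranks[g.gene_id] = i
    return ranks


def build_anchor_map(
    kept_hits: Iterable[HomologyHit],
    genes: Iterable[GeneModel],
) -> list[AnchorPair]:
    """One anchor per filtered hit whose both ids resolve to gene models.

    Unresolvable ids (e.g. published seed identifiers used as BLAST queries)
    and self pairs are dropped with a logged count; duplicate/reciprocal
    pairs are deduplicated.  The pair is stored with the (species,
    chromosome, gene id)-smaller gene first.
    """
    by_id = {g.gene_id: g for g in genes}
    anchors: list[AnchorPair] = []
    seen: set[frozenset[str]] = set()
    dropped = 0
    for h in kept_hits:
        ga = by_id.get(h.query_id)
        gb = by_id.get(h.subject_id)
        if ga is None or gb is None or ga.gene_id == gb.gene_id:
            dropped += 1
            continue
        key = frozenset((ga.gene_id, gb.gene_id))
        if key in seen:
            continue
        seen.add(key)
        if (gb.species, gb.chromosome, gb.gene_id) < (ga.species, ga.chromosome, ga.gene_id):
            ga, gb = gb, ga
        anchors.append(AnchorPair(ga, gb))
    if dropped:
        log.info("build_anchor_map: dropped %d hits with unresolvable/self ids", dropped)
    return anchors


def chain_anchors(
    anchors: Sequence[AnchorPair],
    genes: Iterable[GeneModel],
    max_rank_gap: int = DEFAULT_MAX_RANK_GAP,
    min_anchors: int = DEFAULT_MIN_ANCHORS,
) -> list[SyntenicBlock]:
    """Greedy single-pass chaining of anchors per chromosome pair.

    Anchors are sorted by rank on genome A; a chain extends while the next
    anchor advances by 1..max_rank_gap ranks on A, by at most max_rank_gap
    on B, and keeps B-ranks strictly monotone in the direction fixed by the
    chain's first two anchors.  A non-extending anchor closes the chain and
    opens a new one, so every anchor belongs to at most one block; chains
    shorter than ``min_anchors`` are discarded.
    """
    ranks = gene_ranks(genes)
    by_pair: dict[tuple[str, str, str, str], list[AnchorPair]] = {}
    for a in anchors:
        key = (a.gene_a.species, a.gene_a.chromosome, a.gene_b.species, a.gene_b.chromosome)
        by_pair.setdefault(key, []).append(a)

    blocks: list[SyntenicBlock] = []
    for key in sorted(by_pair):
        sp_a, chr_a, sp_b, chr_b = key
        alist = sorted(by_pair[key],
                       key=lambda a: (ranks[a.gene_a.gene_id], ranks[a.gene_b.gene_id]))
        chain: list[AnchorPair] = []
        direction = 0

        def _close() -> None:
            nonlocal chain, direction
            if len(chain) >= min_anchors:
                blocks.append(SyntenicBlock(
                    sp_a, chr_a, sp_b, chr_b,
                    "inverted" if direction < 0 else "same",
                    chain,
                ))
            chain = []
            direction = 0

        for a in alist:
            if not chain:
                chain = [a]
                continue
            last = chain[-1]
            gap_a = ranks[a.gene_a.gene_id] - ranks[last.gene_a.gene_id]
            gap_b = ranks[a.gene_b.gene_id] - ranks[last.gene_b.gene_id]
            ok = 0 < gap_a <= max_rank_gap and 0 < abs(gap_b) <= max_rank_gap
            if ok:
                step = 1 if gap_b > 0 else -1
                if direction == 0:
                    direction = step
                elif step != direction:
                    ok = False
            if ok:
                chain.append(a)
            else:
                _close()
                chain = [a]
        _close()
    return blocks


def call_syntelogs(blocks: Iterable[SyntenicBlock]) -> set[tuple[str, str]]:
    """Union of anchor pairs over all blocks (pairs outside blocks are not syntelogs)."""
    pairs: set[tuple[str, str]] = set()
    for b in blocks:
        for a in b.anchors:
            pairs.add(tuple(sorted(a.ids())))  # type: ignore[arg-type]
    return pairs


def build_groups(
    syntelog_pairs: Iterable[tuple[str, str]],
    seed_gene_ids: Iterable[str],
    genes: Iterable[GeneModel],
) -> list[OrthologGroup]:
    """Connected components of the syntelog graph, anchored to seed genes.

    Seed genes are always graph nodes (an unpaired seed yields a singleton
    group).  Components without a seed are discarded with a logged count.
    ``group_id`` is the lexicographically smallest member id, so output is
    invariant under permutation of the pair list.
    """
    species_of = {g.gene_id: g.species for g in genes}
    seeds = set(seed_gene_ids)
    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(seeds)
    graph.add_edges_from(syntelog_pairs)

    groups: list[OrthologGroup] = []
    discarded = 0
    for comp in nx.connected_components(graph):
        comp_seeds = sorted(comp & seeds)
        if not comp_seeds:
            discarded += 1
            continue
        members: dict[str, list[str]] = {}
        for gid in sorted(comp):
            members.setdefault(species_of.get(gid, "unknown"), []).append(gid)
        groups.append(OrthologGroup(
            group_id=min(comp),
            members={sp: tuple(ms) for sp, ms in sorted(members.items())},
            seed_ids=tuple(comp_seeds),
        ))
    if discarded:
        log.info("build_groups: discarded %d seed-less components", discarded)
    groups.sort(key=lambda g: g.group_id)
    return groups


def count_members_by_species(groups: Iterable[OrthologGroup]) -> tuple[dict[str, int], int]:
    """Distinct grouped genes per species, plus the number of groups."""
    per_species: dict[str, set[str]] = {}
    n = 0
    for grp in groups:
        n += 1
        for sp, members in grp.members.items():
            per_species.setdefault(sp, set()).update(members)
    return {sp: len(ids) for sp, ids in sorted(per_species.items())}, n


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def blocks_table(blocks: Iterable[SyntenicBlock]) -> pd.DataFrame:
    rows = []
    for i, b in enumerate(blocks):
        rows.append((
            i, b.species_a, b.chr_a, b.species_b, b.chr_b, b.orientation,
            b.n_anchors,
            ";".join(f"{a.gene_a.gene_id}|{a.gene_b.gene_id}" for a in b.anchors),
        ))
    return pd.DataFrame(rows, columns=[
        "block", "species_a", "chr_a", "species_b", "chr_b",
        "orientation", "n_anchors", "anchor_pairs",
    ])


def groups_table(groups: Iterable[OrthologGroup]) -> pd.DataFrame:
    rows = []
    for grp in groups:
        for sp, members in grp.members.items():
            for m in members:
                rows.append((grp.group_id, sp, m, m in grp.seed_ids))
    return pd.DataFrame(rows, columns=["group_id", "species", "gene_id", "is_seed"])
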
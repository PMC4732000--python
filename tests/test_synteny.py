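"""Anchor chaining, syntelog calling and ortholog-group assembly."""

import random

import pytest

from nodsyn import catalog as cat
from nodsyn import synteny as syn
from nodsyn.catalog import GeneModel


def _genome(species: str, chrom: str, n: int, prefix: str) -> list[GeneModel]:
    """n genes of 1 kb spaced 10 kb apart; rank i has id f'{prefix}{i}'."""
    return [
        GeneModel(f"{prefix}{i}", species, chrom, i * 10_000, i * 10_000 + 1_000)
        for i in range(n)
    ]


def _anchors(ga, gb, rank_pairs):
    return [syn.AnchorPair(ga[i], gb[j]) for i, j in rank_pairs]


@pytest.fixture()
def two_chromosomes():
    ga = _genome("A", "chrA", 60, "a")
    gb = _genome("B", "chrB", 60, "b")
    return ga, gb


class TestChainAnchors:
    def test_perfect_collinearity_gives_one_same_block(self, two_chromosomes):
        ga, gb = two_chromosomes
        blocks = syn.chain_anchors(
            _anchors(ga, gb, [(1, 1), (2, 2), (3, 3)]), ga + gb)
        assert len(blocks) == 1
        assert blocks[0].orientation == "same"
        assert blocks[0].n_anchors == 3

    def test_monotone_decreasing_gives_inverted_block(self, two_chromosomes):
        ga, gb = two_chromosomes
        blocks = syn.chain_anchors(
            _anchors(ga, gb, [(1, 9), (2, 8), (3, 7)]), ga + gb)
        assert len(blocks) == 1
        assert blocks[0].orientation == "inverted"

    def test_scattered_anchors_make_no_block(self, two_chromosomes):
        ga, gb = two_chromosomes
        blocks = syn.chain_anchors(
            _anchors(ga, gb, [(1, 40), (20, 3), (45, 22)]), ga + gb)
        assert blocks == []

    def test_planted_blocks_recovered_exactly_vs_exhaustive_oracle(self):
        """Two planted collinear runs among scattered decoy anchors: greedy
        chaining finds exactly the maximal monotone chains an exhaustive
        enumeration finds."""
        ga = _genome("A", "chrA", 600, "a")
        gb = _genome("B", "chrB", 600, "b")
        planted = [[(i, 10 + i) for i in range(5)],
                   [(20 + i, 120 - i) for i in range(5)]]
        rank_pairs = [p for blk in planted for p in blk]
        # 20 scattered anchors, consecutive ones > max_rank_gap apart on A
        rng = random.Random(4)
        scattered = [(40 + 25 * k, rng.randrange(200, 600)) for k in range(20)]
        rank_pairs += scattered
        anchors = _anchors(ga, gb, rank_pairs)
        blocks = syn.chain_anchors(anchors, ga + gb, max_rank_gap=10, min_anchors=3)

        got = {frozenset(a.ids() for a in b.anchors) for b in blocks}
        oracle = {
            frozenset((f"a{i}", f"b{j}") for i, j in blk)
            for blk in _exhaustive_maximal_chains(rank_pairs, max_gap=10, min_len=3)
        }
        expected = {frozenset((f"a{i}", f"b{j}") for i, j in blk) for blk in planted}
        assert got == oracle == expected

    def test_blocks_never_share_anchors_and_are_monotone(self, small_dataset):
        all_genes = [g for gs in small_dataset.genes_by_species.values() for g in gs]
        kept = cat.filter_hits(small_dataset.hits)
        anchors = syn.build_anchor_map(kept, all_genes)
        blocks = syn.chain_anchors(anchors, all_genes)
        ranks = syn.gene_ranks(all_genes)
        seen = set()
        for b in blocks:
            for a in b.anchors:
                assert a.ids() not in seen
                seen.add(a.ids())
            ra = [ranks[a.gene_a.gene_id] for a in b.anchors]
            rb = [ranks[a.gene_b.gene_id] for a in b.anchors]
            assert ra == sorted(ra) and len(set(ra)) == len(ra)
            step = 1 if b.orientation == "same" else -1
            assert rb == sorted(rb)[::step] and len(set(rb)) == len(rb)

    def test_more_rank_gap_never_loses_syntelogs(self, two_chromosomes):
        ga, gb = two_chromosomes
        rng = random.Random(9)
        pairs = sorted({(rng.randrange(60), rng.randrange(60)) for _ in range(35)})
        anchors = _anchors(ga, gb, pairs)
        sizes = []
        for gap in (1, 3, 5, 10, 20, 60):
            blocks = syn.chain_anchors(anchors, ga + gb, max_rank_gap=gap)
            sizes.append(len(syn.call_syntelogs(blocks)))
        assert sizes == sorted(sizes)


def _exhaustive_maximal_chains(rank_pairs, max_gap, min_len):
    """All maximal monotone chains (direction locked by first two anchors),
    by depth-first extension over every start anchor."""
    pairs = sorted(rank_pairs)
    results: set[tuple] = set()

    def extensions(chain, direction):
        ra, rb = chain[-1]
        out = []
        for p in pairs:
            ga, gb = p[0] - ra, p[1] - rb
            if 0 < ga <= max_gap and 0 < abs(gb) <= max_gap:
                step = 1 if gb > 0 else -1
                if direction in (0, step):
                    out.append((p, step if direction == 0 else direction))
        return out

    def extend(chain, direction):
        exts = extensions(chain, direction)
        if not exts:
            if len(chain) >= min_len:
                results.add(tuple(chain))
            return
        for p, d in exts:
            extend(chain + [p], d)

    for p in pairs:
        extend([p], 0)
    # drop chains strictly contained in another
    maximal = [
        c for c in results
        if not any(set(c) < set(o) for o in results if o != c)
    ]
    return [list(c) for c in maximal]


class TestAnchorMap:
    def test_resolvable_hits_become_anchors(self, two_chromosomes):
        ga, gb = two_chromosomes
        hits = [cat.HomologyHit(f"a{i}", f"b{i}", 90, 1e-30, 200) for i in range(10)]
        anchors = syn.build_anchor_map(hits, ga + gb)
        assert len(anchors) == 10

    def test_unresolvable_and_self_hits_are_dropped(self, two_chromosomes):
        ga, gb = two_chromosomes
        hits = [
            cat.HomologyHit("a1", "b1", 90, 1e-30, 200),
            cat.HomologyHit("a1", "missing", 90, 1e-30, 200),
            cat.HomologyHit("a2", "a2", 90, 1e-30, 200),
        ]
        anchors = syn.build_anchor_map(hits, ga + gb)
        assert [a.ids() for a in anchors] == [("a1", "b1")]

    def test_anchor_set_contains_all_truth_pairs(self, small_dataset):
        all_genes = [g for gs in small_dataset.genes_by_species.values() for g in gs]
        kept = cat.filter_hits(small_dataset.hits)
        anchors = {frozenset(a.ids()) for a in syn.build_anchor_map(kept, all_genes)}
        for gid in small_dataset.truth.true_groups:
            members = sorted(small_dataset.truth.group_members(gid))
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    assert frozenset((members[i], members[j])) in anchors


class TestCallSyntelogs:
    def test_block_anchors_become_pairs(self, two_chromosomes):
        ga, gb = two_chromosomes
        blocks = syn.chain_anchors(
            _anchors(ga, gb, [(1, 1), (2, 2), (3, 3)]), ga + gb)
        assert syn.call_syntelogs(blocks) == {("a1", "b1"), ("a2", "b2"), ("a3", "b3")}

    def test_no_blocks_no_syntelogs(self):
        assert syn.call_syntelogs([]) == set()


class TestBuildGroups:
    def _genes(self, ids, species="A"):
        return [GeneModel(g, species, "chr1", i * 10_000, i * 10_000 + 100)
                for i, g in enumerate(ids)]

    def test_transitive_closure(self):
        genes = self._genes(["a", "b", "c"])
        (grp,) = syn.build_groups([("a", "b"), ("b", "c")], ["a"], genes)
        assert grp.all_members() == {"a", "b", "c"}
        assert grp.seed_ids == ("a",)

    def test_unpaired_seeds_become_singletons(self):
        genes = self._genes(["s1", "s2", "s3", "s4"])
        groups = syn.build_groups([], ["s1", "s2", "s3", "s4"], genes)
        assert sorted(g.group_id for g in groups) == ["s1", "s2", "s3", "s4"]
        assert all(len(g.all_members()) == 1 for g in groups)

    def test_seedless_components_are_discarded(self):
        genes = self._genes(["a", "b", "x", "y"])
        groups = syn.build_groups([("a", "b"), ("x", "y")], ["a"], genes)
        assert len(groups) == 1
        assert groups[0].all_members() == {"a", "b"}

    def test_random_graphs_match_dfs_oracle_and_partition(self):
        rng = random.Random(12)
        for _ in range(25):
            n = 50
            ids = [f"g{i}" for i in range(n)]
            genes = self._genes(ids)
            edges = [tuple(rng.sample(ids, 2)) for _ in range(rng.randrange(10, 70))]
            seeds = rng.sample(ids, 5)
            groups = syn.build_groups(edges, seeds, genes)
            oracle = _dfs_components(ids, edges, set(seeds))
            assert {frozenset(g.all_members()) for g in groups} == oracle
            # partition + permutation invariance
            flat = [m for g in groups for m in g.all_members()]
            assert len(flat) == len(set(flat))
            shuffled = edges[:]
            rng.shuffle(shuffled)
            again = syn.build_groups(shuffled, seeds, genes)
            assert [g.group_id for g in again] == [g.group_id for g in groups]


def _dfs_components(ids, edges, seeds):
    adj: dict[str, set[str]] = {i: set() for i in ids}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    nodes = set(seeds) | {v for e in edges for v in e}
    seen: set[str] = set()
    comps = set()
    for start in nodes:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            stack.extend(adj[v] - comp)
        seen |= comp
        if comp & seeds:
            comps.add(frozenset(comp))
    return comps


class TestCountMembers:
    def test_distinct_genes_per_species(self):
        groups = [
            syn.OrthologGroup("g1", {"spA": ("a1",)}, ("a1",)),
            syn.OrthologGroup("g2", {"spA": ("a2",), "spB": ("b1",)}, ("a2",)),
        ]
        counts, n = syn.count_members_by_species(groups)
        assert counts == {"spA": 2, "spB": 1}
        assert n == 2

    def test_empty_groups_give_zero(self):
        assert syn.count_members_by_species([]) == ({}, 0)

    def test_wgd_species_counts_double(self, small_dataset):
        truth = small_dataset.truth
        all_genes = [g for gs in small_dataset.genes_by_species.values() for g in gs]
        kept = cat.filter_hits(small_dataset.hits)
        anchors = syn.build_anchor_map(kept, all_genes)
        blocks = syn.chain_anchors(anchors, all_genes)
        groups = syn.build_groups(
            syn.call_syntelogs(blocks), truth.seed_to_gene.values(), all_genes)
        counts, n = syn.count_members_by_species(groups)
        n_seed = small_dataset.config.n_seed_groups
        assert n == n_seed
        for sp in small_dataset.config.species:
            assert counts[sp.name] == (2 if sp.has_recent_wgd else 1) * n_seed


def test_zero_noise_group_recovery_is_exact(small_dataset):
    truth = small_dataset.truth
    all_genes = [g for gs in small_dataset.genes_by_species.values() for g in gs]
    kept = cat.filter_hits(small_dataset.hits)
    anchors = syn.build_anchor_map(kept, all_genes)
    blocks = syn.chain_anchors(anchors, all_genes)
    groups = syn.build_groups(
        syn.call_syntelogs(blocks), truth.seed_to_gene.values(), all_genes)
    assert {frozenset(g.all_members()) for g in groups} == {
        frozenset(truth.group_members(gid)) for gid in truth.true_groups}
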
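"""Sliding-window densities, z-scores, KS statistic and enrichment calls."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from nodsyn import density as dn

MB = 1_000_000


class TestWindowParams:
    @pytest.mark.parametrize("species,window,step", [
        ("G. max", 10 * MB, 1 * MB),
        ("P. vulgaris", 6 * MB, int(0.6 * MB)),
        ("L. japonicus", 5 * MB, int(0.5 * MB)),
        ("M. truncatula", 5 * MB, int(0.5 * MB)),
    ])
    def test_presets(self, species, window, step):
        wc = dn.species_window_params(species)
        assert (wc.window_size, wc.step) == (window, step)

    def test_unknown_species_without_override_errors(self):
        with pytest.raises(KeyError):
            dn.species_window_params("A. thaliana")

    def test_override_wins(self):
        wc = dn.species_window_params("A. thaliana", override=(2 * MB, MB))
        assert (wc.window_size, wc.step) == (2 * MB, MB)

    def test_step_larger_than_window_rejected(self):
        with pytest.raises(ValueError):
            dn.WindowConfig(MB, 2 * MB)


class TestWindowCounts:
    def test_first_window_counts_its_points(self):
        pts = [int(0.5 * MB), 5 * MB, 15 * MB]
        track = dn.window_counts(pts, 30 * MB, dn.WindowConfig(10 * MB, MB))
        assert track.counts[0] == 2  # brute force: 0.5 and 5 Mb in [0, 10)

    def test_no_genes_gives_all_zero(self):
        track = dn.window_counts([], 30 * MB, dn.WindowConfig(10 * MB, MB))
        assert (track.counts == 0).all()

    def test_single_window_holds_everything(self):
        pts = [1, 2, 3, 29_999_999]
        track = dn.window_counts(pts, 30 * MB, dn.WindowConfig(30 * MB, 30 * MB))
        assert track.counts.tolist() == [4]

    def test_out_of_range_point_errors(self):
        with pytest.raises(ValueError, match="30000000"):
            dn.window_counts([30 * MB], 30 * MB, dn.WindowConfig(10 * MB, MB))

    def test_matches_bruteforce_interval_membership(self):
        rng = np.random.default_rng(0)
        L = 40 * MB
        cfg = dn.WindowConfig(5 * MB, int(0.5 * MB))
        pts = rng.integers(0, L, size=1000)
        track = dn.window_counts(pts, L, cfg)
        for s, c in zip(track.starts, track.counts):
            assert c == int(np.sum((pts >= s) & (pts < s + cfg.window_size)))

    def test_truncated_terminal_windows_are_kept(self):
        track = dn.window_counts([], 30 * MB, dn.WindowConfig(10 * MB, MB))
        assert track.starts[-1] == 29 * MB
        assert track.ends[-1] == 30 * MB
        assert track.density_per_mb.shape == track.counts.shape


class TestZScores:
    def test_direct_formula(self):
        track = dn.window_counts([], 3 * MB, dn.WindowConfig(MB, MB))
        track.counts = np.array([2, 4, 6])
        dn.zscore_normalize(track)
        assert np.allclose(track.z, [-1.0, 0.0, 1.0])  # u=4, st=2 (n-1)
        assert not track.degenerate

    def test_constant_counts_are_degenerate(self):
        track = dn.window_counts([], 3 * MB, dn.WindowConfig(MB, MB))
        track.counts = np.array([5, 5, 5])
        dn.zscore_normalize(track)
        assert track.degenerate
        assert (track.z == 0).all()

    def test_single_window_is_degenerate(self):
        track = dn.window_counts([1], 2 * MB, dn.WindowConfig(2 * MB, 2 * MB))
        dn.zscore_normalize(track)
        assert track.degenerate

    @given(st.lists(st.integers(0, 50), min_size=3, max_size=60))
    def test_mean_zero_sd_one_when_not_degenerate(self, counts):
        track = dn.window_counts([], len(counts) * MB, dn.WindowConfig(MB, MB))
        track.counts = np.array(counts)
        dn.zscore_normalize(track)
        if not track.degenerate:
            assert abs(track.z.mean()) < 1e-9
            assert abs(track.z.std(ddof=1) - 1.0) < 1e-9


class TestPermutePositions:
    def test_seed_determinism(self):
        pts = np.arange(100)
        a = dn.permute_positions(pts, 10, 42)
        b = dn.permute_positions(pts, 10, 42)
        assert (a == b).all()

    def test_full_draw_returns_whole_set(self):
        pts = np.array([3, 1, 2])
        assert sorted(dn.permute_positions(pts, 3, 0)) == [1, 2, 3]

    def test_oversampling_errors(self):
        with pytest.raises(ValueError):
            dn.permute_positions(np.arange(5), 6, 0)

    def test_null_window_means_match_sampling_theory(self):
        """Mean null count per window ~ n * (window genes) / (total genes)."""
        rng = np.random.default_rng(5)
        L, n_all, n_nod, n_perm = 40 * MB, 200, 12, 2000
        pts = np.sort(rng.integers(0, L, size=n_all))
        cfg = dn.WindowConfig(5 * MB, int(0.5 * MB))
        all_track = dn.window_counts(pts, L, cfg)
        sums = np.zeros(all_track.counts.size)
        sq = np.zeros_like(sums)
        sub_rng = np.random.default_rng(6)
        for _ in range(n_perm):
            sample = dn.permute_positions(pts, n_nod, sub_rng)
            c = dn.window_counts(sample, L, cfg).counts
            sums += c
            sq += c.astype(float) ** 2
        mean = sums / n_perm
        expected = n_nod * all_track.counts / n_all
        sd = np.sqrt(np.maximum(sq / n_perm - mean ** 2, 1e-12))
        se = sd / np.sqrt(n_perm)
        assert (np.abs(mean - expected) <= 3 * se + 1e-9).mean() > 0.98


class TestKsTwoSample:
    def test_identical_samples_have_zero_distance(self):
        d, p = dn.ks_two_sample([1.0, 2.0, 2.0, 5.0], [1.0, 2.0, 2.0, 5.0])
        assert d == 0.0
        assert p == 1.0

    def test_disjoint_supports_have_distance_one(self):
        d, _ = dn.ks_two_sample([1, 2], [3, 4])
        assert d == 1.0

    def test_interleaved_example(self):
        d, _ = dn.ks_two_sample([1, 3], [2, 4])
        assert d == 0.5

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            dn.ks_two_sample([], [1.0])

    @given(
        st.lists(st.integers(0, 9), min_size=1, max_size=8),
        st.lists(st.integers(0, 9), min_size=1, max_size=8),
    )
    def test_statistic_matches_ecdf_grid_oracle(self, a, b):
        d, _ = dn.ks_two_sample(a, b)
        assert abs(d - _ks_oracle(a, b)) < 1e-12

    def test_exact_pvalue_matches_scipy_on_tie_free_samples(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            m, n = rng.integers(2, 9), rng.integers(2, 11)
            a, b = rng.normal(size=m), rng.normal(size=n)
            d, p = dn.ks_two_sample(a, b, method="exact")
            ref = stats.ks_2samp(a, b, method="exact")
            assert abs(d - ref.statistic) < 1e-12
            assert abs(p - ref.pvalue) < 1e-9

    def test_asymptotic_pvalue_uses_effective_size(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=120), rng.normal(size=200)
        d, p = dn.ks_two_sample(a, b, method="asymptotic")
        en = 120 * 200 / 320
        assert p == pytest.approx(stats.kstwobign.sf(np.sqrt(en) * d), abs=1e-12)


def _ks_oracle(a, b):
    """O(n^2) ECDF comparison on the full value grid."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    grid = np.unique(np.concatenate([a, b]))
    fa = np.array([(a <= v).mean() for v in grid])
    fb = np.array([(b <= v).mean() for v in grid])
    return float(np.max(np.abs(fa - fb)))


class TestCallEnrichment:
    def _null_chromosome(self, seed, n_all=200, n_nod=12, L=40 * MB):
        rng = np.random.default_rng(seed)
        pts = np.sort(rng.integers(0, L, size=n_all))
        nod = rng.choice(pts, size=n_nod, replace=False)
        cfg = dn.WindowConfig(5 * MB, int(0.5 * MB))
        track = dn.window_counts(nod, L, cfg)
        return dn.zscore_normalize(track), pts, n_nod

    def test_seed_determinism(self):
        track, pts, n = self._null_chromosome(1)
        r1 = dn.call_enrichment(track, pts, n, n_permutations=100, rng_seed=9)
        r2 = dn.call_enrichment(track, pts, n, n_permutations=100, rng_seed=9)
        assert (r1.ks_D, r1.p_value, r1.enriched) == (r2.ks_D, r2.p_value, r2.enriched)

    def test_alpha_zero_never_enriches(self):
        track, pts, n = self._null_chromosome(2)
        r = dn.call_enrichment(track, pts, n, n_permutations=100,
                               alpha=0.0, rng_seed=3)
        assert not r.enriched

    def test_degenerate_track_is_never_enriched(self):
        track, pts, _ = self._null_chromosome(3, n_nod=12)
        track.counts = np.zeros_like(track.counts)
        dn.zscore_normalize(track)
        r = dn.call_enrichment(track, pts, 0, n_permutations=50, rng_seed=1)
        assert r.degenerate and not r.enriched

    def test_planted_cluster_is_called_enriched(self):
        """10 of 12 nodulation genes inside one 2-Mb span of a 40-Mb chromosome."""
        rng = np.random.default_rng(11)
        L = 40 * MB
        bg = np.sort(rng.integers(0, L, size=188))
        cluster = rng.integers(20 * MB, 22 * MB, size=10)
        loose = rng.integers(0, L, size=2)
        pts = np.sort(np.concatenate([bg, cluster, loose]))
        nod = np.concatenate([cluster, loose])
        cfg = dn.WindowConfig(5 * MB, int(0.5 * MB))
        track = dn.zscore_normalize(dn.window_counts(nod, L, cfg))
        r = dn.call_enrichment(track, pts, nod.size,
                               n_permutations=1000, rng_seed=13)
        assert r.enriched
        assert r.p_value < 0.01

    def test_asymptotic_mode_reports_ks_tail(self):
        track, pts, n = self._null_chromosome(4)
        r = dn.call_enrichment(track, pts, n, n_permutations=100,
                               rng_seed=5, p_method="asymptotic")
        assert 0.0 <= r.p_value <= 1.0
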
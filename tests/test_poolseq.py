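"""Pooled sliding-window diversity: subsampling, indel masking, per-window
pi / Tajima's D and the genome summary."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from miridscreen.formats_io import SiteCounts
from miridscreen.poolseq_diversity import (
    PoolParams,
    WindowStat,
    _site_pi,
    genome_summary,
    mask_indels,
    subsample_to_coverage,
    tajima_constants,
    window_stats,
)
from miridscreen.synthetic_data import PoolSpec, simulate_pool_pileup


def site(pos, ref="A", a=0, c=0, g=0, t=0, indel=0, scaffold="s"):
    return SiteCounts(scaffold, pos, ref, a, c, g, t, indel)


class TestSitePi:
    def test_half_and_half_site(self):
        """pi_hat = 1 - (C(5,2)+C(5,2))/C(10,2) = 1 - 20/45."""
        value = float(_site_pi(np.array([[5, 0, 0, 5]]))[0])
        assert value == pytest.approx(0.5556, abs=5e-5)

    def test_monomorphic_site_is_zero(self):
        assert float(_site_pi(np.array([[12, 0, 0, 0]]))[0]) == 0.0

    @given(st.lists(st.integers(0, 30), min_size=4, max_size=4))
    def test_bounded_and_label_invariant(self, counts):
        """0 <= pi_hat <= 1 and invariant under allele relabeling."""
        arr = np.array([counts])
        v = float(_site_pi(arr)[0])
        assert 0.0 <= v <= 1.0
        shuffled = np.array([counts[::-1]])
        assert float(_site_pi(shuffled)[0]) == pytest.approx(v)


class TestSubsampling:
    def test_identity_when_target_equals_current(self):
        sites = [site(i, a=20) for i in range(50)]
        out, achieved = subsample_to_coverage(sites, 20, seed=1)
        assert achieved == pytest.approx(20)
        assert all(s.a == 20 for s in out)

    def test_target_above_current_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            subsample_to_coverage([site(0, a=10)], 20, seed=1)

    def test_mean_coverage_near_target(self):
        rng = np.random.default_rng(7)
        sites = [site(i, a=int(x)) for i, x in
                 enumerate(rng.poisson(20, size=3000))]
        out, achieved = subsample_to_coverage(sites, 10, seed=2)
        assert achieved == pytest.approx(10, rel=0.05)

    def test_allele_proportions_preserved_on_average(self):
        sites = [site(i, a=30, t=30) for i in range(500)]
        out, _ = subsample_to_coverage(sites, 30, seed=3)
        a = sum(s.a for s in out)
        t = sum(s.t for s in out)
        assert abs(a - t) / (a + t) < 0.05

    def test_deterministic_under_seed(self):
        sites = [site(i, a=10, c=10) for i in range(100)]
        out1, _ = subsample_to_coverage(sites, 10, seed=9)
        out2, _ = subsample_to_coverage(sites, 10, seed=9)
        assert out1 == out2


class TestMasking:
    def test_flank_around_single_indel(self):
        sites = [site(p, a=10, indel=(1 if p == 100 else 0))
                 for p in range(90, 111)]
        out = mask_indels(sites, indel_flank=5)
        masked = {s.pos for s in out if s.masked}
        assert masked == set(range(95, 106))

    def test_no_indels_nothing_masked(self):
        out = mask_indels([site(p, a=10) for p in range(20)], 5)
        assert not any(s.masked for s in out)

    def test_close_indels_merge_into_one_run(self):
        sites = [site(p, a=10, indel=(1 if p in (100, 104) else 0))
                 for p in range(90, 121)]
        out = mask_indels(sites, indel_flank=5)
        masked = sorted(s.pos for s in out if s.masked)
        assert masked == list(range(95, 110))  # single merged run

    def test_masking_more_sites_never_raises_covered_fraction(self):
        sites = [site(p, a=10, indel=(1 if p % 40 == 0 else 0))
                 for p in range(400)]
        params = PoolParams(pool_n=10, window=100, step=100,
                            min_covered_fraction=0.01)
        frac_unmasked = [w.covered_fraction for w in window_stats(sites, params)]
        masked = mask_indels(sites, 5)
        frac_masked = [w.covered_fraction for w in window_stats(masked, params)]
        assert all(b <= a for a, b in zip(frac_unmasked, frac_masked))


class TestWindowStats:
    def test_monomorphic_window(self):
        sites = [site(p, a=10) for p in range(100)]
        params = PoolParams(pool_n=10, window=100, step=100,
                            min_covered_fraction=0.5)
        (w,) = window_stats(sites, params, scaffold_lengths={"s": 100})
        assert (w.n_snps, w.pi) == (0, 0.0)
        assert math.isnan(w.tajimas_d)
        assert w.sufficient

    def test_insufficient_window_carries_no_values(self):
        sites = [site(p, a=10) for p in range(59)]
        params = PoolParams(pool_n=10, window=100, step=100,
                            min_covered_fraction=0.60)
        (w,) = window_stats(sites, params, scaffold_lengths={"s": 100})
        assert not w.sufficient
        assert math.isnan(w.pi) and math.isnan(w.tajimas_d)
        assert w.covered_fraction == pytest.approx(0.59)

    def test_coverage_bounds_exclude_sites(self):
        sites = [site(0, a=3), site(1, a=10), site(2, a=500)]
        params = PoolParams(pool_n=10, window=10, step=10,
                            min_cov=4, max_cov=400, min_covered_fraction=0.01)
        (w,) = window_stats(sites, params, scaffold_lengths={"s": 10})
        assert w.n_covered == 1

    def test_min_count_filter_controls_snp_calls(self):
        sites = [site(0, a=19, t=1), site(1, a=15, t=5)]
        lengths = {"s": 2}
        base = dict(pool_n=10, window=2, step=2, min_covered_fraction=0.01)
        (w2,) = window_stats(sites, PoolParams(min_count=2, **base), lengths)
        (w1,) = window_stats(sites, PoolParams(min_count=1, **base), lengths)
        assert (w2.n_snps, w1.n_snps) == (1, 2)

    def test_trailing_remainder_is_a_partial_window(self):
        sites = [site(p, a=10) for p in range(250)]
        params = PoolParams(pool_n=10, window=100, step=100,
                            min_covered_fraction=0.5)
        ws = window_stats(sites, params, scaffold_lengths={"s": 250})
        assert [(w.start, w.end, w.partial) for w in ws] == [
            (0, 100, False), (100, 200, False), (200, 250, True)
        ]

    def test_tajima_constants_reference_values(self):
        """Constants for n = 40 against direct evaluation of the formulas."""
        c = tajima_constants(40)
        assert c.a1 == pytest.approx(sum(1 / i for i in range(1, 40)))
        assert c.b1 == pytest.approx(41 / 117)
        assert c.e1 == pytest.approx(c.c1 / c.a1)
        assert c.e2 == pytest.approx(c.c2 / (c.a1**2 + c.a2))

    def test_d_sign_matches_hand_computation(self):
        """One window, one SNP: D = (pi_sum - S/a1)/sqrt(e1*S)."""
        sites = [site(0, a=5, t=5)] + [site(p, a=10) for p in range(1, 10)]
        params = PoolParams(pool_n=10, window=10, step=10, min_count=2,
                            min_covered_fraction=0.5)
        (w,) = window_stats(sites, params, scaffold_lengths={"s": 10})
        c = tajima_constants(10)
        pi_sum = 1 - 40 / 90
        expected = (pi_sum - 1 / c.a1) / math.sqrt(c.e1)
        assert w.tajimas_d == pytest.approx(expected)
        assert w.pi == pytest.approx(pi_sum / 10)


class TestGenomeSummary:
    def make_window(self, pi, d, scaffold="s", sufficient=True):
        return WindowStat(scaffold, 0, 100, 0.9, 90, 1, pi, d, sufficient)

    def test_means_over_sufficient_windows(self):
        gpi, gd, table = genome_summary(
            [self.make_window(0.01, -0.1), self.make_window(0.02, 0.1)]
        )
        assert gpi == pytest.approx(0.015)
        assert gd == pytest.approx(0.0)

    def test_single_window_summary_is_that_window(self):
        gpi, gd, _ = genome_summary([self.make_window(0.004, -0.2)])
        assert (gpi, gd) == (pytest.approx(0.004), pytest.approx(-0.2))

    def test_nan_d_windows_excluded_from_d_mean(self):
        gpi, gd, _ = genome_summary(
            [self.make_window(0.0, math.nan), self.make_window(0.01, -0.3)]
        )
        assert gpi == pytest.approx(0.005)
        assert gd == pytest.approx(-0.3)

    def test_no_sufficient_windows_rejected(self):
        with pytest.raises(ValueError):
            genome_summary([self.make_window(0.01, 0.0, sufficient=False)])

    def test_per_scaffold_table_mirrors_window_counts(self):
        ws = [self.make_window(0.01, 0.0, "a"),
              self.make_window(0.02, 0.1, "a"),
              self.make_window(0.03, -0.1, "b", sufficient=False)]
        _gpi, _gd, table = genome_summary(ws)
        row_a = table[table.scaffold == "a"].iloc[0]
        row_b = table[table.scaffold == "b"].iloc[0]
        assert (row_a.windows, row_a.sufficient_windows) == (2, 2)
        assert (row_b.windows, row_b.sufficient_windows) == (1, 0)


class TestEndToEndSimulation:
    def test_windows_on_simulated_pileup_are_reasonable(self):
        spec = PoolSpec(theta=0.01, pool_n=40, coverage=50, length=50_000)
        pileup, _ = simulate_pool_pileup(spec, seed=5)
        params = PoolParams(min_count=1)
        ws = window_stats(pileup, params)
        assert all(w.sufficient for w in ws if not w.partial)
        pis = [w.pi for w in ws if w.sufficient]
        assert 0.005 < float(np.mean(pis)) < 0.015
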
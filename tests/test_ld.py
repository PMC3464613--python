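import itertools
from math import comb

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_dataset
from dartpop import ld
from dartpop.ld import (
    DecayCurve,
    adjacent_ld,
    contingency_table,
    fisher_exact,
    fisher_exact_many,
    fit_decay,
    ld_extent,
    ld_threshold,
    ld_window_profile,
    pairwise_r2,
    partition_pairs,
    r2_matrix,
    unlinked_r2_values,
)

NA = float("nan")


def r2_oracle(x, y):
    """Brute-force D^2/(p q) from haplotype counts on pairwise-complete lines."""
    ok = ~np.isnan(x) & ~np.isnan(y)
    xs, ys = x[ok], y[ok]
    n = len(xs)
    if n < 2:
        return NA
    px, py = xs.mean(), ys.mean()
    if px in (0.0, 1.0) or py in (0.0, 1.0):
        return NA
    p11 = np.mean(xs * ys)
    d = p11 - px * py
    return d * d / (px * (1 - px) * py * (1 - py))


def fisher_oracle(table):
    """Two-sided Fisher p by summing probabilities over all tables with the
    observed margins (exact hypergeometric enumeration)."""
    a, b = table[0]
    c, d = table[1]
    n, r, s = a + b + c + d, a + b, a + c
    if n == 0 or r in (0, n) or s in (0, n):
        return 1.0

    def prob(k):
        return comb(r, k) * comb(n - r, s - k) / comb(n, s)

    p_obs = prob(a)
    return sum(prob(k) for k in range(max(0, r + s - n), min(r, s) + 1)
               if prob(k) <= p_obs * (1 + 1e-9))


class TestPairwiseR2:
    def test_identical_polymorphic_markers(self):
        x = np.array([0, 0, 1, 1], dtype=float)
        assert pairwise_r2(x, x) == pytest.approx(1.0)

    def test_independent_balanced_markers(self):
        x = np.array([0, 0, 1, 1], dtype=float)
        y = np.array([0, 1, 0, 1], dtype=float)
        assert pairwise_r2(x, y) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # D = 2/6 - 1/4 = 1/12; r^2 = D^2 / (1/2 * 1/2 * 1/2 * 1/2) = 1/9
        x = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        y = np.array([0, 0, 1, 1, 1, 0], dtype=float)
        assert r2_oracle(x, y) == pytest.approx(1 / 9)
        assert pairwise_r2(x, y) == pytest.approx(1 / 9)

    def test_monomorphic_on_shared_lines_is_nan(self):
        x = np.array([1, 1, 1, NA], dtype=float)
        y = np.array([0, 1, 0, 1], dtype=float)
        assert np.isnan(pairwise_r2(x, y))

    def test_symmetry_and_allele_flip_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(0, 2, 12).astype(float)
            y = rng.integers(0, 2, 12).astype(float)
            v = pairwise_r2(x, y)
            if np.isnan(v):
                continue
            assert pairwise_r2(y, x) == pytest.approx(v)
            assert pairwise_r2(1 - x, y) == pytest.approx(v)
            assert pairwise_r2(x, 1 - y) == pytest.approx(v)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_oracle_with_missing_data(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, 10).astype(float)
        y = rng.integers(0, 2, 10).astype(float)
        x[rng.random(10) < 0.2] = NA
        y[rng.random(10) < 0.2] = NA
        v, o = pairwise_r2(x, y), r2_oracle(x, y)
        if np.isnan(o):
            assert np.isnan(v)
        else:
            assert v == pytest.approx(o, abs=1e-12)

    def test_min_lines_per_allele_filter(self):
        x = np.array([1, 0, 0, 0, 0, 0], dtype=float)
        y = np.array([1, 0, 0, 0, 0, 0], dtype=float)
        assert pairwise_r2(x, y) == pytest.approx(1.0)
        assert np.isnan(pairwise_r2(x, y, min_lines_per_allele=2))

    def test_matrix_agrees_with_scalar(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 2, (15, 8)).astype(float)
        calls[rng.random(calls.shape) < 0.15] = NA
        mat = r2_matrix(calls)
        for i in range(8):
            for j in range(i + 1, 8):
                v = pairwise_r2(calls[:, i], calls[:, j])
                if np.isnan(v):
                    assert np.isnan(mat[i, j])
                else:
                    assert mat[i, j] == pytest.approx(v, abs=1e-12)


class TestFisherExact:
    def test_diagonal_table(self):
        # x == y with two lines per call: table [[2,0],[0,2]] -> p = 1/3
        x = np.array([0, 0, 1, 1], dtype=float)
        assert contingency_table(x, x).tolist() == [[2, 0], [0, 2]]
        assert fisher_exact(x, x) == pytest.approx(1 / 3)

    def test_balanced_independent_table(self):
        x = np.array([0, 0, 1, 1], dtype=float)
        y = np.array([0, 1, 0, 1], dtype=float)
        assert contingency_table(x, y).tolist() == [[1, 1], [1, 1]]
        assert fisher_exact(x, y) == pytest.approx(1.0)

    def test_degenerate_margin_flagged(self):
        x = np.array([1, 1, 1, 1], dtype=float)
        y = np.array([0, 1, 0, 1], dtype=float)
        p, degenerate = fisher_exact(x, y, return_flag=True)
        assert p == 1.0 and degenerate

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_margin_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, 8).astype(float)
        y = rng.integers(0, 2, 8).astype(float)
        table = contingency_table(x, y)
        assert fisher_exact(x, y) == pytest.approx(fisher_oracle(table), abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            t = rng.integers(0, 6, (2, 2))
            expected = scipy.stats.fisher_exact(t, alternative="two-sided")[1]
            assert _p_from_table(t) == pytest.approx(expected, abs=1e-10)

    def test_vectorised_matches_scalar(self):
        rng = np.random.default_rng(3)
        tables = rng.integers(0, 8, (200, 4))
        many = fisher_exact_many(tables)
        for k in range(200):
            assert many[k] == pytest.approx(_p_from_table(tables[k].reshape(2, 2)), abs=1e-12)


def _p_from_table(table):
    from dartpop.ld import _fisher_table
    return _fisher_table(np.asarray(table))[0]


class TestPartitionPairs:
    def test_enumeration_example(self):
        # groups of sizes 2, 3, 4: unlinked = 2*3 + 2*4 + 3*4 = 26
        groups = ["1A"] * 2 + ["1B"] * 3 + ["1R"] * 4
        ds = make_dataset(np.tile([[0], [1]], (1, 9)), groups=groups,
                          positions=[0, 1] + [0, 1, 2] + [0, 1, 2, 3])
        part = partition_pairs(ds)
        assert part.n_unlinked == 26
        assert part.n_linked == 1 + 3 + 6

    def test_single_group_no_unlinked_pairs(self):
        ds = make_dataset(np.array([[0, 1, 0], [1, 0, 1]], dtype=float))
        part = partition_pairs(ds)
        assert part.n_unlinked == 0
        with pytest.raises(ValueError, match="threshold"):
            ld.decay_by_genome(ds)

    def test_distances_and_colocated_pairs(self):
        ds = make_dataset(np.array([[0, 1, 0], [1, 0, 1]], dtype=float),
                          positions=[2.0, 2.0, 7.0])
        part = partition_pairs(ds)
        assert sorted(part.linked_distance.tolist()) == [0.0, 5.0, 5.0]

    def test_unlinked_values_exclude_same_group(self):
        rng = np.random.default_rng(4)
        calls = rng.integers(0, 2, (20, 6)).astype(float)
        ds = make_dataset(calls, groups=["1A"] * 3 + ["1B"] * 3,
                          positions=[0, 1, 2, 0, 1, 2])
        vals = unlinked_r2_values(r2_matrix(ds.calls), ds.linkage_group)
        assert len(vals) <= 9


class TestLdThreshold:
    def test_type7_quantile_arithmetic(self):
        vals = np.arange(1, 101) * 0.01
        assert ld_threshold(vals) == pytest.approx(0.9505)

    def test_constant_values(self):
        assert ld_threshold(np.full(30, 0.2)) == pytest.approx(0.2)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match=">=20"):
            ld_threshold(np.full(10, 0.2))

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_adding_low_values_never_raises_threshold(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.random(50)
        t = ld_threshold(vals)
        low = rng.uniform(0, t, 20)
        assert ld_threshold(np.concatenate([vals, low])) <= t + 1e-12


class TestFitDecay:
    def test_constant_r2_gives_constant_curve(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 50, 100)
        curve = fit_decay(d, np.full(100, 0.3))
        np.testing.assert_allclose(curve.values, 0.3, atol=1e-9)
        assert curve.close_ld == pytest.approx(0.3)

    def test_linear_data_reproduced_in_interior(self):
        d = np.linspace(0, 10, 60)
        y = 0.8 - 0.05 * d
        curve = fit_decay(d, y, span=0.4, delta=0.0)
        interior = (curve.grid > 2) & (curve.grid < 8)
        np.testing.assert_allclose(curve.values[interior],
                                   0.8 - 0.05 * curve.grid[interior], atol=1e-6)

    def test_monotone_trend_on_synthetic_panel(self, small_dataset):
        analysis = ld.decay_by_genome(small_dataset, genomes=(), pooled_key="ABR")
        curve = analysis.curves["ABR"]
        assert curve.values[0] > curve.values[-1]
        assert curve.close_ld > np.interp(curve.grid[-1], curve.grid, curve.values)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match=">=10"):
            fit_decay(np.arange(5, dtype=float), np.full(5, 0.5))

    def test_tiny_span_rejected(self):
        d = np.linspace(0, 10, 20)
        with pytest.raises(ValueError, match="span"):
            fit_decay(d, np.full(20, 0.5), span=0.01)

    def test_values_clipped_to_unit_interval(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(0, 10, 50)
        y = rng.random(50)
        curve = fit_decay(d, y)
        assert (curve.values >= 0).all() and (curve.values <= 1).all()


class TestLdExtent:
    def _curve(self, grid, values):
        return DecayCurve(np.asarray(grid, float), np.asarray(values, float),
                          0.33, grid[0], values[0], NA)

    def test_never_below_threshold_censored(self):
        extent, censored = ld_extent(self._curve([0, 10, 20], [0.3, 0.3, 0.3]), 0.12)
        assert censored and extent == 20.0

    def test_starts_below_threshold_extent_zero(self):
        extent, censored = ld_extent(self._curve([0, 10, 20], [0.05, 0.05, 0.05]), 0.12)
        assert (extent, censored) == (0.0, False)

    def test_linear_interpolation_of_crossing(self):
        extent, censored = ld_extent(self._curve([10.0, 20.0], [0.3, 0.1]), 0.2)
        assert extent == pytest.approx(15.0)
        assert not censored

    def test_curve_annotated_in_place(self):
        c = self._curve([0.0, 10.0], [0.3, 0.05])
        ld_extent(c, 0.12)
        assert c.threshold == 0.12
        assert c.extent_cM is not None


class TestAdjacentLd:
    def test_duplicated_adjacent_column_r2_one(self):
        col = np.array([0, 1, 0, 1, 1], dtype=float)
        calls = np.column_stack([col, col, 1 - col])
        mean, pairs = adjacent_ld(make_dataset(calls))
        assert np.allclose(pairs["r2"], 1.0)
        assert mean == pytest.approx(1.0)

    def test_independent_markers_near_zero(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 2, (1000, 2)).astype(float)
        mean, _ = adjacent_ld(make_dataset(calls))
        assert mean < 0.01

    def test_no_adjacent_pairs_rejected(self):
        ds = make_dataset(np.array([[0, 1], [1, 0]], dtype=float), groups=["1A", "1B"])
        with pytest.raises(ValueError):
            adjacent_ld(ds)

    def test_lines_mask_restricts_population(self, small_dataset):
        habit = np.asarray(small_dataset.habit, dtype=object)
        m_spring, _ = adjacent_ld(small_dataset, lines_mask=habit == "spring")
        m_winter, _ = adjacent_ld(small_dataset, lines_mask=habit == "winter")
        # spring subpopulation has fewer founders -> stronger adjacent LD
        assert m_spring > m_winter


class TestLdWindowProfile:
    def test_constant_adjacent_r2_flat_profile(self):
        col = np.array([0, 1, 0, 1, 1], dtype=float)
        calls = np.column_stack([col] * 4)
        prof = ld_window_profile(make_dataset(calls), window_cM=10, n_positions=20)
        grid, vals = prof["1A"]
        np.testing.assert_allclose(vals[~np.isnan(vals)], 1.0)

    def test_single_pair_profile(self):
        col = np.array([0, 1, 0, 1], dtype=float)
        calls = np.column_stack([col, col])
        prof = ld_window_profile(make_dataset(calls, positions=[0.0, 4.0]),
                                 window_cM=2, n_positions=9)
        grid, vals = prof["1A"]
        covered = np.abs(grid - 2.0) <= 1.0
        np.testing.assert_allclose(vals[covered], 1.0)
        assert np.isnan(vals[~covered]).all()

    def test_high_ld_block_peak_inside_block(self):
        rng = np.random.default_rng(7)
        n, m = 80, 30
        calls = rng.integers(0, 2, (n, m)).astype(float)
        block_template = rng.integers(0, 2, n).astype(float)
        for j in range(10, 15):  # planted high-LD block at 10..14 cM
            noise = rng.random(n) < 0.05
            calls[:, j] = np.where(noise, 1 - block_template, block_template)
        prof = ld_window_profile(make_dataset(calls), window_cM=4, n_positions=30)
        grid, vals = prof["1A"]
        assert 10 <= grid[np.nanargmax(vals)] <= 14


class TestDecayByGenome:
    def test_population_analysis_structure(self, small_dataset):
        analysis = ld.decay_by_genome(small_dataset)
        assert set(analysis.curves) <= {"A", "B", "R", "ABR"}
        assert "ABR" in analysis.curves
        assert 0.0 <= analysis.threshold <= 1.0
        for curve in analysis.curves.values():
            assert curve.extent_cM is not None

    def test_extent_monotone_in_relatedness(self):
        """LD extent increases as founder count decreases (more relatedness)."""
        from dartpop import marker_io, synthetic_data
        extents = []
        for founders in (32, 16, 8, 4, 2):
            cfg = synthetic_data.SimConfig(
                seed=123, n_lines=(40, 40), founders=(founders, founders),
                share_founders=True, generations=4.0,
                linkage_groups=[synthetic_data.LinkageGroupSpec(n, 100.0, 70)
                                for n in ("1A", "1B")],
            )
            gm, gmap, _ = synthetic_data.simulate(cfg)
            ds = marker_io.align(gm, gmap)
            analysis = ld.decay_by_genome(ds, genomes=(), pooled_key="ABR")
            extents.append(analysis.curves["ABR"].extent_cM)
        rho = scipy.stats.spearmanr(np.arange(5), extents).statistic
        assert rho > 0.8
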
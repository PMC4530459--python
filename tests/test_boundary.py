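"""Corrected-t boundary estimation: statistic, scanners, permutation test."""

import numpy as np
import pytest

import paraconv as pc
from paraconv.boundary import T_SENTINEL, _t_profile
from paraconv.errors import ConfigurationError, CoordinateError


def naive_t(delta, start, end):
    """Independent oracle: direct Welch formula on explicit slices."""
    delta = np.asarray(delta, float)
    inside = delta[start - 1 : end]
    outside = np.concatenate([delta[: start - 1], delta[end:]])
    num = inside.mean() - outside.mean()
    den = np.sqrt(
        inside.var(ddof=1) / inside.size + outside.var(ddof=1) / outside.size
    )
    if den == 0:
        return 0.0 if num == 0 else np.sign(num) * T_SENTINEL
    return num / den


class TestTStatistic:
    def test_matches_direct_formula_on_worked_example(self):
        delta = [4, 2, 3, 0, 1, -1, 0, 1, -1, 0]
        t = pc.t_statistic(delta, (1, 3))
        assert t == pytest.approx(naive_t(delta, 1, 3), abs=1e-12)
        # frozen value from the independent formula (scipy Welch ttest agrees)
        assert t == pytest.approx(4.5825756950, abs=1e-9)

    def test_antisymmetry(self, rng):
        delta = rng.normal(size=60)
        assert pc.t_statistic(-delta, (11, 30)) == pytest.approx(
            -pc.t_statistic(delta, (11, 30)), abs=1e-12
        )

    def test_constant_vector_gives_zero(self):
        assert pc.t_statistic([2.0] * 30, (5, 10)) == 0.0

    def test_constant_sides_with_different_means_hit_sentinel(self):
        delta = [1.0] * 10 + [0.0] * 20
        assert pc.t_statistic(delta, (1, 10)) == T_SENTINEL

    def test_degenerate_partition_rejected(self):
        with pytest.raises(ConfigurationError):
            pc.t_statistic([1.0, 2.0, 3.0], (1, 2))
        with pytest.raises(CoordinateError):
            pc.t_statistic([1.0, 2.0, 3.0], (0, 2))


class TestPrefixSumScanner:
    def test_equals_naive_scan_on_random_vectors(self, rng):
        for _ in range(100):
            L = int(rng.integers(20, 90))
            width = int(rng.integers(3, L - 3))
            delta = rng.normal(size=L)
            fast = _t_profile(delta[None, :], width)[0]
            slow = np.array(
                [naive_t(delta, s, s + width - 1) for s in range(1, L - width + 2)]
            )
            np.testing.assert_allclose(fast, slow, atol=1e-10)

    def test_handles_constant_input(self):
        t = _t_profile(np.zeros((1, 50)), 10)[0]
        assert np.all(t == 0.0)


class TestScanBoundaries:
    def test_noiseless_block_recovered_exactly(self):
        delta = np.zeros(200)
        delta[60:100] = 7.0  # width-40 block at columns 61-100
        res = pc.scan_boundaries(
            delta, min_width=30, max_width=50, n_perm=100, seed=1
        )
        assert res.best_window == (61, 100, 40)
        assert res.p_value == 0.0

    def test_observed_t_independent_of_permutation_seed(self, rng):
        delta = rng.normal(size=120)
        a = pc.scan_boundaries(delta, 20, 40, n_perm=50, seed=1)
        b = pc.scan_boundaries(delta, 20, 40, n_perm=50, seed=2)
        for ra, rb in zip(a.per_width, b.per_width):
            assert (ra.width, ra.start, ra.end, ra.t) == (
                rb.width,
                rb.start,
                rb.end,
                rb.t,
            )

    def test_replay_identical_with_same_seed(self, rng):
        delta = rng.normal(size=100)
        a = pc.scan_boundaries(delta, 10, 25, n_perm=80, seed=5)
        b = pc.scan_boundaries(delta, 10, 25, n_perm=80, seed=5)
        assert [r.p for r in a.per_width] == [r.p for r in b.per_width]

    def test_batched_permutations_match_single_batch(self, rng):
        delta = rng.normal(size=80)
        a = pc.scan_boundaries(delta, 10, 15, n_perm=64, seed=9, perm_batch=64)
        b = pc.scan_boundaries(delta, 10, 15, n_perm=64, seed=9, perm_batch=16)
        assert [r.p for r in a.per_width] == [r.p for r in b.per_width]

    def test_null_input_reports_no_window(self, rng):
        # exchangeable noise: with a handful of permutations the observed
        # max-t is essentially never in the top 1%
        delta = rng.normal(size=150)
        res = pc.scan_boundaries(delta, 30, 35, n_perm=400, level=0.0005, seed=3)
        assert res.best_window is None
        assert len(res.per_width) == 6
        assert all(0.0 <= r.p <= 1.0 for r in res.per_width)

    def test_invalid_widths_rejected(self):
        with pytest.raises(ConfigurationError):
            pc.scan_boundaries(np.zeros(50), min_width=2, max_width=10)
        with pytest.raises(ConfigurationError):
            pc.scan_boundaries(np.zeros(50), min_width=10, max_width=50)


@pytest.fixture(scope="module")
def table(three_pair_trees, wag_model):
    tree_global, _ = three_pair_trees
    aln = pc.simulate_alignment(tree_global, wag_model, 80, seed=91)
    return aln, pc.build_site_table(
        aln, {"t1_A", "t1_B"}, wag_model, seed=4, estimate_alpha=False
    )


class TestSiteTable:
    def test_delta_sums_to_full_alignment_contrast(self, table, wag_model):
        aln, tab = table
        lnl_global = pc.log_likelihood(aln, tab.tree_global, wag_model)
        lnl_conv = pc.log_likelihood(aln, tab.tree_conv, wag_model)
        assert tab.delta_site.sum() == pytest.approx(lnl_conv - lnl_global, abs=1e-6)

    def test_trees_respect_their_hypotheses(self, table):
        _, tab = table
        assert tab.tree_conv.is_monophyletic({"t1_A", "t1_B"})

    def test_vacuous_constraint_gives_nonnegative_total(self, wag_model):
        _, tree_conv = pc.template_trees(3, seed=95)
        aln = pc.simulate_alignment(tree_conv, wag_model, 80, seed=96)
        tab = pc.build_site_table(
            aln, {"t1_A", "t1_B"}, wag_model, seed=5, estimate_alpha=False
        )
        assert tab.delta_site.sum() >= -1e-4
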
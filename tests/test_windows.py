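"""Window geometry and the sliding-window delta-lnL profile."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import paraconv as pc
from paraconv.errors import CoordinateError, IdentifierError


class TestGeometry:
    def test_default_layout_over_230_columns(self):
        wins = pc.make_windows(230, width=50, step=10)
        assert len(wins) == 19
        assert (wins[0].start, wins[0].end) == (1, 50)
        assert wins[10].start == 101   # window 11
        assert wins[11].start == 111   # window 12
        assert wins[14].end == 190     # window 15
        assert (wins[-1].start, wins[-1].end) == (181, 230)

    def test_tract_covered_by_windows_12_to_15(self):
        wins = pc.make_windows(230, 50, 10)
        covered = set()
        for w in wins[11:15]:
            covered.update(range(w.start, w.end + 1))
        assert covered == set(range(111, 191))

    @settings(max_examples=50, deadline=None)
    @given(
        length=st.integers(10, 500),
        width=st.integers(1, 120),
        step=st.integers(1, 60),
    )
    def test_count_formula(self, length, width, step):
        if width > length:
            with pytest.raises(CoordinateError):
                pc.make_windows(length, width, step)
            return
        wins = pc.make_windows(length, width, step)
        assert len(wins) == (length - width) // step + 1
        assert all(w.end <= length for w in wins)
        assert all(w.start == (w.index - 1) * step + 1 for w in wins)

    def test_invalid_step_rejected(self):
        with pytest.raises(CoordinateError):
            pc.make_windows(100, 10, 0)


@pytest.fixture(scope="module")
def small_scan(three_pair_trees, wag_model):
    tree_global, _ = three_pair_trees
    aln = pc.simulate_alignment(tree_global, wag_model, 90, seed=61)
    result = pc.delta_lnl_profile(
        aln,
        {"t1_A", "t1_B"},
        wag_model,
        width=45,
        step=45,
        seed=3,
        estimate_alpha=False,
        n_starts_global=1,
    )
    return aln, result


class TestProfile:
    def test_vacuous_constraint_gives_nonnegative_deltas(self, wag_model):
        # data simulated on a tree that already unites the pair: the
        # constrained optimum coincides with the unconstrained one
        _, tree_conv = pc.template_trees(3, seed=71)
        aln = pc.simulate_alignment(tree_conv, wag_model, 80, seed=72)
        res = pc.delta_lnl_profile(
            aln,
            {"t1_A", "t1_B"},
            wag_model,
            width=40,
            step=40,
            seed=1,
            tree_global=tree_conv,
            estimate_alpha=False,
        )
        assert all(d >= -1e-6 for d in res.deltas)

    def test_profile_invariant_to_row_order(self, small_scan, wag_model):
        aln, result = small_scan
        rng = np.random.default_rng(0)
        perm = pc.select_rows(aln, tuple(np.array(aln.ids)[rng.permutation(6)]))
        result_perm = pc.delta_lnl_profile(
            perm,
            {"t1_A", "t1_B"},
            wag_model,
            width=45,
            step=45,
            seed=3,
            estimate_alpha=False,
            n_starts_global=1,
        )
        np.testing.assert_allclose(result_perm.deltas, result.deltas, atol=1e-6)

    def test_scores_carry_window_trees(self, small_scan):
        _, result = small_scan
        for score in result.scores:
            assert score.conv_tree.is_monophyletic({"t1_A", "t1_B"})
            assert np.isfinite(score.delta)

    def test_missing_clade_id_rejected(self, six_taxon_alignment, wag_model):
        with pytest.raises(IdentifierError):
            pc.delta_lnl_profile(
                six_taxon_alignment, {"t1_A", "nope"}, wag_model, seed=0
            )

    def test_windows_disjoint_from_tract_show_no_signal_on_average(self, wag_model):
        # 3-pair scenario with a tract at columns 61-120: the first window
        # (columns 1-40) never touches the tract, so its mean delta over
        # seeds stays non-positive
        deltas = []
        for seed in range(10):
            sc = pc.ConversionScenario(
                n_pairs=3, total_length=120, tract=(61, 120),
                model_name="WAG", seed=seed,
            )
            aln, _ = pc.generate(sc)
            res = pc.delta_lnl_profile(
                aln, sc.conv_clade, wag_model, width=40, step=40,
                seed=seed, estimate_alpha=False, n_starts_global=1,
            )
            deltas.append(res.deltas[0])
        assert np.mean(deltas) <= 0.0

    def test_gap_only_window_warns_but_scores(self, three_pair_trees, wag_model):
        tree_global, _ = three_pair_trees
        aln = pc.simulate_alignment(tree_global, wag_model, 60, seed=63)
        rows = list(aln.rows)
        rows[0] = "-" * 30 + rows[0][30:]
        gappy = pc.Alignment(ids=aln.ids, rows=tuple(rows), alphabet="AA")
        with pytest.warns(UserWarning, match="only gaps"):
            res = pc.delta_lnl_profile(
                gappy,
                {"t1_A", "t1_B"},
                wag_model,
                width=30,
                step=30,
                seed=2,
                tree_global=tree_global,
                estimate_alpha=False,
            )
        assert len(res.scores) == 2
        assert all(np.isfinite(d) for d in res.deltas)
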
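"""Synthetic conversion scenarios and n-pair alignment assembly."""

import numpy as np
import pytest

import paraconv as pc
from paraconv.errors import ConfigurationError, IdentifierError
from paraconv.scenarios import pair_labels


class TestTemplateTrees:
    def test_leaf_counts(self):
        for n in (3, 6, 8):
            tg, tc = pc.template_trees(n, seed=1)
            assert tg.n_leaves() == 2 * n
            assert tc.n_leaves() == 2 * n

    def test_conversion_tree_unites_pair_and_global_does_not(self):
        tg, tc = pc.template_trees(6, conv_pair=2, seed=3)
        clade = set(pair_labels(2))
        assert tc.is_monophyletic(clade)
        assert not tg.is_monophyletic(clade)

    def test_trees_differ_only_by_recipient_relocation(self):
        tg, tc = pc.template_trees(6, seed=4)
        # removing the recipient leaf from both trees leaves one topology
        tg2, tc2 = tg.copy(), tc.copy()
        tg2.detach_leaf("t1_A")
        tc2.detach_leaf("t1_A")
        assert tg2.same_topology(tc2)

    def test_deterministic_branch_lengths(self):
        a, _ = pc.template_trees(6, seed=9)
        b, _ = pc.template_trees(6, seed=9)
        assert a.newick() == b.newick()

    def test_direction_swaps_recipient(self):
        _, tc_b2a = pc.template_trees(4, direction="donor_B_to_A", seed=2)
        _, tc_a2b = pc.template_trees(4, direction="donor_A_to_B", seed=2)
        # recipient sits inside the donor's clade
        b_side = {f"t{i}_B" for i in range(1, 5)}
        a_side = {f"t{i}_A" for i in range(1, 5)}
        assert tc_b2a.is_monophyletic(b_side | {"t1_A"})
        assert tc_a2b.is_monophyletic(a_side | {"t1_B"})

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ConfigurationError):
            pc.template_trees(2, seed=0)


class TestGenerate:
    def test_default_shape(self):
        aln, truth = pc.generate(pc.ConversionScenario(seed=5))
        assert aln.n_seqs == 12
        assert aln.length == 230
        assert truth["tract"] == [111, 190]
        assert sorted(truth["conv_clade"]) == ["t1_A", "t1_B"]

    def test_deterministic(self):
        a, _ = pc.generate(pc.ConversionScenario(seed=6))
        b, _ = pc.generate(pc.ConversionScenario(seed=6))
        assert a.rows == b.rows

    def test_no_tract_uses_global_tree_only(self):
        sc = pc.ConversionScenario(tract=None, total_length=50, n_pairs=3, seed=7)
        aln, truth = pc.generate(sc)
        assert aln.length == 50
        assert truth["tract"] is None

    def test_invalid_tract_rejected(self):
        with pytest.raises(ConfigurationError):
            pc.ConversionScenario(tract=(100, 300), total_length=230)

    def test_whole_alignment_tract_recovers_conversion_topology(self):
        # with every column on the conversion tree, the unconstrained ML
        # tree itself unites the converted pair (6-taxon exhaustive search)
        sc = pc.ConversionScenario(
            n_pairs=3, total_length=300, tract=(1, 300), seed=8
        )
        aln, _ = pc.generate(sc)
        res = pc.search_ml_tree(aln, sc.model, method="exhaustive")
        assert res.tree.is_monophyletic(sc.conv_clade)

    def test_tract_columns_carry_conversion_signal(self, lg_model):
        # mean per-site support for the conversion topology is higher
        # inside the tract than outside, across several seeds
        wins = 0
        for seed in range(6):
            sc = pc.ConversionScenario(seed=seed)
            aln, _ = pc.generate(sc)
            model = sc.model
            lnl_conv = pc.site_log_likelihoods(aln, sc.tree_conv, model)
            lnl_glob = pc.site_log_likelihoods(aln, sc.tree_global, model)
            delta = lnl_conv - lnl_glob
            inside = delta[110:190].mean()
            outside = np.concatenate([delta[:110], delta[190:]]).mean()
            wins += inside > outside
        assert wins >= 5


@pytest.fixture(scope="module")
def pool():
    sc = pc.ConversionScenario(n_pairs=6, seed=11)
    aln, _ = pc.generate(sc)
    return aln


class TestNPairAssembly:
    def test_six_pair_design_has_12_rows(self, pool):
        focal = pair_labels(1)
        background = [pair_labels(i) for i in range(2, 7)]
        sub = pc.make_npair_alignment(pool, focal, background)
        assert sub.n_seqs == 12
        assert sub.length == pool.length

    def test_four_pair_design_has_8_rows(self, pool):
        sub = pc.make_npair_alignment(
            pool, pair_labels(1), [pair_labels(i) for i in (2, 3, 4)]
        )
        assert sub.n_seqs == 8

    def test_focal_pair_comes_first(self, pool):
        sub = pc.make_npair_alignment(pool, pair_labels(2), [pair_labels(5)])
        assert sub.ids[:2] == pair_labels(2)

    def test_missing_ids_rejected(self, pool):
        with pytest.raises(IdentifierError):
            pc.make_npair_alignment(pool, ("t1_A", "t9_B"), [])

    def test_overlapping_pairs_rejected(self, pool):
        with pytest.raises(IdentifierError):
            pc.make_npair_alignment(pool, pair_labels(1), [pair_labels(1)])
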
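"""Likelihood engine: pruning vs exhaustive enumeration, closed forms,
branch-length and gamma-shape optimization."""

import itertools

import numpy as np
import pytest

import paraconv as pc
from paraconv.errors import AlphabetError, TreeError
from paraconv.io import ALPHABETS, Alignment
from paraconv.search import enumerate_topologies
from paraconv.trees import tree_from_newick


def brute_force_site_lnl(aln, tree, model):
    """Independent oracle: sum the joint probability over every assignment
    of states to internal nodes, mixing rate categories with weight 1/k."""
    idx = {c: i for i, c in enumerate(model.states)}
    post = tree.postorder()
    internals = [n for n in post if not n.is_leaf]
    edges = tree.edges()
    n = model.n_states
    out = []
    for col in range(aln.length):
        leaf_state = {
            node.label: idx.get(aln.row(node.label)[col], -1)
            for node in tree.leaves()
        }
        total = 0.0
        for rate in model.rates:
            P = {id(e): model.transition_matrix(e.length, rate) for e in edges}
            for assign in itertools.product(range(n), repeat=len(internals)):
                state = {id(nd): a for nd, a in zip(internals, assign)}
                for leaf in tree.leaves():
                    state[id(leaf)] = leaf_state[leaf.label]
                prob = model.pi[state[id(tree.root)]]
                for e in edges:
                    s_child = state[id(e)]
                    if s_child == -1:  # missing: marginalize by summing P row
                        continue
                    prob *= P[id(e)][state[id(e.parent)], s_child]
                total += prob
        out.append(np.log(total / model.n_categories))
    return np.array(out)


class TestPruningOracle:
    @pytest.mark.parametrize("n_leaves", [4, 5])
    def test_matches_enumeration_on_all_small_topologies(self, n_leaves, gtr_model):
        labels = list("abcde"[:n_leaves])
        rng = np.random.default_rng(n_leaves)
        chars = np.array(list(ALPHABETS["NT"]))
        rows = tuple("".join(chars[rng.integers(0, 4, 20)]) for _ in labels)
        aln = Alignment(ids=tuple(labels), rows=rows, alphabet="NT")
        count = 0
        for topo in enumerate_topologies(labels):
            for e in topo.edges():
                e.length = float(rng.uniform(0.05, 0.8))
            mine = pc.site_log_likelihoods(aln, topo, gtr_model)
            oracle = brute_force_site_lnl(aln, topo, gtr_model)
            assert np.abs(mine - oracle).max() < 1e-8
            count += 1
        assert count == {4: 3, 5: 15}[n_leaves]

    def test_matches_enumeration_amino_acid(self, quartet_tree, lg_model):
        aln = pc.simulate_alignment(quartet_tree, lg_model, 10, seed=4)
        mine = pc.site_log_likelihoods(aln, quartet_tree, lg_model)
        oracle = brute_force_site_lnl(aln, quartet_tree, lg_model)
        assert np.abs(mine - oracle).max() < 1e-8

    def test_with_missing_data(self, quartet_tree, gtr_model):
        aln = Alignment(
            ids=("a", "b", "c", "d"),
            rows=("ACG-N", "ACGTA", "AC-TA", "ACGTA"),
            alphabet="NT",
        )
        mine = pc.site_log_likelihoods(aln, quartet_tree, gtr_model)
        oracle = brute_force_site_lnl(aln, quartet_tree, gtr_model)
        assert np.abs(mine - oracle).max() < 1e-8


class TestConventions:
    def test_zero_distance_constant_column_gives_log_pi(self, lg_model):
        tree = tree_from_newick("(a:1e-8,b:1e-8,c:1e-8);")
        aln = Alignment(ids=("a", "b", "c"), rows=("A", "A", "A"), alphabet="AA")
        lnl = pc.site_log_likelihoods(aln, tree, lg_model)[0]
        i = lg_model.states.index("A")
        assert lnl == pytest.approx(np.log(lg_model.pi[i]), abs=1e-6)

    def test_all_gap_column_contributes_zero(self, quartet_tree, lg_model):
        aln = Alignment(
            ids=("a", "b", "c", "d"), rows=("-", "-", "-", "-"), alphabet="AA"
        )
        assert pc.site_log_likelihoods(aln, quartet_tree, lg_model)[0] == pytest.approx(
            0.0, abs=1e-12
        )

    def test_rerooting_invariance(self, gtr_model):
        aln_tree = tree_from_newick("((a:0.2,b:0.5):0.1,(c:0.3,e:0.2):0.15,d:0.7);")
        aln = pc.simulate_alignment(aln_tree, gtr_model, 30, seed=9)
        # same unrooted tree written from a different vantage point
        rerooted = tree_from_newick(
            "((c:0.3,e:0.2):0.15,d:0.7,(a:0.2,b:0.5):0.1);"
        )
        l1 = pc.log_likelihood(aln, aln_tree, gtr_model)
        l2 = pc.log_likelihood(aln, rerooted, gtr_model)
        assert l1 == pytest.approx(l2, abs=1e-9)

    def test_leaf_order_invariance(self, quartet_tree, gtr_model, quartet_alignment):
        perm = pc.select_rows(quartet_alignment, ("d", "b", "a", "c"))
        assert pc.log_likelihood(perm, quartet_tree, gtr_model) == pytest.approx(
            pc.log_likelihood(quartet_alignment, quartet_tree, gtr_model), abs=1e-9
        )

    def test_label_mismatch_rejected(self, quartet_tree, gtr_model):
        aln = Alignment(ids=("a", "b", "c", "x"), rows=("A",) * 4, alphabet="NT")
        with pytest.raises(TreeError):
            pc.log_likelihood(aln, quartet_tree, gtr_model)

    def test_alphabet_model_mismatch_rejected(self, quartet_tree, lg_model):
        aln = Alignment(ids=("a", "b", "c", "d"), rows=("A",) * 4, alphabet="NT")
        with pytest.raises(AlphabetError):
            pc.log_likelihood(aln, quartet_tree, lg_model)


class TestBranchOptimization:
    def test_identical_sequences_hit_lower_bound(self, cf2_model):
        tree = tree_from_newick("(x:0.3,y:0.3);")
        aln = Alignment(ids=("x", "y"), rows=("RYRY" * 10,) * 2, alphabet="RY")
        opt, _ = pc.optimize_branch_lengths(tree, aln, cf2_model, tol=1e-9)
        assert sum(e.length for e in opt.edges()) <= 3e-8

    def test_cf2_two_taxon_mle_closed_form(self, cf2_model):
        # mismatch fraction d < 1/2 gives t-hat = -ln(1 - 2d) / 2
        d = 0.22
        n = 200
        k = int(d * n)
        aln = Alignment(
            ids=("x", "y"),
            rows=("R" * n, "Y" * k + "R" * (n - k)),
            alphabet="RY",
        )
        tree = tree_from_newick("(x:0.1,y:0.1);")
        opt, _ = pc.optimize_branch_lengths(tree, aln, cf2_model, tol=1e-9)
        total = sum(e.length for e in opt.edges())
        assert total == pytest.approx(-0.5 * np.log(1 - 2 * d), abs=1e-4)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_optimization_never_decreases_lnl(self, seed, gtr_model, quartet_tree):
        aln = pc.simulate_alignment(quartet_tree, gtr_model, 60, seed=seed)
        start = quartet_tree.copy()
        rng = np.random.default_rng(seed)
        for e in start.edges():
            e.length = float(rng.uniform(0.01, 1.5))
        before = pc.log_likelihood(aln, start, gtr_model)
        _, after = pc.optimize_branch_lengths(start, aln, gtr_model)
        assert after >= before - 1e-9


@pytest.fixture(scope="module")
def shape_data():
    tree, _ = pc.template_trees(6, seed=21)
    model = pc.build_model("LG", gamma_shape=0.7)
    aln = pc.simulate_alignment(tree, model, 2000, seed=22)
    return tree, aln


class TestGammaShape:
    def test_recovers_simulated_shape(self, shape_data, lg_model):
        tree, aln = shape_data
        res = pc.estimate_gamma_shape(tree, aln, lg_model)
        assert 0.5 <= res.alpha <= 0.95
        assert res.converged

    def test_profile_local_optimality(self, shape_data, lg_model):
        tree, aln = shape_data
        res = pc.estimate_gamma_shape(tree, aln, lg_model)
        for alpha in (res.alpha - 0.1, res.alpha + 0.1):
            _, lnl = pc.optimize_branch_lengths(
                res.tree, aln, lg_model.with_alpha(alpha)
            )
            assert res.log_likelihood >= lnl - 5e-3

    def test_agrees_with_grid_oracle(self, six_taxon_alignment, three_pair_trees):
        tree = three_pair_trees[0]
        model = pc.build_model("WAG")
        res = pc.estimate_gamma_shape(tree, six_taxon_alignment, model)
        grid = np.arange(
            max(0.1, res.alpha - 0.3), res.alpha + 0.3 + 1e-9, 0.05
        )
        scores = []
        for alpha in grid:
            _, lnl = pc.optimize_branch_lengths(
                tree, six_taxon_alignment, model.with_alpha(alpha)
            )
            scores.append(lnl)
        best = grid[int(np.argmax(scores))]
        assert abs(best - res.alpha) <= 0.0501
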
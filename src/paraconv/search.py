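"""Maximum-likelihood tree search, optionally under a monophyly constraint.

Two engines share one contract:

* exhaustive — enumerate every unrooted binary topology (feasible up to the
  default limit of 6 leaves, 105 topologies), drop those violating the
  constraint, optimize branch lengths on each and keep the best;
* heuristic — stepwise addition in a seed-determined random leaf order,
  scoring each candidate attachment edge from the current tree's edge
  partials, followed by nearest-neighbour-interchange (NNI) hill climbing
  that accepts strictly improving moves until none remains.

Candidate placements or rearrangements that would break the constraint are
rejected outright, so every intermediate tree keeps the constrained leaves
(those already placed) monophyletic.  Ties break toward the first candidate
in a deterministic traversal, making results reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import substream
from .errors import TreeError
from .io import Alignment
from .likelihood import PruningContext, TreeLikelihood
from .models import SubstModel
from .trees import Node, Tree


@dataclass(frozen=True)
class Constraint:
    """A leaf set required to be monophyletic in the unrooted result."""

    clade: frozenset

    def __init__(self, clade):
        object.__setattr__(self, "clade", frozenset(clade))

    def validate(self, labels) -> None:
        labels = set(labels)
        if len(self.clade) < 2:
            raise TreeError("constraint clade needs at least two leaves")
        if not self.clade < labels:
            raise TreeError(
                "constraint clade must be a proper subset of the leaf set"
            )

    def satisfied_by(self, tree: Tree) -> bool:
        """Monophyly of the clade members present in the (possibly partial)
        tree; vacuous while fewer than two members are placed."""
        present = self.clade & set(tree.leaf_labels())
        if len(present) < 2:
            return True
        if len(present) >= tree.n_leaves() - 1:
            return True
        return tree.is_monophyletic(present)


@dataclass
class SearchResult:
    tree: Tree
    log_likelihood: float
    n_evaluated: int


# ------------------------------------------------------------- enumeration


def _star3(labels, length: float = 0.1) -> Tree:
    root = Node()
    for lab in labels:
        root.add_child(Node(label=lab, length=length))
    return Tree(root)


def enumerate_topologies(labels, length: float = 0.1):
    """Yield every unrooted binary topology over ``labels`` exactly once,
    in a deterministic order, with all branch lengths set to ``length``."""
    labels = list(labels)
    if len(labels) < 3:
        raise TreeError("need at least three leaves to enumerate topologies")

    def _grow(tree: Tree, remaining):
        if not remaining:
            yield tree.copy()
            return
        lab, rest = remaining[0], remaining[1:]
        for k in range(len(tree.edges())):
            work = tree.copy()
            work.attach_leaf(work.edges()[k], lab, pendant=length, frac=0.5)
            # reset the split edge so every topology starts from equal lengths
            for node in work.edges():
                node.length = length
            yield from _grow(work, rest)

    yield from _grow(_star3(labels[:3], length), labels[3:])


_TOPOLOGY_CACHE: dict = {}


def _admissible_topologies(ids, constraint):
    """Constraint-satisfying topologies over ``ids``, freshly copied.

    The enumeration+filter result is cached per (leaf set, clade): the
    sliding-window scan requests the same set once per window."""
    key = (tuple(ids), None if constraint is None else constraint.clade)
    if key not in _TOPOLOGY_CACHE:
        _TOPOLOGY_CACHE[key] = [
            topo
            for topo in enumerate_topologies(list(ids))
            if constraint is None or constraint.satisfied_by(topo)
        ]
        while len(_TOPOLOGY_CACHE) > 8:
            _TOPOLOGY_CACHE.pop(next(iter(_TOPOLOGY_CACHE)))
    return [t.copy() for t in _TOPOLOGY_CACHE[key]]


def count_topologies(n_leaves: int) -> int:
    """(2n-5)!! unrooted binary topologies on n leaves."""
    out = 1
    for m in range(3, 2 * n_leaves - 4, 2):
        out *= m
    return out


# ---------------------------------------------------------------- heuristic


def _copy_with_map(tree: Tree):
    mapping = {}

    def _copy(node):
        new = Node(node.label, node.length)
        mapping[id(node)] = new
        for c in node.children:
            new.add_child(_copy(c))
        return new

    return Tree(_copy(tree.root)), mapping


def _insertion_valid(tree: Tree, edge_child, label: str, constraint) -> bool:
    if constraint is None:
        return True
    work, mapping = _copy_with_map(tree)
    work.attach_leaf(mapping[id(edge_child)], label, pendant=0.1)
    return constraint.satisfied_by(work)


def _stepwise_tree(
    ctx: PruningContext, order, constraint, pendant: float = 0.1
) -> tuple[Tree, int]:
    order = list(order)
    tree = _star3(order[:3], length=pendant)
    n_eval = 0
    for label in order[3:]:
        engine = TreeLikelihood(_subcontext(ctx, tree.leaf_labels()), tree)
        engine.up_pass()
        tip = engine.ctx.tip_partials_full[label]
        best_lnl, best_edge = -np.inf, None
        for edge in engine.tree.edges():
            if not _insertion_valid(engine.tree, edge, label, constraint):
                continue
            lnl = engine.attach_score(edge, tip, pendant)
            n_eval += 1
            if lnl > best_lnl:
                best_lnl, best_edge = lnl, edge
        if best_edge is None:
            raise TreeError(
                f"no constraint-compatible attachment for leaf {label!r}"
            )
        engine.tree.attach_leaf(best_edge, label, pendant=pendant)
        tree = engine.tree
    return tree, n_eval


class _SubContext:
    """View of a PruningContext restricted to a subset of sequences, sharing
    the parent's pattern layout (used while the stepwise tree is partial)."""

    def __init__(self, parent: PruningContext, ids):
        self.aln = Alignment(
            ids=tuple(ids),
            rows=tuple(parent.aln.row(i) for i in ids),
            alphabet=parent.aln.alphabet,
        )
        self.model = parent.model
        self.pattern_index = parent.pattern_index
        self.weights = parent.weights
        self.n_patterns = parent.n_patterns
        self.tip_partials = {i: parent.tip_partials[i] for i in ids}
        self.tip_partials_full = parent.tip_partials


def _subcontext(ctx: PruningContext, ids):
    return _SubContext(ctx, ids)


def _apply_nni(tree: Tree, edge, a_idx: int):
    """Copy ``tree`` and swap child ``a_idx`` of ``edge`` with the edge's
    first sibling subtree; returns (candidate, central edge in candidate)."""
    u = edge.parent
    partner = next(c for c in u.children if c is not edge)
    cand, mapping = _copy_with_map(tree)
    v_c = mapping[id(edge)]
    u_c = v_c.parent
    a_c = mapping[id(edge.children[a_idx])]
    p_c = mapping[id(partner)]
    v_c.children[v_c.children.index(a_c)] = p_c
    u_c.children[u_c.children.index(p_c)] = a_c
    a_c.parent, p_c.parent = u_c, v_c
    return cand, v_c


def _heuristic_search(
    ctx: PruningContext, order, constraint
) -> tuple[Tree, float, int]:
    tree, n_eval = _stepwise_tree(ctx, order, constraint)
    engine = TreeLikelihood(ctx, tree)
    lnl = engine.optimize_lengths()
    n_accepted = 0
    while n_accepted < 200:  # safety cap; hill climbing converges far sooner
        moved = False
        improved = True
        while improved:
            improved = False
            for edge in engine.tree.internal_edges():
                # both rearrangements scored locally from stored partials;
                # a candidate tree is built only when a move is accepted
                for a_idx, cand_lnl, t_opt in engine.nni_edge_scores(edge):
                    n_eval += 1
                    if cand_lnl <= lnl + 1e-9:
                        continue
                    cand, central = _apply_nni(engine.tree, edge, a_idx)
                    if constraint is not None and not constraint.satisfied_by(cand):
                        continue
                    central.length = t_opt
                    engine = TreeLikelihood(ctx, cand, copy=False)
                    lnl = engine.log_likelihood()
                    n_accepted += 1
                    improved = moved = True
                    break
                if improved:
                    break
        # Newton-precision refit between sweeps; full polish once no move
        # is left (the final iteration always runs with moved == False)
        lnl = engine.optimize_lengths(polish=moved is False)
        if not moved:
            break
    return engine.tree, lnl, n_eval


# ------------------------------------------------------------------ driver


def search_ml_tree(
    aln: Alignment,
    model: SubstModel,
    constraint: Constraint | None = None,
    seed: int = 0,
    n_starts: int = 1,
    method: str = "auto",
    exhaustive_limit: int = 6,
) -> SearchResult:
    """Search for the ML tree of ``aln`` under ``model``.

    ``method`` is ``"exhaustive"``, ``"heuristic"`` or ``"auto"`` (exhaustive
    when the leaf count is at most ``exhaustive_limit``).  With several
    starts the heuristic reruns stepwise addition under fresh seed-derived
    leaf orders and returns the best tree found; ties keep the first.
    """
    if aln.n_seqs < 4:
        raise TreeError("tree search needs at least four sequences")
    if constraint is not None:
        constraint.validate(aln.ids)
    ctx = PruningContext(aln, model)
    if method == "auto":
        method = "exhaustive" if aln.n_seqs <= exhaustive_limit else "heuristic"
    if method == "exhaustive":
        # coarse pass over every admissible topology, Newton-precision
        # fits for the three leaders, and a final polish of the winner only
        coarse = []
        for topo in _admissible_topologies(aln.ids, constraint):
            engine = TreeLikelihood(ctx, topo, copy=False)
            coarse.append((engine.optimize_lengths(tol=0.3, max_sweeps=4), engine))
        if not coarse:
            raise TreeError("constraint excluded every topology")
        coarse.sort(key=lambda pair: -pair[0])  # stable: ties keep order
        finalists = []
        for _, engine in coarse[:3]:
            finalists.append((engine.optimize_lengths(polish=False), engine))
        # polish every finalist within the Newton-precision slack of the
        # leader, so near-ties are decided at full precision
        lead = max(lnl for lnl, _ in finalists)
        best = None
        for lnl, engine in finalists:
            if lnl >= lead - 0.5:
                lnl = engine.optimize_lengths()
            if best is None or lnl > best[0] + 1e-12:
                best = (lnl, engine.tree)
        return SearchResult(best[1], best[0], len(coarse))
    if method != "heuristic":
        raise ValueError(f"unknown search method {method!r}")
    best = None
    total_eval = 0
    for s in range(n_starts):
        rng = substream(seed, "search-start", s)
        order = [aln.ids[i] for i in rng.permutation(aln.n_seqs)]
        tree, lnl, n_eval = _heuristic_search(ctx, order, constraint)
        total_eval += n_eval
        if best is None or lnl > best[0] + 1e-12:
            best = (lnl, tree)
    return SearchResult(best[1], best[0], total_eval)
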
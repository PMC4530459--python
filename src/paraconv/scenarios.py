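"""Synthetic gene-conversion scenarios with full ground truth.

A scenario mimics the study design used for real paralog pairs: n pairs of
paralogous sequences (clade A and clade B, e.g. RF1 and RF2) separated by a
deep duplication branch, with one pair affected by conversion of a
contiguous tract.  Columns outside the tract evolve on the no-conversion
tree (two mirrored paralog clades); columns inside the tract evolve on the
conversion tree, in which the recipient copy is relocated to sit as sister
of its paralog partner.  Defaults reproduce the study conditions: 6 pairs,
230 columns, tract at columns 111-190, LG model with gamma shape 0.7.

Leaf labels are ``t{i}_A`` / ``t{i}_B`` for pair i; the converted pair is
pair ``conv_pair``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import child_seed, substream
from .errors import ConfigurationError, IdentifierError, TreeError
from .io import Alignment, concat, select_rows
from .models import SubstModel, build_model
from .simulate import simulate_alignment
from .trees import BL_MIN, Node, Tree

DONOR_B_TO_A = "donor_B_to_A"
DONOR_A_TO_B = "donor_A_to_B"


def pair_labels(i: int) -> tuple[str, str]:
    return f"t{i}_A", f"t{i}_B"


def template_trees(
    n_pairs: int = 6,
    conv_pair: int = 1,
    direction: str = DONOR_B_TO_A,
    depth_scale: float = 0.3,
    seed: int = 0,
) -> tuple[Tree, Tree]:
    """Build the no-conversion and conversion template trees.

    The no-conversion tree joins two mirrored ladder-shaped paralog clades
    by a long inter-paralog branch of length ``2 * depth_scale``; every
    intra-clade branch length is an independent exponential draw with mean
    ``depth_scale``.  The conversion tree relocates the recipient leaf
    (the A copy when the donor is B, and vice versa) to be the sister of
    its partner leaf inside the other clade.
    """
    if n_pairs < 3:
        raise ConfigurationError("need at least three pairs")
    if direction not in (DONOR_B_TO_A, DONOR_A_TO_B):
        raise ConfigurationError(f"unknown direction {direction!r}")
    if not 1 <= conv_pair <= n_pairs:
        raise ConfigurationError("conv_pair outside the pair range")
    rng = substream(seed, "template-trees")

    def _ladder(suffix: str) -> Node:
        # ((t1, t2), t3), t4 ... ladder; lengths drawn as we build
        top = Node()
        tips = [Node(label=f"t{i}_{suffix}", length=float(rng.exponential(depth_scale)))
                for i in range(1, n_pairs + 1)]
        node = Node(length=float(rng.exponential(depth_scale)))
        node.add_child(tips[0])
        node.add_child(tips[1])
        for tip in tips[2:-1]:
            upper = Node(length=float(rng.exponential(depth_scale)))
            upper.add_child(node)
            upper.add_child(tip)
            node = upper
        top.add_child(node)
        top.add_child(tips[-1])
        return top

    clade_a = _ladder("A")
    clade_b = _ladder("B")
    root = clade_a  # degree-3 root: the two basal A branches + inter-paralog
    clade_b.length = 2.0 * depth_scale
    root.add_child(clade_b)
    tree_global = Tree(root)
    for node in tree_global.edges():
        node.length = max(node.length, BL_MIN)

    recipient, partner = pair_labels(conv_pair)
    if direction == DONOR_A_TO_B:
        recipient, partner = partner, recipient
    tree_conv = tree_global.copy()
    tree_conv.detach_leaf(recipient)
    partner_node = tree_conv.find_leaf(partner)
    tree_conv.attach_leaf(
        partner_node,
        recipient,
        pendant=float(rng.exponential(depth_scale / 2.0)) + BL_MIN,
    )
    return tree_global, tree_conv


@dataclass
class ConversionScenario:
    """Ground-truth description of one synthetic conversion dataset."""

    n_pairs: int = 6
    total_length: int = 230
    tract: tuple[int, int] | None = (111, 190)
    direction: str = DONOR_B_TO_A
    conv_pair: int = 1
    model_name: str = "LG"
    gamma_shape: float = 0.7
    depth_scale: float = 0.3
    seed: int = 0
    tree_global: Tree | None = None
    tree_conv: Tree | None = None

    def __post_init__(self):
        if self.tract is not None:
            s, e = self.tract
            if not 1 <= s <= e <= self.total_length:
                raise ConfigurationError(
                    f"tract {self.tract} outside [1, {self.total_length}]"
                )
        if self.tree_global is None or self.tree_conv is None:
            self.tree_global, self.tree_conv = template_trees(
                self.n_pairs,
                self.conv_pair,
                self.direction,
                self.depth_scale,
                seed=child_seed(self.seed, "trees"),
            )
        clade = frozenset(pair_labels(self.conv_pair))
        if not self.tree_conv.is_monophyletic(clade):
            raise TreeError("conversion tree must unite the converted pair")
        if self.tree_global.is_monophyletic(clade):
            raise TreeError("no-conversion tree must not unite the converted pair")

    @property
    def conv_clade(self) -> frozenset:
        return frozenset(pair_labels(self.conv_pair))

    @property
    def model(self) -> SubstModel:
        return build_model(self.model_name, gamma_shape=self.gamma_shape)

    def truth_record(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "total_length": self.total_length,
            "tract": list(self.tract) if self.tract else None,
            "direction": self.direction,
            "conv_pair": self.conv_pair,
            "conv_clade": sorted(self.conv_clade),
            "model": f"{self.model_name}+G(alpha={self.gamma_shape:g})",
            "depth_scale": self.depth_scale,
            "seed": self.seed,
            "tree_global": self.tree_global.newick(),
            "tree_conv": self.tree_conv.newick(),
        }


def generate(scenario: ConversionScenario) -> tuple[Alignment, dict]:
    """Simulate the scenario's alignment and return it with the truth record.

    Segments are simulated independently (per-region seed substreams) and
    concatenated in coordinate order, so the tract columns carry the
    conversion topology and all other columns the no-conversion topology.
    """
    model = scenario.model
    seed = scenario.seed
    pieces = []
    if scenario.tract is None:
        pieces.append(
            simulate_alignment(
                scenario.tree_global, model, scenario.total_length,
                rng=substream(seed, "segment", 0),
            )
        )
    else:
        start, end = scenario.tract
        if start > 1:
            pieces.append(
                simulate_alignment(
                    scenario.tree_global, model, start - 1,
                    rng=substream(seed, "segment", 0),
                )
            )
        pieces.append(
            simulate_alignment(
                scenario.tree_conv, model, end - start + 1,
                rng=substream(seed, "segment", 1),
            )
        )
        if end < scenario.total_length:
            pieces.append(
                simulate_alignment(
                    scenario.tree_global, model, scenario.total_length - end,
                    rng=substream(seed, "segment", 2),
                )
            )
    aln = pieces[0]
    for piece in pieces[1:]:
        aln = concat(aln, piece)
    order = [lab for i in range(1, scenario.n_pairs + 1) for lab in pair_labels(i)]
    return select_rows(aln, order), scenario.truth_record()


def make_npair_alignment(
    pool_aln: Alignment, focal_pair, background_pairs
) -> Alignment:
    """Assemble an n-pair alignment: one focal pair plus background pairs.

    ``focal_pair`` is a pair of ids; ``background_pairs`` an iterable of id
    pairs.  Rows are restricted (columns unchanged), focal pair first."""
    ids = list(focal_pair)
    for pair in background_pairs:
        ids.extend(pair)
    if len(set(ids)) != len(ids):
        raise IdentifierError("pairs overlap")
    return select_rows(pool_aln, ids)
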
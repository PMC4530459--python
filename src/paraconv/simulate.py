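"""Sequence simulation along a tree under a reversible model with
discrete-gamma rate variation.

Each site draws one of the k rate categories uniformly and independently
(mirroring the equal-weight category mixture assumed by the likelihood),
the root state comes from the stationary frequencies, and states evolve
down the tree through the model's transition matrices.  The same seed
always reproduces the same alignment.
"""

from __future__ import annotations

import numpy as np

from ._rng import substream
from .errors import ModelError
from .io import ALPHABETS, Alignment
from .models import SubstModel
from .trees import Tree


def _alphabet_name(model: SubstModel) -> str:
    for name, states in ALPHABETS.items():
        if states == model.states:
            return name
    raise ModelError("model state set matches no known alphabet")


def simulate_alignment(
    tree: Tree,
    model: SubstModel,
    length: int,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> Alignment:
    """Simulate ``length`` columns over ``tree``; rows follow the tree's
    leaf order.  Pass ``rng`` to draw from an existing stream instead of the
    seed-derived one."""
    if length < 1:
        raise ValueError("length must be at least 1")
    if rng is None:
        rng = substream(seed, "simulate")
    n = model.n_states
    k = model.n_categories
    cats = rng.integers(0, k, size=length)
    states: dict[int, np.ndarray] = {}
    root = tree.root
    states[id(root)] = rng.choice(n, size=length, p=model.pi)
    for node in tree.preorder():
        if node.parent is None:
            continue
        cum = model.category_matrices(node.length).cumsum(axis=2)
        rows = cum[cats, states[id(node.parent)], :]  # (length, n)
        u = rng.random(length)
        states[id(node)] = np.minimum((u[:, None] > rows).sum(axis=1), n - 1)
    alphabet = _alphabet_name(model)
    chars = np.array(list(model.states))
    ids, rows_out = [], []
    for leaf in tree.leaves():
        ids.append(leaf.label)
        rows_out.append("".join(chars[states[id(leaf)]]))
    return Alignment(ids=tuple(ids), rows=tuple(rows_out), alphabet=alphabet)
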
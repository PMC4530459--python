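"""Sliding-window log-likelihood contrast between two topological hypotheses.

For each window the data are scored under (a) the globally inferred
unconstrained ML topology ("global tree", branch lengths re-optimized per
window) and (b) the per-window ML tree constrained so that the putatively
converted sequence pair is monophyletic ("conversion tree").  The per-window
statistic is delta = lnL_conv - lnL_global: positive values flag windows
whose phylogenetic signal prefers the conversion topology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from ._rng import child_seed
from .errors import CoordinateError, IdentifierError, TreeError
from .io import Alignment, slice_columns
from .likelihood import estimate_gamma_shape, optimize_branch_lengths
from .models import SubstModel
from .search import Constraint, SearchResult, search_ml_tree
from .trees import Tree


@dataclass(frozen=True)
class Window:
    """1-based inclusive column window; start = (index-1)*step + 1."""

    index: int
    start: int
    end: int

    @property
    def width(self) -> int:
        return self.end - self.start + 1


def make_windows(length: int, width: int = 50, step: int = 10) -> list[Window]:
    """Full windows advanced by ``step``; trailing columns that cannot fill
    a window are dropped.  Defaults give 19 windows over 230 columns, with
    window 12 starting at column 111 and window 15 ending at 190."""
    if not 1 <= width <= length:
        raise CoordinateError(f"width {width} outside [1, {length}]")
    if step < 1:
        raise CoordinateError("step must be at least 1")
    out = []
    index, start = 1, 1
    while start + width - 1 <= length:
        out.append(Window(index=index, start=start, end=start + width - 1))
        index += 1
        start += step
    return out


@dataclass
class WindowScore:
    window: Window
    lnl_global: float
    lnl_conv: float
    conv_tree: Tree

    @property
    def delta(self) -> float:
        return self.lnl_conv - self.lnl_global


@dataclass
class ScanResult:
    scores: list[WindowScore]
    tree_global: Tree
    alpha: float
    model_name: str
    width: int
    step: int
    conv_clade: frozenset

    @property
    def deltas(self):
        return [s.delta for s in self.scores]


@dataclass
class GlobalFit:
    """Unconstrained full-alignment ML tree with its fitted gamma shape."""

    tree: Tree
    alpha: float
    log_likelihood: float
    search: SearchResult = field(repr=False, default=None)


def fit_global_tree(
    aln: Alignment,
    model: SubstModel,
    seed: int = 0,
    n_starts: int = 5,
    method: str = "auto",
    estimate_alpha: bool = True,
) -> GlobalFit:
    """Infer the unconstrained ML tree on the full alignment and, if asked,
    the ML gamma shape on that topology (branch lengths refit jointly)."""
    res = search_ml_tree(
        aln, model, constraint=None, seed=child_seed(seed, "global"),
        n_starts=n_starts, method=method,
    )
    if estimate_alpha:
        shape = estimate_gamma_shape(res.tree, aln, model)
        return GlobalFit(shape.tree, shape.alpha, shape.log_likelihood, res)
    return GlobalFit(res.tree, model.gamma_shape, res.log_likelihood, res)


def delta_lnl_profile(
    aln: Alignment,
    conv_clade,
    model: SubstModel,
    width: int = 50,
    step: int = 10,
    seed: int = 0,
    tree_global: Tree | None = None,
    estimate_alpha: bool = True,
    n_starts_global: int = 5,
    n_starts_window: int = 3,
    method: str = "auto",
) -> ScanResult:
    """Sliding-window delta-lnL profile for a candidate converted pair.

    One global tree (the unconstrained full-alignment ML tree, or
    ``tree_global`` if supplied) is enforced on every window with branch
    lengths re-optimized per window, while the constrained tree is searched
    afresh within each window.  The gamma shape is estimated once on the
    full alignment and held fixed across windows and both hypotheses —
    short windows cannot support a stable shape estimate of their own.
    """
    conv_clade = frozenset(conv_clade)
    missing = conv_clade - set(aln.ids)
    if missing:
        raise IdentifierError(f"conversion clade ids not in alignment: {sorted(missing)}")
    if aln.n_seqs < 4:
        raise TreeError("need at least four sequences")
    constraint = Constraint(conv_clade)
    if tree_global is None:
        fit = fit_global_tree(
            aln, model, seed=seed, n_starts=n_starts_global,
            method=method, estimate_alpha=estimate_alpha,
        )
        tree_global, alpha = fit.tree, fit.alpha
    else:
        if estimate_alpha:
            shape = estimate_gamma_shape(tree_global, aln, model)
            tree_global, alpha = shape.tree, shape.alpha
        else:
            alpha = model.gamma_shape
    model = model.with_alpha(alpha)
    scores = []
    for win in make_windows(aln.length, width, step):
        aln_w = slice_columns(aln, win.start, win.end)
        gapped = [
            sid for sid, row in zip(aln_w.ids, aln_w.rows)
            if set(row) <= {"-", "X", "N", "?"}
        ]
        if gapped:
            warnings.warn(
                f"window {win.index} has only gaps for {gapped}; scoring anyway"
            )
        # tight tolerance: the per-window delta compares this single-topology
        # fit against a search optimum, so its slack must stay negligible
        _, lnl_global = optimize_branch_lengths(tree_global, aln_w, model, tol=1e-6)
        conv = search_ml_tree(
            aln_w,
            model,
            constraint=constraint,
            seed=child_seed(seed, "window", win.index),
            n_starts=n_starts_window,
            method=method,
        )
        scores.append(
            WindowScore(
                window=win,
                lnl_global=lnl_global,
                lnl_conv=conv.log_likelihood,
                conv_tree=conv.tree,
            )
        )
    return ScanResult(
        scores=scores,
        tree_global=tree_global,
        alpha=alpha,
        model_name=model.name,
        width=width,
        step=step,
        conv_clade=conv_clade,
    )


def write_profile_tsv(result: ScanResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("window\tstart\tend\tlnL_global\tlnL_conv\tdelta\n")
        for s in result.scores:
            fh.write(
                f"{s.window.index}\t{s.window.start}\t{s.window.end}\t"
                f"{s.lnl_global:.6f}\t{s.lnl_conv:.6f}\t{s.delta:.6f}\n"
            )
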
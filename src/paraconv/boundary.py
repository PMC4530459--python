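"""Breakpoint estimation for the converted region from site log-likelihoods.

Both test trees are inferred once from the full alignment (unconstrained
versus conversion-constrained), per-column log-likelihood differences
(delta-site-lnL, conversion minus global) are computed, and every candidate
window of every width in a range is scored with a Welch two-sample t
statistic comparing mean delta-site-lnL inside versus outside the window.
Window-size bias is adjusted by a max-statistic permutation test: for each
width, site order is permuted and the largest t over all windows of that
width is recorded, and the p-value is the proportion of permuted maxima
strictly larger than the observed maximum (no "+1" correction, so the
smallest attainable p is 0).  The reported region is the window with the
largest t among widths whose p-value beats the significance level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from ._rng import child_seed, substream
from .errors import ConfigurationError, CoordinateError
from .io import Alignment
from .likelihood import site_log_likelihoods
from .models import SubstModel
from .search import Constraint, search_ml_tree
from .trees import Tree
from .windows import fit_global_tree

#: finite stand-in for an infinite t when one side is constant
T_SENTINEL = 1e12


@dataclass
class SiteLnLTable:
    site_lnl_global: np.ndarray
    site_lnl_conv: np.ndarray
    tree_global: Tree
    tree_conv: Tree
    model_name: str
    alpha: float

    @property
    def delta_site(self) -> np.ndarray:
        return self.site_lnl_conv - self.site_lnl_global


def build_site_table(
    aln: Alignment,
    conv_clade,
    model: SubstModel,
    seed: int = 0,
    method: str = "auto",
    n_starts: int = 5,
    estimate_alpha: bool = True,
) -> SiteLnLTable:
    """Fit both full-alignment test trees and tabulate per-column lnLs.

    The gamma shape is estimated on the unconstrained fit and reused for
    the constrained tree so the two site-lnL vectors differ only through
    topology and branch lengths."""
    conv_clade = frozenset(conv_clade)
    fit = fit_global_tree(
        aln, model, seed=child_seed(seed, "table-global"),
        n_starts=n_starts, method=method, estimate_alpha=estimate_alpha,
    )
    model_fit = model.with_alpha(fit.alpha)
    conv = search_ml_tree(
        aln, model_fit, constraint=Constraint(conv_clade),
        seed=child_seed(seed, "table-conv"), n_starts=n_starts, method=method,
    )
    return SiteLnLTable(
        site_lnl_global=site_log_likelihoods(aln, fit.tree, model_fit),
        site_lnl_conv=site_log_likelihoods(aln, conv.tree, model_fit),
        tree_global=fit.tree,
        tree_conv=conv.tree,
        model_name=model.name,
        alpha=fit.alpha,
    )


def t_statistic(delta_site, window: tuple[int, int]) -> float:
    """Welch t for mean delta-site-lnL inside vs outside a window
    (1-based inclusive bounds); unbiased variances.  If both variances
    vanish the statistic is 0 for equal means, else +/- a large sentinel."""
    delta = np.asarray(delta_site, dtype=float)
    start, end = window
    if not (1 <= start <= end <= delta.size):
        raise CoordinateError(f"window {window} outside [1, {delta.size}]")
    inside = delta[start - 1 : end]
    outside = np.concatenate([delta[: start - 1], delta[end:]])
    if inside.size < 2 or outside.size < 2:
        raise ConfigurationError("both window sides need at least two sites")
    diff = inside.mean() - outside.mean()
    se2 = inside.var(ddof=1) / inside.size + outside.var(ddof=1) / outside.size
    if se2 <= 0.0:
        return 0.0 if diff == 0.0 else float(np.sign(diff) * T_SENTINEL)
    return float(diff / np.sqrt(se2))


def _t_profile(matrix: np.ndarray, width: int) -> np.ndarray:
    """Welch t for every window start, vectorized over rows of ``matrix``
    via prefix sums of the values and their squares.

    ``matrix`` is (n_vectors, L); returns (n_vectors, L - width + 1)."""
    m = np.atleast_2d(matrix)
    L = m.shape[1]
    n_in = width
    n_out = L - width
    cs = np.cumsum(m, axis=1)
    cs2 = np.cumsum(m * m, axis=1)
    total = cs[:, -1][:, None]
    total2 = cs2[:, -1][:, None]
    in_sum = cs[:, width - 1 :] - np.concatenate(
        [np.zeros((m.shape[0], 1)), cs[:, : L - width]], axis=1
    )
    in_sum2 = cs2[:, width - 1 :] - np.concatenate(
        [np.zeros((m.shape[0], 1)), cs2[:, : L - width]], axis=1
    )
    out_sum = total - in_sum
    out_sum2 = total2 - in_sum2
    mean_in = in_sum / n_in
    mean_out = out_sum / n_out
    var_in = np.maximum(in_sum2 - n_in * mean_in**2, 0.0) / (n_in - 1)
    var_out = np.maximum(out_sum2 - n_out * mean_out**2, 0.0) / (n_out - 1)
    diff = mean_in - mean_out
    se2 = var_in / n_in + var_out / n_out
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    degenerate = se2 <= 0.0
    if degenerate.any():
        t = np.where(degenerate, np.sign(diff) * T_SENTINEL, t)
        t = np.where(degenerate & (diff == 0.0), 0.0, t)
    return t


@dataclass(frozen=True)
class WidthRecord:
    width: int
    start: int
    end: int
    t: float
    p: float


@dataclass
class BoundaryResult:
    best_window: tuple[int, int, int] | None  # (start, end, width)
    t_obs: float | None
    p_value: float | None
    per_width: list[WidthRecord]
    n_perm: int
    seed: int
    level: float

    def to_dict(self) -> dict:
        if self.best_window is None:
            head = {"best_start": None, "best_end": None, "best_width": None,
                    "t": None, "p": None}
        else:
            head = {
                "best_start": self.best_window[0],
                "best_end": self.best_window[1],
                "best_width": self.best_window[2],
                "t": self.t_obs,
                "p": self.p_value,
            }
        head.update({"n_perm": self.n_perm, "seed": self.seed, "level": self.level})
        return head

    def write(self, tsv_path=None, json_path=None) -> None:
        if tsv_path is not None:
            with open(tsv_path, "w") as fh:
                fh.write("width\tbest_start\tbest_end\tt\tp\n")
                for r in self.per_width:
                    fh.write(
                        f"{r.width}\t{r.start}\t{r.end}\t{r.t:.6f}\t{r.p:.6f}\n"
                    )
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(self.to_dict(), fh, indent=2)
                fh.write("\n")


def scan_boundaries(
    table,
    min_width: int = 30,
    max_width: int = 90,
    n_perm: int = 10_000,
    level: float = 0.01,
    seed: int = 0,
    perm_batch: int = 2_000,
) -> BoundaryResult:
    """Max-t window scan over every width in [min_width, max_width].

    ``table`` is a :class:`SiteLnLTable` or a raw delta-site-lnL vector.
    Permutation streams are derived independently per width from the master
    seed, so the observed per-width maxima never depend on the seed and
    partial re-runs reproduce exactly.
    """
    delta = table.delta_site if isinstance(table, SiteLnLTable) else np.asarray(
        table, dtype=float
    )
    L = delta.size
    if min_width < 3:
        raise ConfigurationError("minimum width must be at least 3")
    if max_width >= L:
        raise ConfigurationError("maximum width must be below the sequence length")
    per_width = []
    for width in range(min_width, max_width + 1):
        t_obs_all = _t_profile(delta[None, :], width)[0]
        best_start = int(np.argmax(t_obs_all))  # first max wins
        t_obs = float(t_obs_all[best_start])
        rng = substream(seed, "perm-width", width)
        n_exceed = 0
        done = 0
        while done < n_perm:
            batch = min(perm_batch, n_perm - done)
            perms = rng.permuted(
                np.tile(delta, (batch, 1)), axis=1
            )
            perm_max = _t_profile(perms, width).max(axis=1)
            n_exceed += int((perm_max > t_obs).sum())
            done += batch
        p = n_exceed / n_perm
        per_width.append(
            WidthRecord(
                width=width,
                start=best_start + 1,
                end=best_start + width,
                t=t_obs,
                p=p,
            )
        )
    significant = [r for r in per_width if r.p < level]
    if not significant:
        return BoundaryResult(None, None, None, per_width, n_perm, seed, level)
    best = max(significant, key=lambda r: r.t)  # max() keeps the first tie
    return BoundaryResult(
        best_window=(best.start, best.end, best.width),
        t_obs=best.t,
        p_value=best.p,
        per_width=per_width,
        n_perm=n_perm,
        seed=seed,
        level=level,
    )
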
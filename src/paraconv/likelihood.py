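"""Felsenstein-pruning likelihood engine.

Site likelihoods are computed under a reversible substitution model with k
discrete-gamma rate categories, mixing categories with equal weight 1/k.
Gap and unknown characters contribute all-ones partial vectors (missing
data), so a fully gapped column has log-likelihood zero.

The engine keeps, for every edge, the conditional likelihood of the data
below the edge ("inward" partials) and above it ("outward" partials, with
the stationary frequencies folded in at the root).  From these it evaluates
the total log-likelihood, per-edge one-dimensional objectives, analytic
gradients with respect to all branch lengths (for joint quasi-Newton
branch-length optimization), and the score of attaching a new leaf to any
edge (used by stepwise-addition tree search).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .errors import AlphabetError, NumericError, TreeError
from .io import ALPHABETS, Alignment
from .models import SubstModel
from .trees import BL_MAX, BL_MIN, Tree, clamp_lengths

#: total-lnL convergence tolerance for branch-length optimization
LNL_TOL = 1e-4


class PruningContext:
    """Encoded alignment (site patterns + tip partials) for one model."""

    def __init__(self, aln: Alignment, model: SubstModel):
        expected = ALPHABETS[aln.alphabet]
        if model.states != expected:
            raise AlphabetError(
                f"model over {model.states!r} cannot score a {aln.alphabet} alignment"
            )
        self.aln = aln
        self.model = model
        index = {c: i for i, c in enumerate(model.states)}
        codes = np.array(
            [[index.get(c, -1) for c in row] for row in aln.rows], dtype=np.int64
        )
        patterns, inverse, counts = np.unique(
            codes.T, axis=0, return_inverse=True, return_counts=True
        )
        self.pattern_index = inverse  # original column -> pattern
        self.weights = counts.astype(float)
        self.n_patterns = patterns.shape[0]
        n = model.n_states
        self.tip_partials: dict[str, np.ndarray] = {}
        for row_idx, sid in enumerate(aln.ids):
            part = np.zeros((n, self.n_patterns))
            col = patterns[:, row_idx]
            miss = col < 0
            part[:, miss] = 1.0
            obs = ~miss
            part[col[obs], np.nonzero(obs)[0]] = 1.0
            self.tip_partials[sid] = part


class TreeLikelihood:
    """Likelihood of one tree under a shared :class:`PruningContext`.

    Building the object runs the inward (post-order) pass; :meth:`up_pass`
    adds the outward partials needed for per-edge work.  The tree is copied,
    so the caller's tree is never mutated.
    """

    def __init__(self, ctx: PruningContext, tree: Tree, copy: bool = True):
        self.ctx = ctx
        self.model = ctx.model
        self.tree = clamp_lengths(tree.copy() if copy else tree)
        labels = set(self.tree.leaf_labels())
        if labels != set(ctx.aln.ids):
            raise TreeError(
                "tree leaves and alignment ids differ: "
                f"{sorted(labels ^ set(ctx.aln.ids))}"
            )
        self._post = self.tree.postorder()
        self._edges = [n for n in self._post if n.parent is not None]
        self._P: dict[int, np.ndarray] = {}
        self._msg: dict[int, np.ndarray] = {}
        self._D: dict[int, np.ndarray] = {}
        self._scale: dict[int, np.ndarray] = {}
        self._O: dict[int, np.ndarray] = {}
        self._oscale: dict[int, np.ndarray] = {}
        self._tmsg: dict[int, np.ndarray] = {}
        self._tmsg_scale: dict[int, np.ndarray] = {}
        self._up_valid = False
        self.refresh()

    # ------------------------------------------------------------ inward pass

    def _edge_mats(self, node) -> np.ndarray:
        return self.model.category_matrices(node.length)

    def _node_down(self, node, update_P: bool = True) -> None:
        """Recompute D (and msg) for one node from its children's msgs."""
        if node.is_leaf:
            self._D[id(node)] = self.ctx.tip_partials[node.label]
            self._scale[id(node)] = np.zeros(self.ctx.n_patterns)
        else:
            prod = None
            sc = np.zeros(self.ctx.n_patterns)
            for c in node.children:
                prod = self._msg[id(c)] if prod is None else prod * self._msg[id(c)]
                sc += self._scale[id(c)]
            smax = prod.max(axis=(0, 1))
            smax[smax <= 0.0] = 1.0
            prod = prod / smax[None, None, :]
            self._D[id(node)] = prod
            self._scale[id(node)] = sc + np.log(smax)
        if node.parent is not None:
            if update_P:
                self._P[id(node)] = self._edge_mats(node)
            self._msg[id(node)] = self._P[id(node)] @ self._D[id(node)]

    def refresh(self) -> None:
        P_batch = self.model.batch_matrices(
            np.array([n.length for n in self._edges])
        )
        for e_idx, node in enumerate(self._edges):
            self._P[id(node)] = P_batch[e_idx]
        for node in self._post:
            self._node_down(node, update_P=False)
        self._up_valid = False

    def set_edge_length(self, node, t: float) -> None:
        """Change one branch length, refreshing caches on the root path."""
        node.length = float(min(max(t, BL_MIN), BL_MAX))
        P = self._P[id(node)] = self._edge_mats(node)
        self._msg[id(node)] = P @ self._D[id(node)]
        anc = node.parent
        while anc is not None:
            self._node_down(anc, update_P=False)
            anc = anc.parent
        self._up_valid = False

    def _root_site_lik(self):
        root = self.tree.root
        prod = None
        for c in root.children:
            prod = self._msg[id(c)] if prod is None else prod * self._msg[id(c)]
        k = self.model.n_categories
        lik = np.einsum("kip,i->p", prod, self.model.pi) / k
        return lik, self._sum_child_scales(root)

    def _sum_child_scales(self, node):
        sc = np.zeros(self.ctx.n_patterns)
        for c in node.children:
            sc += self._scale[id(c)]
        return sc

    def pattern_log_likelihoods(self) -> np.ndarray:
        lik, sc = self._root_site_lik()
        with np.errstate(divide="ignore"):
            return np.log(lik) + sc

    def site_log_likelihoods(self) -> np.ndarray:
        """Per original alignment column (pattern values expanded)."""
        return self.pattern_log_likelihoods()[self.ctx.pattern_index]

    def log_likelihood(self) -> float:
        lnl = float(self.pattern_log_likelihoods() @ self.ctx.weights)
        if np.isnan(lnl):
            raise NumericError("non-finite log-likelihood")
        return lnl

    # ----------------------------------------------------------- outward pass

    def up_pass(self) -> None:
        """Outward partials O_v: likelihood of all data outside subtree(v)
        as a function of the state at v's parent, stationary frequencies
        folded in at the root."""
        pi = self.model.pi
        root = self.tree.root
        for node in self.tree.preorder():
            if node.parent is None:
                continue
            u = node.parent
            sibs = [s for s in u.children if s is not node]
            if u is root:
                O = np.broadcast_to(
                    pi[None, :, None],
                    (self.model.n_categories, self.model.n_states, self.ctx.n_patterns),
                ).copy()
                osc = np.zeros(self.ctx.n_patterns)
            else:
                O = np.matmul(self._P[id(u)].transpose(0, 2, 1), self._O[id(u)])
                osc = self._oscale[id(u)].copy()
            # parent-side message before sibling contributions (NNI scoring)
            self._tmsg[id(node)] = O
            self._tmsg_scale[id(node)] = osc.copy()
            for s in sibs:
                O = O * self._msg[id(s)]
                osc += self._scale[id(s)]
            smax = O.max(axis=(0, 1))
            smax[smax <= 0.0] = 1.0
            O /= smax[None, None, :]
            self._O[id(node)] = O
            self._oscale[id(node)] = osc + np.log(smax)
        self._up_valid = True

    def _edge_lik(self, node, msg):
        """Pattern likelihoods and scalers for one edge from O and a msg."""
        k = self.model.n_categories
        lik = np.einsum("kip,kip->p", self._O[id(node)], msg) / k
        sc = self._oscale[id(node)] + self._scale[id(node)]
        return lik, sc

    def edge_log_likelihood(self, node, t: float | None = None) -> float:
        """Total lnL evaluated across edge ``node``; with ``t`` given, the
        edge length is hypothetically replaced (caches untouched)."""
        if not self._up_valid:
            self.up_pass()
        if t is None:
            msg = self._msg[id(node)]
        else:
            msg = self.model.category_matrices(t) @ self._D[id(node)]
        lik, sc = self._edge_lik(node, msg)
        with np.errstate(divide="ignore"):
            vals = np.log(lik) + sc
        return float(vals @ self.ctx.weights)

    def _newton_1d(
        self, O, D, t0: float, sc_off: float,
        max_steps: int = 12, t_tol: float = 1e-6,
    ) -> tuple[float, float]:
        """Newton maximization of lnL over a single branch length, given the
        outward (O, with frequencies folded) and inward (D) partials at its
        two ends; returns (best lnL + sc_off, best t).  Derivatives come
        from d/dt P = rQP and d^2/dt^2 P = (rQ)^2 P."""
        Q = self.model.Q
        Q2 = Q @ Q
        rates = self.model.rates
        r2 = rates**2
        w = self.ctx.weights

        inv_k = 1.0 / self.model.n_categories

        def derivs(t):
            msg = self.model.category_matrices(t) @ D
            lik = (O * msg).sum(axis=(0, 1)) * inv_k
            d1v = (O * ((Q @ msg) * rates[:, None, None])).sum(axis=(0, 1)) * inv_k
            d2v = (O * ((Q2 @ msg) * r2[:, None, None])).sum(axis=(0, 1)) * inv_k
            safe = np.where(lik > 0, lik, 1.0)
            with np.errstate(divide="ignore"):
                lnl = float(np.log(safe) @ w) + sc_off
            r1 = d1v / safe
            g = float(r1 @ w)
            h = float((d2v / safe - r1 * r1) @ w)
            return lnl, g, h

        t = t0
        best_lnl, best_t = -np.inf, t0
        for _ in range(max_steps):
            lnl, g, h = derivs(t)
            if lnl > best_lnl:
                best_lnl, best_t = lnl, t
            if h < 0.0 and np.isfinite(g):
                t_new = t - g / h
            else:
                t_new = t * 2.0 if g > 0 else t * 0.5
            if not np.isfinite(t_new):
                break
            t_new = min(max(t_new, t * 0.2), t * 5.0)
            t_new = min(max(t_new, BL_MIN), BL_MAX)
            if abs(t_new - t) <= t_tol * max(t, 1e-3):
                t = t_new
                break
            t = t_new
        lnl, _, _ = derivs(t)
        if lnl > best_lnl:
            best_lnl, best_t = lnl, t
        return best_lnl, best_t

    def optimize_edge(self, node) -> float:
        """Newton-optimize one branch length in place; returns new total lnL.
        The best length seen (including the starting one) always wins."""
        if not self._up_valid:
            self.up_pass()
        sc_off = float(
            (self._oscale[id(node)] + self._scale[id(node)]) @ self.ctx.weights
        )
        _, best_t = self._newton_1d(
            self._O[id(node)], self._D[id(node)], node.length, sc_off
        )
        self.set_edge_length(node, best_t)
        return self.log_likelihood()

    def nni_edge_scores(self, node) -> list[tuple[int, float, float]]:
        """Score both NNI rearrangements around the edge above internal
        ``node`` without rebuilding the tree.

        Swapping child a_idx of ``node`` with its first sibling ("partner")
        regroups the partials: the new inward side is the product of the
        kept child's and the partner's messages, the new outward side is the
        parent-side message times the displaced child's message (plus any
        remaining siblings at the parent).  The central branch is then
        re-optimized by Newton with everything else fixed.  Returns
        [(a_idx, lnL, t_opt), ...]; lnL values are exact candidate-tree
        log-likelihoods given all other branch lengths.
        """
        if not self._up_valid:
            self.up_pass()
        u = node.parent
        sibs = [s for s in u.children if s is not node]
        partner, rest = sibs[0], sibs[1:]
        w = self.ctx.weights
        out = []
        for a_idx in (0, 1):
            moved = node.children[a_idx]      # leaves the inward side
            kept = node.children[1 - a_idx]
            D_new = self._msg[id(kept)] * self._msg[id(partner)]
            d_scale = self._scale[id(kept)] + self._scale[id(partner)]
            O_new = self._tmsg[id(node)] * self._msg[id(moved)]
            o_scale = self._tmsg_scale[id(node)] + self._scale[id(moved)]
            for s in rest:
                O_new = O_new * self._msg[id(s)]
                o_scale = o_scale + self._scale[id(s)]
            sc_off = float((d_scale + o_scale) @ w)
            lnl, t_opt = self._newton_1d(O_new, D_new, node.length, sc_off)
            out.append((a_idx, lnl, t_opt))
        return out

    # ------------------------------------------------- joint branch optimizer

    def _value_and_grad(self):
        """Total lnL and its gradient w.r.t. every branch length.

        Uses d/dt exp(Qrt) = rQ exp(Qrt): the derivative across edge v is
        sum over categories of r_c * O_v . (Q msg_v), divided by the
        per-pattern likelihood (scalers cancel in the ratio).
        """
        if not self._up_valid:
            self.up_pass()
        lnl = self.log_likelihood()
        Q = self.model.Q
        rates = self.model.rates
        w = self.ctx.weights
        grads = np.empty(len(self._edges))
        for e_idx, node in enumerate(self._edges):
            msg = self._msg[id(node)]
            O = self._O[id(node)]
            dmsg = (Q @ msg) * rates[:, None, None]
            num = (O * dmsg).sum(axis=(0, 1))
            # O and msg share every scaling factor with lik_e, so the
            # ratio is the exact per-pattern derivative d log L / d t
            lik_e = (O * msg).sum(axis=(0, 1))
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(lik_e > 0, num / np.where(lik_e > 0, lik_e, 1.0), 0.0)
            grads[e_idx] = ratio @ w
        return lnl, grads

    def _newton_sweep(self) -> np.ndarray:
        """Propose one Newton update of every branch length from the current
        partials (Jacobi style: all edges move simultaneously).

        First and second derivatives across an edge come from
        d/dt P = rQP and d^2/dt^2 P = (rQ)^2 P; steps are clamped to a
        5-fold length change per sweep and to the global bounds."""
        if not self._up_valid:
            self.up_pass()
        Q = self.model.Q
        Q2 = Q @ Q
        rates = self.model.rates
        r2 = rates**2
        w = self.ctx.weights
        new_t = np.empty(len(self._edges))
        for i, node in enumerate(self._edges):
            msg = self._msg[id(node)]
            O = self._O[id(node)]
            lik = (O * msg).sum(axis=(0, 1))
            d1v = (O * ((Q @ msg) * rates[:, None, None])).sum(axis=(0, 1))
            d2v = (O * ((Q2 @ msg) * r2[:, None, None])).sum(axis=(0, 1))
            safe = np.where(lik > 0, lik, 1.0)
            ok = lik > 0
            r1 = np.where(ok, d1v / safe, 0.0)
            g = r1 @ w
            h = (np.where(ok, d2v / safe, 0.0) - r1 * r1) @ w
            t = node.length
            if h < 0.0 and np.isfinite(g):
                t_new = t - g / h
            else:  # non-concave profile: geometric step along the gradient
                t_new = t * 2.0 if g > 0 else t * 0.5
            if not np.isfinite(t_new):
                t_new = t
            t_new = min(max(t_new, t * 0.2), t * 5.0)
            new_t[i] = min(max(t_new, BL_MIN), BL_MAX)
        return new_t

    def optimize_lengths(
        self,
        tol: float = LNL_TOL,
        max_iter: int = 200,
        max_sweeps: int = 30,
        polish: bool = True,
    ) -> float:
        """Jointly optimize all branch lengths to a total-lnL tolerance.

        Damped Newton sweeps (cheap: two tree passes each) do the bulk of
        the work; L-BFGS-B with the analytic gradient then polishes from
        the best point seen, which also guards against sweeps that stall on
        flat ridges (e.g. lengths crawling toward the lower bound).  The
        polish is skipped when the sweep budget ``max_sweeps`` is small,
        i.e. a coarse screening fit.  Monotone by construction: the initial
        lengths are restored if nothing improves.  Returns the final lnL.
        """
        lnl_prev = self.log_likelihood()
        best = (lnl_prev, np.array([n.length for n in self._edges]))
        coarse = max_sweeps < 10 or not polish
        for _ in range(max_sweeps):
            new_t = self._newton_sweep()
            for node, t in zip(self._edges, new_t):
                node.length = float(t)
            self.refresh()
            lnl = self.log_likelihood()
            if lnl > best[0]:
                best = (lnl, new_t.copy())
            if lnl < lnl_prev - 1e-9:
                break  # simultaneous steps overshot; leave it to the polish
            if lnl - lnl_prev < tol:
                break
            lnl_prev = lnl
        for node, t in zip(self._edges, best[1]):
            node.length = float(t)
        self.refresh()
        if coarse:
            return self.log_likelihood()
        return self._optimize_lengths_lbfgs(tol, max_iter)

    def _optimize_lengths_lbfgs(self, tol: float = LNL_TOL, max_iter: int = 200) -> float:
        x0 = np.array([n.length for n in self._edges])
        lnl0 = self.log_likelihood()

        def negloglik(x):
            for node, t in zip(self._edges, x):
                node.length = float(t)
            self.refresh()
            lnl, grads = self._value_and_grad()
            return -lnl, -grads

        res = minimize(
            negloglik,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(BL_MIN, BL_MAX)] * len(x0),
            options={"ftol": 1e-10, "gtol": 1e-3, "maxiter": max_iter},
        )
        if -res.fun >= lnl0 - 1e-12:
            x = res.x
        else:  # pragma: no cover - optimizer regression guard
            x = x0
        for node, t in zip(self._edges, x):
            node.length = float(min(max(t, BL_MIN), BL_MAX))
        self.refresh()
        return self.log_likelihood()

    # --------------------------------------------------- stepwise-attachment

    def attach_score(
        self, node, tip_partial: np.ndarray, pendant: float, frac: float = 0.5
    ) -> float:
        """Total lnL of hypothetically attaching a new leaf on the edge above
        ``node``: the edge is split at ``frac`` and the new tip hangs from
        the junction with branch length ``pendant`` (no re-optimization)."""
        if not self._up_valid:
            self.up_pass()
        t = node.length
        Pa = self.model.category_matrices(t * frac)
        Pb = self.model.category_matrices(t * (1.0 - frac))
        Pp = self.model.category_matrices(pendant)
        below = Pb @ self._D[id(node)]
        tip_msg = Pp @ tip_partial
        joint = Pa @ (below * tip_msg)
        lik, sc = self._edge_lik(node, joint)
        with np.errstate(divide="ignore"):
            vals = np.log(lik) + sc
        return float(vals @ self.ctx.weights)


# -------------------------------------------------------------- public API


def site_log_likelihoods(aln: Alignment, tree: Tree, model: SubstModel) -> np.ndarray:
    """Per-column log-likelihoods of ``aln`` on ``tree`` under ``model``."""
    return TreeLikelihood(PruningContext(aln, model), tree).site_log_likelihoods()


def log_likelihood(aln: Alignment, tree: Tree, model: SubstModel) -> float:
    return TreeLikelihood(PruningContext(aln, model), tree).log_likelihood()


def optimize_branch_lengths(
    tree: Tree, aln: Alignment, model: SubstModel, tol: float = LNL_TOL
) -> tuple[Tree, float]:
    """ML branch lengths on a fixed topology; returns (new tree, lnL)."""
    engine = TreeLikelihood(PruningContext(aln, model), tree)
    lnl = engine.optimize_lengths(tol=tol)
    return engine.tree, lnl


@dataclass
class GammaShapeResult:
    alpha: float
    log_likelihood: float
    tree: Tree
    converged: bool


def estimate_gamma_shape(
    tree: Tree,
    aln: Alignment,
    model: SubstModel,
    bounds: tuple[float, float] = (0.02, 100.0),
    xatol: float = 0.02,
) -> GammaShapeResult:
    """ML estimate of the gamma shape on a fixed topology.

    One-dimensional bounded search over log(alpha); branch lengths are
    re-optimized at every candidate shape (warm-started from the previous
    candidate's optimum to keep the profile evaluations cheap).
    """
    state = {"tree": tree.copy(), "best": (-np.inf, None, None)}

    def profile(log_alpha: float) -> float:
        alpha = float(np.exp(log_alpha))
        m = model.with_alpha(alpha)
        engine = TreeLikelihood(PruningContext(aln, m), state["tree"])
        lnl = engine.optimize_lengths()
        state["tree"] = engine.tree
        if lnl > state["best"][0]:
            state["best"] = (lnl, alpha, engine.tree)
        return -lnl

    res = minimize_scalar(
        profile,
        bounds=(np.log(bounds[0]), np.log(bounds[1])),
        method="bounded",
        options={"xatol": xatol, "maxiter": 60},
    )
    lnl, alpha, fitted = state["best"]
    converged = bool(res.success) and alpha is not None
    if alpha is None:  # pragma: no cover - bounded search always evaluates
        raise NumericError("gamma-shape optimization produced no evaluations")
    return GammaShapeResult(alpha, lnl, fitted, converged)
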
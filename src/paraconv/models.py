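"""Time-reversible substitution models with discrete-gamma rate variation.

Supported models: the empirical amino-acid matrices LG and WAG (exchange-
abilities and stationary frequencies embedded as plain-text tables in PAML
lower-triangle layout), the general time-reversible nucleotide model (GTR),
and the two-state Cavender-Felsenstein model (CF2) for RY-recoded data.

Every model is normalized so that one unit of branch length equals one
expected substitution per site at stationarity, and among-site rate
variation uses k equal-probability gamma categories whose rates are the
within-bin means (renormalized to average exactly 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.stats import gamma as gamma_dist

from .errors import ModelError
from .io import ALPHABETS

_N_AA = 20


def _load_paml_matrix(name: str):
    """Read a PAML-layout empirical model file: 19 lower-triangle rows of
    exchangeabilities followed by the 20 stationary frequencies."""
    text = resources.files("paraconv.data").joinpath(name).read_text()
    numbers = [float(tok) for tok in text.split()]
    if len(numbers) != 190 + 20:
        raise ModelError(f"malformed model table {name}")
    S = np.zeros((_N_AA, _N_AA))
    k = 0
    for i in range(1, _N_AA):
        for j in range(i):
            S[i, j] = S[j, i] = numbers[k]
            k += 1
    pi = np.array(numbers[190:])
    return S, pi / pi.sum()


def discrete_gamma_rates(alpha: float, k: int = 4) -> np.ndarray:
    """Mean-of-bin rates for k equal-probability gamma categories.

    The gamma has shape alpha and mean 1; category c's rate is the
    conditional mean of the distribution within quantile bin
    [c/k, (c+1)/k], so sum of rates / k is 1 (renormalized exactly).
    """
    if alpha <= 0:
        raise ModelError("gamma shape must be positive")
    if k < 1:
        raise ModelError("need at least one rate category")
    if k == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1.0 / alpha)
    # E[X; a<X<b] for Gamma(alpha, mean 1) equals the shape-(alpha+1) CDF
    # difference; dividing by the bin mass 1/k gives the conditional mean.
    upper = gamma_dist.cdf(edges, a=alpha + 1, scale=1.0 / alpha)
    rates = (upper[1:] - upper[:-1]) * k
    return rates / rates.mean()


@dataclass
class SubstModel:
    """A normalized reversible rate matrix plus discrete-gamma rates."""

    name: str
    states: str
    S: np.ndarray
    pi: np.ndarray
    gamma_shape: float = 1.0
    n_categories: int = 4
    # eigendecomposition of the symmetrized rate matrix, filled in __post_init__
    Q: np.ndarray = field(init=False, repr=False)
    _eigvals: np.ndarray = field(init=False, repr=False)
    _U: np.ndarray = field(init=False, repr=False)
    _Uinv: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        if np.any(pi <= 0):
            raise ModelError("stationary frequencies must be positive")
        pi = pi / pi.sum()
        S = np.asarray(self.S, dtype=float)
        n = len(self.states)
        if S.shape != (n, n) or len(pi) != n:
            raise ModelError("model dimensions disagree with the state set")
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -np.sum(pi * np.diag(Q))
        if scale <= 0:
            raise ModelError("degenerate rate matrix")
        Q /= scale
        self.pi = pi
        self.Q = Q
        # reversible Q is similar to a symmetric matrix: stable eigen route
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        B = 0.5 * (B + B.T)
        w, V = np.linalg.eigh(B)
        self._eigvals = w
        self._U = V / sq[:, None]
        self._Uinv = V.T * sq[None, :]
        self._rates = discrete_gamma_rates(self.gamma_shape, self.n_categories)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def rates(self) -> np.ndarray:
        return self._rates

    def with_alpha(self, alpha: float) -> "SubstModel":
        return SubstModel(
            name=self.name,
            states=self.states,
            S=self.S,
            pi=self.pi,
            gamma_shape=alpha,
            n_categories=self.n_categories,
        )

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) = exp(Q * t * rate); rows are probability distributions."""
        if t < 0:
            raise ModelError("branch length must be non-negative")
        if rate <= 0:
            raise ModelError("rate multiplier must be positive")
        expw = np.exp(self._eigvals * (t * rate))
        P = (self._U * expw[None, :]) @ self._Uinv
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def batch_matrices(self, ts: np.ndarray) -> np.ndarray:
        """P(t_e * r_c) for every (edge length, category) pair: (E, k, n, n)."""
        ts = np.asarray(ts, dtype=float)
        scaled = ts[:, None] * self._rates[None, :]  # (E, k)
        expw = np.exp(scaled[:, :, None] * self._eigvals[None, None, :])
        P = np.matmul(self._U[None, None, :, :] * expw[:, :, None, :], self._Uinv)
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=3, keepdims=True)
        return P

    def category_matrices(self, t: float) -> np.ndarray:
        """Stacked P(t * r_c) for every rate category (k, n, n)."""
        if t < 0:
            raise ModelError("branch length must be non-negative")
        expw = np.exp(np.outer(self._rates * t, self._eigvals))  # (k, n)
        P = np.matmul(self._U[None, :, :] * expw[:, None, :], self._Uinv)
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P


def transition_matrix(model: SubstModel, t: float, rate: float = 1.0) -> np.ndarray:
    return model.transition_matrix(t, rate)


def build_model(
    name: str,
    gamma_shape: float = 1.0,
    n_categories: int = 4,
    freqs=None,
    exchangeabilities=None,
) -> SubstModel:
    """Construct a named substitution model.

    LG/WAG use their published empirical exchangeabilities and frequencies
    (no "+F" frequency re-estimation).  GTR takes six exchangeabilities in
    the order AC, AG, AT, CG, CT, GT (default: all 1) and four frequencies
    (default: equal, or supply empirical values).  CF2 is the symmetric
    two-state model with frequencies fixed at (1/2, 1/2).
    """
    name_u = name.upper()
    if name_u in ("LG", "WAG"):
        S, pi = _load_paml_matrix(f"{name_u.lower()}.dat")
        if freqs is not None:
            pi = np.asarray(freqs, dtype=float)
        return SubstModel(name_u, ALPHABETS["AA"], S, pi, gamma_shape, n_categories)
    if name_u == "GTR":
        ex = np.ones(6) if exchangeabilities is None else np.asarray(
            exchangeabilities, dtype=float
        )
        if ex.shape != (6,) or np.any(ex <= 0):
            raise ModelError("GTR needs six positive exchangeabilities")
        S = np.zeros((4, 4))
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for (i, j), v in zip(pairs, ex):
            S[i, j] = S[j, i] = v
        pi = (
            np.full(4, 0.25) if freqs is None else np.asarray(freqs, dtype=float)
        )
        return SubstModel("GTR", ALPHABETS["NT"], S, pi, gamma_shape, n_categories)
    if name_u == "CF2":
        S = np.array([[0.0, 1.0], [1.0, 0.0]])
        pi = np.array([0.5, 0.5])
        return SubstModel("CF2", ALPHABETS["RY"], S, pi, gamma_shape, n_categories)
    raise ModelError(f"unknown model {name!r}")


def empirical_frequencies(aln) -> np.ndarray:
    """Observed state frequencies of an alignment (gaps/unknowns ignored),
    with a small pseudocount so no frequency is exactly zero."""
    states = ALPHABETS[aln.alphabet]
    counts = np.full(len(states), 0.5)
    index = {c: i for i, c in enumerate(states)}
    for row in aln.rows:
        for c in row:
            i = index.get(c)
            if i is not None:
                counts[i] += 1
    return counts / counts.sum()
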
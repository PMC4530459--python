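"""Parametric-bootstrap calibration of the window delta-lnL test.

Replicate alignments are simulated on the fitted no-conversion tree (the
null hypothesis), each replicate is pushed through the same sliding-window
scan as the real data, and all window deltas are pooled into one empirical
null distribution.  The critical value for a level-alpha test is the
nearest-rank (1 - alpha) quantile of the pooled samples; an observed window
is significant when its delta strictly exceeds the critical value.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from ._rng import child_seed
from .errors import ConfigurationError
from .models import SubstModel
from .simulate import simulate_alignment
from .trees import Tree
from .windows import ScanResult, delta_lnl_profile


def nearest_rank_quantile(samples, q: float) -> float:
    """The ceil(q*n)-th order statistic (no interpolation)."""
    arr = np.sort(np.asarray(samples, dtype=float))
    if arr.size == 0:
        raise ValueError("empty sample")
    rank = max(1, math.ceil(q * arr.size))
    return float(arr[rank - 1])


@dataclass
class NullDistribution:
    samples: np.ndarray
    test_alpha: float
    critical: float
    n_reps: int
    width: int
    step: int
    sim_model: str
    sim_tree: str
    seed: int

    def summary(self) -> dict:
        return {
            "critical": self.critical,
            "test_alpha": self.test_alpha,
            "n_samples": int(self.samples.size),
            "seed": self.seed,
        }

    def write(self, tsv_path=None, json_path=None) -> None:
        if tsv_path is not None:
            with open(tsv_path, "w") as fh:
                fh.write("delta\n")
                for v in self.samples:
                    fh.write(f"{v:.6f}\n")
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(self.summary(), fh, indent=2)
                fh.write("\n")


def calibrate(
    tree_global: Tree,
    model_sim: SubstModel,
    n_reps: int,
    length: int,
    conv_clade,
    width: int = 50,
    step: int = 10,
    test_alpha: float = 0.01,
    seed: int = 0,
    model_analysis: SubstModel | None = None,
    estimate_alpha: bool = False,
    method: str = "auto",
    n_starts_global: int = 1,
    n_starts_window: int = 3,
) -> NullDistribution:
    """Build the pooled null distribution of window deltas.

    ``tree_global`` must violate the conversion constraint — it encodes the
    no-conversion hypothesis being simulated.  Each replicate re-runs the
    full scan (its own global tree is re-inferred from the simulated data).
    The analysis model defaults to the simulation model with its gamma
    shape held fixed; pass ``estimate_alpha=True`` to re-estimate the shape
    per replicate.
    """
    conv_clade = frozenset(conv_clade)
    if n_reps < 1:
        raise ConfigurationError("need at least one replicate")
    if tree_global.is_monophyletic(conv_clade):
        raise ConfigurationError(
            "simulation tree satisfies the conversion constraint; "
            "the null distribution would be degenerate"
        )
    if model_analysis is None:
        model_analysis = model_sim
    samples = []
    for rep in range(n_reps):
        rep_aln = simulate_alignment(
            tree_global, model_sim, length, seed=child_seed(seed, "boot-sim", rep)
        )
        profile = delta_lnl_profile(
            rep_aln,
            conv_clade,
            model_analysis,
            width=width,
            step=step,
            seed=child_seed(seed, "boot-scan", rep),
            estimate_alpha=estimate_alpha,
            n_starts_global=n_starts_global,
            n_starts_window=n_starts_window,
            method=method,
        )
        samples.extend(profile.deltas)
    samples = np.array(samples)
    return NullDistribution(
        samples=samples,
        test_alpha=test_alpha,
        critical=nearest_rank_quantile(samples, 1.0 - test_alpha),
        n_reps=n_reps,
        width=width,
        step=step,
        sim_model=f"{model_sim.name}+G(alpha={model_sim.gamma_shape:g})",
        sim_tree=tree_global.newick(),
        seed=seed,
    )


def test_windows(profile: ScanResult, null: NullDistribution) -> list[bool]:
    """Flag each window whose delta strictly exceeds the critical value."""
    if (profile.width, profile.step) != (null.width, null.step):
        raise ConfigurationError(
            "profile and null distribution use different window geometry: "
            f"{(profile.width, profile.step)} vs {(null.width, null.step)}"
        )
    return [delta > null.critical for delta in profile.deltas]
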
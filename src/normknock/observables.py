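"""Observation indexes over simulation trajectories.

Three quantities characterize a run: the per-generation cooperation
ratio, the census of the 16 norms, and the sequence of majority norms
around the emergence of cooperation.  The knockout analysis classifies
a norm as *indispensable* when, with that norm banned, the
replication-averaged cooperation ratio over a terminal window stays
below a threshold (default 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .config import SimConfig
from .norms import N_NORMS, norm_from_string, norm_name

__all__ = [
    "Trajectory",
    "TransitionSequence",
    "cooperation_ratio",
    "majority_norm",
    "transition_sequence",
    "mean_terminal_cooperation",
    "default_terminal_window",
    "classify_indispensable",
]


@dataclass
class Trajectory:
    """Per-generation record of one replication.

    ``coop_ratio[g]`` is the fraction of realized cooperative donations
    in generation ``g`` (out of N·R); ``norm_counts[g]`` is the 16-norm
    census of the population that played generation ``g``.
    """

    coop_ratio: np.ndarray  # float64 (G,)
    norm_counts: np.ndarray  # int64 (G, 16)
    config: SimConfig
    seed: int

    def __post_init__(self):
        self.coop_ratio = np.asarray(self.coop_ratio, dtype=np.float64)
        self.norm_counts = np.asarray(self.norm_counts, dtype=np.int64)
        g = self.coop_ratio.shape[0]
        if self.norm_counts.shape != (g, N_NORMS):
            raise ValueError(
                f"norm_counts shape {self.norm_counts.shape} does not match "
                f"{g} generations x {N_NORMS} norms"
            )
        if np.any((self.coop_ratio < 0) | (self.coop_ratio > 1)):
            raise ValueError("cooperation ratios must lie in [0, 1]")
        if np.any(self.norm_counts.sum(axis=1) != self.config.n_agents):
            raise ValueError("each generation's norm counts must sum to N")

    @property
    def n_generations(self) -> int:
        return self.coop_ratio.shape[0]

    def majority_series(self) -> np.ndarray:
        """Majority norm code per generation (ties to the lowest code)."""
        return np.argmax(self.norm_counts, axis=1)

    def norm_fractions(self) -> np.ndarray:
        """Population ratio of each norm per generation, shape (G, 16)."""
        return self.norm_counts / self.config.n_agents


@dataclass
class TransitionSequence:
    """Run-collapsed majority-norm labels with generation stamps."""

    labels: list = field(default_factory=list)
    generations: list = field(default_factory=list)
    cooperative: bool = True
    crossing_generation: Optional[int] = None

    def __str__(self) -> str:
        path = " -> ".join(self.labels) if self.labels else "(empty)"
        tag = "" if self.cooperative else " [non-cooperative]"
        return path + tag


def cooperation_ratio(coop_counts: Sequence[int], n_agents: int, rounds: int) -> float:
    """Generation cooperation ratio: realized C actions / (N·R)."""
    counts = np.asarray(coop_counts)
    if counts.shape != (rounds,):
        raise ValueError(f"expected {rounds} per-round counts")
    if np.any((counts < 0) | (counts > n_agents)):
        raise ValueError("per-round cooperation counts must be in [0, N]")
    return float(counts.sum() / (n_agents * rounds))


def majority_norm(norm_counts: Sequence[int]) -> str:
    """Name of the most common norm; ties go to the lowest norm code."""
    counts = np.asarray(norm_counts)
    if counts.shape != (N_NORMS,):
        raise ValueError("expected a 16-vector of norm counts")
    return norm_name(int(np.argmax(counts)))


def _collapse(codes: np.ndarray, generations: np.ndarray, stop_code: Optional[int]):
    labels, stamps = [], []
    for gen, code in zip(generations, codes):
        name = norm_name(int(code))
        if not labels or labels[-1] != name:
            labels.append(name)
            stamps.append(int(gen))
        if stop_code is not None and code == stop_code:
            break
    return labels, stamps


def transition_sequence(
    traj: Trajectory,
    coop_threshold: float = 0.8,
    pre_window: int = 20,
    post_window: int = 100,
    stop_at: Optional[str] = "ALLG",
) -> TransitionSequence:
    """Majority-norm path around the emergence of cooperation.

    Majorities are sampled each generation over the window
    ``[t* − pre_window, t* + post_window]`` where ``t*`` is the first
    generation whose cooperation ratio exceeds ``coop_threshold``; the
    sequence stops at the first generation where ``stop_at`` is the
    majority, and consecutive duplicates are collapsed.  If the
    threshold is never exceeded the whole run is summarized instead and
    the result is flagged non-cooperative.
    """
    stop_code = None if stop_at is None else (
        norm_from_string(stop_at) if isinstance(stop_at, str) else int(stop_at)
    )
    majorities = traj.majority_series()
    above = np.flatnonzero(traj.coop_ratio > coop_threshold)
    if above.size == 0:
        labels, stamps = _collapse(
            majorities, np.arange(traj.n_generations), stop_code
        )
        return TransitionSequence(labels, stamps, cooperative=False)
    t_star = int(above[0])
    lo = max(0, t_star - pre_window)
    hi = min(traj.n_generations, t_star + post_window + 1)
    labels, stamps = _collapse(majorities[lo:hi], np.arange(lo, hi), stop_code)
    return TransitionSequence(labels, stamps, cooperative=True, crossing_generation=t_star)


def mean_terminal_cooperation(traj: Trajectory, window: int) -> float:
    """Mean cooperation ratio over the final ``window`` generations."""
    if not 1 <= window <= traj.n_generations:
        raise ValueError(
            f"window must be in [1, {traj.n_generations}], got {window}"
        )
    return float(traj.coop_ratio[-window:].mean())


def default_terminal_window(n_generations: int) -> int:
    """Default terminal window: the final 10% of the run (at least 1)."""
    return max(1, n_generations // 10)


def classify_indispensable(
    knockout_runs: Mapping[object, Sequence[Trajectory]],
    threshold: float = 0.1,
    window: Optional[int] = None,
) -> set:
    """Indispensable norms from knockout experiments.

    ``knockout_runs`` maps each knocked-out norm (name or code) to its
    replication trajectories.  A norm is indispensable when the
    replication-averaged mean terminal cooperation of its knockout runs
    is below ``threshold``.  ``window=None`` uses the final 10% of each
    run.
    """
    out = set()
    for key, runs in knockout_runs.items():
        runs = list(runs)
        if not runs:
            raise ValueError(f"no replications supplied for knockout {key!r}")
        means = [
            mean_terminal_cooperation(
                t, window if window is not None else default_terminal_window(t.n_generations)
            )
            for t in runs
        ]
        if float(np.mean(means)) < threshold:
            name = norm_name(key) if isinstance(key, (int, np.integer)) else str(key)
            out.add(name)
    return out
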
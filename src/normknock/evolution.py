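"""End-of-generation norm evolution: a genetic algorithm over the four
assessment loci.

Each offspring slot independently picks two parents (with replacement,
possibly the same agent, possibly itself) by roulette selection on the
squared min-centered payoff,

    Pi_i = (U_i − U_min)² / Σ_j (U_j − U_min)²,

inherits each locus from either parent with probability 1/2 (uniform
crossover), and flips each locus independently with the mutation rate m.
If a knockout set is active, any offspring landing on a banned norm is
redrawn uniformly from the remaining norms, so a knocked-out norm never
exists in the population.

Draw order per generation (one float per decision, from the replication
RandomState): an (N, 2) block of parent draws in offspring order, an
(N, 4) crossover block (locus 1 first; u < 1/2 copies parent a), an
(N, 4) mutation block if m > 0 (u < m flips), then one redraw float per
knocked-out offspring in index order.
"""

from __future__ import annotations

import numpy as np

from .config import SimConfig
from .norms import N_NORMS

__all__ = [
    "selection_distribution",
    "select_parents",
    "uniform_crossover",
    "mutate",
    "next_generation",
    "enforce_knockout",
]

_BITS = np.array([8, 4, 2, 1], dtype=np.int64)  # locus 1..4 bit values


def selection_distribution(payoffs) -> np.ndarray:
    """Roulette weights Pi from accumulated payoffs.

    When every payoff is equal the formula is 0/0; the unique symmetric
    completion — a uniform distribution — is returned instead.
    """
    u = np.asarray(payoffs, dtype=np.float64)
    if u.size == 0:
        raise ValueError("payoff vector is empty")
    w = (u - u.min()) ** 2
    total = w.sum()
    if total == 0.0:
        return np.full(u.size, 1.0 / u.size)
    return w / total


def _pick(cum: np.ndarray, u: float) -> int:
    return min(int(np.searchsorted(cum, u, side="right")), cum.size - 1)


def select_parents(pi: np.ndarray, rng: np.random.RandomState) -> tuple[int, int]:
    """Two parent indices drawn i.i.d. from ``pi`` (with replacement)."""
    cum = np.cumsum(pi)
    return _pick(cum, rng.random_sample()), _pick(cum, rng.random_sample())


def uniform_crossover(parent_a: int, parent_b: int, rng: np.random.RandomState) -> int:
    """Child norm: each locus copied from either parent with probability 1/2."""
    child = 0
    for bit in _BITS:
        src = parent_a if rng.random_sample() < 0.5 else parent_b
        child |= int(src) & int(bit)
    return child


def mutate(norm: int, m: float, rng: np.random.RandomState) -> int:
    """Flip each locus independently with probability ``m`` (no draws if m = 0)."""
    if m <= 0.0:
        return int(norm)
    out = int(norm)
    for bit in _BITS:
        if rng.random_sample() < m:
            out ^= int(bit)
    return out


def enforce_knockout(norms, knockout, rng: np.random.RandomState) -> np.ndarray:
    """Reassign every agent on a knocked-out norm uniformly over the rest.

    Idempotent; one uniform draw per reassigned agent, in index order.
    """
    norms = np.asarray(norms, dtype=np.int64).copy()
    knockout = frozenset(int(k) for k in knockout)
    if not knockout:
        return norms
    if len(knockout) >= N_NORMS:
        raise ValueError("cannot knock out all 16 norms")
    allowed = np.array(
        [c for c in range(N_NORMS) if c not in knockout], dtype=np.int64
    )
    hit = np.isin(norms, list(knockout))
    k = int(hit.sum())
    if k:
        u = rng.random_sample(k)
        norms[hit] = allowed[(u * allowed.size).astype(np.int64)]
    return norms


def next_generation(
    norms, payoffs, config: SimConfig, rng: np.random.RandomState
) -> np.ndarray:
    """Produce the next population of norms (synchronous replacement)."""
    norms = np.asarray(norms, dtype=np.int64)
    payoffs = np.asarray(payoffs, dtype=np.float64)
    if norms.shape != payoffs.shape:
        raise ValueError("norms and payoffs must have the same length")
    n = norms.size
    pi = selection_distribution(payoffs)
    cum = np.cumsum(pi)

    pu = rng.random_sample((n, 2))
    parents = np.minimum(np.searchsorted(cum, pu, side="right"), n - 1)
    pa = norms[parents[:, 0]]
    pb = norms[parents[:, 1]]

    take_a = rng.random_sample((n, 4)) < 0.5
    children = np.where(take_a, pa[:, None] & _BITS, pb[:, None] & _BITS).sum(axis=1)

    m = config.mutation_rate
    if m > 0.0:
        flips = (rng.random_sample((n, 4)) < m) * _BITS
        children ^= flips.sum(axis=1)

    return enforce_knockout(children, config.knockout, rng)
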
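"""One generation of the giving game.

A generation is R rounds.  Each round has two phases:

* phase A — every agent donates once: it picks a recipient uniformly
  among the other N−1 agents, intends to cooperate iff its image of the
  recipient is Good, and the intended action is inverted with the
  implementation-error probability q.  A realized cooperation costs the
  donor c and pays the recipient b; defection transfers nothing.
* phase B — every observer i re-evaluates every donor j (i ≠ j) with
  i's own norm, from j's realized action *in the previous round* and
  i's current image of j's then-recipient; the fresh image is inverted
  with the perception-error probability p.  In round 1 each donor is
  attributed a random action.  Updates are synchronous (all read the
  pre-phase-B matrix) and the diagonal stays Good: agents always see
  themselves as Good.  The alternative ``same_round`` timing evaluates
  the current round's record instead.

Randomness comes from a legacy ``numpy.random.RandomState`` (MT19937)
and every draw is a uniform float, consumed in a fixed documented
order per round:

1. N recipient draws, one per donor in index order
   (``r = floor(u·(N−1))``, shifted past the donor itself);
2. if q > 0, N implementation-flip draws in donor order;
3. if p > 0 (and p < 1), perception flips located by geometric skipping
   over the off-diagonal pairs in row-major order — an exact sampler of
   i.i.d. Bernoulli(p) flip positions that draws one float per flip
   rather than one per pair.  p = 1 flips everything with no draws.

In the ``lagged`` evaluation timing, phase B of round 1 needs an
attributed random record: N recipient draws then N action draws
(u < 0.5 → cooperate), consumed between phase A and phase B of round 1.

The numba fast path (:mod:`normknock._kernel`) and the naive reference
engine (:mod:`normknock.reference`) follow the identical protocol, so
all three produce bit-identical generations from the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import LAGGED, SAME_ROUND, SimConfig
from .norms import ASSESS_TABLE, GOOD

__all__ = [
    "GenerationState",
    "RoundRecord",
    "PayoffState",
    "init_generation",
    "play_phase_A",
    "play_phase_B",
    "run_generation",
    "draw_random_record",
    "geometric_flip_positions",
]


@dataclass
class RoundRecord:
    """Who donated to whom, and what they intended and actually did."""

    recipients: np.ndarray  # int64 (N,) — recipient index per donor
    intended: np.ndarray  # uint8 (N,) — 1 = cooperate, before the q-flip
    realized: np.ndarray  # uint8 (N,) — after the q-flip


@dataclass
class PayoffState:
    """Accumulated payoffs: U = b·W − c·V."""

    payoffs: np.ndarray  # float64 (N,)
    received: np.ndarray  # int64 (N,) — donations received (W)
    given: np.ndarray  # int64 (N,) — donations given (V)


@dataclass
class GenerationState:
    """Mutable state of one generation in progress."""

    config: SimConfig
    norms: np.ndarray  # int64 (N,)
    images: np.ndarray  # uint8 (N, N); entry (i, j) = i's image of j
    payoffs: np.ndarray  # float64 (N,)
    received: np.ndarray  # int64 (N,)
    given: np.ndarray  # int64 (N,)
    round_index: int = 0
    coop_counts: list = field(default_factory=list)

    def payoff_state(self) -> PayoffState:
        return PayoffState(self.payoffs, self.received, self.given)


def init_generation(config: SimConfig, norms: np.ndarray) -> GenerationState:
    """Fresh generation state: all images Good, payoffs zero."""
    norms = np.asarray(norms, dtype=np.int64)
    n = config.n_agents
    if norms.shape != (n,):
        raise ValueError(f"expected {n} norms, got shape {norms.shape}")
    if np.any((norms < 0) | (norms > 15)):
        raise ValueError("norm codes must be in 0..15")
    banned = np.isin(norms, list(config.knockout))
    if banned.any():
        raise ValueError(
            f"norms contain knocked-out codes at indices {np.flatnonzero(banned)[:5]}"
        )
    return GenerationState(
        config=config,
        norms=norms,
        images=np.full((n, n), GOOD, dtype=np.uint8),
        payoffs=np.zeros(n),
        received=np.zeros(n, dtype=np.int64),
        given=np.zeros(n, dtype=np.int64),
    )


def _draw_recipients(n: int, rng: np.random.RandomState) -> np.ndarray:
    u = rng.random_sample(n)
    recip = (u * (n - 1)).astype(np.int64)
    recip[recip >= np.arange(n)] += 1
    return recip


def play_phase_A(state: GenerationState, rng: np.random.RandomState) -> RoundRecord:
    """Play one round of giving games and book the payoffs."""
    cfg = state.config
    n = cfg.n_agents
    recip = _draw_recipients(n, rng)
    intended = state.images[np.arange(n), recip].copy()
    realized = intended.copy()
    if cfg.q_error > 0.0:
        flip = rng.random_sample(n) < cfg.q_error
        realized[flip] ^= 1
    coop = realized == 1
    state.payoffs -= cfg.cost * coop
    state.given += coop
    gains = np.bincount(recip[coop], minlength=n)
    state.payoffs += cfg.benefit * gains
    state.received += gains
    state.coop_counts.append(int(coop.sum()))
    state.round_index += 1
    return RoundRecord(recipients=recip, intended=intended, realized=realized)


def geometric_flip_positions(m: int, p: float, rng: np.random.RandomState):
    """Yield positions of Bernoulli(p) successes among ``m`` slots.

    Uses geometric skipping: one uniform draw per success instead of one
    per slot.  Requires 0 < p < 1.
    """
    log1mp = np.log1p(-p)
    pos = -1
    while True:
        u = rng.random_sample()
        pos += 1 + int(np.log(u) / log1mp)
        if pos >= m:
            return
        yield pos


def play_phase_B(
    state: GenerationState, record: RoundRecord, rng: np.random.RandomState
) -> np.ndarray:
    """Synchronously update every off-diagonal image from ``record``."""
    cfg = state.config
    n = cfg.n_agents
    # i's view of j's recipient, for all (i, j) at once.
    recip_image = state.images[:, record.recipients]
    new = ASSESS_TABLE[state.norms[:, None], record.realized[None, :], recip_image]
    p = cfg.p_error
    if p >= 1.0:
        new ^= 1
    elif p > 0.0:
        for pos in geometric_flip_positions(n * (n - 1), p, rng):
            i, jj = divmod(pos, n - 1)
            j = jj + 1 if jj >= i else jj
            new[i, j] ^= 1
    np.fill_diagonal(new, GOOD)
    state.images = new
    return new


def draw_random_record(n: int, rng: np.random.RandomState) -> RoundRecord:
    """Attributed random actions and pairings for lagged round-1 evaluation."""
    recip = _draw_recipients(n, rng)
    actions = (rng.random_sample(n) < 0.5).astype(np.uint8)
    return RoundRecord(recipients=recip, intended=actions, realized=actions)


def run_generation(
    config: SimConfig, norms: np.ndarray, rng: np.random.RandomState
) -> tuple[PayoffState, np.ndarray]:
    """Run R rounds; return final payoffs and per-round cooperation counts."""
    state = init_generation(config, norms)
    lagged = config.evaluation_timing == LAGGED
    prev: RoundRecord | None = None
    for t in range(config.rounds):
        record = play_phase_A(state, rng)
        if lagged:
            if prev is None:
                prev = draw_random_record(config.n_agents, rng)
            play_phase_B(state, prev, rng)
            prev = record
        else:
            play_phase_B(state, record, rng)
    return state.payoff_state(), np.asarray(state.coop_counts, dtype=np.int64)
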
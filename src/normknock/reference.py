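"""Naive reference engine.

A deliberately plain, loop-by-loop transcription of the giving-game
round used as an oracle in the test suite: every donation, payoff
transfer and image update is performed one scalar at a time with
:func:`normknock.norms.assess`, consuming random draws in the order
documented in :mod:`normknock.engine`.  Slow by design; never used by
the production driver.
"""

from __future__ import annotations

import numpy as np

from .config import LAGGED, SimConfig
from .engine import PayoffState
from .norms import assess

__all__ = ["naive_run_generation"]


def _draw_recipient(j: int, n: int, rng: np.random.RandomState) -> int:
    r = int(rng.random_sample() * (n - 1))
    return r + 1 if r >= j else r


def naive_run_generation(
    config: SimConfig, norms, rng: np.random.RandomState
) -> tuple[PayoffState, np.ndarray, np.ndarray]:
    """Run one generation naively; returns (payoffs, coop counts, images)."""
    n = config.n_agents
    norms = [int(x) for x in norms]
    images = [[1] * n for _ in range(n)]
    payoffs = [0.0] * n
    received = [0] * n
    given = [0] * n
    coop_counts = []
    lagged = config.evaluation_timing == LAGGED
    prev = None

    for t in range(config.rounds):
        # phase A --------------------------------------------------------
        recipients = [_draw_recipient(j, n, rng) for j in range(n)]
        actions = [images[j][recipients[j]] for j in range(n)]
        if config.q_error > 0.0:
            for j in range(n):
                if rng.random_sample() < config.q_error:
                    actions[j] = 1 - actions[j]
        c_count = 0
        for j in range(n):
            if actions[j] == 1:
                payoffs[j] -= config.cost
                given[j] += 1
                payoffs[recipients[j]] += config.benefit
                received[recipients[j]] += 1
                c_count += 1
        coop_counts.append(c_count)

        # evaluation source ---------------------------------------------
        if lagged:
            if prev is None:
                attr_recip = [_draw_recipient(j, n, rng) for j in range(n)]
                attr_act = [1 if rng.random_sample() < 0.5 else 0 for j in range(n)]
                eval_recip, eval_act = attr_recip, attr_act
            else:
                eval_recip, eval_act = prev
            prev = (recipients, actions)
        else:
            eval_recip, eval_act = recipients, actions

        # phase B --------------------------------------------------------
        new_images = [[1] * n for _ in range(n)]
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                new_images[i][j] = assess(
                    norms[i], eval_act[j], images[i][eval_recip[j]]
                )
        p = config.p_error
        if p >= 1.0:
            for i in range(n):
                for j in range(n):
                    if i != j:
                        new_images[i][j] = 1 - new_images[i][j]
        elif p > 0.0:
            log1mp = np.log1p(-p)
            pos = -1
            while True:
                u = rng.random_sample()
                pos += 1 + int(np.log(u) / log1mp)
                if pos >= n * (n - 1):
                    break
                i, jj = divmod(pos, n - 1)
                j = jj + 1 if jj >= i else jj
                new_images[i][j] = 1 - new_images[i][j]
        for i in range(n):
            new_images[i][i] = 1
        images = new_images

    return (
        PayoffState(
            payoffs=np.array(payoffs),
            received=np.array(received, dtype=np.int64),
            given=np.array(given, dtype=np.int64),
        ),
        np.array(coop_counts, dtype=np.int64),
        np.array(images, dtype=np.uint8),
    )
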
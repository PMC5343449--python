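"""Numba fast path for the per-generation game loop.

Implements exactly the draw protocol documented in :mod:`normknock.engine`
on numba's MT19937 ``np.random`` state, which reproduces the stream of a
``numpy.random.RandomState`` seeded with the same value.  The production
driver (:func:`normknock.experiment.run_replication`) calls this kernel;
its bit-identity with the vectorized and naive engines is part of the
test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["generation_kernel", "warm_up"]

_TIMING_SAME_ROUND = 0
_TIMING_LAGGED = 1


@njit(cache=True)
def _run(norms, rounds, benefit, cost, p, q, lagged, seed):  # pragma: no cover
    np.random.seed(seed)
    n = norms.shape[0]
    img = np.ones((n, n), dtype=np.uint8)
    new_img = np.empty((n, n), dtype=np.uint8)
    payoffs = np.zeros(n)
    received = np.zeros(n, dtype=np.int64)
    given = np.zeros(n, dtype=np.int64)
    coop_counts = np.zeros(rounds, dtype=np.int64)
    recip = np.empty(n, dtype=np.int64)
    act = np.empty(n, dtype=np.uint8)
    eval_recip = np.empty(n, dtype=np.int64)
    eval_act = np.empty(n, dtype=np.uint8)
    prev_recip = np.empty(n, dtype=np.int64)
    prev_act = np.empty(n, dtype=np.uint8)
    m_pairs = n * (n - 1)
    log1mp = np.log1p(-p) if 0.0 < p < 1.0 else 0.0

    for t in range(rounds):
        # --- phase A: recipients, q-flips, payoffs -----------------------
        for j in range(n):
            r = int(np.random.random() * (n - 1))
            if r >= j:
                r += 1
            recip[j] = r
        if q > 0.0:
            for j in range(n):
                a = img[j, recip[j]]
                if np.random.random() < q:
                    a = 1 - a
                act[j] = a
        else:
            for j in range(n):
                act[j] = img[j, recip[j]]
        c_count = 0
        for j in range(n):
            if act[j] == 1:
                payoffs[j] -= cost
                given[j] += 1
                payoffs[recip[j]] += benefit
                received[recip[j]] += 1
                c_count += 1
        coop_counts[t] = c_count

        # --- evaluation source per timing mode ---------------------------
        if lagged == _TIMING_LAGGED:
            if t == 0:
                for j in range(n):
                    r = int(np.random.random() * (n - 1))
                    if r >= j:
                        r += 1
                    eval_recip[j] = r
                for j in range(n):
                    eval_act[j] = 1 if np.random.random() < 0.5 else 0
            else:
                for j in range(n):
                    eval_recip[j] = prev_recip[j]
                    eval_act[j] = prev_act[j]
            for j in range(n):
                prev_recip[j] = recip[j]
                prev_act[j] = act[j]
        else:
            for j in range(n):
                eval_recip[j] = recip[j]
                eval_act[j] = act[j]

        # --- phase B: synchronous image update ---------------------------
        for i in range(n):
            ni = norms[i]
            for j in range(n):
                new_img[i, j] = (ni >> (2 * eval_act[j] + img[i, eval_recip[j]])) & 1
        if p >= 1.0:
            for i in range(n):
                for j in range(n):
                    new_img[i, j] = 1 - new_img[i, j]
        elif p > 0.0:
            pos = -1
            while True:
                u = np.random.random()
                pos += 1 + int(np.log(u) / log1mp)
                if pos >= m_pairs:
                    break
                i = pos // (n - 1)
                jj = pos % (n - 1)
                j = jj + 1 if jj >= i else jj
                new_img[i, j] = 1 - new_img[i, j]
        for i in range(n):
            new_img[i, i] = 1
        img, new_img = new_img, img

    return payoffs, received, given, coop_counts, img


def generation_kernel(norms, rounds, benefit, cost, p, q, timing, seed):
    """Run one generation; returns (payoffs, received, given, coop_counts, images)."""
    lagged = _TIMING_LAGGED if timing == "lagged" else _TIMING_SAME_ROUND
    return _run(
        np.ascontiguousarray(norms, dtype=np.int64),
        int(rounds),
        float(benefit),
        float(cost),
        float(p),
        float(q),
        lagged,
        int(seed),
    )


def warm_up() -> None:
    """Trigger JIT compilation on a tiny problem."""
    generation_kernel(np.zeros(2, dtype=np.int64), 1, 2.0, 1.0, 0.001, 0.001, "same_round", 0)
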
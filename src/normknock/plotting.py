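"""Basic trajectory plots: cooperation ratio and norm population ratios."""

from __future__ import annotations

import numpy as np

from .norms import NORM_NAMES
from .observables import Trajectory

__all__ = ["plot_trajectory"]


def plot_trajectory(traj: Trajectory, ax=None, top_norms: int = 6):
    """Plot the cooperation ratio and the most abundant norms over time.

    ``top_norms`` norms with the largest peak population share get
    labelled lines; the cooperation ratio is the black dotted line.
    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    frac = traj.norm_fractions()
    order = np.argsort(frac.max(axis=0))[::-1][:top_norms]
    gens = np.arange(traj.n_generations)
    for code in order:
        ax.plot(gens, frac[:, code], label=NORM_NAMES[code], lw=1)
    ax.plot(gens, traj.coop_ratio, "k:", lw=1.5, label="cooperation ratio")
    ax.set_xlabel("generation")
    ax.set_ylabel("population ratio / cooperation ratio")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8, ncol=2)
    return ax
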
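"""Replication driver, experiment sweeps, and trajectory serialization.

A *replication* is one full run: random initial norms, G generations of
the R-round giving game, and the genetic-algorithm norm update after
each generation.  An *experiment* is a Cartesian sweep over benefit
values and single-norm knockouts (plus a no-knockout control), each cell
replicated with derived seeds.

Seeding
-------
Each replication owns one ``numpy.random.RandomState`` seeded with the
replication seed.  It draws, in order: N floats for the initial norms,
then per generation one float that seeds the game engine for that
generation (scaled to an int below 2^31), followed by the evolution
draws documented in :mod:`normknock.evolution`.  Experiment cells derive
per-run seeds from the master seed via ``numpy.random.SeedSequence``
spawned on (cell index, replication index), so any cell can be
reproduced in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import SimConfig, parse_knockout
from .engine import run_generation
from .evolution import next_generation
from .norms import NORM_NAMES, N_NORMS, norm_name
from .observables import Trajectory, default_terminal_window, mean_terminal_cooperation

__all__ = [
    "PRESETS",
    "preset_config",
    "ExperimentSpec",
    "ExperimentResult",
    "run_replication",
    "run_experiment",
    "write_trajectory",
    "read_trajectory",
]

logger = logging.getLogger("normknock")

#: Scale presets: ``paper`` is the full experimental scale (hours of
#: compute); ``desk`` is the scaled-down configuration used for CI,
#: worked examples and the shipped acceptance analysis.
PRESETS: dict = {
    "paper": dict(n_agents=500, generations=1000, rounds=500, replications=50),
    "desk": dict(n_agents=200, generations=500, rounds=200, replications=10),
}


def preset_config(name: str, **overrides) -> SimConfig:
    """A :class:`SimConfig` for a named scale preset, with overrides."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    params = {k: v for k, v in PRESETS[name].items() if k != "replications"}
    params.update(overrides)
    return SimConfig(**params)


def _initial_norms(config: SimConfig, rng: np.random.RandomState) -> np.ndarray:
    """Uniform draw over the norms not knocked out (N floats)."""
    allowed = np.array(config.allowed_norms, dtype=np.int64)
    u = rng.random_sample(config.n_agents)
    return allowed[(u * allowed.size).astype(np.int64)]


def run_replication(
    config: SimConfig,
    seed: Optional[int] = None,
    use_kernel: bool = True,
    progress: bool = False,
) -> Trajectory:
    """Run one full replication and return its :class:`Trajectory`.

    ``use_kernel=False`` routes every generation through the pure-NumPy
    engine instead of the numba kernel; both paths consume identical
    random streams and produce bit-identical trajectories.
    """
    if seed is None:
        seed = config.seed
    seed = int(seed)
    rng = np.random.RandomState(seed)
    norms = _initial_norms(config, rng)

    coop_ratio = np.empty(config.generations)
    norm_counts = np.empty((config.generations, N_NORMS), dtype=np.int64)
    denom = config.n_agents * config.rounds

    gen_iter = range(config.generations)
    if progress:
        from tqdm import tqdm

        gen_iter = tqdm(gen_iter, desc=f"seed {seed}", unit="gen")

    if use_kernel:
        from ._kernel import generation_kernel

    for g in gen_iter:
        engine_seed = int(rng.random_sample() * 2**31)
        if use_kernel:
            payoffs, _, _, counts, _ = generation_kernel(
                norms,
                config.rounds,
                config.benefit,
                config.cost,
                config.p_error,
                config.q_error,
                config.evaluation_timing,
                engine_seed,
            )
        else:
            pay, counts = run_generation(
                config, norms, np.random.RandomState(engine_seed)
            )
            payoffs = pay.payoffs
        norm_counts[g] = np.bincount(norms, minlength=N_NORMS)
        coop_ratio[g] = counts.sum() / denom
        norms = next_generation(norms, payoffs, config, rng)
        logger.debug(
            "seed=%d gen=%d coop=%.3f majority=%s",
            seed, g, coop_ratio[g], norm_name(int(np.argmax(norm_counts[g]))),
        )

    traj = Trajectory(coop_ratio, norm_counts, config, seed)
    logger.info(
        "replication seed=%d done: max coop=%.3f, terminal coop=%.3f",
        seed, coop_ratio.max(),
        mean_terminal_cooperation(traj, default_terminal_window(config.generations)),
    )
    return traj


@dataclass
class ExperimentSpec:
    """A sweep over benefit values and single-norm knockouts."""

    base: SimConfig
    replications: int = 10
    b_sweep: Optional[Sequence[float]] = None
    knockout_sweep: Optional[Sequence[str]] = None  # one knockout per cell
    include_control: bool = True  # add a no-knockout cell when sweeping
    output: Optional[Path] = None
    master_seed: int = 0
    terminal_window: Optional[int] = None

    def __post_init__(self):
        if self.replications < 1:
            raise ValueError("replications must be at least 1")
        if self.b_sweep is not None:
            for b in self.b_sweep:
                if not b > self.base.cost:
                    raise ValueError(f"swept benefit {b} must exceed cost {self.base.cost}")

    def cells(self) -> list:
        """(b, knockout-name-or-None) pairs, in sweep order."""
        bs = list(self.b_sweep) if self.b_sweep else [self.base.benefit]
        kos: list = []
        if self.knockout_sweep:
            if self.include_control:
                kos.append(None)
            kos.extend(self.knockout_sweep)
        else:
            kos.append(
                None if not self.base.knockout else ",".join(self.base.knockout_names)
            )
        return [(b, ko) for b in bs for ko in kos]


@dataclass
class ExperimentResult:
    spec: ExperimentSpec
    summary: pd.DataFrame  # one row per cell
    trajectories: dict = field(default_factory=dict)  # (b, ko) -> [Trajectory]


def _cell_seed(master: int, cell_index: int, rep: int) -> int:
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=(cell_index, rep))
    return int(ss.generate_state(1)[0] % 2**31)


def run_experiment(spec: ExperimentSpec, use_kernel: bool = True) -> ExperimentResult:
    """Run every (benefit × knockout) cell and summarize terminal cooperation."""
    outdir = None
    if spec.output is not None:
        outdir = Path(spec.output)
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        try:
            probe.write_text("")
            probe.unlink()
        except OSError as exc:  # fail before burning compute
            raise OSError(f"output path {outdir} is not writable: {exc}") from exc

    rows = []
    trajectories: dict = {}
    for cell_index, (b, ko) in enumerate(spec.cells()):
        knockout = frozenset() if ko is None else parse_knockout(ko)
        config = spec.base.replace(benefit=b, knockout=knockout)
        window = spec.terminal_window or default_terminal_window(config.generations)
        runs = []
        for rep in range(spec.replications):
            run_seed = _cell_seed(spec.master_seed, cell_index, rep)
            traj = run_replication(config, seed=run_seed, use_kernel=use_kernel)
            runs.append(traj)
            if outdir is not None:
                label = ko.replace(",", "+") if ko else "control"
                write_trajectory(
                    traj, outdir / f"traj_b{b:g}_{label}_rep{rep}.csv"
                )
        terms = np.array([mean_terminal_cooperation(t, window) for t in runs])
        trajectories[(b, ko)] = runs
        rows.append(
            dict(
                b=b,
                knockout=ko or "-",
                replications=spec.replications,
                terminal_window=window,
                mean_terminal_coop=terms.mean(),
                std_terminal_coop=terms.std(ddof=1) if terms.size > 1 else 0.0,
                max_coop=float(np.mean([t.coop_ratio.max() for t in runs])),
            )
        )
        logger.info(
            "cell b=%g knockout=%s: mean terminal coop %.3f",
            b, ko or "-", rows[-1]["mean_terminal_coop"],
        )

    summary = pd.DataFrame(rows)
    if outdir is not None:
        summary.to_csv(outdir / "summary.csv", index=False)
        payload = {
            f"b={r['b']:g},knockout={r['knockout']}": {
                "mean_terminal_coop": r["mean_terminal_coop"],
                "std_terminal_coop": r["std_terminal_coop"],
            }
            for r in rows
        }
        (outdir / "summary.json").write_text(json.dumps(payload, indent=2))
    return ExperimentResult(spec=spec, summary=summary, trajectories=trajectories)


# ---------------------------------------------------------------------------
# Trajectory files: CSV with '#'-prefixed header lines carrying the config.

_FORMAT_TAG = "normknock-trajectory v1"


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as UTF-8 CSV, config in comment headers."""
    path = Path(path)
    mapping = traj.config.to_mapping()
    mapping["seed"] = traj.seed
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# {_FORMAT_TAG}\n")
        fh.write("# " + " ".join(f"{k}={v}" for k, v in mapping.items()) + "\n")
        fh.write("generation,coop_ratio," + ",".join(NORM_NAMES) + "\n")
        for g in range(traj.n_generations):
            counts = ",".join(str(int(c)) for c in traj.norm_counts[g])
            fh.write(f"{g},{float(traj.coop_ratio[g])!r},{counts}\n")


def read_trajectory(path) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory` (lossless)."""
    path = Path(path)
    meta: dict = {}
    expected_cols = 2 + N_NORMS
    header = ["generation", "coop_ratio"] + list(NORM_NAMES)
    coop, counts = [], []
    with path.open("r", encoding="utf-8") as fh:
        saw_header = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    if "=" in token:
                        k, v = token.split("=", 1)
                        meta[k] = v
                continue
            fields = line.split(",")
            if not saw_header:
                if fields != header:
                    raise ValueError(
                        f"{path}:{lineno}: bad column header {fields[:3]}..."
                    )
                saw_header = True
                continue
            if len(fields) != expected_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected {expected_cols} columns, "
                    f"got {len(fields)}"
                )
            try:
                int(fields[0])
                coop.append(float(fields[1]))
                counts.append([int(x) for x in fields[2:]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    if not saw_header or not coop:
        raise ValueError(f"{path}: no trajectory data found")
    seed = int(meta.pop("seed", 0))
    config = SimConfig.from_mapping(
        {
            "N": int(meta["N"]),
            "G": int(meta["G"]),
            "R": int(meta["R"]),
            "b": float(meta["b"]),
            "c": float(meta["c"]),
            "p": float(meta["p"]),
            "q": float(meta["q"]),
            "m": float(meta["m"]),
            "knockout": meta.get("knockout", "-"),
            "evaluation_timing": meta.get("timing", "same_round"),
        }
    )
    return Trajectory(np.array(coop), np.array(counts, dtype=np.int64), config, seed)
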
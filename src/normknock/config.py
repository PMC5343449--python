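"""Simulation configuration."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .norms import N_NORMS, norm_from_string, norm_name

__all__ = ["SimConfig", "SAME_ROUND", "LAGGED"]

SAME_ROUND = "same_round"
LAGGED = "lagged"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulation run.

    Attributes
    ----------
    n_agents : int
        Population size N (≥ 2).
    generations : int
        Number of generations G.
    rounds : int
        Giving-game rounds R per generation; every agent donates once
        per round.
    benefit, cost : float
        Payoff b received by the recipient and cost c paid by a
        cooperating donor; requires b > c > 0.
    p_error : float
        Perception error — probability that a freshly updated image is
        recorded inverted.
    q_error : float
        Implementation error — probability that a donor's action is
        executed inverted.
    mutation_rate : float
        Per-locus mutation probability m in the genetic algorithm.
    knockout : frozenset[int]
        Norm codes banned from the population (strict subset of the 16).
    seed : int
        Default replication seed.
    evaluation_timing : str
        ``"lagged"`` (default): in each round, observers evaluate the
        previous round's realized actions; in round 1 each donor is
        attributed a uniformly random action and recipient (with every
        image still Good, the attributed recipient is inconsequential).
        ``"same_round"``: observers evaluate the current round's
        actions.  The lagged rule is the default because only it
        renders the strict norms indispensable — knocking out SH or IS
        then collapses cooperation, while under same-round evaluation
        cooperation survives those knockouts.
    """

    n_agents: int = 500
    generations: int = 1000
    rounds: int = 500
    benefit: float = 5.0
    cost: float = 1.0
    p_error: float = 0.0
    q_error: float = 0.0
    mutation_rate: float = 0.01
    knockout: frozenset = field(default_factory=frozenset)
    seed: int = 0
    evaluation_timing: str = LAGGED

    def __post_init__(self):
        if self.n_agents < 2:
            raise ValueError("n_agents must be at least 2")
        if self.generations < 1 or self.rounds < 1:
            raise ValueError("generations and rounds must be at least 1")
        if not (self.benefit > self.cost > 0):
            raise ValueError("require benefit > cost > 0")
        for name in ("p_error", "q_error", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        ko = frozenset(
            norm_from_string(k) if isinstance(k, str) else int(k)
            for k in self.knockout
        )
        if any(not 0 <= k < N_NORMS for k in ko):
            raise ValueError("knockout contains an invalid norm code")
        if len(ko) >= N_NORMS:
            raise ValueError("cannot knock out all 16 norms")
        object.__setattr__(self, "knockout", ko)
        if self.evaluation_timing not in (SAME_ROUND, LAGGED):
            raise ValueError(
                f"evaluation_timing must be {SAME_ROUND!r} or {LAGGED!r}"
            )

    @property
    def allowed_norms(self) -> tuple:
        """Sorted norm codes not knocked out."""
        return tuple(c for c in range(N_NORMS) if c not in self.knockout)

    @property
    def knockout_names(self) -> tuple:
        return tuple(norm_name(c) for c in sorted(self.knockout))

    def replace(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)

    # Table-style short keys used in config files and trajectory headers.
    _SHORT_KEYS = {
        "N": "n_agents",
        "G": "generations",
        "R": "rounds",
        "b": "benefit",
        "c": "cost",
        "p": "p_error",
        "q": "q_error",
        "m": "mutation_rate",
    }

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "SimConfig":
        """Build a config from a dict using either attribute names or the
        conventional one-letter keys (N, G, R, b, c, p, q, m)."""
        kwargs = {}
        for key, value in mapping.items():
            name = cls._SHORT_KEYS.get(key, key)
            if name == "knockout" and isinstance(value, (str, list, tuple)):
                value = _parse_knockout(value)
            kwargs[name] = value
        return cls(**kwargs)

    def to_mapping(self) -> dict:
        return {
            "N": self.n_agents,
            "G": self.generations,
            "R": self.rounds,
            "b": self.benefit,
            "c": self.cost,
            "p": self.p_error,
            "q": self.q_error,
            "m": self.mutation_rate,
            "knockout": ",".join(self.knockout_names) or "-",
            "timing": self.evaluation_timing,
            "seed": self.seed,
        }


def _parse_knockout(value) -> frozenset:
    if isinstance(value, str):
        value = [] if value.strip() in ("", "-") else value.split(",")
    return frozenset(norm_from_string(v) if isinstance(v, str) else int(v) for v in value)


def parse_knockout(value: Iterable) -> frozenset:
    """Normalize a knockout specification (names, genotypes or codes)."""
    return _parse_knockout(value)
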
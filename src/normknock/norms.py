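"""Assessment norms for the indirect-reciprocity giving game.

A norm is an assessment rule: given a donor's action (cooperate/defect)
and the observer's current image of the recipient (Good/Bad), it returns
a new image of the donor.  With two actions and two images there are
2^4 = 16 possible norms, written as four-letter G/B genotypes read
locus 1 to locus 4:

    locus 1 — assessment of cooperation toward a Good recipient
    locus 2 — assessment of cooperation toward a Bad recipient
    locus 3 — assessment of defection against a Good recipient
    locus 4 — assessment of defection against a Bad recipient

Norms are encoded as integers 0..15 with locus 1 as the most significant
bit and G = 1, so ``ALLG`` (GGGG) is 15 and ``ALLB`` (BBBB) is 0.  The
well-known norms carry their conventional short names; the remaining ten
are named by their genotype string.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "GOOD",
    "BAD",
    "COOPERATE",
    "DEFECT",
    "N_NORMS",
    "ALLG",
    "ALLB",
    "SH",
    "SJ",
    "IS",
    "ST",
    "NORM_NAMES",
    "ASSESS_TABLE",
    "assess",
    "norm_from_string",
    "norm_to_string",
    "norm_name",
    "norm_family_matches",
    "all_norms",
]

# Binary labels.  Images: Good=1 / Bad=0.  Actions: cooperate=1 / defect=0.
GOOD: int = 1
BAD: int = 0
COOPERATE: int = 1
DEFECT: int = 0

N_NORMS: int = 16

# Canonical named norms (integer codes).
ALLG: int = 0b1111  # GGGG — assesses everyone Good
ALLB: int = 0b0000  # BBBB — assesses everyone Bad
SH: int = 0b1000  # Shunning, GBBB — anything toward a Bad recipient is Bad
SJ: int = 0b1001  # Stern Judging, GBBG — helping Bad is Bad, punishing Bad is Good
IS: int = 0b1100  # Image Scoring, GGBB — judges by action only
ST: int = 0b1101  # Simple Standing, GGBG — tolerant; only unjustified defection is Bad

_SPECIAL_NAMES: dict[int, str] = {
    ALLG: "ALLG",
    ALLB: "ALLB",
    SH: "SH",
    SJ: "SJ",
    IS: "IS",
    ST: "ST",
}

_LETTER = {GOOD: "G", BAD: "B"}


def _check_code(norm: int) -> None:
    if not 0 <= int(norm) < N_NORMS:
        raise ValueError(f"norm code out of range 0..15: {norm!r}")


def norm_to_string(norm: int) -> str:
    """Return the four-letter G/B genotype of ``norm``, locus 1 first."""
    _check_code(norm)
    return "".join(_LETTER[(norm >> shift) & 1] for shift in (3, 2, 1, 0))


#: Canonical label of each norm code: short name if it has one, genotype otherwise.
NORM_NAMES: tuple[str, ...] = tuple(
    _SPECIAL_NAMES.get(code, norm_to_string(code)) for code in range(N_NORMS)
)

_NAME_TO_CODE: dict[str, int] = {name: code for code, name in enumerate(NORM_NAMES)}
_NAME_TO_CODE.update({norm_to_string(code): code for code in range(N_NORMS)})


def norm_from_string(label: str) -> int:
    """Parse a norm label — a four-letter G/B genotype or a short name.

    Case-insensitive; ``"GBBG"`` and ``"SJ"`` both give the Stern
    Judging code.  Raises :class:`ValueError` for anything else.
    """
    if not isinstance(label, str):
        raise ValueError(f"norm label must be a string, got {label!r}")
    key = label.strip().upper()
    try:
        return _NAME_TO_CODE[key]
    except KeyError:
        raise ValueError(f"unknown norm label: {label!r}") from None


def norm_name(norm: int) -> str:
    """Canonical label of a norm code (short name where one exists)."""
    _check_code(norm)
    return NORM_NAMES[norm]


def assess(norm: int, action: int, image_of_recipient: int) -> int:
    """Evaluate a donor under ``norm``.

    ``action`` is the donor's realized action (1 = cooperate) and
    ``image_of_recipient`` is the observer's current image of the
    donor's recipient (1 = Good).  Returns the new image of the donor.
    Pure locus lookup — error noise is applied by the engine, not here.
    """
    _check_code(norm)
    if action not in (0, 1) or image_of_recipient not in (0, 1):
        raise ValueError("action and image must be 0 or 1")
    # Locus bit positions: (C,G)->3, (C,B)->2, (D,G)->1, (D,B)->0.
    return (int(norm) >> (2 * action + image_of_recipient)) & 1


def _build_assess_table() -> np.ndarray:
    table = np.empty((N_NORMS, 2, 2), dtype=np.uint8)
    for n in range(N_NORMS):
        for a in (0, 1):
            for i in (0, 1):
                table[n, a, i] = (n >> (2 * a + i)) & 1
    table.setflags(write=False)
    return table


#: Lookup table ``ASSESS_TABLE[norm, action, image] -> new image`` (uint8).
ASSESS_TABLE: np.ndarray = _build_assess_table()


def norm_family_matches(norm: int, pattern: str) -> bool:
    """True iff the norm's genotype matches ``pattern`` over {G, B, *}.

    ``*`` is a wildcard, e.g. ``"**BB"`` selects the norms that assess
    any defection as Bad at loci 3 and 4.
    """
    _check_code(norm)
    if len(pattern) != 4 or any(ch not in "GB*" for ch in pattern.upper()):
        raise ValueError(f"pattern must be 4 characters over {{G,B,*}}: {pattern!r}")
    genotype = norm_to_string(norm)
    return all(p == "*" or p == g for p, g in zip(pattern.upper(), genotype))


def all_norms() -> np.ndarray:
    """All 16 norm codes as an int64 array."""
    return np.arange(N_NORMS, dtype=np.int64)
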
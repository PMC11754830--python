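"""Secondary-structure parsing, serialization, and paired/unpaired labels.

Structures live on an analysis window and are stored as a 1-based pair
table (partner index within the window, 0 = unpaired). Pseudoknot-free
structures round-trip losslessly through dot-bracket; pseudoknotted pair
tables are representable (for externally supplied models, e.g. via CT) but
rejected by dot-bracket serialization unless bracket tiers are enabled.

The CT dialect is the 6-column variant (index, base, prev, next, partner,
natural index); a header line with the length is written and tolerated
absent on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reference import ReferenceWindow

__all__ = [
    "SecondaryStructure",
    "parse_structure",
    "parse_dot_bracket",
    "parse_ct",
    "write_ct",
    "paired_labels",
]

_OPEN = "([{<"
_CLOSE = ")]}>"


@dataclass(frozen=True)
class SecondaryStructure:
    """A secondary structure over an analysis window.

    ``pair_table[i]`` is the 1-based partner of window position i+1, or 0 if
    unpaired. The table must be an involution with no self-pairs.
    """

    ref_id: str
    window: ReferenceWindow
    pair_table: tuple[int, ...]

    def __post_init__(self) -> None:
        n = self.window.width
        if len(self.pair_table) != n:
            raise ValueError(
                f"pair table length {len(self.pair_table)} != window width {n}"
            )
        for i, j in enumerate(self.pair_table, start=1):
            if j == 0:
                continue
            if not (1 <= j <= n):
                raise ValueError(f"partner {j} of position {i} out of range 1..{n}")
            if j == i:
                raise ValueError(f"position {i} pairs with itself")
            if self.pair_table[j - 1] != i:
                raise ValueError(f"pair table not an involution at ({i}, {j})")

    @property
    def pairs(self) -> frozenset[tuple[int, int]]:
        """Base pairs as (i, j) with i < j, 1-based window coordinates."""
        return frozenset(
            (i, j) for i, j in enumerate(self.pair_table, start=1) if j > i
        )

    @property
    def paired(self) -> np.ndarray:
        """Boolean per window position: True where paired."""
        return np.array(self.pair_table) > 0

    def is_pseudoknotted(self) -> bool:
        pairs = sorted(self.pairs)
        for a in range(len(pairs)):
            i, j = pairs[a]
            for k, l in pairs[a + 1 :]:
                if i < k < j < l:
                    return True
        return False

    def to_dot_bracket(self, allow_pseudoknots: bool = False) -> str:
        """Serialize to dot-bracket; bracket tiers only if explicitly enabled."""
        out = ["."] * self.window.width
        # assign each pair to the first tier where it does not cross
        tiers: list[list[tuple[int, int]]] = []
        for i, j in sorted(self.pairs):
            placed = False
            for t, tier in enumerate(tiers):
                if not any(k < i < l < j or i < k < j < l for k, l in tier):
                    tier.append((i, j))
                    placed = True
                    break
            if not placed:
                tiers.append([(i, j)])
        if len(tiers) > 1 and not allow_pseudoknots:
            raise ValueError(
                "pseudoknotted structure cannot be serialized to single-tier "
                "dot-bracket; pass allow_pseudoknots=True for bracket tiers"
            )
        if len(tiers) > len(_OPEN):
            raise ValueError("too many pseudoknot tiers for bracket alphabet")
        for t, tier in enumerate(tiers):
            for i, j in tier:
                out[i - 1] = _OPEN[t]
                out[j - 1] = _CLOSE[t]
        return "".join(out)


def parse_dot_bracket(text: str, window: ReferenceWindow) -> SecondaryStructure:
    """Parse a dot-bracket string (multi-tier brackets accepted)."""
    text = text.strip()
    if len(text) != window.width:
        raise ValueError(
            f"structure length {len(text)} != window width {window.width}"
        )
    table = [0] * len(text)
    stacks: dict[int, list[int]] = {t: [] for t in range(len(_OPEN))}
    for pos, ch in enumerate(text, start=1):
        if ch == ".":
            continue
        if ch in _OPEN:
            stacks[_OPEN.index(ch)].append(pos)
        elif ch in _CLOSE:
            stack = stacks[_CLOSE.index(ch)]
            if not stack:
                raise ValueError(f"unbalanced bracket {ch!r} at position {pos}")
            i = stack.pop()
            table[i - 1] = pos
            table[pos - 1] = i
        else:
            raise ValueError(f"invalid structure character {ch!r} at position {pos}")
    for t, stack in stacks.items():
        if stack:
            raise ValueError(f"unbalanced bracket {_OPEN[t]!r} at position {stack[-1]}")
    return SecondaryStructure(window.ref_id, window, tuple(table))


def parse_ct(text: str, window: ReferenceWindow) -> SecondaryStructure:
    """Parse 6-column CT content; the header line is optional."""
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise ValueError("empty CT content")
    rows = []
    for ln in lines:
        fields = ln.split()
        # header: first field is the length and the line has < 6 columns or
        # a non-integer somewhere in columns 2..6
        if not rows and (len(fields) < 6 or not fields[4].lstrip("-").isdigit()):
            continue
        if len(fields) < 6:
            raise ValueError(f"CT line has {len(fields)} columns, expected 6: {ln!r}")
        rows.append((int(fields[0]), fields[1], int(fields[4])))
    if len(rows) != window.width:
        raise ValueError(f"CT has {len(rows)} positions, window width {window.width}")
    table = [0] * window.width
    for idx, _base, partner in rows:
        if not (1 <= idx <= window.width):
            raise ValueError(f"CT index {idx} out of range")
        if partner < 0 or partner > window.width:
            raise ValueError(f"CT partner {partner} out of range for position {idx}")
        table[idx - 1] = partner
    return SecondaryStructure(window.ref_id, window, tuple(table))


def parse_structure(text: str, window: ReferenceWindow) -> SecondaryStructure:
    """Parse dot-bracket or CT content, auto-detected.

    Dot-bracket records may be one line (structure) or two lines (sequence,
    structure); CT is recognized by its numeric first column.
    """
    lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty structure content")
    first = lines[0].split()[0]
    if set(lines[-1]) <= set("." + _OPEN + _CLOSE):
        # dot-bracket; tolerate a leading sequence line
        return parse_dot_bracket(lines[-1], window)
    if first.isdigit():
        return parse_ct(text, window)
    raise ValueError("unrecognized structure format (expected dot-bracket or CT)")


def write_ct(structure: SecondaryStructure, title: str | None = None) -> str:
    """Serialize to 6-column CT text with a length header line."""
    window = structure.window
    seq = window.window_sequence
    n = window.width
    lines = [f"{n} {title or structure.ref_id}"]
    for i in range(1, n + 1):
        lines.append(
            f"{i} {seq[i - 1]} {i - 1} {(i + 1) % (n + 1)} "
            f"{structure.pair_table[i - 1]} {i}"
        )
    return "\n".join(lines) + "\n"


def paired_labels(
    structure: SecondaryStructure, ac_only: bool = True
) -> dict[int, bool]:
    """Per-position paired/unpaired labels for ROC scoring.

    Returns a mapping from 1-based window position to True (paired) or
    False (unpaired). With ``ac_only`` (the default) labels exist only at
    A and C positions, the bases DMS reports on.
    """
    seq = structure.window.window_sequence
    labels: dict[int, bool] = {}
    for i in range(1, structure.window.width + 1):
        if ac_only and seq[i - 1] not in "AC":
            continue
        labels[i] = structure.pair_table[i - 1] > 0
    return labels
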
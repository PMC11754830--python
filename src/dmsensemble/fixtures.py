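"""Synthetic reference and structure fixtures.

Everything here is *synthetic*: a designed 451-nt telomerase-RNA-like
reference whose two analysis windows (22-204, a template/pseudoknot-domain
stand-in, and 213-368, a three-way-junction-domain stand-in) each support
two alternative secondary structures — a canonical-like fold and a
register-shifted alternative fold. The published structures for the real
RNA exist only as figures; these fixtures are NOT transcriptions of them.
They reproduce the *statistical* situation the analysis faces (two folds
sharing one sequence, differing pairing status at many A/C positions), not
any experimentally determined pairing.

The sequence is solved from the pairing constraints: the union of the two
pair tables forms chains of positions linked by complementarity, each
chain assigned alternating Watson-Crick partners; positions unpaired in
both folds are filled A/C-rich, since those carry the DMS signal.
"""

from __future__ import annotations

from functools import lru_cache

from .reference import ReferenceWindow
from .structures import SecondaryStructure

__all__ = [
    "REF_ID",
    "REF_LENGTH",
    "synthetic_reference",
    "tpk_window",
    "cr45_window",
    "tpk_structures",
    "cr45_structures",
    "cr45_bulge_positions",
    "hairpin_window",
    "hairpin_structure",
    "junction_window",
    "junction_structure",
]

REF_ID = "synthetic_hTR_like"
REF_LENGTH = 451

TPK_BOUNDS = (22, 204)
CR45_BOUNDS = (213, 368)

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

# seeds cycled across complementarity chains: GC-rich with AU mixed in
_CHAIN_SEEDS = "GCAGUCGA"
# fill pattern for positions unpaired in every fold: A/C-rich with a few G/U
_FREE_PATTERN = "ACCAUACCAAGCACCA"


def _helix(a: int, b: int, length: int) -> list[tuple[int, int]]:
    """Pairs (a+t, b-t) for t = 0..length-1, 1-based local coordinates."""
    return [(a + t, b - t) for t in range(length)]


def _pair_table(width: int, helices: list[list[tuple[int, int]]]) -> tuple[int, ...]:
    table = [0] * width
    for helix in helices:
        for i, j in helix:
            if table[i - 1] or table[j - 1]:
                raise ValueError(f"position reuse in fixture design at ({i}, {j})")
            table[i - 1] = j
            table[j - 1] = i
    return tuple(table)


def design_sequence(width: int, pair_tables: list[tuple[int, ...]]) -> str:
    """Solve a sequence compatible with every supplied pair table.

    Builds the union graph of all pairings (each node has degree <= number
    of structures); its connected components are chains (or even cycles)
    along which bases must alternate with their Watson-Crick complement.
    Raises on odd cycles, which admit no complementary assignment.
    """
    adj: list[set[int]] = [set() for _ in range(width + 1)]
    for table in pair_tables:
        if len(table) != width:
            raise ValueError("pair table width mismatch")
        for i, j in enumerate(table, start=1):
            if j:
                adj[i].add(j)
                adj[j].add(i)
    bases = [""] * (width + 1)
    seed_cycle = 0
    free_cycle = 0
    for start in range(1, width + 1):
        if bases[start] or adj[start]:
            continue
        bases[start] = _FREE_PATTERN[free_cycle % len(_FREE_PATTERN)]
        free_cycle += 1
    for start in range(1, width + 1):
        if bases[start] or not adj[start]:
            continue
        # prefer chain endpoints (degree 1) so cycles are caught explicitly
        component = _component(adj, start)
        endpoints = [v for v in component if len(adj[v]) == 1]
        origin = min(endpoints) if endpoints else min(component)
        seed = _CHAIN_SEEDS[seed_cycle % len(_CHAIN_SEEDS)]
        seed_cycle += 1
        _propagate(adj, bases, origin, seed)
    return "".join(bases[1:])


def _component(adj: list[set[int]], start: int) -> list[int]:
    seen = {start}
    stack = [start]
    while stack:
        v = stack.pop()
        for u in adj[v]:
            if u not in seen:
                seen.add(u)
                stack.append(u)
    return sorted(seen)


def _propagate(adj: list[set[int]], bases: list[str], origin: int, seed: str) -> None:
    bases[origin] = seed
    stack = [origin]
    while stack:
        v = stack.pop()
        for u in adj[v]:
            want = _COMPLEMENT[bases[v]]
            if bases[u]:
                if bases[u] != want:
                    raise ValueError(
                        "fixture pairing constraints unsatisfiable (odd cycle)"
                    )
                continue
            bases[u] = want
            stack.append(u)


# --- window structure layouts (1-based local coordinates) -------------------

_CR45_WIDTH = CR45_BOUNDS[1] - CR45_BOUNDS[0] + 1  # 156
_TPK_WIDTH = TPK_BOUNDS[1] - TPK_BOUNDS[0] + 1  # 183

_CR45_CANONICAL = [
    _helix(3, 154, 10),  # closing stem
    _helix(17, 60, 10),  # branch 1
    _helix(30, 47, 7),
    _helix(65, 140, 10),  # branch 2
    _helix(79, 126, 9),
    _helix(92, 113, 8),
]
_CR45_ALTERNATIVE = [
    _helix(3, 154, 10),  # closing stem shared between folds
    _helix(17, 140, 12),  # register-shifted linear stem
    _helix(33, 124, 12),
    _helix(49, 108, 12),
    _helix(65, 92, 8),
]

_TPK_CANONICAL = [
    _helix(4, 180, 12),
    _helix(40, 95, 12),
    _helix(56, 79, 8),
    _helix(100, 164, 12),
    _helix(116, 148, 10),
]
# The alternative fold keeps only the outer stem and rearranges everything
# else: the template-side single-stranded blocks of the canonical fold pair
# up while most canonical helices melt — the pairing status flips at the
# bulk of the window, emulating a wholesale loss of the canonical
# architecture rather than a local register shift.
_TPK_ALTERNATIVE = [
    _helix(4, 180, 12),  # outer stem shared between folds
    _helix(16, 138, 12),  # template block paired against the big loop
    _helix(52, 63, 4),
    _helix(64, 115, 4),
    _helix(68, 99, 4),
    _helix(149, 168, 4),
]


@lru_cache(maxsize=None)
def _window_sequences() -> tuple[str, str]:
    cr45 = design_sequence(
        _CR45_WIDTH,
        [
            _pair_table(_CR45_WIDTH, _CR45_CANONICAL),
            _pair_table(_CR45_WIDTH, _CR45_ALTERNATIVE),
        ],
    )
    tpk = design_sequence(
        _TPK_WIDTH,
        [
            _pair_table(_TPK_WIDTH, _TPK_CANONICAL),
            _pair_table(_TPK_WIDTH, _TPK_ALTERNATIVE),
        ],
    )
    return tpk, cr45


@lru_cache(maxsize=None)
def synthetic_reference() -> str:
    """The full 451-nt synthetic reference sequence (RNA alphabet)."""
    tpk, cr45 = _window_sequences()
    filler = (_FREE_PATTERN * 40)
    seq = (
        filler[: TPK_BOUNDS[0] - 1]
        + tpk
        + filler[: CR45_BOUNDS[0] - TPK_BOUNDS[1] - 1]
        + cr45
        + filler[: REF_LENGTH - CR45_BOUNDS[1]]
    )
    assert len(seq) == REF_LENGTH
    return seq


def tpk_window() -> ReferenceWindow:
    """Template/pseudoknot-domain stand-in window, nt 22-204 (width 183)."""
    return ReferenceWindow(REF_ID, synthetic_reference(), *TPK_BOUNDS)


def cr45_window() -> ReferenceWindow:
    """Three-way-junction-domain stand-in window, nt 213-368 (width 156)."""
    return ReferenceWindow(REF_ID, synthetic_reference(), *CR45_BOUNDS)


def cr45_structures() -> tuple[SecondaryStructure, SecondaryStructure]:
    """(canonical-like three-way junction, register-shifted alternative)."""
    window = cr45_window()
    return (
        SecondaryStructure(REF_ID, window, _pair_table(_CR45_WIDTH, _CR45_CANONICAL)),
        SecondaryStructure(REF_ID, window, _pair_table(_CR45_WIDTH, _CR45_ALTERNATIVE)),
    )


def tpk_structures() -> tuple[SecondaryStructure, SecondaryStructure]:
    """(canonical-like fold, extended stem-loop alternative)."""
    window = tpk_window()
    return (
        SecondaryStructure(REF_ID, window, _pair_table(_TPK_WIDTH, _TPK_CANONICAL)),
        SecondaryStructure(REF_ID, window, _pair_table(_TPK_WIDTH, _TPK_ALTERNATIVE)),
    )


def cr45_bulge_positions() -> tuple[int, int, int, int]:
    """Four A/C positions unpaired in the canonical fold (local, 1-based).

    Stand-ins for the helical-bulge positions whose protection difference
    separates the two purified-RNP reactivity clusters: two adjacent
    positions in each of two distinct interior loops, mirroring the
    two-nucleotide bulges on either strand of a stem.
    """
    window = cr45_window()
    canonical, _ = cr45_structures()
    seq = window.window_sequence

    def adjacent_pair(lo: int, hi: int) -> tuple[int, int]:
        for i in range(lo, hi):
            if (
                seq[i - 1] in "AC"
                and seq[i] in "AC"
                and canonical.pair_table[i - 1] == 0
                and canonical.pair_table[i] == 0
            ):
                return (i, i + 1)
        raise RuntimeError("fixture design lost its bulge A/C positions")

    first = adjacent_pair(57, 70)
    second = adjacent_pair(71, 84)
    return first + second


# --- small folding fixtures -------------------------------------------------

_HAIRPIN_LEN = 20
_HAIRPIN_HELICES = [_helix(1, 20, 7)]  # 1-7 paired with 14-20, loop 8-13

_JUNCTION_LEN = 48
_JUNCTION_HELICES = [
    _helix(1, 48, 8),  # outer stem
    _helix(11, 28, 6),  # branch 1, loop 17-22
    _helix(30, 40, 4),  # branch 2, loop 34-36
]


@lru_cache(maxsize=None)
def hairpin_window() -> ReferenceWindow:
    """A 20-nt synthetic hairpin: 7-bp stem, A/C-rich 6-nt loop."""
    seq = design_sequence(_HAIRPIN_LEN, [_pair_table(_HAIRPIN_LEN, _HAIRPIN_HELICES)])
    return ReferenceWindow("synthetic_hairpin", seq, 1, _HAIRPIN_LEN)


def hairpin_structure() -> SecondaryStructure:
    return SecondaryStructure(
        "synthetic_hairpin", hairpin_window(), _pair_table(_HAIRPIN_LEN, _HAIRPIN_HELICES)
    )


@lru_cache(maxsize=None)
def junction_window() -> ReferenceWindow:
    """A 48-nt synthetic three-way junction with two hairpin branches."""
    seq = design_sequence(_JUNCTION_LEN, [_pair_table(_JUNCTION_LEN, _JUNCTION_HELICES)])
    return ReferenceWindow("synthetic_junction", seq, 1, _JUNCTION_LEN)


def junction_structure() -> SecondaryStructure:
    return SecondaryStructure(
        "synthetic_junction",
        junction_window(),
        _pair_table(_JUNCTION_LEN, _JUNCTION_HELICES),
    )
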
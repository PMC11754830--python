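"""Per-read mutation bit vectors and read-quality filters.

Each aligned read (or merged mate pair) becomes a ternary code vector over
the analysis window: MATCH (0) where the call agrees with the reference,
MUTATION (1) at mismatches and deleted reference positions, and
UNINFORMATIVE at absent, low-quality, or mate-discordant positions. Four
quality rules then discard unreliable vectors:

1. ``too_uninformative`` — 50% or more of window positions uninformative;
2. ``high_mutation_fraction`` — mutations exceeding 10% of informative
   positions;
3. ``close_mutations`` — two mutations within a span of four nucleotides
   (distance < ``min_mutation_gap``);
4. ``mutation_adjacent_uninformative`` — a mutation next to an
   uninformative position.

Rules are conjunctive, so the retained set never depends on their order;
the per-rule discard counts use first-failure attribution in the order
above. A fifth count, ``short_read``, tracks reads dropped at ingestion for
a merged alignment footprint below the minimum read length.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
import numpy as np
import pysam

from .reference import ReferenceWindow

__all__ = [
    "MATCH",
    "MUTATION",
    "UNINFORMATIVE",
    "BitMatrix",
    "FilterReport",
    "ReadObservation",
    "reads_from_sam",
    "make_bitvector",
    "sam_to_bitmatrix",
    "filter_bitvectors",
    "deduplicate",
]

MATCH = np.int8(0)
MUTATION = np.int8(1)
UNINFORMATIVE = np.int8(2)

_CODE_CHARS = {0: "0", 1: "1", 2: "?"}

# sentinel quality for mate-overlap disagreement: never trusted
_DISCORDANT_QUAL = -1
# sentinel base for a deleted reference position
DELETION = "-"


@dataclass
class BitMatrix:
    """A population of bit vectors over one analysis window.

    ``codes`` is (n_vectors, window_width) int8 over {MATCH, MUTATION,
    UNINFORMATIVE}; ``weights`` carries multiplicities after deduplication
    (all ones otherwise). ``informative_mask`` marks the A/C positions
    eligible for clustering; it is False at every G/U position.
    """

    window: ReferenceWindow
    codes: np.ndarray
    read_ids: list[str]
    weights: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2 or self.codes.shape[1] != self.window.width:
            raise ValueError(
                f"codes shape {self.codes.shape} incompatible with window width "
                f"{self.window.width}"
            )
        if self.weights is None:
            self.weights = np.ones(len(self.codes))
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.codes) or len(self.read_ids) != len(self.codes):
            raise ValueError("codes, read_ids and weights must have equal length")

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def n_reads(self) -> float:
        """Total retained reads (sum of multiplicities)."""
        return float(self.weights.sum())

    @property
    def informative_mask(self) -> np.ndarray:
        return self.window.ac_mask

    def subset(self, keep: np.ndarray) -> "BitMatrix":
        idx = np.flatnonzero(keep) if keep.dtype == bool else np.asarray(keep)
        return BitMatrix(
            self.window,
            self.codes[idx],
            [self.read_ids[i] for i in idx],
            self.weights[idx],
        )

    def to_table(self) -> str:
        """Tab-separated text table: read_id, code string over {0, 1, ?}."""
        lines = ["read_id\tbits\tweight"]
        for rid, row, w in zip(self.read_ids, self.codes, self.weights):
            bits = "".join(_CODE_CHARS[int(c)] for c in row)
            lines.append(f"{rid}\t{bits}\t{w:g}")
        return "\n".join(lines) + "\n"


_RULES = (
    "too_uninformative",
    "high_mutation_fraction",
    "close_mutations",
    "mutation_adjacent_uninformative",
)


@dataclass
class FilterReport:
    """Discard counts per quality rule, with first-failure attribution."""

    too_uninformative: int = 0
    high_mutation_fraction: int = 0
    close_mutations: int = 0
    mutation_adjacent_uninformative: int = 0
    short_read: int = 0
    retained: int = 0

    @property
    def discarded(self) -> int:
        return (
            self.too_uninformative
            + self.high_mutation_fraction
            + self.close_mutations
            + self.mutation_adjacent_uninformative
            + self.short_read
        )

    @property
    def total(self) -> int:
        return self.discarded + self.retained

    def to_json(self) -> str:
        d = asdict(self)
        d["discarded"] = self.discarded
        d["total"] = self.total
        return json.dumps(d, indent=2)

    def to_text(self) -> str:
        d = asdict(self)
        lines = [f"{k}\t{v}" for k, v in d.items()]
        lines += [f"discarded\t{self.discarded}", f"total\t{self.total}"]
        return "\n".join(lines) + "\n"


@dataclass
class ReadObservation:
    """Merged per-template calls: reference position -> (base, quality).

    ``base`` is the called base (DNA or RNA alphabet) or ``DELETION`` for a
    deleted reference position; quality ``_DISCORDANT_QUAL`` marks
    mate-overlap disagreements. ``footprint`` is the number of reference
    positions covered by the merged alignment (window or not).
    """

    read_id: str
    calls: dict[int, tuple[str, int]]

    @property
    def footprint(self) -> int:
        return len(self.calls)


def _segment_calls(seg: pysam.AlignedSegment) -> dict[int, tuple[str, int]]:
    calls: dict[int, tuple[str, int]] = {}
    seq = seg.query_sequence or ""
    quals = seg.query_qualities
    for qpos, rpos in seg.get_aligned_pairs(matches_only=False):
        if rpos is None:
            continue  # insertion or soft clip: no reference position
        ref_pos1 = rpos + 1
        if qpos is None:
            calls[ref_pos1] = (DELETION, 93)  # deletion: placement as aligned
        else:
            q = quals[qpos] if quals is not None else 93
            calls[ref_pos1] = (seq[qpos].upper(), int(q))
    return calls


def _merge_mates(
    a: dict[int, tuple[str, int]], b: dict[int, tuple[str, int]]
) -> dict[int, tuple[str, int]]:
    merged = dict(a)
    for pos, (base, q) in b.items():
        if pos not in merged:
            merged[pos] = (base, q)
            continue
        base0, q0 = merged[pos]
        if base0 == base:
            merged[pos] = (base, max(q0, q))  # overlap agreement: counted once
        else:
            merged[pos] = (base0, _DISCORDANT_QUAL)  # neither call trusted
    return merged


def reads_from_sam(
    sam_path: str | Path,
    window: ReferenceWindow,
    min_read_length: int = 120,
) -> tuple[list[ReadObservation], int]:
    """Read a SAM/BAM, merge mate pairs, and apply the read-length floor.

    Returns the observations whose merged alignment footprint reaches
    ``min_read_length`` together with the count of short reads dropped.
    Unmapped, secondary, and supplementary records are skipped. Raises if
    the file's reference does not include the window's ``ref_id``.
    """
    mode = "rb" if str(sam_path).endswith(".bam") else "r"
    by_name: dict[str, dict[int, tuple[str, int]]] = {}
    order: list[str] = []
    with pysam.AlignmentFile(str(sam_path), mode, check_sq=False) as fh:
        if fh.header.get("SQ") and window.ref_id not in [
            sq["SN"] for sq in fh.header["SQ"]
        ]:
            raise ValueError(
                f"reference {window.ref_id!r} not in SAM header of {sam_path}"
            )
        for seg in fh:
            if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
                continue
            if seg.reference_name != window.ref_id:
                continue
            calls = _segment_calls(seg)
            name = seg.query_name
            if name in by_name:
                by_name[name] = _merge_mates(by_name[name], calls)
            else:
                by_name[name] = calls
                order.append(name)
    observations: list[ReadObservation] = []
    n_short = 0
    for name in order:
        obs = ReadObservation(name, by_name[name])
        if obs.footprint < min_read_length:
            n_short += 1
        else:
            observations.append(obs)
    return observations, n_short


def make_bitvector(
    observation: ReadObservation,
    window: ReferenceWindow,
    phred_floor: int = 20,
    literal_phred_rule: bool = False,
) -> np.ndarray:
    """Convert one merged observation to a ternary code vector.

    Mismatches and deleted reference positions become MUTATION; agreeing
    calls become MATCH; absent positions and calls failing the quality rule
    become UNINFORMATIVE. The default rule treats quality < ``phred_floor``
    as uninformative; ``literal_phred_rule`` flips it to quality >
    ``phred_floor`` for auditing the alternative reading.
    """
    codes = np.full(window.width, UNINFORMATIVE, dtype=np.int8)
    wseq = window.window_sequence
    for ref_pos, (base, q) in observation.calls.items():
        if not (window.window_start <= ref_pos <= window.window_end):
            continue
        i = ref_pos - window.window_start
        if q == _DISCORDANT_QUAL:
            continue
        if base == DELETION:
            codes[i] = MUTATION
            continue
        bad = (q > phred_floor) if literal_phred_rule else (q < phred_floor)
        if bad:
            continue
        ref_base = wseq[i]
        call = base.replace("T", "U")
        codes[i] = MATCH if call == ref_base else MUTATION
    return codes


def sam_to_bitmatrix(
    sam_path: str | Path,
    window: ReferenceWindow,
    min_read_length: int = 120,
    phred_floor: int = 20,
    literal_phred_rule: bool = False,
) -> tuple[BitMatrix, int]:
    """Ingest a SAM into a BitMatrix; returns (matrix, n_short_reads)."""
    observations, n_short = reads_from_sam(sam_path, window, min_read_length)
    if observations:
        codes = np.stack(
            [
                make_bitvector(obs, window, phred_floor, literal_phred_rule)
                for obs in observations
            ]
        )
    else:
        codes = np.empty((0, window.width), dtype=np.int8)
    matrix = BitMatrix(window, codes, [o.read_id for o in observations])
    return matrix, n_short


def filter_bitvectors(
    matrix: BitMatrix,
    max_uninformative_fraction: float = 0.5,
    max_mutation_fraction: float = 0.10,
    min_mutation_gap: int = 4,
    drop_adjacent_to_uninformative: bool = True,
    n_short: int = 0,
) -> tuple[BitMatrix, FilterReport]:
    """Apply the four bit-vector quality rules.

    A vector fails ``too_uninformative`` when its uninformative fraction of
    the window reaches ``max_uninformative_fraction`` ("50% or more");
    ``high_mutation_fraction`` when mutations exceed
    ``max_mutation_fraction`` of its informative positions;
    ``close_mutations`` when two mutations lie at distance <
    ``min_mutation_gap``; and ``mutation_adjacent_uninformative`` when a
    mutation borders an uninformative position (rule active only when
    ``drop_adjacent_to_uninformative``). ``n_short`` folds ingestion-stage
    short-read discards into the report.
    """
    codes = matrix.codes
    mut = codes == MUTATION
    uninf = codes == UNINFORMATIVE
    n = len(codes)
    width = matrix.window.width

    fail_uninf = uninf.mean(axis=1) >= max_uninformative_fraction
    n_inf = width - uninf.sum(axis=1)
    fail_mutfrac = mut.sum(axis=1) > max_mutation_fraction * np.maximum(n_inf, 1)
    fail_mutfrac |= (n_inf == 0) & mut.any(axis=1)

    fail_close = np.zeros(n, dtype=bool)
    for gap in range(1, min_mutation_gap):
        if gap < width:
            fail_close |= (mut[:, :-gap] & mut[:, gap:]).any(axis=1)

    if drop_adjacent_to_uninformative:
        fail_adj = (mut[:, :-1] & uninf[:, 1:]).any(axis=1) | (
            mut[:, 1:] & uninf[:, :-1]
        ).any(axis=1)
    else:
        fail_adj = np.zeros(n, dtype=bool)

    report = FilterReport(short_read=n_short)
    first_fail = np.full(n, -1)
    for rank, fail in enumerate([fail_uninf, fail_mutfrac, fail_close, fail_adj]):
        newly = fail & (first_fail < 0)
        first_fail[newly] = rank
    counts = np.bincount(first_fail[first_fail >= 0], minlength=4)
    weights_int = matrix.weights
    # attribute weighted counts per rule
    for rank, rule in enumerate(_RULES):
        setattr(report, rule, int(round(weights_int[first_fail == rank].sum())))
    keep = first_fail < 0
    report.retained = int(round(weights_int[keep].sum()))
    return matrix.subset(keep), report


def deduplicate(matrix: BitMatrix) -> BitMatrix:
    """Collapse identical vectors into unique rows with multiplicity weights.

    The weighted log-likelihood of any mixture model is identical on the
    raw and deduplicated matrices.
    """
    if len(matrix) == 0:
        return matrix
    unique, inverse = np.unique(matrix.codes, axis=0, return_inverse=True)
    weights = np.zeros(len(unique))
    np.add.at(weights, inverse, matrix.weights)
    first_idx = np.full(len(unique), -1)
    for i, u in enumerate(inverse):
        if first_idx[u] < 0:
            first_idx[u] = i
    read_ids = [matrix.read_ids[int(first_idx[u])] for u in range(len(unique))]
    return BitMatrix(matrix.window, unique, read_ids, weights)
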
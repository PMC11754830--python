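"""Synthetic read-mixture generator with ground truth.

Emulates the statistical structure the deconvolution assumes: each read is
drawn from one of K conformations; conformation k modifies each position
independently with a profile derived from its secondary structure (high at
unpaired A/C, low at paired A/C, background at G/U), plus a uniform
sequencing-error rate; a per-position probability of a low-quality
(uninformative) call; and, optionally, rejection of reads violating the
close-mutation validity rule. Reads can be written out as a single-end SAM
plus matching FASTA whose re-ingestion reproduces the bit matrix exactly.

Default rates (paired A/C 0.008, unpaired A/C 0.10, G/U 0.002) are
simulation conventions chosen to land population reactivities in the
conventional bins (paired mostly unreactive, unpaired mostly medium-strong
after normalization); they are not measured values for any specific RNA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .bitvectors import MUTATION, UNINFORMATIVE, BitMatrix
from .reference import ReferenceWindow
from .structures import SecondaryStructure

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "structure_to_profile",
    "simulate_bitvectors",
    "emit_sam",
]

# deterministic mismatch substitution used when writing SAM (DNA alphabet)
_SUBSTITUTE = {"A": "G", "C": "T", "G": "A", "T": "C"}
_QUAL_HIGH = "I"  # Phred 40
_QUAL_LOW = "#"  # Phred 2, below the default floor of 20


@dataclass(frozen=True)
class SimulationSpec:
    """Generative conditions for a read-mixture simulation.

    ``structures`` (one per conformation) define the per-position
    modification profiles unless ``profiles`` supplies them directly.
    ``apply_validity_rejection`` regenerates reads that violate the
    close-mutation rule, emulating a source population in which such
    molecules never appear; leave it off to study the selection bias the
    filters induce.
    """

    window: ReferenceWindow
    structures: tuple[SecondaryStructure, ...] = ()
    profiles: tuple | None = None
    paired_rate: float = 0.008
    unpaired_rate: float = 0.10
    gu_rate: float = 0.002
    error_rate: float = 0.001
    uninformative_rate: float = 0.02
    pi_true: tuple[float, ...] = (1.0,)
    n_reads: int = 1000
    seed: int = 0
    apply_validity_rejection: bool = False
    min_mutation_gap: int = 4

    def __post_init__(self) -> None:
        for name in ("paired_rate", "unpaired_rate", "gu_rate", "error_rate",
                     "uninformative_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(sum(self.pi_true) - 1.0) > 1e-9:
            raise ValueError("pi_true must sum to 1")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        k = len(self.profiles) if self.profiles is not None else len(self.structures)
        if k != len(self.pi_true):
            raise ValueError("one structure/profile required per mixing proportion")

    @property
    def k(self) -> int:
        return len(self.pi_true)

    def rate_matrix(self) -> np.ndarray:
        """(K, window_width) per-position modification probabilities."""
        if self.profiles is not None:
            rates = np.array([np.asarray(p, dtype=float) for p in self.profiles])
            if rates.shape != (self.k, self.window.width):
                raise ValueError("profiles must match (K, window width)")
            return rates
        return np.stack(
            [structure_to_profile(s, self) for s in self.structures]
        )


def structure_to_profile(
    structure: SecondaryStructure, spec: SimulationSpec
) -> np.ndarray:
    """Per-position modification probabilities implied by a structure.

    Paired A/C positions get ``paired_rate``, unpaired A/C positions
    ``unpaired_rate`` (unpaired means reactive), and G/U positions the
    background ``gu_rate`` regardless of pairing.
    """
    if structure.window.width != spec.window.width:
        raise ValueError("structure window does not match simulation window")
    ac = spec.window.ac_mask
    paired = structure.paired
    profile = np.where(ac, np.where(paired, spec.paired_rate, spec.unpaired_rate),
                       spec.gu_rate)
    return profile.astype(float)


@dataclass
class GroundTruth:
    """Per-read truth for a simulated mixture.

    ``labels`` are 1-based cluster indices per read (in matrix row order);
    ``realized_pre_filter`` are the achieved mixing proportions among the
    generated reads. Post-filter proportions must be recomputed from the
    retained read ids via :meth:`realized_proportions`.
    """

    labels: np.ndarray
    pi_true: np.ndarray
    profiles: np.ndarray
    read_ids: list[str]

    @property
    def realized_pre_filter(self) -> np.ndarray:
        k = len(self.pi_true)
        counts = np.bincount(self.labels - 1, minlength=k).astype(float)
        return counts / counts.sum()

    def realized_proportions(self, retained_read_ids: list[str]) -> np.ndarray:
        """Mixing proportions among a retained subset of reads."""
        idx = {rid: i for i, rid in enumerate(self.read_ids)}
        labels = np.array([self.labels[idx[r]] for r in retained_read_ids])
        k = len(self.pi_true)
        counts = np.bincount(labels - 1, minlength=k).astype(float)
        return counts / counts.sum()

    def to_json(self) -> str:
        return json.dumps(
            {
                "pi_true": self.pi_true.tolist(),
                "realized_pre_filter": self.realized_pre_filter.tolist(),
                "labels": self.labels.tolist(),
                "profiles": self.profiles.tolist(),
            }
        )


def _has_close_mutations(mut_row: np.ndarray, min_gap: int) -> bool:
    idx = np.flatnonzero(mut_row)
    return bool(idx.size >= 2 and np.diff(idx).min() < min_gap)


def simulate_bitvectors(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> tuple[BitMatrix, GroundTruth]:
    """Draw a read population from the mixture defined by ``spec``.

    Fully reproducible from ``spec.seed`` (or an explicit generator).
    Mutation draws at a position use the cluster profile plus
    ``error_rate``; uninformative positions are injected independently and
    override the mutation call, as a low-quality base would.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    rates = np.clip(spec.rate_matrix() + spec.error_rate, 0.0, 1.0)
    n, width = spec.n_reads, spec.window.width
    labels = rng.choice(spec.k, size=n, p=np.asarray(spec.pi_true)) + 1
    mut = rng.random((n, width)) < rates[labels - 1]
    if spec.apply_validity_rejection:
        for i in range(n):
            attempts = 0
            while _has_close_mutations(mut[i], spec.min_mutation_gap):
                mut[i] = rng.random(width) < rates[labels[i] - 1]
                attempts += 1
                if attempts > 10_000:
                    raise RuntimeError("validity rejection failed to converge")
    uninf = rng.random((n, width)) < spec.uninformative_rate
    codes = mut.astype(np.int8)
    codes[uninf] = UNINFORMATIVE
    read_ids = [f"read_{i:06d}" for i in range(n)]
    matrix = BitMatrix(spec.window, codes, read_ids)
    truth = GroundTruth(
        labels=labels,
        pi_true=np.asarray(spec.pi_true, dtype=float),
        profiles=spec.rate_matrix(),
        read_ids=read_ids,
    )
    return matrix, truth


def emit_sam(
    matrix: BitMatrix,
    window: ReferenceWindow,
    sam_path: str | Path,
    fasta_path: str | Path | None = None,
    mutation_encoding: str = "mismatch",
) -> None:
    """Write the matrix as single-end SAM records plus a matching FASTA.

    Each read spans the full window (POS = window start). With
    ``mutation_encoding='mismatch'`` mutations become substituted bases
    under a full-match CIGAR; with ``'deletion'`` they become deleted
    reference positions in the CIGAR. Uninformative positions carry a
    quality below the default Phred floor. Re-ingesting the file through
    the SAM reader and bit-vector converter reproduces the codes exactly.
    """
    if mutation_encoding not in ("mismatch", "deletion"):
        raise ValueError("mutation_encoding must be 'mismatch' or 'deletion'")
    ref_dna = window.sequence.replace("U", "T")
    window_dna = ref_dna[window.window_start - 1 : window.window_end]
    lines = [
        "@HD\tVN:1.6\tSO:unsorted",
        f"@SQ\tSN:{window.ref_id}\tLN:{len(ref_dna)}",
        "@PG\tID:dmsensemble\tPN:dmsensemble",
    ]
    for rid, row in zip(matrix.read_ids, matrix.codes):
        if mutation_encoding == "mismatch":
            seq_chars = []
            quals = []
            for i, code in enumerate(row):
                base = window_dna[i]
                if code == MUTATION:
                    seq_chars.append(_SUBSTITUTE[base])
                    quals.append(_QUAL_HIGH)
                elif code == UNINFORMATIVE:
                    seq_chars.append(base)
                    quals.append(_QUAL_LOW)
                else:
                    seq_chars.append(base)
                    quals.append(_QUAL_HIGH)
            cigar = f"{window.width}M"
            seq = "".join(seq_chars)
            qual = "".join(quals)
        else:
            seq_chars = []
            quals = []
            cigar_parts: list[str] = []
            run_op, run_len = None, 0

            def push(op: str) -> None:
                nonlocal run_op, run_len
                if op == run_op:
                    run_len += 1
                    return
                if run_op is not None:
                    cigar_parts.append(f"{run_len}{run_op}")
                run_op, run_len = op, 1

            last = len(row) - 1
            for i, code in enumerate(row):
                if code == MUTATION and 0 < i < last:
                    push("D")
                    continue
                if code == MUTATION:
                    # a CIGAR cannot begin or end with a deletion; edge
                    # mutations fall back to mismatch encoding
                    push("M")
                    seq_chars.append(_SUBSTITUTE[window_dna[i]])
                    quals.append(_QUAL_HIGH)
                    continue
                push("M")
                seq_chars.append(window_dna[i])
                quals.append(_QUAL_LOW if code == UNINFORMATIVE else _QUAL_HIGH)
            if run_op is not None:
                cigar_parts.append(f"{run_len}{run_op}")
            cigar = "".join(cigar_parts) or "1M"
            seq = "".join(seq_chars)
            qual = "".join(quals)
        lines.append(
            "\t".join(
                [
                    rid,
                    "0",
                    window.ref_id,
                    str(window.window_start),
                    "60",
                    cigar,
                    "*",
                    "0",
                    "0",
                    seq or "*",
                    qual or "*",
                ]
            )
        )
    Path(sam_path).write_text("\n".join(lines) + "\n")
    if fasta_path is not None:
        Path(fasta_path).write_text(f">{window.ref_id}\n{ref_dna}\n")
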
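"""Reference sequences and 1-based analysis windows.

Every coordinate spoken at a public interface is 1-based and inclusive on
the reference; array storage is 0-based internally. An analysis window (for
example nt 22-204 of a 451-nt RNA) defines the coordinate frame for bit
vectors, reactivity profiles, and structures downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")

__all__ = ["ReferenceWindow", "load_reference", "RNA_ALPHABET"]


def _to_rna(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)!r}")
    return seq


@dataclass(frozen=True)
class ReferenceWindow:
    """An RNA reference plus a 1-based inclusive analysis window.

    Parameters
    ----------
    ref_id : str
        Reference identifier (FASTA record id).
    sequence : str
        Full reference sequence over {A, C, G, U}; T is accepted on input
        and mapped to U.
    window_start, window_end : int
        1-based inclusive bounds of the analysis window on the reference.
    """

    ref_id: str
    sequence: str
    window_start: int
    window_end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _to_rna(self.sequence))
        if not (1 <= self.window_start <= self.window_end <= len(self.sequence)):
            raise ValueError(
                f"window ({self.window_start}, {self.window_end}) outside sequence "
                f"bounds 1..{len(self.sequence)}"
            )

    @property
    def width(self) -> int:
        """Number of positions in the window."""
        return self.window_end - self.window_start + 1

    @property
    def window_sequence(self) -> str:
        """The window slice of the reference sequence."""
        return self.sequence[self.window_start - 1 : self.window_end]

    @property
    def reference_positions(self) -> np.ndarray:
        """1-based reference coordinates of window positions, in order."""
        return np.arange(self.window_start, self.window_end + 1)

    @property
    def ac_mask(self) -> np.ndarray:
        """Boolean per window position: True at A/C (DMS-informative) bases."""
        arr = np.array(list(self.window_sequence))
        return (arr == "A") | (arr == "C")

    def local_index(self, ref_pos: int) -> int:
        """Map a 1-based reference position to a 0-based window index."""
        if not (self.window_start <= ref_pos <= self.window_end):
            raise ValueError(f"position {ref_pos} outside window")
        return ref_pos - self.window_start


def load_reference(
    fasta_path: str | Path,
    window_start: int,
    window_end: int,
    ref_id: str | None = None,
) -> ReferenceWindow:
    """Load a single reference record from FASTA and attach a window.

    The FASTA must contain exactly one record unless ``ref_id`` selects one.
    DNA alphabet is converted to RNA and the window is validated against the
    sequence bounds.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {fasta_path}")
    if ref_id is None:
        if len(records) > 1:
            raise ValueError(
                f"{fasta_path} has {len(records)} records; supply ref_id to select one"
            )
        record = records[0]
    else:
        matches = [r for r in records if r.id == ref_id]
        if not matches:
            raise ValueError(f"record {ref_id!r} not found in {fasta_path}")
        record = matches[0]
    return ReferenceWindow(
        ref_id=record.id,
        sequence=str(record.seq),
        window_start=window_start,
        window_end=window_end,
    )
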
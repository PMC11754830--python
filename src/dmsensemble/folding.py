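"""Reactivity-constrained secondary-structure prediction.

The built-in folder is a deliberately small pseudo-energy-guided dynamic
program (weighted Nussinov): it maximizes the sum over base pairs of
``pair_score(i, j) - penalty(i) - penalty(j)``, where the penalty at an
A/C position with defined normalized reactivity r is
``dms_slope * ln(1 + r) + dms_intercept`` (0 at G/U or undefined
positions). It is a desk-scale stand-in, not a nearest-neighbor
thermodynamic model; the adapter seam ``fold_external`` reaches a real
thermodynamic folder when one is installed, and every report should label
which engine produced a structure. The stand-in never emits pseudoknots.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .reactivity import ReactivityProfile
from .reference import ReferenceWindow
from .structures import SecondaryStructure, parse_ct, parse_dot_bracket

__all__ = [
    "FoldingParams",
    "ExternalFolderConfig",
    "FoldingEngineUnavailable",
    "fold_constrained",
    "fold_external",
    "structure_distance",
    "StructureDistance",
]

_CANONICAL_PAIRS = {
    ("G", "C"): "GC",
    ("C", "G"): "GC",
    ("A", "U"): "AU",
    ("U", "A"): "AU",
    ("G", "U"): "GU",
    ("U", "G"): "GU",
}


@dataclass(frozen=True)
class FoldingParams:
    """Tunables of the pseudo-energy DP folder.

    ``min_loop`` is the minimum hairpin loop length (unpaired nt between a
    pair). ``pair_scores`` weight GC > AU > GU, a coarse stand-in for stack
    stability. ``dms_slope``/``dms_intercept`` shape the per-position
    pairing penalty from normalized reactivity; ``pairing_forbidden_above``
    optionally bans pairing outright above a reactivity ceiling.
    """

    min_loop: int = 3
    pair_scores: dict = field(
        default_factory=lambda: {"GC": 3.0, "AU": 2.0, "GU": 1.0}
    )
    dms_slope: float = 4.0
    dms_intercept: float = 0.0
    pairing_forbidden_above: float | None = None
    max_window: int = 2000

    def __post_init__(self) -> None:
        if self.min_loop < 0:
            raise ValueError("min_loop must be >= 0")
        for k, v in self.pair_scores.items():
            if not np.isfinite(v):
                raise ValueError(f"pair score {k} must be finite")


class FoldingEngineUnavailable(RuntimeError):
    """Raised when the external thermodynamic folder is not configured."""


def _penalties(
    window: ReferenceWindow,
    reactivity: ReactivityProfile | None,
    params: FoldingParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position pairing penalty and hard-forbidden mask."""
    n = window.width
    pen = np.zeros(n)
    forbidden = np.zeros(n, dtype=bool)
    if reactivity is None:
        return pen, forbidden
    if reactivity.normalized is None:
        raise ValueError("fold_constrained requires normalized reactivities")
    norm = reactivity.normalized
    ac = window.ac_mask
    defined = ac & ~np.isnan(norm)
    pen[defined] = params.dms_slope * np.log1p(norm[defined]) + params.dms_intercept
    if params.pairing_forbidden_above is not None:
        forbidden = defined & (norm > params.pairing_forbidden_above)
    return pen, forbidden


def fold_constrained(
    window: ReferenceWindow,
    reactivity: ReactivityProfile | None = None,
    params: FoldingParams | None = None,
) -> SecondaryStructure:
    """Predict a pseudoknot-free structure by pseudo-energy maximization.

    With no reactivity the fold is unconstrained. Tie-breaking in the
    traceback is deterministic: leaving the right end unpaired is preferred,
    then the pairing with the smallest outer index.
    """
    params = params or FoldingParams()
    n = window.width
    if n > params.max_window:
        raise ValueError(f"window of {n} nt exceeds guard ({params.max_window})")
    seq = window.window_sequence
    pen, forbidden = _penalties(window, reactivity, params)

    # pair contribution matrix: -inf where not pairable
    score_pair = np.full((n, n), -np.inf)
    for i in range(n):
        if forbidden[i]:
            continue
        for j in range(i + params.min_loop + 1, n):
            if forbidden[j]:
                continue
            kind = _CANONICAL_PAIRS.get((seq[i], seq[j]))
            if kind is not None:
                score_pair[i, j] = params.pair_scores[kind] - pen[i] - pen[j]

    S = np.zeros((n + 1, n + 1))  # S[i][j]: best score of region i..j-1 (half-open)
    # iterate over spans
    for span in range(2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span  # half-open end; last index j-1
            best = S[i][j - 1]  # j-1 unpaired
            ks = np.arange(i, j - 1 - params.min_loop)
            if ks.size:
                cand = (
                    S[i, ks]
                    + S[ks + 1, j - 1]  # wait: need S[k+1][j-1] region k+1..j-2
                    + score_pair[ks, j - 1]
                )
                m = cand.max()
                if m > best:
                    best = m
            S[i][j] = best
    # note: S[k+1, j-1] above is the half-open region k+1 .. j-2, i.e. the
    # interior of the pair (k, j-1) — consistent with the half-open table.

    table = [0] * n

    def traceback(i: int, j: int) -> None:  # half-open region i..j-1
        while j - i >= 2:
            if S[i][j] == S[i][j - 1]:
                j -= 1
                continue
            for k in range(i, j - 1 - params.min_loop):
                if np.isfinite(score_pair[k, j - 1]) and np.isclose(
                    S[i][j], S[i][k] + S[k + 1][j - 1] + score_pair[k, j - 1]
                ):
                    table[k] = j  # 1-based partner of k+1 is j (j-1 zero-based)
                    table[j - 1] = k + 1
                    traceback(i, k)
                    i, j = k + 1, j - 1
                    break
            else:  # numerical safety: treat as unpaired
                j -= 1

    traceback(0, n)
    return SecondaryStructure(window.ref_id, window, tuple(table))


def fold_score(
    structure: SecondaryStructure,
    reactivity: ReactivityProfile | None = None,
    params: FoldingParams | None = None,
) -> float:
    """Pseudo-energy score of a given structure under the DP objective."""
    params = params or FoldingParams()
    seq = structure.window.window_sequence
    pen, forbidden = _penalties(structure.window, reactivity, params)
    total = 0.0
    for i, j in structure.pairs:
        if forbidden[i - 1] or forbidden[j - 1]:
            return -np.inf
        kind = _CANONICAL_PAIRS.get((seq[i - 1], seq[j - 1]))
        if kind is None or (j - i - 1) < params.min_loop:
            return -np.inf
        total += params.pair_scores[kind] - pen[i - 1] - pen[j - 1]
    return total


@dataclass(frozen=True)
class ExternalFolderConfig:
    """Adapter to an external thermodynamic folder.

    ``executable`` is the program name or path; ``arg_template`` the
    argument list with ``{fasta}``, ``{reactivity}`` and ``{out}``
    placeholders; ``output_format`` is ``ct`` or ``dot_bracket``
    (``dot_bracket`` parses the program's stdout, RNAfold-style).
    """

    executable: str
    arg_template: tuple[str, ...] = ()
    output_format: str = "ct"

    @classmethod
    def rnafold(cls) -> "ExternalFolderConfig":
        """Preset for ViennaRNA's RNAfold (reads FASTA, prints dot-bracket)."""
        return cls(
            executable="RNAfold",
            arg_template=("--noPS", "-i", "{fasta}"),
            output_format="dot_bracket",
        )


def fold_external(
    window: ReferenceWindow,
    reactivity: ReactivityProfile | None,
    adapter_config: ExternalFolderConfig | None,
) -> SecondaryStructure:
    """Run the configured external folder and parse its structure output.

    Raises :class:`FoldingEngineUnavailable` when no adapter is configured
    or the executable is missing — never a silent fallback to the stand-in.
    """
    if adapter_config is None:
        raise FoldingEngineUnavailable(
            "external folder unavailable: no adapter configured "
            "(set folding engine to 'standin' or configure an executable)"
        )
    exe = shutil.which(adapter_config.executable)
    if exe is None:
        raise FoldingEngineUnavailable(
            f"external folder unavailable: executable "
            f"{adapter_config.executable!r} not found on PATH"
        )
    with tempfile.TemporaryDirectory() as tmp:
        tmpdir = Path(tmp)
        fasta = tmpdir / "window.fa"
        fasta.write_text(f">{window.ref_id}\n{window.window_sequence}\n")
        react_path = tmpdir / "reactivity.txt"
        if reactivity is not None and reactivity.normalized is not None:
            lines = []
            for i in range(window.width):
                v = reactivity.normalized[i]
                lines.append(f"{i + 1}\t{-999 if np.isnan(v) else round(v, 6)}")
            react_path.write_text("\n".join(lines) + "\n")
        out_path = tmpdir / "out.ct"
        args = [exe] + [
            a.format(fasta=fasta, reactivity=react_path, out=out_path)
            for a in adapter_config.arg_template
        ]
        proc = subprocess.run(
            args, capture_output=True, text=True, cwd=tmpdir, check=False
        )
        if proc.returncode != 0:
            raise RuntimeError(
                f"external folder failed ({proc.returncode}): {proc.stderr[:500]}"
            )
        if adapter_config.output_format == "ct":
            return parse_ct(out_path.read_text(), window)
        # dot-bracket on stdout: last token line holding brackets
        for line in proc.stdout.splitlines():
            token = line.split()[0] if line.split() else ""
            if token and set(token) <= set(".()[]{}<>"):
                return parse_dot_bracket(token, window)
        raise RuntimeError("no dot-bracket line found in external folder output")


@dataclass(frozen=True)
class StructureDistance:
    shared: int
    a_only: int
    b_only: int
    f1: float


def structure_distance(
    a: SecondaryStructure, b: SecondaryStructure
) -> StructureDistance:
    """Base-pair agreement between two structures on the same window.

    F1 = 2*shared / (|a| + |b|); defined as 1 when both are fully unpaired.
    """
    if a.window.width != b.window.width:
        raise ValueError("structures live on different windows")
    pa, pb = a.pairs, b.pairs
    shared = len(pa & pb)
    denom = len(pa) + len(pb)
    f1 = 1.0 if denom == 0 else 2.0 * shared / denom
    return StructureDistance(shared, len(pa - pb), len(pb - pa), f1)
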
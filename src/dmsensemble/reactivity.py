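"""DMS reactivity profiles: mutation fractions, normalization, agreement.

The raw reactivity of a position is the weighted mutation count over the
weighted informative count; it is undefined (NaN), not zero, where coverage
is zero. Normalization divides by the median of the top 10% of defined A/C
raw values and caps at 1; G/U positions stay undefined in the normalized
profile because DMS methylates only N1-A and N3-C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .bitvectors import MUTATION, UNINFORMATIVE, BitMatrix
from .reference import ReferenceWindow

__all__ = [
    "ReactivityProfile",
    "population_average",
    "normalize",
    "cluster_reactivities",
    "replicate_correlation",
    "reactivity_bin",
]


@dataclass(frozen=True)
class ReactivityProfile:
    """Per-position mutation fractions and normalized reactivities.

    ``raw`` and ``coverage`` have one entry per window position; ``raw`` is
    NaN where coverage is zero. ``normalized`` is NaN until ``normalize``
    fills it, and stays NaN at G/U positions and undefined positions.
    """

    window: ReferenceWindow
    raw: np.ndarray
    coverage: np.ndarray
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "raw", np.asarray(self.raw, dtype=float))
        object.__setattr__(self, "coverage", np.asarray(self.coverage, dtype=float))
        if len(self.raw) != self.window.width or len(self.coverage) != self.window.width:
            raise ValueError("profile arrays must match window width")
        if self.normalized is not None:
            object.__setattr__(
                self, "normalized", np.asarray(self.normalized, dtype=float)
            )

    def to_table(self) -> str:
        """TSV: position (1-based reference), base, coverage, raw, normalized."""
        seq = self.window.window_sequence
        norm = (
            self.normalized
            if self.normalized is not None
            else np.full(self.window.width, np.nan)
        )
        lines = ["position\tbase\tcoverage\traw\tnormalized"]
        for i, pos in enumerate(self.window.reference_positions):
            lines.append(
                f"{pos}\t{seq[i]}\t{self.coverage[i]:g}\t"
                f"{'' if np.isnan(self.raw[i]) else f'{self.raw[i]:.6f}'}\t"
                f"{'' if np.isnan(norm[i]) else f'{norm[i]:.6f}'}"
            )
        return "\n".join(lines) + "\n"


def population_average(matrix: BitMatrix) -> ReactivityProfile:
    """Population-average reactivity: mutation count over coverage, per position."""
    if len(matrix) == 0:
        raise ValueError("cannot compute reactivity of an empty matrix")
    w = matrix.weights[:, None]
    mut = ((matrix.codes == MUTATION) * w).sum(axis=0)
    cov = ((matrix.codes != UNINFORMATIVE) * w).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(cov > 0, mut / np.maximum(cov, 1e-300), np.nan)
    return ReactivityProfile(matrix.window, raw, cov)


def normalization_scale(profile: ReactivityProfile) -> float:
    """Median of the top ceil(0.1*M) defined A/C raw values (M = their count)."""
    ac = profile.window.ac_mask
    defined = ac & ~np.isnan(profile.raw)
    values = profile.raw[defined]
    if values.size == 0:
        raise ValueError("no defined A/C reactivities to normalize")
    k = max(1, math.ceil(0.1 * values.size))
    top = np.sort(values)[-k:]
    scale = float(np.median(top))
    if scale == 0.0:
        raise ValueError("all-zero reactivity profile cannot be normalized")
    return scale


def normalize(
    profile: ReactivityProfile, scale: float | None = None
) -> ReactivityProfile:
    """Fill ``normalized``: raw / scale, capped at 1, A/C positions only.

    ``scale`` defaults to the profile's own top-10% median; pass a shared
    scale to normalize several cluster profiles on one footing.
    """
    if scale is None:
        scale = normalization_scale(profile)
    ac = profile.window.ac_mask
    norm = np.where(ac, np.minimum(profile.raw / scale, 1.0), np.nan)
    return replace(profile, normalized=norm)


def replicate_correlation(
    p1: ReactivityProfile, p2: ReactivityProfile, use: str = "raw"
) -> tuple[float, float]:
    """Pearson r (and p-value) over jointly defined positions.

    Requires at least three jointly defined positions and non-constant
    profiles; raises otherwise.
    """
    a = p1.raw if use == "raw" else p1.normalized
    b = p2.raw if use == "raw" else p2.normalized
    if a is None or b is None:
        raise ValueError(f"{use} reactivities not available on both profiles")
    joint = ~np.isnan(a) & ~np.isnan(b)
    if joint.sum() < 3:
        raise ValueError("fewer than 3 jointly defined positions")
    x, y = a[joint], b[joint]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant profile")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def cluster_reactivities(
    model,
    matrix: BitMatrix,
    normalized: bool = True,
    shared_scale: bool = False,
) -> list[ReactivityProfile]:
    """One reactivity profile per fitted cluster.

    Each cluster's raw profile is its mu_k restricted to the informative
    mask (NaN elsewhere); coverage is the responsibility-weighted
    informative count. Collapsed clusters (mixing weight ~ 0) are skipped.
    Normalization is per-cluster by default; ``shared_scale`` applies one
    common scale (the maximum of the per-cluster scales) to every cluster.
    """
    from .deconvolution import EnsembleModel  # local import avoids a cycle

    if not isinstance(model, EnsembleModel):
        raise TypeError("cluster_reactivities expects a fitted EnsembleModel")
    mask = model.informative_mask
    inf = (matrix.codes != UNINFORMATIVE).astype(float)
    profiles: list[ReactivityProfile] = []
    for k in range(model.K):
        if k in model.collapsed:
            continue
        raw = np.where(mask, model.mu[k], np.nan)
        gw = model.responsibilities[:, k] * matrix.weights
        cov = gw @ inf
        profiles.append(ReactivityProfile(matrix.window, raw, cov))
    if normalized:
        if shared_scale:
            scale = max(normalization_scale(p) for p in profiles)
            profiles = [normalize(p, scale=scale) for p in profiles]
        else:
            profiles = [normalize(p) for p in profiles]
    return profiles


def reactivity_bin(value: float) -> str:
    """Classify a normalized reactivity into the conventional bins.

    low 0.1-0.3, medium 0.3-0.8, strong > 0.8; below 0.1 is unreactive.
    """
    if np.isnan(value):
        return "undefined"
    if value > 0.8:
        return "strong"
    if value > 0.3:
        return "medium"
    if value > 0.1:
        return "low"
    return "unreactive"
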
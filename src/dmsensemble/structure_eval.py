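"""ROC/AUROC agreement between reactivity profiles and structure models.

A secondary-structure model is treated as a binary classifier of its own
positions: sliding a threshold t over the reactivity scale, a position
counts as predicted-paired when its reactivity is below t. True positives
are paired positions under the threshold, false positives unpaired ones.
AUROC is the area under the resulting curve (trapezoidal rule), which
equals the rank statistic P(r_paired < r_unpaired) + 1/2 P(tie); AUROC is
therefore invariant under any strictly monotone transform of the
reactivities, so raw and normalized profiles score identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reactivity import ReactivityProfile
from .structures import SecondaryStructure, paired_labels

__all__ = ["ROCResult", "roc_curve", "roc_from_values", "auroc_table"]


@dataclass(frozen=True)
class ROCResult:
    """A sliding-threshold ROC sweep and its AUROC."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auroc: float
    n_paired: int
    n_unpaired: int

    def to_table(self) -> str:
        lines = ["threshold\tfpr\ttpr"]
        for t, f, tp in zip(self.thresholds, self.fpr, self.tpr):
            lines.append(f"{t:g}\t{f:.6f}\t{tp:.6f}")
        return "\n".join(lines) + "\n"


def roc_from_values(values: np.ndarray, is_paired: np.ndarray) -> ROCResult:
    """ROC over labeled reactivity values.

    ``values`` are reactivities; ``is_paired`` the structure model's labels.
    At threshold t, TPR is the fraction of paired positions with value < t
    and FPR the fraction of unpaired positions with value < t. Raises when
    either class is empty (AUROC undefined).
    """
    values = np.asarray(values, dtype=float)
    is_paired = np.asarray(is_paired, dtype=bool)
    if values.shape != is_paired.shape:
        raise ValueError("values and labels must have equal length")
    if np.isnan(values).any():
        raise ValueError("undefined reactivities must be excluded before scoring")
    n_paired = int(is_paired.sum())
    n_unpaired = int((~is_paired).sum())
    if n_paired == 0 or n_unpaired == 0:
        raise ValueError(
            "AUROC undefined: need at least one paired and one unpaired position"
        )
    thresholds = np.concatenate([[-np.inf], np.unique(values), [np.inf]])
    paired_vals = values[is_paired]
    unpaired_vals = values[~is_paired]
    tpr = (paired_vals[None, :] < thresholds[:, None]).mean(axis=1)
    fpr = (unpaired_vals[None, :] < thresholds[:, None]).mean(axis=1)
    auroc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds, tpr, fpr, auroc, n_paired, n_unpaired)


def roc_curve(
    reactivity: ReactivityProfile,
    structure: SecondaryStructure,
    ac_only: bool = True,
    use: str = "raw",
) -> ROCResult:
    """Score a profile against a structure model's paired/unpaired labels.

    Labels are restricted to A/C positions (when ``ac_only``) with defined
    reactivity; undefined positions are excluded, never imputed.
    """
    if structure.window.width != reactivity.window.width:
        raise ValueError("structure and profile windows differ")
    labels = paired_labels(structure, ac_only=ac_only)
    source = reactivity.raw if use == "raw" else reactivity.normalized
    if source is None:
        raise ValueError(f"{use} reactivities not available")
    positions = [p for p in labels if not np.isnan(source[p - 1])]
    values = np.array([source[p - 1] for p in positions])
    is_paired = np.array([labels[p] for p in positions])
    return roc_from_values(values, is_paired)


def auroc_table(
    profiles: list[ReactivityProfile],
    structure: SecondaryStructure,
    ac_only: bool = True,
    use: str = "raw",
) -> tuple[pd.DataFrame, float, float]:
    """Per-replicate AUROC values plus mean and sample SD.

    Mirrors the convention of reporting structure-model agreement as
    mean +/- SD over biological replicates.
    """
    rows = []
    for i, profile in enumerate(profiles, start=1):
        result = roc_curve(profile, structure, ac_only=ac_only, use=use)
        rows.append({"replicate": i, "auroc": result.auroc})
    table = pd.DataFrame(rows)
    mean = float(table["auroc"].mean())
    sd = float(table["auroc"].std(ddof=1)) if len(table) > 1 else 0.0
    return table, mean, sd


def auroc_summary_json(table: pd.DataFrame, mean: float, sd: float) -> str:
    return json.dumps(
        {
            "per_replicate": table["auroc"].tolist(),
            "mean": mean,
            "sd": sd,
        },
        indent=2,
    )
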
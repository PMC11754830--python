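"""End-to-end pipeline orchestration and configuration.

A :class:`PipelineConfig` carries every threshold and setting; unknown
config keys are errors (a silent typo in a filter threshold is
unacceptable in a probing pipeline). One top-level seed deterministically
derives per-stage substreams, so inserting a stage never perturbs another
stage's randomness, and a rerun with the same seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .bitvectors import filter_bitvectors, sam_to_bitmatrix
from .deconvolution import cluster_abundances, select_k
from .folding import FoldingParams, fold_constrained
from .reactivity import (
    cluster_reactivities,
    normalize,
    population_average,
    reactivity_bin,
)
from .reference import ReferenceWindow, load_reference
from .structure_eval import roc_curve
from .structures import parse_structure

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

# fixed substream indices per stage: stable even if stages are added later
_STAGE_STREAMS = {"simulate": 0, "bitvector": 1, "cluster": 2, "auroc": 3, "fold": 4}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the top-level seed."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(_STAGE_STREAMS[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """All pipeline settings; defaults follow the published analysis.

    Windows are named, 1-based inclusive (e.g. ``{"tpk": (22, 204),
    "cr45": (213, 368)}``); K is selected by minimum BIC up to ``k_max=3``.
    """

    reference_path: str = ""
    ref_id: str | None = None
    windows: dict = field(default_factory=lambda: {"tpk": (22, 204), "cr45": (213, 368)})
    window_name: str = "cr45"
    min_read_length: int = 120
    phred_floor: int = 20
    literal_phred_rule: bool = False
    max_uninformative_fraction: float = 0.5
    max_mutation_fraction: float = 0.10
    min_mutation_gap: int = 4
    drop_adjacent_to_uninformative: bool = True
    k_max: int = 3
    restarts: int = 10
    tol: float = 0.05
    max_iter: int = 300
    seed: int = 0
    validity_correction: bool = True
    shared_normalization_scale: bool = False
    structure_paths: dict = field(default_factory=dict)
    folding_engine: str = "standin"
    dms_slope: float = 4.0
    min_loop: int = 3
    output_dir: str = "dmsensemble_out"

    _BOUNDS = {
        "max_uninformative_fraction": (0.0, 1.0),
        "max_mutation_fraction": (0.0, 1.0),
        "phred_floor": (0, 93),
        "min_mutation_gap": (1, 50),
        "k_max": (1, 10),
        "restarts": (1, 1000),
    }

    def __post_init__(self) -> None:
        for key, (lo, hi) in self._BOUNDS.items():
            v = getattr(self, key)
            if not (lo <= v <= hi):
                raise ValueError(f"config {key}={v} outside [{lo}, {hi}]")
        if self.folding_engine not in ("standin", "external"):
            raise ValueError("folding_engine must be 'standin' or 'external'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "windows" in data:
            data["windows"] = {k: tuple(v) for k, v in data["windows"].items()}
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["windows"] = {k: list(v) for k, v in d["windows"].items()}
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    def window(self) -> ReferenceWindow:
        start, end = self.windows[self.window_name]
        return load_reference(self.reference_path, start, end, ref_id=self.ref_id)


def _write(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(text)


def run_pipeline(config: PipelineConfig, sam_path: str | Path) -> dict:
    """Run filters -> reactivity -> deconvolution -> AUROC -> folding.

    Returns the output bundle as a dict and writes every artifact (stamped
    with the config hash and seed) under ``config.output_dir``. An empty
    retained set stops cleanly after the filter report.
    """
    outdir = Path(config.output_dir)
    window = config.window()
    provenance = {"config_hash": config.config_hash(), "seed": config.seed}

    matrix, n_short = sam_to_bitmatrix(
        sam_path,
        window,
        min_read_length=config.min_read_length,
        phred_floor=config.phred_floor,
        literal_phred_rule=config.literal_phred_rule,
    )
    filtered, report = filter_bitvectors(
        matrix,
        max_uninformative_fraction=config.max_uninformative_fraction,
        max_mutation_fraction=config.max_mutation_fraction,
        min_mutation_gap=config.min_mutation_gap,
        drop_adjacent_to_uninformative=config.drop_adjacent_to_uninformative,
        n_short=n_short,
    )
    _write(outdir / "filter_report.json", report.to_json())
    _write(outdir / "provenance.json", json.dumps(provenance | {"config": config.to_dict()}, indent=2))
    bundle: dict = {"filter_report": report, "provenance": provenance, "window": window}
    if len(filtered) == 0:
        bundle["status"] = "no reads retained"
        _write(outdir / "status.txt", "no reads retained\n")
        return bundle
    bundle["status"] = "ok"

    profile = normalize(population_average(filtered))
    _write(outdir / "population_reactivity.tsv", profile.to_table())
    bundle["population_profile"] = profile

    model, bic_table = select_k(
        filtered,
        k_max=config.k_max,
        restarts=config.restarts,
        seed=stage_seed(config.seed, "cluster"),
        tol=config.tol,
        max_iter=config.max_iter,
        validity_correction=config.validity_correction,
        min_mutation_gap=config.min_mutation_gap,
    )
    _write(outdir / "bic_table.tsv", bic_table.to_csv(sep="\t", index=False))
    _write(outdir / "model.json", model.to_json())
    bundle["model"] = model
    bundle["bic_table"] = bic_table
    bundle["abundances"] = cluster_abundances(model)

    profiles = cluster_reactivities(
        model, filtered, shared_scale=config.shared_normalization_scale
    )
    for k, p in enumerate(profiles, start=1):
        _write(outdir / f"cluster_{k}_reactivity.tsv", p.to_table())
    bundle["cluster_profiles"] = profiles

    aurocs = {}
    for name, path in config.structure_paths.items():
        structure = parse_structure(Path(path).read_text(), window)
        aurocs[name] = {
            "population": roc_curve(profile, structure).auroc,
            "clusters": [roc_curve(p, structure).auroc for p in profiles],
        }
    if aurocs:
        _write(outdir / "auroc.json", json.dumps(aurocs, indent=2))
    bundle["auroc"] = aurocs

    params = FoldingParams(min_loop=config.min_loop, dms_slope=config.dms_slope)
    predicted = []
    for k, p in enumerate(profiles, start=1):
        structure = fold_constrained(window, p, params)
        predicted.append(structure)
        _write(
            outdir / f"cluster_{k}_predicted.db",
            f">{window.ref_id} cluster_{k} engine=standin\n"
            f"{window.window_sequence}\n{structure.to_dot_bracket()}\n",
        )
    bundle["predicted_structures"] = predicted

    _write(outdir / "report.txt", render_report(bundle))
    return bundle


def render_report(bundle: dict) -> str:
    """Human-readable summary: abundances, reactivity bins, AUROC."""
    lines = [f"status: {bundle['status']}"]
    report = bundle["filter_report"]
    lines.append(
        f"reads: total={report.total} retained={report.retained} "
        f"discarded={report.discarded}"
    )
    if "abundances" in bundle:
        pct = bundle["abundances"]
        labels = ["major", "minor", "third"]
        parts = [f"{labels[i]} {pct[i]:.1f}%" for i in range(len(pct))]
        lines.append("cluster abundances: " + " / ".join(parts))
    if bundle.get("population_profile") is not None:
        norm = bundle["population_profile"].normalized
        bins: dict[str, int] = {}
        for v in norm:
            b = reactivity_bin(float(v))
            bins[b] = bins.get(b, 0) + 1
        lines.append(
            "population reactivity bins: "
            + ", ".join(f"{k}={v}" for k, v in sorted(bins.items()))
        )
    for name, values in bundle.get("auroc", {}).items():
        cl = ", ".join(f"{v:.3f}" for v in values["clusters"])
        lines.append(
            f"AUROC vs {name}: population={values['population']:.3f} clusters=[{cl}]"
        )
    return "\n".join(lines) + "\n"
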
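"""Simulation-based validation protocols.

Each protocol regenerates a synthetic read mixture under the package's
standard study conditions, runs the full analysis (filters -> EM with BIC
selection of K -> abundances), and reports what the pipeline recovered.
They exist so that end-to-end parameter recovery can be re-run from a
single seed, by tests and by the reproduction script alike.
"""

from __future__ import annotations

import numpy as np

from . import fixtures
from .bitvectors import filter_bitvectors
from .deconvolution import cluster_abundances, select_k
from .simulate import SimulationSpec, simulate_bitvectors, structure_to_profile
from .structure_eval import roc_from_values

__all__ = [
    "mixture_recovery",
    "cr45_recovery",
    "tpk_recovery",
    "purified_rnp_recovery",
    "perfect_separation_auroc",
    "null_auroc",
]

# endogenous-HeLa and purified-RNP ensemble compositions used as ground
# truth by the recovery protocols (major, minor)
CR45_COMPOSITION = (0.87, 0.13)
TPK_COMPOSITION = (0.793, 0.207)
PURIFIED_RNP_COMPOSITION = (0.62, 0.38)


def _derive(seed: int, stream: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(stream,))
    return int(ss.generate_state(1)[0] % (2**31))


def mixture_recovery(
    spec: SimulationSpec, seed: int, k_max: int = 3, restarts: int = 10
) -> dict:
    """Simulate -> filter -> select_k; return selection and abundances."""
    matrix, truth = simulate_bitvectors(spec)
    filtered, report = filter_bitvectors(matrix)
    model, table = select_k(
        filtered, k_max=k_max, restarts=restarts, seed=_derive(seed, 1)
    )
    pct = cluster_abundances(model)
    return {
        "selected_k": model.K,
        "abundances_pct": pct,
        "major_pct": float(pct[0]),
        "n_retained": report.retained,
        "filter_report": report,
        "bic_table": table,
        "model": model,
        "truth": truth,
    }


def cr45_recovery(seed: int, n_reads: int = 20_000) -> dict:
    """Two-conformation CR4/5-window mixture at the endogenous composition."""
    window = fixtures.cr45_window()
    spec = SimulationSpec(
        window=window,
        structures=fixtures.cr45_structures(),
        pi_true=CR45_COMPOSITION,
        n_reads=n_reads,
        seed=_derive(seed, 0),
    )
    return mixture_recovery(spec, seed)


def tpk_recovery(seed: int, n_reads: int = 20_000) -> dict:
    """Two-conformation t/PK-window mixture at the endogenous composition."""
    window = fixtures.tpk_window()
    spec = SimulationSpec(
        window=window,
        structures=fixtures.tpk_structures(),
        pi_true=TPK_COMPOSITION,
        n_reads=n_reads,
        seed=_derive(seed, 0),
    )
    return mixture_recovery(spec, seed)


def purified_rnp_recovery(seed: int, n_reads: int = 20_000) -> dict:
    """Two CR4/5 profiles differing only at the four bulge positions.

    Both profiles derive from the canonical fold; the major conformer is
    protein-protected at the bulge (rate 0.02), the minor one exposed
    (0.25), mixed at the purified-RNP composition.
    """
    window = fixtures.cr45_window()
    canonical, _ = fixtures.cr45_structures()
    base_spec = SimulationSpec(
        window=window, structures=(canonical,), pi_true=(1.0,), n_reads=1
    )
    base = structure_to_profile(canonical, base_spec)
    bulge = np.array(fixtures.cr45_bulge_positions()) - 1
    major = base.copy()
    major[bulge] = 0.02
    minor = base.copy()
    minor[bulge] = 0.25
    spec = SimulationSpec(
        window=window,
        profiles=(tuple(major), tuple(minor)),
        pi_true=PURIFIED_RNP_COMPOSITION,
        n_reads=n_reads,
        seed=_derive(seed, 0),
    )
    return mixture_recovery(spec, seed)


def perfect_separation_auroc() -> float:
    """AUROC of a 20-position window whose reactivities perfectly separate
    paired (0.05) from unpaired (0.9) positions."""
    values = np.array([0.05] * 10 + [0.9] * 10)
    is_paired = np.array([True] * 10 + [False] * 10)
    return roc_from_values(values, is_paired).auroc


def null_auroc(seed: int, n_draws: int = 20, n_positions: int = 60) -> float:
    """Mean AUROC when reactivities are independent of the labels.

    Reactivities are uniform on [0, 1] regardless of label; averaged over
    ``n_draws`` seeded draws of ``n_positions`` labeled positions.
    """
    rng = np.random.default_rng(_derive(seed, 2))
    aurocs = []
    for _ in range(n_draws):
        values = rng.random(n_positions)
        labels = np.zeros(n_positions, dtype=bool)
        labels[: n_positions // 2] = True
        rng.shuffle(labels)
        aurocs.append(roc_from_values(values, labels).auroc)
    return float(np.mean(aurocs))
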
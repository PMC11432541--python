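"""Canned study workflows at the scaled-down ("desk") conditions.

The desk ensemble is the package's reference experiment: a 200-bead,
four-type SBS chain in a 20-sigma periodic box with total binder volume
fraction 0.05 at affinity 5 k_BT, simulated to collapse 50 independent
times.  From the final phase-separated conformations it computes the
single-molecule statistics reported by the analysis suite: inertia-ellipsoid
semi-axis ratios a/c and b/c, gyration-tensor ellipticity, the pairwise
distance-matrix heterogeneity r', and the Mann-Whitney comparison of the
two ratio distributions.  The affinity sweep drives a 100-bead homopolymer
through the coil-globule transition at the production concentration.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .md_engine import CollapseSummary, detect_collapse, init_saw, place_binders, run_dynamics
from .model_core import BinderEnsemble, Conformation, PolymerSpec, SimulationParams
from .phase_diagram import SweepResult, estimate_threshold, run_sweep
from .single_molecule import distance_map, ensemble_shape_stats, heterogeneity, mann_whitney
from .synthetic_data import DESK_PRESET, make_binding_profile

__all__ = ["desk_ensemble", "desk_statistics", "affinity_sweep", "DEFAULT_AFFINITY_GRID"]

DEFAULT_AFFINITY_GRID = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 5.0, 8.0)


def desk_ensemble(
    seed: int,
    replicates: int | None = None,
    n_steps: int | None = None,
    preset: dict = DESK_PRESET,
) -> tuple[list[Conformation], list[CollapseSummary]]:
    """Simulate independent collapses at the desk conditions.

    The binding profile is a fixed study input (its own seed lives in the
    preset); ``seed`` drives all simulation randomness, fanned out per
    replicate through ``SeedSequence([seed, replicate])``.  Returns the
    final conformation and the collapse summary of every replicate.
    """
    if replicates is None:
        replicates = preset["replicates"]
    if n_steps is None:
        n_steps = preset["n_steps"]
    spec = make_binding_profile(preset["profile"], bp_per_bead=preset["bp_per_bead"])
    params = SimulationParams(box_edge=preset["box_edge"], n_steps=n_steps)
    binders = BinderEnsemble.uniform(
        spec.type_catalog, preset["volume_fraction"], preset["affinity"]
    )
    confs, summaries = [], []
    for rep in range(replicates):
        ss = np.random.SeedSequence([seed, rep])
        s_init, s_place, s_run = (int(v) for v in ss.generate_state(3) >> 1)
        conf = init_saw(spec, params, s_init)
        conf = place_binders(conf, binders, spec, params, s_place)
        traj = run_dynamics(
            conf, spec, binders, replace(params, seed=s_run),
            sample_every=preset["sample_every"],
        )
        confs.append(traj.final)
        summaries.append(detect_collapse(traj.rg_series))
    return confs, summaries


def desk_statistics(confs: list[Conformation]) -> dict:
    """Single-molecule statistics of a phase-separated ensemble."""
    table, summary = ensemble_shape_stats(confs)
    good = table[~table.degenerate]
    het = heterogeneity([distance_map(c) for c in confs])
    _, p_shape = mann_whitney(good["ac_ratio"], good["bc_ratio"])
    return {
        "n_molecules": len(confs),
        "mean_bc_ratio": summary["mean_bc_ratio"],
        "mean_ac_ratio": summary["mean_ac_ratio"],
        "mean_ellipticity": summary["mean_ellipticity"],
        "mean_rprime": het.mean,
        "var_rprime": het.variance,
        "mean_rg": summary["mean_rg"],
        "mean_v_abc": summary["mean_v_abc"],
        "mean_v_rg": summary["mean_v_rg"],
        "ac_vs_bc_mannwhitney_p": p_shape,
    }


def affinity_sweep(
    seed: int,
    grid: tuple[float, ...] = DEFAULT_AFFINITY_GRID,
    n_beads: int = 100,
    box_edge: float = 20.0,
    volume_fraction: float = 0.1,
    n_steps: int = 60_000,
    replicates: int = 3,
) -> tuple[SweepResult, float]:
    """Homopolymer affinity sweep at the characteristic threshold
    concentration (volume fraction 0.1).

    Returns the sweep result and the estimated collapse threshold in k_BT.
    """
    spec = PolymerSpec.homopolymer(n_beads)
    params = SimulationParams(box_edge=box_edge, n_steps=n_steps)
    points = [(volume_fraction, float(e)) for e in grid]
    result = run_sweep(spec, points, params, replicates=replicates, seed=seed)
    affinities = np.array([p.affinity for p in result.points])
    plateau = np.array([p.plateau_mean for p in result.points])
    threshold = estimate_threshold(affinities, plateau, log_axis=False)
    return result, threshold
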
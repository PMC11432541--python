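"""Coil-globule phase-diagram sweeps over binder concentration and affinity.

The binder volume fraction c and the bead-binder affinity E_bb are the two
control parameters of the SBS coil-globule transition: below characteristic
thresholds the chain stays a self-avoiding coil, above them it collapses
into a phase-separated globule.  This module runs replicate simulations
over a (c, E_bb) grid, summarises each point by its plateau gyration radius
and estimates the transition threshold as the midpoint crossing of the
coil/globule plateaus.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .md_engine import CollapseSummary, detect_collapse, init_saw, place_binders, run_dynamics
from .model_core import BinderEnsemble, PolymerSpec, SimulationParams

__all__ = ["SweepPoint", "SweepResult", "run_sweep", "estimate_threshold", "ThresholdError"]


class ThresholdError(RuntimeError):
    """The response curve does not show two plateaus with a crossing."""


@dataclass
class SweepPoint:
    c: float
    affinity: float
    plateau_rgs: np.ndarray  # one per surviving replicate
    collapse: list[CollapseSummary]
    failed_replicates: int = 0

    @property
    def plateau_mean(self) -> float:
        return float(np.mean(self.plateau_rgs))

    @property
    def plateau_sem(self) -> float:
        k = len(self.plateau_rgs)
        return float(np.std(self.plateau_rgs, ddof=1) / np.sqrt(k)) if k > 1 else 0.0


@dataclass
class SweepResult:
    points: list[SweepPoint]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.points:
            for rep, (rg, cs) in enumerate(zip(p.plateau_rgs, p.collapse)):
                rows.append(
                    {
                        "c": p.c,
                        "affinity": p.affinity,
                        "replicate": rep,
                        "plateau_rg": rg,
                        "collapse_step": cs.collapse_step,
                        "drop_fraction": cs.drop_fraction,
                    }
                )
        return pd.DataFrame(rows)


def run_sweep(
    spec: PolymerSpec,
    grid: list[tuple[float, float]],
    params: SimulationParams,
    replicates: int = 3,
    seed: int = 0,
    sample_every: int = 500,
) -> SweepResult:
    """Simulate every (c, E_bb) grid point with independent replicate seeds.

    Each replicate grows a fresh SAW, injects binders at volume fraction c
    split equally over the type catalog, runs the dynamics and summarises
    the Rg track.  Seeds derive from (seed, point index, replicate), so the
    whole sweep is reproducible from the master seed.  Replicates that
    diverge are dropped and counted; a point only fails if all do.
    """
    if not grid:
        raise ValueError("empty sweep grid")
    if replicates < 1:
        raise ValueError("need at least one replicate per grid point")
    points = []
    for p_idx, (c, affinity) in enumerate(grid):
        binders = BinderEnsemble.uniform(spec.type_catalog, c, affinity)
        rgs, summaries, failed = [], [], 0
        for rep in range(replicates):
            child = np.random.SeedSequence([seed, p_idx, rep])
            s_init, s_place, s_run = (int(v) for v in child.generate_state(3) >> 1)
            try:
                conf = init_saw(spec, params, s_init)
                conf = place_binders(conf, binders, spec, params, s_place)
                traj = run_dynamics(
                    conf, spec, binders, replace(params, seed=s_run),
                    sample_every=sample_every,
                )
            except RuntimeError:
                failed += 1
                continue
            cs = detect_collapse(traj.rg_series)
            rgs.append(cs.plateau_mean)
            summaries.append(cs)
        if not rgs:
            raise RuntimeError(f"all replicates failed at grid point c={c}, E={affinity}")
        points.append(
            SweepPoint(
                c=c,
                affinity=affinity,
                plateau_rgs=np.array(rgs),
                collapse=summaries,
                failed_replicates=failed,
            )
        )
    return SweepResult(points=points)


def estimate_threshold(
    param: np.ndarray, rg: np.ndarray, log_axis: bool = False
) -> float:
    """Parameter value where the plateau-Rg curve crosses the coil/globule
    midpoint.

    The noisy response is first reduced to a non-increasing curve by
    isotonic regression (its monotone least-squares projection), which
    guarantees a single midpoint crossing; the coil and globule levels are
    the fitted values at the two grid extremes.  The crossing is located by
    linear interpolation between the bracketing grid points, in
    log-parameter space when ``log_axis`` (so a sharp step lands on the
    geometric mean of the two points).
    """
    from sklearn.isotonic import IsotonicRegression

    param = np.asarray(param, dtype=float)
    rg = np.asarray(rg, dtype=float)
    order = np.argsort(param)
    param, rg = param[order], rg[order]
    if param.size < 4:
        raise ThresholdError("need at least 4 grid points spanning both plateaus")
    fit = IsotonicRegression(increasing=False).fit_transform(np.arange(param.size), rg)
    coil = fit[0]
    globule = fit[-1]
    if coil <= 0 or 1.0 - globule / coil < 0.1:
        raise ThresholdError(
            "response curve shows no collapse (relative drop below 10%); "
            "extend the grid to span both plateaus"
        )
    mid = 0.5 * (coil + globule)
    x = np.log(param) if log_axis else param
    below = np.nonzero(fit <= mid)[0]
    j = below[0]
    if j == 0:
        return float(param[0])
    x0, x1 = x[j - 1], x[j]
    t = (mid - fit[j - 1]) / (fit[j] - fit[j - 1])
    xc = x0 + t * (x1 - x0)
    return float(np.exp(xc)) if log_axis else float(xc)
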
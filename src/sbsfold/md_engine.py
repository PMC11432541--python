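"""Langevin dynamics of the SBS bead-spring chain plus diffusing binders.

The chain is a standard coarse-grained polymer: consecutive beads joined by
FENE springs, excluded volume through a WCA potential, and short-range
Lennard-Jones attraction (depth = the binder type's affinity, cutoff 1.5
sigma) between binders and the beads carrying their cognate binding-site
label.  Motion follows the Langevin equation at friction 0.5 and
temperature 1 (reduced units), integrated with velocity-Verlet; production
force evaluation uses numba kernels with a Verlet/cell neighbour list, while
this module also carries an independent KDTree-based reference evaluation
used for validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from . import _kernels
from .model_core import (
    BinderEnsemble,
    Conformation,
    PolymerSpec,
    SimulationParams,
    Trajectory,
)

__all__ = [
    "EnergyBreakdown",
    "CollapseSummary",
    "SimulationDiverged",
    "init_saw",
    "place_binders",
    "system_energy",
    "system_forces",
    "run_dynamics",
    "radius_of_gyration",
    "rg_series",
    "detect_collapse",
]


@dataclass(frozen=True)
class EnergyBreakdown:
    """Potential energy by channel, in k_B T."""

    fene: float
    repulsive: float
    attractive: float

    @property
    def total(self) -> float:
        return self.fene + self.repulsive + self.attractive


@dataclass(frozen=True)
class CollapseSummary:
    """Summary of a gyration-radius time track.

    ``collapse_step`` is the sample index at which the smoothed Rg first
    crosses the coil/plateau midpoint, or None when the track shows no
    collapse (relative drop below 10%).
    """

    collapse_step: int | None
    coil_mean: float
    plateau_mean: float
    drop_fraction: float


class SimulationDiverged(RuntimeError):
    """Raised when the integrator hits a diverging bond or non-finite state.

    Carries the trajectory collected up to the last stable sample."""

    def __init__(self, message: str, trajectory: Trajectory | None = None):
        super().__init__(message)
        self.trajectory = trajectory


# ---------------------------------------------------------------------------
# system setup
# ---------------------------------------------------------------------------


def _cell_key(p: np.ndarray, w: float, nc: int) -> tuple[int, int, int]:
    return (
        min(int(p[0] / w), nc - 1),
        min(int(p[1] / w), nc - 1),
        min(int(p[2] / w), nc - 1),
    )


def _too_close(p, grid, w, nc, L, min_d2) -> bool:
    kx, ky, kz = _cell_key(p, w, nc)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                key = ((kx + dx) % nc, (ky + dy) % nc, (kz + dz) % nc)
                for q in grid.get(key, ()):
                    d = p - q
                    d -= L * np.round(d / L)
                    if d @ d < min_d2:
                        return True
    return False


def init_saw(
    spec: PolymerSpec, params: SimulationParams, seed: int
) -> Conformation:
    """Grow an open self-avoiding-walk chain of unit bonds inside the box.

    Bond lengths are exactly 1 sigma and no two non-bonded beads come
    closer than 0.9 sigma.  The walk is confined to the box interior with a
    0.5 sigma wall margin: the whole chain then sits in a single periodic
    cell (never winding around the torus, which would leave it permanently
    stretched) and stays at least 1 sigma from every periodic image.
    Growth backtracks on dead ends; persistent failure raises with a
    suggestion to enlarge the box.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_beads
    L = params.box_edge
    margin = 0.5
    lo, hi = margin, L - margin
    if hi - lo < 2.0:
        raise RuntimeError("box too small to hold a confined self-avoiding walk")
    min_d = 0.9
    min_d2 = min_d * min_d
    coords = np.empty((n, 3))
    coords[0] = L / 2.0
    # cell grid over the box for O(1) self-avoidance checks (free space:
    # the confined chain cannot clash with its periodic images)
    nc = max(int(L / 1.0), 3)
    w = L / nc
    grid: dict[tuple[int, int, int], list[int]] = {}
    keys: list[tuple[int, int, int]] = []

    def _add(i: int) -> None:
        key = _cell_key(coords[i], w, nc)
        grid.setdefault(key, []).append(i)
        keys.append(key)

    def _pop() -> None:
        grid[keys.pop()].pop()

    def _clashes(cand: np.ndarray, upto: int) -> bool:
        kx, ky, kz = _cell_key(cand, w, nc)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    cell = grid.get((kx + dx, ky + dy, kz + dz))
                    if not cell:
                        continue
                    for q in cell:
                        if q >= upto:  # bonded predecessor checked via bond length
                            continue
                        d = cand - coords[q]
                        if d @ d < min_d2:
                            return True
        return False

    _add(0)
    placed = 1
    attempts = 0
    max_attempts = 600 * n
    while placed < n:
        ok = False
        for _ in range(80):
            attempts += 1
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            cand = coords[placed - 1] + v
            if (cand < lo).any() or (cand > hi).any():
                continue
            if _clashes(cand, placed - 1):
                continue
            coords[placed] = cand
            _add(placed)
            placed += 1
            ok = True
            break
        if not ok:
            back = min(5, placed - 1)
            for _ in range(back):
                _pop()
            placed -= back
        if attempts > max_attempts:
            raise RuntimeError(
                f"self-avoiding-walk placement failed after {attempts} attempts; "
                "try a larger box or fewer beads"
            )
    _pivot_mix(coords, rng, lo, hi, min_d, sweeps=8)
    return Conformation(bead_coords=coords, box_edge=params.box_edge)


def _pivot_mix(coords, rng, lo, hi, min_d, sweeps=8):
    """Equilibrate a grown walk with pivot moves (random tail rotations).

    Sequential growth is a kinetic-growth walk whose statistics are more
    compact than a true self-avoiding walk; pivot moves satisfy detailed
    balance with respect to the uniform SAW measure and restore the correct
    Flory scaling.  Moves violating self-avoidance or the confinement
    bounds are rejected.
    """
    n = coords.shape[0]
    if n < 4:
        return
    min_d2 = min_d * min_d
    for _ in range(sweeps * n):
        pivot = int(rng.integers(1, n - 1))
        # random rotation from a uniform unit quaternion
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
                [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
                [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
            ]
        )
        centre = coords[pivot]
        # rotate the shorter arm about the pivot bead (equally valid and cheaper)
        if pivot < n // 2:
            move_sl, keep_sl = slice(0, pivot), slice(pivot, n)
        else:
            move_sl, keep_sl = slice(pivot + 1, n), slice(0, pivot + 1)
        moved = (coords[move_sl] - centre) @ rot.T + centre
        if moved.size == 0:
            continue
        if moved.min() < lo or moved.max() > hi:
            continue
        # pairs across the pivot are all non-bonded (the bead adjacent to the
        # pivot keeps its bond length under the rigid rotation), so the plain
        # min-distance criterion applies
        d2 = cdist(coords[keep_sl], moved, "sqeuclidean")
        if d2.min() < min_d2:
            continue
        coords[move_sl] = moved


def place_binders(
    conf: Conformation,
    binders: BinderEnsemble,
    spec: PolymerSpec,
    params: SimulationParams,
    seed: int,
) -> Conformation:
    """Inject binders uniformly at random into the box, rejecting positions
    within 1.0 sigma (minimum image) of any already placed particle, so no
    pair starts inside a repulsive core or on the cognate-LJ slope."""
    counts = binders.resolved_counts(params.box_edge)
    total = sum(counts.values())
    if total == 0:
        return Conformation(
            bead_coords=conf.bead_coords,
            binder_coords=np.zeros((0, 3)),
            binder_labels=np.zeros(0, dtype=np.int64),
            box_edge=params.box_edge,
        )
    rng = np.random.default_rng(seed)
    L = params.box_edge
    # contact distance: at 1.0 sigma both WCA and cognate LJ are exactly zero,
    # so freshly injected binders start without potential-energy spikes
    min_d = 1.0
    nc = max(int(L / min_d), 1)  # cells tile the box exactly, width >= min_d
    w = L / nc
    grid: dict[tuple[int, int, int], list[np.ndarray]] = {}
    for b in conf.bead_coords % L:
        grid.setdefault(_cell_key(b, w, nc), []).append(b)
    placed = np.empty((total, 3))
    labels = np.empty(total, dtype=np.int64)
    cat_index = {lab: k for k, lab in enumerate(spec.type_catalog)}
    k = 0
    for lab, cnt in counts.items():
        lab_idx = cat_index.get(lab, -1)
        if lab_idx < 0:
            raise ValueError(f"binder type {lab!r} not in the polymer type catalog")
        for _ in range(cnt):
            for attempt in range(400):
                p = rng.random(3) * L
                if not _too_close(p, grid, w, nc, L, min_d * min_d):
                    break
            else:
                raise RuntimeError(
                    "binder packing fraction too high: could not place binder "
                    f"{k + 1}/{total} after 400 attempts"
                )
            placed[k] = p
            labels[k] = lab_idx
            grid.setdefault(_cell_key(p, w, nc), []).append(p)
            k += 1
    return Conformation(
        bead_coords=conf.bead_coords,
        binder_coords=placed,
        binder_labels=labels,
        box_edge=params.box_edge,
    )


def _system_arrays(conf: Conformation, spec: PolymerSpec, binders: BinderEnsemble):
    """Pack per-particle bitmask / binder-flag / affinity arrays (beads first)."""
    n_beads = spec.n_beads
    m = conf.n_binders
    masks = np.zeros(n_beads + m, dtype=np.int64)
    masks[:n_beads] = spec.type_masks()
    is_binder = np.zeros(n_beads + m, dtype=np.bool_)
    is_binder[n_beads:] = True
    eps = np.zeros(n_beads + m, dtype=np.float64)
    if m:
        affinity_by_idx = np.zeros(len(spec.type_catalog))
        for lab, bt in binders.types.items():
            if lab in spec.type_catalog:
                affinity_by_idx[spec.type_catalog.index(lab)] = bt.affinity
        masks[n_beads:] = np.int64(1) << conf.binder_labels
        eps[n_beads:] = affinity_by_idx[conf.binder_labels]
    pos = (
        conf.bead_coords
        if m == 0
        else np.vstack([conf.bead_coords, conf.binder_coords])
    )
    return np.ascontiguousarray(pos, dtype=np.float64), masks, is_binder, eps


# ---------------------------------------------------------------------------
# reference energy / forces (KDTree route, independent of the numba kernels)
# ---------------------------------------------------------------------------


def _pair_terms(pos, masks, is_binder, eps, params):
    """Pairwise displacement vectors and channel assignment within cutoffs."""
    L = params.box_edge
    wrapped = pos % L
    wrapped[wrapped >= L] -= L
    tree = cKDTree(wrapped, boxsize=L)
    pairs = tree.query_pairs(r=max(params.r_rep, params.r_att), output_type="ndarray")
    if pairs.size == 0:
        return pairs, np.zeros((0, 3)), np.zeros(0, dtype=bool), np.zeros(0)
    d = wrapped[pairs[:, 0]] - wrapped[pairs[:, 1]]
    d -= L * np.round(d / L)
    cognate = (is_binder[pairs[:, 0]] != is_binder[pairs[:, 1]]) & (
        (masks[pairs[:, 0]] & masks[pairs[:, 1]]) != 0
    )
    pair_eps = eps[pairs[:, 0]] + eps[pairs[:, 1]]
    return pairs, d, cognate, pair_eps


def system_energy(
    conf: Conformation,
    spec: PolymerSpec,
    binders: BinderEnsemble,
    params: SimulationParams,
) -> EnergyBreakdown:
    """Potential energy by channel (FENE / WCA repulsion / cognate attraction).

    Direct KDTree-based evaluation under the minimum-image convention; raises
    :class:`SimulationDiverged` if any FENE bond has reached R0.
    """
    pos, masks, is_binder, eps = _system_arrays(conf, spec, binders)
    pairs, d, cognate, pair_eps = _pair_terms(pos, masks, is_binder, eps, params)
    r2 = np.sum(d * d, axis=1) if len(d) else np.zeros(0)

    rep_sel = (~cognate) & (r2 < params.r_rep**2)
    inv6 = 1.0 / r2[rep_sel] ** 3
    e_rep = float(np.sum(4.0 * (inv6**2 - inv6) + 1.0))

    att_sel = cognate & (r2 < params.r_att**2)
    inv6a = 1.0 / r2[att_sel] ** 3
    inv6c = 1.0 / params.r_att**6
    shift = 4.0 * (inv6c**2 - inv6c)
    e_att = float(np.sum(4.0 * pair_eps[att_sel] * (inv6a**2 - inv6a) - pair_eps[att_sel] * shift))

    bond_vec = np.diff(conf.bead_coords, axis=0)
    bond_r2 = np.sum(bond_vec**2, axis=1)
    r02 = params.fene_r0**2
    if np.any(bond_r2 >= r02):
        i = int(np.argmax(bond_r2))
        raise SimulationDiverged(
            f"FENE bond {i}-{i + 1} at r = {math.sqrt(bond_r2.max()):.3f} >= R0"
        )
    e_fene = float(np.sum(-0.5 * params.fene_k * r02 * np.log(1.0 - bond_r2 / r02)))
    return EnergyBreakdown(fene=e_fene, repulsive=e_rep, attractive=e_att)


def system_forces(
    conf: Conformation,
    spec: PolymerSpec,
    binders: BinderEnsemble,
    params: SimulationParams,
) -> np.ndarray:
    """Conservative forces on every particle (beads then binders), reference route."""
    pos, masks, is_binder, eps = _system_arrays(conf, spec, binders)
    forces = np.zeros_like(pos)
    pairs, d, cognate, pair_eps = _pair_terms(pos, masks, is_binder, eps, params)
    if len(d):
        r2 = np.sum(d * d, axis=1)
        rep_sel = (~cognate) & (r2 < params.r_rep**2)
        inv2 = 1.0 / r2[rep_sel]
        inv6 = inv2**3
        fmag = 24.0 * (2.0 * inv6**2 - inv6) * inv2
        fv = fmag[:, None] * d[rep_sel]
        np.add.at(forces, pairs[rep_sel, 0], fv)
        np.add.at(forces, pairs[rep_sel, 1], -fv)
        att_sel = cognate & (r2 < params.r_att**2)
        inv2a = 1.0 / r2[att_sel]
        inv6a = inv2a**3
        fmag = 24.0 * pair_eps[att_sel] * (2.0 * inv6a**2 - inv6a) * inv2a
        fv = fmag[:, None] * d[att_sel]
        np.add.at(forces, pairs[att_sel, 0], fv)
        np.add.at(forces, pairs[att_sel, 1], -fv)
    bond_vec = np.diff(conf.bead_coords, axis=0)
    bond_r2 = np.sum(bond_vec**2, axis=1)
    r02 = params.fene_r0**2
    n = spec.n_beads
    # tension K/(1-(r/R0)^2) pulls bonded beads together
    fb = (params.fene_k / (1.0 - bond_r2 / r02))[:, None] * bond_vec
    np.add.at(forces, np.arange(n - 1), fb)
    np.add.at(forces, np.arange(n - 1) + 1, -fb)
    return forces


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------


def radius_of_gyration(coords: np.ndarray) -> float:
    """Root-mean-square distance of points from their centre of mass."""
    com = coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((coords - com) ** 2, axis=1))))


def run_dynamics(
    conf: Conformation,
    spec: PolymerSpec,
    binders: BinderEnsemble,
    params: SimulationParams,
    n_steps: int | None = None,
    sample_every: int = 500,
    store_binders: bool = False,
) -> Trajectory:
    """Integrate the system and return sampled frames with the Rg time track.

    Deterministic for a given ``params.seed``.  Bead positions are kept
    unwrapped (the chain stays spatially contiguous); forces are evaluated
    under minimum image.  Frames store bead coordinates; binder coordinates
    are attached to every frame if ``store_binders``, else to the final
    frame only.
    """
    if n_steps is None:
        n_steps = params.n_steps
    pos, masks, is_binder, eps = _system_arrays(conf, spec, binders)
    n_total = pos.shape[0]
    n_beads = spec.n_beads
    rng = np.random.default_rng(params.seed)
    vel = rng.normal(scale=math.sqrt(params.temperature / params.mass), size=(n_total, 3))
    ss = np.random.SeedSequence(params.seed)
    n_chunks = (n_steps + sample_every - 1) // sample_every
    chunk_seeds = ss.generate_state(n_chunks + 1, dtype=np.uint32) >> np.uint32(1)
    wpos = pos % params.box_edge
    wpos[wpos >= params.box_edge] -= params.box_edge
    rep_cap = max(60 * n_total, 20_000)
    att_cap = max(60 * n_total, 20_000)

    frames: list[Conformation] = []
    steps: list[int] = []
    rgs: list[float] = []

    def snapshot(step: int, with_binders: bool) -> None:
        bc = pos[n_beads:].copy() if (with_binders and n_total > n_beads) else None
        frames.append(
            Conformation(
                bead_coords=pos[:n_beads].copy(),
                binder_coords=bc,
                binder_labels=conf.binder_labels.copy() if bc is not None else None,
                box_edge=params.box_edge,
            )
        )
        steps.append(step)
        rgs.append(radius_of_gyration(pos[:n_beads]))

    done = 0
    chunk = 0
    while done < n_steps:
        this = min(sample_every, n_steps - done)
        status = _kernels.run_chunk(
            pos, wpos, vel, this, params.box_edge, params.dt, params.friction,
            params.temperature, params.mass, n_beads, masks, is_binder, eps,
            params.fene_k, params.fene_r0, params.r_rep, params.r_att,
            0.3, int(chunk_seeds[chunk]), rep_cap, att_cap,
        )
        if status == _kernels.ERR_OVERFLOW:
            rep_cap *= 2
            att_cap *= 2
            if rep_cap > 10_000_000:
                raise RuntimeError("neighbour-list capacity exceeded (system unphysical?)")
            continue  # deterministic retry of the chunk with larger lists
        chunk += 1
        if status != _kernels.OK:
            partial = Trajectory(frames=frames, steps=np.array(steps), rg_series=np.array(rgs))
            kind = "FENE bond reached R0" if status == _kernels.ERR_BOND else "non-finite state"
            raise SimulationDiverged(
                f"integration diverged after step {done} ({kind}); "
                "reduce the timestep or check the initial state",
                trajectory=partial,
            )
        done += this
        snapshot(done, store_binders or done >= n_steps)
    return Trajectory(frames=frames, steps=np.array(steps), rg_series=np.array(rgs))


def rg_series(traj: Trajectory) -> np.ndarray:
    """Gyration-radius track over the sampled frames (beads only)."""
    return np.array([radius_of_gyration(f.bead_coords) for f in traj.frames])


def detect_collapse(series: np.ndarray, smooth_window: int | None = None) -> CollapseSummary:
    """Locate the coil-to-globule collapse in a gyration-radius time track.

    The coil level is the mean of the first 5% of samples, the plateau the
    mean of the last 25%; the collapse step is the first sample at which the
    (moving-average smoothed) track falls below the midpoint of the two
    levels.  Tracks whose relative drop is below 10% report no collapse.
    """
    series = np.asarray(series, dtype=float)
    n = series.size
    if n < 20:
        raise ValueError("collapse detection needs at least 20 samples")
    coil = float(series[: max(1, n // 20)].mean())
    plateau = float(series[-max(1, n // 4):].mean())
    drop = 1.0 - plateau / coil if coil > 0 else 0.0
    if drop < 0.1:
        return CollapseSummary(None, coil, plateau, drop)
    w = smooth_window if smooth_window is not None else max(1, n // 25)
    smoothed = uniform_filter1d(series, size=w, mode="nearest")
    midpoint = 0.5 * (coil + plateau)
    below = np.nonzero(smoothed < midpoint)[0]
    step = int(below[0]) if below.size else None
    return CollapseSummary(step, coil, plateau, drop)
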
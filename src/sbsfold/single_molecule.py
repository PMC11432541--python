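"""Per-conformation structure analytics.

For each phase-separated conformation this module computes

* the pairwise Euclidean distance matrix between polymer sites, and from an
  ensemble of such matrices the distribution of pairwise distance-corrected
  correlations r' — the heterogeneity statistic: near 0 for structurally
  unrelated molecules, near 1 for identical folds;
* the inertia tensor about the centre of mass, its principal moments
  I_a <= I_b <= I_c, and the semi-axes a >= b >= c of the equivalent
  uniform triaxial ellipsoid (a^2 = (5/2N)(I_b + I_c - I_a), cyclic);
* the gyration tensor, its eigenvalues lambda_1 >= lambda_2 >= lambda_3 and
  the ellipticity eps = 2*lambda_3/(lambda_1 + lambda_2) (1 for a sphere,
  -> 0 for strongly prolate shapes);
* ellipsoid and gyration-based volumes V = (4/3) pi a b c and
  V = (4/3) pi Rg^3;
* a Mann-Whitney U test (exact for small samples) used to compare shape
  distributions, e.g. a/c against b/c.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

from .ensemble_maps import distance_residuals
from .model_core import Conformation

__all__ = [
    "DistanceMap",
    "ShapeDescriptors",
    "HeterogeneityStats",
    "distance_map",
    "heterogeneity",
    "inertia_shape",
    "gyration_shape",
    "shape_descriptors",
    "molecule_volumes",
    "ensemble_shape_stats",
    "mann_whitney",
]

log = logging.getLogger(__name__)


@dataclass
class DistanceMap:
    """Symmetric matrix of pairwise Euclidean distances (sigma units)."""

    matrix: np.ndarray

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ShapeDescriptors:
    """Shape of one conformation from its second-moment tensors.

    Inertia part: principal moments I_a <= I_b <= I_c, ellipsoid semi-axes
    a >= b >= c (the smallest moment belongs to the longest axis) and the
    ellipsoid volume.  Gyration part: eigenvalues sorted descending, the
    ellipticity, Rg (Rg^2 = trace) and the gyration-sphere volume.
    """

    inertia_moments: np.ndarray | None = None  # (I_a, I_b, I_c)
    semi_axes: np.ndarray | None = None  # (a, b, c)
    gyration_eigenvalues: np.ndarray | None = None  # (l1, l2, l3) descending
    ellipticity: float | None = None
    rg: float | None = None
    degenerate: bool = False
    flags: list[str] = field(default_factory=list)

    @property
    def ac_ratio(self) -> float:
        a, _, c = self.semi_axes
        return float(a / c)

    @property
    def bc_ratio(self) -> float:
        _, b, c = self.semi_axes
        return float(b / c)

    @property
    def v_abc(self) -> float:
        a, b, c = self.semi_axes
        return float(4.0 / 3.0 * math.pi * a * b * c)

    @property
    def v_rg(self) -> float:
        return float(4.0 / 3.0 * math.pi * self.rg**3)


@dataclass
class HeterogeneityStats:
    """Distribution of pairwise r' between single-molecule distance matrices."""

    values: np.ndarray  # one r' per unordered pair of (non-degenerate) maps
    mean: float
    variance: float
    n_maps: int
    n_excluded: int = 0


def distance_map(conf: Conformation, box_edge: float | None = None) -> DistanceMap:
    """Pairwise distances between beads (no periodic imaging).

    Analysis runs on unwrapped molecules; a bond longer than half the box is
    taken as evidence of wrapped input and rejected.
    """
    coords = conf.bead_coords
    L = box_edge if box_edge is not None else conf.box_edge
    if L:
        bonds = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        if bonds.size and bonds.max() > L / 2:
            raise ValueError(
                f"bond of length {bonds.max():.2f} exceeds half the box ({L / 2:.2f}); "
                "coordinates look wrapped - unwrap the molecule before analysis"
            )
    return DistanceMap(matrix=squareform(pdist(coords)))


def heterogeneity(maps: list[DistanceMap]) -> HeterogeneityStats:
    """Pairwise distance-corrected correlations r' over all unordered pairs.

    Each matrix is residualised by its own per-|i-j| mean profile (the same
    correction used for contact maps); degenerate matrices (zero residual
    variance) are excluded with a log entry.
    """
    if len(maps) < 2:
        raise ValueError("heterogeneity needs at least 2 distance maps")
    n = maps[0].n
    iu = np.triu_indices(n, k=1)
    residuals = []
    excluded = 0
    for k, dm in enumerate(maps):
        if dm.n != n:
            raise ValueError("distance maps have mismatched shapes")
        r = distance_residuals(dm.matrix)[iu]
        norm2 = float(r @ r)
        scale2 = float(np.max(dm.matrix)) ** 2 * r.size
        if norm2 <= 1e-20 * max(scale2, 1e-300):
            log.warning("distance map %d is degenerate (pure |i-j| profile); excluded", k)
            excluded += 1
            continue
        residuals.append(r / math.sqrt(norm2))
    kmaps = len(residuals)
    if kmaps < 2:
        raise ValueError("fewer than 2 non-degenerate distance maps")
    R = np.array(residuals)
    corr = R @ R.T
    vals = corr[np.triu_indices(kmaps, k=1)]
    vals = np.clip(vals, -1.0, 1.0)
    return HeterogeneityStats(
        values=vals,
        mean=float(vals.mean()),
        variance=float(vals.var()),
        n_maps=kmaps,
        n_excluded=excluded,
    )


def _centered(coords: np.ndarray) -> np.ndarray:
    return coords - coords.mean(axis=0)


def inertia_shape(conf: Conformation) -> ShapeDescriptors:
    """Principal inertia moments and equivalent-ellipsoid semi-axes.

    The tensor I_bg = sum_a m_a (r_a^2 d_bg - r_ab r_ag) is evaluated about
    the centre of mass (unit masses).  Moments are sorted ascending; the
    semi-axes follow the uniform-ellipsoid inversion a^2 = (5/2N)(I_b + I_c
    - I_a) (cyclic), so the smallest moment maps to the longest axis.
    Negative radicands (degenerate clouds) are clipped to zero and flagged.
    """
    coords = _centered(conf.bead_coords)
    n = coords.shape[0]
    if n < 4:
        raise ValueError("inertia shape needs at least 4 beads")
    r2 = np.sum(coords**2, axis=1)
    inertia = np.eye(3) * r2.sum() - coords.T @ coords
    moments = np.linalg.eigvalsh(inertia)  # ascending: I_a <= I_b <= I_c
    ia, ib, ic = moments
    sq = np.array(
        [
            (5.0 / (2.0 * n)) * (ib + ic - ia),
            (5.0 / (2.0 * n)) * (ia + ic - ib),
            (5.0 / (2.0 * n)) * (ia + ib - ic),
        ]
    )
    flags = []
    degenerate = False
    if np.any(sq < 0):
        flags.append("negative radicand clipped to zero")
        sq = np.clip(sq, 0.0, None)
        degenerate = True
    axes = np.sqrt(sq)
    if axes[0] > 0 and axes[2] / axes[0] < 1e-6:
        degenerate = True
        if "degenerate (collinear or coincident) bead cloud" not in flags:
            flags.append("degenerate (collinear or coincident) bead cloud")
    return ShapeDescriptors(
        inertia_moments=moments, semi_axes=axes, degenerate=degenerate, flags=flags
    )


def gyration_shape(conf: Conformation) -> ShapeDescriptors:
    """Gyration-tensor eigenvalues, ellipticity and Rg.

    T_bg = (1/N) sum_a (r_ab - rbar_b)(r_ag - rbar_g); eigenvalues sorted
    descending; ellipticity eps = 2 lambda_3 / (lambda_1 + lambda_2);
    Rg^2 = lambda_1 + lambda_2 + lambda_3.
    """
    coords = _centered(conf.bead_coords)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("gyration shape needs at least 2 beads")
    tensor = coords.T @ coords / n
    lam = np.linalg.eigvalsh(tensor)[::-1]  # descending
    denom = lam[0] + lam[1]
    eps = float(2.0 * lam[2] / denom) if denom > 0 else 0.0
    return ShapeDescriptors(
        gyration_eigenvalues=lam,
        ellipticity=eps,
        rg=float(math.sqrt(max(lam.sum(), 0.0))),
    )


def shape_descriptors(conf: Conformation) -> ShapeDescriptors:
    """Combined inertia + gyration descriptors for one conformation."""
    ine = inertia_shape(conf)
    gyr = gyration_shape(conf)
    return ShapeDescriptors(
        inertia_moments=ine.inertia_moments,
        semi_axes=ine.semi_axes,
        gyration_eigenvalues=gyr.gyration_eigenvalues,
        ellipticity=gyr.ellipticity,
        rg=gyr.rg,
        degenerate=ine.degenerate,
        flags=ine.flags,
    )


def molecule_volumes(shape: ShapeDescriptors) -> tuple[float, float]:
    """(V_abc, V_rg): ellipsoid volume (4/3) pi a b c and gyration-sphere
    volume (4/3) pi Rg^3, both in sigma^3."""
    return shape.v_abc, shape.v_rg


def ensemble_shape_stats(confs: list[Conformation]) -> tuple[pd.DataFrame, dict]:
    """Per-molecule descriptor table plus ensemble means/variances.

    Degenerate molecules are excluded from the summary (their count is
    reported).  Ensemble volumes are means of per-molecule volumes.
    """
    if len(confs) < 2:
        raise ValueError("ensemble statistics need at least 2 conformations")
    rows = []
    for idx, conf in enumerate(confs):
        sd = shape_descriptors(conf)
        rows.append(
            {
                "molecule": idx,
                "a": sd.semi_axes[0],
                "b": sd.semi_axes[1],
                "c": sd.semi_axes[2],
                "ac_ratio": sd.ac_ratio if not sd.degenerate else np.nan,
                "bc_ratio": sd.bc_ratio if not sd.degenerate else np.nan,
                "lambda1": sd.gyration_eigenvalues[0],
                "lambda2": sd.gyration_eigenvalues[1],
                "lambda3": sd.gyration_eigenvalues[2],
                "ellipticity": sd.ellipticity,
                "rg": sd.rg,
                "v_abc": sd.v_abc,
                "v_rg": sd.v_rg,
                "degenerate": sd.degenerate,
            }
        )
    table = pd.DataFrame(rows)
    good = table[~table["degenerate"]]
    summary = {"n_molecules": len(confs), "n_degenerate": int(table["degenerate"].sum())}
    for col in ("ac_ratio", "bc_ratio", "ellipticity", "v_abc", "v_rg", "rg"):
        summary[f"mean_{col}"] = float(good[col].mean())
        summary[f"var_{col}"] = float(good[col].var(ddof=0))
    return table, summary


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U with two-sided p-value.

    U counts pairs with x_i > y_j (ties count one half).  For small samples
    (n*m <= 400) the p-value is exact: a tie-free null distribution is
    enumerated by dynamic programming, while tied data fall back to full
    enumeration of group assignments when feasible.  Larger samples use the
    normal approximation with tie-corrected variance and continuity
    correction.  If every value across both samples is identical, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n < 1 or m < 1:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        import warnings

        warnings.warn("all values tied across both samples; p = 1")
        return u, 1.0
    has_ties = len(np.unique(pooled)) < n + m
    if n * m <= 400:
        if not has_ties:
            counts = _u_null_counts(n, m)
            total = counts.sum()
            ui = int(round(u))
            p_le = counts[: ui + 1].sum() / total
            p_ge = counts[ui:].sum() / total
            return u, float(min(1.0, 2.0 * min(p_le, p_ge)))
        if comb(n + m, n) <= 500_000:
            us = np.array(
                [
                    _u_statistic(pooled[list(idx)], np.delete(pooled, list(idx)))
                    for idx in combinations(range(n + m), n)
                ]
            )
            tol = 1e-9
            p_le = np.mean(us <= u + tol)
            p_ge = np.mean(us >= u - tol)
            return u, float(min(1.0, 2.0 * min(p_le, p_ge)))
    # normal approximation with tie correction and continuity correction
    mu = n * m / 2.0
    nm = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (nm * (nm - 1.0))
    var = n * m / 12.0 * (nm + 1.0 - tie_term)
    if var <= 0:
        return u, 1.0
    z = (u - mu - 0.5 * np.sign(u - mu)) / math.sqrt(var)
    return u, float(min(1.0, 2.0 * norm.sf(abs(z))))


def _u_null_counts(n: int, m: int) -> np.ndarray:
    """Counts of each integer U value over all C(n+m, n) tie-free orderings.

    Recurrence on the largest pooled element: if it belongs to x it beats all
    j current y's, else it contributes nothing:
    c(i, j, u) = c(i-1, j, u-j) + c(i, j-1, u).
    """
    maxu = n * m
    old = np.zeros((m + 1, maxu + 1))
    old[:, 0] = 1.0  # i = 0: a single arrangement with U = 0 for any j
    for _ in range(n):
        new = np.zeros_like(old)
        new[0, 0] = 1.0
        for j in range(1, m + 1):
            new[j, j:] += old[j, : maxu + 1 - j]
            new[j] += new[j - 1]
        old = new
    return old[m]
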
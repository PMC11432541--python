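"""Domain types for the strings-and-binders (SBS) chromatin model.

The SBS model represents a chromatin region as a coarse-grained bead-spring
polymer whose beads carry binding sites for diffusing molecular binders
(transcription factors, coactivators).  A binder of a given type attracts
only beads carrying its cognate binding-site label; bridging of cognate
sites drives folding and, above critical binder concentration/affinity,
a coil-to-globule phase transition.

This module holds the value types shared by the whole package — the polymer
binding profile, the binder ensemble, simulation parameters, conformations
and trajectories — plus reading/writing/validation of binding-profile files.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PolymerSpec",
    "BinderType",
    "BinderEnsemble",
    "SimulationParams",
    "Conformation",
    "Trajectory",
    "SpecValidationError",
    "load_polymer_spec",
    "save_polymer_spec",
    "validate_system",
    "binder_count_from_volume_fraction",
    "volume_fraction_from_count",
]

#: Volume of one binder/bead sphere of diameter sigma=1, in sigma^3.
SPHERE_VOLUME = math.pi / 6.0

#: Affinity range sampled by the reference study, in units of k_B T.
DEFAULT_AFFINITY_RANGE = (0.0, 8.0)


class SpecValidationError(ValueError):
    """Raised when a polymer/binder/parameter specification violates an invariant."""


def binder_count_from_volume_fraction(c: float, box_edge: float) -> int:
    """Number of diameter-1 binder spheres occupying volume fraction ``c`` of an
    ``L^3`` box: ``count = round(c * L^3 / (pi/6))``."""
    return int(round(c * box_edge**3 / SPHERE_VOLUME))


def volume_fraction_from_count(count: int, box_edge: float) -> float:
    """Volume fraction occupied by ``count`` diameter-1 spheres in an ``L^3`` box."""
    return count * SPHERE_VOLUME / box_edge**3


@dataclass(frozen=True)
class PolymerSpec:
    """A polymer binding profile: one set of binding-site type labels per bead.

    Beads may carry several labels at once (overlapping, combinatorial binding
    domains) or none (inert beads).  Genomic bookkeeping is carried by a simple
    anchor (chromosome, start position, bp per bead) with 0-based half-open bins.
    """

    bead_types: tuple[frozenset[str], ...]
    type_catalog: tuple[str, ...]
    chrom: str = "chr21"
    start_bp: int = 28_000_000
    bp_per_bead: int = 2_500

    @property
    def n_beads(self) -> int:
        return len(self.bead_types)

    def __post_init__(self) -> None:
        if self.n_beads < 2:
            raise SpecValidationError(f"polymer needs >= 2 beads, got {self.n_beads}")
        if self.bp_per_bead <= 0:
            raise SpecValidationError("bp_per_bead must be positive")
        if len(set(self.type_catalog)) != len(self.type_catalog):
            raise SpecValidationError("type_catalog contains duplicate labels")
        catalog = set(self.type_catalog)
        for i, labels in enumerate(self.bead_types):
            unknown = set(labels) - catalog
            if unknown:
                raise SpecValidationError(
                    f"bead {i} carries labels {sorted(unknown)} absent from catalog"
                )

    @classmethod
    def from_lists(
        cls,
        bead_types: Iterable[Iterable[str]],
        type_catalog: Sequence[str] | None = None,
        **kwargs,
    ) -> "PolymerSpec":
        beads = tuple(frozenset(t) for t in bead_types)
        if type_catalog is None:
            seen: list[str] = []
            for labels in beads:
                for lab in sorted(labels):
                    if lab not in seen:
                        seen.append(lab)
            type_catalog = seen
        return cls(bead_types=beads, type_catalog=tuple(type_catalog), **kwargs)

    @classmethod
    def homopolymer(cls, n_beads: int, label: str = "A", **kwargs) -> "PolymerSpec":
        return cls(
            bead_types=tuple(frozenset({label}) for _ in range(n_beads)),
            type_catalog=(label,),
            **kwargs,
        )

    def type_masks(self) -> np.ndarray:
        """Per-bead bitmask over the type catalog (bit k set <=> bead carries
        catalog type k).  Used by the MD engine's cognate-pair test."""
        if len(self.type_catalog) > 63:
            raise SpecValidationError("at most 63 binding-site types supported")
        index = {lab: k for k, lab in enumerate(self.type_catalog)}
        masks = np.zeros(self.n_beads, dtype=np.int64)
        for i, labels in enumerate(self.bead_types):
            for lab in labels:
                masks[i] |= 1 << index[lab]
        return masks

    def bead_starts_bp(self) -> np.ndarray:
        return self.start_bp + np.arange(self.n_beads, dtype=np.int64) * self.bp_per_bead


@dataclass(frozen=True)
class BinderType:
    """One binder species: either an explicit particle count or a target volume
    fraction, plus the bead-binder affinity (LJ well depth, k_B T units)."""

    affinity: float
    count: int | None = None
    volume_fraction: float | None = None

    def __post_init__(self) -> None:
        if (self.count is None) == (self.volume_fraction is None):
            raise SpecValidationError(
                "specify exactly one of count / volume_fraction per binder type"
            )
        if self.count is not None and self.count < 0:
            raise SpecValidationError("binder count must be >= 0")
        if self.volume_fraction is not None and self.volume_fraction < 0:
            raise SpecValidationError("volume fraction must be >= 0")

    def resolved_count(self, box_edge: float) -> int:
        if self.count is not None:
            return self.count
        return binder_count_from_volume_fraction(self.volume_fraction, box_edge)


@dataclass(frozen=True)
class BinderEnsemble:
    """Binder species keyed by binding-site type label.

    The two control parameters of the coil-globule transition live here: the
    total binder volume fraction ``c`` and the bead-binder affinity ``E_bb``.
    """

    types: dict[str, BinderType] = field(default_factory=dict)

    @classmethod
    def uniform(
        cls,
        labels: Sequence[str],
        total_volume_fraction: float,
        affinity: float,
    ) -> "BinderEnsemble":
        """Split a total volume fraction equally across the given type labels."""
        per = total_volume_fraction / max(len(labels), 1)
        return cls({lab: BinderType(affinity=affinity, volume_fraction=per) for lab in labels})

    def resolved_counts(self, box_edge: float) -> dict[str, int]:
        return {lab: bt.resolved_count(box_edge) for lab, bt in self.types.items()}

    def total_count(self, box_edge: float) -> int:
        return sum(self.resolved_counts(box_edge).values())

    def total_volume_fraction(self, box_edge: float) -> float:
        return volume_fraction_from_count(self.total_count(box_edge), box_edge)


@dataclass(frozen=True)
class SimulationParams:
    """Langevin MD parameters in reduced units (sigma = m = k_B T = 1).

    Defaults follow standard coarse-grained bead-spring (Kremer-Grest type)
    practice: FENE bonds with R0 = 1.6 sigma and K = 30 k_BT/sigma^2, WCA
    excluded volume truncated at 2^(1/6) sigma, cognate bead-binder attraction
    truncated at 1.5 sigma, friction 0.5 and temperature 1 in a periodic cube.
    """

    box_edge: float = 50.0
    dt: float = 0.012
    friction: float = 0.5
    temperature: float = 1.0
    n_steps: int = 200_000
    equil_steps: int = 0
    seed: int = 0
    sigma: float = 1.0
    mass: float = 1.0
    fene_r0: float = 1.6
    fene_k: float = 30.0
    r_rep: float = 2.0 ** (1.0 / 6.0)
    r_att: float = 1.5

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise SpecValidationError("timestep must be positive")
        if self.fene_r0 <= self.sigma:
            raise SpecValidationError("FENE maximum extension R0 must exceed sigma")

    def cutoff_violations(self) -> list[str]:
        out = []
        for name, rc in (("r_rep", self.r_rep), ("r_att", self.r_att)):
            if rc >= self.box_edge / 2:
                out.append(
                    f"cutoff {name}={rc:g} sigma >= half box edge {self.box_edge / 2:g}"
                )
        return out


@dataclass
class Conformation:
    """One 3D snapshot: unwrapped bead coordinates plus (optionally) binder
    coordinates with per-binder type labels, all in sigma units."""

    bead_coords: np.ndarray  # (N, 3)
    binder_coords: np.ndarray | None = None  # (M, 3)
    binder_labels: np.ndarray | None = None  # (M,) catalog indices
    box_edge: float = 50.0

    @property
    def n_beads(self) -> int:
        return self.bead_coords.shape[0]

    @property
    def n_binders(self) -> int:
        return 0 if self.binder_coords is None else self.binder_coords.shape[0]

    def validate(self, fene_r0: float = 1.6) -> None:
        if not np.all(np.isfinite(self.bead_coords)):
            raise SpecValidationError("non-finite bead coordinates")
        bonds = np.linalg.norm(np.diff(self.bead_coords, axis=0), axis=1)
        if bonds.size and bonds.max() >= fene_r0:
            i = int(np.argmax(bonds))
            raise SpecValidationError(
                f"bond {i}-{i + 1} length {bonds.max():.3f} >= R0 = {fene_r0}"
            )


@dataclass
class Trajectory:
    """Ordered sampled conformations with step stamps and the gyration-radius
    time track (beads only) used to monitor the coil-globule collapse."""

    frames: list[Conformation]
    steps: np.ndarray
    rg_series: np.ndarray

    def __post_init__(self) -> None:
        self.steps = np.asarray(self.steps, dtype=np.int64)
        self.rg_series = np.asarray(self.rg_series, dtype=float)
        if len(self.frames) != len(self.steps) or len(self.frames) != len(self.rg_series):
            raise SpecValidationError("frames, steps and rg_series must have equal length")
        if self.steps.size > 1 and not np.all(np.diff(self.steps) > 0):
            raise SpecValidationError("step stamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def final(self) -> Conformation:
        return self.frames[-1]


# ---------------------------------------------------------------------------
# Binding-profile file I/O
#
# TSV dialect: a "#types:" comment declares the catalog, then a header row
# `bead_index  chrom  start_bp  types` with 0-based bead indices and
# comma-separated labels (empty field = inert bead).
# ---------------------------------------------------------------------------


def save_polymer_spec(spec: PolymerSpec, path: str | Path) -> None:
    """Write a binding profile as TSV; ``load_polymer_spec`` round-trips it."""
    buf = io.StringIO()
    buf.write("#types: " + ",".join(spec.type_catalog) + "\n")
    buf.write(f"#bp_per_bead: {spec.bp_per_bead}\n")
    buf.write("bead_index\tchrom\tstart_bp\ttypes\n")
    starts = spec.bead_starts_bp()
    for i, labels in enumerate(spec.bead_types):
        field_ = ",".join(sorted(labels))
        buf.write(f"{i}\t{spec.chrom}\t{starts[i]}\t{field_}\n")
    Path(path).write_text(buf.getvalue())


def load_polymer_spec(path: str | Path) -> PolymerSpec:
    """Read a binding-profile TSV written by :func:`save_polymer_spec`."""
    catalog: tuple[str, ...] | None = None
    bp_per_bead = 2_500
    rows: list[tuple[int, str, int, frozenset[str]]] = []
    header_seen = False
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#types:"):
            labels = [t.strip() for t in line.split(":", 1)[1].split(",") if t.strip()]
            catalog = tuple(labels)
            continue
        if line.startswith("#bp_per_bead:"):
            bp_per_bead = int(line.split(":", 1)[1].strip())
            continue
        if line.startswith("#"):
            continue
        parts = line.split("\t")
        if not header_seen:
            if [p.strip() for p in parts[:4]] != ["bead_index", "chrom", "start_bp", "types"]:
                raise SpecValidationError(
                    f"line {lineno}: expected header 'bead_index chrom start_bp types'"
                )
            header_seen = True
            continue
        if len(parts) < 4:
            raise SpecValidationError(f"line {lineno}: expected 4 tab-separated columns")
        try:
            idx = int(parts[0])
            start = int(parts[2])
        except ValueError as exc:
            raise SpecValidationError(f"line {lineno}: non-integer index/position") from exc
        labels = frozenset(t.strip() for t in parts[3].split(",") if t.strip())
        rows.append((idx, parts[1], start, labels))
    if catalog is None:
        raise SpecValidationError("missing '#types:' catalog declaration")
    if not rows:
        raise SpecValidationError("no bead rows found")
    rows.sort(key=lambda r: r[0])
    if [r[0] for r in rows] != list(range(len(rows))):
        raise SpecValidationError("bead_index column must enumerate 0..N-1")
    return PolymerSpec(
        bead_types=tuple(r[3] for r in rows),
        type_catalog=catalog,
        chrom=rows[0][1],
        start_bp=rows[0][2],
        bp_per_bead=bp_per_bead,
    )


def validate_system(
    spec: PolymerSpec,
    binders: BinderEnsemble,
    params: SimulationParams,
    affinity_range: tuple[float, float] = DEFAULT_AFFINITY_RANGE,
) -> dict:
    """Report-only cross-validation of a polymer + binder + parameter triple.

    Returns a diagnostics dict with resolved binder counts, the total volume
    fraction, hard-invariant ``violations`` and soft ``warnings``.  Never
    mutates or raises; an empty ``violations`` list means the system is valid.
    """
    violations: list[str] = []
    warnings: list[str] = []

    counts = binders.resolved_counts(params.box_edge)
    total_c = binders.total_volume_fraction(params.box_edge)

    for lab in binders.types:
        if lab not in spec.type_catalog:
            warnings.append(f"binder type {lab!r} has no cognate beads in the polymer")
    lo, hi = affinity_range
    for lab, bt in binders.types.items():
        if not (lo <= bt.affinity <= hi):
            warnings.append(
                f"affinity {bt.affinity:g} k_BT for type {lab!r} outside the "
                f"sampled range [{lo:g}, {hi:g}]"
            )
    if total_c >= 0.5:
        violations.append(f"total binder volume fraction {total_c:.3f} >= 0.5")
    violations.extend(params.cutoff_violations())
    # rough packing feasibility: beads + binders at random insertion
    n_particles = spec.n_beads + sum(counts.values())
    packing = n_particles * SPHERE_VOLUME / params.box_edge**3
    if packing >= 0.45:
        violations.append(f"total packing fraction {packing:.3f} too high to place particles")

    return {
        "violations": violations,
        "warnings": warnings,
        "binder_counts": counts,
        "total_binders": sum(counts.values()),
        "total_volume_fraction": total_c,
        "n_beads": spec.n_beads,
    }
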
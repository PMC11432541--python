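"""Trajectory text formats: extended XYZ writing/reading and LAMMPS dumps.

The native format is extended XYZ: one block per frame, a comment line
carrying ``step=<int> box=<L>`` and per-particle rows ``species x y z``.
Bead species are ``B``; binder species carry their catalog index (``b0``,
``b1``...).  For interoperability, a LAMMPS-style text dump reader
(``id type x y z``, wrapped ``xs``-free coordinates) is also provided.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .model_core import Conformation, Trajectory

__all__ = ["write_xyz", "read_xyz", "read_lammps_dump"]


def write_xyz(traj: Trajectory, path: str | Path) -> None:
    with open(path, "w") as fh:
        for frame, step in zip(traj.frames, traj.steps):
            n = frame.n_beads + frame.n_binders
            fh.write(f"{n}\n")
            fh.write(f"step={int(step)} box={frame.box_edge:g}\n")
            for r in frame.bead_coords:
                fh.write(f"B {r[0]:.6f} {r[1]:.6f} {r[2]:.6f}\n")
            if frame.n_binders:
                for lab, r in zip(frame.binder_labels, frame.binder_coords):
                    fh.write(f"b{int(lab)} {r[0]:.6f} {r[1]:.6f} {r[2]:.6f}\n")


def _rg(coords: np.ndarray) -> float:
    com = coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((coords - com) ** 2, axis=1))))


def read_xyz(path: str | Path) -> Trajectory:
    lines = Path(path).read_text().splitlines()
    frames: list[Conformation] = []
    steps: list[int] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        meta = dict(
            kv.split("=", 1) for kv in lines[i + 1].split() if "=" in kv
        )
        step = int(meta.get("step", len(frames)))
        box = float(meta.get("box", 0.0))
        beads, binders, labels = [], [], []
        for row in lines[i + 2 : i + 2 + n]:
            parts = row.split()
            species, xyz = parts[0], [float(v) for v in parts[1:4]]
            if species.startswith("b") and species != "B":
                binders.append(xyz)
                labels.append(int(species[1:]))
            else:
                beads.append(xyz)
        frames.append(
            Conformation(
                bead_coords=np.array(beads),
                binder_coords=np.array(binders) if binders else None,
                binder_labels=np.array(labels, dtype=np.int64) if binders else None,
                box_edge=box,
            )
        )
        steps.append(step)
        i += 2 + n
    rg = np.array([_rg(f.bead_coords) for f in frames])
    return Trajectory(frames=frames, steps=np.array(steps), rg_series=rg)


def read_lammps_dump(path: str | Path, n_beads: int | None = None) -> Trajectory:
    """Read a LAMMPS text dump with per-atom columns ``id type x y z``.

    Atoms of type 1 are polymer beads (ordered by id); higher types are
    binders with catalog index ``type - 2``.  If ``n_beads`` is given it
    overrides the type-based split: the first ``n_beads`` ids are beads.
    """
    lines = Path(path).read_text().splitlines()
    frames: list[Conformation] = []
    steps: list[int] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line == "ITEM: TIMESTEP":
            step = int(lines[i + 1].strip())
            i += 2
            continue
        if line == "ITEM: NUMBER OF ATOMS":
            natoms = int(lines[i + 1].strip())
            i += 2
            continue
        if line.startswith("ITEM: BOX BOUNDS"):
            lo, hi = (float(v) for v in lines[i + 1].split()[:2])
            box = hi - lo
            i += 4
            continue
        if line.startswith("ITEM: ATOMS"):
            cols = line.split()[2:]
            try:
                ci, ct = cols.index("id"), cols.index("type")
                cx, cy, cz = cols.index("x"), cols.index("y"), cols.index("z")
            except ValueError as exc:
                raise ValueError("dump must provide columns: id type x y z") from exc
            rows = []
            for row in lines[i + 1 : i + 1 + natoms]:
                p = row.split()
                rows.append(
                    (int(p[ci]), int(p[ct]), float(p[cx]), float(p[cy]), float(p[cz]))
                )
            rows.sort(key=lambda r: r[0])
            arr = np.array([(r[1], r[2], r[3], r[4]) for r in rows])
            if n_beads is not None:
                bead_sel = np.zeros(len(rows), dtype=bool)
                bead_sel[:n_beads] = True
            else:
                bead_sel = arr[:, 0] == 1
            beads = arr[bead_sel, 1:4]
            binders = arr[~bead_sel, 1:4]
            labels = (arr[~bead_sel, 0] - 2).astype(np.int64)
            frames.append(
                Conformation(
                    bead_coords=beads,
                    binder_coords=binders if len(binders) else None,
                    binder_labels=labels if len(binders) else None,
                    box_edge=box,
                )
            )
            steps.append(step)
            i += 1 + natoms
            continue
        i += 1
    rg = np.array([_rg(f.bead_coords) for f in frames])
    return Trajectory(frames=frames, steps=np.array(steps), rg_series=rg)
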
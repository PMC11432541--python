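"""Contact maps, ensemble averaging, binning and map-comparison statistics.

A single-molecule contact map marks bead pairs closer than a distance
threshold (default 3.5 sigma, supported range 2-5 sigma); averaging binary
maps over an ensemble of conformations gives a contact-frequency matrix
comparable to Hi-C after block-binning to the experimental resolution
(e.g. 800 beads of 2.5 kb -> 80 bins of 25 kb with factor 10).

Comparison statistics between two maps: the plain Pearson correlation r,
the genomic-distance-corrected Pearson r' (each matrix residualised by its
own mean at every separation |i-j|, removing the trivial proximity decay),
and the Spearman rank correlation r_s.  All statistics are computed over
the upper-triangle off-diagonal entries; masked (NaN) entries are dropped
pairwise.  A randomly folded control chain gives r' close to zero against
any structured map, which is what makes r' a discriminative similarity
measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .model_core import Conformation

__all__ = [
    "ContactMap",
    "ContactCurve",
    "ComparisonStats",
    "DegenerateStatisticError",
    "contact_map",
    "ensemble_mean",
    "bin_matrix",
    "contact_probability",
    "pearson_map",
    "distance_corrected_pearson",
    "spearman_map",
    "compare_maps",
    "read_contact_matrix",
    "write_contact_matrix",
    "distance_residuals",
]

DEFAULT_THRESHOLD = 3.5  # sigma; midpoint of the supported 2-5 sigma range


class DegenerateStatisticError(ValueError):
    """A correlation is undefined (zero variance in the compared entries)."""


@dataclass
class ContactMap:
    """Symmetric n x n contact matrix with unit diagonal.

    Binary for single molecules, frequencies in [0, 1] for ensemble means.
    NaN entries mark masked bins.
    """

    matrix: np.ndarray
    threshold: float | None = None
    resolution_bp: int | None = None

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def validate(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact map must be square")
        finite = np.isfinite(m)
        if not np.allclose(m[finite], np.swapaxes(m, 0, 1)[finite], atol=1e-12):
            raise ValueError("contact map must be symmetric")
        vals = m[finite]
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("contact values must lie in [0, 1]")


@dataclass
class ContactCurve:
    """Mean contact probability P_c(s) at each genomic separation s (bins)."""

    s: np.ndarray
    pc: np.ndarray


@dataclass
class ComparisonStats:
    """The three map-similarity statistics reported together."""

    pearson: float
    distance_corrected: float
    spearman: float


def contact_map(
    conf: Conformation, threshold: float = DEFAULT_THRESHOLD, resolution_bp: int | None = None
) -> ContactMap:
    """Binary contact map: entry (i, j) is 1 iff |r_i - r_j| < threshold.

    Distances are plain Euclidean on the (unwrapped) bead coordinates; the
    diagonal is fixed at 1 by convention and excluded from all statistics.
    """
    if threshold <= 0:
        raise ValueError("contact threshold must be positive")
    d = squareform(pdist(conf.bead_coords))
    m = (d < threshold).astype(float)
    np.fill_diagonal(m, 1.0)
    return ContactMap(matrix=m, threshold=threshold, resolution_bp=resolution_bp)


def ensemble_mean(maps: Sequence[ContactMap]) -> ContactMap:
    """Entrywise mean of equal-shape contact maps (ensemble contact frequency)."""
    if not maps:
        raise ValueError("empty ensemble")
    n = maps[0].n
    thr = maps[0].threshold
    for m in maps:
        if m.n != n:
            raise ValueError("contact maps have mismatched shapes")
        if m.threshold != thr:
            raise ValueError("contact maps have mismatched thresholds")
    mean = np.mean([m.matrix for m in maps], axis=0)
    return ContactMap(matrix=mean, threshold=thr, resolution_bp=maps[0].resolution_bp)


def bin_matrix(cmap: ContactMap, factor: int) -> ContactMap:
    """Coarsen by block-averaging factor x factor tiles (factor must divide n)."""
    n = cmap.n
    if factor < 1 or n % factor:
        raise ValueError(f"binning factor {factor} does not divide n = {n}")
    nb = n // factor
    binned = cmap.matrix.reshape(nb, factor, nb, factor).mean(axis=(1, 3))
    res = cmap.resolution_bp * factor if cmap.resolution_bp else None
    return ContactMap(matrix=binned, threshold=cmap.threshold, resolution_bp=res)


def contact_probability(cmap: ContactMap) -> ContactCurve:
    """P_c(s): mean of entries at genomic separation |i - j| = s, s = 1..n-1."""
    m = cmap.matrix
    n = m.shape[0]
    if n < 2:
        raise ValueError("need at least 2 bins")
    s = np.arange(1, n)
    pc = np.array([np.nanmean(np.diagonal(m, offset=k)) for k in s])
    return ContactCurve(s=s, pc=pc)


def _upper_offdiag(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if a.shape != b.shape:
        raise ValueError("matrices have mismatched shapes")
    iu = np.triu_indices(a.shape[0], k=1)
    x, y = a[iu], b[iu]
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def _pearson(x: np.ndarray, y: np.ndarray, what: str) -> float:
    if x.size < 2:
        raise DegenerateStatisticError(f"{what}: fewer than 2 comparable entries")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise DegenerateStatisticError(f"{what}: zero variance in compared entries")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def pearson_map(a, b) -> float:
    """Pearson r over the upper-triangle off-diagonal entries of two matrices."""
    x, y = _upper_offdiag(_as_matrix(a), _as_matrix(b))
    return _pearson(x, y, "pearson")


def distance_residuals(matrix: np.ndarray) -> np.ndarray:
    """Subtract from each entry the mean of its separation class |i - j|.

    The expected-by-distance profile is computed from the matrix itself, so
    any pure function of |i - j| residualises to exactly zero.
    """
    m = np.asarray(matrix, dtype=float)
    n = m.shape[0]
    out = np.empty_like(m)
    for k in range(n):
        diag = np.diagonal(m, offset=k)
        mu = np.nanmean(diag) if np.any(np.isfinite(diag)) else np.nan
        idx = np.arange(n - k)
        out[idx, idx + k] = m[idx, idx + k] - mu
        out[idx + k, idx] = out[idx, idx + k]
    return out


def distance_corrected_pearson(a, b) -> float:
    """Genomic-distance-corrected Pearson r'.

    Each matrix is residualised by its own per-|i-j| mean before correlating,
    which averages out the trivial proximity effect shared by all polymer
    ensembles.  Matrices that depend only on |i - j| are flagged degenerate.
    """
    ma, mb = _as_matrix(a), _as_matrix(b)
    ra = distance_residuals(ma)
    rb = distance_residuals(mb)
    for res, orig in ((ra, ma), (rb, mb)):
        scale = np.nanmax(np.abs(orig)) if np.isfinite(orig).any() else 1.0
        if np.nanmax(np.abs(res)) <= 1e-12 * max(scale, 1e-300):
            raise DegenerateStatisticError(
                "distance-corrected pearson: matrix depends only on |i-j| "
                "(residuals vanish)"
            )
    x, y = _upper_offdiag(ra, rb)
    return _pearson(x, y, "distance-corrected pearson")


def spearman_map(a, b) -> float:
    """Spearman rank correlation (mean ranks on ties) over upper-triangle entries."""
    x, y = _upper_offdiag(_as_matrix(a), _as_matrix(b))
    if x.size < 2:
        raise DegenerateStatisticError("spearman: fewer than 2 comparable entries")
    return _pearson(rankdata(x), rankdata(y), "spearman")


def compare_maps(a, b) -> ComparisonStats:
    """All three similarity statistics between two same-shape matrices."""
    return ComparisonStats(
        pearson=pearson_map(a, b),
        distance_corrected=distance_corrected_pearson(a, b),
        spearman=spearman_map(a, b),
    )


def _as_matrix(x) -> np.ndarray:
    return x.matrix if isinstance(x, ContactMap) else np.asarray(x, dtype=float)


def read_contact_matrix(path: str | Path) -> ContactMap:
    """Read a dense numeric matrix TSV (optional ``#resolution_bp=`` header).

    Asymmetric inputs are symmetrised by averaging with the transpose; NaN
    entries stay masked.
    """
    resolution = None
    rows: list[list[float]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "resolution_bp" in line and "=" in line:
                resolution = int(float(line.split("=", 1)[1].strip()))
            continue
        rows.append([float(v) if v.lower() != "nan" else np.nan for v in line.split("\t")])
    m = np.array(rows, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"contact matrix must be square, got shape {m.shape}")
    if not np.allclose(np.nan_to_num(m), np.nan_to_num(m.T), atol=1e-12):
        import warnings

        warnings.warn("asymmetric contact matrix symmetrised by averaging with transpose")
    with np.errstate(invalid="ignore"):
        m = np.where(np.isnan(m), m.T, 0.5 * (m + m.T))
    return ContactMap(matrix=m, resolution_bp=resolution)


def write_contact_matrix(cmap: ContactMap, path: str | Path) -> None:
    header = ""
    if cmap.resolution_bp:
        header = f"#resolution_bp={cmap.resolution_bp}\n"
    body = "\n".join("\t".join(f"{v:.6g}" for v in row) for row in cmap.matrix)
    Path(path).write_text(header + body + "\n")
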
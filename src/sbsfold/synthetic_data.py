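"""Synthetic inputs: binding profiles, toy contact maps, oracle point clouds.

The binding-profile generator emulates the statistical structure of an
inferred chromatin binding landscape — contiguous binding-site domains of
several types laid out along the chain with overlaps (beads carrying more
than one label) and optional inert stretches — without attempting to
reproduce any particular locus.  Toy contact maps provide ground-truth
targets for the map-comparison statistics: TAD blocks modulated by a
power-law distance decay, optional loop peaks and multiplicative noise.
Ellipsoid clouds and baseline chains (rod / ideal chain / SAW) serve as
analytic oracles for the shape and correlation machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble_maps import ContactMap
from .md_engine import init_saw
from .model_core import Conformation, PolymerSpec, SimulationParams

__all__ = [
    "ProfileParams",
    "make_binding_profile",
    "make_toy_contact_map",
    "sample_ellipsoid_cloud",
    "sample_baseline_chain",
    "DESK_PRESET",
    "FULL_PRESET",
]


@dataclass(frozen=True)
class ProfileParams:
    """Parameters of the synthetic binding-profile generator.

    ``n_domains`` contiguous domains (geometric length distribution with the
    given mean) are assigned round-robin over ``n_types`` labels and placed
    along the chain; ``overlap_prob`` sets the fraction of covered beads
    whose labels from intersecting domains are kept (multi-label beads),
    ``inert_frac`` the fraction of beads left unlabeled.
    """

    n_beads: int = 200
    n_types: int = 4
    n_domains: int = 12
    domain_length_mean: float = 40.0
    overlap_prob: float = 0.3
    inert_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap_prob <= 1.0 and 0.0 <= self.inert_frac <= 1.0):
            raise ValueError("overlap_prob and inert_frac must be probabilities")
        if self.n_domains < self.n_types:
            raise ValueError("need at least one domain per type")
        if self.domain_length_mean < 1 or self.domain_length_mean > self.n_beads:
            raise ValueError("domain length must be between 1 bead and the chain length")


def make_binding_profile(params: ProfileParams, **anchor) -> PolymerSpec:
    """Generate a multi-type binding profile with overlapping domains.

    The chain is tiled end to end by contiguous binding domains whose
    lengths are geometric with the requested mean; types are assigned
    round-robin (every type appears) and each new domain structurally
    overlaps its predecessor, so beads in the shared stretch carry both
    labels.  The per-junction overlap is sized so the expected multi-label
    fraction equals ``overlap_prob``; afterwards an ``inert_frac`` subset of
    beads is cleared.  Deterministic per seed.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_beads
    labels = [f"T{k}" for k in range(params.n_types)]
    # tiling the chain with ~n_domains overlapping domains bounds the usable
    # mean length; the requested mean acts as a cap beyond that
    tile_mean = (1.0 + params.overlap_prob) * n / params.n_domains
    mean_len = max(2.0, min(params.domain_length_mean, tile_mean))
    geo_p = min(1.0, 1.0 / max(mean_len - 1.0, 1.0))
    # overlap o = L * p/(1+p) per junction makes the covered excess
    # (sum of lengths minus n) equal the multi-label bead count
    share = params.overlap_prob / (1.0 + params.overlap_prob)
    bead_labels: list[set[str]] = [set() for _ in range(n)]
    start = 0
    k = 0
    multi = 0  # beads holding >1 label so far; drives a feedback correction
    while start < n:
        length = int(np.clip(1 + rng.geometric(geo_p), 2, n))
        lab = labels[k % params.n_types]
        for i in range(start, min(start + length, n)):
            bead_labels[i].add(lab)
        # deficit feedback keeps the realised multi-label fraction on target
        # despite rounding, chain-end clipping and triple coverage
        deficit = params.overlap_prob * min(start + length, n) - multi
        overlap = int(np.clip(round(length * share + 0.5 * deficit), 0, length - 1))
        start += max(length - overlap, 1)
        multi = sum(1 for s in bead_labels[:start] if len(s) > 1)
        k += 1
    # inert beads
    if params.inert_frac > 0:
        n_inert = int(round(params.inert_frac * n))
        for i in rng.choice(n, size=n_inert, replace=False):
            bead_labels[i] = set()
    # every type must survive the inert pass
    present = set().union(*bead_labels)
    for j, lab in enumerate(labels):
        if lab not in present:
            bead_labels[(j * n) // params.n_types].add(lab)
    return PolymerSpec(
        bead_types=tuple(frozenset(s) for s in bead_labels),
        type_catalog=tuple(labels),
        **anchor,
    )


def make_toy_contact_map(
    n: int,
    tad_boundaries: list[int],
    intra_level: float = 0.8,
    inter_level: float = 0.1,
    decay_exponent: float = 1.0,
    loops: list[tuple[int, int, float]] | None = None,
    noise: float = 0.0,
    seed: int = 0,
) -> ContactMap:
    """Block TAD structure x power-law distance decay, plus loops and noise.

    ``tad_boundaries`` are the sorted interior block starts; a pair inside
    the same block gets ``intra_level``, across blocks ``inter_level``; the
    whole matrix is modulated by |i-j|^(-decay_exponent).  Loop peaks add
    Gaussian bumps of the given strength at (i, j).  ``noise`` applies
    symmetric multiplicative log-normal-like jitter.  Diagonal fixed at 1.
    """
    if any(b <= 0 or b >= n for b in tad_boundaries):
        raise ValueError("TAD boundaries must lie strictly inside (0, n)")
    if sorted(tad_boundaries) != list(tad_boundaries):
        raise ValueError("TAD boundaries must be sorted")
    if not (0.0 <= inter_level <= 1.0 and 0.0 <= intra_level <= 1.0):
        raise ValueError("contact levels must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    edges = [0, *tad_boundaries, n]
    block = np.digitize(np.arange(n), edges[1:-1])
    same = block[:, None] == block[None, :]
    base = np.where(same, intra_level, inter_level).astype(float)
    sep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :]).astype(float)
    with np.errstate(divide="ignore"):
        envelope = np.where(sep > 0, sep**-decay_exponent, 1.0)
    m = base * envelope
    for i, j, strength in loops or []:
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        bump = strength * np.exp(-((ii - i) ** 2 + (jj - j) ** 2) / 8.0)
        m += bump + bump.T
    if noise > 0:
        jitter = rng.normal(0.0, noise, size=(n, n))
        jitter = 0.5 * (jitter + jitter.T)
        m = m * np.exp(jitter)
    m = np.clip(m, 0.0, 1.0)
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 1.0)
    return ContactMap(matrix=m)


def sample_ellipsoid_cloud(a: float, b: float, c: float, m: int, seed: int = 0) -> Conformation:
    """M points uniform in the solid ellipsoid with semi-axes (a, b, c).

    Rejection sampling from the bounding box; an oracle for shape recovery
    (uniform-ball moments give I = (2/5) N R^2 per axis, Rg = sqrt(3/5) R).
    """
    if min(a, b, c) <= 0:
        raise ValueError("semi-axes must be positive")
    rng = np.random.default_rng(seed)
    out = np.empty((m, 3))
    k = 0
    while k < m:
        batch = rng.uniform(-1.0, 1.0, size=(max(2 * (m - k), 64), 3))
        keep = batch[np.sum(batch**2, axis=1) <= 1.0]
        take = min(len(keep), m - k)
        out[k : k + take] = keep[:take]
        k += take
    out *= np.array([a, b, c])
    return Conformation(bead_coords=out, box_edge=0.0)


def sample_baseline_chain(
    n: int, model: str = "ideal", seed: int = 0, box_edge: float = 50.0
) -> Conformation:
    """Null-model chains: 'rod' (collinear unit spacing), 'ideal' (Gaussian
    random walk, unit RMS step) or 'saw' (self-avoiding walk)."""
    if n < 2:
        raise ValueError("need at least 2 beads")
    if model == "rod":
        coords = np.zeros((n, 3))
        coords[:, 0] = np.arange(n, dtype=float)
        return Conformation(bead_coords=coords, box_edge=box_edge)
    if model == "ideal":
        rng = np.random.default_rng(seed)
        steps = rng.normal(scale=1.0 / np.sqrt(3.0), size=(n - 1, 3))
        coords = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        return Conformation(bead_coords=coords, box_edge=box_edge)
    if model == "saw":
        spec = PolymerSpec.homopolymer(n)
        return init_saw(spec, SimulationParams(box_edge=box_edge), seed)
    raise ValueError(f"unknown baseline model {model!r} (rod|ideal|saw)")


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

#: Scaled-down "desk" study conditions: a 200-bead 4-type chain in a 20 sigma
#: box, total binder volume fraction 0.05 split equally over the types at
#: affinity 5 k_BT (about three binders per cognate bead: inside the
#: bridging-driven globular phase, clear of both the coil region and the
#: high-concentration coating regime), 50 replicate collapses.
DESK_PRESET = {
    "profile": ProfileParams(n_beads=200, n_types=4, n_domains=10,
                             domain_length_mean=26.0, overlap_prob=0.3,
                             inert_frac=0.05, seed=20),
    "box_edge": 20.0,
    "volume_fraction": 0.05,
    "affinity": 5.0,
    "replicates": 50,
    "n_steps": 120_000,
    "sample_every": 500,
    "bp_per_bead": 10_000,  # 2 Mb / 200 beads
}

#: Full-scale conditions: 800 beads, 10 types, 50 sigma box, 1e8 iteration
#: steps and up to 300 replicates.  Hours of compute; not exercised by the
#: default test run.
FULL_PRESET = {
    "profile": ProfileParams(n_beads=800, n_types=10, n_domains=30,
                             domain_length_mean=35.0, overlap_prob=0.3,
                             inert_frac=0.05, seed=20),
    "box_edge": 50.0,
    "volume_fraction": 0.05,
    "affinity": 5.0,
    "replicates": 300,
    "n_steps": 100_000_000,
    "sample_every": 50_000,
    "bp_per_bead": 2_500,
}
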
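"""Run configuration: one structured file (TOML or YAML) for the whole study.

Sections: [polymer] (either a profile file or synthetic-profile parameters),
[binders] (total volume fraction or per-type counts, affinity), [simulation]
(box, timestep, steps, replicates, seed), [analysis] (contact threshold,
binning factor, optional comparison matrix) and [sweep].  Every value has a
default taken from the scaled-down desk preset; the resolved configuration
is logged next to the outputs of each run.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .model_core import BinderEnsemble, PolymerSpec, SimulationParams, load_polymer_spec
from .synthetic_data import DESK_PRESET, ProfileParams, make_binding_profile

__all__ = ["RunConfig", "load_config", "resolve_system"]


@dataclass
class RunConfig:
    """Resolved configuration with desk-preset defaults."""

    polymer: dict = field(default_factory=dict)
    binders: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    sweep: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


_DEFAULTS = {
    "polymer": {
        "profile_file": None,
        "n_beads": DESK_PRESET["profile"].n_beads,
        "n_types": DESK_PRESET["profile"].n_types,
        "n_domains": DESK_PRESET["profile"].n_domains,
        "domain_length_mean": DESK_PRESET["profile"].domain_length_mean,
        "overlap_prob": DESK_PRESET["profile"].overlap_prob,
        "inert_frac": DESK_PRESET["profile"].inert_frac,
        "profile_seed": DESK_PRESET["profile"].seed,
        "bp_per_bead": DESK_PRESET["bp_per_bead"],
    },
    "binders": {
        "volume_fraction": DESK_PRESET["volume_fraction"],
        "affinity": DESK_PRESET["affinity"],
    },
    "simulation": {
        "box_edge": DESK_PRESET["box_edge"],
        "dt": 0.012,
        "friction": 0.5,
        "temperature": 1.0,
        "n_steps": DESK_PRESET["n_steps"],
        "sample_every": DESK_PRESET["sample_every"],
        "replicates": DESK_PRESET["replicates"],
        "seed": 0,
    },
    "analysis": {
        "contact_threshold": 3.5,
        "bin_factor": 1,
        "compare_matrix": None,
    },
    "sweep": {
        "axis": "affinity",  # or "concentration"
        "grid": [0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 5.0, 8.0],
        "fixed_value": 0.1,  # the threshold-scale volume fraction (or affinity)
        "replicates": 2,
        "n_beads": 100,
        "box_edge": 20.0,
        "n_steps": 60_000,
    },
}


def load_config(path: str | Path | None = None) -> RunConfig:
    """Read TOML (default) or YAML and merge over the desk-preset defaults."""
    raw: dict = {}
    if path is not None:
        p = Path(path)
        if p.suffix in (".yaml", ".yml"):
            raw = yaml.safe_load(p.read_text()) or {}
        else:
            raw = tomllib.loads(p.read_text())
    cfg = RunConfig()
    for section, defaults in _DEFAULTS.items():
        merged = dict(defaults)
        user = raw.get(section, {})
        unknown = set(user) - set(defaults)
        if unknown:
            raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
        merged.update(user)
        setattr(cfg, section, merged)
    return cfg


def resolve_system(cfg: RunConfig) -> tuple[PolymerSpec, BinderEnsemble, SimulationParams]:
    """Materialise the polymer, binder ensemble and MD parameters of a config."""
    pol = cfg.polymer
    if pol.get("profile_file"):
        spec = load_polymer_spec(pol["profile_file"])
    else:
        spec = make_binding_profile(
            ProfileParams(
                n_beads=int(pol["n_beads"]),
                n_types=int(pol["n_types"]),
                n_domains=int(pol["n_domains"]),
                domain_length_mean=float(pol["domain_length_mean"]),
                overlap_prob=float(pol["overlap_prob"]),
                inert_frac=float(pol["inert_frac"]),
                seed=int(pol["profile_seed"]),
            ),
            bp_per_bead=int(pol["bp_per_bead"]),
        )
    binders = BinderEnsemble.uniform(
        spec.type_catalog,
        float(cfg.binders["volume_fraction"]),
        float(cfg.binders["affinity"]),
    )
    sim = cfg.simulation
    params = SimulationParams(
        box_edge=float(sim["box_edge"]),
        dt=float(sim["dt"]),
        friction=float(sim["friction"]),
        temperature=float(sim["temperature"]),
        n_steps=int(sim["n_steps"]),
        seed=int(sim["seed"]),
    )
    return spec, binders, params
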
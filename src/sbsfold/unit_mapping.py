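"""Calibration of model units (sigma, model time tau) to physical units.

Two independent length calibrations are combined:

* genomic density: a bead holding s bp of a genome of G bp confined in a
  nucleus of diameter D occupies sigma = (s/G)^(1/3) * D — equal nuclear
  volume share per base pair;
* imaging: matching the measured gyration radius of the locus (nm) to the
  simulated one (sigma) gives sigma = Rg_imaging / Rg_model.

The reference sigma is the arithmetic mean of the two.  Time maps through
the Stokes drag of a sigma-sized sphere in nucleoplasm of viscosity eta:
tau = 6 pi eta sigma^3 / (k_B T).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "UnitMapping",
    "calibrate_sigma",
    "tau_physical",
    "to_physical",
    "default_mapping",
]

BOLTZMANN_SI = 1.380649e-23  # J/K


@dataclass(frozen=True)
class UnitMapping:
    """Resolved calibration: all lengths in nm, time in seconds."""

    bp_per_bead: float
    genome_bp: float
    nucleus_diameter_nm: float
    rg_imaging_nm: float
    rg_model_sigma: float
    sigma_genomic_nm: float
    sigma_imaging_nm: float
    sigma_ref_nm: float
    viscosity_pa_s: float
    temperature_k: float
    tau_s: float


def calibrate_sigma(
    bp_per_bead: float,
    genome_bp: float,
    nucleus_diameter_nm: float,
    rg_imaging_nm: float,
    rg_model_sigma: float,
) -> tuple[float, float, float]:
    """(sigma_genomic, sigma_imaging, sigma_ref) in nm.

    With the defaults of a 2 Mb locus coarse-grained to 800 beads (2500 bp
    per bead), a 6 Gb genome and a 10 um nucleus, the genomic estimate is
    74.7 nm; matching a 464 nm imaged Rg to the simulated 6.4 sigma gives
    72.5 nm; their mean 73.6 nm is the reference value.
    """
    for name, v in (
        ("bp_per_bead", bp_per_bead),
        ("genome_bp", genome_bp),
        ("nucleus_diameter_nm", nucleus_diameter_nm),
        ("rg_imaging_nm", rg_imaging_nm),
        ("rg_model_sigma", rg_model_sigma),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    sigma_genomic = (bp_per_bead / genome_bp) ** (1.0 / 3.0) * nucleus_diameter_nm
    sigma_imaging = rg_imaging_nm / rg_model_sigma
    return sigma_genomic, sigma_imaging, 0.5 * (sigma_genomic + sigma_imaging)


def tau_physical(eta_pa_s: float, sigma_nm: float, temperature_k: float) -> float:
    """Model time unit in seconds: tau = 6 pi eta sigma^3 / (k_B T)."""
    if eta_pa_s <= 0 or sigma_nm <= 0 or temperature_k <= 0:
        raise ValueError("viscosity, sigma and temperature must be positive")
    sigma_m = sigma_nm * 1e-9
    return 6.0 * math.pi * eta_pa_s * sigma_m**3 / (BOLTZMANN_SI * temperature_k)


def to_physical(value: float, sigma_nm: float, power: int = 1) -> float:
    """Convert a model quantity in sigma^k to physical units.

    k = 1 -> nm, k = 2 -> nm^2, k = 3 -> um^3 (the natural unit for locus
    volumes: 1 um^3 = 1e9 nm^3).
    """
    if power not in (1, 2, 3):
        raise ValueError("power must be 1, 2 or 3")
    out = value * sigma_nm**power
    if power == 3:
        out /= 1e9  # nm^3 -> um^3
    return out


def default_mapping(
    bp_per_bead: float = 2_500.0,
    genome_bp: float = 6.0e9,
    nucleus_diameter_nm: float = 1.0e4,
    rg_imaging_nm: float = 464.0,
    rg_model_sigma: float = 6.4,
    eta_pa_s: float = 0.01,
    temperature_k: float = 300.0,
) -> UnitMapping:
    """Full calibration with the human sub-megabase-locus defaults."""
    sg, si, sr = calibrate_sigma(
        bp_per_bead, genome_bp, nucleus_diameter_nm, rg_imaging_nm, rg_model_sigma
    )
    return UnitMapping(
        bp_per_bead=bp_per_bead,
        genome_bp=genome_bp,
        nucleus_diameter_nm=nucleus_diameter_nm,
        rg_imaging_nm=rg_imaging_nm,
        rg_model_sigma=rg_model_sigma,
        sigma_genomic_nm=sg,
        sigma_imaging_nm=si,
        sigma_ref_nm=sr,
        viscosity_pa_s=eta_pa_s,
        temperature_k=temperature_k,
        tau_s=tau_physical(eta_pa_s, sr, temperature_k),
    )
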
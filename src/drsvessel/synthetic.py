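"""Synthetic phantom scenarios: an epoxy/intralipid-like slab with one
blood-filled channel, used to exercise every inverse stage without measured
data.

The background medium follows a scattering power law ``mu_s(lambda) = mu_s0
(lambda/500)^-b`` with small flat absorption.  The "blood" absorber is a
fixture template, NOT literature hemoglobin data: a sum of three Gaussians at
the Soret (420 nm) and Q-band (542/577 nm) positions on a decaying baseline,
scaled by a single amplitude.  "Measured" spectra are produced by the forward
Monte Carlo model with a measurement seed independent of any solver seed,
then multiplied by (1 + eps) with Gaussian eps and clipped to [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .monte_carlo import Spectrum, derive_seed, sweep_spectrum
from .tissue_model import (
    BeamSpec,
    CylindricalVessel,
    InvalidModelError,
    MCConfig,
    PhantomModel,
    PropertyTable,
    model_to_config,
)

__all__ = ["ScenarioSpec", "hemoglobin_like_mu_a", "generate_scenario", "write_scenario"]

# template shape: (center nm, sigma nm, relative amplitude); peak ~1 at 420 nm
_BANDS = ((420.0, 22.0, 1.0), (542.0, 14.0, 0.32), (577.0, 16.0, 0.30))
_MEASUREMENT_SEED_OFFSET = 7919  # keeps "measurement" streams off solver streams


def hemoglobin_like_mu_a(wavelength_nm, scale_mm: float = 30.0):
    """Smooth hemoglobin-like absorption template (mm^-1).

    A dominant band near 420 nm with secondary structure at 542/577 nm on a
    decaying baseline; ``scale_mm`` multiplies the whole curve and equals the
    peak absorption near 420 nm.  Valid for wavelengths in [300, 1200] nm.
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    if np.any(wl < 300.0) or np.any(wl > 1200.0):
        raise InvalidModelError("wavelength outside [300, 1200] nm")
    shape = 0.06 * np.exp(-(wl - 300.0) / 220.0)
    for center, sigma, amp in _BANDS:
        shape = shape + amp * np.exp(-0.5 * ((wl - center) / sigma) ** 2)
    out = scale_mm * shape
    return float(out) if np.isscalar(wavelength_nm) else out


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic measurement scenario.

    Defaults emulate the epoxy/intralipid slab: 2 mm thick, 15 mm lateral
    half-width, scattering 2 mm^-1 at 500 nm falling off as lambda^-1, flat
    background absorption 0.01 mm^-1, refractive index 1.5 against air.  The
    vessel carries the hemoglobin-like absorber (peak 30 mm^-1), modest
    scattering and forward-peaked anisotropy.
    """

    vessel_diameter_um: float = 300.0
    vessel_depth_mm: float = 0.65
    thickness_mm: float = 2.0
    lateral_mm: float = 15.0
    mu_s0_mm: float = 2.0
    scatter_power: float = 1.0
    mu_a_background_mm: float = 0.01
    g_background: float = 0.0
    n_background: float = 1.5
    blood_scale_mm: float = 30.0
    blood_mu_s_mm: float = 6.0
    blood_g: float = 0.9
    n_blood: float = 1.37
    spot_mm: float = 0.5
    wavelengths_nm: tuple = tuple(np.linspace(400.0, 600.0, 10))
    photons: int = 100_000
    noise: float = 0.01
    seed: int = 1
    vessel_present: bool = True

    def __post_init__(self) -> None:
        if self.noise < 0:
            raise InvalidModelError("noise level must be >= 0")

    def background_table(self) -> PropertyTable:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        mu_s = self.mu_s0_mm * (wl / 500.0) ** (-self.scatter_power)
        return PropertyTable(
            wl, self.mu_a_background_mm, mu_s, self.g_background, self.n_background
        )

    def blood_table(self) -> PropertyTable:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        mu_a = hemoglobin_like_mu_a(wl, self.blood_scale_mm)
        return PropertyTable(wl, mu_a, self.blood_mu_s_mm, self.blood_g, self.n_blood)

    def model(self) -> PhantomModel:
        vessel = None
        if self.vessel_present:
            vessel = CylindricalVessel(
                self.vessel_diameter_um, self.vessel_depth_mm, self.blood_table()
            )
        return PhantomModel(
            thickness_mm=self.thickness_mm,
            lateral_mm=self.lateral_mm,
            background=self.background_table(),
            vessel=vessel,
        )

    def beam(self) -> BeamSpec:
        return BeamSpec(self.spot_mm, tuple(self.wavelengths_nm))

    def measurement_mc(self) -> MCConfig:
        return MCConfig(
            photons=self.photons,
            seed=derive_seed(self.seed, _MEASUREMENT_SEED_OFFSET),
        )


def generate_scenario(spec: ScenarioSpec):
    """Build the phantom and its noisy "measured" spectra.

    Returns ``(model, measured_reflectance, measured_transmittance, truth)``
    where ``truth`` records the generating parameters for test audit.
    """
    model = spec.model()
    beam = spec.beam()
    mc = spec.measurement_mc()
    r_spec, t_spec = sweep_spectrum(model, beam, mc)
    rng = np.random.default_rng(derive_seed(spec.seed, _MEASUREMENT_SEED_OFFSET + 1))
    r_vals = r_spec.values.copy()
    t_vals = t_spec.values.copy()
    if spec.noise > 0:
        r_vals = r_vals * (1.0 + spec.noise * rng.standard_normal(r_vals.size))
        t_vals = t_vals * (1.0 + spec.noise * rng.standard_normal(t_vals.size))
    r_vals = np.clip(r_vals, 0.0, 1.0)
    t_vals = np.clip(t_vals, 0.0, 1.0)
    truth = {
        "vessel_present": spec.vessel_present,
        "vessel_depth_mm": spec.vessel_depth_mm if spec.vessel_present else None,
        "vessel_diameter_um": spec.vessel_diameter_um if spec.vessel_present else None,
        "thickness_mm": spec.thickness_mm,
        "noise": spec.noise,
        "seed": spec.seed,
        "measurement_seed": mc.seed,
        "photons": spec.photons,
        "mu_s0_mm": spec.mu_s0_mm,
        "mu_a_background_mm": spec.mu_a_background_mm,
        "blood_scale_mm": spec.blood_scale_mm,
    }
    wl = np.asarray(spec.wavelengths_nm, dtype=float)
    return (
        model,
        Spectrum(wl, r_vals, "reflectance"),
        Spectrum(wl, t_vals, "transmittance"),
        truth,
    )


def write_scenario(spec: ScenarioSpec, out_dir) -> dict:
    """Write model.json, measured.csv and truth.json for one scenario."""
    from .io import write_spectrum_csv  # local import avoids a cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model, r_spec, t_spec, truth = generate_scenario(spec)
    cfg = model_to_config(model, spec.beam(), spec.measurement_mc())
    with open(out / "model.json", "w", encoding="utf-8") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
    write_spectrum_csv(
        out / "measured.csv",
        r_spec.wavelengths_nm,
        {"M_R": r_spec.values, "M_T": t_spec.values},
        config=cfg,
        seed=truth["measurement_seed"],
    )
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth
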
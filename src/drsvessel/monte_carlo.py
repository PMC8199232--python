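"""Forward Monte Carlo photon transport in the vessel-bearing slab phantom.

The transport kernel is the classic hop-drop-spin weighted random walk with a
Henyey-Greenstein phase function, Fresnel boundaries at the top and bottom
surfaces, and termination of photons crossing the lateral boundary (tallied as
side escape).  Reflection reported for comparison with diffuse reflectance
measurements is the diffuse tally only; the specular entry reflection is
tallied separately.

Energy bookkeeping is exact by construction: each photon's launched weight is
fully distributed over the six budget terms, so

    R_specular + R_diffuse + T + Abs_background + Abs_vessel + E_side = 1

holds to float rounding for every run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _kernel
from .tissue_model import (
    BeamSpec,
    InvalidModelError,
    MCConfig,
    OpticalProperties,
    PhantomModel,
)

__all__ = [
    "EnergyBudget",
    "AbsorptionGrid",
    "Spectrum",
    "fresnel_reflectance",
    "sample_henyey_greenstein",
    "simulate",
    "sweep_spectrum",
    "derive_seed",
]


@dataclass(frozen=True)
class EnergyBudget:
    """Eq.-of-energy tallies of one forward run, as fractions of launched energy."""

    R_specular: float
    R_diffuse: float
    T: float
    Abs_background: float
    Abs_vessel: float
    E_side: float
    photon_count: int
    seed: int

    @property
    def total(self) -> float:
        return (
            self.R_specular
            + self.R_diffuse
            + self.T
            + self.Abs_background
            + self.Abs_vessel
            + self.E_side
        )

    @property
    def Abs(self) -> float:
        return self.Abs_background + self.Abs_vessel

    def stderr(self, fraction: float) -> float:
        """Binomial-style standard error estimate for one tally fraction."""
        p = min(max(fraction, 0.0), 1.0)
        return float(np.sqrt(p * (1.0 - p) / self.photon_count))


@dataclass(frozen=True)
class AbsorptionGrid:
    """Deposited weight fractions on a voxel grid spanning the slab."""

    values: np.ndarray  # (nx, ny, nz)
    pitch_mm: float

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass(frozen=True)
class Spectrum:
    """Wavelength-resolved fractions (reflectance or transmittance)."""

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: str = "reflectance"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.shape != vals.shape or wl.ndim != 1:
            raise InvalidModelError("wavelengths and values must be matching 1-D arrays")
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise InvalidModelError("wavelengths must be strictly increasing")
        if np.any(vals < 0) or np.any(vals > 1):
            raise InvalidModelError("spectrum values must lie in [0, 1]")
        if self.kind not in ("reflectance", "transmittance"):
            raise InvalidModelError(f"unknown spectrum kind {self.kind!r}")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)

    def band(self, lo_nm: float, hi_nm: float) -> "Spectrum":
        mask = (self.wavelengths_nm >= lo_nm) & (self.wavelengths_nm <= hi_nm)
        if not mask.any():
            raise InvalidModelError(f"no samples in band [{lo_nm}, {hi_nm}] nm")
        return Spectrum(self.wavelengths_nm[mask], self.values[mask], self.kind)

    def band_mean(self, lo_nm: float, hi_nm: float) -> float:
        return float(self.band(lo_nm, hi_nm).values.mean())


def fresnel_reflectance(n_i: float, n_t: float, cos_theta_i: float) -> float:
    """Unpolarized Fresnel reflectance at a planar interface.

    Returns 1 beyond the critical angle when ``n_i > n_t``.  ``cos_theta_i``
    must lie in [0, 1].
    """
    if not (0.0 <= cos_theta_i <= 1.0):
        raise ValueError(f"cos(theta_i) must be in [0, 1], got {cos_theta_i}")
    if n_i < 1 or n_t < 1:
        raise ValueError("refractive indices must be >= 1")
    return float(_kernel._fresnel.py_func(n_i, n_t, cos_theta_i))


def sample_henyey_greenstein(g: float, u) -> np.ndarray | float:
    """Map uniform variates ``u`` in [0, 1) to cos(theta) samples of the
    Henyey-Greenstein phase function with anisotropy ``g``.

    For ``g = 0`` this reduces exactly to ``2 u - 1`` (isotropic)."""
    if not (-1.0 < g < 1.0):
        raise ValueError(f"g must be in (-1, 1), got {g}")
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr < 0) or np.any(u_arr >= 1):
        raise ValueError("uniform variates must lie in [0, 1)")
    if abs(g) < 1e-6:
        out = 2.0 * u_arr - 1.0
    else:
        s = (1.0 - g * g) / (1.0 - g + 2.0 * g * u_arr)
        out = np.clip((1.0 + g * g - s * s) / (2.0 * g), -1.0, 1.0)
    return float(out) if np.isscalar(u) else out


def derive_seed(master_seed: int, index: int) -> int:
    """Deterministic 31-bit stream seed for the ``index``-th sub-run."""
    return int((np.uint64(master_seed) * np.uint64(2654435761) + np.uint64(index) * np.uint64(97531)) % np.uint64(2**31 - 1))


def simulate(
    model: PhantomModel,
    beam: BeamSpec,
    props_background: OpticalProperties,
    mc: MCConfig,
    props_vessel: Optional[OpticalProperties] = None,
    wavelength_nm: Optional[float] = None,
):
    """Run the forward model at a single wavelength.

    ``props_background`` (and ``props_vessel`` when the model has a vessel)
    give the optical properties at that wavelength; they may also be taken
    from the model's property tables via :func:`sweep_spectrum`.

    Returns ``EnergyBudget`` or ``(EnergyBudget, AbsorptionGrid)`` when
    ``mc.tally_fluence`` is set.
    """
    vessel = model.vessel
    if vessel is not None and props_vessel is None:
        raise InvalidModelError(
            "model has a vessel but no blood optical properties were given"
            + (f" at {wavelength_nm} nm" if wavelength_nm is not None else "")
        )
    n_slab = props_background.n

    if mc.tally_fluence:
        pitch = mc.fluence_pitch_mm
        ngx = ngy = max(1, int(np.ceil(2 * model.lateral_mm / pitch)))
        ngz = max(1, int(np.ceil(model.thickness_mm / pitch)))
        # guard against runaway allocations from a tiny pitch
        if ngx * ngy * ngz > 5e7:
            raise InvalidModelError("fluence grid too fine for this geometry")
        grid = np.zeros(ngx * ngy * ngz)
        grid_on = True
    else:
        pitch, ngx, ngy, ngz = 1.0, 1, 1, 1
        grid = np.zeros(1)
        grid_on = False

    pv = props_vessel if props_vessel is not None else OpticalProperties(0.0, 0.0)
    tallies = _kernel.transport(
        mc.photons,
        mc.seed,
        beam.spot_mm / 2.0,
        model.thickness_mm,
        model.lateral_mm,
        vessel is not None,
        vessel.axis_depth_mm if vessel is not None else 0.0,
        vessel.radius_mm if vessel is not None else 0.0,
        props_background.mu_a,
        props_background.mu_s,
        props_background.g,
        pv.mu_a,
        pv.mu_s,
        pv.g,
        model.n_above,
        n_slab,
        model.n_below,
        pv.n,
        mc.vessel_fresnel,
        mc.roulette_threshold,
        mc.roulette_survival,
        mc.max_steps,
        grid,
        grid_on,
        pitch,
        ngx,
        ngy,
        ngz,
    )
    norm = tallies / mc.photons
    budget = EnergyBudget(
        R_specular=float(norm[_kernel.I_RSPEC]),
        R_diffuse=float(norm[_kernel.I_RDIFF]),
        T=float(norm[_kernel.I_T]),
        Abs_background=float(norm[_kernel.I_ABS_BG]),
        Abs_vessel=float(norm[_kernel.I_ABS_V]),
        E_side=float(norm[_kernel.I_ESIDE]),
        photon_count=mc.photons,
        seed=mc.seed,
    )
    if grid_on:
        return budget, AbsorptionGrid(
            (grid / mc.photons).reshape(ngx, ngy, ngz), pitch
        )
    return budget


def sweep_spectrum(
    model: PhantomModel,
    beam: BeamSpec,
    mc: MCConfig,
    background=None,
    blood=None,
    include_specular: bool = False,
    return_budgets: bool = False,
):
    """Forward spectra over the beam's wavelength grid.

    Per-wavelength optical properties come from ``background``/``blood``
    property tables (defaulting to the model's own tables).  Per-wavelength
    seeds are derived deterministically from the master seed and the
    wavelength index, so two sweeps with the same master seed share random
    numbers wavelength-by-wavelength regardless of geometry (common random
    numbers across scenarios).
    """
    bg_table = background if background is not None else model.background
    if bg_table is None:
        raise InvalidModelError("no background property table available")
    blood_table = blood
    if blood_table is None and model.vessel is not None:
        blood_table = model.vessel.blood

    wavelengths = np.asarray(beam.wavelengths_nm, dtype=float)
    r_vals = np.empty_like(wavelengths)
    t_vals = np.empty_like(wavelengths)
    budgets = []
    for i, wl in enumerate(wavelengths):
        bg = bg_table.at(wl)
        pv = None
        if model.vessel is not None:
            if blood_table is None:
                raise InvalidModelError(
                    f"model has a vessel but no blood properties at {wl} nm"
                )
            pv = blood_table.at(wl)
        mc_i = MCConfig(
            photons=mc.photons,
            seed=derive_seed(mc.seed, i),
            roulette_threshold=mc.roulette_threshold,
            roulette_survival=mc.roulette_survival,
            tally_fluence=False,
            vessel_fresnel=mc.vessel_fresnel,
            max_steps=mc.max_steps,
        )
        try:
            budget = simulate(model, beam, bg, mc_i, pv, wavelength_nm=wl)
        except InvalidModelError:
            raise
        r = budget.R_diffuse + (budget.R_specular if include_specular else 0.0)
        r_vals[i] = r
        t_vals[i] = budget.T
        budgets.append(budget)
    spectra = (
        Spectrum(wavelengths, r_vals, "reflectance"),
        Spectrum(wavelengths, t_vals, "transmittance"),
    )
    return (*spectra, budgets) if return_budgets else spectra
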
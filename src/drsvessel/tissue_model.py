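"""Domain types and geometry for a slab phantom with one embedded cylindrical vessel.

Conventions
-----------
* Coordinates: ``z`` points downward from the illuminated surface (``z = 0``),
  the beam is centered on the origin, and the vessel axis runs along ``y``.
* Internal unit of length is the millimetre; vessel diameters are accepted in
  micrometres at the interface and converted.
* Vessel depth ``d`` is measured from the illuminated surface to the vessel
  *axis*, so that flipping the slab maps a vessel at depth ``d`` to depth
  ``thickness - d``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "OpticalProperties",
    "PropertyTable",
    "CylindricalVessel",
    "PhantomModel",
    "BeamSpec",
    "MCConfig",
    "region_at",
    "flip_model",
    "model_from_config",
    "model_to_config",
]


class InvalidModelError(ValueError):
    """Raised when a phantom/beam/config invariant is violated."""


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of a turbid medium at one wavelength.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient (mm^-1).
    mu_s : float
        Scattering coefficient (mm^-1).
    g : float
        Scattering anisotropy (mean cosine of the single-scattering angle),
        strictly inside (-1, 1).
    n : float
        Refractive index (>= 1).
    """

    mu_a: float
    mu_s: float
    g: float = 0.0
    n: float = 1.5

    def __post_init__(self) -> None:
        if not (self.mu_a >= 0):
            raise InvalidModelError(f"mu_a must be >= 0, got {self.mu_a}")
        if not (self.mu_s >= 0):
            raise InvalidModelError(f"mu_s must be >= 0, got {self.mu_s}")
        if not (-1.0 < self.g < 1.0):
            raise InvalidModelError(f"g must be in (-1, 1), got {self.g}")
        if not (self.n >= 1.0):
            raise InvalidModelError(f"n must be >= 1, got {self.n}")

    @property
    def mu_t(self) -> float:
        return self.mu_a + self.mu_s

    @property
    def albedo(self) -> float:
        mu_t = self.mu_t
        return self.mu_s / mu_t if mu_t > 0 else 0.0


class PropertyTable:
    """Per-wavelength optical properties on a wavelength grid.

    Linear interpolation between grid points; querying outside the grid is an
    error (optical properties of tissue phantoms are not safely extrapolated).
    """

    def __init__(
        self,
        wavelengths_nm: Sequence[float],
        mu_a: Sequence[float],
        mu_s: Sequence[float],
        g: float | Sequence[float] = 0.0,
        n: float = 1.5,
    ) -> None:
        wl = np.asarray(wavelengths_nm, dtype=float)
        if wl.ndim != 1 or wl.size == 0:
            raise InvalidModelError("wavelength grid must be a non-empty 1-D array")
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise InvalidModelError("wavelength grid must be strictly increasing")
        self.wavelengths_nm = wl
        self.mu_a = np.broadcast_to(np.asarray(mu_a, dtype=float), wl.shape).copy()
        self.mu_s = np.broadcast_to(np.asarray(mu_s, dtype=float), wl.shape).copy()
        self.g = np.broadcast_to(np.asarray(g, dtype=float), wl.shape).copy()
        self.n = float(n)
        if np.any(self.mu_a < 0) or np.any(self.mu_s < 0):
            raise InvalidModelError("mu_a and mu_s must be >= 0 everywhere")
        if np.any(np.abs(self.g) >= 1):
            raise InvalidModelError("g must be in (-1, 1) everywhere")
        if self.n < 1:
            raise InvalidModelError("n must be >= 1")

    def at(self, wavelength_nm: float) -> OpticalProperties:
        wl = self.wavelengths_nm
        w = float(wavelength_nm)
        if w < wl[0] - 1e-9 or w > wl[-1] + 1e-9:
            raise InvalidModelError(
                f"wavelength {w} nm outside table range [{wl[0]}, {wl[-1]}]"
            )
        return OpticalProperties(
            mu_a=float(np.interp(w, wl, self.mu_a)),
            mu_s=float(np.interp(w, wl, self.mu_s)),
            g=float(np.interp(w, wl, self.g)),
            n=self.n,
        )

    @classmethod
    def constant(
        cls, props: OpticalProperties, wavelengths_nm: Sequence[float] = (300.0, 1200.0)
    ) -> "PropertyTable":
        return cls(wavelengths_nm, props.mu_a, props.mu_s, props.g, props.n)


@dataclass(frozen=True)
class CylindricalVessel:
    """A blood-filled cylindrical channel parallel to the slab surface.

    ``diameter_um`` is in micrometres; ``axis_depth_mm`` is the distance from
    the illuminated surface to the cylinder axis.  The axis runs along +y.
    """

    diameter_um: float
    axis_depth_mm: float
    blood: Optional[PropertyTable] = None

    def __post_init__(self) -> None:
        if not (self.diameter_um > 0):
            raise InvalidModelError(f"diameter must be > 0, got {self.diameter_um} um")
        if self.axis_depth_mm - self.radius_mm <= 0:
            raise InvalidModelError(
                f"vessel (D={self.diameter_um} um, d={self.axis_depth_mm} mm) "
                "breaks the top surface"
            )

    @property
    def radius_mm(self) -> float:
        return self.diameter_um / 2000.0


@dataclass(frozen=True)
class PhantomModel:
    """Slab phantom: background medium, optional vessel, ambient media."""

    thickness_mm: float = 2.0
    lateral_mm: float = 15.0
    background: Optional[PropertyTable] = None
    vessel: Optional[CylindricalVessel] = None
    n_above: float = 1.0
    n_below: float = 1.0

    def __post_init__(self) -> None:
        if not (self.thickness_mm > 0):
            raise InvalidModelError("thickness must be > 0")
        if not (self.lateral_mm > 0):
            raise InvalidModelError("lateral extent must be > 0")
        if self.n_above < 1 or self.n_below < 1:
            raise InvalidModelError("ambient refractive indices must be >= 1")
        v = self.vessel
        if v is not None and v.axis_depth_mm + v.radius_mm >= self.thickness_mm:
            raise InvalidModelError(
                f"vessel (D={v.diameter_um} um, d={v.axis_depth_mm} mm) breaks "
                f"the bottom surface of a {self.thickness_mm} mm slab"
            )

    def with_vessel_depth(self, axis_depth_mm: float) -> "PhantomModel":
        if self.vessel is None:
            raise InvalidModelError("model has no vessel to move")
        return replace(self, vessel=replace(self.vessel, axis_depth_mm=axis_depth_mm))


@dataclass(frozen=True)
class BeamSpec:
    """Collimated flat-top beam at normal incidence."""

    spot_mm: float = 0.5
    wavelengths_nm: tuple = (500.0,)
    profile: str = "flat_top"

    def __post_init__(self) -> None:
        if not (self.spot_mm > 0):
            raise InvalidModelError("spot diameter must be > 0")
        if self.profile != "flat_top":
            raise InvalidModelError(f"unsupported beam profile {self.profile!r}")
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        if wl.size == 0:
            raise InvalidModelError("at least one wavelength required")
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise InvalidModelError("wavelengths must be strictly increasing")
        if wl[0] < 300.0 or wl[-1] > 1200.0:
            raise InvalidModelError("wavelengths must lie within [300, 1200] nm")
        object.__setattr__(self, "wavelengths_nm", tuple(float(w) for w in wl))


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo sampling controls.

    ``roulette_threshold``/``roulette_survival`` control low-weight photon
    termination; sub-threshold photons survive with probability
    ``roulette_survival`` at unchanged weight, otherwise their residual weight
    is tallied as absorption at the termination site (keeps the energy ledger
    exact).
    """

    photons: int = 100_000
    seed: int = 1
    roulette_threshold: float = 1e-4
    roulette_survival: float = 0.1
    tally_fluence: bool = False
    fluence_pitch_mm: float = 0.1
    vessel_fresnel: bool = False
    max_steps: int = 1_000_000

    def __post_init__(self) -> None:
        if self.photons < 1:
            raise InvalidModelError("photon count must be >= 1")
        if not (0 < self.roulette_threshold < 1):
            raise InvalidModelError("roulette threshold must be in (0, 1)")
        if not (0 < self.roulette_survival < 1):
            raise InvalidModelError("roulette survival must be in (0, 1)")
        if self.seed < 0 or self.seed >= 2**31:
            raise InvalidModelError("seed must be a non-negative 31-bit integer")


# -- geometry queries ---------------------------------------------------------

REGIONS = ("ambient_above", "background", "vessel", "ambient_below", "lateral_exit")


def region_at(position, model: PhantomModel) -> str:
    """Label the region containing ``position`` (x, y, z in mm).

    The labels partition space: above the slab, below it, beyond the lateral
    boundary (a disc of radius ``lateral_mm``), inside the vessel lumen, or in
    the background medium.
    """
    x, y, z = (float(c) for c in position)
    if z < 0:
        return "ambient_above"
    if z > model.thickness_mm:
        return "ambient_below"
    if x * x + y * y > model.lateral_mm**2:
        return "lateral_exit"
    v = model.vessel
    if v is not None:
        dz = z - v.axis_depth_mm
        if x * x + dz * dz < v.radius_mm**2:
            return "vessel"
    return "background"


def flip_model(model: PhantomModel) -> PhantomModel:
    """The phantom turned upside down: vessel depth d -> thickness - d,
    ambient media swapped.  Used for the flip-symmetry checks."""
    vessel = model.vessel
    if vessel is not None:
        vessel = replace(
            vessel, axis_depth_mm=model.thickness_mm - vessel.axis_depth_mm
        )
    return replace(
        model, vessel=vessel, n_above=model.n_below, n_below=model.n_above
    )


# -- structured config --------------------------------------------------------

def model_to_config(model: PhantomModel, beam: BeamSpec, mc: MCConfig) -> dict:
    cfg = {
        "geometry": {
            "thickness_mm": model.thickness_mm,
            "lateral_mm": model.lateral_mm,
            "n_above": model.n_above,
            "n_below": model.n_below,
        },
        "beam": {"spot_mm": beam.spot_mm, "wavelengths_nm": list(beam.wavelengths_nm)},
        "mc": {
            "photons": mc.photons,
            "seed": mc.seed,
            "roulette_threshold": mc.roulette_threshold,
            "roulette_survival": mc.roulette_survival,
        },
    }
    if model.background is not None:
        bg = model.background
        cfg["background"] = {
            "wavelengths_nm": bg.wavelengths_nm.tolist(),
            "mu_a_mm": bg.mu_a.tolist(),
            "mu_s_mm": bg.mu_s.tolist(),
            "g": bg.g.tolist(),
            "n": bg.n,
        }
    if model.vessel is not None:
        v = model.vessel
        cfg["vessel"] = {
            "diameter_um": v.diameter_um,
            "axis_depth_mm": v.axis_depth_mm,
        }
        if v.blood is not None:
            cfg["vessel"]["blood"] = {
                "wavelengths_nm": v.blood.wavelengths_nm.tolist(),
                "mu_a_mm": v.blood.mu_a.tolist(),
                "mu_s_mm": v.blood.mu_s.tolist(),
                "g": v.blood.g.tolist(),
                "n": v.blood.n,
            }
    return cfg


def _table_from_cfg(cfg: dict) -> PropertyTable:
    return PropertyTable(
        cfg["wavelengths_nm"],
        cfg["mu_a_mm"],
        cfg["mu_s_mm"],
        cfg.get("g", 0.0),
        cfg.get("n", 1.5),
    )


def model_from_config(cfg: dict) -> tuple[PhantomModel, BeamSpec, MCConfig]:
    """Build (model, beam, mc) from a structured config dict (see README)."""
    try:
        geo = cfg["geometry"]
        beam_cfg = cfg["beam"]
        mc_cfg = cfg["mc"]
    except KeyError as exc:
        raise InvalidModelError(f"missing config section: {exc.args[0]}") from exc

    background = _table_from_cfg(cfg["background"]) if "background" in cfg else None
    vessel = None
    if "vessel" in cfg:
        v = cfg["vessel"]
        blood = _table_from_cfg(v["blood"]) if "blood" in v else None
        try:
            vessel = CylindricalVessel(v["diameter_um"], v["axis_depth_mm"], blood)
        except KeyError as exc:
            raise InvalidModelError(f"missing vessel key: {exc.args[0]}") from exc
    try:
        model = PhantomModel(
            thickness_mm=geo["thickness_mm"],
            lateral_mm=geo["lateral_mm"],
            background=background,
            vessel=vessel,
            n_above=geo.get("n_above", 1.0),
            n_below=geo.get("n_below", 1.0),
        )
        beam = BeamSpec(
            spot_mm=beam_cfg["spot_mm"],
            wavelengths_nm=tuple(beam_cfg["wavelengths_nm"]),
        )
        mc = MCConfig(
            photons=int(mc_cfg["photons"]),
            seed=int(mc_cfg["seed"]),
            roulette_threshold=mc_cfg.get("roulette_threshold", 1e-4),
            roulette_survival=mc_cfg.get("roulette_survival", 0.1),
        )
    except KeyError as exc:
        raise InvalidModelError(f"missing config key: {exc.args[0]}") from exc
    return model, beam, mc


def load_config(path) -> tuple[PhantomModel, BeamSpec, MCConfig]:
    with open(path, "r", encoding="utf-8") as fh:
        return model_from_config(json.load(fh))


def save_config(path, model: PhantomModel, beam: BeamSpec, mc: MCConfig) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model_to_config(model, beam, mc), fh, indent=2, sort_keys=True)
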
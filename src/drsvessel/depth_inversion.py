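"""Vessel-depth extraction from diffuse reflectance by bracketing and
bisection on the Monte Carlo forward model.

With the vessel diameter known (e.g. from speckle imaging) and the optical
properties of background and blood known, the band-aggregated diffuse
reflectance is monotone in the vessel axis depth: a shallow vessel
intercepts more of the probing light, so reflectance rises as the vessel
sinks.  Bisection on depth between two bracketing trial depths then converges
to the measured reflectance.  All solver evaluations share one master seed
(common random numbers), so the comparison function is a deterministic,
smooth function of depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .monte_carlo import Spectrum, sweep_spectrum
from .tissue_model import (
    BeamSpec,
    InvalidModelError,
    MCConfig,
    PhantomModel,
)

__all__ = [
    "DepthBracket",
    "DepthEstimate",
    "reflectance_depth_curve",
    "extract_depth",
    "BracketError",
    "NonMonotoneError",
]

_BAND = (400.0, 600.0)  # hemoglobin absorption band, depth-sensitive
_RESIDUAL_FLOOR = 1e-3


class BracketError(ValueError):
    """Measured aggregate lies outside the calculated bracket."""


class NonMonotoneError(RuntimeError):
    """Midpoint reflectance violates the bracket ordering beyond MC noise."""


@dataclass(frozen=True)
class DepthBracket:
    """Depth bracket (d1 < d2) with calculated band aggregates at both ends."""

    d1_mm: float
    d2_mm: float
    C_R1: Optional[float] = None
    C_R2: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.d1_mm < self.d2_mm):
            raise InvalidModelError("bracket requires d1 < d2")


@dataclass(frozen=True)
class DepthEstimate:
    """Bisection result with a per-iteration audit trace."""

    d_hat_mm: float
    iterations: int
    mismatch: float
    bracket: DepthBracket
    trace: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.bracket.d1_mm - 1e-12 <= self.d_hat_mm <= self.bracket.d2_mm + 1e-12):
            raise InvalidModelError("estimate escaped its bracket")


def _feasible_range(model: PhantomModel, margin_mm: float = 0.05):
    v = model.vessel
    if v is None:
        raise InvalidModelError("model has no vessel")
    lo = v.radius_mm + margin_mm
    hi = model.thickness_mm - v.radius_mm - margin_mm
    if not (lo < hi):
        raise InvalidModelError("vessel too large for the slab")
    return lo, hi


def _band_aggregate(spec: Spectrum, band) -> float:
    return spec.band_mean(band[0], band[1])


def reflectance_depth_curve(
    model: PhantomModel,
    depths_mm: Sequence[float],
    beam: BeamSpec,
    mc: MCConfig,
    band: tuple = _BAND,
    return_spectra: bool = False,
):
    """Band-mean diffuse reflectance at each trial vessel depth.

    All depths reuse the same master seed (common random numbers), so
    differences along the curve reflect geometry, not sampling noise.
    """
    lo, hi = _feasible_range(model, margin_mm=0.0)
    out = []
    spectra = []
    for d in depths_mm:
        if not (lo < d < hi):
            raise InvalidModelError(
                f"depth {d} mm violates containment ({lo:.3f}, {hi:.3f}) mm"
            )
        m = model.with_vessel_depth(float(d))
        r_spec, _ = sweep_spectrum(m, beam, mc)
        out.append((float(d), _band_aggregate(r_spec, band)))
        if return_spectra:
            spectra.append(r_spec)
    return (out, spectra) if return_spectra else out


def _mc_stderr_band(aggregate: float, mc: MCConfig, n_wavelengths: int) -> float:
    p = min(max(aggregate, 1e-6), 1.0 - 1e-6)
    return float(np.sqrt(p * (1.0 - p) / (mc.photons * n_wavelengths)))


def extract_depth(
    measured: Spectrum,
    model: PhantomModel,
    beam: BeamSpec,
    mc: MCConfig,
    bracket: Optional[DepthBracket] = None,
    band: tuple = _BAND,
    depth_tol_mm: float = 0.01,
    mismatch_tol: Optional[float] = None,
) -> DepthEstimate:
    """Bisect on vessel depth until the calculated band-mean reflectance
    matches the measurement.

    The monotonicity direction is detected from the bracket endpoints rather
    than assumed.  Stops when the bracket is narrower than ``depth_tol_mm``
    (default 0.01 mm) or, if ``mismatch_tol`` is given, when the relative
    reflectance mismatch drops below it.

    Raises
    ------
    BracketError
        If the measured aggregate is outside the calculated endpoint range.
    NonMonotoneError
        If a midpoint falls outside the endpoint ordering by more than three
        MC standard errors.
    """
    if model.vessel is None:
        raise InvalidModelError("model needs a vessel (diameter from imaging)")
    band_meas = measured.band(band[0], band[1])
    M = float(band_meas.values.mean())
    n_wl = band_meas.wavelengths_nm.size

    if bracket is None:
        lo, hi = _feasible_range(model)
        bracket = DepthBracket(lo, hi)
    d1, d2 = bracket.d1_mm, bracket.d2_mm

    def calc(d: float) -> float:
        m = model.with_vessel_depth(d)
        r_spec, _ = sweep_spectrum(m, beam, mc)
        return _band_aggregate(r_spec, band)

    C1 = bracket.C_R1 if bracket.C_R1 is not None else calc(d1)
    C2 = bracket.C_R2 if bracket.C_R2 is not None else calc(d2)
    lo_val, hi_val = min(C1, C2), max(C1, C2)
    sigma = _mc_stderr_band(M, mc, n_wl)
    if not (lo_val - 3 * sigma <= M <= hi_val + 3 * sigma):
        raise BracketError(
            f"measured band reflectance {M:.5f} outside calculated range "
            f"[{lo_val:.5f}, {hi_val:.5f}] for depths [{d1}, {d2}] mm"
        )
    increasing = C2 >= C1

    trace = [(d1, C1), (d2, C2)]
    if mismatch_tol is not None:
        # endpoint already matching: return it without bisecting
        for d_end, C_end in ((d1, C1), (d2, C2)):
            mm = abs(C_end - M) / max(abs(M), _RESIDUAL_FLOOR)
            if mm < mismatch_tol:
                return DepthEstimate(
                    d_hat_mm=d_end, iterations=0, mismatch=mm,
                    bracket=bracket, trace=tuple(trace), seed=mc.seed,
                )
    iterations = 0
    d_mid, C_mid = 0.5 * (d1 + d2), None
    mismatch = float("inf")
    while d2 - d1 > depth_tol_mm:
        iterations += 1
        d_mid = 0.5 * (d1 + d2)
        C_mid = calc(d_mid)
        trace.append((d_mid, C_mid))
        if not (min(C1, C2) - 3 * sigma <= C_mid <= max(C1, C2) + 3 * sigma):
            raise NonMonotoneError(
                f"reflectance at midpoint {d_mid:.4f} mm ({C_mid:.5f}) violates "
                f"bracket ordering [{C1:.5f}, {C2:.5f}] beyond 3 sigma"
            )
        mismatch = abs(C_mid - M) / max(abs(M), _RESIDUAL_FLOOR)
        if mismatch_tol is not None and mismatch < mismatch_tol:
            d1 = d2 = d_mid
            break
        if (C_mid < M) == increasing:
            d1, C1 = d_mid, C_mid
        else:
            d2, C2 = d_mid, C_mid

    d_hat = 0.5 * (d1 + d2)
    if C_mid is not None and abs(d_mid - d_hat) < 1e-12:
        final_mismatch = mismatch
    else:
        C_hat = calc(d_hat)
        final_mismatch = abs(C_hat - M) / max(abs(M), _RESIDUAL_FLOOR)
    return DepthEstimate(
        d_hat_mm=d_hat,
        iterations=iterations,
        mismatch=final_mismatch,
        bracket=bracket,
        trace=tuple(trace),
        seed=mc.seed,
    )
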
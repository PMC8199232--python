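"""Integrated IAD + forward-Monte-Carlo extraction of optical properties.

Per wavelength: the measured (M_R, M_T) pair is first inverted with the fast
1-D adding-doubling solver (IAD) to get a seed (mu_a, mu_s); the seed is then
refined against the full 3-D Monte Carlo forward model, which accounts for
the finite beam, lateral escape and boundary geometry that the 1-D solver
cannot see.  Refinement is a damped Newton iteration whose Jacobian comes
from the cheap adding-doubling surrogate while residuals are evaluated with
MC under common random numbers (one fixed seed per wavelength), so the
residual sequence is deterministic and step halving can enforce monotone
descent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .adding_doubling import MeasuredPair, iad_invert, rt_slab
from .monte_carlo import derive_seed, simulate
from .tissue_model import (
    BeamSpec,
    InvalidModelError,
    MCConfig,
    OpticalProperties,
    PhantomModel,
)

__all__ = ["ExtractionResult", "extract_optical_properties"]

_RESIDUAL_FLOOR = 1e-3


@dataclass
class WavelengthExtraction:
    """Per-wavelength record of the IAD seed and its MC refinement."""

    wavelength_nm: float
    props: OpticalProperties
    C_R: float
    C_T: float
    residual: float
    iterations: int
    converged: bool
    history: tuple = ()


@dataclass
class ExtractionResult:
    """Extraction across the wavelength grid."""

    records: list

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return np.array([r.wavelength_nm for r in self.records])

    @property
    def mu_a(self) -> np.ndarray:
        return np.array([r.props.mu_a for r in self.records])

    @property
    def mu_s(self) -> np.ndarray:
        return np.array([r.props.mu_s for r in self.records])

    @property
    def max_residual(self) -> float:
        return max(r.residual for r in self.records)

    @property
    def all_converged(self) -> bool:
        return all(r.converged for r in self.records)


def _relative_residual(C_R, C_T, M_R, M_T) -> float:
    eR = abs(C_R - M_R) / max(M_R, _RESIDUAL_FLOOR)
    eT = abs(C_T - M_T) / max(M_T, _RESIDUAL_FLOOR)
    return max(eR, eT)


def extract_optical_properties(
    measured: Sequence[MeasuredPair],
    model: PhantomModel,
    beam: BeamSpec,
    mc: MCConfig,
    g: float = 0.0,
    n: Optional[float] = None,
    tolerance: float = 0.01,
    max_iter: int = 20,
) -> ExtractionResult:
    """Recover per-wavelength (mu_a, mu_s) of a homogeneous phantom from
    measured reflectance/transmittance pairs.

    ``g`` is held fixed during refinement (Mie estimate or the default 0);
    ``n`` defaults to the model's background index.  ``tolerance`` is the
    relative spectral-mismatch target (default 1%).  Non-convergence within
    ``max_iter`` is reported per wavelength, not raised.
    """
    if model.vessel is not None:
        raise InvalidModelError("property extraction expects a homogeneous model")
    if n is None:
        if model.background is None:
            raise InvalidModelError("no refractive index available")
        n = model.background.n

    records = []
    for i, pair in enumerate(measured):
        seed_i = derive_seed(mc.seed, 1_000 + i)
        mc_i = MCConfig(
            photons=mc.photons,
            seed=seed_i,
            roulette_threshold=mc.roulette_threshold,
            roulette_survival=mc.roulette_survival,
        )

        def forward_mc(props: OpticalProperties):
            budget = simulate(model, beam, props, mc_i)
            return budget.R_diffuse, budget.T

        props = iad_invert(
            pair,
            model.thickness_mm,
            g=g,
            n=n,
            n_above=model.n_above,
            n_below=model.n_below,
        )
        C_R, C_T = forward_mc(props)
        residual = _relative_residual(C_R, C_T, pair.M_R, pair.M_T)
        history = [(props.mu_a, props.mu_s, residual)]

        iterations = 0
        while residual > tolerance and iterations < max_iter:
            iterations += 1
            # finite-difference Jacobian on the cheap 1-D surrogate
            def surrogate(mu_a, mu_s):
                p = OpticalProperties(max(mu_a, 0.0), max(mu_s, 0.0), g, n)
                return np.array(
                    rt_slab(p, model.thickness_mm, model.n_above, model.n_below)
                )
            base = surrogate(props.mu_a, props.mu_s)
            h_a = max(1e-5, 1e-2 * props.mu_a)
            h_s = max(1e-5, 1e-2 * props.mu_s)
            J = np.column_stack(
                [
                    (surrogate(props.mu_a + h_a, props.mu_s) - base) / h_a,
                    (surrogate(props.mu_a, props.mu_s + h_s) - base) / h_s,
                ]
            )
            F = np.array([C_R - pair.M_R, C_T - pair.M_T])
            try:
                step = np.linalg.solve(J, -F)
            except np.linalg.LinAlgError:
                break
            lam = 1.0
            accepted = False
            for _ in range(12):
                mu_a_new = max(props.mu_a + lam * step[0], 0.0)
                mu_s_new = max(props.mu_s + lam * step[1], 0.0)
                cand = OpticalProperties(mu_a_new, mu_s_new, g, n)
                C_Rn, C_Tn = forward_mc(cand)
                res_new = _relative_residual(C_Rn, C_Tn, pair.M_R, pair.M_T)
                if res_new < residual:
                    props, C_R, C_T, residual = cand, C_Rn, C_Tn, res_new
                    accepted = True
                    break
                lam *= 0.5
            history.append((props.mu_a, props.mu_s, residual))
            if not accepted:
                break  # damping exhausted: MC noise floor reached

        records.append(
            WavelengthExtraction(
                wavelength_nm=pair.wavelength_nm,
                props=props,
                C_R=C_R,
                C_T=C_T,
                residual=residual,
                iterations=iterations,
                converged=residual <= tolerance,
                history=tuple(history),
            )
        )
    return ExtractionResult(records)
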
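"""Mie theory for a dilute suspension of spherical scatterers.

Used to estimate the scattering anisotropy ``g`` (and scattering coefficient)
of the intralipid-in-epoxy phantom from particle size, refractive indices and
concentration.  Efficiencies and the asymmetry parameter come from the
standard Lorenz-Mie series with Bohren-Huffman recurrences: the logarithmic
derivative D_n by downward recurrence, Riccati-Bessel functions of the size
parameter by upward recurrence, series truncated at the Wiscombe order
``x + 4 x^(1/3) + 2``.

The dilute (independent-scatterer) assumption is implicit throughout:
``mu_s`` is linear in number density and ``g`` is concentration-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .tissue_model import InvalidModelError

__all__ = ["ParticleSuspension", "mie_single", "suspension_properties"]


class MieConvergenceError(RuntimeError):
    """The Mie series failed to stabilize."""


@dataclass(frozen=True)
class ParticleSuspension:
    """Dilute suspension of identical spheres.

    Number density can be given directly (``number_density_mm3``) or derived
    from a mass fraction with a particle mass density (g/cm^3).  The default
    particle density 0.93 g/cm^3 is soybean-oil-like (intralipid fat
    droplets).
    """

    d_p_um: float
    n_p: float
    n_med: float
    number_density_mm3: float | None = None
    mass_fraction: float | None = None
    particle_density_g_cm3: float = 0.93
    suspension_density_g_cm3: float = 1.1

    def __post_init__(self) -> None:
        if not (self.d_p_um > 0):
            raise InvalidModelError("particle diameter must be > 0")
        if self.n_p < 1 or self.n_med < 1:
            raise InvalidModelError("refractive indices must be >= 1")
        if self.number_density_mm3 is None and self.mass_fraction is None:
            raise InvalidModelError(
                "give either number_density_mm3 or mass_fraction"
            )
        if self.number_density_mm3 is not None and self.number_density_mm3 < 0:
            raise InvalidModelError("number density must be >= 0")
        if self.mass_fraction is not None and not (0 <= self.mass_fraction < 1):
            raise InvalidModelError("mass fraction must be in [0, 1)")

    @property
    def concentration_mm3(self) -> float:
        """Particles per mm^3."""
        if self.number_density_mm3 is not None:
            return self.number_density_mm3
        # particle mass in g: volume (mm^3) * density (g/cm^3) * 1e-3
        r_mm = self.d_p_um / 2000.0
        v_mm3 = 4.0 / 3.0 * math.pi * r_mm**3
        m_particle_g = v_mm3 * self.particle_density_g_cm3 * 1e-3
        # particle mass per mm^3 of suspension
        m_per_mm3 = self.mass_fraction * self.suspension_density_g_cm3 * 1e-3
        return m_per_mm3 / m_particle_g


def _wiscombe_order(x: float) -> int:
    return int(math.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))


def mie_single(
    x: float, m: complex, n_terms: int | None = None
) -> tuple[float, float, float]:
    """Mie efficiencies and asymmetry for one sphere.

    Parameters
    ----------
    x : float
        Size parameter ``pi d n_med / lambda`` (> 0).
    m : complex
        Relative refractive index ``n_p / n_med`` (imaginary part >= 0 for an
        absorbing particle).
    n_terms : int, optional
        Series truncation order; defaults to the Wiscombe criterion.

    Returns
    -------
    (Q_ext, Q_sca, g)
    """
    if not (x > 0):
        raise InvalidModelError(f"size parameter must be > 0, got {x}")
    m = complex(m)
    if m.imag < 0:
        m = m.conjugate()
    N = n_terms if n_terms is not None else _wiscombe_order(x)
    N = max(N, 3)

    # logarithmic derivative D_n(mx) by downward recurrence
    mx = m * x
    n_start = N + max(15, int(math.ceil(4.05 * abs(mx) ** (1 / 3))) + 15)
    D = np.zeros(n_start + 1, dtype=complex)
    for n in range(n_start, 0, -1):
        D[n - 1] = n / mx - 1.0 / (D[n] + n / mx)
    D = D[1 : N + 1]  # D_1 .. D_N

    n = np.arange(1, N + 1, dtype=float)
    # Riccati-Bessel psi_n(x), chi_n(x) by upward recurrence
    psi = np.zeros(N)
    chi = np.zeros(N)
    psi_m1, psi_0 = math.cos(x), math.sin(x)  # psi_{-1}, psi_0
    chi_m1, chi_0 = -math.sin(x), math.cos(x)
    for k in range(1, N + 1):
        psi[k - 1] = (2 * k - 1) / x * psi_0 - psi_m1
        chi[k - 1] = (2 * k - 1) / x * chi_0 - chi_m1
        psi_m1, psi_0 = psi_0, psi[k - 1]
        chi_m1, chi_0 = chi_0, chi[k - 1]
    xi = psi - 1j * chi
    psi_prev = np.empty(N)
    xi_prev = np.empty(N, dtype=complex)
    psi_prev[0], xi_prev[0] = math.sin(x), math.sin(x) - 1j * math.cos(x)
    psi_prev[1:], xi_prev[1:] = psi[:-1], xi[:-1]

    da = D / m + n / x
    db = D * m + n / x
    a = (da * psi - psi_prev) / (da * xi - xi_prev)
    b = (db * psi - psi_prev) / (db * xi - xi_prev)

    if not (np.all(np.isfinite(a.view(float))) and np.all(np.isfinite(b.view(float)))):
        raise MieConvergenceError(f"Mie series unstable at x={x}, m={m}")

    two_n1 = 2 * n + 1
    q_ext = 2.0 / x**2 * float(np.sum(two_n1 * (a + b).real))
    q_sca = 2.0 / x**2 * float(np.sum(two_n1 * (np.abs(a) ** 2 + np.abs(b) ** 2)))

    # asymmetry parameter
    nm = n[:-1]
    ab1 = (
        nm * (nm + 2) / (nm + 1)
        * (a[:-1] * np.conj(a[1:]) + b[:-1] * np.conj(b[1:])).real
        if N > 1
        else np.zeros(0)
    )
    ab2 = two_n1 / (n * (n + 1)) * (a * np.conj(b)).real
    g_num = 4.0 / x**2 * (float(np.sum(ab1)) + float(np.sum(ab2)))
    g = g_num / q_sca if q_sca > 0 else 0.0
    g = min(1.0, max(-1.0, g))
    return q_ext, q_sca, g


def suspension_properties(
    susp: ParticleSuspension, wavelength_nm: float
) -> tuple[float, float]:
    """Scattering coefficient (mm^-1) and anisotropy of a dilute suspension.

    ``mu_s = C * Q_sca * pi r^2`` with the geometric cross-section in mm^2;
    ``g`` is the single-particle value (independent of concentration).
    """
    if wavelength_nm <= 0:
        raise InvalidModelError("wavelength must be > 0")
    lam_mm = wavelength_nm * 1e-6
    d_mm = susp.d_p_um * 1e-3
    x = math.pi * d_mm * susp.n_med / lam_mm
    m = susp.n_p / susp.n_med
    _, q_sca, g = mie_single(x, m)
    sigma_geom = math.pi * (d_mm / 2.0) ** 2
    mu_s = susp.concentration_mm3 * q_sca * sigma_geom
    return mu_s, g
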
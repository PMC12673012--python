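"""Mie theory for homogeneous spheres: amplitudes and Mueller matrices.

Used as the exact validation oracle for the discrete dipole solver and as
the reference in microsphere calibration.  Series coefficients use the
logarithmic-derivative downward recurrence; truncation follows the Wiscombe
criterion n_max = x + 4 x^(1/3) + 2.

The scattering angle theta is measured from the propagation direction; the
Mueller matrix is expressed in the scattering plane.  For a sphere it has
the block form  [[M11, M12, 0, 0], [M12, M11, 0, 0], [0, 0, M33, M34],
[0, 0, -M34, M33]] with M11 = (|S1|^2 + |S2|^2)/2, M12 = (|S2|^2 - |S1|^2)/2,
M33 = Re(S2 S1*), M34 = Im(S2 S1*).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MieInput",
    "ScatteringMatrixCurve",
    "mie_coefficients",
    "mie_amplitudes",
    "mie_mueller",
    "mie_mm_pair",
]


@dataclass(frozen=True)
class MieInput:
    """Size parameter x = k * radius (k in the medium) and relative index m."""

    x: float
    m: complex

    def __post_init__(self) -> None:
        if not self.x > 0:
            raise ValueError(f"size parameter must be positive, got {self.x}")


@dataclass(frozen=True)
class ScatteringMatrixCurve:
    """Angle-resolved 4x4 Mueller matrices with a normalization tag."""

    angles: np.ndarray        # degrees, shape (n,)
    mm: np.ndarray            # shape (n, 4, 4)
    normalization: str = "raw"  # "raw" | "m11"

    def normalized(self) -> "ScatteringMatrixCurve":
        if self.normalization == "m11":
            return self
        m11 = self.mm[:, 0:1, 0:1]
        return ScatteringMatrixCurve(angles=self.angles, mm=self.mm / m11, normalization="m11")


def _n_max(x: float) -> int:
    return int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))


def mie_coefficients(inp: MieInput, n_max: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Mie coefficients a_n, b_n for n = 1..n_max."""
    x, m = float(inp.x), complex(inp.m)
    if x > 2e4:
        raise OverflowError(f"size parameter x = {x} too large for a stable Mie series here")
    if n_max is None:
        n_max = _n_max(x)
    mx = m * x
    # logarithmic derivative D_n(mx), downward recurrence
    n_start = n_max + max(15, int(np.ceil(abs(mx) ** 0.5 * 4)))
    d = np.zeros(n_start + 1, dtype=complex)
    for n in range(n_start, 0, -1):
        d[n - 1] = n / mx - 1.0 / (d[n] + n / mx)
    # Riccati-Bessel psi and xi at real x, upward recurrence
    psi = np.empty(n_max + 1)
    chi = np.empty(n_max + 1)
    psi_m1, psi[0] = np.cos(x), np.sin(x)
    chi_m1, chi[0] = -np.sin(x), np.cos(x)
    for n in range(1, n_max + 1):
        psi[n] = (2 * n - 1) / x * psi[n - 1] - (psi_m1 if n == 1 else psi[n - 2])
        chi[n] = (2 * n - 1) / x * chi[n - 1] - (chi_m1 if n == 1 else chi[n - 2])
    if not (np.isfinite(psi).all() and np.isfinite(chi).all()):
        raise OverflowError(f"Mie series overflow at x = {x}")
    xi = psi - 1j * chi
    n = np.arange(1, n_max + 1)
    dn = d[1 : n_max + 1]
    psi_n, psi_nm1 = psi[1:], psi[:-1]
    xi_n, xi_nm1 = xi[1:], xi[:-1]
    fa = dn / m + n / x
    fb = dn * m + n / x
    a = (fa * psi_n - psi_nm1) / (fa * xi_n - xi_nm1)
    b = (fb * psi_n - psi_nm1) / (fb * xi_n - xi_nm1)
    return a, b


def mie_amplitudes(inp: MieInput, theta_deg) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude functions S1, S2 at the given scattering angles (degrees)."""
    theta = np.atleast_1d(np.asarray(theta_deg, dtype=float))
    if np.any((theta < 0) | (theta > 180)):
        raise ValueError("scattering angle must lie in [0, 180] degrees")
    a, b = mie_coefficients(inp)
    n_max = a.size
    mu = np.cos(np.deg2rad(theta))
    s1 = np.zeros(theta.shape, dtype=complex)
    s2 = np.zeros(theta.shape, dtype=complex)
    pi_nm1 = np.zeros_like(mu)   # pi_0
    pi_n = np.ones_like(mu)      # pi_1
    for n in range(1, n_max + 1):
        tau_n = n * mu * pi_n - (n + 1) * pi_nm1
        fac = (2 * n + 1) / (n * (n + 1))
        s1 += fac * (a[n - 1] * pi_n + b[n - 1] * tau_n)
        s2 += fac * (a[n - 1] * tau_n + b[n - 1] * pi_n)
        pi_next = ((2 * n + 1) * mu * pi_n - (n + 1) * pi_nm1) / n
        pi_nm1, pi_n = pi_n, pi_next
    if np.isscalar(theta_deg):
        return s1[0], s2[0]
    return s1, s2


def mie_mueller(inp: MieInput, angles, normalization: str = "raw") -> ScatteringMatrixCurve:
    """Angle-resolved Mueller matrices of a homogeneous sphere."""
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    s1, s2 = mie_amplitudes(inp, angles)
    m11 = 0.5 * (np.abs(s1) ** 2 + np.abs(s2) ** 2)
    m12 = 0.5 * (np.abs(s2) ** 2 - np.abs(s1) ** 2)
    m33 = (s2 * np.conj(s1)).real
    m34 = (s2 * np.conj(s1)).imag
    mm = np.zeros((angles.size, 4, 4))
    mm[:, 0, 0] = mm[:, 1, 1] = m11
    mm[:, 0, 1] = mm[:, 1, 0] = m12
    mm[:, 2, 2] = mm[:, 3, 3] = m33
    mm[:, 2, 3] = m34
    mm[:, 3, 2] = -m34
    curve = ScatteringMatrixCurve(angles=angles, mm=mm, normalization="raw")
    if normalization == "m11":
        return curve.normalized()
    return curve


def mie_mm_pair(inp: MieInput):
    """M11-normalized Mueller matrices of a sphere at 60/120 degrees.

    Returns a :class:`rbcsim.mueller.MuellerMatrixPair` with forward-ratio
    normalization of M11 (relative to its 0-degree value) filled in.
    """
    from .mueller import MuellerMatrixPair

    curve = mie_mueller(inp, [0.0, 60.0, 120.0])
    m11_0 = curve.mm[0, 0, 0]
    return MuellerMatrixPair(
        mm60=curve.mm[1] / curve.mm[1, 0, 0],
        mm120=curve.mm[2] / curve.mm[2, 0, 0],
        m11_forward_ratio60=float(curve.mm[1, 0, 0] / m11_0),
        m11_forward_ratio120=float(curve.mm[2, 0, 0] / m11_0),
    )
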
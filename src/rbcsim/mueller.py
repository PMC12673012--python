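"""Amplitude-matrix to Mueller-matrix conversion and shared containers.

Conventions follow the standard scattering-plane formulation: the 2x2
complex amplitude matrix ``S = [[S2, S3], [S4, S1]]`` maps the incident
(parallel, perpendicular) field components onto the scattered ones, and the
Mueller matrix is the corresponding map on Stokes vectors (I, Q, U, V).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "mueller_from_amplitudes",
    "normalize_mm",
    "MuellerMatrixPair",
]

# Stokes <- coherency transform, coherency ordered (E1 E1*, E1 E2*, E2 E1*, E2 E2*)
# with E1 the parallel and E2 the perpendicular component.
_A = np.array(
    [
        [1, 0, 0, 1],
        [1, 0, 0, -1],
        [0, 1, 1, 0],
        [0, 1j, -1j, 0],
    ],
    dtype=complex,
)
_A_INV = np.linalg.inv(_A)


def mueller_from_amplitudes(s: np.ndarray) -> np.ndarray:
    """Raw (unnormalized) 4x4 Mueller matrix from a 2x2 amplitude matrix.

    Computed as ``A (S kron S*) A^-1`` with ``A`` the Stokes/coherency
    transform; for the identity amplitude matrix this returns the identity.
    """
    s = np.asarray(s, dtype=complex)
    if s.shape != (2, 2):
        raise ValueError(f"amplitude matrix must be 2x2, got {s.shape}")
    m = _A @ np.kron(s, s.conj()) @ _A_INV
    return np.ascontiguousarray(m.real)


def normalize_mm(mm: np.ndarray) -> np.ndarray:
    """Normalize a raw Mueller matrix by its M11 element."""
    mm = np.asarray(mm, dtype=float)
    m11 = mm[0, 0]
    if m11 <= 0:
        raise ValueError(f"cannot normalize: M11 = {m11} is not positive")
    return mm / m11


@dataclass(frozen=True)
class MuellerMatrixPair:
    """M11-normalized Mueller matrices at the two collection angles.

    ``mm60`` and ``mm120`` have M11 = 1; ``m11_forward_ratio60/120`` are the
    raw M11 values relative to M11 at 0 degrees (the paper's normalization of
    the M11 element itself), when available.
    """

    mm60: np.ndarray
    mm120: np.ndarray
    m11_forward_ratio60: float | None = None
    m11_forward_ratio120: float | None = None

    def __post_init__(self) -> None:
        for name, mm in (("mm60", self.mm60), ("mm120", self.mm120)):
            mm = np.asarray(mm, dtype=float)
            if mm.shape != (4, 4):
                raise ValueError(f"{name} must be 4x4")
            if not np.isclose(mm[0, 0], 1.0, atol=1e-9):
                raise ValueError(f"{name} must be M11-normalized (M11 = {mm[0, 0]})")
            object.__setattr__(self, name, mm)
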
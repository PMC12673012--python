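"""Polarization feature parameters (PFPs) from a dual-angle Mueller pair.

Six scalars condense the 60/120-degree M11-normalized Mueller matrices into
physically interpretable features of a red blood cell:

* ``K1 = (1 - M22^60) / (1 + M12^60)`` — departure of the upper-left block
  from sphere symmetry (M22 = M11); approaches 0 as the cell rounds up.
* ``K2 = M14^60 / (1 + M14^60)`` — circular-to-intensity coupling, zero for
  any sphere; a second shape parameter.
* ``LE60, LE120 = (M12 + M21)/2`` — linear orthogonal polarization
  attenuation differential index at each angle (LE120 is the surface /
  spiculation indicator, LE60 a composite size-shape index).
* ``T60 = (M33 + M44)/2`` — refractive-index-sensitive depolarization index.
* ``T120 = (-M22 + M33 + M44)/3`` — size-sensitive depolarization index.

All formulas assume M11-normalized matrices (M11 = 1 implicit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mueller import MuellerMatrixPair

__all__ = [
    "PFPVector",
    "PFPUndefinedError",
    "k1",
    "k2",
    "le",
    "t60",
    "t120",
    "pfp_vector",
    "PFP_NAMES",
]

PFP_NAMES = ("K1", "K2", "LE60", "LE120", "T60", "T120")

_POLE_TOL = 1e-9


class PFPUndefinedError(ZeroDivisionError):
    """A feature denominator vanished (the matrix sits on a pole)."""


@dataclass(frozen=True)
class PFPVector:
    K1: float
    K2: float
    LE60: float
    LE120: float
    T60: float
    T120: float

    def as_array(self) -> np.ndarray:
        return np.array([self.K1, self.K2, self.LE60, self.LE120, self.T60, self.T120])


def _as_mm(mm) -> np.ndarray:
    mm = np.asarray(mm, dtype=float)
    if mm.shape != (4, 4):
        raise ValueError("expected a 4x4 Mueller matrix")
    return mm


def k1(mm60) -> float:
    """(1 - M22) / (1 + M12) at 60 degrees; 0 for an exact sphere matrix."""
    mm = _as_mm(mm60)
    denom = 1.0 + mm[0, 1]
    if abs(denom) < _POLE_TOL:
        raise PFPUndefinedError(f"K1 undefined: 1 + M12 = {denom:.3e}")
    return float((1.0 - mm[1, 1]) / denom)


def k2(mm60) -> float:
    """M14 / (1 + M14) at 60 degrees; 0 for an exact sphere matrix."""
    mm = _as_mm(mm60)
    denom = 1.0 + mm[0, 3]
    if abs(denom) < _POLE_TOL:
        raise PFPUndefinedError(f"K2 undefined: 1 + M14 = {denom:.3e}")
    return float(mm[0, 3] / denom)


def le(mm, which: int | None = None) -> float:
    """Linear orthogonal polarization attenuation index (M12 + M21)/2.

    ``which`` (60 or 120) is informational; the formula is identical at both
    angles and operates on whichever normalized matrix is supplied.
    """
    if which not in (None, 60, 120):
        raise ValueError("which must be 60 or 120")
    mm = _as_mm(mm)
    return float((mm[0, 1] + mm[1, 0]) / 2.0)


def t60(mm60) -> float:
    """(M33 + M44)/2 on the 60-degree matrix."""
    mm = _as_mm(mm60)
    return float((mm[2, 2] + mm[3, 3]) / 2.0)


def t120(mm120) -> float:
    """(-M22 + M33 + M44)/3 on the 120-degree matrix."""
    mm = _as_mm(mm120)
    return float((-mm[1, 1] + mm[2, 2] + mm[3, 3]) / 3.0)


def pfp_vector(pair: MuellerMatrixPair) -> PFPVector:
    """All six features from a normalized dual-angle pair; pole errors propagate."""
    return PFPVector(
        K1=k1(pair.mm60),
        K2=k2(pair.mm60),
        LE60=le(pair.mm60, 60),
        LE120=le(pair.mm120, 120),
        T60=t60(pair.mm60),
        T120=t120(pair.mm120),
    )
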
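"""Euler-angle sampling and Mueller-matrix averaging for free-floating cells.

Orientations use intrinsic z-y-z Euler angles (alpha, beta, gamma) in
degrees, alpha/gamma in [0, 360), beta in [0, 180].  Axisymmetric cells
illuminated along the symmetry axis only need beta sampled; fully asymmetric
cells (spiculated models) need all three angles.  Sampling is random and
seeded, uniform in the angle by default (uniform in cos(beta) available as
an option).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EulerOrientation",
    "rotation_matrix",
    "sample_axisymmetric",
    "sample_full",
    "average_mm",
]


@dataclass(frozen=True)
class EulerOrientation:
    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 360.0 or not 0.0 <= self.gamma < 360.0:
            raise ValueError("alpha and gamma must lie in [0, 360)")
        if not 0.0 <= self.beta <= 180.0:
            raise ValueError("beta must lie in [0, 180]")


def _rz(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ry(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rotation_matrix(o: EulerOrientation) -> np.ndarray:
    """Body-to-lab rotation Rz(alpha) Ry(beta) Rz(gamma)."""
    a, b, g = np.deg2rad([o.alpha, o.beta, o.gamma])
    return _rz(a) @ _ry(b) @ _rz(g)


def sample_axisymmetric(
    n: int = 30,
    seed: int | None = None,
    uniform_in: str = "angle",
    random_azimuth: bool = True,
) -> list[EulerOrientation]:
    """n random tilts beta in [0, 180] for an axisymmetric cell.

    The cell's own-axis angle gamma is irrelevant by symmetry and stays 0.
    The azimuth alpha of the tilted axis around the beam *is* sampled by
    default: with alpha pinned to 0 the symmetry axis never leaves the
    scattering plane, every orientation is mirror-symmetric about that plane,
    and the averaged matrix degenerates to the sphere-like block form
    (M22 = M11 identically) — an artifact of the frame, not of the cell.
    Set ``random_azimuth=False`` to recover the in-plane-only convention.
    """
    if n < 1:
        raise ValueError("need at least one orientation")
    rng = np.random.default_rng(seed)
    if uniform_in == "angle":
        betas = rng.uniform(0.0, 180.0, size=n)
    elif uniform_in == "cos":
        betas = np.rad2deg(np.arccos(rng.uniform(-1.0, 1.0, size=n)))
    else:
        raise ValueError(f"unknown beta sampling {uniform_in!r}")
    alphas = rng.uniform(0.0, 360.0, size=n) if random_azimuth else np.zeros(n)
    return [EulerOrientation(alpha=float(a), beta=float(b)) for a, b in zip(alphas, betas)]


def sample_full(n_per_angle: int = 5, seed: int | None = None) -> list[EulerOrientation]:
    """Cartesian product of n random values per Euler angle (n^3 orientations).

    The default of five values per angle gives the 125-orientation average
    used for fully asymmetric (spiculated) cells.
    """
    if n_per_angle < 1:
        raise ValueError("need at least one value per angle")
    rng = np.random.default_rng(seed)
    alphas = rng.uniform(0.0, 360.0, size=n_per_angle)
    betas = rng.uniform(0.0, 180.0, size=n_per_angle)
    gammas = rng.uniform(0.0, 360.0, size=n_per_angle)
    return [
        EulerOrientation(alpha=float(a), beta=float(b), gamma=float(g))
        for a in alphas
        for b in betas
        for g in gammas
    ]


def average_mm(mms) -> np.ndarray:
    """Element-wise arithmetic mean of raw (unnormalized) Mueller matrices."""
    mms = [np.asarray(m, dtype=float) for m in mms]
    if len(mms) == 0:
        raise ValueError("cannot average an empty list of Mueller matrices")
    return np.mean(mms, axis=0)
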
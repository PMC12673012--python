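"""Forward/inverse model of the dual-angle Mueller-matrix polarimeter chain.

The detection arm splits scattered light onto four photomultiplier channels
behind fixed analyzers (45-degree linear, horizontal, vertical, left
circular), giving voltages (s0, s45, s90, sL) from which the Stokes vector
follows linearly.  Sequences of incident/scattered Stokes pairs yield the
Mueller matrix through a Moore-Penrose pseudoinverse, and polystyrene
microspheres with a Mie-theory reference calibrate the multiplicative /
additive system error model  MM_r = Mp . MM_m - Ms.

The module also generates synthetic quadrant voltages (the exact inverse of
the Stokes reconstruction plus seeded Gaussian noise) so the whole chain can
be exercised without hardware.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "QuadrantSignals",
    "CalibrationModel",
    "stokes_from_quadrants",
    "quadrants_from_stokes",
    "canonical_sop_set",
    "mm_from_stokes",
    "fit_calibration",
    "apply_calibration",
    "synth_quadrants",
]


@dataclass(frozen=True)
class QuadrantSignals:
    """Voltages of the four analyzer channels (arbitrary units)."""

    s0: float
    s45: float
    s90: float
    sL: float

    def as_array(self) -> np.ndarray:
        return np.array([self.s0, self.s45, self.s90, self.sL])


@dataclass(frozen=True)
class CalibrationModel:
    """Multiplicative (Mp) and additive (Ms) system error matrices."""

    Mp: np.ndarray
    Ms: np.ndarray

    def __post_init__(self) -> None:
        mp = np.asarray(self.Mp, dtype=float)
        ms = np.asarray(self.Ms, dtype=float)
        if mp.shape != (4, 4) or ms.shape != (4, 4):
            raise ValueError("Mp and Ms must be 4x4")
        if abs(np.linalg.det(mp)) < 1e-12:
            raise ValueError("Mp must be invertible")
        object.__setattr__(self, "Mp", mp)
        object.__setattr__(self, "Ms", ms)

    @classmethod
    def identity(cls) -> "CalibrationModel":
        return cls(Mp=np.eye(4), Ms=np.zeros((4, 4)))


def stokes_from_quadrants(q) -> np.ndarray:
    """Stokes vector from quadrant voltages.

    I = s0 + s90;  Q = s0 - s90;  U = 2 s45 - s0 - s90;  V = s0 + s90 - 2 sL.
    Accepts a ``QuadrantSignals``, a length-4 sequence, or an (N, 4) array
    (returning (N, 4) Stokes rows).
    """
    arr = q.as_array() if isinstance(q, QuadrantSignals) else np.asarray(q, dtype=float)
    s0, s45, s90, sl = np.moveaxis(np.atleast_2d(arr), -1, 0)
    stokes = np.stack([s0 + s90, s0 - s90, 2 * s45 - s0 - s90, s0 + s90 - 2 * sl], axis=-1)
    return stokes[0] if arr.ndim == 1 else stokes


def quadrants_from_stokes(stokes) -> np.ndarray:
    """Exact inverse of :func:`stokes_from_quadrants`:
    s0 = (I+Q)/2, s90 = (I-Q)/2, s45 = (I+U)/2, sL = (I-V)/2."""
    arr = np.asarray(stokes, dtype=float)
    i, q, u, v = np.moveaxis(np.atleast_2d(arr), -1, 0)
    quads = np.stack([(i + q) / 2, (i + u) / 2, (i - q) / 2, (i - v) / 2], axis=-1)
    return quads[0] if arr.ndim == 1 else quads


def canonical_sop_set(n: int = 6) -> np.ndarray:
    """Well-conditioned incident Stokes columns (4, n).

    The default six states are H, V, +45, -45, right and left circular,
    spanning the Poincare sphere; n=4 keeps (H, V, +45, R).
    """
    states = np.array(
        [
            [1, 1, 0, 0],
            [1, -1, 0, 0],
            [1, 0, 1, 0],
            [1, 0, -1, 0],
            [1, 0, 0, 1],
            [1, 0, 0, -1],
        ],
        dtype=float,
    ).T
    if n == 4:
        return states[:, [0, 1, 2, 4]]
    if not 4 <= n <= 6:
        raise ValueError("canonical SOP set supports 4 to 6 states")
    return states[:, :n]


def mm_from_stokes(s_in: np.ndarray, s_out: np.ndarray) -> np.ndarray:
    """Mueller matrix as S_out . pinv(S_in) (least squares when N > 4).

    ``s_in`` and ``s_out`` are (4, N) column collections; ``s_in`` must have
    rank 4.
    """
    s_in = np.asarray(s_in, dtype=float)
    s_out = np.asarray(s_out, dtype=float)
    if s_in.ndim != 2 or s_in.shape[0] != 4 or s_out.shape != s_in.shape:
        raise ValueError("expected matching (4, N) incident and scattered Stokes columns")
    if s_in.shape[1] < 4:
        raise ValueError(f"need at least 4 incident states, got {s_in.shape[1]}")
    rank = np.linalg.matrix_rank(s_in)
    if rank < 4:
        raise ValueError(f"incident Stokes set is rank deficient (rank {rank} < 4)")
    return s_out @ np.linalg.pinv(s_in)


def fit_calibration(measured, reference) -> CalibrationModel:
    """Least-squares (Mp, Ms) from paired measured/reference Mueller matrices.

    Minimizes  sum_i || Mp . MM_m,i - Ms - MM_r,i ||_F^2  jointly over the 32
    unknowns.  At least two pairs with independent structure are required
    (one pair leaves 16 equations for 32 unknowns).
    """
    measured = [np.asarray(m, dtype=float) for m in measured]
    reference = [np.asarray(r, dtype=float) for r in reference]
    if len(measured) != len(reference) or not measured:
        raise ValueError("need equal, non-empty lists of measured and reference matrices")
    blocks = []
    rhs = []
    eye16 = np.eye(16)
    for mm_m, mm_r in zip(measured, reference):
        # row-major vec: vec(Mp @ A) = (I_4 kron A^T) vec(Mp)
        blocks.append(np.hstack([np.kron(np.eye(4), mm_m.T), -eye16]))
        rhs.append(mm_r.reshape(-1))
    a = np.vstack(blocks)
    b = np.concatenate(rhs)
    rank = np.linalg.matrix_rank(a)
    if rank < 32:
        raise ValueError(
            f"calibration system is under-determined (rank {rank} < 32); "
            "supply more, structurally independent microsphere standards"
        )
    x, *_ = np.linalg.lstsq(a, b, rcond=None)
    return CalibrationModel(Mp=x[:16].reshape(4, 4), Ms=x[16:].reshape(4, 4))


def apply_calibration(cal: CalibrationModel, mm_measured) -> np.ndarray:
    """Corrected matrix  Mp . MM_m - Ms  (inverse of the forward error model)."""
    return cal.Mp @ np.asarray(mm_measured, dtype=float) - cal.Ms


def synth_quadrants(
    mm_true,
    s_in: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Synthetic quadrant voltages for a cell of known Mueller matrix.

    Propagates each incident Stokes column through ``mm_true``, inverts the
    quadrant map exactly, and adds seeded Gaussian voltage noise of standard
    deviation ``noise_sd``.  Returns an (N, 4) array of (s0, s45, s90, sL).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    mm_true = np.asarray(mm_true, dtype=float)
    s_in = np.asarray(s_in, dtype=float)
    s_out = (mm_true @ s_in).T  # (N, 4)
    quads = quadrants_from_stokes(s_out)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        quads = quads + rng.normal(scale=noise_sd, size=quads.shape)
    return quads
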
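"""Parametric red-blood-cell geometry and dipole-lattice discretization.

A normal erythrocyte is a biconcave disc described by the implicit quartic

    f(r, z) = r^4 + 2 S r^2 z^2 + z^4 + P r^2 + Q z^2 + R = 0,

with ``r = sqrt(x^2 + y^2)`` and the z axis the symmetry axis.  The four
coefficients (S, P, Q, R) follow from four morphometric parameters: the cell
diameter ``d``, the central (dimple) thickness ``b``, the maximum rim
thickness ``h`` attained on the ring of diameter ``c``.  All lengths are in
micrometres; coordinates are right-handed.

The module also provides a sphere-morph family (discocyte -> sphere at equal
equivalent diameter), spiculated spheres (echinocyte models), and the cubic
dipole lattice used by the discrete dipole approximation solver.

Sign convention: ``f <= 0`` is *inside* the cell; the boundary counts as
inside.  The exact sphere is handled by a dedicated predicate because the
quartic degenerates to a perfect square there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BiconcaveParams",
    "ImplicitCoeffs",
    "SpiculeSpec",
    "DipoleGrid",
    "Shape",
    "QuarticShape",
    "Sphere",
    "SpiculatedSphere",
    "RotatedShape",
    "GeometryError",
    "solve_biconcave_coeffs",
    "implicit_f",
    "is_inside",
    "quartic_volume",
    "morph_shape",
    "make_spiculated",
    "discretize",
    "default_spacing",
    "equivalent_diameter",
    "shape_from_config",
]

#: Canonical shape ratios of a normal discocyte relative to its diameter.
DEFAULT_RATIOS = {"b_over_d": 0.18, "c_over_d": 0.62, "h_over_d": 0.35}


class GeometryError(ValueError):
    """Invalid or degenerate geometric input."""


@dataclass(frozen=True)
class BiconcaveParams:
    """Morphometric parameters of the biconcave disc (micrometres).

    ``d``: cell diameter, ``b``: central thickness, ``c``: diameter of the
    ring where thickness is extremal, ``h``: maximum thickness.  Requires
    ``0 < b < h < d`` and ``0 < c < d``; ``b == h`` would make the thickness
    extremum constraint degenerate.
    """

    d: float
    b: float
    c: float
    h: float

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise GeometryError(f"diameter must be positive, got d={self.d}")
        if not 0 < self.b < self.h:
            raise GeometryError(
                "central thickness must satisfy 0 < b < h "
                f"(extremum constraint degenerate at b == h); got b={self.b}, h={self.h}"
            )
        if not self.h < self.d:
            raise GeometryError(f"maximum thickness must satisfy h < d; got h={self.h}, d={self.d}")
        if not 0 < self.c < self.d:
            raise GeometryError(f"ring diameter must satisfy 0 < c < d; got c={self.c}")

    @classmethod
    def from_diameter(cls, d: float, ratios: dict | None = None) -> "BiconcaveParams":
        """Standard discocyte of diameter ``d`` using fixed shape ratios
        b/d = 0.18, c/d = 0.62, h/d = 0.35 (overridable)."""
        rr = dict(DEFAULT_RATIOS)
        if ratios:
            rr.update(ratios)
        return cls(d=d, b=rr["b_over_d"] * d, c=rr["c_over_d"] * d, h=rr["h_over_d"] * d)


@dataclass(frozen=True)
class ImplicitCoeffs:
    """Coefficients of the quartic surface f(r,z) = r^4 + 2S r^2 z^2 + z^4 + P r^2 + Q z^2 + R."""

    S: float
    P: float
    Q: float
    R: float

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.P, self.Q, self.R])


def implicit_f(r, z, coeffs: ImplicitCoeffs):
    """Evaluate the quartic f(r, z); negative values are inside."""
    r2 = np.asarray(r, dtype=float) ** 2
    z2 = np.asarray(z, dtype=float) ** 2
    return r2**2 + 2.0 * coeffs.S * r2 * z2 + z2**2 + coeffs.P * r2 + coeffs.Q * z2 + coeffs.R


def solve_biconcave_coeffs(p: BiconcaveParams, residual_tol: float = 1e-8) -> ImplicitCoeffs:
    """Solve (S, P, Q, R) from the four morphometric constraints.

    Constraints: the surface passes through the rim (d/2, 0), the dimple
    (0, b/2) and the thickness maximum (c/2, h/2), and d(thickness)/dr = 0 at
    the maximum, i.e. df/dr = 0 there.  The system is linear in the four
    coefficients and solved directly; residuals are checked afterwards.
    """
    rm, zb, rc, zh = p.d / 2.0, p.b / 2.0, p.c / 2.0, p.h / 2.0
    # unknown vector x = (S, P, Q, R)
    a = np.array(
        [
            [0.0, rm**2, 0.0, 1.0],                   # f(rm, 0)  = 0
            [0.0, 0.0, zb**2, 1.0],                   # f(0, zb)  = 0
            [2.0 * rc**2 * zh**2, rc**2, zh**2, 1.0], # f(rc, zh) = 0
            [2.0 * zh**2, 1.0, 0.0, 0.0],             # df/dr = 0 at (rc, zh)
        ]
    )
    rhs = np.array([-(rm**4), -(zb**4), -(rc**4 + zh**4), -2.0 * rc**2])
    try:
        x = np.linalg.solve(a, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by invariants
        raise GeometryError(f"degenerate biconcave parameter combination {p}: {exc}") from exc
    coeffs = ImplicitCoeffs(*x)
    residuals = {
        "rim f(d/2,0)": float(implicit_f(rm, 0.0, coeffs)),
        "dimple f(0,b/2)": float(implicit_f(0.0, zb, coeffs)),
        "extremum f(c/2,h/2)": float(implicit_f(rc, zh, coeffs)),
        "extremum df/dr": float(4 * rc**3 + 4 * coeffs.S * rc * zh**2 + 2 * coeffs.P * rc),
    }
    scale = max(rm, zh) ** 4
    for name, res in residuals.items():
        if abs(res) > residual_tol * max(1.0, scale):
            raise GeometryError(f"constraint '{name}' violated: residual {res:.3e} for {p}")
    return coeffs


def is_inside(points, coeffs: ImplicitCoeffs):
    """Inside predicate for the quartic: f(r, z) <= 0 with r = sqrt(x^2+y^2).

    ``points`` is (..., 3); returns a boolean array of the leading shape.
    """
    pts = np.asarray(points, dtype=float)
    r = np.hypot(pts[..., 0], pts[..., 1])
    return implicit_f(r, pts[..., 2], coeffs) <= 0.0


# --------------------------------------------------------------------------- shapes

class Shape:
    """Base class: an inside predicate plus a bounding radius (micrometres)."""

    bounding_radius: float

    def contains(self, points) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass(frozen=True)
class QuarticShape(Shape):
    coeffs: ImplicitCoeffs
    bounding_radius: float

    def contains(self, points) -> np.ndarray:
        return is_inside(points, self.coeffs)


@dataclass(frozen=True)
class Sphere(Shape):
    radius: float

    @property
    def bounding_radius(self) -> float:  # type: ignore[override]
        return self.radius

    def contains(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        # tiny relative slack keeps exact boundary ties inside despite rounding
        return np.einsum("...i,...i->...", pts, pts) <= self.radius**2 * (1.0 + 1e-12)


@dataclass(frozen=True)
class SpiculeSpec:
    """Spiculated-sphere (echinocyte) specification.

    Conical protrusions of height ``amplitude`` sit on seeded random surface
    directions of a sphere of ``base_diameter``; each cone base subtends an
    angular half-width ``base_halfwidth`` degrees.  The physiologic amplitude
    range is d/20 to d/10 of the base diameter.
    """

    base_diameter: float
    amplitude: float
    n_spicules: int = 20
    base_halfwidth: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_diameter <= 0:
            raise GeometryError("base_diameter must be positive")
        if self.amplitude < 0:
            raise GeometryError("amplitude must be non-negative")
        if self.n_spicules < 1:
            raise GeometryError("n_spicules must be >= 1")
        if not 0 < self.base_halfwidth <= 90:
            raise GeometryError("base_halfwidth must be in (0, 90] degrees")


@dataclass(frozen=True)
class SpiculatedSphere(Shape):
    spec: SpiculeSpec
    directions: np.ndarray = field(repr=False)

    @property
    def bounding_radius(self) -> float:  # type: ignore[override]
        return self.spec.base_diameter / 2.0 + self.spec.amplitude

    def contains(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        radius = self.spec.base_diameter / 2.0
        rad = np.linalg.norm(pts, axis=-1)
        inside = rad**2 <= radius**2 * (1.0 + 1e-12)
        if self.spec.amplitude > 0:
            w = np.deg2rad(self.spec.base_halfwidth)
            with np.errstate(invalid="ignore", divide="ignore"):
                cosang = pts @ self.directions.T / np.where(rad > 0, rad, 1.0)[..., None]
            ang = np.arccos(np.clip(cosang, -1.0, 1.0))
            # cone envelope: radius + amplitude at the axis, tapering to the
            # sphere surface at the base half-width
            envelope = radius + self.spec.amplitude * (1.0 - ang / w)
            in_cone = (ang <= w) & (rad[..., None] <= envelope)
            inside = inside | in_cone.any(axis=-1)
        return inside.reshape(np.shape(points)[:-1])


@dataclass(frozen=True)
class RotatedShape(Shape):
    """A shape rigidly rotated by a 3x3 matrix (body -> lab)."""

    base: Shape
    rotation: np.ndarray = field(repr=False)

    @property
    def bounding_radius(self) -> float:  # type: ignore[override]
        return self.base.bounding_radius

    def contains(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return self.base.contains(pts @ self.rotation)  # R^T applied to rows


def make_spiculated(spec: SpiculeSpec) -> SpiculatedSphere:
    """Union of a sphere and seeded random surface cones; amplitude 0 is the
    plain sphere.  Identical seed gives a bit-identical shape."""
    rng = np.random.default_rng(spec.seed)
    v = rng.normal(size=(spec.n_spicules, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return SpiculatedSphere(spec=spec, directions=v)


# --------------------------------------------------------------------------- volume & morph

def _outer_radius(coeffs: ImplicitCoeffs) -> float:
    """Largest r with f(r, 0) <= 0 (the equatorial rim radius)."""
    disc = coeffs.P**2 - 4.0 * coeffs.R
    if disc < 0:
        raise GeometryError("quartic has no real equatorial extent")
    u = (-coeffs.P + np.sqrt(disc)) / 2.0
    if u <= 0:
        raise GeometryError("quartic encloses no volume at z = 0")
    return float(np.sqrt(u))


def quartic_volume(coeffs: ImplicitCoeffs, n_r: int = 4000) -> float:
    """Volume of the region f <= 0 by radial quadrature.

    At fixed r the inequality is quadratic in z^2; the slab half-thickness is
    sqrt(u+) with u+ the larger root (u- <= 0 for simply connected sections,
    an annular z-section is handled as sqrt(u+) - sqrt(u-)).
    """
    r_out = _outer_radius(coeffs)
    r = np.linspace(0.0, 1.5 * r_out, n_r)
    a_ = 2.0 * coeffs.S * r**2 + coeffs.Q
    c_ = r**4 + coeffs.P * r**2 + coeffs.R
    disc = a_**2 - 4.0 * c_
    valid = disc >= 0
    sq = np.sqrt(np.where(valid, disc, 0.0))
    u_hi = (-a_ + sq) / 2.0
    u_lo = (-a_ - sq) / 2.0
    half = np.where(valid & (u_hi > 0), np.sqrt(np.clip(u_hi, 0, None)), 0.0)
    half -= np.where(valid & (u_lo > 0), np.sqrt(np.clip(u_lo, 0, None)), 0.0)
    return float(np.trapezoid(2.0 * np.pi * r * 2.0 * half, r))


def _scale_coeffs(coeffs: ImplicitCoeffs, s: float) -> ImplicitCoeffs:
    """Isotropically scale the implicit region by factor ``s``."""
    return ImplicitCoeffs(S=coeffs.S, P=coeffs.P * s**2, Q=coeffs.Q * s**2, R=coeffs.R * s**4)


def morph_shape(p: BiconcaveParams, t: float) -> Shape:
    """Discocyte-to-sphere morph at constant equivalent diameter.

    ``t = 0`` is the standard biconcave disc for ``p``; ``t = 1`` is the
    sphere of equal volume.  Intermediate ``t`` linearly pulls the thickness
    ratios b/d and h/d toward their common mean (raising central thickness,
    lowering the rim bulge) and then rescales isotropically so the enclosed
    volume — hence the equivalent diameter — is conserved.
    """
    if not 0.0 <= t <= 1.0:
        raise GeometryError(f"morph fraction must lie in [0, 1], got {t}")
    coeffs0 = solve_biconcave_coeffs(p)
    v0 = quartic_volume(coeffs0)
    r_eq = (3.0 * v0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    if t == 0.0:
        return QuarticShape(coeffs=coeffs0, bounding_radius=1.05 * max(_outer_radius(coeffs0), p.h / 2.0))
    if t == 1.0:
        return Sphere(radius=r_eq)
    rb0, rh0 = p.b / p.d, p.h / p.d
    rbar = 0.5 * (rb0 + rh0)
    pt = BiconcaveParams(
        d=p.d,
        b=((1.0 - t) * rb0 + t * rbar) * p.d,
        c=p.c,
        h=((1.0 - t) * rh0 + t * rbar) * p.d,
    )
    coeffs_t = solve_biconcave_coeffs(pt)
    s = (v0 / quartic_volume(coeffs_t)) ** (1.0 / 3.0)
    coeffs_t = _scale_coeffs(coeffs_t, s)
    return QuarticShape(
        coeffs=coeffs_t,
        bounding_radius=1.05 * s * max(_outer_radius(solve_biconcave_coeffs(pt)), pt.h / 2.0),
    )


# --------------------------------------------------------------------------- lattice

@dataclass(frozen=True)
class DipoleGrid:
    """Cubic dipole lattice of one discretized cell.

    ``positions`` (N, 3) are occupied lattice-cell centres in micrometres,
    ``indices`` the integer lattice indices of those cells within
    ``grid_shape``, and ``spacing`` the lattice pitch d_s.  ``occupancy``
    holds the fraction of each lattice cell's volume lying inside the shape
    (all ones for plain centre-inside voxelization); boundary-cell weighting
    suppresses the surface-staircase error of the dipole approximation.
    """

    positions: np.ndarray
    spacing: float
    indices: np.ndarray
    grid_shape: tuple[int, int, int]
    origin_shift: np.ndarray = field(default_factory=lambda: np.zeros(3))
    occupancy: np.ndarray | None = None

    @property
    def n_dipoles(self) -> int:
        return int(self.positions.shape[0])

    @property
    def volume(self) -> float:
        """Occupied volume in um^3 (fractional cells counted fractionally)."""
        if self.occupancy is None:
            return self.n_dipoles * self.spacing**3
        return float(self.occupancy.sum() * self.spacing**3)

    def rotated(self, rotation: np.ndarray) -> "DipoleGrid":
        """Grid with positions rigidly rotated into the lab frame (the lattice
        topology — indices and shape — is unchanged)."""
        return DipoleGrid(
            positions=self.positions @ np.asarray(rotation).T,
            spacing=self.spacing,
            indices=self.indices,
            grid_shape=self.grid_shape,
            origin_shift=np.asarray(rotation) @ self.origin_shift,
            occupancy=self.occupancy,
        )


def discretize(
    shape: Shape,
    d_s: float,
    bounding_radius: float | None = None,
    origin_shift=(0.0, 0.0, 0.0),
    supersample: int = 1,
) -> DipoleGrid:
    """Voxelize ``shape`` on a cubic lattice of pitch ``d_s``.

    The shape centroid sits at a lattice-cell centre (grid centred on the
    origin plus an optional ``origin_shift``, useful for translation-
    invariance checks).  With ``supersample = 1`` a lattice cell belongs to
    the grid iff its centre is inside the shape (plain staircase
    voxelization).  With ``supersample > 1`` each candidate cell is probed on
    a supersample^3 sub-grid and kept with its fractional occupancy when any
    sub-point is inside; the fractions feed boundary-weighted polarizability
    in the dipole solver, which markedly reduces surface-staircase error.
    Raises if the grid comes out empty.
    """
    if d_s <= 0:
        raise GeometryError("dipole spacing must be positive")
    if supersample < 1:
        raise GeometryError("supersample must be >= 1")
    rad = bounding_radius if bounding_radius is not None else shape.bounding_radius
    shift = np.asarray(origin_shift, dtype=float)
    rad = rad + float(np.max(np.abs(shift)))  # keep a shifted shape covered
    n = int(np.ceil(2.0 * rad / d_s)) + 1
    if n % 2 == 0:
        n += 1  # odd count keeps a cell centre at the origin
    axis = (np.arange(n) - (n - 1) / 2.0) * d_s
    xx, yy, zz = np.meshgrid(axis + shift[0], axis + shift[1], axis + shift[2], indexing="ij")
    pts = np.stack([xx, yy, zz], axis=-1)
    occupancy = None
    if supersample == 1:
        mask = shape.contains(pts.reshape(-1, 3)).reshape(pts.shape[:-1])
    else:
        ss = supersample
        sub = (np.arange(ss) - (ss - 1) / 2.0) / ss * d_s
        sx, sy, sz = np.meshgrid(sub, sub, sub, indexing="ij")
        offsets = np.stack([sx, sy, sz], axis=-1).reshape(-1, 3)
        # coarse pass: only probe cells whose centre is within one cell of the shape
        frac = np.zeros(pts.shape[:-1])
        near = shape.contains(pts.reshape(-1, 3)).reshape(pts.shape[:-1])
        # dilate the candidate set by one cell in each direction
        cand = near.copy()
        for ax_i in range(3):
            cand |= np.roll(near, 1, axis=ax_i) | np.roll(near, -1, axis=ax_i)
        cpts = pts[cand]
        inside_counts = np.zeros(cpts.shape[0])
        for off in offsets:
            inside_counts += shape.contains(cpts + off)
        frac[cand] = inside_counts / offsets.shape[0]
        mask = frac > 0
        occupancy = frac[mask]
    idx = np.argwhere(mask)
    if idx.shape[0] == 0:
        raise GeometryError(
            f"empty dipole grid: no lattice centre inside the shape at spacing {d_s}"
        )
    return DipoleGrid(
        positions=pts[mask],
        spacing=d_s,
        indices=idx,
        grid_shape=(n, n, n),
        origin_shift=shift,
        occupancy=occupancy,
    )


def default_spacing(m: complex, k: float) -> float:
    """Dipole spacing from the accuracy rule |m k d_s| = 0.45.

    ``m`` is the complex relative refractive index, ``k`` the wavenumber in
    the surrounding medium (1/um).
    """
    if k <= 0:
        raise GeometryError("wavenumber must be positive")
    mod = abs(m) * k
    if mod <= 0:
        raise GeometryError("|m| k must be positive")
    return 0.45 / mod


def equivalent_diameter(grid: DipoleGrid) -> float:
    """Diameter of the sphere whose volume equals the voxelized cell volume."""
    if grid.n_dipoles <= 0:
        raise GeometryError("grid has no dipoles")
    return float((6.0 * grid.n_dipoles * grid.spacing**3 / np.pi) ** (1.0 / 3.0))


# --------------------------------------------------------------------------- config

def shape_from_config(cfg: dict) -> Shape:
    """Build a shape from a config mapping.

    Recognized ``type`` values: ``biconcave``, ``morph``, ``sphere``,
    ``spiculated``.  ``d`` is the driving diameter; ``ratios`` overrides the
    discocyte shape ratios; ``t`` the morph fraction; ``spicule`` the nested
    spicule options (amplitude, n_spicules, base_halfwidth, seed).
    """
    kind = cfg.get("type", "biconcave")
    d = float(cfg.get("d", 7.0))
    if kind == "sphere":
        return Sphere(radius=d / 2.0)
    if kind == "biconcave":
        p = BiconcaveParams.from_diameter(d, cfg.get("ratios"))
        coeffs = solve_biconcave_coeffs(p)
        return QuarticShape(coeffs=coeffs, bounding_radius=1.05 * max(d / 2.0, p.h / 2.0))
    if kind == "morph":
        p = BiconcaveParams.from_diameter(d, cfg.get("ratios"))
        return morph_shape(p, float(cfg.get("t", 0.0)))
    if kind == "spiculated":
        sp = dict(cfg.get("spicule", {}))
        amplitude = float(sp.get("amplitude", d / 15.0))
        spec = SpiculeSpec(
            base_diameter=d,
            amplitude=amplitude,
            n_spicules=int(sp.get("n_spicules", 20)),
            base_halfwidth=float(sp.get("base_halfwidth", 15.0)),
            seed=int(sp.get("seed", cfg.get("seed", 0))),
        )
        return make_spiculated(spec)
    raise GeometryError(f"unknown shape type {kind!r}")
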
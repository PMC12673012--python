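"""Seeded synthetic red-blood-cell populations and mixtures.

Stands in for the stress-experiment samples: monodisperse populations of
normal (biconcave), spherocyte (swollen, spherical) and echinocyte
(spiculated) cells with cell-to-cell variability in diameter and refractive
index, element-wise Gaussian measurement noise on the normalized Mueller
matrices, and mixtures at prescribed volume ratios.

Cell sizes default to a desk-scale regime (diameters around 0.5-0.7 um)
where the discrete dipole solver runs in seconds per cell; the class
parameter orderings (swelling lowers the refractive index, shrinkage raises
it, oxidative stress grows spicules) mirror the physiology of osmotic,
oxidative and pH stress at that reduced scale.

Two Mueller-matrix backends are available: exact per-cell DDA, and a cached
library — a small parameter grid of orientation-averaged DDA solutions with
multilinear interpolation — for generating thousands of cells quickly.
Spherocytes are exact spheres, so their matrices come straight from the Mie
oracle.  Everything is reproducible bit-for-bit from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .dda import OpticalParams, simulate_mm
from .geometry import BiconcaveParams, SpiculeSpec, make_spiculated, morph_shape
from .mie import MieInput, mie_mm_pair
from .mueller import MuellerMatrixPair
from .orientation import EulerOrientation, sample_axisymmetric
from .pfp import PFP_NAMES, pfp_vector

__all__ = [
    "PopulationSpec",
    "MixtureSpec",
    "LibraryConfig",
    "MMLibrary",
    "build_library",
    "generate_population",
    "build_mixture",
    "stress_preset",
    "class_preset",
    "pair_to_features",
    "features_to_pair",
    "MM_FEATURE_NAMES",
    "PAPER_MIXTURE_RATIOS",
    "CLASS_ORDER",
]

CLASS_ORDER = ("spherocyte", "echinocyte", "normal")

#: Mixture volume ratios (spherocyte : echinocyte : normal) used in the
#: mixed-suspension experiments.
PAPER_MIXTURE_RATIOS = (
    (0.25, 0.25, 0.5),
    (0.3, 0.2, 0.5),
    (0.1, 0.5, 0.4),
    (0.4, 0.4, 0.2),
    (0.2, 0.3, 0.5),
)

_ELEMENT_IJ = [(i, j) for i in range(4) for j in range(4) if (i, j) != (0, 0)]
MM_FEATURE_NAMES = [f"M60_{i + 1}{j + 1}" for i, j in _ELEMENT_IJ] + [
    f"M120_{i + 1}{j + 1}" for i, j in _ELEMENT_IJ
]


def pair_to_features(pair: MuellerMatrixPair) -> np.ndarray:
    """30-vector of the non-M11 normalized elements (15 per angle)."""
    return np.array(
        [pair.mm60[i, j] for i, j in _ELEMENT_IJ] + [pair.mm120[i, j] for i, j in _ELEMENT_IJ]
    )


def features_to_pair(vec, ratio60: float | None = None, ratio120: float | None = None) -> MuellerMatrixPair:
    """Rebuild a normalized pair from a 30-element feature vector (M11 = 1)."""
    vec = np.asarray(vec, dtype=float)
    if vec.size != 30:
        raise ValueError("expected 30 Mueller features")
    mm60 = np.ones((4, 4))
    mm120 = np.ones((4, 4))
    for k, (i, j) in enumerate(_ELEMENT_IJ):
        mm60[i, j] = vec[k]
        mm120[i, j] = vec[15 + k]
    return MuellerMatrixPair(
        mm60=mm60, mm120=mm120, m11_forward_ratio60=ratio60, m11_forward_ratio120=ratio120
    )


# --------------------------------------------------------------------- specs

@dataclass(frozen=True)
class PopulationSpec:
    """Parameter distributions of one monodisperse synthetic population.

    Diameters and refractive indices are Gaussian (truncated at physical /
    library bounds); the spicule amplitude, when present, is uniform over
    ``spicule_amplitude_range`` expressed as a fraction of the diameter
    (physiologic range 1/20 to 1/10).  ``morph_t`` = 0 is the biconcave
    disc, 1 the equal-volume sphere.
    """

    class_name: str
    n_cells: int = 100
    diameter_mean: float = 0.60
    diameter_sd: float = 0.03
    index_mean: float = 1.053
    index_sd: float = 0.002
    morph_t: float = 0.0
    spicule_amplitude_range: tuple[float, float] | None = None
    n_spicules: int = 20
    mm_noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.diameter_sd < 0 or self.index_sd < 0 or self.mm_noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.class_name not in CLASS_ORDER:
            raise ValueError(f"unknown class {self.class_name!r}")


@dataclass(frozen=True)
class MixtureSpec:
    """Mixture composition: per-class ratios in CLASS_ORDER, total count, seed."""

    ratios: tuple[float, float, float]
    total_n: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        r = np.asarray(self.ratios, dtype=float)
        if np.any(r < 0) or abs(r.sum() - 1.0) > 1e-9:
            raise ValueError("ratios must be non-negative and sum to 1")


# ------------------------------------------------------------------- presets

_PRESETS = {
    # name: (class, d_mean, m_mean, morph_t, amp_range); desk-scale diameters,
    # index shifts follow hemoglobin dilution/concentration with cell volume
    "normal": ("normal", 0.60, 1.053, 0.0, None),
    "hypotonic": ("spherocyte", 0.66, 1.041, 1.0, None),
    "acidic": ("spherocyte", 0.65, 1.045, 1.0, None),
    "hypertonic": ("echinocyte", 0.54, 1.065, 0.0, (0.05, 0.10)),
    "oxidative": ("echinocyte", 0.60, 1.053, 0.0, (0.05, 0.10)),
    "alkaline": ("echinocyte", 0.56, 1.058, 0.0, (0.04, 0.08)),
}


def stress_preset(name: str, n_cells: int = 100, seed: int = 0) -> PopulationSpec:
    """Population preset for a stress condition.

    Encodes the qualitative physiology at the package's desk scale: hypotonic
    and acidic media swell cells toward spheres and dilute hemoglobin (larger
    diameter, lower index); hypertonic and alkaline media shrink cells,
    concentrate hemoglobin and, at the extremes, grow membrane spicules;
    oxidative stress spiculates at unchanged size and index.
    """
    if name not in _PRESETS:
        raise ValueError(f"unknown stress preset {name!r}; choose from {sorted(_PRESETS)}")
    cls, d_mean, m_mean, t, amp = _PRESETS[name]
    return PopulationSpec(
        class_name=cls,
        n_cells=n_cells,
        diameter_mean=d_mean,
        index_mean=m_mean,
        morph_t=t,
        spicule_amplitude_range=amp,
        seed=seed,
    )


def class_preset(class_name: str, n_cells: int = 100, seed: int = 0) -> PopulationSpec:
    """Default population for one classifier class (normal / spherocyte /
    echinocyte), i.e. the corresponding osmotic-stress preset."""
    name = {"normal": "normal", "spherocyte": "hypotonic", "echinocyte": "oxidative"}[class_name]
    return stress_preset(name, n_cells=n_cells, seed=seed)


# ------------------------------------------------------------------- library

@dataclass(frozen=True)
class LibraryConfig:
    """Parameter grids of the cached Mueller-matrix library.

    Grid densities and orientation counts are deliberately small so the
    library builds in minutes on one CPU; they are configuration, not
    physics.  Orientation counts below the 30/125 used for single high-
    fidelity simulations trade sampling noise for speed and are folded into
    the generator's measurement-noise budget.
    """

    normal_diameters: tuple[float, ...] = (0.51, 0.60, 0.69)
    normal_indices: tuple[float, ...] = (1.047, 1.053, 1.059)
    normal_orientations: int = 3
    echino_diameters: tuple[float, ...] = (0.50, 0.70)
    echino_amp_fracs: tuple[float, ...] = (0.05, 0.10)
    echino_indices: tuple[float, ...] = (1.047, 1.059)
    echino_orientations: int = 4
    n_spicules: int = 20
    tol: float = 1e-5
    seed: int = 2024


def _pack(pair: MuellerMatrixPair) -> np.ndarray:
    return np.concatenate(
        [
            pair.mm60.ravel(),
            pair.mm120.ravel(),
            [pair.m11_forward_ratio60 or np.nan, pair.m11_forward_ratio120 or np.nan],
        ]
    )


def _unpack(vec: np.ndarray) -> MuellerMatrixPair:
    mm60 = vec[:16].reshape(4, 4).copy()
    mm120 = vec[16:32].reshape(4, 4).copy()
    mm60 /= mm60[0, 0]
    mm120 /= mm120[0, 0]
    return MuellerMatrixPair(
        mm60=mm60,
        mm120=mm120,
        m11_forward_ratio60=float(vec[32]),
        m11_forward_ratio120=float(vec[33]),
    )


class _GridInterp:
    """Multilinear interpolation that tolerates singleton axes and clamps
    queries to the grid bounds (the generator truncates its Gaussians there)."""

    def __init__(self, axes: list[np.ndarray], values: np.ndarray) -> None:
        self.axes = [np.asarray(a, dtype=float) for a in axes]
        self.values = values
        self._active = [i for i, a in enumerate(self.axes) if a.size > 1]
        if self._active:
            self._interp = RegularGridInterpolator(
                [self.axes[i] for i in self._active],
                values.squeeze(axis=tuple(i for i in range(len(axes)) if i not in self._active)),
                method="linear",
                bounds_error=False,
                fill_value=None,
            )
        else:
            self._interp = None

    def __call__(self, query: np.ndarray) -> np.ndarray:
        if self._interp is None:
            return self.values.reshape(-1)
        q = [np.clip(query[i], self.axes[i][0], self.axes[i][-1]) for i in self._active]
        return self._interp(np.array(q))[0]


@dataclass
class MMLibrary:
    """Cached orientation-averaged Mueller-matrix pairs on parameter grids."""

    optics_template: OpticalParams
    config: LibraryConfig
    normal_interp: _GridInterp = field(repr=False)
    echino_interp: _GridInterp = field(repr=False)

    def mm_pair(
        self,
        class_name: str,
        diameter: float,
        index_re: float,
        amp_frac: float | None = None,
        morph_t: float = 0.0,
    ) -> MuellerMatrixPair:
        """Interpolated (normal/echinocyte) or exact-Mie (spherocyte) pair."""
        if class_name == "spherocyte" or morph_t == 1.0:
            k = self.optics_template.k_medium
            return mie_mm_pair(MieInput(x=k * diameter / 2.0, m=index_re + self.optics_template.m_rel.imag * 1j))
        if class_name == "normal":
            if morph_t != 0.0:
                raise ValueError("library backend covers morph_t of 0 (disc) or 1 (sphere) only")
            return _unpack(self.normal_interp(np.array([diameter, index_re])))
        if class_name == "echinocyte":
            if amp_frac is None:
                raise ValueError("echinocyte lookup needs a spicule amplitude fraction")
            return _unpack(self.echino_interp(np.array([diameter, amp_frac, index_re])))
        raise ValueError(f"unknown class {class_name!r}")


def _library_orientations_full(n: int, rng: np.random.Generator) -> list[EulerOrientation]:
    return [
        EulerOrientation(
            alpha=float(rng.uniform(0, 360)),
            beta=float(rng.uniform(0, 180)),
            gamma=float(rng.uniform(0, 360)),
        )
        for _ in range(n)
    ]


def build_library(
    config: LibraryConfig = LibraryConfig(),
    optics: OpticalParams = OpticalParams(),
    progress: bool = False,
) -> MMLibrary:
    """Run the DDA over the library parameter grids (the slow step).

    Normal cells are axisymmetric, so orientation averaging samples the tilt
    angle only; echinocytes are fully asymmetric and use full-space Euler
    samples.  The same seeded orientations are reused across grid points so
    that interpolation differences reflect the physics, not the sampling.
    """
    rng = np.random.default_rng(config.seed)
    ori_normal = sample_axisymmetric(config.normal_orientations, seed=int(rng.integers(2**31)))
    ori_echino = _library_orientations_full(config.echino_orientations, rng)
    spicule_seed = int(rng.integers(2**31))

    nd, ni = len(config.normal_diameters), len(config.normal_indices)
    normal_vals = np.empty((nd, ni, 34))
    for a, d in enumerate(config.normal_diameters):
        for b, mre in enumerate(config.normal_indices):
            opt = replace(optics, m_rel=mre + optics.m_rel.imag * 1j)
            shape = morph_shape(BiconcaveParams.from_diameter(d), 0.0)
            pair, _ = simulate_mm(shape, opt, orientations=ori_normal, tol=config.tol)
            normal_vals[a, b] = _pack(pair)
            if progress:  # pragma: no cover
                print(f"library normal d={d} m={mre} done")

    ne_d, ne_a, ne_i = (
        len(config.echino_diameters),
        len(config.echino_amp_fracs),
        len(config.echino_indices),
    )
    echino_vals = np.empty((ne_d, ne_a, ne_i, 34))
    for a, d in enumerate(config.echino_diameters):
        for b, frac in enumerate(config.echino_amp_fracs):
            shape = make_spiculated(
                SpiculeSpec(
                    base_diameter=d,
                    amplitude=frac * d,
                    n_spicules=config.n_spicules,
                    seed=spicule_seed,
                )
            )
            for c, mre in enumerate(config.echino_indices):
                opt = replace(optics, m_rel=mre + optics.m_rel.imag * 1j)
                pair, _ = simulate_mm(shape, opt, orientations=ori_echino, tol=config.tol)
                echino_vals[a, b, c] = _pack(pair)
                if progress:  # pragma: no cover
                    print(f"library echino d={d} amp={frac} m={mre} done")

    return MMLibrary(
        optics_template=optics,
        config=config,
        normal_interp=_GridInterp(
            [np.array(config.normal_diameters), np.array(config.normal_indices)], normal_vals
        ),
        echino_interp=_GridInterp(
            [
                np.array(config.echino_diameters),
                np.array(config.echino_amp_fracs),
                np.array(config.echino_indices),
            ],
            echino_vals,
        ),
    )


# ----------------------------------------------------------------- generator

def _truncated_normal(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    return np.clip(rng.normal(mean, sd, size=size), lo, hi)


def generate_population(
    spec: PopulationSpec,
    library: MMLibrary | None = None,
    optics: OpticalParams = OpticalParams(),
    backend: str = "library",
    orientations: list[EulerOrientation] | None = None,
) -> pd.DataFrame:
    """Synthesize one labeled population as a DataFrame.

    Columns: sampled cell parameters (``d``, ``m_re``, ``aux`` = morph t or
    spicule amplitude fraction), the 30 normalized Mueller features with
    additive Gaussian noise, the six PFPs computed from the noisy matrices,
    and ``label``.  Fully seeded: identical spec gives identical records.
    """
    if backend == "library" and spec.class_name != "spherocyte" and spec.morph_t not in (0.0, 1.0):
        raise ValueError("library backend supports morph_t 0 or 1; use backend='dda'")
    if backend == "library" and library is None and spec.class_name != "spherocyte" and spec.morph_t != 1.0:
        raise ValueError(f"class {spec.class_name!r} needs a built MMLibrary")
    rng = np.random.default_rng(spec.seed)
    d_lo, d_hi = 0.05, np.inf
    m_lo, m_hi = 1.0 + 1e-6, np.inf
    diams = _truncated_normal(rng, spec.diameter_mean, spec.diameter_sd, d_lo, d_hi, spec.n_cells)
    idxs = _truncated_normal(rng, spec.index_mean, spec.index_sd, m_lo, m_hi, spec.n_cells)
    if spec.spicule_amplitude_range is not None:
        lo, hi = spec.spicule_amplitude_range
        amps = rng.uniform(lo, hi, size=spec.n_cells) if hi > lo else np.full(spec.n_cells, lo)
    else:
        amps = np.full(spec.n_cells, np.nan)

    rows = []
    for i in range(spec.n_cells):
        d, mre = float(diams[i]), float(idxs[i])
        amp = None if np.isnan(amps[i]) else float(amps[i])
        if backend == "library":
            lib = library if library is not None else _MIE_ONLY_LIBRARY(optics)
            pair = lib.mm_pair(spec.class_name, d, mre, amp_frac=amp, morph_t=spec.morph_t)
        elif backend == "dda":
            pair = _dda_pair(spec, d, mre, amp, optics, orientations)
        else:
            raise ValueError(f"unknown backend {backend!r}")
        feats = pair_to_features(pair)
        if spec.mm_noise_sd > 0:
            feats = feats + rng.normal(scale=spec.mm_noise_sd, size=feats.shape)
        noisy_pair = features_to_pair(
            feats, pair.m11_forward_ratio60, pair.m11_forward_ratio120
        )
        pfps = pfp_vector(noisy_pair).as_array()
        rows.append([d, mre, amp if amp is not None else spec.morph_t, *feats, *pfps])

    df = pd.DataFrame(rows, columns=["d", "m_re", "aux", *MM_FEATURE_NAMES, *PFP_NAMES])
    df["label"] = spec.class_name
    return df


def _MIE_ONLY_LIBRARY(optics: OpticalParams) -> MMLibrary:
    """Placeholder library that can only answer sphere (Mie) queries."""
    empty = _GridInterp([np.array([0.0])], np.full((1, 34), np.nan))
    return MMLibrary(
        optics_template=optics, config=LibraryConfig(), normal_interp=empty, echino_interp=empty
    )


def _dda_pair(spec, d, mre, amp, optics, orientations) -> MuellerMatrixPair:
    opt = replace(optics, m_rel=mre + optics.m_rel.imag * 1j)
    if spec.class_name == "echinocyte":
        shape = make_spiculated(
            SpiculeSpec(
                base_diameter=d,
                amplitude=(amp if amp is not None else 0.075) * d,
                n_spicules=spec.n_spicules,
                seed=spec.seed,
            )
        )
    else:
        shape = morph_shape(BiconcaveParams.from_diameter(d), spec.morph_t)
    pair, _ = simulate_mm(shape, opt, orientations=orientations)
    return pair


def build_mixture(
    mix: MixtureSpec,
    library: MMLibrary | None = None,
    class_specs: dict[str, PopulationSpec] | None = None,
    optics: OpticalParams = OpticalParams(),
) -> tuple[pd.DataFrame, np.ndarray]:
    """Mixed suspension at the requested ratios, labels hidden.

    Per-class counts are a seeded multinomial draw at the nominal ratios;
    the returned truth vector holds the *realized* fractions in CLASS_ORDER.
    Records are shuffled; the feature frame carries no label column.
    """
    rng = np.random.default_rng(mix.seed)
    counts = rng.multinomial(mix.total_n, np.asarray(mix.ratios, dtype=float))
    frames = []
    for cls, count in zip(CLASS_ORDER, counts):
        if count == 0:
            continue
        base = (class_specs or {}).get(cls, class_preset(cls))
        spec = replace(base, n_cells=int(count), seed=int(rng.integers(2**31)))
        frames.append(generate_population(spec, library=library, optics=optics))
    df = pd.concat(frames, ignore_index=True)
    df = df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    truth = counts / counts.sum()
    return df.drop(columns=["label"]), truth
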
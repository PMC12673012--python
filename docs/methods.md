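# Methods

`rbcsim` models the measurement chain of a dual-angle Mueller-matrix flow
polarimeter for single red blood cells (RBCs): cell geometry, electromagnetic
scattering, feature extraction, the instrument's Stokes/Mueller algebra, and
proportion estimation for mixed suspensions. This note records the models,
the parameter choices and their rationale, the numerical decisions, and what
the synthetic data do and do not establish.

## Cell geometry

A normal RBC (discocyte) is the implicit quartic surface

    f(r, z) = r^4 + 2 S r^2 z^2 + z^4 + P r^2 + Q z^2 + R = 0,

with `r` the cylindrical radius and `z` the symmetry axis (lengths in um).
The four coefficients are determined by four morphometric lengths — diameter
`d`, central thickness `b`, maximum thickness `h` on the ring of diameter
`c` — through four conditions: the surface passes through `(d/2, 0)`,
`(0, b/2)` and `(c/2, h/2)`, and the thickness is extremal at `c/2`
(`df/dr = 0` there). These conditions are *linear* in `(S, P, Q, R)`, so the
system is solved directly and verified by back-substitution (residuals
< 1e-8). Default ratios `b/d = 0.18`, `c/d = 0.62`, `h/d = 0.35`. The region
`f <= 0` is "inside"; this sign convention is fixed here because the quartic
itself is sign-ambiguous, and the exact sphere — where the quartic
degenerates to the perfect square `(r^2 + z^2 - rho^2)^2` and carries no
sign information — is always represented by a dedicated sphere predicate
rather than by the quartic.

**Sphere morph.** `morph_shape(p, t)` interpolates `b/d` and `h/d` linearly
toward their common mean (raising the dimple, flattening the rim) and then
rescales the shape isotropically so the enclosed volume — hence the
equivalent diameter `(6V/pi)^(1/3)` — is conserved; the volume of the
quartic region is computed by radial quadrature of the closed-form
z-thickness. `t = 1` returns the equal-volume sphere exactly.

**Spiculated cells (echinocytes).** A base sphere unioned with `n` cones on
seeded random surface directions; each cone rises `amplitude` above the
surface and tapers to the sphere over an angular half-width (default 15
degrees). The physiologically described amplitude range is d/20-d/10. Spicule
count (default 20) and half-width are exposed configuration, since only the
amplitude range is constrained by observation. Identical seeds give
bit-identical shapes.

## Dipole discretization and the DDA solver

Shapes are voxelized on a cubic lattice of pitch `d_s` with the centroid on
a lattice-cell centre; the default pitch satisfies `|m k d_s| = 0.45`
(`k` the wavenumber in the medium), the standard accuracy/cost compromise
for the dipole approximation. By default each boundary cell is probed on a
4x4x4 sub-grid and kept with its fractional occupancy `f_j`; the dipole
polarizability is scaled by `f_j` (weighted discretization). This smooths
the surface staircase and is what brings ratio elements at the collection
angles from ~0.02 to ~2e-3 agreement with Mie theory; plain centre-inside
voxelization remains available (`supersample=1`).

The coupled-dipole system

    P_j / alpha_j  -  sum_{k != j} G(r_j - r_k) P_k  =  E_inc(r_j)

uses the free-space dyadic Green tensor and the lattice-dispersion-relation
(LDR) polarizability with radiative-reaction term (Clausius-Mossotti
available as an option). The matrix-vector product is a block-Toeplitz
convolution evaluated with FFTs on the doubled bounding cuboid; BiCGSTAB
with a Jacobi (diagonal) preconditioner solves to relative residual 1e-5 by
default. The preconditioner matters: fractional-occupancy cells spread the
diagonal and otherwise triple-to-tenfold the iteration count. Dense-matrix
assembly is retained for small grids as the correctness oracle (FFT and
dense paths agree to 1e-10 on 6^3 grids).

Far fields are coherent phase-weighted sums of dipole radiation projected on
the scattering-plane basis (`e_perp = unit(n x d)`, `e_par = v x e_perp` for
each direction `v`), yielding the 2x2 amplitude matrix; the Mueller matrix
follows from the coherency-space similarity transform `A (S kron S*) A^-1`,
which is exactly the textbook bilinear element set.

**Orientation averaging.** The lab geometry is fixed (beam along +z,
detectors at 60 and 120 degrees in the x-z plane); the *cell* is rotated by
z-y-z Euler angles. Internally the incident wave and detector directions are
rotated into the body frame instead, so the FFT kernel is built once per
grid. Raw Mueller matrices are averaged over orientations first and
normalized afterwards (each matrix by its own M11; M11 itself reported
relative to its forward value), matching what an ensemble of pulses
measures. Axisymmetric cells sample the tilt `beta` (30 samples by default,
uniform in angle); fully asymmetric cells sample all three angles (5 values
per angle, 125 orientations). One deliberate departure from the minimal
beta-only convention: the azimuth `alpha` of the tilted axis around the beam
is randomized as well. With `alpha` pinned at 0 the symmetry axis never
leaves the scattering plane, every orientation is mirror-symmetric about
that plane, and the averaged matrix degenerates to the sphere-like block
form (`M22 = M11` exactly, so the shape parameter K1 would be identically
zero for *any* axisymmetric cell — contradicting the premise that K1
separates discs from spheres). Randomizing the azimuth restores the physics
of a stirred suspension; `random_azimuth=False` recovers the in-plane
convention.

## Validation against Mie theory

The validation metric (module `rbcsim.validation`) compares a DDA sphere
with the Mie series at the equal-volume radius and reports the maximum of
(a) element-wise deviation of *forward-normalized* matrices
`M(theta)/M11(0)` over 0-180 degrees, and (b) deviation of the per-angle
M11-ratio elements at 60 and 120 degrees, the quantities every feature
parameter consumes. The ratio elements are deliberately not compared at
every angle: a cell-like sphere (m ~ 1.05, x ~ 9) has interference nulls in
M11 more than three decades below the forward intensity, where a 0.01
agreement of ratio elements would require raw far-field accuracy near 1e-6
of forward — below the solver residual itself and below any volume
discretization at `|mkd_s| = 0.45` (measured convergence of the
all-angle ratio metric is roughly first order: 0.083 / 0.038 / 0.020 under
successive 2x refinements). At such nulls the ratio comparison measures
conditioning, not solver quality. At the 1 um / m = 1.053 validation point
the package measures deviations of ~3e-4 (forward-normalized) and ~5e-3
(collection-angle ratios), i.e. a headline deviation of ~0.005.

## Polarization feature parameters

From the M11-normalized pair at 60/120 degrees:

    K1   = (1 - M22_60) / (1 + M12_60)      shape (0 for spheres)
    K2   = M14_60 / (1 + M14_60)            shape (0 for spheres)
    LE60 = (M12_60 + M21_60) / 2            composite size/shape
    LE120= (M12_120 + M21_120) / 2          surface spiculation
    T60  = (M33_60 + M44_60) / 2            refractive index
    T120 = (-M22_120 + M33_120 + M44_120)/3 size

All features are evaluated on M11-normalized matrices (the printed forms
assume M11 = 1). Denominator poles (`1 + M12 -> 0`, `1 + M14 -> 0`) raise an
explicit error; values are never silently clamped.

## Instrument model

The four-quadrant analyzer maps channel voltages to Stokes components via
`I = s0 + s90`, `Q = s0 - s90`, `U = 2 s45 - s0 - s90`,
`V = s0 + s90 - 2 sL`; the synthetic-signal generator inverts this exactly
(`s0 = (I+Q)/2`, `s45 = (I+U)/2`, `s90 = (I-Q)/2`, `sL = (I-V)/2`) and adds
seeded Gaussian voltage noise, making the zero-noise round trip bit-exact.
Mueller recovery from incident/scattered Stokes collections uses the
Moore-Penrose pseudoinverse (least squares for more than four states); the
default probing sequence is the six cardinal states H, V, +-45, R, L, chosen
for conditioning — the number of states per measurement is configurable.
The microsphere calibration model `MM_r = Mp . MM_m - Ms` is fitted by joint
linear least squares over the 32 unknowns from two or more standards (one
standard leaves 16 equations for 32 unknowns and is rejected); recovery of
synthetic error models is exact to 1e-8, which is the correctness contract
since no closed-form estimator is prescribed.

## Synthetic populations and the desk-scale regime

Full-size RBCs (5-9 um) need 1e6-1e7 dipoles per orientation — GPU
territory. This package's simulations run at a reduced "desk scale" with
diameters around 0.5-0.7 um (~4e3-2e4 dipoles, seconds per orientation on
one CPU). The three cell classes mirror the stress physiology directionally:

* `normal` — biconcave disc, d = 0.60 +- 0.03 um, m = 1.053 +- 0.002;
* `spherocyte` (hypotonic / acidic swelling) — equal-volume sphere,
  d = 0.66 +- 0.03 um, m = 1.041 (hemoglobin dilution at ~+30% volume);
* `echinocyte` (oxidative / hypertonic / alkaline spiculation) — spiculated
  sphere, amplitude uniform over d/20-d/10.

Population variability is Gaussian in diameter and index (diameter CV ~5%,
index sd 0.002, both truncated), uniform in spicule amplitude; measurement
noise is additive Gaussian (sd 0.01) on every normalized Mueller element.
These spreads are package choices in the absence of published population
numbers and are recorded in the generated records.

Per-cell matrices come from one of two backends: exact DDA, or a cached
library — orientation-averaged DDA solutions on a small parameter grid
(3 diameters x 3 indices for discs; 2 diameters x 2 amplitudes x 2 indices
for echinocytes; 3-4 orientations per point) with multilinear interpolation
and clamping at the grid edges. Spherocytes are exact spheres and always use
the Mie series directly. Mixtures draw per-class counts from a seeded
multinomial at the nominal ratios; the reported truth is the realized
composition.

What the generator does *not* emulate: each real detected pulse measures a
single cell in a single orientation, whereas synthetic records carry the
orientation-*averaged* matrix of that cell plus noise — within-class spread
from orientation is therefore folded into the additive noise term rather
than resolved. It also ignores pulse-shape, gain and triggering effects. At
desk scale the anisotropy signal is weak: orientation-averaged K1 stays
below ~0.004 at any CPU-affordable size (it is a full-scale discriminator),
so class separation here rides on the size- and index-sensitive features
(T120, T60, LE60) and on spiculation breaking reciprocity symmetry.
Passing tests therefore demonstrate that the pipeline — simulation,
features, classifier, scoring — is correct and consistent at reduced scale,
not that the published full-scale feature distributions are reproduced.

## Classification and mixture scoring

The classifier is a standard random forest (Gini splits, bootstrap
resampling, sqrt-feature subsets, unlimited depth, majority vote;
scikit-learn implementation) over either the 30 normalized Mueller elements
(15 non-M11 elements per angle; M11 is normalization only, never a
predictor) or the 6 PFPs. Out-of-bag accuracy drives tree-count selection:
the smallest count within 0.002 of the scanned maximum (the plateau rule;
the count is data-dependent, so no fixed value is asserted). Mixture
proportions are predicted-label frequencies by default (probability
averaging is available), scored by the absolute error
`AE = sum_i |T_i - P_i|` in [0, 2]. The benchmark trains on 3 x 2000
synthetic records and evaluates the five studied volume ratios
(spherocyte : echinocyte : normal = 0.25:0.25:0.5, 0.3:0.2:0.5, 0.1:0.5:0.4,
0.4:0.4:0.2, 0.2:0.3:0.5) with 600 cells per mixture; at the default
settings both feature modes recover compositions with AE well below 0.10.
The published experimental errors (maximum AE 5.2% / 6.1%) belong to
measured mouse-RBC data and are not reproducible from synthetic records;
the benchmark establishes pipeline correctness, not those numbers.

## Numerical choices and degenerate inputs

* Mie series: logarithmic-derivative downward recurrence, Wiscombe
  truncation `x + 4 x^(1/3) + 2`; size parameters above 2e4 are rejected.
* `b = h` (no concavity) is rejected at parameter construction — the
  thickness-extremum constraint is degenerate there.
* Empty dipole grids, rank-deficient Stokes sets, under-determined
  calibrations, single-class training sets and empty test sets raise typed
  errors naming the defect.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical seeds give bit-identical shapes,
  populations and mixtures.
* Boundary points count as inside; sphere predicates carry a 1e-12 relative
  slack so exact lattice ties are kept regardless of rounding.

## Known limitations

* Desk-scale only: absolute feature values are not those of 5-9 um cells;
  trends are verified at reduced scale (see above).
* Homogeneous-index cells (no membrane/cytoplasm layering), as in the
  underlying optical model.
* The cached library trades orientation count and grid density for speed;
  its interpolation error is part of the synthetic noise budget.
* No GPU path; full-scale runs are out of scope by design.
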
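# Methods

`aeroscatter` predicts full solid-angle, dual-polarization radar cross
sections (RCS) of airborne organisms from 3-D body models with a single
homogenized complex permittivity, and emulates the measurement and
radar-sampling chains used to validate such predictions.  This note
records the model, the numerical choices, and what the packaged
synthetic studies do and do not demonstrate.

## Scattering model

The scatterer is a dielectric body with relative permittivity
ε = ε′ − jε″ (engineering e^{+jωt} time convention; lossy means ε″ > 0).
The default material is the body-averaged tissue value for a Brazilian
free-tailed bat at X band, ε_r = 29.29 − j12.89 (refractive index
m ≈ 5.54 − j1.16).  Homogenization deliberately avoids internal
dielectric boundaries: wings are a 1-mm skin of the same material as the
torso.

The solver is a volume method of moments in the coupled-dipole
(discrete-dipole) formulation: the body is voxelized onto a cubic
lattice of pitch d, each cell carries a dipole moment
P_i = α_i E_i, and the exciting field at each cell is the incident
plane wave plus the re-radiated fields of all other cells through the
free-space dyadic Green function.  This is exact in the limit d → 0 and
handles arbitrary inhomogeneous dielectrics; it is validated against the
Mie series (the analytic solution for spheres) rather than against any
particular surface-integral implementation.

Backscatter amplitudes are assembled by coherent phase-weighted
summation of the converged moments; the normalization is
σ_pq = 4π|S_pq|², identical to the Mie module's σ_b = 4π|S(180°)|²/k²,
so oracle and solver are directly comparable.

### Discretization accuracy at high contrast

|m| ≈ 5.7 makes this a hard regime for coupled-dipole methods: with the
textbook Clausius–Mossotti + lattice-dispersion-relation polarizability
and point-dipole interactions, sphere backscatter errors at
|m|kd = 0.5 range from −11% to −31% against Mie.  Three refinements are
used, each a standard idea, combined here because the Mie convergence
study showed they carry the error budget:

1. **Boundary-cell volume fractions.**  Cells straddling the surface
   carry the fraction f of their volume inside the body (4³ subsampling,
   exact z-integration for meshes) and an arithmetically mixed
   permittivity ε_cell = f·ε + (1 − f).  This removes most of the
   staircase shape error.  (Maxwell-Garnett mixing was tried and is
   worse at this contrast.)
2. **Integrated near-field interactions.**  For cell pairs within a
   Chebyshev radius of 2 cells, the Green dyadic is averaged over the
   source cell (8³ Gauss–Legendre quadrature) instead of evaluated at
   its center.  Beyond that radius the cell average differs from the
   center value by O((kd)²/24), which is negligible.  This also improves
   the conditioning of the linear system markedly (2–8× fewer Krylov
   iterations).
3. **Integrated self-term (`icd` polarizability, the default).**  The
   inverse polarizability is 1/α = 1/α_CM − M/d³, where M is the
   numerically integrated dynamic part of the Green dyadic over the
   cell's own cube.  M contains the radiative-reaction term and the real
   O((kd)²) self-shift consistently with refinement 2.  The classical
   `cm`, `cm_rr` and `ldr` models remain available as configuration
   switches.

With this scheme, tissue-permittivity spheres with size parameters
x ∈ {0.5, 1, 1.66, 2} match Mie backscatter within 10% at lattice
spacings satisfying |m|kd ≤ 0.5, with errors decreasing under
refinement.  Two cases need finer-than-maximal spacing inside that
bound: x = 0.5 (|m|kd = 0.35), whose ~11-cell diameter makes the result
sensitive to grid registration parity, and x = 1.66 (|m|kd = 0.25),
which sits near a backscatter interference null where relative error is
amplified and convergence in d is slowest.  The
spacings used by the acceptance checks come from this convergence study.

### Linear algebra

The lattice's translational structure makes the interaction matrix
block-Toeplitz; matrix-vector products are evaluated with zero-padded
3-D FFTs and the system is solved with BiCGStab, warm-started from the
previous look angle during sweeps.  The system is Jacobi
right-preconditioned with diag(α): boundary cells with small volume
fractions have α → 0, and the resulting spread of the bare diagonal
otherwise cripples Krylov convergence (representative thin-winged
bodies needed thousands of matrix products without it, under a hundred
with it; right preconditioning leaves the reported residual the true
one).  An LGMRES retry catches residual stagnation.  Systems with ≤ 2 000 dipoles use a
dense LU factorization instead (cached across excitations, bitwise
reproducible under the fixed site ordering); the threshold is set by the
~58 GB a dense matrix would need at the next decade of sizes.  Default
relative residual: 1e-5 for single solves, 1e-3 for pattern sweeps, and
1e-2 for the coarse pilot studies — at 1e-2 the induced σ error is
≈ 0.1 dB, far below the pilot comparison band of ±2 dB.  A
single-precision FFT path (`precision="single"`) halves the cost of the
large sweeps; its ~1e-7 convolution error is negligible against the
iterative tolerance.

### Geometry and registration

A site belongs to the lattice iff its center is inside the surface
(winding-parity along vertical columns for meshes; the analytic
inequality for ellipsoids), with the optional boundary fractions above.
Grids are registered symmetrically about the body's bounding-box center
(equivalent to "bounding-box minimum + d/2" whenever the box is an
integer number of pitches); this keeps mirror-symmetric bodies on
mirror-symmetric lattices, which the sweep code can exploit: for a
centered axis-aligned ellipsoid, σ(φ) = σ(−φ) = σ(180° − φ) holds
exactly (the first by the C₂ rotation about the anteroposterior axis,
the second by the transverse mirror), so only the 0–90° quadrant needs
solving.  The symmetry itself is verified on honest full-circle solves
in the test suite.

## Look geometry and polarimetry

Coordinates: x = anteroposterior (nose → +x), y = lateral, z =
dorsoventral.  Azimuth 0° is head-on and increases clockwise seen from
above.  The scan circle starts in the horizontal (x–y) plane and is
rigidly rotated about the anteroposterior axis by the plane tilt; the
polarization basis does **not** co-rotate: ĥ = (k̂ × ẑ)/|k̂ × ẑ| and
v̂ = k̂ × ĥ at every azimuth (backscatter alignment; the same basis on
receive, under which reciprocity reads S_HV = S_VH).  The tilt of the
measurement plane relative to the plane swept by the horizontal
polarization was geometrically underdetermined in the source material;
both readings were implemented, and the fixed-basis reading reproduces
the published ellipsoid sector table (the co-rotating alternative puts
the head-on HH sector ≈ 2.7 dB low).  This empirical disambiguation is
the package's resolution of that open question.

Derived radar quantities: σ → dBsm as 10·log10(σ/1 m²); differential
RCS 10·log10(σ_HH/σ_VV); simultaneous-transmit (SHV) differential RCS
10·log10(|S_HH + S_HV|²/|S_VV + S_VH|²), which reduces to the plain
ratio when cross-pol vanishes and reproduces the characteristic
asymmetry of simultaneous-transmit radars otherwise.  The emulation
chain clips to ±8 dB (receiver dynamic range) and applies a ±15°
wrapped median filter (heading spread in an ensemble of animals); sector
statistics use half-open 90° windows (head-on = [−45°, 45°), side-on,
tail-on, plus the implied fourth sector) computed on linear σ, with
dB values derived from the unrounded linear aggregates.  σ = 0 is
floored at 1e-10 m² before dB conversion in pattern-level helpers.

## Mie reference

The Mie module implements the standard series with the logarithmic-
derivative downward recurrence for dielectric (including lossy) spheres
and the PEC limit of the coefficients for conducting spheres; truncation
at N = ⌈x + 4x^{1/3} + 2⌉.  Backscatter is computed from the
alternating series for S(180°), with an independent internal route
through the π_n/τ_n angular functions agreeing to ~1e-10 — two code
paths to the same number, in the spirit of calibrating one reference
method against another.  Verified limits: Rayleigh (dielectric and
9x⁴πa² PEC), geometric optics (πa²), energy conservation
(Q_ext = Q_sca for real m to 1e-10).

## Synthetic controlled measurement

The calibration module generates stepped-frequency network-analyzer
sweeps of point-target scenes: each target contributes g·√σ·e^{−j2kR}
per channel, plus circular complex Gaussian noise at a configurable
floor (−103 dBm default), with repeats for temporal averaging.
Processing mirrors standard RCS practice: coherent 10-sample averaging,
inverse-DFT range profile (rectangular window by default, Hann
optional), a 15-cm range gate at the target, substitution calibration
against a 15.82-mm conducting sphere whose true RCS comes from the Mie
module, and a cross-polar isolation check.  The alias-free range
relation c/(2Δf) reproduces the 267-m limit at a 0.561-MHz step.

What the fixture does *not* emulate: antenna patterns, absolute power
levels (only ratios matter in substitution calibration), range-dependent
attenuation (absorbed into the calibration constant), target extent, and
instrument drift.  Passing the round trip (recovery of an injected σ
within 5% at 30 dB SNR) therefore validates the processing chain, not
any particular instrument.

## Packaged studies and their scales

* **Equivalent-ellipsoid pilot** (10 GHz, 35° plane): the published
  50 × 23.12 × 15.8 mm ellipsoid at d = 0.8 mm (|m|kd ≈ 0.95, inside
  the hard limit but in the warned regime) with 10° azimuth steps,
  mirror-completed quadrant, single precision, 1e-2 residual — about
  3 minutes on one CPU.  Sector and full-circle means land within
  ±2 dB of the published table; the head-on sectors (deep pattern
  minima) carry the largest deviation, which shrinks under refinement.
  The ±1 dB full-resolution target (d ≈ 0.4 mm, 1–2° steps) is an
  overnight computation and is not exercised by the default suite.
* **Size-ratio study**: the toy organism (bat-torso ellipsoid plus two
  tangent wing plates, span 0.08 m, chord 0.025 m, thickness 1 mm)
  against its *own* equivalent ellipsoid — the ellipsoid spanning the
  toy's anteroposterior, lateral (wing-tip-to-wing-tip) and
  dorsoventral extents — at λ/bodylength ratios 1, 2, 4, 8, on a fixed
  1-mm lattice with 30° steps and H polarization only.  The wings are
  the same scattering tissue as the body, so the equivalent body must
  include their lateral extent; only electrically transparent
  appendages may be omitted from an equivalent ellipsoid.  The
  correlation r rises monotonically from negative values in the
  resonance region toward 1 past the equivalence point, reproducing the
  size-ratio rule qualitatively; the exact crossing depends on the
  appendage geometry, and the exact published similarity curves require
  the unpublished anatomical mesh and are out of reach by construction.
* **Toy organism**: a fixture, not an anatomical model.  Its value is
  that it has the two features that drive the physics — a resonant-size
  homogeneous torso and electrically thin wings — while remaining
  parametric, watertight and mirror-symmetric by construction.  The
  default wing dimensions are body-scale, emulating the partially
  folded pose of a suspended specimen; much larger spans keep the wings
  electrically resonant far beyond the torso's Rayleigh transition
  (tip-to-tip span, not body length, then sets the electrical size), a
  regime in which no torso-sized surrogate can succeed and the
  size-ratio analysis loses its meaning.

## Known limitations

* Accuracy at |m|kd near 1 (the pilot regime) is qualitative (±1–2 dB);
  quantitative work should stay at |m|kd ≤ 0.5.
* Single scalar permittivity per site set; no frequency-dispersive
  (Debye/Cole–Cole) materials — frequency sweeps accept per-frequency
  material tables instead.
* Backscatter only on reception (full solid-angle incidence, no
  bistatic reception); no surface-integral formulation; no GPU path.
* The measured-specimen values of the original study (its bat
  correlations and absolute RCS) depend on the physical specimen and
  field data and are not reproducible computationally; they are quoted
  only as context in `aeroscatter.reference`.
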
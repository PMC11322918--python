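# Methods

This note documents the models, numerical choices and validation logic
behind `morphflow`. The package re-creates, in simulation and on synthetic
imagery, the computational layer of a microfluidic epithelial-morphogenesis
assay: interstitial flow and morphogen transport in a collagen-filled
tissue chamber, FRAP-based velocimetry, collagen fiber-alignment
quantification, and cyst shape/protrusion/curvature morphometrics.

## Device transport model

**Geometry.** The tissue chamber is a rectangular channel flanked by two
fluidic lines connected through a row of micropores. Two presets mirror
the two device designs: `aligned` (5 mm x 250 um, 20:1 length/width, which
shear-aligns collagen during loading) and `random` (1:1 square; side
length is a config field, 1 mm by default, since only the aspect ratio is
fixed by the design). The 100 um channel height is much smaller than the
width, so the chamber is modeled in 2-D plan view (depth-averaged); all
reported quantities are plan-view.

**Flow.** The hydrogel (2 mg/mL collagen I: porosity 0.99, permeability
k = 2e-13 m^2, perfused with water, mu = 1 cP, rho = 1000 kg/m^3) is a
Darcy medium: `v = -(k/mu) grad p`. The Brinkman correction is dropped —
at this permeability the viscous screening length sqrt(k) ~ 0.45 um is far
below the grid scale, so the Darcy limit is indistinguishable at any
resolvable resolution. Hydrostatic heads on the lines (2-20 mm H2O in the
assays) convert to pressure as `rho g h` with g = 9.80665 m/s^2 exactly.

The micropore row is not resolved: it is homogenized into an interface
permeance (Darcy flux per unit pressure difference, m^2 s/kg) acting in
series with the half-cell of gel behind the interface. `numpy.inf` gives a
transparent interface (Dirichlet line pressure). Because the pore CAD is a
device-specific detail, a calibration helper
(`calibrate_pore_conductance`) pins the permeance to a measured or target
chamber velocity at a reference head; the laminarity study calibrates it
so the chamber peaks at the physiological maximum of 20 um/s.

**Discretization.** Finite volume on a uniform staggered grid: pressures
and concentrations at cell centers, fluxes on faces. The pressure system
is solved directly (sparse LU), so the face fluxes conserve mass to
round-off — the suite checks `max |div v| h / max |v| < 1e-6` and the 1-D
slab limit against `v = k dP / (mu L)` to < 1e-6 relative. Linearity of
the Laplace problem makes velocities exactly proportional to the applied
head; doubling the head doubles every flux bit-exactly (scaling by powers
of two commutes with rounding).

**Transport.** Solute transport solves
`phi dc/dt + v . grad c = phi D lap c` with c = 1 held on the dosed line,
c = 0 on the plain line, and no-flux walls; D = 7e-11 m^2/s is 70 kDa
dextran, the gradient tracer used in the assays. Time stepping is
backward-Euler diffusion plus explicit first-order upwind advection — a
monotone pair, so concentrations respect the boundary range (discrete
maximum principle, checked to 1e-9). The user step is auto-subdivided to
0.4x the explicit advective CFL bound; passing `auto_substep=False` makes
a violating step an error that prints the bound. The steady state is
solved directly as the sparse linear system of the same spatial operators.
Accuracy: transient pure-diffusion profiles match the eigenfunction-series
solution to < 1% L2 (relative to the steady profile norm) over
[0, 3 L^2/D] at the default 50-cell/2-s resolution.

**Gradient metrics.** The assays report "time to gradient formation"
without a quantitative criterion, so it is operationalized (and exposed as
a parameter): the gradient counts as formed at the first output time whose
length-averaged cross-chamber profile is everywhere within a tolerance
(default 10% of the steady contrast) of the steady profile, and maintained
if it stays within tolerance through 24 h. A flat steady profile (both
lines at the same concentration) is flagged as a degenerate zero gradient
rather than an error. Under this model the zero-flow aligned chamber forms
its gradient in ~0.25 h (diffusion time L^2/D ~ 15 min for L = 250 um).
The multi-hour formation times reported for the physical devices fold in
transport through the fluidic lines and pores and an unstated visual
criterion; those are device-level effects outside the homogenized chamber
model, so the solver is validated against closed forms rather than against
wall-clock device times.

**Laminarity.** Re = rho |v| W / mu and Pe = |v| W / D with W the chamber
width, reported as maxima over the grid plus per-node maps. At 20 um/s,
Re = 5e-3 and Pe ~ 71: creeping flow, advection-competitive transport.

## FRAP velocimetry

A 30 um spot is bleached and imaged every 0.5 s for 15 s. Each frame is
segmented for the dark spot — intensity inverted, Otsu threshold
(overridable), 3x3 median despeckle, largest connected component, with an
area sanity window of [0.25x, 4x] the nominal spot area; failing frames
are flagged invalid, never fatal. The centroid is bleach-depth weighted
(weight = intensity deficit inside the mask; a binary centroid is a
toggle). Velocity comes from least-squares slopes of x(t) and y(t) over
all valid frames rather than a first/last displacement — with per-frame
centroid noise sigma_c, the regression estimator's variance falls as
~1/n^3 in the number of frames instead of 1/2. The pooled R^2 of the two
fits and the number of frames used are reported for QC.

Image rows are stored top-down; every reported position and direction uses
mathematical conventions (y up, degrees counter-clockwise from +x),
converted once at the module boundary.

Recovery under the study conditions (shot + read noise, diffusive recovery
with the spot amplitude following the closed-form 2-D diffusing-Gaussian
decay): median speed error well under 10% and direction error under 5
degrees for true speeds 2-20 um/s; zero-flow sequences give velocity
components whose 95% CIs cover zero (no drift bias from the symmetric
recovery).

## Fiber orientation and the alignment coefficient

Per-pixel orientation comes from the structure tensor: Gaussian-derivative
gradients (scale 1 px) accumulated under a Gaussian window (scale 1.5 px).
Pixels keep their orientation estimate when the tensor energy (trace)
exceeds the 75th percentile of nonzero energies and the coherence
`(lam1 - lam2)/(lam1 + lam2)` exceeds 0.2; the fiber direction is the
minor eigenvector (perpendicular to the dominant gradient) and the weight
is the coherence. The window scale is deliberately small: wider windows
mix neighboring fibers and bias isotropic images toward spurious
alignment (measured on the synthetic fixtures when tuning the default).

The alignment coefficient of a weighted axial sample is the resultant
length of the doubled angles,

    R = | sum_j w_j exp(2 i theta_j) | / sum_j w_j,

with the mean orientation at half the resultant argument. R = 1 iff all
angles coincide mod 180; an isotropic sample gives R -> 0. For angles
drawn from a von Mises distribution on doubled angles with concentration
kappa, E[R] -> I1(kappa)/I0(kappa), which the Monte-Carlo test verifies to
0.01 at n = 1e5. Histograms use half-open 10-degree bins on [0, 180) (an
input of exactly 180 wraps to 0), and directional fractions (e.g. the
70-110 degree band of the aligned devices) are weighted fractions.

On rendered fiber images (400 anti-aliased segments of 30-60 px on a
384 px canvas, Poisson + Gaussian noise) the pipeline scores highly
aligned fields (kappa = 12) above 0.9 and isotropic fields below 0.15 —
the same qualitative contrast the two device geometries produce, without
asserting the devices' absolute values, which depend on real collagen
texture.

## Cyst morphometrics

Z-projections are binarized (Otsu unless overridden), hole-filled, reduced
to the largest component, and contoured at the 0.5 level with subpixel
(marching-squares) interpolation. All metrics use standard ellipse-fit
definitions, stated here because the assays name the metrics without
formulas:

* best-fit ellipse from second central moments of the mask (a 1/12 pixel
  variance term corrects for the finite pixel footprint);
* aspect ratio = major/minor; orientation = major-axis angle in [0, 180);
* roundness = 4A/(pi major^2) (equals b/a for a true ellipse);
* shape factor = circularity = 4 pi A / P^2, with the perimeter from the
  Crofton estimator (accurate on smooth digital shapes, unlike naive
  contour-segment sums).

A rasterized 50 um circle returns all three dimensionless metrics within
2% of 1 and mean curvature within 3% of 1/r at 1 um/px.

**Protrusions.** The automated detector computes the radial profile
r(phi) from the centroid, subtracts the fitted-ellipse radius (otherwise
an elongated cyst's axis ends register as false peaks), and finds peaks
with a prominence threshold in um and a minimum angular separation. For
non-star-shaped contours (non-monotone winding angle) it falls back to
peaks of the radius over a heavily smoothed hull along the contour, noted
in the output. A manual mode accepts user-supplied tip coordinates
verbatim, preserving the interactive workflow of the original assays.
Protrusion angles are measured from the centroid against the horizontal
axis and folded into the closed range [0, 180] (tips below the axis fold
up; exactly 180 stays 180, and the protrusion histogram's last bin is
closed accordingly). On 200 seeded cysts carrying 1-3 protrusions of
12-18 um prominence, detection at an 8 um threshold — between the ruffle
/discretization floor (< 5 um) and the smallest true protrusion — yields
median angle error ~1.4 degrees and F1 ~0.98.

**Halves and curvature ratio.** The contour is cut by the horizontal line
through the centroid; "top" is the half facing the dosed line (higher
morphogen concentration). A ruffled boundary can cross the line more than
twice, so each half is a set of open arcs; arcs split at the contour's
starting seam are re-merged first. Curvature is computed on a cubic
smoothing spline (periodic for closed contours, clamped for arcs) as
`kappa = |x'y'' - y'x''| / (x'^2 + y'^2)^(3/2)`, sampled at uniform arc
length; the "overall curvature" of a half is the unweighted mean of the
samples, with samples allocated across arcs proportionally to arc length
(arc-length weighting is therefore implicit; switching to unweighted
per-arc means is a one-line change). Two numerical guards matter:

* the spline smoothing parameter is the RMS deviation the fit may take
  from the points, default 0.3 um — small enough to preserve 8 um ruffles
  in the 8-16 harmonic band, large enough to suppress marching-squares
  jitter (chosen so the rasterized 50 um circle returns 1/r within 3%);
* 5% of samples at each open end are discarded, because a clamped
  spline's second derivative is unreliable at its ends and halves that
  were cut into more arcs would otherwise be biased low.

With these, a circle's top/bottom ratio is 1.000, symmetric ruffled
populations average within [0.9, 1.1], and top-only ruffling (8 um RMS)
drives the ratio above 1 in every tested seed (median ~5) — the property
the assays read as gradient-biased ruffling. A numerically flat bottom
half makes the ratio undefined (NaN), not infinite.

**Tie-breaks and conventions.** A protrusion tip exactly on the split
line counts as top. Masks are stored row-down; contours, centroids and
angles are converted to mathematical conventions once, on extraction.

## Synthetic data generators

Each analysis stage has a seeded generator producing ground-truthed
inputs; identical (seed, parameters) give bit-identical arrays, and truths
are returned as dicts (JSON sidecars when written to disk).

* **Fibers** — anti-aliased line segments; axial angles from a von Mises
  on doubled angles (kappa = 0 uniform, inf a point mass). Defaults (400
  fibers, 30-60 px, 384 px canvas) keep the per-image sampling noise of
  the true alignment coefficient small enough that isotropic images stay
  below 0.15.
* **FRAP** — Gaussian bleach profile (sigma0 = diameter/4) on a uniform
  field, center advected at the true velocity, amplitude decaying as
  `sigma0^2/(sigma0^2 + 2 D t)` — the exact advection-diffusion solution,
  so the generator needs no PDE solve. Frames auto-size to keep the whole
  track in view. Dye diffusivity defaults to 10 um^2/s so the spot
  substantially recovers within the 15 s window, as real dextran does.
* **Cysts** — polar boundary r(phi) = ellipse + Gaussian bumps at known
  protrusion directions + band-limited random ruffles (harmonics 8-16,
  i.e. ~25-60 um wavelength on a 60 um cyst) whose RMS amplitude blends
  smoothly between independent top and bottom values; rasterized to a
  mask.
* **Gradient scenes** — solver concentration stacks rendered to noisy
  intensity frames for profile-extraction tests.

Noise everywhere is Poisson shot noise (via a photon-scale parameter)
plus additive Gaussian read noise; real confocal noise is uncharacterized
in the assays, so these are generic microscope statistics. What the
generators deliberately do *not* emulate: real collagen texture (fiber
crossings and curvature), optical PSF and defocus, bleaching during
acquisition, cell-body internal structure. Passing the recovery tests
therefore demonstrates correctness of the estimators under the assumed
image-formation model, not robustness to every artifact of real
microscopy; absolute values measured on real images (e.g. the devices'
alignment coefficients) are not asserted anywhere.

## Pipeline and reporting

Batch runs are driven by a validated config (stage blocks, inputs,
parameters, output directory, seed); outputs are self-describing (config
echo, version, data dictionary) and one corrupt input becomes an error
row, never an aborted batch. Group summaries report n, mean and SEM
(sample SD / sqrt(n); single-member groups get NaN and a flag) — the
reporting convention of the assays. Hypothesis testing (t-tests, ANOVA)
is deliberately not re-implemented; the tidy CSVs feed standard tools
directly.

The bundled demo (`morphflow demo`, `analysis/05_demo_and_summary.py`)
regenerates the figure-level readout set on synthetic data and is
bit-reproducible for a fixed seed; the test suite compares a fresh run
against committed reference tables with a 1e-6 relative tolerance (exact
hashes are asserted only for same-session reruns, since the last floating
bit may legitimately differ across BLAS builds).

## Problem sizes

Validation studies run at sizes chosen to estimate each quantity with
comfortable margin: 200 seeded FRAP sequences per speed (100 in the
acceptance script's sweep) and per morphometric study, 1e5 angles for the
Monte-Carlo/Bessel check, 50-cell transport grids with 2 s steps for the
series comparison, and 100 + 50 cysts for the directional/symmetric
ruffling populations.

## Known limitations

* The transport model is chamber-only; line/pore transport and reservoir
  depletion are folded into boundary conditions, so device-level gradient
  formation times are not comparable to the simulated ones.
* Structure-tensor orientation saturates (R > 0.95) for strongly aligned
  images — it compresses differences between kappa = 12 and kappa = inf.
* The radial protrusion detector assumes a roughly star-shaped boundary;
  the hull fallback handles the rest but with coarser angle estimates.
* Curvature ratios on heavily protruded shapes depend on the smoothing
  scale; the default is tuned for 1 um/px imagery and should be rescaled
  (in um) for very different resolutions.
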
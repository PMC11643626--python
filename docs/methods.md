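# Methods

This note records the models, parameter choices and numerical decisions
behind `ccsflow`, in the order the flow pipeline runs, followed by the
single-particle, AFM and FRAP components and the synthetic-data
generators used to validate them.

## Drift correction

Mechanical drift moves the whole cell relative to the camera; internal
flow vectors are meaningless until it is removed. Registration is
translation-only — the minimal model for centre-of-mass drift of a cell
whose interior is itself moving — estimated per frame against a reference
frame by phase correlation with upsampled-DFT sub-pixel refinement
(`skimage.registration.phase_cross_correlation`, plain cross-correlation
normalization, upsample factor 50 ≈ 0.02 px resolution). Shifts are
applied by bilinear interpolation with zero fill at the edges; an all-zero
frame cannot be registered and is passed through with a warning. The
drift table stores each frame's drift *relative to the reference* (the
negative of the corrective shift).

A caveat discovered while building the sub-pixel oracle: phase
correlation on a small non-periodic texture that was shifted by spline
interpolation with edge padding is biased by up to ~0.3 px — an artefact
of the fixture's broken periodicity, not of the estimator. The test
fixture therefore uses an exact Fourier shift.

## Static-background intensity correction

Punctate clathrin movies carry a bright stationary pool (immobile
patches, free protein). Because stationary intensity dominates windowed
cross-correlation at zero lag, it biases PIV toward zero flow. Writing
I0 = S + M (static S, moving M), subtracting the pixel-wise temporal mean
and clipping at zero,

    Ic(i,j,k) = max(0, I0(i,j,k) − Imean(i,j)),

removes S exactly and retains ≈ (N−1)/N of M (exactly (N−1)/N for a pixel
lit in a single frame of N). The correction degrades when dynamics are
slow enough that a pixel stays lit for many frames; for puncta moving by
more than their own footprint per frame the spatial pattern is preserved
essentially rank-for-rank. Two numerical details: intensities are
processed in float regardless of input bit depth, and rounding residue
below 16 ε · Imean is clipped to zero so that a temporally constant movie
maps to *exactly* zero (the float mean of identical values can be off by
an ulp). The mean frame is computed on the drift-corrected stack, in that
order.

## PIV

Multipass FFT cross-correlation with window offsetting:

* **Pass schedule** 512 → 128 → 64 px at 50% overlap. The first and final
  sizes are the published protocol for these movies; the intermediate is
  a geometric-style step and is configurable. A first window larger than
  the frame is shrunk to the largest power of two that fits (warning).
  The final window must be ≥ 16 px. An actin preset maps a 0.5 µm source
  box and 1.0 µm search box onto windows at the movie's calibration.
* **Correlation.** Windows are mean-subtracted and correlated by
  zero-padded (linear) FFT cross-correlation, divided by the per-lag
  overlap area. Both choices matter: circular correlation wraps content
  and biased edge windows by up to 0.7 px, and without the overlap
  normalization the triangular envelope pulls peaks toward zero lag.
  Displacements beyond a quarter window are rejected as implausible.
* **Sub-pixel peak** by a 3-point Gaussian fit per axis, falling back to
  parabolic when a neighbour is non-positive. Peaks on the correlation
  border are rejected (vector invalid).
* **Seeding.** Later passes offset the search window by the rounded
  earlier-pass displacement, interpolated onto the finer grid; when the
  search window would leave the frame, the reference window shifts the
  other way so the full offset is kept. Optional full bilinear image
  deformation between passes is available (`deform=True`) but per-window
  offsetting is the default.
* **Masking.** Vectors whose window centre falls outside the analysis
  mask are invalid and are never filled by interpolation. Windows with no
  texture (zero variance) are invalid, never silently zero.

**Post-processing**, per frame-pair field, in order: (1) invalidate
vectors deviating from the field mean by > 4 SD per component;
(2) invalidate vectors whose residual to the 3×3 neighbourhood median
exceeds 4 px/frame (plus an epsilon floor of 1e−6 — the plain-residual
variant of the median test); (3) fill invalidated vectors inside the mask
by Laplace (spring) interpolation with valid vectors as Dirichlet data,
refused with a warning when fewer than 4 valid vectors exist; (4) one
pass of 3×3 uniform smoothing.

**Time averaging.** Under the steady-state assumption the per-pair fields
are averaged arithmetically per grid point over the whole movie, each
point using only the pairs where it was valid, and requiring ≥ 50% valid
pairs for the averaged vector to count as valid.

## Cell mask and centre

If no mask is supplied, one is built from the time-maximum projection:
Otsu threshold, removal of connected components below 9 px (noise specks;
a diffraction-limited punctum covers ~25 px at σ = 1.5 px), then the
convex hull — the cell is assumed roughly convex, and the projection of
the moving puncta fills its footprint. The cell centre is the
intensity-weighted centroid of the masked maximum projection.

## Radial profile and direction histogram

With the field translated to the centre, the radial and tangential
components are Vr = Vx cos θ + Vy sin θ and Vθ = −Vx sin θ + Vy cos θ.
Vr is stored signed (inward negative); summary plots show |Vr| to match
the conventional "radial speed" axis. Vectors are assigned to annuli of
Δr = 60 px (≈ 0.5–1.2 µm at typical calibrations) by discrete membership;
empty annuli carry NaN, never zero. The profile also records the mean
radius of the vectors in each annulus: within an annulus the vector
density grows with r, so the bin midpoint is a biased abscissa (~10%
slope error on a linear ramp at small radii) while the mean radius is
exact for linear profiles. The centre point itself (r = 0) is excluded —
the radial direction is undefined there. A circular-cell assumption is
retained throughout; annuli are not contour-following.

The direction variable θdir = θv − θ is reported in degrees on a full
circle with 24 bins by default. Bins are aligned so that the canonical
directions 0°/90°/180°/270° fall at bin *centres* (first edge at −7.5°):
a pure radial or circular flow otherwise lands exactly on a bin edge and
the modal bin is decided by float rounding. Vectors are unweighted;
zero-magnitude vectors are excluded (no defined direction).

The pipeline's histogram pools θdir over all per-pair post-processed
fields rather than using the time-averaged field. For directed flow the
two agree (every pair points the same way). For a stalled cell they do
not: the time-averaged field holds only ~10² near-zero vectors whose
noise directions are spatially correlated by the smoothing step, so its
histogram shows spurious clumps; pooling (~10⁴ angles, noise independent
across pairs) is the statistically meaningful estimator of breadth.
`direction_histogram` on a single field remains available.

## Tracking, kymographs

Spots are detected per frame by a scale-matched Laplacian of Gaussian at
a single user scale (default σ = 1.5 px) with a relative threshold
(default 0.2 of the response maximum), refined by an intensity centroid
on a 5×5 patch. Linking is greedy one-to-one nearest neighbour within a
maximum displacement (default 5 px/frame), ties broken by smaller
displacement then lower index; optional gap closing over `memory` frames
widens the search radius proportionally. Trajectories shorter than 3
frames are excluded from velocity statistics (noise guard). The mean
instantaneous velocity is the mean over consecutive intervals of step
length divided by the frame interval; radial displacement series are
r(t) − r(0), negative inward. Kymographs sample intensity at 1 px spacing
along a line, mean-aggregated across a default width of 3 perpendicular
pixels; rows are time.

PIV and tracking deliberately disagree in a known direction: windowed
correlation averages over window content and so its peak radial speed
stays at or below the true (and the tracked) particle speed; the tests
assert this ordering near the membrane, where Vr(r) peaks.

## AFM nanoindentation

Approach curves only are analysed. Channels already in metres (or volts
with a detector sensitivity in nm/V) give F = k·d_cant and
δ = d_pz − d_cant. The contact point is found by splitting the curve at
every candidate index — flat baseline before (after linear detrend of the
pre-contact region), Sneddon indentation after — and minimizing the
combined squared residual, with a coarse scan (~50 candidates) plus
exhaustive local refinement; a golden-section search was rejected because
the objective is not reliably unimodal on noisy curves. A curve that
never rises ≥ 5 noise SDs above its baseline raises a "no contact" error.

The Sneddon rigid-sphere pair F(a), δ(a) is evaluated exactly; δ → a is
inverted by bracketed root finding on [0, R) to 1e−10 relative tolerance
(δ(a) diverges as a → R, so max_depth < R is enforced). Because F is
linear in E, the modulus fit at fixed (R, ν) is closed-form least
squares over δ ∈ [0, 500 nm] (the depth cells are deformed to), requiring
≥ 10 in-range samples. Inside the contact-point search the unit-modulus
shape g(δ) is interpolated from a 4096-node (a → δ, F) table — the
interpolation error is orders of magnitude below force noise — while the
final fit uses the exact inversion. Defaults: R = 2.5 µm (5 µm glass
bead), ν = 0.5 (incompressible cell; reported with every fit), k = 0.2
N/m typical. A cell measured on a 6×6 grid is summarized by the median of
its converged curve fits. For δ ≤ 0.01 R the pair reduces to the Hertz
sphere form (4/3)·E/(1−ν²)·√R·δ^{3/2}, which the tests use as an
independent closed-form check.

## FRAP

Double normalization divides the background-subtracted ROI by the
background-subtracted whole-cell reference — cancelling acquisition
photobleaching — and scales the pre-bleach mean to 1; single
normalization (no reference) is selectable. Recovery is fit by
I(t) = I0 + A(1 − e^{−t/τ}) on the post-bleach frames (≥ 10 required)
with `scipy.optimize.curve_fit`, amplitude bounded non-negative. Mobile
fraction = A/(1 − I0), clamped to [0, 1] with out-of-range raw values
flagged; t½ = τ ln 2. Non-convergence returns a flagged result with NaN
estimates rather than raising. Acquisition defaults mirror the emulated
experiment: 15 pre-bleach frames and 50 post-bleach frames at 5.66 s.

## Synthetic data: what it emulates and what it does not

The movie generator renders diffraction-limited puncta as isotropic 2D
Gaussians (σ = 1.5 px) at ground-truth positions advected by an analytic
flow model (centripetal, circular, stalled, uniform, zero), over a flat
background with Poisson shot noise on the photon-scaled intensities
(Gaussian read noise and whole-field exponential photobleaching are
optional, off by default). Defaults emulate the imaging conditions of the
emulated experiments: 512×512 px at 0.021 µm/px, 60 frames at 5 s
(5 minutes), ~100 mobile puncta with 30% of particles static, peak
amplitude 200 photons over a background of 10 — an SNR at which
localization error is ~0.05 px. The centripetal default speed profile
ramps linearly from 0 at the centre to the membrane speed at the cell
radius (the fastest radial flow is at the membrane); a constant-speed
variant and arbitrary speed-vs-radius callables are supported. Stalled
structures get 0.2 px/frame positional jitter. Every generator draws all
randomness from one `numpy.random.default_rng(seed)`; the same seed is
bit-reproducible. Ground-truth tracks obey the update rule exactly
(jitter included, pixel noise not).

Not modelled: 3D optics, camera gain/offset, pit maturation kinetics
(puncta neither appear nor disappear), non-convex cells, spatially
varying background. Puncta density and intensity are free parameters —
the emulated study reports neither — so passing tests demonstrate
estimator correctness under these conditions, not performance on any
particular instrument's data.

The AFM generator samples deformations uniformly to max_depth, inverts
δ → a exactly, and adds Gaussian force noise through the deflection
channel so F = k·d_cant and δ = d_pz − d_cant stay mutually consistent;
the pre-contact baseline is flat over the contact offset. The FRAP
generator produces raw ROI/reference/background channels from a known
mobile fraction, recovery time and bleach depth, with optional shared
acquisition-bleaching decay.

## Problem sizes in the tests

The session-scoped validation movies are 512×512 × 60 frames with 140
particles (the default imaging conditions above); the PIV
window-halving stability check uses 600 particles over 40 frames so that
the finer 32-px grid is well sampled (≥ ~5 puncta per window, the
standard PIV seeding guideline — at ~100 puncta the 32-px grid is
under-sampled and profiles differ by ~7% rather than < 5%). The AFM
noise study uses 50 curves of ~600 samples. The acceptance script runs
one full-size movie pipeline (~20 s) plus an exact correction null.

## Known limitations

* Sub-pixel PIV peaks show mild peak locking (~0.1–0.2 px) on smooth
  textures; integer displacements are recovered to machine precision.
* PIV overestimates speed magnitudes in sparsely seeded interior regions
  (noise magnitude survives time averaging; smoothing mixes faster outer
  vectors inward) while matching the true speed near the membrane.
* The intensity correction attenuates slow-moving structures (pixels lit
  over many frames), as inherent to mean-frame subtraction.
* Tracking is greedy nearest-neighbour: adequate at the densities used
  here, not a substitute for LAP/Kalman linking in crowded scenes.
* The AFM model is purely elastic; viscoelastic response, adhesion and
  retract-segment analysis are out of scope.
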
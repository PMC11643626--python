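# ccsflow

Quantification of clathrin-coated-structure (CCS) and cortical actin flow
in live-cell fluorescence movies, together with AFM nanoindentation
analysis and FRAP normalization — the measurement toolkit behind studies of
how intracellular transport stalls when cells express aggregating proteins
(e.g. pathogenic Huntingtin polyQ or TDP-43 in *Drosophila* hemocytes).

## Who this is for

Cell biologists and biophysicists with:

* time-lapse movies of punctate fluorescence (GFP-tagged clathrin light
  chain, actin) who want the collective flow field, its radial profile and
  its directionality;
* AFM approach force curves from bead-functionalized cantilevers who want
  a Young's modulus per cell;
* FRAP traces who want mobile fractions and recovery half-times.

A seeded synthetic-data module generates movies, force curves and FRAP
traces with known ground truth, so the whole chain is testable end to end
without any raw data.

## The measurements

**Flow pipeline.** Movies are drift-corrected by phase-correlation
registration, then the static fluorescence pool is removed by mean-frame
subtraction with clipping,

```
Ic(i,j,k) = max(0, I0(i,j,k) − Imean(i,j)),   Imean = (1/N) Σ_l I0(i,j,l),
```

which cancels stationary intensity exactly and keeps ≈ (N−1)/N of the
moving component. The velocity field v(x, y) per frame pair comes from
multipass FFT cross-correlation PIV (windows 512 → 128 → 64 px, 50%
overlap, 3-point Gaussian sub-pixel peak), post-processed by a global
4-SD filter, a local 3×3 median filter, Laplace interpolation of rejected
vectors and one pass of 3×3 smoothing. The steady-state field
V(x, y) = ⟨v(x, y, k)⟩ is then quantified in polar coordinates about the
cell centre:

* radial speed profile `Vr(r) = ⟨Vx cos θ + Vy sin θ⟩` averaged over
  annuli of Δr = 60 px (negative = inward);
* direction histogram `P(θdir)`, `θdir = θv − θ`: centripetal flow peaks
  at 180°, circular flow at ±90°, stalled cells give a broad distribution.

**Tracking.** Laplacian-of-Gaussian spot detection with sub-pixel centroid
refinement, greedy nearest-neighbour linking, per-CCS mean instantaneous
velocity (mean step length per frame interval), signed radial displacement
series, and kymographs.

**AFM.** Force `F = k·d_cant` and deformation `δ = d_pz − d_cant` from the
raw channels; contact point by a baseline/indentation split search; then a
least-squares fit of the Sneddon rigid-sphere model

```
F(a) = E/(1−ν²) [ (a² + R²)/2 · ln((R+a)/(R−a)) − aR ],
δ(a) = a/2 · ln((R+a)/(R−a)),
```

with bead radius R (default 2.5 µm) and Poisson ratio ν (default 0.5)
fixed, over δ ≤ 500 nm. F is linear in E, so the fit is closed-form.

**FRAP.** Double normalization (background-subtracted ROI over
background-subtracted reference, scaled to unit pre-bleach mean) and a
single-exponential recovery fit giving the mobile fraction and t½.

## Worked example

```python
import ccsflow as cf

# a 5-minute movie (60 frames, 5 s apart) of ~100 puncta advected inward
model = cf.FlowModel("centripetal", (256, 256), speed=cf.linear_ramp(0.5, 230))
movie, truth = cf.generate_ccs_movie(model, n_particles=143, static_fraction=0.3,
                                     n_frames=60, shape=(512, 512), seed=1,
                                     cell_radius=230)
result = cf.run_flow_pipeline(cf.PipelineConfig(seed=1), movie=movie)
print(result.histogram.modal_bin_center_deg)   # 180.0
print(result.profile.vr_um_s)
```

prints a modal direction of **180.0°** — the centripetal signature — and a
radial speed profile that is inward everywhere and fastest near the
membrane:

```
r =  0.80 um   Vr = -0.00048 um/s   (10 vectors)
r =  1.92 um   Vr = -0.00103 um/s   (33 vectors)
r =  3.18 um   Vr = -0.00156 um/s   (57 vectors)
r =  4.20 um   Vr = -0.00184 um/s   (44 vectors)
```

The |Vr| ≈ 0.002 µm/s scale near the membrane sits below the imposed
particle speed (0.5 px/frame ≈ 0.0021 µm/s), as expected for a windowed
correlation estimate. The same API covers the other assays:

```python
curve, _ = cf.generate_force_curve(E=1200.0, R=2.5e-6, nu=0.5, k=0.2, seed=1)
cf.analyze_curve(curve).E_Pa          # 1200.0  (Pa)

trace, _ = cf.generate_frap_trace(mobile_fraction=0.6, tau=10.0, noise_sd=0.01, seed=1)
fit = cf.analyze_trace(trace)
fit.mobile_fraction, fit.t_half_s     # (0.595, 7.0 s)
```

A CLI mirrors the library: `ccsflow simulate-movie | simulate-afm |
simulate-frap | flow | quantify | track | kymo | afm-fit | frap`.

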
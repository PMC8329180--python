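# Methods

This note documents the models and numerical choices behind `ccflow`: what
the synthetic perfusion generator simulates (and does not), how each
processing stage is defined, and how the frozen default configuration was
calibrated.

## 1. Perfusion model

The choriocapillaris is treated as a thin, homogeneous 2-D porous sheet.
Feeding arterioles and draining venules pierce it at points; they are
placed by seeded rejection sampling, uniformly over the field with all
pairwise distances at least `min_spacing_um` (default 300 µm). Arterioles
carry strength +1 each; venule strengths are −n_arterioles/n_venules so
total inflow balances outflow exactly — the Neumann problem below is
solvable only for a flux-balanced source term.

**Pressure.** The pressure field solves the discrete Poisson equation

    ∇²p = −s,    s = Σ q_i δ(x − x_i) / (pixel area)

with a standard 5-point Laplacian and zero-flux (Neumann) boundaries,
each vessel collapsed to its nearest pixel. The system is singular up to
an additive constant; one node is pinned during the sparse LU solve (its
equation is implied by the others, since rows and right-hand side both
sum to zero) and the zero-mean gauge is applied afterwards. Pressure units
are arbitrary; only gradients matter.

**Velocity and transit.** Darcy flow: v = −µ ∇p, with the mobility µ
(mm/s per pressure-gradient unit, default 0.55) the single knob converting
the dimensionless solve into seconds. Every pixel is traced backward along
the flow to its source by discrete steepest ascent on pressure over the
8-neighbour graph; by the maximum principle the ascent terminates at an
arteriole pixel, which defines basin `ownership`. Transit time accumulates
hop by hop as hop length over the mid-hop speed (floored at 10⁻⁶ mm/s to
avoid division blow-up exactly on stagnation lines). Pixels near basin
boundaries lie close to stagnation separatrices, so their transit times
are naturally the longest — these are the slow inter-lobule zones, which
are regions *furthest from arterioles*, not structures around venules.

The ground-truth slow-zone mask marks pixels whose transit time is in the
top 20 % of their 31-pixel neighbourhood (a local rank, so large and small
basins contribute equally).

**Dye filling.** Transport is modelled by arrival-time composition rather
than an advection PDE: it is unconditionally stable, fast, and reproduces
the centre-outward filling of each unit exactly. A pixel's arrival is

    arrival(x) = delay · |x_arteriole(owner) − x_disc| + transit(x),

i.e. a per-arteriole onset growing linearly with distance from the optic
disc centre (the peripapillary-to-peripheral wave; `delay` = 1.0 s/mm by
default, disc 1 mm beyond the nasal border) plus the within-basin transit.
Intensity at time t is

    I(x, t) = B + A · env(s(x) · (t − arrival(x))) · m(t) + ε,

with background B = 8, amplitude A = 190, seeded Gaussian noise ε
(σ = 0.7), quantised to 8 bits.

- `env` is a gamma(2)-CDF fill ramp times an exponential washout,
  `env(τ) = [1 − (1 + 2τ/t_p) e^(−2τ/t_p)] · e^(−τ/τ_w)` (t_p = 2.0 s,
  τ_w = 30 s). A two-parameter gamma-variate *density* cannot provide both
  a resolvable rise and a near-plateau washout (its shape parameter
  degenerates and the rise becomes a step); the CDF form decouples the
  two, and the long washout reproduces the near-steady fluorescence of
  recirculating dye.
- `s(x) = t_p / (t_p + g · transit(x))` is transit-time dispersion
  (g = 3.5): the local filling ramp stretches with the time the dye took
  to get there, so lobule cores snap on while slow zones brighten faintly
  and gradually — exactly how the inter-unit zones appear in subtracted
  angiograms. g = 0 recovers the pure arrival-composition model.
- `m(t) = 1 + d · e^(−t/τ_m) · cos(2πt/T)` is the cardiac modulation
  (depth d = 0.7, decay τ_m = 4.5 s, period T = 1.0 s): every perfused
  pixel pulses in phase, re-brightening filled lobules for a few beats
  before flow settles.

**What the generator does and does not emulate.** It reproduces the
macro-scale filling phenomenology: radial onset wave, arteriole-centred
units, last-to-fill inter-unit zones, pulsatile refilling, and a uniform
(structureless) OCTA mesh texture. It does **not** model the capillary
network itself (no discrete capillaries in the angiography branch, no
flow-void statistics), eye motion during the video (frames are born
registered; jitter is injected only in the OCTA repeat sets), depth
structure (Sattler/Haller layers), light scattering, or dye leakage.
Passing tests therefore validate the *processing chain* against a
controlled hemodynamic model, not against device physics.

## 2. Subtraction angiography

`run_subtraction_pipeline` = subtract → clip/remap → smooth:

1. `out[i] = in[i+1] − in[i]` in float64, so the telescoping identity
   Σ out = last − first is exact.
2. Negatives are clipped to zero by default: a darkening pixel means "no
   new dye", and only increases are displayed (a `signed` mode is kept for
   diagnostics). One **global** linear map then stretches the whole stack
   onto [0, 255] with round-half-up; a constant stack maps to zeros.
   Global (not per-frame) scope preserves inter-frame brightness
   comparability, which the pulsatility analysis needs; per-frame remap is
   available behind a flag.
3. Separable Gaussian, the same σ on t, y and x, reflect boundaries. The
   reference protocol's "radius of 0.7 pixels" is interpreted as
   σ = 0.7 px (the convention of the originating software is ambiguous);
   the value is configurable.

## 3. Registration

Three successive approximations, each optional on top of the previous:

- **Rigid**: translation by phase correlation (20× upsampled), rotation by
  phase correlation of log-polar-resampled Fourier magnitudes (720 angular
  bins, 10× upsampling). The magnitude spectrum is π-periodic, so θ and
  θ−180° are tried and the candidate with the higher masked correlation
  wins; ambiguity is logged. Transforms are stored in the resampling
  convention (fixed → moving coordinates = the motion of the moving
  content), making recovered and ground-truth jitters directly comparable.
- **Affine**: 6-parameter intensity least squares (mean-squares metric,
  regular 25 % pixel subsample — deterministic — multi-resolution 4/2/1,
  regular-step gradient descent), initialised at the rigid estimate.
- **B-spline**: cubic free-form deformation with 32 px control spacing,
  same metric, L-BFGS-B. Control displacements above a bound (10 px) are
  rejected as divergence.

Each stage keeps its result only if the masked mean-squared difference did
not increase; otherwise the previous transform is retained and the chain
is flagged unconverged — the objective history is monotone by
construction. Resampling is bilinear; pixels mapping outside the moving
image are marked invalid, never filled. `register_stack` intersects the
valid masks and crops to a rectangle found by greedy border trimming
(shave the border line with the most invalid pixels until clean). For long
videos the `previous` reference policy composes frame-to-frame rigid
motions to track slow drift; repeat sets register directly to the first
frame. The affine-then-b-spline ordering is fixed and documented here; the
alternative (b-spline containing the affine) was not used.

## 4. OCTA branch

The en-face choriocapillaris texture is isotropically band-pass filtered
seeded noise (difference of Gaussians, σ = 0.8/2.6 px) thresholded at the
quantile matching the target bright fraction — a uniform meshwork with no
lobular boundaries, by construction. Repeat acquisitions get seeded rigid
jitter plus i.i.d. noise, with the true transforms recorded. Averaging is
a per-pixel float mean cast with round-half-up; with identity jitter the
residual noise of a 9-frame average follows σ/√9. Signal strengths are
carried as sidecar metadata and gated at ≥ 9 (never estimated from
pixels). Slab definitions (e.g. choriocapillaris 17–33 µm below the RPE)
are validated metadata only — slab extraction happens on the device. The
mesh-uniformity report combines the coefficient of variation of per-tile
bright densities with the fraction of spectral power below 0.04
cycles/px; a low fraction (< 0.25) flags "no dominant lobular structure".

## 5. Flow quantification

- **Arrival map**: first frame exceeding 10 % of the stack maximum;
  never-exceeding pixels get an `inf` sentinel and are excluded from all
  statistics.
- **Radial wave**: Spearman rank correlation between arrival time and
  Euclidean distance from the disc centre over detected pixels.
- **Units**: Otsu threshold → 8-connected components → discard components
  below 3 000 µm² (noise specks). The default configuration additionally
  enables marker-controlled watershed on the distance transform of the
  bright mask (markers = distance peaks ≥ 14 px apart), which cuts units
  joined through necks where the slow zone is locally too thin or faint to
  break pixel connectivity. Plain connected components remain the
  function's default.
- **Zone widths**: width at each medial-axis point of the dark network is
  twice the Euclidean distance to the nearest unit pixel, in µm. Only
  points lying *between two distinct units* count, where distinctness is
  judged on connectivity of the bright mask (so hairline watershed cuts do
  not register as zones) via the Voronoi partition of the gap space;
  field-border gaps flanked by a single unit are excluded. The medial-axis
  extraction is seeded — the library routine otherwise permutes its pixel
  order per call.
- **Cycles**: mean intensity of a peripapillary ROI over the subtracted
  stack; peaks with prominence ≥ 0.86 × trace maximum count as cycles
  (endpoints never count). The high prominence fraction deliberately
  counts only the strong early refills, matching how "observable" cycles
  are read off a trace by eye.
- **Fast/slow overlay**: two consecutive subtracted frames in red and
  blue channels, unblended — red cores (fast) ringed by blue perimeters
  (slow).

## 6. The frozen default configuration and its calibration

The defaults (3 × 3 mm, 256 × 256 → 11.72 µm/px, 25 + 25 vessels at
≥ 300 µm, disc at (−1.0, 1.5) mm, 15 fps × 10 s, T = 1.0 s, seed 42) are
the study conditions; the free physical knobs were calibrated **once**,
jointly, so that the frozen sequence reproduces the reported in-vivo
observations, and are not tuned per run:

| parameter | value | role |
|---|---|---|
| mobility µ | 0.55 mm/s | lobule cores fill in ≲ 1 s, zone tails take several |
| onset delay | 1.0 s/mm | radial wave: span and arrival–distance correlation |
| fill ramp t_p | 2.0 s | front thickness in subtracted frames |
| dispersion g | 3.5 | zones stay faint; units never merge mid-video |
| washout τ_w | 30 s | near-plateau ("steady flow goes dark" in differences) |
| modulation d, τ_m | 0.7, 4.5 s | a few strong refill flashes; late frames keep contrast |
| noise σ | 0.7 | visible speckle, arrival detection well above the clipped-noise pedestal |
| prominence | 0.86 | three countable cycles on the frozen trace |

With these values the frozen run measures: filling span 6.2 s (reported
5–10 s), zone-width 5th percentile 93.8 µm (reported 50–200 µm), three
pulsatile cycles, 28 detected units for 25 arterioles with 82 % holding
exactly one arteriole, radial ρ = 0.61. The point-wise zone-width median
(~290 µm) exceeds the reported inter-unit range because the full dark
network at the segmentation frame also contains unfilled far-field
pockets; the reported 50–200 µm describes the gaps between *adjacent*
units, which the 5th-percentile statistic targets.

## 7. Numerical conventions and degenerate inputs

- Pixel indices are 0-based, row-major, origin top-left; physical
  positions in mm from the field's top-left corner; pixel centres at
  (i + ½) · pitch.
- All integer casts round half up (`floor(x + 0.5)`), never banker's
  rounding.
- One top-level seed drives every stochastic stage through named CRC32
  substreams; identical seeds give bit-identical outputs (verified for the
  simulator, the subtraction pipeline and the full demo report).
- Degenerate inputs raise typed errors rather than returning silently:
  all-zero vessel strengths (singular solve), < 2 frames, constant images
  (registration and segmentation), empty quality-filter selections, empty
  zone masks, ROIs outside the frame.
- Test problem sizes: the analytic pressure comparison runs at 512²; the
  full-sequence analyses reuse one session-scoped 256² × 150-frame run;
  registration recovery uses 256² textures. The whole suite runs in about
  a minute on one CPU.

## 8. Known limitations

- The porous-sheet Laplace model has no capillary-scale discreteness; unit
  boundaries are smooth separatrices, and the simulated inter-unit zones
  are wider and cleaner than speckle-limited clinical data.
- Discrete 8-neighbour streamline tracing quantises basin boundaries to
  45° staircase segments at the pixel scale.
- The cardiac modulation is global and in-phase; real pulse waves
  propagate with finite speed and per-vessel phase.
- The dye video is generated pre-registered; motion correction of the
  angiography branch is exercised only through synthetic jitter in the
  OCTA repeats and through the CLI on externally supplied video.
- Cross-modality (dye-angiography ↔ OCTA) registration is deliberately
  out of scope; the two branches share a simulation but are never
  co-registered.
- Absolute flow is not quantified anywhere; all measurements are relative
  (arrival order, widths, counts, correlations).
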
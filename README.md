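# ccflow — choriocapillaris flow simulation and subtraction angiography

The choriocapillaris — the capillary sheet beneath the retinal pigment
epithelium that feeds the outer retina — fills with blood in discrete
*functional lobules*: each lobule fills outward from a central feeding
arteriole, and neighbouring lobules are separated by 50–200 µm wide
slow-flow zones that fill last. These units are purely hemodynamic: en-face
OCT angiography of the same tissue shows a uniform capillary meshwork with
no anatomical boundaries. The partition is set by the pressure gradients
between irregularly scattered arterioles and draining venules, not by
vessel walls.

`ccflow` is a research toolkit for studying this dynamic filling pattern at
desk scale. It provides:

- **A ground-truthed perfusion simulator** (`ccflow.synth`). Arterioles
  (point sources) and venules (point sinks) are scattered randomly with a
  minimum spacing; the pressure field solves the discrete Laplace equation
  with zero-flux boundaries; Darcy velocity is the negative pressure
  gradient; every pixel is assigned to the arteriole whose flow basin it
  lies in by backward streamline tracing, with a transit time accumulated
  along the path. An indocyanine-green-style dye bolus then fills the field:
  onset sweeps radially outward from the optic disc, each pixel ramps up
  with a dispersion-stretched fill envelope, and a decaying cardiac
  modulation re-brightens filled lobules for a few beats. Output is an
  8-bit video at 15 frames/s with pixel-exact ground truth (arrival map,
  basin ownership, slow-zone mask).
- **Digital subtraction angiography** (`ccflow.subtraction`): sequential
  frame differences (frame *i+1* − frame *i*), negatives clipped, one global
  remap onto the 8-bit histogram, 3-D Gaussian smoothing (σ = 0.7 px in
  *t, y, x*). The result shows only where fluorescence increased — the
  advancing dye front.
- **Three-step registration** (`ccflow.registration`): phase-correlation
  rigid alignment (log-polar rotation), intensity least-squares affine, and
  cubic b-spline free-form refinement, with non-overlap cropping — for
  angiography videos and OCTA repeat sets.
- **OCTA frame averaging** (`ccflow.octa_averaging`): signal-strength
  gating (≥ 9 of 10), registered 9-frame averaging (noise falls as √N),
  RGB plexus composition, and a mesh-uniformity statistic.
- **Flow quantification** (`ccflow.flow`): arrival-time maps, the Spearman
  correlation of arrival with distance from the disc (the radial wave),
  lobule segmentation (Otsu + connected components, optional watershed
  splitting of merged units), medial-axis slow-zone width statistics,
  red/blue fast–slow overlays and pulsatile cycle counting.

## Worked example

Run the full synthetic study — simulate, subtract, analyse, and process the
OCTA branch — with the frozen default configuration (3 × 3 mm field at
256 × 256, 25 arterioles + 25 venules ≥ 300 µm apart, 15 fps for 10 s,
1.0 s cardiac period, seed 42):

```bash
ccflow demo --out demo_out
```

which prints (abridged):

```json
{
  "filling_span_s": 6.2,
  "first_arrival_s": 1.53,
  "n_cycles": 3,
  "cycle_times_s": [3.8, 4.8, 5.8],
  "n_units": 28,
  "frac_units_single_arteriole": 0.82,
  "radial_spearman": 0.61,
  "zone_width_p5_um": 93.75,
  "zone_width_median_um": 291.8,
  "zone_width_p95_um": 650.7
}
```

Reading these numbers: the dye wave takes **6.2 s** from first appearance
to 95 % coverage (in vivo reports span 5–10 s); arrival time rank-correlates
with distance from the disc at **ρ = 0.61** (the wave is radial); the
maximal-contrast subtracted frame segments into **28 units** for 25 true
arterioles, **82 %** of them containing exactly one arteriole (the units
are arteriole-centred); the thin end of the inter-unit dark zones is
**94 µm** wide (reported range 50–200 µm; the point-wise median is larger
because the full dark network also includes unfilled far-field pockets);
and **3 pulsatile cycles** are detected before the flow settles.
`demo_out/` also receives the angiogram, the subtracted stack, the averaged
choriocapillaris slab, an RGB plexus stack, and summary figures
(`panels.png`, `pulsatility.png`).

The individual stages are available as subcommands
(`simulate | register | subtract | average | rgb | analyze`), e.g.

```bash
ccflow simulate --seed 42 --out angio.tiff --avi
ccflow subtract --input angio.tiff --sigma 0.7 --remap global --clip --out sub.tiff
ccflow analyze --sub sub.tiff --pitch-um 11.72 --out report.json
```

Input videos may be multi-page TIFF or uncompressed 8-bit AVI; compressed
codecs are rejected explicitly.

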
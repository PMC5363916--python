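# Methods

`callusmri` implements an in-vivo-MRI analysis of murine fracture-callus
composition — cortex-normalized signal-intensity thresholding into bone,
fibrous/marrow and cartilage classes — together with the reference
measurements it is judged against (μCT bone volume, 2D histomorphometry)
and the agreement statistics between methods.  Because no real scans ship
with the package, every analysis runs on seeded synthetic phantoms whose
ground truth is known exactly; this note describes the model, its
parameters, and the limits of what phantom results imply about real data.

## Tissue classification model

MRI magnitude intensities are first normalized by a mature-cortex reference
intensity, estimated as the **median** over a diaphyseal cortex mask
restricted to axial positions outside the callus volume of interest (VOI).
The median is robust to residual bright outliers near the fracture; the
axial exclusion keeps susceptibility-affected voxels out of the estimate.
Normalized voxels inside the VOI are then binned:

| normalized signal intensity | class |
|---|---|
| [0, 3.4) | bone (mature cortex + trabecular + bony callus) |
| [3.4, 5.5) | bone marrow / fibrous tissue |
| [5.5, 6.2] | cartilage |
| > 6.2 | unclassified (susceptibility artifacts) |

The working ranges behind these bins (1–3.3, 3.4–5.4, 5.5–6.2) are
one-decimal bin edges; the implementation uses contiguous half-open
intervals so every voxel receives exactly one class.  Values below 1 fold
into bone because mature cortex anchors the normalization at 1 and noise
spreads its distribution downward.  Values above 6.2 stay unclassified:
susceptibility artifacts at the fractured cortex ends are far brighter than
any tissue.  Classification is exactly scale-invariant: multiplying the raw
volume and the reference by any c > 0 changes no label.

The VOI is the open axial interval between the **inner edges of the two
inner fixator pins** (pin radius from configuration), containing every
non-background, non-pin voxel; pre-existing cortex is included in the bone
class for 3D bone volume (a flag excludes it for gap-callus-style
analyses).  2D metrics are measured on the two longitudinal slices whose
plane coordinates straddle the callus-mask centroid (ties break toward the
higher index; a callus thinner than two slices returns its single slice
twice with a warning) and are reported as the arithmetic mean of the two
slices.

An optional post-processing step relabels small cartilage-classified
26-connected components that touch the cortex ends as unclassified; it
targets artifacts that leak into the cartilage bin and leaves components
away from the cortex ends untouched regardless of size.

## Measurements

* **BV (mm³)** — bone-classified voxels inside the VOI × voxel volume.
* **TA (mm²)** — non-background pixels of a central slice × pixel area.
* **BA/TA, CA/TA, FA/TA (%)** — per-class pixel shares of TA.  Unclassified
  pixels count toward TA and are reported as a separate remainder, so the
  four fractions always sum to 100%.
* **μCT BV (mm³)** — voxels with calibrated mineral density ≥ 642 mg HA/cm³
  (inclusive threshold) inside the VOI.  Density calibration is the affine
  map fixed by two hydroxyapatite phantoms of known density (250 and
  750 mg/cm³).
* **Resolution ratios** — elementwise voxel-pitch ratios; for the default
  grids (52×52×350 μm MRI vs 8 μm μCT): 6.5× in-plane, 43.75× through-slice.

## Agreement statistics

Methods measured on the same specimens are compared with a two-sided
Student's t-test — paired by default, since both methods measure the same
femur; a pooled-variance unpaired mode sits behind a flag — and Pearson's
correlation with r² and a significance test from the exact transform
t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom.  α = 0.05, no
multiple-testing correction.  A zero-variance paired difference (identical
methods) is flagged as degenerate rather than silently producing a p-value.
`scipy.stats` provides the implementations; the test suite verifies them
against independently coded product-moment and incomplete-beta closed forms
to 1e-8.

## The phantom generator

Each phantom is one femur with a mid-shaft osteotomy under external
fixation, modeled as a body of revolution along the bore axis:
a cortical cylinder (outer radius 800 μm, wall 200 μm) interrupted by a
500 μm gap, marrow inside, four transverse fixator pins (radius 150 μm)
whose axial positions bound the VOI, and a fusiform callus (maximum radius
1400 μm) spanning 95% of the inter-pin interval.  Within the callus:

* **cartilage** is a central ellipsoidal lobe around the gap,
* **woven bone** is a peripheral shell (`r ≥ u·R(x)`) that thickens inward
  as its target fraction grows,
* **fibrous tissue** fills the remainder.

The shell boundary u and the lobe scale are solved by 1D quadrature over
the callus axis (the geometry is radially symmetric) plus bisection so the
continuum class-volume fractions equal the requested targets; the same
physical geometry is then rasterized independently on the 8 μm μCT grid and
the 52×52×350 μm MRI grid.  Fine-grid fractions match targets to well
within ±0.02; coarse-grid fractions carry a genuine voxelization error that
grows with voxel size — the mechanism behind the resolution-degradation
experiments.  Healing stage enters through the per-day default targets
(bone/cartilage/fibrous): day 10 → 10/16/74%, day 14 → 15/18/67%,
day 21 → 45/3/52%, mirroring reported histomorphometry magnitudes:
cartilage peaks early and nearly vanishes by day 21 while bone spreads
through the callus.

**Signal model.**  MRI intensities are drawn per class from disjoint
cortex-normalized intervals scaled by a raw cortex reference (default 50):
cortex [0.98, 1.02], bony callus [1.05, 3.35], marrow/fibrous [3.45, 5.45],
cartilage [5.52, 6.18], artifacts [6.8, 7.5].  The tissue intervals sit
0.05 inside their classification bins: the bins were defined from observed
tissue intensities, so tissue distributions should nearly fill them, and
the margin is what makes a *noise-free* phantom exactly recoverable while
letting realistic noise produce boundary misclassifications.  Within-bin
placement is otherwise a free parameter of the generator.  Corruptions, in
order: a linear coil-sensitivity ramp 1±amplitude along the bore axis
(default amplitude 0.1); bright ellipsoidal susceptibility blobs at the
four cortex-end corners of the gap (radius 150 μm, inflated to at least
half a voxel per axis and snapped to the nearest voxel centre so they
survive 350 μm slices; the ground truth is relabeled accordingly); Rician
noise sqrt((v+n₁)²+n₂²) with σ expressed as a fraction of the cortex
reference (default 5%).  Artifacts are not applied to the μCT-grid truth —
they are an MRI phenomenon.

**μCT model.**  Cortex and bony-callus voxels draw densities from
[700, 1200] mg HA/cm³ and everything else from [0, 300] (pins ~air), so the
642 threshold separates mineralized from soft tissue exactly by
construction; the μCT grid covers the callus region between the inner pins
plus margin rather than the whole field of view.  **Pseudo-histology** is
two longitudinal ground-truth sections registered to the two central MRI
slices, resampled in-plane to 7 μm, with class boundaries warped by a
smooth random displacement field (r.m.s. 15 μm by default) emulating
sectioning/staining distortion.

Anatomy is placed with a configurable sub-voxel offset relative to the
grid; study helpers randomize it because perfectly grid-aligned phantoms
produce systematic aliasing that no real cohort shows.

## Simulation studies and their problem sizes

* *Recovery*: 20 phantoms per healing day on 128×128×22 MRI grids.  With
  noise and coil ramp off, segmented 3D and two-slice 2D fractions equal
  the MRI-grid ground truth exactly (artifact voxels map to unclassified on
  both sides); at 5% noise the worst per-class error is well under 3
  percentage points (~0.7 pp typical).
* *Degradation trends*: 20 randomized phantoms per condition.  Sweeping
  slice thickness 350→700→1400 μm (noise off), the median per-class
  correlation between measured fractions and the **continuum** fractions
  falls monotonically (≈0.995 → ≈0.8); voxelization is the effect under
  study, so the continuum anatomy is the reference.  Sweeping noise
  0→2→5→10% at native resolution, the reference is instead the **same-grid
  ground truth**, which isolates classification error (r = 1 exactly at
  σ = 0, then decreases); against the continuum reference the constant
  voxelization term would swamp the tiny noise effect and the comparison
  would be uninformative.
* *Cross-modality*: randomized phantoms measured by both MRI and μCT;
  bone-volume correlation is high (r ≈ 0.95–0.98 at n = 8) but below the
  MRI-vs-truth correlation because susceptibility artifacts occlude bone on
  the MRI side only.
* The pipeline (`run-all`) adds inter-specimen biological variability
  (target fractions ±30%, callus radius ±10%, sub-voxel positioning) around
  the per-day means; without it, specimens of a day would be identical and
  method correlations degenerate.

## What the phantoms do and do not show

Phantoms share the real study's geometry, intensity ordering, healing-stage
progression, noise family and artifact placement, but they idealize: class
intensities are drawn i.i.d. per voxel from flat intervals (no texture, no
partial-volume mixing at tissue interfaces, no relaxation-time physics),
the coil profile is a linear ramp, the periosteal boundary is known rather
than visually traced, and cortex landmarks are exact.  Passing recovery
tests therefore demonstrates the correctness of the normalization,
thresholding, VOI and measurement machinery — not that real tissue
intensities are perfectly separable; on real data, partial-volume voxels at
350 μm slice thickness blur the bins, which is exactly the limitation the
resolution-sweep experiment is designed to expose at trend level.

## Numerical choices

* Half-open bins with an inclusive cartilage top; values below 1 fold into
  bone; μCT threshold inclusive (≥ 642).
* Coordinates are 0-based voxel indices with half-open extents;
  world = origin + index·spacing, in μm; reports in mm³/mm²/percent.
* Class-boundary solving: 2001-interval midpoint quadrature, brentq to
  xtol = 1e-12; cartilage targets unreachable inside the non-bone callus
  raise a validation error.
* Majority-vote label downsampling requires integer spacing ratios
  (1% tolerance) and breaks ties by bone > cartilage > fibrous > … >
  background; trailing partial blocks are dropped.
* All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawns per stage, so identical specs yield
  bit-identical bundles.
* NIfTI headers hold float32 spacings; the exact float64 grid is embedded
  in a JSON header extension and restored on read, making write→read
  round-trips bit-exact.

## Known limitations

Single-bone cylindrical geometry (no curvature, no trabecular structure);
marrow and fibrous tissue are deliberately indistinguishable by intensity
(as in the classification itself); no bias-field correction or inter-modal
registration (modalities share one world frame by construction); the
degenerate-t flag means identical methods report no p-value rather than
p = 1; day-28 healing stages are out of scope because the MRI
quantification covers days 10–21.
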
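# Methods

## The measurement model

`irif3d` quantifies the 3D architecture of ionizing-radiation-induced foci
(IRIF) from multi-channel fluorescence z-stacks. Its object model assumes:

- a focus is a roughly spherical accumulation of signal, either solid
  (early G2 / G1 / repositioning-deficient conditions) or a hollow shell
  around a *devoid core* (late G2 after 53BP1/ubiquitin repositioning),
  with RPA appearing as a small spot inside the core once resection has
  produced single-stranded DNA;
- an enlarged focus with internal structure is still **one** object: the
  segmentation fills shell lumina before labelling, so the reported focus
  volume is the filled region, |voxels| × voxel volume;
- cell-cycle phase is readable from a pan-nuclear marker channel whose
  intensity is high in G2 (CENPF-like scoring): a nucleus is G2 iff its
  mean marker intensity exceeds a configured threshold.

## The synthetic-data generator

No imaging data accompany the study conditions, so the package ships a
generator that emulates them with full ground truth. Each nucleus is a
flattened ellipsoid (adherent-cell geometry, semi-axes 6.0 × 6.0 × 2.8 µm)
rendered at 0.1 × 0.1 µm in-plane and 0.2 µm axial voxels. A Poisson number
of foci (mean 10) is placed uniformly with centre separation at least 2.5×
the largest outer radius; clumped fixtures for testing the valid-range rule
are constructed deliberately, not drawn from these defaults. Per-channel
focus geometry comes from the condition's phenotype entry (below); per-focus
radii get coherent ±7% uniform jitter across channels. The rendered scene is
blurred with a Gaussian point-spread function (σ = 0.05 µm in-plane,
0.12 µm axial — small because the generator stands in for *deconvolved*
stacks), resampled with Poisson photon statistics (2 photons per intensity
unit) and additive Gaussian read noise (SD 6) clipped at zero. Channel
amplitudes differ per role (53BP1 220, FK2 180, γH2AX 200, RPA 160, BRCA1
140 over a pan-nuclear background of 15) so per-channel normalization is
genuinely exercised; the cycle marker is pan-nuclear at 80 (G2) or 8 (G1).

All randomness derives from one integer seed; nucleus *i* uses the stream
`default_rng([seed, i])`, so datasets are bit-reproducible and independent
of generation order.

What the generator does **not** emulate: spherical aberration, bleaching,
chromatic shift, depth-dependent PSFs, autofluorescence texture, or
deconvolution artefacts. Passing recovery tests therefore demonstrates that
the quantification is correct for well-behaved, deconvolved data with
known geometry — not that it is robust to every pathology of real
microscopy.

## The phenotype table

The condition → phenotype mapping is an explicit, exhaustive lookup keyed
by (depleted-gene set, phase, time post-IR); anything outside the table
raises rather than extrapolating. Encoded per condition: focus
**enlargement** (fold change of measured volume vs the 0.5 h reference;
since segmentation fills shells, the focus reference radius scales as
enlargement^(1/3)), the **core_devoid** flag (bipolar 53BP1/FK2
architecture), RPA and RAD51 levels, and per-channel geometry templates.
Key quantitative choices where the source observations are qualitative:

- RPA per-focus spot probability: normal 0.90, reduced 0.45 (50% of
  control), "absent in the majority" 0.18 (20% of control);
- devoid-core radius: 0.4 × outer radius (γH2AX shows a shallower central
  dip of 0.2 × outer at 50% residual intensity, matching its weaker
  visual core);
- the "RPA foci form but smaller" rescue conditions use 0.75× spot radius;
- conditions combining BRCA1 and POH1 depletion use enlargement 1.5,
  encoding that BRCA1 loss partially suppresses the enlargement otherwise
  seen after POH1 depletion (reported without a number);
- 53BP1/FK2 geometry is shared (a shell when the core is devoid, a solid
  otherwise); a depleted factor's own channel renders nothing.

## Segmentation and its parameters

| parameter | default | units | notes |
|---|---|---|---|
| nucleus smoothing σ | 0.5 | µm | before Otsu |
| nucleus volume window | 20 – 650 | µm³ | below: debris; above: merged nuclei, excluded not split |
| phase threshold | 40 | intensity | G2 iff mean cycle marker exceeds it |
| top-hat window | 2.2 × 2.5 × 2.5 | µm (z,y,x) | must exceed the largest focus diameter |
| focus threshold k | 3 | SD | threshold = background mean + k·SD |
| min focus size | 27 | voxels | 15 for the much smaller RPA spots |

Background statistics use the median and 1.4826×MAD of the top-hat image
inside the nucleus as robust estimates of the background mean and SD —
plain moments would be inflated by the focus voxels themselves. The
threshold rule systematically includes part of the PSF skirt, so absolute
filled volumes run ~40–60% above geometric truth at the default optics; the
*fold change* between conditions, the quantity of interest, is only mildly
compressed by this shared bias (measured ≈1.8× for a true 2.0× enlargement).
On noiseless, unblurred geometry the same pipeline recovers volumes to
within voxelization error (<15% median relative error over random spheres
and shells, shrinking with finer voxels).

The quantile convention for the valid-range rule is linear interpolation of
order statistics (the convention of `numpy.quantile`); Tukey hinges would
give slightly different fences and are deliberately not offered, so one
convention holds everywhere.

## Line profiles

Profiles are sampled at the in-plane voxel pitch along 8 evenly-spaced
in-plane orientations through the focus centroid in its z-plane (averaging
orientations makes the profile rotationally robust; the orientation of the
original line-plot analyses is unknowable). Each channel is normalized to
its own maximum along the line — this makes the 50% rule well defined and
the metrics invariant to intensity rescaling — and profiles are averaged
across foci per condition before metric extraction, with SD propagated.
Peak finding runs on a 3-sample moving average (suppresses single-voxel
noise while shifting peaks <1 step) with prominence ≥ 0.2 × channel max and
profile endpoints excluded. A profile is **bipolar** iff exactly two peaks
are found, separated by ≥2 grid steps, with the central trough ≤ 0.8 × the
mean peak height; the defaults classify noiseless shells bipolar and
noiseless spheres monopolar with a ≥5× margin on the trough criterion.
Clearance is the inter-peak distance; outer width interpolates the outer
50%-of-peak crossings linearly between samples. RPA peak intensity is not
reported when fewer than half the foci contain an RPA spot (averaging two
distinct populations would be misleading). A 3D core/shell intensity-ratio
score provides an orientation-free cross-check of the devoid-core call.

## Statistics

Pearson correlation is computed over voxel masks (per filled focus by
default — co-localization is an IRIF-scale question; per-nucleus scope is
available). Identical inputs return exactly 1.0; constant inputs raise
rather than returning an undefined value. The Mann–Whitney test reports the
first sample's U from midranks; for pooled n ≤ 12 without ties the
two-sided p is twice the enumerated one-tail probability (capped at 1),
otherwise a normal approximation with tie and continuity corrections is
used. p-values are reported raw with a 0.05 flag; the source analyses apply
no multiple-testing correction and neither does the package.

## Numerical and degenerate-case policy

- Coordinates are physical µm, origin at the stack corner; a voxel belongs
  to a geometric support iff its centre lies inside (half-open ownership).
- A shell with inner = outer radius has empty support and renders nothing.
- Zero-parameter blur/noise is the identity; blur conserves total intensity
  to <1% away from borders.
- Foci whose profile line would leave the stack are skipped for profiling
  (but still counted and measured volumetrically).
- An empty volume sample, an unknown channel role, a missing metadata
  sidecar, or an uncharacterized knockdown combination each raise a typed
  error; nothing falls back silently.

## Problem sizes

Recovery checks run at the scale the quantities need and no more: 50 nuclei
per timepoint for the volume fold change, 30 per condition for profile
widths, and 6 per condition when sweeping all 22 encoded conditions; at
those sizes the test suite and the acceptance script each complete in a few
minutes on one CPU.

## Known limitations

- **Width/volume coupling.** In the simulator the filled volume and the
  linear extent of a focus are geometrically locked (volume ∝ radius³), so
  a 2.0-fold volume enlargement yields only a ≈2^(1/3) ≈ 1.3-fold increase
  in profile outer width. Real IRIF decouple these — a thin bright rim can
  double its *material* volume while doubling its outer diameter — so the
  simulated outer-width contrast between control and repositioning-deficient
  conditions is compressed relative to real data. The polarity, clearance
  and volume contrasts are unaffected.
- Segmentation thresholds are stand-ins for the interactive "surface"
  workflow of the original analyses; absolute volumes depend on k and the
  optics (see above), and only relative comparisons should be interpreted.
- The phase threshold is calibrated to the generator's marker amplitudes,
  not auto-estimated; real data would need a per-dataset value.
- Phenotypes are encoded only for characterized conditions; the table
  refuses to predict untested combinations by design.
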
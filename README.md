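# irif3d

3D quantification of **ionizing-radiation-induced foci (IRIF)** during the
G2-phase switch from non-homologous end-joining to homologous recombination,
with a ground-truth-annotated synthetic microscopy generator.

After a double-strand break, repair proteins accumulate into micron-scale
foci. In G2 phase these foci reorganize as resection commits the break to
homologous recombination: 53BP1 and conjugated-ubiquitin (FK2) signal roughly
doubles in volume and vacates a central *devoid core* where RPA foci form,
with BRCA1 sitting between the 53BP1 rim and the RPA core. Along a line
through the focus centre the 53BP1/FK2 intensity then shows a **bipolar**
profile — two peaks flanking a central trough — whereas early foci, G1 foci,
and BRCA1-depleted foci stay **monopolar**. `irif3d` implements the image
quantification behind those observations and a seeded simulator whose
condition presets encode the knockdown phenotypes (siBRCA1, siPOH1,
siPOH1+RAP80, …), so the whole pipeline can be exercised end to end and
validated against known ground truth.

## What it measures

For a multi-channel z-stack (channels: 53BP1, FK2, RPA, γH2AX, BRCA1, and a
pan-nuclear cell-cycle marker):

- **Nuclei & phase** — Otsu segmentation of the pan-nuclear marker channel;
  G2 called when mean marker intensity exceeds a threshold (marker-positive
  scoring).
- **Foci** — per-nucleus top-hat background subtraction, threshold at
  background mean + *k*·SD, hole closing so a hollow shell and its lumen are
  ONE focus, 3D connected components. Volume is the filled region:
  V = |voxels| · voxel volume.
- **Valid-range rule** — the *maximum valid value* of a volume sample is the
  highest datum still within 1.5·IQR of the upper quartile
  (fence = Q3 + 1.5·(Q3 − Q1)), discarding abnormally large values caused by
  focus clumping and resolution limits; summaries report median, minimum,
  maximum valid value, and the number excluded.
- **Line profiles** — intensity along lines through the focus centroid
  (8 in-plane orientations, trilinear interpolation), averaged across foci,
  normalized per channel. Metrics: polarity (bipolar/monopolar),
  **clearance** (distance between the two peaks), and **outer width** (the
  distance between the outer edges of the peaks at 50% of the respective
  peak intensity; FWHM for a single peak).
- **Statistics** — Pearson correlation between channels over voxel masks
  (full co-localization is 1.0), and two-sided Mann–Whitney rank-sum tests
  (exact by enumeration for small tie-free samples, tie/continuity-corrected
  normal approximation otherwise; significance at p < 0.05, no
  multiple-testing adjustment).

## Worked example

```python
import numpy as np
from irif3d import SimulationConfig, parse_condition_label
from irif3d.pipeline import measure_condition

cfg = SimulationConfig(n_nuclei=8, seed=11)
late  = measure_condition(parse_condition_label("control_G2_8h"),   cfg)
early = measure_condition(parse_condition_label("control_G2_0.5h"), cfg, seed=12)
brca1 = measure_condition(parse_condition_label("siBRCA1_G2_8h"),   cfg, seed=13)

for m in (late, early, brca1):
    print(m.label, round(m.volume_summary.median, 2),
          m.metrics["FK2"].polarity, round(np.mean(m.rpa_counts), 1))
print("volume ratio 8h/0.5h:",
      round(late.volume_summary.median / early.volume_summary.median, 2))
```

prints

```
control_G2_8h 2.69 bipolar 7.5
control_G2_0.5h 1.44 monopolar 1.5
siBRCA1_G2_8h 1.43 monopolar 5.6
volume ratio 8h/0.5h: 1.87
```

i.e. late G2 control foci have roughly double the median volume of early
foci and a bipolar ubiquitin-chain profile (the devoid core), BRCA1
depletion blocks both, and RPA spot counts fall from ~7.5 per nucleus
(normal resection) through ~5.6 (reduced) to ~1.5 (background level at the
early timepoint).

The same workflow is available from the shell:

```sh
irif3d simulate --condition control_G2_8h --n 50 --seed 7 --out data/
irif3d quantify --in data/ --out foci.csv
irif3d profile  --in data/ --out prof
irif3d report   --foci foci.csv --metrics prof_metrics.csv --out report.csv
irif3d list-conditions          # the supported knockdown-condition table
```

`simulate` writes one TIFF + JSON-sidecar stack per nucleus plus a
ground-truth CSV; `report` compares every condition against the control and
the encoded phenotype table and exits nonzero if a phenotype check fails.

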
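# synquant

Quantification of B-cell immune-synapse microscopy.

When a B cell meets an antigen-coated surface — a 3 µm bead carrying BCR
ligand and ovalbumin (OVA), or a ligand-coated coverslip — it forms an
immune synapse (IS), polarizes its lysosomes toward the contact site and
extracts the immobilized antigen. `synquant` implements the image-analysis
readouts used to study this process on multi-channel fluorescence z-stacks
(LAMP1/LAMP2 lysosomes, LC3 autophagosomes, GEF-H1, OVA, F-actin), plus
the western-blot densitometry arithmetic and the group statistics used to
report them. A synthetic scene generator with analytic ground truth makes
every metric testable without microscope data.

## Metrics

For a cell with centroid **CC**, bead center **B** and a channel whose
intensity-weighted center of mass (on the z-sum projection) is **CL**
relative to CC, with **CB** = B − CC:

* **Polarity index** = (CL · CB) / |CB|² — the scalar projection of CL
  onto the cell-to-bead axis over |CB|; +1 fully polarized toward the
  bead, −1 anti-polarized, 0 unpolarized.
* **Antigen extraction**: bead OVA is the background-corrected total
  intensity in a fixed disk around the bead on the sum-of-slices
  projection; percent extracted = 100 × (1 − F/F₀) against the time-0
  bead population mean F₀, clipped to [0, 100].
* **Recruitment fraction**: share of a channel's fluorescence inside a
  concentric synapse disk (default radius = 2 × bead radius = 3 µm).
* **GEF-H1 bead fold change**: disk signal normalized by the time-0
  population mean.
* **Central enrichment** (spreading cells): channel density inside a
  concentric ellipse of ⅓ the footprint area over whole-footprint
  density, minus 1 (0 = uniform).
* **Z distribution**: mean intensity per 0.2 µm slice from the synapse
  plane up; **bottom/top ratio** = Σ lower half / Σ upper half (the
  middle slice of an odd stack counts half to each side).
* **Manders M1**: fraction of LAMP intensity on pixels where LC3 exceeds
  its threshold (per-channel Otsu after median background subtraction by
  default).
* **Densitometry**: normalizedᵢ = targetᵢ × (loading_ctrl / loadingᵢ);
  fold changeᵢ = normalizedᵢ / normalized_ctrl — exactly invariant to
  per-lane loading and global rescaling.
* **Statistics**: mean ± SEM summaries, one/two-way ANOVA, Sidak
  (p_adj = 1 − (1 − p)^m) or Dunnett post hoc, with the usual star bands.

## Worked example

```python
from synquant import SceneConfig, make_bead_scene, polarity_index

cfg = SceneConfig(lamp_positions_um=((0.0, 5.0),), n_lysosome_puncta=1,
                  noise=(0.0, 0.0), blur_sigma_um=0.0, seed=0)
stack, truth = make_bead_scene(cfg)
geom = polarity_index(stack, "LAMP", None, truth.true_bead_center,
                      cell_center_um=truth.true_cell_center)
print(f"{geom.index:+.6f}")
```

prints `+1.000000`: all LAMP mass sits at the bead center, so CL projects
onto the full length of CB. `examples/antigen_extraction.py` shows the
extraction readout recovering programmed OVA loss under shot noise:

```
retained 0.75 -> measured  25.6 % extracted (true 25 %)
retained 0.50 -> measured  50.9 % extracted (true 50 %)
retained 0.25 -> measured  76.1 % extracted (true 75 %)
```

The other scripts in `examples/` cover z-distribution, colocalization,
densitometry and group comparisons. A thin CLI wraps the same pipeline:

```bash
synquant simulate bead-scene --seed 7 --out scenes/ --n 5
synquant quantify scenes/
synquant blot lanes.csv
synquant selftest --seed 1
```

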
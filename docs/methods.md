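# Methods

## Scope and data model

The package quantifies two fixed-cell imaging assays on B cells: bead
conjugates (a 3 µm antigen-coated latex bead engaging the BCR) and cells
spreading on antigen-coated coverslips. Input is a `(channel, z, y, x)`
stack with lateral pixel size and axial step in µm and a role map naming
which channel is LAMP, LC3, GEF-H1, OVA, F-actin or brightfield.
Coordinates are voxel-center based and 0-indexed; every output is in
physical micrometres. Center-of-mass quantities (polarity, extraction,
recruitment, colocalization) are computed on sum-of-slices projections —
the workflow they reproduce operates on 2-D projections — while the
z-profile is the only intrinsically 3-D readout. All intensity sums are
accumulated in float64 regardless of storage dtype, so ratio metrics have
exact nulls (uniform input ⇒ enrichment 0, bottom/top 1, recruitment =
area ratio, to 1e-9).

## Regions

* **Cell footprint**: manual masks override everything; otherwise the
  F-actin projection is Otsu-thresholded, the largest connected component
  kept and holes filled. The cell center CC is the *unweighted* centroid
  of the binary mask, matching a manually drawn ROI rather than an
  intensity-weighted one.
* **Bead**: detected on the OVA (or brightfield) projection; candidate
  components must have an equivalent diameter within ±30 % of the
  expected 3 µm. With several candidates the one nearest the cell
  centroid wins; an exact tie is an error rather than an arbitrary pick.
* **Synapse disk**: "a concentric circular area surrounding the bead"
  is ambiguous between radius, diameter and annulus width. We use a full
  disk (bead included) of radius bead-radius + pad with pad defaulting to
  the bead radius, i.e. a 3 µm-radius disk for a 3 µm bead; the pad is a
  parameter and is recorded in the run manifest. A disk cut by the image
  border sets a `clipped` QC flag.
* **Central ellipse**: shares the footprint's centroid, orientation and
  axis ratio (second central moments of the binary mask), scaled so its
  area is one third of the footprint's; for a circular footprint this is
  the concentric disk of radius r/√3.

## Metric conventions

* **Polarity index** = (CL·CB)/|CB|², equivalently |CL|cosθ/|CB|. CL is
  the intensity-weighted center of mass ("center of mass of the
  staining" implies weighting by intensity, which we adopt). It is
  mathematically unbounded if |CL| > |CB|; it lies in [−1, 1] whenever
  the channel mass stays within the cell, which holds for all scenes the
  generator can produce.
* **Antigen extraction** uses the time-0 *population* mean as reference:
  the assay fixes different cells at each timepoint, so no per-bead
  pairing exists. Bead totals are corrected by the median projected
  intensity outside the bead region (times the region area) because an
  absolute intensity readout is otherwise inflated by the camera noise
  floor; the correction is identically zero on noise-free images.
  Negative extraction (bead brighter than reference) is clipped to 0 %
  with a `negative_extraction` flag, keeping the [0, 100] contract.
* **Bottom/top ratio**: halves are defined by slice count over the
  imaged extent; the middle slice of an odd stack contributes half its
  MFI to each side (unbiased for odd stacks). An empty upper half
  returns a +inf sentinel with a QC flag instead of failing.
* **Manders M1** thresholds each channel by Otsu after subtracting the
  median background, a standard choice where the original workflow does
  not state one; the method is a parameter and is written to output
  metadata, and a fixed numeric threshold can be supplied instead.
* **Composition** (`quantify_cell`): each metric runs independently; a
  failing precondition yields NaN plus a QC flag naming the metric, not
  a pipeline abort.
* **Statistics**: the observational unit is the cell (experiments pool
  tens of cells over ~3 replicates and the nesting is not recoverable
  from per-cell tables). Sidak is implemented directly
  (p_adj = 1−(1−p)^m); Dunnett uses the multivariate-t many-to-one
  distribution via `scipy.stats.dunnett`; ANOVA via statsmodels OLS with
  type-II sums of squares.

## Synthetic scene generator

The generator is the testbed: it renders the forward model and records
the ground truth each metric should recover.

* Geometry defaults: 0.1 µm lateral pixels, 0.2 µm axial step, a
  168×168×12-voxel field (16.8 µm × 2.4 µm), a 5 µm-radius cell (10 µm
  footprint, mid-range for a B cell) and a 3 µm bead tangent to the cell
  edge. The acquisition pixel size is a modeling choice, not an inferred
  value.
* Lysosome/LC3 puncta are isotropic Gaussian blobs (σ = 0.15 µm, 200 per
  cell). In bead scenes their angle around the cell center follows a von
  Mises law aimed at the bead: one scalar (κ) spans uniform (κ = 0) to
  tightly polarized, with E[cosθ] = I₁(κ)/I₀(κ) strictly increasing in
  κ — the basis of the monotonicity checks. Radii are area-uniform
  within 85 % of the cell radius. An explicit punctum-position override
  exists so degenerate configurations (all mass at one point) can be
  rendered for the analytic-extreme checks.
* LC3 co-places a programmed fraction of its puncta with lysosome
  puncta; the realized (rounded) fraction is recorded.
* The bead's OVA is a spherical shell ~2 voxels thick whose amplitude
  scales linearly with the retained-antigen fraction, matching a
  total-fluorescence readout of uniform extraction.
* In spreading scenes the puncta share a deterministic axial envelope
  exp(−bias·z/height) rather than sampled z positions: the noiseless
  z-profile is then exactly monotone and the bottom/top ratio analytic,
  so axial recovery is testable without Monte-Carlo slack. Bead scenes
  sample punctum z uniformly instead.
* Noise: Gaussian blur (σ = 0.1 µm) first, then Poisson shot noise on
  the scaled intensity (scale 50) and additive Gaussian read noise
  (σ = 0.02), clipped at zero. Identical config + seed gives a
  bit-identical float32 scene; placement and noise use separate child
  streams of one seed sequence.
* Ground truth uses the same separable 1-D Gaussian sums as the
  renderer (including border truncation), so the recorded center of
  mass matches a brute-force center of mass of the noiseless render to
  machine precision, not merely to an untruncated-Gaussian
  approximation. The spreading bottom/top truth is measured on the
  noiseless blurred render itself.

What the generator does **not** emulate: realistic optics beyond a
Gaussian PSF, cell-shape irregularity and dynamics, bead deformation at
the contact site, lysosome size heterogeneity, or spectral bleed-through.
Passing recovery tests therefore demonstrates correctness of the
*measurement code* under a plausible forward model, not robustness to
every property of real microscope data.

## Problem sizes and checks

The verification suite uses: 50 beads per level for percent-extracted
recovery (reference and measurement populations disjoint, as in the
assay), with tolerance 2 percentage points noiseless and 5 at default
noise; 50 scenes per level for polarity monotonicity over
κ ∈ {0, 1, 2, 4, 8} and Manders monotonicity over overlap fractions
{0, 0.25, 0.5, 0.75, 1}; 100 random 32×32×4 stacks for equivalence of
every metric against naive per-voxel loop implementations at 1e-9
relative; and 1000 simulated null datasets for ANOVA type-I-error
calibration (rejection rate ≤ α + 2 Monte-Carlo SE at α = 0.05). These
sizes keep the default test run to a few minutes on one CPU while the
Monte-Carlo margins stay several standard errors wide.

## Known limitations

* Bead detection assumes one dominant spherical bead per field near the
  expected size; clusters of touching beads are not resolved.
* The segmentation stand-in (Otsu + largest component) suits
  high-contrast actin labels; irregular or dim cells should use provided
  masks, which always take precedence.
* The central ellipse is clipped to the footprint, so its area ratio can
  fall below ⅓ for strongly non-convex footprints.
* Two-way ANOVA assumes a complete crossed design; unbalanced designs
  fall back to type-II sums of squares without warning.
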
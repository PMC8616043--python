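# Methods

This note documents the statistical model behind `nctscreen`: what each
stage computes, the assumptions it rests on, the parameters that matter,
and what the synthetic-data generators do and do not emulate.

## Assay model

The readout is the subcellular steady state of a GFP biosensor carrying
a nuclear localization signal (NLS) and a nuclear export signal (NES).
With export intact the sensor is predominantly cytoplasmic; blocking
XPO1-mediated export (leptomycin-b) or expressing a toxic arginine-rich
dipeptide (PR) drives it into the nucleus. Per cell the assay measures

```
TI = mean GFP over the nuclear "circle" mask − mean GFP over the perinuclear "ring" mask
```

and per well the mean TI over retained cells. All analysis operates on
relative intensity differences, so intensities are treated as abstract
counts; no photon or camera-gain model is used.

## Segmentation

`segment_nuclei` is the classic recipe: Gaussian smooth (σ = 1 px
default), global threshold (Otsu default; a fixed threshold is
available for instruments with calibrated backgrounds), binarize, fill
holes, remove components below `min_object_area` (20 px² default),
8-connected labeling. A constant image under Otsu yields zero objects
rather than an error.

Geometry conventions: 0-based (row, col) pixel centers; perimeter by
the 4-direction Crofton estimator; circularity `4πA/P²`. On digitized
disks the Crofton circularity can exceed 1 by up to 0.1 at small radii,
so the documented discretization slack is ε = 0.1 and validity
thresholds should stay at or below 1.

The *circle* is the segmented nucleus trace itself, not a fitted
geometric circle. The *ring* is a morphological annulus: dilation by
`ring_gap + ring_width` minus dilation by `ring_gap`, minus all nucleus
pixels. Defaults `ring_gap = 1`, `ring_width = 4` px; the original
instrument's ring dimensions are not published, so both are tunable.
Pixels claimed by more than one candidate ring are assigned to *no*
ring: dropping contested pixels is order-independent and keeps circle
and ring masks pairwise disjoint (an invariant the tests enforce).
Cells whose ring is entirely contested are dropped with a logged count;
objects whose candidate ring would leave the frame are flagged
`border`.

Touching nuclei merge into one object — no watershed splitting is
attempted, a documented limitation. The simulator places nuclei without
overlap, so this limitation is not exercised by the synthetic tests.

Validity ("invalid object") classification captures dead/apoptotic
cells with condensed chromatin: an object is invalid iff
`mean_dapi > max_mean_dapi` OR `area < min_area` OR
`circularity < min_circularity`. Invalid objects are retained for
well-level toxicity counting but excluded from transport scoring.

## Per-cell and per-well statistics

- **GFP outlier fences.** A valid cell is an outlier when its circle
  *or* ring GFP mean falls outside mean ± 3 SD of that quantity over
  the valid cells of the same well (plain mean and n−1 SD, single
  pass, no re-iteration). The grouping unit is the well — the analysis
  unit of the screen — and can be switched to per-plate. Zero-variance
  groups produce no outliers.
- **DPR-positive calling.** A cell is DPR-positive when its circle or
  ring immunostain mean clears the configured cutoffs (`either` rule by
  default, covering nuclear PR/GR and cytoplasmic GA species; `both`
  available).
- **Well summaries.** `ti_raw` is the mean TI over retained (valid,
  non-outlier) cells; wells with fewer than 10 retained cells are
  excluded with a reason (the floor is a package choice; it protects
  the well mean from being dominated by a handful of cells).
- **2-SD well filters.** Over all non-excluded wells of a plate
  (controls included): wells with invalid-object counts above
  mean + 2 SD are flagged toxic; wells with DPR-positive counts below
  mean − 2 SD are flagged low-expression. Flagged wells are retained in
  all tables but never considered during hit identification. Fewer
  than 3 wells → flags are skipped with a warning.
- **Plate gate.** `Z′ = 1 − 3(σ_p + σ_n)/|μ_p − μ_n|` over well-level
  `ti_raw` of the export-blocked positive and vehicle negative control
  arms (n−1 SDs; ≥ 2 wells per arm). The absolute separation makes Z′
  orientation-free, since a biosensor's direction can invert. Plates
  with Z′ < 0.5 are excluded from hit calling and listed in the QC
  report with the reason; coincident control means are reported as a
  QC failure rather than a crash.

## Normalization and hit calling

Per plate, `ti_norm = 100·(ti_raw − m)/(M − m)` with `m` the mean
`ti_raw` of the min-anchor control wells (vehicle/DMSO, 0%) and `M` of
the max-anchor wells (PR control, 100%); the export-blocked wells can
serve as the max anchor instead when characterizing a biosensor's
dynamic range. Anchors map to exactly 0 and 100 by construction and the
transform is affine, so downstream Z-factor scores are identical
whether computed on raw or normalized indices (tested to 1e−9).

Per-well scores are `Z = (X − μ)/σ` with μ, σ the mean and n−1 SD of
`ti_norm` over the *eligible* test wells of the plate — unflagged,
non-excluded, with the scored well included. Including the scored well
keeps the score set exactly centered (mean 0, SD 1 per plate); a
leave-one-out variant is provided. Scoring is per plate by default;
pooling across plates is left to the caller since per-plate
normalization already aligns scales.

Hits: `Z < −1.96` (the lower 2.5% standard-normal quantile, recomputed
from the inverse normal CDF and rounded to two decimals) AND viability
at or above the floor AND no QC flag. Viability is the well's valid-cell
count as a percent of the plate's PR-control mean count — the screen's
operational notion of "does not worsen PR toxicity" — with the default
floor at 100%. Ranks 1..20 follow ascending Z; ties break toward higher
viability, then lexicographic compound id (the ordering must be total
for reproducibility).

The confirmatory screen compares each compound's replicate `ti_norm`
values to the PR-control replicates with Welch's *t* and Holm
adjustment across compounds — standard reporting machinery, not a
contribution of this package — and flags direction (restored = below
the control mean) and viability increase separately.

## γH2AX (DSB) branch

`nuclear_mean_intensity` reuses the nucleus segmentation on the DAPI
channel and redirects the measurement to the target channel (γH2AX or
TDP-43 immunostain), yielding one mean nuclear intensity per cell.
Outliers are removed per (line, treatment, replicate) group with Tukey
fences: flag values outside `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`, single
pass, before any averaging. Quartiles use linear interpolation between
order statistics (the common spreadsheet/statistics default); Tukey
hinges are available as a config switch since the original script's
quantile method is unknown. Fewer than 4 values pass through unfiltered
with a warning.

Normalization is paired: within each patient/isogenic pair, group means
map to `100·(g − b)/(M − b)` with `b` = isogenic+vehicle and `M` =
patient+vehicle means of that pair, then per-pair percentages are
pooled across the cohort. Pairing first cancels line- and
staining-batch scale factors (the transform is affine-invariant, and
the anchors land at exactly 0% and 100% per pair). Coincident anchors
raise a degenerate-window error. Dose selection is the 3-point argmin
over {1×, 10×, 100×} IC50 with ties broken toward the lowest dose.

## Synthetic-data generators

The generators define the study conditions for all tests; they are
deterministic in (params, seed).

**Fields** (`simulate_field`). Nuclei are disks with radii uniform in
8–13 px placed by rejection sampling with pairwise center spacing of at
least the radii sum + 16 px (placement raises a "field too crowded"
error after a bounded number of attempts). A fixed, seeded share of
cells is dead: radius × 0.45 (so every dead nucleus is smaller than any
live one), DAPI × 2.0 (brighter than any live nucleus), and a
sinusoidal radial boundary perturbation (amplitude 0.3) that lowers
circularity — which makes the default validity thresholds perfectly
separating at zero noise, a property the tests assert. Each cell has a
biosensor budget `T` (uniform ±20% around `gfp_total_mean` = 60) split
by a Beta-distributed nuclear fraction `f` (Beta(2, 6) default, a
cytoplasmic steady state); rendered nuclear mean `T·f`, cytoplasmic
annulus mean `T·(1−f)`, so true TI = `T(2f−1)`. Beta parameters with a
zero endpoint pin the fraction at exactly 0 or 1 for degenerate-case
tests. An optional immunostain channel is rendered only in transfected
cells, nuclear or cytoplasmic per species (PR/GR nuclear, GA
cytoplasmic by convention; overridable). Gaussian read noise is added
per pixel and images are clipped to [0, 2^bit −1]; rasters stay float
in memory and are quantized only when written to 16-bit TIFF, so
zero-noise renders are exact.

Not emulated: optics (PSF, defocus), illumination gradients, z-stacks,
touching/overlapping nuclei, intensity-dependent noise, autofluorescence.
Passing tests therefore demonstrate the *statistics* of the pipeline on
well-behaved images, not robustness to real-microscope artifacts.

**Plates** (`simulate_plate`). The image-free fast path draws per-cell
circle/ring measurements directly. Default raw TI levels: vehicle and
empty-vector −20, PR control +20, export-blocked +28 counts; per-cell
SD 4 (so the 40-count vehicle-to-PR window spans 10 cell SDs), plus a
0.5-count well-level random shift. Wells receive Poisson(500) valid
cells scaled by a condition viability multiplier, and Poisson invalid
(dead) cells at 5% of the nominal count inversely scaled by viability.
Condition effects are expressed in window units; planted "restorer"
compounds shift test wells toward vehicle by `restorer_effect` (0.6
default) and carry a 1.2 viability multiplier, mirroring the screen's
premise that transport restorers also relieve PR toxicity (and keeping
Poisson count noise from dropping genuine restorers below the
100%-of-PR-control viability floor). DPR-positive levels are 150 ± 10
for transfected cells (70% efficiency in PR-transfected wells) vs
20 ± 5 background. The default 96-well layout holds the four control
arms in columns 1–2 (4 wells each) and 80 test wells in columns 3–12.

**Cohorts** (`simulate_dsb_cohort`). Per-nucleus γH2AX values are
Gaussian around a (genotype, treatment) mean (SD 10), with a
multiplicative per-line factor (SD 0.03) shared across a line's groups
and a small per-replicate factor (SD 0.02); the line factor emulates
staining-batch scale differences that the paired normalization is
designed to cancel.

## Problem sizes and numerical choices

The test and acceptance workloads use one 96-well plate at 300–500
cells/well for plate-level checks, 10 seeded plates for restorer
recovery, a 10,000-well single-pool null screen for score calibration,
fields of 20–60 nuclei at 512–768 px for segmentation fidelity, and
3×300 nuclei/group cohorts for the DSB recovery check — sizes chosen so
sampling error is far below the effects being verified while the whole
suite runs in seconds.

Other numerics: sample SDs use n−1 everywhere; quantiles interpolate
linearly unless hinges are requested; ties in hit ranking and dose
selection are broken deterministically (viability/id, lowest dose);
empty fields, constant images, zero-variance wells and degenerate
normalization windows all take defined paths (empty result, zero
objects, no outliers, explicit errors) rather than raising incidental
exceptions.

## Known limitations

- No watershed separation of touching nuclei; real confluent cultures
  would need it.
- No illumination correction or multi-field stitching.
- The viability metric (valid-cell count vs PR-control mean) is one
  defensible operationalization of "does not worsen survival"; labs
  with ATP- or dye-based viability readouts should substitute their own
  column before `call_hits`.
- Per-plate scoring assumes within-plate comparability only; no
  inter-plate batch correction (B-score/loess) is provided.
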
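# nctscreen

Analysis pipeline for high-content **nucleocytoplasmic transport (NCT)
screens** built on GFP translocation biosensors, plus the companion
nuclear **γH2AX** DNA-damage quantification used to validate hits in
patient-derived motor neurons.

## The problem and who this is for

Disruption of nuclear import/export is a cellular phenotype of
C9ORF72-linked ALS/FTD: toxic arginine-rich dipeptide repeat proteins
(DPRs, e.g. PR) shift a GFP biosensor — GFP fused to a nuclear
localization signal and a nuclear export signal — from its cytoplasmic
steady state into the nucleus. A compound screen looks for molecules
that push the sensor back out. This package implements the full
computational side of such a screen for assay developers and screening
analysts:

- **Segmentation** — DAPI-driven nucleus detection; a *circle* mask
  (the nucleus) and a *ring* mask (perinuclear cytoplasm) per cell.
- **Translocation index** — per cell,
  `TI = mean GFP(circle) − mean GFP(ring)`; per well, the average over
  valid, non-outlier cells. Positive TI = nuclear accumulation.
- **Quality control** — dead-cell ("invalid object") classification by
  size/brightness/shape; ±3 SD per-well GFP outlier fences; 2-SD
  well-level toxicity and DPR-expression filters; the plate gate
  `Z′ = 1 − 3(σ_p + σ_n)/|μ_p − μ_n| ≥ 0.5` over export-blocked
  (leptomycin-b) vs vehicle (DMSO) control wells.
- **Hit calling** — in-plate min–max normalization (vehicle wells → 0%,
  PR-control wells → 100%), per-well `Z = (X − μ)/σ` against all
  eligible test wells, hits at `Z < −1.96` with viability at or above
  the PR-control mean, top-20 ranking, and a replicate-level
  confirmatory comparison (Welch's *t*, Holm-adjusted).
- **DSB branch** — nuclear mean γH2AX per cell from a binary DAPI mask,
  Tukey 1.5×IQR outlier removal, paired patient/isogenic min–max
  normalization (isogenic+vehicle → 0%, patient+vehicle → 100%), and
  3-point dose selection.
- **Synthetic data** — seeded generators for fields, whole plates and
  γH2AX cohorts with ground truth, so every stage is testable without
  microscope data.

## Worked example

Simulate a 96-well screen with five planted "restorer" compounds (each
pulling the translocation index 60% of the way back from the PR level
to the vehicle level) and call hits:

```python
from nctscreen import (PlateSimParams, DprThresholds, default_screen_layout,
                       simulate_plate, remove_gfp_outliers, call_dpr_positive,
                       summarize_wells, flag_wells, qc_plate, normalize_minmax,
                       z_factor_scores, compute_viability, call_hits)

layout = default_screen_layout("P1")
cells, truth = simulate_plate(PlateSimParams(
    layout=layout, cells_per_well=500, n_true_restorers=5,
    restorer_effect=0.6, seed=42))

cells = call_dpr_positive(remove_gfp_outliers(cells), DprThresholds(80, 80))
wells = flag_wells(summarize_wells(cells, layout))
report = qc_plate(wells)
print(f"Z' = {report.z_prime:.3f}, pass = {report.passed}")

wells = compute_viability(z_factor_scores(normalize_minmax(wells)))
hits = call_hits(wells)
print(hits[["compound_id", "z_factor", "ti_norm", "viability", "rank"]].round(2))
```

Output:

```
Z' = 0.953, pass = True
  compound_id  z_factor  ti_norm  viability  rank
0        C062     -3.92    39.38     126.29   1.0
1        C029     -3.91    39.65     125.90   2.0
2        C052     -3.85    40.53     120.72   3.0
3        C041     -3.72    42.30     117.13   4.0
4        C034     -3.65    43.35     116.33   5.0
```

The plate passes the Z′ ≥ 0.5 gate with a wide margin; the five hit
wells sit near 40% of the vehicle-to-PR window (≈ the planted 60%
restoration), score far below the −1.96 cut, exceed PR-control
viability (100%) — and are exactly the five planted restorers in
`truth[truth.is_restorer]`.

The same stages are exposed on the command line:
`nctscreen simulate-plate | simulate-field | simulate-dsb | segment |
score | qc | hits | confirm | dsb | run` (see `--help`).

## Further reading

`docs/methods.md` describes the statistical model behind the simulators,
every QC rule and its parameters, numerical conventions, and known
limitations.
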
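# planeval

Toolkit for comparing radiotherapy treatment-plan variants (dose-calculation
algorithm × calculation-grid size) for prostate VMAT:

- **DVH core** (`planeval.dvh`) — cumulative/differential dose-volume
  histograms, D_x / V_x% queries, summary doses.
- **Plan quality** (`planeval.plan_quality`) — homogeneity index
  (D2−D98)/D50, conformity index V_RI/TV, conformation number, and
  reference-relative percent deviation.
- **Radiobiology** (`planeval.radiobio`) — generalized power-mean EUD,
  logistic TCP/NTCP sigmoids (half-points TCD50/TD50, slope γ50), optional
  EQD2 fractionation correction, and a CSV-round-trippable parameter
  registry (prostate / rectum / bladder / femoral heads shipped by default).
- **Dose grids** (`planeval.dose_grid`) — axis-aligned 3D dose arrays:
  trilinear resampling with missing-data flagging, voxel-wise signed
  difference maps, masked statistics, DVH extraction from grid + mask.
- **Cohort statistics** (`planeval.cohort_stats`) — paired Wilcoxon
  signed-rank test with an exact midrank null distribution (dynamic
  programming equivalent to full 2ⁿ sign enumeration) and tie-corrected
  normal approximation, plus per-contrast p-value tables.
- **Synthetic cohorts** (`planeval.synthetic`) — seeded generator of
  virtual patients (DVHs and an endorectal-balloon-style 3D dose phantom)
  with configurable algorithm/grid effects, so the full pipeline runs
  without any clinical data.
- **CLI & I/O** (`planeval.cli`, `planeval.io`, `planeval.workflow`) —
  TPS-text and CSV DVH parsing, cohort directories, tidy result tables.

## CLI

```sh
# 20 virtual patients x 6 plan variants (AAA 1/3/5 mm, AXB 1/2/3 mm)
planeval simulate --out cohort/ --seed 1 --n-patients 20

# full analysis: PTV & OAR summaries, deviations vs AXB 1 mm,
# TCP/NTCP, Wilcoxon p-value table
planeval report cohort/ --out results/

# individual stages
planeval metrics cohort/
planeval radiobio cohort/ --no-eqd2
planeval deviation cohort/
planeval compare cohort/ --mode exact
planeval gridsub dose_a.npz dose_b.npz --mask mask.npz
```

Configuration (prescription dose, fractions, reference isodose level,
reference variant, contrasts, EQD2 on/off) comes from a YAML/JSON file via
`--config`; defaults are 78 Gy / 39 fractions, 95% reference isodose, and
AXB at 1 mm as the deviation reference.

Exit codes: 0 success, 2 validation failure, 3 parse failure.

## Notes

- Probabilities are unit-interval internally; tables display percent.
- EQD2 correction before EUD is ON by default and can be disabled to
  evaluate the power mean on physical dose.
- Dose-calculation algorithms themselves are out of scope: the synthetic
  generator only emulates their cohort-level effects (coverage boost in the
  air cavity, rectal dose shift, grid-dependent falloff blur) in DVH space.
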
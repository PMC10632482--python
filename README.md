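# immunomet

Immuno-metabolic profiling of dendritic-cell (DC) vaccine cohorts from
Python: per-cell **SCENITH** metabolic-dependence scoring, single-cell
glycolytic/mitochondrial state binning, **Seahorse** bioenergetic index
derivation, supernatant glucose/lactate flux accounting, **ELISPOT**
response calls, and metabolic-biomarker **survival** statistics — plus a
seeded synthetic-cohort generator so every stage can be exercised and
validated without patient data.

## Who this is for

Groups running translational DC-vaccine (or other myeloid cell-therapy)
studies who need the downstream analysis of their metabolic monitoring
assays to be reproducible and testable: flow/mass-cytometry SCENITH panels,
extracellular-flux (XF) plates, supernatant metabolite meters, ELISPOT
plates and clinical follow-up.

## The quantities at the core

**SCENITH.** Protein synthesis (puromycin incorporation, measured as median
fluorescence intensity, MFI) is read after short inhibitor treatments:
C (control), 2DG (2-deoxy-glucose), O (oligomycin), Eto (etomoxir),
Tele (CB-839), DGO (2DG+O). With Δ = C − DGO the percent parameters are

```
glucose dependence        = 100 (C − 2DG) / Δ       glycolytic capacity = 100 − mitochondrial dep.
mitochondrial dependence  = 100 (C − O)   / Δ       FAAO capacity       = 100 − glucose dep.
FAO dependence            = 100 (C − Eto) / Δ
glutaminolysis dependence = 100 (C − Tele)/ Δ
```

**Oligomycin quantile binning.** Cells that keep translating after ATP-synthase
inhibition are glycolytic; the oligomycin-condition puromycin distribution is
cut at its 25/50/75 percentiles into four metabolic states (bin 1
mitochondrial-dependent … bin 4 glycolytic) whose occupancy is compared
across clinical groups.

**Seahorse indices.** With OCR/ECAR segment summaries around the
oligomycin → FCCP → rotenone/antimycin A injections:
basal respiration = OCR(pre-Oligo) − OCR(post-R/A); maximal = OCR(post-FCCP) −
OCR(post-R/A); spare = maximal − basal; proton leak = OCR(post-Oligo) −
OCR(post-R/A); ATP-linked = basal − leak; basal glycolysis and glycolytic
capacity are the ECAR analogues; exogenous FAO is the post-FCCP contrast of a
control vs a palmitate+etomoxir well.

**Survival.** Kaplan–Meier estimation, the two-group log-rank test,
maximally selected rank-statistic cutpoints (with an honest warning that the
naive p at a selected cutpoint is inflated, and a permutation p to fix it),
and univariate Cox proportional hazards with Efron tie handling — all
implemented in-repo and oracle-tested; routed two-group tests
(Shapiro–Wilk → t / rank-sum), Holm and Benjamini–Hochberg adjustment,
Spearman matrices and ANOVA+Tukey round out the cohort statistics.

## Worked example

```bash
python examples/scenith_profiles.py
```

generates 5 000 cells/condition for one sample with ground-truth
dependencies (glucose 40, mitochondrial 80, FAO 25, glutaminolysis 30) and
prints:

```
SCENITH parameters (percent of translation dynamic range):
  glucose_dependence          39.20
  mitochondrial_dependence    79.96
  fao_dependence              25.18
  glutaminolysis_dependence   30.74
  glycolytic_capacity         20.04
  faao_capacity               60.80
```

Each recovered dependence sits within a few points of its truth, and the
complement identities hold exactly (79.96 + 20.04 = 100). The other
examples cover quantile binning (`metabolic_binning.py`), Seahorse indices
(`seahorse_indices.py`), flux + ELISPOT (`flux_and_elispot.py`), biomarker
survival analysis (`survival_biomarkers.py`) and the full pipeline with its
run manifest (`full_pipeline.py`).

A thin CLI wraps the pipeline for shell use:

```bash
immunomet simulate --config sim.yaml --out inputs/
immunomet run --config run.yaml --stages scenith,binning,survival
immunomet validate --config run.yaml
```

Exit codes: 0 success, 2 config error, 3 stage failure.

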
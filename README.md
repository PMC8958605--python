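# iodoscreen

Analysis toolkit for cell-based high-throughput screens of iodide transport,
with downstream dose–response quantification, radioiodide-uptake calibration,
and a gene-expression recurrence-risk model for thyroid cancer cohorts.

## Scientific problem

Radioiodide therapy for thyroid cancer depends on the sodium–iodide symporter
(NIS) delivering iodide into tumor cells. Many tumors lose functional iodide
transport, so a central translational question is which small molecules restore
it. A practical readout is a yellow fluorescent protein (YFP) variant whose
fluorescence is quenched by intracellular iodide: in cells co-expressing NIS
and the YFP biosensor, adding iodide to the medium produces a rapid
fluorescence decay whose depth reflects transport activity. This package
implements the full analysis chain for such a screen:

1. **Primary screen scoring** — normalize kinetic fluorescence reads across
   plates and well positions, and call hits against DMSO controls with a
   viability gate.
2. **Assay QC** — Z′-factor per plate from iodide-injected (positive) and
   buffer-injected (negative) control wells.
3. **Secondary dose–response** — four-parameter logistic (4PL) fits for EC50,
   and area-under-curve comparison of a NIS-expressing line against a
   YFP-only control line (ΔAUC) to separate transport-specific activity from
   fluorescence artifacts.
4. **Direct uptake quantification** — conversion of gamma-counter readings of
   radioiodide (¹²⁵I⁻) to picomoles per microgram protein, fold-change with
   propagated SEM, and a perchlorate-block specificity check.
5. **Recurrence risk** — a multi-gene Cox proportional-hazards risk score on
   log-transformed expression, with ROC/Youden cutpoint selection,
   Kaplan–Meier stratification, log-rank testing, and covariate-adjusted
   hazard ratios.

A synthetic-data module generates screens, dose panels, uptake experiments and
survival cohorts with known ground truth, so every stage can be validated end
to end without external data.

## Core model and statistics

**Normalization chain.** For each well, fluorescence quench after iodide
injection is

&nbsp;&nbsp;%YFP = (YFP₀ − YFP₄) / YFP₀ × 100,

where YFP₀ is the pre-injection read and YFP₄ the fourth kinetic cycle.
Plate-to-plate variation is removed by dividing by the plate's interquartile
mean (spreadsheet TRIMMEAN with 50% total trim) over all wells:

&nbsp;&nbsp;S_IQM = %YFP / μ_IQ(plate).

Systematic well-position effects (edge effects, dispenser bias) are removed by
a second division by the interquartile mean of S_IQM at the same (row, column)
across all plates:

&nbsp;&nbsp;S_IQMW = S_IQM / μ_IQW(position).

Both corrections are ratios, so any multiplicative distortion confined to one
plate or one well position cancels exactly. The final effect size is a
z-score against vehicle controls:

&nbsp;&nbsp;ΔYFP = (S_IQMW(drug) − mean S_IQMW(plate-matched DMSO)) / SD(screen-wide DMSO).

A drug is a hit when ΔYFP > 1.5 (strict) **and** viability ≥ 0.70; replicate
wells are averaged per drug before thresholding.

**QC.** Z′ = 1 − 3(σ₊ + σ₋)/|μ₊ − μ₋| with sample SDs; a plate is suitable
for screening when Z′ > 0.5.

**Dose–response.** 4PL on log₁₀ dose,
r(d) = bottom + (top − bottom)/(1 + (EC50/d)^h), fit by nonlinear least
squares; an EC50 is reported only when it falls inside the tested dose window
extended one decade on each side. AUC integrates the positive part of the
response against log₁₀ dose; ΔAUC = AUC(NIS line) − AUC(control line).

**Uptake.** pmol I⁻/µg = 5000 × (counts/protein) / 12000 (counter
calibration: 12,000 cpm per 5,000 pmol). Fold-change SEM uses first-order
propagation of the two arms' relative errors. NIS specificity requires the
perchlorate-blocked signal to fall below 20% of the treated signal.

**Recurrence risk.** Expression enters as log₂(FPKM + 1). Differential
expression uses the Kolmogorov–Smirnov test with Benjamini–Hochberg FDR.
The risk score is Σ βg·log₂(FPKMg + 1) with βg from a multivariate Cox fit
(Breslow tie handling). Discrimination is ROC AUC; patients are stratified at
the median score (or by outer percentiles), compared by Kaplan–Meier and
log-rank, and the score's hazard ratio is re-estimated with clinical
covariates in the model.

## Worked example

The `demo` command generates a complete synthetic study (15-plate screen of
1,200 drugs, 5-drug dose panel, uptake experiment, 600-patient cohort) and
analyzes it:

```bash
iodoscreen demo --seed 1 --out demo_out
cat demo_out/report.txt
```

```
Primary screen
  wells: 1440, drugs: 1200, hits: 141 (true actives: 109)
  sensitivity among viable actives: 100.00%
  min plate Z': 0.829   screen DMSO SD: 0.0611

Secondary dose-response (dAUC ranking)
  HIT_02: dAUC=3.373, EC50=3.288 uM (true 3.462)
  HIT_04: dAUC=2.529, EC50=5.789 uM (true 5.612)
  ...

Radioiodide uptake
  treated: fold=4.367 +/- 0.087 (NIS-specific: True)

Recurrence risk model
  n=600 patients, 405 events
  risk-score AUC: 0.689
  high vs low HR: 2.902 (log-rank p=5.35e-26)
  covariate-adjusted risk HR: 3.07 (p=9.99e-25)
```

Every hit threshold is applied before ground truth is consulted; the 141
called hits include all 109 screenable true actives plus the expected ~5%
false-positive rate of the strict-z threshold on 1,091 inactive drugs.

The same steps are available individually (`iodoscreen simulate screen`,
`iodoscreen score`, `iodoscreen doseresponse`, `iodoscreen uptake`,
`iodoscreen risk`, `iodoscreen validate`) on TSV/CSV tables; see
`iodoscreen --help`.

Python API sketch:

```python
from iodoscreen import (ScreenSimSpec, simulate_screen,
                        score_screen, call_hits)

wells, truth = simulate_screen(ScreenSimSpec(seed=1))
normalized, stats = score_screen(wells)
hits = [w for w in call_hits(normalized) if w.hit]
```

## Documentation

See `docs/methods.md` for the full methods note: model definitions, synthetic
generator defaults and their rationale, numerical conventions, and known
limitations.
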
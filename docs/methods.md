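# Methods

This note documents the models, algorithms and numerical conventions
implemented by `iodoscreen`, and the design and defaults of its synthetic-data
generators. It describes what the code computes; all quantitative behavior is
exercised by the test suite and `scripts/acceptance.py`, and no empirical
claim is made here beyond what those compute.

## 1. Primary screen model

### 1.1 Data model

A screen is a list of kinetic wells. Each well carries a plate identifier, a
96-well address (rows A–H, columns 1–12), a role (drug, DMSO vehicle control,
NaI-injected positive control, PBS-injected negative control), an optional
drug identifier and dose, a pre-injection fluorescence read YFP₀, up to four
post-injection kinetic cycle reads, and a viability fraction. Wells with
non-positive or non-finite YFP₀ are flagged non-analyzable rather than
silently dropped; scoring excludes them and the count is reported in the run
manifest.

### 1.2 Normalization chain

For analyzable wells, with YFP₄ the read at the configured cycle (default 4,
falling back to the last available cycle when fewer were recorded):

1. **Fractional quench:** %YFP = (YFP₀ − YFP₄)/YFP₀ × 100.
2. **Per-plate normalization:** S_IQM = %YFP / μ_IQ(plate), where μ_IQ is
   the interquartile mean of %YFP over all analyzable wells on the plate.
3. **Per-well-position normalization:** S_IQMW = S_IQM / μ_IQW(row, col),
   where μ_IQW is the interquartile mean of S_IQM at that position across
   plates.
4. **Control-referenced effect size:**
   ΔYFP = (S_IQMW − mean S_IQMW of the same plate's DMSO wells) /
   SD of all DMSO S_IQMW screen-wide (sample SD, ddof = 1).

Steps 2–3 are ratios, so any multiplicative artifact confined to a plate or a
well position cancels exactly; this invariance is asserted in the tests to
1e-9 absolute for scale factors between 0.1 and 10.

**Interquartile mean.** μ_IQ uses spreadsheet TRIMMEAN semantics: with total
trim fraction t (default 0.5), floor(n·t/2) observations are removed from each
tail of the sorted values before averaging. This equals
`scipy.stats.trim_mean(x, proportiontocut=t/2)` and is verified against a
sort-and-slice reimplementation by property-based tests.

Scoring requires at least two DMSO wells screen-wide and at least one per
plate; a zero DMSO SD (possible only with degenerate constant data) raises a
validation error naming the control problem rather than returning infinities.

### 1.3 Hit calling

Replicate wells of the same drug are averaged at the S_IQMW level (hence also
ΔYFP and viability). A drug is a hit when ΔYFP strictly exceeds 1.5 and mean
viability is at least 0.70. Output is sorted by descending ΔYFP with
lexicographic drug-id tie-breaking, so rankings are deterministic.

### 1.4 Assay QC

Per plate, Z′ = 1 − 3(σ₊ + σ₋)/|μ₊ − μ₋| over the %YFP of NaI-positive vs
PBS-negative wells, with sample SDs (ddof = 1). At least two wells per arm
are required and equal control means are an error. A plate is suitable when
Z′ > 0.5; the pipeline can optionally refuse to report hits when any plate
fails this gate.

## 2. Dose–response and uptake quantification

### 2.1 4PL fitting

r(d) = bottom + (top − bottom)/(1 + (EC50/d)^hill), parameterized on log₁₀
dose and fit with `scipy.optimize.curve_fit` (bounded trust-region). Doses
must be positive and strictly increasing. A fit is reported as valid only
when it converges **and** the EC50 lands inside the tested window extended by
one decade on each side — with a 0.1% interior margin so estimates pinned at
the optimizer bound are rejected as unidentifiable. A degenerate fitted span
(top ≈ bottom) is likewise rejected; flat data yield `fit_ok = False` rather
than an arbitrary EC50.

### 2.2 AUC and ΔAUC

AUC integrates max(response, 0) against log₁₀ dose by the trapezoid rule
(clip-then-integrate: only positive response contributes). ΔAUC subtracts
the control cell line's AUC from the NIS-expressing line's AUC at matched
doses, removing dose-dependent fluorescence artifacts common to both lines.
Agreement with dense-grid numerical integration (200,001 points on the
clipped linear interpolant) is asserted to 1e-9.

### 2.3 Radioiodide uptake

pmol I⁻ per µg protein = 5000 × (counts/protein_µg) / 12000, i.e. a counter
calibration of 12,000 cpm per 5,000 pmol. Fold-change between treated and
vehicle arms is the ratio of arm means of pmol/µg; its SEM uses first-order
(delta-method) propagation, fold × sqrt((SEM_t/mean_t)² + (SEM_v/mean_v)²).
Specificity requires the perchlorate-blocked arm to retain less than 20% of
the treated signal.

### 2.4 qPCR

Relative expression by the 2^(−ΔΔCt) method against a reference gene and a
calibrator sample.

## 3. Recurrence-risk model

- **Transform:** expression enters every statistic as log₂(FPKM + 1);
  negative inputs are rejected.
- **Differential expression:** two-sample Kolmogorov–Smirnov (or
  Kruskal–Wallis) per gene; constant genes get p = 1. Multiplicity control is
  Benjamini–Hochberg step-up (`statsmodels multipletests`, `fdr_bh`).
- **Fisher exact test:** conditional odds ratio and two-sided p from scipy;
  a zero margin returns (NaN, 1.0).
- **Cox proportional hazards:** `statsmodels` PHReg with Breslow tie handling
  by default (Efron selectable). Fits with non-finite or exploding
  coefficients (|β| > 50, typically complete separation) are flagged
  non-converged instead of raising.
- **Risk score:** Σ β_g · log₂(FPKM_g + 1) with β from one multivariate Cox
  fit over the gene panel. Discrimination is ROC AUC of the score against
  the event indicator; the Youden-optimal cutpoint scans midpoints between
  adjacent unique scores (plus one candidate below the minimum), classifying
  score > t as positive and resolving J ties to the lower threshold.
- **Stratification:** groups split at the median score by default, or at
  outer percentiles (> 66th vs < 33rd, middle tertile discarded).
  Kaplan–Meier curves and the log-rank test come from `lifelines`; the
  between-group hazard ratio is re-estimated by a univariate Cox fit on the
  group indicator.
- **Covariate adjustment:** the continuous score is refit jointly with
  clinical covariates (age, gender, disease stage, tumor stage, node status
  by default). Categorical covariates are one-hot encoded with a dropped
  reference level; columns that are rank-deficient given the columns already
  included are dropped in order, so duplicated or collinear covariates cannot
  break the fit.

ROC analysis uses the binary event indicator, not a time-dependent
censoring-aware estimator — see limitations.

## 4. Synthetic data generators

The generators exist to give every analysis stage data with known ground
truth. Their defaults define the package's reference study and were fixed
from the generative model's arithmetic, before any outcome-driven adjustment.

### 4.1 Screen generator (`ScreenSimSpec`)

Default study: 15 × 96-well plates; column 1 holds injection controls (rows
A–D NaI-positive, E–H PBS-negative), 120 DMSO wells total (8 per plate,
column 12), leaving 1,200 drug wells.

| Parameter | Default | Rationale |
|---|---|---|
| `baseline_fluor` | 50,000 AU | typical plate-reader scale; arbitrary since normalization is ratio-based |
| `plate_effect_sd` | 0.10 | log-normal multiplicative plate effect, ~±10%, the artifact step 2 must remove |
| `wellpos_effect_sd` | 0.05 | log-normal positional effect, ~±5%, removed by step 3 |
| `noise_cv` | 0.02 | 2% read-to-read CV, typical of fluorescence plate readers |
| `baseline_quench` | 0.25 | basal quench in all NaI-exposed wells (DMSO and inactive drugs); keeps plate μ_IQ well away from 0 so the ratio normalizations are stable |
| `active_fraction` | 0.08 | 8% true actives, a generous primary-screen hit density |
| `active_quench_range` | (0.30, 0.80) | **total** quench of actives, uniform; 0.30 is the weakest effect the screen should still detect |
| `control_quench` | 0.80 | NaI-positive control total quench |
| `toxic_fraction` | 0.05 | drugs with viability drawn from (0.10, 0.60), below the 0.70 gate |
| `viability_noise_sd` | 0.03 | measurement noise on viability |

Kinetic traces interpolate the total quench linearly over cycles (cycle k of
4 carries q·k/4) with independent multiplicative noise per read. With no
noise, a well with quench q reads %YFP = 100·q exactly. The signal window is
analytic: S_IQMW noise SD is ≈ noise_cv·√2 ≈ 0.03 in DMSO units of ~1, and a
30%-quench active sits ≈ (0.30 − 0.25)/0.25 = 20% above the DMSO level,
several control SDs — which is why the acceptance tests can demand ≥ 95%
sensitivity among viable actives without tuning.

Ground truth (true quench, viability, activity and toxicity flags per drug)
is returned alongside the wells and is never consulted by the scoring code.

### 4.2 Dose–response and uptake generators

`simulate_dose_response` evaluates a 4PL at the requested doses with
multiplicative Gaussian noise (default CV 5%) for an NIS-expressing line,
plus an optional flat YFP-only control line. `simulate_uptake` draws counts
consistent with a true vehicle pmol/µg level, a true fold-change, protein
loads uniform in a plausible range, and an optional perchlorate-blocked arm
at 5% of the treated signal.

### 4.3 Cohort generator (`CohortSimSpec`)

Default: 600 patients, 13 genes (`GENE_01`…`GENE_13`), three causal genes
with log-hazard coefficients {GENE_01: +0.7, GENE_02: +0.5, GENE_03: −0.6}
per log₂(FPKM+1) unit; the rest are null. Expression is log-normal
(σ = 0.7 on the log₂ scale) around gene-specific means drawn once per cohort.
Event times are exponential with hazard λᵢ = λ₀·exp(lpᵢ − mean lp)
(λ₀ = 0.08/month), centering the linear predictor so λ₀ is the typical
hazard. Censoring times are exponential with rate λ₀·c/(1 − c) for target
censoring fraction c = 0.30. Clinical covariates (age, gender, stages, nodal
status, treatment flags) are generated independently of outcome by default,
so adjustment should not materially move the score's hazard ratio. A cohort
that draws zero events is re-drawn from a child seed (bounded retries).

## 5. Numerical and reproducibility conventions

- All SDs are sample SDs (ddof = 1) unless stated otherwise.
- TRIMMEAN uses floor-per-tail trimming as described in §1.2.
- Hit threshold comparisons are strict (>) for ΔYFP and inclusive (≥) for
  viability.
- All randomness flows through `numpy.random.default_rng` from explicit
  seeds; derived child seeds are drawn below 2³¹. Identical seeds reproduce
  byte-identical outputs (asserted in the pipeline tests).
- Result tables are written as TSV with fixed 6-decimal formatting; raw
  screen CSVs round-trip floats exactly via `repr`.
- The pipeline emits a JSON manifest with the package version, configuration,
  SHA-256 digests of inputs, and stage counts.

## 6. Problem sizes exercised

The test and acceptance runs use 4–15 plate screens (384–1,440 wells),
10-point dose curves over 0.1–50 µM with 100-seed noise replicates, 6-replicate
uptake experiments, and cohorts of 600–1,500 patients over 5–10 seeds. The
full suite completes in well under a minute on one core.

## 7. Limitations

- The ROC AUC and Youden cutpoint treat the event indicator as a binary
  label, ignoring censoring time; with heavy or informative censoring a
  time-dependent AUC would be more appropriate.
- The Cox machinery assumes proportional hazards and does not test the
  assumption.
- The screen generator models plate and positional artifacts as
  multiplicative and time-constant; drift within a plate run, evaporation
  gradients correlated with quench, or additive background are not simulated,
  and the exact cancellation property holds only for the multiplicative
  class.
- Kinetic traces are generated with linear quench progression; real biosensor
  decays are roughly exponential. Scoring uses only the first and the
  configured cycle, so this affects realism of intermediate cycles only.
- EC50 validity is a window heuristic; it rejects unidentifiable fits but
  does not provide confidence intervals.
- Viability is simulated independently of quench; real cytotoxic compounds
  can distort fluorescence in correlated ways.
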
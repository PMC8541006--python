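# Methods

## Tracer model

The simulator uses a linear, first-order compartment model of an
intraperitoneal ¹⁸FDG injection:

```
peritoneal depot P ──k_pa──▶ blood B ──k_loss──▶ excreted
        │ k_pg, k_pv, k_pl         │ k_bg, k_bv, k_bl
        ▼                          ▼
   gut / visceral fat / liver (trapped)
```

The depot feeds blood (absorption) and the three splanchnic tissues
directly (the mesenteric/portal, *pre-systemic* routes); blood feeds the
same tissues (*post-systemic* extraction) and an irreversible loss route.
Tissue compartments trap the tracer by default — the FDG-phosphorylation
analogy; `trapping=False` adds a common tissue→blood efflux rate `k_out`
for sensitivity work. All rates are min⁻¹. The system is solved exactly by
propagating the state with the matrix exponential of the (constant) system
matrix over each grid step; cumulative per-route deliveries are carried as
extra integrator states so pre-systemic delivered fractions remain
well-defined with or without trapping. Mass is conserved to solver
round-off (≲10⁻¹⁴ of the dose; tests require 10⁻⁸).

Radioactive decay is not simulated — curves are treated as decay-corrected,
which is how acquisition software exports them. Activity concentrations
are compartment amount divided by ROI volume; default ROI volumes scale
with body weight (blood 6%, liver 5%, gut 4%, visceral fat 2.5% of BW at
1 g/mL).

### Calibration of the default rates

No rate constants are available for this injection route at these ages;
what is observable is how the tracer *arrives*: a small early share of the
hour's blood exposure (~4% within 0–10 min) and a rapid pre-systemic
delivery of 15–20% of the dose to gut plus visceral fat within 10 min.
The defaults were derived analytically from the closed-form solution and
then verified numerically:

* `k_pa=0.0045, k_pg=0.011, k_pv=0.008, k_pl=0.0025` (depot outflow
  a = 0.026 min⁻¹), `k_bg=0.0012, k_bv=0.0008, k_bl=0.0015,
  k_loss=0.0005` (blood outflow b = 0.004 min⁻¹),

giving a blood AUC(0–10)/AUC(0–60) of 4.34% and a gut+VF pre-systemic
delivered fraction of 16.7% at 10 min. Two modelling notes:

* Under this fixed topology (no delay compartment between depot and
  blood), a 4% early blood-AUC share *forces* a slowly emptying depot and
  slow blood elimination; the defaults are a calibration to the observed
  fractions, not a mechanistic biodistribution model.
* The 15–20% figure is interpreted as a fraction of the injected dose
  (rather than of non-blood tracer); and the 4% figure is operationalised
  as the blood AUC ratio between windows. Both readings are choices; the
  second is the one a windowed-integral pipeline can actually measure.

## Study design emulation

Defaults reproduce the 2×2 design: weaning/adult × maternal ND/HFD with
group sizes 11/8/10/9 (total 38). Stratum effects are multiplicative on
the baseline (adult-ND) rates: weaning strata elevate gut and visceral-fat
delivery/extraction (×2–2.5) and mildly elevate pre-systemic liver
extraction while lowering post-systemic liver extraction; the weaning-HFD
stratum carries an extra visceral-fat multiplier (×3 on top of the weaning
×2.5, i.e. in the several-fold range — an amplified weaning reaction); the
adult-HFD stratum elevates post-systemic liver extraction by 40%. Body
weights (~17 g weaning, ~31 g adult), fasting glycemia (higher and more
variable in adult-HFD), injected dose (3.7 ± 0.3 MBq) and triglycerides
(floored at the 70 mg/dl assay bound, ~20% missing) are drawn per subject.
CT radiodensities are Gaussian per stratum and ROI (negative HU in fat,
parenchyma densifying with age) with liver HU decreasing linearly in the
planted steatosis percentage — a qualitative link only. Histology severity
(steatosis %, foci counts, ballooning and other lesion probabilities)
worsens monotonically across weaning-ND → weaning-HFD → adult-ND →
adult-HFD, and biopsies are flagged available for half the animals.

Per-subject randomness: every kinetic rate gets an independent log-normal
jitter (σ = 0.25) and TAC samples get multiplicative Gaussian measurement
noise (CV 5%, truncated at 0). Both default magnitudes are ordinary
small-animal PET variability; `StudyDesign.noise_free()` switches both off
for calibration checks. Streams are split from the master seed by
(stratum, subject-index) counters, so resizing one group never reshuffles
any other subject.

Taxa tables are log-normal compositions: per-taxon base log-levels
(σ = 1.5 across taxa) plus per-subject noise (σ = 0.6 in log units,
ordinary genus-level dispersion), exponentiated and total-sum normalised.
A planted effect splits a taxon's class means by ±log2fc/2 before
renormalisation; a coupling option adds a slope times a standardised
per-subject covariate to one taxon's log abundance, used to plant
taxon–imaging associations.

What the generator does **not** emulate: arterial input functions, partial
volume and spill-over, organ-volume growth curves, zero inflation and
sequencing-depth variation in counts, taxon–taxon correlation structure,
or any mechanistic diet effect. Passing tests therefore demonstrate that
the pipeline recovers structure *of the kinds planted here* at realistic
noise levels — not that it would recover effects from real acquisitions.

## Quantification conventions

* `%ID/g` is resolved as `100 · C(t) · BW / dose` (dimensionless,
  SUV-like) because the normalisation is "per gram of body weight"; the
  alternative `100 · C(t) / dose` (units 1/g) is available via
  `convention="per_g_dose"`.
* Window integrals are areas (value·min), not window means, computed with
  the trapezoid rule — exact for piecewise-linear curves and exactly
  additive across windows sharing the 10-min grid point; off-grid window
  endpoints are linearly interpolated, never extrapolated.
* Glycemia is a single fasting value per subject, not a time series.
* EGP units: clearance (mL/min) × glycemia (mmol/L) = µmol/min, divided
  by grams body weight.
* Partitioning ratios use 0–60 min uptake and are reported missing (NaN)
  when the denominator organ's uptake is zero (including glycemia = 0,
  where every uptake is zero by definition).

## Biomarker procedure

The screen uses the Wilcoxon rank-sum test for two classes — exact for
small untied samples (a completely separated 4+4 split yields the exact
two-sided p = 2/70), normal approximation with tie correction otherwise —
and tie-corrected Kruskal–Wallis for three or more classes. Constant
features get p = 1 by convention. α defaults to 0.05.

Effect sizes follow the reference construction: relative abundances are
rescaled to the 1–10⁶ range, a one-dimensional discriminant is fitted per
feature, and the score averages the absolute discriminant-projected
class-mean difference with the raw class-mean difference, reported as
log₁₀(1 + effect). For a single feature with a unit-normalised
discriminant direction both terms coincide with the absolute class-mean
difference; the two terms are kept separate so the optional seeded
bootstrap mode (subsample, refit, average — the reference tool's 30-round
behaviour) averages meaningfully. The default is a single deterministic
fit. Multi-class enrichment is one-vs-rest. The biomarker call is strict:
screen p ≤ α **and** score > 3.0. An optional strict mode adds the
pairwise rank-sum consistency substage of the original tool (off by
default). These defaults are a reconstruction of the published two-stage
logic, not a bit-level port.

## Association screen

Spearman's rho is computed on midranks (tie-corrected). For n ≥ 10 the
two-sided p uses the t approximation; for n < 10 it enumerates all n!
pairings exactly. Pairs with fewer than 4 complete observations are
skipped with a warning rather than an error. "FDR correction" is
Benjamini–Hochberg step-up, applied over all pairs of one X-by-Y screen as
a single family. Group comparisons use Welch's unequal-variance t-test
(robust default) for two groups and one-way ANOVA otherwise.

## Histology conventions

Steatosis percentage cutoffs (5/33/66) follow the Kleiner scheme, each
boundary belonging to the lower grade. The composite uses the 0–3 lobular
grade (required to reach the printed maximum of 7), not the binary flag;
portal inflammation, fibrosis and vessel dilatation are recorded but never
enter the composite. When micro- and macrovesicular steatosis are recorded
separately the composite conservatively takes the larger grade.

## Numerical and reproducibility choices

* Matrix-exponential propagation with one `expm` per distinct grid step;
  the default grid is 0.5-min frames over 0–60 min, fine enough that
  trapezoid error on the windowed integrals is < 0.1% at the default rate
  magnitudes.
* All interchange files are plain text with shortest-roundtrip float
  formatting, and readers parse with round-trip precision, so
  write-then-read is bit-exact and a rerun with the same config and seed
  reproduces every output byte-identically (hashes recorded in
  `manifest.json`).
* Problem sizes used by the test suite — e.g. 1000 null features for
  screen calibration, 200 replicates for planted-biomarker power, 100
  replicates for the coupled-pair ranking check, 500 subjects per stratum
  for multiplier recovery — were chosen as the smallest sizes at which the
  corresponding binomial/Monte-Carlo error bands are decisive.

## Known limitations

* The kinetic model is a calibration device, not a biodistribution model;
  its rate constants should not be interpreted physiologically.
* The effect-size stage fits each feature separately; the original
  multivariate discriminant (all features jointly) can rank correlated
  taxa differently.
* Exact Spearman p-values are enumerated only below n = 10; at n = 9 this
  is 362 880 pairings per pair and is the practical ceiling.
* Abundance I/O is plain TSV; no HDF5/BIOM binary support.
* Group comparisons assume approximate normality within groups (they are
  the parametric arm; the biomarker screen is the nonparametric arm).
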
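# viscnet

Analysis pipeline for the **visceral network** — gut, visceral fat and
liver — in small-animal studies that combine intraperitoneal-¹⁸FDG PET/CT
imaging, liver histology and gut-microbiota profiling.

After an intraperitoneal (i.p.) tracer injection, splanchnic organs see
glucose twice: first directly through mesenteric and portal routes
(*pre-systemic*), then from the general circulation (*post-systemic*).
`viscnet` quantifies both phases from extracted region-of-interest
time-activity curves, scores liver biopsies for steatohepatitis, discovers
microbial biomarkers, and screens imaging–microbiota associations — and it
ships a calibrated cohort simulator so every stage is testable end-to-end
without any acquisition. It is aimed at preclinical imaging/microbiome
groups working on developmental programming of metabolic liver disease
(e.g. weaning-age vs adult offspring of normal- vs high-fat-diet dams).

## What it computes

**PET quantification** (`viscnet.quant`). Time-activity curves are
normalised to percent injected dose per gram of body weight,
`%ID/g(t) = 100 · C(t) · BW / dose`, and integrated with the trapezoid rule
over the pre-systemic (0–10 min) and post-systemic (10–60 min) windows to
give the glucose fractional extraction *GE* per organ and window; glucose
uptake is *GU = GE × glycemia*. Organ partitioning is summarised by the
visceral-fat/liver and gut/liver ratios of 0–60 min uptake (and their
reciprocals). From the blood curve: systemic clearance
`CL = dose / ∫₀⁶⁰ C_blood(t) dt`, endogenous glucose production per gram
`EGP = CL · glycemia / BW`, and the fraction of blood tracer exposure in
the first 10 min.

**Histology** (`viscnet.histology`). Kleiner-adapted grading: steatosis
0–3 from the percent of affected hepatocytes (<5, 5–33, >33–66, >66),
lobular inflammation 0–3 from foci per 20× field (0, 1, 2–4, >4),
ballooning and the other lesions 0/1. The composite sum score is
steatosis + lobular + ballooning (0–7); NASH is called at sum ≥ 4.

**Biomarkers** (`viscnet.lefse`). A LEfSe-style two-stage procedure on
total-sum-normalised abundance tables: a nonparametric class screen
(rank-sum / Kruskal–Wallis), then a linear-discriminant effect size on the
1–10⁶ abundance scale reported as log₁₀; features are called at screen
p ≤ 0.05 and LDA score > 3.0.

**Associations** (`viscnet.associations`). Tie-corrected Spearman screen
of imaging metrics against taxa/pathway abundances (exact permutation p
below n = 10), Benjamini–Hochberg FDR over the whole screen, and Welch
t / one-way ANOVA group comparisons.

**Simulator** (`viscnet.simulate`). A linear compartment model
`P → {B, gut, VF, liver}`, `B → {gut, VF, liver, loss}` with irreversible
tissue trapping, calibrated so that noise-free defaults place ~4% of the
0–60 min blood exposure in the first 10 min and deliver 15–20% of the dose
pre-systemically to gut + visceral fat by 10 min; plus per-stratum effects
(2×2 design, 11/8/10/9 animals), histology grade distributions, CT
densities coupled to steatosis, and compositional taxa tables with planted
effects.

## Worked example

```python
from viscnet import KineticParams, integrate_window, simulate_tracer_kinetics

sim = simulate_tracer_kinetics(KineticParams(), dose_MBq=3.7)
blood = sim.tacs["blood"]
early = integrate_window(blood.times, blood.activities, 0, 10)
total = integrate_window(blood.times, blood.activities, 0, 60)
print(f"blood exposure 0-10 min: {early / total:.4f}")
print(f"pre-systemic gut+VF by 10 min: "
      f"{sim.presystemic_fraction(['gut', 'visceral_fat'], 10.0):.4f}")
```

prints

```
blood exposure 0-10 min: 0.0434
pre-systemic gut+VF by 10 min: 0.1673
```

i.e. 4.3% of the hour's blood tracer exposure falls in the first ten
minutes while 16.7% of the dose has already entered gut and visceral fat
through the direct mesenteric/portal routes — the i.p. signature the
windowed metrics exploit.

The full pipeline runs from one command and is reproducible byte-for-byte
given a seed:

```sh
viscnet run --out run1/ --seed 1
```

`run1/metrics.csv` then holds one row per simulated animal. Group means
from that run (seed 1):

| age group | vf_over_liver | clearance (mL/min) | EGP (µmol/min/g) |
|-----------|--------------:|-------------------:|-----------------:|
| weaning   | 24.4          | 0.431              | 0.156            |
| adult     | 6.5           | 0.421              | 0.121            |

— the visceral-fat/liver uptake ratio is several-fold higher at weaning,
the designed maturation effect. `run1/biomarkers.tsv` flags the planted
age-discriminating taxa (e.g. `taxon_0001`, LDA score 4.56, enriched at
weaning; `taxon_0004`, 5.13, enriched in adults), and
`run1/histology_scored.csv` shows NASH calls concentrated in adult
animals. Each stage is also available standalone (`viscnet simulate |
quant | histology | lefse | associate`); exit code 2 flags validation
errors.

## Layout

```
src/viscnet/
  io.py            tabular interchange formats + cleaning rules
  simulate.py      kinetic model, cohort generator, taxa tables
  quant.py         %ID/g normalisation, windowed metrics, clearance/EGP
  histology.py     grading and the composite NASH call
  lefse.py         screen + LDA effect size biomarker discovery
  associations.py  Spearman screen, BH-FDR, group comparisons
  pipeline.py      orchestration + reproducibility manifest
  cli.py           `viscnet` command-line interface
docs/methods.md    model assumptions, calibration, limitations
```
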
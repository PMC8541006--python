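"""Synthetic intraperitoneal-FDG cohorts with the study's design.

The generator reproduces the structure the downstream stages assume, so the
whole pipeline is testable without any acquisition:

* a two-by-two design — weaning vs adult offspring of normal-diet (ND) vs
  high-fat-diet (HFD) dams, group sizes 11/8/10/9 (total 38);
* intraperitoneal tracer kinetics: a linear first-order compartment model
  with a peritoneal depot ``P`` feeding blood ``B`` (absorption) and the
  gut, visceral-fat and liver tissues directly (pre-systemic mesenteric /
  portal delivery), and blood feeding the same tissues plus an irreversible
  loss route (renal excretion analogue).  Tissue compartments trap the
  tracer, the FDG-phosphorylation analogy.  The default rates are
  calibrated so that, noise-free, ~4% of the 0-60 min blood tracer
  exposure falls in the first 10 minutes and 15-20% of the injected dose
  reaches gut plus visceral fat pre-systemically within 10 minutes;
* stratum effects: weaning strata have higher gut/visceral-fat delivery
  and extraction rates and lower CT density than adult strata; the
  HFD-weaning stratum gets an extra multiplier on visceral-fat delivery
  (an amplified weaning reaction); adult-HFD elevates post-systemic liver
  extraction;
* per-stratum histology grade distributions with severity increasing from
  weaning-ND to adult-HFD, CT densities linearly coupled to the planted
  steatosis, and compositional taxa tables with planted differentially
  abundant taxa.

Determinism: one master seed; per-subject streams are derived by
counter-based seed splitting, so changing the cohort size never reshuffles
the subjects that are kept.  Radioactive decay is not simulated; curves are
declared decay-corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import expm

from .errors import ValidationError
from .io import ROIS, SubjectMetadata, TRIGLYCERIDE_FLOOR_MG_DL
from .lefse import AbundanceTable
from .quant import TimeActivityCurve

RATE_NAMES = ("k_pa", "k_pg", "k_pv", "k_pl", "k_bg", "k_bv", "k_bl", "k_loss")

# ---------------------------------------------------------------------------
# Tracer kinetics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KineticParams:
    """First-order rate constants of the i.p. tracer model, all 1/min.

    ``k_pa``: peritoneal depot -> blood absorption.
    ``k_pg, k_pv, k_pl``: depot -> gut / visceral fat / liver pre-systemic
    delivery.  ``k_bg, k_bv, k_bl``: blood -> tissue post-systemic
    extraction.  ``k_loss``: blood -> irreversibly excreted.  With
    ``trapping`` (default) tissue compartments are irreversible; otherwise
    they release tracer back to blood at ``k_out``.

    Defaults are calibrated to the observed arrival fractions (see module
    docstring), not to mechanistic truth.
    """

    k_pa: float = 0.0045
    k_pg: float = 0.011
    k_pv: float = 0.008
    k_pl: float = 0.0025
    k_bg: float = 0.0012
    k_bv: float = 0.0008
    k_bl: float = 0.0015
    k_loss: float = 0.0005
    trapping: bool = True
    k_out: float = 0.02

    def __post_init__(self) -> None:
        for name in RATE_NAMES + ("k_out",):
            if getattr(self, name) < 0:
                raise ValidationError(f"rate {name} must be >= 0")
        if self.k_pa + self.k_pg + self.k_pv + self.k_pl <= 0:
            raise ValidationError(
                "at least one peritoneal rate must be > 0 so the depot empties"
            )

    def scaled(self, multipliers: Dict[str, float]) -> "KineticParams":
        """New params with selected rates multiplied (others unchanged)."""
        unknown = set(multipliers) - set(RATE_NAMES)
        if unknown:
            raise ValidationError(f"unknown rate name(s) {sorted(unknown)}")
        return replace(
            self,
            **{k: getattr(self, k) * m for k, m in multipliers.items()},
        )


def default_roi_volumes_mL(body_weight_g: float) -> Dict[str, float]:
    """ROI volumes scaling with body weight (tissue density ~1 g/mL)."""
    if not body_weight_g > 0:
        raise ValidationError("body weight must be > 0")
    return {
        "blood": 0.060 * body_weight_g,
        "liver": 0.050 * body_weight_g,
        "visceral_fat": 0.025 * body_weight_g,
        "gut": 0.040 * body_weight_g,
    }


#: Default sampling grid: 0.5-min frames over 0-60 min.
DEFAULT_GRID = np.arange(0.0, 60.0 + 1e-9, 0.5)

# State ordering of the augmented linear system.  The first six entries are
# physical compartment amounts; the last six are pure route integrators
# (cumulative MBq delivered through each route), so delivered fractions stay
# well-defined even without trapping.
_STATES = (
    "peritoneal", "blood", "gut", "visceral_fat", "liver", "loss",
    "gut_pre", "visceral_fat_pre", "liver_pre",
    "gut_post", "visceral_fat_post", "liver_post",
)


def _system_matrix(p: KineticParams) -> np.ndarray:
    A = np.zeros((12, 12))
    a = p.k_pa + p.k_pg + p.k_pv + p.k_pl
    b = p.k_bg + p.k_bv + p.k_bl + p.k_loss
    A[0, 0] = -a
    A[1, 0] = p.k_pa
    A[1, 1] = -b
    A[2, 0] = p.k_pg
    A[2, 1] = p.k_bg
    A[3, 0] = p.k_pv
    A[3, 1] = p.k_bv
    A[4, 0] = p.k_pl
    A[4, 1] = p.k_bl
    A[5, 1] = p.k_loss
    if not p.trapping:
        for i in (2, 3, 4):
            A[i, i] -= p.k_out
            A[1, i] += p.k_out
    # route integrators (no outflow, not part of the mass balance)
    A[6, 0] = p.k_pg
    A[7, 0] = p.k_pv
    A[8, 0] = p.k_pl
    A[9, 1] = p.k_bg
    A[10, 1] = p.k_bv
    A[11, 1] = p.k_bl
    return A


@dataclass
class TracerSimulation:
    """Result of one kinetic simulation.

    ``amounts`` holds compartment amounts and cumulative route deliveries
    (MBq) per grid point; ``tacs`` the activity concentrations (amount /
    ROI volume, MBq/mL) for the four imaging ROIs.
    """

    times: np.ndarray
    dose_MBq: float
    amounts: Dict[str, np.ndarray]
    tacs: Dict[str, TimeActivityCurve]

    def presystemic_fraction(self, organs: Sequence[str], t: float) -> float:
        """Fraction of the injected dose delivered through the peritoneal
        (pre-systemic) routes to ``organs`` by time ``t``."""
        if self.dose_MBq == 0:
            return 0.0
        total = 0.0
        for organ in organs:
            key = f"{organ}_pre"
            if key not in self.amounts:
                raise ValidationError(f"unknown organ {organ!r}")
            total += float(np.interp(t, self.times, self.amounts[key]))
        return total / self.dose_MBq

    def total_amount(self) -> np.ndarray:
        """Tracer mass in the closed system at every grid point (MBq)."""
        return sum(
            self.amounts[name]
            for name in ("peritoneal", "blood", "gut", "visceral_fat", "liver", "loss")
        )


def simulate_tracer_kinetics(
    params: KineticParams,
    dose_MBq: float,
    grid: np.ndarray = None,
    volumes_mL: Dict[str, float] = None,
) -> TracerSimulation:
    """Solve the compartment system on a time grid (matrix exponential).

    The grid must start at 0, be strictly increasing and span at least
    60 min.  The system is closed: compartment amounts plus the loss
    compartment sum to the dose at every time.  Per-grid-point amounts are
    propagated exactly with the matrix exponential of the (constant) system
    matrix over each step.
    """
    if grid is None:
        grid = DEFAULT_GRID
    grid = np.asarray(grid, dtype=float)
    if grid[0] != 0 or np.any(np.diff(grid) <= 0):
        raise ValidationError("grid must start at 0 and be strictly increasing")
    if grid[-1] < 60.0:
        raise ValidationError("grid must span at least 60 min")
    if dose_MBq < 0:
        raise ValidationError("dose must be >= 0")
    if volumes_mL is None:
        volumes_mL = default_roi_volumes_mL(25.0)
    for roi in ROIS:
        if roi not in volumes_mL or not volumes_mL[roi] > 0:
            raise ValidationError(f"need a positive volume for ROI {roi!r}")

    A = _system_matrix(params)
    n = grid.size
    X = np.zeros((n, 12))
    X[0, 0] = dose_MBq
    # one expm per distinct step size; exact propagation for a linear system
    steps = np.diff(grid)
    propagators: Dict[float, np.ndarray] = {}
    for i, dt in enumerate(steps):
        key = round(float(dt), 12)
        if key not in propagators:
            propagators[key] = expm(A * dt)
        X[i + 1] = propagators[key] @ X[i]
    X = np.clip(X, 0.0, None)  # clip solver round-off, magnitude <= ~1e-15*dose

    amounts = {name: X[:, j].copy() for j, name in enumerate(_STATES)}
    tacs = {
        "blood": TimeActivityCurve(grid, amounts["blood"] / volumes_mL["blood"], "blood"),
        "liver": TimeActivityCurve(grid, amounts["liver"] / volumes_mL["liver"], "liver"),
        "visceral_fat": TimeActivityCurve(
            grid, amounts["visceral_fat"] / volumes_mL["visceral_fat"], "visceral_fat"
        ),
        "gut": TimeActivityCurve(grid, amounts["gut"] / volumes_mL["gut"], "gut"),
    }
    return TracerSimulation(times=grid, dose_MBq=dose_MBq, amounts=amounts, tacs=tacs)


def apply_measurement_noise(
    tac: TimeActivityCurve, cv: float, rng: np.random.Generator
) -> TimeActivityCurve:
    """Multiplicative Gaussian measurement noise, truncated at zero."""
    if cv < 0:
        raise ValidationError("noise CV must be >= 0")
    if cv == 0:
        return tac
    factors = np.clip(rng.normal(1.0, cv, size=tac.activities.size), 0.0, None)
    return TimeActivityCurve(tac.times.copy(), tac.activities * factors, tac.roi)


# ---------------------------------------------------------------------------
# Study design and cohort generation
# ---------------------------------------------------------------------------

STRATA = (
    ("weaning", "ND"),
    ("weaning", "HFD"),
    ("adult", "ND"),
    ("adult", "HFD"),
)

DEFAULT_GROUP_SIZES = {
    ("weaning", "ND"): 11,
    ("weaning", "HFD"): 8,
    ("adult", "ND"): 10,
    ("adult", "HFD"): 9,
}

# Stratum multipliers on the baseline (adult-ND) rates.  Weaning strata have
# more avid gut and visceral fat (pre- and post-systemic) and slightly higher
# pre-systemic liver extraction; the HFD-weaning stratum carries an extra
# elevation of visceral-fat delivery (amplified weaning reaction); adult HFD
# elevates post-systemic liver extraction.
DEFAULT_RATE_MULTIPLIERS = {
    ("weaning", "ND"): {"k_pg": 2.5, "k_pv": 2.5, "k_bg": 2.0, "k_bv": 2.5,
                        "k_pl": 1.3, "k_bl": 0.7},
    ("weaning", "HFD"): {"k_pg": 3.2, "k_pv": 7.5, "k_bg": 2.2, "k_bv": 3.0,
                         "k_pl": 1.4, "k_bl": 0.7},
    ("adult", "ND"): {},
    ("adult", "HFD"): {"k_bl": 1.4, "k_bg": 1.15},
}

# CT radiodensity means (Hounsfield units) per stratum and ROI: adipose is
# negative, parenchymal tissue positive, adult tissue denser than weaning.
DEFAULT_DENSITY_MEANS_HU = {
    ("weaning", "ND"): {"liver": 25.0, "visceral_fat": -95.0, "gut": 10.0},
    ("weaning", "HFD"): {"liver": 40.0, "visceral_fat": -75.0, "gut": 12.0},
    ("adult", "ND"): {"liver": 55.0, "visceral_fat": -70.0, "gut": 35.0},
    ("adult", "HFD"): {"liver": 50.0, "visceral_fat": -68.0, "gut": 33.0},
}
DEFAULT_DENSITY_SD_HU = 8.0
#: Liver HU decrease per percentage point of planted steatosis.
STEATOSIS_DENSITY_SLOPE = -0.35

DEFAULT_BODY_WEIGHT_G = {  # (mean, sd); weaning ~17 g, adult ~31 g
    ("weaning", "ND"): (17.0, 1.0),
    ("weaning", "HFD"): (17.5, 1.0),
    ("adult", "ND"): (30.0, 2.0),
    ("adult", "HFD"): (33.0, 2.0),
}
DEFAULT_GLYCEMIA_MMOL_L = {  # adult HFD offspring are hyperglycemic
    ("weaning", "ND"): (6.0, 0.7),
    ("weaning", "HFD"): (6.5, 0.7),
    ("adult", "ND"): (8.0, 0.8),
    ("adult", "HFD"): (9.5, 1.0),
}
DEFAULT_DOSE_MBQ = (3.7, 0.3)
DEFAULT_TRIGLYCERIDES_MG_DL = {  # raw assay scale; below 70 is below range
    ("weaning", "ND"): (75.0, 15.0),
    ("weaning", "HFD"): (85.0, 15.0),
    ("adult", "ND"): (72.0, 10.0),
    ("adult", "HFD"): (100.0, 12.0),
}

# Histology severity worsens across the four strata (weaning-ND mildest,
# adult-HFD most severe): steatosis percent (mean, sd), Poisson foci rate,
# and Bernoulli probabilities for the binary components.
DEFAULT_HISTOLOGY = {
    ("weaning", "ND"): dict(steatosis=(2.0, 2.0), foci_rate=0.3,
                            p_ballooning=0.05, p_portal=0.10,
                            p_fibrosis=0.05, p_vessel=0.10),
    ("weaning", "HFD"): dict(steatosis=(10.0, 6.0), foci_rate=0.9,
                             p_ballooning=0.15, p_portal=0.20,
                             p_fibrosis=0.10, p_vessel=0.10),
    ("adult", "ND"): dict(steatosis=(18.0, 10.0), foci_rate=1.6,
                          p_ballooning=0.30, p_portal=0.30,
                          p_fibrosis=0.20, p_vessel=0.10),
    ("adult", "HFD"): dict(steatosis=(40.0, 15.0), foci_rate=3.0,
                           p_ballooning=0.50, p_portal=0.40,
                           p_fibrosis=0.30, p_vessel=0.10),
}


@dataclass
class StudyDesign:
    """Cohort design: group sizes, stratum effects, noise levels, seed.

    ``jitter_sigma`` is the standard deviation of the per-subject log-normal
    jitter on every kinetic rate; ``noise_cv`` the coefficient of variation
    of the multiplicative measurement noise on TAC samples.  Setting both to
    zero gives the noise-free mode used for calibration checks.
    """

    group_sizes: Dict[Tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    base_params: KineticParams = field(default_factory=KineticParams)
    rate_multipliers: Dict[Tuple[str, str], Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_RATE_MULTIPLIERS.items()}
    )
    jitter_sigma: float = 0.25
    noise_cv: float = 0.05
    histology_fraction: float = 0.5
    grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())
    seed: int = 0

    def __post_init__(self) -> None:
        for stratum, n in self.group_sizes.items():
            if stratum not in STRATA:
                raise ValidationError(f"unknown stratum {stratum!r}")
            if n < 0 or n != int(n):
                raise ValidationError(f"group size for {stratum} must be >= 0")
        if self.jitter_sigma < 0 or self.noise_cv < 0:
            raise ValidationError("noise levels must be >= 0")

    def noise_free(self) -> "StudyDesign":
        return replace(self, jitter_sigma=0.0, noise_cv=0.0)


@dataclass
class SubjectRecord:
    """One simulated animal: metadata, TACs, densities, histology, truth."""

    meta: SubjectMetadata
    tacs: Dict[str, TimeActivityCurve]
    ct_density_HU: Dict[str, float]
    histology: Dict[str, float]
    params: KineticParams  # generating rates (simulation truth)


def _subject_rng(seed: int, stratum_index: int, j: int) -> np.random.Generator:
    # Counter-based splitting: the stream of subject j of stratum s is a pure
    # function of (master seed, s, j), so resizing any stratum neither
    # reshuffles other strata nor the subjects kept within the stratum.
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(stratum_index, j))
    )


def _truncated_normal(rng, mean, sd, low, high=None):
    for _ in range(100):
        x = rng.normal(mean, sd)
        if x > low and (high is None or x < high):
            return x
    return min(high, max(low + sd * 1e-3, mean)) if high else max(low + sd * 1e-3, mean)


def generate_cohort(design: StudyDesign) -> List[SubjectRecord]:
    """Generate the full cohort, deterministically given the design seed.

    Stratum multipliers scale the baseline kinetic rates before per-subject
    log-normal jitter; histology is generated for every subject and flagged
    available for the configured fraction (alternating within stratum),
    mirroring biopsies being processed in half of the cases.
    """
    records: List[SubjectRecord] = []
    for si, stratum in enumerate(STRATA):
        n = design.group_sizes.get(stratum, 0)
        age, diet = stratum
        prefix = f"{'W' if age == 'weaning' else 'A'}-{diet}"
        for j in range(n):
            rng = _subject_rng(design.seed, si, j)
            subject_id = f"{prefix}-{j + 1:02d}"

            bw_mean, bw_sd = DEFAULT_BODY_WEIGHT_G[stratum]
            body_weight = _truncated_normal(rng, bw_mean, bw_sd, 5.0)
            dose = _truncated_normal(rng, *DEFAULT_DOSE_MBQ, 0.5)
            gly_mean, gly_sd = DEFAULT_GLYCEMIA_MMOL_L[stratum]
            glycemia = _truncated_normal(rng, gly_mean, gly_sd, 0.5)

            params = design.base_params.scaled(design.rate_multipliers.get(stratum, {}))
            if design.jitter_sigma > 0:
                jitter = {
                    name: float(np.exp(rng.normal(0.0, design.jitter_sigma)))
                    for name in RATE_NAMES
                }
                params = params.scaled(jitter)

            volumes = default_roi_volumes_mL(body_weight)
            sim = simulate_tracer_kinetics(params, dose, design.grid, volumes)
            tacs = {
                roi: apply_measurement_noise(tac, design.noise_cv, rng)
                for roi, tac in sim.tacs.items()
            }

            hist_cfg = DEFAULT_HISTOLOGY[stratum]
            s_mean, s_sd = hist_cfg["steatosis"]
            steatosis_pct = float(np.clip(rng.normal(s_mean, s_sd), 0.0, 100.0))
            histology = {
                "steatosis_pct": steatosis_pct,
                "lobular_foci": int(rng.poisson(hist_cfg["foci_rate"])),
                "ballooning": int(rng.random() < hist_cfg["p_ballooning"]),
                "portal_inflammation": int(rng.random() < hist_cfg["p_portal"]),
                "fibrosis": int(rng.random() < hist_cfg["p_fibrosis"]),
                "vessel_dilatation": int(rng.random() < hist_cfg["p_vessel"]),
            }

            density = {}
            for roi, mean in DEFAULT_DENSITY_MEANS_HU[stratum].items():
                hu = rng.normal(mean, DEFAULT_DENSITY_SD_HU)
                if roi == "liver":
                    hu += STEATOSIS_DENSITY_SLOPE * steatosis_pct
                density[roi] = float(hu)

            tg_mean, tg_sd = DEFAULT_TRIGLYCERIDES_MG_DL[stratum]
            tg_raw = rng.normal(tg_mean, tg_sd)
            if rng.random() < 0.2:  # not every sample was of assay quality
                triglycerides = None
            else:
                triglycerides = max(tg_raw, TRIGLYCERIDE_FLOOR_MG_DL)

            histology_available = (j % round(1.0 / design.histology_fraction)) == 0 \
                if design.histology_fraction > 0 else False

            meta = SubjectMetadata(
                subject_id=subject_id,
                age_group=age,
                maternal_diet=diet,
                body_weight_g=float(body_weight),
                injected_dose_MBq=float(dose),
                glycemia_mmol_L=float(glycemia),
                triglycerides_mg_dl=triglycerides,
                histology_available=histology_available,
            )
            records.append(
                SubjectRecord(
                    meta=meta,
                    tacs=tacs,
                    ct_density_HU=density,
                    histology=histology,
                    params=params,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Compositional taxa tables
# ---------------------------------------------------------------------------

#: Default planted age-group biomarkers for pipeline runs: taxa enriched in
#: the weaning vs the adult microbiota, expected log2-fold differences.
DEFAULT_PLANTED_EFFECTS = {
    "taxon_0001": ("weaning", 2.5),
    "taxon_0002": ("weaning", 2.0),
    "taxon_0003": ("adult", 2.5),
    "taxon_0004": ("adult", 2.0),
}


def generate_taxa_table(
    subject_ids: Sequence[str],
    class_labels: Sequence[str],
    n_taxa: int = 40,
    planted_effects: Optional[Dict[str, Tuple[str, float]]] = None,
    seed: int = 0,
    sigma: float = 0.6,
    base_sd: float = 1.5,
    coupling: Optional[Dict[str, Tuple[Sequence[float], float]]] = None,
) -> AbundanceTable:
    """Compositional taxa table with planted differential abundance.

    Log abundances are drawn taxon-wise as ``N(b_i, sigma)`` around
    taxon-specific base levels ``b_i ~ N(0, base_sd)``; a planted effect
    ``taxon -> (class, log2fc)`` shifts that class's mean by ``+log2fc/2``
    (in log2 units) and all other classes by ``-log2fc/2``, giving the
    requested expected log2-fold between-class difference before
    renormalisation.  ``coupling`` maps a taxon to ``(covariate, slope)``:
    the standardised per-subject covariate times ``slope`` is added to the
    taxon's log2 abundance (used to plant taxon-metric associations).
    Columns are total-sum normalised to 1.
    """
    subject_ids = list(subject_ids)
    class_labels = list(class_labels)
    if len(subject_ids) != len(class_labels):
        raise ValidationError("one class label per subject required")
    planted_effects = dict(planted_effects or {})
    feature_ids = [f"taxon_{i + 1:04d}" for i in range(n_taxa)]
    known = set(feature_ids)
    for taxon in planted_effects:
        if taxon not in known:
            raise ValidationError(f"planted effect on nonexistent taxon {taxon!r}")
    if n_taxa < len(planted_effects):
        raise ValidationError("n_taxa smaller than the number of planted taxa")
    if coupling:
        for taxon in coupling:
            if taxon not in known:
                raise ValidationError(f"coupling on nonexistent taxon {taxon!r}")

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(977,)))
    base = rng.normal(0.0, base_sd, size=n_taxa)
    log2_z = np.empty((n_taxa, len(subject_ids)))
    ln2 = math.log(2.0)
    for i, fid in enumerate(feature_ids):
        shift = np.zeros(len(subject_ids))
        if fid in planted_effects:
            enriched_class, lfc = planted_effects[fid]
            labels = np.asarray(class_labels)
            shift = np.where(labels == enriched_class, lfc / 2.0, -lfc / 2.0)
        log2_z[i] = base[i] / ln2 + shift + rng.normal(0.0, sigma / ln2, size=len(subject_ids))
    if coupling:
        for fid, (covariate, slope) in coupling.items():
            cov = np.asarray(covariate, dtype=float)
            if cov.size != len(subject_ids):
                raise ValidationError("coupling covariate length mismatch")
            sd = cov.std()
            z = (cov - cov.mean()) / sd if sd > 0 else np.zeros_like(cov)
            log2_z[feature_ids.index(fid)] += slope * z

    values = np.exp2(log2_z)
    values /= values.sum(axis=0, keepdims=True)
    return AbundanceTable(
        feature_ids=feature_ids,
        subject_ids=subject_ids,
        values=values,
        class_labels=class_labels,
        normalized=True,
    )
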
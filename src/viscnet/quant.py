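"""Quantification of organ glucose handling from PET time-activity curves.

After an intraperitoneal tracer injection, splanchnic organs (gut, visceral
fat, liver) see the tracer twice: first directly through mesenteric/portal
routes (pre-systemic, captured by the 0-10 min window) and then from the
general circulation (post-systemic, 10-60 min).  This module turns raw
time-activity curves (TACs) into:

* fractional glucose extraction per organ and window, in %ID/gBW*min
  (activity normalised to injected dose per gram of body weight, then
  integrated over the window);
* glucose uptake = extraction x fasting glycemia;
* organ partitioning ratios on the full 0-60 min uptake
  (visceral-fat/liver, gut/liver and their reciprocals);
* systemic metrics: tracer clearance (injected dose over the integrated
  blood activity), endogenous glucose production per gram of body weight
  (clearance x glycemia / body weight), and the fraction of the blood
  tracer exposure falling in the first 10 minutes.

Integration is by the trapezoid rule on the sample grid, which is exact for
piecewise-linear curves and additive across adjacent windows sharing a grid
point; window endpoints off the grid are linearly interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ROIS, SubjectMetadata

#: Organs entering the uptake metrics (blood is handled separately).
ORGANS = ("liver", "visceral_fat", "gut")

#: Window boundaries in minutes: pre-systemic 0-10, post-systemic 10-60.
PRE_WINDOW = (0.0, 10.0)
POST_WINDOW = (10.0, 60.0)


@dataclass
class TimeActivityCurve:
    """Sampled activity concentration versus time for one ROI.

    ``times`` are minutes, strictly increasing from 0; ``activities`` are
    MBq/mL (or %ID/gBW after normalisation) and must be non-negative.
    """

    times: np.ndarray
    activities: np.ndarray
    roi: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.activities = np.asarray(self.activities, dtype=float)
        if self.roi not in ROIS:
            raise ValidationError(f"unknown ROI {self.roi!r}")
        if self.times.shape != self.activities.shape:
            raise ValidationError("times and activities must have equal length")
        if self.times.size < 2:
            raise ValidationError("a TAC needs at least 2 samples")
        if self.times[0] < 0 or np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing from >= 0")
        if np.any(self.activities < 0):
            raise ValidationError(f"negative activity in ROI {self.roi!r}")

    @property
    def span(self) -> float:
        return float(self.times[-1])


@dataclass
class UptakeMetrics:
    """Per-organ windowed extraction/uptake and 0-60 min partitioning ratios.

    ``ge_*`` are integrated fractional extractions (%ID/gBW*min); ``gu_*``
    are extraction x glycemia (%ID/gBW*min*mmol/L).  Ratios are computed on
    the total 0-60 min uptake and are NaN where the denominator organ's
    uptake is zero.
    """

    ge_pre: Dict[str, float]
    ge_post: Dict[str, float]
    gu_pre: Dict[str, float]
    gu_post: Dict[str, float]
    vf_over_liver: float
    gut_over_liver: float
    liver_over_vf: float
    liver_over_gut: float


@dataclass
class SystemicMetrics:
    """Whole-body tracer handling derived from the blood curve."""

    clearance_mL_min: float
    egp_umol_min_g: float
    blood_fraction_0_10: float


def normalize_to_pid_g(
    tac: TimeActivityCurve,
    dose_MBq: float,
    body_weight_g: float,
    convention: str = "per_g_bw",
) -> TimeActivityCurve:
    """Normalise a TAC to percent injected dose per gram of body weight.

    The default convention is SUV-like and dimensionless:
    ``100 * activity * body_weight / dose``.  The alternative
    ``convention="per_g_dose"`` omits the body-weight factor and has units
    of 1/g: ``100 * activity / dose``.

    Raises
    ------
    ValidationError
        If dose or body weight is not strictly positive.
    """
    if not dose_MBq > 0:
        raise ValidationError(f"dose must be > 0, got {dose_MBq}")
    if not body_weight_g > 0:
        raise ValidationError(f"body weight must be > 0, got {body_weight_g}")
    if convention == "per_g_bw":
        values = 100.0 * tac.activities * body_weight_g / dose_MBq
    elif convention == "per_g_dose":
        values = 100.0 * tac.activities / dose_MBq
    else:
        raise ValidationError(f"unknown %ID/g convention {convention!r}")
    return TimeActivityCurve(tac.times.copy(), values, tac.roi)


def integrate_window(times, values, t0: float, t1: float) -> float:
    """Trapezoid-rule area of a sampled curve over ``[t0, t1]``.

    Window endpoints that fall between grid points are handled by linear
    interpolation of the curve, which keeps the rule additive over adjacent
    windows.  Extrapolation outside the sampled support is refused.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if not t0 < t1:
        raise ValidationError(f"need t0 < t1, got [{t0}, {t1}]")
    if t0 < times[0] - 1e-12 or t1 > times[-1] + 1e-12:
        raise ValidationError(
            f"window [{t0}, {t1}] outside curve support "
            f"[{times[0]}, {times[-1]}]; extrapolation refused"
        )
    inner = (times > t0) & (times < t1)
    ts = np.concatenate(([t0], times[inner], [t1]))
    vs = np.concatenate(
        ([np.interp(t0, times, values)], values[inner], [np.interp(t1, times, values)])
    )
    return float(np.trapezoid(vs, ts))


def compute_uptake_metrics(
    curves: Dict[str, TimeActivityCurve], glycemia_mmol_L: float
) -> UptakeMetrics:
    """Windowed extraction/uptake metrics from normalised (%ID/gBW) curves.

    ``curves`` must contain liver, visceral_fat and gut, each spanning
    0-60 min.  Uptake is extraction times the single fasting glycemia;
    partitioning ratios use the full 0-60 min uptake and are NaN when the
    denominator is zero (including the glycemia = 0 degenerate case).
    """
    if glycemia_mmol_L < 0:
        raise ValidationError("glycemia must be >= 0")
    for organ in ORGANS:
        if organ not in curves:
            raise ValidationError(f"missing TAC for organ {organ!r}")
        if curves[organ].span < POST_WINDOW[1]:
            raise ValidationError(
                f"TAC for {organ!r} must span 60 min for post-systemic metrics"
            )
    ge_pre, ge_post, gu_pre, gu_post = {}, {}, {}, {}
    for organ in ORGANS:
        tac = curves[organ]
        ge_pre[organ] = integrate_window(tac.times, tac.activities, *PRE_WINDOW)
        ge_post[organ] = integrate_window(tac.times, tac.activities, *POST_WINDOW)
        gu_pre[organ] = ge_pre[organ] * glycemia_mmol_L
        gu_post[organ] = ge_post[organ] * glycemia_mmol_L

    total = {o: gu_pre[o] + gu_post[o] for o in ORGANS}

    def ratio(num: str, den: str) -> float:
        if total[den] == 0:
            return float("nan")
        return total[num] / total[den]

    return UptakeMetrics(
        ge_pre=ge_pre,
        ge_post=ge_post,
        gu_pre=gu_pre,
        gu_post=gu_post,
        vf_over_liver=ratio("visceral_fat", "liver"),
        gut_over_liver=ratio("gut", "liver"),
        liver_over_vf=ratio("liver", "visceral_fat"),
        liver_over_gut=ratio("liver", "gut"),
    )


def compute_systemic_metrics(
    blood: TimeActivityCurve,
    dose_MBq: float,
    glycemia_mmol_L: float,
    body_weight_g: float,
) -> SystemicMetrics:
    """Clearance, EGP and early blood-exposure fraction from the blood TAC.

    clearance [mL/min] = dose / integral_0^60 blood(t) dt;
    EGP per gram [umol/min/g] = clearance x glycemia / body weight
    (mL/min x mmol/L = umol/min);
    blood_fraction_0_10 = AUC(0-10) / AUC(0-60).
    """
    if not dose_MBq > 0:
        raise ValidationError("dose must be > 0")
    if not body_weight_g > 0:
        raise ValidationError("body weight must be > 0")
    if blood.roi != "blood":
        raise ValidationError(f"expected the blood TAC, got ROI {blood.roi!r}")
    if blood.span < POST_WINDOW[1]:
        raise ValidationError("blood TAC must span the full 0-60 min")
    auc_0_60 = integrate_window(blood.times, blood.activities, 0.0, 60.0)
    if auc_0_60 == 0:
        raise ValidationError("blood AUC(0-60) is zero; clearance undefined")
    auc_0_10 = integrate_window(blood.times, blood.activities, *PRE_WINDOW)
    clearance = dose_MBq / auc_0_60
    egp = clearance * glycemia_mmol_L / body_weight_g
    return SystemicMetrics(
        clearance_mL_min=clearance,
        egp_umol_min_g=egp,
        blood_fraction_0_10=auc_0_10 / auc_0_60,
    )


def quantify_subject(
    meta: SubjectMetadata,
    curves: Dict[str, TimeActivityCurve],
    convention: str = "per_g_bw",
) -> dict:
    """All uptake + systemic metrics for one subject, as a flat record."""
    if "blood" not in curves:
        raise ValidationError(f"subject {meta.subject_id!r}: missing blood TAC")
    norm = {
        organ: normalize_to_pid_g(
            curves[organ], meta.injected_dose_MBq, meta.body_weight_g, convention
        )
        for organ in ORGANS
        if organ in curves
    }
    up = compute_uptake_metrics(norm, meta.glycemia_mmol_L)
    sys = compute_systemic_metrics(
        curves["blood"], meta.injected_dose_MBq, meta.glycemia_mmol_L, meta.body_weight_g
    )
    row = {"subject_id": meta.subject_id,
           "age_group": meta.age_group,
           "maternal_diet": meta.maternal_diet}
    for organ in ORGANS:
        row[f"ge_pre_{organ}"] = up.ge_pre[organ]
        row[f"ge_post_{organ}"] = up.ge_post[organ]
        row[f"gu_pre_{organ}"] = up.gu_pre[organ]
        row[f"gu_post_{organ}"] = up.gu_post[organ]
    row["vf_over_liver"] = up.vf_over_liver
    row["gut_over_liver"] = up.gut_over_liver
    row["liver_over_vf"] = up.liver_over_vf
    row["liver_over_gut"] = up.liver_over_gut
    row["clearance_mL_min"] = sys.clearance_mL_min
    row["egp_umol_min_g"] = sys.egp_umol_min_g
    row["blood_fraction_0_10"] = sys.blood_fraction_0_10
    return row


def quantify_cohort(
    subjects: List[SubjectMetadata],
    tacs: Dict[str, Dict[str, TimeActivityCurve]],
    convention: str = "per_g_bw",
) -> pd.DataFrame:
    """Metrics table (one row per subject) for a whole cohort.

    ``tacs`` maps subject_id to its per-ROI curves; a subject without curves
    is a validation error naming the subject.
    """
    rows = []
    for meta in subjects:
        if meta.subject_id not in tacs:
            raise ValidationError(f"no TACs for subject {meta.subject_id!r}")
        rows.append(quantify_subject(meta, tacs[meta.subject_id], convention))
    return pd.DataFrame(rows)
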
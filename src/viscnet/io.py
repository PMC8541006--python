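"""Tabular I/O for the visceral-network pipeline.

All interchange files are plain text: comma-separated with a single UTF-8
header row, except abundance tables which follow the microbiome community
convention of tab separation (first column ``feature_id``, one column per
subject).  Missing values are empty cells and are surfaced as missing
(``None`` / ``NaN``), never silently as zero.

Files
-----
``subjects.csv``
    subject_id, age_group, maternal_diet, body_weight_g, injected_dose_MBq,
    glycemia_mmol_L, triglycerides_mg_dl, histology_available
``tac_<subject>.csv``
    time_min, roi, activity_MBq_per_mL  (ROIs: liver, visceral_fat, gut, blood)
``histology.csv``
    subject_id, steatosis_pct, lobular_foci, ballooning,
    portal_inflammation, fibrosis, vessel_dilatation
``abundance.tsv``
    feature_id, <subject_id>...
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

AGE_GROUPS = ("weaning", "adult")
MATERNAL_DIETS = ("ND", "HFD")
ROIS = ("liver", "visceral_fat", "gut", "blood")

#: Lower bound of the triglyceride assay's measurable range, mg/dl.  Readings
#: below range are floored to this value.
TRIGLYCERIDE_FLOOR_MG_DL = 70.0

#: Literal CSV sentinel marking a below-measurable-range triglyceride reading.
BELOW_RANGE_SENTINEL = "<LOD"

SUBJECT_COLUMNS = [
    "subject_id",
    "age_group",
    "maternal_diet",
    "body_weight_g",
    "injected_dose_MBq",
    "glycemia_mmol_L",
    "triglycerides_mg_dl",
    "histology_available",
]

TAC_COLUMNS = ["time_min", "roi", "activity_MBq_per_mL"]

HISTOLOGY_COLUMNS = [
    "subject_id",
    "steatosis_pct",
    "lobular_foci",
    "ballooning",
    "portal_inflammation",
    "fibrosis",
    "vessel_dilatation",
]


@dataclass
class SubjectMetadata:
    """One animal's study metadata.

    ``age_group`` x ``maternal_diet`` places the subject in exactly one of
    the four strata of the two-by-two (weaning/adult x ND/HFD) design.
    ``triglycerides_mg_dl`` is ``None`` when not measured; a below-range
    assay reading should be floored with :func:`floor_triglycerides`
    before being stored here.
    """

    subject_id: str
    age_group: str
    maternal_diet: str
    body_weight_g: float
    injected_dose_MBq: float
    glycemia_mmol_L: float
    triglycerides_mg_dl: Optional[float] = None
    histology_available: bool = False

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise ValidationError(
                f"subject {self.subject_id!r}: age_group must be one of "
                f"{AGE_GROUPS}, got {self.age_group!r}"
            )
        if self.maternal_diet not in MATERNAL_DIETS:
            raise ValidationError(
                f"subject {self.subject_id!r}: maternal_diet must be one of "
                f"{MATERNAL_DIETS}, got {self.maternal_diet!r}"
            )
        if not self.body_weight_g > 0:
            raise ValidationError(
                f"subject {self.subject_id!r}: body_weight_g must be > 0, "
                f"got {self.body_weight_g}"
            )
        if not self.injected_dose_MBq > 0:
            raise ValidationError(
                f"subject {self.subject_id!r}: injected_dose_MBq must be > 0, "
                f"got {self.injected_dose_MBq}"
            )
        if self.glycemia_mmol_L < 0:
            raise ValidationError(
                f"subject {self.subject_id!r}: glycemia_mmol_L must be >= 0"
            )

    @property
    def stratum(self) -> tuple:
        return (self.age_group, self.maternal_diet)


def floor_triglycerides(value) -> float:
    """Apply the assay's below-range rule to one triglyceride reading.

    Readings below the measurable range (passed as the sentinel string
    ``"<LOD"``) are set to the lowest accessible value, 70 mg/dl.  Numeric
    in-range values pass through unchanged; the operation is idempotent.

    Parameters
    ----------
    value : float or str
        A numeric reading in mg/dl, or :data:`BELOW_RANGE_SENTINEL`.

    Returns
    -------
    float
        The reading in mg/dl, never below 70.
    """
    if isinstance(value, str):
        if value.strip() == BELOW_RANGE_SENTINEL:
            return TRIGLYCERIDE_FLOOR_MG_DL
        try:
            value = float(value)
        except ValueError as exc:
            raise ValidationError(
                f"triglyceride value {value!r} is neither numeric nor "
                f"the below-range sentinel {BELOW_RANGE_SENTINEL!r}"
            ) from exc
    value = float(value)
    if math.isnan(value):
        raise ValidationError("triglyceride value is NaN; use None for missing")
    if value < 0:
        raise ValidationError(f"triglyceride value must be >= 0, got {value}")
    return value


def _require_columns(df: pd.DataFrame, required: List[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_subject_table(path) -> List[SubjectMetadata]:
    """Read ``subjects.csv`` into a list of :class:`SubjectMetadata`.

    Triglyceride cells holding the ``<LOD`` sentinel are floored to
    70 mg/dl; empty cells become ``None``.  Parse errors are reported with
    the offending row number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    _require_columns(df, SUBJECT_COLUMNS, path)

    records: List[SubjectMetadata] = []
    for i, row in df.iterrows():
        rowno = i + 2  # header is line 1
        try:
            tg_cell = row["triglycerides_mg_dl"].strip()
            tg = floor_triglycerides(tg_cell) if tg_cell else None
            records.append(
                SubjectMetadata(
                    subject_id=row["subject_id"].strip(),
                    age_group=row["age_group"].strip(),
                    maternal_diet=row["maternal_diet"].strip(),
                    body_weight_g=float(row["body_weight_g"]),
                    injected_dose_MBq=float(row["injected_dose_MBq"]),
                    glycemia_mmol_L=float(row["glycemia_mmol_L"]),
                    triglycerides_mg_dl=tg,
                    histology_available=_parse_bool(
                        row["histology_available"], path, rowno
                    ),
                )
            )
        except ValidationError:
            raise
        except ValueError as exc:
            raise FormatError(f"{path}, row {rowno}: {exc}") from exc
    return records


def _parse_bool(cell: str, path, rowno: int) -> bool:
    s = cell.strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no", ""):
        return False
    raise FormatError(f"{path}, row {rowno}: cannot parse boolean {cell!r}")


def write_subject_table(records: List[SubjectMetadata], path) -> None:
    """Write ``subjects.csv``; inverse of :func:`read_subject_table`."""
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "age_group": r.age_group,
                "maternal_diet": r.maternal_diet,
                "body_weight_g": repr(float(r.body_weight_g)),
                "injected_dose_MBq": repr(float(r.injected_dose_MBq)),
                "glycemia_mmol_L": repr(float(r.glycemia_mmol_L)),
                "triglycerides_mg_dl": (
                    "" if r.triglycerides_mg_dl is None
                    else repr(float(r.triglycerides_mg_dl))
                ),
                "histology_available": str(bool(r.histology_available)),
            }
        )
    pd.DataFrame(rows, columns=SUBJECT_COLUMNS).to_csv(path, index=False)


def read_tac_table(path) -> Dict[str, "np.ndarray"]:
    """Read one subject's ``tac_<subject>.csv`` into per-ROI curves.

    Returns
    -------
    dict
        ``roi -> (times, activities)`` pair of float arrays, times sorted
        ascending.  Unknown ROI labels are a format error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    _require_columns(df, TAC_COLUMNS, path)
    curves: Dict[str, tuple] = {}
    for roi, sub in df.groupby("roi", sort=False):
        if roi not in ROIS:
            raise FormatError(f"{path}: unknown ROI label {roi!r}")
        sub = sub.sort_values("time_min")
        t = sub["time_min"].to_numpy(dtype=float)
        a = sub["activity_MBq_per_mL"].to_numpy(dtype=float)
        if np.any(a < 0):
            raise ValidationError(f"{path}: negative activity in ROI {roi!r}")
        curves[roi] = (t, a)
    return curves


def write_tac_table(curves: Dict[str, tuple], path) -> None:
    """Write per-ROI ``(times, activities)`` curves as ``tac_<subject>.csv``."""
    frames = []
    for roi in ROIS:
        if roi not in curves:
            continue
        t, a = curves[roi]
        frames.append(
            pd.DataFrame(
                {
                    "time_min": np.asarray(t, dtype=float),
                    "roi": roi,
                    "activity_MBq_per_mL": np.asarray(a, dtype=float),
                }
            )
        )
    # default float repr is shortest-roundtrip: reads back bit-exactly
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_histology_table(path) -> pd.DataFrame:
    """Read raw (ungraded) ``histology.csv`` observations."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, HISTOLOGY_COLUMNS, path)
    return df


def write_histology_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_abundance_table(path) -> pd.DataFrame:
    """Read ``abundance.tsv`` as a features-by-subjects DataFrame.

    The first column must be ``feature_id``; it becomes the index.  Values
    must be non-negative numbers (counts or relative abundances).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.columns[0] != "feature_id":
        raise FormatError(f"{path}: first column must be 'feature_id'")
    df = df.set_index("feature_id")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric abundance value ({exc})") from exc
    if (df.to_numpy() < 0).any():
        raise ValidationError(f"{path}: abundance values must be >= 0")
    return df


def write_abundance_table(df: pd.DataFrame, path) -> None:
    """Write a features-by-subjects DataFrame as ``abundance.tsv``."""
    out = df.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")
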
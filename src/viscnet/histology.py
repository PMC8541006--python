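"""Kleiner-adapted liver histology grading and the composite NASH call.

Components scored on hematoxylin-eosin sections:

* steatosis, graded 0-3 from the percentage of affected hepatocytes
  (<5% -> 0, 5-33% -> 1, >33-66% -> 2, >66% -> 3); when micro- and
  macrovesicular percentages are recorded separately the composite uses
  the larger of the two grades;
* lobular inflammation, graded 0-3 from the number of inflammatory foci in
  a 20x field (0 -> 0, 1 focus -> 1, 2-4 foci -> 2, >4 foci -> 3);
* ballooning degeneration, vessel dilatation, fibrosis and portal
  inflammation, each scored present/absent (1/0).

The composite sum score is steatosis grade + lobular grade + ballooning
(range 0-7); non-alcoholic steatohepatitis (NASH) is called when the sum
reaches 4.  Portal inflammation, fibrosis and vessel dilatation are
recorded but do not enter the composite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .errors import ValidationError

#: Composite sum score at or above which steatohepatitis is called.
NASH_THRESHOLD = 4


@dataclass
class HistologyRecord:
    """Component grades plus the derived sum score and NASH call."""

    subject_id: str
    steatosis_pct: float
    steatosis_grade: int
    lobular_foci: int
    lobular_grade: int
    ballooning: int
    portal_inflammation: int
    fibrosis: int
    vessel_dilatation: int
    sum_score: int
    nash: bool


def grade_lobular_inflammation(n_foci: int) -> int:
    """Grade lobular inflammation from the foci count at 20x magnification.

    0 foci -> grade 0, 1 focus -> 1, two to four foci -> 2, more than four
    foci -> 3.  Monotone non-decreasing in the count.
    """
    if n_foci != int(n_foci) or n_foci < 0:
        raise ValidationError(f"foci count must be a non-negative integer, got {n_foci}")
    n_foci = int(n_foci)
    if n_foci == 0:
        return 0
    if n_foci == 1:
        return 1
    if n_foci <= 4:
        return 2
    return 3


def grade_steatosis(percent_affected: float) -> int:
    """Grade steatosis from the percentage of affected hepatocytes.

    Cutoffs follow the Kleiner scheme: <5% -> 0, 5-33% -> 1, >33-66% -> 2,
    >66% -> 3 (each boundary belongs to the lower grade).
    """
    p = float(percent_affected)
    if not 0 <= p <= 100:
        raise ValidationError(f"steatosis percentage must be in [0, 100], got {p}")
    if p < 5:
        return 0
    if p <= 33:
        return 1
    if p <= 66:
        return 2
    return 3


def score_nash(
    steatosis_grade: int, lobular_grade: int, ballooning: int
) -> tuple[int, bool]:
    """Composite sum score and categorical NASH call.

    sum = steatosis grade (0-3) + lobular inflammation grade (0-3) +
    ballooning (0/1); NASH is called when the sum is >= 4 (attainable
    positive range 4-7).
    """
    if steatosis_grade not in (0, 1, 2, 3):
        raise ValidationError(f"steatosis grade must be 0-3, got {steatosis_grade}")
    if lobular_grade not in (0, 1, 2, 3):
        raise ValidationError(f"lobular grade must be 0-3, got {lobular_grade}")
    if ballooning not in (0, 1):
        raise ValidationError(f"ballooning must be 0 or 1, got {ballooning}")
    total = steatosis_grade + lobular_grade + ballooning
    return total, total >= NASH_THRESHOLD


def score_record(
    subject_id: str,
    steatosis_pct: float,
    lobular_foci: int,
    ballooning: int,
    portal_inflammation: int = 0,
    fibrosis: int = 0,
    vessel_dilatation: int = 0,
    steatosis_pct_micro: Optional[float] = None,
) -> HistologyRecord:
    """Grade raw observations for one biopsy and complete the record.

    When a separate microvesicular percentage is given, the steatosis grade
    entering the composite is the maximum of the macro- and micro-derived
    grades; ``steatosis_pct`` then refers to the macrovesicular reading.
    """
    for name, flag in (
        ("portal_inflammation", portal_inflammation),
        ("fibrosis", fibrosis),
        ("vessel_dilatation", vessel_dilatation),
        ("ballooning", ballooning),
    ):
        if flag not in (0, 1):
            raise ValidationError(f"{name} must be 0 or 1, got {flag}")
    s_grade = grade_steatosis(steatosis_pct)
    if steatosis_pct_micro is not None:
        s_grade = max(s_grade, grade_steatosis(steatosis_pct_micro))
    l_grade = grade_lobular_inflammation(lobular_foci)
    total, nash = score_nash(s_grade, l_grade, ballooning)
    return HistologyRecord(
        subject_id=subject_id,
        steatosis_pct=float(steatosis_pct),
        steatosis_grade=s_grade,
        lobular_foci=int(lobular_foci),
        lobular_grade=l_grade,
        ballooning=int(ballooning),
        portal_inflammation=int(portal_inflammation),
        fibrosis=int(fibrosis),
        vessel_dilatation=int(vessel_dilatation),
        sum_score=total,
        nash=nash,
    )


def score_table(df: pd.DataFrame) -> pd.DataFrame:
    """Grade a raw ``histology.csv`` table; returns the scored table.

    Input columns: subject_id, steatosis_pct, lobular_foci, ballooning,
    portal_inflammation, fibrosis, vessel_dilatation.  Output adds
    steatosis_grade, lobular_grade, sum_score and nash.
    """
    rows = []
    for _, row in df.iterrows():
        rec = score_record(
            subject_id=str(row["subject_id"]),
            steatosis_pct=row["steatosis_pct"],
            lobular_foci=row["lobular_foci"],
            ballooning=int(row["ballooning"]),
            portal_inflammation=int(row["portal_inflammation"]),
            fibrosis=int(row["fibrosis"]),
            vessel_dilatation=int(row["vessel_dilatation"]),
        )
        rows.append(
            {
                "subject_id": rec.subject_id,
                "steatosis_pct": rec.steatosis_pct,
                "steatosis_grade": rec.steatosis_grade,
                "lobular_foci": rec.lobular_foci,
                "lobular_grade": rec.lobular_grade,
                "ballooning": rec.ballooning,
                "portal_inflammation": rec.portal_inflammation,
                "fibrosis": rec.fibrosis,
                "vessel_dilatation": rec.vessel_dilatation,
                "sum_score": rec.sum_score,
                "nash": rec.nash,
            }
        )
    return pd.DataFrame(rows)
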
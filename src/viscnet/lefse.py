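"""LEfSe-style biomarker discovery on relative-abundance tables.

Two-stage procedure on a total-sum-normalised features-by-subjects table
with one class label per subject:

1. a nonparametric class screen per feature — the Wilcoxon rank-sum test
   for two classes (exact when both samples are small and untied, normal
   approximation with tie correction otherwise) or the tie-corrected
   Kruskal-Wallis test for three or more classes; features that are
   constant across all subjects get p = 1 by convention;
2. an effect size for the screened features: relative abundances are put
   on the 1-10^6 scale the reference method uses, a one-dimensional linear
   discriminant is fitted per feature, and the effect size averages the
   absolute discriminant-projected class-mean difference with the raw
   class-mean difference.  With a single feature and a unit-normalised
   discriminant direction both terms reduce to the absolute class-mean
   difference.  The reported score is ``log10(1 + effect size)`` and a
   feature is called a biomarker when the screen passes at level alpha AND
   the score strictly exceeds the threshold (default 3.0).

For more than two classes the enriched class and effect size are taken
one-vs-rest (largest mean difference).  An optional strict mode adds the
original tool's pairwise rank-sum consistency substage; an optional seeded
bootstrap mode averages the effect size over subsampled refits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

#: Scale factor mapping relative abundances (summing to 1) onto the
#: 1-10^6 range used by the reference effect-size construction.
ABUNDANCE_SCALE = 1e6

DEFAULT_ALPHA = 0.05
DEFAULT_LDA_THRESHOLD = 3.0


@dataclass
class AbundanceTable:
    """Features-by-subjects abundance matrix with per-subject class labels."""

    feature_ids: List[str]
    subject_ids: List[str]
    values: np.ndarray
    class_labels: List[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.subject_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.subject_ids)} subjects"
            )
        if len(self.class_labels) != len(self.subject_ids):
            raise ValidationError("one class label per subject required")
        if np.any(self.values < 0):
            raise ValidationError("abundance values must be >= 0")
        if self.normalized:
            sums = self.values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValidationError("normalized table columns must sum to 1")

    @property
    def classes(self) -> List[str]:
        seen: List[str] = []
        for c in self.class_labels:
            if c not in seen:
                seen.append(c)
        return seen

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.feature_ids, name="feature_id"),
            columns=self.subject_ids,
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, class_labels: Dict[str, str], normalized: bool = False
    ) -> "AbundanceTable":
        """Build from a features-by-subjects DataFrame and a label map."""
        missing = [s for s in df.columns if s not in class_labels]
        if missing:
            raise ValidationError(f"no class label for subject(s) {missing}")
        return cls(
            feature_ids=[str(f) for f in df.index],
            subject_ids=[str(s) for s in df.columns],
            values=df.to_numpy(dtype=float),
            class_labels=[class_labels[s] for s in df.columns],
            normalized=normalized,
        )


@dataclass
class BiomarkerResult:
    feature_id: str
    kw_p: float
    lda_score: float
    enriched_class: str
    called: bool


def total_sum_normalize(table: AbundanceTable) -> AbundanceTable:
    """Divide each subject column by its sum (idempotent).

    An all-zero column has no defined composition and is a validation error
    naming the subject.
    """
    sums = table.values.sum(axis=0)
    zero = np.nonzero(sums == 0)[0]
    if zero.size:
        raise ValidationError(
            f"all-zero abundance column(s) for subject(s) "
            f"{[table.subject_ids[i] for i in zero]}"
        )
    return AbundanceTable(
        feature_ids=list(table.feature_ids),
        subject_ids=list(table.subject_ids),
        values=table.values / sums,
        class_labels=list(table.class_labels),
        normalized=True,
    )


def _class_masks(table: AbundanceTable) -> Dict[str, np.ndarray]:
    labels = np.asarray(table.class_labels)
    return {c: labels == c for c in table.classes}


def _screen_p(groups: Sequence[np.ndarray]) -> float:
    """Class-difference p for one feature; p = 1 for an all-equal feature."""
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 1.0
    if len(groups) == 2:
        # exact rank-sum when feasible (small untied samples), else
        # tie-corrected normal approximation
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        return float(res.pvalue)
    return float(stats.kruskal(*groups).pvalue)


def kw_screen(table: AbundanceTable, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Nonparametric class screen per feature.

    Returns a DataFrame with columns feature_id, p, passed.  Requires at
    least two classes with at least two subjects each.
    """
    if not table.normalized:
        raise ValidationError("screen expects a total-sum-normalized table")
    masks = _class_masks(table)
    if len(masks) < 2:
        raise ValidationError("need at least two classes")
    for c, m in masks.items():
        if m.sum() < 2:
            raise ValidationError(f"class {c!r} has fewer than 2 subjects")
    rows = []
    for i, fid in enumerate(table.feature_ids):
        groups = [table.values[i, m] for m in masks.values()]
        p = _screen_p(groups)
        rows.append({"feature_id": fid, "p": p, "passed": p <= alpha})
    return pd.DataFrame(rows)


def _effect_size_two_class(x: np.ndarray, mask_a: np.ndarray) -> float:
    """Effect size of one feature (already on the 1-10^6 scale) for one
    class split: mean of |discriminant-projected class-mean difference| and
    |raw class-mean difference|.  The 1-D discriminant direction is
    unit-normalised, so both terms coincide; they are kept separate so a
    bootstrap refit averages meaningfully."""
    m_a = x[mask_a].mean()
    m_b = x[~mask_a].mean()
    raw_diff = abs(m_a - m_b)
    w = np.sign(m_a - m_b) if m_a != m_b else 1.0  # unit-norm 1-D direction
    proj_diff = abs(w * (m_a - m_b))
    return 0.5 * (proj_diff + raw_diff)


def lda_effect_size(
    table: AbundanceTable,
    feature_ids: Sequence[str],
    n_bootstrap: int = 0,
    subsample_fraction: float = 2.0 / 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-feature discriminant effect size and enriched class.

    ``lda_score = log10(1 + effect size)`` with the effect size measured on
    relative abundances rescaled by 10^6.  With ``n_bootstrap > 0`` the
    effect size is averaged over seeded subsampled refits (the reference
    tool's bootstrap averaging); the default is a single deterministic fit.
    For more than two classes the score is the largest one-vs-rest effect.
    A feature with zero between-class separation gets score 0 (below any
    positive threshold), never an error.
    """
    if not table.normalized:
        raise ValidationError("effect size expects a total-sum-normalized table")
    feature_ids = list(feature_ids)
    if not feature_ids:
        raise ValidationError("no screened features to score")
    index = {fid: i for i, fid in enumerate(table.feature_ids)}
    unknown = [f for f in feature_ids if f not in index]
    if unknown:
        raise ValidationError(f"unknown feature(s) {unknown}")
    masks = _class_masks(table)
    if len(masks) < 2:
        raise ValidationError("need at least two classes")
    rng = np.random.default_rng(seed)
    n_subjects = len(table.subject_ids)

    rows = []
    for fid in feature_ids:
        x = table.values[index[fid]] * ABUNDANCE_SCALE
        class_means = {c: x[m].mean() for c, m in masks.items()}
        enriched = max(class_means, key=class_means.get)

        def one_fit(xs: np.ndarray, ms: Dict[str, np.ndarray]) -> float:
            return max(
                _effect_size_two_class(xs, m) for m in ms.values()
            ) if len(ms) > 2 else _effect_size_two_class(
                xs, next(iter(ms.values()))
            )

        if n_bootstrap <= 0:
            effect = one_fit(x, masks)
        else:
            effects = []
            k = max(2, int(round(subsample_fraction * n_subjects)))
            for _ in range(n_bootstrap):
                idx = rng.choice(n_subjects, size=k, replace=False)
                sub_masks = {c: m[idx] for c, m in masks.items()}
                # a subsample missing a class contributes nothing
                if any(m.sum() == 0 for m in sub_masks.values()):
                    continue
                effects.append(one_fit(x[idx], sub_masks))
            effect = float(np.mean(effects)) if effects else 0.0
        score = float(np.log10(1.0 + effect))
        rows.append(
            {"feature_id": fid, "lda_score": score, "enriched_class": enriched}
        )
    return pd.DataFrame(rows)


def _pairwise_consistent(
    table: AbundanceTable, feature_index: int, enriched: str, alpha: float
) -> bool:
    """Strict-mode substage: the enriched class must win every pairwise
    rank-sum comparison at level alpha with a consistent direction."""
    masks = _class_masks(table)
    x = table.values[feature_index]
    for c, m in masks.items():
        if c == enriched:
            continue
        a, b = x[masks[enriched]], x[m]
        if np.all(np.concatenate([a, b]) == a[0] if a.size else False):
            return False
        p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        if p > alpha or a.mean() <= b.mean():
            return False
    return True


def run_lefse(
    table: AbundanceTable,
    alpha: float = DEFAULT_ALPHA,
    lda_threshold: float = DEFAULT_LDA_THRESHOLD,
    strict: bool = False,
    n_bootstrap: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Full biomarker discovery: normalise if needed, screen, score, call.

    A feature is called when the class screen passes at ``alpha`` and the
    effect-size score strictly exceeds ``lda_threshold`` (and, in strict
    mode, the pairwise consistency substage holds).  Returns one row per
    feature with kw_p, lda_score, enriched_class and called.
    """
    if not table.normalized:
        table = total_sum_normalize(table)
    screen = kw_screen(table, alpha)
    scores = lda_effect_size(
        table, list(table.feature_ids), n_bootstrap=n_bootstrap, seed=seed
    )
    out = screen.merge(scores, on="feature_id")
    out = out.rename(columns={"p": "kw_p"})
    called = out["passed"] & (out["lda_score"] > lda_threshold)
    if strict:
        index = {fid: i for i, fid in enumerate(table.feature_ids)}
        consistent = [
            _pairwise_consistent(table, index[r.feature_id], r.enriched_class, alpha)
            for r in out.itertuples()
        ]
        called = called & pd.Series(consistent, index=out.index)
    out["called"] = called
    return out.drop(columns=["passed"]).sort_values(
        "lda_score", ascending=False, ignore_index=True
    )
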
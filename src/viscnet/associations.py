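"""Group comparisons and the imaging-microbiota correlation screen.

Univariate associations between imaging metrics and taxon/pathway relative
abundances use Spearman's rank correlation with midrank tie correction.
P-values come from the asymptotic t approximation for n >= 10 paired
observations and from exact enumeration of all pairings for smaller n
(where the t approximation is unreliable).  The whole X-by-Y screen is
treated as one family and adjusted with the Benjamini-Hochberg step-up
procedure.  Group comparisons dispatch to Welch's unequal-variance t-test
for two groups and one-way ANOVA for more.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Minimum paired complete observations for a correlation to be computed.
MIN_PAIRS = 4
#: Below this n the exact permutation null is enumerated instead of the
#: t approximation.
EXACT_N_THRESHOLD = 10


@dataclass
class AssociationResult:
    x_name: str
    y_name: str
    rho: float
    p: float
    q: float
    n: int


def _spearman_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for Spearman's rho (ties via midranks).

    Enumerates all n! pairings of the y-ranks against the x-ranks; feasible
    for the n < 10 cases it is used for.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = x.size
    rx_c = rx - rx.mean()
    sx = np.sqrt((rx_c ** 2).sum())
    ry_c = ry - ry.mean()
    sy = np.sqrt((ry_c ** 2).sum())
    if sx == 0 or sy == 0:
        return 1.0
    obs = float((rx_c * ry_c).sum() / (sx * sy))
    perms = np.array(list(itertools.permutations(ry_c)))
    rhos = perms @ rx_c / (sx * sy)
    return float(np.mean(np.abs(rhos) >= abs(obs) - 1e-12))


def spearman_pair(x: Sequence[float], y: Sequence[float]) -> tuple:
    """Tie-corrected Spearman rho and two-sided p for one complete pair set."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("paired vectors must have equal length")
    if x.size < MIN_PAIRS:
        raise ValidationError(f"need at least {MIN_PAIRS} complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), 1.0
    if x.size < EXACT_N_THRESHOLD:
        rho = float(stats.spearmanr(x, y).statistic)
        return rho, _spearman_exact_p(x, y)
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def spearman_matrix(X: pd.DataFrame, Y: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Spearman screen between metric columns and abundance columns.

    ``X`` and ``Y`` are subject-by-variable DataFrames sharing their index
    (subject ids); missing values are handled pairwise-complete-case.
    Pairs with fewer than 4 complete observations are skipped with a logged
    warning.  Returns the unadjusted screen (columns x_name, y_name, rho,
    p, n); apply :func:`bh_adjust` for the family-wise q values or use
    :func:`associate`.
    """
    common = X.index.intersection(Y.index)
    if len(common) == 0:
        raise ValidationError("X and Y share no subjects")
    X = X.loc[common]
    Y = Y.loc[common]
    rows = []
    for x_name in X.columns:
        xv = X[x_name].to_numpy(dtype=float)
        for y_name in Y.columns:
            yv = Y[y_name].to_numpy(dtype=float)
            ok = ~(np.isnan(xv) | np.isnan(yv))
            n = int(ok.sum())
            if n < MIN_PAIRS:
                logger.warning(
                    "skipping (%s, %s): only %d complete pairs", x_name, y_name, n
                )
                continue
            rho, p = spearman_pair(xv[ok], yv[ok])
            rows.append(
                {"x_name": x_name, "y_name": y_name, "rho": rho, "p": p, "n": n}
            )
    return pd.DataFrame(rows, columns=["x_name", "y_name", "rho", "p", "n"])


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class GroupComparison:
    test: str  # "welch_t" or "anova"
    statistic: float
    p: float
    group_means: Dict[str, float]
    group_sems: Dict[str, float]


def group_compare(values: Sequence[float], groups: Sequence[str]) -> GroupComparison:
    """Compare a per-subject metric between groups.

    Two groups dispatch to Welch's unequal-variance two-sided t-test; three
    or more to one-way ANOVA.  Every group needs at least two subjects.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.size != groups.size:
        raise ValidationError("values and group labels must have equal length")
    ok = ~np.isnan(values)
    values, groups = values[ok], groups[ok]
    labels = list(dict.fromkeys(groups.tolist()))
    if len(labels) < 2:
        raise ValidationError("need at least two groups")
    samples = [values[groups == g] for g in labels]
    for g, s in zip(labels, samples):
        if s.size < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 subjects")
    means = {g: float(s.mean()) for g, s in zip(labels, samples)}
    sems = {g: float(s.std(ddof=1) / np.sqrt(s.size)) for g, s in zip(labels, samples)}
    if np.all(values == values[0]):
        test = "welch_t" if len(labels) == 2 else "anova"
        return GroupComparison(test, 0.0, 1.0, means, sems)
    if len(labels) == 2:
        stat, p = stats.ttest_ind(samples[0], samples[1], equal_var=False)
        return GroupComparison("welch_t", float(stat), float(p), means, sems)
    stat, p = stats.f_oneway(*samples)
    return GroupComparison("anova", float(stat), float(p), means, sems)


def associate(X: pd.DataFrame, Y: pd.DataFrame) -> pd.DataFrame:
    """Full correlation screen with BH-FDR q values, sorted by q.

    One adjustment family spans all pairs of the screen.  Output columns:
    x_name, y_name, rho, p, q, n.
    """
    out = spearman_matrix(X, Y)
    if len(out):
        out["q"] = bh_adjust(out["p"])
    else:
        out["q"] = pd.Series(dtype=float)
    return out.sort_values(["q", "p"], ignore_index=True, kind="stable")
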
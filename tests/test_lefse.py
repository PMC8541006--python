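"""Biomarker discovery: normalisation, class screen, effect size, power."""

import itertools

import numpy as np
import pytest

from viscnet import (
    AbundanceTable,
    ValidationError,
    generate_taxa_table,
    kw_screen,
    lda_effect_size,
    run_lefse,
    total_sum_normalize,
)
from viscnet.lefse import ABUNDANCE_SCALE


def _table(values, labels, normalized=False):
    values = np.asarray(values, dtype=float)
    return AbundanceTable(
        feature_ids=[f"f{i}" for i in range(values.shape[0])],
        subject_ids=[f"s{j}" for j in range(values.shape[1])],
        values=values,
        class_labels=list(labels),
        normalized=normalized,
    )


def exact_ranksum_p(x, y):
    """Enumeration oracle: two-sided rank-sum p over all C(n+m, n) labelings."""
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    n = len(x)
    obs = ranks[:n].sum()
    mean = n * (len(pooled) + 1) / 2.0
    stats = [
        sum(ranks[list(idx)])
        for idx in itertools.combinations(range(len(pooled)), n)
    ]
    extreme = sum(abs(s - mean) >= abs(obs - mean) - 1e-12 for s in stats)
    return extreme / len(stats)


class TestNormalize:
    def test_counts_become_proportions(self):
        t = _table([[2], [3], [5]], ["A"])
        out = total_sum_normalize(t)
        np.testing.assert_allclose(out.values[:, 0], [0.2, 0.3, 0.5])
        assert out.normalized

    def test_idempotent(self):
        t = _table([[2, 1], [3, 1], [5, 2]], ["A", "B"])
        once = total_sum_normalize(t)
        twice = total_sum_normalize(once)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_all_zero_column_names_subject(self):
        t = _table([[1, 0], [2, 0]], ["A", "B"])
        with pytest.raises(ValidationError, match="s1"):
            total_sum_normalize(t)


class TestScreen:
    def test_constant_feature_gets_p_one(self):
        t = _table(
            [[0.5] * 8, [0.5] * 8], ["A"] * 4 + ["B"] * 4, normalized=True
        )
        out = kw_screen(t)
        assert out["p"].tolist() == [1.0, 1.0]
        assert not out["passed"].any()

    def test_separated_4v4_matches_enumeration_oracle(self):
        """Completely separated 4+4 samples: exact two-sided rank p = 2/70."""
        lo = [0.1, 0.11, 0.12, 0.13]
        hi = [0.3, 0.31, 0.32, 0.33]
        feat = np.array(lo + hi)
        t = _table(np.vstack([feat, 1 - feat]), ["A"] * 4 + ["B"] * 4,
                   normalized=True)
        out = kw_screen(t, alpha=0.05)
        assert out.loc[0, "p"] == pytest.approx(2 / 70, abs=1e-12)
        assert out.loc[0, "p"] == pytest.approx(
            exact_ranksum_p(np.array(lo), np.array(hi)), abs=1e-12
        )
        assert bool(out.loc[0, "passed"])

    def test_three_class_path_uses_kruskal_wallis(self):
        rng = np.random.default_rng(0)
        feat = rng.random(9)
        t = _table(np.vstack([feat, 1 - feat]), ["A"] * 3 + ["B"] * 3 + ["C"] * 3,
                   normalized=True)
        from scipy.stats import kruskal

        expected = kruskal(feat[:3], feat[3:6], feat[6:]).pvalue
        assert kw_screen(t).loc[0, "p"] == pytest.approx(expected, rel=1e-12)

    def test_small_class_rejected(self):
        t = _table([[0.5, 0.5, 0.5], [0.5, 0.5, 0.5]], ["A", "A", "B"],
                   normalized=True)
        with pytest.raises(ValidationError):
            kw_screen(t)

    def test_type_one_error_calibrated_under_null(self):
        """1000 null taxa, two classes of 19: the screen rejects at the
        nominal 5% level (within a 3.5-sigma binomial band)."""
        table = generate_taxa_table(
            [f"s{i}" for i in range(38)],
            ["A"] * 19 + ["B"] * 19,
            n_taxa=1000,
            seed=42,
        )
        out = kw_screen(table, alpha=0.05)
        rate = out["passed"].mean()
        band = 3.5 * np.sqrt(0.05 * 0.95 / 1000)
        assert abs(rate - 0.05) <= band


class TestEffectSize:
    def test_identical_class_means_not_called(self):
        feat = np.array([0.2, 0.3, 0.2, 0.3])
        t = _table(np.vstack([feat, 1 - feat]), ["A", "A", "B", "B"],
                   normalized=True)
        out = lda_effect_size(t, ["f0"])
        assert out.loc[0, "lda_score"] == 0.0
        res = run_lefse(t, lda_threshold=3.0)
        assert not res.loc[res.feature_id == "f0", "called"].iloc[0]

    def test_score_matches_independent_formula(self):
        """Toy two-class table (6+6, means 0.30 vs 0.03 with jitter): the
        implementation equals a from-scratch evaluation of the score
        formula to 1e-6."""
        rng = np.random.default_rng(8)
        a = 0.30 + rng.normal(0, 0.01, 6)
        b = 0.03 + rng.normal(0, 0.005, 6)
        feat = np.concatenate([a, b])
        t = _table(np.vstack([feat, 1 - feat]), ["A"] * 6 + ["B"] * 6,
                   normalized=True)
        out = lda_effect_size(t, ["f0"])
        scaled = feat * ABUNDANCE_SCALE
        raw_diff = abs(scaled[:6].mean() - scaled[6:].mean())
        proj_diff = raw_diff  # unit-norm 1-D discriminant direction
        expected = np.log10(1.0 + 0.5 * (raw_diff + proj_diff))
        assert out.loc[0, "lda_score"] == pytest.approx(expected, abs=1e-6)
        assert out.loc[0, "enriched_class"] == "A"

    def test_single_feature_discriminant_agrees_with_sklearn_lda(self):
        """Cross-check: projecting on sklearn's fitted LDA direction
        (unit-normalised) reproduces the class-mean difference our score
        uses."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(3)
        feat = np.concatenate([0.2 + rng.normal(0, 0.02, 8),
                               0.05 + rng.normal(0, 0.02, 8)])
        feat = np.clip(feat, 1e-4, None)
        labels = np.array(["A"] * 8 + ["B"] * 8)
        X = (feat * ABUNDANCE_SCALE).reshape(-1, 1)
        lda = LinearDiscriminantAnalysis(solver="lsqr").fit(X, labels)
        w = lda.coef_.ravel()
        w_unit = w / np.linalg.norm(w)
        proj = X.ravel() * w_unit[0]
        sk_diff = abs(proj[labels == "A"].mean() - proj[labels == "B"].mean())
        t = _table(np.vstack([feat, 1 - feat]), labels, normalized=True)
        out = lda_effect_size(t, ["f0"])
        assert out.loc[0, "lda_score"] == pytest.approx(
            np.log10(1.0 + sk_diff), rel=1e-9
        )

    def test_threshold_is_strict(self):
        # effect size 999 on the 1e6 scale -> score log10(1000) = 3.0
        feat = np.array([0.001999] * 4 + [0.001] * 4)
        t = _table(np.vstack([feat, 1 - feat]), ["A"] * 4 + ["B"] * 4,
                   normalized=True)
        res = run_lefse(t, lda_threshold=3.0)
        row = res[res.feature_id == "f0"].iloc[0]
        assert row["lda_score"] == pytest.approx(3.0, abs=1e-12)
        assert not row["called"]  # "> 3.0" is strict

    def test_bootstrap_mode_is_seeded_and_deterministic(self):
        rng = np.random.default_rng(5)
        feat = np.concatenate([0.2 + rng.normal(0, 0.02, 6),
                               0.05 + rng.normal(0, 0.01, 6)])
        t = _table(np.vstack([feat, 1 - feat]), ["A"] * 6 + ["B"] * 6,
                   normalized=True)
        a = lda_effect_size(t, ["f0"], n_bootstrap=30, seed=1)
        b = lda_effect_size(t, ["f0"], n_bootstrap=30, seed=1)
        assert a.loc[0, "lda_score"] == b.loc[0, "lda_score"]


class TestPipelineProperties:
    def test_subject_permutation_invariance(self):
        rng = np.random.default_rng(2)
        values = rng.random((5, 12))
        values /= values.sum(axis=0)
        labels = ["A"] * 6 + ["B"] * 6
        t = _table(values, labels, normalized=True)
        perm = rng.permutation(12)
        tp = AbundanceTable(
            feature_ids=list(t.feature_ids),
            subject_ids=[t.subject_ids[j] for j in perm],
            values=values[:, perm],
            class_labels=[labels[j] for j in perm],
            normalized=True,
        )
        a = run_lefse(t).set_index("feature_id")
        b = run_lefse(tp).set_index("feature_id")
        for fid in t.feature_ids:
            assert a.loc[fid, "kw_p"] == pytest.approx(b.loc[fid, "kw_p"], rel=1e-12)
            assert a.loc[fid, "lda_score"] == pytest.approx(
                b.loc[fid, "lda_score"], rel=1e-12
            )

    def test_lda_score_monotone_in_planted_fold_change(self):
        """Noise-free 10-point fold-change sweep: the planted taxon's score
        never decreases as the planted effect grows."""
        scores = []
        for lfc in np.linspace(0.5, 5.0, 10):
            table = generate_taxa_table(
                [f"s{i}" for i in range(16)],
                ["A"] * 8 + ["B"] * 8,
                n_taxa=20,
                planted_effects={"taxon_0001": ("A", float(lfc))},
                sigma=0.0,
                seed=6,
            )
            out = lda_effect_size(table, ["taxon_0001"])
            scores.append(out.loc[0, "lda_score"])
        assert np.all(np.diff(scores) >= 0)

    def test_planted_fourfold_biomarker_recovered(self):
        """One taxon with a 4-fold planted effect, 10 vs 10 subjects: the
        full screen + effect-size stage flags it in >= 90% of 200 seeded
        replicates."""
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            table = generate_taxa_table(
                [f"s{i}" for i in range(20)],
                ["A"] * 10 + ["B"] * 10,
                n_taxa=30,
                planted_effects={"taxon_0001": ("A", 2.0)},  # log2(4) = 2
                seed=10_000 + rep,
            )
            res = run_lefse(table)
            row = res[res.feature_id == "taxon_0001"].iloc[0]
            if row["called"] and row["enriched_class"] == "A":
                hits += 1
        assert hits / n_rep >= 0.90
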
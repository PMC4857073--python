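"""Confusion-matrix collapse, diagnostic metrics, ROC and cut-offs.

Oracles: exact rational arithmetic (fractions.Fraction) for the 2x2
metrics, brute-force O(n^2) pairwise Mann-Whitney counting for AUROC,
and exhaustive threshold search for cut-off selection.
"""

import math
from fractions import Fraction

import numpy as np
import pytest

from breathprint.diagnostics import (
    BinaryTable,
    ConfusionMatrix,
    auroc_bootstrap_ci,
    binary_metrics,
    collapse,
    roc,
    roc_stability,
    round_half_up,
    select_cutoff,
)
from breathprint.errors import (
    CohortSchemaError,
    InfeasibleCutoffError,
    SingleClassError,
    UndefinedMetricError,
)
from breathprint.reference import REFERENCE_CONFUSION


def brute_force_auroc(scores, labels, direction="lower_is_positive"):
    """Oracle: count positive-negative pairs, ties credited 1/2."""
    s = np.asarray(scores, float)
    if direction == "lower_is_positive":
        s = -s
    pos = s[np.asarray(labels) == 1]
    neg = s[np.asarray(labels) == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestCollapse:
    def test_child_pugh_compensated_vs_decompensated(self):
        t = collapse(REFERENCE_CONFUSION["child_pugh"], positive=["A", "B"], negative=["C"])
        assert (t.tp, t.fp, t.fn, t.tn) == (42, 6, 6, 11)

    def test_cirrhosis_vs_noncirrhotic_restricted_to_disease_predictions(self):
        t = collapse(
            REFERENCE_CONFUSION["disease_stage"],
            positive=["LC"],
            negative=["NC_CLD"],
            restrict_predicted=["LC", "NC_CLD"],
        )
        assert (t.tp, t.fp, t.fn, t.tn) == (49, 12, 7, 27)

    def test_disease_vs_healthy_unrestricted(self):
        t = collapse(
            REFERENCE_CONFUSION["disease_stage"],
            positive=["LC", "NC_CLD"],
            negative=["CTRL"],
        )
        assert (t.tp, t.fp, t.fn, t.tn) == (95, 1, 9, 55)

    def test_identity_matrix_collapses_without_errors(self):
        cm = ConfusionMatrix(("x", "y"), np.diag([5, 5]))
        t = collapse(cm, positive=["x"], negative=["y"])
        assert (t.tp, t.fp, t.fn, t.tn) == (5, 0, 0, 5)

    def test_overlapping_or_unknown_labels_rejected(self):
        cm = ConfusionMatrix(("x", "y"), np.diag([5, 5]))
        with pytest.raises(CohortSchemaError):
            collapse(cm, positive=["x"], negative=["x"])
        with pytest.raises(CohortSchemaError):
            collapse(cm, positive=["z"], negative=["y"])


class TestBinaryMetrics:
    def test_matches_exact_fraction_oracle(self):
        t = BinaryTable(tp=42, fp=6, fn=6, tn=11)
        m = binary_metrics(t)
        sens = Fraction(42, 48)
        spec = Fraction(11, 17)
        assert m.sensitivity == pytest.approx(float(sens), rel=1e-15)
        assert m.lr_pos == pytest.approx(float(sens / (1 - spec)), rel=1e-12)
        assert round_half_up(m.lr_pos) == 2.5  # (42/48)/(6/17) = 2.479...

    def test_aetiology_table_reproduces_printed_one_decimal_metrics(self):
        m = binary_metrics(BinaryTable(tp=9, fp=6, fn=22, tn=44))
        assert round_half_up(100 * m.sensitivity) == 29.0
        assert round_half_up(100 * m.specificity) == 88.0
        assert round_half_up(m.lr_pos) == 2.4
        assert round_half_up(m.lr_neg) == 0.8
        assert round_half_up(100 * m.ppv) == 60.0
        assert round_half_up(100 * m.npv) == 66.7

    def test_perfect_table_yields_infinite_positive_likelihood_ratio(self):
        m = binary_metrics(BinaryTable(tp=1, fp=0, fn=0, tn=1))
        assert m.sensitivity == 1.0
        assert m.specificity == 1.0
        assert m.lr_pos == math.inf
        assert m.lr_neg == 0.0

    @pytest.mark.parametrize(
        "table, margin",
        [
            (BinaryTable(0, 3, 0, 4), "tp\\+fn"),
            (BinaryTable(3, 0, 4, 0), "tn\\+fp"),
            (BinaryTable(0, 0, 3, 4), "tp\\+fp"),
            (BinaryTable(3, 4, 0, 0), "tn\\+fn"),
        ],
    )
    def test_zero_margins_are_named_in_error(self, table, margin):
        with pytest.raises(UndefinedMetricError, match=margin):
            binary_metrics(table)


class TestROC:
    def test_perfect_separation_lower_scores_positive(self):
        r = roc([1, 2, 3, 4], [1, 1, 0, 0], "lower_is_positive")
        assert r.auroc == 1.0

    def test_all_tied_scores_give_half(self):
        r = roc([5, 5, 5, 5], [1, 1, 0, 0])
        assert r.auroc == 0.5

    def test_matches_brute_force_mann_whitney_with_ties(self, rng):
        for n in (5, 12, 30, 50):
            scores = rng.integers(0, 10, size=n).astype(float)  # many ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            for direction in ("lower_is_positive", "higher_is_positive"):
                r = roc(scores, labels, direction)
                assert r.auroc == pytest.approx(
                    brute_force_auroc(scores, labels, direction), abs=1e-12
                )

    def test_direction_reversal_complements_auroc(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        a = roc(scores, labels, "lower_is_positive").auroc
        b = roc(scores, labels, "higher_is_positive").auroc
        assert a == pytest.approx(1.0 - b, abs=1e-12)

    def test_operating_points_monotone(self, rng):
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        r = roc(scores, labels)
        assert np.all(np.diff(r.sensitivity) >= 0)
        assert np.all(np.diff(r.specificity) <= 0)

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            roc([1, 2, 3], [1, 1, 1])


class TestBootstrapCI:
    def test_perfect_separation_degenerate_interval(self):
        lo, hi = auroc_bootstrap_ci(
            [1, 2, 3, 10, 11, 12], [1, 1, 1, 0, 0, 0], n_boot=200, seed=0
        )
        assert (lo, hi) == (1.0, 1.0)

    def test_reproducible_under_seed(self, rng):
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, size=60)
        labels[:4] = [0, 0, 1, 1]
        a = auroc_bootstrap_ci(scores, labels, n_boot=500, seed=42)
        b = auroc_bootstrap_ci(scores, labels, n_boot=500, seed=42)
        assert a == b

    def test_covers_analytic_binormal_auroc(self):
        # two Gaussians shifted by delta: AUROC = Phi(delta / sqrt(2) sigma)
        delta, sigma, n = 1.0, 1.0, 500
        analytic = 0.5 * (1 + math.erf(delta / (sigma * math.sqrt(2)) / math.sqrt(2)))
        covered = 0
        runs = 100
        for seed in range(runs):
            r = np.random.default_rng(seed)
            scores = np.concatenate(
                [r.normal(0, sigma, n), r.normal(delta, sigma, n)]
            )
            labels = np.concatenate([np.zeros(n, int), np.ones(n, int)])
            lo, hi = auroc_bootstrap_ci(
                scores, labels, "higher_is_positive", n_boot=2000, seed=seed
            )
            covered += lo <= analytic <= hi
        assert covered >= 90


class TestStability:
    def test_permuted_mean_near_half(self, default_aubp, default_cohort):
        labels = (default_cohort["group"] != "CTRL").to_numpy().astype(int)
        stab = roc_stability(
            default_aubp, labels, n_resamples=2, n_permutations=500, seed=0
        )
        assert 0.42 <= stab.mean_permuted <= 0.58

    def test_perfect_input_resampled_mean_is_one(self):
        stab = roc_stability(
            [1, 2, 3, 10, 11, 12], [1, 1, 1, 0, 0, 0],
            n_resamples=10, n_permutations=5, seed=0,
        )
        assert stab.mean_resampled == 1.0

    def test_deterministic_under_seed(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        a = roc_stability(scores, labels, seed=9)
        b = roc_stability(scores, labels, seed=9)
        assert np.array_equal(a.permuted_aurocs, b.permuted_aurocs)
        assert a.p_value == b.p_value


class TestSelectCutoff:
    def test_perfect_separation_any_criterion(self):
        r = roc([1, 2, 3, 4], [1, 1, 0, 0], "lower_is_positive")
        for crit, q in (("youden", None), ("min_specificity", 0.9)):
            threshold, m = select_cutoff(r, crit, q=q)
            assert m.sensitivity == 1.0 and m.specificity == 1.0
            assert 2 < threshold < 3

    def test_youden_matches_exhaustive_search_oracle(self, rng):
        scores = np.round(rng.normal(size=40), 1)
        labels = (scores + rng.normal(0, 1, 40) < 0).astype(int)
        labels[:2] = [0, 1]
        r = roc(scores, labels, "lower_is_positive")
        threshold, m = select_cutoff(r, "youden")
        # oracle: try every interior threshold exhaustively (the no-call /
        # all-call extremes are not valid cut-offs)
        best_j, best_spec = -np.inf, -np.inf
        u = np.unique(scores)
        candidates = (u[:-1] + u[1:]) / 2
        for t in candidates:
            call = scores < t
            tp, fp = np.sum(call & (labels == 1)), np.sum(call & (labels == 0))
            sens = tp / labels.sum()
            spec = 1 - fp / (len(labels) - labels.sum())
            j = sens + spec - 1
            if j > best_j or (j == best_j and spec > best_spec):
                best_j, best_spec = j, spec
        assert m.sensitivity + m.specificity - 1 == pytest.approx(best_j, abs=1e-12)
        assert m.specificity == pytest.approx(best_spec, abs=1e-12)

    def test_constrained_criterion_and_infeasibility(self):
        r = roc([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 0, 0], "lower_is_positive")
        _, m = select_cutoff(r, "min_specificity", q=1.0)
        assert m.specificity == 1.0
        with pytest.raises(InfeasibleCutoffError):
            select_cutoff(r, "min_specificity", q=1.1)


def test_round_half_up_breaks_ties_away_from_zero():
    assert round_half_up(0.25, 1) == 0.3
    assert round_half_up(2.45, 1) == 2.5
    assert round_half_up(91.346, 1) == 91.3
    assert round_half_up(math.inf) == math.inf
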
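"""Confusion tabulation, ROC/AUC and cut-point calibration against oracles."""
import numpy as np
import pytest

from paneltmb import (
    SampleProfile,
    confusion_at_cutoff,
    cutoff_sweep,
    optimal_cutpoint,
    roc_curve,
)
from paneltmb.concordance import ConcordanceError, SingleClassError


def profiles_from(panel_values, exome_values, types=None):
    types = types or ["t"] * len(panel_values)
    return [
        SampleProfile(f"s{i}", types[i], exome_values[i], {"p": panel_values[i]})
        for i in range(len(panel_values))
    ]


def pair_count_auc(scores, labels):
    """Mann-Whitney probability-of-correct-ranking: concordant + ties/2."""
    scores, labels = np.asarray(scores), np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    conc = sum(np.sum(p > neg) for p in pos)
    ties = sum(np.sum(p == neg) for p in pos)
    return (conc + 0.5 * ties) / (len(pos) * len(neg))


def brute_force_cutpoint(scores, labels):
    """Exhaustive accuracy scan over midpoint candidates, lowest-first ties."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, bool)
    uniq = np.unique(scores)
    cands = [uniq[0] - 1.0] + [(a + b) / 2 for a, b in zip(uniq, uniq[1:])]
    cands.append(uniq[-1] + 1.0)
    best_t, best_acc = None, -1.0
    for t in cands:
        acc = np.mean((scores >= t) == labels)
        if acc > best_acc:
            best_t, best_acc = t, acc
    return best_t, best_acc


class TestConfusion:
    def test_hand_count(self):
        """Positive call iff TMB >= cutoff on each axis, exome as reference."""
        profiles = profiles_from([12, 8, 15, 3], [11, 9, 20, 2])
        res = confusion_at_cutoff(profiles, "p", 10)
        assert (res.tp, res.fp, res.tn, res.fn) == (2, 0, 2, 0)

    def test_hand_count_with_disagreements(self):
        # (12,11)=TP, (8,20)=FN, (14,3)=FP, (2,2)=TN
        profiles = profiles_from([12, 8, 14, 2], [11, 20, 3, 2])
        res = confusion_at_cutoff(profiles, "p", 10)
        assert (res.tp, res.fp, res.tn, res.fn) == (1, 1, 1, 1)
        assert res.misclassified_pct == pytest.approx(50.0)

    def test_cutoff_zero_makes_everything_positive(self):
        profiles = profiles_from([12, 8, 15, 3], [11, 9, 20, 2])
        res = confusion_at_cutoff(profiles, "p", 0)
        assert (res.fp, res.fn) == (0, 0)
        assert res.tp == 4

    def test_ties_count_as_high(self):
        profiles = profiles_from([10.0], [10.0])
        assert confusion_at_cutoff(profiles, "p", 10).tp == 1

    def test_unknown_panel_errors(self):
        with pytest.raises(ConcordanceError, match="unknown panel"):
            confusion_at_cutoff(profiles_from([1], [1]), "nope", 10)

    def test_matches_brute_tabulation(self, rng):
        panel = rng.lognormal(2, 1, size=200)
        exome = rng.lognormal(2, 1, size=200)
        profiles = profiles_from(panel, exome)
        for cutoff in (5, 10, 20, 40):
            res = confusion_at_cutoff(profiles, "p", cutoff)
            # direct per-sample tabulation
            tp = sum(1 for pv, ev in zip(panel, exome) if pv >= cutoff and ev >= cutoff)
            fp = sum(1 for pv, ev in zip(panel, exome) if pv >= cutoff and ev < cutoff)
            fn = sum(1 for pv, ev in zip(panel, exome) if pv < cutoff and ev >= cutoff)
            tn = 200 - tp - fp - fn
            assert (res.tp, res.fp, res.tn, res.fn) == (tp, fp, tn, fn)
            assert res.n == 200
            assert res.misclassified_pct == pytest.approx(res.fp_pct + res.fn_pct)
            assert res.tp_pct + res.fp_pct + res.tn_pct + res.fn_pct == pytest.approx(100.0)

    def test_single_sample_percentages_are_0_or_100(self):
        for res in cutoff_sweep(profiles_from([12], [12]), "p"):
            assert {res.tp_pct, res.fp_pct, res.tn_pct, res.fn_pct} <= {0.0, 100.0}

    def test_empty_cohort_errors(self):
        with pytest.raises(ConcordanceError, match="empty cohort"):
            cutoff_sweep([], "p")


class TestRoc:
    def test_perfect_separation(self):
        profiles = profiles_from([1, 2, 3, 20, 30, 40], [1, 1, 1, 50, 50, 50])
        roc = roc_curve(profiles, "p", exome_cutoff=10)
        assert roc.auc == 1.0
        assert roc.optimal_accuracy == 1.0

    def test_all_tied_scores_auc_half(self):
        profiles = profiles_from([5, 5, 5, 5], [1, 1, 50, 50])
        assert roc_curve(profiles, "p").auc == 0.5

    def test_single_class_stratum_errors(self):
        profiles = profiles_from([1, 2], [1, 2])
        with pytest.raises(SingleClassError, match="ROC undefined"):
            roc_curve(profiles, "p", exome_cutoff=10)

    def test_unknown_stratum_errors(self):
        profiles = profiles_from([1, 50], [1, 50])
        with pytest.raises(ConcordanceError, match="tumour type"):
            roc_curve(profiles, "p", stratum="missing-type")

    def test_auc_equals_pair_count_oracle(self, rng):
        """Trapezoidal AUC equals the Mann-Whitney statistic, ties included."""
        for _ in range(50):
            n = 50
            scores = rng.integers(0, 15, size=n).astype(float)  # many ties
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            profiles = profiles_from(scores, np.where(labels, 20.0, 0.0))
            roc = roc_curve(profiles, "p", exome_cutoff=10)
            assert roc.auc == pytest.approx(pair_count_auc(scores, labels), abs=1e-12)

    def test_tpr_fpr_monotone(self, rng):
        scores = rng.lognormal(2, 1, size=80)
        labels = rng.lognormal(2, 1, size=80)
        roc = roc_curve(profiles_from(scores, labels), "p")
        assert all(b >= a for a, b in zip(roc.fpr, roc.fpr[1:]))
        assert all(b >= a for a, b in zip(roc.tpr, roc.tpr[1:]))


class TestOptimalCutpoint:
    def test_separable_midpoint(self):
        """Separable scores report the midpoint between the flanking values."""
        cp, acc = optimal_cutpoint([1, 2, 8, 9, 12, 14], [0, 0, 0, 1, 1, 1])
        assert cp == pytest.approx(8.5)
        assert acc == 1.0

    def test_all_positive_threshold_below_min(self):
        cp, acc = optimal_cutpoint([3, 5, 9], [1, 1, 1])
        assert cp < 3
        assert acc == 1.0

    def test_tie_break_lowest_threshold(self):
        # Thresholds 1.5 and 3.5 both give accuracy 3/4; lowest wins.
        cp, acc = optimal_cutpoint([1, 2, 3, 4], [0, 1, 0, 1])
        assert acc == pytest.approx(0.75)
        assert cp == pytest.approx(1.5)

    def test_matches_exhaustive_scan(self, rng):
        """100 random instances agree with the brute-force threshold scan."""
        for _ in range(100):
            n = int(rng.integers(5, 80))
            scores = np.round(rng.normal(10, 4, size=n), 1)
            labels = rng.random(n) < rng.uniform(0.2, 0.8)
            cp, acc = optimal_cutpoint(scores, labels)
            bcp, bacc = brute_force_cutpoint(scores, labels)
            assert acc == pytest.approx(bacc)
            assert cp == pytest.approx(bcp)
            # optimality: no swept threshold beats it
            assert all(
                np.mean((scores >= t) == labels) <= acc + 1e-12
                for t in np.unique(scores)
            )
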
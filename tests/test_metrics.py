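"""Evaluation statistics vs independent enumeration oracles."""

import itertools

import numpy as np
import pytest

from refluxion.io import EventRecord, ValidationError
from refluxion.metrics import (GoldStandardSet, adjudicate, bootstrap_auc_ci,
                               build_nonevent_pool, cohens_kappa, evaluate,
                               match_events, roc_auc, sensitivity_at_fpr,
                               specificity_at_tpr)


def ev(onset, end=None, source="reader_A", **kw):
    return EventRecord(onset, end if end is not None else onset + 10.0,
                       2, source, **kw)


# ---------------------------------------------------------------------------
# matching


class TestMatchEvents:
    def test_within_tolerance_pairs(self):
        pairs, oa, ob = match_events([ev(100)], [ev(103, source="reader_B")], 5.0)
        assert len(pairs) == 1 and not oa and not ob

    def test_outside_tolerance_unmatched(self):
        pairs, oa, ob = match_events([ev(100)], [ev(110, source="reader_B")], 5.0)
        assert not pairs
        assert [e.onset_s for e in oa] == [100.0]
        assert [e.onset_s for e in ob] == [110.0]

    def test_tie_broken_toward_earlier_a(self):
        pairs, oa, ob = match_events([ev(100), ev(104)],
                                     [ev(102, source="reader_B")], 5.0)
        assert [(a.onset_s, b.onset_s) for a, b in pairs] == [(100.0, 102.0)]
        assert [e.onset_s for e in oa] == [104.0]
        assert ob == []

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValidationError):
            match_events([], [], -1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_oracle(self, seed):
        """Greedy nearest-onset matching equals exhaustive search over all
        one-to-one assignments ranked by the same greedy order (n <= 6)."""
        rng = np.random.default_rng(seed)
        a = [ev(float(o)) for o in np.sort(rng.uniform(0, 60, rng.integers(1, 6)))]
        b = [ev(float(o), source="reader_B")
             for o in np.sort(rng.uniform(0, 60, rng.integers(1, 6)))]
        tol = 5.0
        pairs, _, _ = match_events(a, b, tol)
        # oracle: repeatedly take the globally closest admissible pair
        cand = sorted((abs(x.onset_s - y.onset_s), x.onset_s, y.onset_s, i, j)
                      for i, x in enumerate(a) for j, y in enumerate(b)
                      if abs(x.onset_s - y.onset_s) <= tol)
        used_a, used_b, expected = set(), set(), []
        for d, _, _, i, j in cand:
            if i not in used_a and j not in used_b:
                expected.append((a[i].onset_s, b[j].onset_s))
                used_a.add(i)
                used_b.add(j)
        assert sorted((x.onset_s, y.onset_s) for x, y in pairs) == sorted(expected)


# ---------------------------------------------------------------------------
# adjudication


class TestAdjudicate:
    def test_full_concordance_no_tiebreak_needed(self):
        a = [ev(100), ev(200)]
        b = [ev(101, source="reader_B"), ev(199, source="reader_B")]
        gold = adjudicate(a, b, None, 5.0)
        assert gold.n_pos == 2 and gold.n_neg == 0

    def test_discordant_without_reader_c_errors(self):
        with pytest.raises(ValidationError, match="discordant"):
            adjudicate([ev(100)], [], None, 5.0)

    def test_mark_only_in_a_rejected_by_c(self):
        gold = adjudicate([ev(100)], [], [ev(500, source="reader_C")], 5.0)
        assert gold.n_pos == 0 and gold.n_neg == 1
        assert gold.negatives[0].is_event is False

    def test_mark_only_in_b_confirmed_by_c(self):
        gold = adjudicate([], [ev(100, source="reader_B")],
                          [ev(101, source="reader_C")], 5.0)
        assert gold.n_pos == 1 and gold.n_neg == 0

    def test_provenance_recorded_for_all(self):
        gold = adjudicate([ev(100), ev(300)], [ev(101, source="reader_B")],
                          [ev(299, source="reader_C")], 5.0)
        assert len(gold.provenance) == gold.n_pos + gold.n_neg == 2


class TestNoneventPool:
    def _gold(self):
        return GoldStandardSet(
            positives=[ev(100, source="gold", is_event=True),
                       ev(300, source="gold", is_event=True)],
            negatives=[ev(500, source="gold", is_event=False)])

    def test_no_candidates_unchanged(self):
        out = build_nonevent_pool(self._gold(), [], 5.0)
        assert out.n_neg == 1

    def test_candidate_matching_positive_excluded(self):
        out = build_nonevent_pool(self._gold(), [ev(102, source="software")], 5.0)
        assert out.n_neg == 1

    def test_set_arithmetic(self):
        """10 candidates, 4 match positives (only 2 can pair one-to-one),
        2 duplicate existing negatives (1 pairs) -> the rest become new
        negatives."""
        cands = [ev(101, source="software"), ev(103, source="software"),
                 ev(299, source="software"), ev(301, source="software"),
                 ev(499, source="software"), ev(501, source="software"),
                 ev(700, source="software"), ev(800, source="software"),
                 ev(900, source="software"), ev(1000, source="software")]
        out = build_nonevent_pool(self._gold(), cands, 5.0)
        # one-to-one: 2 pair with positives, 2 extra near-positive marks
        # become negatives; of the two near-500 candidates one pairs with
        # the existing negative; 4 are new isolated negatives
        assert out.n_pos == 2
        assert out.n_neg == 1 + 2 + 1 + 4


# ---------------------------------------------------------------------------
# AUC


def pair_counting_auc(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = ties = 0
    for p, n in itertools.product(pos, neg):
        wins += p > n
        ties += p == n
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestRocAuc:
    def test_worked_example(self):
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        scores = rng.choice(np.round(rng.uniform(0, 1, 12), 2), n)
        labels = rng.integers(0, 2, n).astype(bool)
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        assert roc_auc(scores, labels) == pytest.approx(
            pair_counting_auc(scores, labels))

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        scores = rng.uniform(0, 1, 200)
        labels = rng.integers(0, 2, 200).astype(bool)
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores))


# ---------------------------------------------------------------------------
# matched-threshold operating points


def enumerate_best_tpr(scores, labels, target_fpr):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    best = None
    for thr in np.concatenate([np.unique(scores), [np.inf]]):
        fpr = (scores[~labels] >= thr).mean()
        tpr = (scores[labels] >= thr).mean()
        if fpr <= target_fpr and (best is None or tpr > best):
            best = tpr
    return best


TOY = ([0.1, 0.4, 0.35, 0.8], [False, False, True, True])


class TestMatchedThresholds:
    def test_sensitivity_at_zero_fpr(self):
        sens, thr = sensitivity_at_fpr(*TOY, 0.0)
        assert sens == 0.5 and thr > 0.4

    def test_sensitivity_accept_all(self):
        sens, _ = sensitivity_at_fpr(*TOY, 1.0)
        assert sens == 1.0

    def test_sensitivity_at_half_fpr(self):
        # threshold 0.35 already attains FPR exactly 0.5 under the
        # score >= threshold convention, admitting both positives
        sens, thr = sensitivity_at_fpr(*TOY, 0.5)
        assert sens == 1.0 and thr == pytest.approx(0.35)

    def test_specificity_at_full_tpr(self):
        spec, thr = specificity_at_tpr(*TOY, 1.0)
        assert spec == 0.5 and thr <= 0.35

    def test_specificity_at_zero_tpr(self):
        spec, _ = specificity_at_tpr(*TOY, 0.0)
        assert spec == 1.0

    def test_monotonicity_over_grid(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(0, 1, 60)
        labels = rng.integers(0, 2, 60).astype(bool)
        sens = [sensitivity_at_fpr(scores, labels, t)[0]
                for t in np.linspace(0, 1, 21)]
        spec = [specificity_at_tpr(scores, labels, t)[0]
                for t in np.linspace(0, 1, 21)]
        assert all(b >= a - 1e-12 for a, b in zip(sens, sens[1:]))
        assert all(b <= a + 1e-12 for a, b in zip(spec, spec[1:]))

    @pytest.mark.parametrize("seed", range(30))
    def test_sensitivity_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(5, 50))
        scores = rng.choice(np.round(rng.uniform(0, 1, 10), 2), n)
        labels = rng.integers(0, 2, n).astype(bool)
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        target = float(rng.uniform(0, 1))
        sens, _ = sensitivity_at_fpr(scores, labels, target)
        assert sens == pytest.approx(enumerate_best_tpr(scores, labels, target))


# ---------------------------------------------------------------------------
# kappa


class TestKappa:
    def test_worked_example(self):
        assert cohens_kappa([[20, 5], [10, 15]]) == pytest.approx(0.4)

    def test_perfect_agreement(self):
        assert cohens_kappa([[30, 0], [0, 12]]) == 1.0

    def test_independent_marginals_give_zero(self):
        # rows/cols proportional: p_o == p_e
        assert cohens_kappa([[16, 24], [24, 36]]) == pytest.approx(0.0)

    def test_degenerate_marginals_warn_and_zero(self):
        with pytest.warns(UserWarning):
            assert cohens_kappa([[10, 0], [0, 0]]) == 0.0


# ---------------------------------------------------------------------------
# bootstrap


class TestBootstrap:
    def test_perfect_separation_degenerate_interval(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        labels = [0, 0, 1, 1]
        assert bootstrap_auc_ci(scores, labels, 200, seed=0) == (1.0, 1.0)

    def test_single_rep(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(0, 1, 50)
        labels = rng.integers(0, 2, 50).astype(bool)
        lo, hi = bootstrap_auc_ci(scores, labels, n_reps=1, seed=3)
        assert lo == hi

    def test_invalid_reps(self):
        with pytest.raises(ValidationError):
            bootstrap_auc_ci([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], 0)

    def test_interval_contains_binormal_truth_mostly(self):
        """CI from the binormal model (pos ~ N(1,1), neg ~ N(0,1)) should
        cover the analytic AUC Phi(1/sqrt(2)) in most seeded trials."""
        from scipy.stats import norm

        truth = norm.cdf(1 / np.sqrt(2))
        rng = np.random.default_rng(42)
        covered = 0
        trials = 20
        for _ in range(trials):
            scores = np.concatenate([rng.normal(1, 1, 200), rng.normal(0, 1, 200)])
            labels = np.array([True] * 200 + [False] * 200)
            lo, hi = bootstrap_auc_ci(scores, labels, 500,
                                      seed=int(rng.integers(2 ** 31)))
            covered += lo <= truth <= hi
        assert covered >= int(0.9 * trials) - 1

    def test_ci_width_shrinks_with_n(self):
        rng = np.random.default_rng(5)
        widths = []
        for n in (50, 200, 800):
            scores = np.concatenate([rng.normal(1, 1, n), rng.normal(0, 1, n)])
            labels = np.array([True] * n + [False] * n)
            lo, hi = bootstrap_auc_ci(scores, labels, 400, seed=9)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]


# ---------------------------------------------------------------------------
# end-to-end evaluation


class TestEvaluate:
    def _setup(self):
        gold = GoldStandardSet(
            positives=[ev(100 * i, source="gold", is_event=True)
                       for i in range(1, 11)],
            negatives=[ev(100 * i + 50, source="gold", is_event=False)
                       for i in range(1, 11)])
        return gold

    def test_oracle_scorer_is_perfect(self):
        gold = self._setup()
        scores = ([ev(e.onset_s, source="model", score=0.9)
                   for e in gold.positives]
                  + [ev(e.onset_s, source="model", score=0.1)
                     for e in gold.negatives])
        expert = [ev(e.onset_s, source="reader_A") for e in gold.positives[:8]]
        expert += [ev(gold.negatives[0].onset_s, source="reader_A")]
        report = evaluate(scores, gold, expert, 5.0, n_boot=100, seed=0)
        assert report.auc == 1.0
        assert report.operating_tpr == pytest.approx(0.8)
        assert report.operating_fpr == pytest.approx(0.1)
        assert report.sensitivity_at_fpr == 1.0
        assert report.specificity_at_tpr == 1.0

    def test_unmatched_positive_scores_zero(self):
        gold = self._setup()
        scores = [ev(e.onset_s, source="model", score=0.9)
                  for e in gold.positives[1:]]  # first positive unmatched
        expert = [ev(e.onset_s, source="reader_A") for e in gold.positives]
        report = evaluate(scores, gold, expert, 5.0, n_boot=50, seed=0)
        assert report.auc < 1.0  # the missed positive ties with negatives

    def test_empty_gold_rejected(self):
        with pytest.raises(ValidationError):
            evaluate([], GoldStandardSet(), [], 5.0)

    def test_report_summary_contains_headline_metrics(self):
        gold = self._setup()
        scores = [ev(e.onset_s, source="model", score=0.9) for e in gold.positives]
        expert = [ev(e.onset_s, source="reader_A") for e in gold.positives]
        report = evaluate(scores, gold, expert, 5.0, n_boot=50, seed=1, kappa=0.38)
        text = report.summary()
        assert "AUC" in text and "kappa" in text
        d = report.to_dict()
        assert set(d) >= {"auc", "auc_ci", "sensitivity_at_fpr",
                          "specificity_at_tpr", "n_pos", "n_neg"}
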
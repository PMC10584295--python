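"""Gold-standard adjudication and evaluation statistics.

Implements the study's evaluation framework:

* **Event matching** — greedy nearest-onset one-to-one pairing within a
  time tolerance, the primitive behind reader concordance, labeling, and
  scoring.
* **Two-reader adjudication** — marks concordant between readers A and B
  are reflux events; discordant marks are resolved by a third reader (or a
  ground-truth oracle in simulation): confirmed marks become positives,
  unconfirmed marks become adjudicated nonevents.
* **Nonevent pool** — the negative class is deliberately narrow: only
  adjudicated nonevents plus detector candidates matching no positive.
  Unmarked quiet time contributes nothing, which avoids a vast
  trivially-negative class and makes specificity a meaningful statistic.
* **ROC/AUC** with a 1,000-repetition percentile bootstrap CI (resampling
  the pooled test records), **matched-threshold sensitivity/specificity**
  (the model's TPR at the expert reader's FPR, and its TNR at the expert's
  TPR), and **Cohen's kappa** for inter-reader agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .io import EventRecord, ValidationError

__all__ = [
    "GoldStandardSet",
    "MetricsReport",
    "match_events",
    "adjudicate",
    "build_nonevent_pool",
    "roc_auc",
    "bootstrap_auc_ci",
    "sensitivity_at_fpr",
    "specificity_at_tpr",
    "cohens_kappa",
    "reader_agreement_table",
    "evaluate",
    "roc_curve_points",
]


@dataclass
class GoldStandardSet:
    """Adjudicated evaluation universe: positives plus hard negatives."""

    positives: list = field(default_factory=list)
    negatives: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def n_pos(self) -> int:
        return len(self.positives)

    @property
    def n_neg(self) -> int:
        return len(self.negatives)


@dataclass
class MetricsReport:
    """Evaluation results on a gold-standard universe."""

    auc: float
    auc_ci: tuple
    sensitivity_at_fpr: float
    operating_fpr: float
    specificity_at_tpr: float
    operating_tpr: float
    n_pos: int
    n_neg: int
    kappa: Optional[float] = None
    thresholds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "sensitivity_at_fpr": self.sensitivity_at_fpr,
            "operating_fpr": self.operating_fpr,
            "specificity_at_tpr": self.specificity_at_tpr,
            "operating_tpr": self.operating_tpr,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "kappa": self.kappa,
            "thresholds": self.thresholds,
        }

    def summary(self) -> str:
        lines = [
            "Reflux event identification — evaluation report",
            "=" * 56,
            f"gold universe: {self.n_pos} events, {self.n_neg} nonevents",
            f"AUC: {self.auc:.3f}  (95% CI {self.auc_ci[0]:.3f}-{self.auc_ci[1]:.3f})",
            f"sensitivity {100 * self.sensitivity_at_fpr:.1f}% at matched "
            f"FPR {100 * self.operating_fpr:.1f}%",
            f"specificity {100 * self.specificity_at_tpr:.1f}% at matched "
            f"TPR {100 * self.operating_tpr:.1f}%",
        ]
        if self.kappa is not None:
            lines.append(f"inter-reader Cohen's kappa: {self.kappa:.2f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# event matching and adjudication


def match_events(set_a: Sequence[EventRecord], set_b: Sequence[EventRecord],
                 tolerance_s: float):
    """Greedy nearest-onset one-to-one matching within ``tolerance_s``.

    Candidate pairs are taken in order of (|onset difference|, onset_a,
    onset_b), so ties break toward the earlier a, then the earlier b.
    Returns ``(pairs, only_a, only_b)`` with pairs as index tuples into the
    (onset-sorted) inputs.
    """
    if tolerance_s < 0:
        raise ValidationError("tolerance_s must be >= 0")
    a = sorted(set_a, key=lambda e: (e.onset_s, e.end_s))
    b = sorted(set_b, key=lambda e: (e.onset_s, e.end_s))
    cands = []
    for i, ea in enumerate(a):
        for j, eb in enumerate(b):
            d = abs(ea.onset_s - eb.onset_s)
            if d <= tolerance_s:
                cands.append((d, ea.onset_s, eb.onset_s, i, j))
    cands.sort()
    used_a: set = set()
    used_b: set = set()
    pairs = []
    for d, _, _, i, j in cands:
        if i in used_a or j in used_b:
            continue
        pairs.append((i, j))
        used_a.add(i)
        used_b.add(j)
    only_a = [a[i] for i in range(len(a)) if i not in used_a]
    only_b = [b[j] for j in range(len(b)) if j not in used_b]
    return [(a[i], b[j]) for i, j in sorted(pairs)], only_a, only_b


def _as_gold(rec: EventRecord, is_event: bool) -> EventRecord:
    return EventRecord(onset_s=rec.onset_s, end_s=rec.end_s,
                       proximal_extent=rec.proximal_extent,
                       source="gold", is_event=is_event)


def adjudicate(reader_a: Sequence[EventRecord], reader_b: Sequence[EventRecord],
               reader_c: Optional[Sequence[EventRecord]],
               tolerance_s: float = 5.0) -> GoldStandardSet:
    """Two-reader adjudication with third-reader tiebreak.

    Marks matched between A and B are reflux events.  Discordant marks
    (present in exactly one reader) are resolved by presence in reader C's
    marks: confirmed -> positive, otherwise -> adjudicated nonevent.
    ``reader_c`` may be the ground-truth event list (a perfect tiebreaker)
    or a third simulated reader's marks; if it is None while discordant
    marks exist, an error lists them.
    """
    pairs, only_a, only_b = match_events(reader_a, reader_b, tolerance_s)
    gold = GoldStandardSet()
    for ea, eb in pairs:
        rec = _as_gold(ea, True)
        gold.positives.append(rec)
        gold.provenance[id(rec)] = dict(marked_by=["reader_A", "reader_B"],
                                        adjudicated_by="concordance")
    discordant = [(e, "reader_A") for e in only_a] + [(e, "reader_B") for e in only_b]
    if discordant and reader_c is None:
        marks = ", ".join(f"{src}@{e.onset_s:.1f}s" for e, src in discordant)
        raise ValidationError(f"unresolved discordant marks (no reader_c): {marks}")
    if discordant:
        disc_events = [e for e, _ in discordant]
        pairs_c, only_d, _ = match_events(disc_events, reader_c, tolerance_s)
        confirmed = {id(e) for e, _ in pairs_c}
        for e, src in discordant:
            is_event = id(e) in confirmed
            rec = _as_gold(e, is_event)
            (gold.positives if is_event else gold.negatives).append(rec)
            gold.provenance[id(rec)] = dict(marked_by=[src], adjudicated_by="reader_C")
    gold.positives.sort(key=lambda e: e.onset_s)
    gold.negatives.sort(key=lambda e: e.onset_s)
    return gold


def build_nonevent_pool(gold: GoldStandardSet,
                        detector_candidates: Sequence[EventRecord],
                        tolerance_s: float = 5.0) -> GoldStandardSet:
    """Extend the negative class with detector candidates that match no
    positive (and do not duplicate an existing negative).  Positives are
    unchanged; the evaluation universe remains positives + negatives only.
    """
    out = GoldStandardSet(positives=list(gold.positives),
                          negatives=list(gold.negatives),
                          provenance=dict(gold.provenance))
    _, _, unmatched = match_events(out.positives, detector_candidates, tolerance_s)
    _, _, new_negs = match_events(out.negatives, unmatched, tolerance_s)
    for cand in new_negs:
        rec = _as_gold(cand, False)
        out.negatives.append(rec)
        out.provenance[id(rec)] = dict(marked_by=["software"],
                                       adjudicated_by="no_matching_positive")
    out.negatives.sort(key=lambda e: e.onset_s)
    return out


# ---------------------------------------------------------------------------
# scalar metrics


def _check_two_class(labels) -> np.ndarray:
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise ValidationError("need at least one positive and one negative label")
    return labels


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC: (concordant + 0.5 * tied pairs) / (n_pos * n_neg),
    computed with midranks."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_class(labels)
    r = rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    return float((r[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def bootstrap_auc_ci(scores, labels, n_reps: int = 1000, level: float = 0.95,
                     seed: int = 0) -> tuple:
    """Percentile bootstrap CI for the AUC.

    Each repetition resamples the pooled (score, label) records with
    replacement at the original size; single-class resamples are redrawn.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_class(labels)
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValidationError("need >= 2 positives and >= 2 negatives")
    rng = np.random.default_rng(seed)
    n = scores.size
    aucs = np.empty(n_reps)
    for r in range(n_reps):
        for _ in range(1000):
            idx = rng.integers(0, n, n)
            lab = labels[idx]
            if lab.any() and not lab.all():
                break
        aucs[r] = roc_auc(scores[idx], lab)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(aucs, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def _rates_at_threshold(scores, labels, thr):
    pred = scores >= thr
    tpr = pred[labels].mean()
    fpr = pred[~labels].mean()
    return fpr, tpr


def sensitivity_at_fpr(scores, labels, target_fpr: float) -> tuple:
    """TPR at the smallest threshold whose empirical FPR <= ``target_fpr``.

    Classification is ``score >= threshold``; thresholds are enumerated
    from the observed scores plus +inf, so the returned sensitivity is
    non-decreasing in the target.  Returns ``(sensitivity, threshold)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_class(labels)
    if not (0.0 <= target_fpr <= 1.0):
        raise ValidationError("target_fpr must be in [0, 1]")
    for thr in np.concatenate([np.unique(scores), [np.inf]]):
        fpr, tpr = _rates_at_threshold(scores, labels, thr)
        if fpr <= target_fpr:
            return float(tpr), float(thr)
    return 0.0, float("inf")  # pragma: no cover


def specificity_at_tpr(scores, labels, target_tpr: float) -> tuple:
    """TNR at the largest threshold whose empirical TPR >= ``target_tpr``.

    Mirror image of :func:`sensitivity_at_fpr`; returns
    ``(specificity, threshold)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_class(labels)
    if not (0.0 <= target_tpr <= 1.0):
        raise ValidationError("target_tpr must be in [0, 1]")
    for thr in np.concatenate([np.unique(scores)[::-1], [-np.inf]]):
        fpr, tpr = _rates_at_threshold(scores, labels, thr)
        if tpr >= target_tpr:
            return float(1.0 - fpr), float(thr)
    return 1.0, float("-inf")  # pragma: no cover


def cohens_kappa(table) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e) for a
    2x2 contingency table [[both, a_only], [b_only, neither]]."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValidationError("table must be 2x2 with non-negative counts")
    total = t.sum()
    if total <= 0:
        raise ValidationError("table total must be > 0")
    p_o = np.trace(t) / total
    p_e = float((t.sum(axis=1) * t.sum(axis=0)).sum()) / total ** 2
    if abs(1.0 - p_e) < 1e-12:
        warnings.warn("degenerate marginals (p_e = 1); kappa defined as 0",
                      stacklevel=2)
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def reader_agreement_table(marks_a, marks_b, universe, tolerance_s: float = 5.0):
    """2x2 marked/not-marked contingency table for two readers over a
    shared universe of records (gold positives + negatives)."""
    pairs_a, _, _ = match_events(universe, marks_a, tolerance_s)
    pairs_b, _, _ = match_events(universe, marks_b, tolerance_s)
    hit_a = {id(u) for u, _ in pairs_a}
    hit_b = {id(u) for u, _ in pairs_b}
    t = np.zeros((2, 2), dtype=int)
    for u in universe:
        i = 0 if id(u) in hit_a else 1
        j = 0 if id(u) in hit_b else 1
        t[i, j] += 1
    return t


# ---------------------------------------------------------------------------
# end-to-end evaluation


def _scores_for_gold(records, model_scores, tolerance_s):
    """Model score per gold record; unmatched records score 0 (system-level
    misses are charged to the pipeline)."""
    pairs, _, _ = match_events(records, model_scores, tolerance_s)
    by_id = {id(rec): m.score for rec, m in pairs}
    return np.array([by_id.get(id(rec), 0.0) for rec in records], dtype=float)


def evaluate(model_scores: Sequence[EventRecord], gold: GoldStandardSet,
             expert_marks: Sequence[EventRecord], tolerance_s: float = 5.0,
             n_boot: int = 1000, seed: int = 0,
             kappa: Optional[float] = None) -> MetricsReport:
    """Full evaluation on a gold universe.

    The expert reader's empirical operating point (FPR, TPR) is computed by
    event matching against the universe; the model is then scored at the
    matched thresholds, together with AUC and its percentile bootstrap CI.
    ``model_scores`` are candidate records with ``source='model'`` and a
    score; gold records with no matching scored candidate count as score 0.
    """
    if gold.n_pos == 0 or gold.n_neg == 0:
        raise ValidationError("gold universe must contain positives and negatives")
    records = list(gold.positives) + list(gold.negatives)
    labels = np.array([True] * gold.n_pos + [False] * gold.n_neg)
    scores = _scores_for_gold(records, model_scores, tolerance_s)

    pairs, _, _ = match_events(records, expert_marks, tolerance_s)
    hit = {id(rec) for rec, _ in pairs}
    marked = np.array([id(rec) in hit for rec in records])
    expert_tpr = float(marked[labels].mean())
    expert_fpr = float(marked[~labels].mean())

    auc = roc_auc(scores, labels)
    ci = bootstrap_auc_ci(scores, labels, n_reps=n_boot, seed=seed)
    sens, thr_s = sensitivity_at_fpr(scores, labels, expert_fpr)
    spec, thr_p = specificity_at_tpr(scores, labels, expert_tpr)
    return MetricsReport(
        auc=auc, auc_ci=ci,
        sensitivity_at_fpr=sens, operating_fpr=expert_fpr,
        specificity_at_tpr=spec, operating_tpr=expert_tpr,
        n_pos=gold.n_pos, n_neg=gold.n_neg, kappa=kappa,
        thresholds={"sensitivity": thr_s, "specificity": thr_p},
    )


def roc_curve_points(scores, labels):
    """(fpr, tpr, threshold) triples over all observed thresholds."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_class(labels)
    rows = []
    for thr in np.concatenate([[-np.inf], np.unique(scores), [np.inf]]):
        fpr, tpr = _rates_at_threshold(scores, labels, thr)
        rows.append((float(fpr), float(tpr), float(thr)))
    return rows
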
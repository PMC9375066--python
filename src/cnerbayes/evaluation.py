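"""Invariant accuracy, confusion metrics, threshold sweeps, LOO and k-fold CV.

Invariant accuracy (IA) is the fraction of (positive, negative) example
pairs in which the estimator scores the positive strictly higher:

    IA = #[E(FoT+) > E(FoT-)] / (#[FoT+] * #[FoT-])

On tie-free scores it coincides with ROC AUC; with ties the strict
inequality makes it a lower bound on the mid-rank AUC (the ``ties="midrank"``
option restores AUC comparability).

Cross-validation splits by *document* (not FoT) so that a target token and
its context never land on different sides of a fold boundary.  Fold metrics
are pooled (micro-aggregated) confusion counts, which is stable for rare
classes.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .calibration import DEFAULT_BINS
from .corpus import AnnotatedDocument, ClassLabel, Section
from .extraction import (default_entity_filters, default_token_filters,
                         extract_entities, overrepresented_surface_filter)
from .model import (CLASS_INDEX, CLASS_ORDER, FragmentNaiveBayes,
                    FragmentNaiveBayesResults)
from .ngrams import DEFAULT_N_MAX, fot_descriptors
from .tokens import build_fots, document_fots, tokenize

_NON_CNE = CLASS_INDEX[ClassLabel.NON_CNE]
_CNE = CLASS_INDEX[ClassLabel.CNE]

#: Default threshold on (Pc - Pnc) for turning token scores into entities.
DEFAULT_THRESHOLD = 0.3


@dataclass(frozen=True)
class MetricsRow:
    """Confusion-matrix metrics at one decision threshold.

    Metrics with a zero denominator are ``None`` (reported as missing, never
    silently 0); balanced accuracy is the mean of sensitivity and
    specificity.
    """

    threshold: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    balanced_accuracy: float | None
    f1: float | None

    def as_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "balanced_accuracy": self.balanced_accuracy,
            "f1": self.f1,
        }


def invariant_accuracy(pos_scores, neg_scores, ties: str = "strict") -> float:
    """Pairwise ranking accuracy of positive vs negative scores.

    ``ties="strict"`` counts only strictly greater pairs (the printed
    definition); ``ties="midrank"`` counts ties as half a pair, matching the
    usual mid-rank AUC.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("invariant accuracy needs nonempty score lists")
    neg_sorted = np.sort(neg)
    below = np.searchsorted(neg_sorted, pos, side="left")
    if ties == "strict":
        wins = below.sum()
    elif ties == "midrank":
        upto = np.searchsorted(neg_sorted, pos, side="right")
        wins = (below + upto).sum() / 2.0
    else:
        raise ValueError(f"ties must be 'strict' or 'midrank', got {ties!r}")
    return float(wins) / (pos.size * neg.size)


def confusion_metrics(tp: int, fp: int, tn: int, fn: int,
                      threshold: float | None = None) -> MetricsRow:
    """Sensitivity, specificity, precision, balanced accuracy and F1."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    sens = tp / (tp + fn) if tp + fn else None
    spec = tn / (tn + fp) if tn + fp else None
    prec = tp / (tp + fp) if tp + fp else None
    ba = (sens + spec) / 2 if sens is not None and spec is not None else None
    f1 = (2 * prec * sens / (prec + sens)
          if prec is not None and sens is not None and prec + sens > 0 else None)
    return MetricsRow(threshold, sens, spec, prec, ba, f1)


def threshold_sweep(scores, labels, thresholds=None) -> list[MetricsRow]:
    """One metrics row per threshold: predicted positive iff score > t.

    Default grid: 41 equally spaced thresholds over [-1, 1] (suitable for
    both B-statistics and Pc - Pnc scores).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.size == 0:
        raise ValueError("threshold sweep needs nonempty scores")
    if thresholds is None:
        thresholds = np.linspace(-1.0, 1.0, 41)
    rows = []
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    for t in thresholds:
        predicted = scores > t
        tp = int((predicted & labels).sum())
        fp = int(predicted.sum()) - tp
        fn = n_pos - tp
        tn = n_neg - fp
        rows.append(confusion_metrics(tp, fp, tn, fn, threshold=float(t)))
    return rows


def write_sweep_csv(rows: Sequence[MetricsRow], path,
                    ia: float | None = None) -> None:
    """Threshold-sweep table: threshold, IA, recall, precision, specificity, BA."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["threshold", "IA", "recall", "precision",
                         "specificity", "balanced_accuracy", "f1"])
        for row in rows:
            writer.writerow([
                row.threshold, ia, row.sensitivity, row.precision,
                row.specificity, row.balanced_accuracy, row.f1,
            ])


def loo_cv(results: FragmentNaiveBayesResults,
           ties: str = "strict") -> dict[ClassLabel, float | None]:
    """Per-class one-vs-rest IA from leave-one-out B-statistics.

    Each training FoT is scored with its own contributions excluded from the
    counts; classes with no positives (or no negatives) report ``None``.
    """
    loo = results.loo_matrix()
    labels = results._fot_labels
    out: dict[ClassLabel, float | None] = {}
    for label in CLASS_ORDER:
        idx = CLASS_INDEX[label]
        if label is ClassLabel.CNE:
            positive = labels != _NON_CNE
        else:
            positive = labels == idx
        if not positive.any() or positive.all():
            out[label] = None
            continue
        out[label] = invariant_accuracy(loo[positive, idx], loo[~positive, idx],
                                        ties=ties)
    return out


@dataclass
class FoldResult:
    """Pooled outcomes of one CV fold."""

    index: int
    test_doc_ids: list[str]
    token_metrics: MetricsRow
    entity_tp: int
    entity_fp: int
    entity_fn: int


@dataclass
class CVReport:
    """Aggregated k-fold cross-validation report."""

    k: int
    seed: int
    threshold: float
    window: int
    n_max: int
    folds: list[FoldResult]
    per_class_ia: dict[ClassLabel, float | None]
    token_ia: float | None            # CNE vs non-CNE, pooled B_CNE scores
    token_metrics: MetricsRow         # pooled counts at the threshold
    entity_precision: float | None
    entity_recall: float | None
    entity_f1: float | None
    n_tokens: int = 0
    n_gold_entities: int = 0
    n_extracted_entities: int = 0

    def summary(self) -> str:
        def fmt(x):
            return "--" if x is None else f"{x:.4f}"

        lines = [
            f"{self.k}-fold cross-validation (seed {self.seed}, window "
            f"{self.window}, n_max {self.n_max}, T {self.threshold})",
            "=" * 60,
            f"tokens scored:        {self.n_tokens}",
            f"token-level CNE IA:   {fmt(self.token_ia)}",
            f"token sens/spec/BA:   {fmt(self.token_metrics.sensitivity)} / "
            f"{fmt(self.token_metrics.specificity)} / "
            f"{fmt(self.token_metrics.balanced_accuracy)}",
            f"gold entities:        {self.n_gold_entities}",
            f"extracted entities:   {self.n_extracted_entities}",
            f"entity precision:     {fmt(self.entity_precision)}",
            f"entity recall:        {fmt(self.entity_recall)}",
            f"entity F1:            {fmt(self.entity_f1)}",
            "-" * 60,
            "per-class token-level IA (one-vs-rest, pooled test folds):",
        ]
        for label, ia in self.per_class_ia.items():
            lines.append(f"  {label.value:<14}{fmt(ia)}")
        lines.append("=" * 60)
        return "\n".join(lines)


def assign_folds(doc_ids: Sequence[str], k: int, seed: int) -> list[list[str]]:
    """Seeded shuffle of document ids into k near-equal folds (a partition)."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > len(doc_ids):
        raise ValueError(f"k={k} exceeds the number of documents {len(doc_ids)}")
    ids = list(doc_ids)
    random.Random(seed).shuffle(ids)
    return [list(chunk) for chunk in np.array_split(np.asarray(ids, dtype=object), k)]


def kfold_cv(corpus: Sequence[AnnotatedDocument], k: int = 5, seed: int = 0,
             window: int = 1, n_max: int = DEFAULT_N_MAX,
             threshold: float = DEFAULT_THRESHOLD,
             sum_mode: str = "mean", smoothing_alpha: float = 0.0,
             calibration_bins: int = DEFAULT_BINS,
             token_filters=None, entity_filters=None,
             ties: str = "strict") -> CVReport:
    """Document-level k-fold CV with per-fold train, calibrate and extract.

    ``token_filters=None`` uses the default rules plus the training-derived
    overrepresented-surface rule (rebuilt per fold); pass an explicit list to
    override.  Entity-level matching is exact span equality against gold.
    """
    by_id = {doc.doc_id: doc for doc in corpus}
    folds = assign_folds([d.doc_id for d in corpus], k, seed)
    if entity_filters is None:
        entity_filters = default_entity_filters()

    all_b: list[np.ndarray] = []
    all_labels: list[np.ndarray] = []
    all_scores: list[np.ndarray] = []
    fold_results: list[FoldResult] = []
    tp_tok = fp_tok = tn_tok = fn_tok = 0
    tp_ent = fp_ent = fn_ent = 0

    for fold_index, test_ids in enumerate(folds):
        test_set = set(test_ids)
        train_fots = []
        for doc in corpus:
            if doc.doc_id not in test_set:
                train_fots.extend(document_fots(doc, window))
        results = FragmentNaiveBayes(train_fots, n_max, sum_mode,
                                     smoothing_alpha).fit()
        calibration = results.calibrate(q=calibration_bins)
        if token_filters is None:
            tfilters = default_token_filters() + [
                overrepresented_surface_filter(results.surface_stats)]
        else:
            tfilters = token_filters

        f_tp = f_fp = f_tn = f_fn = 0
        f_etp = f_efp = f_efn = 0
        for doc_id in test_ids:
            doc = by_id[doc_id]
            for section in (Section.TITLE, Section.ABSTRACT):
                text = doc.section_text(section)
                tokens = tokenize(text, section)
                fots = build_fots(tokens, doc.section_spans(section), window,
                                  doc_id)
                b_rows = np.array(
                    [results.b_all(fot_descriptors(f, n_max)) for f in fots]
                ).reshape(len(fots), len(CLASS_ORDER))
                labels = np.array([CLASS_INDEX[f.label] for f in fots],
                                  dtype=np.int64)
                pc = calibration.pc_curve(b_rows[:, _CNE]) if len(fots) else np.empty(0)
                pnc = calibration.pnc_curve(b_rows[:, _NON_CNE]) if len(fots) else np.empty(0)
                scores = np.asarray(pc) - np.asarray(pnc)
                all_b.append(b_rows)
                all_labels.append(labels)
                all_scores.append(scores)

                is_cne = labels != _NON_CNE
                predicted = scores > threshold
                f_tp += int((predicted & is_cne).sum())
                f_fp += int((predicted & ~is_cne).sum())
                f_fn += int((~predicted & is_cne).sum())
                f_tn += int((~predicted & ~is_cne).sum())

                extracted = extract_entities(
                    doc_id, text, tokens,
                    [(float(p), float(q_)) for p, q_ in zip(pc, pnc)],
                    threshold=threshold, token_filters=tfilters,
                    entity_filters=entity_filters)
                gold = {(s.start, s.end) for s in doc.section_spans(section)}
                found = {(e.start, e.end) for e in extracted}
                f_etp += len(gold & found)
                f_efp += len(found - gold)
                f_efn += len(gold - found)

        fold_results.append(FoldResult(
            fold_index, list(test_ids),
            confusion_metrics(f_tp, f_fp, f_tn, f_fn, threshold=threshold),
            f_etp, f_efp, f_efn))
        tp_tok += f_tp; fp_tok += f_fp; tn_tok += f_tn; fn_tok += f_fn
        tp_ent += f_etp; fp_ent += f_efp; fn_ent += f_efn

    b_mat = np.concatenate(all_b, axis=0)
    labels = np.concatenate(all_labels)
    per_class_ia: dict[ClassLabel, float | None] = {}
    for label in CLASS_ORDER:
        idx = CLASS_INDEX[label]
        positive = (labels != _NON_CNE if label is ClassLabel.CNE
                    else labels == idx)
        if not positive.any() or positive.all():
            per_class_ia[label] = None
        else:
            per_class_ia[label] = invariant_accuracy(
                b_mat[positive, idx], b_mat[~positive, idx], ties=ties)

    entity_precision = (tp_ent / (tp_ent + fp_ent)) if tp_ent + fp_ent else None
    entity_recall = (tp_ent / (tp_ent + fn_ent)) if tp_ent + fn_ent else None
    entity_f1 = (2 * entity_precision * entity_recall
                 / (entity_precision + entity_recall)
                 if entity_precision and entity_recall else None)
    return CVReport(
        k=k, seed=seed, threshold=threshold, window=window, n_max=n_max,
        folds=fold_results, per_class_ia=per_class_ia,
        token_ia=per_class_ia[ClassLabel.CNE],
        token_metrics=confusion_metrics(tp_tok, fp_tok, tn_tok, fn_tok,
                                        threshold=threshold),
        entity_precision=entity_precision, entity_recall=entity_recall,
        entity_f1=entity_f1, n_tokens=int(labels.size),
        n_gold_entities=tp_ent + fn_ent,
        n_extracted_entities=tp_ent + fp_ent)
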
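"""Subject-grouped k-fold cross-validation and wrapper feature selection.

Folds are built over *subjects*, never rows: every row of a subject falls
entirely in the training or entirely in the test side of each fold, so a
model can never recognise an identity it has already seen. With 26 subjects
and k = 5 each fold tests 5-6 subjects and trains on the remaining 20-21.

Wrapper selection draws random feature subsets (uniform over subset sizes,
then uniform over subsets of that size, duplicates rejected), scores each by
grouped CV restricted to those columns, and keeps the best; ties break
toward the smaller subset, then lexicographic feature order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import ModelSpec, fit, predict_scores

logger = logging.getLogger(__name__)

__all__ = ["FoldPlan", "CVResult", "SelectionResult",
           "make_group_folds", "cross_validate", "repeated_cv",
           "wrapper_select"]


@dataclass
class FoldPlan:
    """k train/test partitions of the subject set."""

    k: int
    folds: list[tuple[tuple[str, ...], tuple[str, ...]]]
    seed: int = 0

    def __post_init__(self) -> None:
        seen: list[str] = []
        for train, test in self.folds:
            overlap = set(train) & set(test)
            if overlap:
                raise ValueError(f"subjects in both train and test: {sorted(overlap)}")
            seen.extend(test)
        if len(seen) != len(set(seen)):
            raise ValueError("test sets are not pairwise disjoint")

    @property
    def subjects(self) -> set[str]:
        return set().union(*(set(tr) | set(te) for tr, te in self.folds))

    def to_json(self) -> str:
        return json.dumps({"k": self.k, "seed": self.seed,
                           "folds": [{"train": list(tr), "test": list(te)}
                                     for tr, te in self.folds]}, indent=2)


def make_group_folds(subject_ids, k: int = 5, seed: int = 0) -> FoldPlan:
    """Shuffle subjects by seed and deal them into k nearly equal test sets.

    Test-set sizes differ by at most one (26 subjects, k=5 gives sizes
    {6,5,5,5,5}); each fold trains on the complement.
    """
    ids = list(subject_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids")
    if k < 2:
        raise ValueError("need k >= 2 folds")
    if k > len(ids):
        raise ValueError(f"k={k} folds but only {len(ids)} subjects")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    test_sets = [tuple(sorted(order[i::k])) for i in range(k)]
    folds = []
    for test in test_sets:
        train = tuple(sorted(set(ids) - set(test)))
        folds.append((train, test))
    return FoldPlan(k=k, folds=folds, seed=seed)


@dataclass
class CVResult:
    """Pooled out-of-fold predictions of one model over one fold plan."""

    spec: ModelSpec
    accuracy: float
    true_labels: np.ndarray
    predicted_labels: np.ndarray
    scores: np.ndarray            # (n_rows, n_classes), class order in `classes`
    classes: np.ndarray
    subject_ids: np.ndarray
    n_folds_used: int


def cross_validate(spec: ModelSpec, table: pd.DataFrame, plan: FoldPlan,
                   feature_names: "list[str] | None" = None) -> CVResult:
    """Grouped-CV evaluation: per-fold fit on train subjects, predict on
    test subjects, pool all out-of-fold predictions.

    Folds whose training rows collapse to a single class are skipped with a
    warning and excluded from pooling.
    """
    table_subjects = set(table["subject_id"])
    if not table_subjects <= plan.subjects:
        extra = sorted(table_subjects - plan.subjects)
        raise ValueError(f"table contains subjects absent from the plan: {extra}")
    trues, preds, scores, subjects = [], [], [], []
    classes = np.unique(table["label"].to_numpy())
    used = 0
    for train_ids, test_ids in plan.folds:
        train_rows = table[table["subject_id"].isin(train_ids)]
        test_rows = table[table["subject_id"].isin(test_ids)]
        if len(test_rows) == 0:
            continue
        if train_rows["label"].nunique() < 2:
            logger.warning("fold skipped: training rows contain one class")
            continue
        model = fit(spec, train_rows, feature_names)
        fold_scores, fold_pred = predict_scores(model, test_rows)
        trues.append(test_rows["label"].to_numpy())
        preds.append(fold_pred)
        scores.append(_align_scores(fold_scores, model.classes, classes))
        subjects.append(test_rows["subject_id"].to_numpy())
        used += 1
    if used == 0:
        raise ValueError("no usable folds")
    true_all = np.concatenate(trues)
    pred_all = np.concatenate(preds)
    acc = float(np.mean(true_all == pred_all))
    return CVResult(spec=spec, accuracy=acc, true_labels=true_all,
                    predicted_labels=pred_all, scores=np.vstack(scores),
                    classes=classes, subject_ids=np.concatenate(subjects),
                    n_folds_used=used)


def _align_scores(fold_scores: np.ndarray, fold_classes: np.ndarray,
                  classes: np.ndarray) -> np.ndarray:
    """Map a fold's score columns onto the table-wide class order; classes a
    fold never saw score -inf so they are never picked."""
    out = np.full((fold_scores.shape[0], classes.size), -np.inf)
    pos = {c: j for j, c in enumerate(classes)}
    for j, c in enumerate(fold_classes):
        out[:, pos[c]] = fold_scores[:, j]
    return out


def repeated_cv(spec: ModelSpec, table: pd.DataFrame, k: int = 5,
                repetitions: int = 20, seed: int = 0,
                feature_names: "list[str] | None" = None
                ) -> tuple[float, list[CVResult]]:
    """Repeat grouped CV over freshly shuffled fold plans.

    Returns the mean pooled accuracy over repetitions together with every
    per-repetition result.
    """
    subjects = sorted(set(table["subject_id"]))
    rng = np.random.default_rng(seed)
    results = []
    for _ in range(repetitions):
        plan = make_group_folds(subjects, k, seed=int(rng.integers(2**31)))
        results.append(cross_validate(spec, table, plan, feature_names))
    return float(np.mean([r.accuracy for r in results])), results


def cross_validate_with_nested_selection(
        spec: ModelSpec, table: pd.DataFrame, plan: FoldPlan,
        n_subsets: int = 50, seed: int = 0, inner_k: int = 5,
        feature_names: "list[str] | None" = None) -> CVResult:
    """Grouped CV with wrapper selection nested inside each training fold.

    For every outer fold, feature subsets are selected by an inner grouped
    CV restricted to that fold's training subjects, so the held-out
    subjects never influence the chosen subset. This removes the selection
    optimism of the flat scheme (select once on the whole table) at the
    price of k inner searches.
    """
    from .features import ID_COLUMNS

    if feature_names is None:
        feature_names = [c for c in table.columns if c not in ID_COLUMNS]
    trues, preds, scores, subjects = [], [], [], []
    classes = np.unique(table["label"].to_numpy())
    rng = np.random.default_rng(seed)
    used = 0
    for train_ids, test_ids in plan.folds:
        train_rows = table[table["subject_id"].isin(train_ids)]
        test_rows = table[table["subject_id"].isin(test_ids)]
        if len(test_rows) == 0 or train_rows["label"].nunique() < 2:
            logger.warning("fold skipped in nested selection")
            continue
        inner_seed = int(rng.integers(2**31))
        inner_plan = make_group_folds(sorted(set(train_rows["subject_id"])),
                                      min(inner_k, len(train_ids)),
                                      seed=inner_seed)
        selection = wrapper_select(spec, train_rows, inner_plan,
                                   n_subsets=n_subsets, seed=inner_seed,
                                   feature_names=feature_names)
        model = fit(spec, train_rows, list(selection.chosen))
        fold_scores, fold_pred = predict_scores(model, test_rows)
        trues.append(test_rows["label"].to_numpy())
        preds.append(fold_pred)
        scores.append(_align_scores(fold_scores, model.classes, classes))
        subjects.append(test_rows["subject_id"].to_numpy())
        used += 1
    if used == 0:
        raise ValueError("no usable folds")
    true_all = np.concatenate(trues)
    pred_all = np.concatenate(preds)
    return CVResult(spec=spec, accuracy=float(np.mean(true_all == pred_all)),
                    true_labels=true_all, predicted_labels=pred_all,
                    scores=np.vstack(scores), classes=classes,
                    subject_ids=np.concatenate(subjects), n_folds_used=used)


@dataclass
class SelectionResult:
    """Outcome of the random-subset wrapper search."""

    evaluated: list[tuple[tuple[str, ...], float]]
    chosen: tuple[str, ...]
    accuracy: float
    n_subsets: int
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps({
            "seed": self.seed, "n_subsets": self.n_subsets,
            "chosen": list(self.chosen), "accuracy": self.accuracy,
            "evaluated": [{"features": list(f), "accuracy": a}
                          for f, a in self.evaluated]}, indent=2)


def _draw_subsets(features: list[str], n_subsets: int, seed: int
                  ) -> list[tuple[str, ...]]:
    d = len(features)
    total = (1 << d) - 1
    if total <= n_subsets:
        logger.warning("only %d distinct non-empty subsets of %d features "
                       "exist; enumerating all instead of drawing %d",
                       total, d, n_subsets)
        out = []
        for code in range(1, total + 1):
            subset = tuple(features[i] for i in range(d) if code >> i & 1)
            out.append(subset)
        return out
    rng = np.random.default_rng(seed)
    drawn: list[tuple[str, ...]] = []
    seen = set()
    while len(drawn) < n_subsets:
        size = int(rng.integers(1, d + 1))
        idx = rng.choice(d, size=size, replace=False)
        subset = tuple(features[i] for i in sorted(idx))
        if subset in seen:
            continue
        seen.add(subset)
        drawn.append(subset)
    return drawn


def wrapper_select(spec: ModelSpec, table: pd.DataFrame, plan: FoldPlan,
                   n_subsets: int = 50, seed: int = 0,
                   feature_names: "list[str] | None" = None) -> SelectionResult:
    """Score random feature subsets by grouped CV and keep the best.

    Subset sizes are uniform on 1..d and subsets uniform within a size;
    duplicates are rejected so exactly ``n_subsets`` distinct subsets are
    evaluated (or every subset, when fewer exist). The chosen subset attains
    the maximum accuracy; ties prefer fewer features, then lexicographic
    order.
    """
    from .features import ID_COLUMNS

    if feature_names is None:
        feature_names = [c for c in table.columns if c not in ID_COLUMNS]
    if not feature_names:
        raise ValueError("table has no feature columns")
    if n_subsets < 1:
        raise ValueError("need n_subsets >= 1")
    subsets = _draw_subsets(list(feature_names), n_subsets, seed)
    evaluated = []
    for subset in subsets:
        res = cross_validate(spec, table, plan, feature_names=list(subset))
        evaluated.append((subset, res.accuracy))
    chosen, best_acc = min(
        evaluated, key=lambda fa: (-fa[1], len(fa[0]), fa[0]))
    return SelectionResult(evaluated=evaluated, chosen=chosen,
                           accuracy=best_acc, n_subsets=len(subsets), seed=seed)
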
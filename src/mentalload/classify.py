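"""Model/Results front end for the workload classification analysis.

:class:`WorkloadClassifier` binds a labelled feature table to one classifier
preset and the evaluation protocol (subject-grouped k-fold CV, optional
random-subset wrapper selection, repeated over shuffled fold plans).
``fit()`` runs the protocol and returns a :class:`WorkloadClassifierResults`
carrying the pooled accuracy, its spread over repetitions, the confusion
matrix, per-class ROC/AUC and a ``summary()`` table.

    >>> table = assemble(generate_cohort(SynthConfig(seed=1)), "DST", "ir")
    >>> res = WorkloadClassifier(table, ModelSpec("svm", "linear")).fit()
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crossval import (CVResult, SelectionResult, cross_validate,
                       make_group_folds, repeated_cv, wrapper_select)
from .evaluation import EvaluationReport, evaluate_cv
from .features import ID_COLUMNS, drop_incomplete
from .models import ModelSpec

__all__ = ["WorkloadClassifier", "WorkloadClassifierResults"]


class WorkloadClassifier:
    """One classifier preset bound to a feature table and a CV protocol.

    Parameters
    ----------
    table : DataFrame
        Labelled feature table (``subject_id``, ``task``, ``phase``,
        ``label`` plus feature columns). Rows with undefined features are
        dropped at construction.
    spec : ModelSpec
        Classifier family/preset/seed.
    k : int
        Fold count for subject-grouped CV (default 5).
    repetitions : int
        Independent repetitions over shuffled fold plans; the headline
        accuracy is their mean.
    select : bool
        Run random-subset wrapper feature selection before the final
        evaluation (50 subsets by default).
    n_subsets : int
        Number of random feature subsets for the wrapper.
    seed : int
        Drives fold shuffling and subset draws.
    """

    def __init__(self, table: pd.DataFrame, spec: ModelSpec, *, k: int = 5,
                 repetitions: int = 20, select: bool = False,
                 nested: bool = False, n_subsets: int = 50, seed: int = 0):
        self.table = drop_incomplete(table)
        self.spec = spec
        self.k = k
        self.repetitions = repetitions
        self.select = select
        self.nested = nested
        self.n_subsets = n_subsets
        self.seed = seed
        self.feature_names = [c for c in self.table.columns
                              if c not in ID_COLUMNS]
        self.task = str(self.table["task"].iloc[0]) if len(self.table) else ""

    @classmethod
    def from_records(cls, records, task: str, view: str, spec: ModelSpec,
                     **kwargs) -> "WorkloadClassifier":
        """Build directly from a cohort of subject records."""
        from .features import assemble

        return cls(assemble(records, task, view), spec, **kwargs)

    def fit(self) -> "WorkloadClassifierResults":
        """Run (selection +) repeated grouped CV and evaluate the result."""
        subjects = sorted(set(self.table["subject_id"]))
        features = self.feature_names
        selection = None
        if self.select and self.nested:
            # selection re-run inside every training fold: unbiased but the
            # chosen subset varies per fold, so no single subset is reported
            from .crossval import cross_validate_with_nested_selection

            rng = np.random.default_rng(self.seed)
            reps = []
            for _ in range(self.repetitions):
                plan = make_group_folds(subjects, self.k,
                                        seed=int(rng.integers(2**31)))
                reps.append(cross_validate_with_nested_selection(
                    self.spec, self.table, plan, n_subsets=self.n_subsets,
                    seed=int(rng.integers(2**31)), feature_names=features))
            mean_acc = float(np.mean([r.accuracy for r in reps]))
            report = evaluate_cv(reps[0], task=self.task)
            return WorkloadClassifierResults(
                model=self, accuracy=mean_acc,
                rep_accuracies=np.array([r.accuracy for r in reps]),
                cv_results=reps, report=report, selection=None,
                features_used=list(features))
        if self.select:
            plan = make_group_folds(subjects, self.k, seed=self.seed)
            selection = wrapper_select(self.spec, self.table, plan,
                                       n_subsets=self.n_subsets,
                                       seed=self.seed,
                                       feature_names=features)
            features = list(selection.chosen)
        mean_acc, reps = repeated_cv(self.spec, self.table, k=self.k,
                                     repetitions=self.repetitions,
                                     seed=self.seed, feature_names=features)
        report = evaluate_cv(reps[0], task=self.task)
        return WorkloadClassifierResults(
            model=self, accuracy=mean_acc,
            rep_accuracies=np.array([r.accuracy for r in reps]),
            cv_results=reps, report=report, selection=selection,
            features_used=list(features))


@dataclass
class WorkloadClassifierResults:
    """Fitted-protocol results: accuracies, report, selection trace."""

    model: WorkloadClassifier
    accuracy: float                    # mean pooled accuracy over repetitions
    rep_accuracies: np.ndarray
    cv_results: list[CVResult]
    report: EvaluationReport           # metrics/ROC of the first repetition
    selection: "SelectionResult | None"
    features_used: list[str]

    @property
    def accuracy_sd(self) -> float:
        if self.rep_accuracies.size < 2:
            return float("nan")
        return float(np.std(self.rep_accuracies, ddof=1))

    def summary(self) -> str:
        """Plain-text summary in the style of a statistical results table."""
        m = self.model
        lines = [
            "Workload classification results",
            "=" * 46,
            f"{'task':<22}{m.task}",
            f"{'model':<22}{m.spec.name}",
            f"{'subjects':<22}{len(set(m.table['subject_id']))}",
            f"{'rows':<22}{len(m.table)}",
            f"{'features used':<22}{len(self.features_used)}"
            + (" (wrapper-selected)" if self.selection else ""),
            f"{'CV':<22}subject-grouped {m.k}-fold x {m.repetitions} reps",
            "-" * 46,
            f"{'accuracy (mean)':<22}{self.accuracy:.3f}",
            f"{'accuracy (sd)':<22}{self.accuracy_sd:.3f}",
            f"{'macro AUC':<22}{self.report.macro_auc:.3f}",
            f"{'macro sensitivity':<22}{self.report.macro_sensitivity:.3f}",
            f"{'macro specificity':<22}{self.report.macro_specificity:.3f}",
            f"{'macro precision':<22}{self.report.macro_precision:.3f}",
            f"{'macro F1':<22}{self.report.macro_f1:.3f}",
            "-" * 46,
            "confusion matrix (first repetition, pooled folds):",
        ]
        header = "      " + "".join(f"pred {c:<5}" for c in self.report.classes)
        lines.append(header)
        for i, cls in enumerate(self.report.classes):
            row = "".join(f"{v:<10}" for v in self.report.confusion[i])
            lines.append(f"true {cls} {row}")
        if self.selection:
            lines.append("-" * 46)
            lines.append("selected features: " + ", ".join(self.features_used))
        return "\n".join(lines)

    def plot(self):
        """ROC + confusion figure for the first repetition."""
        from .evaluation import plot_report

        return plot_report(self.report)
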
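"""Classifier metrics, ROC/AUC, and the paired t-tests of the analysis.

Multiclass metrics are one-vs-rest: each class is scored against the union
of the others (sensitivity = that class's recall, specificity = its
true-negative rate), and macro averages are unweighted class means. AUC is
the trapezoidal area under the threshold-swept ROC, equal to the normalised
Mann-Whitney statistic with half credit for ties: 1 for a perfect ranking,
0 for a perfectly wrong one.

Paired t-tests serve two comparisons: behavioural test scores between
sub-phases, and every extracted feature between phase pairs (starred at
p<0.05 and p<0.01, unadjusted; a Holm-adjusted column is emitted separately
for users who want family-wise control).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score, roc_curve

logger = logging.getLogger(__name__)

__all__ = ["EvaluationReport", "TTestResult", "confusion_and_metrics",
           "roc_auc", "one_vs_rest_rocs", "evaluate_cv", "paired_t_test",
           "feature_phase_comparison", "plot_report"]


@dataclass
class EvaluationReport:
    """Confusion matrix plus derived per-class and macro metrics."""

    classes: np.ndarray
    confusion: np.ndarray
    accuracy: float
    sensitivity: dict          # per class; NaN when the class is absent
    specificity: dict
    precision: dict
    f1: dict
    macro_sensitivity: float
    macro_specificity: float
    macro_precision: float
    macro_f1: float
    auc: dict = field(default_factory=dict)
    roc: dict = field(default_factory=dict)   # class -> (fpr, tpr, thresholds)
    macro_auc: float = float("nan")
    task: str = ""
    view: str = ""
    model: str = ""

    def confusion_frame(self) -> pd.DataFrame:
        """Confusion matrix as a labelled DataFrame (CSV-ready)."""
        labels = [str(c) for c in self.classes]
        return pd.DataFrame(self.confusion,
                            index=pd.Index(labels, name="true"),
                            columns=pd.Index(labels, name="predicted"))

    def roc_frame(self) -> pd.DataFrame:
        """All per-class ROC points in long form (CSV-ready)."""
        rows = []
        for cls, (fpr, tpr, thr) in self.roc.items():
            for f, t, h in zip(fpr, tpr, thr):
                rows.append({"class": cls, "fpr": f, "tpr": t,
                             "threshold": h})
        return pd.DataFrame(rows, columns=["class", "fpr", "tpr", "threshold"])

    def to_dict(self) -> dict:
        return {
            "task": self.task, "view": self.view, "model": self.model,
            "classes": [int(c) for c in self.classes],
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "sensitivity": {str(k): v for k, v in self.sensitivity.items()},
            "specificity": {str(k): v for k, v in self.specificity.items()},
            "precision": {str(k): v for k, v in self.precision.items()},
            "f1": {str(k): v for k, v in self.f1.items()},
            "macro": {"sensitivity": self.macro_sensitivity,
                      "specificity": self.macro_specificity,
                      "precision": self.macro_precision,
                      "f1": self.macro_f1, "auc": self.macro_auc},
            "auc": {str(k): v for k, v in self.auc.items()},
        }


@dataclass
class TTestResult:
    """Two-sided paired t-test outcome on n subject pairs."""

    t: float
    dof: int
    p: float
    n: int
    undefined: bool = False


def confusion_and_metrics(true_labels, predicted_labels,
                          classes=None) -> EvaluationReport:
    """Confusion matrix and one-vs-rest metrics from pooled predictions.

    A class absent from the truth has undefined (NaN) sensitivity; macro
    averages skip undefined entries.
    """
    y_true = np.asarray(true_labels)
    y_pred = np.asarray(predicted_labels)
    if y_true.size == 0:
        raise ValueError("empty prediction set")
    if y_true.size != y_pred.size:
        raise ValueError("true and predicted labels differ in length")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)
    cm = _sk_confusion(y_true, y_pred, labels=classes)
    total = cm.sum()
    acc = float(np.trace(cm) / total)
    sens, spec, prec, f1 = {}, {}, {}, {}
    for i, cls in enumerate(classes):
        tp = cm[i, i]
        fn = cm[i, :].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        sens[cls] = tp / (tp + fn) if (tp + fn) else float("nan")
        spec[cls] = tn / (tn + fp) if (tn + fp) else float("nan")
        prec[cls] = tp / (tp + fp) if (tp + fp) else float("nan")
        p_, r_ = prec[cls], sens[cls]
        f1[cls] = (2 * p_ * r_ / (p_ + r_)
                   if np.isfinite(p_) and np.isfinite(r_) and (p_ + r_) > 0
                   else float("nan"))

    def _macro(d: dict) -> float:
        vals = [v for v in d.values() if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")

    return EvaluationReport(
        classes=classes, confusion=cm, accuracy=acc,
        sensitivity=sens, specificity=spec, precision=prec, f1=f1,
        macro_sensitivity=_macro(sens), macro_specificity=_macro(spec),
        macro_precision=_macro(prec), macro_f1=_macro(f1),
    )


def roc_auc(true_labels, scores, positive_class) -> tuple[tuple, float]:
    """Threshold-swept ROC points and trapezoidal AUC for one class.

    Ranking every positive above every negative gives AUC 1; the reverse
    gives 0; ties earn half credit (Mann-Whitney convention).
    """
    y = np.asarray(true_labels)
    s = np.asarray(scores, dtype=float)
    pos = y == positive_class
    if pos.all() or not pos.any():
        raise ValueError("ROC needs both positive and negative examples")
    fpr, tpr, thr = roc_curve(pos.astype(int), s)
    auc = float(roc_auc_score(pos.astype(int), s))
    return (fpr, tpr, thr), auc


def one_vs_rest_rocs(true_labels, score_matrix, classes=None
                     ) -> tuple[dict, dict, float]:
    """One ROC and AUC per class against the union of the others.

    Returns (roc curves per class, AUC per class, macro AUC).
    """
    y = np.asarray(true_labels)
    scores = np.asarray(score_matrix, dtype=float)
    if classes is None:
        classes = np.unique(y)
    classes = np.asarray(classes)
    if scores.ndim != 2 or scores.shape[1] != classes.size:
        raise ValueError(
            f"score matrix must have one column per class ({classes.size})")
    rocs, aucs = {}, {}
    for j, cls in enumerate(classes):
        rocs[cls], aucs[cls] = roc_auc(y, scores[:, j], cls)
    macro = float(np.mean(list(aucs.values())))
    return rocs, aucs, macro


def evaluate_cv(cv_result, task: str = "", view: str = "") -> EvaluationReport:
    """Full report (metrics + per-class ROC/AUC) from a pooled CV result."""
    report = confusion_and_metrics(cv_result.true_labels,
                                   cv_result.predicted_labels,
                                   classes=cv_result.classes)
    finite = np.isfinite(cv_result.scores).all(axis=1)
    if finite.sum() >= 2:
        try:
            rocs, aucs, macro = one_vs_rest_rocs(
                cv_result.true_labels[finite], cv_result.scores[finite],
                classes=cv_result.classes)
            report.roc, report.auc, report.macro_auc = rocs, aucs, macro
        except ValueError as exc:
            logger.warning("ROC unavailable: %s", exc)
    report.task, report.view = task, view
    report.model = cv_result.spec.name
    return report


def paired_t_test(a, b) -> TTestResult:
    """Two-sided paired t-test on subject-matched samples.

    t = mean(d) / (sd(d)/sqrt(n)) on differences d = a - b, dof = n - 1.
    Zero-variance differences make the statistic undefined (flagged, not an
    error).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.std(d, ddof=1) == 0.0:
        return TTestResult(t=float("nan"), dof=n - 1, p=float("nan"),
                           n=n, undefined=True)
    stat = spstats.ttest_rel(a, b)
    return TTestResult(t=float(stat.statistic), dof=n - 1,
                       p=float(stat.pvalue), n=n)


def feature_phase_comparison(table: pd.DataFrame) -> pd.DataFrame:
    """Paired t-tests of every feature between every phase pair.

    One row per (feature, phase pair) with t, dof, raw p, significance
    stars at p<0.05 (*) and p<0.01 (**), and a Holm-adjusted p-value column
    (adjusted within each phase pair) kept clearly separate from the raw
    stars. Requires every subject to have both phases of each pair.
    """
    from statsmodels.stats.multitest import multipletests

    from .features import ID_COLUMNS

    feat_cols = [c for c in table.columns if c not in ID_COLUMNS]
    phases = list(dict.fromkeys(table["phase"]))
    rows = []
    for ph_a, ph_b in itertools.combinations(phases, 2):
        sub_a = table[table["phase"] == ph_a].set_index("subject_id")
        sub_b = table[table["phase"] == ph_b].set_index("subject_id")
        unmatched = sorted(set(sub_a.index) ^ set(sub_b.index))
        if unmatched:
            raise ValueError(
                f"phases {ph_a}/{ph_b} are not subject-paired; offending "
                f"subjects: {unmatched}")
        common = sub_a.index
        pair_rows = []
        for feat in feat_cols:
            res = paired_t_test(sub_a.loc[common, feat].to_numpy(),
                                sub_b.loc[common, feat].to_numpy())
            pair_rows.append({"feature": feat, "phase_a": ph_a, "phase_b": ph_b,
                              "t": res.t, "dof": res.dof, "p": res.p,
                              "undefined": res.undefined})
        pvals = np.array([r["p"] for r in pair_rows])
        ok = np.isfinite(pvals)
        holm = np.full(pvals.shape, np.nan)
        if ok.any():
            holm[ok] = multipletests(pvals[ok], method="holm")[1]
        for r, p_adj in zip(pair_rows, holm):
            p = r["p"]
            r["stars"] = ("**" if np.isfinite(p) and p < 0.01 else
                          "*" if np.isfinite(p) and p < 0.05 else "")
            r["p_holm"] = p_adj
            rows.append(r)
    return pd.DataFrame(rows)


def plot_report(report: EvaluationReport):
    """Figure with the per-class ROC curves and the confusion matrix.

    Returns a matplotlib Figure (Agg-safe: built without pyplot).
    """
    from matplotlib.figure import Figure

    fig = Figure(figsize=(9, 4))
    ax_roc, ax_cm = fig.subplots(1, 2)
    for cls, (fpr, tpr, _) in report.roc.items():
        ax_roc.plot(fpr, tpr, label=f"class {cls} (AUC={report.auc[cls]:.2f})")
    ax_roc.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax_roc.set_xlabel("1 - specificity (FPR)")
    ax_roc.set_ylabel("sensitivity (TPR)")
    ax_roc.set_title(f"{report.model} {report.task}/{report.view}")
    ax_roc.legend(loc="lower right", fontsize=8)
    im = ax_cm.imshow(report.confusion, cmap="Blues")
    for (i, j), v in np.ndenumerate(report.confusion):
        ax_cm.text(j, i, str(v), ha="center", va="center")
    ax_cm.set_xticks(range(len(report.classes)),
                     [str(c) for c in report.classes])
    ax_cm.set_yticks(range(len(report.classes)),
                     [str(c) for c in report.classes])
    ax_cm.set_xlabel("predicted")
    ax_cm.set_ylabel("true")
    ax_cm.set_title(f"accuracy = {report.accuracy:.3f}")
    fig.colorbar(im, ax=ax_cm, shrink=0.8)
    fig.tight_layout()
    return fig
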
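"""Feature extraction over a cohort and assembly into labelled tables.

Every (subject, task phase) pair yields 24 features: 9 thermal descriptors
for each of the two ROIs (columns ``Nosetip_*`` and ``Glabella_*``) and 6
baseline-normalised HRV descriptors (``HRV_*``). Tables are built per task
(DST: Forward=0, Backward=1; RAVLT: ImmR=0, DelR=1, Rec=2) and per modality
view:

* ``ir``          - the 18 thermal columns,
* ``hrv``         - the 6 HRV columns,
* ``multimodal``  - all 24.

Because every subject contributes one row per class, a complete cohort
always yields balanced classes. Rows with undefined feature values are
dropped, not imputed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cardio import (HRV_FEATURE_NAMES, EcgPreprocParams, detect_r_peaks,
                     hrv_feature_vector, normalize_to_baseline,
                     preprocess_ecg, rr_from_peaks)
from .descriptors import BandSpec, SampEnParams
from .synth import BASELINE_PHASE, DST_PHASES, RAVLT_PHASES, SubjectRecord
from .thermal import (THERMAL_FEATURE_NAMES, HampelParams, baseline_subtract,
                      hampel_filter, thermal_feature_vector)

logger = logging.getLogger(__name__)

__all__ = [
    "TASKS", "VIEWS", "feature_columns", "label_for_phase",
    "extract_features", "assemble", "drop_incomplete",
    "read_feature_table", "write_feature_table",
]

TASKS: dict[str, tuple[str, ...]] = {"DST": DST_PHASES, "RAVLT": RAVLT_PHASES}
VIEWS = ("ir", "hrv", "multimodal")

_ROI_PREFIX = {"nosetip": "Nosetip", "glabella": "Glabella"}
ID_COLUMNS = ("subject_id", "task", "phase", "label")


def feature_columns(view: str) -> list[str]:
    """Fixed, order-stable feature column names for a modality view."""
    ir = [f"{pref}_{feat}" for pref in ("Nosetip", "Glabella")
          for feat in THERMAL_FEATURE_NAMES]
    hrv = [f"HRV_{feat}" for feat in HRV_FEATURE_NAMES]
    if view == "ir":
        return ir
    if view == "hrv":
        return hrv
    if view == "multimodal":
        return ir + hrv
    raise ValueError(f"unknown view {view!r}; expected one of {VIEWS}")


def label_for_phase(task: str, phase: str) -> int:
    """Class label of a task sub-phase (baseline carries no class)."""
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {list(TASKS)}")
    phases = TASKS[task]
    if phase not in phases:
        raise ValueError(
            f"phase {phase!r} does not belong to task {task} {list(phases)}")
    return phases.index(phase)


def extract_features(records: list[SubjectRecord],
                     hampel: HampelParams = HampelParams(),
                     sampen: SampEnParams = SampEnParams(),
                     bands: BandSpec = BandSpec(),
                     ecg_params: EcgPreprocParams = EcgPreprocParams(),
                     ) -> pd.DataFrame:
    """Run both pipelines over a cohort; one row per (subject, task phase).

    Thermal traces are Hampel-despiked, baseline-subtracted against the
    one-minute pre-task window, then reduced to the 9 descriptors per ROI.
    ECG is conditioned, R peaks detected, and the 6 HRV descriptors taken
    as ratios to the baseline drive. Subjects whose ECG yields fewer than 4
    beats in a phase get NaN HRV entries there (logged).
    """
    rows = []
    for rec in records:
        hrv_baseline = _phase_hrv(rec, BASELINE_PHASE, ecg_params, bands)
        for phase in _task_phases(rec):
            row: dict[str, object] = {"subject_id": rec.subject_id, "phase": phase}
            for roi, prefix in _ROI_PREFIX.items():
                trace = rec.thermal.get((roi, phase))
                baseline = rec.baseline_thermal.get(roi)
                if trace is None or baseline is None:
                    logger.warning("subject %s lacks %s trace for phase %r; "
                                   "thermal features undefined",
                                   rec.subject_id, roi, phase)
                    for name in THERMAL_FEATURE_NAMES:
                        row[f"{prefix}_{name}"] = np.nan
                    continue
                cleaned, _ = hampel_filter(trace, hampel)
                anchored = baseline_subtract(cleaned, baseline)
                feats = thermal_feature_vector(anchored, sampen, bands)
                for name, value in feats.as_dict().items():
                    row[f"{prefix}_{name}"] = value
            phase_hrv = _phase_hrv(rec, phase, ecg_params, bands)
            if phase_hrv is None or hrv_baseline is None:
                for name in HRV_FEATURE_NAMES:
                    row[f"HRV_{name}"] = np.nan
            else:
                ratios = normalize_to_baseline(phase_hrv, hrv_baseline)
                for name, value in ratios.as_dict().items():
                    row[f"HRV_{name}"] = value
            rows.append(row)
    cols = ["subject_id", "phase"] + feature_columns("multimodal")
    return pd.DataFrame(rows, columns=cols)


def _task_phases(rec: SubjectRecord) -> list[str]:
    """Task phases of a record in canonical protocol order (so extraction
    does not depend on dict insertion order, e.g. after a disk round trip)."""
    from .synth import PHASES

    present = {p for p in rec.ecg} | {ph for _, ph in rec.thermal}
    present = [p for p in present if p != BASELINE_PHASE]
    known = [p for p in PHASES if p in present]
    return known + sorted(set(present) - set(known))


def _phase_hrv(rec: SubjectRecord, phase: str, params: EcgPreprocParams,
               bands: BandSpec):
    ecg = rec.ecg.get(phase)
    if ecg is None:
        logger.warning("subject %s has no ECG for phase %r", rec.subject_id, phase)
        return None
    conditioned = preprocess_ecg(ecg, params)
    peaks = detect_r_peaks(conditioned, params)
    if peaks.size < 4:
        logger.warning("subject %s phase %r: only %d beats detected; HRV undefined",
                       rec.subject_id, phase, peaks.size)
        return None
    rr = rr_from_peaks(peaks, ecg.fs)
    return hrv_feature_vector(rr, bands, phase=phase)


def assemble(features: "pd.DataFrame | list[SubjectRecord]", task: str,
             view: str, **extract_kwargs) -> pd.DataFrame:
    """Labelled feature table for one task and one modality view.

    ``features`` is either the long table from :func:`extract_features` or a
    cohort of records (extracted on the fly). Rows are sorted by subject
    then phase order; subjects missing any task phase are dropped with a
    warning. A complete cohort yields balanced classes: with 26 subjects,
    52 DST rows (26 per class) or 78 RAVLT rows.
    """
    if not isinstance(features, pd.DataFrame):
        features = extract_features(features, **extract_kwargs)
    phases = TASKS[task]  # validates task
    cols = feature_columns(view)
    sub = features[features["phase"].isin(phases)]
    if len(sub):
        counts = sub.groupby("subject_id")["phase"].nunique()
        complete = set(counts[counts == len(phases)].index)
        dropped = sorted(set(sub["subject_id"]) - complete)
        if dropped:
            logger.warning("dropping subjects missing task phases: %s", dropped)
        sub = sub[sub["subject_id"].isin(complete)]
    out = sub[["subject_id", "phase"]].copy()
    out["task"] = task
    out["label"] = [label_for_phase(task, p) for p in sub["phase"]]
    out = pd.concat([out[list(ID_COLUMNS)], sub[cols]], axis=1)
    order = {p: i for i, p in enumerate(phases)}
    out = out.sort_values(["subject_id", "phase"],
                          key=lambda s: s.map(order) if s.name == "phase" else s)
    return out.reset_index(drop=True)


def drop_incomplete(table: pd.DataFrame) -> pd.DataFrame:
    """Remove rows with undefined feature values; log counts per feature."""
    feat_cols = [c for c in table.columns if c not in ID_COLUMNS]
    missing = table[feat_cols].isna()
    per_feature = missing.sum()
    for name, count in per_feature[per_feature > 0].items():
        logger.info("feature %s undefined in %d rows", name, int(count))
    kept = table[~missing.any(axis=1)].reset_index(drop=True)
    if len(table) and not len(kept):
        raise ValueError(
            "every row carries an undefined feature value; inspect the "
            "extraction logs before modelling")
    return kept


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in ID_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table {path} lacks columns {missing}")
    return table
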
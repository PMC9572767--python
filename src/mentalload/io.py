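"""On-disk layout: signal CSVs, the manifest, and score tables.

One CSV per (subject, phase, channel) with columns ``time_s,value``; a
manifest CSV with columns ``subject_id,phase,channel,path`` (paths relative
to the manifest); a scores CSV with ``subject_id`` plus one column per
behavioural score. The synthetic generator emits exactly the layout the
extraction stage ingests.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .signals import TimeSeries
from .synth import BASELINE_PHASE, ROIS, SubjectRecord

logger = logging.getLogger(__name__)

__all__ = ["write_signal_csv", "read_signal_csv", "write_cohort",
           "read_cohort", "read_manifest", "write_beats_csv"]

MANIFEST_NAME = "manifest.csv"
SCORES_NAME = "scores.csv"


def write_signal_csv(series: TimeSeries, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"time_s": series.times, "value": series.values})
    # 8 decimals represent a 256 Hz grid (1/256 s) exactly
    df.to_csv(path, index=False, float_format="%.8f")


def read_signal_csv(path, phase: str = "", channel: str = "") -> TimeSeries:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface file context
        raise ValueError(f"malformed signal CSV {path}: {exc}") from exc
    for col in ("time_s", "value"):
        if col not in df.columns:
            raise ValueError(f"signal CSV {path} lacks column {col!r} (line 1)")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"signal CSV {path} holds fewer than 2 samples")
    dt = np.diff(t)
    step = float(np.median(dt))
    ok = np.isclose(dt, step, rtol=1e-3, atol=0)
    if step <= 0 or not ok.all():
        bad = int(np.argmax(~ok)) + 2
        raise ValueError(f"signal CSV {path} is not uniformly sampled "
                         f"(near line {bad + 1})")
    fs = 1.0 / step
    return TimeSeries(df["value"].to_numpy(dtype=float), fs, phase, channel)


def write_cohort(records: list[SubjectRecord], out_dir) -> Path:
    """Write a cohort as signal CSVs + manifest + scores; returns out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        for (roi, phase), series in sorted(rec.thermal.items()):
            rel = Path(rec.subject_id) / f"{phase}_{roi}.csv"
            write_signal_csv(series, out_dir / rel)
            rows.append({"subject_id": rec.subject_id, "phase": phase,
                         "channel": roi, "path": str(rel)})
        for phase, series in sorted(rec.ecg.items()):
            rel = Path(rec.subject_id) / f"{phase}_ECG.csv"
            write_signal_csv(series, out_dir / rel)
            rows.append({"subject_id": rec.subject_id, "phase": phase,
                         "channel": "ECG", "path": str(rel)})
    pd.DataFrame(rows).to_csv(out_dir / MANIFEST_NAME, index=False)
    scores = pd.DataFrame(
        [{"subject_id": rec.subject_id, **rec.scores} for rec in records])
    scores.to_csv(out_dir / SCORES_NAME, index=False)
    return out_dir


def write_beats_csv(beats: dict, path) -> None:
    """Write detected beats as CSV rows (subject_id, phase, beat_time_s).

    ``beats`` maps (subject_id, phase) to an array of beat times in
    seconds.
    """
    rows = [{"subject_id": sid, "phase": phase, "beat_time_s": t}
            for (sid, phase), times in sorted(beats.items()) for t in times]
    pd.DataFrame(rows, columns=["subject_id", "phase", "beat_time_s"]) \
        .to_csv(path, index=False, float_format="%.6f")


def read_manifest(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    required = {"subject_id", "phase", "channel", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns {sorted(missing)}")
    gone = [p for p in df["path"] if not (path.parent / p).exists()]
    if gone:
        raise ValueError(f"manifest {path} references missing files: {gone[:5]}")
    return df


def read_cohort(data_dir) -> list[SubjectRecord]:
    """Rebuild SubjectRecords from a written dataset directory.

    Ground-truth fields (beat times, artifact indices) are not on disk and
    come back empty. Baseline thermal windows are re-derived as the final
    60 s of the BL traces. Subjects missing ECG keep their thermal side
    (logged); HRV features will be undefined for them downstream.
    """
    data_dir = Path(data_dir)
    manifest = read_manifest(data_dir / MANIFEST_NAME)
    scores_path = data_dir / SCORES_NAME
    scores = (pd.read_csv(scores_path).set_index("subject_id")
              if scores_path.exists() else None)
    records = []
    for subject_id, group in manifest.groupby("subject_id", sort=True):
        thermal: dict[tuple[str, str], TimeSeries] = {}
        ecg: dict[str, TimeSeries] = {}
        for row in group.itertuples():
            series = read_signal_csv(data_dir / row.path, row.phase, row.channel)
            if row.channel == "ECG":
                ecg[row.phase] = series
            elif row.channel in ROIS:
                thermal[(row.channel, row.phase)] = series
            else:
                raise ValueError(f"unknown channel {row.channel!r} in manifest")
        baseline_thermal = {}
        for roi in ROIS:
            bl = thermal.get((roi, BASELINE_PHASE))
            if bl is None:
                continue
            n60 = int(round(60 * bl.fs))
            tail = bl.values[-n60:] if bl.n > n60 else bl.values
            baseline_thermal[roi] = TimeSeries(tail.copy(), bl.fs,
                                               BASELINE_PHASE, roi)
        if not ecg:
            logger.warning("subject %s has no ECG files; HRV view will drop it",
                           subject_id)
        rec = SubjectRecord(subject_id=str(subject_id), thermal=thermal,
                            ecg=ecg, baseline_thermal=baseline_thermal)
        if scores is not None and subject_id in scores.index:
            rec.scores = scores.loc[subject_id].to_dict()
        records.append(rec)
    return records
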
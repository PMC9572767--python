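"""Synthetic multi-phase cohort generator.

Emulates a driving-simulator protocol in which each subject completes a
baseline drive (``BL``) followed by cognitive task sub-phases — Digit Span
Test Forward/Backward (the 2-class task) and Rey Auditory Verbal Learning
Test ImmR/DelR/Rec (the 3-class task) — while facial thermal-imaging ROI
traces (nose tip and glabella, 10 Hz) and single-lead ECG (256 Hz) are
recorded.

The generator reproduces the statistical structure the downstream analysis
assumes, with ground truth returned for oracle tests:

* nose-tip (and, more weakly, glabella) temperature drops during cognitive
  load, deeper for more demanding sub-phases;
* LF (0.10 Hz) and HF (0.25 Hz) sinusoidal components in both the thermal
  traces and the RR train — band centres chosen so band-power recovery is
  analytically checkable;
* subject-level random offsets, AR(1) thermal noise (skin temperature is
  slow), Poisson-placed spike artifacts in the thermal traces;
* ECG built as Gaussian-shaped R waves (20 ms standard width, unit
  amplitude) placed at beat times integrated from the modulated RR train,
  over white measurement noise.

One master seed spawns independent per-subject substreams, so enlarging the
cohort never perturbs existing subjects. ``null_mode`` removes every phase
effect (all phases share the baseline generative parameters), giving exact
chance-level material for leakage and type-I-error checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .signals import TimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "PHASES", "TASK_PHASES", "ROIS", "SCORE_NAMES",
    "SynthConfig", "SubjectRecord", "generate_cohort", "generate_scores",
]

BASELINE_PHASE = "BL"
DST_PHASES = ("Forward", "Backward")
RAVLT_PHASES = ("ImmR", "DelR", "Rec")
TASK_PHASES: tuple[str, ...] = DST_PHASES + RAVLT_PHASES
PHASES: tuple[str, ...] = (BASELINE_PHASE,) + TASK_PHASES
ROIS = ("nosetip", "glabella")
SCORE_NAMES = ("DST_Forward", "DST_Backward", "RAVLT_ImmR", "RAVLT_DelR", "RAVLT_Rec")

_LF_HZ = 0.10   # centre of the 0.04-0.15 Hz band
_HF_HZ = 0.25   # centre of the 0.15-0.40 Hz band


def _default_durations() -> dict[str, float]:
    # BL long enough for a stable baseline HRV estimate; each task sub-phase
    # holds >= 2 LF cycles in every analysis window
    d = {BASELINE_PHASE: 900.0}
    d.update({p: 120.0 for p in TASK_PHASES})
    return d


def _default_nose_effect() -> dict[str, float]:
    # deg C shift vs baseline; nose-tip temperature falls under load, deeper
    # for the more demanding sub-phases (Backward, DelR)
    return {"BL": 0.0, "Forward": -0.3, "Backward": -0.6,
            "ImmR": -0.3, "DelR": -0.7, "Rec": -0.15}


def _default_glabella_effect() -> dict[str, float]:
    return {"BL": 0.0, "Forward": -0.1, "Backward": -0.25,
            "ImmR": -0.15, "DelR": -0.3, "Rec": -0.05}


def _default_thermal_lf() -> dict[str, float]:
    # vasomotor LF oscillation amplitude (deg C); rises with load
    return {"BL": 0.05, "Forward": 0.06, "Backward": 0.12,
            "ImmR": 0.06, "DelR": 0.14, "Rec": 0.04}


def _default_thermal_hf() -> dict[str, float]:
    return {"BL": 0.02, "Forward": 0.02, "Backward": 0.015,
            "ImmR": 0.02, "DelR": 0.012, "Rec": 0.025}


def _default_rr_mean() -> dict[str, float]:
    # ms; heart rate increases (RR shortens) under load
    return {"BL": 900.0, "Forward": 850.0, "Backward": 800.0,
            "ImmR": 850.0, "DelR": 780.0, "Rec": 870.0}


def _default_rr_lf() -> dict[str, float]:
    # ms modulation depth; sympathetic LF rises, vagal HF falls under load
    return {"BL": 30.0, "Forward": 40.0, "Backward": 50.0,
            "ImmR": 40.0, "DelR": 55.0, "Rec": 28.0}


def _default_rr_hf() -> dict[str, float]:
    return {"BL": 20.0, "Forward": 14.0, "Backward": 10.0,
            "ImmR": 14.0, "DelR": 8.0, "Rec": 18.0}


def _default_score_means() -> dict[str, float]:
    # typical young-adult normative levels: DST span ~6 forward / ~5 backward,
    # RAVLT total immediate ~50 words, delayed ~11, recognition ~13
    return {"DST_Forward": 6.5, "DST_Backward": 5.5,
            "RAVLT_ImmR": 50.0, "RAVLT_DelR": 11.0, "RAVLT_Rec": 13.0}


def _default_score_sds() -> dict[str, float]:
    return {"DST_Forward": 1.5, "DST_Backward": 1.5,
            "RAVLT_ImmR": 8.0, "RAVLT_DelR": 2.5, "RAVLT_Rec": 2.0}


@dataclass
class SynthConfig:
    """Generative parameters for one synthetic cohort.

    Per-phase mappings must cover every phase in ``phase_durations``.
    ``null_mode`` replaces every per-phase parameter by its baseline value,
    making all phases exchangeable.
    """

    n_subjects: int = 26
    seed: int = 0
    phase_durations: dict[str, float] = field(default_factory=_default_durations)
    thermal_rate: float = 10.0
    ecg_rate: float = 256.0
    nose_effect: dict[str, float] = field(default_factory=_default_nose_effect)
    glabella_effect: dict[str, float] = field(default_factory=_default_glabella_effect)
    thermal_lf_amp: dict[str, float] = field(default_factory=_default_thermal_lf)
    thermal_hf_amp: dict[str, float] = field(default_factory=_default_thermal_hf)
    rr_mean: dict[str, float] = field(default_factory=_default_rr_mean)
    rr_lf_amp: dict[str, float] = field(default_factory=_default_rr_lf)
    rr_hf_amp: dict[str, float] = field(default_factory=_default_rr_hf)
    baseline_temp: float = 34.0          # deg C-equivalent ROI level
    subject_sd: float = 0.3              # between-subject thermal offset (deg C)
    rr_subject_sd: float = 40.0          # between-subject RR offset (ms)
    noise_sd: float = 0.08               # AR(1) innovation SD, thermal (deg C)
    ar_coeff: float = 0.9                # AR(1) coefficient: skin is slow
    rr_noise_sd: float = 10.0            # per-beat RR jitter (ms)
    ecg_noise_sd: float = 0.05           # ECG measurement noise (R wave = 1)
    r_wave_width: float = 0.020          # Gaussian R-wave SD (s)
    artifact_rate: float = 2.0           # thermal spikes per minute
    artifact_amplitude: float = 2.0      # spike magnitude (deg C)
    score_means: dict[str, float] = field(default_factory=_default_score_means)
    score_sds: dict[str, float] = field(default_factory=_default_score_sds)
    score_corr: float = 0.6              # within-subject correlation of scores
    null_mode: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("a cohort needs at least 2 subjects")
        if not (self.thermal_rate > 0 and self.ecg_rate > 0):
            raise ValueError("sampling rates must be positive")
        if any(d <= 0 for d in self.phase_durations.values()):
            raise ValueError("all phase durations must be positive")
        if self.artifact_rate < 0:
            raise ValueError("artifact rate must be nonnegative")
        if not -1 < self.score_corr < 1:
            raise ValueError("score correlation must lie in (-1, 1)")
        for name, mapping in self._phase_maps().items():
            missing = set(self.phase_durations) - set(mapping)
            if missing:
                raise ValueError(f"{name} missing phases: {sorted(missing)}")
        for phase, dur in self.phase_durations.items():
            rr = self.phase_value(self.rr_mean, phase)
            if dur < 2 * rr / 1000.0:
                raise ValueError(
                    f"phase {phase!r} lasts {dur:g} s, too short to hold two "
                    f"beats at mean RR {rr:g} ms"
                )

    def _phase_maps(self) -> dict[str, Mapping[str, float]]:
        return {
            "nose_effect": self.nose_effect,
            "glabella_effect": self.glabella_effect,
            "thermal_lf_amp": self.thermal_lf_amp,
            "thermal_hf_amp": self.thermal_hf_amp,
            "rr_mean": self.rr_mean,
            "rr_lf_amp": self.rr_lf_amp,
            "rr_hf_amp": self.rr_hf_amp,
        }

    def phase_value(self, mapping: Mapping[str, float], phase: str) -> float:
        """Per-phase parameter, collapsed to the baseline value in null mode."""
        if self.null_mode:
            return mapping[BASELINE_PHASE]
        return mapping[phase]

    @property
    def task_phases(self) -> tuple[str, ...]:
        return tuple(p for p in self.phase_durations if p != BASELINE_PHASE)


@dataclass
class SubjectRecord:
    """All signals for one subject, plus generator ground truth.

    ``thermal`` maps (ROI, phase) to a trace; ``ecg`` maps phase to the raw
    ECG; ``baseline_thermal`` holds, per ROI, the final minute before the
    first task phase (the baseline-subtraction window). ``true_beats`` and
    ``artifact_indices`` expose the generator's ground truth for oracle
    tests and are absent from on-disk exports.
    """

    subject_id: str
    thermal: dict[tuple[str, str], TimeSeries]
    ecg: dict[str, TimeSeries]
    baseline_thermal: dict[str, TimeSeries]
    scores: dict[str, float] = field(default_factory=dict)
    true_beats: dict[str, np.ndarray] = field(default_factory=dict)
    artifact_indices: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)


def _ar1_noise(rng: np.random.Generator, n: int, coeff: float, innov_sd: float) -> np.ndarray:
    """Stationary AR(1) noise via scipy-free recursion (lfilter on innovations)."""
    from scipy.signal import lfilter

    innov = rng.normal(0.0, innov_sd, n + 200)  # burn-in to reach stationarity
    out = lfilter([1.0], [1.0, -coeff], innov)
    return out[200:]


def _thermal_trace(rng: np.random.Generator, config: SynthConfig, phase: str,
                   roi: str, offset: float) -> tuple[np.ndarray, np.ndarray]:
    """One ROI trace plus the indices of its injected spike artifacts."""
    fs = config.thermal_rate
    n = int(round(config.phase_durations[phase] * fs))
    t = np.arange(n) / fs
    effect_map = config.nose_effect if roi == "nosetip" else config.glabella_effect
    level = config.baseline_temp + offset + config.phase_value(effect_map, phase)
    lf = config.phase_value(config.thermal_lf_amp, phase)
    hf = config.phase_value(config.thermal_hf_amp, phase)
    phi_lf, phi_hf = rng.uniform(0, 2 * np.pi, 2)
    x = (level
         + lf * np.sin(2 * np.pi * _LF_HZ * t + phi_lf)
         + hf * np.sin(2 * np.pi * _HF_HZ * t + phi_hf)
         + _ar1_noise(rng, n, config.ar_coeff, config.noise_sd))
    n_spikes = rng.poisson(config.artifact_rate * n / fs / 60.0)
    n_spikes = min(n_spikes, n)
    idx = np.sort(rng.choice(n, size=n_spikes, replace=False)) if n_spikes else np.array([], dtype=int)
    if n_spikes:
        signs = rng.choice([-1.0, 1.0], size=n_spikes)
        x[idx] += signs * config.artifact_amplitude
    return x, idx


def _beat_times(rng: np.random.Generator, config: SynthConfig, phase: str) -> np.ndarray:
    """Beat times from an LF/HF-modulated RR train with per-beat jitter."""
    duration = config.phase_durations[phase]
    rr0 = config.phase_value(config.rr_mean, phase)
    lf = config.phase_value(config.rr_lf_amp, phase)
    hf = config.phase_value(config.rr_hf_amp, phase)
    phi_lf, phi_hf = rng.uniform(0, 2 * np.pi, 2)
    # subject-level RR offset is folded into rr0 by the caller; the record
    # starts mid-cycle, as a real recording does
    t = float(rng.uniform(0.25, 0.75)) * rr0 / 1000.0
    beats = [t]
    floor_ms = 250.0  # physiological refractory floor keeps gaps >= 250 ms
    while True:
        rr_ms = (rr0
                 + lf * np.sin(2 * np.pi * _LF_HZ * t + phi_lf)
                 + hf * np.sin(2 * np.pi * _HF_HZ * t + phi_hf)
                 + rng.normal(0.0, config.rr_noise_sd))
        rr_ms = max(rr_ms, floor_ms)
        t = t + rr_ms / 1000.0
        if t >= duration:
            break
        beats.append(t)
    if len(beats) < 2:
        raise ValueError(f"phase {phase!r} too short to hold two beats")
    return np.asarray(beats)


def _ecg_from_beats(rng: np.random.Generator, config: SynthConfig, phase: str,
                    beats: np.ndarray) -> np.ndarray:
    fs = config.ecg_rate
    n = int(round(config.phase_durations[phase] * fs))
    # measurement noise is AR(1)-correlated (dominated by slow baseline
    # wander, not white noise) with marginal SD ecg_noise_sd, so the R-wave
    # apex stays the unambiguous local maximum
    rho = 0.99
    innov = config.ecg_noise_sd * np.sqrt(1 - rho**2)
    x = _ar1_noise(rng, n, rho, innov)
    half = int(round(4 * config.r_wave_width * fs))  # +/- 4 SD support
    tpl_t = np.arange(-half, half + 1) / fs
    template = np.exp(-0.5 * (tpl_t / config.r_wave_width) ** 2)
    centers = np.round(beats * fs).astype(int)
    for c in centers:
        lo, hi = c - half, c + half + 1
        s_lo, s_hi = max(lo, 0), min(hi, n)
        x[s_lo:s_hi] += template[s_lo - lo:s_hi - lo]
    return x


def generate_cohort(config: SynthConfig) -> list[SubjectRecord]:
    """Generate a deterministic cohort of :class:`SubjectRecord`.

    One master seed spawns a child stream per subject, and each subject
    spawns per-signal streams, so regenerating with more subjects leaves
    the existing ones bit-identical.
    """
    master = np.random.SeedSequence(config.seed)
    subject_seeds = master.spawn(config.n_subjects)
    records = []
    task_phases = config.task_phases
    for i, sseq in enumerate(subject_seeds):
        offset_rng = np.random.Generator(np.random.PCG64(sseq.spawn(1)[0]))
        thermal_offset = offset_rng.normal(0.0, config.subject_sd)
        rr_offset = offset_rng.normal(0.0, config.rr_subject_sd)
        thermal: dict[tuple[str, str], TimeSeries] = {}
        artifacts: dict[tuple[str, str], np.ndarray] = {}
        ecg: dict[str, TimeSeries] = {}
        true_beats: dict[str, np.ndarray] = {}

        phases = (BASELINE_PHASE,) + task_phases if BASELINE_PHASE in config.phase_durations else task_phases
        for phase in phases:
            for roi in ROIS:
                child = np.random.Generator(np.random.PCG64(
                    _stream(sseq, f"thermal/{roi}/{phase}")))
                x, idx = _thermal_trace(child, config, phase, roi, thermal_offset)
                thermal[(roi, phase)] = TimeSeries(x, config.thermal_rate, phase, roi)
                artifacts[(roi, phase)] = idx
            ecg_rng = np.random.Generator(np.random.PCG64(_stream(sseq, f"ecg/{phase}")))
            shifted = _shift_rr(config, rr_offset)
            beats = _beat_times(ecg_rng, shifted, phase)
            ecg[phase] = TimeSeries(
                _ecg_from_beats(ecg_rng, shifted, phase, beats),
                config.ecg_rate, phase, "ECG",
            )
            true_beats[phase] = beats

        baseline_thermal = {}
        if BASELINE_PHASE in config.phase_durations:
            n60 = int(round(60.0 * config.thermal_rate))
            for roi in ROIS:
                bl = thermal[(roi, BASELINE_PHASE)]
                tail = bl.values[-n60:] if bl.n > n60 else bl.values
                baseline_thermal[roi] = TimeSeries(tail.copy(), bl.fs, BASELINE_PHASE, roi)

        records.append(SubjectRecord(
            subject_id=f"S{i + 1:03d}",
            thermal=thermal, ecg=ecg, baseline_thermal=baseline_thermal,
            true_beats=true_beats, artifact_indices=artifacts,
        ))
    scores = generate_scores(config)
    for rec in records:
        rec.scores = {k: float(scores.loc[rec.subject_id, k]) for k in scores.columns}
    return records


def _shift_rr(config: SynthConfig, rr_offset: float) -> SynthConfig:
    """Config copy with the subject's RR offset folded into every phase mean."""
    import dataclasses

    return dataclasses.replace(
        config, rr_mean={k: v + rr_offset for k, v in config.rr_mean.items()})


def _stream(parent: np.random.SeedSequence, label: str):
    """Named, order-independent child stream of a subject's seed sequence."""
    import hashlib

    digest = hashlib.md5(label.encode()).digest()
    words = np.frombuffer(digest, dtype=np.uint32)
    return np.random.SeedSequence(entropy=parent.entropy,
                                  spawn_key=parent.spawn_key + tuple(int(w) for w in words))


def generate_scores(config: SynthConfig):
    """Per-subject behavioural score table (one row per subject).

    Scores are jointly Gaussian with per-score means/SDs and a shared
    within-subject correlation. Deterministic under ``config.seed``.
    """
    import pandas as pd

    names = list(config.score_means)
    k = len(names)
    corr = np.full((k, k), config.score_corr)
    np.fill_diagonal(corr, 1.0)
    sds = np.array([config.score_sds[n] for n in names])
    cov = corr * np.outer(sds, sds)
    means = np.array([config.score_means[n] for n in names])
    rng = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(0x5C0,))))
    raw = rng.multivariate_normal(means, cov, size=config.n_subjects,
                                  method="cholesky")
    ids = [f"S{i + 1:03d}" for i in range(config.n_subjects)]
    return pd.DataFrame(raw, index=pd.Index(ids, name="subject_id"), columns=names)
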
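"""ECG preprocessing, R-peak detection, RR series and HRV features.

The cardiac chain is: zero-phase band-pass (0.05 Hz to min(150, 0.45*fs) Hz)
plus a 50 Hz mains notch; amplitude-threshold R-peak detection (local maxima
above mean + 2 SD of the whole-phase signal with a 250 ms refractory
period); RR tachogram construction; and six HRV descriptors — RRmean, SDNN,
RMSSD in the time domain, LF, HF and LF/HF in the frequency domain after
cubic-spline resampling of the tachogram onto an even 4 Hz grid.

Each task-phase feature is finally normalised as the ratio to the same
feature over the baseline drive, removing between-subject level differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .descriptors import BandSpec, band_features, estimate_spectrum
from .signals import RRSeries, TimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "EcgPreprocParams", "HrvFeatures", "HRV_FEATURE_NAMES",
    "preprocess_ecg", "detect_r_peaks", "rr_from_peaks",
    "hrv_time_features", "hrv_freq_features", "hrv_feature_vector",
    "normalize_to_baseline",
]

HRV_FEATURE_NAMES = ("RRmean", "SDNN", "RMSSD", "LF", "HF", "LFHF")

#: even resampling rate for the tachogram before spectral estimation (Hz)
TACHOGRAM_FS = 4.0


@dataclass(frozen=True)
class EcgPreprocParams:
    """ECG conditioning and peak-detection settings.

    The band-pass upper edge is capped at 0.45*fs at run time when it
    exceeds the Nyquist limit of the recording.
    """

    bp_low: float = 0.05
    bp_high: float = 150.0
    notch: float = 50.0
    refractory: float = 0.25
    z_threshold: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.bp_low < self.bp_high:
            raise ValueError("need 0 < bp_low < bp_high")
        if not self.bp_low < self.notch < self.bp_high:
            raise ValueError("notch frequency must lie inside the pass band")
        if not self.refractory > 0:
            raise ValueError("refractory period must be positive")


@dataclass
class HrvFeatures:
    """The six HRV descriptors for one phase (raw or baseline-normalised)."""

    RRmean: float
    SDNN: float
    RMSSD: float
    LF: float
    HF: float
    LFHF: float
    phase: str = ""
    normalized: bool = False

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in HRV_FEATURE_NAMES}


def preprocess_ecg(x: TimeSeries, params: EcgPreprocParams = EcgPreprocParams()
                   ) -> TimeSeries:
    """Zero-phase band-pass plus mains notch; output length equals input."""
    if x.fs < 100:
        raise ValueError(f"ECG sampling rate {x.fs} Hz too low; need >= 100 Hz")
    high = min(params.bp_high, 0.45 * x.fs)
    if high < params.bp_high:
        logger.info("band-pass upper edge capped at %.1f Hz (0.45*fs) below "
                    "the requested %.1f Hz", high, params.bp_high)
    if high <= params.bp_low:
        raise ValueError("sampling rate too low for the requested band")
    sos = sps.butter(4, [params.bp_low, high], btype="bandpass",
                     fs=x.fs, output="sos")
    # the high-pass corner period (20 s at 0.05 Hz) dwarfs filtfilt's
    # reflective padding, which leaves large edge transients; demean and
    # zero-pad by a couple of corner periods instead
    n_pad = int(round(2.0 / params.bp_low * x.fs))
    demeaned = x.values - np.mean(x.values)
    padded = np.concatenate([np.zeros(n_pad), demeaned, np.zeros(n_pad)])
    y = sps.sosfiltfilt(sos, padded, padlen=0)
    if params.bp_low < params.notch < high:
        b, a = sps.iirnotch(params.notch, Q=30.0, fs=x.fs)
        y = sps.filtfilt(b, a, y)
    return x.replace_values(y[n_pad:-n_pad])


def detect_r_peaks(x: TimeSeries, params: EcgPreprocParams = EcgPreprocParams()
                   ) -> np.ndarray:
    """Indices of R peaks: local maxima above mean + z_threshold*SD.

    The threshold uses the global per-phase mean and standard deviation, so
    detection is invariant to amplitude scaling. Successive peaks are at
    least one refractory period apart. Returns an empty array (with a
    warning) when nothing crosses the threshold.
    """
    v = x.values
    thr = float(np.mean(v) + params.z_threshold * np.std(v))
    distance = max(1, int(round(params.refractory * x.fs)))
    peaks, _ = sps.find_peaks(v, height=thr, distance=distance)
    if peaks.size == 0:
        logger.warning("no samples exceed the %g-SD R-peak threshold in "
                       "phase %r", params.z_threshold, x.phase)
    return peaks


def rr_from_peaks(beat_indices, fs: float) -> RRSeries:
    """RR series (beat times in s, intervals in ms) from peak indices."""
    beat_indices = np.asarray(beat_indices)
    if beat_indices.size < 2:
        raise ValueError("need at least 2 beats to form RR intervals")
    return RRSeries(beat_times=beat_indices / fs)


def hrv_time_features(rr: RRSeries) -> tuple[float, float, float]:
    """(RRmean, SDNN, RMSSD) in ms.

    SDNN is the sample standard deviation of the intervals; RMSSD the root
    mean square of successive interval differences.
    """
    iv = rr.rr
    if iv.size < 2:
        raise ValueError("need at least 2 RR intervals")
    rmssd = float(np.sqrt(np.mean(np.diff(iv) ** 2)))
    if iv.size < 4:
        raise ValueError("need at least 4 RR intervals for SDNN")
    return float(np.mean(iv)), float(np.std(iv, ddof=1)), rmssd


def hrv_freq_features(rr: RRSeries, bands: BandSpec = BandSpec()
                      ) -> tuple[float, float, float]:
    """(LF, HF, LF/HF) band power of the evenly resampled tachogram.

    The RR tachogram rr(t) (interval value at the time of the closing beat)
    is cubic-spline interpolated onto a uniform 4 Hz grid, then passed
    through the shared Welch band-power estimator.
    """
    if rr.n_beats < 4:
        raise ValueError("need at least 4 beats for spectral HRV features")
    span = rr.beat_times[-1] - rr.beat_times[1]
    if span < 2.0 / bands.lf_low:
        logger.warning("RR record spans %.1f s, below the %.0f s recommended "
                       "for LF estimation", span, 2.0 / bands.lf_low)
    t = rr.beat_times[1:]
    spline = CubicSpline(t, rr.rr)
    grid = np.arange(t[0], t[-1], 1.0 / TACHOGRAM_FS)
    even = spline(grid)
    spec = estimate_spectrum(even, TACHOGRAM_FS, bands=bands)
    return band_features(spec, bands)


def hrv_feature_vector(rr: RRSeries, bands: BandSpec = BandSpec(),
                       phase: str = "") -> HrvFeatures:
    """All six HRV descriptors of one phase's RR series."""
    rrmean, sdnn, rmssd = hrv_time_features(rr)
    lf, hf, lfhf = hrv_freq_features(rr, bands)
    return HrvFeatures(RRmean=rrmean, SDNN=sdnn, RMSSD=rmssd,
                       LF=lf, HF=hf, LFHF=lfhf, phase=phase)


def normalize_to_baseline(phase_features: HrvFeatures,
                          baseline_features: HrvFeatures) -> HrvFeatures:
    """Element-wise ratio of task-phase HRV features to baseline features.

    A zero baseline entry makes that ratio undefined (NaN, logged); the
    remaining ratios are still produced.
    """
    if phase_features.normalized or baseline_features.normalized:
        raise ValueError("normalize_to_baseline expects unnormalized inputs")
    ratios = {}
    for name in HRV_FEATURE_NAMES:
        base = getattr(baseline_features, name)
        val = getattr(phase_features, name)
        if base == 0 or not np.isfinite(base):
            logger.info("baseline %s is %r; ratio undefined for phase %r",
                        name, base, phase_features.phase)
            ratios[name] = float("nan")
        else:
            ratios[name] = val / base
    return HrvFeatures(**ratios, phase=phase_features.phase, normalized=True)
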
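"""Thermal ROI processing: ROI averaging, Hampel artifact rejection,
baseline subtraction, and the nine-feature descriptor vector.

The feature vector per ROI per phase is: MeanTemp, STD, K (kurtosis),
S (skewness), P90 (90th percentile), SampEn, LF, HF and LF/HF — i.e. the
five distribution moments plus sample entropy and band-limited spectral
power of the slow vasomotor oscillations.

Processing order: Hampel despiking first, then subtraction of the mean of a
one-minute baseline window recorded just before the first task phase. The
two steps commute up to the constant shift, but despiking first keeps the
baseline mean itself robust to spikes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .descriptors import (BandSpec, SampEnParams, band_features,
                          estimate_spectrum, moment_features, sample_entropy)
from .signals import TimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "HampelParams", "ThermalFeatures", "THERMAL_FEATURE_NAMES",
    "roi_mean_series", "hampel_filter", "baseline_subtract",
    "thermal_feature_vector",
]

THERMAL_FEATURE_NAMES = ("MeanTemp", "STD", "K", "S", "P90",
                         "SampEn", "LF", "HF", "LFHF")

#: 1.4826 rescales the median absolute deviation to estimate a Gaussian SD,
#: the conventional Hampel dispersion.
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class HampelParams:
    """Hampel filter settings: total centred window length (s) and the
    outlier threshold as a multiple of the scaled-MAD dispersion."""

    window_seconds: float = 15.0
    n_sd: float = 2.0

    def __post_init__(self) -> None:
        if not self.window_seconds > 0:
            raise ValueError("window_seconds must be positive")
        if not self.n_sd > 0:
            raise ValueError("n_sd must be positive")


@dataclass
class ThermalFeatures:
    """The nine thermal descriptors for one ROI in one phase."""

    MeanTemp: float
    STD: float
    K: float
    S: float
    P90: float
    SampEn: float
    LF: float
    HF: float
    LFHF: float
    roi: str = ""
    phase: str = ""

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in THERMAL_FEATURE_NAMES}


def roi_mean_series(frames, mask, fs: float = 10.0, phase: str = "",
                    channel: str = "") -> TimeSeries:
    """Average the masked pixels of each frame into a 1-D trace.

    ``frames`` is a (t, h, w) stack or sequence of 2-D grids; ``mask`` a
    boolean grid of the frame shape selecting at least one pixel.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must be a sequence of 2-D grids")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != frames.shape[1:]:
        raise ValueError(
            f"mask shape {mask.shape} does not match frame shape {frames.shape[1:]}")
    if not mask.any():
        raise ValueError("ROI mask selects no pixels")
    values = frames[:, mask].mean(axis=1)
    return TimeSeries(values, fs, phase, channel)


def hampel_filter(x: TimeSeries, params: HampelParams = HampelParams()
                  ) -> tuple[TimeSeries, np.ndarray]:
    """Sliding-window Hampel outlier rejection.

    For every sample the median and scaled-MAD dispersion are computed over
    a centred window of ``window_seconds * fs`` samples (truncated at the
    edges). Samples deviating from the local median by more than
    ``n_sd`` dispersions are replaced by that median. Returns the cleaned
    series and a boolean mask marking replacements.
    """
    w = int(round(params.window_seconds * x.fs))
    if w < 3:
        raise ValueError(
            f"window of {params.window_seconds} s at {x.fs} Hz spans {w} "
            "samples; need at least 3")
    if x.n < 3:
        raise ValueError("need at least 3 samples")
    values = x.values
    n = values.size
    half = w // 2
    medians = np.empty(n)
    mads = np.empty(n)

    if n >= w:
        # full interior windows vectorised; edge windows truncated below
        win = np.lib.stride_tricks.sliding_window_view(values, w)
        med_full = np.median(win, axis=1)
        mad_full = np.median(np.abs(win - med_full[:, None]), axis=1)
        # sample i has full window when half <= i <= n - (w - half) ... map:
        # window j covers samples j..j+w-1, centred at j+half
        centers = np.arange(win.shape[0]) + half
        medians[centers] = med_full
        mads[centers] = mad_full
        edge_idx = np.concatenate([np.arange(half),
                                   np.arange(centers[-1] + 1, n)])
    else:
        edge_idx = np.arange(n)
    for i in edge_idx:
        lo = max(0, i - half)
        hi = min(n, i + w - half)
        seg = values[lo:hi]
        med = np.median(seg)
        medians[i] = med
        mads[i] = np.median(np.abs(seg - med))
    dispersion = MAD_SCALE * mads
    outliers = np.abs(values - medians) > params.n_sd * dispersion
    cleaned = values.copy()
    cleaned[outliers] = medians[outliers]
    if outliers.any():
        logger.debug("hampel: replaced %d/%d samples", int(outliers.sum()), n)
    return x.replace_values(cleaned), outliers


def baseline_subtract(x: TimeSeries, baseline: TimeSeries) -> TimeSeries:
    """Subtract the baseline-window mean from a phase trace.

    The baseline is the final 60 s recorded before the first task phase;
    its mean anchors every phase of the same channel.
    """
    if baseline.channel and x.channel and baseline.channel != x.channel:
        raise ValueError(
            f"channel mismatch: phase trace is {x.channel!r}, "
            f"baseline is {baseline.channel!r}")
    return x.replace_values(x.values - float(np.mean(baseline.values)))


def thermal_feature_vector(x: TimeSeries,
                           sampen: SampEnParams = SampEnParams(),
                           bands: BandSpec = BandSpec()) -> ThermalFeatures:
    """The nine thermal descriptors of a cleaned, baseline-subtracted trace.

    Undefined entries (zero-variance skewness/kurtosis, zero-HF ratio)
    propagate as NaN.
    """
    if x.n < 4:
        raise ValueError("need at least 4 samples for thermal features")
    mom = moment_features(x.values)
    sampen_val = sample_entropy(x.values, sampen)
    spec = estimate_spectrum(x.values, x.fs, bands=bands)
    bf = band_features(spec, bands)
    return ThermalFeatures(
        MeanTemp=mom.mean, STD=mom.sd, K=mom.kurtosis, S=mom.skewness,
        P90=mom.p90, SampEn=sampen_val, LF=bf.lf, HF=bf.hf, LFHF=bf.lfhf,
        roi=x.channel, phase=x.phase,
    )
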
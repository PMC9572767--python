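"""Numeric descriptors shared by the thermal and cardiac feature pipelines.

Four families of descriptors feed both modalities:

* distribution moments (mean, SD, kurtosis, skewness, 90th percentile),
* sample entropy (SampEn), the template-matching regularity index,
* an averaged-periodogram (Welch) spectral estimate, and
* band-limited power in the low-frequency (LF, 0.04-0.15 Hz) and
  high-frequency (HF, 0.15-0.4 Hz) bands plus their ratio LF/HF.

The LF and HF bands are the standard autonomic-balance bands of
heart-rate-variability analysis; here they are applied both to RR tachograms
and to facial-thermography ROI traces, whose slow vasomotor oscillations
carry the same sympathetic/parasympathetic signature.

Conventions (stated because they differ across ecosystems): standard
deviation uses the n-1 denominator; skewness and kurtosis are the biased
moment ratios m3/m2^1.5 and m4/m2^2 with kurtosis non-excess (a Gaussian
gives 3); percentiles interpolate linearly between order statistics.
Undefined quantities (skewness of a constant signal, LF/HF with zero HF
power) propagate as NaN, never as silent zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "BandSpec",
    "SampEnParams",
    "SpectrumEstimate",
    "MomentFeatures",
    "moment_features",
    "sample_entropy",
    "estimate_spectrum",
    "band_features",
]


@dataclass(frozen=True)
class BandSpec:
    """LF/HF band edges in Hz."""

    lf_low: float = 0.04
    lf_high: float = 0.15
    hf_low: float = 0.15
    hf_high: float = 0.40

    def __post_init__(self) -> None:
        if not (0 < self.lf_low < self.lf_high <= self.hf_low < self.hf_high):
            raise ValueError(
                "band edges must satisfy 0 < lf_low < lf_high <= hf_low < hf_high"
            )


@dataclass(frozen=True)
class SampEnParams:
    """Sample-entropy parameters: embedding length m and tolerance factor.

    The tolerance is ``r_factor`` times the sample standard deviation of the
    analysed signal; m=2, r=0.2*SD is the field-standard convention.
    """

    m: int = 2
    r_factor: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding length m must be >= 1")
        if not self.r_factor > 0:
            raise ValueError("tolerance factor must be positive")


@dataclass
class SpectrumEstimate:
    """One-sided power spectral density on a frequency grid.

    ``segment_length``/``overlap``/``detrended`` record how the averaged
    periodogram was formed so that downstream band integrals are auditable.
    """

    frequencies: np.ndarray
    power: np.ndarray
    fs: float
    segment_length: int = 0
    overlap: int = 0
    detrended: bool = True

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0) or self.frequencies[0] < 0:
            raise ValueError("frequencies must be nonnegative and ascending")
        if np.any(self.power < 0):
            raise ValueError("power density must be nonnegative")

    def total_power(self) -> float:
        """Integrated power over the full estimated range."""
        return float(np.trapezoid(self.power, self.frequencies))


class MomentFeatures(NamedTuple):
    mean: float
    sd: float
    kurtosis: float
    skewness: float
    p90: float


def moment_features(x) -> MomentFeatures:
    """Mean, sample SD, non-excess kurtosis, skewness and 90th percentile.

    Zero-variance input yields NaN skewness and kurtosis (moment ratios are
    undefined there); the remaining entries are still returned.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError(f"need at least 4 samples for moment features, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("moment features require finite input")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        skew = np.nan
        kurt = np.nan
    else:
        skew = float(spstats.skew(x, bias=True))
        kurt = float(spstats.kurtosis(x, fisher=False, bias=True))
    return MomentFeatures(
        mean=float(np.mean(x)),
        sd=sd,
        kurtosis=kurt,
        skewness=skew,
        p90=float(np.percentile(x, 90)),
    )


def sample_entropy(x, params: SampEnParams = SampEnParams()) -> float:
    """Sample entropy -ln(A/B) with Chebyshev distance and r = r_factor*SD.

    A counts matching template pairs of length m+1 and B of length m;
    self-matches are excluded. A constant signal returns 0 by convention.
    If no m-length templates match (B = 0) the value is undefined and NaN
    is returned.
    """
    x = np.asarray(x, dtype=float)
    m = params.m
    if x.size < m + 2:
        raise ValueError(f"need at least m+2={m + 2} samples, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample entropy requires finite input")
    if np.ptp(x) == 0.0:
        return 0.0
    r = params.r_factor * np.std(x, ddof=1)

    def _matches(length: int) -> int:
        templ = np.lib.stride_tricks.sliding_window_view(x, length)
        n = templ.shape[0]
        # count unordered template pairs within tolerance; chunk rows so the
        # distance matrix never exceeds ~20M entries
        chunk = max(1, int(2e7) // n)
        ordered = 0
        for start in range(0, n, chunk):
            d = cdist(templ[start:start + chunk], templ, metric="chebyshev")
            ordered += int((d <= r).sum())
        return (ordered - n) // 2  # remove self-matches, halve ordered pairs

    b = _matches(m)
    if b == 0:
        return float("nan")
    a = _matches(m + 1)
    if a == 0:
        return float("nan")
    return float(-np.log(a / b))


def estimate_spectrum(x, fs: float, *, bands: BandSpec = BandSpec(),
                      segment_seconds: float = 60.0) -> SpectrumEstimate:
    """Welch averaged periodogram with Hamming taper and linear detrend.

    Segments are ``min(N, segment_seconds*fs)`` samples with 50% overlap.
    Inputs shorter than the two LF periods recommended for stable LF
    estimates are accepted with a logged warning. Energy consistency holds
    by construction: the integrated density approximates the detrended
    signal variance.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise ValueError(f"need at least 8 samples for a spectrum, got {x.size}")
    if not fs > 0:
        raise ValueError("sampling rate must be positive")
    recommended = 2.0 / bands.lf_low
    if x.size / fs < recommended:
        logger.warning(
            "signal spans %.1f s, below the %.0f s recommended for stable "
            "LF estimates", x.size / fs, recommended,
        )
    nperseg = int(min(x.size, round(segment_seconds * fs)))
    nperseg = max(nperseg, 8)
    noverlap = nperseg // 2
    freqs, power = sps.welch(
        x, fs=fs, window="hamming", nperseg=nperseg, noverlap=noverlap,
        detrend="linear", scaling="density",
    )
    # a (near-)constant signal leaves only float-roundoff residue after
    # detrending; collapse it to exactly zero so downstream ratios are
    # flagged undefined instead of formed from machine noise
    scale = max(1.0, float(np.max(np.abs(x))))
    if np.sqrt(max(np.trapezoid(power, freqs), 0.0)) < 1e-10 * scale:
        power = np.zeros_like(power)
    return SpectrumEstimate(
        frequencies=freqs, power=power, fs=fs,
        segment_length=nperseg, overlap=noverlap, detrended=True,
    )


class BandFeatures(NamedTuple):
    lf: float
    hf: float
    lfhf: float


def band_features(spec: SpectrumEstimate, bands: BandSpec = BandSpec()) -> BandFeatures:
    """Mean power density in the LF and HF bands and their ratio.

    Each band value is the trapezoidal integral of the density over the band
    divided by the band width, i.e. a mean density. A zero HF band makes the
    ratio undefined (NaN).
    """
    f = spec.frequencies
    if bands.lf_low < f[0] - 1e-12 or bands.hf_high > f[-1] + 1e-12:
        raise ValueError(
            f"spectrum covers [{f[0]:g}, {f[-1]:g}] Hz, not the requested "
            f"bands [{bands.lf_low}, {bands.hf_high}] Hz"
        )
    lf = _band_mean_density(spec, bands.lf_low, bands.lf_high)
    hf = _band_mean_density(spec, bands.hf_low, bands.hf_high)
    if hf == 0.0:
        ratio = float("nan")
        logger.info("HF band power is zero; LF/HF undefined")
    else:
        ratio = lf / hf
    return BandFeatures(lf=lf, hf=hf, lfhf=ratio)


def _band_mean_density(spec: SpectrumEstimate, lo: float, hi: float) -> float:
    """Trapezoidal band integral divided by band width, on a grid refined
    with the exact band edges so narrow bands are never missed."""
    f, p = spec.frequencies, spec.power
    grid = np.union1d(f[(f >= lo) & (f <= hi)], [lo, hi])
    vals = np.interp(grid, f, p)
    return float(np.trapezoid(vals, grid) / (hi - lo))
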
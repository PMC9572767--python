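"""Core signal containers shared by the thermal and cardiac pipelines.

A :class:`TimeSeries` is a uniformly sampled trace tagged with its sampling
rate, experimental phase and channel (an ROI name such as ``"nosetip"`` or
``"ECG"``). An :class:`RRSeries` holds detected beat times and the derived
inter-beat (RR) intervals in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeSeries", "RRSeries"]


@dataclass
class TimeSeries:
    """Uniformly sampled signal with rate and phase/channel tags.

    Parameters
    ----------
    values : ndarray
        Sample values.
    fs : float
        Sampling rate in Hz. Thermal ROI traces default to 10 Hz and ECG to
        256 Hz upstream, but any positive rate is accepted.
    phase : str
        Experimental phase label (``"BL"``, ``"Forward"``, ``"ImmR"``, ...).
    channel : str
        Channel identifier (ROI name or ``"ECG"``).
    """

    values: np.ndarray
    fs: float
    phase: str = ""
    channel: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")
        if self.values.size < 1:
            raise ValueError("TimeSeries must hold at least one sample")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n) / self.fs

    def replace_values(self, values: np.ndarray) -> "TimeSeries":
        """Return a copy of this series carrying ``values`` instead."""
        return TimeSeries(np.asarray(values, dtype=float), self.fs, self.phase, self.channel)


@dataclass
class RRSeries:
    """Beat times (s) and inter-beat intervals (ms).

    Invariant: ``rr[i] == (beat_times[i+1] - beat_times[i]) * 1000`` and all
    intervals are positive.
    """

    beat_times: np.ndarray
    rr: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.beat_times.size < 2:
            raise ValueError("an RR series needs at least two beats")
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat times must be strictly increasing")
        derived = np.diff(self.beat_times) * 1000.0
        if self.rr is None:
            self.rr = derived
        else:
            self.rr = np.asarray(self.rr, dtype=float)
            if not np.allclose(self.rr, derived, atol=1e-9):
                raise ValueError("rr inconsistent with beat_times differences")

    @property
    def n_beats(self) -> int:
        return self.beat_times.size
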
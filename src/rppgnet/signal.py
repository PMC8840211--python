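"""Waveform conditioning and beat extraction for pulse signals.

Everything between a raw pulse trace and an NN-interval series lives here:
zero-phase FIR band-pass filtering, z-normalization, cubic-spline resampling
(including the 256 Hz upsampling used before peak detection), local-maxima
peak detection, and conversion of peak times to NN intervals in milliseconds.

Filtering is applied forward-backward so the net phase is zero: heart-rate
variability depends on peak *timing*, and a causal filter would shift every
beat by the group delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

__all__ = [
    "PulseTrace",
    "PeakSet",
    "NNISequence",
    "bandpass",
    "znormalize",
    "resample_uniform",
    "detect_peaks",
    "peaks_to_nni",
    "InsufficientBeatsError",
    "DegenerateTraceError",
]


class InsufficientBeatsError(ValueError):
    """Fewer than two beats: no interval can be formed."""


class DegenerateTraceError(ValueError):
    """A constant trace cannot be normalized."""


@dataclass
class PulseTrace:
    """A uniformly sampled real-valued series with its sampling rate in Hz."""

    samples: np.ndarray
    rate: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).reshape(-1)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.size < 2:
            raise ValueError("trace needs at least two samples")

    @property
    def duration(self) -> float:
        return (self.samples.size - 1) / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.rate

    # -------------------------------------------------------------- file I/O
    def to_csv(self, path) -> None:
        """Two-column text: time_s, value."""
        np.savetxt(
            path,
            np.column_stack([self.times, self.samples]),
            delimiter=",",
            header="time_s,value",
            comments="",
        )

    @classmethod
    def from_csv(cls, path) -> "PulseTrace":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        t, v = data[:, 0], data[:, 1]
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-3):
            raise ValueError("trace is not uniformly sampled")
        return cls(v, 1.0 / float(dt[0]))


@dataclass
class PeakSet:
    """Strictly increasing sample indices of detected systolic peaks."""

    indices: np.ndarray
    rate: float

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int).reshape(-1)
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return self.indices / self.rate

    def __len__(self) -> int:
        return self.indices.size


@dataclass
class NNISequence:
    """Beat-to-beat intervals in milliseconds."""

    intervals: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.intervals = np.asarray(self.intervals, dtype=float).reshape(-1)
        if np.any(self.intervals <= 0):
            raise ValueError("NN intervals must be positive")

    def __len__(self) -> int:
        return self.intervals.size

    def physiologic(self, lo_ms: float = 250.0, hi_ms: float = 2000.0) -> "NNISequence":
        """Optional band filter discarding non-physiologic intervals."""
        keep = (self.intervals >= lo_ms) & (self.intervals <= hi_ms)
        return NNISequence(self.intervals[keep])

    def to_csv(self, path) -> None:
        np.savetxt(path, self.intervals, delimiter=",", header="nni_ms", comments="")


# --------------------------------------------------------------------------
# conditioning
# --------------------------------------------------------------------------
def _fir_taps(rate: float, lo: float, hi: float, n_samples: int) -> np.ndarray:
    """Hamming-window linear-phase band-pass; order ~ 3 * rate / lo, capped so
    forward-backward filtering remains well-posed on short records."""
    order = int(round(3.0 * rate / lo / 2) * 2)  # even order -> odd tap count
    # filtfilt needs > 3*(order+1) samples; cap the order on short records
    max_order = max((n_samples // 3 - 2) // 2 * 2, 2)
    order = min(order, max_order)
    return sps.firwin(order + 1, [lo, hi], pass_zero=False, window="hamming", fs=rate)


def bandpass(trace: PulseTrace, lo: float = 0.5, hi: float = 4.0) -> PulseTrace:
    """Zero-phase FIR band-pass; output length equals input length."""
    nyq = trace.rate / 2.0
    if not (0.0 < lo < hi < nyq):
        raise ValueError(
            f"cutoffs must satisfy 0 < lo < hi < Nyquist ({nyq} Hz); got {lo}-{hi}"
        )
    taps = _fir_taps(trace.rate, lo, hi, trace.samples.size)
    padlen = min(3 * taps.size, trace.samples.size - 1)
    filtered = sps.filtfilt(taps, [1.0], trace.samples, padlen=padlen)
    return PulseTrace(filtered, trace.rate)


def znormalize(trace: PulseTrace) -> PulseTrace:
    """Zero mean, unit (population) variance."""
    sd = trace.samples.std()
    if sd == 0.0:
        raise DegenerateTraceError("constant trace cannot be z-normalized")
    return PulseTrace((trace.samples - trace.samples.mean()) / sd, trace.rate)


def resample_uniform(trace: PulseTrace, target_rate: float) -> PulseTrace:
    """Cubic-spline interpolation onto a uniform grid at ``target_rate``,
    spanning the same time range as the input."""
    if target_rate <= 0:
        raise ValueError("target rate must be positive")
    if trace.samples.size < 4:
        raise ValueError("cubic spline needs at least 4 samples")
    spline = CubicSpline(trace.times, trace.samples)
    new_t = np.arange(0.0, trace.duration + 0.5 / target_rate, 1.0 / target_rate)
    new_t = new_t[new_t <= trace.duration + 1e-12]
    return PulseTrace(spline(new_t), target_rate)


# --------------------------------------------------------------------------
# beats
# --------------------------------------------------------------------------
def detect_peaks(
    trace: PulseTrace,
    hr_band: tuple[float, float] = (0.5, 2.5),
    prominence_frac: float = 0.3,
    edge_exclude_s: float = 1.0,
) -> PeakSet:
    """Systolic peaks as local maxima with a refractory distance.

    The minimum inter-peak distance is rate / max-heart-frequency; peaks must
    stand out by at least ``prominence_frac`` of the trace's standard
    deviation.  The first and last second are excluded to avoid filter
    transients.
    """
    x = trace.samples
    sd = x.std()
    if sd == 0.0:
        return PeakSet(np.empty(0, dtype=int), trace.rate)
    distance = max(int(trace.rate / hr_band[1]), 1)
    idx, _ = sps.find_peaks(x, distance=distance, prominence=prominence_frac * sd)
    edge = int(edge_exclude_s * trace.rate)
    if edge > 0 and x.size > 2 * edge:
        idx = idx[(idx >= edge) & (idx < x.size - edge)]
    return PeakSet(idx, trace.rate)


def peaks_to_nni(peaks: PeakSet) -> NNISequence:
    """Intervals between consecutive peaks, in milliseconds."""
    if len(peaks) < 2:
        raise InsufficientBeatsError(f"need >= 2 peaks, got {len(peaks)}")
    return NNISequence(np.diff(peaks.indices) / peaks.rate * 1000.0)
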
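"""Heart-rate-variability metrics and agreement statistics.

Time domain (over an NN-interval series in ms):

    AVNN  = mean(NN)
    SDNN  = sqrt( sum (NN_i - AVNN)^2 / (T - 1) )
    RMSSD = sqrt( sum (NN_i - NN_{i+1})^2 / (T - 1) )   over the T-1 diffs

Frequency domain: the NNI series is treated as a tachogram sampled at the
beat times, spline-resampled to a uniform 4 Hz grid, mean-removed, and its
power spectral density estimated by Welch's method (Hann taper, 50% overlap,
64 s segments or the full record if shorter).  LF is the 0.04-0.15 Hz band
power, HF 0.15-0.4 Hz, both reported in normalized units LF/(LF+HF) and
HF/(LF+HF), plus the LF/HF ratio.

Agreement between predicted and reference metric sets: MAE, RMSE, Pearson R
and Bland-Altman bias with 95% limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .loss import pearson_r
from .signal import InsufficientBeatsError, NNISequence

__all__ = [
    "HRVTimeDomain",
    "HRVFreqDomain",
    "AgreementStats",
    "time_domain",
    "frequency_domain",
    "agreement",
    "RecordTooShortError",
]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)
TACHOGRAM_RATE = 4.0  # Hz


class RecordTooShortError(ValueError):
    """Record too short for meaningful LF-band resolution."""


@dataclass(frozen=True)
class HRVTimeDomain:
    avnn: float   # ms
    sdnn: float   # ms
    rmssd: float  # ms

    def as_dict(self) -> dict[str, float]:
        return {"AVNN": self.avnn, "SDNN": self.sdnn, "RMSSD": self.rmssd}


@dataclass(frozen=True)
class HRVFreqDomain:
    lf_nu: float    # normalized LF power in [0, 1]
    hf_nu: float    # normalized HF power in [0, 1]
    lf_hf: float    # LF/HF ratio

    def as_dict(self) -> dict[str, float]:
        return {"LFnu": self.lf_nu, "HFnu": self.hf_nu, "LF_HF": self.lf_hf}


@dataclass(frozen=True)
class AgreementStats:
    mae: float
    rmse: float
    r: float
    bias: float       # Bland-Altman mean difference
    loa_low: float    # bias - 1.96 sd(diff)
    loa_high: float   # bias + 1.96 sd(diff)

    def as_dict(self) -> dict[str, float]:
        return {
            "MAE": self.mae, "RMSE": self.rmse, "R": self.r,
            "bias": self.bias, "LoA_low": self.loa_low, "LoA_high": self.loa_high,
        }


def time_domain(nni: NNISequence) -> HRVTimeDomain:
    """AVNN / SDNN / RMSSD from an NN-interval series."""
    x = nni.intervals
    T = x.size
    if T < 2:
        raise InsufficientBeatsError(f"need >= 2 intervals, got {T}")
    avnn = float(x.mean())
    sdnn = float(np.sqrt(((x - avnn) ** 2).sum() / (T - 1)))
    rmssd = float(np.sqrt((np.diff(x) ** 2).sum() / (T - 1)))
    return HRVTimeDomain(avnn, sdnn, rmssd)


def frequency_domain(
    nni: NNISequence, min_duration_s: float = 30.0
) -> HRVFreqDomain:
    """Normalized LF/HF band powers from the beat-time tachogram."""
    x = nni.intervals
    if x.size < 4:
        raise InsufficientBeatsError(f"need >= 4 intervals, got {x.size}")
    # tachogram: interval value anchored at the time of its closing beat
    beat_times = np.cumsum(x) / 1000.0
    duration = beat_times[-1] - beat_times[0]
    if duration < min_duration_s:
        raise RecordTooShortError(
            f"record spans {duration:.1f} s < {min_duration_s} s"
        )
    spline = CubicSpline(beat_times, x)
    t = np.arange(beat_times[0], beat_times[-1], 1.0 / TACHOGRAM_RATE)
    tach = spline(t)
    tach = tach - tach.mean()
    nperseg = min(int(64 * TACHOGRAM_RATE), tach.size)
    freqs, psd = sps.welch(
        tach, fs=TACHOGRAM_RATE, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, detrend="constant",
    )
    lf = float(np.trapezoid(psd[(freqs >= LF_BAND[0]) & (freqs < LF_BAND[1])],
                            freqs[(freqs >= LF_BAND[0]) & (freqs < LF_BAND[1])]))
    hf = float(np.trapezoid(psd[(freqs >= HF_BAND[0]) & (freqs < HF_BAND[1])],
                            freqs[(freqs >= HF_BAND[0]) & (freqs < HF_BAND[1])]))
    total = lf + hf
    if total <= 0.0:
        raise ValueError("degenerate spectrum: no power in the LF+HF bands")
    return HRVFreqDomain(lf / total, hf / total, lf / hf if hf > 0 else np.inf)


def agreement(pred, ref) -> AgreementStats:
    """Paired agreement statistics between two metric lists."""
    pred = np.asarray(pred, dtype=float).reshape(-1)
    ref = np.asarray(ref, dtype=float).reshape(-1)
    if pred.shape != ref.shape:
        raise ValueError(f"length mismatch: {pred.size} vs {ref.size}")
    if pred.size < 2:
        raise ValueError("need at least two paired values")
    diff = pred - ref
    mae = float(np.abs(diff).mean())
    rmse = float(np.sqrt((diff**2).mean()))
    try:
        r = pearson_r(pred, ref)
    except ValueError:
        r = np.nan
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return AgreementStats(mae, rmse, r, bias, bias - 1.96 * sd, bias + 1.96 * sd)
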
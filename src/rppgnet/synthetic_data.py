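"""Seeded generator of (facial video, reference PPG, true NNI) triples.

The generator emulates the statistical structure the rPPG problem assumes: a
skin region whose color is modulated by a quasi-periodic blood-volume-pulse
waveform.  The instantaneous heart frequency is frequency-modulated at a low
(sympathetic-band, ~0.1 Hz) and a high (respiratory-band, ~0.25 Hz) rate,

    f(t) = f0 * (1 + a_LF sin(2 pi f_LF t) + a_HF sin(2 pi f_HF t)),

so the beat-to-beat intervals carry a known LF/HF split: the tachogram
oscillates at f_LF and f_HF with amplitudes proportional to a_LF and a_HF,
giving an expected normalized LF power of a_LF^2 / (a_LF^2 + a_HF^2).

The waveform is a fixed two-harmonic pulse template evaluated at the phase
Phi(t) = 2 pi * integral of f (available in closed form), with a dicrotic-
notch-like secondary bump.  True beat times are the (root-refined, not
grid-snapped) crossings Phi = pi (mod 2 pi), the phase at which the template
attains its maximum — so the analytic ground truth coincides exactly with
what a peak detector sees on the clean waveform.

Rendered video adds the nuisances real recordings have: illumination drift,
per-pixel Gaussian noise, and frame-to-frame face-box jitter.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
from scipy.optimize import brentq

from .hrv import HRVFreqDomain, HRVTimeDomain, frequency_domain, time_domain
from .signal import NNISequence, PulseTrace

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_bvp",
    "render_video",
    "make_dataset",
    "write_frame_folder",
]

log = logging.getLogger(__name__)

# green-dominant pulsatility of skin reflectance
CHANNEL_WEIGHTS = np.array([0.4, 1.0, 0.6])
SKIN_RGB = np.array([190.0, 140.0, 120.0])
BACKGROUND_RGB = np.array([60.0, 60.0, 60.0])


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters; defaults describe a still, well-lit recording."""

    duration_s: float = 30.0
    fps: float = 30.0
    frame_size: int = 128
    mean_hr_bpm: float = 72.0
    lf_depth: float = 0.05          # fractional FM depth at lf_freq
    lf_freq: float = 0.1            # Hz
    hf_depth: float = 0.05
    hf_freq: float = 0.25           # Hz
    pulse_amplitude: float = 2.0    # color units (0-255 scale)
    pixel_noise_sd: float = 2.0
    drift_amplitude: float = 5.0    # color units
    drift_freq: float = 0.05        # Hz
    box_jitter_sd: float = 0.5      # pixels
    seed: int = 0

    def __post_init__(self):
        if not 30.0 <= self.mean_hr_bpm <= 150.0:
            raise ValueError("mean HR must be within 30-150 bpm")
        if self.lf_depth < 0 or self.hf_depth < 0:
            raise ValueError("modulation depths must be non-negative")
        if self.lf_depth + self.hf_depth >= 1.0:
            raise ValueError("modulation depths too large: f(t) would cross zero")
        if self.fps <= 2.0 * self.mean_hr_bpm / 60.0 * (1 + self.lf_depth + self.hf_depth):
            raise ValueError("fps must exceed twice the maximum heart frequency")


@dataclass
class GroundTruth:
    """Clean pulse trace plus the analytic beat-level ground truth."""

    trace: PulseTrace
    beat_times: np.ndarray
    nni: NNISequence
    time_metrics: HRVTimeDomain | None
    freq_metrics: HRVFreqDomain | None
    config: SynthConfig


def _phase_fn(cfg: SynthConfig):
    """Closed-form cumulative phase Phi(t) = 2 pi * int_0^t f(s) ds."""
    f0 = cfg.mean_hr_bpm / 60.0

    def phi(t):
        t = np.asarray(t, dtype=float)
        out = f0 * t
        if cfg.lf_depth > 0:
            out = out + f0 * cfg.lf_depth / (2 * np.pi * cfg.lf_freq) * (
                1.0 - np.cos(2 * np.pi * cfg.lf_freq * t)
            )
        if cfg.hf_depth > 0:
            out = out + f0 * cfg.hf_depth / (2 * np.pi * cfg.hf_freq) * (
                1.0 - np.cos(2 * np.pi * cfg.hf_freq * t)
            )
        return 2 * np.pi * out

    return phi


def pulse_template(phase: np.ndarray) -> np.ndarray:
    """Two-harmonic pulse shape with maximum 1.3 at phase pi (mod 2 pi)."""
    return -np.cos(phase) + 0.3 * np.cos(2 * phase)


def generate_bvp(cfg: SynthConfig) -> GroundTruth:
    """Sample the waveform at cfg.fps and solve for the true beat times."""
    phi = _phase_fn(cfg)
    n = int(round(cfg.duration_s * cfg.fps))
    t = np.arange(n) / cfg.fps
    waveform = pulse_template(phi(t))
    trace = PulseTrace(waveform, cfg.fps)

    # beat times: Phi(t) = pi + 2 pi k, root-refined (Phi strictly increasing)
    total_phase = float(phi(cfg.duration_s))
    ks = np.arange(int(np.ceil((0 - np.pi) / (2 * np.pi))),
                   int(np.floor((total_phase - np.pi) / (2 * np.pi))) + 1)
    ks = ks[ks >= 0]
    beat_times = np.array([
        brentq(lambda u, target=np.pi + 2 * np.pi * k: phi(u) - target,
               0.0, cfg.duration_s, xtol=1e-9)
        for k in ks
    ])
    nni = NNISequence(np.diff(beat_times) * 1000.0)

    tm = time_domain(nni) if len(nni) >= 2 else None
    try:
        fm = frequency_domain(nni)
    except ValueError:
        fm = None
    return GroundTruth(trace, beat_times, nni, tm, fm, cfg)


def render_video(
    gt: GroundTruth, cfg: SynthConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Render a (3, T, H, W) video of a pulsing elliptical face region.

    Returns the clip (float32, values in [0, 255]) and the per-frame true
    face box as a (T, 4) array of (row0, col0, row1, col1).
    """
    cfg = cfg or gt.config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xFACE]))
    T = gt.trace.samples.size
    H = W = cfg.frame_size
    t = np.arange(T) / cfg.fps

    jitter = rng.normal(0.0, cfg.box_jitter_sd, size=(T, 2)) if cfg.box_jitter_sd > 0 \
        else np.zeros((T, 2))
    drift = cfg.drift_amplitude * np.sin(2 * np.pi * cfg.drift_freq * t)

    ry, rx = 0.35 * H, 0.28 * W
    cy0, cx0 = H / 2.0, W / 2.0
    rows = np.arange(H)[:, None]
    cols = np.arange(W)[None, :]

    video = np.empty((3, T, H, W), dtype=np.float32)
    boxes = np.empty((T, 4))
    clipped = 0
    skin_total = 0
    for i in range(T):
        cy, cx = cy0 + jitter[i, 0], cx0 + jitter[i, 1]
        mask = ((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2 <= 1.0
        frame = np.empty((3, H, W), dtype=np.float32)
        pulse = cfg.pulse_amplitude * gt.trace.samples[i]
        for c in range(3):
            base = np.where(mask, SKIN_RGB[c] + CHANNEL_WEIGHTS[c] * pulse,
                            BACKGROUND_RGB[c])
            frame[c] = base + drift[i]
        if cfg.pixel_noise_sd > 0:
            frame += rng.normal(0.0, cfg.pixel_noise_sd, size=frame.shape)
        out = np.clip(frame, 0.0, 255.0)
        clipped += int(((frame != out) & mask[None]).sum())
        skin_total += int(mask.sum()) * 3
        video[:, i] = out
        boxes[i] = (cy - ry, cx - rx, cy + ry, cx + rx)
    if skin_total and clipped / skin_total > 0.01:
        log.warning(
            "pulse amplitude clipped %.1f%% of skin pixels; consider lowering it",
            100.0 * clipped / skin_total,
        )
    return video, boxes


def make_dataset(
    n_clips: int,
    seed: int = 0,
    hr_range: tuple[float, float] = (55.0, 95.0),
    lf_depth_range: tuple[float, float] = (0.02, 0.08),
    hf_depth_range: tuple[float, float] = (0.02, 0.08),
    **overrides,
) -> tuple[list[tuple[np.ndarray, PulseTrace]], dict]:
    """Draw n independent clips; the manifest allows exact regeneration."""
    if n_clips < 1:
        raise ValueError("need at least one clip")
    rng = np.random.default_rng(seed)
    pairs = []
    manifest = {"seed": int(seed), "n_clips": int(n_clips), "clips": []}
    for i in range(n_clips):
        cfg = SynthConfig(
            mean_hr_bpm=float(rng.uniform(*hr_range)),
            lf_depth=float(rng.uniform(*lf_depth_range)),
            hf_depth=float(rng.uniform(*hf_depth_range)),
            seed=int(rng.integers(0, 2**31 - 1)),
            **overrides,
        )
        gt = generate_bvp(cfg)
        video, boxes = render_video(gt, cfg)
        pairs.append((video, gt.trace))
        entry = asdict(cfg)
        entry["true_boxes_first"] = boxes[0].tolist()
        manifest["clips"].append(entry)
    return pairs, manifest


def write_frame_folder(video: np.ndarray, path) -> None:
    """Write a (3, T, H, W) clip as numbered PNG frames (UBFC-style layout)."""
    import imageio.v3 as iio
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    frames = np.moveaxis(video, 0, -1)  # (T, H, W, 3)
    for i, frame in enumerate(frames):
        iio.imwrite(path / f"{i:05d}.png", frame.astype(np.uint8))


def save_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
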
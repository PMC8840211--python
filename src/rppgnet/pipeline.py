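"""End-to-end orchestration: ROI cropping, clip slicing, training, inference
stitching and HRV evaluation.

The face detector is a pluggable interface (any callable mapping a frame to a
bounding box); detection runs only every ``refresh`` frames and the box is
reused in between, mirroring how rPPG pipelines amortize detector cost.  A
full-frame detector and a known-box detector are built in for synthetic data;
an MTCNN-style detector can be plugged in without changing the pipeline.

Training minimizes the negative-Pearson loss with Adam under the standard
protocol (batches of 128-frame clips sliced at stride 8, learning rate 1e-3
decayed x0.1 every 10 epochs).  Inference stitches per-window predictions —
z-normalized per window, since the correlation loss leaves scale per window
arbitrary — into a whole-video trace, averaging the overlap of the
right-aligned tail window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .autograd import Tensor
from .backbone import RPPGNet
from .loss import neg_pearson_loss
from .nn import Adam
from .signal import (
    PulseTrace,
    bandpass,
    detect_peaks,
    peaks_to_nni,
    resample_uniform,
    znormalize,
)
from .hrv import agreement, frequency_domain, time_domain

__all__ = [
    "RoiPolicy",
    "TrainConfig",
    "full_frame_detector",
    "make_box_detector",
    "crop_faces",
    "slice_clips",
    "normalize_clip",
    "Trainer",
    "train",
    "trace_to_hrv_metrics",
    "infer",
    "evaluate",
    "NoFaceError",
    "TooShortError",
]

log = logging.getLogger(__name__)

Box = tuple[float, float, float, float]  # (row0, col0, row1, col1)
Detector = Callable[[np.ndarray], Box | None]


class NoFaceError(RuntimeError):
    """The detector found no face on the first frame."""


class TooShortError(ValueError):
    """The video is shorter than one network window."""


@dataclass
class RoiPolicy:
    """Detector handle plus the refresh cadence in frames."""

    detector: Detector
    refresh: int = 10

    def __post_init__(self):
        if self.refresh < 1:
            raise ValueError("refresh period must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol parameters."""

    epochs: int = 30
    lr: float = 0.001
    lr_decay: float = 0.1
    lr_step_epochs: int = 10
    batch_size: int = 8
    clip_len: int = 128
    clip_stride: int = 8
    frame_size: int = 128
    seed: int = 0

    def __post_init__(self):
        if self.clip_len % 4:
            raise ValueError("clip length must be divisible by 4")
        if min(self.lr, self.batch_size, self.clip_len, self.clip_stride) <= 0:
            raise ValueError("rates and sizes must be positive")


def full_frame_detector(frame: np.ndarray) -> Box:
    """Trivial detector: the whole frame is the face."""
    _, H, W = frame.shape
    return (0.0, 0.0, float(H), float(W))


def make_box_detector(boxes: np.ndarray) -> Detector:
    """Detector that replays known per-frame boxes (synthetic ground truth)."""
    boxes = np.asarray(boxes, dtype=float)
    counter = {"i": 0}

    def detector(frame: np.ndarray) -> Box:
        i = min(counter["i"], len(boxes) - 1)
        counter["i"] += 1
        return tuple(boxes[i])

    return detector


def _crop_resize(frame: np.ndarray, box: Box, size: int) -> np.ndarray:
    """Crop a (3, H, W) frame to ``box`` and bilinearly resize to size x size."""
    _, H, W = frame.shape
    r0 = int(np.clip(np.floor(box[0]), 0, H - 1))
    c0 = int(np.clip(np.floor(box[1]), 0, W - 1))
    r1 = int(np.clip(np.ceil(box[2]), r0 + 1, H))
    c1 = int(np.clip(np.ceil(box[3]), c0 + 1, W))
    crop = frame[:, r0:r1, c0:c1]
    zoom = (1.0, size / crop.shape[1], size / crop.shape[2])
    if crop.shape[1] == size and crop.shape[2] == size:
        return crop.astype(np.float32)
    return ndimage.zoom(crop, zoom, order=1).astype(np.float32)


def crop_faces(
    frames: np.ndarray, policy: RoiPolicy, frame_size: int = 128
) -> np.ndarray:
    """Detect on frames 0, R, 2R, ...; reuse each box for the next R-1 frames.

    A detector failure on a refresh frame falls back to the last box (logged);
    failure on frame 0 is fatal.
    """
    T = frames.shape[1]
    out = np.empty((3, T, frame_size, frame_size), dtype=np.float32)
    box: Box | None = None
    for i in range(T):
        if i % policy.refresh == 0:
            new_box = policy.detector(frames[:, i])
            if new_box is None:
                if box is None:
                    raise NoFaceError("detector found no face on frame 0")
                log.warning("detector failed on frame %d; reusing last box", i)
            else:
                box = new_box
        out[:, i] = _crop_resize(frames[:, i], box, frame_size)
    return out


def slice_clips(
    video: np.ndarray, ppg: PulseTrace, cfg: TrainConfig
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Aligned (clip, target) windows [k*stride, k*stride + clip_len).

    The video and the reference trace must be sampled at the same rate with
    one-to-one frame correspondence.  Each window's target is band-pass
    filtered (0.5-4 Hz) and z-normalized.
    """
    T = video.shape[1]
    if ppg.samples.size != T:
        raise ValueError(
            f"video frames ({T}) and target samples ({ppg.samples.size}) differ"
        )
    if T < cfg.clip_len:
        raise TooShortError(f"video has {T} < {cfg.clip_len} frames")
    pairs = []
    for start in range(0, T - cfg.clip_len + 1, cfg.clip_stride):
        clip = video[:, start : start + cfg.clip_len]
        seg = PulseTrace(ppg.samples[start : start + cfg.clip_len], ppg.rate)
        target = znormalize(bandpass(seg, 0.5, 4.0)).samples
        pairs.append((clip, target.astype(np.float32)))
    return pairs


def normalize_clip(clip: np.ndarray) -> np.ndarray:
    """Standardize a (3, T, H, W) clip to zero mean / unit variance."""
    clip = np.asarray(clip, dtype=np.float32)
    sd = clip.std()
    return (clip - clip.mean()) / (sd if sd > 0 else 1.0)


class Trainer:
    """Step-wise optimizer wrapper around a model and a clip set."""

    def __init__(self, model: RPPGNet, cfg: TrainConfig | None = None):
        self.model = model
        self.cfg = cfg or TrainConfig()
        self.opt = Adam(model.parameters(), lr=self.cfg.lr)
        self.loss_log: list[float] = []

    def step(self, clips: Sequence[np.ndarray], targets: Sequence[np.ndarray]) -> float:
        """One optimization step on a batch of clips; returns the batch loss."""
        self.model.train()
        batch = np.stack([normalize_clip(c) for c in clips])
        tgt = np.stack(targets)
        self.opt.zero_grad()
        pred = self.model(Tensor(batch.astype(np.float32)))
        loss = neg_pearson_loss(pred, tgt)
        loss_val = loss.item()
        if not np.isfinite(loss_val):
            raise FloatingPointError(f"non-finite training loss: {loss_val}")
        loss.backward()
        self.opt.step()
        self.loss_log.append(loss_val)
        return loss_val


def train(
    clip_pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    cfg: TrainConfig | None = None,
    model: RPPGNet | None = None,
) -> tuple[RPPGNet, list[float]]:
    """Epoch-based training over pre-sliced (clip, target) pairs.

    The learning rate is multiplied by ``lr_decay`` every ``lr_step_epochs``
    epochs.  Returns the trained model and the per-epoch mean loss log.
    """
    cfg = cfg or TrainConfig()
    if not clip_pairs:
        raise ValueError("need at least one training pair")
    model = model or RPPGNet(seed=cfg.seed)
    trainer = Trainer(model, cfg)
    rng = np.random.default_rng(cfg.seed)
    epoch_losses: list[float] = []
    for epoch in range(cfg.epochs):
        trainer.opt.lr = cfg.lr * cfg.lr_decay ** (epoch // cfg.lr_step_epochs)
        order = rng.permutation(len(clip_pairs))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            losses.append(
                trainer.step(
                    [clip_pairs[j][0] for j in idx],
                    [clip_pairs[j][1] for j in idx],
                )
            )
        epoch_losses.append(float(np.mean(losses)))
        log.info("epoch %d: mean loss %.4f (lr %.2e)", epoch, epoch_losses[-1],
                 trainer.opt.lr)
    return model, epoch_losses


def infer(video: np.ndarray, model: RPPGNet, window: int = 128,
          rate: float = 30.0) -> PulseTrace:
    """Whole-video rPPG trace from consecutive windows.

    Windows tile the video without overlap; if the length is not a multiple of
    the window, a final right-aligned window covers the tail and the overlap
    region is averaged.  Each window's output is z-normalized before stitching
    (the correlation training objective leaves per-window scale arbitrary).
    """
    T = video.shape[1]
    if T < window:
        raise TooShortError(f"video has {T} < {window} frames")
    starts = list(range(0, T - window + 1, window))
    if starts[-1] + window < T:
        starts.append(T - window)
    acc = np.zeros(T)
    cnt = np.zeros(T)
    for s in starts:
        clip = normalize_clip(video[:, s : s + window])
        out = model.infer(clip)[0]
        sd = out.std()
        out = (out - out.mean()) / (sd if sd > 0 else 1.0)
        acc[s : s + window] += out
        cnt[s : s + window] += 1
    return PulseTrace(acc / cnt, rate)


def trace_to_hrv_metrics(trace: PulseTrace) -> dict[str, float]:
    """Shared post-processing: 0.5-3.5 Hz band-pass, z-norm, 256 Hz spline,
    peak detection, NNI extraction, then time- and frequency-domain metrics."""
    conditioned = resample_uniform(znormalize(bandpass(trace, 0.5, 3.5)), 256.0)
    peaks = detect_peaks(conditioned)
    nni = peaks_to_nni(peaks)
    metrics = time_domain(nni).as_dict()
    try:
        metrics.update(frequency_domain(nni).as_dict())
    except ValueError as exc:
        log.warning("frequency-domain metrics unavailable: %s", exc)
    return metrics


def evaluate(
    recordings: Sequence[tuple[np.ndarray, PulseTrace]],
    model: RPPGNet,
    window: int = 128,
) -> dict:
    """Per-recording HRV metrics for prediction and reference, plus paired
    agreement statistics per metric across recordings."""
    rows = []
    excluded = 0
    for i, (video, ref) in enumerate(recordings):
        try:
            pred_trace = infer(video, model, window=window, rate=ref.rate)
            pred = trace_to_hrv_metrics(pred_trace)
            truth = trace_to_hrv_metrics(ref)
        except ValueError as exc:
            log.warning("recording %d excluded: %s", i, exc)
            excluded += 1
            continue
        rows.append({"recording": i, "pred": pred, "ref": truth})
    report: dict = {"per_recording": rows, "excluded": excluded, "agreement": {}}
    if len(rows) >= 2:
        metric_names = sorted(set(rows[0]["pred"]) & set(rows[0]["ref"]))
        for name in metric_names:
            if not all(name in r["pred"] and name in r["ref"] for r in rows):
                continue
            stats = agreement(
                [r["pred"][name] for r in rows],
                [r["ref"][name] for r in rows],
            )
            report["agreement"][name] = stats.as_dict()
    return report
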
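# rppgnet

Remote photoplethysmography (rPPG) recovers the blood-volume-pulse waveform
from ordinary video of a person's face: each heartbeat changes the blood
volume in skin microvasculature, which modulates how much light the skin
absorbs, and a camera can pick up that subtle color change. Heart-rate
**variability** (HRV) analysis raises the bar well beyond average heart-rate
estimation — it needs the *timing of every individual beat*, so the recovered
waveform must preserve peak positions to a few milliseconds.

This package is for researchers and engineers working on camera-based
physiological measurement. It provides:

- **An efficient 3-D spatiotemporal attention network** that maps a facial
  video volume (3 × T × 128 × 128) to an rPPG trace with one sample per
  frame. The encoder is built from inverted-residual blocks using 3-D
  depth-wise separable convolutions (mobilenet-v3 style, ReLU6 early,
  h-swish `x·ReLU6(x+3)/6` in the deeper blocks), each carrying a 3-D
  **shuffle-attention** block (grouped channel + spatial gating with a
  channel shuffle); the temporal decoder restores the compressed temporal
  axis with depth-wise transposed convolutions; a three-layer fused
  **ConvGRU** head accumulates long-range temporal context before spatial
  pooling and a 1×1×1 output convolution. Everything runs on a small
  numpy-based autodiff engine — no deep-learning framework required.
- **Negative-Pearson training loss** `L = 1 − r(x, y)`, which cares about
  waveform trend and peak timing rather than absolute scale.
- **The complete HRV pipeline**: zero-phase FIR band-pass filtering,
  cubic-spline resampling to 256 Hz, peak detection, NN-interval extraction,
  time-domain metrics

  `AVNN = mean(NN)`, `SDNN = √(Σ(NNᵢ−AVNN)²/(T−1))`,
  `RMSSD = √(Σ(NNᵢ−NNᵢ₊₁)²/(T−1))`,

  and frequency-domain metrics from the 4 Hz-resampled tachogram via Welch's
  method: LFnu and HFnu (0.04–0.15 Hz and 0.15–0.4 Hz band powers in
  normalized units) and their ratio LF/HF; plus MAE/RMSE/Pearson-R and
  Bland–Altman agreement statistics.
- **A closed-form complexity profiler** implementing the multiplication
  counts of standard vs depth-wise separable 3-D convolution
  (`Dk³Dg²MNT` vs `Dk³Dg²MT + Dg²MNT`, ratio `1/N + 1/Dk³`) and walking the
  network layer by layer to total MACs and trainable parameters.
- **A seeded synthetic-data generator** producing (facial video, reference
  PPG, true beat times) triples with frequency-modulated beat intervals
  (controllable LF/HF content), illumination drift, pixel noise and face-box
  jitter — so the whole pipeline is testable end-to-end without downloading
  any dataset.

## Worked example

Generate two minutes of synthetic pulse with equal low- and high-frequency
modulation, run the analysis pipeline, and compare against the generator's
analytic ground truth:

```python
from rppgnet import SynthConfig, generate_bvp
from rppgnet.signal import resample_uniform, detect_peaks, peaks_to_nni
from rppgnet.hrv import time_domain, frequency_domain

cfg = SynthConfig(duration_s=120.0, mean_hr_bpm=72.0,
                  lf_depth=0.05, hf_depth=0.05, seed=1)
gt = generate_bvp(cfg)
peaks = detect_peaks(resample_uniform(gt.trace, 256.0))
nni = peaks_to_nni(peaks)
td, fd = time_domain(nni), frequency_domain(nni)
```

This prints (via the obvious format calls):

```
beats detected : 142
AVNN  :   833.25 ms   (truth   833.33 ms)
SDNN  :    40.28 ms   (truth    40.35 ms)
RMSSD :    37.36 ms   (truth    36.51 ms)
LFnu  :    0.524      (truth    0.533)
HFnu  :    0.476      (truth    0.467)
LF/HF :    1.102      (truth    1.141)
```

Every detected beat lands within one 256 Hz sample (±3.9 ms) of the true
beat time; the mean interval (AVNN ≈ 60000/72 ms), its spread, and the
LF/HF power split (equal modulation depths → LFnu ≈ 0.5) are all recovered.

The CLI exposes the same machinery:

```bash
rppgnet synth --n-clips 2 --seed 0 --out data/       # synthetic dataset
rppgnet train --data data/ --config small.yaml --out ckpt.npz
rppgnet infer --video data/clip000.npy --checkpoint ckpt.npz --out trace.csv
rppgnet hrv --trace trace.csv                        # metrics from a trace
rppgnet eval --data data/ --checkpoint ckpt.npz --out report.json
rppgnet profile                                      # complexity accounting
```

(`small.yaml` holds `TrainConfig` overrides such as `epochs: 2` — the
defaults implement the full 30-epoch protocol, which is a long run on CPU.)

`rppgnet profile` prints:

```
input 3x128x128x128: 4.374 GMACs, 1.720 M parameters
```

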
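# scopemotion

Colonoscope-movement analysis from procedure video: Horn–Schunck optical
flow rendered as color images, a small convolutional network that classifies
each moment as **insertion**, **withdrawal** or **stop**, a turning-point
statistic that estimates the **cecum time-location**, and a color-coded
timeline summary report.

## The problem

Cecal intubation time — the time from scope insertion until the cecum is
reached — is a standard colonoscopy quality indicator, and the cecum is the
turning point separating the insertion phase from the withdrawal phase in
which most mucosal inspection happens.  Annotating it by hand, or skimming a
20–40 minute video to find it, is tedious.  This package reconstructs that
information from the video alone, for endoscopy researchers and for anyone
building automated procedure reports.

## Method

1. **Ingest** — frames are sampled every 0.5 s (close enough that motion
   stays "small" for differential optical flow) and cropped to the
   endoscopic region (850×750 px of a 1920×1080 source in the reference
   setup).
2. **Informative-frame filter** — seven per-frame statistics (mean,
   variance, skewness, co-occurrence correlation and contrast, energy of
   Laplacian, energy of gradient) feed an RBF support-vector classifier that
   discards blurred, over-dark, over-bright or streaked frames.
3. **Optical flow** — between consecutive frames the Horn–Schunck energy

   ```
   E(u, v) = Σ (Ex·u + Ey·v + Et)² + α² (‖∇u‖² + ‖∇v‖²)
   ```

   is minimised by the classical fixed-point iteration; the flow field is
   encoded as a color image (hue = direction, saturation = magnitude).
4. **Direction CNN** — a three-block network (3×3 conv → ReLU → 2×2 max
   pool, 16/32/64 filters) with one 128-unit hidden layer, dropout 0.5 and a
   softmax over the three movement classes, trained by SGD-momentum at batch
   size 128 with randomized hyperparameter search (learning rate in
   [1e−7, 1e−2], momentum in [0.8, 0.99], L2 in [1e−10, 1e−2]) and 5-fold
   cross-validation.  Implemented directly on NumPy arrays; no GPU needed.
5. **Cecum locator** — the class sequence becomes a signal x(t) ∈ {+1, −1, 0}.
   Every insertion→withdrawal transition is a cecum candidate; each is
   scored over a ±t/2 window by the signed area after the candidate minus
   the signed area before it, which is −t for an ideal phase change and near
   zero for brief back-and-forth oscillations.  The minimum-score candidate
   is the cecum estimate; t ∈ {10, 20, 30} s in practice, safely longer than
   ordinary repetitive movements (≲ 10 s).
6. **Timeline report (SRCV)** — the signal is drawn as rows of colored
   squares at 1 s / 10 s / 30 s per square (majority class per bin), with
   the cecum marked; coarser scales suppress outliers and make the phase
   boundary obvious.

## Worked example

```python
from scopemotion import (SignalScenarioParams, generate_direction_signal,
                         locate_cecum, cecum_hit, build_report, render_report)

params = SignalScenarioParams(
    insertion_duration=600.0, withdrawal_duration=400.0,
    oscillation_spec=((120.0, 4.0), (760.0, 3.0)),   # brief back-and-forth
    stop_prob=0.10, label_noise_prob=0.05, seed=8,
)
signal, true_time = generate_direction_signal(params)
estimate = locate_cecum(signal, t=30.0)
print(f"true cecum time : {true_time:.1f} s")
print(f"estimated time  : {estimate.time:.1f} s")
print(f"window score    : {estimate.score:.1f} value*s over {estimate.n_candidates} candidates")
print(f"hit within t/2  : {cecum_hit(estimate.time, true_time, 30.0)}")
report = build_report(signal, estimate, scales=(1, 10, 30))
render_report(report, "srcv.png")
```

prints

```
true cecum time : 600.0 s
estimated time  : 600.0 s
window score    : -23.5 value*s over 86 candidates
hit within t/2  : True
```

A 1000 s procedure with two short oscillations, 10% stop frames and 5% label
noise produces 86 insertion→withdrawal transitions, yet the windowed-area
score singles out the true phase change exactly: its window is almost purely
insertion before and withdrawal after (score −23.5 of the ideal −30; noise
accounts for the gap), while every spurious transition scores near zero.
`srcv.png` shows the three timeline rows with the cecum tick at 600 s.

The same steps are available from the shell:

```bash
scopemotion simulate signal --seed 3 --out sig/
scopemotion locate --signal sig/signal.csv --t 30 --out cecum.json
scopemotion report --signal sig/signal.csv --cecum cecum.json --out srcv.png
```

plus `extract`, `flow`, `filter`, `train`, `classify` and `metrics` for the
image-side pipeline.

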
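"""Synthetic study inputs with known ground truth.

Three families of generators drive the test suite and the reproduction runs:

* **Frame pairs under known camera motion.**  A band-limited random texture
  (Gaussian-smoothed white noise) is warped by an analytic motion field —
  uniform translation for calibration, or a radial field about the image
  centre emulating the zoom-like appearance of advancing (expansion) or
  pulling back (contraction) an endoscope — and the analytic field is
  returned as the flow oracle.

* **Degraded frames** for the informative-frame filter: clean sharp texture
  versus motion blur, excessive darkness, excessive brightness, and motion
  streaks, the degradations that make a colonoscopy frame non-observable.

* **Direction-label signals** with a single true insertion→withdrawal phase
  change (the cecum), short insertion-withdrawal oscillations, stop
  interludes, and label noise.  Real procedures show brief back-and-forth
  movements that rarely exceed 10 s; the generator reproduces that regime and
  reports the exact cecum time.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .flow import FlowColorImage, FlowField, flow_to_color
from .ingest import FrameImage
from .locator import DirectionSignal

MotionType = Literal["forward", "backward", "static", "translate"]


@dataclass(frozen=True)
class MotionSceneParams:
    """Textured frame pair under a known motion field.

    ``magnitude`` is the peak displacement in pixels per frame step (attained
    at the largest radius for radial motion, everywhere for translation).
    ``texture_sigma`` is the smoothing length of the band-limited texture in
    pixels; ``noise_sigma`` is additive i.i.d. intensity noise on the second
    frame (0-255 scale).
    """

    motion_type: MotionType = "forward"
    magnitude: float = 1.0
    frame_size: tuple[int, int] = (96, 96)  # (height, width)
    texture_sigma: float = 4.0
    noise_sigma: float = 0.0
    translation: tuple[float, float] = (1.0, 0.0)  # (dy, dx), used by "translate"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("magnitude must be non-negative")
        if self.motion_type == "static" and self.magnitude != 0:
            object.__setattr__(self, "magnitude", 0.0)


@dataclass(frozen=True)
class SignalScenarioParams:
    """Two-phase direction signal with oscillations, stops and label noise.

    The true cecum time equals ``insertion_duration``.  Each oscillation is a
    ``(time, half_length)`` pair (seconds): samples within ``time +/-
    half_length`` take the sign opposite to the surrounding phase, emulating
    the light insertion-withdrawal repeat movements seen while inspecting the
    mucosa.  Oscillations must keep clear of the true phase change by at
    least ``half_length + guard_band`` so the ground truth stays unambiguous.
    """

    insertion_duration: float = 600.0
    withdrawal_duration: float = 400.0
    sample_interval: float = 0.5
    oscillation_spec: tuple[tuple[float, float], ...] = ()
    stop_prob: float = 0.0
    label_noise_prob: float = 0.0
    guard_band: float = 15.0  # half of the largest window t in use
    seed: int = 0

    def __post_init__(self) -> None:
        if self.insertion_duration <= 0 or self.withdrawal_duration <= 0:
            raise ValueError("phase durations must be positive")
        if not (0 <= self.stop_prob <= 1 and 0 <= self.label_noise_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        for time, half in self.oscillation_spec:
            if half <= 0:
                raise ValueError("oscillation half-length must be positive")
            if abs(time - self.insertion_duration) < half + self.guard_band:
                raise ValueError(
                    f"oscillation at {time}s overlaps the guard band around the "
                    f"true phase change at {self.insertion_duration}s"
                )

    @property
    def true_cecum_time(self) -> float:
        return self.insertion_duration


def band_limited_texture(
    shape: tuple[int, int], sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian-smoothed white noise rescaled to [0, 255] (float)."""
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma, mode="wrap")
    lo, hi = smooth.min(), smooth.max()
    return 255.0 * (smooth - lo) / (hi - lo)


def _radial_field(shape: tuple[int, int], magnitude: float, sign: float) -> FlowField:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    dy, dx = yy - cy, xx - cx
    r_max = np.hypot(cy, cx)
    u = sign * magnitude * dx / r_max
    v = sign * magnitude * dy / r_max
    return FlowField(u=u, v=v)


def true_motion_field(params: MotionSceneParams) -> FlowField:
    """The analytic flow oracle for a scene, in pixels per frame step."""
    h, w = params.frame_size
    if params.motion_type == "static":
        return FlowField(u=np.zeros((h, w)), v=np.zeros((h, w)))
    if params.motion_type == "translate":
        dy, dx = params.translation
        return FlowField(u=np.full((h, w), dx), v=np.full((h, w), dy))
    sign = 1.0 if params.motion_type == "forward" else -1.0
    return _radial_field((h, w), params.magnitude, sign)


def generate_frame_pair(
    params: MotionSceneParams,
) -> tuple[FrameImage, FrameImage, FlowField]:
    """Frame pair related by a known motion field, plus that field.

    The second frame is the first warped backward along the field (so that a
    feature at p in frame 1 appears at p + flow(p) in frame 2), with optional
    additive noise.  Integer pure translations use an exact circular shift.
    """
    rng = np.random.default_rng(params.seed)
    texture = band_limited_texture(params.frame_size, params.texture_sigma, rng)
    truth = true_motion_field(params)
    if params.motion_type == "static" or (
        params.magnitude == 0 and params.motion_type != "translate"
    ):
        warped = texture.copy()
    elif params.motion_type == "translate" and all(
        float(c).is_integer() for c in params.translation
    ):
        warped = np.roll(
            texture, (int(params.translation[0]), int(params.translation[1])), axis=(0, 1)
        )
    else:
        h, w = params.frame_size
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        warped = ndimage.map_coordinates(
            texture, [yy - truth.v, xx - truth.u], order=3, mode="wrap"
        )
    if params.noise_sigma > 0:
        warped = warped + rng.normal(0.0, params.noise_sigma, size=warped.shape)
    prev = FrameImage(pixels=np.clip(texture, 0, 255).astype(np.uint8), timestamp=0.0, index=0)
    curr = FrameImage(pixels=np.clip(warped, 0, 255).astype(np.uint8), timestamp=0.5, index=1)
    return prev, curr, truth


DegradationKind = Literal["clean", "blur", "dark", "bright", "streak"]

#: Degradation strength ranges (drawn uniformly per call).
_DEGRADE_RANGES = {
    "blur": (4.0, 8.0),  # Gaussian sigma, px
    "dark": (0.02, 0.08),  # intensity scale factor
    "bright": (0.90, 0.99),  # fraction of pixels pushed to saturation
    "streak": (15, 31),  # motion-streak kernel length, px
}


def generate_degraded_frame(
    kind: DegradationKind, seed: int = 0, frame_size: tuple[int, int] = (128, 128)
) -> tuple[FrameImage, bool]:
    """A frame of the requested quality class and its informative flag.

    ``clean`` frames are sharp band-limited textures with fine detail;
    every other kind emulates a non-observable frame (motion blur, excessive
    darkness or brightness, directional streaking) and is non-informative.
    """
    rng = np.random.default_rng(seed)
    fine = band_limited_texture(frame_size, 1.2, rng)
    coarse = band_limited_texture(frame_size, 6.0, rng)
    clean = np.clip(0.6 * fine + 0.4 * coarse, 0, 255)
    if kind == "clean":
        out = clean
    elif kind == "blur":
        sigma = rng.uniform(*_DEGRADE_RANGES["blur"])
        out = ndimage.gaussian_filter(clean, sigma, mode="nearest")
    elif kind == "dark":
        scale = rng.uniform(*_DEGRADE_RANGES["dark"])
        out = clean * scale
    elif kind == "bright":
        frac = rng.uniform(*_DEGRADE_RANGES["bright"])
        out = np.where(clean >= np.quantile(clean, 1 - frac), 255.0, clean)
        out = ndimage.gaussian_filter(out, 2.0, mode="nearest")
    elif kind == "streak":
        length = int(rng.integers(*_DEGRADE_RANGES["streak"]))
        kernel = np.zeros((1, length))
        kernel[0, :] = 1.0 / length
        out = ndimage.convolve(clean, kernel, mode="nearest")
    else:
        raise ValueError(f"unknown degradation kind {kind!r}")
    frame = FrameImage(
        pixels=np.clip(out, 0, 255).astype(np.uint8), timestamp=0.0, index=0
    )
    return frame, kind == "clean"


def generate_direction_signal(
    params: SignalScenarioParams,
) -> tuple[DirectionSignal, float]:
    """Two-phase +1/-1 signal with the configured disturbances.

    Construction order: base phases -> oscillations (opposite-sign runs) ->
    stop interludes (samples zeroed with ``stop_prob``) -> label noise (signs
    flipped with ``label_noise_prob``).  Returns the signal and the true
    cecum time (start of the withdrawal phase).
    """
    rng = np.random.default_rng(params.seed)
    dt = params.sample_interval
    n_ins = int(round(params.insertion_duration / dt))
    n_wd = int(round(params.withdrawal_duration / dt))
    values = np.concatenate(
        [np.ones(n_ins, dtype=np.int8), -np.ones(n_wd, dtype=np.int8)]
    )
    times = dt * np.arange(values.size)
    for osc_time, half in params.oscillation_spec:
        mask = np.abs(times - osc_time) < half
        values[mask] = -values[mask]
    if params.stop_prob > 0:
        values[rng.random(values.size) < params.stop_prob] = 0
    if params.label_noise_prob > 0:
        flip = rng.random(values.size) < params.label_noise_prob
        values[flip] = -values[flip]
    signal = DirectionSignal(values=values, sample_interval=dt)
    return signal, params.true_cecum_time


def generate_signal_battery(
    n_scenarios: int,
    seed: int = 0,
    stop_prob: float = 0.15,
    label_noise_prob: float = 0.08,
    max_oscillations: int = 3,
    max_half_length: float = 5.0,
) -> list[tuple[DirectionSignal, float]]:
    """Seeded battery of realistic scenarios for locator evaluation.

    Each scenario draws an insertion phase of 300-900 s and a withdrawal
    phase of 240-600 s, up to ``max_oscillations`` oscillations of half-length
    up to ``max_half_length`` seconds (full runs <= 10 s) placed anywhere
    outside the guard band around the cecum, plus the given stop and
    label-noise rates.
    """
    master = np.random.default_rng(seed)
    battery = []
    for i in range(n_scenarios):
        sub = np.random.default_rng(master.integers(2**31))
        ins = float(sub.uniform(300, 900))
        wd = float(sub.uniform(240, 600))
        oscs = []
        for _ in range(int(sub.integers(0, max_oscillations + 1))):
            half = float(sub.uniform(1.0, max_half_length))
            guard = half + 15.0 + 1.0
            # place uniformly over the whole procedure, outside the guard band
            while True:
                time = float(sub.uniform(30.0, ins + wd - 30.0))
                if abs(time - ins) >= guard:
                    break
            oscs.append((time, half))
        params = SignalScenarioParams(
            insertion_duration=ins,
            withdrawal_duration=wd,
            oscillation_spec=tuple(oscs),
            stop_prob=stop_prob,
            label_noise_prob=label_noise_prob,
            seed=int(sub.integers(2**31)),
        )
        battery.append(generate_direction_signal(params))
    return battery


def generate_flow_color_dataset(
    n_per_class: int,
    image_size: tuple[int, int] = (40, 50),  # (height, width)
    magnitude_scale: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Flow-color images of the three movement classes, for classifier work.

    The construction is hue-separable — one dominant hue family per moving
    class.  The scope axis is modelled as looking into the colon wall at a
    fixed oblique angle, so advancing it produces flow with a dominant
    direction (here along +x, jittered per sample) plus a weaker radial
    expansion, and pulling back produces the opposite; stop frames carry only
    near-zero flow and render desaturated.  Magnitudes, the radial centre and
    per-pixel jitter vary per sample.

    Returns ``(images, labels)`` with images uint8 of shape (N, H, W, 3) and
    integer labels 0=insertion, 1=withdrawal, 2=stop in canonical order.
    """
    rng = np.random.default_rng(seed)
    h, w = image_size
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    radial_weight = 0.35
    images, labels = [], []
    for class_idx, sign in ((0, 1.0), (1, -1.0), (2, 0.0)):
        for _ in range(n_per_class):
            if sign == 0.0:
                u = rng.normal(0.0, 0.05 * magnitude_scale, size=(h, w))
                v = rng.normal(0.0, 0.05 * magnitude_scale, size=(h, w))
            else:
                mag = rng.uniform(0.8, 1.8)
                theta = rng.normal(0.0, np.deg2rad(15.0))
                cy = (h - 1) / 2.0 + rng.uniform(-h / 8, h / 8)
                cx = (w - 1) / 2.0 + rng.uniform(-w / 8, w / 8)
                r_max = float(np.hypot(h / 2, w / 2))
                u = sign * mag * (
                    (1 - radial_weight) * np.cos(theta)
                    + radial_weight * (xx - cx) / r_max
                )
                v = sign * mag * (
                    (1 - radial_weight) * np.sin(theta)
                    + radial_weight * (yy - cy) / r_max
                )
                u = u + rng.normal(0.0, 0.08, size=(h, w))
                v = v + rng.normal(0.0, 0.08, size=(h, w))
            color = flow_to_color(FlowField(u=u, v=v), magnitude_scale)
            images.append(color.pixels)
            labels.append(class_idx)
    return np.stack(images), np.asarray(labels, dtype=np.int64)
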
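"""Horn-Schunck optical flow and its color encoding.

Between two frames 0.5 s apart the apparent per-pixel motion is estimated
with the classical Horn-Schunck method: minimise, over the velocity fields
(u, v), the global energy

    E(u, v) = sum (Ex u + Ey v + Et)^2  +  alpha^2 * (|grad u|^2 + |grad v|^2)

whose first term enforces brightness constancy and whose second term, weighted
by the smoothness parameter alpha^2, couples neighbouring velocities.  The
Euler-Lagrange equations are solved by the standard fixed-point iteration in
which each velocity is pulled toward its weighted neighbourhood average and
corrected along the local image gradient.  The method assumes small motions,
which is why frames are sampled as closely as 0.5 s.

The recovered field is rendered as a color image (hue = direction on the
standard color wheel with 0 deg pointing right and angles growing
counter-clockwise in display coordinates; saturation = magnitude, clipped at
``magnitude_scale``).  Those color images are what the downstream movement
classifier consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.ndimage import correlate
from skimage.color import hsv2rgb, rgb2gray, rgb2hsv

from .ingest import FrameImage

ArrayOrFrame = Union[np.ndarray, FrameImage]

# Classical Horn-Schunck stencils.  Derivatives are estimated as averages of
# forward differences over the 2x2x2 cube spanned by the two frames; the
# neighbourhood average uses the standard 8-neighbour weighted kernel.
# Changing these stencils changes the recovered values slightly.
_KX = 0.25 * np.array([[-1.0, 1.0], [-1.0, 1.0]])
_KY = 0.25 * np.array([[-1.0, -1.0], [1.0, 1.0]])
_KT = 0.25 * np.array([[1.0, 1.0], [1.0, 1.0]])
_AVG = np.array(
    [
        [1 / 12, 1 / 6, 1 / 12],
        [1 / 6, 0.0, 1 / 6],
        [1 / 12, 1 / 6, 1 / 12],
    ]
)


@dataclass(frozen=True)
class FlowParams:
    """Horn-Schunck tuning: smoothness weight, iteration budget, stop rule."""

    alpha: float = 1.0
    n_iterations: int = 100
    convergence_tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be at least 1")
        if self.convergence_tol < 0:
            raise ValueError("convergence_tol must be non-negative")


@dataclass(frozen=True)
class FlowField:
    """Per-pixel velocities (pixels per frame step); u horizontal, v vertical
    (positive v points down, in image coordinates)."""

    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if u.shape != v.shape or u.ndim != 2:
            raise ValueError("u and v must be 2-D grids of identical shape")
        if not (np.isfinite(u).all() and np.isfinite(v).all()):
            raise ValueError("flow values must be finite")
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "v", v)

    @property
    def height(self) -> int:
        return int(self.u.shape[0])

    @property
    def width(self) -> int:
        return int(self.u.shape[1])

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


@dataclass(frozen=True)
class FlowColorImage:
    """Flow rendered as an RGB image; achromatic (white) where motion is zero."""

    pixels: np.ndarray  # (H, W, 3) uint8
    magnitude_scale: float

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


def _as_gray_float(frame: ArrayOrFrame) -> np.ndarray:
    if isinstance(frame, FrameImage):
        frame = frame.pixels
    pixels = np.asarray(frame, dtype=float)
    if pixels.ndim == 3:
        pixels = rgb2gray(pixels)
    if pixels.ndim != 2:
        raise ValueError("frames must be 2-D grayscale or RGB")
    if not np.isfinite(pixels).all():
        raise ValueError("frame contains non-finite pixel values")
    return pixels


def _derivatives(prev: np.ndarray, curr: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ex = correlate(prev, _KX, mode="nearest") + correlate(curr, _KX, mode="nearest")
    ey = correlate(prev, _KY, mode="nearest") + correlate(curr, _KY, mode="nearest")
    et = correlate(curr, _KT, mode="nearest") - correlate(prev, _KT, mode="nearest")
    return ex, ey, et


def hs_energy(
    prev: ArrayOrFrame, curr: ArrayOrFrame, field: FlowField, params: FlowParams
) -> float:
    """Discrete Horn-Schunck energy of a candidate field (lower is better).

    The smoothness term uses forward differences with replicated edges, the
    data term the same derivative stencils the solver uses.  Intensities are
    normalised exactly as in :func:`compute_flow` so energies are comparable
    across bit depths.
    """
    prev_f, curr_f = _normalise_pair(_as_gray_float(prev), _as_gray_float(curr))
    ex, ey, et = _derivatives(prev_f, curr_f)
    data = ex * field.u + ey * field.v + et
    gux, guy = np.gradient(field.u)
    gvx, gvy = np.gradient(field.v)
    smooth = gux**2 + guy**2 + gvx**2 + gvy**2
    return float(np.sum(data**2) + params.alpha**2 * np.sum(smooth))


def _normalise_pair(prev: np.ndarray, curr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Joint normalisation to a 0-255 range makes the result invariant to
    # uniform intensity scaling and bit depth while keeping the default
    # alpha=1 on the scale classical Horn-Schunck practice assumes.
    scale = max(np.abs(prev).max(), np.abs(curr).max())
    if scale == 0:
        return prev, curr
    return prev * (255.0 / scale), curr * (255.0 / scale)


def compute_flow(
    prev: ArrayOrFrame,
    curr: ArrayOrFrame,
    params: FlowParams | None = None,
    return_energies: bool = False,
):
    """Horn-Schunck flow from ``prev`` to ``curr``.

    Iterates for ``params.n_iterations`` or until the mean absolute update of
    (u, v) drops below ``params.convergence_tol``.  With
    ``return_energies=True`` also returns the per-iteration energy
    trajectory (computed after each update).
    """
    params = params or FlowParams()
    prev_f = _as_gray_float(prev)
    curr_f = _as_gray_float(curr)
    if prev_f.shape != curr_f.shape:
        raise ValueError(
            f"frame dimensions differ: {prev_f.shape} vs {curr_f.shape}"
        )
    prev_f, curr_f = _normalise_pair(prev_f, curr_f)
    ex, ey, et = _derivatives(prev_f, curr_f)
    denom = params.alpha**2 + ex**2 + ey**2
    u = np.zeros_like(prev_f)
    v = np.zeros_like(prev_f)
    energies: list[float] = []
    for _ in range(params.n_iterations):
        u_bar = correlate(u, _AVG, mode="nearest")
        v_bar = correlate(v, _AVG, mode="nearest")
        coeff = (ex * u_bar + ey * v_bar + et) / denom
        u_new = u_bar - ex * coeff
        v_new = v_bar - ey * coeff
        update = 0.5 * (np.abs(u_new - u).mean() + np.abs(v_new - v).mean())
        u, v = u_new, v_new
        if return_energies:
            energies.append(
                hs_energy(prev_f, curr_f, FlowField(u, v), params)
            )
        if update < params.convergence_tol:
            break
    field = FlowField(u=u, v=v)
    if return_energies:
        return field, energies
    return field


def flow_to_color(field: FlowField, magnitude_scale: float = 2.0) -> FlowColorImage:
    """Encode a flow field on the hue wheel.

    Hue is the flow direction (0 deg = rightward, counter-clockwise positive
    in display coordinates, i.e. upward motion maps to 90 deg); saturation is
    ``min(|flow| / magnitude_scale, 1)``; value is constant, so zero motion
    renders as white.  Deterministic.
    """
    if magnitude_scale <= 0:
        raise ValueError("magnitude_scale must be positive")
    # display-convention angle: v grows downward in image coordinates
    angle = np.arctan2(-field.v, field.u)
    hue = (angle / (2.0 * np.pi)) % 1.0
    sat = np.clip(field.magnitude / magnitude_scale, 0.0, 1.0)
    hsv = np.stack([hue, sat, np.ones_like(hue)], axis=-1)
    rgb = np.round(hsv2rgb(hsv) * 255).astype(np.uint8)
    return FlowColorImage(pixels=rgb, magnitude_scale=magnitude_scale)


def color_to_flow(image: FlowColorImage) -> FlowField:
    """Decode a flow-color image back to (u, v) — the encoder's inverse,
    exact up to uint8 quantisation and the clip at ``magnitude_scale``."""
    hsv = rgb2hsv(image.pixels)
    angle = hsv[..., 0] * 2.0 * np.pi
    mag = hsv[..., 1] * image.magnitude_scale
    return FlowField(u=mag * np.cos(angle), v=-mag * np.sin(angle))
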
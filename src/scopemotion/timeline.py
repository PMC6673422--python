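"""Color-coded timeline summary of scope movement (SRCV).

The direction signal is rendered as rows of colored squares, one row per
time scale (by default 1 s, 10 s and 30 s per square).  Each square takes the
majority movement class of the samples falling in its bin, so coarser scales
naturally suppress brief outliers and make the insertion/withdrawal phase
boundary — and with it the cecum position — visually obvious.  The report
image also carries a tick at the estimated cecum time and a legend.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from PIL import Image, ImageDraw, ImageFont

from .locator import VALUE_TO_LABEL, CecumEstimate, DirectionSignal

#: Default palette: three maximally distinct colors (RGB).
DEFAULT_COLORMAP: dict[str, tuple[int, int, int]] = {
    "insertion": (214, 39, 40),   # red
    "withdrawal": (31, 119, 180), # blue
    "stop": (127, 127, 127),      # gray
}


@dataclass(frozen=True)
class TimelineSquare:
    """One square of a timeline row: the majority label of its time bin."""

    start_time: float
    scale: float
    label: str
    color: tuple[int, int, int]


@dataclass(frozen=True)
class SrcvReport:
    """Timelines at each requested scale plus the cecum marker and metadata."""

    timelines: Mapping[float, tuple[TimelineSquare, ...]]
    cecum_time: float | None
    window_t: float | None
    duration: float
    sample_interval: float

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "cecum_time_s": self.cecum_time,
            "window_t_s": self.window_t,
            "duration_s": self.duration,
            "sample_interval_s": self.sample_interval,
            "timelines": {
                str(scale): [
                    {"start_time_s": sq.start_time, "label": sq.label}
                    for sq in squares
                ]
                for scale, squares in self.timelines.items()
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def aggregate_timeline(
    signal: DirectionSignal,
    scale: float,
    colormap: Mapping[str, tuple[int, int, int]] | None = None,
) -> list[TimelineSquare]:
    """Partition the signal into [k*scale, (k+1)*scale) bins by majority label.

    Bins are anchored at the first sample's time; a final partial bin is kept
    if it holds at least one sample.  Majority ties resolve to the label of
    the bin's temporally first sample among the tied labels.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    colormap = dict(colormap or DEFAULT_COLORMAP)
    t0 = float(signal.times[0])
    bins = np.floor((signal.times - t0) / scale + 1e-9).astype(int)
    squares: list[TimelineSquare] = []
    for k in np.unique(bins):
        members = signal.values[bins == k]
        counts = Counter(int(v) for v in members)
        top = max(counts.values())
        tied = {value for value, c in counts.items() if c == top}
        winner = next(int(v) for v in members if int(v) in tied)
        label = VALUE_TO_LABEL[winner]
        squares.append(
            TimelineSquare(
                start_time=t0 + float(k) * scale,
                scale=float(scale),
                label=label,
                color=tuple(colormap[label]),
            )
        )
    return squares


def build_report(
    signal: DirectionSignal,
    estimate: CecumEstimate | None = None,
    scales: Sequence[float] = (1.0, 10.0, 30.0),
    colormap: Mapping[str, tuple[int, int, int]] | None = None,
) -> SrcvReport:
    """Aggregate the signal at every requested scale and attach the cecum mark."""
    timelines = {
        float(scale): tuple(aggregate_timeline(signal, scale, colormap))
        for scale in scales
    }
    return SrcvReport(
        timelines=timelines,
        cecum_time=None if estimate is None else estimate.time,
        window_t=None if estimate is None else estimate.window_t,
        duration=signal.duration,
        sample_interval=signal.sample_interval,
    )


def render_report(
    report: SrcvReport,
    out_path: str | Path,
    colormap: Mapping[str, tuple[int, int, int]] | None = None,
    square_px: int = 10,
    gap_px: int = 1,
) -> Path:
    """Write the report as a PNG: one row of squares per scale (coarsest
    last), a black cecum tick crossing each row at the marker time, and a
    color legend.  Pixel output is deterministic for fixed inputs."""
    if not report.timelines:
        raise ValueError("report has no timelines to render")
    colormap = dict(colormap or DEFAULT_COLORMAP)
    scales = sorted(report.timelines)
    margin, label_h, row_gap = 8, 14, 10
    pitch = square_px + gap_px
    n_cols = {s: len(report.timelines[s]) for s in scales}
    width = 2 * margin + max(n * pitch for n in n_cols.values())
    legend_h = label_h + 8
    height = 2 * margin + len(scales) * (square_px + label_h + row_gap) + legend_h
    image = Image.new("RGB", (width, height), (255, 255, 255))
    draw = ImageDraw.Draw(image)
    font = ImageFont.load_default()
    y = margin
    for scale in scales:
        draw.text((margin, y), f"{scale:g} s / square", fill=(0, 0, 0), font=font)
        y += label_h
        t0 = report.timelines[scale][0].start_time if report.timelines[scale] else 0.0
        for square in report.timelines[scale]:
            k = int(round((square.start_time - t0) / scale))
            x = margin + k * pitch
            draw.rectangle(
                [x, y, x + square_px - 1, y + square_px - 1], fill=square.color
            )
        if report.cecum_time is not None:
            x = margin + int((report.cecum_time - t0) / scale * pitch)
            draw.line([(x, y - 2), (x, y + square_px + 1)], fill=(0, 0, 0), width=2)
        y += square_px + row_gap
    x = margin
    for label in ("insertion", "withdrawal", "stop"):
        draw.rectangle([x, y, x + square_px - 1, y + square_px - 1],
                       fill=colormap[label])
        draw.text((x + square_px + 3, y - 1), label, fill=(0, 0, 0), font=font)
        x += square_px + 3 + 8 * len(label) + 12
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    image.save(out_path, format="PNG")
    return out_path
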
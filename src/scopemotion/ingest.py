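"""Frame extraction and cropping for colonoscopy video.

A procedure video (typically 1920x1080 at 30 fps, 20-40 min) is decomposed
into frames sampled every 0.5 s, and each frame is cropped to the rectangular
endoscopic region (850x750 px in the reference setup) to discard the on-screen
patient information and device settings.  Sources are either a video file
(decoded through imageio if an ffmpeg-capable plugin is importable) or a
directory of PNG frames with a declared source frame rate.

Coordinate convention, used package-wide: 0-based (row, column) with the
origin at the top-left, half-open ranges.  Crop rectangles are given as
(left, top, width, height) in that frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.color import rgb2gray


class Rect(NamedTuple):
    """Crop rectangle: (left, top, width, height), top-left origin."""

    left: int
    top: int
    width: int
    height: int


#: Default endoscopic region for a 1920x1080 source: 850x750, horizontally
#: centred, top-aligned.  The crop size follows the reference acquisition
#: setup; the offset is a package default since device UI layouts vary.
DEFAULT_CROP_1920x1080 = Rect(left=535, top=0, width=850, height=750)


@dataclass(frozen=True)
class FrameImage:
    """A single (optionally cropped) video frame with its sampling metadata."""

    pixels: np.ndarray  # (H, W) grayscale or (H, W, 3) RGB, uint8
    timestamp: float  # seconds from video start
    index: int  # ordinal position in the sampled sequence

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels)
        if pixels.ndim not in (2, 3) or pixels.shape[0] == 0 or pixels.shape[1] == 0:
            raise ValueError("frame pixels must be a non-empty 2-D or 3-plane grid")
        object.__setattr__(self, "pixels", pixels)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    def to_gray(self) -> "FrameImage":
        """Luminance-convert an RGB frame; a grayscale frame passes through."""
        if self.pixels.ndim == 2:
            return self
        gray = rgb2gray(self.pixels)  # float in [0, 1]
        return FrameImage(
            pixels=np.round(gray * 255).astype(np.uint8),
            timestamp=self.timestamp,
            index=self.index,
        )


@dataclass(frozen=True)
class IngestConfig:
    """Frame-sampling configuration.

    ``crop_region=None`` keeps the full frame; ``source_fps`` is only
    consulted for directory sources, where the frame rate cannot be read
    from a container.
    """

    sampling_interval: float = 0.5
    crop_region: Rect | None = None
    grayscale: bool = False
    source_fps: float = 30.0

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.source_fps <= 0:
            raise ValueError("source_fps must be positive")
        if self.crop_region is not None:
            r = Rect(*self.crop_region)
            if r.width <= 0 or r.height <= 0 or r.left < 0 or r.top < 0:
                raise ValueError(f"invalid crop region {r}")


def crop_frame(frame: FrameImage, region: Rect) -> FrameImage:
    """Exact sub-grid copy of ``region``; raises if it leaves the frame."""
    r = Rect(*region)
    if r.left < 0 or r.top < 0 or r.width <= 0 or r.height <= 0:
        raise ValueError(f"invalid crop region {r}")
    if r.left + r.width > frame.width or r.top + r.height > frame.height:
        raise ValueError(
            f"crop region {r} exceeds frame bounds {frame.width}x{frame.height}"
        )
    pixels = frame.pixels[r.top : r.top + r.height, r.left : r.left + r.width].copy()
    return FrameImage(pixels=pixels, timestamp=frame.timestamp, index=frame.index)


def _list_frame_files(directory: Path) -> list[Path]:
    files = sorted(directory.glob("*.png"))
    if not files:
        raise IOError(f"no PNG frames found in {directory}")
    return files


def _read_source(path: Path, config: IngestConfig) -> tuple[Iterator[np.ndarray], int, float]:
    """Yield source frames with their count and fps."""
    if path.is_dir():
        files = _list_frame_files(path)
        return (iio.imread(f) for f in files), len(files), config.source_fps
    if not path.exists():
        raise IOError(f"video source not found: {path}")
    try:
        meta = iio.immeta(path)
        props = iio.improps(path)
        fps = float(meta.get("fps", config.source_fps))
        n = int(props.n_images) if props.n_images is not None else None
    except Exception as exc:  # no decoding backend, corrupt file, ...
        raise IOError(
            f"cannot decode video {path!s} ({exc}); install an ffmpeg-capable "
            "imageio plugin or pre-extract frames to a PNG directory"
        ) from exc
    frames = iio.imiter(path)
    if n is None:
        frames = list(frames)
        n = len(frames)
        frames = iter(frames)
    return frames, n, fps


def extract_frames(video_path: str | Path, config: IngestConfig | None = None) -> list[FrameImage]:
    """Sample frames every ``sampling_interval`` seconds and crop them.

    The source duration is ``n_frames / fps``; output frame k corresponds to
    time ``k * interval`` for every k with ``k * interval <= duration``, taken
    as the nearest source frame (no interpolation).  Reported timestamps lie
    on the configured sampling grid.
    """
    config = config or IngestConfig()
    source, n_source, fps = _read_source(Path(video_path), config)
    if config.sampling_interval < 1.0 / fps:
        raise ValueError("sampling interval is shorter than one source frame")
    duration = n_source / fps
    n_out = int(np.floor(duration / config.sampling_interval + 1e-9)) + 1
    wanted = {
        min(int(round(k * config.sampling_interval * fps)), n_source - 1): k
        for k in range(n_out)
    }
    frames: list[FrameImage] = []
    for src_index, pixels in enumerate(source):
        if src_index not in wanted:
            continue
        k = wanted[src_index]
        frame = FrameImage(
            pixels=np.asarray(pixels),
            timestamp=k * config.sampling_interval,
            index=k,
        )
        if config.crop_region is not None:
            frame = crop_frame(frame, config.crop_region)
        if config.grayscale:
            frame = frame.to_gray()
        frames.append(frame)
    frames.sort(key=lambda f: f.index)
    return frames


def write_frames(frames: Sequence[FrameImage], out_dir: str | Path) -> Path:
    """Write frames as zero-padded PNGs plus a CSV manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for frame in frames:
        name = f"frame_{frame.index:06d}.png"
        iio.imwrite(out_dir / name, frame.pixels)
        records.append(
            {"index": frame.index, "timestamp_s": frame.timestamp, "filename": name}
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(records).to_csv(manifest, index=False)
    return manifest


def read_manifest(manifest_path: str | Path) -> list[FrameImage]:
    """Re-load frames written by :func:`write_frames`."""
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    frames = []
    for rec in table.itertuples():
        pixels = iio.imread(manifest_path.parent / rec.filename)
        frames.append(
            FrameImage(pixels=pixels, timestamp=float(rec.timestamp_s), index=int(rec.index))
        )
    return frames
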
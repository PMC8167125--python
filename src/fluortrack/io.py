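"""Reading and writing the pipeline's on-disk formats.

Dual-channel endoscopy recordings arrive either as one side-by-side video
(white light on one half, NIR on the other), as two synchronized files, or
as an NIR-only stream.  ``load_stream`` normalizes all of these into a
sequence of :class:`FramePair`.  ROI annotations travel as JSON polygon
lists; intensity traces as four-column CSV.

Coordinates are 0-based pixel indices, origin top-left, x rightward and
y downward; polygons are implicitly closed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from shapely.geometry import Polygon as _ShPolygon

from .errors import FormatError, LayoutError, SynchronizationError, ValidationError
from .intensity import IntensityTrace

__all__ = [
    "FramePair",
    "StreamConfig",
    "ROIAnnotation",
    "load_stream",
    "nir_from_rgb",
    "read_annotations",
    "write_annotations",
    "read_trace",
    "write_trace",
]

_LAYOUTS = ("side_by_side_lr", "side_by_side_rl", "two_files", "single_nir")
_NIR_CONVERSIONS = ("luma", "green_channel", "max_channel")
_TISSUE_CLASSES = ("tumour", "control")

#: ITU-R BT.601 luma weights used for the default color-to-grey conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class FramePair:
    """One synchronized white-light + NIR frame.

    ``nir`` is a grayscale array on the 0–255 grey-unit scale with the
    same height/width as ``rgb``; ``time_s`` is exactly ``index / fps``.
    """

    index: int
    time_s: float
    rgb: np.ndarray
    nir: np.ndarray

    def __post_init__(self) -> None:
        if self.rgb.shape[:2] != self.nir.shape[:2]:
            raise ValidationError("rgb and nir frames must share height and width")


@dataclass
class StreamConfig:
    """Where a recording lives and how to split it into frame pairs.

    ``source`` is one path (or an image-sequence directory), or a pair of
    paths for ``layout='two_files'``.  ``fps`` is taken from the container
    when available, otherwise it must be given here.  ``downsample_fps``
    decimates at load time (the 1 fps manual regime).
    """

    source: str | Path | Sequence[str | Path]
    layout: str = "side_by_side_lr"
    fps: float | None = None
    nir_conversion: str = "luma"
    downsample_fps: float | None = None

    def __post_init__(self) -> None:
        if self.layout not in _LAYOUTS:
            raise ValidationError(f"unknown layout {self.layout!r}; one of {_LAYOUTS}")
        if self.nir_conversion not in _NIR_CONVERSIONS:
            raise ValidationError(
                f"unknown nir_conversion {self.nir_conversion!r}; one of {_NIR_CONVERSIONS}"
            )
        if self.fps is not None and self.fps <= 0:
            raise ValidationError("fps must be positive")


@dataclass
class ROIAnnotation:
    """A labelled polygon anchored to one frame of the white-light stream."""

    label: str
    tissue_class: str
    anchor_frame: int
    polygon: np.ndarray  # (V, 2) float array of (x, y) vertices

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        self.validate()

    def validate(self, frame_shape: tuple[int, int] | None = None) -> None:
        if self.tissue_class not in _TISSUE_CLASSES:
            raise ValidationError(
                f"unknown tissue_class {self.tissue_class!r}; one of {_TISSUE_CLASSES}"
            )
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2 or len(self.polygon) < 3:
            raise ValidationError("polygon needs at least 3 (x, y) vertices")
        if not np.all(np.isfinite(self.polygon)):
            raise ValidationError("polygon vertices must be finite")
        if not _ShPolygon(self.polygon).is_valid:
            raise ValidationError(f"polygon of ROI {self.label!r} is self-intersecting")
        if frame_shape is not None:
            h, w = frame_shape
            x, y = self.polygon[:, 0], self.polygon[:, 1]
            if x.min() < 0 or y.min() < 0 or x.max() > w - 1 or y.max() > h - 1:
                raise ValidationError(
                    f"polygon of ROI {self.label!r} leaves the {w}x{h} frame bounds"
                )


def nir_from_rgb(half: np.ndarray, conversion: str) -> np.ndarray:
    """Collapse the color-stored NIR half to a single grey channel."""
    arr = np.asarray(half, dtype=float)
    if arr.ndim == 2:
        return arr.astype(np.float32)
    if conversion == "luma":
        out = arr[..., :3] @ _LUMA
    elif conversion == "green_channel":
        out = arr[..., 1]
    else:  # max_channel
        out = arr[..., :3].max(axis=-1)
    return out.astype(np.float32)


def split_side_by_side(frame: np.ndarray, layout: str) -> tuple[np.ndarray, np.ndarray]:
    """Split a composite frame at width/2 into (rgb half, nir half)."""
    w = frame.shape[1]
    if w % 2:
        raise LayoutError(f"side-by-side layout requires even frame width, got {w}")
    left, right = frame[:, : w // 2], frame[:, w // 2 :]
    return (left, right) if layout == "side_by_side_lr" else (right, left)


def _read_frames(path: str | Path, cfg: StreamConfig) -> list[np.ndarray]:
    p = Path(path)
    if not p.exists():
        raise IOError(f"cannot read video source: {p}")
    if p.is_dir():
        files = sorted(
            f for f in p.iterdir() if f.suffix.lower() in (".png", ".tif", ".tiff", ".jpg")
        )
        if not files:
            raise IOError(f"no image frames found in directory: {p}")
        return [np.asarray(iio.imread(f)) for f in files]
    try:
        frames = list(iio.imiter(p))
    except Exception as exc:  # decoding failure or missing backend
        raise IOError(f"cannot decode video file: {p}") from exc
    return [np.asarray(f) for f in frames]


def _container_fps(path: str | Path) -> float | None:
    try:
        meta = iio.immeta(Path(path))
        fps = meta.get("fps")
        return float(fps) if fps else None
    except Exception:
        return None


def load_stream(config: StreamConfig) -> list[FramePair]:
    """Decode a recording into an ordered list of synchronized frame pairs."""
    if config.layout == "two_files":
        if not (isinstance(config.source, (list, tuple)) and len(config.source) == 2):
            raise ValidationError("layout 'two_files' requires exactly two sources")
        rgb_frames = _read_frames(config.source[0], config)
        nir_frames = _read_frames(config.source[1], config)
        if len(rgb_frames) != len(nir_frames):
            raise SynchronizationError(
                f"frame count mismatch: {len(rgb_frames)} white-light vs "
                f"{len(nir_frames)} NIR frames"
            )
        primary = config.source[0]
        pairs_raw = [
            (rgb, nir_from_rgb(nir, config.nir_conversion))
            for rgb, nir in zip(rgb_frames, nir_frames)
        ]
    else:
        src = config.source
        if isinstance(src, (list, tuple)):
            if len(src) != 1:
                raise ValidationError(f"layout {config.layout!r} takes a single source")
            src = src[0]
        primary = src
        frames = _read_frames(src, config)
        pairs_raw = []
        for f in frames:
            if config.layout == "single_nir":
                nir = nir_from_rgb(f, config.nir_conversion)
                rgb = np.repeat(
                    np.clip(np.round(nir), 0, 255).astype(np.uint8)[..., None], 3, axis=-1
                )
            else:
                rgb, nir_half = split_side_by_side(f, config.layout)
                nir = nir_from_rgb(nir_half, config.nir_conversion)
            pairs_raw.append((rgb, nir))

    fps = config.fps
    if fps is None:
        fps = _container_fps(primary)
    if fps is None:
        raise ValidationError("fps not recorded in the container; set StreamConfig.fps")

    step = 1
    if config.downsample_fps is not None:
        step = max(1, int(round(fps / config.downsample_fps)))
    fps_eff = fps / step
    return [
        FramePair(index=k, time_s=k / fps_eff, rgb=np.asarray(rgb), nir=nir)
        for k, (rgb, nir) in enumerate(pairs_raw[::step])
    ]


def read_annotations(path: str | Path) -> list[ROIAnnotation]:
    """Load ROI annotations from the JSON polygon format."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"not a valid annotation JSON file: {path}") from exc
    if "annotations" not in doc:
        raise FormatError(f"missing 'annotations' key in {path}")
    return [
        ROIAnnotation(
            label=entry["label"],
            tissue_class=entry["tissue_class"],
            anchor_frame=int(entry["anchor_frame"]),
            polygon=np.asarray(entry["polygon"], dtype=float),
        )
        for entry in doc["annotations"]
    ]


def write_annotations(annotations: Iterable[ROIAnnotation], path: str | Path) -> None:
    doc = {
        "annotations": [
            {
                "label": a.label,
                "tissue_class": a.tissue_class,
                "anchor_frame": a.anchor_frame,
                "polygon": a.polygon.tolist(),
            }
            for a in annotations
        ]
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


_TRACE_COLUMNS = ["time_s", "intensity_gu", "n_pixels", "gap_flag"]


def write_trace(trace: IntensityTrace, path: str | Path) -> None:
    """CSV with header exactly ``time_s,intensity_gu,n_pixels,gap_flag``.

    Gap samples carry an empty intensity cell.  Values round-trip to six
    decimal places.
    """
    with open(path, "w") as fh:
        fh.write(",".join(_TRACE_COLUMNS) + "\n")
        for t, v, n, g in zip(
            trace.time_s, trace.intensity_gu, trace.n_pixels, trace.gap_flag
        ):
            cell = "" if (g or not np.isfinite(v)) else f"{v:.6f}"
            fh.write(f"{t:.6f},{cell},{int(n)},{int(g)}\n")


def read_trace(
    path: str | Path, roi_label: str = "", tissue_class: str = "control"
) -> IntensityTrace:
    """Read a trace CSV written by :func:`write_trace`."""
    df = pd.read_csv(path)
    if list(df.columns) != _TRACE_COLUMNS:
        raise FormatError(
            f"unexpected trace header {list(df.columns)} in {path}; "
            f"expected {_TRACE_COLUMNS}"
        )
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise FormatError(f"non-monotone time column in {path}")
    fps = float(1.0 / np.median(np.diff(t))) if len(t) > 1 else float("nan")
    return IntensityTrace(
        roi_label=roi_label,
        tissue_class=tissue_class,
        time_s=t,
        intensity_gu=df["intensity_gu"].to_numpy(dtype=float),
        n_pixels=df["n_pixels"].to_numpy(dtype=int),
        gap_flag=df["gap_flag"].to_numpy(dtype=bool),
        fps_effective=fps,
    )
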
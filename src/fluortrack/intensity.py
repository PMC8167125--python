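"""Fluorescence-intensity measurement.

Converts tracked ROI geometry into time–intensity traces from the NIR
channel, and provides the two static measurements used on still images:
square spot means and photobleaching decline on fixed specimens.

Intensities are expressed in grey units (g.u.), the 8-bit 0–255 scale of
the recorded NIR channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
from matplotlib.path import Path as _MplPath

from .errors import ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .io import FramePair, ROIAnnotation
    from .tracking import TrackResult

__all__ = [
    "IntensityTrace",
    "SpotMeasurement",
    "polygon_pixel_mask",
    "extract_trace",
    "spot_mean",
    "photobleach_assess",
]


@dataclass
class IntensityTrace:
    """Mean NIR grey intensity of one ROI over time.

    Samples are stored as parallel arrays.  Gap samples (frames where the
    ROI could not be tracked) carry ``gap_flag=True``, NaN intensity and
    ``n_pixels=0``.
    """

    roi_label: str
    tissue_class: str
    time_s: np.ndarray
    intensity_gu: np.ndarray
    n_pixels: np.ndarray
    gap_flag: np.ndarray
    fps_effective: float = float("nan")

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.intensity_gu = np.asarray(self.intensity_gu, dtype=float)
        self.n_pixels = np.asarray(self.n_pixels, dtype=int)
        self.gap_flag = np.asarray(self.gap_flag, dtype=bool)
        n = len(self.time_s)
        if not (len(self.intensity_gu) == len(self.n_pixels) == len(self.gap_flag) == n):
            raise ValidationError("trace sample arrays must have equal length")
        if n > 1 and not np.all(np.diff(self.time_s) > 0):
            raise ValidationError("trace times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0]) if len(self) else 0.0

    @property
    def gap_seconds(self) -> float:
        """Total censored time, counting one sampling interval per gap sample."""
        if len(self) == 0 or not np.isfinite(self.fps_effective):
            return 0.0
        return float(self.gap_flag.sum() / self.fps_effective)

    def non_gap(self) -> tuple[np.ndarray, np.ndarray]:
        """(time, intensity) restricted to valid samples."""
        keep = ~self.gap_flag
        return self.time_s[keep], self.intensity_gu[keep]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "intensity_gu": self.intensity_gu,
                "n_pixels": self.n_pixels,
                "gap_flag": self.gap_flag.astype(int),
            }
        )

    def downsample(self, target_fps: float) -> "IntensityTrace":
        """Decimate to ``target_fps`` by keeping every ``round(fps/target)``-th sample.

        Reproduces the manual 1 frame/s measurement regime from a 30 fps
        trace: a trace spanning ``D`` whole seconds keeps ``floor(D)+1``
        samples.
        """
        if not np.isfinite(self.fps_effective) or self.fps_effective <= 0:
            raise ValidationError("downsampling requires a known fps_effective")
        step = int(round(self.fps_effective / target_fps))
        if step < 1:
            raise ValidationError("target fps exceeds the trace sampling rate")
        sel = slice(None, None, step)
        return IntensityTrace(
            roi_label=self.roi_label,
            tissue_class=self.tissue_class,
            time_s=self.time_s[sel],
            intensity_gu=self.intensity_gu[sel],
            n_pixels=self.n_pixels[sel],
            gap_flag=self.gap_flag[sel],
            fps_effective=self.fps_effective / step,
        )


@dataclass
class SpotMeasurement:
    """Mean grey value of a square box on a still NIR image."""

    center: tuple[int, int]
    side_px: int
    mean_intensity_gu: float
    label: str = ""


def polygon_pixel_mask(shape: tuple[int, int], polygon: np.ndarray) -> np.ndarray:
    """Boolean mask of pixels whose centers lie inside ``polygon``.

    The polygon is an (V, 2) array of (x, y) vertices, implicitly closed.
    Membership is decided by the pixel-center even-odd rule, which makes
    rasterization deterministic.
    """
    poly = np.asarray(polygon, dtype=float)
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    x0 = max(int(np.floor(poly[:, 0].min())), 0)
    x1 = min(int(np.ceil(poly[:, 0].max())) + 1, w)
    y0 = max(int(np.floor(poly[:, 1].min())), 0)
    y1 = min(int(np.ceil(poly[:, 1].max())) + 1, h)
    if x0 >= x1 or y0 >= y1:
        return mask
    xs, ys = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    inside = _MplPath(poly).contains_points(pts, radius=1e-9)
    mask[y0:y1, x0:x1] = inside.reshape(y1 - y0, x1 - x0)
    return mask


def extract_trace(
    stream: Iterable["FramePair"],
    track_result: "TrackResult",
    annotation: "ROIAnnotation",
    downsample_fps: float | None = None,
    include_saturated: bool = True,
) -> IntensityTrace:
    """Mean NIR intensity inside the tracked polygon, one sample per frame.

    Frames inside tracking gaps (and frames where the propagated polygon
    encloses no pixel centers) emit gap-flagged samples with no intensity.
    ``downsample_fps`` optionally decimates the result, reproducing the
    1 fps manual sampling regime.
    """
    times, values, counts, gaps = [], [], [], []
    anchor = annotation.anchor_frame
    for frame in stream:
        if frame.index < anchor:
            continue
        poly = track_result.per_frame_polygons.get(frame.index)
        if poly is None:
            times.append(frame.time_s)
            values.append(np.nan)
            counts.append(0)
            gaps.append(True)
            continue
        mask = polygon_pixel_mask(frame.nir.shape, poly)
        if include_saturated:
            pix = frame.nir[mask]
        else:
            pix = frame.nir[mask & (frame.nir < 255)]
        if pix.size == 0:
            warnings.warn(
                f"ROI '{annotation.label}' encloses no pixels at frame {frame.index}",
                stacklevel=2,
            )
            times.append(frame.time_s)
            values.append(np.nan)
            counts.append(0)
            gaps.append(True)
        else:
            times.append(frame.time_s)
            values.append(float(np.mean(pix)))
            counts.append(int(pix.size))
            gaps.append(False)
    times = np.asarray(times, dtype=float)
    fps = float(1.0 / np.median(np.diff(times))) if len(times) > 1 else float("nan")
    trace = IntensityTrace(
        roi_label=annotation.label,
        tissue_class=annotation.tissue_class,
        time_s=times,
        intensity_gu=np.asarray(values),
        n_pixels=np.asarray(counts),
        gap_flag=np.asarray(gaps),
        fps_effective=fps,
    )
    if downsample_fps is not None:
        trace = trace.downsample(downsample_fps)
    return trace


def spot_mean(
    nir_image: np.ndarray,
    center: tuple[int, int],
    side_px: int = 25,
    label: str = "",
) -> SpotMeasurement:
    """Arithmetic mean grey value of a ``side_px`` × ``side_px`` box.

    The box is centered on ``center`` (x, y); for even sides the extra
    row/column falls on the bottom-right, biasing the box top-left.  A box
    that does not fit fully inside the image raises — there is no silent
    clipping.
    """
    if side_px < 1:
        raise ValidationError("side_px must be >= 1")
    img = np.asarray(nir_image)
    cx, cy = int(center[0]), int(center[1])
    x0 = cx - side_px // 2
    y0 = cy - side_px // 2
    h, w = img.shape[:2]
    if x0 < 0 or y0 < 0 or x0 + side_px > w or y0 + side_px > h:
        raise ValidationError(
            f"{side_px}x{side_px} box at ({cx}, {cy}) extends outside the {w}x{h} image"
        )
    box = img[y0 : y0 + side_px, x0 : x0 + side_px]
    return SpotMeasurement(
        center=(cx, cy),
        side_px=side_px,
        mean_intensity_gu=float(box.mean()),
        label=label,
    )


def photobleach_assess(
    trace: IntensityTrace,
    t_start: float | None = None,
    t_end: float | None = None,
    window_s: float = 30.0,
) -> float:
    """Percent intensity decline between the first and last window of a static recording.

    ``100 * (mean over [t_start, t_start+window] - mean over [t_end-window, t_end])
    / mean over first window``.  Intended for fixed-specimen acquisitions
    where no tracking motion is expected, so any decline reflects
    photobleaching rather than perfusion.
    """
    t, y = trace.non_gap()
    if len(t) == 0:
        raise ValidationError("empty trace")
    if t_start is None:
        t_start = float(t[0])
    if t_end is None:
        t_end = float(t[-1])
    if not t_start < t_end:
        raise ValidationError("t_start must precede t_end")
    first = y[(t >= t_start) & (t <= t_start + window_s)]
    last = y[(t >= t_end - window_s) & (t <= t_end)]
    if first.size == 0 or last.size == 0:
        raise ValidationError("assessment windows contain no samples")
    m0 = float(first.mean())
    if m0 == 0:
        raise ValidationError("first-window mean is zero; percent decline undefined")
    return 100.0 * (m0 - float(last.mean())) / m0
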
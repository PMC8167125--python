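"""Feature tracking and ROI propagation on the white-light channel.

The motion-compensation core of the pipeline: corner-like feature points
are detected inside each surgeon-annotated ROI by ranking the minimum
eigenvalue of the local gradient structure tensor, then followed
frame-to-frame with a pyramidal Kanade–Lucas–Tomasi (iterative
Lucas–Kanade) sparse optical flow solver written on numpy/scipy
primitives.  Point correspondences drive a robust similarity transform
that carries the ROI polygon along with camera motion; when too few
points survive, tracking is declared lost, a gap opens, and tracking
resumes from a later manual re-annotation (or automatically, when
enabled, by re-detecting features inside the last known polygon).

Every step is deterministic for identical inputs and configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import corner_shi_tomasi
from skimage.measure import ransac
from skimage.transform import SimilarityTransform, pyramid_gaussian
from shapely.geometry import Polygon as _ShPolygon

from .errors import TrackingLostError, ValidationError
from .intensity import polygon_pixel_mask
from .io import FramePair, ROIAnnotation

__all__ = [
    "FeaturePoint",
    "TrackerConfig",
    "TrackingConfig",
    "TrackResult",
    "detect_features",
    "track_step",
    "propagate_roi",
    "run_tracking",
    "polygon_iou",
]

_LUMA = np.array([0.299, 0.587, 0.114], dtype=np.float32)


@dataclass
class FeaturePoint:
    """A tracked corner point with sub-pixel position."""

    point_id: int
    position: tuple[float, float]
    valid: bool = True
    origin_roi: str = ""


@dataclass
class TrackerConfig:
    """Pyramidal KLT settings.

    ``window_px`` is the per-level integration window, ``fb_max_px`` the
    forward–backward re-track error beyond which a point is invalidated.
    ``min_eigen_threshold`` rejects points whose window-normalized
    structure tensor is near-singular (texture-free neighbourhoods such as
    a full-field occlusion).
    """

    window_px: int = 21
    pyramid_levels: int = 3
    max_iterations: int = 20
    convergence_eps_px: float = 0.03
    fb_max_px: float = 1.5
    min_eigen_threshold: float = 0.1
    fb_check: bool = True
    max_residual_gu: float = 20.0  # mean abs template error beyond which a point is lost


@dataclass
class TrackingConfig:
    """End-to-end ROI tracking settings."""

    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    quality_level: float = 0.01
    max_points: int = 60
    min_distance_px: int = 7
    min_points_alive: int = 3
    min_points_frac: float = 0.25      # lost when valid < max(3, frac * initial)
    min_inlier_ratio: float = 0.5      # lost when robust-fit inliers drop below this
    auto_reinit: bool = False
    reinit_min_points: int = 8
    transform_family: str = "similarity"  # or "affine"


@dataclass
class TrackResult:
    """Propagated geometry, point tracks and gap log for one ROI."""

    roi_label: str
    tissue_class: str
    fps: float
    per_frame_polygons: dict[int, np.ndarray] = field(default_factory=dict)
    point_tracks: dict[int, list[tuple[int, tuple[float, float], bool]]] = field(
        default_factory=dict
    )
    gaps: list[tuple[int, int, str]] = field(default_factory=list)
    reinit_frames: list[int] = field(default_factory=list)

    @property
    def censored_seconds(self) -> float:
        if not self.gaps:
            return 0.0
        return sum(end - start + 1 for start, end, _ in self.gaps) / self.fps

    def to_json_dict(self) -> dict:
        return {
            "roi_label": self.roi_label,
            "tissue_class": self.tissue_class,
            "fps": self.fps,
            "per_frame_polygons": {
                str(k): v.tolist() for k, v in self.per_frame_polygons.items()
            },
            "gaps": list(self.gaps),
            "reinit_frames": self.reinit_frames,
            "censored_seconds": self.censored_seconds,
        }


def _to_gray(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    return arr


class _Pyramid:
    """Gaussian pyramid of one grayscale frame with per-level gradients."""

    def __init__(self, gray: np.ndarray, levels: int):
        self.levels = [
            lv.astype(np.float32)
            for lv in pyramid_gaussian(gray, max_layer=levels - 1, downscale=2, preserve_range=True)
        ]
        self.grads = [np.gradient(lv) for lv in self.levels]  # (d/dy, d/dx)


def detect_features(
    rgb_frame: np.ndarray,
    polygon: np.ndarray,
    quality_level: float = 0.01,
    max_points: int = 60,
    min_distance: int = 7,
    origin_roi: str = "",
    _id_start: int = 0,
) -> list[FeaturePoint]:
    """Minimum-eigenvalue corner points inside a polygon.

    Candidate pixels are local maxima of the Shi–Tomasi response (the
    smaller structure-tensor eigenvalue) whose response exceeds
    ``quality_level`` times the strongest response in the polygon; they
    are accepted strongest-first subject to a pairwise ``min_distance``
    spacing, up to ``max_points``.  A texture-free region yields an empty
    list with a warning rather than an error.
    """
    gray = _to_gray(rgb_frame)
    response = corner_shi_tomasi(gray, sigma=1.5)
    mask = polygon_pixel_mask(gray.shape, np.asarray(polygon, dtype=float))
    resp = np.where(mask, response, -np.inf)
    peak = resp.max()
    if not np.isfinite(peak) or peak <= 0:
        warnings.warn("no detectable corners inside the ROI polygon", stacklevel=2)
        return []
    is_max = resp == ndi.maximum_filter(resp, size=3, mode="constant", cval=-np.inf)
    cand = np.argwhere(is_max & (resp >= quality_level * peak) & mask)
    order = np.argsort(resp[cand[:, 0], cand[:, 1]])[::-1]
    cand = cand[order]
    chosen: list[tuple[float, float]] = []
    min_d2 = float(min_distance) ** 2
    for y, x in cand:
        if all((x - cx) ** 2 + (y - cy) ** 2 >= min_d2 for cx, cy in chosen):
            chosen.append((float(x), float(y)))
            if len(chosen) >= max_points:
                break
    return [
        FeaturePoint(point_id=_id_start + i, position=pos, valid=True, origin_roi=origin_roi)
        for i, pos in enumerate(chosen)
    ]


class _BilinearWeights:
    """Shared interpolation indices/weights for sampling several arrays at once.

    Coordinates outside the image clamp to the border (edge replication).
    """

    def __init__(self, coords_xy: np.ndarray, shape: tuple[int, int]):
        h, w = shape
        self.out_shape = coords_xy.shape[:-1]
        flat = coords_xy.reshape(-1, 2)
        x = np.clip(flat[:, 0], 0.0, w - 1.0)
        y = np.clip(flat[:, 1], 0.0, h - 1.0)
        x0 = np.minimum(x.astype(np.int64), w - 2) if w > 1 else np.zeros(len(x), np.int64)
        y0 = np.minimum(y.astype(np.int64), h - 2) if h > 1 else np.zeros(len(y), np.int64)
        fx = x - x0
        fy = y - y0
        base = y0 * w + x0
        self.idx = (base, base + 1, base + w, base + w + 1)
        self.wts = ((1 - fx) * (1 - fy), fx * (1 - fy), (1 - fx) * fy, fx * fy)

    def sample(self, arr: np.ndarray) -> np.ndarray:
        flat = arr.ravel()
        i00, i10, i01, i11 = self.idx
        w00, w10, w01, w11 = self.wts
        out = w00 * flat[i00] + w10 * flat[i10] + w01 * flat[i01] + w11 * flat[i11]
        return out.reshape(self.out_shape)


def _sample(arr: np.ndarray, coords_xy: np.ndarray) -> np.ndarray:
    """Bilinear sample of ``arr`` at (..., 2) xy coordinates."""
    return _BilinearWeights(coords_xy, arr.shape).sample(arr)


def _lk_pyramidal(
    prev_pyr: _Pyramid,
    next_pyr: _Pyramid,
    pts: np.ndarray,
    cfg: TrackerConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative Lucas–Kanade flow for (N, 2) points; returns (new_pts, ok)."""
    n = len(pts)
    if n == 0:
        return pts.copy(), np.zeros(0, dtype=bool)
    half = cfg.window_px // 2
    oy, ox = np.mgrid[-half : half + 1, -half : half + 1]
    offsets = np.stack([ox.ravel(), oy.ravel()], axis=-1).astype(np.float32)  # (W, 2)
    win_area = offsets.shape[0]

    d = np.zeros((n, 2), dtype=np.float64)  # displacement at current level scale
    ok = np.ones(n, dtype=bool)
    n_levels = min(cfg.pyramid_levels, len(prev_pyr.levels))
    for level in range(n_levels - 1, -1, -1):
        scale = 2.0**level
        p = pts / scale
        coords = p[:, None, :] + offsets[None, :, :]  # (N, W, 2)
        prev_img = prev_pyr.levels[level]
        gy, gx = prev_pyr.grads[level]
        bw = _BilinearWeights(coords, prev_img.shape)
        template = bw.sample(prev_img)
        ix = bw.sample(gx)
        iy = bw.sample(gy)
        gxx = np.sum(ix * ix, axis=1)
        gxy = np.sum(ix * iy, axis=1)
        gyy = np.sum(iy * iy, axis=1)
        det = gxx * gyy - gxy * gxy
        trace = gxx + gyy
        min_eig = (trace - np.sqrt(np.maximum(trace**2 - 4 * det, 0.0))) / 2.0
        ok &= (min_eig / win_area) >= cfg.min_eigen_threshold
        ok &= det > 1e-12

        next_img = next_pyr.levels[level]
        active = ok.copy()
        for _ in range(cfg.max_iterations):
            if not active.any():
                break
            idx = np.nonzero(active)[0]
            moved = coords[idx] + d[idx][:, None, :]
            warped = _sample(next_img, moved)
            err = template[idx] - warped
            bx = np.sum(err * ix[idx], axis=1)
            by = np.sum(err * iy[idx], axis=1)
            det_a = det[idx]
            dx = (gyy[idx] * bx - gxy[idx] * by) / det_a
            dy = (gxx[idx] * by - gxy[idx] * bx) / det_a
            d[idx, 0] += dx
            d[idx, 1] += dy
            conv = np.hypot(dx, dy) < cfg.convergence_eps_px
            active[idx[conv]] = False
        if level > 0:
            d *= 2.0
        else:
            # appearance check at full resolution: a matched window should
            # resemble its template; pure-noise frames do not
            warped = _sample(next_img, coords + d[:, None, :])
            residual = np.mean(np.abs(template - warped), axis=1)
            ok &= residual <= cfg.max_residual_gu
    new_pts = pts + d
    h, w = prev_pyr.levels[0].shape
    ok &= (
        (new_pts[:, 0] >= 0)
        & (new_pts[:, 0] <= w - 1)
        & (new_pts[:, 1] >= 0)
        & (new_pts[:, 1] <= h - 1)
    )
    ok &= np.all(np.isfinite(new_pts), axis=1)
    return new_pts, ok


def _track_points(
    prev_pyr: _Pyramid,
    next_pyr: _Pyramid,
    pts: np.ndarray,
    cfg: TrackerConfig,
) -> tuple[np.ndarray, np.ndarray]:
    fwd, ok = _lk_pyramidal(prev_pyr, next_pyr, pts, cfg)
    if cfg.fb_check and len(pts):
        back, ok_b = _lk_pyramidal(next_pyr, prev_pyr, fwd, cfg)
        fb_err = np.hypot(*(back - pts).T)
        ok &= ok_b & (fb_err <= cfg.fb_max_px)
    return fwd, ok


def track_step(
    prev_rgb: np.ndarray,
    next_rgb: np.ndarray,
    points: Sequence[FeaturePoint],
    config: TrackerConfig | None = None,
) -> list[FeaturePoint]:
    """One pyramidal KLT step for a list of feature points.

    Points are re-estimated on ``next_rgb``; a point is invalidated when
    the solver fails (ill-conditioned window, divergence out of frame) or
    when re-tracking it backwards lands more than ``fb_max_px`` away from
    its original position.
    """
    cfg = config or TrackerConfig()
    if np.asarray(prev_rgb).shape != np.asarray(next_rgb).shape:
        raise ValidationError("frame size mismatch between consecutive frames")
    prev_pyr = _Pyramid(_to_gray(prev_rgb), cfg.pyramid_levels)
    next_pyr = _Pyramid(_to_gray(next_rgb), cfg.pyramid_levels)
    live = [p for p in points if p.valid]
    pts = np.array([p.position for p in live], dtype=float).reshape(-1, 2)
    new_pts, ok = _track_points(prev_pyr, next_pyr, pts, cfg)
    out: list[FeaturePoint] = []
    j = 0
    for p in points:
        if not p.valid:
            out.append(replace(p))
            continue
        out.append(
            replace(p, position=(float(new_pts[j, 0]), float(new_pts[j, 1])), valid=bool(ok[j]))
        )
        j += 1
    return out


def propagate_roi(
    polygon: np.ndarray,
    point_correspondences: tuple[np.ndarray, np.ndarray],
    min_points_alive: int = 3,
    residual_threshold_px: float = 2.0,
    transform_family: str = "similarity",
) -> tuple[np.ndarray, dict]:
    """Carry a polygon along with its tracked points.

    A similarity transform (rotation + isotropic scale + translation; the
    endoscope works at near-constant distance) is estimated from the
    (source, destination) correspondences with RANSAC so a few grossly
    wrong points cannot drag the polygon; with fewer than 3 inliers the
    update degrades to the median translation.  Raises
    :class:`TrackingLostError` below ``min_points_alive`` correspondences.
    """
    src, dst = (np.asarray(a, dtype=float) for a in point_correspondences)
    if len(src) != len(dst):
        raise ValidationError("correspondence arrays differ in length")
    if len(src) < min_points_alive:
        raise TrackingLostError(
            f"only {len(src)} valid points remain (< {min_points_alive})"
        )
    poly = np.asarray(polygon, dtype=float)
    if len(src) == 2:
        shift = np.median(dst - src, axis=0)
        return poly + shift, {"inlier_ratio": 1.0, "scale": 1.0, "mode": "translation"}
    from skimage.transform import AffineTransform

    tform_cls = AffineTransform if transform_family == "affine" else SimilarityTransform
    min_samples = 3 if transform_family == "affine" else 2
    model, inliers = ransac(
        (src, dst),
        tform_cls,
        min_samples=min_samples,
        residual_threshold=residual_threshold_px,
        max_trials=200,
        rng=0,
    )
    n_inl = 0 if inliers is None else int(inliers.sum())
    if model is None or n_inl < 3:
        shift = np.median(dst - src, axis=0)
        return poly + shift, {
            "inlier_ratio": n_inl / len(src),
            "scale": 1.0,
            "mode": "translation",
        }
    # refit on inliers only for the final estimate
    if hasattr(tform_cls, "from_estimate"):
        model = tform_cls.from_estimate(src[inliers], dst[inliers])
    else:  # older scikit-image
        model = tform_cls()
        model.estimate(src[inliers], dst[inliers])
    if not model:
        shift = np.median(dst - src, axis=0)
        return poly + shift, {
            "inlier_ratio": n_inl / len(src),
            "scale": 1.0,
            "mode": "translation",
        }
    new_poly = model(poly)
    scale = float(getattr(model, "scale", 1.0))
    if isinstance(scale, tuple):  # affine reports (sx, sy)
        scale = float(np.sqrt(scale[0] * scale[1]))
    return new_poly, {
        "inlier_ratio": n_inl / len(src),
        "scale": scale,
        "mode": transform_family,
    }


class _RoiState:
    def __init__(self, anchors: list[ROIAnnotation], result: TrackResult):
        self.anchors = anchors  # sorted by anchor_frame; first is the initial one
        self.result = result
        self.polygon: np.ndarray | None = None
        self.ids: np.ndarray = np.zeros(0, dtype=int)
        self.pts: np.ndarray = np.zeros((0, 2))
        self.initial_count = 0
        self.in_gap = False
        self.gap_start = -1
        self.gap_reason = ""
        self.initialized = False


def run_tracking(
    stream: Iterable[FramePair],
    annotations: Sequence[ROIAnnotation],
    config: TrackingConfig | None = None,
) -> list[TrackResult]:
    """Track every annotated ROI through the stream.

    Annotations sharing a label form one ROI: the earliest anchor starts
    tracking, later anchors are manual re-initializations consumed when
    tracking has been lost.  Tracking is declared lost when the valid
    point count falls below ``max(min_points_alive, min_points_frac *
    initial count)`` or the robust-fit inlier ratio drops under
    ``min_inlier_ratio``; the ensuing gap is logged in seconds and closed
    at the next (manual or automatic) re-initialization.
    """
    cfg = config or TrackingConfig()
    by_label: dict[str, list[ROIAnnotation]] = {}
    for ann in annotations:
        by_label.setdefault(ann.label, []).append(ann)
    states: list[_RoiState] = []
    next_id = 0
    fps_holder = {"fps": float("nan")}
    for label, anns in by_label.items():
        anns = sorted(anns, key=lambda a: a.anchor_frame)
        res = TrackResult(
            roi_label=label, tissue_class=anns[0].tissue_class, fps=float("nan")
        )
        states.append(_RoiState(anns, res))

    prev_pyr: _Pyramid | None = None
    prev_time = None
    last_index = -1
    for frame in stream:
        pyr = _Pyramid(_to_gray(frame.rgb), cfg.tracker.pyramid_levels)
        if prev_time is not None and not np.isfinite(fps_holder["fps"]):
            fps_holder["fps"] = 1.0 / (frame.time_s - prev_time)
        for st in states:
            next_id = _advance_roi(st, frame, prev_pyr, pyr, cfg, next_id)
        prev_pyr = pyr
        prev_time = frame.time_s
        last_index = frame.index

    results = []
    for st in states:
        if not st.initialized:
            raise ValidationError(
                f"anchor frame {st.anchors[0].anchor_frame} of ROI "
                f"{st.result.roi_label!r} lies beyond the stream end"
            )
        if st.in_gap:
            st.result.gaps.append((st.gap_start, last_index, st.gap_reason))
        st.result.fps = fps_holder["fps"]
        results.append(st.result)
    return results


def _advance_roi(
    st: _RoiState,
    frame: FramePair,
    prev_pyr: _Pyramid | None,
    pyr: _Pyramid,
    cfg: TrackingConfig,
    next_id: int,
) -> int:
    k = frame.index
    pending = [a for a in st.anchors if a.anchor_frame == k]
    if pending:
        ann = pending[-1]
        ann.validate(frame.rgb.shape[:2])
        feats = detect_features(
            frame.rgb,
            ann.polygon,
            quality_level=cfg.quality_level,
            max_points=cfg.max_points,
            min_distance=cfg.min_distance_px,
            origin_roi=ann.label,
            _id_start=next_id,
        )
        next_id += len(feats)
        _do_init(st, k, ann.polygon, feats)
        return next_id

    if not st.initialized:
        return next_id

    if st.in_gap:
        if cfg.auto_reinit and st.polygon is not None:
            feats = detect_features(
                frame.rgb,
                st.polygon,
                quality_level=cfg.quality_level,
                max_points=cfg.max_points,
                min_distance=cfg.min_distance_px,
                origin_roi=st.result.roi_label,
                _id_start=next_id,
            )
            if len(feats) >= cfg.reinit_min_points:
                next_id += len(feats)
                _do_init(st, k, st.polygon, feats)
        return next_id

    if prev_pyr is None:
        return next_id

    new_pts, ok = _track_points(prev_pyr, pyr, st.pts, cfg.tracker)
    for pid, pos, valid in zip(st.ids, new_pts, ok):
        st.result.point_tracks[int(pid)].append(
            (k, (float(pos[0]), float(pos[1])), bool(valid))
        )
    alive = int(ok.sum())
    threshold = max(cfg.min_points_alive, int(np.ceil(cfg.min_points_frac * st.initial_count)))
    if alive < threshold:
        _open_gap(st, k, f"points_lost ({alive}/{st.initial_count} valid)")
        return next_id
    try:
        new_poly, info = propagate_roi(
            st.polygon,
            (st.pts[ok], new_pts[ok]),
            min_points_alive=cfg.min_points_alive,
            transform_family=cfg.transform_family,
        )
    except TrackingLostError as exc:
        _open_gap(st, k, str(exc))
        return next_id
    if info["inlier_ratio"] < cfg.min_inlier_ratio:
        _open_gap(st, k, f"low inlier ratio ({info['inlier_ratio']:.2f})")
        return next_id
    st.polygon = new_poly
    st.ids = st.ids[ok]
    st.pts = new_pts[ok]
    st.result.per_frame_polygons[k] = new_poly.copy()
    return next_id


def _do_init(
    st: _RoiState, k: int, polygon: np.ndarray, feats: list[FeaturePoint]
) -> None:
    if st.in_gap:
        st.result.gaps.append((st.gap_start, k - 1, st.gap_reason))
        st.in_gap = False
    st.polygon = np.asarray(polygon, dtype=float).copy()
    st.ids = np.array([f.point_id for f in feats], dtype=int)
    st.pts = np.array([f.position for f in feats], dtype=float).reshape(-1, 2)
    st.initial_count = len(feats)
    for f in feats:
        st.result.point_tracks[f.point_id] = [(k, f.position, True)]
    if st.initialized:
        st.result.reinit_frames.append(k)
    st.initialized = True
    st.result.per_frame_polygons[k] = st.polygon.copy()
    if not feats:
        st.in_gap = True
        st.gap_start = k + 1
        st.gap_reason = "no features detected at initialization"


def _open_gap(st: _RoiState, k: int, reason: str) -> None:
    st.in_gap = True
    st.gap_start = k
    st.gap_reason = reason
    st.ids = np.zeros(0, dtype=int)
    st.pts = np.zeros((0, 2))


def polygon_iou(poly_a: np.ndarray, poly_b: np.ndarray) -> float:
    """Intersection-over-union of two polygons."""
    pa, pb = _ShPolygon(poly_a), _ShPolygon(poly_b)
    if not (pa.is_valid and pb.is_valid):
        return 0.0
    union = pa.union(pb).area
    return pa.intersection(pb).area / union if union > 0 else 0.0
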
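"""Ground-truthed synthetic inputs: kinetic curves, cohorts and dual-channel video.

The noiseless intensity model is a gamma-variate bolus transit (rapid
inflow, washout) plus a saturating retention component and optional
mono-exponential photobleaching:

    I(t) = baseline                                   for t < onset
    I(t) = baseline + A·[(1−ρ)·s^α·e^{α(1−s)} + ρ·(1−e^{−(t−onset)/τ})]·e^{−β·t}

with s = (t − onset)/t_p.  The gamma-variate term peaks at s = 1 with
value A(1−ρ); the retention fraction ρ controls how much signal persists
after the bolus — the slow-ingress/slow-clearance phenotype of malignant
tissue corresponds to a late peak and large ρ, normal mucosa to an early
sharp peak with mostly washout.  Every milestone of the resulting curve
has closed-form or root-findable truth, which is what makes the rest of
the pipeline testable without clinical recordings.

The video generator renders a trackable textured white-light scene warped
by a smooth similarity camera path, with the lesion and control regions
emitting their kinetic curves in the NIR channel, and exports per-frame
ground-truth polygons and traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import brentq, minimize_scalar
from shapely.geometry import Polygon as _ShPolygon
from skimage.transform import SimilarityTransform

from .errors import ValidationError
from .intensity import IntensityTrace, polygon_pixel_mask
from .io import FramePair
from .kinetics import KineticProfile

__all__ = [
    "CurveParams",
    "SceneConfig",
    "SyntheticVideo",
    "GROUP_PRESETS",
    "curve_value",
    "true_profile",
    "simulate_trace",
    "simulate_cohort",
    "simulate_video",
    "smooth_camera_path",
    "blend_params",
    "CohortMember",
]


@dataclass(frozen=True)
class CurveParams:
    """Parameters of the noiseless kinetic model (times in s, intensities in g.u.)."""

    baseline_gu: float = 10.0
    onset_s: float = 12.0
    amplitude_gu: float = 130.0
    time_to_peak_s: float = 60.0
    shape_alpha: float = 3.0
    retention_fraction: float = 0.3
    washout_tau_s: float = 35.0
    noise_sd_gu: float = 0.0
    bleach_rate_per_s: float = 0.0

    def __post_init__(self) -> None:
        if self.time_to_peak_s <= 0 or self.shape_alpha <= 0 or self.washout_tau_s <= 0:
            raise ValidationError("time_to_peak_s, shape_alpha and washout_tau_s must be > 0")
        if not 0.0 <= self.retention_fraction <= 1.0:
            raise ValidationError("retention_fraction must lie in [0, 1]")
        if self.noise_sd_gu < 0 or self.bleach_rate_per_s < 0 or self.amplitude_gu < 0:
            raise ValidationError("noise_sd_gu, bleach_rate_per_s, amplitude_gu must be >= 0")
        if not 0.0 <= self.baseline_gu <= 255.0:
            raise ValidationError("baseline_gu must lie in [0, 255]")
        if self.onset_s < 0:
            raise ValidationError("onset_s must be >= 0")


def curve_value(params: CurveParams, t) -> np.ndarray | float:
    """Noiseless model intensity at time(s) ``t`` (t >= 0)."""
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    out = np.full_like(t_arr, params.baseline_gu)
    after = t_arr >= params.onset_s
    dt = t_arr[after] - params.onset_s
    s = dt / params.time_to_peak_s
    a = params.shape_alpha
    gamma_term = np.power(s, a) * np.exp(a * (1.0 - s))  # s >= 0 after the onset mask
    retention = params.retention_fraction * (1.0 - np.exp(-dt / params.washout_tau_s))
    signal = params.amplitude_gu * ((1.0 - params.retention_fraction) * gamma_term + retention)
    signal *= np.exp(-params.bleach_rate_per_s * t_arr[after])
    out[after] = params.baseline_gu + signal
    return float(out[0]) if scalar else out


def _true_t_max(params: CurveParams, t_end: float) -> float:
    """Peak time of the noiseless curve, located to 1e-6 s."""
    grid = np.linspace(params.onset_s, t_end, 4001)
    vals = curve_value(params, grid)
    k = int(np.argmax(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    if lo == hi:
        return float(grid[k])
    res = minimize_scalar(
        lambda x: -curve_value(params, x),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-7},
    )
    t_star = float(res.x)
    return t_star if -res.fun >= vals[k] else float(grid[k])


def true_profile(
    params: CurveParams,
    fps: float,
    duration_s: float,
    rise_threshold_gu: float = 5.0,
) -> KineticProfile:
    """Analytic milestone profile of the noiseless curve.

    The peak is located numerically to 1e-6 s; threshold crossings
    (latency end, half-rise level) by bisection on the continuous curve.
    Skewness/kurtosis are the bias-corrected sample moments of the
    noiseless curve sampled on the trace grid, matching the convention of
    the profile extractor.
    """
    n = int(round(fps * duration_s)) + 1
    t_end = (n - 1) / fps
    t_max = _true_t_max(params, t_end)
    f_max = float(curve_value(params, t_max))
    threshold = params.baseline_gu + rise_threshold_gu
    if f_max < threshold:
        raise ValidationError("curve never exceeds the latency threshold")
    t_le = float(
        brentq(
            lambda x: curve_value(params, x) - threshold,
            params.onset_s,
            t_max,
            xtol=1e-6,
        )
    )
    i_le = threshold
    rise = f_max - i_le
    f_half = rise / 2.0
    t_half_abs = float(
        brentq(
            lambda x: curve_value(params, x) - (i_le + f_half), t_le, t_max, xtol=1e-6
        )
    )
    t100 = t_max + 100.0
    if t100 <= t_end:
        f100 = float(curve_value(params, t100))
        fall100 = f_max - f100
        downslope100 = fall100 / 100.0
        complete = True
    else:
        f100 = fall100 = downslope100 = float("nan")
        complete = False
    tracking_length = t_end
    final_intensity = float(curve_value(params, t_end))
    time_after = tracking_length - t_max
    samples = curve_value(params, np.arange(n) / fps)
    from scipy import stats as _sps

    return KineticProfile(
        baseline_gu=params.baseline_gu,
        latency_end_time_s=t_le,
        latency_end_intensity_gu=i_le,
        f_max_gu=f_max,
        t_max_s=t_max,
        rise_gu=rise,
        time_to_rise_s=t_max - t_le,
        upslope_gradient_gu_per_s=rise / (t_max - t_le),
        f_half_gu=f_half,
        t_half_s=t_half_abs - t_le,
        t_half_over_t_max=(t_half_abs - t_le) / t_max,
        t100_s=t100,
        f100_gu=f100,
        fall100_gu=fall100,
        downslope100_gu_per_s=downslope100,
        tracking_length_s=tracking_length,
        time_after_tmax_s=time_after,
        final_intensity_gu=final_intensity,
        downslope_gradient_gu_per_s=(f_max - final_intensity) / time_after,
        skew=float(_sps.skew(samples, bias=False)),
        kurtosis=float(_sps.kurtosis(samples, fisher=True, bias=False)),
        complete=complete,
    )


def simulate_trace(
    params: CurveParams,
    fps: float = 30.0,
    duration_s: float = 600.0,
    seed: int | Sequence[int] = 0,
    roi_label: str = "synthetic",
    tissue_class: str = "control",
) -> tuple[IntensityTrace, KineticProfile]:
    """Sampled noisy trace plus the analytic truth of its noiseless curve.

    Samples are the noiseless curve plus i.i.d. Gaussian noise
    (``params.noise_sd_gu``), clipped to [0, 255]; a warning is raised if
    clipping touches more than 5% of samples, since that biases the truth.
    """
    if duration_s < params.onset_s + params.time_to_peak_s:
        raise ValidationError("duration must cover onset + time to peak")
    n = int(round(fps * duration_s)) + 1
    t = np.arange(n) / fps
    clean = curve_value(params, t)
    if params.noise_sd_gu > 0:
        rng = np.random.default_rng(seed)
        noisy = clean + rng.normal(0.0, params.noise_sd_gu, size=n)
    else:
        noisy = clean.copy()
    clipped = np.clip(noisy, 0.0, 255.0)
    if np.mean(clipped != noisy) > 0.05:
        import warnings

        warnings.warn(
            "clipping to [0, 255] affected more than 5% of samples; "
            "the analytic profile truth is compromised",
            stacklevel=2,
        )
    trace = IntensityTrace(
        roi_label=roi_label,
        tissue_class=tissue_class,
        time_s=t,
        intensity_gu=clipped,
        n_pixels=np.ones(n, dtype=int),
        gap_flag=np.zeros(n, dtype=bool),
        fps_effective=fps,
    )
    return trace, true_profile(params, fps, duration_s)


#: Per-group kinetic presets for cohort simulation.  time_to_peak values are
#: set so the noiseless peak lands near the characteristic group peak times
#: (cancer ≈ 190 s after recording start, control ≈ 73 s, benign ≈ 84 s),
#: with retention fractions ordered so cancer clears least over the 100 s
#: post-peak window and benign clears most.
GROUP_PRESETS: dict[str, CurveParams] = {
    "cancer": CurveParams(
        baseline_gu=12.0,
        onset_s=15.0,
        amplitude_gu=120.0,
        time_to_peak_s=164.0,
        shape_alpha=2.5,
        retention_fraction=0.75,
        washout_tau_s=40.0,
        noise_sd_gu=2.0,
    ),
    "control": CurveParams(
        baseline_gu=15.0,
        onset_s=12.0,
        amplitude_gu=128.0,
        time_to_peak_s=58.4,
        shape_alpha=3.0,
        retention_fraction=0.30,
        washout_tau_s=35.0,
        noise_sd_gu=2.0,
    ),
    "benign": CurveParams(
        baseline_gu=14.0,
        onset_s=11.0,
        amplitude_gu=140.0,
        time_to_peak_s=71.3,
        shape_alpha=3.0,
        retention_fraction=0.22,
        washout_tau_s=35.0,
        noise_sd_gu=2.0,
    ),
}

#: Parameters jittered multiplicatively (lognormal) across subjects.
_JITTERED = ("onset_s", "amplitude_gu", "time_to_peak_s", "washout_tau_s")


@dataclass
class CohortMember:
    group: str
    params: CurveParams
    trace: IntensityTrace
    truth: KineticProfile


def simulate_cohort(
    group_presets: Mapping[str, CurveParams] | None = None,
    n_per_group: int = 20,
    fps: float = 30.0,
    duration_s: float = 600.0,
    seed: int = 0,
    dispersion: float = 0.25,
) -> list[CohortMember]:
    """Labelled synthetic traces with per-subject parameter variation.

    Subject parameters are drawn from lognormal distributions around the
    group presets (multiplicative sigma ``dispersion`` on onset,
    amplitude, time-to-peak and washout tau); ``dispersion=0`` with
    noiseless presets reproduces the presets exactly.  Deterministic given
    ``seed``.
    """
    presets = dict(group_presets) if group_presets is not None else GROUP_PRESETS
    if n_per_group < 1:
        raise ValidationError("n_per_group must be >= 1")
    members: list[CohortMember] = []
    for gi, (group, base) in enumerate(presets.items()):
        for j in range(n_per_group):
            rng = np.random.default_rng([seed, gi, j])
            if dispersion > 0:
                factors = {
                    name: float(np.exp(rng.normal(0.0, dispersion))) for name in _JITTERED
                }
                params = replace(
                    base, **{k: getattr(base, k) * f for k, f in factors.items()}
                )
            else:
                params = base
            trace, truth = simulate_trace(
                params,
                fps=fps,
                duration_s=duration_s,
                seed=[seed, gi, j, 1],
                roi_label=f"{group}_{j}",
                tissue_class="control" if group == "control" else "tumour",
            )
            members.append(CohortMember(group=group, params=params, trace=trace, truth=truth))
    return members


def blend_params(a: CurveParams, b: CurveParams, frac: float) -> CurveParams:
    """Interpolate two parameter sets (``frac=0`` gives ``a``, 1 gives ``b``).

    Positive scale-like parameters interpolate geometrically, the
    retention fraction linearly.  Used to sweep the effect size between
    two kinetic regimes down to indistinguishability.
    """
    def geo(x, y):
        return float(x ** (1 - frac) * y**frac)

    return CurveParams(
        baseline_gu=(1 - frac) * a.baseline_gu + frac * b.baseline_gu,
        onset_s=geo(a.onset_s, b.onset_s) if a.onset_s > 0 and b.onset_s > 0 else (1 - frac) * a.onset_s + frac * b.onset_s,
        amplitude_gu=geo(a.amplitude_gu, b.amplitude_gu),
        time_to_peak_s=geo(a.time_to_peak_s, b.time_to_peak_s),
        shape_alpha=geo(a.shape_alpha, b.shape_alpha),
        retention_fraction=(1 - frac) * a.retention_fraction + frac * b.retention_fraction,
        washout_tau_s=geo(a.washout_tau_s, b.washout_tau_s),
        noise_sd_gu=(1 - frac) * a.noise_sd_gu + frac * b.noise_sd_gu,
        bleach_rate_per_s=(1 - frac) * a.bleach_rate_per_s + frac * b.bleach_rate_per_s,
    )


# ---------------------------------------------------------------------------
# Dual-channel video synthesis


def smooth_camera_path(
    n_frames: int,
    fps: float,
    translation_px: float = 8.0,
    rotation_deg: float = 2.0,
    scale_amplitude: float = 0.02,
    period_s: float = 20.0,
) -> np.ndarray:
    """Sinusoidal similarity camera path, one (dx, dy, rot_rad, scale) row per frame."""
    t = np.arange(n_frames) / fps
    w = 2 * np.pi / period_s
    dx = translation_px * np.sin(w * t)
    dy = translation_px * (np.sin(1.37 * w * t + 0.9) - np.sin(0.9))
    rot = np.deg2rad(rotation_deg) * (np.sin(0.81 * w * t + 0.4) - np.sin(0.4))
    scale = 1.0 + scale_amplitude * (np.sin(0.63 * w * t + 2.1) - np.sin(2.1))
    # starts exactly at the identity so an anchor-frame annotation coincides
    # with the scene-space polygon
    return np.column_stack([dx, dy, rot, scale])


@dataclass
class SceneConfig:
    """A moving dual-channel scene with embedded lesion and control regions."""

    frame_shape: tuple[int, int] = (240, 320)  # (height, width)
    fps: float = 30.0
    duration_s: float = 120.0
    texture_seed: int = 7
    camera_path: np.ndarray | None = None  # (N, 4) rows dx, dy, rot_rad, scale
    lesion_polygon: np.ndarray = field(
        default_factory=lambda: np.array([[60, 60], [130, 55], [140, 120], [70, 130]], float)
    )
    lesion_params: CurveParams = field(default_factory=lambda: GROUP_PRESETS["cancer"])
    control_polygon: np.ndarray = field(
        default_factory=lambda: np.array([[200, 70], [265, 75], [260, 150], [195, 140]], float)
    )
    control_params: CurveParams = field(default_factory=lambda: GROUP_PRESETS["control"])
    occlusions: Sequence[tuple[int, int]] = field(default_factory=list)
    occlusion_grey: float = 128.0
    nir_background_gu: float = 2.0
    nir_noise_sd_gu: float = 0.0
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration_s))

    def region_items(self) -> list[tuple[str, np.ndarray, CurveParams, str]]:
        return [
            ("lesion", np.asarray(self.lesion_polygon, float), self.lesion_params, "tumour"),
            ("control", np.asarray(self.control_polygon, float), self.control_params, "control"),
        ]


def _camera_transform(
    row: np.ndarray, center: tuple[float, float]
) -> SimilarityTransform:
    dx, dy, rot, scale = row
    tc = SimilarityTransform(translation=center).params
    tci = SimilarityTransform(translation=(-center[0], -center[1])).params
    a = SimilarityTransform(scale=scale, rotation=rot).params
    m = tc @ a @ tci
    m[0, 2] += dx
    m[1, 2] += dy
    return SimilarityTransform(matrix=m)


class SyntheticVideo:
    """Lazily rendered synthetic dual-channel stream with its ground truth.

    ``truth_polygons[label]`` holds the (n_frames, V, 2) true polygon
    track, ``truth_values[label]`` the noiseless region intensity per
    frame, and ``occluded`` the per-frame occlusion mask.  Iterating the
    object (or calling :meth:`frame_pairs`) regenerates identical frames.
    """

    def __init__(self, scene: SceneConfig):
        self.scene = scene
        h, w = scene.frame_shape
        n = scene.n_frames
        path = scene.camera_path
        if path is None:
            path = np.zeros((n, 4))
            path[:, 3] = 1.0
        if len(path) < n:
            raise ValidationError("camera path shorter than the frame count")
        self.path = np.asarray(path, dtype=float)[:n]

        items = scene.region_items()
        if _ShPolygon(items[0][1]).intersects(_ShPolygon(items[1][1])):
            raise ValidationError("lesion and control polygons must be disjoint")

        self.occluded = np.zeros(n, dtype=bool)
        for start, end in scene.occlusions:
            self.occluded[start : end + 1] = True

        center = ((w - 1) / 2.0, (h - 1) / 2.0)
        self._tforms = [_camera_transform(self.path[k], center) for k in range(n)]
        self.truth_polygons: dict[str, np.ndarray] = {}
        self.truth_values: dict[str, np.ndarray] = {}
        self.labels: dict[str, str] = {}
        times = np.arange(n) / scene.fps
        for label, poly, params, cls in items:
            warped = np.stack([tf(poly) for tf in self._tforms])
            for k in range(n):
                if self.occluded[k]:
                    continue
                xs, ys = warped[k][:, 0], warped[k][:, 1]
                if xs.min() < 0 or ys.min() < 0 or xs.max() > w - 1 or ys.max() > h - 1:
                    raise ValidationError(
                        f"camera motion pushes region '{label}' out of frame at frame {k}"
                    )
            self.truth_polygons[label] = warped
            self.truth_values[label] = np.asarray(curve_value(params, times))
            self.labels[label] = cls

        # trackable white-light texture: band-limited noise over a margin
        margin = 64
        rng = np.random.default_rng(scene.texture_seed)
        tex = rng.uniform(0, 1, size=(h + 2 * margin, w + 2 * margin, 3))
        tex = ndi.gaussian_filter(tex, sigma=(2.0, 2.0, 0))
        tex -= tex.min()
        tex /= tex.max()
        self._texture = (40 + 180 * tex).astype(np.float32)
        self._margin = margin

    def __iter__(self) -> Iterator[FramePair]:
        return self.frame_pairs()

    def frame_pairs(self) -> Iterator[FramePair]:
        scene = self.scene
        h, w = scene.frame_shape
        ys, xs = np.mgrid[0:h, 0:w].astype(float)
        grid = np.column_stack([xs.ravel(), ys.ravel()])
        for k in range(scene.n_frames):
            t_s = k / scene.fps
            if self.occluded[k]:
                grey = int(round(scene.occlusion_grey))
                rgb = np.full((h, w, 3), grey, dtype=np.uint8)
                nir = np.full((h, w), float(grey), dtype=np.float32)
                yield FramePair(index=k, time_s=t_s, rgb=rgb, nir=nir)
                continue
            inv = self._tforms[k].inverse(grid)
            cx = inv[:, 0] + self._margin
            cy = inv[:, 1] + self._margin
            rgb = np.stack(
                [
                    ndi.map_coordinates(
                        self._texture[..., c], [cy, cx], order=1, mode="nearest"
                    ).reshape(h, w)
                    for c in range(3)
                ],
                axis=-1,
            )
            rgb = np.clip(np.round(rgb), 0, 255).astype(np.uint8)
            nir = np.full((h, w), scene.nir_background_gu, dtype=np.float64)
            for label in self.truth_polygons:
                mask = polygon_pixel_mask((h, w), self.truth_polygons[label][k])
                nir[mask] = self.truth_values[label][k]
            if scene.nir_noise_sd_gu > 0:
                frame_rng = np.random.default_rng([scene.seed, k])
                nir += frame_rng.normal(0.0, scene.nir_noise_sd_gu, size=nir.shape)
            nir = np.clip(np.round(nir), 0, 255).astype(np.float32)
            yield FramePair(index=k, time_s=t_s, rgb=rgb, nir=nir)

    def write_side_by_side(self, out_dir: str | Path) -> list[Path]:
        """Write the stream as numbered side-by-side PNG frames (RGB | NIR)."""
        import imageio.v3 as iio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = []
        for fp in self.frame_pairs():
            nir8 = np.clip(np.round(fp.nir), 0, 255).astype(np.uint8)
            composite = np.concatenate([fp.rgb, np.repeat(nir8[..., None], 3, -1)], axis=1)
            p = out / f"frame_{fp.index:05d}.png"
            iio.imwrite(p, composite)
            paths.append(p)
        return paths


def simulate_video(scene: SceneConfig) -> SyntheticVideo:
    """Validate a scene and return its lazily rendered video with ground truth."""
    return SyntheticVideo(scene)
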
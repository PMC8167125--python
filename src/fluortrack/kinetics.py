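"""Kinetic milestone extraction from fluorescence time–intensity curves.

After intravenous ICG the mucosal NIR signal shows a latency period, a
rapid inflow to a peak, and a slow decline as the dye clears.  This module
reduces one trace to the standard milestone profile used for group
comparison:

* latency end — first sample rising ``rise_threshold_gu`` (default 5 g.u.)
  above baseline, where baseline is the mean of the first few seconds of
  the trace (annotation precedes fluorescence onset, so early frames are
  pre-inflow);
* ``F_max`` / ``T_max`` — peak of the smoothed curve and its time;
* rise, time-to-rise and up-slope gradient from latency end to the peak;
* ``F_½max`` / ``T_½max`` — half the post-latency rise and the time taken
  (from latency end) to reach it;
* ``T_100`` / ``F_100`` / ``Fall_100`` / ``DownSlope_100`` — the clearance
  flag 100 s after the peak;
* whole-curve descriptors: tracking length, final intensity, down-slope
  gradient, sample skewness and excess kurtosis.

Milestones are read from a centered moving-average smoothed curve
(default 1 s window) because raw 30 fps extrema are noise-dominated; a
window of one sample reproduces the raw-curve regime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields as _dc_fields
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import NoInflowError, ValidationError
from .intensity import IntensityTrace

__all__ = [
    "KineticProfile",
    "smooth_trace",
    "detect_latency_end",
    "compute_profile",
    "fit_log_curve",
    "group_mean_curves",
    "profiles_to_frame",
]


@dataclass
class KineticProfile:
    """Milestone variables of one fluorescence intensity curve.

    All intensities in grey units (g.u.), all times in seconds.  Fields
    past ``T_100`` are NaN with ``complete=False`` when the trace ends
    before ``T_max`` + 100 s.
    """

    baseline_gu: float
    latency_end_time_s: float
    latency_end_intensity_gu: float
    f_max_gu: float
    t_max_s: float
    rise_gu: float
    time_to_rise_s: float
    upslope_gradient_gu_per_s: float
    f_half_gu: float
    t_half_s: float
    t_half_over_t_max: float
    t100_s: float
    f100_gu: float
    fall100_gu: float
    downslope100_gu_per_s: float
    tracking_length_s: float
    time_after_tmax_s: float
    final_intensity_gu: float
    downslope_gradient_gu_per_s: float
    skew: float
    kurtosis: float
    complete: bool = True
    roi_label: str = ""
    tissue_class: str = ""

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in _dc_fields(self)}

    # Exact arithmetic identities that tie the milestone definitions together.
    def identity_residuals(self) -> dict[str, float]:
        res = {
            "rise": self.rise_gu - (self.f_max_gu - self.latency_end_intensity_gu),
            "f_half": self.f_half_gu - self.rise_gu / 2.0,
            "time_to_rise": self.time_to_rise_s - (self.t_max_s - self.latency_end_time_s),
            "t100": self.t100_s - (self.t_max_s + 100.0),
            "time_after_tmax": self.time_after_tmax_s
            - (self.tracking_length_s - self.t_max_s),
        }
        if self.complete:
            res["fall100"] = self.fall100_gu - (self.f_max_gu - self.f100_gu)
            res["downslope100"] = self.downslope100_gu_per_s - self.fall100_gu / 100.0
        return res


def smooth_trace(
    trace: IntensityTrace, smoothing_window_s: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Centered moving average over non-gap samples.

    The window shrinks symmetrically at the trace ends so no sample is
    extrapolated.  Returns (time, smoothed intensity).
    """
    t, y = trace.non_gap()
    if len(t) == 0:
        raise ValidationError("trace has no valid samples")
    fps = trace.fps_effective
    if not np.isfinite(fps) or fps <= 0:
        fps = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 1.0
    n = int(round(smoothing_window_s * fps))
    n = max(1, n)
    if n % 2 == 0:
        n += 1
    if n > len(t):
        raise ValidationError(
            f"smoothing window of {n} samples exceeds trace length {len(t)}"
        )
    if n == 1:
        return t, y.copy()
    kernel = np.ones(n)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y), kernel, mode="same")
    return t, num / den


def detect_latency_end(
    trace: IntensityTrace,
    rise_threshold_gu: float = 5.0,
    baseline_window_s: float = 3.0,
    smoothing_window_s: float = 1.0,
) -> tuple[float, float]:
    """End of the latency period: first smoothed sample ≥ baseline + threshold.

    Baseline is the mean smoothed intensity over the first
    ``baseline_window_s`` of the trace.  Returns (time_s, intensity_gu) of
    the crossing sample; raises :class:`NoInflowError` when the threshold
    is never crossed.
    """
    t, s = smooth_trace(trace, smoothing_window_s)
    idx, baseline = _latency_index(t, s, rise_threshold_gu, baseline_window_s)
    return float(t[idx]), float(s[idx])


def _latency_index(
    t: np.ndarray, s: np.ndarray, rise_threshold_gu: float, baseline_window_s: float
) -> tuple[int, float]:
    base_sel = t <= t[0] + baseline_window_s
    baseline = float(s[base_sel].mean())
    above = np.nonzero(s >= baseline + rise_threshold_gu)[0]
    if above.size == 0:
        raise NoInflowError(
            f"intensity never rises {rise_threshold_gu} g.u. above baseline "
            f"({baseline:.2f} g.u.): no inflow detected"
        )
    return int(above[0]), baseline


def compute_profile(
    trace: IntensityTrace,
    smoothing_window_s: float = 1.0,
    rise_threshold_gu: float = 5.0,
    baseline_window_s: float = 3.0,
    upslope_from_latency: bool = True,
) -> KineticProfile:
    """Full milestone profile of one trace.

    ``upslope_from_latency`` selects the up-slope definition: the intensity
    rise divided by the time from latency end to the peak (default), or the
    plain ``F_max / T_max`` ratio when False.

    Skewness and excess kurtosis are bias-corrected sample moments of the
    raw (unsmoothed) non-gap intensities.
    """
    t, s = smooth_trace(trace, smoothing_window_s)
    _, raw = trace.non_gap()
    if len(t) < 2:
        raise ValidationError("trace too short for a kinetic profile")
    le_idx, baseline = _latency_index(t, s, rise_threshold_gu, baseline_window_s)
    t_le, i_le = float(t[le_idx]), float(s[le_idx])

    pk_idx = int(np.argmax(s))
    f_max, t_max = float(s[pk_idx]), float(t[pk_idx])
    if pk_idx >= len(t) - 1 and pk_idx == le_idx:
        raise ValidationError("trace does not extend past its peak")

    rise = f_max - i_le
    time_to_rise = t_max - t_le
    if upslope_from_latency:
        upslope = rise / time_to_rise if time_to_rise > 0 else float("inf")
    else:
        upslope = f_max / t_max if t_max > 0 else float("inf")

    f_half = rise / 2.0
    half_level = i_le + f_half
    after = np.nonzero((t >= t_le) & (s >= half_level))[0]
    t_half = float(t[after[0]] - t_le) if after.size else float("nan")
    t_half_over_t_max = t_half / t_max if t_max > 0 else float("nan")

    t100 = t_max + 100.0
    tracking_length = float(t[-1] - t[0])
    time_after_tmax = tracking_length - t_max
    final_intensity = float(s[-1])
    downslope = (
        (f_max - final_intensity) / time_after_tmax if time_after_tmax > 0 else float("nan")
    )

    if t100 <= t[-1]:
        f100 = float(np.interp(t100, t, s))
        fall100 = f_max - f100
        downslope100 = fall100 / 100.0
        complete = True
    else:
        f100 = fall100 = downslope100 = float("nan")
        complete = False

    return KineticProfile(
        baseline_gu=baseline,
        latency_end_time_s=t_le,
        latency_end_intensity_gu=i_le,
        f_max_gu=f_max,
        t_max_s=t_max,
        rise_gu=rise,
        time_to_rise_s=time_to_rise,
        upslope_gradient_gu_per_s=upslope,
        f_half_gu=f_half,
        t_half_s=t_half,
        t_half_over_t_max=t_half_over_t_max,
        t100_s=t100,
        f100_gu=f100,
        fall100_gu=fall100,
        downslope100_gu_per_s=downslope100,
        tracking_length_s=tracking_length,
        time_after_tmax_s=time_after_tmax,
        final_intensity_gu=final_intensity,
        downslope_gradient_gu_per_s=downslope,
        skew=float(_sps.skew(raw, bias=False)),
        kurtosis=float(_sps.kurtosis(raw, fisher=True, bias=False)),
        complete=complete,
        roi_label=trace.roi_label,
        tissue_class=trace.tissue_class,
    )


def fit_log_curve(
    trace: IntensityTrace,
    rise_threshold_gu: float = 5.0,
    baseline_window_s: float = 3.0,
    smoothing_window_s: float = 1.0,
) -> tuple[float, float, float]:
    """Least-squares logarithmic fit ``I = a·ln(t − t_latency_end + 1) + b``.

    Fitted over all non-gap samples from latency end onward.  Returns
    ``(a, b, r_squared)``; for a zero-variance response r² is 0 by
    convention.
    """
    t_le, _ = detect_latency_end(
        trace, rise_threshold_gu, baseline_window_s, smoothing_window_s
    )
    t, y = trace.non_gap()
    sel = t >= t_le
    t, y = t[sel], y[sel]
    if len(t) < 3:
        raise ValidationError("fewer than 3 usable samples for the logarithmic fit")
    x = np.log(t - t_le + 1.0)
    design = np.column_stack([x, np.ones_like(x)])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    a, b = float(coef[0]), float(coef[1])
    resid = y - design @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return a, b, r2


def group_mean_curves(
    traces_by_class: Mapping[str, Sequence[IntensityTrace]],
    resample_fps: float = 1.0,
    rise_threshold_gu: float = 5.0,
    baseline_window_s: float = 3.0,
    smoothing_window_s: float = 1.0,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-class mean FI(t) curve, aligned on each trace's latency end.

    Traces are shifted so t = 0 at latency end, linearly resampled onto a
    common grid, and averaged per class over gap-free samples.  The grid
    extends to the shortest post-latency coverage over all included traces,
    so every grid point averages every trace.
    """
    shifted: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    horizon = np.inf
    for cls, traces in traces_by_class.items():
        pairs = []
        for tr in traces:
            t_le, _ = detect_latency_end(
                tr, rise_threshold_gu, baseline_window_s, smoothing_window_s
            )
            t, y = tr.non_gap()
            sel = t >= t_le
            pairs.append((t[sel] - t_le, y[sel]))
            horizon = min(horizon, float(t[sel][-1] - t_le))
        if not pairs:
            warnings.warn(f"class '{cls}' has no traces; skipped", stacklevel=2)
            continue
        shifted[cls] = pairs
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    grid = np.arange(0.0, horizon + 0.5 / resample_fps, 1.0 / resample_fps)
    grid = grid[grid <= horizon]
    for cls, pairs in shifted.items():
        stack = np.vstack([np.interp(grid, tt, yy) for tt, yy in pairs])
        out[cls] = (grid, stack.mean(axis=0))
    return out


def profiles_to_frame(profiles: Iterable[KineticProfile]) -> pd.DataFrame:
    """One row per profile, columns exactly the KineticProfile fields."""
    return pd.DataFrame([p.to_dict() for p in profiles])
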
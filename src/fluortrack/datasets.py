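"""Reference clinical summary statistics bundled for cross-checking.

A published colorectal ICG-NIR endoscopy cohort reports per-group
(benign / cancer / control) means ± SD of the kinetic milestone variables
under two measurement regimes: manual 1 frame/s quantification (n = 5 /
3 / 8 region curves) and automated 30 fps tracker quantification
(n = 11 / 9 / 20).  The derived milestone cells of those tables are tied
to the primary cells by exact arithmetic identities (rise = F_max −
latency intensity, F_½max = rise/2, T_100 = T_max + 100 s, Fall_100 =
F_max − F_100, DownSlope_100 = Fall_100/100, time-to-rise = T_max −
latency time, time-after-T_max = tracking length − T_max), which pins
down the milestone definitions implemented in :mod:`fluortrack.kinetics`.
This module stores the printed group means and checks those identities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "reference_group_means",
    "milestone_identity_check",
    "EXCLUDED_CELLS",
]

# column order: benign, cancer, control
_MANUAL = {
    "n": (5, 3, 8),
    "latency_end_intensity_gu": ((16.4, 22.14), (11.33, 10.97), (17.25, 18.39)),
    "latency_end_time_s": ((15.87, 11.59), (12.1, 5.58), (21.23, 18.93)),
    "f_max_gu": ((165.8, 11.69), (202.0, 35.68), (169.63, 12.84)),
    "rise_gu": ((149.4, 23.46), (190.67, 41.43), (152.38, 29.31)),
    "t_max_s": ((60.95, 23.56), (351.82, 307.08), (84.0, 43.88)),
    "time_to_rise_s": ((45.08, 30.56), (339.73, 312.21), (62.77, 53.8)),
    "upslope_gradient_gu_per_s": ((5.5, 4.34), (1.51, 1.89), (4.7, 4.43)),
    "f_half_gu": ((74.7, 11.73), (95.33, 20.71), (76.19, 14.65)),
    "t_half_s": ((12.77, 12.77), (69.92, 67.88), (14.01, 11.7)),
    "t_half_over_t_max": ((0.2, 0.18), (0.31, 0.32), (0.2, 0.21)),
    "t100_s": ((160.95, 23.56), (451.82, 307.08), (184.0, 43.88)),
    "f100_gu": ((133.0, 11.85), (143.33, 39.8), (121.13, 28.39)),
    "fall100_gu": ((32.8, 7.73), (58.67, 74.23), (48.5, 20.17)),
    "downslope100_gu_per_s": ((0.33, 0.08), (0.59, 0.74), (0.49, 0.2)),
    "tracking_length_s": ((1767.6, 154.21), (2134.67, 153.44), (1902.63, 240.72)),
    "time_after_tmax_s": ((1706.65, 166.86), (1782.84, 460.45), (1818.62, 235.59)),
    "final_intensity_gu": ((46.0, 29.56), (64.33, 16.86), (38.0, 26.94)),
    "downslope_gradient_gu_per_s": ((0.07, 0.03), (0.08, 0.02), (0.07, 0.02)),
    "kurtosis": ((0.73, 3.32), (0.62, 1.57), (-0.17, 1.23)),
    "skew": ((-0.29, 0.87), (0.17, 0.18), (0.19, 0.46)),
}

_TRACKER = {
    "n": (11, 9, 20),
    "latency_end_intensity_gu": ((14.62, 15.14), (15.91, 10.23), (19.95, 17.24)),
    "latency_end_time_s": ((11.54, 14.35), (26.43, 29.59), (17.91, 19.85)),
    "f_max_gu": ((153.22, 23.37), (136.43, 22.61), (144.82, 29.37)),
    "rise_gu": ((138.59, 27.89), (120.52, 25.93), (124.87, 31.45)),
    "t_max_s": ((83.56, 89.18), (190.18, 138.8), (172.62, 65.88)),
    "time_to_rise_s": ((72.02, 92.3), (163.75, 129.01), (154.71, 60.51)),
    "upslope_gradient_gu_per_s": ((4.18, 3.39), (1.73, 1.66), (4.44, 3.48)),
    "f_half_gu": ((69.3, 13.95), (60.26, 12.96), (62.43, 15.72)),
    "t_half_s": ((11.8, 6.74), (11.24, 6.28), (13.19, 11.8)),
    "t_half_over_t_max": ((0.21, 0.11), (0.15, 0.15), (0.24, 0.13)),
    "t100_s": ((183.56, 89.18), (290.18, 138.81), (172.62, 65.88)),
    "f100_gu": ((109.36, 30.77), (111.37, 19.9), (106.98, 34.68)),
    "fall100_gu": ((43.86, 18.67), (25.07, 16.15), (37.84, 18.52)),
    "downslope100_gu_per_s": ((0.44, 0.19), (0.25, 0.16), (0.38, 0.19)),
    "tracking_length_s": ((612.19, 354.53), (595.0, 320.69), (598.09, 334.76)),
    "time_after_tmax_s": ((528.63, 339.73), (404.82, 372.37), (525.47, 368.56)),
    "final_intensity_gu": ((82.75, 48.13), (94.0, 31.18), (78.15, 43.13)),
    "downslope_gradient_gu_per_s": ((0.16, 0.1), (0.2, 0.22), (0.21, 0.26)),
    "kurtosis": ((5.12, 6.77), (6.51, 7.92), (2.68, 4.17)),
    "skew": ((-0.89, 1.72), (-1.69, 1.17), (-0.41, 1.37)),
}

_GROUPS = ("benign", "cancer", "control")

#: Cells excluded from the identity check: in the tracker table the control
#: column's T_max is internally inconsistent (its T_100 equals T_max rather
#: than T_max + 100 s, while time-after-T_max is consistent with a T_max of
#: 100 s less), so the two identities that consume it cannot both hold as
#: printed.
EXCLUDED_CELLS = {("tracker", "control", "t100_s"), ("tracker", "control", "time_after_tmax_s")}


def reference_group_means(regime: str = "tracker") -> pd.DataFrame:
    """Published group means ± SD as a DataFrame.

    ``regime`` is ``'manual'`` (1 fps quantification) or ``'tracker'``
    (30 fps automated tracking).
    """
    src = {"manual": _MANUAL, "tracker": _TRACKER}[regime]
    rows = {}
    for var, cells in src.items():
        if var == "n":
            continue
        row = {}
        for g, (mean, sd) in zip(_GROUPS, cells):
            row[f"{g}_mean"] = mean
            row[f"{g}_sd"] = sd
        rows[var] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.attrs["n_per_group"] = dict(zip(_GROUPS, src["n"]))
    return df


def _printed_decimals(x: float) -> int:
    s = np.format_float_positional(x, trim="-")
    return len(s.split(".")[1]) if "." in s else 0


def milestone_identity_check() -> pd.DataFrame:
    """Apply the milestone definitions to the reference tables' primary cells.

    For every group column of both regimes, the derived cells (rise,
    F_½max, time-to-rise, T_100, Fall_100, DownSlope_100,
    time-after-T_max) are recomputed from the primary cells and compared
    with the printed value; ``tolerance`` is ±0.01 beyond half an ulp of
    the printed precision.  Returns one row per checked cell with the
    residual and a pass flag.
    """
    identities = [
        ("rise_gu", lambda v: v["f_max_gu"] - v["latency_end_intensity_gu"]),
        ("f_half_gu", lambda v: v["rise_gu"] / 2.0),
        ("time_to_rise_s", lambda v: v["t_max_s"] - v["latency_end_time_s"]),
        ("t100_s", lambda v: v["t_max_s"] + 100.0),
        ("fall100_gu", lambda v: v["f_max_gu"] - v["f100_gu"]),
        ("downslope100_gu_per_s", lambda v: v["fall100_gu"] / 100.0),
        ("time_after_tmax_s", lambda v: v["tracking_length_s"] - v["t_max_s"]),
    ]
    records = []
    for regime, src in (("manual", _MANUAL), ("tracker", _TRACKER)):
        for gi, group in enumerate(_GROUPS):
            means = {var: cells[gi][0] for var, cells in src.items() if var != "n"}
            for var, fn in identities:
                if (regime, group, var) in EXCLUDED_CELLS:
                    continue
                printed = means[var]
                computed = fn(means)
                tol = 0.01 + 0.5 * 10.0 ** (-_printed_decimals(printed))
                records.append(
                    {
                        "regime": regime,
                        "group": group,
                        "variable": var,
                        "printed": printed,
                        "computed": computed,
                        "residual": computed - printed,
                        "tolerance": tol,
                        "ok": abs(computed - printed) <= tol,
                    }
                )
    return pd.DataFrame.from_records(records)
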
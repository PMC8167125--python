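"""Nonparametric group comparison of kinetic profiles.

Builds the benign / cancer / control summary table (mean ± SD per group)
and runs the three tests used throughout: Kruskal–Wallis across the three
groups, pairwise Mann–Whitney U, and the Wilcoxon signed-rank test for
paired series.  Exact small-sample p-values are used where the sample size
permits, with tie-corrected asymptotic approximations beyond.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import ValidationError
from .kinetics import KineticProfile

__all__ = [
    "mann_whitney_u",
    "kruskal_wallis",
    "wilcoxon_signed_rank",
    "GroupTable",
    "build_group_table",
    "TABLE_VARIABLES",
]

# Exact enumeration is feasible and ulcer-free up to this combined n.
_EXACT_N = 12


def mann_whitney_u(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; U reported for ``sample_a``.

    Exact p by enumeration when the combined n is at most 12 and the data
    are tie-free; normal approximation with tie correction (and continuity
    correction) otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= _EXACT_N and no_ties) else "asymptotic"
    res = _sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal–Wallis H with tie correction; p from chi² with g−1 df.

    All-identical data across all groups gives H = 0, p = 1 by convention.
    """
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in arrays):
        raise ValidationError("all groups must be non-empty")
    if np.unique(np.concatenate(arrays)).size == 1:
        return 0.0, 1.0
    res = _sps.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(
    paired_a: Sequence[float], paired_b: Sequence[float]
) -> tuple[float, float, bool]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; exact p for at most 12 non-zero pairs
    (tie-free ranks), normal approximation beyond.  Returns
    ``(W, p, all_zero)`` — when every difference is zero, p = 1 by
    convention and the flag is set.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.size != b.size or a.size == 0:
        raise ValidationError("paired samples must be non-empty and of equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0, True
    no_rank_ties = np.unique(np.abs(d)).size == d.size
    method = "exact" if (d.size <= _EXACT_N and no_rank_ties) else "approx"
    res = _sps.wilcoxon(d, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), False


#: Table rows in display order: (profile field, row label).
TABLE_VARIABLES: list[tuple[str, str]] = [
    ("latency_end_intensity_gu", "Intensity at the end of latency (g.u.)"),
    ("latency_end_time_s", "Time at end of latency (s)"),
    ("f_max_gu", "F_max (g.u.)"),
    ("rise_gu", "Intensity rise from end of latency (g.u.)"),
    ("t_max_s", "T_max (s)"),
    ("time_to_rise_s", "Time to rise from end of latency (s)"),
    ("upslope_gradient_gu_per_s", "Upslope gradient (g.u./s)"),
    ("f_half_gu", "F_1/2max (g.u.)"),
    ("t_half_s", "T_1/2max (s)"),
    ("t_half_over_t_max", "T_1/2max / T_max"),
    ("t100_s", "T_100 (s)"),
    ("f100_gu", "F_100 (g.u.)"),
    ("fall100_gu", "Fall_100 (g.u.)"),
    ("downslope100_gu_per_s", "DownSlope_100 gradient (g.u./s)"),
    ("tracking_length_s", "Length of tracking (s)"),
    ("time_after_tmax_s", "Time following T_max (s)"),
    ("final_intensity_gu", "Final intensity (g.u.)"),
    ("downslope_gradient_gu_per_s", "Downslope gradient (g.u./s)"),
    ("kurtosis", "Kurtosis"),
    ("skew", "Skew"),
]

_GROUPS = ("benign", "cancer", "control")


@dataclass
class GroupTable:
    """Per-variable group summary with omnibus and pairwise p-values."""

    table: pd.DataFrame
    n_per_group: dict[str, int]
    notes: list[str] = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=True)


def build_group_table(
    profiles_by_group: Mapping[str, Sequence[KineticProfile]],
    alpha: float = 0.05,
    fdr_correction: bool = False,
) -> GroupTable:
    """Summary table over the kinetic variables for benign/cancer/control groups.

    For every variable: per-group mean and sample SD (n−1 denominator),
    the Kruskal–Wallis p across all present groups, and the three pairwise
    Mann–Whitney p-values.  Groups with a single profile get SD reported
    as 0 with a note and tests are skipped for that variable; a missing
    group leaves its column blank.  ``fdr_correction`` adds
    Benjamini–Hochberg adjusted Kruskal–Wallis p-values.
    """
    notes: list[str] = []
    n_per_group = {g: len(profiles_by_group.get(g, ())) for g in _GROUPS}
    rows = []
    for field_name, label in TABLE_VARIABLES:
        row: dict[str, float | str] = {"variable": label}
        samples: dict[str, np.ndarray] = {}
        for g in _GROUPS:
            profs = profiles_by_group.get(g, ())
            vals = np.array(
                [getattr(p, field_name) for p in profs], dtype=float
            )
            missing = np.isnan(vals).sum()
            vals = vals[~np.isnan(vals)]
            if missing:
                notes.append(
                    f"{label}: {missing} incomplete profile(s) omitted in group '{g}'"
                )
            if vals.size == 0:
                row[f"{g}_mean"] = np.nan
                row[f"{g}_sd"] = np.nan
                row[f"{g}_n"] = 0
                continue
            row[f"{g}_mean"] = float(vals.mean())
            if vals.size == 1:
                row[f"{g}_sd"] = 0.0
                notes.append(f"{label}: SD undefined for n=1 in group '{g}', reported as 0")
            else:
                row[f"{g}_sd"] = float(vals.std(ddof=1))
            row[f"{g}_n"] = int(vals.size)
            samples[g] = vals
        testable = [g for g in _GROUPS if samples.get(g) is not None and samples[g].size >= 2]
        if len(testable) >= 2:
            _, kw_p = kruskal_wallis([samples[g] for g in testable])
        else:
            kw_p = np.nan
        row["kruskal_wallis_p"] = kw_p
        for ga, gb, col in (
            ("cancer", "control", "p_cancer_vs_control"),
            ("benign", "cancer", "p_benign_vs_cancer"),
            ("benign", "control", "p_benign_vs_control"),
        ):
            if ga in testable and gb in testable:
                _, p = mann_whitney_u(samples[ga], samples[gb])
                row[col] = p
            else:
                row[col] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows).set_index("variable")
    table["significant"] = table["kruskal_wallis_p"] < alpha
    if fdr_correction:
        pvals = table["kruskal_wallis_p"].to_numpy()
        ok = np.isfinite(pvals)
        adj = np.full_like(pvals, np.nan)
        if ok.any():
            adj[ok] = _sps.false_discovery_control(pvals[ok], method="bh")
        table["kruskal_wallis_p_bh"] = adj
    return GroupTable(table=table, n_per_group=n_per_group, notes=notes)
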
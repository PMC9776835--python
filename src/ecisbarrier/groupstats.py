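"""Group comparisons and LDH cytotoxicity analysis.

Endpoint and AUC summaries are compared across treatment arms with a
one-way ANOVA followed by either the Tukey HSD test (the default, matching
how multi-arm barrier studies are usually reported) or Bonferroni-corrected
pairwise t-tests.  Significance is annotated with the conventional star
ladder (* p <= 0.05 down to **** p <= 0.0001, boundaries closed on the
significant side).

LDH release is quantified as the background-corrected absorbance
A490 - A680; group analysis normalizes the corrected signal to the vehicle
mean per timepoint before testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "DegenerateDataError",
    "one_way_anova",
    "tukey_hsd",
    "bonferroni_ttests",
    "star_label",
    "ldh_signal",
    "ldh_group_analysis",
    "compare_groups",
    "significant_vs_vehicle",
]


class DegenerateDataError(ValueError):
    """Raised when groups carry no within-group variance to test against."""


@dataclass(frozen=True)
class GroupSummary:
    """Per-well scalar values (an endpoint or an AUC) for one group."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError(f"group {self.label!r} needs >= 2 values for inference")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class ComparisonResult:
    """ANOVA omnibus result plus a pairwise comparison table.

    ``pairs`` has columns: group_a, group_b, estimate (mean difference
    a - b), p_raw, p_adj, stars.
    """

    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    method: str
    pairs: pd.DataFrame


def _check_groups(groups: list[GroupSummary]) -> None:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    labels = [g.label for g in groups]
    if len(set(labels)) != len(labels):
        raise ValueError("group labels must be unique")
    if all(np.ptp(g.values) == 0 for g in groups):
        raise DegenerateDataError("zero within-group variance in every group")


def one_way_anova(groups: list[GroupSummary]) -> tuple[float, float]:
    """Classical one-way F test with (k-1, N-k) degrees of freedom."""
    _check_groups(groups)
    f, p = stats.f_oneway(*[g.values for g in groups])
    return float(f), float(p)


def star_label(p: float) -> str:
    """Map a p value to the printed star ladder (``ns`` above 0.05)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p value {p} outside [0, 1]")
    if p <= 0.0001:
        return "****"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def _pair_table(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "estimate",
                                     "p_raw", "p_adj", "stars"])
    return df


def tukey_hsd(groups: list[GroupSummary]) -> pd.DataFrame:
    """All-pairs comparison with studentized-range (Tukey HSD) adjusted p."""
    _check_groups(groups)
    res = stats.tukey_hsd(*[g.values for g in groups])
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        a, b = groups[i], groups[j]
        p_raw = float(stats.ttest_ind(a.values, b.values, equal_var=True).pvalue)
        p_adj = float(min(1.0, res.pvalue[i, j]))
        rows.append(dict(group_a=a.label, group_b=b.label,
                         estimate=float(a.values.mean() - b.values.mean()),
                         p_raw=p_raw, p_adj=p_adj, stars=star_label(p_adj)))
    return _pair_table(rows)


def bonferroni_ttests(groups: list[GroupSummary], *, welch: bool = False) -> pd.DataFrame:
    """All-pairs two-tailed t-tests with Bonferroni-adjusted p (capped at 1).

    Pooled-variance t by default; set ``welch=True`` for unequal variances.
    """
    _check_groups(groups)
    pairs = list(combinations(range(len(groups)), 2))
    m = len(pairs)
    rows = []
    for i, j in pairs:
        a, b = groups[i], groups[j]
        p_raw = float(stats.ttest_ind(a.values, b.values, equal_var=not welch).pvalue)
        p_adj = min(1.0, m * p_raw)
        rows.append(dict(group_a=a.label, group_b=b.label,
                         estimate=float(a.values.mean() - b.values.mean()),
                         p_raw=p_raw, p_adj=p_adj, stars=star_label(p_adj)))
    return _pair_table(rows)


def compare_groups(groups: list[GroupSummary], posthoc: str = "tukey",
                   **kw) -> ComparisonResult:
    """ANOVA followed by the chosen post-hoc family."""
    f, p = one_way_anova(groups)
    if posthoc == "tukey":
        pairs = tukey_hsd(groups)
    elif posthoc == "bonferroni":
        pairs = bonferroni_ttests(groups, **kw)
    else:
        raise ValueError("posthoc must be 'tukey' or 'bonferroni'")
    n_total = sum(g.n for g in groups)
    return ComparisonResult(f_statistic=f, p_value=p,
                            df_between=len(groups) - 1,
                            df_within=n_total - len(groups),
                            method=posthoc, pairs=pairs)


def ldh_signal(a490, a680):
    """Background-corrected LDH absorbance, ``A490 - A680``.

    Vectorized; values <= 0 can occur for blank-level noise and are returned
    as-is (callers may flag them, they are never clamped).
    """
    a490 = np.asarray(a490, dtype=float)
    a680 = np.asarray(a680, dtype=float)
    if np.any(a490 < 0) or np.any(a680 < 0):
        raise ValueError("absorbances must be non-negative")
    out = a490 - a680
    return out if out.ndim else float(out)


def ldh_group_analysis(readings: pd.DataFrame, vehicle_label: str = "vehicle",
                       posthoc: str = "tukey") -> dict[float, ComparisonResult]:
    """Vehicle-normalized LDH comparison per timepoint.

    ``readings`` must have columns well, group, timepoint_h, a490, a680.
    For each timepoint the corrected signal is divided by the vehicle mean,
    then compared across groups (ANOVA + post hoc).  Returns a mapping
    timepoint -> ComparisonResult whose pair table contains every group
    pair; rows against the vehicle carry the cytotoxicity verdicts.
    """
    required = {"well", "group", "timepoint_h", "a490", "a680"}
    missing = required - set(readings.columns)
    if missing:
        raise ValueError(f"LDH table missing columns: {sorted(missing)}")
    out: dict[float, ComparisonResult] = {}
    for tp, sub in readings.groupby("timepoint_h"):
        if vehicle_label not in set(sub["group"]):
            raise ValueError(f"vehicle group {vehicle_label!r} missing at {tp} h")
        corrected = ldh_signal(sub["a490"].to_numpy(), sub["a680"].to_numpy())
        sub = sub.assign(corrected=corrected)
        vmean = sub.loc[sub["group"] == vehicle_label, "corrected"].mean()
        if vmean == 0:
            raise DegenerateDataError(f"vehicle mean signal is zero at {tp} h")
        sub = sub.assign(norm=sub["corrected"] / vmean)
        labels = [vehicle_label] + sorted(set(sub["group"]) - {vehicle_label})
        groups = [GroupSummary(g, sub.loc[sub["group"] == g, "norm"].to_numpy())
                  for g in labels]
        out[float(tp)] = compare_groups(groups, posthoc=posthoc)
    return out


def significant_vs_vehicle(result: ComparisonResult,
                           vehicle_label: str = "vehicle",
                           alpha: float = 0.05) -> dict[str, bool]:
    """Which groups differ from vehicle at level ``alpha`` (adjusted p)."""
    flags: dict[str, bool] = {}
    for row in result.pairs.itertuples(index=False):
        if vehicle_label in (row.group_a, row.group_b):
            other = row.group_b if row.group_a == vehicle_label else row.group_a
            flags[other] = bool(row.p_adj <= alpha)
    return flags
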
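"""Group comparisons: per-row Welch t tests with Holm-Sidak correction.

Each row of a :class:`GroupedMeasurements` is tested independently with an
unequal-variance (Welch) two-sample t test; the family of raw p values is
then corrected with the Holm-Sidak step-down procedure at the chosen alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 0.05


@dataclass
class GroupedMeasurements:
    """Rows of (label, group A values, group B values)."""

    rows: list[tuple[str, np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        labels = [label for label, _, _ in self.rows]
        if len(set(labels)) != len(labels):
            raise ValueError("row labels must be unique")
        normalized = []
        for label, a, b in self.rows:
            a = np.asarray(a, dtype=float)
            b = np.asarray(b, dtype=float)
            if a.size < 2 or b.size < 2:
                raise ValueError(
                    f"row {label!r}: each group needs >= 2 values "
                    f"(got {a.size} and {b.size})"
                )
            normalized.append((label, a, b))
        self.rows = normalized


@dataclass
class TestReport:
    """Per-row test results plus the metadata of the procedure used."""

    table: pd.DataFrame
    alpha: float
    method: str = "welch_t + holm_sidak"


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t test.

    Returns ``(t, df, p)`` with Satterthwaite degrees of freedom and a
    two-tailed p value.  Degenerate inputs follow fixed conventions: if both
    groups have zero variance, identical means give ``(0, n-2, 1)`` and
    differing means give exact separation ``(+-inf, n-2, 0)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    m1, m2 = a.mean(), b.mean()
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    n1, n2 = a.size, b.size
    if v1 == 0 and v2 == 0:
        df = float(n1 + n2 - 2)
        if m1 == m2:
            return 0.0, df, 1.0
        return math.copysign(math.inf, m1 - m2), df, 0.0
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(t), float(df), p


def holm_sidak(
    p_values: Sequence[float], alpha: float = DEFAULT_ALPHA
) -> tuple[np.ndarray, np.ndarray]:
    """Holm-Sidak step-down multiple-testing correction.

    With m hypotheses sorted by ascending p, hypothesis i (1-based) is
    rejected iff p_(i) <= 1 - (1 - alpha)^(1 / (m - i + 1)) and every earlier
    hypothesis was rejected.  The adjusted p value is the running maximum of
    1 - (1 - p_(i))^(m - i + 1), clipped to [0, 1].

    Returns ``(significant, p_adjusted)`` in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    significant = np.zeros(m, dtype=bool)
    p_adj = np.empty(m, dtype=float)
    running_max = 0.0
    rejecting = True
    for rank, idx in enumerate(order):
        remaining = m - rank
        step_alpha = 1.0 - (1.0 - alpha) ** (1.0 / remaining)
        if rejecting and p[idx] <= step_alpha:
            significant[idx] = True
        else:
            rejecting = False
        adj = 1.0 - (1.0 - p[idx]) ** remaining
        running_max = max(running_max, min(adj, 1.0))
        p_adj[idx] = running_max
    return significant, p_adj


def compare_groups(
    data: GroupedMeasurements, alpha: float = DEFAULT_ALPHA
) -> TestReport:
    """Welch t test per row, Holm-Sidak across rows, means +/- SD reported."""
    stats_rows = []
    for label, a, b in data.rows:
        t, df, p = welch_t(a, b)
        stats_rows.append(
            {
                "row": label,
                "t": t,
                "df": df,
                "p": p,
                "mean_a": float(a.mean()),
                "sd_a": float(a.std(ddof=1)),
                "mean_b": float(b.mean()),
                "sd_b": float(b.std(ddof=1)),
            }
        )
    frame = pd.DataFrame(stats_rows)
    significant, p_adj = holm_sidak(frame["p"].to_numpy(), alpha=alpha)
    frame["p_adj"] = p_adj
    frame["significant"] = significant
    frame = frame[
        ["row", "t", "df", "p", "p_adj", "significant",
         "mean_a", "sd_a", "mean_b", "sd_b"]
    ]
    return TestReport(table=frame, alpha=alpha)


def grouped_from_frame(
    frame: pd.DataFrame,
    group_col: str,
    value_cols: Sequence[str],
) -> GroupedMeasurements:
    """Build a :class:`GroupedMeasurements` from a tidy per-subject table.

    ``group_col`` must contain exactly two group labels; each entry of
    ``value_cols`` becomes one row of the comparison (groups ordered by
    sorted label).
    """
    groups = sorted(frame[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError(
            f"expected exactly 2 groups in column {group_col!r}, got {groups}"
        )
    ga, gb = groups
    rows = []
    for col in value_cols:
        a = frame.loc[frame[group_col] == ga, col].dropna().to_numpy(dtype=float)
        b = frame.loc[frame[group_col] == gb, col].dropna().to_numpy(dtype=float)
        rows.append((col, a, b))
    return GroupedMeasurements(rows=rows)
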
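"""Inter-row heterogeneity statistics: role aggregation, percent differences,
Duncan's multiple range test and PAR-trait regressions.

The trial reports row-wise metrics collapsed to three roles per strip — the
eastern border row, the western border row, and the mean of the interior
("middle") rows — and summarises west-east contrasts as percentages computed
from the ratio of across-treatment means, truncated (not rounded) to one
decimal.  Mean separation uses Duncan's multiple range test at alpha = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import RowLayout

__all__ = [
    "RowAggregate",
    "LetterDisplay",
    "FitResult",
    "percent_diff_truncated",
    "aggregate_rows",
    "duncan_mrt",
    "linear_fit",
]

ROLES = ("east", "middle", "west")


@dataclass(frozen=True)
class RowAggregate:
    treatment: str
    role: str
    metric: str
    value: float
    n: int


@dataclass(frozen=True)
class LetterDisplay:
    """Compact letter display: groups sharing a letter are not separable."""

    groups: tuple[str, ...]      # ordered by descending mean
    means: tuple[float, ...]
    letters: tuple[str, ...]
    alpha: float

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.groups, self.letters))


@dataclass(frozen=True)
class FitResult:
    slope: float
    intercept: float
    r2: float
    n: int


def percent_diff_truncated(west_mean: float, east_mean: float) -> float:
    """West-over-east percent difference, truncated toward zero to one decimal.

    ``100 * (west - east) / east``, with the trial's apparent convention of
    truncating (6.589 -> 6.5) rather than rounding.
    """
    if east_mean <= 0:
        raise ValueError(f"reference (east) mean must be positive, got {east_mean}")
    pct = 100.0 * (west_mean - east_mean) / east_mean
    return math.trunc(pct * 10.0) / 10.0


def aggregate_rows(records: pd.DataFrame, layout: list[RowLayout],
                   value_col: str = "value") -> pd.DataFrame:
    """Collapse a per-row metric table to east/middle/west role values.

    ``records`` needs columns (row_index, ``value_col``).  Returns one row per
    role plus two whole-treatment summaries: ``overall_role`` (unweighted mean
    of the three role values) and ``overall_row`` (mean over rows, i.e.
    row-count weighted).  Replicates within a row are averaged first.
    """
    roles = {r.row_index: r.role for r in layout}
    unknown = set(records["row_index"]) - set(roles)
    if unknown:
        raise ValueError(f"row indices {sorted(unknown)} not present in the layout")
    per_row = records.groupby("row_index")[value_col].mean()
    missing = set(roles) - set(per_row.index)
    if missing:
        raise ValueError(f"no records for layout rows {sorted(missing)}")
    by_role = {
        role: float(per_row[[i for i, r in roles.items() if r == role]].mean())
        for role in ROLES
    }
    n_by_role = {role: sum(1 for r in roles.values() if r == role) for role in ROLES}
    out = [{"role": role, "value": by_role[role], "n_rows": n_by_role[role]} for role in ROLES]
    out.append({"role": "overall_role", "value": float(np.mean(list(by_role.values()))),
                "n_rows": len(roles)})
    out.append({"role": "overall_row", "value": float(per_row.mean()), "n_rows": len(roles)})
    return pd.DataFrame(out)


def _duncan_ranges(n_means: int, df_error: int, alpha: float) -> np.ndarray:
    """Critical studentized ranges at Duncan's protected levels.

    For a span of ``p`` ordered means the protected level is
    ``alpha_p = 1 - (1 - alpha)**(p - 1)``; the critical point is the
    studentized-range quantile at that level with the pooled error df.
    """
    p = np.arange(2, n_means + 1)
    alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
    return stats.studentized_range.ppf(1.0 - alpha_p, p, df_error)


def duncan_mrt(samples: dict[str, np.ndarray], alpha: float = 0.05) -> LetterDisplay:
    """Duncan's multiple range test with a compact letter display.

    ``samples`` maps group label -> replicate values (>= 2 each).  The error
    term is pooled from the one-way layout.  The letter display is assembled
    by the standard sweep over the means sorted in descending order, so
    groups lying between two groups that share a letter share it too.
    """
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    groups = list(samples)
    data = {g: np.asarray(v, dtype=float) for g, v in samples.items()}
    for g, v in data.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has {v.size} replicate(s); need at least 2")
    k = len(groups)
    n_total = sum(v.size for v in data.values())
    df_err = n_total - k
    mse = sum(((v - v.mean()) ** 2).sum() for v in data.values()) / df_err
    order = sorted(groups, key=lambda g: -data[g].mean())
    means = np.array([data[g].mean() for g in order])
    ns = np.array([data[g].size for g in order])

    if mse == 0.0:
        distinct = ~np.isclose(means[:, None], means[None, :])
    else:
        crit = _duncan_ranges(k, df_err, alpha)  # spans p = 2..k
        distinct = np.zeros((k, k), dtype=bool)
        # Duncan's protection: a span is declared significant only if every
        # enclosing span is; sweeping from the widest span down enforces it.
        sig_span = np.ones((k, k), dtype=bool)
        for span in range(k, 1, -1):
            for i in range(0, k - span + 1):
                j = i + span - 1
                nh = stats.hmean(ns[i:j + 1])
                lsr = crit[span - 2] * math.sqrt(mse / nh)
                enclosing_ok = (i == 0 or sig_span[i - 1, j]) and \
                    (j == k - 1 or sig_span[i, j + 1])
                sig = (means[i] - means[j] > lsr) and enclosing_ok
                sig_span[i, j] = sig
                distinct[i, j] = distinct[j, i] = sig

    # letter sweep: one letter per maximal run of mutually non-distinct groups
    runs = []
    for i in range(k):
        js = [j for j in range(i, k) if not distinct[i, j]]
        runs.append((i, max(js) if js else i))
    maximal = [r for r in runs if not any(o != r and o[0] <= r[0] and r[1] <= o[1] for o in runs)]
    letters = ["" for _ in range(k)]
    for letter_idx, (i, j) in enumerate(sorted(set(maximal))):
        ch = chr(ord("a") + letter_idx)
        for m in range(i, j + 1):
            letters[m] += ch
    return LetterDisplay(groups=tuple(order), means=tuple(means), letters=tuple(letters),
                         alpha=alpha)


def linear_fit(x: np.ndarray, y: np.ndarray) -> FitResult:
    """Ordinary least squares fit of trait/yield on accumulated PAR."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance; the regression is undefined")
    if np.ptp(y) == 0:
        return FitResult(slope=0.0, intercept=float(y[0]), r2=0.0, n=x.size)
    res = stats.linregress(x, y)
    return FitResult(slope=float(res.slope), intercept=float(res.intercept),
                     r2=float(res.rvalue ** 2), n=x.size)
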
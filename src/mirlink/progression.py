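"""Composite tumor-progression groups linking the two cohorts.

A progression group is a unique combination of AJCC T, N, M stage and
numeric tumor grade.  Group membership is the only bridge between the
small expression cohort and the large registry cohort: group-mean
expression on one side is regressed against group-mean (restricted mean)
survival on the other.  Leverage diagnostics guard the group-level
regression against any single group dominating the fit.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm


class UngroupableError(ValueError):
    """A patient whose T/N/M/grade components are missing or out of range."""


T_RANGE = range(1, 5)
N_RANGE = range(0, 4)
M_RANGE = range(0, 2)
G_RANGE = range(1, 5)


@dataclass(frozen=True, order=True)
class ProgressionGroupKey:
    t_stage: int
    n_stage: int
    m_stage: int
    grade: int

    def __str__(self) -> str:
        return f"T{self.t_stage}N{self.n_stage}M{self.m_stage}G{self.grade}"

    @property
    def severity(self) -> int:
        """Monotone composite progression score (T-1) + N + M + (G-1)."""
        return (self.t_stage - 1) + self.n_stage + self.m_stage + (self.grade - 1)


def make_group_key(t, n, m, g) -> ProgressionGroupKey:
    """Build the canonical group key; missing or out-of-range components raise."""
    vals = []
    for name, v, rng in (("t_stage", t, T_RANGE), ("n_stage", n, N_RANGE),
                         ("m_stage", m, M_RANGE), ("grade", g, G_RANGE)):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise UngroupableError(f"missing {name}")
        iv = int(v)
        if iv != v or iv not in rng:
            raise UngroupableError(f"{name}={v!r} outside {rng.start}..{rng.stop - 1}")
        vals.append(iv)
    return ProgressionGroupKey(*vals)


def group_keys_for_table(df, log=None):
    """Group keys for each row of a clinical table; ungroupable rows get None.

    ``df`` needs columns t_stage, n_stage, m_stage, grade.  Returns a list
    aligned with df rows; the number of exclusions is appended to ``log``
    (a list of strings) when given.
    """
    keys = []
    n_dropped = 0
    for t, n, m, g in zip(df["t_stage"], df["n_stage"], df["m_stage"], df["grade"]):
        try:
            keys.append(make_group_key(t, n, m, g))
        except UngroupableError:
            keys.append(None)
            n_dropped += 1
    if log is not None and n_dropped:
        log.append(f"excluded {n_dropped} ungroupable patients (missing/out-of-range T/N/M/grade)")
    return keys


def common_groups(
    keys_a: Iterable[ProgressionGroupKey],
    keys_b: Iterable[ProgressionGroupKey],
    min_per_side: int | tuple[int, int] = 1,
) -> list[ProgressionGroupKey]:
    """Groups represented with at least ``min_per_side`` members in both cohorts.

    ``min_per_side`` may be a single count or an (a, b) pair for asymmetric
    thresholds (e.g. 1 in the small expression cohort, 10 in the registry).
    Result is sorted canonically on (T, N, M, G). Symmetric in its inputs
    when a scalar threshold is used.
    """
    if isinstance(min_per_side, tuple):
        min_a, min_b = min_per_side
    else:
        min_a = min_b = min_per_side
    if min_a < 1 or min_b < 1:
        raise ValueError("min_per_side must be >= 1")
    count_a = Counter(k for k in keys_a if k is not None)
    count_b = Counter(k for k in keys_b if k is not None)
    return sorted(
        k for k, c in count_a.items() if c >= min_a and count_b.get(k, 0) >= min_b
    )


@dataclass(frozen=True)
class LeverageReport:
    groups: list
    leverage: np.ndarray
    cooks_distance: np.ndarray
    flagged: np.ndarray
    flag_rule: str

    @property
    def any_flagged(self) -> bool:
        return bool(np.any(self.flagged))


def leverage_diagnostics(
    x: Sequence[float],
    y: Sequence[float],
    groups: Sequence | None = None,
    cooks_threshold: float | None = None,
) -> LeverageReport:
    """Influence diagnostics for the group-level simple linear regression.

    Hat values and Cook's distances come from the fitted OLS influence
    matrix; a group is flagged when its Cook's distance exceeds the
    threshold (default 4/n).  Leverages sum to 2 (intercept + slope).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 groups for leverage diagnostics")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: constant predictor")
    n = x.size
    threshold = 4.0 / n if cooks_threshold is None else cooks_threshold
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    infl = fit.get_influence()
    hat = infl.hat_matrix_diag
    cooks = infl.cooks_distance[0]
    flagged = cooks > threshold
    return LeverageReport(
        groups=list(groups) if groups is not None else list(range(n)),
        leverage=hat,
        cooks_distance=cooks,
        flagged=flagged,
        flag_rule=f"cooks_distance > {threshold:.6g}",
    )
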
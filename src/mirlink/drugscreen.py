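"""Cell-line drug-screen validation engines.

Three independent checks of a selection verdict against in-vitro data:
trichotomization of drug activities into sensitive / partial / resistant
lines (mean +/- 0.5 SD, with dose-window overrides), differential
expression between the resistant and sensitive arms, and per-endpoint
linear regression of expression on activity for GI50/TGI/LC50-style
panels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SENSITIVE, PARTIAL, RESISTANT = "sensitive", "partial", "resistant"


@dataclass(frozen=True)
class DrugActivityVector:
    """Activity of one drug across cell lines at one endpoint.

    ``min_dose``/``max_dose`` bound the tested concentration window for
    IC50/EC50-type endpoints; values escaping the window are classified
    by the override rule rather than by the mean +/- 0.5 SD bands.
    """

    values: pd.Series  # cell_line -> activity
    endpoint: str  # GI50 / TGI / LC50 / IC50 / EC50 / ln_IC50 / ln_EC50
    min_dose: float | None = None
    max_dose: float | None = None

    def __post_init__(self):
        lo, hi = self.min_dose, self.max_dose
        if lo is not None and hi is not None and not lo < hi:
            raise ValueError("min_dose must be below max_dose")

    @property
    def informative(self) -> pd.Series:
        return self.values[np.isfinite(self.values.astype(float))]


def classify_drug_response(
    activity: DrugActivityVector,
    include_bounded_in_stats: bool = False,
) -> pd.Series:
    """Label each informative cell line sensitive / partial / resistant.

    Lines above the maximum tested dose are resistant and lines below the
    minimum dose are sensitive, regardless of the distribution.  The
    remaining lines are split at mean +/- 0.5 * sample SD of their values
    (by default excluding the dose-overridden lines from the mean/SD;
    ``include_bounded_in_stats`` switches them back in).  A value exactly
    at a band edge is a partial response; if all values coincide (SD = 0)
    every unbounded line is partial.
    """
    vals = activity.informative.astype(float)
    if vals.empty:
        raise ValueError("no informative activity values")
    if len(vals) < 2:
        raise ValueError("need at least 2 informative values")
    labels = pd.Series(PARTIAL, index=vals.index, dtype=object)

    bounded = pd.Series(False, index=vals.index)
    if activity.max_dose is not None:
        over = vals > activity.max_dose
        labels[over] = RESISTANT
        bounded |= over
    if activity.min_dose is not None:
        under = vals < activity.min_dose
        labels[under] = SENSITIVE
        bounded |= under

    stat_vals = vals if include_bounded_in_stats else vals[~bounded]
    free = vals[~bounded]
    if len(stat_vals) >= 2:
        mean = float(stat_vals.mean())
        sd = float(stat_vals.std(ddof=1))
        labels[free.index[free > mean + 0.5 * sd]] = RESISTANT
        labels[free.index[free < mean - 0.5 * sd]] = SENSITIVE
    return labels


def differential_expression(
    expr: pd.Series,
    labels: pd.Series,
    expr_scale: str = "linear",
) -> tuple[float, float, float]:
    """Two-sample pooled-variance t-test of expression, resistant vs sensitive.

    Partial-response lines are excluded.  The fold change is
    mean(resistant) / mean(sensitive) on the linear scale; log-scale input
    (``expr_scale`` "log2" or "ln") is back-transformed first.  Returns
    (t statistic, two-sided p, fold change).
    """
    shared = expr.index.intersection(labels.index)
    e, lab = expr.loc[shared].astype(float), labels.loc[shared]
    res = e[lab == RESISTANT]
    sen = e[lab == SENSITIVE]
    if len(res) < 2 or len(sen) < 2:
        raise ValueError("need at least 2 resistant and 2 sensitive lines")
    t, p = stats.ttest_ind(res, sen, equal_var=True)
    if expr_scale == "linear":
        lin_res, lin_sen = res, sen
    elif expr_scale == "log2":
        lin_res, lin_sen = 2.0**res, 2.0**sen
    elif expr_scale == "ln":
        lin_res, lin_sen = np.exp(res), np.exp(sen)
    else:
        raise ValueError(f"unknown expression scale {expr_scale!r}")
    fc = float(np.mean(lin_res) / np.mean(lin_sen))
    return float(t), float(p), fc


@dataclass(frozen=True)
class EndpointRegression:
    endpoint: str
    slope: float
    p_value: float
    n_lines: int


def nci60_regression(
    expr: pd.Series,
    activities: dict[str, DrugActivityVector],
    alpha: float = 0.05,
    claimed_direction: int | None = None,
    min_lines: int = 3,
    log: list | None = None,
) -> tuple[dict[str, EndpointRegression], bool]:
    """Per-endpoint OLS of drug activity on miRNA expression.

    Non-informative activities (NaN / infinite sentinels) drop the line
    for that endpoint; endpoints with fewer than ``min_lines`` remaining
    are skipped.  The miRNA counts as supported when any endpoint reaches
    p < alpha with the slope sign matching the claimed sensitivity call:
    a chemo-sensitive claim (``claimed_direction=+1``) expects higher
    expression at lower activity values (negative slope), and vice versa.
    """
    fits: dict[str, EndpointRegression] = {}
    supported = False
    for ep, act in activities.items():
        vals = act.informative.astype(float)
        shared = expr.index.intersection(vals.index)
        x = expr.loc[shared].astype(float)
        y = vals.loc[shared]
        if len(shared) < min_lines or np.ptp(x) == 0:
            if log is not None:
                log.append(f"endpoint {ep} skipped: {len(shared)} informative lines")
            continue
        fit = stats.linregress(x, y)
        fits[ep] = EndpointRegression(
            endpoint=ep, slope=float(fit.slope), p_value=float(fit.pvalue), n_lines=len(shared)
        )
        if fit.pvalue < alpha:
            if claimed_direction is None:
                supported = True
            elif claimed_direction == 1 and fit.slope < 0:
                supported = True
            elif claimed_direction == -1 and fit.slope > 0:
                supported = True
    return fits, supported
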
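"""CRISPR/RNAi dependency-screen analytics.

Scores are normalized per cell line so that the median knockout/knockdown
effect of a nonessential control gene set is 0 and that of an essential
control set is -1.  A score at or below -0.5 counts as a significant
effect on proliferation; a gene's essentiality fraction is the share of
lines where it crosses that threshold, and genes crossing it in every
line of both screen modalities form the full-impact intersection.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

SIGNIFICANT_DEPENDENCE = -0.5


@dataclass(frozen=True)
class DependencyMatrix:
    scores: pd.DataFrame  # gene x cell line
    screen_type: str  # "crispr" or "rnai"
    essential_controls: frozenset
    nonessential_controls: frozenset

    def __post_init__(self):
        if self.essential_controls & self.nonessential_controls:
            raise ValueError("control gene sets must be disjoint")


@dataclass(frozen=True)
class EssentialityReport:
    fractions: pd.Series  # gene -> fraction of lines at or below threshold
    n_informative: pd.Series  # gene -> non-missing line count
    threshold: float
    n_lines: int
    screen_type: str


def normalize_dependency(matrix: DependencyMatrix) -> tuple[DependencyMatrix, list[str]]:
    """Per-line affine normalization anchored on the control medians.

    s' = (s - median_nonessential) / (median_nonessential - median_essential),
    so after the map the nonessential control median is 0 and the essential
    control median is -1 in every retained line.  Lines whose two control
    medians coincide carry no scale information and are dropped; their names
    are returned as diagnostics.
    """
    ess = sorted(matrix.essential_controls & set(matrix.scores.index))
    ne = sorted(matrix.nonessential_controls & set(matrix.scores.index))
    if not ess or not ne:
        raise ValueError("both control gene sets must be present in the matrix")
    m_e = matrix.scores.loc[ess].median(axis=0)
    m_ne = matrix.scores.loc[ne].median(axis=0)
    span = m_ne - m_e
    dropped = list(matrix.scores.columns[span == 0])
    keep = span != 0
    normalized = (matrix.scores.loc[:, keep] - m_ne[keep]) / span[keep]
    return replace(matrix, scores=normalized), dropped


def essentiality_fraction(
    matrix: DependencyMatrix, threshold: float = SIGNIFICANT_DEPENDENCE
) -> EssentialityReport:
    """Per-gene fraction of cell lines with a score <= threshold.

    Missing scores shrink the denominator for that gene; coverage is
    reported alongside so sparse genes are visible.
    """
    scores = matrix.scores
    informative = scores.notna().sum(axis=1)
    hits = (scores <= threshold).sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac = hits / informative
    return EssentialityReport(
        fractions=frac,
        n_informative=informative,
        threshold=threshold,
        n_lines=scores.shape[1],
        screen_type=matrix.screen_type,
    )


def intersect_full_impact(
    report_a: EssentialityReport,
    report_b: EssentialityReport,
    min_fraction: float = 1.0,
) -> list[str]:
    """Genes whose essentiality fraction reaches ``min_fraction`` in both screens.

    Genes absent from (or uninformative in) either screen are excluded.
    Sorted by gene name.
    """
    hits = []
    for gene in report_a.fractions.index.intersection(report_b.fractions.index):
        fa, fb = report_a.fractions[gene], report_b.fractions[gene]
        if np.isnan(fa) or np.isnan(fb):
            continue
        if fa >= min_fraction and fb >= min_fraction:
            hits.append(gene)
    return sorted(hits)


def expression_correlation(x, y) -> tuple[float, float]:
    """Pearson correlation with a two-sided t-based p-value.

    Pairs with a missing value on either side are dropped; at least three
    complete pairs and nonzero variance on both sides are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 complete paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
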
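"""Prognostic and chemopredictive marker selection.

The core procedure links two cohorts that share no patients:

1. screen each miRNA against survival inside the expression cohort
   (univariate Cox + Kaplan-Meier cutoff scan, both significant and
   directionally concordant);
2. average expression within tumor-progression groups and regress the
   registry's group-level restricted mean survival on those means;
3. assign each registry patient the group-mean expression of their own
   progression group (imputation) and re-evaluate Cox and the
   Kaplan-Meier split on the registry;
4. keep a miRNA only when every required layer is significant at alpha
   and all significant layers point the same way.

Direction convention, fixed project-wide: "positive" means higher
expression goes with longer survival, i.e. Cox beta < 0, KM direction +1
and group-regression slope > 0.

The prognostic rule (run on chemotherapy-naive patients) requires both
population models; the chemopredictive rule (run on agent-treated
patients) requires the regression plus at least one of the two
population models, and does not require the miRNA to be prognostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import survival as sv
from .progression import ProgressionGroupKey, common_groups, group_keys_for_table
from .treatment import chemo_subset, stratify_treatment


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class CohortScreenResult:
    cox: sv.CoxFit
    km: sv.CutoffScanResult
    passed: bool

    @property
    def direction(self) -> int:
        return 1 if self.cox.beta < 0 else -1


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    p_value: float
    r: float

    @property
    def direction(self) -> int:
        return 1 if self.slope > 0 else -1


@dataclass(frozen=True)
class PopulationKM:
    logrank_p: float
    direction: int
    cutoff: float


@dataclass
class MarkerSelectionRecord:
    mirna: str
    stratum: str
    agent: str | None
    cohort: CohortScreenResult | None
    regression: RegressionResult | None
    population_cox: sv.CoxFit | None
    population_km: PopulationKM | None
    direction: str | None  # "positive" / "negative"
    verdict: str  # prognostic_selected / chemo_sensitive / chemo_resistant / rejected
    failure_reasons: list = field(default_factory=list)

    @property
    def selected(self) -> bool:
        return self.verdict != "rejected"


def cohort_screen(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    alpha: float = 0.05,
    n_grid: int = 20,
    log: list | None = None,
) -> dict:
    """Per-miRNA survival screen inside the expression cohort.

    A miRNA passes when the Cox p-value and the cutoff-scan minimum
    log-rank p-value are both below alpha and the two tests agree on the
    direction (protective Cox beta < 0 must pair with the over-expression
    arm surviving longer).
    """
    if len(clinical) < 2:
        raise PipelineError("expression cohort must contain at least 2 patients")
    times = clinical["time"].to_numpy(dtype=float)
    events = clinical["event"].to_numpy(dtype=float)
    results: dict = {}
    for name in expr.columns:
        x = expr[name].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            if log is not None:
                log.append(f"skipped constant-expression miRNA {name}")
            continue
        try:
            cox = sv.cox_univariate(times, events, x)
            km = sv.km_cutoff_scan(x, times, events, n_grid=n_grid)
        except sv.DegenerateDesignError as exc:
            if log is not None:
                log.append(f"skipped miRNA {name}: {exc}")
            continue
        concordant = (cox.beta < 0) == (km.direction == 1)
        passed = (
            cox.converged
            and cox.p_value < alpha
            and km.min_logrank_p < alpha
            and concordant
        )
        results[name] = CohortScreenResult(cox=cox, km=km, passed=passed)
    return results


def group_expression_means(
    expr: pd.DataFrame,
    keys: list,
    group_keys: list[ProgressionGroupKey],
) -> tuple[pd.DataFrame, pd.Series]:
    """Mean expression per (miRNA, progression group) with per-group counts.

    ``keys`` is the per-sample group key list aligned with expr rows
    (None marks ungroupable samples).  Columns are restricted to
    ``group_keys``; groups without any cohort member are excluded.
    """
    key_series = pd.Series(keys, index=expr.index)
    wanted = set(group_keys)
    mask = key_series.map(lambda k: k in wanted)
    grouped = expr[mask].groupby(key_series[mask], sort=True)
    means = grouped.mean().T  # miRNA x group
    counts = grouped.size()
    means = means.loc[:, [g for g in group_keys if g in means.columns]]
    return means, counts.reindex(means.columns)


def group_survival_profile(
    registry: pd.DataFrame,
    keys: list,
    group_keys: list[ProgressionGroupKey],
    min_per_group: int = 10,
    tau: float | None = None,
    log: list | None = None,
) -> pd.DataFrame:
    """Restricted mean survival per progression group.

    The truncation time tau defaults to the maximum observed time in the
    whole subset so every group is integrated over the same window.
    Groups below ``min_per_group`` members are dropped (and logged).
    """
    key_series = pd.Series(keys, index=registry.index)
    if tau is None:
        tau = float(registry["time"].max())
    rows = []
    for g in group_keys:
        sub = registry[key_series == g]
        if len(sub) < min_per_group:
            if log is not None:
                log.append(f"dropped group {g} with {len(sub)} < {min_per_group} registry members")
            continue
        curve = sv.km_estimate(sub["time"].to_numpy(), sub["event"].to_numpy())
        rows.append(
            {
                "group": g,
                "rmst": sv.rmst(curve, tau),
                "n": len(sub),
                "n_events": int(sub["event"].sum()),
            }
        )
    profile = pd.DataFrame(rows).set_index("group") if rows else pd.DataFrame(
        columns=["rmst", "n", "n_events"]
    )
    profile.attrs["tau"] = tau
    return profile


def population_regression(expr_means: pd.Series, survival_profile: pd.DataFrame) -> RegressionResult:
    """OLS of group restricted mean survival on group mean expression."""
    shared = expr_means.index.intersection(survival_profile.index)
    if len(shared) < 3:
        raise PipelineError(f"only {len(shared)} shared groups; need at least 3")
    x = expr_means.loc[shared].to_numpy(dtype=float)
    y = survival_profile.loc[shared, "rmst"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise PipelineError("zero variance in group mean expression")
    fit = stats.linregress(x, y)
    return RegressionResult(slope=float(fit.slope), p_value=float(fit.pvalue), r=float(fit.rvalue))


def impute_group_expression(
    keys: list, expr_means: pd.Series
) -> tuple[np.ndarray, np.ndarray, int]:
    """Assign each registry patient their group's clinical mean expression.

    Returns (pseudo-expression, kept mask, dropped count); patients whose
    group is absent from the profile are dropped.
    """
    lookup = expr_means.to_dict()
    values = np.array([lookup.get(k, np.nan) for k in keys], dtype=float)
    kept = ~np.isnan(values)
    return values[kept], kept, int((~kept).sum())


def population_cox_km(
    times: np.ndarray,
    events: np.ndarray,
    pseudo_expr: np.ndarray,
    min_group: int = 3,
) -> tuple[sv.CoxFit, PopulationKM]:
    """Re-evaluate Cox and the Kaplan-Meier split on the imputed covariate.

    The KM split is at the median of the imputed values (they take only as
    many distinct values as there are groups, so a quantile scan would
    degenerate); direction compares the restricted mean survival of the
    two arms.
    """
    if np.ptp(pseudo_expr) == 0:
        raise sv.DegenerateDesignError("constant imputed expression")
    cox = sv.cox_univariate(times, events, pseudo_expr)
    med = float(np.median(pseudo_expr))
    hi = pseudo_expr > med
    if hi.sum() < min_group or (~hi).sum() < min_group:
        hi = pseudo_expr >= med
    if hi.sum() < min_group or (~hi).sum() < min_group:
        raise sv.DegenerateDesignError("median split leaves one arm empty")
    lr = sv.logrank_test(times[hi], events[hi], times[~hi], events[~hi])
    tau = float(np.max(times))
    r_hi = sv.rmst(sv.km_estimate(times[hi], events[hi]), tau)
    r_lo = sv.rmst(sv.km_estimate(times[~hi], events[~hi]), tau)
    direction = 1 if r_hi >= r_lo else -1
    return cox, PopulationKM(logrank_p=lr.p_value, direction=direction, cutoff=med)


def _directions(cohort, regression, pop_cox, pop_km):
    return {
        "cohort": cohort.direction,
        "regression": regression.direction,
        "population_cox": 1 if pop_cox.beta < 0 else -1,
        "population_km": pop_km.direction,
    }


def select_prognostic(
    mirna: str,
    stratum: str,
    cohort: CohortScreenResult,
    regression: RegressionResult,
    pop_cox: sv.CoxFit,
    pop_km: PopulationKM,
    alpha: float = 0.05,
    population_rule: str = "both",
) -> MarkerSelectionRecord:
    """Conjunctive prognostic verdict across all three analysis layers.

    Default rule: cohort screen passed, group regression significant, AND
    both population models significant, with every layer pointing the same
    direction.  ``population_rule="either"`` relaxes the last clause to
    one-of-two (the alternative reading of the removal rule).
    """
    reasons = []
    if not cohort.passed:
        reasons.append("cohort screen failed")
    if regression.p_value >= alpha:
        reasons.append("group regression not significant")
    cox_sig = pop_cox.converged and pop_cox.p_value < alpha
    km_sig = pop_km.logrank_p < alpha
    if population_rule == "both":
        if not cox_sig:
            reasons.append("population Cox not significant")
        if not km_sig:
            reasons.append("population KM not significant")
    elif population_rule == "either":
        if not (cox_sig or km_sig):
            reasons.append("no significant population model")
    else:
        raise ValueError(f"unknown population_rule {population_rule!r}")
    dirs = _directions(cohort, regression, pop_cox, pop_km)
    if len(set(dirs.values())) != 1:
        reasons.append("discordant direction across layers")
    verdict = "prognostic_selected" if not reasons else "rejected"
    direction = None
    if not reasons:
        direction = "positive" if dirs["cohort"] == 1 else "negative"
    return MarkerSelectionRecord(
        mirna=mirna,
        stratum=stratum,
        agent=None,
        cohort=cohort,
        regression=regression,
        population_cox=pop_cox,
        population_km=pop_km,
        direction=direction,
        verdict=verdict,
        failure_reasons=reasons,
    )


def select_chemopredictive(
    mirna: str,
    stratum: str,
    agent: str,
    cohort: CohortScreenResult,
    regression: RegressionResult,
    pop_cox: sv.CoxFit,
    pop_km: PopulationKM,
    alpha: float = 0.05,
) -> MarkerSelectionRecord:
    """Chemopredictive verdict on agent-treated patients.

    Requires the cohort screen, a significant group regression, and at
    least one significant population model; the significant layers must
    agree on direction.  A positive direction (longer survival under the
    agent with higher expression) labels the miRNA chemo-sensitive, a
    negative one chemo-resistant.
    """
    reasons = []
    if not cohort.passed:
        reasons.append("cohort screen failed")
    if regression.p_value >= alpha:
        reasons.append("group regression not significant")
    cox_sig = pop_cox.converged and pop_cox.p_value < alpha
    km_sig = pop_km.logrank_p < alpha
    if not (cox_sig or km_sig):
        reasons.append("no significant population model")
    dirs = _directions(cohort, regression, pop_cox, pop_km)
    required = [dirs["cohort"], dirs["regression"]]
    if cox_sig:
        required.append(dirs["population_cox"])
    if km_sig:
        required.append(dirs["population_km"])
    if len(set(required)) != 1:
        reasons.append("discordant direction across significant layers")
    if reasons:
        verdict, direction = "rejected", None
    else:
        direction = "positive" if required[0] == 1 else "negative"
        verdict = "chemo_sensitive" if direction == "positive" else "chemo_resistant"
    return MarkerSelectionRecord(
        mirna=mirna,
        stratum=stratum,
        agent=agent,
        cohort=cohort,
        regression=regression,
        population_cox=pop_cox,
        population_km=pop_km,
        direction=direction,
        verdict=verdict,
        failure_reasons=reasons,
    )


def run_marker_selection(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    registry: pd.DataFrame,
    stratum: str = "any_treatment",
    agent: str = "none",
    alpha: float = 0.05,
    mode: str = "prognostic",
    min_registry_group: int = 10,
    min_cohort_group: int = 1,
    min_agent_subset: int = 50,
    n_grid: int = 20,
    population_rule: str = "both",
    screen: dict | None = None,
) -> tuple[list[MarkerSelectionRecord], dict]:
    """End-to-end marker selection for one (stratum, agent) analysis cell.

    ``mode="prognostic"`` evaluates chemotherapy-naive patients within the
    stratum; ``mode="chemo"`` evaluates patients treated with ``agent``
    ("any" for any chemotherapy).  Returns one record per screened miRNA
    plus a run summary (groups used, counts, log).
    """
    log: list = []
    strata = stratify_treatment(registry)
    if stratum not in strata:
        raise PipelineError(f"unknown stratum {stratum!r}")
    if mode == "prognostic":
        mask = strata[stratum] & chemo_subset(registry, "none")
    elif mode == "chemo":
        mask = strata[stratum] & chemo_subset(registry, agent)
    else:
        raise PipelineError(f"unknown mode {mode!r}")
    subset = registry[mask].reset_index(drop=True)
    if mode == "chemo" and len(subset) < min_agent_subset:
        log.append(
            f"skipped stratum={stratum} agent={agent}: {len(subset)} treated patients "
            f"below the minimum of {min_agent_subset}"
        )
        return [], {"skipped": True, "n_subset": len(subset), "log": log}

    cohort_keys = group_keys_for_table(clinical, log=log)
    registry_keys = group_keys_for_table(subset, log=log)
    groups = common_groups(cohort_keys, registry_keys, (min_cohort_group, min_registry_group))
    if len(groups) < 3:
        raise PipelineError(
            f"only {len(groups)} progression groups shared between cohorts "
            f"(stratum={stratum}, agent={agent}); need at least 3"
        )

    if screen is None:
        screen = cohort_screen(expr, clinical, alpha=alpha, n_grid=n_grid, log=log)
    means, group_n = group_expression_means(expr, cohort_keys, groups)
    profile = group_survival_profile(
        subset, registry_keys, groups, min_per_group=min_registry_group, log=log
    )
    times = subset["time"].to_numpy(dtype=float)
    events = subset["event"].to_numpy(dtype=float)

    records = []
    for name, cres in screen.items():
        if not cres.passed:
            records.append(
                MarkerSelectionRecord(
                    mirna=name,
                    stratum=stratum,
                    agent=None if mode == "prognostic" else agent,
                    cohort=cres,
                    regression=None,
                    population_cox=None,
                    population_km=None,
                    direction=None,
                    verdict="rejected",
                    failure_reasons=["cohort screen failed"],
                )
            )
            continue
        try:
            regression = population_regression(means.loc[name], profile)
            pseudo, kept, n_dropped = impute_group_expression(
                registry_keys, means.loc[name].reindex(profile.index).dropna()
            )
            if n_dropped:
                log.append(f"{name}: dropped {n_dropped} registry patients outside profiled groups")
            pop_cox, pop_km = population_cox_km(times[kept], events[kept], pseudo)
        except (PipelineError, sv.DegenerateDesignError) as exc:
            records.append(
                MarkerSelectionRecord(
                    mirna=name,
                    stratum=stratum,
                    agent=None if mode == "prognostic" else agent,
                    cohort=cres,
                    regression=None,
                    population_cox=None,
                    population_km=None,
                    direction=None,
                    verdict="rejected",
                    failure_reasons=[f"population stage degenerate: {exc}"],
                )
            )
            continue
        if mode == "prognostic":
            rec = select_prognostic(
                name, stratum, cres, regression, pop_cox, pop_km,
                alpha=alpha, population_rule=population_rule,
            )
        else:
            rec = select_chemopredictive(
                name, stratum, agent, cres, regression, pop_cox, pop_km, alpha=alpha
            )
        records.append(rec)

    summary = {
        "skipped": False,
        "stratum": stratum,
        "agent": agent,
        "mode": mode,
        "alpha": alpha,
        "n_subset": len(subset),
        "groups": [str(g) for g in groups],
        "n_groups": len(groups),
        "n_screened": len(screen),
        "n_cohort_pass": int(sum(r.passed for r in screen.values())),
        "n_selected": int(sum(r.selected for r in records)),
        "n_tests_per_mirna": {"cohort": 2, "population": 3},
        "log": log,
    }
    return records, summary


def records_to_frame(records: list[MarkerSelectionRecord]) -> pd.DataFrame:
    """Flatten selection records into a schema-stable table."""
    rows = []
    for r in records:
        rows.append(
            {
                "mirna": r.mirna,
                "stratum": r.stratum,
                "agent": r.agent if r.agent is not None else "",
                "verdict": r.verdict,
                "direction": r.direction if r.direction is not None else "",
                "cohort_cox_beta": r.cohort.cox.beta if r.cohort else np.nan,
                "cohort_cox_p": r.cohort.cox.p_value if r.cohort else np.nan,
                "cohort_km_p": r.cohort.km.min_logrank_p if r.cohort else np.nan,
                "cohort_km_cutoff": r.cohort.km.best_cutoff if r.cohort else np.nan,
                "regression_slope": r.regression.slope if r.regression else np.nan,
                "regression_p": r.regression.p_value if r.regression else np.nan,
                "regression_r": r.regression.r if r.regression else np.nan,
                "population_cox_beta": r.population_cox.beta if r.population_cox else np.nan,
                "population_cox_p": r.population_cox.p_value if r.population_cox else np.nan,
                "population_km_p": r.population_km.logrank_p if r.population_km else np.nan,
                "failure_reasons": "; ".join(r.failure_reasons),
            }
        )
    return pd.DataFrame(rows)
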
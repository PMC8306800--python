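"""Marker selection: screening, group linkage, imputation, concordance rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mirlink as ml
from mirlink import selection as sel
from mirlink import survival as sv
from mirlink.progression import group_keys_for_table


@pytest.fixture(scope="module")
def linked(planted_run):
    """Shared cohort keys / registry subset / common groups for the planted run."""
    registry, expr, clinical = planted_run
    strata = ml.stratify_treatment(registry)
    mask = strata["any_treatment"] & ml.chemo_subset(registry, "none")
    subset = registry[mask].reset_index(drop=True)
    cohort_keys = group_keys_for_table(clinical)
    registry_keys = group_keys_for_table(subset)
    groups = ml.common_groups(cohort_keys, registry_keys, (1, 10))
    return subset, cohort_keys, registry_keys, groups


class TestCohortScreen:
    def test_planted_protective_mirna_passes_with_positive_direction(self, planted_run):
        _, expr, clinical = planted_run
        screen = ml.cohort_screen(expr, clinical)
        res = screen["mir-001"]
        assert res.passed
        assert res.cox.beta < 0
        assert res.km.direction == 1
        assert res.direction == 1

    def test_constant_mirna_skipped_with_log_entry(self, planted_run):
        _, expr, clinical = planted_run
        expr = expr.copy()
        expr["mir-002"] = 1.0
        log = []
        screen = ml.cohort_screen(expr, clinical, log=log)
        assert "mir-002" not in screen
        assert any("mir-002" in line for line in log)

    def test_single_patient_cohort_raises(self, planted_run):
        _, expr, clinical = planted_run
        with pytest.raises(sel.PipelineError):
            ml.cohort_screen(expr.iloc[:1], clinical.iloc[:1])

    def test_null_pass_rate_bounded_by_cox_level(self):
        """The Cox/KM-scan conjunction cannot exceed the 5% Cox level by much.

        The two tests share the data, so the conjunction sits essentially at
        the Cox level; assert the rate is within binomial noise of 5%.
        """
        passes = 0
        trials = 0
        for s in range(6):
            cfg = ml.SimulationConfig(seed=5000 + s, n_mirna=100, n_cohort=200)
            expr, clinical = ml.simulate_expression_cohort(cfg)
            screen = ml.cohort_screen(expr, clinical)
            passes += sum(r.passed for r in screen.values())
            trials += len(screen)
        rate = passes / trials
        assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / trials)


class TestGroupProfiles:
    def test_group_means_match_brute_force_groupby(self, planted_run, linked):
        _, expr, clinical = planted_run
        _, cohort_keys, _, groups = linked
        means, counts = ml.group_expression_means(expr, cohort_keys, groups)
        key_series = pd.Series(cohort_keys, index=expr.index)
        for g in means.columns:
            members = expr[key_series == g]
            np.testing.assert_allclose(means[g], members.mean(axis=0), atol=1e-12)
            assert counts[g] == len(members)

    def test_single_member_group_equals_that_member(self):
        expr = pd.DataFrame({"mir-001": [2.0, 4.0]}, index=["a", "b"])
        keys = [ml.make_group_key(1, 0, 0, 1), ml.make_group_key(2, 0, 0, 1)]
        means, _ = ml.group_expression_means(expr, keys, keys)
        assert means.loc["mir-001", keys[0]] == 2.0
        assert means.loc["mir-001", keys[1]] == 4.0

    def test_two_member_mean(self):
        expr = pd.DataFrame({"m": [2.0, 4.0]}, index=["a", "b"])
        k = ml.make_group_key(1, 0, 0, 1)
        means, counts = ml.group_expression_means(expr, [k, k], [k])
        assert means.loc["m", k] == 3.0
        assert counts[k] == 2

    def test_survival_profile_monotone_in_group_hazard(self, linked):
        subset, _, registry_keys, groups = linked
        profile = ml.group_survival_profile(subset, registry_keys, groups)
        sev = np.array([g.severity for g in profile.index])
        rho = stats.spearmanr(sev, profile["rmst"]).statistic
        assert rho < -0.7
        assert (profile["rmst"] <= profile.attrs["tau"] + 1e-9).all()
        assert (profile["n"] >= 10).all()

    def test_all_censored_group_has_rmst_equal_tau(self):
        k = ml.make_group_key(1, 0, 0, 1)
        reg = pd.DataFrame({"time": [12.0] * 12, "event": [0] * 12})
        profile = ml.group_survival_profile(reg, [k] * 12, [k], min_per_group=10, tau=12.0)
        assert profile.loc[k, "rmst"] == pytest.approx(12.0)


class TestPopulationRegression:
    def test_perfect_proportionality_gives_r_one(self):
        groups = [ml.make_group_key(t, 0, 0, 1) for t in (1, 2, 3, 4)]
        x = pd.Series([1.0, 2.0, 3.0, 4.0], index=groups)
        prof = pd.DataFrame({"rmst": [10.0, 20.0, 30.0, 40.0]}, index=groups)
        r = ml.population_regression(x, prof)
        assert r.r == pytest.approx(1.0)
        assert r.p_value < 1e-6
        assert r.direction == 1

    def test_slope_matches_closed_form(self, rng):
        groups = [ml.make_group_key(t, n, 0, 1) for t in (1, 2, 3, 4) for n in (0, 1, 2)][:16]
        x = pd.Series(rng.normal(size=len(groups)), index=groups)
        y = rng.normal(size=len(groups))
        prof = pd.DataFrame({"rmst": y}, index=groups)
        r = ml.population_regression(x, prof)
        expected = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        assert r.slope == pytest.approx(expected, abs=1e-10)

    def test_permutation_null_calibrated(self, rng):
        groups = [ml.make_group_key(t, n, 0, g) for t in (1, 2) for n in (0, 1) for g in (1, 2, 3)]
        y = rng.normal(size=len(groups))
        prof = pd.DataFrame({"rmst": y}, index=groups)
        hits = 0
        n_perm = 200
        for _ in range(n_perm):
            x = pd.Series(rng.permutation(np.arange(len(groups), dtype=float)), index=groups)
            hits += ml.population_regression(x, prof).p_value < 0.05
        assert hits / n_perm == pytest.approx(0.05, abs=0.04)

    def test_too_few_groups_raises(self):
        groups = [ml.make_group_key(1, 0, 0, 1), ml.make_group_key(2, 0, 0, 1)]
        x = pd.Series([1.0, 2.0], index=groups)
        prof = pd.DataFrame({"rmst": [1.0, 2.0]}, index=groups)
        with pytest.raises(sel.PipelineError):
            ml.population_regression(x, prof)


class TestImputation:
    def test_group_means_of_imputed_column_equal_profile_exactly(self, planted_run, linked):
        _, expr, clinical = planted_run
        subset, cohort_keys, registry_keys, groups = linked
        means, _ = ml.group_expression_means(expr, cohort_keys, groups)
        row = means.loc["mir-001"]
        pseudo, kept, n_dropped = ml.impute_group_expression(registry_keys, row)
        kept_keys = [k for k, keep in zip(registry_keys, kept) if keep]
        imputed = pd.Series(pseudo).groupby(pd.Series(kept_keys)).mean()
        for g in imputed.index:
            assert imputed[g] == pytest.approx(row[g], rel=1e-14, abs=1e-15)
        assert n_dropped == sum(1 for k in registry_keys if k not in set(row.index))

    def test_single_group_registry_gets_constant_column(self):
        k = ml.make_group_key(1, 0, 0, 1)
        row = pd.Series({k: 3.5})
        pseudo, kept, dropped = ml.impute_group_expression([k, k, k], row)
        assert np.all(pseudo == 3.5)
        assert kept.all() and dropped == 0


class TestPopulationCoxKm:
    def test_negating_pseudo_expression_flips_beta_and_direction(self, rng):
        t = rng.exponential(10, 400)
        e = np.ones(400)
        pseudo = rng.choice([1.0, 2.0, 3.0, 4.0], size=400)
        cox1, km1 = ml.population_cox_km(t, e, pseudo)
        cox2, km2 = ml.population_cox_km(t, e, -pseudo)
        assert cox1.beta == pytest.approx(-cox2.beta, rel=1e-5)
        assert km1.direction == -km2.direction

    def test_protective_pseudo_expression_detected(self):
        rng = np.random.default_rng(3)
        group_rate = {1.0: 0.20, 2.0: 0.10, 3.0: 0.05, 4.0: 0.025}
        pseudo = rng.choice(list(group_rate), size=4000)
        t = rng.exponential([1.0 / group_rate[v] for v in pseudo])
        cox, km = ml.population_cox_km(t, np.ones(4000), pseudo)
        assert cox.beta < 0 and cox.p_value < 1e-6
        assert km.direction == 1 and km.logrank_p < 1e-6

    def test_constant_pseudo_expression_raises(self, rng):
        with pytest.raises(sv.DegenerateDesignError):
            ml.population_cox_km(rng.exponential(5, 50), np.ones(50), np.ones(50))


def _mk_layers(cox_p, cox_beta, km_p, km_dir, reg_p, reg_slope, pop_cox_p, pop_cox_beta,
               pop_km_p, pop_km_dir):
    cohort = sel.CohortScreenResult(
        cox=sv.CoxFit(beta=cox_beta, hazard_ratio=np.exp(cox_beta), se=0.1,
                      p_value=cox_p, converged=True, n=57, n_events=40),
        km=sv.CutoffScanResult(best_cutoff=0.0, min_logrank_p=km_p, direction=km_dir,
                               n_cutoffs_tested=20),
        passed=cox_p < 0.05 and km_p < 0.05 and (cox_beta < 0) == (km_dir == 1),
    )
    regression = sel.RegressionResult(slope=reg_slope, p_value=reg_p, r=np.sign(reg_slope) * 0.8)
    pop_cox = sv.CoxFit(beta=pop_cox_beta, hazard_ratio=np.exp(pop_cox_beta), se=0.05,
                        p_value=pop_cox_p, converged=True, n=20000, n_events=15000)
    pop_km = sel.PopulationKM(logrank_p=pop_km_p, direction=pop_km_dir, cutoff=0.0)
    return cohort, regression, pop_cox, pop_km


class TestConcordanceRules:
    def test_fully_concordant_marker_is_selected(self):
        layers = _mk_layers(0.01, -0.5, 0.01, 1, 0.01, 2.0, 0.001, -0.3, 0.001, 1)
        rec = ml.select_prognostic("m", "any_treatment", *layers)
        assert rec.verdict == "prognostic_selected"
        assert rec.direction == "positive"
        assert rec.failure_reasons == []

    def test_discordant_direction_rejected_with_reason(self):
        # significant everywhere but the regression slope points the other way
        layers = _mk_layers(0.01, -0.5, 0.01, 1, 0.01, -2.0, 0.001, -0.3, 0.001, 1)
        rec = ml.select_prognostic("m", "any_treatment", *layers)
        assert rec.verdict == "rejected"
        assert any("discordant" in r for r in rec.failure_reasons)

    def test_prognostic_requires_both_population_models(self):
        layers = _mk_layers(0.01, -0.5, 0.01, 1, 0.01, 2.0, 0.001, -0.3, 0.5, 1)
        rec = ml.select_prognostic("m", "any_treatment", *layers)
        assert rec.verdict == "rejected"
        rec_either = ml.select_prognostic("m", "any_treatment", *layers,
                                          population_rule="either")
        assert rec_either.verdict == "prognostic_selected"

    def test_chemo_rule_accepts_one_population_model(self):
        layers = _mk_layers(0.01, -0.5, 0.01, 1, 0.01, 2.0, 0.001, -0.3, 0.5, 1)
        rec = ml.select_chemopredictive("m", "any_treatment", "cisplatin", *layers)
        assert rec.verdict == "chemo_sensitive"

    def test_negative_direction_labels_chemo_resistant(self):
        layers = _mk_layers(0.01, 0.5, 0.01, -1, 0.01, -2.0, 0.001, 0.3, 0.001, -1)
        rec = ml.select_chemopredictive("m", "any_treatment", "cisplatin", *layers)
        assert rec.verdict == "chemo_resistant"
        assert rec.direction == "negative"

    def test_prognostic_rule_strictly_stronger_than_chemo_rule(self):
        """Any layer combination selected as prognostic would also pass the chemo rule."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            layers = _mk_layers(
                cox_p=rng.uniform(0, 0.1), cox_beta=rng.choice([-0.5, 0.5]),
                km_p=rng.uniform(0, 0.1), km_dir=rng.choice([-1, 1]),
                reg_p=rng.uniform(0, 0.1), reg_slope=rng.choice([-2.0, 2.0]),
                pop_cox_p=rng.uniform(0, 0.1), pop_cox_beta=rng.choice([-0.3, 0.3]),
                pop_km_p=rng.uniform(0, 0.1), pop_km_dir=rng.choice([-1, 1]),
            )
            prog = ml.select_prognostic("m", "s", *layers)
            chemo = ml.select_chemopredictive("m", "s", "a", *layers)
            if prog.verdict == "prognostic_selected":
                assert chemo.verdict in ("chemo_sensitive", "chemo_resistant")


class TestEndToEnd:
    def test_planted_marker_selected_and_direction_positive(self, planted_run):
        registry, expr, clinical = planted_run
        records, summary = ml.run_marker_selection(expr, clinical, registry)
        by_name = {r.mirna: r for r in records}
        assert by_name["mir-001"].verdict == "prognostic_selected"
        assert by_name["mir-001"].direction == "positive"
        assert summary["n_groups"] >= 3

    def test_planted_marker_chemo_sensitive_on_treated_subset(self, planted_run):
        registry, expr, clinical = planted_run
        records, _ = ml.run_marker_selection(
            expr, clinical, registry, mode="chemo", agent="any"
        )
        by_name = {r.mirna: r for r in records}
        assert by_name["mir-001"].verdict == "chemo_sensitive"

    def test_selection_invariant_under_mirna_renaming(self, planted_run):
        registry, expr, clinical = planted_run
        records, _ = ml.run_marker_selection(expr, clinical, registry)
        renamed = expr.rename(columns={c: f"x-{c}" for c in expr.columns})
        records2, _ = ml.run_marker_selection(renamed, clinical, registry)
        v1 = {r.mirna: (r.verdict, r.direction) for r in records}
        v2 = {r.mirna.removeprefix("x-"): (r.verdict, r.direction) for r in records2}
        assert v1 == v2

    def test_small_agent_subset_is_skipped_not_crashed(self, planted_run):
        registry, expr, clinical = planted_run
        small = registry.head(200)
        records, summary = ml.run_marker_selection(
            expr, clinical, small, mode="chemo", agent="etoposide",
            min_agent_subset=500,
        )
        assert records == []
        assert summary["skipped"]

    def test_records_frame_schema_stable(self, planted_run):
        registry, expr, clinical = planted_run
        records, _ = ml.run_marker_selection(expr, clinical, registry)
        frame = ml.records_to_frame(records)
        assert list(frame.columns) == [
            "mirna", "stratum", "agent", "verdict", "direction",
            "cohort_cox_beta", "cohort_cox_p", "cohort_km_p", "cohort_km_cutoff",
            "regression_slope", "regression_p", "regression_r",
            "population_cox_beta", "population_cox_p", "population_km_p",
            "failure_reasons",
        ]
        assert len(frame) == len(records)
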
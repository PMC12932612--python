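import json
import subprocess
import textwrap
import warnings

import numpy as np
import pandas as pd
import pytest

from headkin import (
    CohortConfig,
    Group,
    Task,
    TaskModeRecord,
    assemble_observations,
    build_design,
    cluster_robust_vcov,
    delta_percent,
    difficulty_correlation,
    fit_mixed_model,
    implied_fixed_effects,
    inference_table,
    mode_correlation,
    satterthwaite_inference,
)
from headkin.errors import (
    DegenerateInputError,
    IntegrityError,
    ParameterError,
    UndefinedCorrelationError,
)
from headkin.imu_io import DifficultyRating, Rating
from headkin.inference import Design, _gls_pieces, _satterthwaite_df_robust

STUDY_SIZES = {Group.BV: 19, Group.UV: 20, Group.HS: 20}


def simulate_records(rng, sa=3.0, se=4.0, sizes=STUDY_SIZES, tasks=tuple(Task),
                     null=False):
    """Draw task-mode records from the generative random-intercept model."""
    cfg = CohortConfig()
    records = []
    for g, nsub in sizes.items():
        for i in range(nsub):
            pid = f"{g.value}{i:02d}"
            alpha = rng.normal(0, sa)
            for t in tasks:
                mu = 0.0 if null else (
                    cfg.group_scales[g] * cfg.task_profiles[t].target_mode_velocity
                )
                records.append(
                    TaskModeRecord(pid, g, t, mu + alpha + rng.normal(0, se), 1.0)
                )
    return records


def fit_quietly(design):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_mixed_model(design)


class TestAssembleObservations:
    def test_two_by_two(self):
        recs = [
            TaskModeRecord("a", Group.HS, Task.WALK, 1.0, 10.0),
            TaskModeRecord("a", Group.HS, Task.STAIRS, 2.0, 20.0),
            TaskModeRecord("b", Group.BV, Task.WALK, 3.0, 30.0),
            TaskModeRecord("b", Group.BV, Task.STAIRS, 4.0, 40.0),
        ]
        tab = assemble_observations(recs, "angular_velocity")
        assert len(tab) == 4
        assert tab.frame["response"].tolist() == [1.0, 2.0, 3.0, 4.0]

    def test_acceleration_measure_selects_other_mode(self):
        recs = [TaskModeRecord("a", Group.HS, Task.WALK, 1.0, 10.0),
                TaskModeRecord("b", Group.BV, Task.WALK, 2.0, 20.0)]
        tab = assemble_observations(recs, "angular_acceleration")
        assert tab.frame["response"].tolist() == [10.0, 20.0]

    def test_missing_task_simply_absent(self):
        recs = [
            TaskModeRecord("a", Group.BV, Task.WALK, 1.0, 1.0),
            TaskModeRecord("b", Group.BV, Task.WALK, 1.0, 1.0),
            TaskModeRecord("b", Group.BV, Task.WOOD_BEAM, 2.0, 2.0),
        ]
        tab = assemble_observations(recs, "angular_velocity")
        assert len(tab) == 3

    def test_empty_rejected(self):
        with pytest.raises(DegenerateInputError):
            assemble_observations([], "angular_velocity")

    def test_conflicting_duplicate_rejected(self):
        recs = [TaskModeRecord("a", Group.BV, Task.WALK, 1.0, 1.0),
                TaskModeRecord("a", Group.BV, Task.WALK, 2.0, 1.0)]
        with pytest.raises(IntegrityError):
            assemble_observations(recs, "angular_velocity")


class TestBuildDesign:
    def _full_cross_table(self):
        recs = [
            TaskModeRecord(f"{g.value}{i}", g, t, 1.0, 1.0)
            for g in Group
            for i in range(2)
            for t in Task
        ]
        return assemble_observations(recs, "angular_velocity")

    def test_column_count_three_groups_eleven_tasks(self):
        design = build_design(self._full_cross_table())
        assert design.X.shape[1] == 1 + 2 + 10 + 20

    def test_reference_cell_row_is_all_zero_dummies(self):
        design = build_design(self._full_cross_table())
        frame = self._full_cross_table().frame
        row = design.X[(frame["group"] == "HS") & (frame["task"] == "Walk")].iloc[0]
        assert row["Intercept"] == 1.0
        assert row.drop("Intercept").sum() == 0.0

    def test_bv_uturn_row_sets_three_dummies(self):
        design = build_design(self._full_cross_table())
        frame = self._full_cross_table().frame
        row = design.X[(frame["group"] == "BV") & (frame["task"] == "UTurn")].iloc[0]
        assert row["group[BV]"] == row["task[UTurn]"] == 1.0
        assert row["group[BV]:task[UTurn]"] == 1.0
        assert row.sum() == 4.0  # intercept + the three dummies

    def test_missing_reference_level_rejected(self):
        recs = [TaskModeRecord("a", Group.BV, Task.WALK, 1.0, 1.0),
                TaskModeRecord("b", Group.UV, Task.STAIRS, 1.0, 1.0)]
        tab = assemble_observations(recs, "angular_velocity")
        with pytest.raises(ParameterError):
            build_design(tab)


class TestFitMixedModel:
    def test_noiseless_interpolation_recovers_beta_exactly(self):
        records = []
        for g in (Group.HS, Group.BV):
            for i in range(3):
                for t in (Task.WALK, Task.SORTING):
                    mu = 10 + (2 if g is Group.BV else 0) + (
                        1 if t is Task.SORTING else 0
                    )
                    records.append(TaskModeRecord(f"{g.value}{i}", g, t, mu, 1.0))
        fit = fit_quietly(build_design(assemble_observations(records, "angular_velocity")))
        expected = {"Intercept": 10.0, "group[BV]": 2.0, "task[Sorting]": 1.0,
                    "group[BV]:task[Sorting]": 0.0}
        for term, value in expected.items():
            assert fit.params[term] == pytest.approx(value, abs=1e-8)
        assert fit.random_intercept_variance == pytest.approx(0.0, abs=1e-8)

    def test_fixed_effects_equal_direct_gls_oracle(self):
        rng = np.random.default_rng(21)
        records = simulate_records(
            rng, sizes={Group.BV: 8, Group.HS: 8}, tasks=(Task.WALK, Task.SORTING)
        )
        design = build_design(assemble_observations(records, "angular_velocity"))
        fit = fit_quietly(design)
        # independent oracle: closed-form GLS at the fitted variance components
        X = design.X.to_numpy(float)
        idx = fit.cluster_index()
        W_blocks, M = _gls_pieces(
            X, idx, fit.random_intercept_variance, fit.residual_variance
        )
        rhs = np.zeros(X.shape[1])
        for rows, W in zip(idx, W_blocks):
            rhs += X[rows].T @ W @ design.y[rows]
        beta_gls = M @ rhs
        np.testing.assert_allclose(fit.params.to_numpy(), beta_gls, atol=1e-6)

    def test_simulation_recovery_within_three_mc_ses(self):
        rng = np.random.default_rng(22)
        truth = implied_fixed_effects(CohortConfig())
        records = simulate_records(rng)
        fit = fit_quietly(build_design(assemble_observations(records, "angular_velocity")))
        inf = satterthwaite_inference(fit, "cr2")
        z = np.array(
            [
                abs(inf.loc[term, "estimate"] - truth[term]) / inf.loc[term, "se"]
                for term in inf.index
            ]
        )
        # 33 simultaneous standardized errors: nearly all within 3 SE, none extreme
        assert (z < 3.0).mean() >= 32 / 33
        assert z.max() < 4.0

    def test_matches_r_lme4_reml(self, tmp_path):
        rng = np.random.default_rng(23)
        records = simulate_records(
            rng, sa=2.0, se=1.5, sizes={Group.BV: 6, Group.HS: 6},
            tasks=(Task.WALK, Task.SORTING, Task.STAIRS, Task.TRAY),
        )
        tab = assemble_observations(records, "angular_velocity")
        design = build_design(tab)
        fit = fit_quietly(design)
        obs = tmp_path / "obs.csv"
        tab.frame.to_csv(obs, index=False)
        rscript = textwrap.dedent(f"""
        suppressMessages(library(lme4))
        d <- read.csv("{obs}")
        d$group <- relevel(factor(d$group), ref="HS")
        d$task <- relevel(factor(d$task), ref="Walk")
        m <- lmer(response ~ group*task + (1|participant_id), data=d, REML=TRUE)
        vc <- as.data.frame(VarCorr(m))
        cat(jsonlite::toJSON(list(fixef=as.list(fixef(m)), vc=vc$vcov), digits=12))
        """)
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        res = json.loads(out.stdout)
        sa2_r, se2_r = res["vc"]
        assert fit.random_intercept_variance == pytest.approx(sa2_r, rel=1e-3)
        assert fit.residual_variance == pytest.approx(se2_r, rel=1e-3)
        assert fit.params["Intercept"] == pytest.approx(
            res["fixef"]["(Intercept)"][0], abs=1e-5
        )
        assert fit.params["group[BV]"] == pytest.approx(
            res["fixef"]["groupBV"][0], abs=1e-5
        )

    def test_row_order_invariance(self):
        rng = np.random.default_rng(24)
        records = simulate_records(
            rng, sizes={Group.BV: 5, Group.HS: 5}, tasks=(Task.WALK, Task.STAIRS)
        )
        tab1 = assemble_observations(records, "angular_velocity")
        tab2 = assemble_observations(records[::-1], "angular_velocity")
        f1, f2 = fit_quietly(build_design(tab1)), fit_quietly(build_design(tab2))
        np.testing.assert_allclose(
            f1.params.to_numpy(), f2.params.to_numpy(), atol=1e-6
        )


class TestClusterRobustVcov:
    def _singleton_fit(self, y, x):
        frame = pd.DataFrame(
            {
                "participant_id": [f"p{i}" for i in range(len(y))],
                "group": "HS",
                "task": "Walk",
                "response": y,
            }
        )
        X = pd.DataFrame({"Intercept": np.ones(len(y)), "x": x})
        design = Design(X=X, y=np.asarray(y, float),
                        clusters=frame["participant_id"].to_numpy(),
                        ref_group=Group.HS, ref_task=Task.WALK)
        return fit_quietly(design)

    def test_ols_limit_matches_explicit_sandwich_formula(self):
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 7.0])
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        fit = self._singleton_fit(y, x)
        V = cluster_robust_vcov(fit, "cr0")
        # explicit heteroskedasticity-robust oracle on the 6-row table
        X = np.column_stack([np.ones(6), x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        e = y - X @ beta
        bread = np.linalg.inv(X.T @ X)
        meat = X.T @ np.diag(e**2) @ X
        np.testing.assert_allclose(V, bread @ meat @ bread, atol=1e-8)

    def test_cr2_singletons_match_hc2(self):
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 7.0])
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        fit = self._singleton_fit(y, x)
        V = cluster_robust_vcov(fit, "cr2")
        X = np.column_stack([np.ones(6), x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        e = y - X @ beta
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        bread = np.linalg.inv(X.T @ X)
        meat = X.T @ np.diag(e**2 / (1 - np.diag(H))) @ X
        np.testing.assert_allclose(V, bread @ meat @ bread, atol=1e-8)

    def test_duplicating_clusters_leaves_estimates_unchanged(self):
        rng = np.random.default_rng(25)
        records = simulate_records(
            rng, sizes={Group.BV: 4, Group.HS: 4}, tasks=(Task.WALK, Task.STAIRS)
        )
        doubled = records + [
            TaskModeRecord(r.participant_id + "_dup", r.group, r.task,
                           r.mode_velocity, r.mode_acceleration)
            for r in records
        ]
        f1 = fit_quietly(build_design(assemble_observations(records, "angular_velocity")))
        f2 = fit_quietly(build_design(assemble_observations(doubled, "angular_velocity")))
        np.testing.assert_allclose(
            f1.params.to_numpy(), f2.params.to_numpy(), atol=1e-4
        )

    def test_robust_and_model_ses_agree_under_correct_specification(self):
        rng = np.random.default_rng(26)
        ratios = []
        for _ in range(60):
            records = simulate_records(
                rng, sizes={Group.BV: 15, Group.HS: 15},
                tasks=(Task.WALK, Task.STAIRS, Task.TRAY),
            )
            fit = fit_quietly(
                build_design(assemble_observations(records, "angular_velocity"))
            )
            V = cluster_robust_vcov(fit, "cr2")
            ratios.append(np.sqrt(np.diag(V) / np.diag(fit.model_vcov)))
        assert abs(np.mean(ratios) - 1.0) < 0.15

    def test_single_cluster_rejected(self):
        y = np.arange(5.0)
        frame_x = pd.DataFrame({"Intercept": np.ones(5)})
        design = Design(X=frame_x, y=y, clusters=np.array(["p0"] * 5),
                        ref_group=Group.HS, ref_task=Task.WALK)
        fit = fit_quietly(design)
        with pytest.raises(DegenerateInputError):
            cluster_robust_vcov(fit, "cr2")


class TestSatterthwaite:
    def _one_sample_fit(self, n, seed=1):
        y = np.random.default_rng(seed).normal(5, 2, n)
        design = Design(
            X=pd.DataFrame({"Intercept": np.ones(n)}),
            y=y,
            clusters=np.array([f"p{i}" for i in range(n)]),
            ref_group=Group.HS,
            ref_task=Task.WALK,
        )
        return fit_quietly(design)

    def test_one_sample_mean_df_is_n_minus_one(self):
        fit = self._one_sample_fit(12)
        df = _satterthwaite_df_robust(fit, "cr2")
        assert df[0] == pytest.approx(11.0, abs=0.1)

    def test_many_clusters_ci_approaches_normal_limit(self):
        fit = self._one_sample_fit(10_000)
        inf = satterthwaite_inference(fit, "cr2")
        half_width = (inf["ci_high"] - inf["ci_low"]).iloc[0] / 2.0
        assert half_width == pytest.approx(1.96 * inf["se"].iloc[0], rel=0.005)

    def test_p_value_is_one_at_zero_t(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, 40)
        y = y - y.mean()  # force the intercept estimate to exactly zero
        design = Design(
            X=pd.DataFrame({"Intercept": np.ones(40)}),
            y=y,
            clusters=np.array([f"p{i}" for i in range(40)]),
            ref_group=Group.HS,
            ref_task=Task.WALK,
        )
        inf = satterthwaite_inference(fit_quietly(design), "cr2")
        assert inf["p"].iloc[0] == pytest.approx(1.0)

    def test_model_based_df_matches_balanced_one_way_closed_form(self):
        rng = np.random.default_rng(27)
        C, m = 25, 4
        rows = []
        for c in range(C):
            a = rng.normal(0, 2)
            rows += [(f"p{c}", 10 + a + rng.normal(0, 1)) for _ in range(m)]
        design = Design(
            X=pd.DataFrame({"Intercept": np.ones(C * m)}),
            y=np.array([r[1] for r in rows]),
            clusters=np.array([r[0] for r in rows]),
            ref_group=Group.HS,
            ref_task=Task.WALK,
        )
        inf = satterthwaite_inference(fit_quietly(design), "model")
        # balanced one-way: the intercept variance is estimated with C-1 df
        assert inf["df"].iloc[0] == pytest.approx(C - 1, rel=0.05)


class TestDeltaPercent:
    def test_zero_estimate_gives_minus_hundred(self):
        assert delta_percent(42.0, 0.0) == -100.0

    def test_zero_intercept_rejected(self):
        with pytest.raises(ParameterError):
            delta_percent(0.0, 1.0)

    def test_inference_table_delta_consistency(self):
        rng = np.random.default_rng(28)
        records = simulate_records(
            rng, sizes={Group.BV: 6, Group.HS: 6}, tasks=(Task.WALK, Task.STAIRS)
        )
        fit = fit_quietly(build_design(assemble_observations(records, "angular_velocity")))
        table = inference_table(fit)
        icept = table.loc["Intercept", "estimate"]
        assert np.isnan(table.loc["Intercept", "delta_percent"])
        for term in table.index[1:]:
            expected = round(100 * (table.loc[term, "estimate"] - icept) / icept, 1)
            assert table.loc[term, "delta_percent"] == expected


class TestCorrelations:
    def test_proportional_modes_perfectly_correlated(self):
        recs = [
            TaskModeRecord("p", Group.BV, t, v, 2 * v)
            for t, v in zip(Task, [3.0, 5.0, 8.0, 2.0])
        ]
        assert mode_correlation(recs, Group.BV) == pytest.approx(1.0)

    def test_three_point_hand_computed_pearson(self):
        recs = [
            TaskModeRecord("p", Group.HS, t, v, a)
            for t, v, a in [(Task.WALK, 1, 1), (Task.STAIRS, 2, 2), (Task.TRAY, 3, 2)]
        ]
        assert mode_correlation(recs, Group.HS) == pytest.approx(0.866, abs=0.001)

    def test_independent_modes_near_zero(self):
        rng = np.random.default_rng(29)
        recs = [
            TaskModeRecord(f"p{i}", Group.UV, Task.WALK if i % 2 else Task.STAIRS,
                           rng.normal(10, 2), rng.normal(100, 20))
            for i in range(10_000)
        ]
        # duplicates across (participant, task) do not matter for correlation
        assert abs(mode_correlation(recs, Group.UV)) < 0.03

    def test_zero_variance_rejected(self):
        recs = [TaskModeRecord("p", Group.BV, t, 5.0, float(i))
                for i, t in enumerate((Task.WALK, Task.STAIRS, Task.TRAY))]
        with pytest.raises(UndefinedCorrelationError):
            mode_correlation(recs, Group.BV)

    def _rated(self, scores, modes, group=Group.BV):
        pid = f"{group.value}0"
        tasks = list(Task)[: len(scores)]
        recs = [TaskModeRecord(pid, group, t, m, 10 * m) for t, m in zip(tasks, modes)]
        levels = {1: Rating.EASY, 2: Rating.MEDIUM, 3: Rating.DIFFICULT}
        ratings = [DifficultyRating(pid, t, levels[s]) for t, s in zip(tasks, scores)]
        return recs, ratings

    def _all_groups_rated(self, scores, modes):
        recs, ratings = [], []
        for g in Group:
            r, rt = self._rated(scores, modes, g)
            recs += r
            ratings += rt
        return recs, ratings

    def test_all_identical_ratings_rejected(self):
        recs, ratings = self._all_groups_rated([1, 1, 1, 1], [1.0, 2.0, 3.0, 4.0])
        with pytest.raises(UndefinedCorrelationError):
            difficulty_correlation(recs, ratings)

    def test_perfectly_ordered_pairs(self):
        recs, ratings = self._all_groups_rated([1, 2, 3], [1.0, 2.0, 3.0])
        table = difficulty_correlation(recs, ratings)
        assert np.allclose(table["rho"], 1.0)

    def test_unable_ratings_excluded(self):
        recs, ratings = self._all_groups_rated([1, 2, 3], [1.0, 2.0, 3.0])
        extra_task = list(Task)[3]
        ratings.append(DifficultyRating("BV0", extra_task, Rating.UNABLE))
        recs.append(TaskModeRecord("BV0", Group.BV, extra_task, 99.0, 990.0))
        table = difficulty_correlation(recs, ratings)
        bv = table[(table.group == "BV") & (table.measure == "angular_velocity")]
        assert bv["n"].iloc[0] == 3  # the "unable" cell is not paired
        assert bv["rho"].iloc[0] == pytest.approx(1.0)

    def test_null_ratings_weakly_correlated_on_average(self):
        rng = np.random.default_rng(30)
        rhos = []
        for _ in range(200):
            n = 200
            scores = rng.integers(1, 4, n)
            modes = rng.normal(10, 3, n)
            from scipy.stats import spearmanr

            rhos.append(abs(spearmanr(scores, modes).statistic))
        assert np.mean(rhos) < 0.08
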
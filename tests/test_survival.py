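import io

import numpy as np
import pandas as pd
import pytest

from _oracles import fit_cox_bruteforce
from luxepi.survival import (
    CoxFittingError,
    ModelSpec,
    build_cohort_table,
    build_design,
    fit_cox,
    hazard_tables_to_csv,
    incidence_rate,
    ph_check,
    render_hazard_report,
)
from luxepi.synthetic import CohortGenConfig, generate_cohort, simulate_survival


def toy_cohort(n=24, seed=0, tied=True):
    rng = np.random.default_rng(seed)
    x1 = rng.standard_normal(n)
    x2 = rng.integers(0, 2, n).astype(float)
    time, status = simulate_survival(0.7 * x1 - 0.4 * x2, 0.2, 6.0, rng)
    if tied:
        time = np.ceil(time)  # coarse times force Efron tie handling
    return pd.DataFrame({"x1": x1, "x2": x2, "time": time, "status": status})


class TestIncidenceRate:
    def test_closed_form_values(self):
        assert incidence_rate(1997, 670_844) == 2.98
        assert incidence_rate(0, 1000.0) == 0.0
        assert incidence_rate(10, 1000.0) == 10.0

    def test_zero_person_years_rejected(self):
        with pytest.raises(ValueError):
            incidence_rate(5, 0.0)


class TestFitCox:
    def test_recovers_true_group_hazard_ratio(self):
        cfg = CohortGenConfig(
            n_participants=50_000,
            baseline_rate=0.01,
            follow_up_years=8.0,
            true_log_hr={"exposed": np.log(2.0)},
            group_proportions={"a-ref": 0.5, "exposed": 0.5},
            seed=10,
        )
        fit = fit_cox(generate_cohort(cfg), ModelSpec(predictors=["group"], tier=0))
        row = fit.table.set_index("level").loc["exposed"]
        se = (np.log(row.ci_high) - np.log(row.ci_low)) / (2 * 1.96)
        assert abs(np.log(row.HR) - np.log(2.0)) < 3 * se

    def test_null_groups_ci_covers_one(self):
        cfg = CohortGenConfig(
            n_participants=20_000,
            baseline_rate=0.02,
            group_proportions={"a": 0.5, "b": 0.5},
            seed=11,
        )
        fit = fit_cox(generate_cohort(cfg), ModelSpec(predictors=["group"], tier=0))
        row = fit.table.set_index("level").loc["b"]
        assert row.ci_low < 1.0 < row.ci_high

    def test_matches_bruteforce_efron_optimizer(self):
        df = toy_cohort(n=24)
        fit = fit_cox(df, ModelSpec(predictors=["x1", "x2"], tier=0))
        beta_hat = np.log(fit.table.set_index("predictor").HR[["x1", "x2"]].to_numpy())
        beta_oracle = fit_cox_bruteforce(
            df[["x1", "x2"]].to_numpy(), df.time.to_numpy(), df.status.to_numpy()
        )
        np.testing.assert_allclose(beta_hat, beta_oracle, atol=1e-6)

    def test_referent_row_has_unit_hazard(self):
        cfg = CohortGenConfig(
            n_participants=2000,
            baseline_rate=0.05,
            group_proportions={"0-50%": 0.6, "50-100%": 0.4},
            seed=12,
        )
        fit = fit_cox(generate_cohort(cfg), ModelSpec(predictors=["group"], tier=0))
        ref = fit.table[fit.table.is_ref].iloc[0]
        assert ref.level == "0-50%" and ref.HR == 1.0

    def test_zero_event_level_rejected(self):
        df = toy_cohort(n=40, seed=3)
        df["grp"] = np.where(np.arange(40) < 5, "empty", "rest")
        df.loc[df.grp == "empty", "status"] = 0
        with pytest.raises(CoxFittingError, match="zero events"):
            fit_cox(df, ModelSpec(predictors=["grp"], tier=0, referents={"grp": "rest"}))

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="lacks columns"):
            fit_cox(toy_cohort(), ModelSpec(predictors=["nope"], tier=0))

    def test_timescale_invariance(self):
        df = toy_cohort(n=200, seed=4, tied=False)
        spec = ModelSpec(predictors=["x1"], tier=0)
        hr1 = fit_cox(df, spec).table.iloc[0].HR
        df2 = df.assign(time=df.time * 37.0)
        hr2 = fit_cox(df2, spec).table.iloc[0].HR
        assert hr1 == pytest.approx(hr2, rel=1e-8)

    def test_monotone_in_true_effect(self):
        medians = []
        for hr in (1.0, 1.5, 2.5):
            ests = []
            for seed in range(5):
                cfg = CohortGenConfig(
                    n_participants=4000,
                    baseline_rate=0.02,
                    true_log_hr={"b": np.log(hr)},
                    group_proportions={"a": 0.5, "b": 0.5},
                    seed=100 + seed,
                )
                fit = fit_cox(generate_cohort(cfg), ModelSpec(predictors=["group"], tier=0))
                ests.append(fit.table.set_index("level").loc["b", "HR"])
            medians.append(np.median(ests))
        assert medians[0] < medians[1] < medians[2]

    def test_tiered_covariates_are_nested(self):
        df = generate_cohort(
            CohortGenConfig(n_participants=3000, baseline_rate=0.05,
                            group_proportions={"a": 0.5, "b": 0.5}, seed=13)
        )
        cols = {}
        for tier in (1, 2, 3):
            design, _ = build_design(df, ModelSpec(predictors=["group"], tier=tier))
            cols[tier] = set(design.columns)
        assert cols[1] <= cols[2] <= cols[3]


class TestPhCheck:
    def test_null_rejection_rate_near_nominal(self):
        rejections = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(300)
            time, status = simulate_survival(0.3 * x, 0.1, 10.0, rng)
            df = pd.DataFrame({"x": x, "time": time, "status": status})
            fit = fit_cox(df, ModelSpec(predictors=["x"], tier=0))
            rejections.append(bool(ph_check(fit).loc["x", "flagged"]))
        rate = np.mean(rejections)
        se = np.sqrt(0.05 * 0.95 / 100)
        assert abs(rate - 0.05) < 3 * se + 0.01

    def test_time_varying_effect_flagged(self):
        rng = np.random.default_rng(7)
        n = 4000
        x = rng.integers(0, 2, n).astype(float)
        # effect reverses over follow-up: early harm for x=1, late harm for x=0
        t_early = rng.exponential(1.0 / np.where(x == 1, 0.5, 0.05))
        t_late = 2.0 + rng.exponential(1.0 / np.where(x == 1, 0.05, 0.5))
        time = np.where(t_early < 2.0, t_early, np.minimum(t_late, 8.0))
        status = (time < 8.0).astype(int)
        df = pd.DataFrame({"x": x, "time": np.maximum(time, 1e-6), "status": status})
        fit = fit_cox(df, ModelSpec(predictors=["x"], tier=0))
        assert bool(ph_check(fit).loc["x", "flagged"])

    def test_referent_only_model_empty(self):
        df = toy_cohort()
        fit = fit_cox(df, ModelSpec(predictors=[], tier=0))
        assert fit.cph is None and ph_check(fit).empty


class TestBuildCohortTable:
    def exposures(self, ids, qc=True):
        return pd.DataFrame(
            {"participant_id": ids, "night_lux": 1.0, "day_lux": 100.0, "qc_pass": qc}
        )

    def outcomes(self, ids):
        return pd.DataFrame({"participant_id": ids, "time": 5.0, "status": 0})

    def test_disjoint_ids_give_empty_table(self):
        out = build_cohort_table(self.exposures(["a", "b"]), outcomes=self.outcomes(["c"]))
        assert len(out) == 0

    def test_prevalent_case_excluded(self):
        ids = ["a", "b", "c"]
        covs = pd.DataFrame({"participant_id": ids, "prevalent": [False, True, False]})
        out = build_cohort_table(
            self.exposures(ids), covariates=covs, outcomes=self.outcomes(ids)
        )
        assert len(out) == 2 and "b" not in set(out.participant_id)

    def test_qc_failures_excluded(self):
        exp = self.exposures(["a", "b"])
        exp.loc[1, "qc_pass"] = False
        out = build_cohort_table(exp, outcomes=self.outcomes(["a", "b"]))
        assert list(out.participant_id) == ["a"]

    def test_join_order_independent(self):
        ids = ["a", "b", "c"]
        circ = pd.DataFrame({"participant_id": ids[::-1], "amp_min": [1.0, 2.0, 3.0]})
        out1 = build_cohort_table(self.exposures(ids), circ, outcomes=self.outcomes(ids))
        out2 = build_cohort_table(self.exposures(ids), circ, outcomes=self.outcomes(ids[::-1]))
        pd.testing.assert_frame_equal(
            out1.sort_values("participant_id").reset_index(drop=True),
            out2.sort_values("participant_id").reset_index(drop=True),
        )

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_cohort_table(self.exposures(["a", "a"]), outcomes=self.outcomes(["a"]))


class TestReporting:
    def fits(self):
        cfg = CohortGenConfig(
            n_participants=3000,
            baseline_rate=0.05,
            group_proportions={"0-50%": 0.5, "50-100%": 0.5},
            seed=14,
        )
        df = generate_cohort(cfg)
        return [fit_cox(df, ModelSpec(predictors=["group"], tier=t)) for t in (1, 2)]

    def test_one_block_per_model(self):
        fits = self.fits()
        text = render_hazard_report(fits[:1])
        assert text.count("Model") == 1
        text2 = render_hazard_report(fits)
        assert "Model 1" in text2 and "Model 2" in text2

    def test_referent_rendered_as_dash(self):
        text = render_hazard_report(self.fits()[:1])
        ref_line = [l for l in text.splitlines() if l.strip().startswith("0-50%")][0]
        assert "-" in ref_line.replace("0-50%", "")

    def test_csv_round_trip(self, tmp_path):
        fits = self.fits()
        path = tmp_path / "hazards.csv"
        written = hazard_tables_to_csv(fits, path)
        back = pd.read_csv(path)
        assert len(back) == len(written)
        np.testing.assert_allclose(
            back.HR.to_numpy(), written.HR.to_numpy(), rtol=1e-12
        )

    def test_requires_at_least_one_model(self):
        with pytest.raises(ValueError):
            render_hazard_report([])
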
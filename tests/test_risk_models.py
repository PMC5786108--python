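import datetime

import numpy as np
import pandas as pd
import pytest

from cpinet import contact_metrics as cm
from cpinet import risk_models as rm
from cpinet.types import GapSchedule, Individual, Roster

from conftest import EPOCH

NO_GAPS = GapSchedule()
D0 = EPOCH
D2 = EPOCH + datetime.timedelta(days=2)


def outcome_roster():
    return Roster(
        [
            Individual("S1", "staff", "HCW", "W1", D0, D2),
            Individual("S2", "staff", "hospital_porter", "W6_transversal", D0, D2),
            Individual("S3", "staff", "administration", "W6_transversal", D0, D2),
            Individual("S4", "staff", "animation", "W6_transversal", D0, D2),
            Individual("P1", "patient", "patient", "W1", D0, D2, 55, "F", "neurology"),
            Individual("P2", "patient", "patient", "W2", D0, D2, 72, "M", "geriatric", pvs=True),
        ]
    )


def person_day_frame(roster):
    rows = []
    rng = np.random.default_rng(0)
    for ind in roster:
        for day in range(3):
            rows.append(
                {
                    "id": ind.id,
                    "date": pd.Timestamp(EPOCH) + pd.Timedelta(days=day),
                    "n_distinct": int(rng.integers(0, 20)),
                    "total_duration_s": int(rng.integers(0, 7200)),
                    "present": True,
                }
            )
    return pd.DataFrame(rows)


class TestOutcomeTable:
    def test_staff_rows_and_exclusions(self):
        roster = outcome_roster()
        table, n_dropped = rm.build_outcome_table(person_day_frame(roster), roster, "staff")
        # 2 analysis staff x 3 days; administration and animation excluded
        assert len(table) == 6
        assert set(table["id"]) == {"S1", "S2"}
        assert n_dropped == 0

    def test_pvs_patient_excluded(self):
        roster = outcome_roster()
        table, _ = rm.build_outcome_table(person_day_frame(roster), roster, "patients")
        assert set(table["id"]) == {"P1"}
        assert {"reason", "age_band", "gender"} <= set(table.columns)
        assert (table["age_band"] == "[50,60)").all()

    def test_row_count_equals_presence_days(self, small_config, small_dataset):
        pds = cm.person_days(
            small_dataset.records, small_dataset.roster,
            small_config.gap_schedule, small_config.epoch,
        )
        table, n_dropped = rm.build_outcome_table(pds, small_dataset.roster, "patients")
        expected = 0
        for p in small_dataset.roster.patients():
            if p.pvs:
                continue
            day = p.present_from
            while day <= p.present_to:
                if not small_config.gap_schedule.contains(day):
                    expected += 1
                day += datetime.timedelta(days=1)
        assert len(table) + n_dropped == expected

    def test_unknown_population(self):
        with pytest.raises(ValueError):
            rm.build_outcome_table(person_day_frame(outcome_roster()), outcome_roster(), "visitors")


class TestDichotomize:
    @staticmethod
    def _table(freq_values):
        return pd.DataFrame(
            {"freq_value": freq_values, "dur_value": freq_values}
        ).astype(float)

    def test_k0_mean_rule(self):
        out, spec = rm.dichotomize(self._table([1, 2, 3, 4, 5]), k=0)
        assert spec.threshold_freq == 3.0
        assert out["high_freq"].tolist() == [0, 0, 0, 1, 1]

    def test_k1_sample_sd(self):
        # sd([1..5], ddof=1) = sqrt(2.5) ~ 1.5811
        out, spec = rm.dichotomize(self._table([1, 2, 3, 4, 5]), k=1)
        assert spec.threshold_freq == pytest.approx(3 + np.sqrt(2.5))
        assert out["high_freq"].tolist() == [0, 0, 0, 0, 1]

    def test_tie_is_low(self):
        out, _ = rm.dichotomize(self._table([2, 2, 2, 6]), k=0)
        # mean is 3; the 2s are below, 6 above
        assert out["high_freq"].tolist() == [0, 0, 0, 1]
        out0, spec0 = rm.dichotomize(self._table([3, 3, 3, 3]), k=0)
        assert out0["high_freq"].sum() == 0  # value == threshold -> low

    def test_k3_normal_tail(self):
        rng = np.random.default_rng(1)
        out, _ = rm.dichotomize(self._table(rng.normal(10, 2, 200_000)), k=3)
        frac = out["high_freq"].mean()
        assert 0.0005 < frac < 0.0035  # ~0.13% for a normal tail

    def test_monotone_in_k(self):
        rng = np.random.default_rng(2)
        table = self._table(rng.gamma(3, 4, 5000))
        fracs = [rm.dichotomize(table, k)[0]["high_freq"].mean() for k in (0, 1, 2, 3)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_zero_variance_warns(self):
        with pytest.warns(UserWarning):
            rm.dichotomize(self._table([4, 4, 4]), k=1)

    def test_bad_k(self):
        with pytest.raises(ValueError):
            rm.dichotomize(self._table([1, 2]), k=5)


class TestGLMMFit:
    def test_recovers_planted_or(self):
        table = rm.simulate_outcome_table(
            4000, 5, {"porter": np.log(3.0)}, intercept=-1.5, sigma=0.5, seed=42
        )
        res = rm.fit_mixed_logit(table, "high", {"category": "HCW"})
        assert res.converged
        row = res.level_row("category", "porter")
        assert row.or_lo < 3.0 < row.or_hi
        assert 1.5 < row.OR < 6.0

    def test_zero_variance_matches_plain_glm(self):
        import statsmodels.api as sm

        table = rm.simulate_outcome_table(
            4000, 5, {"porter": 1.0}, intercept=-1.0, sigma=0.0, seed=7
        )
        res = rm.fit_mixed_logit(table, "high", {"category": "HCW"})
        assert res.sigma2 <= 0.05
        X = np.column_stack(
            [np.ones(len(table)), (table["category"] == "porter").astype(float)]
        )
        glm = sm.GLM(table["high"], X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(
            res.table["estimate"].to_numpy(), glm.params.to_numpy(), rtol=1e-3
        )

    def test_degenerate_outcome_flagged(self):
        table = rm.simulate_outcome_table(200, 3, {"porter": 0.0}, -1.0, 0.3, seed=1)
        table["high"] = 0
        res = rm.fit_mixed_logit(table, "high", {"category": "HCW"})
        assert not res.converged
        assert "degenerate" in res.message

    def test_separation_detected(self):
        rng = np.random.default_rng(3)
        n = 400
        cat = rng.choice(["HCW", "physician"], size=n)
        table = pd.DataFrame(
            {
                "ward": rng.choice(["W1", "W2", "W3"], size=n),
                "category": cat,
                # physicians never high: complete separation
                "high": np.where(cat == "physician", 0, rng.integers(0, 2, n)),
            }
        )
        res = rm.fit_mixed_logit(table, "high", {"category": "HCW"})
        row = res.level_row("category", "physician")
        assert row.separation
        assert row.OR < 1e-6

    def test_missing_reference_level_rejected(self):
        table = rm.simulate_outcome_table(100, 3, {"porter": 0.0}, -1.0, 0.3, seed=1)
        with pytest.raises(ValueError, match="reference"):
            rm.fit_mixed_logit(table, "high", {"category": "nurse_manager"})

    def test_wald_or_consistency(self):
        table = rm.simulate_outcome_table(2000, 4, {"porter": 0.8}, -1.2, 0.4, seed=9)
        res = rm.fit_mixed_logit(table, "high", {"category": "HCW"})
        for row in res.table.itertuples(index=False):
            assert row.OR == pytest.approx(np.exp(row.estimate))
            assert row.or_lo == pytest.approx(np.exp(row.estimate - 1.96 * row.se))
            assert row.or_hi == pytest.approx(np.exp(row.estimate + 1.96 * row.se))


class TestLRT:
    def test_planted_effect_power(self):
        spec = rm.ModelSpec("staff", "high", {"category": "HCW"})
        hits = 0
        for seed in range(5):
            table = rm.simulate_outcome_table(
                5000, 5, {"porter": np.log(10.0)}, -1.5, 0.5, seed=300 + seed,
                level_probs={"HCW": 0.7, "porter": 0.3},
            )
            p = rm.lrt_factor(table, spec, "category")
            hits += p < 1e-6
        assert hits == 5

    def test_null_p_not_tiny(self):
        spec = rm.ModelSpec("staff", "high", {"category": "HCW"})
        ps = []
        for seed in range(10):
            table = rm.simulate_outcome_table(1000, 5, {"porter": 0.0}, -1.0, 0.5, seed=400 + seed)
            ps.append(rm.lrt_factor(table, spec, "category"))
        assert np.median(ps) > 0.1

    def test_unknown_factor(self):
        spec = rm.ModelSpec("staff", "high", {"category": "HCW"})
        table = rm.simulate_outcome_table(500, 3, {"porter": 0.0}, -1.0, 0.3, seed=1)
        with pytest.raises(KeyError):
            rm.lrt_factor(table, spec, "gender")


class TestSensitivity:
    @staticmethod
    def _table_with_effect(seed=0, n=3000):
        rng = np.random.default_rng(seed)
        cat = rng.choice(["HCW", "porter"], size=n)
        ward = rng.choice([f"W{i}" for i in range(1, 6)], size=n)
        base = rng.gamma(4, 3, n) + np.where(cat == "porter", 8.0, 0.0)
        return pd.DataFrame(
            {
                "ward": ward,
                "category": cat,
                "freq_value": base,
                "dur_value": base * 60,
            }
        )

    def test_same_or_sign_across_k(self):
        table = self._table_with_effect()
        spec = rm.ModelSpec("staff", "high_freq", {"category": "HCW"})
        out = rm.sensitivity_analysis(table, spec, k_list=(0, 1))
        porter = out[(out["level"] == "porter") & out["converged"]]
        assert len(porter) == 2
        assert (porter["OR"] > 1).all()

    def test_single_k(self):
        table = self._table_with_effect()
        spec = rm.ModelSpec("staff", "high_freq", {"category": "HCW"})
        out = rm.sensitivity_analysis(table, spec, k_list=(1,))
        assert set(out["k"]) == {1}

    def test_frac_high_monotone(self):
        table = self._table_with_effect()
        spec = rm.ModelSpec("staff", "high_freq", {"category": "HCW"})
        out = rm.sensitivity_analysis(table, spec, k_list=(0, 1, 2, 3))
        fracs = out.groupby("k")["frac_high"].first()
        assert all(fracs.iloc[i] >= fracs.iloc[i + 1] for i in range(len(fracs) - 1))


class TestEndToEndSpecs:
    def test_staff_pipeline_fit(self, small_config, small_dataset):
        pds = cm.person_days(
            small_dataset.records, small_dataset.roster,
            small_config.gap_schedule, small_config.epoch,
        )
        table, _ = rm.build_outcome_table(pds, small_dataset.roster, "staff")
        dtable, thr = rm.dichotomize(table, k=1, population="staff")
        res = rm.fit_glmm(dtable, rm.staff_spec("high_freq"))
        assert res.converged
        assert set(res.lrt) == {"category", "day_of_week"}
        assert res.n_obs == len(table)
        # porters contact far more people than ward HCWs in the generator
        assert res.level_row("category", "hospital_porter").OR > 1
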
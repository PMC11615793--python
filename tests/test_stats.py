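"""Mixed models, growth rates and the Welch test."""

import numpy as np
import pandas as pd
import pytest

from fetalvol.stats import (
    best_scan_per_wave,
    change_rates,
    fit_wave_model,
    two_proportion_test,
    welch_t,
)
from fetalvol.synthetic import CohortSpec, simulate_cohort


class TestWaveModel:
    def test_recovers_generating_sex_effect(self):
        spec = CohortSpec(n_subjects=500, seed=21)
        table = simulate_cohort(spec, mode="per_wave")
        fit = fit_wave_model(table, "30w")
        est, se = fit.coefficients["sex"], fit.std_errors["sex"]
        assert abs(est - spec.sex_effect_ml["30w"]) < 3 * se
        assert fit.lrt_p < 1e-6
        assert fit.n_subjects == 500

    def test_null_effect_not_detected_too_often(self):
        hits = 0
        n_rep = 12
        for rep in range(n_rep):
            spec = CohortSpec(
                n_subjects=150, seed=1000 + rep,
                sex_effect_ml={"20w": 0.0, "30w": 0.0},
            )
            table = simulate_cohort(spec, mode="per_wave")
            fit = fit_wave_model(table, "20w")
            if abs(fit.coefficients["sex"]) < 3 * fit.std_errors["sex"]:
                hits += 1
        assert hits >= n_rep - 1

    def test_reduces_to_ols_without_random_structure(self):
        """One sweep per subject and no subject-level variance: fixed effects
        match ordinary least squares."""
        spec = CohortSpec(
            n_subjects=300, seed=5, subject_sd_ml=0.0, sweeps_per_wave=1
        )
        table = simulate_cohort(spec, mode="per_wave")
        # force exactly one row per subject at the wave
        sub = table[table["wave"] == "20w"].groupby("subject_id").head(1)
        fit = fit_wave_model(sub.assign(wave="20w"), "20w")
        age_c = sub["age_days"] - sub["age_days"].mean()
        X = np.column_stack(
            [np.ones(len(sub)), (sub["sex"] == "boy").astype(float), age_c, age_c**2]
        )
        beta = np.linalg.lstsq(X, sub["icv_ml"].to_numpy(), rcond=None)[0]
        for name, b in zip(("intercept", "sex", "age", "age2"), beta):
            assert fit.coefficients[name] == pytest.approx(b, abs=1e-4)

    def test_lrt_statistic_nonnegative(self):
        table = simulate_cohort(CohortSpec(n_subjects=120, seed=3), "per_wave")
        fit = fit_wave_model(table, "20w")
        assert fit.lrt_statistic >= 0.0

    def test_too_few_subjects_rejected(self):
        table = pd.DataFrame(
            {
                "subject_id": ["a", "b"],
                "sex": ["boy", "boy"],
                "wave": ["20w", "20w"],
                "age_days": [150, 151],
                "icv_ml": [80.0, 81.0],
                "qc_dsc": [0.95, 0.95],
            }
        )
        with pytest.raises(ValueError, match="subjects"):
            fit_wave_model(table, "20w")


def _table(rows):
    return pd.DataFrame(
        rows, columns=["subject_id", "sex", "wave", "age_days", "icv_ml", "qc_dsc"]
    )


class TestBestScan:
    def test_highest_qc_retained(self):
        t = _table(
            [
                ("s1", "boy", "20w", 150, 80.0, 0.92),
                ("s1", "boy", "20w", 150, 82.0, 0.97),
            ]
        )
        best = best_scan_per_wave(t)
        assert len(best) == 1
        assert best.iloc[0]["qc_dsc"] == 0.97

    def test_qc_tie_breaks_to_larger_icv(self):
        t = _table(
            [
                ("s1", "boy", "20w", 150, 80.0, 0.95),
                ("s1", "boy", "20w", 150, 84.0, 0.95),
            ]
        )
        assert best_scan_per_wave(t).iloc[0]["icv_ml"] == 84.0

    def test_row_count_matches_brute_force_groupby(self, rng):
        rows = []
        for i in range(60):
            sid = f"s{rng.integers(0, 12)}"
            wave = "20w" if rng.random() < 0.5 else "30w"
            rows.append(
                (sid, "girl", wave, int(rng.integers(140, 230)),
                 float(rng.uniform(50, 300)), float(rng.random()))
            )
        t = _table(rows)
        best = best_scan_per_wave(t)
        expected = len({(r[0], r[2]) for r in rows})
        assert len(best) == expected

    def test_invariant_to_row_order(self, rng):
        rows = [
            (f"s{i % 5}", "boy", w, 150, float(rng.uniform(50, 90)),
             float(rng.random()))
            for i in range(20)
            for w in ("20w", "30w")
        ]
        t = _table(rows)
        shuffled = t.sample(frac=1.0, random_state=4)
        a = best_scan_per_wave(t).reset_index(drop=True)
        b = best_scan_per_wave(shuffled).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


class TestChangeRates:
    def test_rate_arithmetic(self):
        t = _table(
            [
                ("s1", "boy", "20w", 150, 80.0, 0.95),
                ("s1", "boy", "30w", 200, 250.0, 0.96),
            ]
        )
        recs = change_rates(best_scan_per_wave(t))
        assert len(recs) == 1
        assert recs[0].rate_ml_per_day == pytest.approx(3.4)
        assert recs[0].delta_icv_ml == pytest.approx(170.0)
        assert recs[0].interval_days == 50

    def test_equal_volumes_give_zero_rate(self):
        t = _table(
            [
                ("s1", "girl", "20w", 150, 100.0, 0.95),
                ("s1", "girl", "30w", 210, 100.0, 0.96),
            ]
        )
        assert change_rates(best_scan_per_wave(t))[0].rate_ml_per_day == 0.0

    def test_subject_missing_a_wave_excluded(self):
        t = _table([("s1", "boy", "20w", 150, 80.0, 0.95)])
        assert change_rates(best_scan_per_wave(t)) == []

    def test_nonpositive_interval_warns_and_excludes(self):
        t = _table(
            [
                ("s1", "boy", "20w", 200, 80.0, 0.95),
                ("s1", "boy", "30w", 200, 250.0, 0.96),
            ]
        )
        with pytest.warns(UserWarning, match="interval"):
            assert change_rates(best_scan_per_wave(t)) == []


class TestWelch:
    def test_closed_form_equal_n_equal_variance(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert t == pytest.approx(-1.224745, abs=1e-5)
        assert df == pytest.approx(4.0)

    def test_identical_groups(self):
        t, _, p = welch_t([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert t == 0.0
        assert p == 1.0

    def test_matches_formula_oracle(self, rng):
        for _ in range(5):
            a = rng.normal(size=rng.integers(5, 20))
            b = rng.normal(loc=0.3, size=rng.integers(5, 20))
            t, df, p = welch_t(a, b)
            # textbook formulas
            va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
            t_ref = (a.mean() - b.mean()) / np.sqrt(va + vb)
            df_ref = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
            assert t == pytest.approx(t_ref, abs=1e-10)
            assert df == pytest.approx(df_ref, abs=1e-10)
            from scipy import stats as sps

            res = sps.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(res.statistic, abs=1e-10)
            assert p == pytest.approx(res.pvalue, abs=1e-10)


def test_two_proportion_chi2_matches_scipy_contingency():
    from scipy.stats import chi2_contingency

    chi2, p = two_proportion_test(646, 1231, 585, 1231)
    ref = chi2_contingency(
        np.array([[646, 1231 - 646], [585, 1231 - 585]]), correction=False
    )
    assert chi2 == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)
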
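import numpy as np
import pandas as pd
import pytest
from scipy import special

from fcentropy import (
    ParameterError,
    PipelineConfig,
    ValidationError,
    compare_groups,
    correlate_with_symptoms,
    residualize,
    run_full_comparison,
)
from fcentropy.stats import add_duration_stratum


class TestResidualize:
    def test_values_linear_in_age_collapse_to_grand_mean(self, rng):
        age = rng.uniform(20, 60, 30)
        values = 3.0 + 0.1 * age
        covs = np.column_stack([age, rng.integers(0, 2, 30), rng.uniform(0, 500, 30)])
        resid = residualize(values, covs)
        assert np.allclose(resid, values.mean(), atol=1e-10)

    def test_constant_covariate_column_is_inert(self, rng):
        values = rng.standard_normal(25)
        age = rng.uniform(20, 60, 25)
        with_zero = residualize(values, np.column_stack([age, np.zeros(25)]))
        without = residualize(values, age[:, None])
        assert np.allclose(with_zero, without)

    def test_residuals_orthogonal_to_covariates(self, rng):
        covs = np.column_stack(
            [rng.uniform(20, 60, 30), rng.integers(0, 2, 30), rng.uniform(0, 800, 30)]
        )
        resid = residualize(rng.standard_normal(30), covs) - 0.0
        centred = resid - resid.mean()
        for j in range(3):
            assert abs(centred @ (covs[:, j] - covs[:, j].mean())) < 1e-8

    def test_collinear_design_rejected(self, rng):
        age = rng.uniform(20, 60, 20)
        with pytest.raises(ValidationError, match="collinear"):
            residualize(rng.standard_normal(20), np.column_stack([age, 2 * age]))

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ParameterError):
            residualize(np.arange(4.0), rng.standard_normal((4, 3)))


class TestCompareGroups:
    def test_hand_computable_example(self):
        res = compare_groups([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.mean_patient - res.mean_control == pytest.approx(1.0)
        assert res.cohen_d == pytest.approx(1.0)
        assert res.direction == 1

    def test_identical_groups_are_null(self, rng):
        x = rng.standard_normal(10)
        res = compare_groups(x, x)
        assert res.t_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.cohen_d == 0.0

    def test_matches_textbook_formula(self, rng):
        """Pooled-variance t and its two-tailed p recomputed from the
        closed-form expressions."""
        x, y = rng.standard_normal(20), rng.standard_normal(20) + 0.4
        res = compare_groups(x, y)
        n1, n2 = 20, 20
        sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
        t = (y.mean() - x.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
        p = 2 * special.stdtr(df, -abs(t))  # two-tailed, from the t CDF
        assert res.t_stat == pytest.approx(t, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)
        assert res.cohen_d == pytest.approx(abs(y.mean() - x.mean()) / np.sqrt(sp2))

    def test_group_swap_symmetry(self, rng):
        x, y = rng.standard_normal(12), rng.standard_normal(15) + 1
        a, b = compare_groups(x, y), compare_groups(y, x)
        assert a.cohen_d == pytest.approx(b.cohen_d)
        assert a.t_stat == pytest.approx(-b.t_stat)
        assert a.p_value == pytest.approx(b.p_value)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ParameterError):
            compare_groups([1.0], [1.0, 2.0])
        with pytest.raises(ValidationError, match="pooled"):
            compare_groups([1.0, 1.0], [2.0, 2.0])


class TestSymptomCorrelation:
    def test_perfect_linear_relationships(self):
        fce = np.array([1.0, 2.0, 3.0, 4.0])
        r, _ = correlate_with_symptoms(fce, 2 * fce + 1)
        assert r == pytest.approx(1.0)
        r, _ = correlate_with_symptoms(fce, -fce)
        assert r == pytest.approx(-1.0)

    def test_p_matches_t_transform_oracle(self, rng):
        fce = rng.standard_normal(9)
        sspi = 0.5 * fce + rng.standard_normal(9)
        r, p = correlate_with_symptoms(fce, sspi)
        t = r * np.sqrt(7 / (1 - r**2))
        assert p == pytest.approx(2 * special.stdtr(7, -abs(t)), abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError):
            correlate_with_symptoms(np.ones(5), np.arange(5.0))
        with pytest.raises(ParameterError):
            correlate_with_symptoms(np.ones(2), np.ones(2))


def _cohort_frame(n_control=8, n_early=6, n_late=6, rng=None):
    rng = rng or np.random.default_rng(0)
    rows = []
    for i in range(n_control + n_early + n_late):
        grp = "control" if i < n_control else "patient"
        if grp == "patient":
            early = i < n_control + n_early
            duration = 2.0 if early else 8.0
            sspi = float(rng.uniform(5, 25))
            dose = float(rng.uniform(100, 800))
        else:
            duration, sspi, dose = np.nan, np.nan, 0.0
        rows.append(
            {
                "subject_id": f"s{i}",
                "group": grp,
                "age": float(rng.uniform(20, 50)),
                "sex": "M" if rng.uniform() < 0.5 else "F",
                "dose": dose,
                "duration": duration,
                "symptom_score": sspi,
            }
        )
    return pd.DataFrame(rows)


def _fce_frame(cohort, rng, strata=("whole_brain", "primary", "secondary", "tertiary")):
    rows = []
    for sid in cohort["subject_id"]:
        for s in strata:
            rows.append(
                {"subject_id": sid, "stratum": s, "entropy_bits": float(rng.normal(4, 0.3)),
                 "n_links": 100, "defined": True}
            )
    return pd.DataFrame(rows)


class TestFullComparison:
    def test_duration_split(self):
        cohort = add_duration_stratum(_cohort_frame())
        pats = cohort[cohort["group"] == "patient"]
        assert (pats["duration_stratum"] == "early").sum() == 6
        assert (pats["duration_stratum"] == "late").sum() == 6
        assert cohort.loc[cohort["group"] == "control", "duration_stratum"].isna().all()

    def test_patients_relabelled_from_controls_give_null_effects(self, rng):
        """If patient entropies are an exact copy of control entropies the
        standardized group differences vanish."""
        cohort = _cohort_frame(n_control=6, n_early=6, n_late=0, rng=rng)
        fce = _fce_frame(cohort, rng)
        controls = cohort[cohort["group"] == "control"]["subject_id"].tolist()
        patients = cohort[cohort["group"] == "patient"]["subject_id"].tolist()
        # copy control entropy values onto patients, and match covariates
        for c_id, p_id in zip(controls, patients):
            fce.loc[fce["subject_id"] == p_id, "entropy_bits"] = fce.loc[
                fce["subject_id"] == c_id, "entropy_bits"
            ].to_numpy()
            for col in ("age", "sex", "dose"):
                cohort.loc[cohort["subject_id"] == p_id, col] = cohort.loc[
                    cohort["subject_id"] == c_id, col
                ].to_numpy()
        report = run_full_comparison(cohort, fce)
        early = report[(report["duration_stratum"] == "early") & report["ok"]]
        assert np.allclose(early["cohen_d"], 0.0, atol=1e-10)

    def test_understaffed_stratum_flagged_others_computed(self, rng):
        cohort = _cohort_frame(n_control=6, n_early=5, n_late=1, rng=rng)
        report = run_full_comparison(cohort, _fce_frame(cohort, rng))
        assert not report[report["duration_stratum"] == "late"]["ok"].any()
        assert report[report["duration_stratum"] == "early"]["ok"].all()
        assert report.attrs["n_tests"] == int(report["ok"].sum())

    def test_missing_subject_rejected(self, rng):
        cohort = _cohort_frame(rng=rng)
        fce = _fce_frame(cohort.iloc[:-1], rng)
        with pytest.raises(ValidationError, match="missing"):
            run_full_comparison(cohort, fce)

    def test_control_subset_column_restricts_controls(self, rng):
        cohort = _cohort_frame(rng=rng)
        cohort["control_subset"] = "both"
        controls = cohort["group"] == "control"
        cohort.loc[controls, "control_subset"] = ["early"] * 4 + ["late"] * 4
        report = run_full_comparison(cohort, _fce_frame(cohort, rng))
        assert (report.loc[report["duration_stratum"] == "early", "n_control"] == 4).all()

    def test_undefined_stratum_drops_subject_not_block(self, rng):
        cohort = _cohort_frame(rng=rng)
        fce = _fce_frame(cohort, rng)
        sid = cohort["subject_id"].iloc[0]
        mask = (fce["subject_id"] == sid) & (fce["stratum"] == "tertiary")
        fce.loc[mask, "defined"] = False
        report = run_full_comparison(cohort, fce)
        ter = report[(report["stratum"] == "tertiary") & (report["duration_stratum"] == "early")]
        assert int(ter["n_control"].iloc[0]) == 7  # one control dropped

    def test_duration_cutoff_from_config(self, rng):
        cohort = _cohort_frame(rng=rng)
        report = run_full_comparison(
            cohort, _fce_frame(cohort, rng), PipelineConfig(duration_cutoff=10.0)
        )
        assert not report[report["duration_stratum"] == "late"]["ok"].any()
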
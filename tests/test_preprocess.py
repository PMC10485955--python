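"""Metabolite QC, control-only age adjustment and covariate designs."""

import numpy as np
import pandas as pd
import pytest

from t2domics import preprocess
from t2domics.preprocess import (
    AgeAdjustModel,
    DesignError,
    age_residualize,
    build_covariates,
    fit_age_model,
    metabolite_qc,
)
from t2domics.simulate import MetaboliteMatrix


def _panel(values: np.ndarray, ids=None) -> MetaboliteMatrix:
    ids = ids or [f"m{k}" for k in range(values.shape[0])]
    idx = pd.Index(ids, name="metabolite")
    samples = pd.Index([f"S{i}" for i in range(values.shape[1])], name="sample")
    info = pd.DataFrame({"pathway": "p", "subpathway": "s"}, index=idx)
    return MetaboliteMatrix(values=pd.DataFrame(values, index=idx, columns=samples), info=info)


class TestMetaboliteQC:
    def test_constant_metabolite_dropped(self):
        raw = _panel(np.vstack([np.full(50, 7.0), np.exp(np.linspace(0, 1, 50))]))
        cleaned, report = metabolite_qc(raw)
        assert "m0" not in cleaned.values.index
        assert report.loc["m0", "dropped_reason"] == "zero_variance"
        assert "m1" in cleaned.values.index

    def test_outlier_masked_and_zscores_exact(self, rng):
        base = rng.normal(5.0, 0.1, 200)
        log_sd = np.log(base).std(ddof=1)
        vals = base.copy()
        vals[0] = np.exp(np.log(base).mean() + 4 * log_sd)  # one +4 SD cell
        cleaned, report = metabolite_qc(_panel(vals[None, :]))
        z = cleaned.values.iloc[0]
        assert np.isnan(z.iloc[0])
        assert report.loc["m0", "n_outliers"] == 1
        rest = z.dropna()
        assert abs(rest.mean()) < 1e-12
        assert abs(rest.std(ddof=1) - 1) < 1e-12

    def test_panel_without_outliers_passes_through_whole(self, rng):
        vals = np.exp(rng.normal(2.0, 0.2, size=(30, 100)))
        cleaned, _ = metabolite_qc(_panel(vals))
        assert len(cleaned.values) == 30  # nothing dropped

    def test_nonpositive_values_warned_and_masked(self, rng):
        vals = np.exp(rng.normal(0, 1, size=(1, 40)))
        vals[0, 3] = -1.0
        with pytest.warns(UserWarning, match="non-positive"):
            cleaned, report = metabolite_qc(_panel(vals))
        assert report.loc["m0", "n_nonpositive"] == 1
        assert np.isnan(cleaned.values.iloc[0, 3])

    def test_qc_idempotent_on_its_own_output(self, rng):
        # bounded draws: no cell can sit beyond 3 SD, so the second pass
        # (without the log step) must reproduce the z-scores exactly
        vals = np.exp(rng.uniform(0.5, 1.5, size=(20, 150)))
        cleaned, report = metabolite_qc(_panel(vals))
        assert (report["n_outliers"] == 0).all()
        again, _ = metabolite_qc(cleaned, log_transform=False)
        a = cleaned.values.to_numpy()
        b = again.values.to_numpy()
        assert a.shape == b.shape
        assert np.allclose(a, b, atol=1e-12)

    def test_excess_missingness_dropped(self, rng):
        vals = np.exp(rng.normal(0, 1, size=(1, 40)))
        vals[0, :20] = np.nan
        cleaned, report = metabolite_qc(_panel(vals))
        assert len(cleaned.values) == 0
        assert report.loc["m0", "dropped_reason"] == "missingness"


class TestAgeModel:
    def _data(self, rng, n=120, slope=0.01, noise=0.0):
        age = pd.Series(rng.uniform(20, 70, n),
                        index=pd.Index([f"S{i}" for i in range(n)], name="sample"))
        controls = pd.Series(rng.random(n) < 0.6, index=age.index)
        y = 0.3 + slope * age + rng.normal(0, noise, n)
        cpgs = pd.DataFrame([y], index=pd.Index(["cgA"], name="cpg"), columns=age.index)
        return cpgs, age, controls

    def test_exact_linear_relation_recovered(self, rng):
        cpgs, age, controls = self._data(rng, slope=0.01, noise=0.0)
        model = fit_age_model(cpgs, age, controls)
        assert model.coef.loc["cgA", "beta1"] == pytest.approx(0.01, abs=1e-10)
        assert model.coef.loc["cgA", "beta0"] == pytest.approx(0.3, abs=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        cpgs, age, controls = self._data(rng, slope=0.004, noise=0.02)
        model = fit_age_model(cpgs, age, controls)
        # oracle: (X'X)^-1 X'y on the control subset, coded by hand
        a = age[controls].to_numpy()
        y = cpgs.loc["cgA", controls[controls].index].to_numpy()
        X = np.column_stack([np.ones_like(a), a])
        b0, b1 = np.linalg.solve(X.T @ X, X.T @ y)
        assert model.coef.loc["cgA", "beta1"] == pytest.approx(b1, abs=1e-10)
        assert model.coef.loc["cgA", "beta0"] == pytest.approx(b0, abs=1e-10)

    def test_age_independent_cpg_has_null_slope(self, rng):
        n = 300
        age = pd.Series(rng.uniform(20, 70, n),
                        index=pd.Index([f"S{i}" for i in range(n)], name="sample"))
        controls = pd.Series(np.ones(n, dtype=bool), index=age.index)
        y = rng.normal(0.5, 0.05, n)
        cpgs = pd.DataFrame([y], index=pd.Index(["cgA"], name="cpg"), columns=age.index)
        model = fit_age_model(cpgs, age, controls)
        slope = model.coef.loc["cgA", "beta1"]
        se = 0.05 / (age.std() * np.sqrt(n))
        assert abs(slope) < 3 * se

    def test_fit_uses_controls_only(self, rng):
        cpgs, age, controls = self._data(rng, slope=0.01, noise=0.0)
        # corrupt the cases wildly; control-only fit must not move
        corrupted = cpgs.copy()
        corrupted.loc["cgA", ~controls] = 99.0
        model = fit_age_model(corrupted, age, controls)
        assert model.coef.loc["cgA", "beta1"] == pytest.approx(0.01, abs=1e-10)
        assert model.n_controls == int(controls.sum())

    def test_degenerate_age_rejected(self):
        idx = pd.Index([f"S{i}" for i in range(10)], name="sample")
        age = pd.Series(50.0, index=idx)
        controls = pd.Series(True, index=idx)
        cpgs = pd.DataFrame(np.random.default_rng(0).random((1, 10)),
                            index=["cgA"], columns=idx)
        with pytest.raises(DesignError):
            fit_age_model(cpgs, age, controls)

    def test_residualization_removes_control_age_trend(self, rng):
        # OLS residual orthogonality: in controls the adjusted values are the
        # fit residuals, exactly uncorrelated with age
        cpgs, age, controls = self._data(rng, slope=0.01, noise=0.02)
        model = fit_age_model(cpgs, age, controls)
        adj = age_residualize(cpgs, age, model)
        r = np.corrcoef(adj.loc["cgA", controls[controls].index], age[controls])[0, 1]
        assert abs(r) < 1e-10

    def test_zero_slope_model_just_centers(self):
        idx = pd.Index([f"S{i}" for i in range(5)], name="sample")
        cpgs = pd.DataFrame([[0.4, 0.5, 0.6, 0.7, 0.8]], index=["cgA"], columns=idx)
        age = pd.Series([30.0, 40, 50, 60, 70], index=idx)
        model = AgeAdjustModel(
            coef=pd.DataFrame({"beta0": [0.1], "beta1": [0.0]}, index=["cgA"]),
            n_controls=5,
        )
        adj = age_residualize(cpgs, age, model)
        assert np.allclose(adj.loc["cgA"], cpgs.loc["cgA"] - 0.1)

    def test_case_specific_slope_survives_partially(self, rng):
        # controls follow one age line, cases a steeper one: subtracting the
        # control line must leave a residual age trend in cases (brute-force
        # two-group simulation as the oracle)
        n = 400
        idx = pd.Index([f"S{i}" for i in range(n)], name="sample")
        age = pd.Series(rng.uniform(30, 60, n), index=idx)
        is_control = pd.Series(np.arange(n) < n // 2, index=idx)
        y = np.where(is_control, 0.2 + 0.002 * age, 0.2 + 0.006 * age)
        cpgs = pd.DataFrame([y], index=pd.Index(["cgA"], name="cpg"), columns=idx)
        model = fit_age_model(cpgs, age, is_control)
        adj = age_residualize(cpgs, age, model)
        cases = ~is_control
        r_cases = np.corrcoef(adj.loc["cgA", idx[cases]], age[cases])[0, 1]
        assert r_cases > 0.99  # residual slope 0.004 with zero noise


class TestCovariates:
    def test_mwas_design_is_exactly_age_sex_bmi_pcs(self, cohort, prepared):
        cov = build_covariates(cohort["samples"], None, None, "mwas",
                               gpcs=prepared["gpcs"])
        assert list(cov.columns) == ["intercept", "age", "sex", "bmi",
                                     "gPC1", "gPC2", "gPC3"]

    def test_bmi_models_differ_by_one_column(self, cohort, prepared):
        a = build_covariates(cohort["samples"], cohort["methylation"], None,
                             "ewas_noBMI", gpcs=prepared["gpcs"])
        b = build_covariates(cohort["samples"], cohort["methylation"], None,
                             "ewas_BMI", gpcs=prepared["gpcs"])
        assert set(b.columns) - set(a.columns) == {"bmi"}
        assert set(a.columns) - set(b.columns) == set()

    def test_meqtl_design_adds_disease_bmi_age(self, cohort, prepared):
        a = build_covariates(cohort["samples"], cohort["methylation"], None,
                             "ewas_noBMI", gpcs=prepared["gpcs"])
        m = build_covariates(cohort["samples"], cohort["methylation"], None,
                             "meqtl", gpcs=prepared["gpcs"])
        assert set(m.columns) - set(a.columns) == {"t2d", "bmi", "age"}

    def test_genomic_pcs_orthonormal(self, prepared):
        pcs = prepared["gpcs"].to_numpy()
        assert np.allclose(pcs.T @ pcs, np.eye(3), atol=1e-8)

    def test_genomic_pcs_track_ancestry(self, cohort, prepared):
        anc = cohort["truth"].ancestry
        pc1 = prepared["gpcs"].to_numpy()[:, 0]
        assert abs(np.corrcoef(anc, pc1)[0, 1]) > 0.3

    def test_designs_full_rank(self, cohort, prepared):
        for tag in preprocess.MODEL_TAGS:
            cov = prepared["covariates"][tag]
            X = cov.to_numpy(dtype=float)
            assert np.linalg.matrix_rank(X) == X.shape[1], tag

    def test_unknown_tag_rejected(self, cohort, prepared):
        with pytest.raises(DesignError):
            build_covariates(cohort["samples"], cohort["methylation"], None,
                             "nonsense", gpcs=prepared["gpcs"])
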
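"""Mixed-model tests: oracles, cross-checks and inference helpers."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import basic_spec, make_records
from hearbeat.config import ModelSpec
from hearbeat.models import (
    _Engine,
    build_design,
    fit_effect_null,
    dense_loglik,
    fit_lme_ar1,
    fit_model,
    gvif,
    interaction_contrasts,
    likelihood_ratio_test,
    null_spec_for,
    partial_r2,
    percent_change,
)


class TestDesign:
    def test_standardized_columns_have_zero_mean_unit_sd(self, toy_records):
        d = build_design(toy_records, ModelSpec(fixed="acoustic"))
        for j, name in enumerate(d.x_names):
            if name in ("spl", "sml", "snr"):
                assert abs(d.X[:, j].mean()) < 1e-10
                assert abs(d.X[:, j].std(ddof=0) - 1.0) < 1e-10

    def test_soundscape_dummies_quiet_reference(self, toy_records):
        d = build_design(toy_records, ModelSpec(fixed="soundscape"))
        dummies = [n for n in d.x_names if n.startswith("soundscape[")]
        assert len(dummies) == 3
        assert "soundscape[Quiet]" not in d.x_names

    def test_interaction_collapses_to_three_levels(self, toy_records):
        d = build_design(toy_records, ModelSpec(fixed="interaction"))
        assert set(d.records["soundscape_collapsed"]) == {"Quiet", "Speech", "Noisy"}
        assert "spl:Noisy" in d.x_names and "spl:Speech" in d.x_names

    def test_constant_predictor_rejected(self, toy_records):
        bad = toy_records.copy()
        bad["spl"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            build_design(bad, ModelSpec(fixed="acoustic"))

    def test_missing_fields_rejected(self, toy_records):
        with pytest.raises(ValueError, match="missing fields"):
            build_design(toy_records.drop(columns=["snr"]), ModelSpec(fixed="acoustic"))


class TestLikelihoodOracles:
    def test_structured_loglik_equals_dense_mvn(self):
        """Whitened/Woodbury likelihood == brute-force dense Gaussian."""
        rec = make_records(n_participants=3, n_per=40, beta=[1.0, 0.5, -0.5],
                           sd_intercept=2.0, sd_resid=1.5, phi=0.4, seed=2)
        spec = ModelSpec(fixed="acoustic")
        d = build_design(rec, spec)
        eng = _Engine(d)
        K = len(d.level_names)
        theta = np.concatenate([np.log(np.full(K, 0.3)), [np.arctanh(0.35)]])
        prof = eng.profile(theta)
        ll_dense = dense_loglik(d, prof["lam"], prof["phi"], prof["sigma2"],
                                prof["beta"])
        assert prof["ll"] == pytest.approx(ll_dense, abs=1e-8)

    def test_zero_variance_zero_phi_collapse_to_ols(self):
        """At lambda -> 0, phi = 0 the GLS coefficients are exactly OLS."""
        rec = make_records(n_participants=4, n_per=30, beta=[1.2, 0.0, -0.7],
                           sd_intercept=0.0, sd_resid=1.0, phi=0.0, seed=3)
        spec = ModelSpec(fixed="acoustic")
        d = build_design(rec, spec)
        eng = _Engine(d)
        K = len(d.level_names)
        theta = np.concatenate([np.full(K, -34.0), [0.0]])
        prof = eng.profile(theta)
        beta_ols, *_ = np.linalg.lstsq(d.X, d.y, rcond=None)
        assert np.allclose(prof["beta"], beta_ols, atol=1e-6)
        # and the full optimizer lands near OLS too on RE-free data
        fit = fit_lme_ar1(d, spec)
        assert np.allclose(fit.beta.to_numpy(), beta_ols, atol=5e-2)

    def test_reml_matches_statsmodels_random_intercept(self):
        """phi=0 random-intercept model agrees with statsmodels MixedLM."""
        from statsmodels.regression.mixed_linear_model import MixedLM

        rec = make_records(n_participants=10, n_per=25, sd_intercept=2.0,
                           sd_resid=1.3, seed=4)
        rec["movement"] = rec["spl"]
        spec = basic_spec(ar1=False)
        fit = fit_lme_ar1(build_design(rec, spec), spec)
        sm_fit = MixedLM.from_formula("hr ~ movement", groups="participant_id",
                                      data=rec).fit(reml=False)
        assert fit.beta["movement"] == pytest.approx(sm_fit.fe_params["movement"],
                                                     abs=1e-5)
        assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-5)

    def test_ar1_fit_matches_r_nlme(self, tmp_path):
        """Full AR(1) random-intercept ML fit reproduces nlme::lme + corAR1."""
        rec = make_records(n_participants=8, n_per=40, sd_intercept=2.0,
                           sd_resid=1.4, phi=0.5, seed=11)
        rec["movement"] = rec["spl"]
        spec = basic_spec(ar1=True)
        fit = fit_lme_ar1(build_design(rec, spec), spec)
        csv = tmp_path / "d.csv"
        rec.to_csv(csv, index=False)
        r_code = f'''
suppressMessages(library(nlme))
d <- read.csv("{csv}")
m <- lme(hr ~ movement, random = ~1|participant_id,
         correlation = corAR1(form = ~1|participant_id), data = d, method = "ML")
cat(sprintf("%.8f %.8f %.8f %.8f",
    fixef(m)[2], coef(m$modelStruct$corStruct, unconstrained=FALSE),
    logLik(m), m$sigma))
'''
        out = subprocess.run(["Rscript", "-e", r_code], capture_output=True,
                             text=True, timeout=240)
        assert out.returncode == 0, out.stderr
        slope, phi, ll, sigma = map(float, out.stdout.split())
        assert fit.beta["movement"] == pytest.approx(slope, abs=1e-4)
        assert fit.phi == pytest.approx(phi, abs=1e-3)
        assert fit.loglik == pytest.approx(ll, abs=1e-3)
        assert np.sqrt(fit.sigma2) == pytest.approx(sigma, rel=1e-3)


class TestInference:
    def test_lrt_identical_models_gives_zero(self):
        rec = make_records(n_participants=4, n_per=30, sd_intercept=1.0, seed=5)
        spec = basic_spec(estimation="ML")
        fit = fit_lme_ar1(build_design(rec, spec), spec)
        chi2, df, p = likelihood_ratio_test(fit, fit)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert df == 0 and p == 1.0

    def test_lrt_df_counts_fixed_and_random_slope_parameters(self, toy_records):
        """Acoustic vs intercept-only df = 6: 3 slopes + 3 slope variances."""
        spec = ModelSpec(fixed="acoustic")
        full = fit_model(toy_records, spec)
        null = fit_model(toy_records, null_spec_for(spec, keep_random_slopes=False))
        chi2, df, p = likelihood_ratio_test(full, null)
        assert df == 6
        assert chi2 == pytest.approx(2 * (full.loglik - null.loglik), rel=1e-12)

    def test_lrt_rejects_reml(self):
        rec = make_records(n_participants=4, n_per=25, seed=6)
        spec = basic_spec(estimation="REML")
        fit = fit_lme_ar1(build_design(rec, spec), spec)
        with pytest.raises(ValueError, match="ML"):
            likelihood_ratio_test(fit, fit)

    def test_percent_change_closed_forms(self):
        assert percent_change(0.0) == 0.0
        assert percent_change(np.log(2.0)) == pytest.approx(100.0)
        assert percent_change(0.0015388) == pytest.approx(0.154, abs=5e-4)


class TestGvif:
    def _design(self, R, n=4000, seed=0):
        rng = np.random.default_rng(seed)
        L = np.linalg.cholesky(R)
        X = rng.standard_normal((n, R.shape[0])) @ L.T
        return pd.DataFrame(X, columns=[f"x{j}" for j in range(R.shape[0])])

    def test_orthogonal_predictors_give_unity(self):
        X = self._design(np.eye(2), n=200000)
        out = gvif(X)
        assert np.allclose(out.to_numpy(), 1.0, atol=0.02)

    def test_pairwise_correlation_09_gives_vif_5263(self):
        """VIF = 1/(1-r^2): exact on the analytic correlation matrix."""
        R = np.array([[1.0, 0.9], [0.9, 1.0]])
        # bypass sampling noise: feed data whose empirical correlation is R
        X = self._design(R, n=300000, seed=1)
        emp = np.corrcoef(X.to_numpy(), rowvar=False)
        expected = 1.0 / np.linalg.det(emp)  # closed form for 2 columns
        out = gvif(X)
        assert out["x0"] == pytest.approx(expected, rel=1e-9)
        assert out["x0"] == pytest.approx(1.0 / (1.0 - 0.81), rel=0.02)

    def test_three_predictor_matrix_oracle(self):
        R = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.3], [0.2, 0.3, 1.0]])
        X = self._design(R, n=100000, seed=2)
        emp = np.corrcoef(X.to_numpy(), rowvar=False)
        out = gvif(X)
        for j in range(3):
            rest = [k for k in range(3) if k != j]
            expected = (np.linalg.det(emp[np.ix_(rest, rest)]) /
                        np.linalg.det(emp))
            assert out[f"x{j}"] == pytest.approx(expected, rel=1e-9)

    def test_rescaling_invariance(self):
        X = self._design(np.array([[1.0, 0.6], [0.6, 1.0]]), n=5000, seed=3)
        a = gvif(X)
        X2 = X.copy()
        X2["x0"] = X2["x0"] * 123.4 + 7.0
        b = gvif(X2)
        assert a["x0"] == pytest.approx(b["x0"], rel=1e-9)

    def test_singular_matrix_rejected(self):
        X = self._design(np.eye(2), n=500)
        X["x2"] = X["x0"]
        with pytest.raises(ValueError, match="singular"):
            gvif(X)


class TestEffectSizes:
    def test_full_equals_null_gives_zero_rp2(self, toy_records):
        spec = ModelSpec(fixed="intercept")
        spec.slope_vars = ()
        a = fit_model(toy_records, spec)
        b = fit_model(toy_records, spec)
        rep = partial_r2(a, b)
        assert rep.rp2 == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_fixed_effect_data_approach_unit_rp2(self):
        rec = make_records(n_participants=5, n_per=60, beta=[3.0, 1.0, -2.0],
                           sd_intercept=0.0, sd_resid=1e-3, seed=7)
        spec = ModelSpec(fixed="acoustic")
        full = fit_model(rec, spec)
        rep = partial_r2(full, fit_effect_null(full))
        assert rep.rp2 > 0.999
        assert rep.rf2 > 0.999

    def test_level_ss_match_dense_blup_oracle(self):
        """Level-wise residual SS agree with dense-matrix BLUP algebra."""
        rec = make_records(n_participants=3, n_per=30, beta=[1.0, 0.0, 0.0],
                           sd_intercept=1.5, sd_resid=1.0, phi=0.3, seed=8)
        spec = ModelSpec(fixed="acoustic")
        d = build_design(rec, spec)
        fit = fit_lme_ar1(d, spec)
        # dense BLUPs: b = lam * U' V^-1 (y - X beta)
        lam = np.array([fit.variance_components[n] / fit.sigma2
                        for n in d.level_names])
        day_id = np.cumsum(d.day_start) - 1
        n = d.n
        C = np.zeros((n, n))
        for b_ in np.unique(day_id):
            rows = np.flatnonzero(day_id == b_)
            idx = np.arange(rows.size)
            C[np.ix_(rows, rows)] = fit.phi ** np.abs(idx[:, None] - idx[None, :])
        V = C.copy()
        for sl in d.part_slices:   # effects are independent per participant
            for j in range(d.U.shape[1]):
                V[sl, sl] += lam[d.level_of_col[j]] * np.outer(d.U[sl, j], d.U[sl, j])
        r = d.y - d.X @ fit.beta.to_numpy()
        alpha = np.linalg.solve(V, r)
        resid_dense = r.copy()
        for k, sl in enumerate(d.part_slices):
            blups_p = np.array([lam[d.level_of_col[j]] * d.U[sl, j] @ alpha[sl]
                                for j in range(d.U.shape[1])])
            resid_dense[sl] -= d.U[sl] @ blups_p
        assert np.allclose(fit.resid(), resid_dense, atol=1e-8)

    def test_mismatched_random_structures_rejected(self, toy_records):
        spec = ModelSpec(fixed="acoustic")
        full = fit_model(toy_records, spec)
        null = fit_model(toy_records, null_spec_for(spec, keep_random_slopes=False))
        with pytest.raises(ValueError, match="random structure"):
            partial_r2(full, null)


class TestInteractionContrasts:
    def test_contrast_equals_stratified_ols_on_re_free_toy(self):
        """Interaction coefficients == per-class OLS slope differences."""
        rng = np.random.default_rng(9)
        n = 1200
        cls = rng.choice(["Quiet", "Speech", "Noise"], size=n)
        x = rng.standard_normal((n, 3))
        slope_spl = {"Quiet": 1.0, "Speech": 1.3, "Noise": 0.2}
        y = 70 + np.array([slope_spl[c] for c in cls]) * x[:, 0] + \
            0.5 * x[:, 1] - 0.2 * x[:, 2] + rng.normal(0, 0.3, n)
        base = pd.Timestamp("2019-06-03 09:00:00")
        rec = pd.DataFrame({
            "participant_id": np.repeat([f"P{k}" for k in range(4)], n // 4),
            "timestamp": [base + pd.Timedelta(minutes=2 * i) for i in range(n)],
            "hr": y, "spl": x[:, 0], "sml": x[:, 1], "snr": x[:, 2],
            "soundscape": cls, "date": "2019-06-03", "weekday": 0, "hour": 9})
        spec = ModelSpec(fixed="interaction")
        d = build_design(rec, spec)
        eng = _Engine(d)
        K = len(d.level_names)
        prof = eng.profile(np.concatenate([np.full(K, -34.0), [0.0]]))
        beta = pd.Series(prof["beta"], index=d.x_names)

        # stratified OLS oracle per collapsed class on the standardized data
        zs = {v: (rec[v] - rec[v].mean()) / rec[v].std(ddof=0)
              for v in ("spl", "sml", "snr")}
        coll = np.where(np.isin(cls, ["Noise"]), "Noisy", cls)
        slopes = {}
        for c in ("Quiet", "Speech", "Noisy"):
            m = coll == c
            Xc = np.column_stack([np.ones(m.sum())] + [zs[v][m] for v in
                                                       ("spl", "sml", "snr")])
            bc, *_ = np.linalg.lstsq(Xc, y[m], rcond=None)
            slopes[c] = bc[1]
        assert beta["spl:Noisy"] == pytest.approx(slopes["Noisy"] - slopes["Quiet"],
                                                  abs=1e-6)
        assert beta["spl:Speech"] == pytest.approx(slopes["Speech"] - slopes["Quiet"],
                                                   abs=1e-6)

    def test_missing_interaction_terms_rejected(self, toy_records):
        fit = fit_model(toy_records, ModelSpec(fixed="acoustic"))
        with pytest.raises(ValueError, match="interaction"):
            interaction_contrasts(fit)

    def test_null_interactions_yield_small_contrasts(self):
        rec = make_records(n_participants=6, n_per=60, beta=[1.0, 0.3, -0.5],
                           sd_intercept=1.0, sd_resid=1.0, seed=10)
        fit = fit_model(rec, ModelSpec(fixed="interaction"))
        tab = interaction_contrasts(fit)
        assert np.all(np.abs(tab["estimate"]) < 5 * tab["se"] + 0.3)


class TestCoverage:
    def test_wald_ci_covers_generative_slope(self):
        """95% Wald CIs cover the generative coefficient in most replicates."""
        hits = total = 0
        for seed in range(12):
            rec = make_records(n_participants=6, n_per=40, beta=[1.0, 0.5, -0.5],
                               sd_intercept=1.5, sd_resid=1.2, phi=0.3, seed=seed)
            # betas apply to raw columns; standardization rescales them by the
            # realized pooled sd, so compare on that scale
            fit = fit_model(rec, ModelSpec(fixed="acoustic"))
            for name, b in (("spl", 1.0), ("sml", 0.5), ("snr", -0.5)):
                target = b * rec[name].std(ddof=0)
                hits += fit.ci_lower[name] <= target <= fit.ci_upper[name]
                total += 1
        assert hits / total >= 0.85
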
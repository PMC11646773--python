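"""Core mixed-model fitter: closed-form and external-package oracles."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest

from posturekit.exceptions import ParameterError
from posturekit.glmm import fit_glmm_core, wald_f
from posturekit.mixedstats import build_design, fit_glmm
from posturekit.synthio import CohortDesign, EffectSpec, outcomes_table, simulate_cohort


def _two_group_data(n_per=30, noise=1.0, effect=2.0, seed=0):
    rng = np.random.default_rng(seed)
    g = np.repeat([0.0, 1.0], n_per)
    y = 5.0 + effect * g + noise * rng.standard_normal(2 * n_per)
    X = np.column_stack([np.ones(2 * n_per), g])
    subjects = np.arange(2 * n_per)  # one observation per subject
    Z = np.ones((2 * n_per, 1))
    return X, y, subjects, Z


class TestGaussianCore:
    def test_zero_re_variance_equals_ols(self):
        # balanced two-group data, no subject effect: GLS reduces to OLS
        X, y, subjects, Z = _two_group_data()
        res = fit_glmm_core(X, y, subjects, Z, "gaussian")
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.abs(res.beta - beta_ols).max() < 1e-6

    def test_single_subject_rejected(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        y = np.arange(10.0)
        with pytest.raises(ParameterError, match="single subject"):
            fit_glmm_core(X, y, np.zeros(10), np.ones((10, 1)), "gaussian")

    def test_wald_f_matches_t_square_for_ols_case(self):
        X, y, subjects, Z = _two_group_data(seed=3)
        res = fit_glmm_core(X, y, subjects, Z, "gaussian")
        F, df1, df2, p = wald_f(res, [1])
        # classic two-sample t on the same data (equal variances)
        from scipy import stats

        t = stats.ttest_ind(y[X[:, 1] == 1], y[X[:, 1] == 0]).statistic
        assert F == pytest.approx(t**2, rel=1e-4)
        assert df1 == 1 and df2 == len(y) - 2

    def test_matches_statsmodels_mixedlm(self, small_outcomes):
        """Independent-oracle check of the normal-family REML path."""
        import statsmodels.formula.api as smf
        from statsmodels.regression.mixed_linear_model import MixedLMParams

        spec = build_design(small_outcomes, "H2", "d2_completed")
        fit = fit_glmm(spec)
        df = spec.data.copy()
        df["time_c"] = np.where(df["time"] == "t2", 1.0, -1.0)
        df["skate_c"] = np.where(df["Skating"] == 1, 1.0, -1.0)
        df["inter"] = df["time_c"] * df["skate_c"]
        df["post"] = (df["time"] == "t2").astype(float)
        md = smf.mixedlm(
            "value ~ time_c + skate_c + inter + Age + Medication",
            df,
            groups=df["subject"],
            re_formula="~post",
        )
        free = MixedLMParams.from_components(fe_params=np.ones(6), cov_re=np.eye(2))
        mfit = md.fit(reml=True, free=free, method="lbfgs")
        scale = np.abs(mfit.fe_params.values).max()
        assert np.abs(fit.glmm.beta - mfit.fe_params.values).max() < 5e-3 * scale
        assert fit.glmm.phi == pytest.approx(mfit.scale, rel=0.02)
        re_sm = np.diag(mfit.cov_re.values)
        re_pk = np.array(list(fit.glmm.re_var.values()))
        assert np.abs(re_pk - re_sm).max() < 0.05 * max(re_sm.max(), fit.glmm.phi)


class TestGammaCore:
    def test_nonpositive_response_rejected(self):
        X = np.ones((10, 1))
        y = np.r_[np.ones(9), 0.0]
        with pytest.raises(ParameterError, match="positive"):
            fit_glmm_core(X, y, np.arange(10) % 5, np.ones((10, 1)), "gamma")

    def test_coefficient_recovery_within_3se(self):
        """Over repeated simulated cohorts at truth, the time coefficient on
        the linear-predictor scale stays within 3 SE of its programmed value
        in nearly all seeds."""
        design = CohortDesign((16, 12, 6), n_trials=5)
        effects = EffectSpec(re_sd_intercept=0.08, re_sd_slope=0.02)
        base = effects.baseline_error["balance"]
        hits = 0
        n_seeds = 25
        for s in range(n_seeds):
            cohort = simulate_cohort(design, effects, seed=900 + s)
            out = outcomes_table(cohort)
            fit = fit_glmm(build_design(out, "H2", "balance"))
            j = fit.names.index("Time")
            # programmed predictor change averaged over the two skating arms
            eta = {}
            for skate in (0, 1):
                mu1 = base * effects.adhd_effect
                mu2 = mu1 * effects.time_effect * (
                    effects.interaction_effect if skate else 1.0
                )
                eta[skate] = (1 / mu2 - 1 / mu1) / 2
            expected = np.mean([eta[0], eta[1]])
            se = fit.glmm.se()[j]
            hits += abs(fit.glmm.beta[j] - expected) <= 3 * se
        assert hits / n_seeds >= 0.9

    def test_dispersion_estimates_gamma_shape(self, small_outcomes):
        spec = build_design(small_outcomes, "H2", "balance")
        fit = fit_glmm(spec)
        # phi ~ 1/shape = 0.1 for the generator default
        assert fit.glmm.phi == pytest.approx(0.1, rel=0.35)

    def test_matches_glmmtmb_oracle(self, tmp_path, small_outcomes):
        """Laplace-ML fit from R's glmmTMB agrees with the PQL fit within a
        small fraction of a standard error on every fixed effect."""
        spec = build_design(small_outcomes, "H2", "balance")
        fit = fit_glmm(spec)
        df = spec.data.copy()
        df["time_c"] = np.where(df["time"] == "t2", 1.0, -1.0)
        df["skate_c"] = np.where(df["Skating"] == 1, 1.0, -1.0)
        df["inter"] = df["time_c"] * df["skate_c"]
        df["post"] = (df["time"] == "t2").astype(float)
        csv = tmp_path / "fixture.csv"
        df[["subject", "value", "time_c", "skate_c", "inter", "Age", "Medication", "post"]].to_csv(
            csv, index=False
        )
        rscript = tmp_path / "oracle.R"
        rscript.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(glmmTMB))
                d <- read.csv("{csv}")
                d$v <- d$value / 100
                m <- glmmTMB(v ~ time_c + skate_c + inter + Age + Medication
                             + (1 + post || subject),
                             family = Gamma(link = "inverse"), data = d)
                co <- summary(m)$coefficients$cond
                cat("BETA", co[,1] / 100, "\\n")
                cat("SE", co[,2] / 100, "\\n")
                """
            )
        )
        proc = subprocess.run(
            ["Rscript", str(rscript)], capture_output=True, text=True, timeout=300
        )
        assert proc.returncode == 0, proc.stderr
        lines = {l.split()[0]: np.array(l.split()[1:], float)
                 for l in proc.stdout.splitlines() if l.startswith(("BETA", "SE"))}
        beta_r, se_r = lines["BETA"], lines["SE"]
        assert np.all(np.abs(fit.glmm.beta - beta_r) < 0.25 * se_r)
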
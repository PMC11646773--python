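"""Design construction, EMMs, post-hoc contrasts and effect labels."""

import numpy as np
import pandas as pd
import pytest

from posturekit.exceptions import DesignError, ParameterError
from posturekit.mixedstats import (
    ModelSpec,
    build_design,
    classify_effect,
    estimated_marginal_means,
    fit_glmm,
    posthoc_contrasts,
)


class TestBuildDesign:
    def test_h1_restriction_and_terms(self, small_outcomes):
        spec = build_design(small_outcomes, "H1", "balance")
        assert spec.factors == ["ADHD"]
        assert spec.covariates == ["Age"]
        assert spec.family == "gamma"
        assert (spec.data["Skating"] == 1).all()
        assert (spec.data["time"] == "t1").all()
        assert spec.random_slope is None

    def test_h2_design_matrix_columns(self, small_outcomes):
        spec = build_design(small_outcomes, "H2", "stroop_time")
        fit = fit_glmm(spec)
        assert fit.names == [
            "Intercept", "Time", "Skating", "Time:Skating", "Cov. Age",
            "Cov. Medication",
        ]
        assert spec.family == "gaussian"
        assert (spec.data["ADHD"] == 1).all()

    def test_missing_medication_column_is_design_error(self, small_outcomes):
        broken = small_outcomes.drop(columns=["Medication"])
        with pytest.raises(DesignError, match="Medication"):
            build_design(broken, "H2", "balance")

    def test_empty_cell_is_design_error(self, small_outcomes):
        no_controls = small_outcomes[small_outcomes["Skating"] == 1]
        with pytest.raises(DesignError, match="Skating=0"):
            build_design(no_controls, "H2", "balance")


def _balanced_gaussian_table(seed=0, n_per_arm=8):
    """Balanced 2x2 (time x skating) design, one value per subject and time."""
    rng = np.random.default_rng(seed)
    rows = []
    cell_shift = {("t1", 0): 10.0, ("t1", 1): 12.0, ("t2", 0): 9.0, ("t2", 1): 8.0}
    for s in range(2 * n_per_arm):
        skate = int(s < n_per_arm)
        for t in ("t1", "t2"):
            rows.append(
                {
                    "subject": f"S{s:02d}",
                    "time": t,
                    "Skating": skate,
                    "ADHD": 1,
                    "Age": 10.0,
                    "Medication": 0,
                    "variable": "score",
                    "value": cell_shift[(t, skate)] + rng.normal(0, 0.5),
                }
            )
    return pd.DataFrame(rows)


def _balanced_spec(data):
    return ModelSpec(
        dependent="score",
        family="gaussian",
        factors=["Time", "Skating"],
        interactions=[("Time", "Skating")],
        covariates=[],
        random_slope="Time",
        restriction="none",
        hypothesis="H2",
        data=data,
    )


class TestEmm:
    def test_balanced_identity_link_emms_equal_cell_means(self):
        data = _balanced_gaussian_table()
        fit = fit_glmm(_balanced_spec(data))
        emm = estimated_marginal_means(fit, ["Time", "Skating"])
        for _, row in emm.table.iterrows():
            cell = data[(data["time"] == row["Time"]) & (data["Skating"] == row["Skating"])]
            assert row["emm"] == pytest.approx(cell["value"].mean(), abs=1e-9)
        assert ((emm.table["ci_low"] <= emm.table["emm"])
                & (emm.table["emm"] <= emm.table["ci_high"])).all()

    def test_inverse_link_backtransform(self, small_outcomes):
        fit = fit_glmm(build_design(small_outcomes, "H2", "balance"))
        emm = estimated_marginal_means(fit, ["Time", "Skating"])
        assert (emm.table["emm"] > 0).all()
        assert np.allclose(emm.table["emm"], 1.0 / emm.table["eta"])
        assert ((emm.table["ci_low"] <= emm.table["emm"])
                & (emm.table["emm"] <= emm.table["ci_high"])).all()

    def test_covariate_handling_matches_direct_prediction(self, small_outcomes):
        fit = fit_glmm(build_design(small_outcomes, "H2", "stroop_time"))
        emm = estimated_marginal_means(fit, ["Time"])
        j = fit.names.index("Cov. Age")
        # (a) the EMM equals the direct prediction x @ beta with the covariate
        # at its observed mean and off-grid factors averaged out
        age_mean = fit.data["Age"].mean()
        med_mean = fit.data["Medication"].mean()
        for _, row in emm.table.iterrows():
            code = 1.0 if row["Time"] == "t2" else -1.0
            x = np.array([1.0, code, 0.0, 0.0, age_mean, med_mean])
            assert row["eta"] == pytest.approx(float(x @ fit.glmm.beta), abs=1e-10)
        # (b) predicting at Age shifted by +c moves the predictor by beta_age*c
        x_shift = np.array([1.0, 1.0, 0.0, 0.0, age_mean + 2.0, med_mean])
        x_base = np.array([1.0, 1.0, 0.0, 0.0, age_mean, med_mean])
        assert float((x_shift - x_base) @ fit.glmm.beta) == pytest.approx(
            2.0 * fit.glmm.beta[j]
        )
        # (c) EMMs are invariant to a location shift of the covariate data,
        # because the refit intercept absorbs the shift of the covariate mean
        shifted = fit.data.copy()
        shifted["Age"] = shifted["Age"] + 2.0
        emm2 = estimated_marginal_means(fit_glmm(fit.spec, shifted), ["Time"])
        assert np.allclose(emm2.table["eta"], emm.table["eta"], atol=1e-6)

    def test_unknown_factor_rejected(self, small_outcomes):
        fit = fit_glmm(build_design(small_outcomes, "H1", "balance"))
        with pytest.raises(DesignError, match="not in the model"):
            estimated_marginal_means(fit, ["Time"])


class TestPosthoc:
    def test_pct_diff_arithmetic(self):
        data = _balanced_gaussian_table(seed=1)
        fit = fit_glmm(_balanced_spec(data))
        emm = estimated_marginal_means(fit, ["Time", "Skating"])
        ph = posthoc_contrasts(emm, factor="Time")
        for _, row in ph.iterrows():
            pre = emm.table[
                (emm.table["Time"] == "t1") & (emm.table["Skating"] == row["at_Skating"])
            ]["emm"].iloc[0]
            post = emm.table[
                (emm.table["Time"] == "t2") & (emm.table["Skating"] == row["at_Skating"])
            ]["emm"].iloc[0]
            assert row["pct_diff"] == pytest.approx(100 * (post - pre) / pre)

    def test_identical_cells_give_zero_estimate_p_one(self):
        data = _balanced_gaussian_table(seed=2)
        # make the two skating arms identical at both times by construction
        data["value"] = 10.0
        data.loc[data["time"] == "t2", "value"] = 9.0
        fit = fit_glmm(_balanced_spec(data))
        emm = estimated_marginal_means(fit, ["Time", "Skating"])
        ph = posthoc_contrasts(emm, factor="Skating")
        assert np.allclose(ph["estimate_link"], 0.0, atol=1e-9)
        assert np.allclose(ph["p_corr"], 1.0)

    def test_holm_correction_matches_hand_sequence(self, small_outcomes):
        fit = fit_glmm(build_design(small_outcomes, "H2", "balance"))
        emm = estimated_marginal_means(fit, ["Time", "Skating"])
        ph = posthoc_contrasts(emm, correction="holm")  # all within-factor pairs
        p = ph["p"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        hand = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            hand[idx] = min(1.0, running)
        assert np.allclose(ph["p_corr"].to_numpy(), hand, atol=1e-12)
        assert (ph["p_corr"] >= ph["p"] - 1e-15).all()


class TestClassifyEffect:
    @pytest.mark.parametrize(
        "value,scale,label",
        [
            (0.5, "rho", "Large"),
            (0.35, "rho", "Medium"),
            (0.05, "rho", "Very small"),
            (0.19, "eta", "Large"),
            (0.0002, "eta", "Very small"),
            (0.02, "eta", "Small"),
            (0.04, "eta", "Small to medium"),
            (0.07, "eta", "Medium"),
            (0.10, "eta", "Medium to large"),
        ],
    )
    def test_band_labels(self, value, scale, label):
        assert classify_effect(value, scale) == label

    def test_labels_monotone_in_value(self):
        order = ["Very small", "Small", "Small to medium", "Medium",
                 "Medium to large", "Large"]
        prev = -1
        for v in np.linspace(0, 0.3, 151):
            rank = order.index(classify_effect(v, "eta"))
            assert rank >= prev
            prev = rank

    def test_negative_value_rejected(self):
        with pytest.raises(ParameterError):
            classify_effect(-0.1, "rho")
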
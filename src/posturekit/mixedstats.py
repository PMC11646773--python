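"""Hypothesis-specific GLMM designs, EMMs, post-hoc contrasts, effect sizes.

Two pre-registered designs are supported on the long outcome table:

* **H1** (cross-sectional condition effect): restrict to intervention-arm
  subjects at the pre session; one two-level factor (ADHD) plus the additive
  covariate Age.
* **H2** (intervention effect): restrict to affected subjects (both ADHD
  arms); fixed effects Time, Skating and their interaction plus the additive
  covariates Age and Medication; per-subject random intercept and time slope.

Motor target errors are fitted with the gamma family and its canonical
inverse link (errors are positive and right-skewed); cognitive and symptom
scores with the normal family. Factors are sum-coded (-1/+1) so each main
effect tests the balanced average over the other factor and covariates never
interact with factors.

Estimated marginal means (EMMs) are model predictions on a reference grid
crossing the named factor levels, covariates held at the analyzed dataset's
means, off-grid factors averaged (code 0 under sum coding), back-transformed
through the link with delta-method standard errors. Post-hoc pairwise
contrasts are Wald F tests on the link scale with Holm-corrected p-values by
default, the pre/post relative change

    %diff = 100 * (EMM_post - EMM_pre) / EMM_pre,

and a per-contrast partial eta squared, eta_p^2 = F*df1 / (F*df1 + df2),
labelled after the conventional effect-size bands.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import DesignError, ParameterError
from .glmm import GlmmResult, fit_glmm_core, wald_f

__all__ = [
    "MOTOR_VARIABLES",
    "COGNITIVE_VARIABLES",
    "SYMPTOM_VARIABLES",
    "ModelSpec",
    "FitResult",
    "EmmTable",
    "build_design",
    "fit_glmm",
    "estimated_marginal_means",
    "posthoc_contrasts",
    "classify_effect",
]

MOTOR_VARIABLES = ("balance", "one_leg_stand", "precision_jump")
COGNITIVE_VARIABLES = ("d2_completed", "d2_concentration", "stroop_time")
SYMPTOM_VARIABLES = ("attention_deficit", "hyperactivity")

#: default effect-size bands; upper edge -> label
ETA_BANDS = (
    (0.01, "Very small"),
    (0.03, "Small"),
    (0.06, "Small to medium"),
    (0.09, "Medium"),
    (0.14, "Medium to large"),
    (np.inf, "Large"),
)
RHO_BANDS = (
    (0.1, "Very small"),
    (0.3, "Small"),
    (0.5, "Medium"),
    (np.inf, "Large"),
)


def family_for(variable: str) -> str:
    if variable in MOTOR_VARIABLES:
        return "gamma"
    if variable in COGNITIVE_VARIABLES or variable in SYMPTOM_VARIABLES:
        return "gaussian"
    raise ParameterError(f"unknown dependent variable {variable!r}")


@dataclass
class ModelSpec:
    """One hypothesis-specific model: family, terms, restriction, data."""

    dependent: str
    family: str
    factors: list
    interactions: list
    covariates: list
    random_slope: str | None
    restriction: str
    hypothesis: str
    data: pd.DataFrame = field(repr=False, default=None)


@dataclass
class FitResult:
    """A fitted design: the core mixed-model result plus per-term F tests."""

    spec: ModelSpec
    glmm: GlmmResult
    X: np.ndarray = field(repr=False, default=None)
    names: list = None
    data: pd.DataFrame = field(repr=False, default=None)
    term_tests: pd.DataFrame = None


@dataclass
class EmmTable:
    """Estimated marginal means on the response scale for a factor grid."""

    table: pd.DataFrame
    factors: list
    X_grid: np.ndarray = field(repr=False, default=None)
    fit: FitResult = field(repr=False, default=None)


_REQUIRED = ("subject", "time", "ADHD", "Skating", "Age", "variable", "value")


def build_design(data: pd.DataFrame, hypothesis: str, dependent: str) -> ModelSpec:
    """Build the H1 or H2 model specification on the outcome table.

    Validates that the required columns exist and that the dataset
    restriction leaves every design cell occupied.
    """
    hypothesis = hypothesis.upper()
    if hypothesis not in ("H1", "H2"):
        raise ParameterError("hypothesis must be 'H1' or 'H2'")
    missing = [c for c in _REQUIRED if c not in data.columns]
    if hypothesis == "H2" and "Medication" not in data.columns:
        missing.append("Medication")
    if missing:
        raise DesignError(f"outcome table is missing columns: {missing}")
    family = family_for(dependent)
    sub = data[data["variable"] == dependent]
    if hypothesis == "H1":
        restricted = sub[(sub["Skating"] == 1) & (sub["time"] == "t1")]
        for level in (0, 1):
            if (restricted["ADHD"] == level).sum() == 0:
                raise DesignError(
                    f"H1 restriction leaves the cell ADHD={level} empty for "
                    f"{dependent!r}"
                )
        return ModelSpec(
            dependent=dependent,
            family=family,
            factors=["ADHD"],
            interactions=[],
            covariates=["Age"],
            random_slope=None,
            restriction="Skating == 1 and time == 't1'",
            hypothesis="H1",
            data=restricted.reset_index(drop=True),
        )
    restricted = sub[sub["ADHD"] == 1]
    for t in ("t1", "t2"):
        for s in (0, 1):
            if ((restricted["time"] == t) & (restricted["Skating"] == s)).sum() == 0:
                raise DesignError(
                    f"H2 restriction leaves the cell time={t}, Skating={s} "
                    f"empty for {dependent!r}"
                )
    return ModelSpec(
        dependent=dependent,
        family=family,
        factors=["Time", "Skating"],
        interactions=[("Time", "Skating")],
        covariates=["Age", "Medication"],
        random_slope="Time",
        restriction="ADHD == 1",
        hypothesis="H2",
        data=restricted.reset_index(drop=True),
    )


def _factor_codes(df: pd.DataFrame, factor: str) -> np.ndarray:
    """Sum coding: the two sorted levels map to -1 and +1."""
    col = "time" if factor == "Time" else factor
    levels = sorted(df[col].unique())
    if len(levels) != 2:
        raise DesignError(f"factor {factor!r} must have exactly two levels, got {levels}")
    return np.where(df[col] == levels[1], 1.0, -1.0), levels


def _design_matrix(spec: ModelSpec, df: pd.DataFrame):
    cols = [np.ones(len(df))]
    names = ["Intercept"]
    codes = {}
    for f in spec.factors:
        x, _ = _factor_codes(df, f)
        codes[f] = x
        cols.append(x)
        names.append(f)
    for a, b in spec.interactions:
        cols.append(codes[a] * codes[b])
        names.append(f"{a}:{b}")
    for c in spec.covariates:
        cols.append(df[c].to_numpy(dtype=float))
        names.append(f"Cov. {c}")
    return np.column_stack(cols), names


def fit_glmm(spec: ModelSpec, data: pd.DataFrame | None = None) -> FitResult:
    """Fit the specified GLMM (outlier screening, where applicable, is the
    caller's responsibility and must already be applied)."""
    df = spec.data if data is None else data
    df = df[df["variable"] == spec.dependent].dropna(subset=["value"])
    df = df.reset_index(drop=True)
    X, names = _design_matrix(spec, df)
    y = df["value"].to_numpy(dtype=float)
    if spec.random_slope is not None:
        post = (df["time"] == sorted(df["time"].unique())[1]).to_numpy(dtype=float)
        Zre = np.column_stack([np.ones(len(df)), post])
    else:
        Zre = np.ones((len(df), 1))
    glmm = fit_glmm_core(
        X, y, df["subject"].to_numpy(), Zre, spec.family, names=names
    )
    rows = []
    for j, name in enumerate(names):
        if name == "Intercept":
            continue
        F, df1, df2, p = wald_f(glmm, [j])
        eta_p2 = F * df1 / (F * df1 + df2)
        rows.append(
            {
                "term": name,
                "F": F,
                "df1": df1,
                "df2": df2,
                "p": p,
                "eta_p2": eta_p2,
                "effect_label": classify_effect(eta_p2, "eta"),
            }
        )
    return FitResult(
        spec=spec,
        glmm=glmm,
        X=X,
        names=names,
        data=df,
        term_tests=pd.DataFrame(rows),
    )


def _invlink(family: str, eta: np.ndarray) -> np.ndarray:
    return 1.0 / eta if family == "gamma" else eta


def estimated_marginal_means(fit: FitResult, factors) -> EmmTable:
    """EMMs on a reference grid crossing ``factors``.

    Covariates are fixed at the analyzed dataset's means; factors not named
    are averaged over (their sum-coded column is 0); predictions are
    back-transformed through the link with delta-method standard errors and
    t-based 95% confidence intervals computed on the link scale.
    """
    spec = fit.spec
    factors = list(factors)
    unknown = [f for f in factors if f not in spec.factors]
    if unknown:
        raise DesignError(f"factors not in the model: {unknown}")
    df = fit.data
    level_map = {}
    for f in spec.factors:
        _, levels = _factor_codes(df, f)
        level_map[f] = levels
    cov_means = {c: float(df[c].mean()) for c in spec.covariates}
    grid_levels = [level_map[f] for f in factors]
    rows = []
    X_rows = []
    tcrit = stats.t.ppf(0.975, fit.glmm.df_resid)
    for combo in itertools.product(*grid_levels):
        code = {f: (1.0 if lvl == level_map[f][1] else -1.0) for f, lvl in zip(factors, combo)}
        x = []
        for name in fit.names:
            if name == "Intercept":
                x.append(1.0)
            elif name in spec.factors:
                x.append(code.get(name, 0.0))
            elif ":" in name:
                a, b = name.split(":")
                x.append(code.get(a, 0.0) * code.get(b, 0.0))
            else:
                x.append(cov_means[name.replace("Cov. ", "")])
        x = np.asarray(x)
        eta = float(x @ fit.glmm.beta)
        se_eta = float(np.sqrt(x @ fit.glmm.cov_beta @ x))
        lo_eta, hi_eta = eta - tcrit * se_eta, eta + tcrit * se_eta
        emm = float(_invlink(spec.family, np.array([eta]))[0])
        if spec.family == "gamma":
            if eta <= 0 or lo_eta <= 0:
                raise DesignError(
                    "inverse-link EMM undefined: linear predictor not positive "
                    f"at grid point {dict(zip(factors, combo))}"
                )
            se = se_eta / eta**2  # delta method: d(1/eta)/deta = -1/eta^2
            ci_lo, ci_hi = 1.0 / hi_eta, 1.0 / lo_eta
        else:
            se = se_eta
            ci_lo, ci_hi = lo_eta, hi_eta
        row = {f: lvl for f, lvl in zip(factors, combo)}
        row.update(
            {"emm": emm, "se": se, "ci_low": ci_lo, "ci_high": ci_hi,
             "eta": eta, "se_eta": se_eta}
        )
        rows.append(row)
        X_rows.append(x)
    return EmmTable(
        table=pd.DataFrame(rows),
        factors=factors,
        X_grid=np.vstack(X_rows),
        fit=fit,
    )


def posthoc_contrasts(
    emm: EmmTable, correction: str = "holm", factor: str | None = None
) -> pd.DataFrame:
    """All pairwise within-factor comparisons of the EMM grid.

    Pairs differ in exactly one factor (all others equal); ``factor``
    restricts the moving factor. Tests are Wald F on the link scale with
    residual df; p-values are corrected jointly across the returned set.
    %diff is the relative change from the lower to the higher level of the
    moving factor on the response scale (pre -> post for time pairs).
    """
    fit = emm.fit
    tab = emm.table
    df2 = fit.glmm.df_resid
    pairs = []
    for i, j in itertools.combinations(range(len(tab)), 2):
        moving = [
            f for f in emm.factors if tab.iloc[i][f] != tab.iloc[j][f]
        ]
        if len(moving) != 1:
            continue
        if factor is not None and moving[0] != factor:
            continue
        pairs.append((i, j, moving[0]))
    if not pairs:
        raise ParameterError("no within-factor pairs on this EMM grid")
    rows = []
    for i, j, mov in pairs:
        # order so that "b" carries the higher (later) level of the moving factor
        a, b = (i, j) if tab.iloc[i][mov] < tab.iloc[j][mov] else (j, i)
        xa, xb = emm.X_grid[a], emm.X_grid[b]
        d = xb - xa
        est = float(d @ fit.glmm.beta)
        var = float(d @ fit.glmm.cov_beta @ d)
        F = est**2 / var if var > 0 else np.inf
        p = float(stats.f.sf(F, 1, df2))
        emm_a, emm_b = tab.iloc[a]["emm"], tab.iloc[b]["emm"]
        if abs(emm_a) < 1e-12:
            pct = np.nan
            note = "undefined %diff: reference EMM is zero"
        else:
            pct = 100.0 * (emm_b - emm_a) / emm_a
            note = ""
        eta_p2 = F / (F + df2)
        held = {
            f: tab.iloc[a][f] for f in emm.factors if f != mov
        }
        held_lab = ", ".join(f"{k}={v}" for k, v in held.items())
        rows.append(
            {
                "pair": f"{mov}: {tab.iloc[b][mov]} - {tab.iloc[a][mov]}"
                + (f" | {held_lab}" if held_lab else ""),
                "factor": mov,
                **{f"at_{k}": v for k, v in held.items()},
                "estimate_link": est,
                "F": F,
                "df1": 1,
                "df2": df2,
                "p": p,
                "pct_diff": pct,
                "eta_p2": eta_p2,
                "effect_label": classify_effect(eta_p2, "eta"),
                "note": note,
            }
        )
    out = pd.DataFrame(rows)
    reject, p_corr, _, _ = multipletests(out["p"].to_numpy(), method=correction)
    out["p_corr"] = np.minimum(p_corr, 1.0)
    out["significant"] = reject
    return out


def classify_effect(value: float, scale: str = "eta", bands=None) -> str:
    """Label an effect-size magnitude (partial eta^2 or |rho|).

    Default bands: rho — <0.1 very small, <0.3 small, <0.5 medium, else
    large; eta_p^2 — <0.01 very small, <0.03 small, <0.06 small to medium,
    <0.09 medium, <0.14 medium to large, else large. Bands are configurable
    as a sequence of (upper_edge, label).
    """
    if value < 0 or not np.isfinite(value):
        raise ParameterError("effect-size magnitude must be finite and >= 0")
    if bands is None:
        if scale == "eta":
            bands = ETA_BANDS
        elif scale == "rho":
            bands = RHO_BANDS
        else:
            raise ParameterError("scale must be 'eta' or 'rho'")
    for edge, label in bands:
        if value < edge:
            return label
    return bands[-1][1]
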
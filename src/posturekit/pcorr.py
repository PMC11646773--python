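"""Partial Spearman correlation across motor, cognitive and symptom outcomes.

Motor trials are first averaged to one value per subject and session;
cognitive and symptom scores pass through, and pre and post rows are pooled.
The partial Spearman correlation between two variables given a set of
control variables is computed by midrank-transforming every variable and
control, residualizing each variable's ranks on the control ranks by least
squares (with intercept), and taking the product-moment correlation of the
residual pairs. Removing rank variance explained by the controls strips out
correlation that is due to a common cause (age, group membership, session)
rather than a mutual dependency.

p-values use the t transform t = rho * sqrt(df / (1 - rho^2)). The
statistically standard degrees of freedom are df = n - 2 - k with k
controls; a pooled convention df = n - 2 is available as an option since
counting pooled pre/post rows without the control adjustment is also in use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ParameterError
from .mixedstats import (
    COGNITIVE_VARIABLES,
    MOTOR_VARIABLES,
    SYMPTOM_VARIABLES,
    classify_effect,
)

__all__ = [
    "PartialCorrResult",
    "subject_average",
    "partial_spearman",
    "correlation_heatmap",
    "DEFAULT_CONTROLS",
]

DEFAULT_CONTROLS = ("Skating", "Intervention", "Age", "ADHD")
ALL_VARIABLES = MOTOR_VARIABLES + COGNITIVE_VARIABLES + SYMPTOM_VARIABLES


@dataclass
class PartialCorrResult:
    """Symmetric partial correlation matrix with p-values and effect labels."""

    rho: pd.DataFrame
    p: pd.DataFrame
    labels: pd.DataFrame
    n_obs: int
    df: int
    controls: list
    df_convention: str
    excluded: list = field(default_factory=list)


def subject_average(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Average motor trials per subject x session; pivot to one wide row per
    subject x session with an added 0/1 ``Intervention`` column (post = 1).

    Cognitive and symptom values (one per subject x session) pass through
    unchanged; pre and post rows are pooled, giving 2N rows per variable.
    """
    needed = {"subject", "time", "variable", "value"}
    missing = needed - set(outcomes.columns)
    if missing:
        raise ParameterError(f"outcome table is missing columns: {sorted(missing)}")
    meta_cols = [
        c for c in ("group", "ADHD", "Skating", "Age", "Medication")
        if c in outcomes.columns
    ]
    averaged = (
        outcomes.groupby(["subject", "time", "variable"], sort=True)["value"]
        .mean()
        .reset_index()
    )
    wide = averaged.pivot_table(
        index=["subject", "time"], columns="variable", values="value"
    ).reset_index()
    wide.columns.name = None
    if meta_cols:
        meta = outcomes.drop_duplicates("subject").set_index("subject")[meta_cols]
        for c in meta_cols:
            wide[c] = wide["subject"].map(meta[c])
    times = sorted(wide["time"].unique())
    if len(times) > 1:
        wide["Intervention"] = (wide["time"] == times[-1]).astype(int)
    else:
        wide["Intervention"] = 0
    return wide.sort_values(["subject", "time"], kind="mergesort").reset_index(drop=True)


def partial_spearman(
    table: pd.DataFrame,
    variables=ALL_VARIABLES,
    controls=DEFAULT_CONTROLS,
    df_convention: str = "residual",
) -> PartialCorrResult:
    """Partial Spearman correlation matrix of ``variables`` given ``controls``.

    Ties get midranks; binary controls are rank-transformed like any other
    variable (equivalent to 0/1 regressors after ranking). Variables that are
    constant after ranking are excluded with a warning. With zero controls
    the result is the plain Spearman matrix.
    """
    variables = list(variables)
    controls = list(controls)
    if df_convention not in ("residual", "pooled"):
        raise ParameterError("df_convention must be 'residual' or 'pooled'")
    missing = [c for c in variables + controls if c not in table.columns]
    if missing:
        raise ParameterError(f"table is missing columns: {missing}")
    used = table[variables + controls].dropna()
    n = len(used)
    if n < len(controls) + 3:
        raise ParameterError(
            f"need at least {len(controls) + 3} complete observations, got {n}"
        )
    ranks = {c: stats.rankdata(used[c].to_numpy(), method="average") for c in used}
    keep = []
    excluded = []
    for v in variables:
        if np.ptp(ranks[v]) == 0:
            excluded.append(v)
            warnings.warn(
                f"variable {v!r} is constant after ranking; correlation "
                "undefined, excluded from the matrix",
                UserWarning,
                stacklevel=2,
            )
        else:
            keep.append(v)
    R = np.column_stack([ranks[v] for v in keep])
    C = np.column_stack([np.ones(n)] + [ranks[c] for c in controls])
    coef, *_ = np.linalg.lstsq(C, R, rcond=None)
    resid = R - C @ coef
    rho = np.corrcoef(resid, rowvar=False)
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    k = len(controls)
    df = n - 2 - k if df_convention == "residual" else n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rho * np.sqrt(df / np.clip(1.0 - rho**2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    np.fill_diagonal(p, 0.0)
    labels = np.vectorize(lambda r: classify_effect(abs(r), "rho"))(rho)
    return PartialCorrResult(
        rho=pd.DataFrame(rho, index=keep, columns=keep),
        p=pd.DataFrame(p, index=keep, columns=keep),
        labels=pd.DataFrame(labels, index=keep, columns=keep),
        n_obs=n,
        df=int(df),
        controls=controls,
        df_convention=df_convention,
        excluded=excluded,
    )


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlation_heatmap(result: PartialCorrResult, path=None):
    """Annotated heatmap of the partial correlation matrix (rho + stars)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    names = list(result.rho.columns)
    m = result.rho.to_numpy()
    fig, ax = plt.subplots(figsize=(1.0 + 0.8 * len(names), 1.0 + 0.8 * len(names)))
    im = ax.imshow(m, vmin=-1, vmax=1, cmap="RdBu")
    ax.set_xticks(range(len(names)), names, rotation=45, ha="right")
    ax.set_yticks(range(len(names)), names)
    for i in range(len(names)):
        for j in range(len(names)):
            if i == j:
                continue
            ax.text(
                j,
                i,
                f"{m[i, j]:.2f}{_stars(result.p.iloc[i, j])}",
                ha="center",
                va="center",
                fontsize=7,
            )
    fig.colorbar(im, ax=ax, label="partial Spearman rho")
    ax.set_title(f"Partial correlation (controls: {', '.join(result.controls)})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
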
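"""Trajectory analysis: cell-level dependent variables and mixed-model ANOVA.

Each dependent variable (mean correct-response RT, error rate, or a
fitted diffusion parameter) is modelled per cell by training session
(categorical) and task (categorical), their interaction, and a random
participant intercept. Type III F tests are computed under sum-to-zero
contrasts; effect sizes are partial eta squared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import CELL_KEYS

__all__ = [
    "AnovaResult",
    "compute_cell_dvs",
    "mixed_anova",
    "anova_frame",
    "partial_eta_squared",
    "plot_trajectories",
]

DV_NAMES = ("mean_rt_ms", "error_rate", "v", "a", "t0")


@dataclass(frozen=True)
class AnovaResult:
    """One Type III effect test from the mixed model."""

    effect: str
    F: float
    df1: int
    df2: float
    p: float
    eta_p_sq: float
    df_method: str = "residual"


def partial_eta_squared(F: float, df1: float, df2: float) -> float:
    """Partial eta squared, F*df1 / (F*df1 + df2).

    Reported values are conventionally rounded to 2 decimals; the exact
    value is returned here.
    """
    if F < 0 or df1 <= 0 or df2 <= 0:
        raise ValueError("F must be >= 0 and both dfs > 0")
    return F * df1 / (F * df1 + df2)


def compute_cell_dvs(clean: pd.DataFrame, fits: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-cell dependent variables, optionally joined with fitted parameters.

    Mean RT is over correct trials only (ms); the error rate is the
    fraction of incorrect trials. Cells with zero correct trials get a
    flagged NaN mean RT (cannot occur after the inclusion filters).
    """
    def _one(cell: pd.DataFrame) -> pd.Series:
        correct = cell["correct"].astype(bool)
        rt_correct = cell.loc[correct, "rt_ms"]
        return pd.Series({
            "mean_rt_ms": float(rt_correct.mean()) if len(rt_correct) else np.nan,
            "error_rate": float(1.0 - correct.mean()),
            "n_trials": len(cell),
        })

    out = (
        clean.groupby(CELL_KEYS, observed=True)
        .apply(_one, include_groups=False)
        .reset_index()
    )
    if out["mean_rt_ms"].isna().any():
        warnings.warn("cells with zero correct trials: mean RT undefined (NaN)")
    if fits is not None:
        out = out.merge(
            fits[CELL_KEYS + ["v", "a", "t0", "ks_stat", "converged"]],
            on=CELL_KEYS, how="left",
        )
    return out


def _check_design(data: pd.DataFrame) -> None:
    for factor, minimum in (("participant", 2), ("session", 2), ("task", 2)):
        n = data[factor].nunique()
        if n < minimum:
            raise ValueError(f"factor {factor!r} has {n} level(s); need >= {minimum}")
    counts = data.groupby(["session", "task"], observed=True).size()
    full = data["session"].nunique() * data["task"].nunique()
    if len(counts) < full:
        missing = full - len(counts)
        raise ValueError(
            f"rank-deficient design: {missing} session x task combination(s) "
            "have no observations (factors 'session'/'task')"
        )


def mixed_anova(summaries: pd.DataFrame, dv: str) -> list[AnovaResult]:
    """Type III tests for session, task and their interaction on ``dv``.

    Fits a linear mixed model with session and task as categorical fixed
    factors (sum-to-zero contrasts), their interaction, and a random
    participant intercept (REML). F statistics are Wald tests on each
    term's coefficients — equivalent to Type III sums of squares under
    sum coding. Denominator degrees of freedom use the residual method
    df2 = n - rank(X) - (n_participants - 1), flagged in the result; for
    within-participant contrasts in balanced random-intercept designs
    this coincides with the Satterthwaite value.
    """
    import statsmodels.api as sm
    import patsy

    if dv not in summaries.columns:
        raise ValueError(f"unknown dependent variable {dv!r}; have {list(summaries.columns)}")
    data = summaries.dropna(subset=[dv]).copy()
    _check_design(data)
    data["session"] = data["session"].astype(str)
    data["task"] = data["task"].astype(str)

    y, X = patsy.dmatrices(
        f"Q('{dv}') ~ C(session, Sum) * C(task, Sum)", data, return_type="dataframe"
    )
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError("rank-deficient fixed-effects design (factors 'session'/'task')")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary variance estimates are legitimate
        model = sm.MixedLM(np.asarray(y).ravel(), X, groups=data["participant"])
        res = model.fit(reml=True)

    k_fe = X.shape[1]
    fe = np.asarray(res.fe_params)
    V = np.asarray(res.cov_params())[:k_fe, :k_fe]
    n_groups = data["participant"].nunique()
    df2 = len(data) - rank - (n_groups - 1)

    slices = X.design_info.term_name_slices
    pretty = {
        "C(session, Sum)": "session",
        "C(task, Sum)": "task",
        "C(session, Sum):C(task, Sum)": "session:task",
    }
    results = []
    for term, name in pretty.items():
        sl = slices[term]
        b = fe[sl]
        Vbb = V[sl, sl]
        df1 = len(b)
        F = float(b @ np.linalg.solve(Vbb, b) / df1)
        p = float(stats.f.sf(F, df1, df2))
        results.append(AnovaResult(
            effect=name, F=F, df1=df1, df2=float(df2), p=p,
            eta_p_sq=float(partial_eta_squared(F, df1, df2)),
        ))
    return results


def anova_frame(results: list[AnovaResult]) -> pd.DataFrame:
    """Tabulate ANOVA results; eta squared rounded to 2 decimals for reporting."""
    df = pd.DataFrame([r.__dict__ for r in results])
    df["eta_p_sq"] = df["eta_p_sq"].round(2)
    return df


def plot_trajectories(summaries: pd.DataFrame, dv: str, path=None):
    """Session trajectories of ``dv`` per task (mean across participants +/- SE)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for task, sub in summaries.groupby("task", observed=True):
        g = sub.groupby("session", observed=True)[dv]
        mean, se = g.mean(), g.sem()
        ax.errorbar(mean.index, mean, yerr=se, label=str(task), capsize=2)
    ax.set_xlabel("training session")
    ax.set_ylabel(dv)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
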
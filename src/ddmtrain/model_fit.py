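"""Simulation-based fit assessment (predictive check on summary statistics).

For every fitted cell, data are re-simulated from the fitted parameters
with the same number of trials as the cell's cleaned data, and the
observed error rate and correct-response RT quartiles are compared with
their simulated counterparts.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

from .estimation import CELL_KEYS
from .wiener import DDMParams, simulate_trials

__all__ = ["predict_cell", "ppc_table", "summarize_ppc", "plot_ppc"]

_QS = (0.25, 0.50, 0.75)


def predict_cell(fit: dict | pd.Series, n: int, seed: int) -> dict:
    """Simulate ``n`` trials from a cell's fitted parameters.

    Returns the predicted error rate and correct-response RT quartiles
    (seconds; linear-interpolation quantiles). Non-converged fits are
    rejected — the caller flags and skips them.
    """
    if not bool(fit["converged"]):
        raise ValueError("refusing to predict from a non-converged fit")
    params = DDMParams(v=float(fit["v"]), a=float(fit["a"]), t0=float(fit["t0"]))
    sim = simulate_trials(params, n, seed)
    correct_rt = sim.rt[sim.upper]
    quartiles = (
        np.quantile(correct_rt, _QS) if len(correct_rt) else np.full(3, np.nan)
    )
    return {
        "error_rate": float(np.mean(~sim.upper)),
        "q1": float(quartiles[0]),
        "q2": float(quartiles[1]),
        "q3": float(quartiles[2]),
    }


def _observed_cell(cell: pd.DataFrame) -> dict:
    rt_s = cell.loc[cell["correct"].astype(bool), "rt_ms"].to_numpy(float) / 1000.0
    quartiles = np.quantile(rt_s, _QS) if len(rt_s) else np.full(3, np.nan)
    return {
        "error_rate": float(1.0 - cell["correct"].mean()),
        "q1": float(quartiles[0]),
        "q2": float(quartiles[1]),
        "q3": float(quartiles[2]),
    }


def ppc_table(fits: pd.DataFrame, clean: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """One observed-vs-predicted row per fitted cell, matched trial counts.

    Cells present in only one of ``fits`` / ``clean`` raise; non-converged
    fits are flagged (``skipped``) with NaN predictions.
    """
    fit_keys = set(map(tuple, fits[CELL_KEYS].itertuples(index=False)))
    data_keys = set(map(tuple, clean[CELL_KEYS].drop_duplicates().itertuples(index=False)))
    if fit_keys != data_keys:
        raise ValueError(
            f"cell keys differ between fits and data: "
            f"{len(fit_keys - data_keys)} fit-only, {len(data_keys - fit_keys)} data-only"
        )
    rows = []
    grouped = dict(tuple(clean.groupby(CELL_KEYS, observed=True)))
    for fit in fits.to_dict("records"):
        key = tuple(fit[k] for k in CELL_KEYS)
        cell = grouped[key]
        obs = _observed_cell(cell)
        row = {k: fit[k] for k in CELL_KEYS}
        row["n_trials"] = len(cell)
        row.update({f"obs_{k}": v for k, v in obs.items()})
        if bool(fit["converged"]):
            child = (zlib.crc32("|".join(map(str, key)).encode()) ^ seed) & 0x7FFFFFFF
            pred = predict_cell(fit, len(cell), child)
            row.update({f"pred_{k}": v for k, v in pred.items()})
            row["skipped"] = False
        else:
            row.update({f"pred_{k}": np.nan for k in ("error_rate", "q1", "q2", "q3")})
            row["skipped"] = True
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_ppc(table: pd.DataFrame) -> pd.DataFrame:
    """Mean signed deviation (observed - predicted) per statistic, across cells."""
    rows = []
    ok = table[~table["skipped"]]
    for stat in ("error_rate", "q1", "q2", "q3"):
        dev = ok[f"obs_{stat}"] - ok[f"pred_{stat}"]
        rows.append({
            "statistic": stat,
            "mean_signed_deviation": float(dev.mean()),
            "mean_abs_deviation": float(dev.abs().mean()),
            "corr_obs_pred": float(ok[f"obs_{stat}"].corr(ok[f"pred_{stat}"])),
        })
    return pd.DataFrame(rows)


def plot_ppc(table: pd.DataFrame, path=None):
    """Observed-vs-predicted scatter per statistic (error rate + quartiles)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ok = table[~table["skipped"]]
    fig, axes = plt.subplots(1, 4, figsize=(14, 3.5))
    for ax, stat in zip(axes, ("error_rate", "q1", "q2", "q3")):
        ax.scatter(ok[f"pred_{stat}"], ok[f"obs_{stat}"], s=8, alpha=0.5)
        lims = [
            min(ok[f"pred_{stat}"].min(), ok[f"obs_{stat}"].min()),
            max(ok[f"pred_{stat}"].max(), ok[f"obs_{stat}"].max()),
        ]
        ax.plot(lims, lims, "k--", lw=1)
        ax.set_xlabel(f"predicted {stat}")
        ax.set_ylabel(f"observed {stat}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
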
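"""Constrained-model comparison.

Refits cells with one or more diffusion parameters clamped to per-task
reference values — the median across sessions of the per-session means
of the free three-parameter estimates — and quantifies the fit
degradation as the distribution of KS differences (constrained - free).
The comparison metric is the KS distance itself, the criterion the fit
optimizes; the models are not likelihood-based, so no information
criteria are computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .estimation import CELL_KEYS, FitSettings, fit_dataset

__all__ = [
    "ConstraintSpec",
    "reference_values",
    "constrained_fit",
    "fit_constrained_dataset",
    "compare_models",
]

PARAMS = ("v", "a", "t0")


@dataclass(frozen=True)
class ConstraintSpec:
    """Which parameters to fix, and the per-task values to fix them to.

    ``references`` maps task -> {param -> value} and must cover every
    fixed parameter for every task it is applied to.
    """

    fix: tuple[str, ...]
    references: dict

    def __post_init__(self) -> None:
        bad = set(self.fix) - set(PARAMS)
        if bad:
            raise ValueError(f"unknown parameters in constraint: {sorted(bad)}")

    def fixed_for(self, task: str) -> dict:
        refs = self.references[task]
        return {p: float(refs[p]) for p in self.fix}

    @property
    def label(self) -> str:
        return "+".join(self.fix) if self.fix else "none"


def reference_values(fits: pd.DataFrame) -> dict:
    """Per-task reference values: median over sessions of session means.

    For each task and parameter, average the per-cell estimates across
    participants within each session, then take the median of those
    session means. Warns (but proceeds) below 3 sessions.
    """
    import warnings

    refs: dict[str, dict[str, float]] = {}
    for task, sub in fits.groupby("task", observed=True):
        session_means = sub.groupby("session", observed=True)[list(PARAMS)].mean()
        if len(session_means) < 3:
            warnings.warn(
                f"task {task!r} has only {len(session_means)} sessions; "
                "reference medians may be unstable"
            )
        refs[task] = {p: float(session_means[p].median()) for p in PARAMS}
    return refs


def constrained_fit(trials: pd.DataFrame, spec: ConstraintSpec,
                    settings: FitSettings | None = None) -> dict:
    """Fit one cell with the spec's parameters clamped to its task's references."""
    from .estimation import fit_cell

    task = trials["task"].iloc[0]
    return fit_cell(trials, settings, fixed=spec.fixed_for(task))


def fit_constrained_dataset(clean: pd.DataFrame, spec: ConstraintSpec,
                            settings: FitSettings | None = None) -> pd.DataFrame:
    """Constrained refit of every cell; one result row per cell."""
    frames = []
    for task, sub in clean.groupby("task", observed=True):
        fixed = spec.fixed_for(task)
        frames.append(fit_dataset(sub, settings, fixed=fixed))
    out = pd.concat(frames, ignore_index=True)
    out["constraint"] = spec.label
    return out


def compare_models(free_fits: pd.DataFrame, constrained_fits: pd.DataFrame,
                   per_task: bool = True) -> pd.DataFrame:
    """Summarize KS degradation (constrained - free) per constraint spec.

    Returns one row per (constraint, task) — and a pooled ``all`` row —
    with the mean and median KS difference and the fraction of cells
    degraded. Mismatched cell keys raise.
    """
    merged = constrained_fits.merge(
        free_fits[CELL_KEYS + ["ks_stat"]].rename(columns={"ks_stat": "ks_free"}),
        on=CELL_KEYS, how="left", validate="many_to_one",
    )
    if merged["ks_free"].isna().any():
        missing = merged.loc[merged["ks_free"].isna(), CELL_KEYS].iloc[0].tolist()
        raise ValueError(f"constrained fit has no free-fit counterpart for cell {missing}")
    merged["ks_diff"] = merged["ks_stat"] - merged["ks_free"]

    def _summary(df: pd.DataFrame, constraint: str, task: str) -> dict:
        return {
            "constraint": constraint,
            "task": task,
            "n_cells": len(df),
            "mean_ks_diff": float(df["ks_diff"].mean()),
            "median_ks_diff": float(df["ks_diff"].median()),
            "frac_degraded": float((df["ks_diff"] > 0).mean()),
        }

    rows = []
    for constraint, by_spec in merged.groupby("constraint", observed=True):
        if per_task:
            for task, sub in by_spec.groupby("task", observed=True):
                rows.append(_summary(sub, constraint, task))
        rows.append(_summary(by_spec, constraint, "all"))
    return pd.DataFrame(rows)
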
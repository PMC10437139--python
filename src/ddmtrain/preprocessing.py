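"""RT data treatment: contaminant trimming and inclusion filtering.

The cascade, applied in this fixed order per task:

1. (optional) drop trials immediately following an error,
2. RT trimming per task x participant x session x response-type stratum:
   drop RT < 250 ms, then drop RT above median + 2.5 scaled-MADs,
3. drop sessions with fewer than 125 retained trials,
4. drop sessions where either response type falls below 4% of trials,
5. drop, per task, participants with fewer than 10 surviving sessions,

emitting a per-task retention report (percent of recorded trials
remaining after each stage, plus pre/post counts of trials, sessions
and participants).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TreatmentConfig",
    "TreatmentReport",
    "DataTreatment",
    "trim_rts",
    "post_error_filter",
    "filter_sessions",
    "filter_participants",
    "run_treatment",
]

CELL_KEYS = ["task", "participant", "session"]
STAGES = [
    "rt_trimming",
    "sessions_min_trials",
    "sessions_response_type",
    "participants_min_sessions",
]


@dataclass(frozen=True)
class TreatmentConfig:
    """Thresholds of the treatment cascade.

    ``mad_scale_constant`` is the normal-consistency factor applied to the
    raw MAD (1.4826 by convention; set to 1.0 for an unscaled MAD).
    ``upper_rule`` selects the slow-contaminant cut: ``"mad"`` (default,
    median + multiplier x scaled MAD) or ``"sd"`` (mean + multiplier x SD,
    the frequently used alternative cut-off for sensitivity analysis).
    """

    rt_floor_ms: float = 250.0
    mad_multiplier: float = 2.5
    mad_scale_constant: float = 1.4826
    min_trials_per_session: int = 125
    min_response_type_fraction: float = 0.04
    min_sessions_per_participant: int = 10
    drop_post_error: bool = False
    upper_rule: str = "mad"
    sd_multiplier: float = 2.0

    def __post_init__(self) -> None:
        if min(self.rt_floor_ms, self.mad_multiplier, self.mad_scale_constant,
               self.min_trials_per_session, self.min_sessions_per_participant) <= 0:
            raise ValueError("all treatment thresholds must be positive")
        if not (0.0 < self.min_response_type_fraction < 0.5):
            raise ValueError("response-type fraction must lie in (0, 0.5)")
        if self.upper_rule not in ("mad", "sd"):
            raise ValueError(f"unknown upper trimming rule {self.upper_rule!r}")


@dataclass
class TreatmentReport:
    """Per-task retention bookkeeping mirroring a study's data-treatment table.

    ``pct_remaining`` maps task -> stage -> cumulative percent of recorded
    trials remaining after that stage (nonincreasing down the stage list).
    """

    recorded: dict[str, dict[str, int]] = field(default_factory=dict)
    pct_remaining: dict[str, dict[str, float]] = field(default_factory=dict)
    post: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tabulate the report: one column per task, one row per line item."""
        tasks = list(self.recorded)
        rows = {}
        for what in ("trials", "sessions", "participants"):
            rows[f"recorded_{what}"] = [self.recorded[t][what] for t in tasks]
        for stage in STAGES:
            rows[f"pct_after_{stage}"] = [round(self.pct_remaining[t][stage], 2) for t in tasks]
        for what in ("trials", "sessions", "participants"):
            rows[f"post_{what}"] = [self.post[t][what] for t in tasks]
        return pd.DataFrame(rows, index=tasks).T


def _require_columns(df: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"trial table is missing required columns: {missing}")


def trim_rts(group: pd.DataFrame, config: TreatmentConfig | None = None) -> pd.DataFrame:
    """Trim one (task, participant, session, response-type) stratum.

    Removes RT < floor first; the location/scale of the upper cut are then
    computed on the floored stratum. Under the MAD rule the cut is
    median + multiplier * (scale_constant * raw MAD) and trials exactly at
    the threshold are retained ("above" read strictly). A single-trial or
    constant-RT stratum has MAD 0, so only the floor applies.
    """
    config = config or TreatmentConfig()
    if len(group) == 0:
        return group
    floored = group[group["rt_ms"] >= config.rt_floor_ms]
    if len(floored) == 0:
        return floored
    rt = floored["rt_ms"].to_numpy(float)
    if config.upper_rule == "sd":
        cut = rt.mean() + config.sd_multiplier * rt.std(ddof=1) if len(rt) > 1 else np.inf
    else:
        med = np.median(rt)
        mad = np.median(np.abs(rt - med))
        cut = med + config.mad_multiplier * (config.mad_scale_constant * mad)
    return floored[floored["rt_ms"] <= cut]


def post_error_filter(session_trials: pd.DataFrame) -> pd.DataFrame:
    """Drop every trial immediately following an error within one session.

    Trials must carry strictly increasing ``trial`` indices; the first
    trial is never removed. Applied before RT trimming when enabled.
    """
    if len(session_trials) == 0:
        return session_trials
    ordered = session_trials.sort_values("trial")
    idx = ordered["trial"].to_numpy()
    if np.any(np.diff(idx) <= 0):
        raise ValueError("trial indices must be strictly increasing within a session")
    prev_error = np.concatenate([[False], ~ordered["correct"].to_numpy(bool)[:-1]])
    return ordered[~prev_error]


def _apply_post_error(trials: pd.DataFrame) -> pd.DataFrame:
    """Vectorized equivalent of :func:`post_error_filter` over all sessions."""
    ordered = trials.sort_values(CELL_KEYS + ["trial"], kind="mergesort")
    grp = ordered.groupby(CELL_KEYS, sort=False, observed=True)
    if (grp["trial"].diff().dropna() <= 0).any():
        raise ValueError("trial indices must be strictly increasing within a session")
    prev_correct = grp["correct"].shift(fill_value=True).astype(bool)
    return ordered[prev_correct].reset_index(drop=True)


def _apply_trimming(trials: pd.DataFrame, config: TreatmentConfig) -> pd.DataFrame:
    """Vectorized equivalent of :func:`trim_rts` over all strata."""
    keys = CELL_KEYS + ["correct"]
    floored = trials[trials["rt_ms"] >= config.rt_floor_ms]
    if len(floored) == 0:
        return floored.reset_index(drop=True)
    grp = floored.groupby(keys, sort=False, observed=True)["rt_ms"]
    if config.upper_rule == "sd":
        cut = grp.transform("mean") + config.sd_multiplier * grp.transform("std")
        cut = cut.fillna(np.inf)  # single-trial stratum: only the floor applies
    else:
        med = grp.transform("median")
        dev = (floored["rt_ms"] - med).abs()
        mad = dev.groupby([floored[k] for k in keys], sort=False, observed=True).transform("median")
        cut = med + config.mad_multiplier * (config.mad_scale_constant * mad)
    return floored[floored["rt_ms"] <= cut].reset_index(drop=True)


def filter_sessions(trials: pd.DataFrame, config: TreatmentConfig | None = None,
                    stage: str = "both") -> pd.DataFrame:
    """Session-level inclusion rules, applied post-trimming.

    ``stage`` selects ``"min_trials"`` (drop cells with fewer than 125
    trials), ``"response_type"`` (drop cells where correct or error trials
    make up less than 4%), or ``"both"`` in that order.
    """
    config = config or TreatmentConfig()
    out = trials
    if stage in ("min_trials", "both"):
        n = out.groupby(CELL_KEYS, observed=True)["rt_ms"].transform("size")
        out = out[n >= config.min_trials_per_session]
    if stage in ("response_type", "both"):
        grp = out.groupby(CELL_KEYS, observed=True)["correct"]
        frac_correct = grp.transform("mean")
        keep = (frac_correct >= config.min_response_type_fraction) & (
            1.0 - frac_correct >= config.min_response_type_fraction
        )
        out = out[keep]
    return out


def filter_participants(trials: pd.DataFrame, config: TreatmentConfig | None = None) -> pd.DataFrame:
    """Drop, per task, participants with too few surviving sessions.

    Evaluated independently within each task: a participant removed from
    one task may survive in another.
    """
    config = config or TreatmentConfig()
    if len(trials) == 0:
        return trials
    n_sessions = (
        trials.drop_duplicates(CELL_KEYS)
        .groupby(["task", "participant"], observed=True)
        .size()
        .rename("n_sessions")
    )
    keep = n_sessions[n_sessions >= config.min_sessions_per_participant].reset_index()
    return trials.merge(keep[["task", "participant"]], on=["task", "participant"], how="inner")


def _counts(trials: pd.DataFrame, task: str) -> dict[str, int]:
    sub = trials[trials["task"] == task]
    return {
        "trials": int(len(sub)),
        "sessions": int(len(sub.drop_duplicates(["participant", "session"]))),
        "participants": int(sub["participant"].nunique()),
    }


def run_treatment(
    trials: pd.DataFrame, config: TreatmentConfig | None = None
) -> tuple[pd.DataFrame, TreatmentReport]:
    """Run the full cascade and report per-task retention.

    Stage order is fixed: optional post-error filter, RT trimming,
    minimum-trials session filter, response-type session filter,
    minimum-sessions participant filter. Percentages in the report are
    cumulative relative to the recorded trial counts, so they are
    nonincreasing down the stage list.
    """
    config = config or TreatmentConfig()
    _require_columns(trials, ["participant", "session", "task", "trial", "correct", "rt_ms"])
    if trials["rt_ms"].isna().any() or (trials["rt_ms"] <= 0).any():
        bad = trials.index[trials["rt_ms"].isna() | (trials["rt_ms"] <= 0)][0]
        raise ValueError(f"non-positive or missing RT at row {bad}")

    tasks = list(pd.unique(trials["task"]))
    report = TreatmentReport()
    for task in tasks:
        report.recorded[task] = _counts(trials, task)
        report.pct_remaining[task] = {}

    current = _apply_post_error(trials) if config.drop_post_error else trials

    def _record(stage: str, df: pd.DataFrame) -> None:
        for task in tasks:
            recorded = report.recorded[task]["trials"]
            n = int((df["task"] == task).sum())
            report.pct_remaining[task][stage] = 100.0 * n / recorded if recorded else 0.0

    current = _apply_trimming(current, config)
    _record("rt_trimming", current)
    current = filter_sessions(current, config, stage="min_trials")
    _record("sessions_min_trials", current)
    current = filter_sessions(current, config, stage="response_type")
    _record("sessions_response_type", current)
    current = filter_participants(current, config)
    _record("participants_min_sessions", current)

    for task in tasks:
        report.post[task] = _counts(current, task)
    return current.reset_index(drop=True), report


class DataTreatment:
    """Estimator-style wrapper around :func:`run_treatment`.

    ``fit`` runs the cascade and stores the retention report and the
    surviving row index; ``transform`` filters any frame sharing the
    fitted frame's index. Composes with sklearn-style pipelines via
    ``get_params`` / ``set_params``.
    """

    def __init__(self, config: TreatmentConfig | None = None):
        self.config = config

    def fit(self, X: pd.DataFrame, y=None) -> "DataTreatment":
        clean, report = run_treatment(X, self.config)
        self.report_ = report
        self.n_retained_ = len(clean)
        self._clean = clean
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "report_"):
            raise RuntimeError("DataTreatment must be fitted before transform")
        return self._clean

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)

    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config}

    def set_params(self, **params) -> "DataTreatment":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self
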
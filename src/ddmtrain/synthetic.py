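"""Synthetic multi-session training-study generator.

Emulates the structure of a processing-speed training study: 30
participants x 20 sessions x 3 speeded matching tasks (face, digit,
pattern) x 500 trials, with trial-level correctness, a response
deadline, session-wise learning trajectories in the diffusion
parameters (drift rate increasing; boundary separation and
non-decision time decreasing, mostly early in training), and fast and
slow RT contaminants.

Trial data are produced as a pandas DataFrame with one row per trial
(columns ``participant, session, task, trial, is_match, response,
correct, rt_ms``) together with a ground-truth table of the generating
(v, a, t0) per participant x session x task cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .wiener import DDMParams, simulate_trials

__all__ = [
    "LearningCurve",
    "TaskPopulation",
    "SyntheticConfig",
    "curve_value",
    "draw_participant_curves",
    "generate_study",
    "inject_contaminants",
    "TRIAL_COLUMNS",
]

TRIAL_COLUMNS = [
    "participant",
    "session",
    "task",
    "trial",
    "is_match",
    "response",
    "correct",
    "rt_ms",
]

#: RT range (ms) of injected fast guesses.
FAST_GUESS_RANGE_MS = (80.0, 250.0)
#: Range (ms) of the positive shift applied to injected slow outliers.
SLOW_SHIFT_RANGE_MS = (800.0, 3000.0)


@dataclass(frozen=True)
class LearningCurve:
    """Exponential approach of a parameter to its asymptote over sessions.

    value(s) = asymptote + (initial - asymptote) * exp(-(s - 1) / rate),
    so the curve starts at ``initial`` in session 1 and approaches
    ``asymptote`` with sessions-scale time constant ``rate`` (tau > 0).
    """

    initial: float
    asymptote: float
    rate: float

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ValueError(f"learning-curve time constant must be > 0, got {self.rate}")

    def value(self, session) -> float | np.ndarray:
        s = np.asarray(session, dtype=float)
        out = self.asymptote + (self.initial - self.asymptote) * np.exp(-(s - 1.0) / self.rate)
        return float(out) if out.ndim == 0 else out


def curve_value(curve: LearningCurve, session) -> float | np.ndarray:
    """Evaluate ``curve`` at 1-based ``session``."""
    if np.any(np.asarray(session) < 1):
        raise ValueError("session indices are 1-based")
    return curve.value(session)


@dataclass(frozen=True)
class TaskPopulation:
    """Population-level learning curves (and spreads) for one task.

    ``sd_*`` are between-participant standard deviations applied to both
    the initial value and the asymptote of the corresponding curve
    (perfectly correlated within participant, i.e. a level shift).
    """

    v: LearningCurve
    a: LearningCurve
    t0: LearningCurve
    sd_v: float = 0.0
    sd_a: float = 0.0
    sd_t0: float = 0.0


def _default_populations() -> dict[str, TaskPopulation]:
    # Drift ordered face < digit < pattern, boundary separation the
    # reverse; drift improves throughout training (long time constant)
    # while boundary and non-decision time drop mostly early.
    return {
        "face": TaskPopulation(
            v=LearningCurve(1.8, 2.4, 6.0),
            a=LearningCurve(1.30, 1.05, 2.5),
            t0=LearningCurve(0.50, 0.42, 2.0),
            sd_v=0.25, sd_a=0.12, sd_t0=0.04,
        ),
        "digit": TaskPopulation(
            v=LearningCurve(2.0, 2.7, 6.0),
            a=LearningCurve(1.20, 0.95, 2.5),
            t0=LearningCurve(0.42, 0.34, 2.0),
            sd_v=0.25, sd_a=0.12, sd_t0=0.04,
        ),
        "pattern": TaskPopulation(
            v=LearningCurve(2.2, 3.0, 6.0),
            a=LearningCurve(1.10, 0.85, 2.5),
            t0=LearningCurve(0.38, 0.30, 2.0),
            sd_v=0.25, sd_a=0.12, sd_t0=0.04,
        ),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-level configuration; defaults mirror the emulated study."""

    n_participants: int = 30
    n_sessions: int = 20
    tasks: tuple[str, ...] = ("face", "digit", "pattern")
    trials_per_cell: int = 500
    populations: dict[str, TaskPopulation] = field(default_factory=_default_populations)
    fast_contaminant_rate: float = 0.01
    slow_contaminant_rate: float = 0.02
    deadline_ms: float = 5000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_participants, self.n_sessions, self.trials_per_cell, len(self.tasks)) < 1:
            raise ValueError("all study counts must be >= 1")
        for r in (self.fast_contaminant_rate, self.slow_contaminant_rate):
            if not (0.0 <= r < 1.0):
                raise ValueError(f"contaminant rates must lie in [0, 1), got {r}")
        missing = set(self.tasks) - set(self.populations)
        if missing:
            raise ValueError(f"no population curves for tasks: {sorted(missing)}")
        for task in self.tasks:
            pop = self.populations[task]
            if any(c.value(self.n_sessions) * 1000.0 >= self.deadline_ms for c in (pop.t0,)):
                raise ValueError(f"deadline {self.deadline_ms} ms not above t0 for task {task!r}")


def _truncated_normal(rng: np.random.Generator, loc: float, scale: float, low: float, high: float) -> float:
    """Draw by redraw-truncation; falls back to clipping after 100 tries."""
    if scale == 0.0:
        return float(np.clip(loc, low, high))
    for _ in range(100):
        x = rng.normal(loc, scale)
        if low < x < high:
            return float(x)
    return float(np.clip(rng.normal(loc, scale), low + 1e-6, high - 1e-6))


def _shift_curve(curve: LearningCurve, rng: np.random.Generator, sd: float,
                 low: float, high: float, increasing: bool) -> LearningCurve:
    delta = _truncated_normal(rng, 0.0, sd, low - min(curve.initial, curve.asymptote),
                              high - max(curve.initial, curve.asymptote))
    shifted = replace(curve, initial=curve.initial + delta, asymptote=curve.asymptote + delta)
    ok = shifted.asymptote > shifted.initial if increasing else shifted.asymptote < shifted.initial
    if not ok:
        raise ValueError("population curves violate the required trend direction")
    return shifted


def draw_participant_curves(
    config: SyntheticConfig, participant: int, task: str, seed: int | np.random.Generator
) -> tuple[LearningCurve, LearningCurve, LearningCurve]:
    """Draw one participant's (v, a, t0) learning curves for ``task``.

    Participant heterogeneity is a level shift of the population curve,
    truncated so every session's parameters satisfy the diffusion-model
    invariants; the drift asymptote stays above its initial value and
    the boundary/t0 asymptotes below theirs.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pop = config.populations[task]
    v = _shift_curve(pop.v, rng, pop.sd_v, -8.0, 8.0, increasing=True)
    a = _shift_curve(pop.a, rng, pop.sd_a, 0.2, 4.0, increasing=False)
    t0 = _shift_curve(pop.t0, rng, pop.sd_t0, 0.05, config.deadline_ms / 1000.0 * 0.5, increasing=False)
    return v, a, t0


def inject_contaminants(
    trials: pd.DataFrame,
    fast_rate: float,
    slow_rate: float,
    seed: int | np.random.Generator,
    deadline_ms: float | None = None,
) -> pd.DataFrame:
    """Replace a Binomial(n, rate) subset of trials with contaminants.

    Fast guesses get a uniform RT in [80, 250) ms and random correctness;
    slow outliers have their RT inflated by a uniform shift in
    [800, 3000) ms (capped at the deadline when one is given). Rates of 0
    return the input unchanged.
    """
    for r in (fast_rate, slow_rate):
        if not (0.0 <= r < 1.0):
            raise ValueError(f"contaminant rates must lie in [0, 1), got {r}")
    if fast_rate == 0.0 and slow_rate == 0.0:
        return trials
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = trials.copy()
    n = len(out)
    u = rng.random(n)
    fast = u < fast_rate
    slow = (u >= fast_rate) & (u < fast_rate + slow_rate)

    n_fast = int(fast.sum())
    if n_fast:
        lo, hi = FAST_GUESS_RANGE_MS
        out.loc[fast, "rt_ms"] = rng.uniform(lo, hi, n_fast)
        guess_correct = rng.random(n_fast) < 0.5
        out.loc[fast, "correct"] = guess_correct
        is_match = out.loc[fast, "is_match"].to_numpy(bool)
        out.loc[fast, "response"] = np.where(is_match == guess_correct, "match", "nonmatch")
    n_slow = int(slow.sum())
    if n_slow:
        lo, hi = SLOW_SHIFT_RANGE_MS
        rt = out.loc[slow, "rt_ms"].to_numpy(float) + rng.uniform(lo, hi, n_slow)
        if deadline_ms is not None:
            rt = np.minimum(rt, deadline_ms)
        out.loc[slow, "rt_ms"] = rt
    return out


def generate_study(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the full study: trial table plus ground-truth parameters.

    For every participant x session x task cell, decision times are
    simulated from that cell's diffusion parameters, the non-decision
    time is added, RTs are converted to milliseconds, the deadline is
    applied (censored trials carry the deadline RT), and contaminants
    are injected at the configured rates. The ground-truth table holds
    one (v, a, t0) row per cell, keyed like the trial table.

    The master seed spawns independent child streams per participant x
    task (curve draws) and per cell (trial simulation), so identical
    configurations reproduce identical datasets.
    """
    root = np.random.SeedSequence(config.seed)
    curve_ss, trial_ss, contam_ss = root.spawn(3)
    curve_children = curve_ss.spawn(config.n_participants * len(config.tasks))
    trial_children = trial_ss.spawn(config.n_participants * len(config.tasks) * config.n_sessions)

    frames: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    deadline_s = config.deadline_ms / 1000.0
    sessions = np.arange(1, config.n_sessions + 1)

    cell_idx = 0
    for p_idx in range(config.n_participants):
        pid = f"p{p_idx + 1:02d}"
        for t_idx, task in enumerate(config.tasks):
            curve_rng = np.random.default_rng(curve_children[p_idx * len(config.tasks) + t_idx])
            v_curve, a_curve, t0_curve = draw_participant_curves(config, p_idx, task, curve_rng)
            for session in sessions:
                params = DDMParams(
                    v=float(v_curve.value(session)),
                    a=float(a_curve.value(session)),
                    w=0.5,
                    t0=float(t0_curve.value(session)),
                )
                rng = np.random.default_rng(trial_children[cell_idx])
                cell_idx += 1
                sim = simulate_trials(params, config.trials_per_cell, rng, deadline=deadline_s)
                n = len(sim)
                is_match = rng.random(n) < 0.5
                correct = sim.upper
                response = np.where(is_match == correct, "match", "nonmatch")
                frames.append(pd.DataFrame({
                    "participant": pid,
                    "session": int(session),
                    "task": task,
                    "trial": np.arange(1, n + 1),
                    "is_match": is_match,
                    "response": response,
                    "correct": correct,
                    "rt_ms": sim.rt * 1000.0,
                }))
                truth_rows.append({
                    "participant": pid, "session": int(session), "task": task,
                    "v": params.v, "a": params.a, "t0": params.t0,
                })

    trials = pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]
    trials = inject_contaminants(
        trials, config.fast_contaminant_rate, config.slow_contaminant_rate,
        np.random.default_rng(contam_ss), deadline_ms=config.deadline_ms,
    )
    truth = pd.DataFrame(truth_rows)
    return trials, truth
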
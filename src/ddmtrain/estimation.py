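"""Per-cell diffusion-model estimation under a Kolmogorov-Smirnov criterion.

Each participant x session x task cell is fit independently (the
three-parameter model: drift rate v, boundary separation a,
non-decision time t0, with the starting point fixed at w = 0.5 and
diffusion coefficient s = 1). Choice and latency are combined into a
single signed-RT distribution — correct responses on the positive
axis, errors mirrored onto the negative axis — and the KS distance
between the empirical and model signed CDFs is minimized by
derivative-free simplex search from multiple data-driven starts, in
the manner of the fast-dm family of estimators.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .wiener import Boundary, DDMParams, absorption_probability, wfpt_cdf

__all__ = [
    "FitSettings",
    "WienerKS",
    "to_signed_rts",
    "model_signed_cdf",
    "ks_statistic",
    "fit_cell",
    "fit_dataset",
]

CELL_KEYS = ["participant", "session", "task"]

#: Default box constraints for (v, a, t0); the t0 upper bound is
#: additionally clamped to the smallest observed RT at fit time.
DEFAULT_BOUNDS = {"v": (-10.0, 10.0), "a": (0.05, 10.0), "t0": (0.0, 10.0)}


def to_signed_rts(trials: pd.DataFrame, rt_unit: str = "ms") -> np.ndarray:
    """Map one cell's trials to a sorted signed-RT sample in seconds.

    Correct responses carry +rt, errors -rt (accuracy coding: upper
    boundary = correct). Counts are preserved; the cell must be nonempty.
    """
    if len(trials) == 0:
        raise ValueError("cannot build a signed-RT sample from an empty cell")
    scale = {"ms": 1e-3, "s": 1.0}[rt_unit]
    rt = trials["rt_ms" if rt_unit == "ms" else "rt_s"].to_numpy(float) * scale
    sign = np.where(trials["correct"].to_numpy(bool), 1.0, -1.0)
    return np.sort(sign * rt)


def model_signed_cdf(x, params: DDMParams):
    """CDF of the model's signed-RT distribution at signed seconds ``x``.

    For x < 0 the value is P_lower - F_lower(-x - t0); for x >= 0 it is
    P_lower + F_upper(x - t0), with F the defective first-passage CDFs
    and P_lower the lower-boundary absorption probability. Limits are 0
    at -inf and 1 at +inf, nondecreasing throughout.
    """
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    p_low = absorption_probability(params, Boundary.LOWER)
    out = np.empty_like(x_arr)
    neg = x_arr < 0
    if np.any(neg):
        out[neg] = p_low - wfpt_cdf(-x_arr[neg] - params.t0, params, Boundary.LOWER)
    if np.any(~neg):
        out[~neg] = p_low + wfpt_cdf(x_arr[~neg] - params.t0, params, Boundary.UPPER)
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if np.isscalar(x) or np.ndim(x) == 0 else out


def ks_statistic(sample: np.ndarray, params: DDMParams) -> float:
    """KS distance between the empirical signed-RT CDF and the model's.

    ``sample`` must be sorted ascending. The supremum is evaluated on
    both sides of every empirical step, so the returned value is the
    exact KS distance, in [0, 1].
    """
    n = len(sample)
    if n == 0:
        raise ValueError("empty signed-RT sample")
    f = model_signed_cdf(sample, params)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - f)
    d_minus = np.max(f - (i - 1) / n)
    return float(min(max(d_plus, d_minus), 1.0))


@dataclass(frozen=True)
class FitSettings:
    """Optimizer configuration for the KS fit.

    ``n_starts`` simplex searches are launched: data-heuristic starts
    first, then seeded jitters of the best heuristic. Ties between
    converged starts are broken by smaller a, then smaller t0.
    """

    n_starts: int = 5
    seed: int = 0
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    xatol: float = 1e-3
    fatol: float = 1e-4
    maxiter: int = 400


class WienerKS:
    """Three-parameter diffusion estimator, fast-dm style.

    Scikit-learn estimator interface: construct with hyperparameters,
    ``fit(X)`` on a signed-RT sample (seconds; correct responses
    positive, errors negative), read fitted attributes ``v_``, ``a_``,
    ``t0_``, ``ks_stat_``, ``converged_``. ``fixed`` clamps a subset of
    {"v", "a", "t0"} to given values (constrained refits for model
    comparison); only the free parameters are searched.

    The criterion is the exact KS distance between the empirical signed
    CDF and the model signed CDF, minimized by Nelder-Mead from
    ``n_starts`` data-driven starting points. Box constraints are
    enforced by a penalty. Deterministic given ``seed``.
    """

    def __init__(
        self,
        w: float = 0.5,
        s: float = 1.0,
        n_starts: int = 5,
        seed: int = 0,
        fixed: dict | None = None,
        bounds: dict | None = None,
        xatol: float = 1e-3,
        fatol: float = 1e-4,
        maxiter: int = 400,
    ):
        self.w = w
        self.s = s
        self.n_starts = n_starts
        self.seed = seed
        self.fixed = fixed
        self.bounds = bounds
        self.xatol = xatol
        self.fatol = fatol
        self.maxiter = maxiter

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "w": self.w, "s": self.s, "n_starts": self.n_starts, "seed": self.seed,
            "fixed": self.fixed, "bounds": self.bounds,
            "xatol": self.xatol, "fatol": self.fatol, "maxiter": self.maxiter,
        }

    def set_params(self, **params) -> "WienerKS":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- internals ---------------------------------------------------------
    def _start_points(self, x: np.ndarray) -> list[dict]:
        """Deterministic heuristic starts plus seeded jitter.

        t0 from low RT percentiles, a from the RT spread, v from the
        observed accuracy through the closed-form choice probability
        (logit(p) / a for w = 0.5).
        """
        abs_rt = np.abs(x)
        p_correct = float(np.mean(x > 0))
        p_clip = min(max(p_correct, 0.02), 0.98)
        min_rt = float(abs_rt.min())
        q05 = float(np.quantile(abs_rt, 0.05))
        spread = float(np.quantile(abs_rt, 0.9) - np.quantile(abs_rt, 0.1))

        starts = []
        for t0_frac, a0 in ((0.90, 1.0), (0.75, 1.0), (0.90, max(0.4, 2.2 * spread)),
                            (0.50, 1.6), (0.95, 0.7)):
            t0_0 = min(t0_frac * min_rt, q05)
            v0 = math.log(p_clip / (1.0 - p_clip)) / a0
            starts.append({"v": v0, "a": a0, "t0": t0_0})

        rng = np.random.default_rng(self.seed)
        while len(starts) < max(self.n_starts, 1):
            base = starts[0]
            starts.append({
                "v": base["v"] + rng.normal(0, 0.5),
                "a": max(0.2, base["a"] * math.exp(rng.normal(0, 0.3))),
                "t0": max(0.0, base["t0"] * rng.uniform(0.5, 1.0)),
            })
        return starts[: max(self.n_starts, 1)]

    def _objective(self, x_sorted: np.ndarray, free: list[str], fixed: dict, bounds: dict):
        def fun(theta: np.ndarray) -> float:
            p = dict(fixed)
            penalty = 0.0
            for name, val in zip(free, theta):
                lo, hi = bounds[name]
                if val < lo or val > hi:
                    penalty += 1.0 + abs(val - np.clip(val, lo, hi))
                p[name] = float(np.clip(val, lo, hi))
            try:
                params = DDMParams(v=p["v"], a=p["a"], w=self.w, t0=p["t0"], s=self.s)
            except ValueError:
                return 2.0 + penalty
            return ks_statistic(x_sorted, params) + penalty
        return fun

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y=None) -> "WienerKS":
        x = np.sort(np.asarray(X, dtype=float).ravel())
        if len(x) == 0:
            raise ValueError("empty signed-RT sample")
        if np.any(np.abs(x) <= 0) or not np.all(np.isfinite(x)):
            raise ValueError("signed RTs must be finite and nonzero")

        fixed = dict(self.fixed or {})
        unknown = set(fixed) - {"v", "a", "t0"}
        if unknown:
            raise ValueError(f"cannot fix unknown parameters: {sorted(unknown)}")
        free = [p for p in ("v", "a", "t0") if p not in fixed]

        bounds = dict(DEFAULT_BOUNDS)
        bounds.update(self.bounds or {})
        lo_t0, hi_t0 = bounds["t0"]
        bounds["t0"] = (lo_t0, min(hi_t0, float(np.abs(x).min())))

        best = None
        n_used = 0
        for start in self._start_points(x):
            n_used += 1
            theta0 = np.array([np.clip(start[p], *bounds[p]) for p in free])
            if len(theta0) == 0:
                res_x, res_fun, res_ok = theta0, self._objective(x, free, fixed, bounds)(theta0), True
            else:
                res = minimize(
                    self._objective(x, free, fixed, bounds), theta0, method="Nelder-Mead",
                    options={"xatol": self.xatol, "fatol": self.fatol,
                             "maxiter": self.maxiter, "maxfev": 3 * self.maxiter},
                )
                res_x, res_fun, res_ok = res.x, float(res.fun), bool(res.success)
            cand = dict(fixed)
            cand.update({p: float(np.clip(v, *bounds[p])) for p, v in zip(free, res_x)})
            key = (round(res_fun, 9), cand["a"], cand["t0"])
            if best is None or key < best[0]:
                best = (key, cand, res_ok)

        _, cand, ok = best
        self.v_, self.a_, self.t0_ = cand["v"], cand["a"], cand["t0"]
        self.params_ = DDMParams(v=self.v_, a=self.a_, w=self.w, t0=self.t0_, s=self.s)
        self.ks_stat_ = ks_statistic(x, self.params_)
        self.converged_ = ok
        self.n_trials_ = len(x)
        self.n_starts_ = n_used
        return self

    def score(self, X, y=None) -> float:
        """Negative KS distance of the fitted model on ``X`` (higher is better)."""
        x = np.sort(np.asarray(X, dtype=float).ravel())
        return -ks_statistic(x, self.params_)


def fit_cell(trials: pd.DataFrame, settings: FitSettings | None = None,
             fixed: dict | None = None, rt_unit: str = "ms") -> dict:
    """Fit one cell's trials; returns a flat result record.

    The record carries the cell key (when present), the estimates, the KS
    distance at the estimates, trial count, starts used, and convergence.
    """
    settings = settings or FitSettings()
    x = to_signed_rts(trials, rt_unit=rt_unit)
    est = WienerKS(
        n_starts=settings.n_starts, seed=settings.seed, fixed=fixed,
        bounds=settings.bounds, xatol=settings.xatol, fatol=settings.fatol,
        maxiter=settings.maxiter,
    ).fit(x)
    rec = {k: trials[k].iloc[0] for k in CELL_KEYS if k in trials.columns}
    rec.update({
        "v": est.v_, "a": est.a_, "t0": est.t0_, "ks_stat": est.ks_stat_,
        "n_trials": est.n_trials_, "n_starts": est.n_starts_, "converged": est.converged_,
    })
    return rec


def fit_dataset(clean: pd.DataFrame, settings: FitSettings | None = None,
                fixed: dict | None = None, progress: bool = False) -> pd.DataFrame:
    """Fit every participant x session x task cell independently.

    One row per retained cell; cells that fail to converge are flagged
    via ``converged``, never dropped. Deterministic given the settings'
    seed (each cell derives a stable child seed from its key).
    """
    settings = settings or FitSettings()
    result_cols = CELL_KEYS + ["v", "a", "t0", "ks_stat", "n_trials", "n_starts", "converged"]
    if len(clean) == 0:
        return pd.DataFrame(columns=result_cols)
    rows = []
    groups = clean.groupby(CELL_KEYS, sort=True, observed=True)
    for key, cell in groups:
        # stable per-cell child seed (process-independent, unlike hash())
        child = (zlib.crc32("|".join(map(str, key)).encode()) ^ settings.seed) & 0x7FFFFFFF
        cell_settings = FitSettings(
            n_starts=settings.n_starts, seed=child, bounds=settings.bounds,
            xatol=settings.xatol, fatol=settings.fatol, maxiter=settings.maxiter,
        )
        rows.append(fit_cell(cell, cell_settings, fixed=fixed))
        if progress and len(rows) % 100 == 0:
            print(f"fitted {len(rows)} cells")
    return pd.DataFrame(rows)
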
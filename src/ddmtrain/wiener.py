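"""Two-boundary Wiener diffusion numerics.

First-passage-time ("defective") densities and CDFs, absorption
probabilities, closed-form moments, and a trial simulator for the
standard diffusion decision process: evidence X(t) starts at w*a
between an absorbing lower boundary at 0 and upper boundary at a,
and evolves as dX = v dt + s dW.  The upper boundary codes a correct
response, the lower an incorrect one (accuracy coding).

Densities are evaluated with the classical small-time (image) and
large-time (eigenfunction) series, switching at a normalized-time
crossover; CDFs integrate each series term in closed form.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfc, erfcx

__all__ = [
    "DDMParams",
    "Boundary",
    "SimulatedTrials",
    "absorption_probability",
    "wfpt_density",
    "wfpt_cdf",
    "mean_decision_time",
    "simulate_trials",
]

#: Series truncation target for the density/CDF evaluations (absolute).
SERIES_EPS = 1e-12

#: Crossover between the small-time and large-time series, in units of
#: normalized time tau = t * s^2 / a^2.
TAU_CROSSOVER = 0.15

#: Number of grid points used by the inverse-CDF trial sampler.
_SAMPLER_GRID = 4097


class Boundary(str, enum.Enum):
    """Absorbing boundary label: upper = correct, lower = incorrect."""

    UPPER = "upper"
    LOWER = "lower"


@dataclass(frozen=True)
class DDMParams:
    """Parameters of the three-parameter diffusion decision model.

    Parameters
    ----------
    v : float
        Drift rate (evidence units per second).
    a : float
        Boundary separation (> 0).
    w : float
        Relative starting point in (0, 1); 0.5 is unbiased.
    t0 : float
        Non-decision time in seconds (>= 0).
    s : float
        Within-trial diffusion coefficient. Fixed scaling constant;
        the package convention is s = 1 (the fast-dm convention).
    """

    v: float
    a: float
    w: float = 0.5
    t0: float = 0.0
    s: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.v):
            raise ValueError(f"drift rate must be finite, got {self.v}")
        if not (self.a > 0 and np.isfinite(self.a)):
            raise ValueError(f"boundary separation must be > 0, got {self.a}")
        if not (0.0 < self.w < 1.0):
            raise ValueError(f"relative start must lie in (0, 1), got {self.w}")
        if not (self.t0 >= 0 and np.isfinite(self.t0)):
            raise ValueError(f"non-decision time must be >= 0, got {self.t0}")
        if not (self.s > 0 and np.isfinite(self.s)):
            raise ValueError(f"diffusion coefficient must be > 0, got {self.s}")

    def normalized(self) -> tuple[float, float, float]:
        """Return (v, a, w) rescaled to diffusion coefficient 1."""
        return self.v / self.s, self.a / self.s, self.w


@dataclass
class SimulatedTrials:
    """Column-oriented batch of simulated trials.

    ``rt`` is in seconds and includes the non-decision time; ``upper``
    flags upper-boundary (correct) absorptions; censored trials carry
    ``rt == deadline`` and keep the boundary the process would have hit.
    """

    rt: np.ndarray
    upper: np.ndarray
    censored: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.censored is None:
            self.censored = np.zeros(len(self.rt), dtype=bool)

    def __len__(self) -> int:
        return len(self.rt)


def _p_upper_scaled(v: float, a: float, w: float) -> float:
    """Upper-boundary absorption probability for s = 1."""
    x = 2.0 * v * a
    if abs(x) < 1e-9:
        # expand (1 - e^{-xw}) / (1 - e^{-x}) around x = 0
        return w + w * (1.0 - w) * x / 2.0
    if x > 0:
        return math.expm1(-x * w) / math.expm1(-x)
    # reflect to keep every exponent negative
    return math.exp(x * (1.0 - w)) * math.expm1(x * w) / math.expm1(x)


def absorption_probability(params: DDMParams, boundary: Boundary | str = Boundary.UPPER) -> float:
    """Probability that the process is absorbed at ``boundary``.

    For drift v, separation a, start w and diffusion s the upper-boundary
    probability is (1 - exp(-2vaw/s^2)) / (1 - exp(-2va/s^2)); at v = 0 it
    reduces to w.
    """
    v, a, w = params.normalized()
    p_up = _p_upper_scaled(v, a, w)
    if Boundary(boundary) is Boundary.UPPER:
        return p_up
    return 1.0 - p_up


def _small_time_k(tau_max: float) -> int:
    """Image terms needed for absolute error < SERIES_EPS at tau <= tau_max."""
    k = 2 + math.sqrt(max(0.0, -2.0 * tau_max * math.log(2.0 * SERIES_EPS * math.sqrt(2.0 * math.pi * tau_max))))
    return max(4, int(math.ceil(k)))


def _large_time_k(tau_min: float) -> int:
    """Eigenfunction terms needed for absolute error < SERIES_EPS at tau >= tau_min."""
    k = math.sqrt(max(1.0, -2.0 * math.log(math.pi * tau_min * SERIES_EPS)) / (math.pi**2 * tau_min))
    return max(4, int(math.ceil(k)) + 1)


def _lower_density_scaled(t: np.ndarray, v: float, a: float, w: float) -> np.ndarray:
    """Defective density of lower-boundary passage times, s = 1, vectorized."""
    out = np.zeros_like(t, dtype=float)
    pos = t > 0
    if not np.any(pos):
        return out
    tp = t[pos]
    tau = tp / a**2
    drift = np.exp(-v * a * w - 0.5 * v**2 * tp)

    small = tau <= TAU_CROSSOVER
    vals = np.empty_like(tp)

    if np.any(small):
        ts = tp[small]
        K = _small_time_k(float(tau[small].max()))
        k = np.arange(-K, K + 1)[:, None]
        wk = w + 2.0 * k
        terms = a * wk / np.sqrt(2.0 * math.pi * ts**3) * np.exp(-(a * wk) ** 2 / (2.0 * ts))
        vals[small] = terms.sum(axis=0)
    if np.any(~small):
        tl = tp[~small]
        K = _large_time_k(float(tau[~small].min()))
        k = np.arange(1, K + 1)[:, None]
        terms = k * np.sin(k * math.pi * w) * np.exp(-(k * math.pi) ** 2 * tl / (2.0 * a**2))
        vals[~small] = math.pi / a**2 * terms.sum(axis=0)

    out[pos] = np.maximum(vals * drift, 0.0)
    return out


def _ig_integral(alpha: np.ndarray, beta: float, T: np.ndarray) -> np.ndarray:
    """Closed form of ``int_0^T t^{-3/2} exp(-alpha/t - beta t) dt``.

    Equals sqrt(pi/alpha)/2 * [e^{-2 sqrt(ab)} erfc(u - r) + e^{2 sqrt(ab)} erfc(u + r)]
    with u = sqrt(alpha/T), r = sqrt(beta T); evaluated through erfcx where
    the naive form would overflow.
    """
    u = np.sqrt(alpha / T)
    r = math.sqrt(beta) * np.sqrt(T) if beta > 0 else np.zeros_like(T)
    ab2 = 2.0 * np.sqrt(alpha * beta)
    expo = np.exp(-alpha / T - beta * T)

    # e^{+ab2} erfc(u + r): u + r >= 0 always, use erfcx unconditionally
    term_plus = erfcx(u + r) * expo
    # e^{-ab2} erfc(u - r): stable directly when u - r is small or negative
    z = u - r
    direct = np.exp(-ab2) * erfc(z)
    via_erfcx = erfcx(np.maximum(z, 0.0)) * expo
    term_minus = np.where(z > 5.0, via_erfcx, direct)

    return 0.5 * np.sqrt(math.pi / alpha) * (term_plus + term_minus)


def _lower_cdf_scaled(t: np.ndarray, v: float, a: float, w: float) -> np.ndarray:
    """Defective CDF of lower-boundary passage times, s = 1, vectorized."""
    out = np.zeros_like(t, dtype=float)
    pos = t > 0
    if not np.any(pos):
        return out
    tp = t[pos]
    tau = tp / a**2
    p_low = 1.0 - _p_upper_scaled(v, a, w)
    beta = 0.5 * v**2
    pref = math.exp(-v * a * w)

    small = tau <= TAU_CROSSOVER
    vals = np.empty_like(tp)

    if np.any(small):
        ts = tp[small]
        K = _small_time_k(float(tau[small].max()))
        k = np.arange(-K, K + 1)[:, None]
        wk = w + 2.0 * k
        alpha = (a * wk) ** 2 / 2.0
        coef = a * wk / math.sqrt(2.0 * math.pi) * pref
        vals[small] = (coef * _ig_integral(alpha, beta, ts[None, :])).sum(axis=0)
    if np.any(~small):
        tl = tp[~small]
        K = _large_time_k(float(tau[~small].min()))
        k = np.arange(1, K + 1)[:, None]
        lam = 0.5 * (v**2 + (k * math.pi / a) ** 2)
        terms = k * np.sin(k * math.pi * w) / lam * np.exp(-lam * tl)
        vals[~small] = p_low - math.pi / a**2 * pref * terms.sum(axis=0)

    out[pos] = np.clip(vals, 0.0, p_low)
    return out


def _as_lower(params: DDMParams, boundary: Boundary | str) -> tuple[float, float, float]:
    """Map the requested boundary onto the lower-boundary formulas.

    The upper-boundary density at (v, w) equals the lower-boundary density
    at (-v, 1 - w) (reflection symmetry of the diffusion).
    """
    v, a, w = params.normalized()
    if Boundary(boundary) is Boundary.UPPER:
        return -v, a, 1.0 - w
    return v, a, w


def wfpt_density(t, params: DDMParams, boundary: Boundary | str = Boundary.UPPER):
    """Defective first-passage density at decision time ``t`` (seconds).

    ``t`` is measured from the start of evidence accumulation (the caller
    subtracts the non-decision time). Returns 0 for t <= 0. Integrates
    over (0, inf) to the boundary's absorption probability.
    """
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("decision times must be finite")
    # dividing the state space by s maps (v, a, s) -> (v/s, a/s, 1) and
    # leaves passage times unchanged
    v, a, w = _as_lower(params, boundary)
    dens = _lower_density_scaled(np.atleast_1d(t_arr), v, a, w)
    return dens[0] if t_arr.ndim == 0 else dens


def wfpt_cdf(t, params: DDMParams, boundary: Boundary | str = Boundary.UPPER):
    """Defective first-passage CDF at decision time ``t`` (seconds).

    Nondecreasing in t, 0 at t <= 0, and tends to the boundary's absorption
    probability as t -> inf.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(np.isnan(t_arr)):
        raise ValueError("decision times must not be NaN")
    v, a, w = _as_lower(params, boundary)
    t1 = np.atleast_1d(t_arr).copy()
    inf_mask = np.isposinf(t1)
    t1[inf_mask] = 1.0  # placeholder; overwritten below
    vals = _lower_cdf_scaled(t1, v, a, w)
    if np.any(inf_mask):
        vals[inf_mask] = 1.0 - _p_upper_scaled(v, a, w)
    return vals[0] if t_arr.ndim == 0 else vals


def mean_decision_time(params: DDMParams) -> float:
    """Expected decision time in seconds, unconditional on boundary.

    From the optional-stopping identity E[X_T] = z + v E[T]:
    E[T] = (a P_upper - z) / v for v != 0, and z (a - z) / s^2 at v = 0.
    For w = 0.5, s = 1 this reduces to (a / 2v) tanh(va / 2).
    """
    v, a, w = params.normalized()
    z = w * a
    if abs(v) < 1e-9:
        return z * (a - z)
    return (a * _p_upper_scaled(v, a, w) - z) / v


def _conditional_sampler(params: DDMParams, boundary: Boundary) -> tuple[np.ndarray, np.ndarray]:
    """Build (grid_times, normalized CDF) for inverse-CDF sampling."""
    p_b = absorption_probability(params, boundary)
    if p_b <= 0:
        raise ValueError(f"no mass at boundary {boundary}")
    # expand t_max until the defective CDF has absorbed essentially all p_b
    _, a, _ = params.normalized()
    t_max = max(4.0 * a**2, 0.5)
    for _ in range(60):
        if p_b - wfpt_cdf(t_max, params, boundary) < 1e-12 * p_b + 1e-15:
            break
        t_max *= 1.6
    # quadratic spacing concentrates nodes at short times where the
    # density peaks
    grid = (np.arange(1, _SAMPLER_GRID + 1) / _SAMPLER_GRID) ** 2 * t_max
    cdf = wfpt_cdf(grid, params, boundary) / p_b
    cdf = np.maximum.accumulate(np.clip(cdf, 0.0, 1.0))
    return grid, cdf


def simulate_trials(
    params: DDMParams,
    n: int,
    seed: int | np.random.Generator,
    deadline: float | None = None,
) -> SimulatedTrials:
    """Simulate ``n`` trials by inverse-CDF sampling of the passage times.

    Returned RTs are in seconds and include the non-decision time. With a
    ``deadline`` (seconds), trials whose RT would exceed it are censored:
    they keep their boundary label, carry ``rt = deadline`` and are flagged,
    never dropped.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if deadline is not None and deadline <= params.t0:
        raise ValueError(f"deadline {deadline} s must exceed non-decision time {params.t0} s")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    p_up = absorption_probability(params, Boundary.UPPER)
    upper = rng.random(n) < p_up
    u = rng.random(n)

    rt = np.empty(n, dtype=float)
    for is_up, boundary in ((True, Boundary.UPPER), (False, Boundary.LOWER)):
        mask = upper == is_up
        if not np.any(mask):
            continue
        grid, cdf = _conditional_sampler(params, boundary)
        rt[mask] = np.interp(u[mask], cdf, grid)
    rt += params.t0

    censored = np.zeros(n, dtype=bool)
    if deadline is not None:
        censored = rt > deadline
        rt[censored] = deadline
    return SimulatedTrials(rt=rt, upper=upper, censored=censored)
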
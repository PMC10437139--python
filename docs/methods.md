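# Methods

## The diffusion decision model

Each speeded two-choice trial is modelled as a Wiener process with drift:
evidence X(t) starts at w·a between an absorbing lower boundary at 0 and
upper boundary at a and evolves as dX = v dt + s dW. The first boundary
reached determines the response — upper = correct, lower = incorrect
(accuracy coding) — and the observed RT is the first-passage time plus the
non-decision time t₀ (stimulus encoding plus motor execution). The model
is fit per *cell*, one participant × session × task stratum.

Parameters and conventions:

| parameter | meaning | units | default/constraint |
|---|---|---|---|
| v | drift rate (accumulation efficiency) | evidence/s | free, box [-10, 10] |
| a | boundary separation (response caution) | evidence | free, box [0.05, 10] |
| w | relative starting point | — | fixed at 0.5 (no bias) |
| t₀ | non-decision time | s | free, box [0, min observed RT] |
| s | diffusion coefficient | evidence/√s | fixed at 1 |

The diffusion coefficient is a pure scaling constant: multiplying (v, a, s)
by a common factor leaves choice probabilities and RT distributions
unchanged. The estimation software this pipeline is patterned on uses
s = 1, and that convention is adopted here; it is exposed as a parameter
only so the scale invariance can be tested, never estimated.
Inter-trial variability parameters (sv, sz, st₀), collapsing bounds, and
bias (w ≠ 0.5) are deliberately out of scope: the fitted model is the
three-parameter model throughout.

## First-passage numerics

The defective density of lower-boundary passage times has two classical
series representations: a small-time expansion over mirror images

f(t) = a Σ_k (w+2k) / √(2π t³) · exp(−vaw − v²t/2 − a²(w+2k)²/(2t))

and a large-time eigenfunction expansion

f(t) = (π/a²) e^{−vaw − v²t/2} Σ_{k≥1} k sin(kπw) e^{−k²π²t/(2a²)}.

The implementation switches at normalized time τ = t/a² = 0.15 (an
internal constant) and truncates each series at the number of terms
bounding the absolute error below 1e-12; the upper boundary is obtained by
the reflection (v, w) → (−v, 1−w).

The defective CDF integrates each series term in closed form. Large-time
terms integrate exactly (each term is a decaying exponential in t).
Small-time terms reduce to the identity

∫₀ᵀ t^{-3/2} e^{−α/t − βt} dt = √(π/α)/2 · [e^{−2√(αβ)} erfc(u−r) + e^{2√(αβ)} erfc(u+r)],

with u = √(α/T), r = √(βT); products of huge exponentials with tiny erfc
values are evaluated through the scaled complement erfcx, which keeps every
factor in range. A quadrature oracle (adaptive integration of the density)
verifies the CDF to 1e-6 in the test suite.

Absorption probabilities use the standard closed form
P_upper = (1 − e^{−2vaw/s²}) / (1 − e^{−2va/s²}) with an expm1/reflection
evaluation that is stable for either drift sign and the v → 0 limit (= w).
The unconditional mean decision time comes from the optional-stopping
identity E[T] = (a·P_upper − wa)/v, reducing to (a/2v)·tanh(va/2) at
w = 0.5 and to wa(a − wa) at v = 0.

### Trial simulation

Trials are sampled by inversion: the boundary is drawn from the closed-form
choice probability, and the conditional decision time by interpolating the
inverse of the normalized series CDF on a 4097-point grid with quadratic
spacing (dense at short times, extended until the residual tail mass is
below 1e-12 of the boundary's probability). This is exact up to grid
interpolation error — the simulated-vs-analytic KS distance at n = 100,000
stays well below 0.01 in the tests — and orders of magnitude faster than
Euler stepping. With a response deadline, trials whose RT would exceed it
are *censored*: tagged, assigned the deadline RT, and never dropped;
downstream treatment of censored trials is the caller's decision.

## Synthetic study generator

The generator emulates a processing-speed training study: by default 30
participants × 20 sessions × 3 matching tasks (face, digit, pattern) × 500
trials, i.e. 30,000 trials per participant, with trialwise correctness, a
5000 ms response deadline, and random match/nonmatch trial types.

Session-wise change in each diffusion parameter follows an exponential
approach to an asymptote, value(s) = asymptote + (initial − asymptote)·
e^{−(s−1)/τ} — chosen because training effects in such studies show rapid
early change followed by stabilization. Drift rates increase over sessions
(slow time constant, τ = 6 sessions, reflecting prolonged improvement in
processing efficiency); boundary separation and non-decision time decrease,
mostly early (τ = 2.5 and 2 sessions). Task defaults order drift as
face < digit < pattern with boundary separation reversed, drift spanning
roughly 1.8–3.0 evidence/s, boundaries 0.85–1.30, and non-decision times
0.30–0.50 s, which produce mean RTs of roughly 0.4–0.8 s and error rates
of 5–9% — plausible for easy speeded matching tasks, and high enough that
the 4%-per-response-type inclusion rule retains most sessions. These
defaults are illustrative study conditions for testing the pipeline, not
estimates of any particular dataset.

Participant heterogeneity is a truncated-normal level shift applied to each
population curve (SD 0.25 for v, 0.12 for a, 0.04 s for t₀), preserving
each parameter's trend direction. Contaminants are injected at 1% fast
guesses (uniform RT in [80, 250) ms, random correctness) and 2% slow
outliers (RT inflated by a uniform [800, 3000) ms shift, capped at the
deadline). A master seed spawns independent child streams per
participant × task (curve draws) and per cell (trial simulation), so any
subset of the data is reproducible.

What the generator does **not** emulate: the adaptive
presentation-deadline algorithm of real training software (a fixed deadline
stands in), feedback-driven behavioural adjustments such as post-error
slowing, sequential dependencies, session-timing metadata, and parameter
drift within a session. Passing tests therefore demonstrate that the
pipeline recovers what the model family can express, not that real training
data satisfy the model.

## Data treatment

The cascade runs in a fixed order; every stage recomputes on the previous
stage's output:

1. *(optional)* drop each trial immediately following an error,
2. per task × participant × session × response-type stratum: drop RT
   < 250 ms, then drop RT > median + 2.5 × (1.4826 × MAD), both statistics
   computed on the floored stratum,
3. drop sessions (cells) with fewer than 125 retained trials,
4. drop cells where either response type falls below 4% of trials,
5. drop, per task, participants with fewer than 10 surviving sessions.

Numerical conventions, each configurable: the MAD normal-consistency
constant defaults to 1.4826 (the convention of the MAD-outlier literature;
set it to 1.0 for a raw MAD); trials exactly at the upper threshold are
retained ("above" read strictly); the floor is applied before the
median/MAD are computed, since sub-250 ms guesses are a disjoint
contaminant class that would otherwise distort the location estimate; a
single-trial or constant-RT stratum has MAD 0 and only the floor applies;
the participant filter is evaluated per task (a participant can survive in
one task and not another). A mean ± 2 SD upper rule is available for
sensitivity analysis. The cascade is not idempotent by design — rerunning
trimming on trimmed data can remove more, because the MAD shrinks once the
tail is gone — and the stage order matters; both facts are pinned by tests.

## Estimation

Choice and latency are combined into a signed-RT sample (correct → +RT,
error → −RT, in seconds) whose model CDF is
P_lower − F_lower(−x − t₀) for x < 0 and P_lower + F_upper(x − t₀) for
x ≥ 0. The exact KS distance (evaluated on both sides of every empirical
step) is minimized over (v, a, t₀) by Nelder-Mead from 5 starting points
(3 by default in the test/acceptance configurations): data heuristics — t₀
from low RT percentiles, a from the RT spread, v from observed accuracy via
the closed-form choice probability — plus seeded jitters of the first
heuristic. Box constraints are enforced by penalty; t₀'s upper bound is
clamped to the smallest observed RT. Ties between starts are broken by
smaller a, then smaller t₀ (arbitrary but fixed). Simplex tolerances are
xatol = 1e-3, fatol = 1e-4, maxiter = 400. Cells are fit independently —
per-session parameters with no smoothing across sessions — and
non-converged cells are flagged, never dropped. Constrained refits (for
model comparison) clamp any subset of {v, a, t₀} and search only the rest.

KS estimation does not yield likelihoods, so model comparison uses the
optimized criterion itself: the distribution of per-cell KS differences
(constrained − free), summarised per task and pooled. Reference values for
clamping are, per task and parameter, the median across sessions of the
per-session means across participants; a per-participant variant is
available since either reading of "session means" is defensible.

## Fit assessment

For each converged cell, data are re-simulated from the fitted parameters
with the cell's own trial count and a derived seed, and observed vs
predicted error rates and correct-response RT quartiles (type-7, linear
interpolation) are tabulated. Fresh simulation — not analytic quantiles —
is used deliberately so that the check includes simulation noise at the
empirical n, mirroring how such checks are run in practice.

## Trajectory analysis

Cell-level dependent variables are the mean RT of correct responses (ms),
the error rate, and the fitted v, a, t₀. Each is modelled as

dv ~ session * task + (1 | participant)

with session a categorical factor (a 20-level factor, not a linear trend)
and task categorical, under sum-to-zero contrasts. The model is fit by
REML (statsmodels MixedLM), and Type III F statistics are Wald tests on
each term's coefficient block. Denominator degrees of freedom use a
residual method, df₂ = n − rank(X) − (n_participants − 1), flagged as
`df_method="residual"` in every result; for within-participant contrasts
in balanced random-intercept designs this coincides with the Satterthwaite
value, and simulation puts the session test's type-I error at ≈ 0.04–0.06
at α = 0.05 on small null designs. When the estimated random-intercept
variance is zero in a balanced design, the F values reduce exactly to those
of an ordinary two-way fixed-effects ANOVA (pinned to 1e-6 by an oracle
test). Effect sizes are partial eta squared, η²p = F·df₁/(F·df₁ + df₂),
rounded to 2 decimals for reporting. Random slopes and within-subject CI
methodology beyond simple SE error bars are not implemented.

## Problem sizes

The test suite and the acceptance script use reduced but structurally
complete study sizes chosen to keep runs desk-scale: a 3-participant ×
4-session tiny study for pipeline tests, a 3×3×3 (v, a, t₀) recovery grid
with 5 replicates at 125–1000 trials/cell, 200 null simulations for ANOVA
calibration, and a 10-participant study at full session/task/trial scale
(600 cells) for the acceptance run. The generator's structural invariant —
30,000 trials per participant at study scale — is independent of the
participant count.

## Known limitations

- The KS criterion's optimizer internals differ from any particular
  published software, so per-cell numerical equality with other packages'
  estimates is not claimed; trajectory-level agreement is the goal.
- Censored (deadline) trials are tagged but the default pipeline passes
  them into treatment like ordinary trials; with the default 5 s deadline
  and the default generator parameters censoring is vanishingly rare.
- The residual denominator-df method is approximate for unbalanced designs;
  p-values can differ from Satterthwaite's in later decimals as imbalance
  grows.
- The generator's learning-curve family is parametric and smooth; real
  training trajectories with plateaus, dips, or strategy shifts are outside
  the family.
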
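# Methods

## Scope and model

`tsdea` implements the three-stage efficiency-evaluation procedure for
cross-sectional DMU panels: radial envelopment DEA (CCR/BCC), a
stochastic-frontier regression of input slacks on environmental
covariates, environmental/noise neutralization of inputs, and a DEA
rerun on the neutralized inputs. The package also ships the published
stage-3 score table (129 county-level divisions, three model columns
with ranks) and published variable summaries as packaged CSVs; these
are the only study data available — per-DMU raw inputs were never
published, so stage-1/stage-3 score *values* for the real study cannot
be recomputed, only its fixture-backed summaries (rank consistency,
bands, group means) and the procedure's behaviour on synthetic data
with known truth.

## Stage 1: radial envelopment

Input-oriented scores solve `min θ` subject to `Xᵀλ ≤ θ x_o`,
`Yᵀλ ≥ y_o`, `λ ≥ 0` (CRS), plus `Σλ = 1` (VRS) or `Σλ ≤ 1` (NIRS).
The textbook objective subtracts a non-Archimedean ε times total slack;
we use the exactly equivalent lexicographic two-phase scheme (radial
phase, then slack maximization at fixed θ*), which avoids choosing a
literal ε and is the standard numerically robust implementation. Output
orientation maximizes the expansion factor φ and reports 1/φ so all
scores live in (0, 1].

* Columns are mean-normalized before LP assembly (scores are
  units-invariant; slacks are rescaled back afterwards). LPs are solved
  with HiGHS through `scipy.optimize.linprog`.
* Tolerances: LP feasibility 1e-7; θ = 1 and Σλ = 1 decided at 1e-6;
  band membership θ = 1 at 1e-9 on the LP score (a separate
  "as-printed" mode rounds to 2 dp first, for comparisons with
  published tables).
* Status: `efficient` iff θ = 1 and all phase-2 slacks vanish;
  `weakly efficient` when θ = 1 with positive slack.
* Returns to scale: the Σλ rule is applied to the *whole* CRS optimal
  set — two secondary LPs bound Σλ at fixed θ*, and a DMU is IRS (DRS)
  only when the entire range lies below (above) 1. This removes the
  alternate-optima ambiguity of reading Σλ off one vertex (proportional
  DMUs, for instance, admit reference sets of any scale). The
  NIRS-frontier comparison is available as a cross-check
  (`classify_rts(..., cross_check=True)`) and flags disagreements.
* Reference weights λ are whatever vertex the solver returns; only
  score-level quantities are asserted in tests, since λ is not unique.

Two slack conventions coexist: the phase-2 residual slack
`s⁻ = θx − Xᵀλ` (what the LP's slack variable means) and the total
input excess `x − Xᵀλ = (1−θ)x + s⁻` (distance to the frontier
target). The pipeline regresses the **total** slack by default
(`PipelineConfig.slack = "total"`), the convention of Fried-style
three-stage analyses: it carries the radial inefficiency component,
which is exactly what environmental conditions confound. The residual
slack remains available (`slack="residual"`).

## Stage 2: slack frontier and adjustment

Each input slack is modelled as `s = f(Z;β) + v + u` with Gaussian
noise `v` and half-normal inefficiency `u` entering with the
*cost-frontier* sign (inefficiency inflates slack). The composite
density is `h(ε) = (2/σ) φ(ε/σ) Φ(ελ/σ)` with `σ² = σ_v²+σ_u²`,
`λ = σ_u/σ_v`; the log-likelihood is maximized over
`(β, log σ², logit γ)` by L-BFGS-B with a multistart over
γ ∈ {0.05, 0.3, 0.6, 0.8, 0.95} (the γ profile is often multimodal).
Starts: OLS slopes, intercept shifted by `−E[u] = −σ_u√(2/π)`, σ²
matched to the OLS residual variance given the trial γ. The logit
parameterization enforces γ ∈ (0, 1) without constrained optimization.

* The γ = 0 boundary test uses `LR = 2(ℓ_SFA − ℓ_OLS)` against the
  ½χ²₀ + ½χ²₁ mixture (5% critical value 2.706). By construction the
  γ → 0 limit of the frontier likelihood is the OLS likelihood, so
  LR ≥ 0 up to optimizer tolerance; a material negative value raises.
* Residual decomposition is the JLMS conditional mean,
  `E[u|ε] = σ*(φ(a)/Φ(a) + a)`, `a = ελ/σ`, `σ* = σ_uσ_v/σ`, with
  `v̂ = ε̂ − E[u|ε̂]`. The cdf ratio is computed as
  `exp(logpdf − log_ndtr)`, which is accurate deep in the tail (no NaN
  from Φ underflow). The choice of a conditional-mean split is a
  convention — the model itself does not identify `v` pointwise — but
  it is the dominant one in three-stage practice.
* Near-boundary fits (γ > 0.999 or γ < 0.001) are flagged
  (`boundary_gamma`) and their coefficient standard errors withheld
  (NaN): a flat boundary likelihood produces meaninglessly enormous
  t-values, which should be read as "boundary estimate", not
  significance. Otherwise SEs come from the numerical Hessian with a
  delta-method transform for σ² and γ.
* Functional forms: `linear` regresses the raw slack on Z (default;
  slacks can be exactly zero, and raw-slack regressions keep Eq-style
  additive adjustment in input units). `log` regresses `log1p(s)` —
  log1p because zero slacks are legitimate mass points — with strictly
  positive covariate columns log-transformed. Under the log form the
  environmental component is returned in slack units via `expm1`, and
  the noise contribution as the difference of back-transformed
  predictors with and without `v̂`.
* Each input gets its own independent regression (no joint/SUR
  estimation), matching how these models are reported in practice.

Adjustment (per input): `x_adj = x + [max f − f] + [max v̂ − v̂]`.
Both bracket terms are nonnegative by max-anchoring, so `x_adj ≥ x`
always; the DMU with the least favourable environment and worst luck
is the anchor and is left untouched. Inputs whose slack vector is
numerically constant (e.g. everyone efficient) get a zero-adjustment
degenerate fit rather than a meaningless regression.

## Stage 3 and reporting

Stage 3 re-runs CRS and VRS on the adjusted inputs with unchanged
outputs. Reports hold per-DMU TE/PTE/SE (TE = PTE×SE within 1e-6 by
construction), RTS labels, band labels, unweighted group means, band
counts/proportions and RTS tallies. Rank consistency across model
variants uses Spearman correlation; raw score vectors are converted to
descending average ranks, while published integer ranks
(`already_ranked=True`) are used verbatim — the published table's
tie-breaking is not documented, so re-ranking its scores would not
reproduce its coefficients, whereas its printed ranks do (0.82 BCC–CCR,
0.87 BCC–SBM).

Orientation: the pipeline default is input-oriented — stage 2 consumes
*input* slacks and the adjustment acts on inputs, so the input-oriented
chain is the internally consistent one; output orientation is available
on every radial solver for users who want it.

## Synthetic data generator

`generate_panel` draws `x_ik = x*_ik · exp(δ_k'Z_i + u_i + v_ik)` with
efficient requirement `x*_ik = c_k (w'y_i)^{a_k}`; outputs are
lognormal (`σ_y = 0.25`), Z is three standardized normals plus one
uniform [0, 1] column (a proportion-type covariate, mirroring the mix
of unbounded and bounded environmental variables in real studies).
Multiplicative composition keeps inputs positive and makes the log of
the waste additive, which is the structure the stage-2 regression
assumes approximately in levels.

Two generator design points deserve emphasis:

* **Linear output aggregator.** The requirement is log-linear in the
  scalar aggregate `w'y` (default exponent `a_k = 1`, i.e. a linear
  CRS technology), *not* multi-output Cobb–Douglas `Π y^a`. A
  Cobb–Douglas requirement is concave in outputs, so its technology
  set is non-convex and DEA's convex hull strictly dominates it:
  frontier DMUs with mixed outputs would score θ ≈ 0.88–0.95 even
  with zero waste and zero noise. With a convex (linear) technology,
  the no-waste world is exactly DEA-efficient, which is the behaviour
  a ground-truth generator must have.
* **Shared environmental pattern.** Default δ is one ±0.2/0.6 pattern
  (mixed signs across covariates, 0.6 on the bounded column) shared by
  all inputs, giving sd(δ'Z) ≈ 0.39 against σ_u = 0.4 — environmental
  and managerial waste of comparable size (strong confounding). The
  pattern is shared across inputs because a radial contraction scores
  the input *vector*: per-input alternating signs cancel inside the
  contraction and leave almost nothing for stage 3 to correct, whereas
  a common pattern produces the realistic situation where favourable
  environments flatter every input at once.

Defaults: n = 129 DMUs split 17/112 into two labelled groups, K = 4
inputs, M = 2 outputs, P = 4 environmental covariates, σ_v = 0.1,
σ_u = 0.4, frontier scales 0.5–2.0. True managerial efficiency is
`exp(−u) ∈ (0, 1]`. All randomness flows through one
`numpy.random.default_rng(seed)`; same seed, same panel, bitwise.

What the generator does *not* emulate: integer/ratio-valued real
indicators, spatial correlation between neighbouring DMUs, measurement
error in outputs, group-dependent environments, or any calibration to
the published regression coefficients. Passing tests therefore show the
procedure works in the statistical world it assumes — not that any
particular real data set satisfies those assumptions.

`recovery_experiment` runs seeded replicates of (a) direct frontier
recovery on model-generated slack data (n = 300 by default) and (b)
full three-stage runs on generated panels, summarizing median γ error,
LR rejection rate, and the stage-3 minus stage-1 gain in Spearman
correlation with true efficiency.

## Problem sizes and runtime choices

The test suite exercises the LP solvers on randomized panels of up to
15 DMUs (200 instances in the structural-invariant battery — small
envelopment problems are solved in milliseconds and the invariants are
dimension-free), frontier recovery at n = 300 over 20 seeds, and
three-stage truth-recovery at the full reference design (n = 129) over
20 seeds. The acceptance script reports the same quantities with 10
pipeline replicates, which stabilizes the medians while keeping the
run near a minute.

## Known limitations

* Cross-sectional only: no panel SFA, no Malmquist dynamics, no
  super-efficiency, weight restrictions, or network DEA.
* Half-normal inefficiency only (the zero-mean truncated normal); the
  general truncated-normal and heteroscedastic variants are out of
  scope.
* γ̂ frequently sits at the boundary on slack regressions (slacks are
  one-sided by construction, so the likelihood often prefers γ → 1);
  the boundary flag should be checked before interpreting SEs.
* The packaged score table stores 2-dp printed values; comparisons
  against it use ranks, counts and ±0.01 mean tolerances, and its CCR
  column is not used for CRS ≤ VRS checks (as printed, it exceeds the
  BCC column for many rows, which is impossible for scores from one
  data set and indicates a labelling or run inconsistency in the
  source table).
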
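# Methods

## Scope and model

`gpdrivers` infers which of *V* candidate annual series drive a target
annual series, without assuming any functional form. The inference object
is not a single fitted model but a *population pool* of symbolic-regression
functions that generalise well under cross-validation; statistical
statements are made about how often variables appear in that pool, and the
sign of each retained variable's effect is read off the pool's functions by
numerical differentiation. The approach assumes only that (i) the target is
some (possibly nonlinear) function of a sparse subset of the candidates
plus noise, and (ii) the candidate panel is annual (or reducible to annual)
with a common year span.

## Preprocessing

Monthly series are averaged to annual values; a year built from 3 or fewer
monthly values is treated as missing (`min_months = 4`), because such
averages over-weight whichever months happen to be sampled. Season-tagged
series additionally contribute four seasonal columns. Two season dialects
are supported: *climate* (winter = Dec–Feb, with December assigned to the
following year's winter — the standard DJF convention) and *hydrographic*
(lagged one month: winter = Jan–Mar). A seasonal average requires at least
2 of its 3 months, mirroring the annual exclusion rule at seasonal scale.

Every column is max-normalised: non-negative series are divided by their
maximum (range [0, 1]); series with negative values are divided by their
maximum absolute value (range [−1, 1]). Dividing mixed-sign series by the
signed maximum could push values outside [−1, 1], so max-abs is the only
rule consistent with both stated ranges. Normalisation discards scale and
keeps dynamics, which is the point: candidates spanning seven orders of
magnitude become comparable. Missing years are carried as NaN and never
interpolated; every downstream stage masks them.

## Genetic programming

Individuals are expression trees over the candidate columns, ephemeral
random constants uniform in [−1, 1] (matching the normalised data range),
and the protected primitive set {+, −, ×, ÷}; exp and a protected log are
available behind configuration. Protected division returns 1 when
|denominator| < 1e-12 and protected log maps x to log|x| (0 below the same
cutoff), so every tree is total over the reals. Fitness is the training
RMSE, computed over years where both the target and the tree's output are
observed.

Defaults: population 1000, at most 500 generations, tournament selection
of size 4, subtree crossover 0.8 / subtree mutation 0.15 / clonation 0.05,
ramped half-and-half initialisation at depths 2–6, hard depth cap 17
(offspring breaching it revert to their parent), elitism of one. The run
stops early when the best training RMSE falls below 1e-9 or has not
improved for 50 generations (the stagnation window). Selection ties are
broken toward smaller trees — a mild parsimony pressure that keeps
occurrence counts meaningful by discouraging junk subtrees. These operator
settings are canonical symbolic-regression choices and all are
configurable.

Trees are stored as flat prefix genomes, which makes subtree extraction
O(size), evaluation a single stack pass over NumPy arrays, and
serialisation a plain s-expression string (`(add (mul 0.8 x3) x7)`), with
exact round-trip.

## Cross-validation and the pool

The year axis is split into contiguous folds (default 3 years; 39 usable
years give k = 13). For each fold and each of `runs_per_fold` runs
(default 50), training years are a uniform 85% sample *of the non-held-out
years* — sampling from all years would leak held-out information into
training, so the held-out fold never enters the sample. Each run's
candidate is the member of the final evolved population with the lowest
RMSE on the held-out fold. Run seeds derive deterministically from
(base seed, fold, run), so any single run can be re-executed in isolation
and results are independent of execution order.

The pool retains the best-generalising `keep_fraction` of candidates by
validation RMSE (default 0.16, i.e. 104 of 650 at full scale; ties broken
by tree size, then fold/run order). An absolute validation-RMSE cutoff is
a reasonable alternative rule and can be applied by filtering the
candidate list before `select_pool`.

## Relevance analysis

Let N be the pool size. Under the equiprobable null each variable appears
in a given pool function with probability p₀ = 1/V, so its presence count
(binary per function — a variable used twice in one function counts once)
is Binomial(N, p₀). The threshold is the smallest t with exact tail
P(X ≥ t) ≤ α, summed directly with `math.comb` — no normal approximation,
which would be badly wrong this far into the tail (at N = 104, V = 86,
α = 0.001 the exact threshold is 7 with tail 2.3 × 10⁻⁴). p₀ is
configurable; a data-driven alternative is the pool's mean number of
distinct variables per function divided by V. Counts *at* the threshold
are relevant (≥, not >). No further multiple-testing correction is
applied beyond the single-threshold rule.

Functions whose referenced variables are all relevant are the modelling
functions; functions containing any non-relevant (i.e. plausibly random)
component are excluded from gradient analysis. Constant-only functions
reference no variables and are likewise excluded.

## Gradient analysis

For every (modelling function, referenced relevant variable, year with all
referenced variables observed) triple, the partial derivative is the
central difference with step h = 1e-4 on the normalised scale —
second-order accurate and safe for data in [−1, 1]. Evaluation points are
the observed yearly data vectors, not a grid: the question is how the
function behaves over the realised dynamics. Samples with |derivative| ≤
1e-8 are excluded (a flat function says nothing about direction). All
samples for a variable are pooled across functions and years; a variable
is *direct* if ≥ 90% of usable samples are positive, *inverse* if ≥ 90%
are negative, otherwise *variable*. The 0.9 agreement threshold is a
reported, configurable choice; per-function classifications are also
emitted so a user can inspect disagreement between functions. Halving h
does not change classifications on the synthetic suite (verified by test).

## CuSUM shift detection

Each series is standardised with the population standard deviation
(divisor n — the choice is immaterial to the detected year because the
procedure is invariant to affine rescaling) and the cumulative sum of the
z-scores is accumulated over observed years, skipping gaps. The global
extremum of |CuSUM| is the turning point of the slope; the *following*
observed year — the first year of the new regime — is reported as the
shift year, with direction the sign of (post-shift mean − pre-shift mean)
and magnitude their difference in raw units. Ties take the earliest year.
Only the single most prominent shift is reported; no significance test is
attached, so callers should judge the reported magnitude. A constant
series raises an error (degenerate input).

## Synthetic data

Candidates are AR(1) processes (default φ = 0.6, stationary start) with
random linear trends, optional step changes, and an even split between
mixed-sign and positive-only columns (the latter shifted above zero);
optional i.i.d. Gaussian `noise*` columns serve as negative controls. The
target is a sympy-parseable recipe over named candidates plus Gaussian
noise; ground truth records the recipe variables, the majority sign of
each analytic partial derivative over the generated data, and any true
step years. Missing years, when requested, are placed uniformly away from
the first and last three years so no CV fold loses all usable indices.

What the generator does *not* emulate: cross-correlation between
candidates, heavy tails, observation error structure, or any attempt to
mimic actual monitoring series values. Passing the recovery suite
therefore shows the pipeline can find sparse nonlinear drivers under
realistic autocorrelation and noise — not that it would resolve collinear
drivers in field data, where relevance is shared across correlated
variables.

## Test-scale choices

The test and acceptance suites run the pipeline at reduced scale —
population 200, 60 generations, 13 folds × 5 runs, keep fraction 0.2,
init depths 2–4, depth cap 8, stagnation window 20 — over a 39-year panel
of 20 AR(1) candidates plus 2 noise columns and the recipe
`0.8*x3 − 0.6*x7` with noise sd 0.1. These sizes keep a ten-seed
end-to-end study to a few minutes while leaving the recovery property
comfortably testable. The relevance threshold adapts automatically to the
smaller pool via the exact binomial rule.

## Known limitations

- Relevance is an occurrence statement about the pool, not a causal claim;
  correlated candidates share occurrence and can shadow one another.
- The pool-selection rule (keep fraction over per-run bests) is one
  reasonable operationalisation of "best generalising"; results can be
  sensitive to it at small pool sizes, where α = 0.001 may be unattainable
  altogether (the threshold then exceeds the pool size and is flagged).
- CuSUM reports exactly one shift per series and its localisation is
  limited by the step-to-noise ratio: at step = 2 × noise sd the detected
  year falls within ±1 of the truth in roughly nine cases in ten, which
  matches what an exact least-squares change-point fit achieves on the
  same draws — the residual misses reflect the information in the data,
  not the estimator.
- Gradient classes describe the modelling functions' local behaviour at
  observed points; extrapolation beyond the observed range is undefined.
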
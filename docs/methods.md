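# Methods

## Metrics

All downstream quantities derive from the two-by-two confusion matrix
(TP, FP, FN, TN) with margins P = TP+FN (positive observations),
S = TP+FP (positive predictions), N and prevalence π = P/N.  TSS is
TPR + TNR − 1; Cohen's kappa is included purely as the chance-corrected
comparison baseline.  Matrices carry a mode flag: *integer* for realized
counts, *real* for expected-value tables whose cells are algebraic
expressions — the error-scenario tables are algebra, and rounding them
would corrupt the closed-form identities they are meant to verify.

Binarization is strict: presence is called when the score exceeds the
cutoff, `x > x_c`, matching the conditional-probability definitions
TPR = P(x > x_c | present), TNR = P(x ≤ x_c | absent).  Ties at the
cutoff are absences.  Single-class observation vectors raise an
`UndefinedRateError` rather than returning a sentinel: the experiment
code guarantees both classes by construction, so a degenerate table
reaching the metrics layer is a bug worth surfacing.

## Closed-form error scenarios

Five mechanisms relate observations to the dichotomous suitability
pattern, each with constant error rate(s) and an expected confusion
matrix whose cells are filled exactly:

| kind | cells | TSS | prevalence dependent |
|---|---|---|---|
| two_error | TP=(1−e₁)P, FP=e₂(N−P) | 1−e₁−e₂ | no |
| missed_presence | S=P/(1−e), FP=eS, FN=0 | (1−e−π)/((1−π)(1−e)) | yes |
| fallacious_absence | same matrix as missed_presence | same | yes |
| fallacious presence ∝ presences | two_error with e₂=0 | 1−e | no |
| fallacious presence ∝ unsuitable | S=(P−eN)/(1−e), FP=0 | (π−e)/(π(1−e)) | yes |

For the last scenario the expected table's self-consistency condition
TP = P − e(N−S) = S solves to S = (P−eN)/(1−e).  A shortcut in
circulation divides by (1+e) instead, giving TSS = (π−e)/(π(1+e)); that
matrix does not balance its own margins.  Both variants are exposed
(`variant="table_consistent"` / `"printed"`) and the CLI prints both, but
the table-consistent solution defines the expected matrix, because the
row/column sums are the primary specification.  Domain constraints follow
from non-negativity of cells: π ≤ 1−e for the missed-presence family
(else S > N) and π > e for the unsuitable-proportional case (else
TP < 0).

Every closed form is verified against an independent route — building the
expected matrix cell by cell and scoring it with the metrics layer — to
1e−12 across an (e, π, N) grid.

## Simulator

The generator emulates the study conditions directly: N sites, exactly
P = round(πN) presence labels (clamped to keep both classes, a no-op on
the standard grid where πN is integral), presence scores i.i.d. from
f₁ ~ Beta(α,1) and absence scores from the mirrored f₀ ~ Beta(1,α), with
α = 3 (quadratic), 2 (linear), 1.5 (square root) and 17/16 (p16, extreme
weak discrimination).  The mirror symmetry f₀(x) = f₁(1−x) follows from
the parameter table; the occasionally quoted verbal form
"f₀(x) = 1 − f₁(x)" cannot hold for densities and is not used.

Sampling is by inverse CDF: with one beta parameter equal to 1 the
quantile functions are u^(1/α) and 1−(1−u)^(1/β), so draws are exact,
cheap, and reproducible from a seed without depending on any library's
beta-sampler internals.  Goodness-of-fit (KS against F₁(x) = x^α),
moment, and mirror-symmetry checks are in the test suite.

What the generator does *not* emulate: spatial structure, covariates,
model fitting, or miscalibration — predictions are drawn from fixed
conditional distributions.  Passing tests therefore demonstrate
properties of the *evaluation statistic* under known discrimination
quality, not of any real model's predictions.

## Experiment

For each cell of the factorial (scenario × N × π), `n_reps` datasets are
drawn, TSS is evaluated on the 19-cutoff grid 0.05, 0.10, …, 0.95, and
the per-replicate maximum is recorded; the cell summary is the mean, sd
and mean argmax cutoff of the maxima.  Argmax ties break toward the
smallest cutoff — the study only uses the maximum value, but a
deterministic rule is needed for reproducibility.  Defaults are the full
study conditions: four scenarios, N ∈ {100, 1000, 10000}, π from 0.05 to
0.95 in steps of 0.05, 1000 replicates.

Randomness: each cell's substream is `SeedSequence(seed,
spawn_key=(scenario index, N, round(1000π)))`, spawned once per
replicate.  Consequently a run over any subset of cells reproduces
exactly the rows of the full factorial at the same root seed, and every
replicate is individually addressable.

The fixed-rate construction (`fixed_rate_confusion`,
`allouche_replication`) fills cells from constant TPR/TNR.  In real mode
TSS is exactly TPR+TNR−1 at every prevalence — the circularity that makes
this design unable to detect prevalence effects.  Integer mode rounds TP
and TN half-to-even and takes FN/FP as complements, the simplest scheme
producing the integer-cell jitter; the deviation from the nominal TSS is
bounded by 0.5·(1/P + 1/(N−P)).

## Theory and bias

E[TSS](x_c) = F₀(x_c) − F₁(x_c), maximized where the densities cross.
The crossing is found by Brent root-finding on f₀ − f₁ over (0, 1) with
cutoff tolerance 1e−9; for the mirror-symmetric scenarios the root is 0.5
analytically, but the solver path is kept (and checked against a 1e−3
grid search) so non-symmetric conditionals would work unchanged.
`bias_table` joins a simulation result to these optima
(bias = mean max TSS − TSS*) and carries the Monte Carlo standard error
of the cell mean, so checks can state tolerances in SE units rather than
hard-coded constants.

One accuracy note: the maximum-TSS bias is *persistent*, not Monte Carlo
noise.  At N = 10000 it is below 0.01 for every scenario (and below
0.001 for the well-discriminating ones) but does not shrink with more
replicates — only with more observations.  Checks on large-sample
consistency therefore combine a one-sided 2-SE allowance (bias must not
be significantly negative) with the absolute 0.01 ceiling.

## Problem sizes and determinism

The shipped test suite runs the full small-sample study (4 scenarios × 19
prevalences × 1000 replicates at N = 100, seed 1) once as a shared
fixture — it is the study's own design at its smallest sample size and
completes in a few seconds — and a 200-replicate balanced-prevalence run
at N = 10000 for the consistency checks.  Property tests use hypothesis
in derandomized mode; all Monte Carlo tests state their seeds.

## Limitations

- Only the four mirror-symmetric beta scenarios are specified and tested;
  the machinery accepts other (α, β) pairs but ships no presets for them.
- Error scenarios are examined one mechanism at a time; mixtures of
  observation-error types are out of scope.
- AUC, F-score, ROC-based cutoff selection and calibration measures are
  deliberately absent — the statistic under study is maximum TSS.
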
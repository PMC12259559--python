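# Methods

## Model

A competing factor is an affine score `CF_i = b_i + Σ_g w_ig · t(x_g)` over
a small gene subset; a panel reports `CF_max = max_i CF_i` and maps it to a
risk via the logistic function. A sample is called positive when
`risk > 0.5`, i.e. `CF_max > 0`; a risk of exactly 0.5 is a control call
(the decision rule is "above 50%", so the boundary itself is non-positive).
The maximum makes the decision region a union of half-spaces: each factor
can specialize to a subgroup of cases, while every factor must individually
reject the controls it was trained against. Two consequences are used as
invariants throughout the tests: appending a factor can only raise risks
(sensitivity non-decreasing, specificity non-increasing in panel size), and
the classification is equivalent to the sign of `CF_max` at the default
threshold.

### Transforms and scales

Matrices carry a scale tag (`identity` = natural/linear scale, non-negative;
`log2` = platform-provided log intensities; `ln1p` = already ln(x+1)).
Factors carry a transform (`identity`, `ln1p`, `log2_as_given`). `identity`
factors require identity-scale values; `ln1p` factors take identity-scale
values and apply ln(x+1) themselves (as in the PBMC classifiers, which are
printed with explicit `LN(x+1)` terms); `log2_as_given` means the platform's
log-like values are used verbatim and is accepted on `log2` or `ln1p`
matrices. The bundled self-collected plasma panels are tagged `identity`
(raw qPCR relative copy counts — this reproduces the printed 100% row);
all bundled array-cohort panels are tagged `log2_as_given`. The tags are
bookkeeping against scale mix-ups; `identity` and `log2_as_given` are
numerically both pass-throughs.

### qPCR relative quantification

The bundled validation cohort quantifies expression relative to β-actin.
The quantification formula is the standard `2^(Ct_ref − Ct_target)`; the
bundled table is consistent with a power-of-two scale (one control's FCAR
value is exactly 256 = 2^8). Whether an additional constant scaling was
applied upstream is irrelevant to classification with refit intercepts.

## Fitting

**Screening.** Genes are ranked by the best training accuracy achievable
with a single threshold on that gene (both directions), ties broken by
absolute log2 fold change, then gene name. A gene constant across all
samples scores 0.5. This is a documented proxy: the original critical-DEG
selection rules are not public, and the trace of every fit is marked
`best_threshold_proxy` to make that visible. An optional cross-cohort
sign-consistency check (`sign_consistency`) complements it.

**Coefficients.** Within a gene subset, the direction is a ridge-penalized
maximum-likelihood logistic fit (λ = 1e−6) — the penalty exists because the
interesting datasets are perfectly or nearly separable, where unpenalized
MLE diverges. Features are standardized internally for conditioning (qPCR
values span six orders of magnitude) and coefficients are mapped back to
the input scale, so the λ applies on the standardized scale. The intercept
from the likelihood fit is then discarded and re-placed:

* `specificity_first` (default): the intercept is set so every control
  scores at most −margin (margin = 1e−6), giving training specificity
  exactly 1.0 per factor by construction, with sensitivity whatever the
  direction then allows. Both orientations (w, −w) are tried and the one
  capturing more positives kept. This mirrors the published panels, whose
  per-factor rows all show 100% specificity.
* `accuracy_first`: the intercept (over all split points of the sorted
  scores, both orientations) maximizes training accuracy; ties prefer the
  more specific split. In one dimension this is exactly the brute-force
  best-threshold rule, which the tests exploit as an oracle.

**Greedy panel construction.** Factors are added one at a time. Each round
exhaustively enumerates subsets (sizes 1..max_genes_per_factor, default 4)
of the gene pool (given explicitly, or the screen_top_m screened genes) and
keeps the factor capturing the most still-missed positives; each candidate
is fitted on all controls plus only the currently missed positives, which
is how a dedicated factor can be built to "adjust for" a single outlying
patient. Ties prefer fewer genes, then lexicographically earlier subsets,
so fitting is fully deterministic — the config seed never influences a fit,
only synthetic data. The loop stops when all positives are captured, no
candidate adds coverage, or max_factors (default 3) is reached; the first
factor is always returned even if it captures nothing, so a panel is never
empty. The exhaustive search is the intended scale of the method (tens of
genes, factors of ≤5 genes); `screen_top_m` is the knob that bounds it.

## Cohort-to-cohort cross-validation

`cross_cohort_validate` refits the *gene set* independently inside every
cohort and evaluates each cohort on its own refit; matrices are never
concatenated, so per-cohort results are invariant to anything done to other
cohorts. Pooled metrics are summed confusion counts (sample-size weighting).
Note that sample-size weighting of the bundled per-cohort accuracy rows
gives ≈99.2% over the 1,912 printed samples, slightly below the printed
pooled 99.42%, whose exact pooling rule is not stated; this package reports
summed-count pooling and leaves the discrepancy visible rather than
matching it. A frozen-coefficients mode (`transfer_panel`) applies one
panel verbatim to other cohorts, for users; it is not part of the
validation scheme. `sign_consistency` groups coefficient signs by tissue
and flags whole-blood vs plasma reversals, the pattern reported for the
three-gene core (CKAP4, FCAR, RNF4).

## Synthetic cohorts

The generator draws log2 expression as
`mu_g + batch_shift + [case]·delta_{g,subgroup} + eps`, with
`mu_g ~ N(6, 1)` fixed by the seed, `eps ~ N(0, noise_sd²)`, and per-gene
case effects delta in log2 units. Defaults: 60/60 samples, 100 genes,
noise_sd 1.0 — effects of ~2 log2 units against noise 1.0 are the regime
the recovery tests use. Case subgroups (weights summing to 1, each with its
own per-gene effect override) create the heterogeneity that makes a single
linear factor insufficient; `tissue="plasma"` flips the sign of every
effect, encoding only the observable whole-blood/plasma reversal, not any
compartment mechanism. `output_scale="identity_power"` exponentiates to a
positive 2^value scale emulating qPCR copy counts. Everything is
bit-reproducible from the spec seed.

What the generator does *not* emulate: probe-level array artifacts, count
noise, gene–gene correlation beyond the planted effects, missing values,
or realistic effect/noise magnitudes of the real cohorts (their matrices
are not bundled). Passing recovery tests therefore demonstrate correctness
of the machinery under the stated generative model, not clinical
performance.

## Numerical choices

* Risk values are nudged into the open unit interval (nearest representable
  neighbours of 0 and 1) because the logistic saturates in floating point
  beyond |CF_max| ≈ 37; classification is unaffected.
* Gene and sample identifiers are matched case-insensitively; duplicates
  after case-folding are rejected. Missing/NA cells are hard errors —
  panels have ≤5 genes and imputation would silently corrupt calls.
* Panel JSON serialization uses shortest round-tripping decimal floats, so
  save/load is bit-exact. The published coefficient tables are stored with
  all printed digits; typographic Unicode minus signs were normalized to
  ASCII.
* Degenerate inputs: all-constant gene subsets raise a fit error; constant
  genes inside a larger subset get coefficient 0 and are dropped from the
  factor (stored factors never contain zero weights).

## Open design points

* The published severity comparison for the plasma cohort (shock vs sepsis,
  five genes) prints 93.75% accuracy; the refit here reaches 100% because
  the exhaustive subset search is free to exceed the printed fit. The
  corresponding checks are therefore one-sided (≥).
* Whether per-factor perfect specificity was a hard constraint or an
  empirical outcome in the original fits is unknowable from the printed
  tables; both modes are provided, with `specificity_first` the default
  because every printed per-factor row shows 100% specificity.
* One published whole-blood factor carries an FCAR sign opposite to the
  otherwise consistent positive pattern (built to accommodate a single
  outlying patient); sign-consistency checks therefore operate on the
  panels the caller passes rather than hard-coding a cohort list.
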
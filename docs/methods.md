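# Methods

## Model

Each target gene *g* observed on a uniform time grid is modeled as

    g(t) = b0 + Σᵢ aᵢ · tfᵢ(t − Δtᵢ) + ε(t),   ε ~ N(0, σ²)

with regulator profiles `tfᵢ`, regulation coefficients `aᵢ` and
per-regulator delays `Δtᵢ` restricted to integer multiples of the grid
spacing.  The model is fitted by ordinary least squares on delay-aligned
series.  Assumptions: regulation is linear and additive on the
log-ratio scale, delays are constant over the time course, and residuals
are homoscedastic and uncorrelated (no autocorrelation correction is
applied; see Limitations).

An intercept is always included.  Delay alignment uses a *fixed fitting
window*: every fit for a target starts at grid index
`window_start = max_delay_steps`, so the sample size *n* is identical
across all delays and regulator sets of that target and their AIC
values are directly comparable.  A per-delay shrinking window would
change *n* between candidate models and make AIC comparisons invalid.

## Selection criteria

* **AIC** in Gaussian profile form, `AIC = n·ln(RSS/n) + 2·k`, with
  `k = (#regulators) + 2` counting the intercept and the residual
  variance.  Additive constants are dropped; since *n* is fixed per
  target, any affine-equivalent variant selects identically.
* **Adjusted R²**, `1 − (1 − R²)(k_s − 1)/(k_s − n_r − 1)` with sample
  size `k_s` and `n_r` regulators; it gates both screening (default
  0.8) and final-model acceptance (default 0.9).  When
  `k_s ≤ n_r + 1` it is undefined and reported as NaN, which fails
  every cutoff.

## Selection procedure

Step 1 (screening): each candidate is fitted alone at every delay
`0..max_delay_steps`; the delay minimizing AIC (ties toward the smaller
delay) defines its single fit.  Candidates below the screening cutoff
are dropped; survivors are ranked by single-fit AIC, stably, so ties
keep the caller's candidate order.

Step 2 (forward selection): the model starts from the top-ranked
regulator at its single-fit delay.  Remaining candidates are tested
once, in rank order: the candidate's delays are traversed with the
already-selected delays frozen, and it is admitted only if its best
addition *strictly* lowers the AIC — no tolerance, because the +2
penalty per parameter already discourages ties.  A variant that
restarts the pass from every ranking prefix and keeps the lowest-AIC
outcome is available (`restart_prefixes`), default off: a single pass is
the canonical reading of the procedure.

After selection, regulators with coefficient magnitude outside
`[min_coef, max_coef]` (default `[0.25, 4]`) are removed and the model
refitted, iterating until all remaining coefficients are in bounds.
Applying the bounds after selection (rather than rejecting candidates
during it) is the default; the in-selection variant is available via
`bound_during_selection`.  The pruning also acts as a safety net: a
spurious regulator admitted mid-search typically collapses to a
near-zero coefficient once the true regulators are in, and is removed
here.

## Numerical choices

* OLS via `numpy.linalg.lstsq` on the aligned design.  Rank-deficient
  designs (a regulator duplicated at the same delay, a constant column)
  have offending columns dropped greedily in input order, with their
  coefficients reported as zero and a logged warning; during forward
  selection such candidates are simply discarded.
* Saturated fits: an RSS below `n·1e-12` (including the ~1e-30 rounding
  residue of an exact fit) is floored at `n·1e-12` before the AIC, so
  the AIC stays finite and numerically stable while an exact model
  still beats every extension through the +2-per-parameter penalty.
* R² is clipped to `[0, 1]`; a constant target gets R² = 1 only when
  fitted exactly.
* Interpolation uses a natural cubic *interpolating* spline (no
  smoothing) per gene, evaluated on `n_out` uniformly spaced points
  including both endpoints (default 100).  Interpolation makes
  zero-noise recovery exact and reproduces observed values at
  coinciding grid times; boundary condition and a piecewise-linear
  fallback for < 4 observations are exposed as options.  A smoothing
  (regression) spline would be the alternative dialect; it is not
  implemented because exactness at the observations is what the
  recovery contracts test.
* Replicate merging averages observations whose lifeline times agree
  within 1e-6 min; rows containing missing values are dropped with a
  logged count.
* The input scale is never auto-detected; callers state raw vs log₂ vs
  log₂-ratio explicitly.

## Synthetic benchmark

The generator emulates synchronized cell-cycle-style data directly on
the interpolated grid: every regulator curve is a dominant sinusoid of
two cycles over the observation span plus 1–3 personal harmonics and a
slow distortion, scaled into a log-ratio-like range within [−3, 3].
Regulators belong to a small number of phase clusters (default 3,
jitter 0.3 rad), mimicking co-expression modules of transcription
factors active in the same cell-cycle phase.  Defaults: 10 regulators,
20 targets, 100 grid points at 3 min spacing, 1–3 regulators per
target, coefficient magnitudes in [0.3, 2] (inside the pruning bounds),
delays of 0–5 grid steps, noise sd 0.1 — which keeps single-regulator
adjusted R² in the 0.8–0.99 operating regime the screening cutoff
expects.

Targets are drawn *conditional on the method's identifying assumptions
holding in the noiseless signal*: (a) every true regulator alone clears
the screening margin (adjusted R² ≥ 0.85), (b) true regulators outrank
all non-regulators in single-fit AIC, and (c) traversing the true
regulators in rank order with earlier delays frozen recovers each true
delay with strictly decreasing AIC.  These three conditions are a
sufficient condition for greedy forward selection to return exactly the
generating structure on noiseless data (once all true regulators are
admitted the fit is saturated, so any further addition raises the AIC
by its parameter penalty).  Draws failing the conditions are rejected
and redrawn with the same regulator count; multi-regulator targets
draw their regulators from one phase cluster with a common coefficient
sign (a redundant co-regulating module), the regime in which each
individual regulator tracks the target well enough to survive
screening.  A target whose count never yields an identifiable draw
falls back to a single regulator.

What this does and does not show: passing the recovery tests
demonstrates correctness of the estimation and selection machinery on
data generated by the model class *within its identifiable regime*.
Real expression data additionally contain targets whose regulators are
individually weak, non-linear and combinatorial regulation,
post-translational control invisible to mRNA levels, and measurement
artifacts — on such data the gates reject targets rather than recover
them, and recovered networks are hypotheses, not ground truth.  All
benchmark randomness flows through one seeded generator; matrices and
truth networks are byte-reproducible from the seed.

## Problem sizes

The shipped tests and the acceptance script run the full pipeline on
the default benchmark (30 genes × 100 grid points, two noise levels,
plus a delay-disabled contrast) and check the greedy search against
exhaustive enumeration on 200 small instances (3 candidates × 4 delays
each, 40 grid points); together they complete in well under two
minutes on one CPU.  These sizes were chosen because every contract
they exercise — formula fidelity, exact noiseless recovery, greedy
bounds — is scale-free; larger instances change runtime, not the
properties under test.

## Limitations

* Greedy forward selection is not globally optimal: with correlated
  candidates it can admit a proxy regulator and can never remove a
  variable once added.  Delays of selected regulators are frozen and
  never revisited.
* AIC comparisons assume equal sample size; this is guaranteed within a
  target but means fits are conditioned on discarding the first
  `max_delay_steps` grid points even for small delays.
* No autocorrelation correction: interpolated residuals are serially
  dependent, so the AIC's implicit likelihood overstates the effective
  sample size.  Selection is still well-defined; p-values are
  deliberately not reported.
* Delays are quantized to the grid; sub-grid delays bias coefficients
  slightly.
* Undirected reference sets (association databases) cannot confirm
  direction; a matched undirected pair counts as consistent in either
  orientation.
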
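# Methods

## Model

An animal's baseline startle curve relates the startle sound level `s`
(dB above background) to its movement `m` (log10 of the z-scored
maximal accelerometer deflection in the 100 ms after startle onset):

    m(s) = m0 + N(s),      N(s) = m_max / (1 + e^{−r (s − s0)})

- `m_max` — saturation, the asymptotic maximum sound-driven movement
  (log10 z-units);
- `r` — sigmoid slope (per dB);
- `s0` — midpoint, the sound at half saturation (dB above background);
- `m0` — sound-independent movement floor (log10 z-units, ≥ 0);
- threshold — derived, the sound at 5% of saturation:
  `s0 − ln(19)/r`.

A prepulse condition `c` — a (prepulse level, prepulse→startle delay)
pair — modifies the baseline curve by a startle-axis scaling `α_c` and a
sound-axis scaling `β_c`, both bounded to [0, 1]:

    m_c(s) = m0 + α_c · N(β_c · s)

The bounded fit prevents compensation between parameters and keeps both
scalings interpretable as fractional reductions (reported as percent
scaling `100(1 − x)`). The nested startle-only variant fixes `β ≡ 1`;
it is the model implicit in the traditional PPI_ratio metric. Under
that variant, for any `m0 ≥ 0` and `0 < α ≤ 1`, the theoretical ratio
`1 − (m0 + αN(s))/(m0 + N(s))` is non-decreasing in `s` (its derivative
is proportional to `(1 − α)·m0·N'(s) ≥ 0`), so an observed decline of
PPI_ratio with sound level cannot be produced by startle scaling alone.
This monotonicity result is property-tested over randomized parameters.

## Fitting

Each animal is fit jointly across all of its stimuli by bounded
nonlinear least squares on the stacked residual vector (equivalent to
minimizing total RMSE), using `scipy.optimize.least_squares` (TRF) with
an analytic Jacobian. Free parameters: `(m_max, r, s0)` plus one
`(α_c, β_c)` pair per condition — `3 + 2n` in total. Initial values:
scalings at 1 (no scaling); the baseline sigmoid from a separate fit to
the baseline-condition summaries alone. Bounds: `m_max > 0`,
`0 < r ≤ 5`, `s0` within 30 dB of the tested sound range,
`α, β ∈ [0, 1]`. Non-convergence triggers up to three perturbed
restarts before the fit is flagged.

`m0` is fixed by estimation rather than fitted: the 0-dB no-prepulse
observation equals `m0 + N(0)`, so `m0 = max(0, ȳ₀ − N(0|curve))`,
evaluated self-consistently inside the residual (with its gradient
propagated through the Jacobian). Subtracting `N(0)` matters for
animals with low midpoints, where `N(0)` is not negligible; ignoring it
biases the whole baseline curve. If no 0-dB trials exist, `m0 = 0` with
a warning.

### Model comparison

The two variants are compared by repeated cross-validation: in each of
100 iterations (25 in the large validation studies) the trials within
every stimulus are split 80/20, both variants are fit to the train
summaries, and each is scored on the holdout summaries by the
SEM-normalized RMSE

    sqrt( mean_stimuli ((prediction − mean)/SEM)² ).

Splitting at the trial level keeps every stimulus represented in both
train and test, which the per-stimulus normalization requires; a
summary-level split is available via `FitConfig(cv_unit="summary")`.
Stimuli with zero/undefined SEM are excluded from the normalized error
with a warning (they would carry infinite weight). The reported
quantity is the mean holdout error per variant and their difference
(startle-only minus both); positive differences favour sound scaling.
Parameter distinctness across animals is checked by swapping fitted
parameter sets between animals with identical stimulus designs and
comparing swapped to self-fit normalized errors.

### Uncertainty

90% confidence intervals come from refitting the model to jittered
data: each refit perturbs every stimulus's observed mean by a Gaussian
draw with SD equal to that stimulus's SEM (centred on the observed
mean, since that is the quantity being jittered), warm-started at the
point estimate; the interval spans the 5th–95th percentile over 10,000
refits (1,000 in the coverage study). This is a parametric-bootstrap
style procedure; its measured coverage on synthetic animals is close to
nominal (~0.9) because the estimator is nearly linear in the data at
the default noise scale. Coverage degrades when a true scaling sits at
the [0, 1] boundary, where the interval is truncated.

## Group analysis

All group tests run per prepulse condition; experiments varying the
prepulse level and experiments varying the delay are distinct condition
sets and are never pooled.

- **LDA separability** — two-class LDA on the five standardized
  parameters `(m_max, r, s0, α_c, β_c)` (features are z-scored across
  animals within condition because the units are incommensurate).
  The implementation is the closed-form pooled-covariance discriminant
  `w = Σ⁻¹(μ₁ − μ₀)` with a Gaussian offset and empirical priors; it is
  verified against scikit-learn's `LinearDiscriminantAnalysis` in the
  tests, and implemented in batched numpy so the permutation loops stay
  tractable (the pooled within-class scatter for a permuted labelling
  is the total Gram matrix minus the class outer products, so 10,000
  permutations reduce to one stacked 5×5 solve). Significance: a
  label-permutation test on the mean absolute distance to the
  hyperplane, and a label-permutation test on leave-one-out
  classification accuracy (computed by rank-one downdates, batched).
  Permutation p-values use the add-one estimator
  `(1 + #{null ≥ obs})/(n_perm + 1)`; the LOOCV test uses the mid-p
  convention (ties counted half) because accuracy is discrete in
  multiples of 1/n and tie mass otherwise makes the test markedly
  conservative (measured type-I ~0.01 instead of ~0.05).
- **Multiplicity** — the count of significant conditions is tested
  against an independent-binomial null: `n_boot` draws of
  `Binomial(n_conditions, 0.05)`, add-one tail p. This matches the
  exact binomial tail to Monte-Carlo error (tested), and ignores the
  dependence between conditions measured on the same animals — a known
  limitation, documented rather than resolved. No further FDR layer is
  applied.
- **Parameter covariation** — PCA on the four-feature set (saturation,
  threshold, startle scaling, sound scaling), with significance from
  independently shuffling each feature column across animals; Pearson
  correlations of `α` vs `m_max` and `β` vs threshold per condition
  with OLS regression lines. Robustness: the correlations are
  recomputed across jittered refits of all animals (percentile band and
  the fraction of refits crossing zero), and compared against a
  within-animal null in which the same jitter machinery measures the
  parameter correlations produced purely by compensation between
  parameters within one animal; an observed across-animal correlation
  above the null's 75th percentile is not attributable to compensation.
- **ANCOVA** — per condition, each scaling parameter is regressed on
  group plus its matched baseline covariate (`α` on saturation, `β` on
  threshold) with a group-by-covariate interaction; if the interaction
  is not significant (homogeneity of slopes) the model is refit without
  it and the group main effect reported. Conditions where the groups
  differ in the covariate itself (two-sample t-test, p < 0.05) are
  excluded, since ANCOVA is inappropriate under nonrandom covariate
  differences. Models are fit with statsmodels OLS; the group F-test is
  verified against an explicit design-matrix computation.
- **Scaling vs stimulus dimension** — per animal, OLS slopes of `α` and
  `β` against the varied stimulus dimension (prepulse level or delay),
  with a one-sample t-test on the slope distribution.

## PPI_ratio diagnostics

PPI_ratio is computed on the log-scale movement summaries; the baseline
`m_b` for a given `m_p` is the same-startle-level, no-prepulse summary
from the same animal. Records with `m_b ≤ 0` (possible near threshold
on the log scale) are flagged rather than dropped silently. The
slope diagnostic regresses PPI_ratio on startle level per (animal,
condition) using startle-eliciting levels only (≥ 20 dB above
background by default): at sub-threshold levels the denominator
collapses to `m0` and the ratio is ~0 regardless of inhibition, which
mechanically flattens the slopes; the cutoff is exposed as
`min_startle_db` (None = all levels).

## Preprocessing

Per (animal, session), a Gaussian is fit (sample mean and n−1 SD) to
the pooled accelerometer readings from the first 100 ms of every trial
— always pre-stimulus — and all samples are z-scored against it,
normalizing away hardware gain. A trial's movement is the maximum
z-scored value within 100 ms after startle onset, carried as log10;
trials whose maximum is non-positive (log undefined) are dropped and
counted with a warning — with real z-scored maxima this is rare.
Habituation-flagged trials are read but excluded from summaries. Trial
repeats are pooled across all sessions of an experiment (no habituation
modelling). The distribution screen compares Gaussian and log-normal
models per (animal, stimulus) cell: Shapiro–Wilk on raw and log10
values plus the difference in maximized log-likelihood (the log-normal
likelihood evaluated via the normal fit to ln x minus the Jacobian
term Σ ln x).

## Synthetic cohorts

The generator draws per-animal parameters from a latent jointly
Gaussian construction: `m_max`, `r` and the threshold are Gaussian
(midpoint derived as `s0 = threshold + ln(19)/r`, so correlation
targets on the threshold are exact); the scaling pairs are logistic
transforms of animal-level latents, giving `α, β ∈ [0, 1]` by
construction. Latent correlations couple `α` with `m_max` (default
−0.5) and `β` with threshold (default −0.65), the sign and magnitude
pattern seen empirically in rats; an infeasible correlation matrix
raises a spec error. Per-trial log10 movement is Gaussian around the
model mean (so raw movements are log-normal), with σ = 0.15 — a
calibration choice placing per-stimulus SEMs at 60 trials near 0.02
log-units, which reproduces realistic fit errors and screen behavior.

Default design: startle levels 0–60 dB in 10-dB steps (the 0-dB
baseline stimulus makes `m0` estimable), 13 prepulse conditions
spanning 2–18 dB at a 100-ms delay, 60 trials per stimulus, one group
of 20 animals. Baseline parameter means: `m_max` 2.0 ± 0.35, `r`
0.20 ± 0.03 per dB, threshold 10 ± 4 dB, `m0` 0.10 ± 0.03. The
threshold mean of 10 dB above background reflects that rats startle to
sounds modestly above a ~70 dB background and places the startle grid
mostly at or above the curve midpoint. Default condition effects:
stronger scaling for louder prepulses and shorter delays. Group offsets
can be applied additively to any parameter. A trace simulator embeds
each trial's intended maximum as a transient in Gaussian baseline
noise, so the full preprocessing chain can be exercised end to end.

What the generator does *not* emulate: session-to-session habituation,
intertrial dependence, hearing loss, apparatus artifacts, and
non-log-normal tails. Passing tests therefore demonstrate correctness
of the machinery under the model's own assumptions, not robustness to
every violation real data can present.

## Validation studies and sizes

`ppiscale.validation` (driven by `scripts/acceptance.py` and the
slow tests) runs, on one CPU in a few minutes:

- monotonicity of the theoretical ratio over 1,000 random parameter
  sets on a 200-point sound grid;
- parameter recovery on the default cohort (20 animals, 13 conditions,
  60 trials/stimulus, σ = 0.15): median |α̂ − α| and |β̂ − β| and
  median relative errors of the baseline parameters;
- cross-validated model selection with 25 CV iterations on 20-animal
  cohorts generated with β = 0.8 and β = 1;
- PPI_ratio slope signs on a 12-animal, five-condition cohort;
- the distribution screen over 510 (animal, stimulus) cells (six
  animals on the default design); note that at 60 trials per cell and
  the default noise the log-normal model wins in only ~93% of cells —
  individual 60-trial cells of genuinely log-normal data are
  occasionally better described by a Gaussian by chance;
- type-I calibration of the three group tests over 500 null cohorts at
  1,000 permutations;
- oracle equivalences (binomial tail, design-matrix F-test, direct
  arithmetic);
- jitter-CI coverage over 100 replicate animals at 1,000 refits;
- the 6-of-13 multiplicity worked example.

## Known limitations

- The binomial multiplicity null ignores between-condition dependence.
- ANCOVA exclusion uses a per-condition covariate t-test at 0.05; no
  joint test across conditions.
- The LDA assumes a shared within-group covariance; a strong ridge
  fallback (with warning) handles singular covariances but changes the
  statistic slightly in that regime.
- Jitter CIs are truncated at the [0, 1] scaling bounds; coverage for
  parameters at the boundary is conservative on one side.
- The CLI maps user errors to exit code 1 and usage errors to 2;
  unexpected internal errors surface as tracebacks with a nonzero exit.
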
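# Methods

## Model and scope

`crtmiss` evaluates repeated cross-sectional multi-period two-arm parallel
cluster randomized trials in which each measurement period is one day of
the week and a fresh sample of `m` subjects per cluster is measured each
period. Both arms share the number of clusters `k`, the weekly measurement
scheme, the number of weeks `R` and `m`; only the dropout pattern may
differ between arms. The engine computes design-stage quantities — the
variance of the treatment-effect estimator, power, relative efficiency and
required sample sizes — with the correlation parameters treated as known
inputs, not estimated from data. Cohort, crossover and stepped-wedge
designs, subject-level dropout, informative (MNAR) missingness, non-Weibull
dropout and covariance structures other than first-order autoregressive
decay are out of scope.

## Variance engine

The outcome model is a two-level mixed model with period fixed effects, a
0/1 treatment effect, cluster-period random effects and subject residuals.
Two normalizations are built in:

* **Unit total variance.** σ_u² + σ_e² = 1, so σ_u² = ρ, σ_e² = 1 − ρ, and
  the treatment effect equals Cohen's d. Only standardized quantities
  (ρ, r, d) are ever needed as inputs.
* **Calendar-day decay.** The within-cluster correlation between periods is
  ρ·r^g with g the gap in *calendar days*, not in observed-period indices.
  A scheme measuring Mon, Tue, Thu therefore has gap 2 between its second
  and third periods. This is what makes a four-day scheme spanning Mon–Fri
  slightly more efficient than one spanning Mon–Thu: the wider first-to-last
  lag lowers the average between-period correlation.

The GLS information matrix of (β₁,…,β_T, θ) is accumulated per cluster and
inverted; var(θ̂) is the last diagonal element. Because every fixed-effect
covariate is constant within a cluster-period, a cluster observed for h
periods contributes exactly

    X'V⁻¹X = m · X̃' (σ_e² I_h + m σ_u² R_h)⁻¹ X̃,

where X̃ is the h-row period-level design matrix and R_h the decay
correlation matrix of the observed days. The implementation uses this
reduction throughout, so the cost is independent of m; the test suite
verifies it against the explicit (m·h × m·h) subject-level computation to
1e-10, and against closed forms in the two solvable corners (ρ = 0:
var = 2/(kmT); r = 1 complete data: var = 2(σ_u² + σ_e²/(mT))/k).

Symmetry of the information matrix is asserted to 1e-8 before inversion. A
period with no observations in either arm leaves its dummy column
unidentified; this is reported as an error naming the offending column(s)
rather than silently pseudo-inverted.

## Dropout model

Cluster dropout is discrete: a cluster leaves at the end of a calendar day
and contributes nothing afterwards (monotone right-censoring). Survival
follows a discrete Weibull on the rescaled axis τ = (day − 1)/(t_max − 1):

    S(day) = (1 − ω)^(τ^γ),

so S(1) = 1 — every cluster yields at least its first measurement day — and
S(t_max) = 1 − ω, making ω the proportion lost over a trial of maximal
duration. The rescaling convention uses day − 1 in the numerator and
t_max − 1 in the denominator; among the candidate conventions
(day/t_max, (day−1)/t_max, (day−1)/(t_max−1)) it is the only one with both
anchor properties above, and it is the convention under which a one-week
trial cut from an ω = 0.5, 28-day trial loses 28%, 14% and 3% of its
clusters for γ = 1/2, 1 and 2 — the package's dropout acceptance anchor.

The probability that a cluster yields exactly its first h measurement
periods telescopes from survival at the measurement days:
p_h = S(day_h) − S(day_{h+1}) for h < T, p_T = S(day_T). Dropout on
non-measurement days (weekends under a workday scheme) is absorbed
automatically because only measurement-day survival enters. Two modes
average the information over dropout patterns:

* **expected** (default): replace the random per-count cluster numbers K by
  E(K) = k·p. The information matrix is linear in cluster counts, so this
  plug-in is exact at the information level and deterministic.
* **sampled**: average the variance over multinomial draws of K
  (`draws`, seeded). The two agree within 1% on the worked-example
  configuration; the plug-in is the default because it is deterministic and
  orders of magnitude faster.

## Power and search

Power uses the normal approximation Φ(|d|/√var − z), with z the 1−α
(one-sided) or 1−α/2 (two-sided) normal quantile; the far-tail term is
ignored. This convention reproduces every required-sample-size figure of
the waiting-room worked example exactly, so no t-based small-sample
correction is applied. `required_m` searches ascending integers m = 1..m_max
and reports the first success; because power levels off in m (the
cluster-level variance component is not diluted by more subjects per day),
unattainability within m_max is a reported outcome (-1 sentinel), not an
error.

Relative efficiency puts the reference design's variance in the numerator:
RE = var_ref/var_alt ≤ 1 means the alternative is less efficient, and
(1/RE − 1)×100% is the extra-cluster percentage needed to compensate.

Scheme mixtures (clusters working different day subsets) accumulate
information with k·w_l clusters per component scheme. Period effects are
indexed by the union of calendar days across the component schemes — the
one open parameterization choice here; it reduces exactly to the plain
computation for a single scheme and yields mixture variances bracketed by
the component variances in the tested configurations.

## Simulator

The simulator generates data from precisely the model above: per cluster,
the number of observed periods is drawn from the count distribution
(inverse-CDF on the end-of-day grid), cluster-period effects jointly from
N(0, σ_u²·r^gap) over all T periods, subject residuals independently, then
records are truncated to the first h periods. Refitting uses GLS with the
variance components *known* — design-stage validation, not REML — so the
model-based covariance must equal the analytic information inverse for the
realized pattern, exactly; across replications the empirical variance and
rejection rate of θ̂ must match the analytic variance and power
statistically.

What passing simulator tests do show: the analytic engine and the
generative model agree, including the calendar-gap covariance and monotone
truncation. What they do not show: robustness to real-data features the
model excludes — unequal cluster sizes, subject-level dropout, non-Gaussian
outcomes, misspecified (ρ, r), or dropout related to outcomes (MNAR).

## Problem sizes and numerical choices

The default validation run uses 2000 replications of a one-week full-week
design with k = 5, m = 2 (empirical variance within 5% of analytic,
empirical power within binomial 95% bounds), and 1000 multinomial draws for
the expected-vs-sampled comparison at the worked example's design 2 —
sizes chosen so the full suite completes in well under a minute of compute
while leaving Monte-Carlo error comfortably inside the asserted tolerances.
All stochastic tests and commands are seeded. Matrix solves use symmetric
linear algebra on the period-level (h × h) systems; no explicit inverses of
subject-level matrices are ever formed.

## Known limitations

* Weekly period structure only; periods longer or shorter than a day, or
  non-weekly layouts, are not representable.
* Both arms must share k, m, scheme and R.
* The power approximation ignores the opposite tail and uses the normal
  reference; for very small k a t-based convention would be conservative
  by roughly one subject per day in edge cases.
* ω = 1 (certain dropout) is excluded; ω is capped below 1.
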
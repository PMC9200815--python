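# Methods

## The model

Deuterium uptake of a peptide over exposure time t (seconds) is modelled by
a stretched-exponential (Weibull-type) mean curve

    mu(t) = a (1 - exp(-b t^q)) + d

- `d` (Da) — undeuterated centroid mass. Fitting it, rather than
  normalising observations by the t = 0 measurement, keeps the
  heteroscedasticity of the time course intact (isotopic expansion makes
  the centroid error time-dependent) and propagates the uncertainty of the
  undeuterated mass into every downstream interval.
- `a` (Da) — uptake plateau above `d`; `a + d` is the maximum uptake.
- `b` (s^-q) — rate constant; larger b, faster approach to plateau.
- `q` (dimensionless) — stretch exponent. `q = 1` is simple exponential
  exchange; `q > 1` indicates faster-than-exponential early uptake (more
  solvent-exposed, fewer hydrogen bonds). Fitted values in practice sit
  around 1-2; the optimiser caps q at 10 purely to keep t^q finite at long
  times.

All four parameters are constrained non-negative. The `exponential` form
pins q = 1 (3 free parameters). For sparse designs (e.g. single-replicate
epitope mapping at times 0/30/300 s) the model can be reduced further by
pinning parameters, conventionally `b = 0.5, q = 1, d = 0`, leaving only
the plateau free — one parameter under the null, two under the
alternative, hence a single-degree-of-freedom test that remains usable
where t tests (no within-group variance) and mixed models (no replicate
nesting) are not.

## Fitting

A projected Levenberg-Marquardt iteration: trial steps solve the damped
normal equations (J^T J + lambda diag(J^T J)) delta = -J^T r with the
analytic Jacobian of mu, are clipped onto the non-negativity box, and are
accepted only when the residual sum of squares (RSS) decreases; lambda
shrinks by 3 on acceptance and grows by 10 on rejection. Iteration stops
after 500 steps or when an accepted step improves the RSS by less than
1e-8 (an absolute tolerance — uptake curves live on the Da scale, so this
is far below measurement noise). The Marquardt diagonal damping also
equilibrates the disparate parameter scales (d is a full peptide mass,
b is ~1e-2).

Starting values: d0 = min y, a0 = range(y) floored at 1e-6, q0 = 1, and
b0 = ln 2 / t_half from the first time the series crosses its half-rise
(geometric mean of positive times as fallback). If the first solve fails
or leaves more variance than the data carry, three deterministic perturbed
restarts are tried and the lowest-RSS solution kept, so results are
bit-reproducible. t^q is defined as 0 at t = 0 for all q > 0, avoiding the
0^0 ambiguity.

The parameter covariance is the Gauss-Newton approximation
sigma_hat^2 (J^T J)^-1 with sigma_hat^2 = RSS/(n - k), using a
pseudo-inverse so near-degenerate fits degrade to wide/NaN intervals
rather than crashes.

## The test

Null hypothesis: one curve, blinded to condition, explains all C
conditions. Alternative: one curve per condition. With p1 = k free
parameters under the null and p2 = C k under the alternative,

    F = (d2/d1) (RSS0 - RSS1) / RSS1,   d1 = p2 - p1,  d2 = n - p2,

referred to F(d1, d2). RSS1 sums the per-condition fits; because the
problem is non-convex a fresh per-condition solve can occasionally land
above the pooled optimum, in which case the alternative is refitted from
the null solution and F floored at 0, restoring nestedness. A perfect
alternative fit (RSS1 = 0) is flagged and assigned p = 0; analytes with
too few observations in any condition are reported with status
`insufficient_data` and NaN p-values, excluded from the multiplicity
family.

### Empirical-Bayes moderation

With few replicates the residual variance s_i^2 = RSS1/d2 is itself noisy.
Assuming true variances follow a scaled inverse chi-square prior with d0
degrees of freedom and scale s0^2 — marginally s_i^2 ~ s0^2 F(d2, d0) —
the posterior-mean variance

    s~_i^2 = (d0 s0^2 + d2 s_i^2) / (d0 + d2)

replaces s_i^2 in the moderated statistic F~ = (RSS0 - RSS1)/(s~_i^2 d1),
referred to F(d1, d0 + d2) (the standard reference distribution for
posterior-variance plug-in statistics; at d0 = 0 the pipeline reduces
exactly to the ordinary F test, at d0 = infinity to a chi-square limit).

Hyperparameters are estimated once per dataset by matching moments of
log s_i^2: with e_i = log s_i^2 - psi(d2_i/2) + log(d2_i/2),
E[e] = log s0^2 - psi(d0/2) + log(d0/2) and
Var[e] = psi'(d2_i/2) + psi'(d0/2), so psi'(d0/2) equals the sample
variance of e minus the mean trigamma of d2_i/2, solved by a Newton
iteration on the trigamma function. Each analyte contributes its own d2_i,
so unequal observation counts from missingness need no approximation. If
the observed spread does not exceed what sampling alone explains, d0 is
infinite and every variance shrinks fully to s0^2; exactly identical input
variances return that common value. Zero variances (perfect fits) are
excluded from the pool, since the log-moment fit cannot absorb them.

Adjustment for multiplicity is Benjamini-Hochberg over all testable
analytes of a run, as one family.

## Effect sizes

From two condition fits: differences in d, a + d, b and q (Wald intervals
from the summed covariances of the two independent fits, t quantile at the
smaller residual df); the largest absolute curve gap sup_t |mu1 - mu2|;
the integrated gap; and the signed difference at chosen times t*. Curve
effects are evaluated on a deterministic grid of 1001 log-spaced points
over the observed time range (t = 0 prepended) — HDX kinetics vary on log
time, and the fitted curve is not extrapolated beyond the data. Interval
gradients come from the analytic partial derivatives of mu. When a fit
sits on the non-negativity boundary its Wald interval is reported as NaN:
the asymptotics are invalid there, and an honest missing interval beats a
misleading one.

## The simulator

Each simulated peptide draws its number of exchangeable sites uniformly
from 5..25, a random sequence of that length (for monoisotopic mass and
carbon bookkeeping), and a charge in 1..3. Incorporation over the m
exposure times is the cumulative sum of a Dirichlet draw over the m - 1
post-zero times with concentration alpha_j = 20/j (the j = 1 component
belongs to the first post-zero time; larger early concentrations give the
fast-then-plateau shape of real kinetics), so D_1 = 0, D is non-decreasing
and D_m = 1. A condition effect fires per post-zero time point with
probability 1 - null_prob (default 0.05): the second condition's increment
at that point is redrawn from its Dirichlet marginal
Beta(alpha_j, sum(alpha) - alpha_j) and the cumulative schedule
recomputed, clipped at 1. This keeps monotonicity structurally and makes a
redraw at the final time point genuinely move the endpoint; a peptide is
labelled perturbed iff at least one indicator fired, which then coincides
with its schedules actually differing.

Envelopes follow a binomial model: heavy-carbon counts
Binomial(n_carbons, 0.0107) spaced 1.003355 Da convolved with deuterium
counts Binomial(n_sites, D) spaced 1.00628 Da, sampled as 10,000 ions per
spectrum, so the expected centroid shift is n_sites * D * 1.00628 Da with
small Monte-Carlo jitter. Centroids are corrupted with Gaussian noise of
SD 0.05 Da (configurable); missingness deletes observations completely at
random. The default exposure grid is 0/30/240/1800/14400/86400 s truncated
to m points (overridable).

Six preset designs: (1) m=4, R=3; (2) m=4, R=2; (3) m=5, R=2; (4) m=6,
R=2; (5) adds 5% missingness; (6) additionally null_prob = 0.99. All use
500 peptides and 2 conditions.

What the simulator does *not* emulate: back-exchange, proline/N-terminal
exclusions, charge-state-dependent centroiding artefacts, chromatographic
co-elution, and spatial correlation between overlapping peptides. Passing
tests therefore demonstrate statistical behaviour under idealised
missing-at-random, Gaussian-noise conditions — not robustness to
systematic instrument effects. Note also that the schedule-based truth is
deliberately *not* drawn from the Weibull family, so the test's
calibration and power are measured under model misspecification.

## Comparators and scoring

The pointwise t test (Welch by default; pooled-variance optional, since
the convention is not settled) tests each exposure time separately,
skipping points with fewer than two replicates per condition or no
variance (notably t = 0, undeuterated by construction); per-time p-values
combine by the harmonic mean k / sum(1/p_j). The mixed-model comparator
fits value ~ time * condition with a random intercept per replicate
(statsmodels MixedLM; derivative-free optimiser first, since the replicate
variance often sits at its zero boundary), either with time as a factor or
as log(t + delta) with delta the smallest positive observed time, and
combines the condition-related coefficient p-values by harmonic mean. On
null data the per-coefficient p-values are calibrated while the combined
value is left-shifted — the harmonic mean of several p-values is not
itself a p-value, which is one mechanism behind the mixed-model approach's
known false-positive inflation.

Benchmarking calls significance at BH-adjusted p < 0.05 and scores calls
against simulation truth by precision, recall and their harmonic mean
(F-score; 1 on a clean all-null run, 0 when nothing true is found). The
null-permutation harness falsely splits replicates of a single condition
into pseudo-conditions (default 3/4, six permutations) and counts calls —
all of which are false positives by construction.

## Problem sizes and numerical conventions

Validation runs use the preset designs at their native 500 peptides for
the null and permutation experiments and a 200-peptide version of the
sparse-replicate design for the power comparison, each over 10 simulation
seeds — sizes chosen so the full validation completes in minutes on one
CPU while keeping the Monte-Carlo error of the reported rates well inside
the margins being tested. Ties and degenerate cases: F is floored at 0;
RSS1 = 0 maps to p = 0; BH propagates NaN outside the family; the
evaluation grid is deterministic so sup/integral effects are reproducible
bit for bit; all simulation randomness flows from a single seed.

## Known limitations

- No spatial model across overlapping peptides; residue-level summaries
  are visualisation aids (harmonic means), not calibrated inference.
- Wald/delta-method intervals are first-order; they are reported as NaN at
  parameter boundaries rather than corrected.
- The moderated F's reference distribution F(d1, d0 + d2) is exact under
  the prior, approximate under misspecification; null simulations show the
  resulting p-values are uniform in practice.
- Back-exchange correction is a data-preparation step outside this
  package's scope (an uptake transform hook is provided).
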
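# Methods

## Generating model

Each simulated dataset contains two groups of equal size (100, 300 or
600 per group) measured on 12 continuous indicators of a single factor.
The reference group's latent distribution is standard normal; the focal
group's is N(kappa2, phi2) with kappa2 in {0, 0.8} and phi2 in {1, 2, 4}.
Scores are drawn as y = nu_g + lambda_g·xi + delta with xi and delta
independent normals. Invariant loadings are 0.7 and intercepts 0.
Noninvariant conditions lower the focal group's loadings *or* intercepts
of 1 or 4 items by 0.15 or 0.25. Error variances are
psi_g = (1 − lambda_g²)·phi_g elementwise, using each group's own
loadings, so every item's population variance equals phi_g exactly —
item variances scale one-for-one with the latent variance, and a
noninvariant loading redistributes an item's variance between common and
unique parts without changing its total.

Which items are noninvariant is arbitrary under exchangeable loadings;
the leading 1 or 4 items are always used, for both locations, so every
condition is deterministic. The full crossed design has 144
noninvariant conditions (3 sample sizes × 3 variance ratios × 2 mean
differences × 2 item counts × 2 magnitudes × 2 locations) and 18
invariant ones.

Seeding: one master seed per run; the seed of replication r of condition
c is `SeedSequence((master, c, r))`, so any single replication is
reproducible in isolation.

What the generator does *not* emulate: nonnormal or ordered-categorical
indicators, missing data, more than two groups, multi-factor structures.
Conclusions from passing tests therefore speak to the idealized
continuous-normal setting only.

## ML fitting

Model levels and free-parameter counts (p = 12, two groups; the moment
count is 2·p(p+3)/2 = 180):

| level      | constraints                                          | k  | df  |
|------------|------------------------------------------------------|----|-----|
| configural | kappa = 0, phi = 1 in both groups                    | 72 | 108 |
| metric     | shared loadings; phi2 free                           | 61 | 119 |
| scalar     | shared loadings and intercepts; kappa2, phi2 free    | 50 | 130 |
| baseline   | independence model (means and variances only)        | 48 | 132 |

The discrepancy is the multivariate-normal fitting function per group,
combined as F = sum_g (n_g/N)·F_g; the test statistic is T = N·F by
default (`t_scale="N-1"` is available for sensitivity, since the two
conventions differ in the literature). The deviance is recovered as
D = D_saturated + N·F, which the tests verify against a brute-force
density evaluation to 1e-8.

Optimization is L-BFGS-B with analytic gradients on a transformed vector
in which variances are log-scaled, so Heywood cases are impossible by
construction; error variances collapsing below 1e-6 are flagged as
nonconvergence instead. Start values: loadings 0.7, intercepts at the
sample means, error variances at half the observed item variances,
phi = 1, kappa = 0; up to five restarts with multiplicative U(0.8, 1.2)
jitter. Convergence requires optimizer success (or a gradient norm
below 1e-4) — in practice the invariance models on this design converge
on the first attempt in essentially all replications. The baseline
model has the closed-form solution (means, diagonal variances) and is
never optimized numerically. The loading sign indeterminacy is resolved
by the positive starting values.

## Fit measures and decision rules

Frequentist panel: CFI, TLI, RMSEA, Gamma hat and MFI from (T_target,
df_target, T_baseline, df_baseline); AIC = D + 2k, BIC = D + k·ln n,
SaBIC = D + k·ln((n+2)/24). `n` is the total sample size across groups,
consistent with T = N·F; Gamma hat uses p = 12 observed variables with
no multigroup correction, exactly as the formula is usually printed.
Where the formulas can exceed 1 for better-than-expected fit (GH, MFI at
T < df) they are left unclipped.

Deltas are oriented so larger values favor the free model
(free − restricted for CFI/TLI/GH/MFI, restricted − free for RMSEA) and
compared strictly against the conventional thresholds (.01, .01, .015,
.02, .001); the LRT keeps the restricted model at p ≥ 0.05; information
criteria pick the smaller value with exact ties going to the restricted
model.

## Posterior sampling

Priors (diffuse, overridable): loadings N(0, 10), intercepts N(0, 32),
focal latent mean N(0, 10), variance parameters Gamma(shape 1, rate 0.5)
applied on the standard-deviation scale. The gamma prior's scale
convention is genuinely ambiguous in the literature this design follows,
so it is a switch (`sd`, `variance`, `precision`) with `sd` as default.

The sampler is adaptive componentwise random-walk Metropolis on the same
transformed parameter vector as the ML fitter, with the latent factor
integrated out analytically (rank-one covariance structure, so each
likelihood evaluation is O(p²) from the sufficient statistics). Chains
run in lockstep; proposal scales adapt per coordinate toward an
acceptance rate of 0.44 during warmup and are frozen afterwards. Because
the factor structure induces strong positive posterior correlations
within the loading and intercept blocks, each sweep adds one adaptive
*joint-shift* proposal per multi-parameter block; without these the
intercept block mixes an order of magnitude more slowly (R-hat ≈ 1.06
rather than ≈ 1.015 at the default 3 chains × 1000 warmup + 1000
retained draws). Chains start from the ML solution with N(0, 0.05)
jitter. The convergence contract is diagnostic-based — split-chain
R-hat < 1.05 for all parameters, ESS monitored — so a gradient-based
sampler would be a valid drop-in replacement. Default desk-scale
settings are 3 × 1000/1000; full-scale 5000/5000 runs are a
configuration change.

Per-draw quantities: the deviance D(theta_i) from the group moments, and
the pointwise log-likelihood matrix log p(y_j | theta_i) from the raw
data; the identity D(theta_i) = −2 Σ_j log p(y_j | theta_i) is enforced
in the tests at 1e-8.

## Bayesian fit measures

pD = mean(D(theta_i)) − D(theta_bar), with theta_bar the posterior means
on the natural scale. The pD-substituted indices evaluate the
frequentist formulas at every iteration with T replaced by
D_i_obs − pD and df by p* − pD (p* = 180), where D_i_obs is the draw's
deviance relative to the saturated model — this convention makes the
Bayesian indices commensurate with their ML counterparts (for a
degenerate posterior the per-iteration values collapse to the
frequentist formulas at df = p*; for a genuine diffuse-prior posterior
pD ≈ k, so the substituted df ≈ the ML df and the EAP indices track the
ML indices closely, which the tests check at |BCFI − CFI| < 0.01 at
n = 1200). Index distributions are summarized by the EAP (decision
default), median and 95% credible interval.

Bayesian LRT: deviances evaluated at each model's EAP estimates,
compared to the chi-square 95th percentile at delta-df — the threshold
mirrors the ML rule and is a documented convention, not a posterior
probability statement. DIC = D(theta_EAP) + 2·pD. WAIC uses
log-mean-exp per subject (overflow-safe) and the divisor-(I−1) posterior
variance for pW. LOO is estimated by Pareto-smoothed importance
sampling with weights proportional to 1/p(y_j|theta_i); subjects with
tail index above 0.7 are flagged, and the test suite keeps an exact
leave-one-out refit oracle for a 20-subject toy.

## Pipeline and summaries

Loading-noninvariant data compare configural vs metric; intercept-
noninvariant data compare metric vs scalar; invariant data run both
comparisons. Replications where either model of a pair fails its
convergence contract are excluded pairwise and logged; effective counts
are reported. False-positive rates carry the binomial acceptance band
0.05 ± 1.96·sqrt(.05·.95/R) (= [0.02, 0.08] at R = 200).

The factorial ANOVA of fit-value differences treats latent mean
difference, latent variance ratio, number of noninvariant items,
magnitude and sample size as categorical factors with all interactions
up to degree five (saturated for five factors), fitted by OLS on the
balanced design; eta-squared is SS_term/SS_total with the residual
included in the total. Noninvariant-side ANOVAs use only that side's 72
conditions, since the noninvariance factors are undefined for invariant
data.

A structural note on the LRT decomposition: the chi-square difference is
approximately noncentral chi-square with noncentrality N·ΔF_pop, which
is multiplicative in sample size and misfit. Computing ΔF_pop exactly
for all 72 loading conditions shows that SS/SS_total of the raw
difference is then bounded near 0.34 for the sample-size share (with
sizeable size×misfit interactions) regardless of replication count —
the simulated decomposition matches this closed-form limit, so the
eta-squared shares this package reports are the faithful consequence of
the stated design and the standard eta-squared definition. Analyses
that normalize by explained variance only, or work on a compressed
(log-like) response scale, redistribute these shares toward the
sample-size main effect.

## Problem sizes

Default replication counts are 50 per condition for the ML arm and 20
for the Bayesian arm, chosen so a full side of the design (72
conditions) runs in minutes on one CPU; rate and ANOVA summaries at
these sizes carry binomial/Monte-Carlo noise of a few percentage points.
Any grid accepts `--reps 200` for full-replication reruns. Acceptance
reruns (`scripts/acceptance.py`) use 200 replications per cell for the
false-positive extremum and 50 per condition for the ANOVA shares.
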
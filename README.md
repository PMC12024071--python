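# misim — factorial invariance testing under heterogeneous latent distributions

`misim` is a Monte Carlo toolkit for studying how well frequentist and
Bayesian fit measures detect measurement noninvariance in two-group
confirmatory factor analysis (CFA) when the groups' latent distributions
differ in mean and variance. It is aimed at methodologists who want to
rerun, extend or stress-test this style of simulation without a
lavaan/blavaan stack: the data generator, the multigroup ML fitter, the
MCMC engine and the entire fit-measure panel are implemented directly on
the model's moment structure.

## The model

Observed scores for subject *j* in group *g* follow a one-factor model
with *p* = 12 indicators:

    y_jg = nu_g + lambda_g * xi_jg + delta_jg,
    xi_jg ~ N(kappa_g, phi_g),   delta_jg ~ N(0, Psi_g)  (Psi_g diagonal)

so the implied moments are `mu_g = nu_g + lambda_g kappa_g` and
`Sigma_g = phi_g lambda_g lambda_g' + Psi_g`. Group 1 is the reference
(kappa = 0, phi = 1); the focal group may differ in latent mean (0 or
0.8), latent variance (1, 2 or 4) and, in noninvariant conditions, in the
loadings or intercepts of 1 or 4 items (lowered by 0.15 or 0.25). All
invariant loadings are 0.7 and error variances are (1 − lambda²)·phi_g,
so every item's population variance equals phi_g.

Invariance is tested through the usual nested sequence — configural
(all measurement parameters free), metric (equal loadings, focal latent
variance freed) and scalar (equal loadings and intercepts, focal latent
mean and variance freed) — fitted by

* **maximum likelihood**: minimizing the multigroup discrepancy
  `F = sum_g (n_g/N) [log|Sigma| − log|S_g| + tr(S_g Sigma^{-1}) − p +
  (xbar_g − mu)' Sigma^{-1} (xbar_g − mu)]` with T = N·F, and
* **MCMC** under diffuse priors (loadings N(0, 10), intercepts N(0, 32),
  variance parameters Gamma(1, 0.5) on the SD scale), with split-chain
  R-hat and ESS diagnostics.

The measure panel covers the LRT, CFI, TLI, RMSEA, Gamma hat, MFI, AIC,
BIC and SaBIC on the ML side, and their pD-substituted Bayesian analogs
plus the Bayesian LRT, DIC, WAIC and PSIS-LOO on the posterior side.
Decision rules: restricted model kept if the LRT has p ≥ .05, or
dCFI < .01, dTLI < .01, dRMSEA < .015, dMFI < .02, dGH < .001; for
information criteria the smaller value wins. Performance is summarized
as false/true positive rates with binomial acceptance bands and a
full-factorial ANOVA (eta-squared) of the fit-value differences.

## Worked example

```python
import misim as mi

# a strongly intercept-noninvariant condition: 4 items lowered by 0.25,
# focal latent variance 4x the reference, 600 subjects per group
spec = mi.make_population(600, 4.0, 0.0, 4, 0.25, "intercept")
decisions = mi.run_condition(spec, n_reps=50, engine="ml", master_seed=7)
rates = mi.rate_table(mi.decisions_frame(decisions), "noninvariant")
print(rates[["measure", "rate"]].to_string(index=False))
```

prints the true-positive rate of each measure for the metric-vs-scalar
comparison on this condition:

```
measure  rate
    lrt  1.00
    cfi  0.00
    tli  0.00
  rmsea  0.16
    mfi  0.30
     gh  1.00
    aic  1.00
    bic  0.00
  sabic  0.68
```

i.e. with a latent variance ratio of 4 the LRT, Gamma hat and AIC still
detect the intercept noninvariance in every replication, while the
CFI/TLI thresholds and the BIC never do — the heterogeneous latent
variance shrinks the fit-value differences these measures compare. The
same condition with equal latent variances (`lvar_ratio=1.0`) puts every
measure's detection rate near 1.

The same machinery is scriptable from the shell:

```sh
misim run-grid --engine ml --reps 50 --seed 7 --out results/
misim rates results/ --truth noninvariant --out rates.csv
misim anova results/ --side intercept --out eta.csv
```

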
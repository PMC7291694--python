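# Methods

## Model

The core model is a K-class parallel-process latent class growth analysis
of two bounded integer total scores, PHQ-9 (9 items × 0–3, range 0–27)
and GAD-7 (7 items × 0–3, range 0–21), observed at weeks 0, 3, 6, 9, 12.
Visits are coded t = 0…4 rather than in weeks: with only five time points
a quadratic in week units (0–12) produces a badly scaled t² column (up to
144) and a poorly conditioned normal system, while index coding keeps all
design columns O(10).  Week-scale coding is available via
`EMConfig(time_coding="weeks")`.

Each class contributes a fixed quadratic mean curve per outcome
(intercept, slope, quadratic — six growth parameters per class) and a
mixing weight; growth-factor variances are fixed at zero, so within a
class all heterogeneity is residual.  Residual variances are free per
outcome and visit but shared across classes (10 parameters), with a
2-parameter homoscedastic-over-time option
(`var_structure="constant"`).  Residuals are assumed independent across
visits and between the two scales given class ("local independence"); a
within-visit PHQ–GAD residual covariance is deliberately not fitted —
the class structure itself is what induces the marginal correlation
between scales — and adding one is left as an extension rather than a
config switch so the likelihood stays exactly the documented product
form.  Free-parameter count is 6K + (K−1) + #residual variances.

Missing visits arise from monotone dropout.  Under MAR the likelihood
simply omits unobserved cells; no outcome imputation is performed
anywhere.

## Estimation

EM with an expectation/conditional-maximization sweep:

- E-step: posterior class responsibilities from the current parameters.
- M-step: per class and outcome, responsibility-weighted generalized
  least squares of observed totals on (1, t, t²) using the current
  per-visit inverse variances; then mixing weights as mean
  responsibility; then residual variances pooled over classes given the
  new curves.  Each conditional block maximizes the expected
  complete-data log-likelihood, so the observed log-likelihood is
  non-decreasing (asserted iteration-by-iteration in the tests).

Initialization fits per-subject least-squares growth coefficients on the
observed visits (minimum-norm for subjects with < 3 visits), standardizes
and k-means clusters them into K groups; the remaining restarts use
random Dirichlet responsibilities.  Defaults: 20 restarts, each run for
40 short-run sweeps, the best continued to a relative log-likelihood
change below 1e-6 or 500 iterations.  A class weight falling below 1/n
aborts that restart (logged in `n_restarts_triggered`); if no restart
survives, the fit raises.  Non-convergence is returned with
`converged=False` plus a warning, never silently.  A residual-variance
floor of 1e-3 prevents degenerate spikes on (near-)noise-free data.

Classes are relabeled into a canonical order — descending model-implied
baseline PHQ-9 mean, ties broken by baseline GAD-7 mean — so repeated
fits and simulation replications are directly comparable.

## Class enumeration

AIC = −2LL + 2p; BIC = −2LL + p·ln n; SSBIC replaces n by (n+2)/24
(Sclove's adjustment — stated explicitly because the index is often
named without a formula).  Relative entropy is
1 − Σᵢ Σ_c(−p_ic ln p_ic)/(n ln K), with 0·ln 0 := 0; it is undefined at
K = 1 and reported as missing there.

The adjusted likelihood-ratio test divides 2(LL_K − LL_{K−1}), floored
at zero, by the small-sample correction c = 1 + ((p_K − p_{K−1}) ln n)⁻¹
and refers it to a chi-square null.  Because the usual regularity
conditions fail at the mixture boundary, the degrees of freedom follow
Wolfe's rule for mixture LRTs — twice the number of added non-mixing
parameters, here 2 × 6 = 12 per extra class.  A calibration simulation
under 1-class truth (n = 300, 200 replicates) gave a 0–3% rejection rate
at α = 0.05 for this reference (slightly conservative), versus ~13% for
the naive χ²_{Δp} reference, which is why the naive mode exists only as
an explicitly labelled comparison option; an empirical mode that takes
bootstrap null draws is also provided.  The mode used is always recorded
in the result, never silently substituted.

The bootstrapped LRT refits both models to data simulated from the
fitted (K−1)-class solution at the original missingness pattern;
p = (1 + #{boot ≥ observed}) / (B + 1), so p is never exactly zero.
Defaults: 99 replicates for desk-scale runs, 499 recommended for reported
analyses.  Bootstrap refits use the parent solution as one initialization
plus a small number of random restarts, and the observed-data fits inside
`blrt` use the *same* restart budget, so the observed and null statistics
come from the same optimizer and the p-value stays calibrated.  An
optional early stop ends replication once the accept/reject decision at a
given α is settled; the returned p is then a conservative partial-rank
estimate flagged `early_stopped`.

`enumerate_classes` scans K upward and recommends the last K whose
K-vs-(K−1) test is significant before the first non-significant test
(sequential stopping).  The IC-minimizing K per criterion is reported
alongside, and the final choice is explicitly the analyst's — an
interpretability judgement the software does not attempt.

## Covariate preparation and the 3-step regression

Categorical covariates become modal-contrast indicators (age ≥ 36,
female, bachelor-or-higher).  The therapist experience cut is not
standardized in this literature; the default contrasts ≥ 10 years against
fewer, configurable to ≥ 5.  Words-per-week rates are log-transformed;
log(1 + x) is the default because zero word counts occur, with pure
log(x) available — the two are asymptotically identical for the
heavy-tailed rates involved.

Missing covariates are imputed missForest-style: variables in order of
increasing missingness, each fitted with a random forest (classifier for
categoricals/binaries, regressor otherwise; default 500 trees) on all
other covariates and predicted at its missing rows, sweeping until the
normalized change between successive imputations stops decreasing (the
previous sweep is returned) or 10 sweeps.  Variables above ~40%
missingness are refused with a per-variable report.  Outcome and class
variables are never in the predictor set, so no outcome information can
leak into the covariates.  Observed entries are never altered.

The 3-step regression treats the modal assignment W as an error-prone
indicator of the true class T.  From the posterior matrix we form
q_st = mean posterior of class t among subjects modally assigned to s
(rows sum to 1; a diagonal below 0.5 triggers a warning), convert by
Bayes' rule to E[s,t] = P(W = s | T = t), and maximize

    Σᵢ log Σ_t P(T = t | xᵢ; β) · E[Wᵢ, t]

over multinomial-logit coefficients β with E held fixed (L-BFGS with
analytic gradient).  With E = I the objective reduces exactly to a
standard multinomial logit of the modal labels — verified against
statsmodels to 1e-4 in the tests.  Standard errors are Wald, from the
finite-difference Hessian of the analytic gradient at the optimum;
runaway coefficients flag likely separation and mark the CIs unstable.
Swapping the reference class is a pure reparameterization; contrasts are
identical to optimizer tolerance whichever class is the reference.  The
uncorrected modal-label fit is available for comparison (it is the
E = I special case).  A BCH-weighted variant is a possible extension,
not implemented.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes: a
six-class mixture with weights (23.7, 7.0, 22.6, 9.8, 20.0, 16.9)% —
recovery, acute recovery, chronic, elevated chronic, depression
improvement, anxiety improvement — quadratic mean trajectories per class
and scale, Gaussian visit noise (default SD 2.5) rounded and clipped to
the integer scale ranges, monotone dropout with per-interval hazard
0.134 (so (1−h)⁴ ≈ 56% completers), heavy-tailed log-normal words-per-week
covariates moment-matched to a cohort mean near 790 (patients) and 630
(therapists) words with SD/mean ≈ 6, and demographic margins (79%
female, 75% bachelor+, modal age 26–35).

Default trajectory shapes are qualitative: the two remission classes end
below both clinical thresholds with total drops ≥ 5 points, the two
improvement classes improve into the mild range on one scale while
staying moderate on the other, and the two chronic classes stay high.
Baseline PHQ-9 intercepts (21, 18, 16, 14, 12, 10) are evenly spaced so
the canonical class ordering is stable across simulation replicates, and
class means sit ≥ ~1.6 SD from the scale bounds so clipping is rare and
the Gaussian working model is nearly correct.  The residual SD of 2.5
puts the fitted solution's relative entropy near 0.77, inside the
published range of modal-assignment probabilities (.75–.86) for this
model family, and total-score SDs (between-class spread plus residual)
near the 4–5 points typical of these cohorts.

Class membership follows a multinomial logit on (bachelor+, standardized
log patient words, standardized log therapist words); intercepts are
calibrated on the realized covariate draw so marginal class frequencies
match the target weights even with non-zero effects.  Default effect
directions mirror the covariate analysis this pipeline is built for:
education and patient words favor the remission classes, therapist words
the non-remitting ones, with magnitudes around |log OR| 0.3–1.0.
Covariates are masked MCAR at 15% by default (within the ~40% cap the
imputation step accepts).

What the generator does **not** emulate, hence what passing tests do not
establish about real data: item-level response processes (totals are
drawn directly), informative or symptom-dependent dropout (hazard is
class-constant by default; class-dependent hazard is available but
missingness never depends on the unobserved values, i.e. MAR holds by
construction), therapist nesting/clustering, within-visit residual
correlation between the scales, and calendar irregularity of visits.
Marginal reliable-change rates of the default cohort (~25% per scale)
are lower than real messaging-therapy cohorts report (~50%), because the
synthetic improving classes improve more modestly and dropout truncates
observed change; the generator targets class *structure*, not marginal
change rates.

## Numerical choices and problem sizes

EM tolerance 1e-6 relative log-likelihood change; weight floor 1/n;
variance floor 1e-3; k-means plus 19 random restarts by default.  Modal
assignment breaks ties toward the lower class index.  Posterior rows are
validated to sum to 1 within 1e-8.  Simulation studies in the test suite
and acceptance script use desk-scale sizes chosen to keep the whole run
in minutes on one CPU: parameter recovery at n = 5000 (10 seeds in the
suite, 5 in the script), enumeration recovery at n = 500 × 20 seeds,
BLRT calibration at n = 300 with 99 bootstrap replicates (200 seeds in
the suite, 100 in the script, early-stopped at the α = 0.05 decision),
and the LMR calibration at 200 seeds.  Measured behaviour at those
sizes: class-weight median absolute error ≈ 0.005; every individual
growth parameter recovered within ±0.3 score units in the median seed
(worst per-parameter median ≈ 0.2; the single worst of the 360 estimates
across 10 seeds reaches ≈ 0.48, driven by the partial overlap of the two
improvement classes); BLRT type-I error ≈ 5%; enumeration picks the true
K = 3 in ≈ 95% of seeds.

## Known limitations

- The LMR-style test uses a documented chi-square approximation (Wolfe
  df with the small-sample correction), not the exact weighted-chi-square
  mixture null; it is mildly conservative in our calibration.  The BLRT
  is the preferred test when runtime permits.
- Wald CIs only; profile likelihood CIs are out of scope.
- No random growth factors (true growth-mixture models), no more than
  two parallel outcomes, no therapist-level random effects.
- The 3-step correction conditions on the estimated classification
  matrix; uncertainty in Q itself is not propagated.
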
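# symtraj

Parallel-process latent class growth analysis (LCGA) of co-measured
depression (PHQ-9) and anxiety (GAD-7) symptom trajectories over a
12-week course of treatment, with class enumeration, a
classification-error-adjusted 3-step covariate regression, and a
synthetic-cohort generator for fully reproducible end-to-end runs.

The package is aimed at psychotherapy-outcomes researchers who want to
move beyond average pre/post effects and ask *which subpopulations* of
patients improve, stall, or remain symptomatic — and which patient and
therapist characteristics predict membership in those subpopulations.

## The model

Patients are assessed at weeks 0, 3, 6, 9 and 12 (coded t = 0…4) on two
total scores, PHQ-9 (depression, 0–27) and GAD-7 (anxiety, 0–21).  An
LCGA with K latent classes assigns each class *c* a fixed quadratic mean
curve per outcome *o*:

    E[y_iot | c] = i_{co} + s_{co}·t + q_{co}·t²,
    y_iot | c ~ Normal(·, σ²_{ot})

with the growth-factor variances fixed to zero (each class is a curve,
not a distribution of curves), residual variances shared across classes,
and residuals independent across visits and between the two scales given
class.  Classes are defined by the *joint* PHQ-9/GAD-7 pattern (a
parallel-process model).  Estimation is maximum likelihood by EM; missing
visits from monotone dropout contribute nothing to the likelihood (MAR
marginalization).  Model selection compares K = 1…K_max via AIC, BIC,
sample-size-adjusted BIC, relative entropy, an adjusted likelihood-ratio
test and the bootstrapped LRT.  Covariate effects on membership are
estimated with the 3-step maximum-likelihood correction: modal class
assignments are treated as error-prone indicators with misclassification
probabilities fixed from the posterior matrix, so odds ratios are not
attenuated by assignment error.

Scale utilities implement the clinical threshold (total ≥ 10 on either
scale) and "reliable and clinically significant change" (a drop of ≥ 5
points ending below threshold at the last observed visit).

## Worked example

The analysis is organised as numbered drivers over the `symtraj` library:

```bash
python analysis/01_simulate_cohort.py --n 2000 --seed 1
python analysis/02_prepare_covariates.py --trees 100 --max-iter 3
python analysis/03_enumerate_classes.py --kmax 7
python analysis/04_fit_trajectories.py --k 6 --plot
python analysis/05_regress_membership.py --ref 5 --ref 1
python analysis/06_report.py
```

Step 03 prints the fit-index table (BIC and SSBIC both bottom out at the
6-class solution on this cohort):

```
 K     loglik       AIC       BIC     SSBIC  entropy  lmr_p
 1 -42700.712 85433.425 85523.039 85472.206      NaN    NaN
 2 -39925.586 79897.172 80025.993 79952.921    0.843  0.000
 ...
 6 -37820.379 75742.757 76028.403 75866.373    0.771  0.000
 7 -37809.559 75735.118 76059.970 75875.701    0.767  0.047
IC minimizers: {'AIC': 7, 'BIC': 6, 'SSBIC': 6}
```

Step 04 fits the 6-class solution; classes come out in canonical order
(descending baseline PHQ-9 mean), here matching the generating classes
elevated-chronic, acute-recovery, chronic, depression-improvement,
anxiety-improvement, recovery:

```
fitted K=6 (seed 1): loglik -37820.37, converged=True
  class weights: [0.09, 0.085, 0.226, 0.22, 0.15, 0.229]
  relative entropy: 0.771
```

Step 05 prints the error-adjusted odds-ratio table.  With the recovery
class (class 5) as reference, higher education and more patient words per
week protect against the chronic trajectory while more therapist words
accompany it — the direction built into the generator:

```
Ref: class_5
  vs class_0
    bachelor_plus          OR   0.43  95% CI 0.27-0.66  p 0.000161
    log_patient_words      OR   0.77  95% CI 0.69-0.86  p 2.62e-06
    log_therapist_words    OR   1.47  95% CI 1.31-1.64  p 3.93e-11
```

Step 06 aggregates fitted class weights into outcome groups
(`remission 31.3% / improvement 37.1% / chronic 31.6%` on this cohort)
and reports reliable-change rates per scale.

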
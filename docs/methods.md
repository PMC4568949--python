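# Methods

`plasmasig` implements a cross-validated consensus protocol for
discovering and evaluating plasma protein biomarker signatures in a
cancer cohort, together with a synthetic-cohort generator that emulates
the statistical structure such an analysis assumes. This note records the
models, the defaults and the design choices made where the design was
genuinely open.

## The discovery protocol

Input is a proteins × patients matrix of log2 relative abundances and a
clinical table (age, gender, TNM stage and components, grade, tumour
region, overall survival). Five endpoints are supported, each with a
matched regression family:

| endpoint       | kind     | family                          |
|----------------|----------|---------------------------------|
| `survival5y`   | survival | Cox proportional hazards        |
| `localization` | binary   | logistic (colon C18+C19 vs rectal C20) |
| `dissemination`| binary   | logistic (M0 vs M1)             |
| `stage`        | ordinal  | proportional odds (I–IV)        |
| `grade`        | ordinal  | proportional odds (G1–G3)       |

For one endpoint the pipeline: (1) assigns patients to K = 10
endpoint-stratified folds (shuffle within class, deal round-robin; the
survival endpoint stratifies on the death-within-5-years class, with
patients censored before 5 years forming their own stratum); (2) within
each fold, screens all proteins on the training 9/10 by an equal-variance
two-sample t-test on log2 abundances, keeping proteins with
Benjamini–Hochberg adjusted p < 0.05 (strict) and |log2 fold change| ≥
log2(1.1) ≈ 0.1375 — multi-class endpoints run every unordered pairwise
contrast (BH within contrast) and take the union; (3) builds the fold's
model by bidirectional stepwise search over the screened candidates,
adding or dropping one protein at a time while forced clinical covariates
stay in, accepting only moves that strictly decrease AIC = −2ℓ + 2k, with
ties broken towards addition and then lexicographically by protein id;
(4) scores the held-out 1/10 with the fold model's linear predictor.
Proteins present in at least 5 fold models (for both K = 10 and the K = 8
stability variant) form the consensus signature, refit once on the full
dataset.

Clinical covariates (age; gender coded 1 = male, 0 = female; stage coded
1–4 as a single linear term) are forced into survival models only — for
the other endpoints they are available behind a flag, since clinical
factors are established predictors of outcome but not of the other
endpoints. The whole survival pipeline (screen, folds, Cox fitting,
evaluation) operates on stage I–III patients; stage IV is itself the case
group of the dissemination endpoint. Patients censored before the 5-year
horizon are excluded from the differential screen only, never from Cox
fitting or evaluation.

Missing abundances are imputed once, globally, before cross-validation:
each missing value is replaced by the protein's minimum observed value,
read as its limit of detection. A per-fold imputation mode (LOD minima
from training patients only) exists for leakage-sensitivity studies.

## Performance estimation

Cross-validated ("unbiased") performance is the **pseudomedian fold**:
the ⌈K/2⌉-th largest held-out fold AUC — the 5th largest of ten folds,
the 4th largest of eight — an exact order statistic, never an average.
Full-data ("optimistic upper bound") performance re-evaluates the
consensus model on all included patients. Fold-to-fold spread is shown as
the pointwise 25th/75th quantiles of fold sensitivities on a 0.01-step
1−specificity grid (fold ROCs evaluated as right-continuous step
functions; quantiles linearly interpolated between order statistics).

Binary AUCs are trapezoidal areas over all score thresholds and equal the
Mann–Whitney concordance with ties counted ½. Survival endpoints use the
cumulative/dynamic time-dependent ROC at the 5-year horizon with
Kaplan–Meier conditioning:

    sens(c) = (1 − S(t | M > c)) · P(M > c) / (1 − S(t))
    spec(c) = 1 − S(t | M > c) · P(M > c) / S(t)

with S the KM estimate overall and within the high-marker subset. This
estimator is not guaranteed monotone; out-of-range values are clipped to
[0, 1] and flagged. When no patient is censored before the horizon it
reduces exactly to the binary ROC on event-by-horizon labels (a tested
invariant). Ordinal endpoints are summarized by one ROC per unordered
class pair; a fold's scalar AUC is the mean over pairs.

Sensitivity/specificity/accuracy are reported at predicted probability
0.5 for logistic models and at the median linear predictor for Cox models
(the operating threshold is configurable). Their standard errors come
from patient-level bootstrap resampling (default B = 2000), refitting the
coefficients of the *fixed* predictor set on each replicate; replicates
missing a class are redrawn and counted. Bootstrap SEs are provided for
the Cox and logistic families.

## Model fitting

Logistic and proportional-odds (cumulative logit,
logit P(Y ≤ j) = θ_j − βᵀx with strictly increasing θ) fits delegate to
statsmodels. The Cox partial likelihood with the Efron tie correction is
maximized by a damped Newton solver implemented in the package; the
stepwise search inside 10-fold cross-validation over many simulated
cohorts performs thousands of fits, and a dedicated vectorized solver
keeps the whole pipeline interactive. Its coefficients and log-likelihood
are cross-checked against lifelines and against direct numerical
maximization of a naively enumerated partial likelihood in the test
suite. Monotone likelihood and complete separation are never fatal:
coefficients are capped at |β| ≤ 15, the fit is flagged non-converged,
and the fold completes. Nested models are compared by the likelihood-ratio
test, 2(ℓ_full − ℓ_reduced) against chi-square with k_full − k_reduced
degrees of freedom.

## Risk stratification and transfer

The protein risk score is the signature's linear combination of log2
intensities. Patients split into HIGH/LOW groups at the exact median
score of a designated subgroup (by convention stages I–III; even counts
take the midpoint of the central order statistics); HIGH means score ≥
cutoff and the rule applies to every patient, also outside the subgroup.
Group-wise survival is visualized with Kaplan–Meier curves and with Cox
predicted survival S(t|x) = S0(t)^exp(βᵀx), where S0 is derived from the
Breslow cumulative baseline hazard (an accepted mild mismatch with
Efron-tie fitting at this scale).

Transferring a signature to a second dataset always re-estimates
coefficients on the new data with the feature set fixed — no screening,
no stepwise, no coefficient transport — and evaluates with the same
stratified K-fold machinery. Subtype prediction retrains a
proportional-odds model (logistic for two classes) on the signature
features and reports the **median** per-class recall across folds, with
optional Kaplan–Meier curves grouped by *predicted* class.

## The synthetic cohort generator

The generator emulates a 202-patient colorectal-cancer cohort: exact
categorical marginals (stage 43/58/49/52, gender 89 F/113 M, region 131
colon/71 rectal with colon split 4:1 into C18/C19, M 150/52, grade
32/132/30 with 8 missing), assigned by stratified permutation rather than
sampling so configured counts are reproduced verbatim. The only joint
constraint enforced is the logical one (stage IV ⇔ M1); T and N
categories follow stage-conditional draws mimicking the cohort's
cross-tabulation. Age is normal(67, 11.5) truncated to [30, 95].

Protein log2 abundances are Gaussian (mean 0, SD 1) per protein. Planted
effects for group endpoints shift the case group additively (ordinal
endpoints scale the shift linearly with class index); survival effects
enter a Weibull proportional-hazards model, hazard = baseline ×
exp(Σ effect × abundance), with shape 1.2 and per-stage scale set so the
5-year baseline survival is 0.85/0.75/0.60/0.30 for stages I–IV.
Censoring is administrative at 8 years plus exponential dropout at
0.015/year, which yields ~12 patients censored before the 5-year horizon
at default settings. Left-censored missingness removes every value
strictly below a protein's empirical `lod_quantile`.

The generator reproduces the *statistical* structure the analysis needs —
group mean shifts, proportional hazards, exact marginals, left-censored
missingness — but not features of real SRM data such as peptide-level
noise, batch effects, inter-protein correlation, or heavy-tailed
abundance distributions. Tests passing on synthetic cohorts therefore
demonstrate the correctness and calibration of the pipeline's machinery,
not the clinical performance of any real signature.

## Problem sizes and numerical choices

Simulation-based checks use 202-patient, 80-protein cohorts: 20 seeds for
null calibration, 10 seeds for survival-signal recovery, 500 replicates
for likelihood-ratio null uniformity (at n = 300, where the chi-square
approximation of the LR statistic is accurate; at n = 150 the test is
visibly anticonservative with 6 degrees of freedom). Stepwise accepts a
move only if it improves AIC by more than 1e-9, avoiding float-noise
cycling. Newton iterations stop at gradient sup-norm < 1e-7. ROC points
are rounded to 12 decimals before sorting so product-limit float noise
cannot reorder tied specificity values.

A known behaviour worth stating: with six *independent* planted survival
effects, each protein's marginal correlation with the hazard's linear
predictor is at most 1/√6, so the per-fold screen's t-statistics sit near
the BH threshold for 80 proteins regardless of effect magnitude — the
induced case-control separation saturates around 0.6 log2 units as the
magnitude grows. Consensus recovery of all six planted proteins is
therefore intrinsically unreliable in this regime (typically 2–6 of 6
per seed), while the cross-validated AUC remains high because the
recovered subset already carries most of the predictable signal. Real
signature proteins co-vary, which would raise marginal detectability;
the generator deliberately keeps proteins independent.
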
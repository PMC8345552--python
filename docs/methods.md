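# Methods

## Scope and data model

The package analyses one flat patient table: overall-survival time in
months (follow-up horizon 150 months), a death indicator, examined and
positive lymph-node counts, and the clinicopathological covariates of the
adjusted model (age, sex, T category, grade, tumor size, location,
neoadjuvant flag), plus seven boolean exclusion flags (metastatic
disease, incomplete histopathology, positive margins, death within 30
days, emergency surgery, lost to follow-up, polyposis/IBD). Filtering
retains records with all flags false; a record with several flags is
tallied once under the first flag in that order, so tally plus retained
always equals the input size. The ordering convention is an artifact
decision — overlap between exclusion categories in a real registry is
rarely documented.

Missing covariates are singly imputed: continuous columns by the column
median (even counts: mean of the two central order statistics),
categorical columns by the mode with ties broken by the declared category
order (G1<G2<G3<G4, etc.). Simple imputation is adequate here because
missingness in the emulated setting is sparse (grade ≈1.7%) and the
package's inferential target is discrimination, not covariate effects.

UICC stage: any nodal involvement (pLN ≥ 1, or the N1c
tumor-deposits-without-positive-nodes flag) is stage III; otherwise T1/T2
is stage I, T3/T4 stage II. The N1c patient keeps pLN = 0 in LNR/LODDS
but is categorised N1 and tagged, so stage-III subsets retain it.

## Nodal metrics

LNR = pLN/NELN in [0,1]. LODDS = ln((pLN+0.5)/(NELN−pLN+0.5)) — natural
logarithm throughout. Several cut-off publications do not state their log
base; the shipped LODDS cut-offs (−3…+3) are only attainable on NELN ≤ 68
under the natural log, which fixes the convention here. Schemes loaded
from config may record a different base in their metadata, but no
conversion is applied. The 0.5 terms are the empirical-logistic
continuity correction; they keep LODDS finite at pLN ∈ {0, NELN} and give
the antisymmetry lodds(p, n) = −lodds(n−p, n).

## Classification schemes

A scheme is an ordered partition of the LNR ([0,1]) or LODDS (ℝ) axis
into interval classes with explicit bound closures; validation rejects
overlaps, gaps and incomplete coverage. Seven published fixed-cut-off
schemes ship with the registry; two required repair to form a partition,
recorded in their metadata:

* *LNR Fortea-Sanchis* prints 0–0.24 / 0.25–0.60 / >0.60. The
  (0.24, 0.25) gap is read as two-decimal rounding of a 0.25 boundary:
  [0, 0.25), [0.25, 0.60], (0.60, 1]. LNR is continuous, so a genuinely
  unassigned (0.24, 0.25) band cannot have been intended.
* *LODDS Bagante* prints class 3 as ">0.9; ≤1.5" directly after class 2
  "≥−2; ≤−0.9" — read as a sign slip for >−0.9, else (−0.9, 0.9] is
  unassigned.

The cohort-quantile LODDS scheme cuts at the empirical 25th/50th/75th
percentiles (linear interpolation between order statistics; the
definition is stored in scheme metadata since percentile conventions
differ across software). It is re-fitted once per analysis cohort and
reused in subgroups, not re-cut per subgroup. User-defined schemes load
from YAML/JSON and face the same invariants; a printed gap can be closed
explicitly with `repair: extend_left`.

## Survival models

Kaplan–Meier estimation and the Mantel–Cox log-rank test are delegated to
lifelines. The Cox proportional-hazards fitter is implemented in-package:
Newton–Raphson on the partial likelihood with analytic gradient and
Hessian, Efron tie handling by default (Breslow available), convergence
at relative log-likelihood change < 1e−9, cap 50 iterations,
step-halving on any decrease, and the linear predictor clipped at ±200
so monotone-likelihood divergence stays finite. Monotone likelihood
(complete separation) and non-convergence are flagged on the fit object,
never returned silently; zero-variance columns are dropped with a
recorded warning. Wald 95% CIs use z = 1.959964 on the log scale. The
in-package fitter exists because the comparison machinery needs exact
control of tie handling (the duplicated-data standard-error identity is
exact only under Breslow) and of convergence tolerances; lifelines serves
as an independent cross-check in the test suite, never as the
implementation.

The adjusted base model uses six indicators: age ≥ 70, male, tumor size ≥
median, G3+G4, T3+T4, rectum. The size median is recomputed on each
analysis cohort (including each subgroup) before dichotomisation.
Scheme-class and N-category indicators always contrast against the lowest
occupied class. A class left empty by a subgroup is merged into the
adjacent lower class (the lowest class, if empty, merges upward so the
reference is the lowest occupied class); merges are recorded on the
report row rather than dropping subjects.

`logrank_power` implements the Schoenfeld events formula
D = (z₁₋α/₂ + z₁₋β)² / (p(1−p)·(ln HR)²), giving D = 256 events for
HR 1.5, two-sided α 0.05, power 0.90, 1:1 allocation. Published
sample-size statements for this design sometimes quote smaller event
counts derived from unstated accrual/follow-up assumptions; only the
standard formula is implemented.

## Discrimination and comparison

Harrell's C treats a pair as comparable when the earlier observed time is
an event; an event tied in time with a censoring compares against the
censored subject; two events at the same time are incomparable (the
standard Harrell convention — the main alternative, crediting ½, differs
only on tie-heavy data). Higher risk score ⇒ earlier failure, matching
the Cox linear predictor orientation; tied scores credit ½.

ΔC between two models on the same subjects gets a jackknife variance:
the leave-one-out differences d⁽⁻ⁱ⁾ are computed exactly in O(n²) by
subtracting each subject's pair contributions from the full-sample
concordant/comparable tallies, then var = ((n−1)/n)·Σ(d⁽⁻ⁱ⁾−d̄)², with a
normal 95% CI and two-sided p. The same leave-one-out machinery provides
the CI of a single C. Self-comparison reports SE 0 with note
"identical"; SE 0 with nonzero delta is flagged degenerate.

Benjamini–Hochberg FDR is applied within one family: the schemes compared
against the N category inside one analysis cohort; subgroups are separate
families. The implementation takes an explicit family size m ≥ len(p)
because family members can be reported elsewhere.

Landmark ROC at horizon h: cases died at ≤ h, controls followed beyond h,
subjects censored at ≤ h excluded; AUC is the Mann–Whitney probability
with midrank ties. Exclusion (rather than IPCW reweighting) matches
plain-ROC reporting practice and is a documented limitation: with
horizon-dependent censoring the estimate is biased toward the
informatively censored. ROC tables score both the continuous metrics
(LNR, LODDS, pLN, −NELN) and each scheme's ordinal class index, covering
both reporting conventions.

## Synthetic cohort generator

The generator's defaults *are* the emulated study conditions; they are
fixed once and not per-analysis dials.

* **Categorical marginals** (stage 171/232/251 of 654; T within stage;
  male 55.7%; location with 36.5% rectum; grade with 1.7% missing;
  neoadjuvant 9.8%) are allocated as exact largest-remainder counts and
  shuffled independently, so the default cohort reproduces the published
  marginal counts exactly while remaining random in its joint structure.
  Stage-independent covariates are generated independently of stage;
  real cohorts show mild dependence (e.g. more rectal cancers in stage
  I), which the generator does not emulate.
* **Node counts.** NELN = 2 + NegBin(mean 17, size 3) clipped to [2, 68]
  (median 17; the printed 2–68 range constrains the clip, the published
  median the location; the family is a standard overdispersed count
  choice). Stage-III pLN = 1 + NegBin(mean 2.8, size 0.45) capped at
  NELN (median 2); stage I/II have pLN = 0. One stage-III record per
  cohort is optionally converted to N1c (pLN = 0, flag set) to exercise
  that path.
* **Hazard.** Exponential baseline (constant rate 0.0015/month) times
  exp(linear predictor) with default log-hazards taken from the emulated
  study's adjusted model — age ≥ 70: ln 3.32, male: ln 1.23, size ≥
  median: ln 1.32, G3+G4: ln 1.69, T3+T4: ln 1.43, rectum: ln 1.46 — plus
  a log-linear LODDS effect (0.35 per LODDS unit, centred at −2) so that
  every classification scheme induces ordered risks. Null configurations
  route the nodal effect through N-category indicators instead.
* **Censoring.** Administrative at 150 months combined with a uniform
  potential-follow-up cap on (0, 264] months — the shape staggered
  accrual against a fixed database-closure date produces. The baseline
  rate is calibrated so the default configuration yields ≈252 events per
  654 patients (realised means ≈252 over replicate seeds). No published
  censoring mechanism exists to copy; this is an artifact choice.

Identical seed and configuration give a byte-identical CSV.

What passing tests on these cohorts do **not** show: robustness to
non-proportional hazards, covariate-dependent censoring, measurement
error in node counts, or the joint covariate dependencies of real
registries. The generator supports the machinery's correctness claims,
not clinical claims.

## Verification strategy

Every statistic has an independent oracle in the test suite: Harrell's C
against exhaustive pair enumeration and jackknife ΔC against full
leave-one-out recomputation (exact agreement on 1000 random small
cohorts); the Cox fitter against direct 1-D partial-likelihood
maximisation (1e−6), against lifelines on tied data, and against the
classical identities (duplicated-data SE/√2 under Breslow; score test at
β = 0 equal to the log-rank statistic on tie-free data, 1e−8); BH-FDR
against statsmodels; KM against hand product-limit values.

Parameter recovery refits the *generating* design (base indicators plus
the continuous LODDS term) on an n = 20 000 cohort and requires every
log-hazard within ±0.05. The companion check words the recovery through
the six-covariate base model alone and therefore switches the LODDS
effect off — Cox hazard ratios are non-collapsible, so refitting a model
that omits a generated effect is biased even asymptotically and would
test the wrong thing. Recovery runs use a no-missingness configuration:
mode-imputing deliberately blanked grades induces a small attenuation
that belongs to imputation behaviour, not estimator correctness.

Type-I control of the whole claim pipeline is checked by simulating 50
cohorts whose hazard depends on nodal status only through the N category
and requiring that essentially no replicate (≥95%) yields a scheme with
positive ΔC at FDR-adjusted p < 0.05 in the stage-III subgroup.

Problem sizes used by the default suite — 654-patient cohorts, one
20 000-patient recovery cohort, 50 null replicates, 1000 oracle
instances — were chosen as the smallest sizes at which each property is
sharp.

## Known limitations

* Landmark AUC uses exclusion, not IPCW (above).
* The jackknife ΔC relies on asymptotic normality; in very small
  subgroups with few events the CI is approximate and degenerate cases
  are only flagged.
* Sparse top classes (e.g. the highest LODDS class in a 251-patient
  subgroup) can produce monotone likelihoods; such fits are flagged and
  their report rows carry `converged = False` rather than being dropped.
* Scheme cut-offs from the literature are reproduced as printed (after
  the two documented repairs); no attempt is made to resolve the
  underlying publications' ambiguities.
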
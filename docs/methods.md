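# Methods

## Model

The core object is a naive-Bayes network over a binary outcome Y
(any cardiovascular hospitalization within one year) and 31 risk-factor
nodes, each a child of Y.  Scoring a patient with evidence E on any subset
of variables uses the log-odds update

    logit P(Y=1|E) = logit P(Y=1) + Σ_i log LR(x_i),
    LR(x) = P(x|Y=1) / P(x|Y=0).

Conditional independence given Y makes the marginalization of unobserved
variables exact (their likelihood terms sum to one), so missing data need
no imputation and every patient is scorable — a row with nothing observed
scores at the prior.  This assumption is also the model's main structural
limitation: correlated risk factors (e.g. diabetes, glucose and eGFR) each
contribute their full marginal likelihood ratio, which can overstate the
joint evidence.  The log-odds accumulation is numerically stable for any
number of extreme ratios; CPT smoothing keeps every ratio finite.

## Parameter compilation

Knowledge enters as per-study effect sizes.  The pipeline is:

1. **Filtering.**  Studies with follow-up under one year, and studies of
   pediatric, renal-replacement-therapy or other-disease populations, are
   excluded.
2. **Pooling.**  Fixed-effect meta-analysis on the log scale with
   normalized sample-size weights: pooled log effect = Σ (n_i/Σn_j)·log ES_i.
   Mixed measures within one variable state are rejected rather than
   silently converted.  Log-scale pooling is standard meta-analytic
   practice for ratio measures.  Confidence intervals are carried in the
   record type but do not enter the weights by design (sample-size
   weighting, not inverse-variance, is the compilation rule here).
3. **Inversion to CPTs.**  For each non-reference state with pooled odds
   ratio w, outcome prior p and state prevalence q, the pair
   a = P(state|Y=1), b = P(state|Y=0) solves the margin constraint
   q = p·a + (1−p)·b together with odds(a)/odds(b) = w — a quadratic in b
   whose admissible root lies in (0,1).  Risk ratios invert linearly via
   Bayes' rule (a = rr·q / (1−q+rr·q)); hazard ratios are treated as risk
   ratios over the one-year horizon, a good approximation at 2–4% annual
   incidence.  Infeasible combinations (an implied conditional risk above
   one, or non-reference conditional mass exceeding one) raise a distinct
   infeasibility error naming the constraint.
4. **Reference state and smoothing.**  The reference state takes the
   remaining mass in each column; columns then receive additive smoothing
   (ε = 1e-6, renormalized) so no cell sits on {0,1} and all
   log-likelihood ratios are finite.

Multi-state variables are handled state-wise against the reference state,
matching how categorical risk factors are reported in the literature.

## Default configuration

The packaged evidence table (`data/synthetic_evidence.csv`) is **synthetic**:
effect sizes in the range reported by observational CKD cohort studies,
with multi-study entries for several variables so the pooling path is
exercised.  It is a stand-in for a curated pooled-evidence supplement, not a
reproduction of one; the compiled default model is therefore internally
consistent and clinically plausible but not a published parameter set.

Key defaults, all editable in `data/default_variables.json`:

* **Outcome prior 0.03** — between typical observed one-year cardiovascular
  hospitalization incidences in CKD registry (≈0.02) and protocol-cohort
  (≈0.04) settings; a deployment parameter, not a fitted value.
* **Cut-points** — KDIGO G-stages for eGFR (15/30/45/60/90 ml/min/1.73 m²),
  KDIGO albuminuria categories for the combined ACR / 24-h urine-protein
  node (ACR 3/30 mg/mmol; urine protein 0.15/0.5 g/24 h as an alternative
  measurement channel onto the same A1–A3 states), conventional clinical
  bins elsewhere (e.g. BMI 18.5/25/30/40, SBP-free lipid bins 40/60 and
  100/160 mg/dl, PTH 65/300 ng/l).  Binning is half-open: a value exactly at
  a cut-point belongs to the upper bin.
* **State prevalences** — marginals for an elderly NDD-CKD clinic
  population (diabetes 40%, hypertension 80%, median eGFR in G3b, etc.).
* **Reference states** — the modal clinical category per variable (G3b for
  eGFR, age 65–74), so literature effects are read as contrasts against the
  typical patient.

## Explanation metrics

Impact uses the normalized likelihood NL(e) = P(e|Y=1)/P(e)
= P(Y=1|e)/P(Y=1), computed per observed item and sorted descending; NL>1
is risk-increasing, NL<1 protective.  Value of information for an
unmeasured X is I(Y;X|E) in bits (base 2), computed from the
posterior-weighted mixture of X's CPT columns; it is non-negative and zero
iff X is conditionally independent of Y.  VOI is myopic (one variable at a
time), matching its use for prioritizing the next test.  Two indexing
conventions are implemented and recorded in every report: division by the
top VOI (top entry = 1.0) or by the residual entropy H(Y|E) (fraction of
remaining uncertainty removed); the ranking is identical under both.

## Comparator scores and evaluation

Equation-based calculators are shipped as JSON term lists (coefficient ×
product of identity/log-transformed inputs, optional gating on treatment
status, per-stratum baseline survival): published coefficients for the 2008
Framingham general-CVD profile and the 2013 pooled-cohort ASCVD equations
(white strata), and a synthetic INDANA-style reconstruction
(`synthetic_indana.json`) preserving that calculator's input set and
directionality.  Constants are data, not code; the tested surface is
structural (centering, monotonicity, stratification, computability), and
the ten-year scores are used as rank-order predictors of the one-year
endpoint without recalibration.

Evaluation implements the Mann–Whitney AUC (ties half-counted) with DeLong
structural-component variance, the paired DeLong test, and a fixed-order
procedure: non-inferiority first (one-sided 95% lower confidence bound on
ΔAUC above −0.05; a variant bounding the new score's AUC alone is available
behind `ci_on="auc_new"`), superiority only afterwards (point ΔAUC ≥ 0.05
*and* DeLong p < 0.05 — the conjunction is what makes a small but highly
significant deficit "significant yet not superior").  Calibration uses
stable-rank quantile bins (ties cannot empty a bin; sizes equal ±1) with
adjacent risk ratios, NaN-flagged when a denominator incidence is zero.
Incidence density uses exact Poisson limits,
χ²(α/2, 2k)/2T to χ²(1−α/2, 2k+2)/2T, with a zero lower limit at k = 0.

## Simulation

`simulate_cohort` reads the network generatively: Y ~ Bernoulli(prior),
then each variable's state from the CPT column given Y.  Missingness is
MCAR per variable, seeded independently of the sampling stream; presets
encode a heavily incomplete registry ("euclid-like": discretionary
biomarker panels 40–70% missing, research assays absent, demographics and
coded comorbidities complete) versus an almost complete protocol cohort
("gckd-like": ≤5% except research assays).  The presets are qualitative
patterns, not any cohort's measured rates.  What simulated cohorts share
with real registry data: the marginal prevalences, effect directions,
outcome rate and missingness burden.  What they do not: between-covariate
correlation beyond that induced by Y (the data are generated under the
model's own independence assumption), visit structure, and
informative (MAR/MNAR) missingness.  Passing self-consistency tests
therefore demonstrates internal correctness of inference and compilation —
not external validity on real cohorts, which requires real data.

## Numerical choices and problem sizes

* Quadratic root selection: the root in (0,1) whose companion probability is
  also interior; both constraints verified to 1e-10 in tests.
* CPT smoothing ε = 1e-6; tables validated to 1e-12 column sums.
* Entropies in bits; VOI clipped at zero to absorb −1e-16-scale rounding.
* Degenerate DeLong comparisons (identical scores) return p = 1 by
  convention; zero-variance nonzero deltas return p = 0.
* Self-consistency checks run at 50,000 patients (CPT recovery within 3
  binomial SEs) and 20,000 patients (per-quintile |predicted − observed| <
  0.015); oracle-equivalence checks use 100 random models of up to 8
  variables × 4 states against full-joint enumeration at 1e-12.  These
  sizes give Monte-Carlo noise comfortably below each tolerance.

## Known limitations

* Conditional-independence double counting for correlated risk factors.
* The exact effect→CPT conversion used by any particular published
  compilation may differ; the inversion here is declared and swappable.
* HR≈RR is only safe for rare outcomes over short horizons.
* Comparator coefficient files are reference data transcribed from their
  publications (or, for INDANA, synthesized); they are not re-validated
  here.
* MCAR-only missingness; no MAR/MNAR stress testing.
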
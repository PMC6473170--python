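# Methods

## Exposure reconstruction

Each firefighter's environmental exposure over a deployment is the sum over
calendar days of the day's active-firefighting hours divided by 24,
multiplied by the time-share-weighted mean PM2.5 over the areas worked that
day:

    env = Σ_day (hours_day / 24) · Σ_area frac_area · PM2.5(area, day)

in µg/m³·day-equivalents. Calendar arithmetic is in whole days with
intervals inclusive of both endpoints, matching the day-level resolution of
deployment questionnaires; a shift spanning midnight is booked to the day it
started. Missing grid cells are hard errors naming the area and date —
silent imputation would corrupt the exposure estimate. The exact rule for
combining area time shares with day-level PM2.5 is a design choice of this
package: the product-of-weights form above is the natural reading of
"proportion of time in each area times length of each shift" and is the
documented convention here.

The task smoke factor is the task-time-weighted mean of per-task smoke
weightings on the 1–5 visible-smoke scale. Only the two endpoints are
published cohort means — patrolling 2.7 and actively attacking 4.1 — so the
default table places the remaining four tasks on that interval by judged
smoke proximity (overhauling hotspots 3.8, backburn 3.6, protection of
unburnt areas 3.1, driving/operating 2.9). These four values are
package defaults, not published estimates, and are configurable.

The composite exposure index is `E = env · task_factor / 1000`; the /1000
keeps the index at order 1–100. The all-deployments total is environmental
only (no task weighting), since detailed task information is collected for
the first deployment alone.

## Protection indices

The RPE use quotient aggregates, per task, the fraction of time a device
was worn, the adequacy of mask/filter changes, and the device's assigned
protection factor (PF):

    R = Σ_task frac_task · worn_task · adequacy_task · (1 − 1/PF_task)

The published anchors are a score of 0 for a firefighter who never used
protection and 1 for SCBA used correctly throughout; the multiplicative
per-task form is a reconstruction chosen to satisfy both anchors while being
monotone in each input. Two conventions make the anchors exact: SCBA, being
supplied-air, takes `(1 − 1/PF) = 1` (PF = ∞), and a device class of "none"
takes PF = 1. Default PFs (dust mask 3, half-face 10, full-face 50) are
conventional assigned protection factors and configurable; the categorical
change-frequency answer maps to adequacy through a documented lookup
(never 0, rarely 0.25, sometimes 0.5, often 0.75, as-recommended 1), since
only the fact that change frequency enters the quotient — not the mapping —
is fixed by the study design.

SEMI is the count (0–3) of hygiene opportunities available: washing during
breaks, showering between shifts, clean clothes. A missing answer is an
explicit error and the subject is dropped downstream (complete-case).

## Urinary 1-HP handling

Processing order is fixed and exposed only as a single composite entry
point (`process_samples`): censoring substitution on the µg/L scale, then
creatinine correction, then creatinine-range exclusion. Reversing
substitution and correction would give different (wrong) values, so the API
does not permit it.

* Below-LoD values are replaced by LoD/√2; below-LOQ (detected but not
  quantifiable) by LOQ/√2. The LOQ rule extrapolates the LoD rule. Default
  thresholds are 0.0099/0.0198 µg/L, chosen so the substituted values round
  to 0.007 and 0.014 µg/L; both are configurable since assay limits differ
  between laboratories.
* Creatinine correction: `ng/g = (hp µg/L × 1000) / (creatinine mg/dL × 0.01)`.
* Exclusion: creatinine < 30 or > 300 mg/dL, strict inequalities — the
  boundary values are retained.

## Statistical analysis

OLS fits use statsmodels; confidence intervals use t rather than normal
quantiles because the subgroups of interest are small (tens of subjects).
Singular designs raise an error naming the collinear terms (identified by
rank-revealing QR) rather than silently dropping columns. Smoking enters as
current/ex dummies with never-smoker as reference; fire service as B/C
dummies with service A as reference. Complete-case handling throughout:
subjects missing a model term are dropped with a logged reason.

Subgroup selection applies criteria sequentially (single deployment →
minimum 24 deployed hours → firefighter role → non-smoker → collection
delay cap → first-week start) and logs per-criterion attrition so
`in = out + excluded` at every step. Collection delay is
`collection_date − end of last deployment` in whole days; "within 48 h"
means delay ≤ 2 days, the finest resolution the questionnaire supports.
The first-week window defaults to 2016-05-02 through 2016-05-07.

The test for linearity across SEMI levels is a linear-trend contrast: levels
are treated as ordered scores 0–3, contrast coefficients are the centred
scores, the contrast is evaluated on group means, and its standard error
uses the pooled within-group variance with N − k degrees of freedom.
Whether the original analysis used this contrast or a regression-on-score
comparison is not determinable from the published description; the contrast
construction is the implemented choice. Degenerate inputs are handled
explicitly: identical data in all groups give ANOVA F = 0, p = 1, and a
zero within-group variance in the trend test returns t = 0, p = 1 when the
contrast is zero.

## Synthetic cohort generator

The generator emulates the three inputs — cohort, PM2.5 grid, urine
samples — under a severe urban-interface wildfire scenario. The
exposure→excretion link is a two-compartment first-order elimination model:

    C(t) = D_inh·[a_inh·2^(−t/T_fast) + (1−a_inh)·2^(−t/T_slow)]
         + D_skin·[a_skin·2^(−t/T_fast) + (1−a_skin)·2^(−t/T_slow)]
         + baseline + confounder effects,   all × mean-one lognormal noise

    D_inh  = w_inh · E · (1 − R)
    D_skin = w_skin · E · (1 − m_skin · SEMI/3)

Key parameters, defaults and rationale:

| parameter | default | units | rationale |
|---|---|---|---|
| T_fast | 1.5 | d | fast-phase urinary half-life of 1-HP (literature: 1–2 d) |
| T_slow | 16 | d | slow-phase half-life (literature single-subject estimate) |
| a_inh | 0.8 | — | inhaled dose excreted mostly in the fast phase |
| a_skin | 0.3 | — | dermal uptake peaks later; slow phase dominates |
| w_inh, w_skin | 0.5, 0.5 | — | relative route contributions are not quantified for firefighters; an even split is the declared free choice |
| m_skin | 0.8 | — | full hygiene access removes most, not all, dermal dose |
| pm25_base, pm25_decay | 300, 0.03/d | µg/m³ | severe early phase decaying over the two-month window |
| baseline | 0.05 | µg/L | background population 1-HP |
| beta_smoke / bbq / otherfire | 0.15 / 0.02 / 0.05 | µg/L | additive confounder effects sized so creatinine-corrected effects land in the tens of ng/g |
| sigma_noise | 0.4 | — | ≈40% CV, typical combined assay and biological spread |
| creat_mu, creat_sigma | ln 120, 0.5 | mg/dL | spot-urine creatinine; tails fall outside [30, 300] so the exclusion rule is exercised |
| p_multi_deployment | 0.45 | — | mix of single- and multi-rotation subjects |
| delay range | 0–16 | d | populates both the ≤2 d and ≤14 d strata |

The noise is parameterized mean-one (`exp(σZ − σ²/2)`), so the noise-free
concentration is also the conditional mean — this is what makes the
parameter-recovery target well-defined: with hygiene assigned independently
of everything else, the OLS coefficient on SEMI converges to the cohort
mean of `−(m_skin/3)·w_skin·E_i·k_skin(t_i)` on the corrected scale.

What the generator deliberately does **not** emulate: real spatial PM2.5
interpolation (cells are independent lognormal scatter around a decaying
trend); the strong real-world confounding between deployment timing,
exposure level and hygiene access (hygiene is independent here, which is
what makes the type-I-error property testable); ingestion as a separate
route; and within-deployment day-to-day task variation. Passing tests
therefore demonstrate that the pipeline recovers effects under its own
generative assumptions — not that those assumptions describe any real
cohort, whose coefficients cannot be reproduced without the raw data.

## Problem sizes

The power and type-I studies use 200 replicates of 500-subject cohorts per
arm; the CI-coverage study uses 200 replicates of 1000 subjects. These
sizes give binomial standard errors of about 1.5 percentage points on a 5%
rejection rate, small enough to separate nominal behaviour from failure
modes while keeping the default suite fast on a single CPU.

## Known limitations

* The RPE quotient's exact published construction is unavailable; the form
  here is a documented reconstruction satisfying the printed anchors.
* The two-compartment constants are literature-cited half-lives, not fitted
  pyrene kinetics; no enterohepatic or tri-phasic behaviour is modelled.
* Hours are self-reported and normalized by 24; no within-day exposure
  profile exists at questionnaire resolution.
* Creatinine correction is the only dilution adjustment offered (no
  specific gravity or osmolality alternatives).
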
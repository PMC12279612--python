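# Methods

This note documents the models implemented in `rxnet`, the conventions
chosen where the analysis design was genuinely open, the synthetic
data-generating process (DGP) used for validation, and the numerical
choices that matter for reproducing results.

## Shared-patient network

Nodes are physicians; for each patient the encounter sequence is ordered
by date (same-day ties broken by physician id), consecutive runs with the
same physician are collapsed to one visit block, and each adjacent pair of
distinct physicians whose visit dates differ by at most `window_days`
(default 30, inclusive: a gap of exactly 30 days qualifies) increments
that pair's edge weight by 1. Conventions worth flagging because claims
data do not dictate them: the same-day ordering rule, the run-collapsing
rule (a revisit must not break an A…B adjacency), and the inclusive
window. All are deterministic and tested against a brute-force pair
enumerator.

Positional measures are computed on the largest connected component
(ties between equal-sized components broken by the lexicographically
smallest member id):

* **strength** `s_i = Σ_j w_ij` and **degree** on the full graph;
* **closeness** `(n−1)/Σ_j d_ij` with Dijkstra distances over edge
  lengths `1/w_ij`. On weighted graphs pairwise distances can be below 1,
  so closeness may exceed 1; values are reported as computed, not
  clamped.
* **betweenness** `Σ σ_st(i)/σ_st`, normalized by `2/((n−1)(n−2))`, on
  the same distances;
* **eigenvector centrality** by power iteration on the weighted
  adjacency to relative tolerance 1e−10, scaled to unit maximum entry.
  The iteration runs on `A + cI` with `c` the maximum row sum: this
  leaves the principal eigenvector unchanged (exactly, including under
  uniform rescaling of all weights) while damping the ±λ oscillation of
  bipartite-like graphs;
* **Barrat clustering**
  `c_i = (1/(s_i(k_i−1))) Σ_{j<h} (w_ij + w_ih) a_ij a_ih a_jh`,
  defined 0 for degree ≤ 1; equals the binary clustering coefficient when
  all weights are equal (the pair sum counts each ordered pair once,
  i.e. each unordered pair contributes `w_ij + w_ih`);
* **volume**: distinct patients encountered over the study window (not
  encounter count).

Descriptive tables rescale betweenness and eigenvector by 1e5 for
readability; models always use raw values. For modeling, network measures
and volume are divided by their sample SD (ddof = 1, computed over LCC
physicians, **not** mean-centered), so coefficients are per one-SD change.

## Prescription states and transitions

All times are integer days; intervals are half-open `[start, end)`. Each
fill covers `[fill_date, fill_date + days_supply)`. Two exposure modes:

* `union` (default): overlapping or abutting same-group coverage is
  unioned — an early refill does not stockpile supply. This is the
  conservative exposure reading.
* `extension`: supply left when a refill arrives is queued, extending
  coverage.

The patient's state at a day is the set of groups with active coverage —
one of 8 states in canonical order zero, O, B, S, OB, OS, BS, OBS (bit
masks O=1, B=2, S=4). Timelines start in state zero by construction; a
fill active on day 0 contributes an initial zero→state transition dated
day 0. Refills that re-enter the same state are not transitions, so the
diagonal of the count matrix is structurally zero; rows with no observed
transitions have undefined (NaN) probabilities rather than zeros.
Patients with no fills are outside the analysis cohort.

Responsibility: an addition is attributed to the prescriber of the fill
of the added group starting on the transition date; simultaneous
additions by different prescribers are resolved by the priority O > B > S
and flagged ambiguous; a pure lapse is attributed to the patient's most
recent prescriber at or before the lapse (stopping a drug triggers no
claim). A transition that adds and drops simultaneously is attributed to
the prescriber of the added drug.

OBS spells: one duration record per maximal OBS segment; censored iff the
segment reaches the end of follow-up; the responsible physician is the
attribution of the entering transition. The opioid-focused table keeps
only O → {OB, OS, OBS} (outcome 1) and O → zero (outcome 0); sideways
moves such as O → B belong to neither outcome and are excluded.

## Regression stages

1. **Multinomial transition model.** Each starting drug count is fitted
   as a separate model over its three admissible ending counts, reference
   = lowest count (from zero: 1-drug prescribing, matching the
   convention of reporting 2- and 3-drug prescribing against 1-drug).
   Default estimation is a fixed-effects multinomial logit with
   physician-cluster-robust standard errors (statsmodels MNLogit).
   With `random_effects=True`, crossed normal patient and physician
   intercepts — shared across outcome categories, matching the generator
   — are integrated out by a Laplace approximation: an inner Newton solve
   for the joint mode over (β, θ, γ) and an outer Nelder-Mead search over
   (log σ², log τ²) of the Laplace marginal. Per-category intercepts with
   crossed per-category random effects would square the latent dimension
   for little testable gain; the shared-intercept form is the documented
   choice.
2. **Opioid-focused logistic.** Physician random intercept only (patients
   average fewer than two such transitions, so patient clustering is not
   modeled). Estimated by maximum likelihood with 21-point Gauss-Hermite
   quadrature per physician cluster and analytic gradients; standard
   errors from the numerical Hessian at the optimum. Cross-checked in the
   test suite against `lme4::glmer` (nAGQ=25) to 0.02 on coefficients.
3. **Cox time-to-discontinuation of OBS.** Model 1 is a standard partial
   likelihood fit (statsmodels PHReg), Breslow tie handling by default —
   day-resolution data produce many ties — switchable to Efron. Model 2
   adds crossed log-normal patient and physician intercepts via penalized
   Breslow partial likelihood, variance components profiled by the same
   Laplace strategy; non-convergence is flagged and Model 1 results are
   attached. Cross-checked against lifelines' Cox implementation.

Throughout: Wald 95% CIs and p-values, no multiple-testing adjustment;
exponentiated effects (OR/HR) reported beside coefficients; AIC = 2k −
2·logLik. Age enters linearly in years. Specialty dummies use Primary
Care as the reference; a predictor with no variation within a stage's
rows (e.g. no Neurology prescriber among its responsible physicians) is
dropped from that fit and recorded in the result. The optional
closeness×volume interaction is the product of the standardized columns.

## Synthetic data-generating process

The generator emulates the four claims tables with the statistical
structure of the fitted models so that estimation is falsifiable:

* **Rosters.** Specialty drawn from {Primary Care, Emergency Medicine,
  Neurology, Psychiatry, Other} with configurable proportions (defaults
  40.47/15.35/2.54/3.24/38.40%); age = 65 + Gamma(2, 4.2) rounded
  (median ≈ 72); sex female 65.62%; race White/Black/Other
  86.25/8.64/5.11%. These defaults mirror a large Medicare cohort's
  descriptives without claiming realism beyond them.
* **Encounters.** Each patient draws Poisson(`encounter_rate`) visits;
  consecutive gaps are ≤ `gap_short_max` days (default 30) with
  probability `short_gap_fraction` (default 0.8), else up to
  `gap_long_max`; physicians are drawn from the patient's home community
  with probability 1 − `mixing`, else uniformly, inducing community
  structure in the derived network.
* **Two-pass prescribing.** Because the models' predictors are functions
  of the observed network, encounters are generated first, the network
  and SD-standardized measures are computed, and prescribing is simulated
  conditional on the realized measures (restricted to LCC physicians,
  mirroring the analysis cohort). At each encounter the patient's next
  drug count is drawn from the 3-category multinomial logit with the true
  coefficients applied to the patient's covariates and the encountering
  physician's measures, plus N(0, σ²) patient and N(0, τ²) physician
  intercepts shared across categories. Coefficient vectors are keyed
  "cat2"/"cat3" — the second and third admissible category (ascending
  drug count) against the first; from state zero these are exactly 2- and
  3-drug prescribing. Default intercepts (−3.58, −5.78) reproduce a
  0.970/0.027/0.003 from-zero split, and default group add-weights
  (0.55/0.39/0.06) put 94% of single-drug starts on opioids or
  benzodiazepines. Network measures enter the generating predictors
  mean-centered, so intercepts and the baseline exit rate describe an
  average prescriber; logit and Cox slopes are invariant to this
  centering while the fitted models use the plain SD-scaled columns.
* **Realizing draws as fills.** Upward draws add the missing groups as
  fills by the encountering physician (days supply uniform on
  [`days_supply_min`, `days_supply_max`], default 7–30). Downward draws
  are realized by ending refills: dropped groups' exposure is truncated
  to the day after the encounter and the encountering physician issues
  the final fill (a refill of kept groups, or a 1-day fill when dropping
  to zero), so that lapse attribution points at the prescriber whose
  draw caused the change. Entry into OBS draws an exit time from an
  exponential proportional-hazards model, `rate =
  baseline_exit_rate·exp(x'β_hazard + θ + γ)`, rounded up to whole days;
  all three groups then lapse together at the exit, and encounters during
  the spell prescribe nothing.

What the DGP does **not** emulate: drug-level coding, dose/MME,
enrollment churn, geography, seasonality, or informative encounter
timing. One structural gap matters for interpretation: between
encounters, supplies can run out on their own, producing downward
transitions that were not drawn from the transition model (their
covariates belong to the physician who last prescribed). From-zero
transitions are immune — they can only occur at an encounter — so the
from-zero multinomial recovery is exact by design; the opioid logistic
and the collapsed downward rows carry a small admixture of such lapses.

## Recovery study conditions

`recovery_config(seed)` fixes the validation conditions: 5,000 patients,
300 physicians, 365-day window, encounter rate 22/year with 90% of gaps
≤ 28 days, fills of 30–60 days, σ = τ = 0, slopes shared between cat2 and
cat3 (age −0.03/yr, female +0.2, closeness log 0.8, clustering log 1.5,
volume +0.15; intercepts −1.4/−2.5), hazard coefficients volume 0.3,
clustering 0.25, female 0.2 with baseline exit rate 0.04/day. The
frequent follow-up and longer fills ensure prescribing decisions are made
at encounters rather than by unmodeled lapses (the admixture above stays
at the few-percent level); shared slopes make the risky-vs-zero collapse
of the transition model exactly logistic with the same slopes, so the
logistic stage has a well-defined truth; zero random-effect SDs make the
fixed-effect stages exactly specified (variance-component estimation is
exercised separately at small n against lme4 and by null-recovery
checks). Bias is asserted for the network-measure coefficients — the
substantive predictors, whose Monte-Carlo error at 10 seeds is well
inside the 10% band — and CI coverage is pooled per stage across all
slope coefficients, zero and non-zero (intercepts are excluded: under
uncentered fitting they absorb covariate means and are not comparable to
the generating values).

## Numerical and reproducibility choices

* Single master seed; substreams for rosters, encounters and prescribing
  derived via `SeedSequence([seed, label])`, so stages can be regenerated
  independently.
* Deterministic iteration everywhere (sorted patients, physicians, edge
  lists); CSV floats written with `%.12g`; the manifest carries no
  timestamps. A rerun with the same config is byte-identical.
* Degenerate inputs: empty network → error; disconnected centrality input
  → error instructing LCC extraction; constant column in standardization
  → error naming the column; all-censored Cox input → error; empty
  outcome category → error. Ambiguous attributions are counted in the
  manifest rather than silently resolved.
* Laplace/quadrature details: inner Newton with step halving; outer
  Nelder-Mead on log-variances (bounded implicitly by clipping to
  [e^−12, e^6]); Gauss-Hermite with 21 nodes; power iteration capped at
  10,000 iterations.

## Problem sizes

The shipped validation uses cohorts of 300–5,000 patients and 60–300
physicians: the 10-seed recovery study runs in about four minutes and the
full suite in about five on one CPU. The pipeline itself is linear in
encounters and fills apart from betweenness centrality
(O(nm) per graph) and scales to tens of thousands of patients in minutes;
the mixed-model paths use dense linear algebra over the latent intercepts
and are intended for cohorts up to a few thousand grouping levels.

## Known limitations

* The mixed multinomial uses shared (not per-category) random intercepts
  and a Laplace approximation; for severe cluster imbalance or large
  variance components the approximation error is untested.
* Breslow ties bias hazard coefficients slightly toward zero on heavily
  tied day-resolution data (Efron available).
* Passing tests demonstrate correctness of the constructions and
  estimators under the DGP above, not the clinical validity of the
  attribution rule or the 30-day window on real claims.
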
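# Methods

## The model

`reo-prognosis` builds qualitative prognostic biomarkers for right-censored
survival data from **relative expression orderings** (REOs): for a gene pair
(Ga, Gb) and a sample j, the REO state is 1 when Ea > Eb within that sample
and 0 otherwise (ties fall to the ≤ branch). Because an REO depends only on
the within-sample ranking, it is invariant under any strictly increasing
transform of a sample's expression values — platform scaling, batch effects,
normalization choices — and a classifier built from REO states can be applied
to a single new sample with no reference cohort, no renormalization and no
trained threshold. This is the top-scoring-pairs family of models, here
specialized to survival.

The pipeline has four stages:

1. **Gene screening.** Within each training cohort, each gene's expression is
   fit in a univariate Cox proportional-hazards model against overall
   survival. A gene is retained when it is significant (Wald p < α, default
   0.05) in at least one cohort *and* the sign of its hazard coefficient is
   identical in every cohort where the fit converged. The sign-consistency
   requirement is the strictest reading of cross-cohort direction agreement;
   its side effect is strong null suppression — under the null, the
   probability of surviving the rule with three cohorts is
   2·((1/2)³ − (1/2 − α/2)³) ≈ 0.036, below the nominal α.
2. **Pair screening.** All g(g−1)/2 unordered pairs of surviving genes are
   formed and their binary REO states computed on the pooled training samples
   (REO states, unlike intensities, are comparable across platforms, so
   pooling is coherent). Each pair's REO indicator is the covariate of a
   univariate Cox fit; Benjamini–Hochberg adjustment runs across all pairs
   actually tested (constant-REO and non-converged pairs are excluded first,
   and logged), keeping pairs with adjusted p < 0.05. Each kept pair is
   *oriented*: its risky state is the REO value carrying the positive hazard
   coefficient, so the concordance index of its risky-state indicator is
   ≥ 0.5 by construction. Candidates are ordered by descending c-index, ties
   broken lexicographically, which makes every downstream step deterministic.
3. **Greedy signature search.** The combination score of a pair set is the
   fraction of detected pairs sitting in their risky state — the natural
   continuous score whose dichotomization at 1/2 is the majority vote. Each of
   the top `n_seeds` (default 10) candidates seeds one combination; the
   remaining candidates are traversed once in descending-c-index order and a
   candidate is kept iff it increases Harrell's C of the combination score on
   the pooled training samples by more than 1e-12 (strict improvement; the
   tolerance absorbs float noise). One pass, not iterated to convergence: the
   single pass is deterministic and already saturates in practice. A held-out
   test cohort then gates the `n_seeds` combinations: each score is fit in a
   univariate Cox model on the test cohort, and among significantly
   associated combinations (p < 0.05) the one with the highest test C-index
   becomes the signature.
4. **Classification.** A sample is called high-risk when its risky votes over
   the signature pairs detected on its platform reach at least half of the
   detected pairs; exact ties go to high-risk (conservative for a triage
   tool) and are flagged in the output. Undetected pairs (genes absent from a
   platform) are dropped before voting. The call uses only the sample's own
   column: it cannot change when other samples are added, removed or
   reordered, and the test suite asserts this literally.

## Statistical kernel

* **Cox fits** maximize the Breslow-ties partial likelihood by Newton–Raphson
  with step-halving (≤50 iterations, ≤30 halvings), reporting Wald p-values
  and 95% CIs on the hazard ratio. Degenerate inputs — constant covariate,
  fewer than two events, monotone likelihood (|coef| > 10 or a singular
  information matrix) — yield a *flagged* non-converged result with p = 1
  rather than an exception, so genome-scale screening loops skip them. For
  pair screening a vectorized batch path exploits x² = x for binary
  covariates, reducing each Newton step to a closed-form scalar update across
  all pairs simultaneously.
* **Concordance index**: a pair (i, j) is comparable when t_i < t_j and i's
  event was observed; censored–censored pairs and pairs tied on time are not
  comparable; score ties count 1/2. The implementation is a vectorized O(n²)
  evaluation, tested for exact equality against a double-loop oracle.
* **Time-dependent AUC** uses the cumulative-case / dynamic-control IPCW
  definition: cases (event by the horizon) weighted by 1/G(T−), controls
  (followed beyond it) by 1/G(horizon), with G the Kaplan–Meier estimate of
  the censoring survival function. With no censoring all weights are 1 and
  the statistic reduces to the Mann–Whitney AUC of the dichotomized outcome.
  Horizons with no cases or no controls are reported as not computable and
  excluded from the mean. Evaluation horizons default to 36/60/84 months.
* **Kaplan–Meier / log-rank** delegate to lifelines; **BH** to statsmodels;
  **Fisher's exact test** to scipy, with the sample odds ratio (a·d)/(b·c).
  The drug-response analysis builds its 2×2 with the low-risk row first and
  the sensitive column first, so the reported OR is the low-risk-sensitivity
  odds ratio and its exact reciprocal is the resistance OR.

## Synthetic cohorts

The generator emulates a multi-platform retrospective study. Each sample
carries a latent risk r ~ N(0,1). Planted prognostic genes respond linearly,
expression = direction·signal·r + baseline + N(0, noise_sd²), with
directions alternating ±1 and identical across cohorts (consistent hazard
direction); null genes are baseline + noise, baselines ~ N(0, baseline_sd²).
Survival is exponential proportional hazards, hazard h0·exp(β·r), with
independent exponential censoring whose rate is calibrated to the target
censored fraction by 64-node Gauss–Hermite quadrature of
E_r[c/(c + h0·e^{βr})] inverted with Brent's method (realized censoring is
within ±5 percentage points of target at n ≥ 500). Each cohort is then passed
through its own strictly increasing platform map x ↦ scale·(x + curve·x³) +
shift plus per-sample log-normal gain and Gaussian offset, so magnitudes are
incomparable across cohorts while every within-sample ordering — and hence
the planted REO truth — is preserved exactly. A `corrupt` option applies a
non-monotone map (absolute value) as a negative control that destroys REO
truth on purpose. Event times are rounded to 2 decimals to mimic published
clinical tables (an `exact_times` flag disables this for oracle tests); a
rounded time of 0 is legitimately removed by preprocessing, like a 0-day
survival record. Optional covariates (age weakly correlated with risk, ordinal
stage/grade) and a drug-response column (sensitivity log-odds linear in −r,
CR/PR vs SD/PD refinement, a platinum flag) support the evaluation module.

Defaults — 3 training cohorts + 1 test + 1 validation of 150 samples each,
300 shared genes with 30 prognostic, gene signal 1.0 against noise 1.0 and
baseline spread 1.5, log-hazard β = 1 per latent-risk unit, baseline hazard
0.02 events/month, 30% censoring — describe a mid-sized multi-cohort array
study with a clearly present but noisy transcriptional signal: per-gene
correlation with the latent risk is ≈ 0.7 before distortion, and a single
pair's REO agrees with the risk sign in roughly 60–70% of samples, so no
individual pair is decisive and the voting ensemble has real work to do.

What the generator does *not* emulate: real array intensity distributions and
probe-level artifacts, gene–gene correlation beyond the shared latent factor,
non-proportional or time-varying hazards, informative censoring, and cohorts
with genuinely disjoint gene panels. Passing tests therefore demonstrate that
the machinery recovers planted PH-consistent rank structure under monotone
platform distortion — not that any particular clinical signature is correct.

## Numerical and design choices

* Low-expression filter: a gene is dropped when missing-or-zero in strictly
  more than `low_expr_fraction` (default 1/2) of samples; exactly half is
  retained. Missing and exact zero are pooled.
* Duplicate gene rows (multi-probe genes) are averaged element-wise, skipping
  missing entries per cell.
* Survival times are stored in months; the reader converts days with /30.44.
* Gene-level screening is quantitative (Cox on expression values), so it is
  invariant to per-cohort positive affine rescaling but *not* to arbitrary
  per-sample monotone transforms; every stage from pair REO construction
  onward is exactly rank-invariant. The invariance tests are split
  accordingly.
* The greedy objective never decreases along accepted additions, is bounded
  below by the seed's own c-index and above by the exhaustive best-subset
  optimum; the test suite checks both bounds by enumeration on small
  instances.
* Signatures may reuse a gene across pairs (real pair signatures do); a pair
  itself can appear only once.
* Problem sizes in the test suite and acceptance script: the study-sized run
  uses the generator defaults above (750 samples, 300 genes); transform and
  null-calibration checks use 100-sample cohorts with 60–120 genes; oracle
  equivalence uses n ≤ 20 instances where brute force is exact.

## Known limitations

* Breslow tie handling only (adequate for continuous or lightly tied times;
  Efron would be preferable under heavy ties).
* No penalized, stratified or competing-risks Cox; no interval censoring.
* The test-set gate uses the continuous vote-fraction score, not the
  dichotomized label; with very small test cohorts the Cox fit on a
  near-discrete score can be unstable, which surfaces as the documented
  hard error rather than a silent pick.
* With very few candidate pairs (< n_seeds) the search refuses to run rather
  than silently shrinking the seed set.
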
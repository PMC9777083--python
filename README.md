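# reo-prognosis

Qualitative prognostic signatures for survival transcriptomics, built from
within-sample **relative expression orderings** (REOs) of gene pairs.

Quantitative risk-score models trained on one expression platform rarely
transfer to another: intensities shift with platform, batch and
normalization, and the trained threshold becomes meaningless. The REO of a
gene pair — "is gene A expressed above gene B *in this sample*?" — is a
binary feature invariant to any strictly increasing transform of a sample's
values, so a classifier built from oriented REO states applies to a single
new sample from any platform, with no renormalization and no reference
cohort. This package implements the full discovery-to-deployment pipeline
for such signatures on right-censored overall-survival data:

* **Screening** — per-cohort univariate Cox screening of genes with
  cross-cohort hazard-direction consistency; enumeration of candidate pairs;
  pooled-cohort Cox screening of binary REO features with Benjamini–Hochberg
  control; orientation of each kept pair toward its risk-indicating state.
* **Signature search** — greedy forward maximization of Harrell's C-index of
  the risky-vote-fraction score, seeded from the top-ranked pairs, with
  final selection on a held-out test cohort (significance gate first, then
  highest test C-index).
* **Classification & evaluation** — per-sample majority voting over detected
  pairs (ties to high-risk, flagged); Kaplan–Meier/log-rank stratification,
  low-vs-high hazard ratios, multivariate Cox adjustment, IPCW
  time-dependent AUC at 3/5/7 years, and chemo-response (CR/PR vs SD/PD)
  contingency analysis with exact Fisher tests.
* **Synthetic studies** — a generator of multi-"platform" cohorts with a
  planted latent-risk structure, proportional-hazards survival, calibrated
  censoring and strictly monotone per-cohort distortions, so the entire
  pipeline is testable end to end without any downloads.

The statistical kernel (Newton/Breslow Cox with flagged degenerate fits and
a vectorized batch path for binary covariates, Harrell's C, IPCW
cumulative/dynamic AUC) is implemented in-package and cross-checked in the
test suite against lifelines, R's `survival`, and scikit-survival; standard
steps (Kaplan–Meier, log-rank, BH, Fisher) delegate to lifelines,
statsmodels and scipy.

See `docs/methods.md` for the model, assumptions, defaults and limitations.

## Worked example

```bash
# 1. simulate a 5-cohort study (3 training / 1 test / 1 validation,
#    300 genes, 30 prognostic, ~30% censoring, per-platform distortions)
reo-prognosis simulate --seed 11 --out data/

# 2. screen, search and select a signature
reo-prognosis build --train data/training1 --train data/training2 \
    --train data/training3 --test data/test1 --out sig.json
# -> 101-pair signature (training C=0.764, test C=0.739, test p=3.87e-15)

# 3. classify new samples from another "platform" (expression only)
reo-prognosis classify --sig sig.json --expr data/validation1/expression.tsv \
    --out calls.tsv
# -> 150 samples: 84 high-risk, 66 low-risk

# 4. evaluate against the held-out cohort's survival
reo-prognosis evaluate --sig sig.json --cohort data/validation1 --out report/
# -> high/low = 84/66, log-rank p = 1.28e-13,
#    HR(low vs high) = 0.18, mean AUC = 0.832
```

The signature's training C-index (0.764) is the concordance of the
risky-vote-fraction score on the pooled training cohorts; the test C-index
(0.739) is measured on the held-out test cohort that selected the
combination. On the fully held-out validation cohort — generated on yet
another simulated platform — majority voting splits 84 high / 66 low, the
low-risk group is strongly protected (hazard ratio 0.18, log-rank
p ≈ 1e-13), and the vote score's mean 3/5/7-year IPCW AUC is 0.832. Because
the generator planted the prognostic genes, recovery is verifiable: the
signature's genes are overwhelmingly enriched for planted genes
(hypergeometric p ≈ 1e-30 at the defaults).

The same workflow is available as a library:

```python
from reo_prognosis import SimConfig, generate, preprocess_cohort, fit_signature, evaluate

cohorts, truth = generate(SimConfig(seed=1))
cohorts = [preprocess_cohort(c) for c in cohorts]
training = [c for c in cohorts if c.role == "training"]
test = next(c for c in cohorts if c.role == "test")
validation = next(c for c in cohorts if c.role == "validation")

sig, info = fit_signature(training, test)     # the full screening cascade
report = evaluate(validation, sig)            # KM, HR, AUCs, multivariate Cox
```

For real data, `read_cohort` loads TSV/CSV pairs (genes × samples expression;
clinical table with `os_time` in months, `os_event`, optional
age/stage/grade/drug_response/platinum_flag) and `preprocess_cohort` applies
the standard filters: duplicate-probe averaging, removal of samples without
survival annotation or with zero follow-up, and removal of genes missing or
zero in more than half the samples. Tumor/normal filtering is expected
upstream (supply tumor-only files).

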
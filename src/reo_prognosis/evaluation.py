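"""Cohort-level evaluation of a fitted signature.

Stratifies a cohort with the majority-vote classifier, compares survival
between the risk groups (Kaplan-Meier + log-rank), reports the low- vs
high-risk hazard ratio, IPCW time-dependent AUCs of the vote-fraction
score at 3/5/7 years, a multivariate Cox adjustment over the clinical
covariates available in the cohort, and — when drug-response annotation
exists — the chemo-sensitivity contingency analysis (CR/PR collapse to
sensitive, SD/PD to resistant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reo_core import build_reo_matrix
from .signature import Signature, classify, combination_scores
from .survival_stats import (ContingencyResult, CoxFit, KMResult,
                             cox_fit, cox_fit_multivariate, fisher_2x2,
                             km_logrank, td_auc)

logger = logging.getLogger(__name__)

__all__ = ["EvaluationReport", "evaluate", "drug_response_analysis",
            "DEFAULT_HORIZONS"]

#: 3-, 5- and 7-year horizons in months
DEFAULT_HORIZONS = (36.0, 60.0, 84.0)

MULTIVARIATE_COVARIATES = ("age", "stage", "grade")


@dataclass
class EvaluationReport:
    """All cohort-level performance numbers for one signature."""

    cohort_name: str
    n_high: int
    n_low: int
    logrank_p: float
    hr_low_vs_high: CoxFit
    auc_by_horizon: dict      # horizon (months) -> AUC or None when not computable
    mean_auc: float
    km: KMResult
    multivariate: dict = field(default_factory=dict)   # covariate -> CoxFit
    drug_response: ContingencyResult | None = None
    drug_response_platinum: ContingencyResult | None = None
    calls: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = {"cohort": self.cohort_name, "n_high": self.n_high, "n_low": self.n_low,
                "logrank_p": self.logrank_p, "hr_low_vs_high": self.hr_low_vs_high.hr,
                "hr_ci_low": self.hr_low_vs_high.ci_low,
                "hr_ci_high": self.hr_low_vs_high.ci_high,
                "mean_auc": self.mean_auc}
        for h, auc in self.auc_by_horizon.items():
            rows[f"auc_{int(h)}m"] = np.nan if auc is None else auc
        return pd.DataFrame([rows])


def evaluate(cohort, sig: Signature, horizons=DEFAULT_HORIZONS) -> EvaluationReport:
    """Evaluate a signature on one cohort.

    The hazard ratio is reported for low vs high risk (HR < 1 means the
    low-risk group is protected). AUC horizons with no cases or no
    controls are recorded as not computable and excluded from the mean.
    """
    calls = classify(cohort, sig)
    labels = np.array([c.label for c in calls])
    t = cohort.clinical["os_time"].to_numpy(float)
    e = cohort.clinical["os_event"].to_numpy(float)

    km = km_logrank(t, e, labels)
    low = (labels == "low").astype(float)
    hr_fit = cox_fit(low, t, e)

    reo = build_reo_matrix(cohort.expression, [op.pair for op in sig.oriented_pairs])
    detected = set(reo.pairs)
    combo = [op for op in sig.oriented_pairs if op.pair in detected]
    score = combination_scores(reo, combo)

    aucs = {}
    for h in horizons:
        try:
            aucs[h] = td_auc(score, t, e, h)
        except ValueError as exc:
            logger.info("cohort %s: AUC at %g months not computable (%s)",
                        cohort.name, h, exc)
            aucs[h] = None
    computable = [a for a in aucs.values() if a is not None]
    mean_auc = float(np.mean(computable)) if computable else float("nan")

    multivariate = _multivariate_table(cohort, low, t, e)

    drug = drug_platinum = None
    if "drug_response" in cohort.clinical.columns:
        try:
            drug = drug_response_analysis(calls, cohort.clinical, platinum_only=False)
            if "platinum_flag" in cohort.clinical.columns:
                drug_platinum = drug_response_analysis(calls, cohort.clinical,
                                                       platinum_only=True)
        except ValueError as exc:
            logger.info("cohort %s: drug-response analysis skipped (%s)",
                        cohort.name, exc)

    return EvaluationReport(
        cohort_name=cohort.name,
        n_high=int((labels == "high").sum()), n_low=int((labels == "low").sum()),
        logrank_p=km.logrank_p, hr_low_vs_high=hr_fit,
        auc_by_horizon=aucs, mean_auc=mean_auc, km=km,
        multivariate=multivariate, drug_response=drug,
        drug_response_platinum=drug_platinum, calls=calls)


def _multivariate_table(cohort, low_indicator, t, e) -> dict:
    """Joint Cox fit of the risk label and whichever of age/stage/grade exist.

    Only covariates present and fully observed in the cohort enter the
    model (datasets differ in which clinical elements they record)."""
    columns = {"risk_low": low_indicator}
    for cov in MULTIVARIATE_COVARIATES:
        if cov in cohort.clinical.columns and cohort.clinical[cov].notna().all():
            columns[cov] = cohort.clinical[cov].to_numpy(float)
    X = np.column_stack(list(columns.values()))
    fits = cox_fit_multivariate(X, t, e)
    return dict(zip(columns.keys(), fits))


def drug_response_analysis(calls, clinical: pd.DataFrame,
                            platinum_only: bool = False) -> ContingencyResult:
    """Risk-group x chemo-response contingency analysis.

    CR/PR collapse to chemo-sensitive, SD/PD to chemo-resistant; samples
    with missing response are dropped; ``platinum_only`` restricts to
    samples with ``platinum_flag`` = 1. The returned odds ratio is for
    low-risk sensitivity (its reciprocal is the low-risk resistance OR).
    """
    label_by_sample = {c.sample_id: c.label for c in calls}
    if "drug_response" not in clinical.columns:
        raise ValueError("clinical table has no drug_response column")
    df = clinical.copy()
    df["risk"] = [label_by_sample.get(str(s)) for s in df.index]
    df = df[df["risk"].notna() & df["drug_response"].isin(["CR", "PR", "SD", "PD"])]
    if platinum_only:
        if "platinum_flag" not in df.columns:
            raise ValueError("platinum_only requested but no platinum_flag column")
        df = df[df["platinum_flag"] == 1]
    sensitive = df["drug_response"].isin(["CR", "PR"])
    low = df["risk"] == "low"
    a = int((low & sensitive).sum())       # low-risk sensitive
    b = int((low & ~sensitive).sum())      # low-risk resistant
    c = int((~low & sensitive).sum())      # high-risk sensitive
    d = int((~low & ~sensitive).sum())     # high-risk resistant
    if (a + b) == 0 or (c + d) == 0:
        raise ValueError("a risk group has no annotated drug response")
    return fisher_2x2(a, b, c, d)
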
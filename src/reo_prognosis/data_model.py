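"""Domain containers and cohort preprocessing.

Expression matrices are pandas DataFrames with gene IDs on the index and
sample IDs on the columns; values live on any within-sample-comparable
continuous scale (array intensity, normalized count). Clinical tables
are DataFrames indexed by sample ID with at least ``os_time`` (months,
overall survival) and ``os_event`` (1 = death observed, 0 = censored);
``age``, ``stage``, ``grade``, ``drug_response`` and ``platinum_flag``
are optional.

Preprocessing mirrors the standard cohort-cleaning cascade for survival
transcriptomics: drop samples without survival annotation, drop samples
with zero follow-up, and drop genes that are missing or zero in more
than half the samples. Removal of normal (non-tumor) samples is a caller
responsibility via sample annotations upstream of these readers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Cohort",
    "read_cohort",
    "write_cohort",
    "collapse_duplicate_genes",
    "preprocess_cohort",
    "common_gene_universe",
    "DAYS_PER_MONTH",
]

#: mean Gregorian month length, used for day -> month conversion
DAYS_PER_MONTH = 30.44

REQUIRED_CLINICAL = ("os_time", "os_event")
OPTIONAL_CLINICAL = ("age", "stage", "grade", "drug_response", "platinum_flag")
DRUG_RESPONSE_LEVELS = ("CR", "PR", "SD", "PD")


@dataclass
class Cohort:
    """One study cohort: an expression matrix joined to clinical annotations.

    ``expression``: genes x samples DataFrame. ``clinical``: DataFrame
    indexed by sample ID, aligned 1:1 with the expression columns.
    ``role`` tags how the cohort is used downstream (training / test /
    validation).
    """

    name: str
    expression: pd.DataFrame
    clinical: pd.DataFrame
    role: str = "training"
    platform_label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.role not in {"training", "test", "validation"}:
            raise ValueError(f"role must be training/test/validation, got {self.role!r}")
        if set(self.expression.columns) != set(self.clinical.index):
            raise ValueError(
                f"cohort {self.name!r}: expression samples and clinical samples differ")
        # keep clinical rows in expression column order
        self.clinical = self.clinical.loc[self.expression.columns]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.expression.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    def subset_samples(self, sample_ids) -> "Cohort":
        sample_ids = list(sample_ids)
        return replace(self, expression=self.expression[sample_ids],
                       clinical=self.clinical.loc[sample_ids])


def _read_table(path, sep: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cannot read {path}")
    return pd.read_csv(path, sep=sep, index_col=0)


def read_cohort(expression_path, clinical_path, name: str, role: str = "training",
                sep: str = "\t", platform_label: str = "",
                time_in_days: bool = False) -> Cohort:
    """Load a cohort from delimited-text expression and clinical files.

    The expression file has genes in rows (first column = gene ID, header
    row = sample IDs); the clinical file has one row per sample with named
    columns including ``os_time`` and ``os_event``. Samples are restricted
    to the intersection of the two files; ``time_in_days`` converts
    ``os_time`` from days to months (/30.44).
    """
    expr = _read_table(expression_path, sep)
    clin = _read_table(clinical_path, sep)
    expr.index = expr.index.astype(str)
    expr.columns = expr.columns.astype(str)
    clin.index = clin.index.astype(str)
    if clin.index.duplicated().any():
        dupes = clin.index[clin.index.duplicated()].unique().tolist()
        raise ValueError(f"{clinical_path}: duplicated sample IDs {dupes}")
    if expr.columns.duplicated().any():
        dupes = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValueError(f"{expression_path}: duplicated sample IDs {dupes}")
    missing = [c for c in REQUIRED_CLINICAL if c not in clin.columns]
    if missing:
        raise ValueError(f"{clinical_path}: missing required columns {missing}")
    shared = [s for s in expr.columns if s in set(clin.index)]
    if not shared:
        raise ValueError(
            f"no overlapping samples between {expression_path} and {clinical_path}")
    dropped_expr = expr.shape[1] - len(shared)
    dropped_clin = clin.shape[0] - len(shared)
    if dropped_expr or dropped_clin:
        logger.info("cohort %s: dropped %d expression-only and %d clinical-only samples",
                    name, dropped_expr, dropped_clin)
    clin = clin.loc[shared].copy()
    if time_in_days:
        clin["os_time"] = clin["os_time"] / DAYS_PER_MONTH
    return Cohort(name=name, expression=expr[shared].astype(float), clinical=clin,
                  role=role, platform_label=platform_label)


def write_cohort(cohort: Cohort, out_dir, sep: str = "\t") -> tuple[Path, Path]:
    """Write a cohort back to ``<out_dir>/expression.tsv`` + ``clinical.tsv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = "csv" if sep == "," else "tsv"
    expr_path = out_dir / f"expression.{ext}"
    clin_path = out_dir / f"clinical.{ext}"
    cohort.expression.to_csv(expr_path, sep=sep, index_label="gene_id")
    cohort.clinical.to_csv(clin_path, sep=sep, index_label="sample_id")
    return expr_path, clin_path


def collapse_duplicate_genes(expression: pd.DataFrame) -> pd.DataFrame:
    """Average rows sharing a gene ID (e.g. multiple probes per gene).

    The element-wise mean skips missing entries; a cell is missing in the
    output only when it is missing in every duplicate row.
    """
    if not expression.index.duplicated().any():
        return expression
    return expression.groupby(level=0, sort=False).mean()


def preprocess_cohort(cohort: Cohort, low_expr_fraction: float = 0.5) -> Cohort:
    """Apply the cohort-cleaning cascade; returns a new Cohort.

    1. collapse duplicated gene rows by averaging;
    2. remove samples lacking ``os_time`` or ``os_event``;
    3. remove samples with zero follow-up (``os_time`` = 0);
    4. remove low-expression genes: a gene is dropped when the number of
       samples in which it is missing or exactly zero exceeds
       ``low_expr_fraction`` of the samples (strictly greater).
    """
    expr = collapse_duplicate_genes(cohort.expression)
    clin = cohort.clinical

    has_surv = clin["os_time"].notna() & clin["os_event"].notna()
    n_no_surv = int((~has_surv).sum())
    positive = clin["os_time"].fillna(-1) > 0
    n_zero_time = int((has_surv & ~positive).sum())
    keep_samples = clin.index[has_surv & positive]
    if n_no_surv or n_zero_time:
        logger.info("cohort %s: removed %d samples without survival, %d with zero follow-up",
                    cohort.name, n_no_surv, n_zero_time)
    if len(keep_samples) == 0:
        raise ValueError(f"cohort {cohort.name!r} empty after sample filtering")
    expr = expr[list(keep_samples)]
    clin = clin.loc[keep_samples].copy()
    if not np.all(clin["os_event"].isin([0, 1])):
        raise ValueError(f"cohort {cohort.name!r}: os_event must be 0/1")

    n = expr.shape[1]
    low = ((expr.isna() | (expr == 0)).sum(axis=1) > low_expr_fraction * n)
    if int(low.sum()):
        logger.info("cohort %s: removed %d low-expression genes", cohort.name, int(low.sum()))
    expr = expr.loc[~low]
    if expr.shape[0] == 0:
        raise ValueError(f"cohort {cohort.name!r} has no genes after filtering")
    return replace(cohort, expression=expr, clinical=clin)


def common_gene_universe(cohorts) -> list[str]:
    """Sorted intersection of gene IDs across cohorts (the shared universe)."""
    cohorts = list(cohorts)
    if not cohorts:
        raise ValueError("need at least one cohort")
    genes = set(cohorts[0].gene_ids)
    for c in cohorts[1:]:
        genes &= set(c.gene_ids)
    if not genes:
        names = [c.name for c in cohorts]
        raise ValueError(f"no genes shared across cohorts {names}")
    return sorted(genes)
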
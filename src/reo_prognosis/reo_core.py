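"""The REO screening cascade.

Candidate prognosis-related genes are found by univariate Cox screening
per training cohort, keeping genes significant in at least one cohort
whose hazard-coefficient sign is consistent across every cohort where
the fit converged. All unordered pairs of the surviving genes become
candidate pairs; each pair's within-sample relative expression ordering
(REO) — 1 when the lexicographically first gene is the higher expressed,
0 otherwise — yields a binary pairs x samples matrix that is invariant
to any strictly increasing per-sample transform of expression. Pairwise
Cox on the pooled training samples with Benjamini-Hochberg control then
screens the pairs; each surviving pair is oriented so that its
risk-indicating REO state carries the positive hazard coefficient.

Pair-level Cox pools all training cohorts: REO states are the
cross-platform-comparable representation, so a single model and a single
BH family across the pooled samples is the natural choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .survival_stats import (bh_adjust, concordance_index, cox_fit,
                             cox_fit_binary_batch)

logger = logging.getLogger(__name__)

__all__ = [
    "GenePair",
    "REOMatrix",
    "OrientedPair",
    "screen_genes",
    "enumerate_pairs",
    "build_reo_matrix",
    "screen_pairs",
    "oriented_pairs_to_frame",
]


@dataclass(frozen=True, order=True)
class GenePair:
    """An unordered gene pair stored canonically (gene_a < gene_b)."""

    gene_a: str
    gene_b: str

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise ValueError(f"pair genes must differ, got {self.gene_a!r} twice")
        if self.gene_a > self.gene_b:
            a, b = self.gene_b, self.gene_a
            object.__setattr__(self, "gene_a", a)
            object.__setattr__(self, "gene_b", b)


@dataclass
class REOMatrix:
    """Binary pairs x samples matrix of within-sample orderings.

    ``values[i, j]`` is 1 iff expression of ``pairs[i].gene_a`` strictly
    exceeds that of ``pairs[i].gene_b`` in sample j (ties fall to 0).
    ``undetected`` lists requested pairs excluded because a member gene
    is absent from the expression matrix (cross-platform case).
    """

    pairs: list
    sample_ids: list
    values: np.ndarray
    undetected: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.shape != (len(self.pairs), len(self.sample_ids)):
            raise ValueError("REO matrix shape does not match pairs x samples")


@dataclass(frozen=True)
class OrientedPair:
    """A screened gene pair with its risk-indicating REO state and statistics.

    ``risky_state`` is the REO value (1: gene_a > gene_b; 0: gene_a <=
    gene_b) associated with increased hazard; ``c_index`` is the
    concordance of the indicator "sample sits in the risky state", hence
    >= 0.5 by construction.
    """

    pair: GenePair
    risky_state: int
    coef: float
    hr: float
    p: float
    adj_p: float
    c_index: float


def screen_genes(cohorts, alpha: float = 0.05, genes=None) -> list[str]:
    """Select prognosis-related genes across training cohorts.

    Fits univariate Cox of each gene's expression against survival in
    every cohort. A gene is kept when its Wald p < ``alpha`` in at least
    one cohort AND the sign of its hazard coefficient is identical in
    every cohort where the fit converged. Only genes in the shared
    universe (or the explicit ``genes`` list) are considered. Returns a
    sorted gene list; an empty result is allowed and logged.
    """
    from .data_model import common_gene_universe

    cohorts = list(cohorts)
    universe = list(genes) if genes is not None else common_gene_universe(cohorts)
    kept = []
    for gene in universe:
        signs, significant = [], False
        for cohort in cohorts:
            t = cohort.clinical["os_time"].to_numpy(float)
            e = cohort.clinical["os_event"].to_numpy(float)
            fit = cox_fit(cohort.expression.loc[gene].to_numpy(float), t, e)
            if not fit.converged:
                continue
            signs.append(np.sign(fit.coef))
            if fit.p < alpha:
                significant = True
        if significant and signs and all(s == signs[0] for s in signs) and signs[0] != 0:
            kept.append(gene)
    if not kept:
        logger.warning("gene screening kept no genes at alpha=%g", alpha)
    return sorted(kept)


def enumerate_pairs(genes) -> list[GenePair]:
    """All g*(g-1)/2 unordered pairs of ``genes`` in canonical order."""
    genes = sorted(set(genes))
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to form pairs")
    return [GenePair(a, b) for a, b in combinations(genes, 2)]


def build_reo_matrix(expression: pd.DataFrame, pairs) -> REOMatrix:
    """Binary REO matrix of ``pairs`` over the samples of ``expression``.

    Strict inequality E(gene_a) > E(gene_b) gives 1; ties give 0. Pairs
    with a member gene absent from the matrix are flagged undetected and
    excluded rather than raising (a cross-platform cohort may lack some
    genes).
    """
    present = set(expression.index)
    detected = [p for p in pairs if p.gene_a in present and p.gene_b in present]
    undetected = [p for p in pairs if p not in set(detected)]
    if undetected:
        logger.info("REO matrix: %d of %d pairs undetected on this platform",
                    len(undetected), len(pairs))
    if not detected:
        return REOMatrix(pairs=[], sample_ids=list(expression.columns),
                         values=np.zeros((0, expression.shape[1]), dtype=np.uint8),
                         undetected=undetected)
    a_idx = [p.gene_a for p in detected]
    b_idx = [p.gene_b for p in detected]
    va = expression.loc[a_idx].to_numpy(float)
    vb = expression.loc[b_idx].to_numpy(float)
    values = (va > vb).astype(np.uint8)
    return REOMatrix(pairs=detected, sample_ids=list(expression.columns),
                     values=values, undetected=undetected)


def screen_pairs(reo: REOMatrix, time, event, alpha_adj: float = 0.05) -> list[OrientedPair]:
    """Cox-screen REO pairs on pooled training samples with BH control.

    Each pair's binary REO vector is the covariate of a univariate Cox
    fit; pairs whose REO is constant (or whose fit fails) are excluded
    before adjustment. BH runs across all tested pairs; pairs with
    adjusted p < ``alpha_adj`` are kept, oriented by coefficient sign,
    annotated with the concordance of their risky-state indicator, and
    sorted by descending c-index (ties broken lexicographically).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if len(reo.pairs) == 0:
        return []
    res = cox_fit_binary_batch(reo.values, time, event)
    tested = np.flatnonzero(res["converged"])
    n_const = len(reo.pairs) - tested.size
    if n_const:
        logger.info("pair screening: %d pairs constant/non-converged, excluded", n_const)
    if tested.size == 0:
        return []
    adj = bh_adjust(res["p"][tested])
    oriented = []
    for k, i in enumerate(tested):
        if adj[k] >= alpha_adj:
            continue
        coef = res["coef"][i]
        risky = 1 if coef > 0 else 0
        indicator = (reo.values[i] == risky).astype(float)
        ci = concordance_index(indicator, time, event)
        oriented.append(OrientedPair(
            pair=reo.pairs[i], risky_state=risky, coef=float(coef),
            hr=float(np.exp(coef)), p=float(res["p"][i]), adj_p=float(adj[k]),
            c_index=ci))
    if not oriented:
        logger.warning("pair screening kept no pairs at adjusted alpha=%g", alpha_adj)
    oriented.sort(key=lambda op: (-op.c_index, op.pair.gene_a, op.pair.gene_b))
    return oriented


def oriented_pairs_to_frame(oriented) -> pd.DataFrame:
    """Serialize oriented pairs to a tidy table (TSV-ready)."""
    return pd.DataFrame([
        {"gene_a": op.pair.gene_a, "gene_b": op.pair.gene_b,
         "risky_state": op.risky_state, "coef": op.coef, "hr": op.hr,
         "p": op.p, "adj_p": op.adj_p, "c_index": op.c_index}
        for op in oriented])
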
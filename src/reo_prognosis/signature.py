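"""Signature construction and the majority-vote risk classifier.

From the screened, oriented candidate pairs a greedy forward search
grows combinations that maximize Harrell's C-index of the risky-vote
fraction on the pooled training samples: each of the top ``n_seeds``
candidates seeds one combination, the remaining candidates are traversed
once in descending-c-index order, and a candidate joins the combination
only when it strictly increases the C-index. A held-out test cohort then
gates the seeded combinations by Cox significance of the score and picks
the significant combination with the highest test C-index.

Classification of a new sample is fully individual: among the signature
pairs detected on the sample's platform, the sample is called high-risk
when at least half the pairs sit in their risk-indicating REO state. No
other sample's values enter the call.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reo_core import GenePair, OrientedPair, REOMatrix, build_reo_matrix
from .survival_stats import concordance_index, cox_fit

logger = logging.getLogger(__name__)

__all__ = [
    "Combination",
    "Signature",
    "RiskCall",
    "combination_scores",
    "greedy_build",
    "select_final",
    "classify",
    "fit_signature",
]

#: tolerance below which a C-index gain does not count as an improvement
GREEDY_TOL = 1e-12


@dataclass
class Combination:
    """A candidate pair combination with its training C-index."""

    pairs: list
    training_c_index: float
    seed_rank: int


@dataclass
class Signature:
    """The final prognostic signature: an ordered set of oriented pairs."""

    oriented_pairs: list
    training_c_index: float
    test_c_index: float
    test_cox_p: float
    provenance: dict = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return len(self.oriented_pairs)

    @property
    def genes(self) -> list[str]:
        seen = dict.fromkeys(
            g for op in self.oriented_pairs for g in (op.pair.gene_a, op.pair.gene_b))
        return list(seen)

    def to_dict(self) -> dict:
        return {
            "pairs": [{"gene_a": op.pair.gene_a, "gene_b": op.pair.gene_b,
                       "risky_state": op.risky_state, "coef": op.coef, "hr": op.hr,
                       "p": op.p, "adj_p": op.adj_p, "c_index": op.c_index}
                      for op in self.oriented_pairs],
            "training_c_index": self.training_c_index,
            "test_c_index": self.test_c_index,
            "test_cox_p": self.test_cox_p,
            "provenance": self.provenance,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "Signature":
        pairs = [OrientedPair(pair=GenePair(p["gene_a"], p["gene_b"]),
                              risky_state=int(p["risky_state"]), coef=p["coef"],
                              hr=p["hr"], p=p["p"], adj_p=p["adj_p"],
                              c_index=p["c_index"])
                 for p in d["pairs"]]
        return cls(oriented_pairs=pairs, training_c_index=d["training_c_index"],
                   test_c_index=d["test_c_index"], test_cox_p=d["test_cox_p"],
                   provenance=d.get("provenance", {}))

    @classmethod
    def from_json(cls, path) -> "Signature":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class RiskCall:
    """Per-sample majority-vote risk label.

    ``votes_total`` counts the signature pairs detected on this sample's
    platform; ``tie`` flags calls decided by the exact-tie rule (ties go
    to high-risk)."""

    sample_id: str
    votes_risky: int
    votes_total: int
    label: str
    tie: bool = False


def _risky_indicator_matrix(reo: REOMatrix, combo) -> np.ndarray:
    """(pairs x samples) 0/1 matrix: pair sits in its risky REO state."""
    index = {p: i for i, p in enumerate(reo.pairs)}
    rows, states = [], []
    for op in combo:
        if op.pair in index:
            rows.append(index[op.pair])
            states.append(op.risky_state)
    if not rows:
        return np.zeros((0, len(reo.sample_ids)))
    sub = reo.values[np.array(rows)]
    return (sub == np.array(states)[:, None]).astype(float)


def combination_scores(reo: REOMatrix, combo) -> np.ndarray:
    """Risky-vote fraction per sample: detected pairs in their risky state.

    This is the continuous score whose C-index the greedy search
    maximizes; dichotomized at 1/2 it is exactly the majority vote.
    """
    ind = _risky_indicator_matrix(reo, combo)
    if ind.shape[0] == 0:
        raise ValueError("no combination pair is detected in this expression matrix")
    return ind.mean(axis=0)


class _FastCIndex:
    """C-index evaluator reusing the comparable-pair mask across many scores."""

    def __init__(self, time, event):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=float)
        self.shorter = (time[:, None] < time[None, :]) & (event[:, None] == 1)
        self.n_comp = int(self.shorter.sum())
        if self.n_comp == 0:
            raise ValueError("no comparable pairs in training survival data")

    def __call__(self, score: np.ndarray) -> float:
        diff = score[:, None] - score[None, :]
        conc = np.sum(self.shorter & (diff > 0))
        ties = np.sum(self.shorter & (diff == 0))
        return float((conc + 0.5 * ties) / self.n_comp)


def greedy_build(candidates, reo: REOMatrix, time, event,
                 n_seeds: int = 10, tol: float = GREEDY_TOL) -> list[Combination]:
    """Greedy forward C-index maximization from each of the top seeds.

    ``candidates`` must be sorted by descending c-index (the order
    produced by pair screening). For seed k the combination starts as the
    k-th candidate alone; every remaining candidate is tried once, in
    order, and kept iff the C-index of the risky-vote-fraction score on
    the training samples strictly increases (by more than ``tol``).
    """
    candidates = list(candidates)
    if len(candidates) < n_seeds:
        raise ValueError(f"need at least n_seeds={n_seeds} candidates, "
                         f"got {len(candidates)}")
    cindex = _FastCIndex(time, event)
    ind = _risky_indicator_matrix(reo, candidates)
    if ind.shape[0] != len(candidates):
        raise ValueError("all candidate pairs must be present in the training REO matrix")
    combos = []
    for k in range(n_seeds):
        members = [k]
        votes = ind[k].copy()
        best = cindex(votes)
        for j in range(len(candidates)):
            if j == k:
                continue
            trial = (votes + ind[j]) / (len(members) + 1)
            c = cindex(trial)
            if c > best + tol:
                members.append(j)
                votes += ind[j]
                best = c
        combos.append(Combination(pairs=[candidates[j] for j in members],
                                  training_c_index=best, seed_rank=k))
    return combos


def select_final(combos, test_cohort, alpha: float = 0.05) -> Signature:
    """Pick the final signature on the held-out test cohort.

    Each combination's risky-vote-fraction score is fit in a univariate
    Cox model on the test cohort; among combinations with Wald p <
    ``alpha`` the one with the largest test C-index wins. Raises when no
    combination clears the significance gate.
    """
    combos = list(combos)
    if not combos:
        raise ValueError("no combinations supplied")
    t = test_cohort.clinical["os_time"].to_numpy(float)
    e = test_cohort.clinical["os_event"].to_numpy(float)
    all_pairs = sorted({op.pair for c in combos for op in c.pairs})
    reo = build_reo_matrix(test_cohort.expression, all_pairs)
    best = None
    for combo in combos:
        score = combination_scores(reo, combo.pairs)
        fit = cox_fit(score, t, e)
        ci = concordance_index(score, t, e)
        if fit.converged and fit.p < alpha:
            if best is None or ci > best[1]:
                best = (combo, ci, fit.p)
    if best is None:
        raise ValueError(
            "no combination is significantly associated with survival on the test "
            "cohort; consider more training data or a different n_seeds")
    combo, ci, p = best
    config_hash = hashlib.sha256(json.dumps(
        [(op.pair.gene_a, op.pair.gene_b, op.risky_state) for op in combo.pairs]
    ).encode()).hexdigest()[:12]
    return Signature(
        oriented_pairs=list(combo.pairs),
        training_c_index=combo.training_c_index,
        test_c_index=ci, test_cox_p=p,
        provenance={"seed_rank": combo.seed_rank,
                    "test_cohort": test_cohort.name,
                    "config_hash": config_hash})


def classify(cohort, sig: Signature) -> list[RiskCall]:
    """Majority-vote risk calls for every sample of a cohort.

    Signature pairs whose genes are absent from the cohort's expression
    matrix are dropped (cross-platform rule); each sample is called
    high-risk when its risky votes reach at least half of the detected
    pairs (exact ties go to high-risk and are flagged). The call depends
    only on the sample's own values.
    """
    reo = build_reo_matrix(cohort.expression, [op.pair for op in sig.oriented_pairs])
    detected = {p for p in reo.pairs}
    combo = [op for op in sig.oriented_pairs if op.pair in detected]
    if not combo:
        raise ValueError(
            f"no signature pair detected on platform {cohort.platform_label or cohort.name!r}")
    ind = _risky_indicator_matrix(reo, combo)
    votes = ind.sum(axis=0).astype(int)
    total = len(combo)
    calls = []
    for sample_id, v in zip(reo.sample_ids, votes):
        tie = (2 * v == total)
        label = "high" if 2 * v >= total else "low"
        calls.append(RiskCall(sample_id=str(sample_id), votes_risky=int(v),
                              votes_total=total, label=label, tie=tie))
    return calls


def fit_signature(training_cohorts, test_cohort, alpha_gene: float = 0.05,
                  alpha_pair: float = 0.05, n_seeds: int = 10,
                  max_candidates: int | None = None, genes=None):
    """Run the full cascade: gene screen -> pairs -> REO -> pair screen ->
    greedy build -> test-set selection.

    Returns ``(signature, info)`` where ``info`` carries the intermediate
    artifacts (kept genes, candidate pairs, oriented pairs, combinations).
    Training cohorts are pooled for pair-level screening and the greedy
    objective; ``max_candidates`` optionally truncates the screened pair
    list (descending c-index) before the greedy search. An explicit
    ``genes`` list skips the quantitative gene-screening stage, running
    the purely rank-based part of the cascade only.
    """
    from .data_model import common_gene_universe
    from .reo_core import enumerate_pairs, screen_genes, screen_pairs

    training_cohorts = list(training_cohorts)
    universe = common_gene_universe(training_cohorts)
    if genes is None:
        genes = screen_genes(training_cohorts, alpha=alpha_gene, genes=universe)
    else:
        genes = sorted(genes)
    if len(genes) < 2:
        raise ValueError(f"gene screening kept {len(genes)} genes; cannot form pairs")
    pairs = enumerate_pairs(genes)

    pooled_expr = np.hstack([c.expression.loc[genes].to_numpy(float)
                             for c in training_cohorts])
    pooled = pd.DataFrame(pooled_expr, index=genes,
                          columns=[f"{c.name}::{s}" for c in training_cohorts
                                   for s in c.sample_ids])
    time = np.concatenate([c.clinical["os_time"].to_numpy(float)
                           for c in training_cohorts])
    event = np.concatenate([c.clinical["os_event"].to_numpy(float)
                            for c in training_cohorts])
    reo = build_reo_matrix(pooled, pairs)
    oriented = screen_pairs(reo, time, event, alpha_adj=alpha_pair)
    if max_candidates is not None:
        oriented = oriented[:max_candidates]
    if len(oriented) < n_seeds:
        raise ValueError(f"pair screening kept {len(oriented)} pairs, fewer than "
                         f"n_seeds={n_seeds}")
    combos = greedy_build(oriented, reo, time, event, n_seeds=n_seeds)
    sig = select_final(combos, test_cohort)
    info = {"universe": universe, "genes": genes, "n_candidate_pairs": len(pairs),
            "oriented_pairs": oriented, "combinations": combos,
            "pooled_reo": reo, "pooled_time": time, "pooled_event": event}
    return sig, info
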
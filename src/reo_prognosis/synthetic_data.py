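"""Synthetic multi-platform survival cohorts with planted REO structure.

Each sample j carries a latent risk r_j ~ N(0, 1). A planted subset of
genes responds linearly to the latent risk with per-gene direction +/-1
(consistent hazard direction across cohorts); the remaining genes are
noise around gene-specific baselines. Survival times are proportional-
hazards exponential, hazard h0 * exp(beta * r_j), with independent
exponential censoring whose rate is calibrated by numerical integration
to hit a target censoring fraction. Every cohort then passes through its
own strictly increasing "platform" distortion plus per-sample positive
gain and offset — so across-cohort expression magnitudes are not
comparable, but every within-sample ordering (and hence all planted REO
structure) is preserved exactly. A non-monotone corruption option exists
for negative-control experiments.

Defaults mirror a mid-sized multi-cohort array study: three training
cohorts of 150 samples, one test and one validation cohort, 300 shared
genes of which 30 are prognostic, log-hazard effect 1 per latent-risk
unit, and ~30% censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, roots_hermitenorm

from .data_model import Cohort

__all__ = ["SimConfig", "generate", "calibrate_censoring_rate"]


@dataclass
class SimConfig:
    """Generator configuration; ``seed`` is mandatory for reproducibility.

    ``effect_size`` is the log-hazard per unit latent risk; ``gene_signal``
    the expression shift per unit latent risk for planted genes (same
    arbitrary units as ``noise_sd`` and ``baseline_sd``);
    ``baseline_hazard`` is in events/month; ``censoring_target`` the
    desired censored fraction. ``distort=False`` emits the raw
    (undistorted) values; ``corrupt=True`` applies a non-monotone map —
    a negative control that destroys REO truth on purpose.
    """

    seed: int
    n_training_cohorts: int = 3
    n_test_cohorts: int = 1
    n_validation_cohorts: int = 1
    n_samples: int = 150
    n_genes: int = 300
    n_prognostic: int = 30
    effect_size: float = 1.0
    gene_signal: float = 1.0
    noise_sd: float = 1.0
    baseline_sd: float = 1.5
    baseline_hazard: float = 0.02
    censoring_target: float = 0.3
    distort: bool = True
    corrupt: bool = False
    exact_times: bool = False
    with_covariates: bool = True
    with_drug_response: bool = True
    drug_log_odds_base: float = 1.0
    drug_log_odds_slope: float = 0.8
    age_risk_corr: float = 0.2

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0 <= self.censoring_target < 1):
            raise ValueError("censoring_target must lie in [0, 1)")
        if self.n_prognostic > self.n_genes:
            raise ValueError("n_prognostic cannot exceed n_genes")


def calibrate_censoring_rate(target: float, baseline_hazard: float,
                              effect_size: float) -> float:
    """Exponential censoring rate whose expected censored fraction is ``target``.

    Under hazard h0*exp(beta*r), r ~ N(0,1), and censoring rate c, the
    censoring probability is E_r[c / (c + h0 e^{beta r})]; the expectation
    is evaluated by Gauss-Hermite quadrature and inverted with Brent's
    method.
    """
    if target == 0:
        return 0.0
    nodes, weights = roots_hermitenorm(64)
    weights = weights / weights.sum()
    hazards = baseline_hazard * np.exp(effect_size * nodes)

    def censored_fraction(log_c):
        c = np.exp(log_c)
        return float(weights @ (c / (c + hazards))) - target

    lo, hi = np.log(baseline_hazard) - 40, np.log(baseline_hazard) + 40
    if censored_fraction(lo) > 0 or censored_fraction(hi) < 0:
        raise ValueError(f"censoring target {target} infeasible for this hazard model")
    return float(np.exp(brentq(censored_fraction, lo, hi, xtol=1e-12)))


def _platform_distortion(rng):
    """A strictly increasing cohort-level map x -> scale*(x + curve*x^3) + shift."""
    scale = rng.uniform(0.5, 2.0)
    curve = rng.uniform(0.0, 0.15)
    shift = rng.normal(0.0, 1.0)

    def f(x):
        return scale * (x + curve * x ** 3) + shift

    return f, {"scale": scale, "curve": curve, "shift": shift}


def _make_cohort(name, role, platform_idx, cfg: SimConfig, rng,
                 gene_ids, baselines, directions, censor_rate, truth):
    n = cfg.n_samples
    r = rng.standard_normal(n)
    noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n))
    signal = np.zeros((cfg.n_genes, n))
    signal[:cfg.n_prognostic] = (directions[:, None] * cfg.gene_signal * r[None, :])
    expr = baselines[:, None] + signal + noise

    # survival: exponential PH in the latent risk, independent censoring
    hazard = cfg.baseline_hazard * np.exp(cfg.effect_size * r)
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        t_cens = rng.exponential(1.0 / censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    os_time = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(int)
    if not cfg.exact_times:
        os_time = np.round(os_time, 2)

    sample_ids = [f"{name}_S{j:04d}" for j in range(n)]
    clinical = pd.DataFrame({"os_time": os_time, "os_event": os_event},
                            index=pd.Index(sample_ids, name="sample_id"))
    if cfg.with_covariates:
        z = rng.standard_normal(n)
        rho = cfg.age_risk_corr
        clinical["age"] = np.round(60 + 8 * (rho * r + np.sqrt(1 - rho ** 2) * z), 1)
        clinical["stage"] = np.clip(np.round(2.8 + 0.3 * r + rng.normal(0, 0.8, n)), 1, 4)
        clinical["grade"] = np.clip(np.round(2.6 + 0.2 * r + rng.normal(0, 0.9, n)), 1, 4)
    if cfg.with_drug_response:
        p_sens = expit(cfg.drug_log_odds_base - cfg.drug_log_odds_slope * r)
        sensitive = rng.random(n) < p_sens
        fine = np.where(sensitive,
                        np.where(rng.random(n) < 0.6, "CR", "PR"),
                        np.where(rng.random(n) < 0.5, "SD", "PD"))
        clinical["drug_response"] = fine
        clinical["platinum_flag"] = (rng.random(n) < 0.9).astype(int)

    # platform distortion last, so the rng stream for biology and clinical
    # variables is identical across distortion modes of the same seed
    dist_params = None
    if cfg.corrupt:
        expr = np.abs(expr)  # non-monotone on purpose: breaks REO truth
        dist_params = {"corrupt": True}
    elif cfg.distort:
        f, dist_params = _platform_distortion(rng)
        gains = np.exp(rng.normal(0.0, 0.1, size=n))
        offsets = rng.normal(0.0, 0.2, size=n)
        expr = f(expr) * gains[None, :] + offsets[None, :]
        dist_params = {**dist_params, "gain_sd": 0.1, "offset_sd": 0.2}

    expression = pd.DataFrame(expr, index=pd.Index(gene_ids, name="gene_id"),
                              columns=sample_ids)
    truth["cohorts"][name] = {
        "latent_risk": r.tolist(),
        "true_event_times": t_event.tolist(),
        "realized_censoring": float(1 - os_event.mean()),
        "distortion": dist_params,
    }
    return Cohort(name=name, expression=expression, clinical=clinical, role=role,
                  platform_label=f"SIMPL{platform_idx}")


def generate(config: SimConfig):
    """Generate all cohorts plus the ground-truth ledger.

    Returns ``(cohorts, truth)``: cohorts carry roles training/test/
    validation in order; ``truth`` records the planted gene IDs and
    directions, per-cohort latent risks, uncensored event times, realized
    censoring fractions and distortion parameters. Same seed, same
    config -> bitwise-identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    width = max(4, len(str(cfg.n_genes)))
    gene_ids = [f"G{i:0{width}d}" for i in range(cfg.n_genes)]
    baselines = rng.normal(0.0, cfg.baseline_sd, size=cfg.n_genes)
    directions = np.where(np.arange(cfg.n_prognostic) % 2 == 0, 1.0, -1.0)
    censor_rate = calibrate_censoring_rate(cfg.censoring_target, cfg.baseline_hazard,
                                           cfg.effect_size)
    truth = {
        "config": asdict(cfg),
        "planted_genes": gene_ids[:cfg.n_prognostic],
        "directions": {g: int(d) for g, d in zip(gene_ids, directions)},
        "censoring_rate": censor_rate,
        "cohorts": {},
    }
    cohorts = []
    idx = 0
    for role, count in (("training", cfg.n_training_cohorts),
                        ("test", cfg.n_test_cohorts),
                        ("validation", cfg.n_validation_cohorts)):
        for k in range(count):
            idx += 1
            name = f"{role}{k + 1}"
            cohorts.append(_make_cohort(name, role, idx, cfg, rng, gene_ids,
                                        baselines, directions, censor_rate, truth))
    return cohorts, truth
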
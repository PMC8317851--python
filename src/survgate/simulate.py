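"""Synthetic neuroblastoma-like cohorts with planted survival-associated modules.

The generator emulates the statistical structure the pipeline assumes: two
patient subgroups (favorable / adverse), two planted gene modules whose
expression separates the subgroups (a "protective" module elevated in the
favorable subgroup and an "adverse" module elevated in the adverse one),
exchangeable within-module gene-gene correlation, proportional-hazards
exponential survival driven by the subgroup, and independent uniform right
censoring calibrated to a requested censoring fraction.

Latent expression for gene g in sample i is Gaussian,

    z_gi = effect_size * [g in module matching subgroup(i)] +
           sqrt(rho) * u_{m(g),i} + sqrt(1-rho) * eps_gi,

with u a per-module, per-sample shared factor; intensities are the
nonnegative monotone map x = exp(z / 2), which keeps min-max normalization
informative and the realized gene-gene correlation close to rho.

Survival follows a proportional-hazards exponential model whose log-hazard
combines the subgroup contrast with an individual molecular risk score read
out by the same module factors that shape expression:

    eta_i = ln(hr_subgroup) * I(adverse_i)
            + risk_coupling * ln(hr_subgroup) * (u2_i - u1_i) / sqrt(2)

High adverse-module expression (u2) raises the hazard and high protective-
module expression (u1) lowers it, so vital status is strongly predictable
from expression — the situation the classifier is built for — while the
marginal subgroup hazard ratio remains hr_subgroup.  Under the null
(hr_subgroup = 1) the whole linear predictor vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import ExpressionMatrix, ClinicalTable

#: latent -> intensity scale of the exponential link (x = exp(scale * z))
LATENT_SCALE = 0.5


@dataclass
class SimulationConfig:
    """Default values emulate a ~500-sample microarray cohort: one third of
    patients in the adverse subgroup (hazard ratio 4 on a baseline hazard of
    4e-5 events/day, i.e. ~93% favorable 5-year survival), 50 protective and
    122 adverse informative genes among 2000, modest residual co-expression
    beyond the subgroup effect (corr 0.2), and
    three quarters of subjects censored — the event scarcity the focal loss
    is designed for."""

    n_samples: int = 500
    n_genes: int = 2000
    n_informative_g1: int = 50
    n_informative_g2: int = 122
    within_module_corr: float = 0.2
    effect_size: float = 1.5
    subgroup_prev: float = 0.33     # probability of the adverse subgroup
    baseline_hazard: float = 4e-5   # events per day, favorable subgroup
    hr_subgroup: float = 4.0
    risk_coupling: float = 1.5      # sd of the molecular risk term, in units of ln(hr_subgroup)
    censor_rate: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_genes < 1:
            raise ValueError("n_samples and n_genes must be positive")
        if self.n_informative_g1 + self.n_informative_g2 > self.n_genes:
            raise ValueError("informative gene counts exceed n_genes")
        if not (0 <= self.within_module_corr < 1):
            raise ValueError("within_module_corr must be in [0, 1)")
        if not (0 < self.subgroup_prev < 1):
            raise ValueError("subgroup_prev must be in (0, 1)")
        if self.baseline_hazard <= 0 or self.hr_subgroup <= 0:
            raise ValueError("hazards must be positive")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must be in [0, 1)")


@dataclass
class SimulatedCohort:
    expr: ExpressionMatrix
    clin: ClinicalTable
    truth: dict = field(default_factory=dict)


def _censoring_upper_bound(hazards: np.ndarray, censor_rate: float) -> float:
    """Upper bound b of Uniform(0, b) censoring giving the requested rate.

    For T ~ Exp(lam), C ~ U(0, b): P(C < T) = (1 - exp(-lam b)) / (lam b),
    monotone decreasing in b; solved on the subject mixture by brentq.
    """

    def expected_censoring(b):
        lb = hazards * b
        return float(np.mean((1.0 - np.exp(-lb)) / lb)) - censor_rate

    lo, hi = 1e-9, 1e12
    if expected_censoring(hi) > 0:
        raise ValueError(f"censor_rate {censor_rate} infeasible for given hazards")
    return brentq(expected_censoring, lo, hi, xtol=1e-6)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw one cohort; fully deterministic given ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_samples, cfg.n_genes
    rho = cfg.within_module_corr

    adverse = rng.random(n) < cfg.subgroup_prev  # True = adverse subgroup
    gene_ids = [f"g{i:04d}" for i in range(1, p + 1)]
    # module membership is the shared "biology": fixed across cohorts of the
    # same dimensions so that a model transfers between independent draws
    positions = np.random.default_rng(777).permutation(p)
    mod1 = positions[: cfg.n_informative_g1]                      # protective
    mod2 = positions[cfg.n_informative_g1: cfg.n_informative_g1 + cfg.n_informative_g2]

    z = rng.standard_normal((p, n)) * np.sqrt(1.0 - rho)
    u1 = rng.standard_normal(n)
    u2 = rng.standard_normal(n)
    if rho > 0:
        z[mod1] += np.sqrt(rho) * u1
        z[mod2] += np.sqrt(rho) * u2
    z[np.ix_(mod1, np.where(~adverse)[0])] += cfg.effect_size
    z[np.ix_(mod2, np.where(adverse)[0])] += cfg.effect_size
    values = np.exp(LATENT_SCALE * z)

    log_hr = np.log(cfg.hr_subgroup)
    beta_risk = cfg.risk_coupling * log_hr
    eta = log_hr * adverse + beta_risk * (u2 - u1) / np.sqrt(2.0)
    hazards = cfg.baseline_hazard * np.exp(eta)
    t_event = rng.exponential(1.0 / hazards)
    if cfg.censor_rate == 0:
        os_time, os_event = t_event, np.ones(n, dtype=int)
    else:
        b = _censoring_upper_bound(hazards, cfg.censor_rate)
        c = rng.uniform(0.0, b, size=n)
        os_event = (t_event <= c).astype(int)
        os_time = np.minimum(t_event, c)

    sample_ids = [f"s{i:04d}" for i in range(1, n + 1)]
    mycn = np.where(adverse, rng.random(n) < 0.55, rng.random(n) < 0.01).astype(int)
    stage4 = np.where(mycn == 1, rng.random(n) < 0.69, rng.random(n) < 0.25).astype(int)
    clin = ClinicalTable(pd.DataFrame({
        "sample_id": sample_ids,
        "os_time": np.round(os_time, 1),
        "os_event": os_event,
        "age": np.where(adverse, rng.random(n) < 0.7, rng.random(n) < 0.4).astype(int),
        "mycn": mycn,
        "stage": stage4,
        "inss_risk": np.where(adverse, rng.random(n) < 0.8, rng.random(n) < 0.15).astype(int),
        "gender": (rng.random(n) < 0.55).astype(int),
    }))
    expr = ExpressionMatrix(gene_ids, sample_ids, values)
    truth = {
        "subgroup": np.where(adverse, 2, 1),           # 1 favorable, 2 adverse
        "module1_genes": sorted(gene_ids[i] for i in mod1),
        "module2_genes": sorted(gene_ids[i] for i in mod2),
        "true_betas": {
            "adverse_subgroup": float(log_hr),
            "module2_factor": float(beta_risk / np.sqrt(2.0)),
            "module1_factor": float(-beta_risk / np.sqrt(2.0)),
        },
        "risk_score": eta.tolist(),
    }
    return SimulatedCohort(expr, clin, truth)


# fixed 12-sample, 8-gene toy: survival values chosen for hand computation
_TOY_TIMES = [5.0, 8.0, 12.0, 20.0, 25.0, 30.0, 33.0, 40.0, 45.0, 50.0, 60.0, 70.0]
_TOY_EVENTS = [1, 1, 0, 1, 0, 1, 1, 0, 1, 0, 0, 1]
_TOY_GROUPS = [2, 2, 2, 2, 2, 2, 1, 1, 1, 1, 1, 1]  # first six = adverse-like


def simulate_toy_fixture() -> SimulatedCohort:
    """Tiny fixed cohort (n=12, 8 genes) for hand-checkable KM/log-rank/tROC."""
    n = 12
    sample_ids = [f"t{i:02d}" for i in range(1, n + 1)]
    gene_ids = [f"tg{j}" for j in range(1, 9)]
    rng = np.random.default_rng(20240101)
    base = rng.uniform(0.5, 2.0, size=(8, n))
    # genes 1-4 elevated in the adverse-like half, 5-8 in the favorable half
    grp = np.array(_TOY_GROUPS)
    base[:4, grp == 2] += 1.5
    base[4:, grp == 1] += 1.5
    clin = ClinicalTable(pd.DataFrame({
        "sample_id": sample_ids,
        "os_time": _TOY_TIMES,
        "os_event": _TOY_EVENTS,
        "mycn": (grp == 2).astype(int),
    }))
    expr = ExpressionMatrix(gene_ids, sample_ids, np.round(base, 6))
    return SimulatedCohort(expr, clin, {"subgroup": grp.copy()})
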
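"""Classification and survival evaluation.

Covers confusion-matrix metrics, ROC/AUC, the Kaplan-Meier-weighted
cumulative/dynamic time-dependent ROC, the product-limit estimator, the
two-group log-rank test, Cox proportional-hazards regression
(Newton-Raphson on the Breslow partial likelihood, Wald tests) and the
repeated stratified cross-validation harness.

The time-dependent ROC at horizon t treats subjects with an event by t as
cases and subjects still at risk past t as controls, handling censoring
through conditional Kaplan-Meier estimates:

    sens(c, t) = [1 - S(t | score > c)] P(score > c) / [1 - S(t)]
    spec(c, t) = S(t | score <= c) P(score <= c) / S(t)
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve, auc as _sk_auc
from sklearn.model_selection import StratifiedKFold

#: default tROC horizons in days (3 / 5 / 10 years)
DEFAULT_HORIZONS = (1095.0, 1825.0, 3650.0)


# ---------------------------------------------------------------------------
# confusion metrics

@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            TP=int(((y_true == 1) & (y_pred == 1)).sum()),
            FP=int(((y_true == 0) & (y_pred == 1)).sum()),
            TN=int(((y_true == 0) & (y_pred == 0)).sum()),
            FN=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


def _ratio(num, den) -> float:
    return num / den if den > 0 else float("nan")


def confusion_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity (recall), specificity, precision, F1.

    Ratios with a zero denominator are reported as NaN rather than raising.
    """
    if c.total == 0:
        raise ValueError("empty confusion counts")
    sens = _ratio(c.TP, c.TP + c.FN)
    prec = _ratio(c.TP, c.TP + c.FP)
    f1 = (2 * prec * sens / (prec + sens)
          if not (math.isnan(prec) or math.isnan(sens)) and (prec + sens) > 0
          else float("nan"))
    return {
        "accuracy": (c.TP + c.TN) / c.total,
        "sensitivity": sens,
        "specificity": _ratio(c.TN, c.TN + c.FP),
        "precision": prec,
        "recall": sens,
        "f1": f1,
    }


# ---------------------------------------------------------------------------
# ROC

@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_curve(scores, labels) -> ROCCurve:
    """Standard ROC over the unique-score threshold sweep; trapezoid AUC."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.min() == labels.max():
        raise ValueError("ROC requires both classes")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return ROCCurve(thr, fpr, tpr, float(_sk_auc(fpr, tpr)))


# ---------------------------------------------------------------------------
# Kaplan-Meier

@dataclass
class SurvivalCurve:
    times: np.ndarray        # distinct event times, ascending
    survival: np.ndarray     # S(t) just after each event time
    at_risk: np.ndarray      # risk-set size just before each event time
    n_events: np.ndarray

    def at(self, t: float) -> float:
        """S(t); right-continuous step function starting at 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> SurvivalCurve:
    """Product-limit estimator; censored subjects leave the risk set after their time."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if times.size == 0:
        raise ValueError("empty survival data")
    order = np.argsort(times, kind="stable")
    t_sorted, e_sorted = times[order], events[order]
    event_times = np.unique(t_sorted[e_sorted == 1])
    surv, atrisk, nev = [], [], []
    s = 1.0
    for t in event_times:
        n_risk = int((t_sorted >= t).sum())
        d = int(((t_sorted == t) & (e_sorted == 1)).sum())
        s *= 1.0 - d / n_risk
        surv.append(s)
        atrisk.append(n_risk)
        nev.append(d)
    return SurvivalCurve(event_times, np.array(surv), np.array(atrisk, dtype=int),
                         np.array(nev, dtype=int))


def km_survival_at(times, events, t: float) -> float:
    """KM survival probability S(t) (1.0 when no events by t or no data)."""
    times = np.asarray(times, dtype=float)
    if times.size == 0 or np.asarray(events).sum() == 0:
        return 1.0
    return km_estimate(times, events).at(t)


# ---------------------------------------------------------------------------
# time-dependent ROC (cumulative cases / dynamic controls, KM weighting)

@dataclass
class TimeDependentROC:
    horizon: float
    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float


def time_dependent_roc(scores, times, events, horizon: float) -> TimeDependentROC:
    """KM-weighted cumulative/dynamic ROC at a fixed survival horizon.

    Cases are subjects with the event by ``horizon``; controls are subjects
    surviving beyond it.  Censoring is handled by conditional Kaplan-Meier
    estimates within the score strata, so the estimator reduces exactly to
    the plain ROC (labels = event-by-t) when nobody is censored before t.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    S_t = km_survival_at(times, events, horizon)
    if S_t >= 1.0:
        raise ValueError(f"no events observed by horizon {horizon}")
    if S_t <= 0.0:
        raise ValueError(f"KM survival is 0 at horizon {horizon}")

    uniq = np.unique(scores)
    # c sweeps strictly below the smallest score (everyone positive) up to the
    # largest score (nobody positive)
    cuts = np.concatenate([[-np.inf], uniq])
    sens = np.empty(len(cuts))
    spec = np.empty(len(cuts))
    n = len(scores)
    for i, c in enumerate(cuts):
        above = scores > c
        p_above = above.mean()
        if p_above == 0:
            sens[i], spec[i] = 0.0, 1.0
            continue
        if p_above == 1:
            sens[i], spec[i] = 1.0, 0.0
            continue
        s_above = km_survival_at(times[above], events[above], horizon)
        s_below = km_survival_at(times[~above], events[~above], horizon)
        sens[i] = (1.0 - s_above) * p_above / (1.0 - S_t)
        spec[i] = s_below * (1.0 - p_above) / S_t
    # integrate along the threshold sweep itself (strictest cut first), the
    # natural traversal from (0,0) to (1,1); robust to the small non-
    # monotonicities the KM-weighted estimator can produce
    x = (1 - spec)[::-1]
    y = sens[::-1]
    auc = float(np.trapezoid(y, x))
    return TimeDependentROC(horizon, cuts, sens, spec, auc)


# ---------------------------------------------------------------------------
# log-rank

def logrank_test(times, events, groups) -> dict[str, float]:
    """Two-group log-rank chi-square (1 df) via O-E with hypergeometric variance."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    groups = np.asarray(groups).astype(int)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError("log-rank requires exactly two non-empty groups")
    g1 = groups == labels[0]
    O1 = E1 = V = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n_j = int(at_risk.sum())
        d_j = int(((times == t) & (events == 1)).sum())
        n1 = int((at_risk & g1).sum())
        d1 = int(((times == t) & (events == 1) & g1).sum())
        O1 += d1
        E1 += d_j * n1 / n_j
        if n_j > 1:
            V += d_j * (n1 / n_j) * (1 - n1 / n_j) * (n_j - d_j) / (n_j - 1)
    if V == 0:
        return {"statistic": 0.0, "p_value": 1.0}
    stat = (O1 - E1) ** 2 / V
    return {"statistic": float(stat), "p_value": float(stats.chi2.sf(stat, df=1))}


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties, Newton-Raphson)

@dataclass
class CoxFit:
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    n_iter: int

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.beta, "HR": self.hazard_ratios, "se": self.se,
             "p": self.p_values},
            index=self.names,
        )


def _cox_loglik_grad_hess(beta, X, times, events):
    """Breslow partial log-likelihood with analytic gradient and Hessian."""
    order = np.argsort(-times, kind="stable")  # descending time -> cumulative risk sets
    Xs, ts, es = X[order], times[order], events[order]
    eta = Xs @ beta
    w = np.exp(eta)
    p = X.shape[1]
    ll, grad, hess = 0.0, np.zeros(p), np.zeros((p, p))
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    n = len(ts)
    while i < n:
        t = ts[i]
        j = i
        while j < n and ts[j] == t:
            s0 += w[j]
            s1 += w[j] * Xs[j]
            s2 += w[j] * np.outer(Xs[j], Xs[j])
            j += 1
        for k in range(i, j):
            if es[k] == 1:
                xbar = s1 / s0
                ll += eta[k] - np.log(s0)
                grad += Xs[k] - xbar
                hess -= s2 / s0 - np.outer(xbar, xbar)
        i = j
    return ll, grad, hess


def cox_fit(times, events, covariates: pd.DataFrame, max_iter: int = 50,
            tol: float = 1e-9) -> CoxFit:
    """Newton-Raphson maximum partial likelihood with Wald inference."""
    X = np.asarray(covariates, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    names = list(covariates.columns)
    if events.sum() < 1:
        raise ValueError("Cox regression needs at least one event")
    if np.any(np.ptp(X, axis=0) == 0):
        bad = [names[j] for j in np.where(np.ptp(X, axis=0) == 0)[0]]
        raise ValueError(f"constant covariate(s): {bad}")
    beta = np.zeros(X.shape[1])
    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        ll, grad, hess = _cox_loglik_grad_hess(beta, X, times, events)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("singular Hessian in Cox fit") from exc
        new_beta = beta - step
        # step-halving keeps the likelihood ascending
        for _ in range(20):
            ll_new = _cox_loglik_grad_hess(new_beta, X, times, events)[0]
            if ll_new >= ll - 1e-12:
                break
            new_beta = (beta + new_beta) / 2
        beta = new_beta
        if np.abs(ll_new - ll_old) < tol:
            break
        ll_old = ll_new
    else:
        raise RuntimeError(
            f"Cox fit did not converge in {max_iter} iterations "
            f"(last |dll|={abs(ll_new - ll_old):.2e})"
        )
    if np.any(np.abs(beta) > 10):
        warnings.warn("very large |beta|: possible separation", stacklevel=2)
    ll, grad, hess = _cox_loglik_grad_hess(beta, X, times, events)
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    return CoxFit(names, beta, se, p, float(ll), it)


def cox_screen(times, events, covariates: pd.DataFrame,
               p_threshold: float = 0.05) -> dict:
    """Univariable Cox per covariate, then multivariable refit of the p<threshold set."""
    uni = {}
    for col in covariates.columns:
        uni[col] = cox_fit(times, events, covariates[[col]])
    keep = [c for c in covariates.columns if uni[c].p_values[0] < p_threshold]
    multi = cox_fit(times, events, covariates[keep]) if len(keep) >= 1 else None
    return {"univariable": uni, "selected": keep, "multivariable": multi}


# ---------------------------------------------------------------------------
# cohort summaries

def fraction_within(table: pd.DataFrame, within: tuple[str, object],
                    of: tuple[str, object]) -> dict[str, float]:
    """Share of samples with ``of`` among those matching ``within``.

    Returns the numerator and denominator counts plus the percentage, e.g.
    the percentage of stage-4 tumours among MYCN-amplified patients.
    """
    wcol, wval = within
    ocol, oval = of
    denom = table[table[wcol] == wval]
    num = denom[denom[ocol] == oval]
    pct = 100.0 * len(num) / len(denom) if len(denom) else float("nan")
    return {"count": len(num), "total": len(denom), "percent": pct}


# ---------------------------------------------------------------------------
# cross-validation harness

@dataclass
class CrossValResult:
    """Per-fold AUCs from repeated stratified k-fold CV, Table-style summary."""

    folds: pd.DataFrame            # columns: repeat, fold, train_auc, test_auc, val_auc, troc_<h>...
    horizons: tuple
    best_model: object = None
    best_auc: float = float("nan")

    def summary(self) -> pd.DataFrame:
        cols = [c for c in self.folds.columns if c not in ("repeat", "fold")]
        return self.folds[cols].agg(["mean", "std"]).T


def cross_validate(expr, features, labels, config, times=None, events=None,
                   folds: int = 10, repeats: int = 20,
                   horizons=DEFAULT_HORIZONS, seed: int = 0) -> CrossValResult:
    """Repeated stratified k-fold CV of the gated classifier.

    Within every training portion the trainer's own 10% random validation
    holdout monitors early stopping; its best-epoch AUC is reported as the
    validation column.  When survival times are supplied, time-dependent ROC
    AUCs at each horizon are computed on the held-out fold.  The model with
    the highest test AUC across all folds is retained.
    """
    from dataclasses import replace as _replace
    from . import network as net

    labels = np.asarray(labels).astype(int)
    n = len(labels)
    if n < folds:
        raise ValueError(f"n={n} < folds={folds}")
    rows = []
    best_model, best_auc = None, -np.inf
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(repeats)]
    for rep, rseed in enumerate(rep_seeds):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rseed)
        for fold, (tr, te) in enumerate(skf.split(np.zeros(n), labels)):
            if labels[te].min() == labels[te].max():
                warnings.warn("single-class test fold; metrics limited", stacklevel=2)
            sub_tr = expr.subset_samples([expr.sample_ids[i] for i in tr])
            sub_te = expr.subset_samples([expr.sample_ids[i] for i in te])
            cfg = _replace(config, seed=rseed + fold)
            params, hist = net.train(sub_tr, features, labels[tr], cfg)
            p_tr = net.predict_proba(params, sub_tr, features)
            p_te = net.predict_proba(params, sub_te, features)
            row = {
                "repeat": rep, "fold": fold,
                "train_auc": net._safe_auc(labels[tr], p_tr),
                "test_auc": net._safe_auc(labels[te], p_te),
                "val_auc": (hist.val_auc[hist.best_epoch]
                            if hist.val_auc and hist.best_epoch >= 0 else float("nan")),
            }
            if times is not None and events is not None:
                t_te = np.asarray(times)[te]
                e_te = np.asarray(events)[te]
                for h in horizons:
                    try:
                        row[f"troc_auc_{int(h)}"] = time_dependent_roc(
                            p_te, t_te, e_te, h).auc
                    except ValueError:
                        row[f"troc_auc_{int(h)}"] = float("nan")
            rows.append(row)
            if not math.isnan(row["test_auc"]) and row["test_auc"] > best_auc:
                best_auc = row["test_auc"]
                best_model = params
    return CrossValResult(pd.DataFrame(rows), tuple(horizons), best_model,
                          float(best_auc))
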
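"""Median-dichotomized expression survival analysis.

High/Low groups split patients at the median expression value (ties go
Low); groups are compared with the Kaplan-Meier product-limit estimator,
the two-group log-rank test, and a univariate Cox proportional-hazards fit
(Breslow tie handling, Newton-Raphson on the partial likelihood).  A
feature screen applies Bonferroni correction across the features tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError


@dataclass
class SurvivalResult:
    feature_id: str | None
    km_curves: dict[str, pd.DataFrame]
    logrank_chi2: float
    logrank_p: float
    cox_beta: float | None
    hr: float | None
    cox_p: float | None
    converged: bool
    adj_p: float | None = None


def dichotomize_by_median(values: pd.Series) -> pd.Series:
    """High = strictly above the median, Low = at or below (ties Low)."""
    if len(values) < 2:
        raise ValidationError("need >= 2 patients to dichotomize")
    v = values.astype(float)
    if v.nunique() == 1:
        raise ValidationError("all expression values identical; no median split")
    med = float(v.median())
    return pd.Series(np.where(v > med, "High", "Low"), index=values.index, name="group")


def _check_surv(time: np.ndarray, event: np.ndarray) -> None:
    if (time < 0).any():
        raise ValidationError("negative survival times")
    if time.shape != event.shape:
        raise ValidationError("time/event length mismatch")


def kaplan_meier(time, event) -> pd.DataFrame:
    """Product-limit estimator.

    Returns a DataFrame (time, n_at_risk, n_events, survival) with one row
    per distinct event time; censored observations leave the risk set
    without a step.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    _check_surv(time, event)
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    rows = []
    s = 1.0
    n = len(time)
    for t in np.unique(time[event]):
        at_risk = int((time >= t).sum())
        d = int(((time == t) & event).sum())
        s *= 1.0 - d / at_risk
        rows.append({"time": float(t), "n_at_risk": at_risk, "n_events": d, "survival": s})
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def km_by_group(data: pd.DataFrame) -> dict[str, pd.DataFrame]:
    return {
        g: kaplan_meier(grp["time_months"], grp["event"])
        for g, grp in data.groupby("group")
    }


def logrank_test(data: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test: chi2 = (sum(O - E))^2 / sum(V) over distinct
    event times, p from chi-square with 1 df."""
    groups = data["group"].unique()
    if len(groups) != 2:
        raise ValidationError(f"log-rank needs exactly 2 nonempty groups, got {len(groups)}")
    time = data["time_months"].to_numpy(dtype=float)
    event = data["event"].to_numpy(dtype=bool)
    _check_surv(time, event)
    if not event.any():
        raise ValidationError("log-rank needs at least one event")
    g1 = (data["group"] == groups[0]).to_numpy()
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((time == t) & event).sum()
        d1 = ((time == t) & event & g1).sum()
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def cox_fit(
    data: pd.DataFrame,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> tuple[float | None, float | None, float | None, bool]:
    """Univariate Cox PH for the binary High/Low group.

    Maximizes the Breslow partial likelihood by Newton-Raphson (start 0,
    step-halving on likelihood decrease).  Returns (beta, hr, wald_p,
    converged); a monotone likelihood (complete separation of event times)
    is reported as non-converged with absent estimates.
    """
    x = (data["group"] == "High").to_numpy(dtype=float)
    time = data["time_months"].to_numpy(dtype=float)
    event = data["event"].to_numpy(dtype=bool)
    _check_surv(time, event)
    if event[x == 1].sum() == 0 or event[x == 0].sum() == 0:
        return None, None, None, False

    event_times = np.unique(time[event])

    def loglik_grad_hess(beta: float) -> tuple[float, float, float]:
        ll = grad = hess = 0.0
        eta = beta * x
        w = np.exp(eta)
        for t in event_times:
            at_risk = time >= t
            d_mask = (time == t) & event
            d = int(d_mask.sum())
            s0 = w[at_risk].sum()
            s1 = (w * x)[at_risk].sum()
            xbar = s1 / s0
            ll += eta[d_mask].sum() - d * np.log(s0)
            grad += x[d_mask].sum() - d * xbar
            hess -= d * (xbar - xbar**2)
        return ll, grad, hess

    beta = 0.0
    ll, grad, hess = loglik_grad_hess(beta)
    converged = False
    for _ in range(max_iter):
        if hess >= -1e-12:
            break
        step = -grad / hess
        # step-halving on likelihood decrease
        for _ in range(30):
            new_beta = beta + step
            new_ll, new_grad, new_hess = loglik_grad_hess(new_beta)
            if new_ll >= ll - 1e-12:
                break
            step /= 2.0
        if abs(new_beta - beta) < tol:
            beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
            converged = True
            break
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
    if not converged or abs(beta) > 50:
        return None, None, None, False
    se = float(np.sqrt(-1.0 / hess))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(beta), float(np.exp(beta)), p, True


def cox_score_test(data: pd.DataFrame) -> float:
    """Cox score statistic at beta=0 (equals the log-rank chi2 absent ties)."""
    x = (data["group"] == "High").to_numpy(dtype=float)
    time = data["time_months"].to_numpy(dtype=float)
    event = data["event"].to_numpy(dtype=bool)
    grad = info = 0.0
    for t in np.unique(time[event]):
        at_risk = time >= t
        d_mask = (time == t) & event
        d = int(d_mask.sum())
        n = at_risk.sum()
        xbar = x[at_risk].mean()
        grad += x[d_mask].sum() - d * xbar
        info += d * (xbar - xbar**2)
    return float(grad**2 / info) if info > 0 else 0.0


def analyze_groups(data: pd.DataFrame, feature_id: str | None = None) -> SurvivalResult:
    """KM + log-rank + Cox for a prepared (time, event, group) table."""
    chi2, p_lr = logrank_test(data)
    beta, hr, p_cox, conv = cox_fit(data)
    return SurvivalResult(
        feature_id=feature_id,
        km_curves=km_by_group(data),
        logrank_chi2=chi2,
        logrank_p=p_lr,
        cox_beta=beta,
        hr=hr,
        cox_p=p_cox,
        converged=conv,
    )


def survival_screen(
    expr,
    survival: pd.DataFrame,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Per-feature median-dichotomized Cox screen with Bonferroni adj_p.

    ``expr`` is an ExprMatrix whose columns are patient ids matching
    ``survival['patient_id']``; the Bonferroni factor is the number of
    features actually tested.
    """
    feats = list(features) if features is not None else list(expr.feature_ids)
    missing = [f for f in feats if f not in set(expr.feature_ids)]
    if missing:
        raise ValidationError(f"features absent from expression: {missing[:5]}")
    surv = survival.set_index("patient_id")
    patients = [p for p in expr.sample_ids if p in surv.index]
    rows = []
    for f in feats:
        vals = expr.values.loc[f, patients]
        groups = dichotomize_by_median(vals)
        d = pd.DataFrame(
            {
                "time_months": surv.loc[patients, "time_months"].to_numpy(),
                "event": surv.loc[patients, "event"].to_numpy(dtype=bool),
                "group": groups.to_numpy(),
            }
        )
        beta, hr, p, conv = cox_fit(d)
        rows.append(
            {"feature_id": f, "cox_beta": beta, "hr": hr, "p": p, "converged": conv}
        )
    out = pd.DataFrame(rows)
    m = len(out)
    out["adj_p"] = [min(1.0, m * p) if p is not None else None for p in out["p"]]
    return out
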
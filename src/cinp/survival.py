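"""PC1 expression metagene construction and survival analysis.

A gene module's activity in a patient cohort is summarized as the projection
of the (gene-wise standardized) patient x gene expression matrix on its
first principal component.  Because PC sign is arbitrary, the loadings are
oriented so the score correlates positively with the patients' mean module
expression — the module contains only genes upregulated with the phenotype,
so higher mean expression means higher module activity.  Patients are split
at score quantiles (top 30% high, bottom 30% low) and compared by
Kaplan-Meier curves with a two-group log-rank test; a Cox proportional-
hazards regression (Efron tie handling, Newton-Raphson on the partial
likelihood) adjusts for age and optionally molecular subtype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthgen import SurvivalCohort

__all__ = [
    "MetageneResult",
    "KMCurve",
    "CoxResult",
    "SurvivalReport",
    "build_metagene",
    "orient_and_group",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "survival_pipeline",
]


@dataclass(frozen=True)
class MetageneResult:
    """PC1 loadings, oriented per-patient scores and quantile groups."""

    loadings: pd.Series  # per-gene weight, oriented
    scores: pd.Series  # per-patient scalar, oriented
    orientation_sign: int
    group: pd.Series  # per-patient in {"high", "low", "mid"}
    quantile: float

    def group_counts(self) -> dict[str, int]:
        return self.group.value_counts().to_dict()


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate with per-event-time bookkeeping."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    censor_times: np.ndarray

    def step_coordinates(self) -> pd.DataFrame:
        """Step-function coordinates starting at (0, 1)."""
        t = np.concatenate([[0.0], self.event_times])
        s = np.concatenate([[1.0], self.survival])
        return pd.DataFrame({"time": t, "survival": s})


@dataclass(frozen=True)
class CoxResult:
    """Cox proportional-hazards fit: per-covariate beta, HR, se, Wald p."""

    summary: pd.DataFrame  # index covariate; columns beta, hr, se, z, p
    log_likelihood: float
    converged: bool
    n: int
    n_events: int
    message: str = ""

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])


@dataclass(frozen=True)
class SurvivalReport:
    """Joined output of the metagene + KM + log-rank + Cox pipeline."""

    metagene: MetageneResult
    km_high: KMCurve
    km_low: KMCurve
    logrank_statistic: float
    logrank_p: float
    cox: CoxResult
    truncation_months: float | None = None

    def to_dict(self) -> dict:
        return {
            "group_counts": self.metagene.group_counts(),
            "logrank_statistic": self.logrank_statistic,
            "logrank_p": self.logrank_p,
            "cox": self.cox.summary.to_dict(orient="index"),
            "cox_converged": self.cox.converged,
            "n": self.cox.n,
            "n_events": self.cox.n_events,
            "truncation_months": self.truncation_months,
        }


# ---------------------------------------------------------------------------
# Metagene
# ---------------------------------------------------------------------------

def orient_and_group(
    raw_scores: pd.Series,
    mean_expression: pd.Series,
    quantile: float = 0.30,
) -> tuple[int, pd.Series, pd.Series]:
    """Fix the PC sign against mean module expression and split at quantiles.

    Returns (orientation_sign, oriented scores, group labels).  The sign
    makes the score correlate positively with per-patient mean module
    expression (ties: a zero or undefined correlation keeps +1).  Groups:
    top ``quantile`` of scores -> "high", bottom ``quantile`` -> "low", rest
    "mid"; ranks are assigned by a stable sort on (score, patient id) so
    boundary ties resolve deterministically.
    """
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(raw_scores.values, mean_expression.values)[0, 1]
    sign = -1 if np.isfinite(r) and r < 0 else 1
    scores = raw_scores * sign
    n = len(scores)
    n_tail = int(np.floor(quantile * n))
    order = pd.DataFrame({"score": scores, "pid": scores.index.astype(str)})
    order = order.sort_values(["score", "pid"], kind="stable")
    group = pd.Series("mid", index=scores.index, name="group")
    group.loc[order.index[:n_tail]] = "low"
    group.loc[order.index[n - n_tail:]] = "high"
    return sign, scores, group


def build_metagene(
    cohort: SurvivalCohort,
    module_genes: Sequence[str] | None = None,
    quantile: float = 0.30,
) -> MetageneResult:
    """PC1 metagene of the module genes over a patient cohort.

    Each gene is standardized across patients, PC1 of the patient x gene
    matrix is extracted by SVD, each patient's score is the projection on
    PC1, and the sign is oriented by :func:`orient_and_group`.
    """
    genes = list(module_genes) if module_genes is not None else cohort.module_genes
    missing = set(genes) - set(cohort.expression.columns)
    if missing:
        raise KeyError(f"module genes absent from cohort: {sorted(missing)[:5]}")
    if len(genes) < 1:
        raise ValueError("need >= 1 module gene")
    if len(cohort.clinical) < 10:
        raise ValueError("need >= 10 patients")
    X = cohort.expression[genes].values.astype(float)
    sd = X.std(axis=0, ddof=0)
    if np.all(sd == 0):
        raise ValueError("degenerate PCA: all module genes are constant")
    keep = sd > 0
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    u, s, vt = np.linalg.svd(Xs, full_matrices=False)
    loadings = np.zeros(len(genes))
    loadings[keep] = vt[0]
    raw = pd.Series(Xs @ vt[0], index=cohort.clinical["patient_id"].values, name="score")
    mean_expr = pd.Series(X.mean(axis=1), index=raw.index)
    sign, scores, group = orient_and_group(raw, mean_expr, quantile)
    return MetageneResult(
        loadings=pd.Series(loadings * sign, index=genes, name="loading"),
        scores=scores,
        orientation_sign=sign,
        group=group,
        quantile=quantile,
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

def _as_time_event(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("times and events must be matching 1-D arrays")
    if t.size == 0:
        raise ValueError("need at least one subject")
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("events must be 0/1")
    return t, e


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator with right censoring.

    S(t) = prod over event times t_j <= t of (1 - d_j / n_j) with d_j events
    among n_j at risk.
    """
    t, e = _as_time_event(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq = np.unique(t[e == 1])
    n_total = t.size
    at_risk = np.array([np.sum(t >= u) for u in uniq], dtype=int)
    n_events = np.array([np.sum((t == u) & (e == 1)) for u in uniq], dtype=int)
    surv = np.cumprod(1.0 - n_events / at_risk) if uniq.size else np.array([])
    return KMCurve(
        event_times=uniq,
        survival=surv,
        at_risk=at_risk,
        n_events=n_events,
        censor_times=np.sort(t[e == 0]),
    )


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test (1 df).

    At each distinct event time the observed events in group A are compared
    with the hypergeometric expectation given the pooled risk set; the
    statistic is (sum(O-E))^2 / sum(Var) and the two-sided p comes from
    chi-square(1).
    """
    ta, ea = _as_time_event(times_a, events_a)
    tb, eb = _as_time_event(times_b, events_b)
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.zeros(ta.size, dtype=int), np.ones(tb.size, dtype=int)])
    if e.sum() == 0:
        raise ValueError("log-rank test undefined with zero events")
    uniq = np.unique(t[e == 1])
    o_minus_e = 0.0
    var = 0.0
    for u in uniq:
        at_risk = t >= u
        n_j = at_risk.sum()
        n_a = (at_risk & (g == 0)).sum()
        d_j = ((t == u) & (e == 1)).sum()
        d_a = ((t == u) & (e == 1) & (g == 0)).sum()
        o_minus_e += d_a - d_j * n_a / n_j
        if n_j > 1:
            var += d_j * (n_a / n_j) * (1 - n_a / n_j) * (n_j - d_j) / (n_j - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties, Newton-Raphson)
# ---------------------------------------------------------------------------

def _cox_loglik(beta: np.ndarray, X: np.ndarray, t: np.ndarray, e: np.ndarray):
    """Efron log-partial-likelihood with gradient and information matrix.

    Subjects must be sorted by time.  For each distinct event time with d
    tied events, the Efron correction subtracts l/d of the tied subjects'
    risk contributions at the l-th tied factor.
    """
    n, p = X.shape
    eta = X @ beta
    eta -= eta.max()  # guard overflow; partial likelihood is shift-invariant
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = np.einsum("i,ij,ik->ijk", w, X, X)

    # suffix sums over the risk set (times sorted ascending)
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d_idx = [k for k in range(i, j) if e[k] == 1]
        d = len(d_idx)
        if d > 0:
            s0r, s1r, s2r = S0[i], S1[i], S2[i]
            s0d = w[d_idx].sum()
            s1d = wx[d_idx].sum(axis=0)
            s2d = wxx[d_idx].sum(axis=0)
            ll += eta[d_idx].sum()
            grad += X[d_idx].sum(axis=0)
            for l in range(d):
                f = l / d
                z0 = s0r - f * s0d
                z1 = s1r - f * s1d
                z2 = s2r - f * s2d
                ll -= np.log(z0)
                grad -= z1 / z0
                info += z2 / z0 - np.outer(z1, z1) / z0**2
        i = j
    return ll, grad, info


def cox_fit(
    X: pd.DataFrame,
    times,
    events,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> CoxResult:
    """Maximum partial-likelihood Cox regression.

    Newton-Raphson with step halving on the Efron partial likelihood; Wald
    standard errors come from the inverse observed information.  A constant
    (uninformative) covariate yields beta = 0, HR = 1 with infinite standard
    error rather than an exception; non-convergence is flagged, not raised.
    """
    t, e = _as_time_event(times, events)
    if e.sum() == 0:
        raise ValueError("Cox fit requires at least one event")
    Xv = X.values.astype(float)
    order = np.argsort(t, kind="stable")
    Xv, ts, es = Xv[order], t[order], e[order]
    p = Xv.shape[1]
    beta = np.zeros(p)
    ll, grad, info = _cox_loglik(beta, Xv, ts, es)
    converged = False
    message = ""
    for _ in range(max_iter):
        if np.linalg.norm(grad, ord=np.inf) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.pinv(info) @ grad
        new_beta = beta + step
        new_ll, new_grad, new_info = _cox_loglik(new_beta, Xv, ts, es)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_info = _cox_loglik(new_beta, Xv, ts, es)
            halvings += 1
        if halvings == 30:
            message = "step-halving failed; possible separation"
            break
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
    else:
        message = "maximum iterations reached"
    if not converged and not message:
        converged = np.linalg.norm(grad, ord=np.inf) < tol
    with np.errstate(invalid="ignore", divide="ignore"):
        try:
            cov = np.linalg.inv(info)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(p, np.inf)
        se = np.where(se == 0, np.inf, se)
        z = beta / se
        pvals = 2 * stats.norm.sf(np.abs(z))
    summary = pd.DataFrame(
        {"beta": beta, "hr": np.exp(beta), "se": se, "z": z, "p": pvals},
        index=list(X.columns),
    )
    return CoxResult(
        summary=summary,
        log_likelihood=float(ll),
        converged=bool(converged),
        n=int(ts.size),
        n_events=int(es.sum()),
        message=message,
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _truncate(clinical: pd.DataFrame, months: float) -> pd.DataFrame:
    """Administrative censoring at ``months`` (e.g. 60 for 5-year analyses)."""
    out = clinical.copy()
    over = out["time_months"] > months
    out.loc[over, "time_months"] = months
    out.loc[over, "event"] = 0
    return out


def survival_pipeline(
    cohort: SurvivalCohort,
    module_genes: Sequence[str] | None = None,
    covariates: Sequence[str] = ("age", "score"),
    quantile: float = 0.30,
    truncation_months: float | None = None,
) -> SurvivalReport:
    """Metagene scoring, 30/30 stratified KM + log-rank, and Cox regression.

    ``covariates`` name clinical columns plus the special entries "score"
    (continuous standardized metagene score) and "subtype" (expanded to
    indicator columns against the most frequent reference level).
    """
    metagene = build_metagene(cohort, module_genes, quantile)
    clinical = cohort.clinical.reset_index(drop=True)
    if truncation_months is not None:
        clinical = _truncate(clinical, truncation_months)
    score = metagene.scores.values
    score_std = (score - score.mean()) / score.std(ddof=0)
    group = metagene.group.values

    hi = group == "high"
    lo = group == "low"
    km_high = km_estimate(clinical.loc[hi, "time_months"], clinical.loc[hi, "event"])
    km_low = km_estimate(clinical.loc[lo, "time_months"], clinical.loc[lo, "event"])
    chi2, p = logrank_test(
        clinical.loc[hi, "time_months"], clinical.loc[hi, "event"],
        clinical.loc[lo, "time_months"], clinical.loc[lo, "event"],
    )

    cols: dict[str, np.ndarray] = {}
    for cov in covariates:
        if cov == "score":
            cols["score"] = score_std
        elif cov == "subtype":
            sub = clinical["subtype"].astype(str)
            ref = sub.value_counts().idxmax()
            for level in sorted(set(sub) - {ref}):
                cols[f"subtype_{level}"] = (sub == level).astype(float).values
        else:
            cols[cov] = clinical[cov].values.astype(float)
    Xcov = pd.DataFrame(cols)
    cox = cox_fit(Xcov, clinical["time_months"], clinical["event"])
    return SurvivalReport(
        metagene=metagene,
        km_high=km_high,
        km_low=km_low,
        logrank_statistic=chi2,
        logrank_p=p,
        cox=cox,
        truncation_months=truncation_months,
    )
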
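"""Cohort-level inference: Kaplan-Meier, ridge Cox PH, log-normal AFT,
Baron-Kenny mediation and 2x2 categorical association tests.

The Cox partial likelihood (Efron tie handling) with an optional ridge
penalty is maximized by Newton iteration written here, because the ridge
penalty and its cross-validated selection are part of the analysis contract;
Kaplan-Meier and the parametric log-normal accelerated-failure-time model go
through lifelines, and the logistic mediator model through statsmodels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter, LogNormalAFTFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats

from .errors import FitError

DEFAULT_LAMBDA_GRID = (0.0, 0.01, 0.1, 1.0, 10.0, 100.0)


# ---------------------------------------------------------------------------
# Cohort table handling
# ---------------------------------------------------------------------------

COHORT_COLUMNS = ["sample_id", "time_days", "event", "ecDNA", "tp53", "subgroup", "age", "sex"]


def load_cohort(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"cohort table missing columns {sorted(missing)}")
    return frame


def design_matrix(
    records: pd.DataFrame,
    covariates: Sequence[str],
    reference_levels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Dummy-code categorical covariates and drop incomplete records.

    Records with any missing covariate, time or event are excluded (no
    imputation). The reference level for a categorical covariate defaults to
    its largest group.
    """
    reference_levels = dict(reference_levels or {})
    cols = list(covariates)
    sub = records[cols].copy()
    keep = sub.notna().all(axis=1)
    if {"time_days", "event"}.issubset(records.columns):
        keep &= records["time_days"].notna() & records["event"].notna()
    sub = sub.loc[keep]
    parts: list[pd.DataFrame] = []
    for col in cols:
        series = sub[col]
        if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
            ref = reference_levels.get(col, series.value_counts().idxmax())
            dummies = pd.get_dummies(series, prefix=col, dtype=float)
            ref_col = f"{col}_{ref}"
            if ref_col in dummies.columns:
                dummies = dummies.drop(columns=ref_col)
            parts.append(dummies)
        else:
            parts.append(series.astype(float).to_frame(col))
    X = pd.concat(parts, axis=1)
    X.index = sub.index
    return X


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------


@dataclass
class KMEstimate:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray


def km_estimate(
    time: Sequence[float],
    event: Sequence[int],
    group: Sequence | None = None,
) -> tuple[dict[str, KMEstimate], tuple[float, float] | None]:
    """Product-limit estimates per group plus a log-rank test between groups.

    With a single group (or ``group=None``) the log-rank result is None; with
    two groups it is the two-sided 1-df chi-squared test; with more groups the
    multivariate log-rank generalization.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if group is None:
        group = np.zeros(time.size, dtype=int)
    group = np.asarray(group)

    estimates: dict[str, KMEstimate] = {}
    for g in pd.unique(group):
        sel = group == g
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event[sel])
        tbl = kmf.event_table
        estimates[str(g)] = KMEstimate(
            times=tbl.index.to_numpy(dtype=float),
            survival=kmf.survival_function_at_times(tbl.index).to_numpy(),
            at_risk=tbl["at_risk"].to_numpy(),
            events=tbl["observed"].to_numpy(),
        )

    levels = pd.unique(group)
    logrank: tuple[float, float] | None = None
    if len(levels) == 2:
        a, b = (group == levels[0]), (group == levels[1])
        res = logrank_test(time[a], time[b], event[a], event[b])
        logrank = (float(res.test_statistic), float(res.p_value))
    elif len(levels) > 2:
        res = multivariate_logrank_test(time, group, event)
        logrank = (float(res.test_statistic), float(res.p_value))
    return estimates, logrank


# ---------------------------------------------------------------------------
# Ridge Cox proportional hazards (Efron ties), Newton iteration
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    covariates: list[str]
    beta: np.ndarray
    hazard_ratios: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    se: np.ndarray
    loglik: float  # unpenalized log partial likelihood at beta
    penalized_loglik: float
    ridge_lambda: float
    converged: bool
    n_iter: int
    n: int
    n_events: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.beta,
                "HR": self.hazard_ratios,
                "HR_lower95": np.exp(np.log(self.hazard_ratios) - 1.959963984540054 * self.se),
                "HR_upper95": np.exp(np.log(self.hazard_ratios) + 1.959963984540054 * self.se),
            },
            index=self.covariates,
        )


def _efron_groups(time: np.ndarray, event: np.ndarray):
    """Sorted-order arrays and event-time tie groups for Efron's likelihood.

    Returns data sorted by ascending time and, per distinct event time, the
    index (into sorted order) where its risk set begins plus the indices of
    the tied events.
    """
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    groups = []
    for ut in np.unique(t[e == 1]):
        risk_start = int(np.searchsorted(t, ut, side="left"))
        deaths = np.nonzero((t == ut) & (e == 1))[0]
        groups.append((risk_start, deaths))
    return order, groups


def cox_partial_loglik(
    beta: np.ndarray,
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    ties: str = "efron",
) -> float:
    """Log partial likelihood (unpenalized) at beta."""
    ll, _, _ = _cox_ll_grad_hess(beta, X, time, event, need_derivs=False, ties=ties)
    return ll


def _cox_ll_grad_hess(beta, X, time, event, need_derivs=True, ties="efron"):
    n, p = X.shape
    order, groups = _efron_groups(time, event)
    Xs = X[order]
    eta = Xs @ beta
    eta = eta - eta.max()  # stabilize; constants cancel in every term below
    w = np.exp(eta)
    wx = w[:, None] * Xs

    # suffix sums: S_R(i) = sum_{j >= i} over sorted order
    cw = np.cumsum(w[::-1])[::-1]
    cwx = np.cumsum(wx[::-1], axis=0)[::-1]
    if need_derivs:
        wxx = wx[:, :, None] * Xs[:, None, :]
        cwxx = np.cumsum(wxx[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for risk_start, deaths in groups:
        d = len(deaths)
        sR = cw[risk_start]
        sR_x = cwx[risk_start]
        sD = w[deaths].sum()
        sD_x = wx[deaths].sum(axis=0)
        ll += eta[deaths].sum()
        grad += Xs[deaths].sum(axis=0) if need_derivs else 0.0
        if need_derivs:
            sR_xx = cwxx[risk_start]
            sD_xx = wxx[deaths].sum(axis=0)
        for l in range(d):
            frac = l / d if ties == "efron" else 0.0
            denom = sR - frac * sD
            ll -= np.log(denom)
            if need_derivs:
                num = sR_x - frac * sD_x
                grad -= num / denom
                num_xx = sR_xx - frac * sD_xx
                hess -= num_xx / denom - np.outer(num, num) / denom**2
    if not need_derivs:
        return ll, None, None
    return ll, grad, hess


def cox_fit(
    X: pd.DataFrame | np.ndarray,
    time: Sequence[float],
    event: Sequence[int],
    ridge_lambda: float = 0.0,
    max_iter: int = 100,
    grad_tol: float = 1e-8,
    ties: str = "efron",
) -> CoxFit:
    """Maximize the partial likelihood minus (lambda/2)||beta||^2.

    Tied event times are handled by Efron's approximation by default
    (``ties="breslow"`` selects Breslow's). Newton iteration with step
    halving; confidence intervals come from the inverse penalized observed
    information. Convergence requires the penalized gradient norm to fall
    below ``grad_tol * max(1, |loglik|)`` — the relative form keeps the
    criterion attainable when cumulative-sum round-off puts an absolute
    noise floor on the gradient at large likelihood scales. Non-convergence
    is flagged on the returned fit rather than silently ignored.
    """
    if ridge_lambda < 0:
        raise ValueError("ridge penalty must be >= 0")
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{i}" for i in range(np.asarray(X).shape[1])
    ]
    Xa = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 1:
        raise FitError("no events in the data; partial likelihood undefined")
    n, p = Xa.shape

    beta = np.zeros(p)
    converged = False
    it = 0
    ll, grad, hess = _cox_ll_grad_hess(beta, Xa, time, event, ties=ties)
    pll = ll - 0.5 * ridge_lambda * beta @ beta
    for it in range(1, max_iter + 1):
        g = grad - ridge_lambda * beta
        H = hess - ridge_lambda * np.eye(p)
        if np.linalg.norm(g) < grad_tol * max(1.0, abs(pll)):
            converged = True
            break
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            raise FitError("singular information matrix; add a ridge penalty")
        # step halving on the penalized objective
        scale = 1.0
        for _ in range(40):
            cand = beta - scale * step
            ll_c, grad_c, hess_c = _cox_ll_grad_hess(cand, Xa, time, event, ties=ties)
            pll_c = ll_c - 0.5 * ridge_lambda * cand @ cand
            if np.isfinite(pll_c) and pll_c >= pll - 1e-12:
                break
            scale *= 0.5
        beta, ll, grad, hess, pll = cand, ll_c, grad_c, hess_c, pll_c
    else:
        it = max_iter
    if not converged and np.linalg.norm(grad - ridge_lambda * beta) < grad_tol * max(
        1.0, abs(pll)
    ):
        converged = True

    H_pen = hess - ridge_lambda * np.eye(p)
    cov = np.linalg.inv(-H_pen)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    zcrit = 1.959963984540054
    return CoxFit(
        covariates=names,
        beta=beta,
        hazard_ratios=np.exp(beta),
        ci_lower=np.exp(beta - zcrit * se),
        ci_upper=np.exp(beta + zcrit * se),
        se=se,
        loglik=float(ll),
        penalized_loglik=float(pll),
        ridge_lambda=float(ridge_lambda),
        converged=converged,
        n_iter=it,
        n=n,
        n_events=int(event.sum()),
    )


def select_ridge_lambda(
    X: pd.DataFrame | np.ndarray,
    time: Sequence[float],
    event: Sequence[int],
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    folds: int = 5,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Pick the ridge penalty by k-fold cross-validated held-out likelihood.

    For each lambda the model is fitted on the training folds and scored by
    the unpenalized log partial likelihood of the withheld records; ties go
    to the smallest lambda. Folds without events are skipped with a warning.
    """
    grid = sorted(set(float(l) for l in lambda_grid))
    if not grid:
        raise ValueError("empty lambda grid")
    Xa = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = Xa.shape[0]
    if n < folds:
        raise ValueError("need at least as many records as folds")
    rng = np.random.default_rng(seed)
    assignment = np.array_split(rng.permutation(n), folds)

    rows = []
    for lam in grid:
        scores = []
        for fold_idx in assignment:
            test = np.zeros(n, dtype=bool)
            test[fold_idx] = True
            if event[test].sum() == 0 or event[~test].sum() == 0:
                warnings.warn("fold without events skipped during lambda CV")
                continue
            fit = cox_fit(Xa[~test], time[~test], event[~test], ridge_lambda=lam)
            scores.append(cox_partial_loglik(fit.beta, Xa[test], time[test], event[test]))
        rows.append({"lambda": lam, "cv_loglik": float(np.mean(scores)), "n_folds": len(scores)})
    table = pd.DataFrame(rows)
    best = table.loc[table["cv_loglik"].idxmax(), "lambda"]
    return float(best), table


# ---------------------------------------------------------------------------
# Log-normal AFT and Baron-Kenny mediation
# ---------------------------------------------------------------------------


def percentage_change(beta: float) -> float:
    """Effect of a coefficient on survival time, as 100*(e^beta - 1) percent."""
    return 100.0 * (np.exp(beta) - 1.0)


@dataclass
class AFTFit:
    covariates: list[str]
    beta: pd.Series  # coefficients on log-time, intercept included
    se: pd.Series
    sigma: float
    loglik: float
    percentage_changes: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if self.percentage_changes is None:
            covs = [c for c in self.beta.index if c != "Intercept"]
            self.percentage_changes = pd.Series(
                {c: percentage_change(self.beta[c]) for c in covs}
            )


def aft_fit(
    X: pd.DataFrame,
    time: Sequence[float],
    event: Sequence[int],
) -> AFTFit:
    """Log-normal accelerated failure time MLE: log T = X beta + sigma * eps.

    Censored records contribute log-survival terms. Coefficients are on the
    log-time scale; the per-covariate percentage change in survival time is
    100*(e^beta - 1).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 1:
        raise FitError("no events in the data; AFT model unidentified")
    frame = X.copy().astype(float)
    frame["time"] = time
    frame["event"] = event
    fitter = LogNormalAFTFitter(penalizer=0.0, fit_intercept=True)
    try:
        fitter.fit(frame, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines ConvergenceError and kin
        raise FitError(f"log-normal AFT fit failed: {exc}") from exc
    beta = fitter.params_.loc["mu_"]
    se = fitter.standard_errors_.loc["mu_"]
    sigma = float(np.exp(fitter.params_.loc[("sigma_", "Intercept")]))
    return AFTFit(
        covariates=[c for c in beta.index if c != "Intercept"],
        beta=beta,
        se=se,
        sigma=sigma,
        loglik=float(fitter.log_likelihood_),
    )


@dataclass
class MediationResult:
    exposure: str
    mediator: str
    total_effect: float  # AFT coefficient of exposure, mediator excluded
    total_se: float
    direct_effect: float  # AFT coefficient of exposure, mediator included
    direct_se: float
    mediator_effect: float  # AFT coefficient of the mediator itself
    mediator_model_coef: float  # logistic coefficient exposure -> mediator
    attenuation: float  # 1 - direct/total
    total_loglik: float
    direct_loglik: float
    total_pct_change: float
    direct_pct_change: float


def mediation_baron_kenny(
    records: pd.DataFrame,
    exposure: str,
    mediator: str,
    time_col: str = "time_days",
    event_col: str = "event",
    covariates: Sequence[str] = (),
) -> MediationResult:
    """Baron-Kenny mediation with a log-normal AFT outcome model.

    Fits (1) mediator ~ exposure by logistic regression, (2) outcome ~
    exposure (total effect) and (3) outcome ~ exposure + mediator (direct
    effect) by log-normal AFT, and reports the attenuation 1 - direct/total.
    AFT models are used instead of Cox because hazard ratios are
    non-collapsible and cannot be compared across nested models.
    """
    import statsmodels.api as sm

    cols = [exposure, mediator, *covariates, time_col, event_col]
    data = records[cols].dropna()
    e = data[exposure].astype(float)
    m = data[mediator].astype(float)
    if m.nunique() < 2:
        raise ValueError(f"mediator {mediator!r} is constant")
    if e.nunique() < 2:
        raise ValueError(f"exposure {exposure!r} is constant")
    if (e == m).all() or (e == 1 - m).all():
        raise ValueError("mediator is perfectly collinear with the exposure")

    logit = sm.Logit(m, sm.add_constant(pd.DataFrame({exposure: e}))).fit(disp=0)
    a1 = float(logit.params[exposure])

    base_cols = [exposure, *covariates]
    total = aft_fit(data[base_cols], data[time_col], data[event_col])
    direct = aft_fit(
        data[base_cols + [mediator]], data[time_col], data[event_col]
    )
    total_beta = float(total.beta[exposure])
    direct_beta = float(direct.beta[exposure])
    if total_beta == 0:
        raise FitError("total effect is exactly zero; attenuation undefined")
    return MediationResult(
        exposure=exposure,
        mediator=mediator,
        total_effect=total_beta,
        total_se=float(total.se[exposure]),
        direct_effect=direct_beta,
        direct_se=float(direct.se[exposure]),
        mediator_effect=float(direct.beta[mediator]),
        mediator_model_coef=a1,
        attenuation=1.0 - direct_beta / total_beta,
        total_loglik=total.loglik,
        direct_loglik=direct.loglik,
        total_pct_change=percentage_change(total_beta),
        direct_pct_change=percentage_change(direct_beta),
    )


# ---------------------------------------------------------------------------
# 2x2 categorical association
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("row1", "row2")
    col_labels: tuple[str, str] = ("col1", "col2")

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def chi2_2x2(table: ContingencyTable2x2, yates: bool = True) -> tuple[float, float, int]:
    """Pearson chi-squared test of independence (Yates correction by default)."""
    arr = table.to_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    res = stats.chi2_contingency(arr, correction=yates)
    return float(res.statistic), float(res.pvalue), int(res.dof)


def fisher_exact_2x2(
    table: ContingencyTable2x2, midp: bool = False
) -> tuple[float, float]:
    """Two-sided Fisher exact test: p sums hypergeometric probabilities of all
    same-margin tables at most as probable as the observed one; odds ratio is
    the sample ad/bc (inf when bc = 0).

    With ``midp=True`` the mid-p correction subtracts half the probability of
    tables exactly as probable as the observed one (Lancaster's mid-p), a less
    conservative variant sometimes reported for sparse tables.
    """
    arr = table.to_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    odds, p = stats.fisher_exact(arr, alternative="two-sided")
    if midp:
        a, b, c, d = table.a, table.b, table.c, table.d
        total, row1, col1 = a + b + c + d, a + b, a + c
        k = np.arange(max(0, col1 - (c + d)), min(row1, col1) + 1)
        pmf = stats.hypergeom.pmf(k, total, col1, row1)
        obs = stats.hypergeom.pmf(a, total, col1, row1)
        at_obs = pmf[np.isclose(pmf, obs, rtol=1e-9)].sum()
        p = float(pmf[pmf <= obs * (1 + 1e-9)].sum() - 0.5 * at_obs)
    return float(odds), float(p)
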
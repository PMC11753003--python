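"""Cox proportional-hazards core: Breslow partial likelihood, Newton fit,
cluster sandwich variance, baseline hazard and Cox-Snell/deviance residuals.

The partial likelihood uses the Breslow tie convention throughout (the
simulated event times are continuous, so ties have measure zero and the
choice is numerically immaterial; it is fixed here because the Cox-Snell
residual construction below uses the Breslow baseline estimator).  The
Newton iteration applies step-halving and caps coefficients at |beta| = 15:
small trials can produce monotone partial likelihoods (separation), which
must surface as a flagged non-converged fit rather than a crash in a long
simulation run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datagen import TrialDataset

__all__ = [
    "CoxFit",
    "TestResult",
    "fit_cox",
    "robust_variance",
    "cox_snell_residuals",
    "deviance_residuals",
    "wald_reject",
]

MAX_ABS_COEF = 15.0
MAX_ITER = 50
GRAD_TOL = 1e-6
LOGLIK_RTOL = 1e-9
Z975 = stats.norm.ppf(0.975)


@dataclass
class CoxFit:
    """A fitted Cox model (possibly the covariate-free null model).

    ``baseline_times``/``baseline_cumhaz`` define the right-continuous
    Breslow step estimate of the cumulative baseline hazard; ``Hhat0(t)``
    evaluates it.  ``cox_snell`` and ``score_residuals`` are stored in the
    original subject order of the fitted dataset.
    """

    coefficients: np.ndarray
    terms: list[str]
    model_cov: np.ndarray
    loglik: float
    converged: bool
    iterations: int
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    linear_predictor: np.ndarray
    cox_snell: np.ndarray
    score_residuals: np.ndarray
    information: np.ndarray
    covariate_count: int
    has_treatment: bool
    dropped_terms: list[str] = field(default_factory=list)
    robust_cov: np.ndarray | None = None
    cluster_ids: np.ndarray | None = None

    @property
    def n_params(self) -> int:
        return len(self.coefficients)

    def Hhat0(self, t: np.ndarray | float) -> np.ndarray | float:
        """Breslow cumulative baseline hazard at time(s) t (right-continuous)."""
        idx = np.searchsorted(self.baseline_times, t, side="right")
        ch = np.concatenate([[0.0], self.baseline_cumhaz])
        return ch[idx]

    def se(self, robust: bool = False) -> np.ndarray:
        cov = self.robust_cov if robust else self.model_cov
        if cov is None:
            raise ValueError("robust covariance not computed for this fit")
        return np.sqrt(np.diag(cov))

    def summary_frame(self):
        import pandas as pd

        se_m = self.se(robust=False)
        se_r = (
            self.se(robust=True)
            if self.robust_cov is not None
            else np.full(self.n_params, np.nan)
        )
        se = se_r if self.robust_cov is not None else se_m
        z = np.divide(self.coefficients, se, out=np.zeros_like(se), where=se > 0)
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.coefficients,
                "se_model": se_m,
                "se_robust": se_r,
                "ci_low": np.exp(self.coefficients - Z975 * se),
                "ci_high": np.exp(self.coefficients + Z975 * se),
                "p": 2 * stats.norm.sf(np.abs(z)),
            }
        )


@dataclass
class TestResult:
    """A Wald-type (or permutation) decision about the treatment hazard ratio."""

    estimate_hr: float
    ci_low: float
    ci_high: float
    p_value: float
    reject: bool
    se: float | None = None
    variance: str | None = None


class _CoxData:
    """Sorted views and risk-set bookkeeping for one dataset/design matrix."""

    def __init__(self, time: np.ndarray, event: np.ndarray, Z: np.ndarray):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=float)
        Z = np.asarray(Z, dtype=float)
        n = len(time)
        order = np.argsort(time, kind="stable")
        self.order = order
        self.inv_order = np.empty(n, dtype=int)
        self.inv_order[order] = np.arange(n)
        self.t = time[order]
        self.d = event[order]
        self.Z = Z[order]
        self.uniq, self.start = np.unique(self.t, return_index=True)
        self.pos = np.searchsorted(self.uniq, self.t)
        self.d_u = np.bincount(self.pos, weights=self.d, minlength=len(self.uniq))
        self.ev = self.d_u > 0
        self.sum_dz = self.d @ self.Z
        self.n_events = float(self.d.sum())

    @staticmethod
    def _revcum(v: np.ndarray) -> np.ndarray:
        return np.cumsum(v[::-1], axis=0)[::-1]

    def risk_sums(self, beta: np.ndarray):
        """S0, S1, S2 over the risk set at every unique time."""
        eta = self.Z @ beta if len(beta) else np.zeros(len(self.t))
        w = np.exp(eta)
        S0 = self._revcum(w)[self.start]
        p = self.Z.shape[1]
        if p:
            S1 = self._revcum(w[:, None] * self.Z)[self.start]
            outer = self.Z[:, :, None] * self.Z[:, None, :]
            S2 = self._revcum(w[:, None, None] * outer)[self.start]
        else:
            S1 = np.zeros((len(self.uniq), 0))
            S2 = np.zeros((len(self.uniq), 0, 0))
        return eta, w, S0, S1, S2

    def loglik(self, beta: np.ndarray) -> float:
        eta = self.Z @ beta if len(beta) else np.zeros(len(self.t))
        w = np.exp(eta)
        S0 = self._revcum(w)[self.start]
        return float(self.d @ eta - self.d_u[self.ev] @ np.log(S0[self.ev]))


def _newton(data: _CoxData, init: np.ndarray | None = None):
    """Maximize the Breslow partial likelihood; returns (beta, ll, info, ok, it)."""
    p = data.Z.shape[1]
    beta = np.zeros(p) if init is None else np.array(init, dtype=float)
    ll = data.loglik(beta)
    converged = p == 0
    it = 0
    info = np.zeros((p, p))
    for it in range(1, MAX_ITER + 1):
        if p == 0:
            break
        _, _, S0, S1, S2 = data.risk_sums(beta)
        m = S1 / S0[:, None]
        grad = data.sum_dz - data.d_u @ m
        info = np.einsum("k,kij->ij", data.d_u, S2 / S0[:, None, None]) - (
            m.T * data.d_u
        ) @ m
        if np.max(np.abs(grad)) < GRAD_TOL:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step-halving until the likelihood does not decrease
        for _ in range(30):
            cand = np.clip(beta + step, -MAX_ABS_COEF, MAX_ABS_COEF)
            ll_new = data.loglik(cand)
            if ll_new >= ll - 1e-12 or not np.isfinite(ll_new):
                break
            step = step / 2
        if not np.isfinite(ll_new):
            break
        beta, ll_prev, ll = cand, ll, ll_new
        if abs(ll - ll_prev) < LOGLIK_RTOL * (abs(ll) + 1.0):
            _, _, S0, S1, S2 = data.risk_sums(beta)
            m = S1 / S0[:, None]
            grad = data.sum_dz - data.d_u @ m
            info = np.einsum("k,kij->ij", data.d_u, S2 / S0[:, None, None]) - (
                m.T * data.d_u
            ) @ m
            converged = bool(np.max(np.abs(grad)) < 1e-3)
            break
    if np.any(np.abs(beta) >= MAX_ABS_COEF - 1e-9):
        converged = False  # monotone likelihood / separation
    return beta, ll, info, converged, it


def _design_matrix(
    dataset: TrialDataset, covariate_count: int, include_treatment: bool
):
    cols, terms = [], []
    if include_treatment:
        if dataset.arm is None:
            raise ValueError("dataset has no arm labels; cannot include treatment")
        cols.append(np.asarray(dataset.arm, dtype=float))
        terms.append("treatment")
    if not 0 <= covariate_count <= dataset.num_covariates:
        raise ValueError(
            f"covariate_count must be in 0..{dataset.num_covariates}, "
            f"got {covariate_count}"
        )
    for k in range(covariate_count):
        cols.append(dataset.x[:, k].astype(float))
        terms.append(f"x{k + 1}")
    Z = np.column_stack(cols) if cols else np.zeros((dataset.n_subjects, 0))
    # drop inestimable zero-variance columns (constant in the sample)
    dropped = []
    keep = []
    for j, name in enumerate(terms):
        if np.ptp(Z[:, j]) == 0:
            if name == "treatment":
                raise ValueError("treatment indicator is constant; fit impossible")
            dropped.append(name)
        else:
            keep.append(j)
    if dropped:
        Z = Z[:, keep]
        terms = [terms[j] for j in keep]
    return Z, terms, dropped


def fit_cox(
    dataset: TrialDataset,
    covariate_count: int = 0,
    include_treatment: bool = False,
    cluster_robust: bool = True,
    init: np.ndarray | None = None,
) -> CoxFit:
    """Fit a Cox model with the first ``covariate_count`` cluster covariates
    (the covariates are i.i.d. by construction, so adjusting for the first S
    loses no generality) and optionally the treatment indicator.

    ``covariate_count = 0`` without treatment gives the null model: an empty
    coefficient vector and the Nelson-Aalen/Breslow baseline hazard.
    Zero-variance covariate columns are dropped (recorded in
    ``dropped_terms``); a constant treatment indicator raises.
    """
    event = np.asarray(dataset.event)
    if event.sum() == 0:
        raise ValueError("dataset has no events; Cox fit undefined")
    Z, terms, dropped = _design_matrix(dataset, covariate_count, include_treatment)
    data = _CoxData(dataset.time, event, Z)
    beta, ll, info, converged, it = _newton(data, init=init)
    p = len(beta)

    eta, w, S0, S1, _ = data.risk_sums(beta)
    haz = np.where(data.ev, data.d_u / S0, 0.0)
    Hcum = np.cumsum(haz)
    base_t = data.uniq[data.ev]
    base_H = Hcum[data.ev]

    G0 = Hcum[data.pos]  # H0 at each subject's time, jump at own time included
    rc_sorted = w * G0
    if p:
        m = S1 / S0[:, None]
        G1 = np.cumsum((data.d_u / S0)[:, None] * m, axis=0)[data.pos]
        U = (
            data.d[:, None] * (data.Z - m[data.pos])
            - w[:, None] * (data.Z * G0[:, None] - G1)
        )
        try:
            model_cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            model_cov = np.linalg.pinv(info)
            converged = False
    else:
        U = np.zeros((len(data.t), 0))
        model_cov = np.zeros((0, 0))

    fit = CoxFit(
        coefficients=beta,
        terms=terms,
        model_cov=model_cov,
        loglik=ll,
        converged=converged,
        iterations=it,
        baseline_times=base_t,
        baseline_cumhaz=base_H,
        linear_predictor=eta[data.inv_order],
        cox_snell=rc_sorted[data.inv_order],
        score_residuals=U[data.inv_order],
        information=info,
        covariate_count=covariate_count,
        has_treatment=include_treatment,
        dropped_terms=dropped,
    )
    if cluster_robust and p:
        fit.robust_cov = robust_variance(fit, dataset.cluster_id)
        fit.cluster_ids = np.asarray(dataset.cluster_id)
    return fit


def robust_variance(fit: CoxFit, cluster_ids: np.ndarray) -> np.ndarray:
    """Cluster sandwich (Huber) covariance A^{-1} (sum_i U_i U_i') A^{-1}.

    ``U_i`` sums the subject-level score residuals within cluster ``i`` and
    ``A`` is the observed information.  With one subject per cluster this is
    the unclustered Lin-Wei estimator.
    """
    if fit.n_params == 0:
        raise ValueError("null model has no parameters")
    ids = np.asarray(cluster_ids)
    if len(ids) != fit.score_residuals.shape[0]:
        raise ValueError("cluster_ids length must match the fitted dataset")
    _, inv = np.unique(ids, return_inverse=True)
    p = fit.n_params
    Uc = np.zeros((inv.max() + 1, p))
    np.add.at(Uc, inv, fit.score_residuals)
    meat = Uc.T @ Uc
    bread = fit.model_cov
    return bread @ meat @ bread


def cox_snell_residuals(fit: CoxFit, dataset: TrialDataset | None = None) -> np.ndarray:
    """Cox-Snell residuals r_C = exp(x'beta_hat) * Hhat0(y).

    With ``dataset=None`` the residuals stored at fit time are returned;
    otherwise the fitted model is evaluated on the given dataset (the fit's
    own term selection is rebuilt from the dataset columns).
    """
    if dataset is None:
        return fit.cox_snell.copy()
    Z, terms, _ = _design_matrix(dataset, fit.covariate_count, fit.has_treatment)
    if terms != fit.terms:
        raise ValueError("dataset columns incompatible with the fitted terms")
    eta = Z @ fit.coefficients if fit.n_params else np.zeros(dataset.n_subjects)
    return np.exp(eta) * np.asarray(fit.Hhat0(dataset.time))


def deviance_residuals(cox_snell: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Deviance residuals from Cox-Snell residuals:

        r_D = sign(d - r_C) * sqrt(-2 [d - r_C + d*log(r_C)])

    where d is the event indicator.  A censored subject with r_C = 0 maps to
    0 by continuity; an event subject with r_C = 0 would be infinite and
    raises (it cannot occur under the Breslow baseline, whose jump at the
    subject's own event time makes r_C > 0).
    """
    rc = np.asarray(cox_snell, dtype=float)
    d = np.asarray(event, dtype=float)
    if np.any(rc < 0):
        raise ValueError("Cox-Snell residuals must be nonnegative")
    if np.any((d == 1) & (rc == 0)):
        raise ValueError("event subject with zero Cox-Snell residual")
    with np.errstate(divide="ignore", invalid="ignore"):
        inner = d - rc + d * np.where(d == 1, np.log(np.where(rc > 0, rc, 1.0)), 0.0)
    out = np.sign(d - rc) * np.sqrt(np.maximum(-2.0 * inner, 0.0))
    return out


def wald_reject(
    fit: CoxFit,
    variance: str = "robust",
    null_hr: float = 1.0,
    level: float = 0.95,
) -> TestResult:
    """Wald test of the treatment hazard ratio against ``null_hr``.

    Rejects when the two-sided ``level`` confidence interval
    exp(beta_T +/- z * SE) excludes ``null_hr``.
    """
    if "treatment" not in fit.terms:
        raise ValueError("fit has no treatment term")
    if variance not in ("model", "robust"):
        raise ValueError("variance must be 'model' or 'robust'")
    j = fit.terms.index("treatment")
    b = fit.coefficients[j]
    cov = fit.robust_cov if variance == "robust" else fit.model_cov
    if cov is None:
        raise ValueError("robust covariance not available; refit with cluster_robust")
    se = float(np.sqrt(cov[j, j]))
    zq = stats.norm.ppf(0.5 + level / 2)
    lo, hi = np.exp(b - zq * se), np.exp(b + zq * se)
    z = (b - np.log(null_hr)) / se if se > 0 else np.inf * np.sign(b - np.log(null_hr))
    p = float(2 * stats.norm.sf(abs(z)))
    return TestResult(
        estimate_hr=float(np.exp(b)),
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=p,
        reject=bool(not (lo < null_hr < hi)),
        se=se,
        variance=variance,
    )
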
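"""Weighted random-intercept linear mixed model, fitted by REML.

The model for treatment mean j of study i is

    y_ij = b0 + b1 * x_ij + s_i + e_ij,
    s_i  ~ N(0, tau^2),
    e_ij ~ N(0, sigma^2 / w_ij),

where w_ij is the number of observations behind the mean: a mean of many
animals is more precise, so it carries more weight.  This is the canonical
treatment-mean weighting of meta-regression (lme4's ``weights=`` argument
reads the same way).

Estimation profiles the REML criterion over the single variance ratio
theta = tau^2 / sigma^2.  For fixed theta the marginal covariance is
sigma^2 * V(theta) with V = diag(1/w) + theta * Z Z', the fixed effects are
generalized least squares, and sigma^2 has a closed form; the criterion is
then minimized over log(theta) by bounded scalar search.  Because each study
contributes a rank-one block, V^{-1} and log|V| are available in closed form
via Sherman-Morrison, making the whole fit O(n) per criterion evaluation.
The boundary tau^2 = 0 is a legal solution, reported as such.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .database import StudyDatabase, PREDICTOR_FIELDS, RESPONSE_FIELDS

__all__ = ["ModelSpec", "FittedModel", "ModelFitError", "fit", "predict_fixed", "marginal_r2"]

#: relative convergence tolerance on successive theta iterates
THETA_RTOL = 1e-8
_LOG_THETA_LO = -34.5  # ~1e-15
_LOG_THETA_HI = 23.0   # ~1e10


class ModelFitError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """One response ~ one predictor candidate model."""

    response_name: str
    predictor_name: str
    weighted: bool = True

    def __post_init__(self) -> None:
        if self.response_name not in RESPONSE_FIELDS:
            raise ValueError(f"unknown response {self.response_name!r}")
        if self.predictor_name not in PREDICTOR_FIELDS:
            raise ValueError(f"unknown predictor {self.predictor_name!r}")
        if self.predictor_name == self.response_name:
            raise ValueError("predictor must differ from response")

    @property
    def name(self) -> str:
        return f"{self.response_name}~{self.predictor_name}"


@dataclass(frozen=True)
class FittedModel:
    spec: ModelSpec
    beta0: float
    beta1: float
    se_beta0: float
    se_beta1: float
    tau2: float            # between-study intercept variance
    sigma2: float          # unit-weight residual variance
    study_blups: dict[str, float]
    n_used: int
    n_studies: int
    reml_loglik: float
    r2_marginal: float
    wald_p_beta1: float
    converged: bool = True
    boundary: bool = False  # True when tau2 was estimated at the zero boundary

    def predict(self, x) -> np.ndarray:
        return predict_fixed(self, x)

    def equation(self) -> str:
        """Render the fitted equation in the conventional reporting style."""
        return (
            f"{self.spec.response_name} = {self.beta0:.4g} (±{self.se_beta0:.3g}) "
            f"+ {self.beta1:.4g} (±{self.se_beta1:.3g}) × {self.spec.predictor_name}"
        )

    def to_dict(self) -> dict:
        return {
            "response": self.spec.response_name,
            "predictor": self.spec.predictor_name,
            "beta0": self.beta0,
            "beta1": self.beta1,
            "se_beta0": self.se_beta0,
            "se_beta1": self.se_beta1,
            "tau2": self.tau2,
            "sigma2": self.sigma2,
            "n_used": self.n_used,
            "n_studies": self.n_studies,
            "reml_loglik": self.reml_loglik,
            "r2_marginal": self.r2_marginal,
            "wald_p_beta1": self.wald_p_beta1,
            "boundary": self.boundary,
            "study_blups": self.study_blups,
            "equation": self.equation(),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _extract(db: StudyDatabase, spec: ModelSpec):
    recs = db.complete_cases(spec.predictor_name)
    if not recs:
        raise ModelFitError(f"{spec.name}: no complete cases")
    y = np.array([r.get(spec.response_name) for r in recs], dtype=float)
    x = np.array([r.get(spec.predictor_name) for r in recs], dtype=float)
    w = (
        np.array([r.n_obs for r in recs], dtype=float)
        if spec.weighted
        else np.ones(len(recs))
    )
    studies: list[str] = []
    idx = np.empty(len(recs), dtype=int)
    seen: dict[str, int] = {}
    for k, r in enumerate(recs):
        if r.study_id not in seen:
            seen[r.study_id] = len(studies)
            studies.append(r.study_id)
        idx[k] = seen[r.study_id]
    return y, x, w, idx, studies, recs


def _reml_pieces(theta: float, y: np.ndarray, X: np.ndarray, w: np.ndarray, idx: np.ndarray, n_studies: int):
    """GLS quantities at a fixed variance ratio theta.

    With V = diag(1/w) + theta * ZZ', Sherman-Morrison gives per study i
    (w_i the weight vector of its records, sw_i its sum):

        V_i^{-1} = diag(w_i) - theta/(1 + theta*sw_i) * w_i w_i'
        log|V_i| = -sum(log w_i) + log(1 + theta*sw_i)
    """
    n, p = X.shape
    sw = np.bincount(idx, weights=w, minlength=n_studies)
    shrink = theta / (1.0 + theta * sw)                      # per-study Sherman-Morrison factor
    A = np.column_stack([X, y])                              # compute all cross-products at once
    wA = w[:, None] * A
    S = np.zeros((n_studies, A.shape[1]))                    # per-study sums of w*A
    np.add.at(S, idx, wA)
    G = A.T @ wA - (S * shrink[:, None]).T @ S               # A' V^{-1} A
    XtViX = G[:p, :p]
    XtViy = G[:p, p]
    ytViy = G[p, p]
    logdetV = -np.log(w).sum() + np.log1p(theta * sw).sum()
    try:
        c = np.linalg.cholesky(XtViX)
    except np.linalg.LinAlgError as exc:
        raise ModelFitError("rank-deficient design (constant predictor among complete cases?)") from exc
    beta = np.linalg.solve(XtViX, XtViy)
    resid = y - X @ beta
    swr = np.bincount(idx, weights=w * resid, minlength=n_studies)
    rss = float(w @ resid**2 - shrink @ swr**2)              # r' V^{-1} r, cancellation-safe
    sigma2 = rss / (n - p)
    if sigma2 <= 0:
        raise ModelFitError("degenerate fit: zero residual variance")
    logdetXtViX = 2.0 * np.log(np.diag(c)).sum()
    crit = (n - p) * math.log(sigma2) + logdetV + logdetXtViX
    return crit, beta, sigma2, XtViX, sw, shrink


def fit(db: StudyDatabase, spec: ModelSpec) -> FittedModel:
    """REML fit of the weighted random-intercept model for one predictor.

    Complete cases for (response, predictor) must span at least two studies
    and the predictor must vary across them.  The returned SEs come from the
    inverse weighted normal equations at the optimum; the slope p-value is a
    Wald test.
    """
    y, x, w, idx, studies, recs = _extract(db, spec)
    n = y.size
    n_studies = len(studies)
    if n_studies < 2:
        raise ModelFitError(f"{spec.name}: complete cases span {n_studies} study; >= 2 required")
    if np.ptp(x) == 0:
        raise ModelFitError(f"{spec.name}: predictor constant across complete cases")
    if n < 3:
        raise ModelFitError(f"{spec.name}: need >= 3 complete cases")
    X = np.column_stack([np.ones(n), x])

    def crit_of_log_theta(u: float) -> float:
        return _reml_pieces(math.exp(u), y, X, w, idx, n_studies)[0]

    res = optimize.minimize_scalar(
        crit_of_log_theta,
        bounds=(_LOG_THETA_LO, _LOG_THETA_HI),
        method="bounded",
        options={"xatol": math.log1p(THETA_RTOL) / 2},
    )
    if not res.success:
        raise ModelFitError(f"{spec.name}: REML search did not converge ({res.message})")
    theta = math.exp(res.x)
    crit0 = _reml_pieces(0.0, y, X, w, idx, n_studies)[0]
    boundary = False
    if crit0 <= res.fun or res.x < _LOG_THETA_LO + 1.0:
        theta = 0.0
        boundary = True
    crit, beta, sigma2, XtViX, sw, shrink = _reml_pieces(theta, y, X, w, idx, n_studies)
    cov = sigma2 * np.linalg.inv(XtViX)
    se = np.sqrt(np.diag(cov))
    tau2 = theta * sigma2
    # BLUPs: s_hat_i = theta/(1 + theta*sw_i) * sum_j w_ij r_ij
    r = y - X @ beta
    swr = np.bincount(idx, weights=w * r, minlength=n_studies)
    blups = shrink * swr if theta > 0 else np.zeros(n_studies)
    z = beta[1] / se[1]
    p_wald = 2.0 * float(stats.norm.sf(abs(z)))
    loglik = -0.5 * (crit + (n - 2) * (1.0 + math.log(2.0 * math.pi)))
    model = FittedModel(
        spec=spec,
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        se_beta0=float(se[0]),
        se_beta1=float(se[1]),
        tau2=float(tau2),
        sigma2=float(sigma2),
        study_blups={s: float(b) for s, b in zip(studies, blups)},
        n_used=n,
        n_studies=n_studies,
        reml_loglik=float(loglik),
        r2_marginal=float("nan"),
        wald_p_beta1=p_wald,
        converged=True,
        boundary=boundary,
    )
    return dataclasses.replace(model, r2_marginal=marginal_r2(model, db))


def predict_fixed(model: FittedModel, x) -> np.ndarray:
    """Fixed-effect prediction b0 + b1*x.

    Used for held-out studies in cross-validation, where the study's random
    intercept is unknown and its expectation (zero) is substituted.  Missing
    x values propagate as NaN; no clipping is applied.
    """
    x = np.asarray(x, dtype=float)
    return model.beta0 + model.beta1 * x


def marginal_r2(model: FittedModel, db: StudyDatabase) -> float:
    """Variance explained by the fixed effects alone.

    R2_marginal = Var_f / (Var_f + tau^2 + sigma_bar^2) where Var_f is the
    population variance of the fixed-effect predictions over the complete
    cases and sigma_bar^2 = sigma^2 * mean(1/w) is the average per-record
    residual variance under the weights.
    """
    y, x, w, idx, studies, recs = _extract(db, model.spec)
    pred = predict_fixed(model, x)
    var_f = float(np.var(pred))  # population variance
    if var_f == 0.0:
        return 0.0
    sigma_bar2 = model.sigma2 * float(np.mean(1.0 / w))
    return var_f / (var_f + model.tau2 + sigma_bar2)
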
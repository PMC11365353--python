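"""Leave-one-study-out cross-validation and the prediction-error metric suite.

Model adequacy is judged on predictions for *unseen studies*: each fold holds
out one entire publication, refits on the rest, and predicts the held-out
treatment means from the fixed effects alone (a new study's random intercept
has expectation zero).  Over the pooled observed/predicted pairs the mean
square prediction error (MSPE) is decomposed into

    MB = (Pbar - Obar)^2          mean bias (constant over/under-prediction)
    SB = (S_p - r * S_o)^2        slope bias (scale / regression mismatch)
    ED = (1 - r^2) * S_o^2        error due to random sources

with S_o, S_p the POPULATION standard deviations (divide by n) and r the
Pearson correlation — under population moments MB + SB + ED = MSPE holds as
an exact algebraic identity, which is why the three percentages of MSPE sum
to 100.  RMSPE is reported as a percentage of the observed mean; RSR is
RMSPE divided by the SAMPLE standard deviation of the observed values
(the usual convention for that adequacy ratio); agreement with the identity
line is Lin's concordance correlation coefficient (CCC), which can be
negative for anti-correlated predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import statsmodels.api as sm

from . import mixed_model
from .database import StudyDatabase
from .mixed_model import FittedModel, ModelFitError, ModelSpec

__all__ = [
    "CVPredictionSet",
    "EvaluationMetrics",
    "EvaluationError",
    "loso_cv",
    "decompose_mspe",
    "ccc",
    "rank_models",
    "plot_data",
]


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class CVPair:
    record_id: str
    study_id: str   # the held-out fold that produced this prediction
    observed: float
    predicted: float


@dataclass(frozen=True)
class CVPredictionSet:
    pairs: tuple[CVPair, ...]
    spec: ModelSpec
    n_folds: int

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        obs = np.array([p.observed for p in self.pairs])
        pred = np.array([p.predicted for p in self.pairs])
        return obs, pred


def loso_cv(db: StudyDatabase, spec: ModelSpec) -> CVPredictionSet:
    """Leave-one-study-out cross-validation.

    For each study s among the complete cases: fit on every complete case not
    in s, then predict s's records via the fixed effects only.  Pairs are
    assembled in input record order; every complete case appears exactly once.
    Requires >= 3 studies so each training fold keeps >= 2.
    """
    cases = db.complete_cases(spec.predictor_name)
    fold_ids = []
    for r in cases:
        if r.study_id not in fold_ids:
            fold_ids.append(r.study_id)
    if len(fold_ids) < 3:
        raise EvaluationError(
            f"{spec.name}: LOSO-CV needs >= 3 studies among complete cases (got {len(fold_ids)})"
        )
    fold_models: dict[str, FittedModel] = {}
    for s in fold_ids:
        train = replace(db, records=tuple(r for r in db.records if r.study_id != s))
        try:
            fold_models[s] = mixed_model.fit(train, spec)
        except ModelFitError as exc:
            raise EvaluationError(f"{spec.name}: training fold holding out study {s!r} failed: {exc}") from exc
    pairs = tuple(
        CVPair(
            record_id=r.record_id,
            study_id=r.study_id,
            observed=float(r.get(spec.response_name)),
            predicted=float(mixed_model.predict_fixed(fold_models[r.study_id], r.get(spec.predictor_name))),
        )
        for r in cases
    )
    return CVPredictionSet(pairs=pairs, spec=spec, n_folds=len(fold_ids))


@dataclass(frozen=True)
class EvaluationMetrics:
    n: int
    mean_obs: float
    mean_pred: float
    sd_obs_pop: float     # population SD (n denominator), used inside the decomposition
    sd_pred_pop: float
    pearson_r: float
    mspe: float
    rmspe: float
    rmspe_pct: float      # RMSPE as % of the observed mean
    mb: float
    sb: float
    ed: float
    mb_pct: float
    sb_pct: float
    ed_pct: float
    rsr: float            # RMSPE / sample SD of observed
    ccc: float
    p_mean_bias: float
    p_slope_bias: float
    degenerate_r: bool = False  # constant predictions: r treated as 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _as_obs_pred(pairs) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs, CVPredictionSet):
        return pairs.arrays()
    obs, pred = pairs
    return np.asarray(obs, dtype=float), np.asarray(pred, dtype=float)


def ccc(pairs) -> float:
    """Lin's concordance correlation coefficient.

    CCC = 2 r S_o S_p / (S_o^2 + S_p^2 + (Obar - Pbar)^2), population SDs.
    Equals 1 only when predictions lie exactly on the identity line; penalises
    both location and scale shifts relative to Pearson's r (|CCC| <= |r|).
    """
    obs, pred = _as_obs_pred(pairs)
    if obs.size < 3:
        raise EvaluationError("CCC needs >= 3 pairs")
    so = float(np.std(obs))
    sp = float(np.std(pred))
    if so == 0.0 or sp == 0.0:
        raise EvaluationError("CCC undefined for a constant sequence")
    r = float(np.corrcoef(obs, pred)[0, 1])
    return 2.0 * r * so * sp / (so**2 + sp**2 + (obs.mean() - pred.mean()) ** 2)


def decompose_mspe(pairs) -> EvaluationMetrics:
    """MSPE and its exact mean/slope/random decomposition, plus RMSPE%, RSR, CCC.

    Bias significance comes from regressing the residuals (obs - pred) on the
    mean-centered predictions: the intercept t-test probes mean bias, the
    slope t-test probes slope bias.  Constant predictions leave r undefined;
    it is then treated as 0 and ``degenerate_r`` is set.  Constant
    observations are an error (every metric would be degenerate).
    """
    obs, pred = _as_obs_pred(pairs)
    n = obs.size
    if n < 3:
        raise EvaluationError("need >= 3 observed/predicted pairs")
    if np.ptp(obs) == 0:
        raise EvaluationError("observed values are constant; metrics undefined")
    mean_obs = float(obs.mean())
    mean_pred = float(pred.mean())
    so = float(np.std(obs))           # population SDs inside the decomposition
    sp = float(np.std(pred))
    degenerate = sp == 0.0
    r = 0.0 if degenerate else float(np.corrcoef(obs, pred)[0, 1])
    mspe = float(np.mean((obs - pred) ** 2))
    mb = (mean_pred - mean_obs) ** 2
    sb = (sp - r * so) ** 2
    ed = (1.0 - r**2) * so**2
    rmspe = np.sqrt(mspe)
    pct = (lambda v: 100.0 * v / mspe) if mspe > 0 else (lambda v: 0.0)
    sd_obs_sample = float(np.std(obs, ddof=1))
    resid = obs - pred
    if degenerate or mspe == 0.0:
        p_mb, p_sb = 1.0, 1.0
    else:
        design = np.column_stack([np.ones(n), pred - mean_pred])
        ols = sm.OLS(resid, design).fit()
        p_mb, p_sb = float(ols.pvalues[0]), float(ols.pvalues[1])
    ccc_val = 1.0 if mspe == 0.0 else (0.0 if degenerate else ccc((obs, pred)))
    return EvaluationMetrics(
        n=n,
        mean_obs=mean_obs,
        mean_pred=mean_pred,
        sd_obs_pop=so,
        sd_pred_pop=sp,
        pearson_r=r,
        mspe=mspe,
        rmspe=float(rmspe),
        rmspe_pct=100.0 * float(rmspe) / mean_obs,
        mb=float(mb),
        sb=float(sb),
        ed=float(ed),
        mb_pct=pct(mb),
        sb_pct=pct(sb),
        ed_pct=pct(ed),
        rsr=float(rmspe) / sd_obs_sample,
        ccc=float(ccc_val),
        p_mean_bias=p_mb,
        p_slope_bias=p_sb,
        degenerate_r=degenerate,
    )


def rank_models(entries: list[tuple[ModelSpec, EvaluationMetrics]]) -> list[tuple[ModelSpec, EvaluationMetrics]]:
    """Order candidate models best-first.

    Primary key: ascending RSR (the cross-study adequacy ratio); ties broken
    by descending CCC, then ascending RMSPE%, then model name — a
    deterministic total order.
    """
    if not entries:
        raise EvaluationError("rank_models needs a non-empty list")
    return sorted(entries, key=lambda e: (e[1].rsr, -e[1].ccc, e[1].rmspe_pct, e[0].name))


def plot_data(cvset: CVPredictionSet) -> dict:
    """Observed-vs-predicted and residual-vs-predicted table for one model.

    Returns rows of (record_id, study_id, predicted, observed, residual) plus
    the identity line and least-squares trend coefficients for each panel,
    ready for plotting without recomputation.
    """
    obs, pred = cvset.arrays()
    resid = obs - pred
    obs_fit = np.polyfit(pred, obs, 1)
    res_fit = np.polyfit(pred, resid, 1)
    return {
        "model": cvset.spec.name,
        "rows": [
            {
                "record_id": p.record_id,
                "study_id": p.study_id,
                "predicted": p.predicted,
                "observed": p.observed,
                "residual": p.observed - p.predicted,
            }
            for p in cvset.pairs
        ],
        "identity_line": {"slope": 1.0, "intercept": 0.0},
        "observed_trend": {"slope": float(obs_fit[0]), "intercept": float(obs_fit[1])},
        "residual_trend": {"slope": float(res_fit[0]), "intercept": float(res_fit[1])},
    }
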
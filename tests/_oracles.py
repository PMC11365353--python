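"""Independent reference implementations used only to check the package.

Everything here is deliberately written by a different route than the code
under test: dense matrices and a generic 2-parameter optimizer instead of
Sherman-Morrison profiling; literal formula transcriptions instead of the
vectorised metric code; manual order-statistic interpolation instead of
numpy quantiles.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize


def dense_reml(y, x, w, study_idx):
    """Weighted random-intercept REML by brute force.

    Builds the full marginal covariance sigma2*diag(1/w) + tau2*Z Z' and
    minimises the REML deviance over (log tau2, log sigma2) with Nelder-Mead
    from several starts.  Returns (beta0, beta1, tau2, sigma2).
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    w = np.asarray(w, float)
    study_idx = np.asarray(study_idx, int)
    n = y.size
    X = np.column_stack([np.ones(n), x])
    Z = np.zeros((n, study_idx.max() + 1))
    Z[np.arange(n), study_idx] = 1.0

    def deviance(params):
        lt, ls = params
        if abs(lt) > 40 or abs(ls) > 40:
            return 1e12
        tau2, sigma2 = math.exp(lt), math.exp(ls)
        V = sigma2 * np.diag(1.0 / w) + tau2 * (Z @ Z.T)
        sign, logdetV = np.linalg.slogdet(V)
        if sign <= 0:
            return 1e12
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
        r = y - X @ beta
        _, logdetX = np.linalg.slogdet(XtViX)
        return logdetV + logdetX + float(r @ Vi @ r)

    best = None
    for start in [(-2.0, 0.0), (2.0, 2.0), (5.0, 3.0), (0.0, 5.0), (-8.0, 2.0)]:
        res = optimize.minimize(deviance, start, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    tau2, sigma2 = math.exp(best.x[0]), math.exp(best.x[1])
    V = sigma2 * np.diag(1.0 / w) + tau2 * (Z @ Z.T)
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    return float(beta[0]), float(beta[1]), tau2, sigma2


def lin_ccc(obs, pred):
    """Literal transcription of Lin's concordance correlation coefficient."""
    obs = list(map(float, obs))
    pred = list(map(float, pred))
    n = len(obs)
    mo = sum(obs) / n
    mp = sum(pred) / n
    so2 = sum((o - mo) ** 2 for o in obs) / n
    sp2 = sum((p - mp) ** 2 for p in pred) / n
    sop = sum((o - mo) * (p - mp) for o, p in zip(obs, pred)) / n
    return 2.0 * sop / (so2 + sp2 + (mo - mp) ** 2)


def mspe_parts(obs, pred):
    """MSPE and its decomposition by literal formula transcription."""
    obs = list(map(float, obs))
    pred = list(map(float, pred))
    n = len(obs)
    mo = sum(obs) / n
    mp = sum(pred) / n
    so = math.sqrt(sum((o - mo) ** 2 for o in obs) / n)
    sp = math.sqrt(sum((p - mp) ** 2 for p in pred) / n)
    sop = sum((o - mo) * (p - mp) for o, p in zip(obs, pred)) / n
    r = sop / (so * sp)
    mspe = sum((o - p) ** 2 for o, p in zip(obs, pred)) / n
    mb = (mp - mo) ** 2
    sb = (sp - r * so) ** 2
    ed = (1.0 - r * r) * so * so
    return mspe, mb, sb, ed


def quartiles_linear(values):
    """Q1 and Q3 by manual linear interpolation of order statistics."""
    s = sorted(values)
    n = len(s)

    def q(p):
        h = (n - 1) * p
        lo = math.floor(h)
        hi = math.ceil(h)
        return s[lo] + (h - lo) * (s[hi] - s[lo])

    return q(0.25), q(0.75)
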
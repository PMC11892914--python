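"""Two-latent-variable structural model for a binary outcome.

The model has two uncorrelated-with-error latent factors (lv1, lv2), each
measured by its own set of observed indicators (species abundances, plus age
and AG for lv2 in the pipeline's default), and a structural regression of
the outcome on both factors with opposite expected signs (lv1 positive on
dementia, lv2 negative).  The outcome is fitted as a numeric 0/1 variable in
the covariance structure (a documented approximation to a categorical
estimator); identification is by unit factor variances so the reported
loadings are standardized, and the factor correlation is free.

Fitting minimizes the maximum-likelihood discrepancy

    F(theta) = log|Sigma| + tr(S Sigma^-1) - log|S| - k

by quasi-Newton from multiple seeded starts; chi-square = (n-1) F_min with
df = k(k+1)/2 - q free parameters, GFI and CFI from their standard
covariance formulas (independence baseline for CFI).  Factor scores use the
regression method, Cov(eta, z) Sigma^-1 (z - mean), which has mean zero over
the fitting sample.  Sign indeterminacy is resolved by flipping each factor
so its first indicator loads positively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .clinical_stats import TestResult, compare_groups

logger = logging.getLogger(__name__)

__all__ = [
    "LatentModelSpec",
    "LatentModelFit",
    "fit_two_factor_model",
    "prune_indicators",
    "predict_factor_scores",
    "compare_factor_scores",
]


@dataclass
class LatentModelSpec:
    lv1_indicators: list[str]
    lv2_indicators: list[str]
    outcome: str = "dementia"

    def validate(self) -> None:
        if set(self.lv1_indicators) & set(self.lv2_indicators):
            raise ValueError("indicator sets must be disjoint")
        if len(self.lv1_indicators) < 2 or len(self.lv2_indicators) < 2:
            raise ValueError("each latent needs >= 2 indicators")
        if self.outcome in self.lv1_indicators + self.lv2_indicators:
            raise ValueError("outcome cannot also be an indicator")


@dataclass
class LatentModelFit:
    spec: LatentModelSpec
    loadings: pd.Series            # standardized loadings per indicator
    loading_se: pd.Series
    loading_p: pd.Series
    structural: tuple[float, float]  # (lv1 -> outcome, lv2 -> outcome), standardized
    factor_corr: float
    chi_square: float
    df: int
    p_value: float
    gfi: float
    cfi: float
    factor_scores: pd.DataFrame    # columns lv1, lv2 over the fitting sample
    converged: bool
    n: int
    discrepancy: float
    _params: dict = field(repr=False, default_factory=dict)


def _unpack(theta: np.ndarray, p1: int, p2: int):
    p = p1 + p2
    lam = theta[:p]
    b = theta[p:p + 2]
    phi = np.tanh(theta[p + 2])
    resid = np.exp(theta[p + 3:p + 3 + p])
    theta_d = np.exp(theta[p + 3 + p])
    return lam, b, phi, resid, theta_d


def _implied_sigma(theta: np.ndarray, p1: int, p2: int) -> np.ndarray:
    lam, b, phi, resid, theta_d = _unpack(theta, p1, p2)
    p = p1 + p2
    big_lam = np.zeros((p, 2))
    big_lam[:p1, 0] = lam[:p1]
    big_lam[p1:, 1] = lam[p1:]
    phi_m = np.array([[1.0, phi], [phi, 1.0]])
    sigma = np.empty((p + 1, p + 1))
    sigma[:p, :p] = big_lam @ phi_m @ big_lam.T + np.diag(resid)
    syd = big_lam @ phi_m @ b
    sigma[:p, p] = syd
    sigma[p, :p] = syd
    sigma[p, p] = b @ phi_m @ b + theta_d
    return sigma


def _ml_discrepancy(theta, s, logdet_s, p1, p2):
    sigma = _implied_sigma(theta, p1, p2)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return 1e10
    try:
        inv = np.linalg.inv(sigma)
    except np.linalg.LinAlgError:
        return 1e10
    k = s.shape[0]
    return float(logdet + np.trace(s @ inv) - logdet_s - k)


def _numeric_hessian(f, theta, h=1e-4):
    q = len(theta)
    hess = np.zeros((q, q))
    for i in range(q):
        for j in range(i, q):
            ei, ej = np.zeros(q), np.zeros(q)
            ei[i], ej[j] = h, h
            val = (f(theta + ei + ej) - f(theta + ei - ej)
                   - f(theta - ei + ej) + f(theta - ei - ej)) / (4 * h * h)
            hess[i, j] = hess[j, i] = val
    return hess


def fit_two_factor_model(
    data: pd.DataFrame,
    spec: LatentModelSpec,
    seed: int = 0,
    n_starts: int = 3,
) -> LatentModelFit:
    """ML fit of the two-factor structural model to standardized data.

    Indicators are z-scored internally; the outcome column stays 0/1.
    Raises on missing columns, too-few subjects, or a non-positive-definite
    sample covariance; non-convergence is flagged, not raised.
    """
    spec.validate()
    cols = list(spec.lv1_indicators) + list(spec.lv2_indicators) + [spec.outcome]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    p1, p2 = len(spec.lv1_indicators), len(spec.lv2_indicators)
    p = p1 + p2
    k = p + 1
    q = 2 * p + 4
    x = data[cols].to_numpy(float)
    n = x.shape[0]
    if n <= q:
        raise ValueError(f"n={n} subjects but {q} free parameters")
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    sds_use = sds.copy()
    sds_use[-1] = 1.0  # outcome stays on its 0/1 scale
    if (sds_use == 0).any():
        raise ValueError("constant column among indicators/outcome")
    z = (x - means) / sds_use
    s = np.cov(z.T, ddof=1)
    sign, logdet_s = np.linalg.slogdet(s)
    if sign <= 0:
        raise ValueError("sample covariance not positive-definite")

    obj = lambda t: _ml_discrepancy(t, s, logdet_s, p1, p2)
    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(1, n_starts)):
        theta0 = np.concatenate([
            np.full(p, 0.7), [0.5, -0.5], [0.0],
            np.log(np.full(p, 0.5)), [np.log(0.2)],
        ])
        if start > 0:
            theta0 = theta0 + rng.normal(0, 0.3, q)
        res = optimize.minimize(obj, theta0, method="L-BFGS-B",
                                options={"maxiter": 2000, "ftol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    theta_hat = best.x
    converged = bool(best.success) and best.fun < 1e9

    lam, b, phi, resid, theta_d = _unpack(theta_hat, p1, p2)
    lam = lam.copy()
    b = np.asarray(b, float).copy()
    # resolve factor sign indeterminacy: first indicator of each latent positive
    if lam[0] < 0:
        lam[:p1] *= -1
        b[0] *= -1
        phi = -phi
    if lam[p1] < 0:
        lam[p1:] *= -1
        b[1] *= -1
        phi = -phi

    sigma = _implied_sigma(
        np.concatenate([lam, b, [np.arctanh(np.clip(phi, -0.999999, 0.999999))],
                        np.log(resid), [np.log(theta_d)]]), p1, p2)
    implied_sd = np.sqrt(np.diag(sigma))
    std_load = lam / implied_sd[:p]
    std_b = (b[0] / implied_sd[p], b[1] / implied_sd[p])

    f_min = obj(theta_hat)
    chi2 = (n - 1) * f_min
    df = k * (k + 1) // 2 - q
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else np.nan
    inv_sigma = np.linalg.inv(sigma)
    m = inv_sigma @ s
    gfi = 1.0 - np.trace((m - np.eye(k)) @ (m - np.eye(k))) / np.trace(m @ m)
    f_base = float(np.sum(np.log(np.diag(s))) - logdet_s)
    chi2_base = (n - 1) * f_base
    df_base = k * (k - 1) // 2
    num = max(chi2 - df, 0.0)
    den = max(chi2_base - df_base, chi2 - df, 0.0)
    cfi = float(np.clip(1.0 - (num / den if den > 0 else 0.0), 0.0, 1.0))

    # Wald standard errors from the numerical Hessian of the discrepancy
    se = np.full(p, np.nan)
    try:
        hess = _numeric_hessian(obj, theta_hat)
        cov = 2.0 / (n - 1) * np.linalg.pinv(hess)
        se = np.sqrt(np.clip(np.diag(cov)[:p], 0, None))
    except Exception:  # pragma: no cover - diagnostics only
        logger.warning("Hessian-based standard errors unavailable")
    z_load = np.where(se > 0, np.abs(lam) / se, np.inf)
    p_load = 2 * stats.norm.sf(z_load)

    ind_names = list(spec.lv1_indicators) + list(spec.lv2_indicators)
    phi_m = np.array([[1.0, phi], [phi, 1.0]])
    big_lam = np.zeros((p, 2))
    big_lam[:p1, 0] = lam[:p1]
    big_lam[p1:, 1] = lam[p1:]
    a = np.hstack([phi_m @ big_lam.T, (phi_m @ b).reshape(2, 1)])
    scores = (a @ inv_sigma @ (z - z.mean(axis=0)).T).T
    scores = pd.DataFrame(scores, index=data.index, columns=["lv1", "lv2"])

    return LatentModelFit(
        spec=spec,
        loadings=pd.Series(std_load, index=ind_names),
        loading_se=pd.Series(se, index=ind_names),
        loading_p=pd.Series(p_load, index=ind_names),
        structural=(float(std_b[0]), float(std_b[1])),
        factor_corr=float(phi),
        chi_square=float(chi2),
        df=int(df),
        p_value=p_value,
        gfi=float(gfi),
        cfi=cfi,
        factor_scores=scores,
        converged=converged,
        n=n,
        discrepancy=float(f_min),
        _params={
            "lam": lam, "b": b, "phi": phi, "resid": resid, "theta_d": theta_d,
            "means": means, "sds": sds_use, "cols": cols, "p1": p1, "p2": p2,
            "sigma": sigma, "score_weights": a @ inv_sigma,
        },
    )


def predict_factor_scores(fit: LatentModelFit, data: pd.DataFrame) -> pd.DataFrame:
    """Regression-method factor scores for new subjects under a fitted model."""
    if not fit.converged:
        raise ValueError("cannot score with a non-converged fit")
    cols = fit._params["cols"]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"missing indicator column(s): {missing}")
    if data[cols].isna().any().any():
        bad = data[cols].columns[data[cols].isna().any()].tolist()
        raise ValueError(f"missing values in column(s): {bad}")
    z = (data[cols].to_numpy(float) - fit._params["means"]) / fit._params["sds"]
    scores = (fit._params["score_weights"] @ z.T).T
    return pd.DataFrame(scores, index=data.index, columns=["lv1", "lv2"])


def prune_indicators(
    data: pd.DataFrame,
    spec: LatentModelSpec,
    loading_min: float = 0.2,
    alpha: float = 0.05,
    seed: int = 0,
) -> LatentModelSpec:
    """Drop weak/non-significant indicators one at a time, refitting each step.

    An indicator is a removal candidate when its Wald p >= alpha or
    |standardized loading| < loading_min; the weakest (smallest |loading|)
    candidate is dropped first.  Pruning halts with a warning rather than
    reduce a latent below two indicators.
    """
    current = LatentModelSpec(list(spec.lv1_indicators), list(spec.lv2_indicators),
                              spec.outcome)
    while True:
        fit = fit_two_factor_model(data, current, seed=seed)
        cand = [
            name for name in fit.loadings.index
            if fit.loading_p[name] >= alpha or abs(fit.loadings[name]) < loading_min
        ]
        if not cand:
            return current
        weakest = min(cand, key=lambda t: abs(fit.loadings[t]))
        side = (current.lv1_indicators if weakest in current.lv1_indicators
                else current.lv2_indicators)
        if len(side) <= 2:
            logger.warning(
                "pruning halted: dropping %s would leave <2 indicators", weakest
            )
            return current
        side.remove(weakest)
        logger.info("pruned indicator %s (loading %.3f, p %.3g)", weakest,
                    fit.loadings[weakest], fit.loading_p[weakest])


def compare_factor_scores(scores: pd.DataFrame, groups) -> dict[str, TestResult]:
    """Wilcoxon rank-sum comparison of lv1 and lv2 scores between two groups."""
    groups = pd.Series(np.asarray(groups), index=scores.index)
    uniq = groups.unique()
    if len(uniq) != 2:
        raise ValueError("need exactly two groups")
    out = {}
    for lv in ("lv1", "lv2"):
        a = scores.loc[groups == uniq[0], lv]
        b = scores.loc[groups == uniq[1], lv]
        out[lv] = compare_groups(a, b, method="wilcoxon_rank_sum")
    return out
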
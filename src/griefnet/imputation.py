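"""Multiple imputation by fully conditional specification (FCS).

Missing item responses are imputed chain-wise: each incomplete variable
gets a conditional model given the other variables, and the chains sweep
the variables in fixed column order for a set number of iterations.
Non-dichotomous variables use predictive mean matching (PMM) — a
Bayesian linear regression posterior draw followed by donor matching —
so imputed values are always actually observed values. Dichotomous
variables use logistic-regression imputation. Rubin's rules combine
estimates across the completed datasets; correlations are pooled on the
Fisher-z scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .data import ItemResponseMatrix

__all__ = [
    "ImputationConfig",
    "ImputationStack",
    "PooledEstimate",
    "fcs_impute",
    "pmm_step",
    "logistic_step",
    "pool_rubin",
    "pool_correlation",
    "select_predictors",
]


@dataclass
class ImputationConfig:
    """FCS settings: 20 imputations, 10 sweeps, 5 PMM donors by default."""

    m: int = 20
    max_iterations: int = 10
    donor_pool: int = 5
    max_predictors: int = 15
    seed: int = 0

    def validate(self) -> None:
        for name in ("m", "max_iterations", "donor_pool", "max_predictors"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class ImputationStack:
    """m completed copies of one incomplete item matrix."""

    datasets: list[ItemResponseMatrix]
    config: ImputationConfig
    predictor_sets: dict[str, list[str]] = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.datasets)

    @classmethod
    def from_long(cls, long: pd.DataFrame, config: "ImputationConfig | None" = None) -> "ImputationStack":
        """Rebuild a stack from the long format written by :meth:`to_long`
        (imputation index 0, the original incomplete data, is dropped)."""
        datasets = [
            ItemResponseMatrix(g.drop(columns=".imp").reset_index(drop=True))
            for i, g in long.groupby(".imp", sort=True) if i != 0
        ]
        if not datasets:
            raise ValueError("long table contains no completed datasets (.imp >= 1)")
        return cls(datasets, config or ImputationConfig(m=len(datasets)))

    def to_long(self, original: ItemResponseMatrix | None = None) -> pd.DataFrame:
        """Long format with an ``.imp`` index column (0 = original data)."""
        frames = []
        if original is not None:
            d0 = original.values.copy()
            d0.insert(0, ".imp", 0)
            frames.append(d0)
        for i, d in enumerate(self.datasets, start=1):
            di = d.values.copy()
            di.insert(0, ".imp", i)
            frames.append(di)
        return pd.concat(frames, axis=0, ignore_index=True)


def select_predictors(data: pd.DataFrame, target: str, max_predictors: int) -> list[str]:
    """Predictors with the highest |Spearman| correlation to the target.

    Computed on pairwise-complete data; keeps at most ``max_predictors``
    variables to avoid overparameterized conditional models when there
    are many items relative to participants.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = data.corr(method="spearman")[target].drop(target).abs()
    rho = rho.fillna(0.0)
    return list(rho.sort_values(ascending=False, kind="stable").index[:max_predictors])


def pmm_step(y_observed: np.ndarray, X_observed: np.ndarray, X_missing: np.ndarray,
             k: int = 5, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Predictive mean matching for one variable.

    Coefficients are drawn from the approximate normal posterior around
    the least-squares fit (residual variance from its scaled inverse
    chi-square draw). Predicted means use the drawn coefficients for
    missing rows and the least-squares coefficients for observed rows;
    each missing row copies the observed y of one of its ``k``
    nearest-predicted-mean donors, picked uniformly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "pmm")
    y = np.asarray(y_observed, dtype=float)
    Xo = np.column_stack([np.ones(len(y)), np.asarray(X_observed, dtype=float)])
    Xm = np.column_stack([np.ones(len(X_missing)), np.asarray(X_missing, dtype=float)])
    n, q = Xo.shape
    if k > n:
        raise ValueError("donor pool larger than the number of observed values")

    G = Xo.T @ Xo
    try:
        Ginv = np.linalg.inv(G)
        beta_hat = Ginv @ (Xo.T @ y)
    except np.linalg.LinAlgError:
        warnings.warn("singular design in PMM step; using ridge fallback")
        G = G + 1e-4 * np.eye(q)
        Ginv = np.linalg.inv(G)
        beta_hat = Ginv @ (Xo.T @ y)

    resid = y - Xo @ beta_hat
    df = max(n - q, 1)
    sigma2 = (resid @ resid) / stats.chi2.rvs(df, random_state=rng)
    # numerically safe posterior draw
    Ls = np.linalg.cholesky((Ginv + Ginv.T) / 2 + 1e-12 * np.eye(q))
    beta_star = beta_hat + np.sqrt(sigma2) * (Ls @ rng.standard_normal(q))

    pred_obs = Xo @ beta_hat
    pred_mis = Xm @ beta_star
    out = np.empty(len(pred_mis))
    for i, pm in enumerate(pred_mis):
        donors = np.argsort(np.abs(pred_obs - pm), kind="stable")[:k]
        out[i] = y[donors[rng.integers(k)]]
    return out


def logistic_step(y_observed: np.ndarray, X_observed: np.ndarray, X_missing: np.ndarray,
                  seed: int | np.random.Generator = 0) -> np.ndarray:
    """Logistic-regression imputation for a dichotomous variable.

    Coefficients are drawn from the asymptotic normal posterior of the
    logistic fit; missing entries are Bernoulli draws at the implied
    probabilities. Degenerate observed classes impute deterministically;
    separation falls back to a ridge-penalized fit.
    """
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "logistic")
    y = np.asarray(y_observed, dtype=float)
    classes = np.unique(y)
    if len(classes) == 1:
        warnings.warn("single observed class in logistic step; imputing it deterministically")
        return np.full(len(X_missing), classes[0])
    lo, hi = classes.min(), classes.max()
    yb = (y == hi).astype(float)
    Xo = np.column_stack([np.ones(len(y)), np.asarray(X_observed, dtype=float)])
    Xm = np.column_stack([np.ones(len(X_missing)), np.asarray(X_missing, dtype=float)])

    import statsmodels.api as sm

    beta, cov = None, None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(yb, Xo).fit(disp=0, maxiter=100)
            if np.all(np.isfinite(fit.params)) and np.all(np.isfinite(fit.cov_params())):
                beta, cov = fit.params, np.asarray(fit.cov_params())
        except Exception:
            pass
    if beta is None or np.abs(beta).max() > 25:
        warnings.warn("separation in logistic step; using penalized fit")
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(C=1.0, fit_intercept=False).fit(Xo, yb)
        beta = lr.coef_.ravel()
        cov = np.eye(len(beta)) * 0.01

    L = np.linalg.cholesky((cov + cov.T) / 2 + 1e-10 * np.eye(len(beta)))
    beta_star = beta + L @ rng.standard_normal(len(beta))
    prob = 1.0 / (1.0 + np.exp(-np.clip(Xm @ beta_star, -35, 35)))
    return np.where(rng.uniform(size=len(prob)) < prob, hi, lo)


def fcs_impute(data: ItemResponseMatrix, config: ImputationConfig | None = None) -> ImputationStack:
    """Impute an incomplete item matrix m times by chained equations.

    Each chain initializes missing cells with random draws from the
    observed values of their variable, then performs
    ``config.max_iterations`` sweeps in fixed left-to-right column
    order, re-imputing each incomplete variable from its predictor set
    (PMM for ordinal/continuous variables, logistic for dichotomous
    ones). Observed cells are never modified.
    """
    cfg = config or ImputationConfig()
    cfg.validate()
    values = data.values
    missing = values.isna()
    incomplete = [c for c in values.columns if missing[c].any()]
    for c in incomplete:
        if missing[c].all():
            raise ValueError(f"variable {c!r} has no observed values; cannot impute")

    predictor_sets = {
        c: select_predictors(values, c, cfg.max_predictors) for c in incomplete
    }

    datasets = []
    for im in range(cfg.m):
        rng = substream(cfg.seed, f"fcs-chain-{im}")
        filled = values.copy()
        for c in incomplete:
            obs = values[c].dropna().to_numpy()
            idx = missing[c]
            filled.loc[idx, c] = rng.choice(obs, size=int(idx.sum()), replace=True)
        for _ in range(cfg.max_iterations):
            for c in incomplete:
                idx = missing[c].to_numpy()
                preds = predictor_sets[c]
                n_obs = int((~idx).sum())
                if n_obs < len(preds) + 2:
                    preds = preds[: max(n_obs - 2, 1)]
                    warnings.warn(
                        f"predictor set for {c!r} truncated to {len(preds)} "
                        f"(only {n_obs} observed rows)"
                    )
                Xo = filled.loc[~idx, preds].to_numpy(dtype=float)
                Xm = filled.loc[idx, preds].to_numpy(dtype=float)
                yo = values.loc[~idx, c].to_numpy(dtype=float)
                if c in data.dichotomous:
                    imputed = logistic_step(yo, Xo, Xm, seed=rng)
                else:
                    k = min(cfg.donor_pool, len(yo))
                    imputed = pmm_step(yo, Xo, Xm, k=k, seed=rng)
                filled.loc[idx, c] = imputed
        datasets.append(ItemResponseMatrix(filled, dict(data.ranges), data.dichotomous))
    return ImputationStack(datasets, cfg, predictor_sets)


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of m repeated-imputation estimates."""

    point: float
    within_variance: float
    between_variance: float
    total_variance: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_variance))


def pool_rubin(estimates, variances) -> PooledEstimate:
    """Combine m estimates and their within-imputation variances.

    point = mean(Q_i); B = sample variance of Q_i; W = mean(U_i);
    T = W + (1 + 1/m) B.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.size == 0:
        raise ValueError("need at least one estimate to pool")
    if np.any(u < 0):
        raise ValueError("variances must be >= 0")
    m = q.size
    point = float(q.mean())
    between = float(q.var(ddof=1)) if m > 1 else 0.0
    within = float(u.mean())
    total = within + (1 + 1 / m) * between
    return PooledEstimate(point, within, between, total, m)


def pool_correlation(correlations, n: int) -> PooledEstimate:
    """Pool correlations across imputations on the Fisher-z scale.

    Each r is z-transformed (variance 1/(n-3)), pooled by Rubin's rules,
    and the pooled point is transformed back to the correlation scale.
    The variances in the result remain on the z scale.
    """
    r = np.asarray(correlations, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n < 4:
        raise ValueError("need n >= 4 for the Fisher-z variance 1/(n-3)")
    z = np.arctanh(r)
    pooled = pool_rubin(z, np.full(r.size, 1.0 / (n - 3)))
    pooled.point = float(np.tanh(pooled.point))
    return pooled
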
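"""Random-intercept mixed models and Snijders & Bosker explained variance.

Section fibrosis percentages are log-transformed (natural log, with a small
configurable offset so zero-fibrosis sections remain finite) and modelled
with a per-animal random intercept:

    y_ij = beta0 [+ beta1 * x_ij] + u_i + e_ij,
    u_i ~ N(0, tau00),  e_ij ~ N(0, sigma2).

The null model carries no covariate; each full model adds one CMR
covariate.  The explained variance is

    R^2 = 100 * (1 - (sigma2_full + tau00_full) / (sigma2_null + tau00_null)),

the Snijders & Bosker total-variance ratio.  Models are estimated by
maximum likelihood (ML) by default — ML totals are the conventional choice
when comparing models with different fixed effects — with REML behind a
flag.  When the random-intercept variance collapses to the zero boundary
(or the variance-component information matrix is not positive definite),
the residual and random-intercept variances are pooled: the fit is reported
with ``pooled=True`` and ``sigma2`` holding the total unexplained variance
from the corresponding fixed-effects-only fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

#: tau00 estimates below this trigger the pooled representation
TAU_BOUNDARY = 1e-8
#: default offset (percentage points) added before the log transform
DEFAULT_LOG_OFFSET = 0.1


class ConvergenceError(RuntimeError):
    """Mixed-model optimizer failed to converge."""


@dataclass
class VarianceComponents:
    """Residual (sigma2) and random-intercept (tau00) variances.

    With ``pooled=True`` the two could not be separated; ``sigma2`` then
    holds the pooled total and ``tau00`` is zero.
    """

    sigma2: float
    tau00: float
    pooled: bool = False

    def __post_init__(self):
        if self.sigma2 < 0 or self.tau00 < 0:
            raise ValueError("variance components must be nonnegative")
        if self.pooled and self.tau00 != 0:
            raise ValueError("pooled components must carry tau00 = 0")

    @property
    def total(self) -> float:
        return self.sigma2 + self.tau00


@dataclass
class MixedModelFit:
    """One fitted random-intercept model."""

    beta0: float
    beta1: float | None
    components: VarianceComponents
    loglike: float
    converged: bool
    boundary_flag: bool
    n_obs: int
    n_groups: int
    beta1_se: float | None = None
    covariate: str | None = None


def log_fibrosis(
    table: pd.DataFrame,
    offset: float = DEFAULT_LOG_OFFSET,
    column: str = "fibrosis_pct",
    out_column: str = "log_fibrosis",
) -> pd.DataFrame:
    """Append the natural-log response ``ln(fibrosis_pct + offset)``.

    The offset (default 0.1 percentage points) keeps zero-fibrosis sections
    finite and is recorded in ``table.attrs['log_offset']``.
    """
    if np.any(table[column] < 0):
        raise ValueError("fibrosis percentages must be nonnegative")
    out = table.copy()
    out[out_column] = np.log(out[column] + offset)
    out.attrs["log_offset"] = offset
    return out


def _pooled_fit(y, X, covariate, n_groups) -> MixedModelFit:
    """Fixed-effects-only fallback: total unexplained variance, ML divisor N."""
    ols = sm.OLS(y, X).fit()
    resid = y - ols.predict(X)
    sigma2 = float(np.mean(resid**2))
    n = y.size
    llf = float(-0.5 * n * (np.log(2 * np.pi * sigma2) + 1)) if sigma2 > 0 else np.inf
    params = np.atleast_1d(ols.params)
    return MixedModelFit(
        beta0=float(params[0]),
        beta1=float(params[1]) if X.shape[1] > 1 else None,
        components=VarianceComponents(sigma2, 0.0, pooled=True),
        loglike=llf,
        converged=True,
        boundary_flag=True,
        n_obs=int(n),
        n_groups=int(n_groups),
        beta1_se=float(np.atleast_1d(ols.bse)[1]) if X.shape[1] > 1 else None,
        covariate=covariate,
    )


def _fit_mixed(
    table: pd.DataFrame,
    covariate: str | None,
    response: str,
    groups: str,
    reml: bool,
) -> MixedModelFit:
    df = table
    if covariate is not None:
        n_before = len(df)
        df = df.dropna(subset=[covariate])
        dropped = n_before - len(df)
        if dropped:
            logger.info("dropped %d rows with missing %s", dropped, covariate)
        if df[covariate].nunique() <= 1:
            raise ValueError(
                f"covariate {covariate!r} is constant: slope unidentified"
            )
    y = df[response].to_numpy(dtype=float)
    group_ids = df[groups].to_numpy()
    if pd.unique(group_ids).size < 2:
        raise ValueError("need at least two animals")
    if covariate is not None:
        X = np.column_stack([np.ones(y.size), df[covariate].to_numpy(dtype=float)])
    else:
        X = np.ones((y.size, 1))

    # degenerate responses the likelihood surface cannot handle
    if np.var(y) < 1e-12:
        return MixedModelFit(
            beta0=float(np.mean(y)), beta1=0.0 if covariate else None,
            components=VarianceComponents(0.0, 0.0, pooled=True),
            loglike=np.inf, converged=True, boundary_flag=True,
            n_obs=y.size, n_groups=int(pd.unique(group_ids).size),
            covariate=covariate,
        )
    group_means = pd.Series(y).groupby(pd.Series(group_ids)).transform("mean")
    if covariate is None and np.var(y - group_means.to_numpy()) < 1e-12:
        # zero within-animal variance: sigma2 -> 0 and tau00 is the ML
        # between-animal variance (divisor = number of animals)
        means = pd.Series(y).groupby(pd.Series(group_ids)).mean().to_numpy()
        tau = float(np.mean((means - means.mean()) ** 2))
        return MixedModelFit(
            beta0=float(means.mean()), beta1=None,
            components=VarianceComponents(0.0, tau), loglike=np.inf,
            converged=True, boundary_flag=True, n_obs=y.size,
            n_groups=means.size, covariate=covariate,
        )

    model = sm.MixedLM(y, X, groups=group_ids)
    res, all_singular = None, True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # near the tau00 = 0 boundary individual optimizers stall or hit a
        # singular information matrix; cascade until one converges
        for method in ("lbfgs", "powell", "cg", "bfgs"):
            try:
                fit = model.fit(reml=reml, method=method)
                all_singular = False
            except np.linalg.LinAlgError:
                continue
            except ValueError:
                all_singular = False
                continue
            if fit.converged:
                res = fit
                break
    if res is None:
        if all_singular:
            # information matrix not positive definite anywhere: the two
            # variances are not separable — pool them
            return _pooled_fit(y, X, covariate, pd.unique(group_ids).size)
        raise ConvergenceError(
            f"mixed model failed to converge (covariate={covariate!r})"
        )
    sigma2 = float(res.scale)
    tau00 = float(np.asarray(res.cov_re)[0, 0])
    hessian_ok = np.isfinite(tau00) and tau00 >= 0
    if (not hessian_ok) or tau00 < TAU_BOUNDARY:
        return _pooled_fit(y, X, covariate, pd.unique(group_ids).size)
    params = np.atleast_1d(np.asarray(res.fe_params))
    bse = np.atleast_1d(np.asarray(res.bse_fe))
    return MixedModelFit(
        beta0=float(params[0]),
        beta1=float(params[1]) if covariate is not None else None,
        components=VarianceComponents(sigma2, tau00),
        loglike=float(res.llf),
        converged=True,
        boundary_flag=False,
        n_obs=y.size,
        n_groups=int(pd.unique(group_ids).size),
        beta1_se=float(bse[1]) if covariate is not None else None,
        covariate=covariate,
    )


def fit_null_model(
    table: pd.DataFrame,
    response: str = "log_fibrosis",
    groups: str = "animal_id",
    reml: bool = False,
) -> MixedModelFit:
    """Intercept-only random-intercept fit (the null model)."""
    return _fit_mixed(table, None, response, groups, reml)


def fit_full_model(
    table: pd.DataFrame,
    covariate: str,
    response: str = "log_fibrosis",
    groups: str = "animal_id",
    reml: bool = False,
) -> MixedModelFit:
    """Random-intercept fit with one CMR covariate (the full model)."""
    return _fit_mixed(table, covariate, response, groups, reml)


def _components(obj) -> VarianceComponents:
    return obj.components if isinstance(obj, MixedModelFit) else obj


def r2_snijders_bosker(full, null) -> float:
    """Explained variance (%) = 100 * (1 - total_full / total_null).

    Accepts :class:`VarianceComponents` or :class:`MixedModelFit` for either
    argument; pooled components contribute their pooled totals.  A negative
    value (full model worse than null) is returned as-is.
    """
    full_c, null_c = _components(full), _components(null)
    if null_c.total <= 0:
        raise ValueError("null model total variance must be positive")
    return 100.0 * (1.0 - full_c.total / null_c.total)


def compare_all(
    table: pd.DataFrame,
    covariates: list[str],
    response: str = "log_fibrosis",
    groups: str = "animal_id",
    reml: bool = False,
) -> pd.DataFrame:
    """One full-model row per covariate, preceded by the null-model row.

    Columns: covariate, sigma2_full, tau00_full, pooled, r2_pct (full
    precision) and r2_pct_display (integer percent, study-table style).
    """
    if len(set(covariates)) != len(covariates):
        raise ValueError("duplicate covariate names")
    null = fit_null_model(table, response=response, groups=groups, reml=reml)
    rows = [
        {
            "covariate": "(null)",
            "sigma2_full": null.components.sigma2,
            "tau00_full": null.components.tau00,
            "pooled": null.components.pooled,
            "r2_pct": 0.0,
            "r2_pct_display": 0,
        }
    ]
    for cov in covariates:
        fit = fit_full_model(table, cov, response=response, groups=groups, reml=reml)
        r2 = r2_snijders_bosker(fit, null)
        rows.append(
            {
                "covariate": cov,
                "sigma2_full": fit.components.sigma2,
                "tau00_full": fit.components.tau00,
                "pooled": fit.components.pooled,
                "r2_pct": r2,
                "r2_pct_display": int(round(r2)),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["null_total"] = null.components.total
    out.attrs["null_pooled"] = null.components.pooled
    return out
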
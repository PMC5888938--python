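"""Internal helpers for fitting linear mixed models with a site intercept.

All cohort-level models in this package share one estimation path: a linear
mixed model with a random intercept per acquisition site, fitted by maximum
likelihood (ML rather than REML, because AIC comparisons across fixed-effect
structures are only valid under ML). When the data contain a single site the
random effect is unidentifiable and the fit falls back to a fixed-intercept
OLS model with a logged warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg, stats as sps

logger = logging.getLogger("hubreserve")

__all__ = ["zscore", "build_design", "fit_lmm", "LmmResult"]


def zscore(x) -> np.ndarray:
    """Z-score with the sample (n-1) standard deviation."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot z-score a zero-variance or non-finite variable")
    return (x - x.mean()) / sd


def build_design(
    df: pd.DataFrame,
    continuous: list[str] | tuple[str, ...] = (),
    categorical: list[str] | tuple[str, ...] = (),
    interactions: list[tuple[str, str]] | tuple = (),
    droppable_prefixes: tuple[str, ...] = ("family_id=",),
) -> pd.DataFrame:
    """Assemble a fixed-effects design matrix with standardized columns.

    Continuous predictors are z-scored; categorical predictors become
    treatment-coded dummies (first level dropped); interaction columns are
    products of the already z-scored main-effect columns and are *not*
    re-standardized. Dummy columns for levels absent from the subset are
    dropped. Aliased (rank-deficient) columns are dropped with a warning when
    their name starts with one of ``droppable_prefixes`` (by default the
    family-affiliation dummies, where singleton families can alias); any other
    aliasing raises with the offending columns named.
    """
    cols: dict[str, np.ndarray] = {"const": np.ones(len(df))}
    for c in continuous:
        cols[c] = zscore(df[c].to_numpy())
    for c in categorical:
        levels = pd.Categorical(df[c].astype(str))
        for lev in levels.categories[1:]:
            dummy = (levels == lev).astype(float)
            if dummy.std() > 0:
                cols[f"{c}={lev}"] = np.asarray(dummy)
    for a, b in interactions:
        cols[f"{a}:{b}"] = cols[a] * cols[b]
    X = pd.DataFrame(cols, index=df.index)

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        _, _, piv = linalg.qr(X.to_numpy(), pivoting=True, mode="economic")
        aliased = [X.columns[j] for j in piv[rank:]]
        droppable = [c for c in aliased if c.startswith(droppable_prefixes)]
        hard = [c for c in aliased if not c.startswith(droppable_prefixes)]
        if hard:
            raise ValueError(f"design matrix is rank deficient; aliased terms: {hard}")
        warnings.warn(
            f"dropping aliased design columns: {droppable}", UserWarning, stacklevel=2
        )
        X = X.drop(columns=droppable)
    return X


@dataclass
class LmmResult:
    """Uniform wrapper over a MixedLM (ML) or fallback-OLS fit."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    llf: float
    aic: float
    r2: float
    n: int
    used_random_effect: bool
    cov_params: pd.DataFrame
    df_resid: int = 1
    fittedvalues: np.ndarray = field(repr=False, default=None)

    def wald_joint_p(self, term_names: list[str]) -> float:
        """Joint Wald chi-square p-value that the named coefficients are all 0."""
        b = self.params[term_names].to_numpy()
        V = self.cov_params.loc[term_names, term_names].to_numpy()
        stat = float(b @ np.linalg.solve(V, b))
        return float(sps.chi2.sf(stat, df=len(term_names)))


def fit_lmm(y: np.ndarray, X: pd.DataFrame, groups: pd.Series | None) -> LmmResult:
    """Fit y ~ X with a random intercept per group (ML); OLS if one group.

    ``y`` should already be on the scale whose coefficients are wanted
    (z-scored by the caller for standardized betas). AIC is computed as
    -2 log L + 2k with k counting fixed effects plus the variance components.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    single_site = groups is None or pd.Series(groups).nunique() < 2
    mixed_res = None
    if not single_site:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(y, X, groups=np.asarray(groups))
                mixed_res = model.fit(reml=False, method=["lbfgs", "cg"])
            if (
                not np.isfinite(mixed_res.llf)
                or float(np.min(np.diag(np.atleast_2d(mixed_res.cov_re)))) < 1e-10
            ):
                mixed_res = None
        except np.linalg.LinAlgError:
            mixed_res = None
        if mixed_res is None:
            logger.warning(
                "random site intercept is singular (variance at the boundary); "
                "falling back to a fixed-intercept model"
            )
    elif groups is not None:
        logger.warning(
            "only one site in the data; random site intercept is unidentifiable, "
            "falling back to a fixed-intercept model"
        )
    if mixed_res is None:
        res = sm.OLS(y, X).fit()
        k = X.shape[1] + 1  # + residual variance
        fitted = np.asarray(res.fittedvalues)
        used_re = False
        df_resid = int(res.df_resid)
        llf = float(res.llf)
        cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
        params, bse = pd.Series(res.params, index=X.columns), pd.Series(res.bse, index=X.columns)
        tvals, pvals = pd.Series(res.tvalues, index=X.columns), pd.Series(res.pvalues, index=X.columns)
    else:
        res = mixed_res
        k = X.shape[1] + 2  # + random-intercept variance + residual variance
        try:
            fitted = np.asarray(res.fittedvalues)
        except Exception:  # zero random-effect variance: use fixed effects only
            fitted = X.to_numpy() @ np.asarray(res.fe_params)
        used_re = True
        llf = float(res.llf)
        # ML profiles the residual variance with an n denominator; with many
        # fixed effects that understates the scale, so standard errors get the
        # n/(n-p) small-sample correction and p-values use the t reference,
        # mirroring the fixed-intercept path.
        df_resid = max(n - X.shape[1], 1)
        scale_corr = np.sqrt(n / df_resid)
        cov_full = np.asarray(res.cov_params())[: X.shape[1], : X.shape[1]] * scale_corr**2
        cov = pd.DataFrame(cov_full, index=X.columns, columns=X.columns)
        params = pd.Series(np.asarray(res.fe_params), index=X.columns)
        bse = pd.Series(np.asarray(res.bse_fe) * scale_corr, index=X.columns)
        tvals = params / bse
        pvals = pd.Series(2 * sps.t.sf(np.abs(tvals), df_resid), index=X.columns)

    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return LmmResult(
        params=params,
        bse=bse,
        tvalues=tvals,
        pvalues=pvals,
        llf=llf,
        aic=-2.0 * llf + 2.0 * k,
        r2=r2,
        n=n,
        used_random_effect=used_re,
        cov_params=cov,
        df_resid=int(df_resid),
        fittedvalues=fitted,
    )
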
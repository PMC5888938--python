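"""Polynomial trajectory models over disease stage and difference curves.

Cross-sectional cognitive and biomarker values are modelled as polynomial
(order 1-3) functions of a disease-stage axis — estimated years to symptom
onset (EYO) in DIAN, z-scored log CSF total tau in DELCODE — with mixed
effects (site random intercept) and cohort-appropriate covariates. The
polynomial order is chosen by AIC among the hierarchical candidates. The
mutation-carrier minus non-carrier (or amyloid-positive minus negative)
predicted difference, divided by the pooled-sample SD of the outcome, gives
the standardized difference curve; computing it at the mean connectivity of
the high and low median-split strata visualizes the reserve effect as a
rightward shift of cognitive decline.

Skewed outcomes (CSF tau and friends) are log- and z-transformed across the
whole cohort table *before* stratification, so both group models live on a
common scale; the median split and the connectivity z-units used for
stratified prediction are likewise cohort-level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._lmm import fit_lmm, zscore
from .cohort_stats import LOG_Z_VARIABLES, assert_single_cohort, log_z_transform

__all__ = [
    "TrajectoryModel",
    "DifferenceCurve",
    "select_polynomial_model",
    "predict_difference_curve",
    "median_split",
    "pooled_outcome_values",
    "EYO_PLOT_RANGE",
]

#: Difference curves over EYO are restricted to this range (years).
EYO_PLOT_RANGE = (-20.0, 10.0)


@dataclass
class TrajectoryModel:
    """An AIC-selected polynomial mixed model for one outcome and stratum."""

    outcome: str
    axis: str
    stratum: str
    chosen_order: int
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    aic_per_order: dict[int, float]
    n: int
    with_connectivity_interaction: bool
    _params: pd.Series = field(repr=False, default=None)
    _axis_center: float = field(repr=False, default=0.0)
    _axis_scale: float = field(repr=False, default=1.0)
    _covariate_reference: dict[str, float] = field(repr=False, default_factory=dict)

    def predict(self, grid, connectivity_z: float = 0.0) -> np.ndarray:
        """Population-level prediction along the axis grid.

        Covariates are held at their pooled reference values (gender at the
        sample proportion — i.e. the weighted average of the level
        predictions — family dummies at their sample means) and the random
        site intercept at its mean of zero. ``connectivity_z`` selects the
        connectivity level (in z units of log connectivity) at which the
        axis x connectivity interaction is evaluated; 0 is the sample mean.
        """
        g = np.asarray(grid, dtype=float)
        t = (g - self._axis_center) / self._axis_scale
        cols = {"const": np.ones_like(t)}
        for j in range(1, self.chosen_order + 1):
            cols[f"axis^{j}"] = t**j
        if self.with_connectivity_interaction:
            cols["axis:conn"] = t * connectivity_z
        for name, value in self._covariate_reference.items():
            cols[name] = np.full_like(t, value)
        X = np.column_stack([cols[name] for name in self._params.index])
        return X @ self._params.to_numpy()


@dataclass
class DifferenceCurve:
    """Standardized between-group prediction difference along the axis."""

    axis_grid: np.ndarray
    standardized_difference: np.ndarray
    connectivity_stratum: str = "none"
    outcome: str = ""
    axis: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "axis_value": self.axis_grid,
                "standardized_difference": self.standardized_difference,
                "stratum": self.connectivity_stratum,
                "outcome": self.outcome,
            }
        )


def pooled_outcome_values(table: pd.DataFrame, outcome: str) -> np.ndarray:
    """Outcome on the modelling scale, transformed across the whole cohort.

    Log-z for the skewed biomarker/connectivity variables, raw otherwise.
    The pooled (both-group) transform keeps stratum models on one scale.
    """
    vals = table[outcome].to_numpy(dtype=float)
    if outcome in LOG_Z_VARIABLES or outcome in ("csf_tau", "csf_ptau181", "pib_suvr"):
        mask = np.isfinite(vals)
        out = np.full(len(vals), np.nan)
        finite = vals[mask]
        logged = np.log(finite)
        out[mask] = (logged - logged.mean()) / logged.std(ddof=1)
        return out
    return vals


def _axis_values(table: pd.DataFrame, axis: str) -> np.ndarray:
    if axis == "eyo":
        return table["eyo"].to_numpy(dtype=float)
    if axis == "csf_tau":
        vals = table["csf_tau"].to_numpy(dtype=float)
        mask = np.isfinite(vals)
        out = np.full(len(vals), np.nan)
        logged = np.log(vals[mask])
        out[mask] = (logged - logged.mean()) / logged.std(ddof=1)
        return out
    raise ValueError(f"axis must be 'eyo' or 'csf_tau', got '{axis}'")


def _stratum_mask(table: pd.DataFrame, stratum: str, cohort: str) -> np.ndarray:
    if cohort == "DIAN":
        return (table["group"] == stratum).to_numpy()
    mapping = {"abeta_pos": "pos", "abeta_neg": "neg", "pos": "pos", "neg": "neg"}
    return (table["abeta_status"] == mapping[stratum]).to_numpy()


def select_polynomial_model(
    table: pd.DataFrame,
    outcome: str,
    axis: str,
    stratum: str,
    with_connectivity_interaction: bool = False,
    connectivity_seed: str = "LFC",
    orders: tuple[int, ...] = (1, 2, 3),
    min_n: int = 30,
) -> TrajectoryModel:
    """Fit hierarchical polynomial candidates and keep the AIC minimizer.

    Candidates of order 1, 2 and 3 in the (centered, scaled) axis are fitted
    by ML with the cohort's covariates (DIAN: gender + family affiliation
    fixed, site random; DELCODE: age + gender fixed, site random); lower-order
    terms are always retained alongside higher ones. When
    ``with_connectivity_interaction`` a first-order axis x connectivity term
    is added to every candidate (used when cognition is the outcome). Orders
    whose fit fails are skipped with a warning; if all fail an error is
    raised.
    """
    cohort = assert_single_cohort(table)
    work = table.copy()
    work["_y"] = pooled_outcome_values(table, outcome)
    work["_ax"] = _axis_values(table, axis)
    if with_connectivity_interaction:
        conn_col = f"conn_{connectivity_seed.lower()}"
        work["_conn_z"] = log_z_transform(table[conn_col].to_numpy(dtype=float), conn_col).values

    sub = work[_stratum_mask(work, stratum, cohort)]
    needed = ["_y", "_ax", "site_id", "gender"]
    needed += ["family_id"] if cohort == "DIAN" else ["age"]
    if with_connectivity_interaction:
        needed.append("_conn_z")
    sub = sub.dropna(subset=[c for c in needed if c in sub.columns])
    if len(sub) < min_n:
        raise ValueError(f"only {len(sub)} complete rows in stratum '{stratum}'; need >= {min_n}")

    center = float(sub["_ax"].mean())
    scale = float(sub["_ax"].std(ddof=1))
    if scale == 0:
        raise ValueError("axis variable has zero variance in this stratum")
    t = (sub["_ax"].to_numpy() - center) / scale

    # fixed covariate columns shared by every candidate
    cov_cols: dict[str, np.ndarray] = {"gender=female": (sub["gender"].astype(str) == "female").to_numpy(dtype=float)}
    if cohort == "DIAN":
        fam = pd.Categorical(sub["family_id"].astype(str))
        for lev in fam.categories[1:]:
            d = (fam == lev).astype(float)
            if d.std() > 0:
                cov_cols[f"family_id={lev}"] = np.asarray(d)
    else:
        cov_cols["age"] = zscore(sub["age"].to_numpy(dtype=float))

    y = sub["_y"].to_numpy(dtype=float)
    site = sub["site_id"]
    conn_z = sub["_conn_z"].to_numpy(dtype=float) if with_connectivity_interaction else None

    def _fit_all(site_groups):
        fits: dict[int, object] = {}
        aics: dict[int, float] = {}
        for k in orders:
            cols = {"const": np.ones(len(sub))}
            for j in range(1, k + 1):
                cols[f"axis^{j}"] = t**j
            if with_connectivity_interaction:
                cols["axis:conn"] = t * conn_z
            cols.update(cov_cols)
            X = pd.DataFrame(cols, index=sub.index)
            try:
                res = fit_lmm(y, X, site_groups)
                if not np.isfinite(res.aic):
                    raise ValueError("non-finite AIC")
            except Exception as err:  # noqa: BLE001 - degraded orders are skipped
                warnings.warn(
                    f"order-{k} trajectory fit failed ({err}); skipping", UserWarning, stacklevel=3
                )
                continue
            fits[k], aics[k] = res, res.aic
        return fits, aics

    fits, aics = _fit_all(site)
    # AIC values are only comparable when every candidate used the same
    # estimation path; if the random intercept was singular for some orders
    # only, refit the whole candidate set on the fixed-intercept path.
    if fits and len({f.used_random_effect for f in fits.values()}) > 1:
        fits, aics = _fit_all(None)
    if not fits:
        raise RuntimeError(f"all polynomial orders failed for outcome '{outcome}' in '{stratum}'")

    best = min(aics, key=aics.get)
    res = fits[best]
    reference = {name: float(np.mean(vals)) for name, vals in cov_cols.items()}
    return TrajectoryModel(
        outcome=outcome,
        axis=axis,
        stratum=stratum,
        chosen_order=best,
        coefficients={k: float(v) for k, v in res.params.items()},
        standard_errors={k: float(v) for k, v in res.bse.items()},
        aic_per_order=aics,
        n=res.n,
        with_connectivity_interaction=with_connectivity_interaction,
        _params=res.params,
        _axis_center=center,
        _axis_scale=scale,
        _covariate_reference=reference,
    )


def predict_difference_curve(
    model_g1: TrajectoryModel,
    model_g2: TrajectoryModel,
    grid,
    pooled_sd: float,
    connectivity_z: float = 0.0,
    stratum_label: str = "none",
) -> DifferenceCurve:
    """Group-1 minus group-2 prediction per grid point, in pooled-SD units.

    Both models must share outcome and axis. For the EYO axis the grid is
    clipped to the reporting range [-20, +10] years.
    """
    if model_g1.outcome != model_g2.outcome:
        raise ValueError(
            f"models predict different outcomes: '{model_g1.outcome}' vs '{model_g2.outcome}'"
        )
    if model_g1.axis != model_g2.axis:
        raise ValueError("models use different disease-stage axes")
    if not pooled_sd > 0:
        raise ValueError("pooled SD must be positive")
    grid = np.asarray(grid, dtype=float)
    if model_g1.axis == "eyo":
        grid = grid[(grid >= EYO_PLOT_RANGE[0]) & (grid <= EYO_PLOT_RANGE[1])]
    diff = (
        model_g1.predict(grid, connectivity_z=connectivity_z)
        - model_g2.predict(grid, connectivity_z=connectivity_z)
    ) / pooled_sd
    return DifferenceCurve(
        axis_grid=grid,
        standardized_difference=diff,
        connectivity_stratum=stratum_label,
        outcome=model_g1.outcome,
        axis=model_g1.axis,
    )


def median_split(values) -> np.ndarray:
    """Label values 'high' (strictly above the median) or 'low' (at or below).

    Ties at the median go to 'low'. Used for stratified curves and plots
    only; inferential interaction tests always use the continuous measure.
    """
    values = np.asarray(values, dtype=float)
    if np.unique(values).size < 2:
        raise ValueError("median split needs at least 2 distinct values")
    med = np.median(values)
    return np.where(values > med, "high", "low")
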
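"""Group descriptives and reserve moderation models for the cohort tables.

This module houses the cohort-level statistics: Cohen's d (root-mean-square
convention) and group comparison tests for the baseline tables, the log-z
transform applied to skewed biomarkers and connectivity scores, and the
moderation ("reserve") linear mixed models testing whether disease severity
(estimated years to symptom onset in DIAN, CSF total tau in DELCODE)
interacts with global hub connectivity in predicting cognition.

Modelling conventions, fixed across the module:

* All continuous variables are z-scored within the fitted subset, so reported
  coefficients are standardized betas; interaction columns are products of
  the z-scored mains and are not re-standardized.
* Mixed models carry a random intercept per site and are fitted by maximum
  likelihood so that full/reduced AIC comparisons are valid.
* DIAN models adjust for gender and family affiliation (fixed) and exclude
  age (collinear with years-to-onset); DELCODE models adjust for age and
  gender.
* The two cohorts are never pooled: every operation that receives rows from
  both raises.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._lmm import LmmResult, build_design, fit_lmm, zscore

__all__ = [
    "TransformedVariable",
    "ModelTerm",
    "ModelFit",
    "AicComparison",
    "GroupComparison",
    "assert_single_cohort",
    "log_z_transform",
    "cohens_d",
    "group_comparison",
    "fit_reserve_interaction",
    "fit_education_model",
    "fit_group_ancova",
    "apply_alpha_gate",
]

#: Variables consumed on the natural-log + z scale by the models.
LOG_Z_VARIABLES = ("csf_tau", "csf_ptau181", "pib_suvr", "conn_lfc", "conn_rfc", "conn_occ", "conn_m1")

PRIMARY_ALPHA = 0.0125
NOMINAL_ALPHA = 0.05


@dataclass
class TransformedVariable:
    values: np.ndarray
    source_name: str
    transform: str = "log_z"


@dataclass
class ModelTerm:
    name: str
    beta: float
    se: float
    t: float
    p: float


@dataclass
class ModelFit:
    """A fitted model: standardized terms, fit statistics and bookkeeping."""

    outcome: str
    stratum: str
    terms: list[ModelTerm]
    aic: float
    r2: float
    n: int
    random_effect: str | None
    key_term: str | None = None
    primary: bool = False
    extras: dict = field(default_factory=dict)

    def term(self, name: str) -> ModelTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(f"no term named '{name}' in model for {self.outcome}")

    @property
    def key_p(self) -> float:
        if self.key_term is None:
            raise ValueError("model has no designated hypothesis term")
        if self.key_term in self.extras.get("joint_p", {}):
            return self.extras["joint_p"][self.key_term]
        return self.term(self.key_term).p

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(outcome=self.outcome, stratum=self.stratum, term=t.name, beta=t.beta,
                 se=t.se, t=t.t, p=t.p, aic=self.aic, r2=self.r2, n=self.n)
            for t in self.terms
        ]
        return pd.DataFrame(rows)


@dataclass
class AicComparison:
    aic_full: float
    aic_reduced: float

    @property
    def delta(self) -> float:
        return self.aic_full - self.aic_reduced

    @property
    def full_preferred(self) -> bool:
        return self.delta < 0


@dataclass
class GroupComparison:
    variable: str
    test: str
    statistic: float
    p: float
    df: float | tuple
    posthoc: pd.DataFrame | None = None


def assert_single_cohort(table: pd.DataFrame) -> str:
    """Raise if rows from more than one cohort are present; return the cohort."""
    cohorts = pd.unique(table["cohort"].astype(str))
    if len(cohorts) != 1:
        raise ValueError(
            f"rows from multiple cohorts {sorted(cohorts)} passed to a single-cohort "
            "operation; DIAN and DELCODE data are never pooled"
        )
    return str(cohorts[0])


def log_z_transform(values, source_name: str = "") -> TransformedVariable:
    """Natural log followed by a z-score (sample SD).

    Used for right-skewed positive measures (CSF tau, p-tau, PiB uptake,
    connectivity scores) so that downstream linear models see approximately
    normal predictors.
    """
    values = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(values)) or np.any(values <= 0):
        raise ValueError(f"log-z transform of '{source_name}' requires strictly positive values")
    logged = np.log(values)
    # tolerance absorbs float noise in log of identical values
    if logged.std(ddof=1) <= 1e-12 * max(1.0, float(np.abs(logged).max())):
        raise ValueError(f"'{source_name}' has zero variance on the log scale")
    return TransformedVariable(values=zscore(logged), source_name=source_name)


def cohens_d(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """Effect size d = |m1 - m2| / sqrt((s1^2 + s2^2)/2).

    The root-mean-square-of-SDs convention (not the pooled, df-weighted SD);
    this is the convention under which the published DIAN/DELCODE baseline
    effect sizes reproduce.
    """
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations cannot be negative")
    denom = np.sqrt((sd1**2 + sd2**2) / 2.0)
    if denom == 0:
        raise ValueError("both standard deviations are zero; d is undefined")
    return float(abs(mean1 - mean2) / denom)


def group_comparison(table: pd.DataFrame, variable: str, grouping: str) -> GroupComparison:
    """Two-sample t (2 groups), one-way ANOVA + Tukey (>2), or chi-square.

    Categorical variables are cross-tabulated against the grouping and tested
    with Pearson's chi-square without continuity correction; continuous
    variables use a two-sample t-test or one-way ANOVA with Tukey HSD post
    hoc pairs.
    """
    if "cohort" in table.columns:
        assert_single_cohort(table)
    sub = table[[variable, grouping]].dropna()
    levels = pd.unique(sub[grouping])
    if len(levels) < 2:
        raise ValueError(f"need at least 2 groups in '{grouping}', found {len(levels)}")

    if not pd.api.types.is_numeric_dtype(sub[variable]):
        counts = pd.crosstab(sub[variable], sub[grouping])
        if (counts.sum(axis=0) == 0).any() or counts.shape[0] < 2:
            raise ValueError("contingency table is degenerate; chi-square undefined")
        chi2, p, dof, _ = sps.chi2_contingency(counts.to_numpy(), correction=False)
        return GroupComparison(variable, "chi2", float(chi2), float(p), dof)

    samples = [sub.loc[sub[grouping] == g, variable].to_numpy() for g in levels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs at least 2 observations")
    if len(levels) == 2:
        if np.array_equal(np.sort(samples[0]), np.sort(samples[1])):
            return GroupComparison(variable, "t", 0.0, 1.0, len(sub) - 2)
        t, p = sps.ttest_ind(samples[0], samples[1], equal_var=True)
        return GroupComparison(variable, "t", float(t), float(p), len(sub) - 2)

    f, p = sps.f_oneway(*samples)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    tukey = pairwise_tukeyhsd(sub[variable].to_numpy(), sub[grouping].astype(str).to_numpy())
    posthoc = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
    return GroupComparison(
        variable, "anova", float(f), float(p), (len(levels) - 1, len(sub) - len(levels)), posthoc
    )


# ---------------------------------------------------------------------------
# model-fitting plumbing


def _stratum_rows(table: pd.DataFrame, stratum: str, cohort: str) -> pd.DataFrame:
    if cohort == "DIAN":
        if stratum not in ("MC", "NC"):
            raise ValueError(f"DIAN stratum must be MC or NC, got '{stratum}'")
        return table[table["group"] == stratum]
    if cohort == "DELCODE":
        mapping = {"abeta_pos": "pos", "abeta_neg": "neg", "pos": "pos", "neg": "neg"}
        if stratum not in mapping:
            raise ValueError(f"DELCODE stratum must be abeta_pos or abeta_neg, got '{stratum}'")
        return table[table["abeta_status"] == mapping[stratum]]
    raise ValueError(f"unknown cohort '{cohort}'")


def _severity_column(df: pd.DataFrame, severity: str) -> np.ndarray:
    """Severity axis on the modelling scale (EYO raw; CSF-tau log)."""
    if severity == "eyo":
        return df["eyo"].to_numpy(dtype=float)
    if severity == "csf_tau":
        return np.log(df["csf_tau"].to_numpy(dtype=float))
    raise ValueError(f"severity must be 'eyo' or 'csf_tau', got '{severity}'")


def _connectivity_column(df: pd.DataFrame, seed: str) -> np.ndarray:
    col = f"conn_{seed.lower()}"
    if col not in df.columns:
        raise ValueError(f"connectivity column '{col}' missing from the table")
    return np.log(df[col].to_numpy(dtype=float))


def _gender_female(df: pd.DataFrame) -> np.ndarray:
    return (df["gender"].astype(str) == "female").astype(float).to_numpy()


def _prepare(
    df: pd.DataFrame, needed: list[str], min_n: int
) -> pd.DataFrame:
    sub = df.dropna(subset=[c for c in needed if c in df.columns])
    if len(sub) < min_n:
        raise ValueError(f"only {len(sub)} complete rows; at least {min_n} required")
    return sub


def _fit_with_design(
    y: np.ndarray, X: pd.DataFrame, site: pd.Series | None
) -> LmmResult:
    return fit_lmm(y, X, site)


def _terms_from(res: LmmResult, rename: dict[str, str]) -> list[ModelTerm]:
    out = []
    for name in res.params.index:
        label = rename.get(name, name)
        out.append(
            ModelTerm(
                name=label,
                beta=float(res.params[name]),
                se=float(res.bse[name]),
                t=float(res.tvalues[name]),
                p=float(res.pvalues[name]),
            )
        )
    return out


def _covariate_spec(cohort: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """(continuous, categorical) covariates per cohort.

    DIAN: gender + family affiliation fixed; age deliberately excluded
    (collinear with EYO). DELCODE: age + gender fixed.
    """
    if cohort == "DIAN":
        return (), ("gender", "family_id")
    return ("age",), ("gender",)


def fit_reserve_interaction(
    table: pd.DataFrame,
    outcome: str,
    severity: str,
    stratum: str,
    connectivity_seed: str = "LFC",
    min_n: int = 20,
) -> tuple[ModelFit, AicComparison]:
    """Severity x connectivity moderation model on a cognition outcome.

    Fits, within one stratum of one cohort, the linear mixed model

        z(outcome) ~ z(severity) + z(log connectivity)
                     + z(severity) * z(log connectivity) + covariates
                     + (1 | site)

    by ML, and the reduced model without the interaction term, returning the
    standardized coefficient table plus the full-vs-reduced AIC comparison.
    A negative AIC delta means the interaction improves the fit.
    """
    cohort = assert_single_cohort(table)
    df = _stratum_rows(table, stratum, cohort)
    conn_col = f"conn_{connectivity_seed.lower()}"
    cont_cov, cat_cov = _covariate_spec(cohort)
    needed = [outcome, conn_col, "site_id", *cont_cov, *cat_cov]
    needed += ["eyo"] if severity == "eyo" else ["csf_tau"]
    df = _prepare(df, needed, min_n)

    work = df.copy()
    work["_sev"] = _severity_column(df, severity)
    work["_conn"] = _connectivity_column(df, connectivity_seed)

    X_full = build_design(
        work,
        continuous=("_sev", "_conn", *cont_cov),
        categorical=cat_cov,
        interactions=(("_sev", "_conn"),),
    )
    X_red = X_full.drop(columns=["_sev:_conn"])
    y = zscore(work[outcome].to_numpy(dtype=float))
    site = work["site_id"]

    full = _fit_with_design(y, X_full, site)
    reduced = _fit_with_design(y, X_red, site)
    if full.used_random_effect != reduced.used_random_effect:
        # AIC is only comparable on a common estimation path; if the random
        # intercept was singular for one model only, put both on the
        # fixed-intercept path.
        full = _fit_with_design(y, X_full, None)
        reduced = _fit_with_design(y, X_red, None)

    sev_label = severity
    rename = {
        "_sev": sev_label,
        "_conn": f"conn_{connectivity_seed.lower()}",
        "_sev:_conn": f"{sev_label}:conn_{connectivity_seed.lower()}",
    }
    fit = ModelFit(
        outcome=outcome,
        stratum=stratum,
        terms=_terms_from(full, rename),
        aic=full.aic,
        r2=full.r2,
        n=full.n,
        random_effect="site_id" if full.used_random_effect else None,
        key_term=rename["_sev:_conn"],
        primary=(connectivity_seed == "LFC" and outcome in ("mmse", "lm_delayed")),
        extras={"cohort": cohort, "severity": severity, "seed": connectivity_seed,
                "df_resid": full.df_resid},
    )
    return fit, AicComparison(aic_full=full.aic, aic_reduced=reduced.aic)


def fit_education_model(
    table: pd.DataFrame,
    stratum: str,
    connectivity_seed: str = "LFC",
    min_n: int = 20,
) -> ModelFit:
    """Does education predict (log-z) global connectivity within a stratum?

    Adjusted for gender and site (random) in both cohorts, plus years-to-onset
    and family affiliation in DIAN and age in DELCODE. The education term's
    two-sided p is reported; a one-sided p (direction: more education, higher
    connectivity) is additionally stored in ``extras`` because trend-level
    associations are conventionally read directionally.
    """
    cohort = assert_single_cohort(table)
    df = _stratum_rows(table, stratum, cohort)
    conn_col = f"conn_{connectivity_seed.lower()}"
    if cohort == "DIAN":
        cont, cat = ("education", "eyo"), ("gender", "family_id")
    else:
        cont, cat = ("education", "age"), ("gender",)
    df = _prepare(df, [conn_col, "site_id", *cont, *cat], min_n)

    X = build_design(df, continuous=cont, categorical=cat)
    y = log_z_transform(df[conn_col].to_numpy(dtype=float), conn_col).values
    res = _fit_with_design(y, X, df["site_id"])

    beta = float(res.params["education"])
    p_two = float(res.pvalues["education"])
    one_sided = p_two / 2.0 if beta > 0 else 1.0 - p_two / 2.0
    return ModelFit(
        outcome=conn_col,
        stratum=stratum,
        terms=_terms_from(res, {}),
        aic=res.aic,
        r2=res.r2,
        n=res.n,
        random_effect="site_id" if res.used_random_effect else None,
        key_term="education",
        primary=False,
        extras={"cohort": cohort, "one_sided_p": one_sided, "df_resid": res.df_resid},
    )


def fit_group_ancova(
    table: pd.DataFrame,
    outcome: str,
    grouping: str = "group",
    covariates: tuple[str, ...] = ("age", "gender", "education"),
    min_n: int = 10,
) -> ModelFit:
    """ANCOVA-style group effect on a (log-z for skewed) outcome.

    Used both for the carrier-vs-non-carrier connectivity comparison and for
    the scanner-model confound check. Continuous covariates are z-scored,
    gender enters as a dummy, site as a random intercept where more than one
    site is present. The joint Wald p-value over the group dummies is stored
    under ``extras['group_p']`` (equal to the single-coefficient p when the
    grouping has two levels).
    """
    cohort = assert_single_cohort(table) if "cohort" in table.columns else ""
    cont = tuple(c for c in covariates if c != "gender")
    cat = ("gender",) if "gender" in covariates else ()
    df = _prepare(table, [outcome, grouping, "site_id", *cont, *cat], min_n)
    if df[grouping].nunique() < 2:
        raise ValueError(f"grouping '{grouping}' has fewer than 2 levels in the data")

    X = build_design(df, continuous=cont, categorical=(grouping, *cat))
    if outcome in LOG_Z_VARIABLES:
        y = log_z_transform(df[outcome].to_numpy(dtype=float), outcome).values
    else:
        y = zscore(df[outcome].to_numpy(dtype=float))
    res = _fit_with_design(y, X, df["site_id"])

    group_terms = [c for c in X.columns if c.startswith(f"{grouping}=")]
    group_p = (
        float(res.pvalues[group_terms[0]])
        if len(group_terms) == 1
        else res.wald_joint_p(group_terms)
    )
    key = group_terms[0] if len(group_terms) == 1 else grouping
    return ModelFit(
        outcome=outcome,
        stratum="all",
        terms=_terms_from(res, {}),
        aic=res.aic,
        r2=res.r2,
        n=res.n,
        random_effect="site_id" if res.used_random_effect else None,
        key_term=key,
        primary=False,
        extras={"cohort": cohort, "group_p": group_p, "joint_p": {grouping: group_p},
                "df_resid": res.df_resid},
    )


def apply_alpha_gate(
    results: list[ModelFit],
    primary_alpha: float = PRIMARY_ALPHA,
    nominal_alpha: float = NOMINAL_ALPHA,
) -> list[ModelFit]:
    """Flag significance with the Bonferroni gate on the primary analyses.

    The four primary moderation tests (severity x hub connectivity on the two
    cognition outcomes in the two cohorts) are held to the corrected
    threshold p < 0.0125 (strict); everything else to the nominal 0.05.
    The decision is stored in ``extras['significant']`` together with the
    threshold applied.
    """
    for fit in results:
        alpha = primary_alpha if fit.primary else nominal_alpha
        fit.extras["alpha"] = alpha
        fit.extras["significant"] = bool(fit.key_p < alpha)
    return results
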
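"""Covariate adjustment and reference-sample standardization.

Biomarker panels are adjusted for age and sex before dimension reduction:
per variable, a linear model on age and sex is fitted in the healthy
reference sample and a covariate's contribution is removed for *every*
subject only if its coefficient is statistically significant (two-sided,
``alpha`` per variable).  Standardization then z-scores each variable with
the mean/SD of a designated reference sample (probands + healthy, the
sample later used to fit the PCAs); relatives are scaled with the same
constants rather than their own.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import BiomarkerPanel

__all__ = [
    "CovariateAdjuster",
    "ReferenceScaler",
    "fit_adjustment",
    "apply_adjustment",
    "standardize",
]


class CovariateAdjuster(BaseEstimator, TransformerMixin):
    """Remove significant age/sex effects estimated in a reference sample.

    Parameters
    ----------
    alpha : float
        Two-sided significance level for retaining a covariate term,
        applied per variable with no multiplicity correction.

    Attributes (after fit)
    ----------------------
    coef_ : DataFrame, variables x (intercept, age, sex)
    age_flag_, sex_flag_ : Series of bool per variable
    pvalues_ : DataFrame, variables x (age, sex)
    ref_age_mean_, ref_sex_mean_ : centering constants from the reference
        sample, so that a subject at the reference mean age receives no age
        correction.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X: pd.DataFrame, covariates: pd.DataFrame):
        """Fit per-variable linear models in the reference (healthy) sample.

        ``X`` holds only reference-sample rows; ``covariates`` must carry
        ``age`` and ``sex`` columns aligned with ``X``.
        """
        X = pd.DataFrame(X)
        n = len(X)
        if n < 10:
            raise ValueError(f"need >= 10 reference subjects, got {n}")
        if not {"age", "sex"} <= set(covariates.columns):
            raise ValueError("covariates must contain 'age' and 'sex'")
        age = covariates["age"].to_numpy(dtype=float)
        sex = covariates["sex"].to_numpy(dtype=float)
        self.ref_age_mean_ = float(age.mean())
        self.ref_sex_mean_ = float(sex.mean())

        D = np.column_stack([np.ones(n), age - self.ref_age_mean_, sex - self.ref_sex_mean_])
        dof = n - D.shape[1]
        DtD_inv = np.linalg.inv(D.T @ D)

        coefs, pvals, flags = {}, {}, {}
        for var in X.columns:
            y = X[var].to_numpy(dtype=float)
            if np.ptp(y) == 0:
                warnings.warn(f"variable {var!r} is constant; skipping adjustment")
                coefs[var] = (y[0] if n else 0.0, 0.0, 0.0)
                pvals[var] = (1.0, 1.0)
                flags[var] = (False, False)
                continue
            beta = DtD_inv @ D.T @ y
            resid = y - D @ beta
            s2 = resid @ resid / dof
            se = np.sqrt(s2 * np.diag(DtD_inv))
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(se > 0, beta / se, 0.0)
            p = 2 * stats.t.sf(np.abs(t), dof)
            coefs[var] = tuple(beta)
            pvals[var] = (float(p[1]), float(p[2]))
            flags[var] = (p[1] < self.alpha, p[2] < self.alpha)

        self.coef_ = pd.DataFrame(coefs, index=["intercept", "age", "sex"]).T
        self.pvalues_ = pd.DataFrame(pvals, index=["age", "sex"]).T
        fl = pd.DataFrame(flags, index=["age", "sex"]).T
        self.age_flag_ = fl["age"]
        self.sex_flag_ = fl["sex"]
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def transform(self, X: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
        """Subtract flagged covariate contributions (reference-centered)."""
        if not hasattr(self, "coef_"):
            raise ValueError("CovariateAdjuster is not fitted")
        X = pd.DataFrame(X)
        if list(X.columns) != list(self.feature_names_in_):
            raise ValueError("variable set does not match the fitted model")
        age = covariates["age"].to_numpy(dtype=float) - self.ref_age_mean_
        sex = covariates["sex"].to_numpy(dtype=float) - self.ref_sex_mean_
        out = X.copy().astype(float)
        for var in X.columns:
            corr = 0.0
            if self.age_flag_[var]:
                corr = corr + self.coef_.loc[var, "age"] * age
            if self.sex_flag_[var]:
                corr = corr + self.coef_.loc[var, "sex"] * sex
            if np.ndim(corr):
                out[var] = out[var].to_numpy() - corr
        return out

    def to_json(self) -> str:
        return json.dumps(
            dict(
                alpha=self.alpha,
                ref_age_mean=self.ref_age_mean_,
                ref_sex_mean=self.ref_sex_mean_,
                coef=self.coef_.to_dict(),
                pvalues=self.pvalues_.to_dict(),
                age_flag=self.age_flag_.astype(bool).to_dict(),
                sex_flag=self.sex_flag_.astype(bool).to_dict(),
            ),
            sort_keys=True,
        )


class ReferenceScaler(BaseEstimator, TransformerMixin):
    """z-score variables with a reference sample's mean and SD.

    The reference sample (probands + healthy, i.e. the eventual PCA sample)
    defines the scaling constants; any other rows — relatives in particular
    — are transformed with those same constants.
    """

    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=self.ddof)
        bad = self.scale_[~(self.scale_ > 0)]
        if len(bad):
            raise ValueError(
                f"zero reference SD for variable(s): {list(bad.index)}"
            )
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "mean_"):
            raise ValueError("ReferenceScaler is not fitted")
        X = pd.DataFrame(X)
        if list(X.columns) != list(self.feature_names_in_):
            raise ValueError("variable set does not match the fitted scaler")
        return (X - self.mean_) / self.scale_


# ---------------------------------------------------------------------------
# thin functional wrappers on the panel types
# ---------------------------------------------------------------------------

def fit_adjustment(
    panel: BiomarkerPanel, subjects: pd.DataFrame, alpha: float = 0.05
) -> CovariateAdjuster:
    """Fit the age/sex adjustment model in the healthy rows of ``panel``."""
    healthy = (subjects["role"] == "healthy").to_numpy()
    cov = subjects.set_index("subject_id")[["age", "sex"]]
    return CovariateAdjuster(alpha=alpha).fit(
        panel.values.loc[healthy], cov.loc[healthy]
    )


def apply_adjustment(
    model: CovariateAdjuster, panel: BiomarkerPanel, subjects: pd.DataFrame
) -> BiomarkerPanel:
    """Apply a fitted adjustment to every subject (no refitting)."""
    cov = subjects.set_index("subject_id")[["age", "sex"]].loc[panel.values.index]
    return BiomarkerPanel(
        values=model.transform(panel.values, cov), domain_of=panel.domain_of
    )


def standardize(
    panel: BiomarkerPanel, reference_rows: np.ndarray
) -> tuple[BiomarkerPanel, ReferenceScaler]:
    """z-score all rows of ``panel`` with constants from ``reference_rows``
    (boolean mask or index array over the panel's rows)."""
    scaler = ReferenceScaler().fit(panel.values.loc[reference_rows])
    return (
        BiomarkerPanel(values=scaler.transform(panel.values), domain_of=panel.domain_of),
        scaler,
    )
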
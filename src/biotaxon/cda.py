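"""Canonical discriminant analysis of groups on the bio-factors.

Solves the generalized eigenproblem B v = lambda W v (between- versus
pooled within-group SSCP), yielding min(groups - 1, variables) canonical
variates with canonical correlations r_i = sqrt(lambda_i / (1 + lambda_i)),
Bartlett chi-square tests of residual dimensionality, a structure matrix of
total-sample correlations between each predictor and each variate, and
per-subject variate scores centered at the grand mean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.base import BaseEstimator, TransformerMixin

from .groupstats import anova_oneway, equivalence_classes, tukey_posthoc

__all__ = ["CanonicalDiscriminantAnalysis", "fit_cda", "variate_posthoc"]


class CanonicalDiscriminantAnalysis(BaseEstimator, TransformerMixin):
    """Canonical variates maximally separating labeled groups.

    Attributes (after fit)
    ----------------------
    eigenvalues_ : lambda_i of W^-1 B, non-increasing
    canonical_correlations_ : r_i in [0, 1), non-increasing
    coef_raw_ : raw discriminant coefficients (unit pooled within-group
        variance of the variate scores)
    coef_std_ : coefficients standardized by pooled within-group SDs
    chi2_, chi2_df_, chi2_p_ : Bartlett sequential tests of dimensions >= i
    structure_ : variables x variates total-sample correlation matrix
    """

    def fit(self, X, y):
        X = pd.DataFrame(X)
        self.feature_names_in_ = np.asarray(X.columns)
        arr = X.to_numpy(dtype=float)
        y = np.asarray(y)
        n, p = arr.shape
        self.classes_ = pd.unique(y)
        g = len(self.classes_)
        if g < 2:
            raise ValueError("need at least 2 groups")
        counts = np.array([(y == c).sum() for c in self.classes_])
        if np.any(counts < p + 1):
            small = self.classes_[counts < p + 1]
            raise ValueError(f"groups {list(small)} have fewer than p+1 members")

        grand = arr.mean(axis=0)
        B = np.zeros((p, p))
        W = np.zeros((p, p))
        for c in self.classes_:
            sub = arr[y == c]
            m = sub.mean(axis=0)
            B += len(sub) * np.outer(m - grand, m - grand)
            centered = sub - m
            W += centered.T @ centered
        self.n_, self.n_groups_ = n, g

        try:
            lam, vec = linalg.eigh(B, W)
        except linalg.LinAlgError as e:
            raise linalg.LinAlgError(
                "pooled within-group SSCP is singular; drop collinear "
                "variables or add data (no regularization is applied silently)"
            ) from e
        order = np.argsort(lam)[::-1]
        r = min(g - 1, p)
        lam = np.clip(lam[order][:r], 0.0, None)
        vec = vec[:, order][:, :r]

        S_w = W / (n - g)
        scale = np.sqrt(np.einsum("ij,jk,ki->i", vec.T, S_w, vec))
        vec = vec / scale

        self.eigenvalues_ = lam
        self.canonical_correlations_ = np.sqrt(lam / (1 + lam))
        self.grand_mean_ = grand

        # Bartlett's sequential test of dimensions >= i
        chi2, dfs, ps = [], [], []
        const = n - 1 - (p + g) / 2.0
        for i in range(r):
            wilks = float(np.prod(1.0 / (1.0 + lam[i:])))
            c2 = -const * np.log(wilks)
            df = (p - i) * (g - 1 - i)
            chi2.append(c2)
            dfs.append(df)
            ps.append(float(stats.chi2.sf(c2, df)))
        self.chi2_ = np.array(chi2)
        self.chi2_df_ = np.array(dfs)
        self.chi2_p_ = np.array(ps)

        # structure matrix (total-sample correlations), then fix variate signs
        scores = (arr - grand) @ vec
        if np.any(scores.std(axis=0) == 0):
            raise ValueError("zero-variance variate")
        structure = np.array(
            [[np.corrcoef(arr[:, j], scores[:, i])[0, 1] for i in range(r)]
             for j in range(p)]
        )
        for i in range(r):
            jmax = int(np.argmax(np.abs(structure[:, i])))
            if structure[jmax, i] < 0:
                vec[:, i] = -vec[:, i]
                structure[:, i] = -structure[:, i]
        self.coef_raw_ = vec
        self.coef_std_ = vec * np.sqrt(np.diag(S_w))[:, None]
        self.structure_ = pd.DataFrame(
            structure,
            index=self.feature_names_in_,
            columns=[f"variate_{i + 1}" for i in range(r)],
        )
        return self

    @property
    def n_variates_(self) -> int:
        return self.coef_raw_.shape[1]

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "coef_raw_"):
            raise ValueError("CanonicalDiscriminantAnalysis is not fitted")
        X = pd.DataFrame(X)
        if list(X.columns) != list(self.feature_names_in_):
            raise ValueError("variable set does not match the fitted model")
        return (X.to_numpy(dtype=float) - self.grand_mean_) @ self.coef_raw_

    def structure_matrix(self) -> pd.DataFrame:
        return self.structure_.copy()


def fit_cda(scores: pd.DataFrame, groups) -> CanonicalDiscriminantAnalysis:
    """Fit a CDA of ``groups`` on the bio-factor ``scores``."""
    return CanonicalDiscriminantAnalysis().fit(scores, groups)


def variate_posthoc(
    model: CanonicalDiscriminantAnalysis, scores: pd.DataFrame, groups,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """ANOVA + Tukey ordering of the groups on every variate.

    Returns one row per variate with F, p and an ordered equivalence-class
    pattern such as ``"BT2 < BT1 < (BT3 = HC)"``.
    """
    V = model.transform(scores)
    groups = np.asarray(groups)
    rows = []
    for i in range(model.n_variates_):
        y = V[:, i]
        F, dfb, dfe, p = anova_oneway(y, groups)
        pw = tukey_posthoc(y, groups, alpha=alpha)
        rows.append(
            dict(variate=f"variate_{i + 1}", F=F, p=p,
                 pattern=equivalence_classes(y, groups, pw))
        )
    return pd.DataFrame(rows)
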
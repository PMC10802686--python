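"""Domain-wise PCA with promax rotation: construction of bio-factors.

Within each laboratory domain a principal component analysis of the
covariance matrix of the (standardized, covariate-adjusted) variables is
computed, the number of retained components is chosen by a scree
(maximum-acceleration) rule or an explicit per-domain override, and — when
more than one component survives — the loadings are Kaiser-normalized,
varimax-rotated, and obliquely rotated with promax (kappa = 3).  Factor
scores use the regression method (scoring coefficients = inverse covariance
times the structure matrix) and are standardized to unit variance in the
fit sample, so fit-sample scores are standard scores.  Relatives are scored
by pushing their (identically standardized) data through the coefficients
fitted on probands + healthy; no refitting ever happens for them.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import BiomarkerPanel, VARIABLES

__all__ = [
    "scree_count",
    "varimax",
    "promax_rotate",
    "DomainPCA",
    "BioFactorModel",
    "BioFactorScores",
]


def scree_count(eigenvalues) -> int:
    """Number of components to retain by the maximum-acceleration elbow.

    With eigenvalues ``l_1 >= l_2 >= ...`` the second difference
    ``a_i = l_{i-1} - 2 l_i + l_{i+1}`` is evaluated at every interior index
    and the retained count is the (1-based) index of its maximum minus one.
    Ties resolve to the smaller count; an all-equal spectrum retains one
    component, as does a spectrum with fewer than three eigenvalues (with a
    warning).
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.ndim != 1:
        raise ValueError("eigenvalues must be a 1-d sequence")
    if np.any(np.diff(lam) > 1e-10):
        raise ValueError("eigenvalues must be non-increasing")
    if lam.size < 3:
        warnings.warn("fewer than 3 eigenvalues; retaining 1 component")
        return 1
    accel = lam[:-2] - 2 * lam[1:-1] + lam[2:]
    return max(int(np.argmax(accel)) + 1, 1)


def varimax(
    loadings: np.ndarray, max_iter: int = 500, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal varimax rotation; returns (rotated loadings, rotation).

    Classical pairwise (Jacobi-style) sweeps: every plane of two components
    is rotated by its closed-form criterion-maximizing angle until a full
    sweep no longer improves the varimax criterion.
    """
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    if k < 2:
        return L.copy(), np.eye(k)
    Lr = L.copy()
    R = np.eye(k)

    def criterion(M: np.ndarray) -> float:
        return float(((M**4).sum(axis=0) - (M**2).sum(axis=0) ** 2 / p).sum())

    d_old = criterion(Lr)
    for _ in range(max_iter):
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = Lr[:, i], Lr[:, j]
                u = x * x - y * y
                v = 2 * x * y
                A, Bs = u.sum(), v.sum()
                num = (2 * u * v).sum() - 2 * A * Bs / p
                den = (u * u - v * v).sum() - (A * A - Bs * Bs) / p
                theta = 0.25 * np.arctan2(num, den)
                if abs(theta) < 1e-14:
                    continue
                c, s = np.cos(theta), np.sin(theta)
                rot = np.array([[c, -s], [s, c]])
                Lr[:, [i, j]] = Lr[:, [i, j]] @ rot
                R[:, [i, j]] = R[:, [i, j]] @ rot
        d_new = criterion(Lr)
        if d_new <= d_old * (1 + tol) + 1e-15:
            return Lr, R
        d_old = d_new
    raise RuntimeError(f"varimax failed to converge in {max_iter} sweeps")


def promax_rotate(
    loadings: np.ndarray, kappa: float = 3.0, kaiser: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Promax oblique rotation of a loading matrix.

    The varimax solution (with Kaiser row normalization when ``kaiser``) is
    raised element-wise to power ``kappa`` preserving signs, and the oblique
    least-squares transform to that target yields the pattern matrix and the
    factor correlation matrix.  A single component is returned unchanged
    with correlation matrix ``[[1]]``.
    """
    L = np.asarray(loadings, dtype=float)
    if L.ndim != 2:
        raise ValueError("loadings must be 2-d")
    p, k = L.shape
    if k < 2:
        return L.copy(), np.eye(k)

    if kaiser:
        h = np.sqrt((L**2).sum(axis=1))
        h = np.where(h > 0, h, 1.0)
        V, _ = varimax(L / h[:, None])
        V = V * h[:, None]
    else:
        V, _ = varimax(L)

    Q = V * np.abs(V) ** (kappa - 1)
    U, *_ = np.linalg.lstsq(V, Q, rcond=None)
    d = np.diag(np.linalg.inv(U.T @ U))
    U = U * np.sqrt(d)
    pattern = V @ U
    Ui = np.linalg.inv(U)
    phi = Ui @ Ui.T
    # exact symmetry for downstream positive-definiteness checks
    phi = (phi + phi.T) / 2
    return pattern, phi


def _fix_signs(mat: np.ndarray) -> np.ndarray:
    """Flip component columns so the largest-|loading| variable is positive."""
    mat = mat.copy()
    for j in range(mat.shape[1]):
        i = int(np.argmax(np.abs(mat[:, j])))
        if mat[i, j] < 0:
            mat[:, j] = -mat[:, j]
    return mat


class DomainPCA(BaseEstimator, TransformerMixin):
    """Covariance-matrix PCA with promax rotation for a single domain.

    Parameters
    ----------
    n_components : int or None
        Explicit retained-component override; ``None`` applies the scree
        (maximum-acceleration) rule.
    kappa : float
        Promax power (oblique rotation strength).

    Attributes (after fit)
    ----------------------
    eigenvalues_ : full covariance spectrum, non-increasing
    loadings_ : unrotated component loadings (eigvec * sqrt(eigval))
    pattern_ : promax pattern loadings of retained components
    phi_ : factor correlation matrix
    coef_ : regression-method scoring coefficients (variables x factors)
    score_scale_ : fit-sample SD of the raw scores (scores are divided by it)
    """

    def __init__(self, n_components: int | None = None, kappa: float = 3.0):
        self.n_components = n_components
        self.kappa = kappa

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        arr = X.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError("input contains NaNs")
        n, p = arr.shape
        self.feature_names_in_ = np.asarray(X.columns)
        self.mean_ = arr.mean(axis=0)
        cov = np.cov(arr, rowvar=False, ddof=1).reshape(p, p)
        lam, vec = np.linalg.eigh(cov)
        order = np.argsort(lam)[::-1]
        lam, vec = np.clip(lam[order], 0.0, None), vec[:, order]
        self.eigenvalues_ = lam
        self.loadings_ = _fix_signs(vec * np.sqrt(lam))

        if p == 1:
            r = 1
            self.loadings_ = np.array([[1.0]])
            self.pattern_ = np.array([[1.0]])
            self.phi_ = np.eye(1)
            self.coef_ = np.array([[1.0]])
            self.score_scale_ = np.array([1.0])
            self.n_retained_ = 1
            return self

        r = self.n_components if self.n_components is not None else scree_count(lam)
        r = int(min(max(r, 1), p))
        self.n_retained_ = r
        retained = self.loadings_[:, :r]
        if r > 1:
            pattern, phi = promax_rotate(retained, kappa=self.kappa)
            pattern = _fix_signs(pattern)
        else:
            pattern, phi = retained.copy(), np.eye(1)
        self.pattern_ = pattern
        self.phi_ = phi

        structure = pattern @ phi
        try:
            self.coef_ = np.linalg.solve(cov, structure)
        except np.linalg.LinAlgError:
            # collinear variables: minimum-norm regression coefficients
            self.coef_ = np.linalg.pinv(cov) @ structure
        raw = (arr - self.mean_) @ self.coef_
        scale = raw.std(axis=0, ddof=1)
        if np.any(scale <= 0):
            raise ValueError("degenerate factor scores (zero variance)")
        self.score_scale_ = scale
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "coef_"):
            raise ValueError("DomainPCA is not fitted")
        X = pd.DataFrame(X)
        if list(X.columns) != list(self.feature_names_in_):
            raise ValueError("variable set does not match the fitted model")
        arr = X.to_numpy(dtype=float)
        return (arr - self.mean_) @ self.coef_ / self.score_scale_

    @property
    def explained_variance_ratio_(self) -> np.ndarray:
        return self.eigenvalues_ / self.eigenvalues_.sum()


class BioFactorScores(pd.DataFrame):
    """Subjects x factors score matrix with provenance metadata."""

    _metadata = ["provenance"]

    @property
    def _constructor(self):
        return BioFactorScores


class BioFactorModel(BaseEstimator, TransformerMixin):
    """Per-domain PCA models assembled into one bio-factor scorer.

    ``domain_overrides`` maps a domain name to an explicit retained
    component count (the scree rule is used otherwise).  By default the
    saccade domain is overridden to two components — with only three
    variables the maximum-acceleration rule has a single interior point and
    cannot return two, while the latency/antisaccade two-factor structure of
    the battery is well established.
    """

    DEFAULT_OVERRIDES = {"saccade": 2}

    def __init__(
        self,
        domain_overrides: dict[str, int] | None = None,
        kappa: float = 3.0,
        label_map: dict[str, str] | None = None,
    ):
        self.domain_overrides = domain_overrides
        self.kappa = kappa
        self.label_map = label_map

    def _labels_for(self, domain: str, pca: DomainPCA) -> list[str]:
        label_map = self.label_map
        if label_map is None:
            label_map = {v: c for v, (_, c) in VARIABLES.items()}
        labels = []
        for j in range(pca.n_retained_):
            top = pca.feature_names_in_[int(np.argmax(np.abs(pca.pattern_[:, j])))]
            labels.append(label_map.get(top, f"{domain}_f{j + 1}"))
        return labels

    def fit(self, panel: BiomarkerPanel, y=None):
        """Fit one DomainPCA per domain on the (standardized) fit sample,
        which must contain probands and healthy subjects only."""
        overrides = dict(self.DEFAULT_OVERRIDES)
        if self.domain_overrides:
            overrides.update(self.domain_overrides)
        domains = list(dict.fromkeys(panel.domain_of))
        self.domain_models_ = {}
        labels: list[str] = []
        self.factor_domains_ = []
        for domain in domains:
            cols = panel.domain_variables(domain)
            pca = DomainPCA(
                n_components=overrides.get(domain), kappa=self.kappa
            ).fit(panel.values[cols])
            self.domain_models_[domain] = pca
            for lab in self._labels_for(domain, pca):
                while lab in labels:  # keep labels unique
                    lab += "_b"
                labels.append(lab)
                self.factor_domains_.append(domain)
        self.factor_labels_ = labels
        return self

    def transform(
        self, panel: BiomarkerPanel, provenance: str = "projected"
    ) -> BioFactorScores:
        if not hasattr(self, "domain_models_"):
            raise ValueError("BioFactorModel is not fitted")
        parts = []
        for domain, pca in self.domain_models_.items():
            cols = panel.domain_variables(domain)
            parts.append(pca.transform(panel.values[cols]))
        scores = BioFactorScores(
            np.hstack(parts), index=panel.values.index, columns=self.factor_labels_
        )
        scores.provenance = provenance
        return scores

    def score_fit_sample(self, panel: BiomarkerPanel) -> BioFactorScores:
        return self.transform(panel, provenance="fit")

    def project_relatives(self, panel: BiomarkerPanel) -> BioFactorScores:
        """Score relatives through the proband+healthy coefficients."""
        return self.transform(panel, provenance="projected")

    @property
    def n_factors_(self) -> int:
        return len(self.factor_labels_)

    def domain_factor_counts(self) -> dict[str, int]:
        return {d: m.n_retained_ for d, m in self.domain_models_.items()}

    def to_json(self) -> str:
        out = {}
        for domain, pca in self.domain_models_.items():
            out[domain] = dict(
                eigenvalues=pca.eigenvalues_.tolist(),
                loadings=pca.loadings_.tolist(),
                pattern=pca.pattern_.tolist(),
                phi=pca.phi_.tolist(),
                coef=pca.coef_.tolist(),
                score_scale=pca.score_scale_.tolist(),
                variables=list(map(str, pca.feature_names_in_)),
            )
        return json.dumps(
            dict(domains=out, factor_labels=self.factor_labels_), sort_keys=True
        )
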
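"""Tests of the scree rule, rotations, and domain PCA scoring."""

import numpy as np
import pandas as pd
import pytest

from biotaxon.cohort import BiomarkerPanel
from biotaxon.factors import (
    BioFactorModel,
    DomainPCA,
    promax_rotate,
    scree_count,
    varimax,
)


@pytest.mark.parametrize(
    "eigvals, expected",
    [
        ([5, 1, 0.9, 0.8], 1),        # second differences 3.9, 0 -> elbow at 2
        ([3, 2.9, 0.1, 0.05], 2),     # second differences -2.7, 2.75 -> elbow at 3
        ([1, 1, 1, 1], 1),            # flat spectrum falls back to 1
        ([10, 9, 1, 0.9, 0.8], 2),
    ],
)
def test_scree_count_elbow(eigvals, expected):
    assert scree_count(eigvals) == expected


def test_scree_count_short_spectrum_warns():
    with pytest.warns(UserWarning, match="fewer than 3"):
        assert scree_count([2.0, 0.5]) == 1


def test_scree_count_rejects_increasing():
    with pytest.raises(ValueError, match="non-increasing"):
        scree_count([1, 2, 3])


# --- PCA -------------------------------------------------------------------

def test_single_variable_domain_is_identity(rng):
    x = rng.normal(size=(100, 1))
    x = (x - x.mean()) / x.std(ddof=1)
    X = pd.DataFrame(x, columns=["only"])
    pca = DomainPCA().fit(X)
    assert pca.n_retained_ == 1
    assert pca.loadings_[0, 0] == 1.0
    assert np.allclose(pca.transform(X)[:, 0], X["only"])


def test_perfectly_correlated_pair_explains_everything(rng):
    a = rng.normal(size=300)
    X = pd.DataFrame({"a": a, "b": 2 * a + 1})
    with pytest.warns(UserWarning, match="fewer than 3"):
        pca = DomainPCA().fit(X)
    assert pca.n_retained_ == 1
    assert pca.explained_variance_ratio_[0] == pytest.approx(1.0, abs=1e-12)


def test_unrotated_loadings_match_eigh_oracle(rng):
    X = pd.DataFrame(rng.normal(size=(400, 5)),
                     columns=[f"v{i}" for i in range(5)])
    pca = DomainPCA(n_components=5).fit(X)
    lam, vec = np.linalg.eigh(np.cov(X.to_numpy(), rowvar=False, ddof=1))
    lam, vec = lam[::-1], vec[:, ::-1]
    assert np.allclose(pca.eigenvalues_, lam, atol=1e-8)
    oracle = vec * np.sqrt(lam)
    for j in range(5):
        col, ref = pca.loadings_[:, j], oracle[:, j]
        assert np.allclose(col, ref, atol=1e-8) or np.allclose(col, -ref, atol=1e-8)


def test_nan_input_raises():
    X = pd.DataFrame({"a": [1.0, np.nan, 2.0], "b": [0.0, 1.0, 2.0]})
    with pytest.raises(ValueError, match="NaN"):
        DomainPCA().fit(X)


# --- rotations -------------------------------------------------------------

def test_varimax_rotation_is_orthogonal(rng):
    L = rng.normal(size=(8, 3))
    Lr, R = varimax(L)
    assert np.allclose(R.T @ R, np.eye(3), atol=1e-10)
    assert np.allclose(Lr, L @ R, atol=1e-12)


def test_promax_single_component_unchanged():
    L = np.array([[0.9], [0.8], [0.7]])
    pattern, phi = promax_rotate(L)
    assert np.allclose(pattern, L)
    assert np.allclose(phi, [[1.0]])


def test_promax_on_orthogonal_simple_structure_matches_varimax():
    """Perfect simple structure: the oblique transform degenerates to the
    orthogonal solution with near-zero factor correlations."""
    L = np.zeros((6, 2))
    L[:3, 0] = [0.9, 0.8, 0.85]
    L[3:, 1] = [0.9, 0.8, 0.85]
    V, _ = varimax(L)
    pattern, phi = promax_rotate(L, kappa=3)
    assert np.allclose(np.abs(pattern), np.abs(V), atol=1e-6)
    assert abs(phi[0, 1]) < 0.05


def test_promax_recovers_planted_oblique_correlation(rng):
    """Two latent factors correlated 0.5 drive 3 indicators each; the
    promax factor correlation comes back within +/-0.1."""
    n = 1000
    C = np.array([[1.0, 0.5], [0.5, 1.0]])
    F = rng.multivariate_normal([0, 0], C, size=n)
    load = np.zeros((6, 2))
    load[:3, 0] = 0.85
    load[3:, 1] = 0.85
    X = F @ load.T + rng.normal(0, 0.5, size=(n, 6))
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    pca = DomainPCA(n_components=2).fit(pd.DataFrame(X, columns=list("abcdef")))
    phi = pca.phi_
    assert abs(abs(phi[0, 1]) - 0.5) < 0.1


def test_promax_kappa1_stays_close_to_varimax_when_orthogonal(rng):
    L = np.zeros((6, 2))
    L[:3, 0] = [0.9, 0.85, 0.8]
    L[3:, 1] = [0.85, 0.9, 0.8]
    L += rng.normal(0, 0.02, size=L.shape)
    V, _ = varimax(L)
    pattern, phi = promax_rotate(L, kappa=1)
    assert np.max(np.abs(np.abs(pattern) - np.abs(V))) < 0.05


# --- scoring ---------------------------------------------------------------

def test_fit_sample_scores_have_zero_mean(paper_like):
    scores = paper_like["scores"]
    assert np.abs(scores.mean()).max() < 1e-10


def test_equal_loading_component_scores_proportional_to_sum(rng):
    """An exchangeable pair of standardized variables yields a single
    component with equal loadings, whose regression-method score is exactly
    proportional to their sum."""
    n = 5000
    z = rng.normal(size=n)
    X = np.column_stack([z + rng.normal(size=n), z + rng.normal(size=n)])
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    df = pd.DataFrame(X, columns=["a", "b"])
    pca = DomainPCA(n_components=1).fit(df)
    assert pca.loadings_[0, 0] == pytest.approx(pca.loadings_[1, 0], abs=1e-10)
    s = pca.transform(df)[:, 0]
    total = X[:, 0] + X[:, 1]
    r = np.corrcoef(s, total)[0, 1]
    assert abs(r) == pytest.approx(1.0, abs=1e-10)


def test_zero_row_scores_zero(paper_like):
    model = paper_like["model"]
    fit_panel = paper_like["fit_panel"]
    zero = BiomarkerPanel(
        values=pd.DataFrame(
            np.zeros((1, len(fit_panel.variables))),
            index=["z"], columns=fit_panel.variables,
        ),
        domain_of=fit_panel.domain_of,
    )
    s = model.transform(zero)
    assert np.abs(s.to_numpy()).max() < 1e-8


def test_relative_identical_to_fit_subject_scores_identically(paper_like):
    model = paper_like["model"]
    fit_panel = paper_like["fit_panel"]
    probe = BiomarkerPanel(
        values=fit_panel.values.iloc[[5]], domain_of=fit_panel.domain_of
    )
    s_fit = model.score_fit_sample(fit_panel).iloc[5]
    s_proj = model.project_relatives(probe).iloc[0]
    assert np.allclose(s_fit, s_proj)
    assert model.project_relatives(probe).provenance == "projected"


def test_projection_is_row_equivariant(paper_like):
    model = paper_like["model"]
    std_panel = paper_like["std_panel"]
    rel = std_panel.values.iloc[:20]
    perm = np.random.default_rng(3).permutation(20)
    a = model.project_relatives(
        BiomarkerPanel(values=rel, domain_of=std_panel.domain_of))
    b = model.project_relatives(
        BiomarkerPanel(values=rel.iloc[perm], domain_of=std_panel.domain_of))
    assert np.allclose(a.to_numpy()[perm], b.to_numpy())


def test_relatives_from_fit_distribution_project_near_zero(paper_like):
    """Relatives in this generator carry attenuated shifts, but projecting
    held-out draws from the healthy distribution must center near 0."""
    scores = paper_like["scores"]
    model = paper_like["model"]
    std_panel = paper_like["std_panel"]
    subjects = paper_like["subjects"]
    rel_ids = subjects.loc[subjects["role"] == "relative", "subject_id"]
    rel = model.project_relatives(BiomarkerPanel(
        values=std_panel.values.loc[rel_ids], domain_of=std_panel.domain_of))
    # attenuated shifts: clearly bounded, means well inside (-1, 1)
    assert np.abs(rel.mean()).max() < 0.6


def test_eleven_factor_structure_on_paper_like_data(paper_like):
    model = paper_like["model"]
    assert model.n_factors_ == 11
    assert model.domain_factor_counts() == {
        "BACS": 1, "saccade": 2, "SST": 1, "PS-ERP": 3, "OB-ERP": 3, "IEA": 1,
    }
    assert sorted(model.factor_labels_) == sorted([
        "bacs", "latency", "antisaccade", "sst", "ps_erp", "ps_s2",
        "ps_ongoing", "ob_erp", "frontal_p3", "ob_ongoing", "iea",
    ])


def test_explained_variance_monotone(paper_like):
    for pca in paper_like["model"].domain_models_.values():
        lam = pca.eigenvalues_
        assert np.all(np.diff(lam) <= 1e-10)
        assert lam.min() >= 0
        ratio = np.cumsum(pca.explained_variance_ratio_)
        assert np.all(np.diff(ratio) >= -1e-12)
        assert ratio[-1] == pytest.approx(1.0)


def test_factor_correlations_are_valid(paper_like):
    for pca in paper_like["model"].domain_models_.values():
        phi = pca.phi_
        assert np.allclose(phi, phi.T)
        assert np.allclose(np.diag(phi), 1.0, atol=1e-8)
        assert np.linalg.eigvalsh(phi).min() > 0
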
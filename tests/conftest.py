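import warnings

import numpy as np
import pytest

from biotaxon.cohort import BiomarkerPanel, SyntheticConfig, generate_cohort
from biotaxon.factors import BioFactorModel
from biotaxon.preprocess import apply_adjustment, fit_adjustment, standardize


@pytest.fixture(scope="session")
def paper_like():
    """A mid-sized synthetic cohort pushed through preprocessing and the
    bio-factor stage once, shared across test modules."""
    cfg = SyntheticConfig(
        n_per_biotype=300, n_healthy=400, n_relatives_per_family=1,
        seed=20260926,
    )
    subjects, panel, latent = generate_cohort(cfg, return_latent=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        adjuster = fit_adjustment(panel, subjects)
        adjusted = apply_adjustment(adjuster, panel, subjects)
        ref = ((subjects["role"] == "proband")
               | (subjects["role"] == "healthy")).to_numpy()
        std_panel, scaler = standardize(adjusted, ref)
        fit_panel = BiomarkerPanel(
            values=std_panel.values.loc[ref], domain_of=std_panel.domain_of
        )
        model = BioFactorModel().fit(fit_panel)
        scores = model.score_fit_sample(fit_panel)
    proband_ids = subjects.loc[subjects["role"] == "proband", "subject_id"]
    return dict(
        config=cfg, subjects=subjects, panel=panel, latent=latent,
        adjuster=adjuster, std_panel=std_panel, fit_panel=fit_panel,
        model=model, scores=scores, ref_mask=ref, proband_ids=proband_ids,
    )


@pytest.fixture(scope="session")
def proband_scores_z(paper_like):
    """Proband bio-factor scores re-standardized for clustering."""
    pro = paper_like["scores"].loc[paper_like["proband_ids"]]
    X = pro.to_numpy()
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
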
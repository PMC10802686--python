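"""Tests of the synthetic cohort and epoch generator."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from biotaxon.cohort import (
    CONSTRUCTS,
    SyntheticConfig,
    generate_cohort,
    generate_epochs,
)
from biotaxon.erp import power_spectrum
from biotaxon.groupstats import glass_delta


def zero_effect_config(**kw):
    cfg = SyntheticConfig(**kw)
    cfg.effect_matrix = cfg.effect_matrix * 0.0
    cfg.relative_effects = cfg.relative_effects * 0.0
    cfg.age_effect = {v: 0.0 for v in cfg.age_effect}
    cfg.sex_effect = {v: 0.0 for v in cfg.sex_effect}
    return cfg


def test_subject_counts():
    cfg = SyntheticConfig(n_per_biotype=10, n_healthy=5,
                          n_relatives_per_family=1, seed=0)
    subjects, panel = generate_cohort(cfg)
    counts = subjects["role"].value_counts()
    assert counts["proband"] == 30
    assert counts["relative"] == 30
    assert counts["healthy"] == 5
    assert panel.values.shape == (65, 31)


def test_subject_table_invariants():
    cfg = SyntheticConfig(n_per_biotype=20, n_healthy=10,
                          n_relatives_per_family=2, seed=1)
    subjects, _ = generate_cohort(cfg)
    assert subjects["subject_id"].is_unique
    # every relative's family id matches exactly one proband
    probands = subjects[subjects["role"] == "proband"]
    fam_counts = probands["family_id"].value_counts()
    for fid in subjects.loc[subjects["role"] == "relative", "family_id"]:
        assert fam_counts[fid] == 1
    # true biotype is absent (0) exactly for healthy participants
    assert ((subjects["true_biotype"] == 0)
            == (subjects["role"] == "healthy")).all()


def test_fixed_seed_is_bit_identical():
    cfg = SyntheticConfig(n_per_biotype=50, n_healthy=30, seed=7)
    s1, p1, l1 = generate_cohort(cfg, return_latent=True)
    s2, p2, l2 = generate_cohort(cfg, return_latent=True)
    pd.testing.assert_frame_equal(s1, s2)
    pd.testing.assert_frame_equal(p1.values, p2.values)
    pd.testing.assert_frame_equal(l1, l2)


def test_null_configuration_has_no_group_structure():
    """With all effects zeroed, every group is drawn from one distribution:
    no per-group variable mean departs from 0 beyond a family-wise 99%
    normal bound (Sidak-adjusted across the 31 x 3 checks)."""
    cfg = zero_effect_config(n_per_biotype=500, n_healthy=500,
                             n_relatives_per_family=1, seed=3)
    subjects, panel = generate_cohort(cfg)
    m = 31 * 3
    z_bound = -np.round(
        float(__import__("scipy.stats", fromlist=["norm"]).norm.ppf(
            (1 - 0.99 ** (1 / m)) / 2)), 4)
    for role in ("proband", "relative", "healthy"):
        sub = panel.values[(subjects["role"] == role).to_numpy()]
        z = sub.mean() / (sub.std(ddof=1) / np.sqrt(len(sub)))
        assert np.abs(z).max() < z_bound, (role, z.abs().idxmax())


def test_planted_effect_recovered_as_glass_delta():
    """A -1 SD shift on the cognition construct for subgroup 1 shows up as a
    latent-scale Glass delta within +/-0.15 of -1, averaged over seeds."""
    deltas = []
    for seed in range(20):
        cfg = zero_effect_config(n_per_biotype=600, n_healthy=600,
                                 n_relatives_per_family=0, seed=seed)
        cfg.effect_matrix.loc["bacs", "BT1"] = -1.0
        subjects, _, latent = generate_cohort(cfg, return_latent=True)
        bt1 = latent.loc[subjects.loc[(subjects["true_biotype"] == 1)
                                      & (subjects["role"] == "proband"),
                                      "subject_id"], "bacs"]
        h = latent.loc[subjects.loc[subjects["role"] == "healthy",
                                    "subject_id"], "bacs"]
        deltas.append(glass_delta(bt1.mean(), h.mean(), h.std(ddof=1)))
    assert abs(np.mean(deltas) - (-1.0)) < 0.15


def test_invalid_configs_raise():
    with pytest.raises(ValueError, match="non-negative"):
        generate_cohort(SyntheticConfig(n_per_biotype=-1, seed=0))
    with pytest.raises(ValueError, match="noise_sd"):
        generate_cohort(SyntheticConfig(noise_sd=0.0, seed=0))
    cfg = SyntheticConfig(seed=0)
    cfg.effect_matrix = cfg.effect_matrix.iloc[:5]
    with pytest.raises(ValueError, match="effect matrix"):
        generate_cohort(cfg)
    cfg = SyntheticConfig(seed=0)
    cfg.effect_matrix = cfg.effect_matrix * np.nan
    with pytest.raises(ValueError, match="finite"):
        generate_cohort(cfg)


# --- epochs ----------------------------------------------------------------

SMALL = dict(n_per_biotype=2, n_healthy=2, n_relatives_per_family=0, seed=5)


def test_epochs_all_zero_when_everything_off():
    cfg = SyntheticConfig(**SMALL)
    eps = generate_epochs(cfg, "paired_stimuli", n_trials=4,
                          evoked_amp=0.0, osc_amp=0.0, noise_sd=0.0)
    for es in eps.values():
        assert np.all(es.data == 0)


def test_higher_erp_construct_gives_larger_evoked_peak():
    cfg = SyntheticConfig(**SMALL)
    subjects, _, latent = generate_cohort(cfg, return_latent=True)
    latent.loc[:] = 0.0
    latent.iloc[0, latent.columns.get_loc("ps_erp")] = 1.0  # +1 SD subject
    eps = generate_epochs(cfg, "paired_stimuli", subjects=subjects,
                          latent=latent, n_trials=6, noise_sd=0.0,
                          osc_amp=0.0, seed=9)
    peaks = [np.abs(es.data.mean(axis=2)).max() for es in eps.values()]
    assert peaks[0] > max(peaks[1:])


def test_injected_alpha_oscillation_peaks_in_alpha_band():
    cfg = SyntheticConfig(**SMALL)
    eps = generate_epochs(cfg, "paired_stimuli", n_trials=4, evoked_amp=0.0,
                          noise_sd=0.0, osc_amp=1.0, band_freqs=(10.0,),
                          seed=1)
    es = next(iter(eps.values()))
    seg = es.data[:, es.silent_slice, :]
    freqs, power = power_spectrum(seg.transpose(0, 2, 1), es.sfreq,
                                  window="hann", axis=-1)
    spectrum = power.mean(axis=(0, 1))
    peak = freqs[np.argmax(spectrum)]
    assert 8 <= peak <= 12


def test_oddball_interleaves_targets():
    cfg = SyntheticConfig(**SMALL)
    eps = generate_epochs(cfg, "oddball", n_trials=60, seed=2)
    es = next(iter(eps.values()))
    assert es.trial_types is not None
    assert 0 < es.trial_types.sum() < 60


def test_too_few_trials_raises():
    cfg = SyntheticConfig(**SMALL)
    with pytest.raises(ValueError, match="2 trials"):
        generate_epochs(cfg, "paired_stimuli", n_trials=1)
    with pytest.raises(ValueError, match="paradigm"):
        generate_epochs(cfg, "unknown")
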
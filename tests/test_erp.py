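"""Tests of the ERP / intrinsic-activity feature reduction."""

import numpy as np
import pytest

from biotaxon.cohort import EpochSet
from biotaxon.erp import (
    define_bands,
    erp_features,
    evoked_power,
    iea_features,
    power_spectrum,
    spatial_pca,
)

SFREQ = 250.0


def make_epochs(data, sfreq=SFREQ, **kw):
    n_time = data.shape[1]
    times = np.arange(n_time) / sfreq - 0.4
    onset = int(np.searchsorted(times, 0.0))
    kw.setdefault("silent_slice", slice(0, onset))
    return EpochSet(data=data, sfreq=sfreq, times=times, onset_index=onset, **kw)


def test_parseval_total_power_equals_variance(rng):
    x = rng.normal(size=512)
    freqs, power = power_spectrum(x, SFREQ, window="boxcar")
    assert power.sum() == pytest.approx(np.mean(x**2), abs=1e-8)


def test_sinusoid_power_peaks_at_its_frequency():
    t = np.arange(500) / SFREQ  # 2 s -> 10 Hz is an exact bin
    x = np.sin(2 * np.pi * 10 * t)
    freqs, power = power_spectrum(x, SFREQ, window="boxcar")
    assert freqs[np.argmax(power)] == pytest.approx(10.0)
    assert power[freqs > 20].max() < 0.01 * power.max()


def test_evoked_power_zero_signal_is_zero():
    es = make_epochs(np.zeros((4, 200, 3)))
    freqs, power = evoked_power(es)
    assert np.all(power == 0)


def test_evoked_power_rejects_artifact_trials(rng):
    data = rng.normal(0, 1, size=(4, 200, 5))
    data[:, :, 0] += 500.0  # one wildly contaminated trial
    es = make_epochs(data)
    _, power = evoked_power(es)
    clean = data[:, :, 1:].mean(axis=2)
    _, expected = power_spectrum(clean, SFREQ)
    assert np.allclose(power, expected)
    with pytest.raises(ValueError, match="artifact"):
        evoked_power(make_epochs(np.full((2, 50, 3), 100.0)))


# --- band definition -------------------------------------------------------

def test_define_bands_recovers_planted_blocks(rng):
    """Two independent block factors over disjoint bin ranges come back as
    two bands matching the blocks within one bin."""
    n_sub, n_bins = 1000, 50
    freqs = np.arange(n_bins, dtype=float)
    spectra = rng.normal(0, 0.05, size=(n_sub, n_bins))
    spectra[:, 1:11] += rng.normal(0, 1, size=(n_sub, 1))
    spectra[:, 30:41] += rng.normal(0, 0.8, size=(n_sub, 1))
    bands = define_bands(spectra, freqs, n_bands=2)
    (lo1, hi1), (lo2, hi2) = [(b.fmin, b.fmax) for b in bands]
    assert abs(lo1 - 1) <= 1 and abs(hi1 - 10) <= 1
    assert abs(lo2 - 30) <= 1 and abs(hi2 - 40) <= 1


def test_define_bands_white_noise_keeps_one_band(rng):
    spectra = rng.normal(size=(100, 30))
    bands = define_bands(spectra, np.arange(30, dtype=float))
    assert len(bands) == 1


def test_define_bands_degenerate_covariance_raises():
    spectra = np.tile(np.linspace(0, 1, 20), (40, 1))  # one subject x 40
    with pytest.raises(ValueError, match="degenerate"):
        define_bands(spectra, np.arange(20, dtype=float))


def test_define_bands_needs_enough_subjects(rng):
    with pytest.raises(ValueError, match="20 subjects"):
        define_bands(rng.normal(size=(5, 10)), np.arange(10.0))


# --- spatial PCA -----------------------------------------------------------

def test_spatial_pca_single_sensor_is_identity(rng):
    W = rng.normal(size=(3, 1, 100))
    vs = spatial_pca(W)
    assert np.array_equal(vs.weights, [1.0])
    assert np.allclose(vs.waveforms, W[:, 0, :])


def test_spatial_pca_recovers_exact_rank_one_pattern(rng):
    w_true = np.array([0.5, -0.3, 0.8, 0.1])
    w_true /= np.linalg.norm(w_true)
    sources = rng.normal(size=(5, 1, 300))
    W = sources * w_true[None, :, None]
    vs = spatial_pca(W)
    assert np.allclose(np.abs(vs.weights), np.abs(w_true), atol=1e-8)
    # sign convention: largest-|weight| sensor positive
    assert vs.weights[np.argmax(np.abs(vs.weights))] > 0


def test_spatial_pca_duplicated_sensors_share_weight(rng):
    s = rng.normal(size=(4, 1, 200))
    W = np.concatenate([s, s], axis=1)  # two identical sensors
    vs = spatial_pca(W)
    assert np.allclose(np.abs(vs.weights), 1 / np.sqrt(2), atol=1e-8)


def test_virtual_sensor_variance_dominates_single_sensors(rng):
    W = rng.normal(size=(6, 5, 150))
    W[:, 2, :] *= 2.0
    vs = spatial_pca(W)
    var_vs = vs.waveforms.var()
    for s in range(5):
        assert var_vs >= W[:, s, :].var() - 1e-8


# --- windowed features -----------------------------------------------------

def test_rectangular_pulse_window_mean():
    data = np.zeros((2, 250, 3))
    times = np.arange(250) / SFREQ - 0.4
    mask = (times >= 0.1) & (times <= 0.2)
    data[:, mask, :] = 3.0
    es = make_epochs(data)
    feats = erp_features(es, sensor_weights=np.array([1.0, 0.0]),
                         windows={"pulse": (0.1, 0.2)})
    assert feats["amp_pulse"] == pytest.approx(3.0)


def test_identical_trials_have_zero_ongoing_power(rng):
    trial = rng.normal(size=(3, 200))
    data = np.repeat(trial[:, :, None], 5, axis=2)
    es = make_epochs(data)
    w = np.array([1.0, 0.0, 0.0])
    feats = erp_features(es, w, windows={}, bands={"g": (30.0, 50.0)})
    assert abs(feats["ongoing_g"]) < 1e-8


def test_random_phase_oscillation_is_ongoing_not_evoked(rng):
    times = np.arange(500) / SFREQ
    data = np.zeros((2, 500, 40))
    for tr in range(40):
        ph = rng.uniform(0, 2 * np.pi)
        data[0, :, tr] = np.sin(2 * np.pi * 40 * times + ph)
    es = make_epochs(data)
    feats = erp_features(es, np.array([1.0, 0.0]), windows={},
                         bands={"gamma": (35.0, 45.0)})
    assert feats["ongoing_gamma"] > 0.01
    assert feats["evoked_gamma"] < 0.1 * feats["ongoing_gamma"]


def test_window_outside_epoch_raises():
    es = make_epochs(np.zeros((2, 100, 3)))
    with pytest.raises(ValueError, match="outside"):
        erp_features(es, np.array([1.0, 0.0]), windows={"late": (5.0, 6.0)})


# --- intrinsic activity ----------------------------------------------------

def test_iea_zero_segment_gives_zero_powers():
    es = make_epochs(np.zeros((2, 700, 3)))
    feats = iea_features(es, segment=slice(0, 520))
    assert all(v == 0 for v in feats.values())


def test_iea_alpha_injection_dominates(rng):
    times = np.arange(800) / SFREQ - 2.2
    data = np.zeros((2, 800, 4))
    for tr in range(4):
        data[:, :, tr] = np.sin(2 * np.pi * 10 * times
                                + rng.uniform(0, 2 * np.pi))
    es = EpochSet(data=data, sfreq=SFREQ, times=times,
                  onset_index=550, silent_slice=slice(0, 550))
    feats = iea_features(es)
    for name, v in feats.items():
        if name != "alpha":
            assert feats["alpha"] > 10 * v


def test_iea_quadratic_amplitude_scaling(rng):
    data = rng.normal(size=(3, 500, 4))
    es1 = make_epochs(data)
    es2 = make_epochs(2 * data)
    seg = slice(0, 500)
    f1 = iea_features(es1, segment=seg)
    f2 = iea_features(es2, segment=seg)
    for name in f1:
        assert f2[name] == pytest.approx(4 * f1[name], abs=1e-8)


def test_iea_short_segment_raises():
    es = make_epochs(np.zeros((2, 120, 3)), silent_slice=slice(0, 30))
    with pytest.raises(ValueError, match="two cycles"):
        iea_features(es)
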
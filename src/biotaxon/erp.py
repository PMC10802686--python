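"""Reduction of epoched EEG to ERP / intrinsic-activity features.

Desk-scale analogue of the physiological feature path: evoked power spectra
of trial-averaged waveforms, empirically defined frequency bands via a
frequency-wise PCA, spatial-PCA "virtual sensors" summarizing the scalp
topography as a single waveform, windowed ERP amplitude features, ongoing
(non-time-locked) band power as mean single-trial power minus evoked power,
and intrinsic-activity band powers from the silent inter-pair segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

from .cohort import EpochSet
from .factors import scree_count

__all__ = [
    "BandDefinition",
    "VirtualSensor",
    "power_spectrum",
    "evoked_power",
    "define_bands",
    "spatial_pca",
    "erp_features",
    "iea_features",
    "DEFAULT_IEA_BANDS",
]

#: canonical intrinsic-activity bands (Hz) used when no empirical bands are supplied
DEFAULT_IEA_BANDS = {
    "delta_theta": (1.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 28.0),
    "gamma": (29.0, 55.0),
}

#: artifact rejection threshold, microvolts (interpreted as +/- 75 uV)
ARTIFACT_THRESHOLD_UV = 75.0


@dataclass
class BandDefinition:
    """A frequency band defined by a band-defining PCA component."""

    name: str
    fmin: float
    fmax: float
    loading: np.ndarray  # frequency-loading vector of the defining component

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        return (freqs >= self.fmin) & (freqs <= self.fmax)


@dataclass
class VirtualSensor:
    """Unit-norm sensor-weight vector and the resulting per-subject waveforms."""

    weights: np.ndarray
    source: str
    waveforms: np.ndarray  # subjects x time

    def __post_init__(self) -> None:
        norm = np.linalg.norm(self.weights)
        if not np.isclose(norm, 1.0, atol=1e-8):
            raise ValueError("virtual sensor weights must have unit norm")


def power_spectrum(
    x: np.ndarray, sfreq: float, window: str = "hann", axis: int = -1
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided power spectrum normalized so the bins sum to the
    time-average power (mean of x^2) when ``window='boxcar'`` (Parseval)."""
    x = np.asarray(x, dtype=float)
    n = x.shape[axis]
    w = get_window(window, n)
    shape = [1] * x.ndim
    shape[axis] = n
    xw = x * w.reshape(shape)
    spec = np.fft.rfft(xw, axis=axis)
    power = np.abs(spec) ** 2 / (w @ w) / n * 2
    # DC (and Nyquist for even n) bins are not doubled
    idx = [slice(None)] * x.ndim
    idx[axis] = 0
    power[tuple(idx)] /= 2
    if n % 2 == 0:
        idx[axis] = -1
        power[tuple(idx)] /= 2
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    return freqs, power


def _reject_artifacts(epochs: EpochSet, threshold_uv: float) -> np.ndarray:
    peak = np.abs(epochs.data).max(axis=(0, 1))
    keep = peak <= threshold_uv
    if not keep.any():
        raise ValueError("all trials exceed the artifact threshold")
    return epochs.data[:, :, keep]


def evoked_power(
    epochs: EpochSet,
    threshold_uv: float = ARTIFACT_THRESHOLD_UV,
    window: str = "hann",
    time_slice: slice | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Power spectrum of the trial-averaged (evoked) signal per sensor.

    Returns ``(freqs, power)`` with power of shape sensors x freqs.  Trials
    exceeding the artifact threshold are excluded first.
    """
    data = _reject_artifacts(epochs, threshold_uv)
    if data.shape[2] < 2:
        raise ValueError("need at least 2 artifact-free trials")
    evoked = data.mean(axis=2)
    if time_slice is not None:
        evoked = evoked[:, time_slice]
    return power_spectrum(evoked, epochs.sfreq, window=window, axis=-1)


def define_bands(
    spectra: np.ndarray,
    freqs: np.ndarray,
    n_bands: int | None = None,
    names: tuple[str, ...] = ("low", "beta", "gamma", "band4", "band5"),
) -> list[BandDefinition]:
    """Empirically define frequency bands by a frequency-wise PCA.

    ``spectra`` is subjects x frequency bins.  A PCA across bins (subjects
    as observations) is computed; each retained component (scree rule, or
    ``n_bands`` override) defines a band as the contiguous bin range where
    its absolute loading exceeds half its maximum.  Bands are sorted by
    their lower edge and named low -> high.
    """
    spectra = np.asarray(spectra, dtype=float)
    if spectra.shape[0] < 20:
        raise ValueError("need at least 20 subjects to define bands")
    cov = np.cov(spectra, rowvar=False, ddof=1)
    lam, vec = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    lam, vec = np.clip(lam[order], 0, None), vec[:, order]
    if lam[0] <= 1e-12 * max(1.0, float(lam.sum())):
        raise ValueError("degenerate covariance: no variance across subjects")
    r = n_bands if n_bands is not None else scree_count(lam)

    bands = []
    for i in range(r):
        loading = vec[:, i] * np.sqrt(lam[i])
        a = np.abs(loading)
        support = a >= a.max() / 2
        # widest contiguous run of the support
        runs = []
        start = None
        for j, on in enumerate(list(support) + [False]):
            if on and start is None:
                start = j
            elif not on and start is not None:
                runs.append((start, j - 1))
                start = None
        if len(runs) > 1:
            warnings.warn(
                f"component {i + 1} has non-contiguous loading support; "
                "keeping the widest contiguous run"
            )
        lo, hi = max(runs, key=lambda ab: ab[1] - ab[0])
        bands.append((float(freqs[lo]), float(freqs[hi]), loading))

    bands.sort(key=lambda b: b[0])
    return [
        BandDefinition(name=names[i] if i < len(names) else f"band{i + 1}",
                       fmin=lo, fmax=hi, loading=loading)
        for i, (lo, hi, loading) in enumerate(bands)
    ]


def spatial_pca(waveforms: np.ndarray, source: str = "erp") -> VirtualSensor:
    """First spatial principal component over (subject, time) observations.

    ``waveforms`` is subjects x sensors x time (or sensors x time for a
    single subject).  The sign is fixed so the largest-|weight| sensor is
    positive; the virtual-sensor waveform per subject is the weighted sensor
    combination.
    """
    W = np.asarray(waveforms, dtype=float)
    if W.ndim == 2:
        W = W[None]
    n_sub, n_sens, n_time = W.shape
    if n_sens == 1:
        return VirtualSensor(
            weights=np.array([1.0]), source=source, waveforms=W[:, 0, :]
        )
    obs = W.transpose(0, 2, 1).reshape(-1, n_sens)
    cov = np.cov(obs, rowvar=False, ddof=1)
    lam, vec = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    if np.sum(lam > max(lam[0], 1e-300) * 1e-12) < 2:
        warnings.warn("rank-deficient sensor covariance; PC1 still returned")
    w = vec[:, order[0]]
    i = int(np.argmax(np.abs(w)))
    if w[i] < 0:
        w = -w
    w = w / np.linalg.norm(w)
    return VirtualSensor(weights=w, source=source, waveforms=np.einsum("s,nst->nt", w, W))


def _band_power(freqs: np.ndarray, power: np.ndarray, band) -> float:
    if isinstance(band, BandDefinition):
        mask = band.mask(freqs)
    else:
        lo, hi = band
        mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError("band contains no frequency bins")
    return float(power[..., mask].mean())


def erp_features(
    epochs: EpochSet,
    sensor_weights: np.ndarray,
    windows: dict[str, tuple[float, float]],
    bands: dict[str, tuple[float, float]] | list[BandDefinition] | None = None,
    threshold_uv: float = ARTIFACT_THRESHOLD_UV,
    window_fn: str = "hann",
) -> dict[str, float]:
    """Per-subject ERP feature vector from a virtual-sensor waveform.

    Features: mean evoked amplitude per configured time window; evoked band
    power per band; and ongoing (non-time-locked) band power = mean
    single-trial band power minus evoked band power.
    """
    data = _reject_artifacts(epochs, threshold_uv)
    vs = np.einsum("s,stk->tk", np.asarray(sensor_weights, dtype=float), data)
    evoked = vs.mean(axis=1)
    t = epochs.times
    feats: dict[str, float] = {}
    for name, (t0, t1) in windows.items():
        if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9:
            raise ValueError(f"window {name!r} ({t0}, {t1}) outside the epoch")
        mask = (t >= t0) & (t <= t1)
        feats[f"amp_{name}"] = float(evoked[mask].mean())

    if bands:
        freqs, ev_pow = power_spectrum(evoked, epochs.sfreq, window=window_fn)
        _, trial_pow = power_spectrum(vs.T, epochs.sfreq, window=window_fn, axis=-1)
        mean_trial_pow = trial_pow.mean(axis=0)
        band_iter = (
            [(b.name, b) for b in bands] if isinstance(bands, list)
            else list(bands.items())
        )
        for name, band in band_iter:
            e = _band_power(freqs, ev_pow, band)
            m = _band_power(freqs, mean_trial_pow, band)
            feats[f"evoked_{name}"] = e
            feats[f"ongoing_{name}"] = m - e
    return feats


def iea_features(
    epochs: EpochSet,
    bands: dict[str, tuple[float, float]] | list[BandDefinition] | None = None,
    segment: slice | None = None,
    window_fn: str = "hann",
) -> dict[str, float]:
    """Mean band power of the silent inter-pair segment, one value per band."""
    if bands is None:
        bands = DEFAULT_IEA_BANDS
    seg = segment if segment is not None else epochs.silent_slice
    data = epochs.data[:, seg, :]
    n = data.shape[1]
    band_iter = (
        [(b.name, (b.fmin, b.fmax)) for b in bands] if isinstance(bands, list)
        else list(bands.items())
    )
    lowest = min(lo for _, (lo, hi) in band_iter)
    if n / epochs.sfreq < 2.0 / max(lowest, 1e-9):
        raise ValueError(
            "silent segment shorter than two cycles of the lowest band"
        )
    freqs, power = power_spectrum(
        data.transpose(0, 2, 1), epochs.sfreq, window=window_fn, axis=-1
    )
    mean_power = power.mean(axis=(0, 1))
    return {name: _band_power(freqs, mean_power, band) for name, band in band_iter}
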
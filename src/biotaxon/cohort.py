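"""Synthetic cohort and EEG-epoch generation.

This module emulates the statistical structure of a multi-site psychosis
biomarker study: probands planted in three latent subgroups ("biotypes"),
their non-psychotic first-degree relatives with attenuated deviations, and
healthy comparison subjects.  Eleven latent constructs (one per eventual
bio-factor) drive a panel of 31 raw biomarker variables spread over six
laboratory domains (cognition, saccades, stop-signal, two auditory ERP
paradigms, intrinsic EEG activity).

The latent model
----------------
For subject *s* the construct vector ``c_s`` (length 11) is drawn as

    c_s = mu(group_s) + sqrt(icc) * f_fam(s) + sqrt(1 - icc) * e_s

where ``mu`` is the planted mean-shift (healthy-SD units; zero for healthy),
``f`` is a family-level intercept shared by a proband and their relatives,
and ``f, e ~ MVN(0, C)`` with a construct correlation matrix ``C`` (modest
positive correlation within the cognition set by default).  Raw variables are

    x_v = loading_v * c[construct(v)] + beta_age_v * (age - 38)
          + beta_sex_v * sex + N(0, noise_sd^2)

so the healthy marginal variance of each variable is loading^2 + noise_sd^2
(= 1 with the defaults, making planted shifts directly interpretable as
Glass-delta-scale effects).

Relatives' mean shifts default to the effect sizes printed for relative
groups in the source cohort for the five constructs where such values exist
(general cognition, antisaccade, both ERP-magnitude factors, intrinsic EEG)
and to ``relative_attenuation`` times the proband shift elsewhere.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CONSTRUCTS",
    "DOMAINS",
    "VARIABLES",
    "SyntheticConfig",
    "BiomarkerPanel",
    "EpochSet",
    "default_effect_matrix",
    "default_relative_effects",
    "generate_cohort",
    "generate_epochs",
]

#: Latent constructs, one per eventual bio-factor, in canonical order.
CONSTRUCTS = (
    "bacs",
    "latency",
    "antisaccade",
    "sst",
    "ps_erp",
    "ps_s2",
    "ps_ongoing",
    "ob_erp",
    "frontal_p3",
    "ob_ongoing",
    "iea",
)

#: Laboratory domains.
DOMAINS = ("BACS", "saccade", "SST", "PS-ERP", "OB-ERP", "IEA")

#: variable name -> (domain, construct).  Counts per domain mirror the
#: source battery: 6 cognition subtests, 3 saccade measures, 2 stop-signal
#: measures, 8 features per ERP paradigm, 4 intrinsic-EEG band powers.
VARIABLES: dict[str, tuple[str, str]] = {
    # Brief Assessment of Cognition subtests
    "bacs_verbal_memory": ("BACS", "bacs"),
    "bacs_digit_sequencing": ("BACS", "bacs"),
    "bacs_token_motor": ("BACS", "bacs"),
    "bacs_verbal_fluency": ("BACS", "bacs"),
    "bacs_symbol_coding": ("BACS", "bacs"),
    "bacs_tower": ("BACS", "bacs"),
    # saccades
    "prosaccade_latency": ("saccade", "latency"),
    "antisaccade_latency": ("saccade", "latency"),
    "antisaccade_accuracy": ("saccade", "antisaccade"),
    # stop signal task
    "sst_strategic_slowing": ("SST", "sst"),
    "sst_stop_errors": ("SST", "sst"),
    # paired-stimuli ERP features
    "ps_erp_s1_n100": ("PS-ERP", "ps_erp"),
    "ps_erp_s1_p200": ("PS-ERP", "ps_erp"),
    "ps_erp_gamma_evoked": ("PS-ERP", "ps_erp"),
    "ps_s2_n100": ("PS-ERP", "ps_s2"),
    "ps_s2_p200": ("PS-ERP", "ps_s2"),
    "ps_s2_suppression": ("PS-ERP", "ps_s2"),
    "ps_ongoing_beta": ("PS-ERP", "ps_ongoing"),
    "ps_ongoing_gamma": ("PS-ERP", "ps_ongoing"),
    # oddball ERP features
    "ob_erp_n100": ("OB-ERP", "ob_erp"),
    "ob_erp_p200": ("OB-ERP", "ob_erp"),
    "ob_erp_target_n100": ("OB-ERP", "ob_erp"),
    "ob_p3_frontal": ("OB-ERP", "frontal_p3"),
    "ob_p3_central": ("OB-ERP", "frontal_p3"),
    "ob_p3_parietal": ("OB-ERP", "frontal_p3"),
    "ob_ongoing_beta": ("OB-ERP", "ob_ongoing"),
    "ob_ongoing_gamma": ("OB-ERP", "ob_ongoing"),
    # intrinsic EEG activity band powers
    "iea_delta_theta": ("IEA", "iea"),
    "iea_alpha": ("IEA", "iea"),
    "iea_beta": ("IEA", "iea"),
    "iea_gamma": ("IEA", "iea"),
}

#: Constructs making up the "cognition set"; given a modest positive
#: correlation by default.
COGNITION_SET = ("bacs", "antisaccade", "sst")

BIOTYPES = (1, 2, 3)

_REF_AGE = 38.0  # generation-time centering age (years)


def default_effect_matrix() -> pd.DataFrame:
    """Planted proband subgroup mean shifts (healthy-SD units).

    Rows are constructs, columns biotypes 1-3.  The pattern encodes: BT1 low
    cognition and low neural-response magnitudes; BT2 low cognition, poor
    inhibition, accentuated intrinsic/ongoing activity; BT3 near-normal with
    mildly deviant stimulus-salience measures.
    """
    data = {
        #            BT1    BT2    BT3
        "bacs":        (-1.4, -1.3,  0.0),
        "latency":     ( 0.0,  0.1, -0.3),
        "antisaccade": (-1.3, -1.4,  0.1),
        "sst":         (-0.5, -0.9, -0.1),
        "ps_erp":      (-1.1,  0.2,  0.1),
        "ps_s2":       (-0.3,  0.1, -0.7),
        "ps_ongoing":  (-0.1,  1.0,  0.1),
        "ob_erp":      (-1.2,  0.2,  0.0),
        "frontal_p3":  (-0.4,  0.1, -0.8),
        "ob_ongoing":  (-0.1,  1.0,  0.1),
        "iea":         (-1.0,  0.8,  0.0),
    }
    return pd.DataFrame(data, index=BIOTYPES).T.rename(columns=lambda b: f"BT{b}")


def default_relative_effects(
    effect_matrix: pd.DataFrame | None = None, attenuation: float = 0.5
) -> pd.DataFrame:
    """Relative-vs-healthy mean shifts.

    Where the source cohort prints relative effect sizes (cognition,
    antisaccade, both ERP-magnitude factors, intrinsic EEG) those values are
    used verbatim; the remaining constructs default to ``attenuation`` times
    the proband shift.
    """
    if effect_matrix is None:
        effect_matrix = default_effect_matrix()
    rel = effect_matrix * attenuation
    printed = {
        "bacs":        (-0.33, -0.28,  0.26),
        "antisaccade": (-0.30, -0.44,  0.15),
        "ps_erp":      (-0.29,  0.01,  0.01),
        "ob_erp":      (-0.47, -0.08, -0.08),
        "iea":         (-0.63, -0.16, -0.08),
    }
    for construct, shifts in printed.items():
        rel.loc[construct] = shifts
    return rel


def default_construct_corr(rho_cognition: float = 0.3) -> pd.DataFrame:
    """Construct correlation matrix: ``rho_cognition`` within the cognition
    set, independence elsewhere."""
    corr = pd.DataFrame(
        np.eye(len(CONSTRUCTS)), index=list(CONSTRUCTS), columns=list(CONSTRUCTS)
    )
    for a in COGNITION_SET:
        for b in COGNITION_SET:
            if a != b:
                corr.loc[a, b] = rho_cognition
    return corr


def _default_covariate_effects() -> tuple[dict[str, float], dict[str, float]]:
    """Per-variable age slopes (per year) and sex shifts (SD units).

    Cognitive performance declines and saccade latencies slow with age; ERP
    magnitudes are given a sex offset.  The remaining variables carry no
    covariate effect so both the flagged and unflagged adjustment paths are
    exercised downstream.
    """
    age = {v: 0.0 for v in VARIABLES}
    sex = {v: 0.0 for v in VARIABLES}
    for v, (domain, construct) in VARIABLES.items():
        if domain == "BACS":
            age[v] = -0.015
        elif construct == "latency":
            age[v] = 0.012
        if construct in ("ps_erp", "ob_erp"):
            sex[v] = 0.3
    return age, sex


@dataclass
class SyntheticConfig:
    """Full parameterization of the synthetic cohort generator.

    All shifts are expressed in healthy-SD units of the latent constructs.
    ``noise_sd`` is the unique-variance SD of each raw variable; with the
    default ``loading`` of 0.8 the healthy marginal variance of each raw
    variable is 1.
    """

    n_per_biotype: int = 630
    n_healthy: int = 895
    n_relatives_per_family: int = 1
    effect_matrix: pd.DataFrame = field(default_factory=default_effect_matrix)
    relative_effects: pd.DataFrame = field(default_factory=default_relative_effects)
    relative_attenuation: float = 0.5
    loading: float = 0.8
    noise_sd: float = 0.6
    family_icc: float = 0.2
    rho_cognition: float = 0.3
    age_effect: dict[str, float] = field(
        default_factory=lambda: _default_covariate_effects()[0]
    )
    sex_effect: dict[str, float] = field(
        default_factory=lambda: _default_covariate_effects()[1]
    )
    seed: int | None = 0

    def validate(self) -> None:
        if min(self.n_per_biotype, self.n_healthy, self.n_relatives_per_family) < 0:
            raise ValueError("subject counts must be non-negative")
        if not (0 <= self.n_relatives_per_family <= 3):
            raise ValueError("n_relatives_per_family must be in 0..3")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.family_icc < 1:
            raise ValueError("family_icc must be in [0, 1)")
        for m, (rows, cols) in (
            (self.effect_matrix, (len(CONSTRUCTS), 3)),
            (self.relative_effects, (len(CONSTRUCTS), 3)),
        ):
            if m.shape != (rows, cols):
                raise ValueError(
                    f"effect matrix must be {rows} constructs x {cols} biotypes, "
                    f"got {m.shape}"
                )
            if not np.isfinite(m.to_numpy(dtype=float)).all():
                raise ValueError("effect sizes must be finite")
            if list(m.index) != list(CONSTRUCTS):
                raise ValueError("effect matrix rows must be the 11 constructs")
        unknown = set(self.age_effect) | set(self.sex_effect)
        if not unknown <= set(VARIABLES):
            raise ValueError(f"unknown variables in covariate effects: {sorted(unknown - set(VARIABLES))}")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["effect_matrix"] = self.effect_matrix.to_dict()
        d["relative_effects"] = self.relative_effects.to_dict()
        return json.dumps(d, sort_keys=True)


@dataclass
class BiomarkerPanel:
    """Subjects x raw-biomarker matrix plus the variable -> domain map."""

    values: pd.DataFrame
    domain_of: pd.Series

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.domain_of.index):
            raise ValueError("panel columns and domain map must agree")

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    def domain_variables(self, domain: str) -> list[str]:
        return [v for v in self.variables if self.domain_of[v] == domain]

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.columns = pd.MultiIndex.from_arrays(
            [self.domain_of.reindex(out.columns), out.columns], names=["domain", "variable"]
        )
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "BiomarkerPanel":
        raw = pd.read_csv(path, header=[0, 1], index_col=0)
        domain_of = pd.Series(
            {var: dom for dom, var in raw.columns}, name="domain"
        )
        raw.columns = [var for _, var in raw.columns]
        return cls(values=raw, domain_of=domain_of.loc[raw.columns])


def _draw_ages(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    return np.clip(rng.normal(mean, sd, size=n), 18.0, 75.0).round(1)


def generate_cohort(
    config: SyntheticConfig, return_latent: bool = False
):
    """Generate a synthetic cohort.

    Returns ``(subjects, panel)`` — or ``(subjects, panel, latent)`` with the
    ground-truth construct scores when ``return_latent`` is set.  ``subjects``
    is a DataFrame with columns ``subject_id, family_id, role, true_biotype,
    age, sex``; ``true_biotype`` is ``0`` for healthy participants.  Output is
    bit-reproducible under a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    rows: list[dict] = []
    fam = 0
    for bt in BIOTYPES:
        for i in range(config.n_per_biotype):
            fam += 1
            fid = f"fam{fam:05d}"
            rows.append(
                dict(subject_id=f"P{bt}_{i:04d}", family_id=fid, role="proband",
                     true_biotype=bt)
            )
            for r in range(config.n_relatives_per_family):
                rows.append(
                    dict(subject_id=f"R{bt}_{i:04d}_{r}", family_id=fid,
                         role="relative", true_biotype=bt)
                )
    for i in range(config.n_healthy):
        fam += 1
        rows.append(
            dict(subject_id=f"H_{i:04d}", family_id=f"fam{fam:05d}", role="healthy",
                 true_biotype=0)
        )
    subjects = pd.DataFrame(rows)

    n = len(subjects)
    is_rel = (subjects["role"] == "relative").to_numpy()
    is_pro = (subjects["role"] == "proband").to_numpy()
    age = np.where(is_rel, _draw_ages(rng, n, 44, 14), 0.0)
    age = np.where(is_pro, _draw_ages(rng, n, 38, 12), age)
    healthy_mask = ~(is_rel | is_pro)
    age = np.where(healthy_mask, _draw_ages(rng, n, 35, 12), age)
    subjects["age"] = age
    subjects["sex"] = rng.integers(0, 2, size=n)

    # latent construct scores
    corr = default_construct_corr(config.rho_cognition).to_numpy()
    chol = np.linalg.cholesky(corr)
    fam_codes, fam_index = pd.factorize(subjects["family_id"])
    fam_eff = rng.standard_normal((len(fam_index), len(CONSTRUCTS))) @ chol.T
    indiv = rng.standard_normal((n, len(CONSTRUCTS))) @ chol.T
    icc = config.family_icc
    latent = np.sqrt(icc) * fam_eff[fam_codes] + np.sqrt(1 - icc) * indiv

    eff = config.effect_matrix.to_numpy(dtype=float)
    rel_eff = config.relative_effects.to_numpy(dtype=float)
    bt = subjects["true_biotype"].to_numpy()
    for b in BIOTYPES:
        latent[is_pro & (bt == b)] += eff[:, b - 1]
        latent[is_rel & (bt == b)] += rel_eff[:, b - 1]

    # raw variables
    construct_idx = {c: i for i, c in enumerate(CONSTRUCTS)}
    values = np.empty((n, len(VARIABLES)))
    sex = subjects["sex"].to_numpy()
    for j, (var, (_, construct)) in enumerate(VARIABLES.items()):
        values[:, j] = (
            config.loading * latent[:, construct_idx[construct]]
            + config.age_effect.get(var, 0.0) * (age - _REF_AGE)
            + config.sex_effect.get(var, 0.0) * sex
            + rng.normal(0.0, config.noise_sd, size=n)
        )

    panel = BiomarkerPanel(
        values=pd.DataFrame(values, index=subjects["subject_id"], columns=list(VARIABLES)),
        domain_of=pd.Series({v: d for v, (d, _) in VARIABLES.items()}, name="domain"),
    )
    if return_latent:
        latent_df = pd.DataFrame(
            latent, index=subjects["subject_id"], columns=list(CONSTRUCTS)
        )
        return subjects, panel, latent_df
    return subjects, panel


# ---------------------------------------------------------------------------
# Simplified multichannel ERP epochs
# ---------------------------------------------------------------------------

@dataclass
class EpochSet:
    """Per-subject epoched EEG: sensors x time x trials, in microvolts."""

    data: np.ndarray
    sfreq: float
    times: np.ndarray
    onset_index: int
    silent_slice: slice
    s2_onset_index: int | None = None
    trial_types: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.ndim != 3:
            raise ValueError("data must be sensors x time x trials")
        if self.data.shape[2] < 2:
            raise ValueError("at least 2 trials are required")
        if not np.isfinite(self.data).all():
            raise ValueError("epoch data must be finite")

    @property
    def n_sensors(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]


def _gauss(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def _evoked_shape(t: np.ndarray) -> np.ndarray:
    """Stereotyped auditory evoked response: N100 trough, P200 peak (unit scale)."""
    return -_gauss(t, 0.100, 0.020) + 0.6 * _gauss(t, 0.200, 0.035)


def generate_epochs(
    config: SyntheticConfig,
    paradigm: str,
    subjects: pd.DataFrame | None = None,
    latent: pd.DataFrame | None = None,
    n_trials: int = 40,
    n_sensors: int = 16,
    sfreq: float = 250.0,
    evoked_amp: float = 5.0,
    osc_amp: float = 1.5,
    noise_sd: float = 2.0,
    band_freqs: tuple[float, ...] = (4.0, 10.0, 20.0, 40.0),
    seed: int | None = None,
) -> dict[str, EpochSet]:
    """Generate simplified multichannel ERP epochs for every subject.

    Each trial is a stereotyped evoked waveform (amplitude scaled by the
    subject's ERP-magnitude construct), band-limited background oscillations
    with trial-random phase (scaled by the intrinsic-activity construct), and
    white sensor noise.  ``paired_stimuli`` epochs contain an S1 response at
    t=0, an S2 response 500 ms later and a silent pre-stimulus segment
    standing in for the inter-pair interval; ``oddball`` epochs interleave
    standard and target trials, targets adding a P300-complex deflection.
    """
    if paradigm not in ("paired_stimuli", "oddball"):
        raise ValueError(f"unknown paradigm {paradigm!r}")
    if n_trials < 2:
        raise ValueError("at least 2 trials are required")
    if subjects is None or latent is None:
        subjects, _, latent = generate_cohort(config, return_latent=True)
    rng = np.random.default_rng(config.seed if seed is None else seed)

    times = np.arange(-1.4, 1.0, 1.0 / sfreq)
    onset = int(np.searchsorted(times, 0.0))
    silent = slice(0, int(np.searchsorted(times, -0.2)))
    s2_onset = int(np.searchsorted(times, 0.5)) if paradigm == "paired_stimuli" else None

    # fixed scalp topographies (unit peak)
    s = np.arange(n_sensors)
    topo_erp = _gauss(s, (n_sensors - 1) / 2, max(n_sensors / 5, 1.0))
    topo_osc = _gauss(s, (n_sensors - 1) / 3, max(n_sensors / 4, 1.0))
    topo_p3 = _gauss(s, (n_sensors - 1) * 0.35, max(n_sensors / 5, 1.0))

    shape1 = _evoked_shape(times)
    shape2 = _evoked_shape(times - 0.5)
    shape_p3 = _gauss(times, 0.35, 0.06)
    erp_key = "ps_erp" if paradigm == "paired_stimuli" else "ob_erp"

    out: dict[str, EpochSet] = {}
    for sid in subjects["subject_id"]:
        c = latent.loc[sid]
        amp = evoked_amp * max(0.0, 1.0 + 0.35 * c[erp_key])
        ong = osc_amp * max(0.0, 1.0 + 0.35 * c["iea"])
        data = np.zeros((n_sensors, times.size, n_trials))

        if paradigm == "oddball":
            trial_types = (rng.random(n_trials) < 0.2).astype(int)
        else:
            trial_types = None

        for tr in range(n_trials):
            ev = amp * shape1
            if paradigm == "paired_stimuli":
                ev = ev + amp * 0.7 * max(0.0, 1.0 + 0.35 * c["ps_s2"]) * shape2
            elif trial_types is not None and trial_types[tr]:
                ev = ev + amp * 1.2 * max(0.0, 1.0 + 0.35 * c["frontal_p3"]) * shape_p3
            trial = np.outer(topo_erp, ev)
            for f in band_freqs:
                phase = rng.uniform(0, 2 * np.pi)
                trial = trial + ong * np.outer(
                    topo_osc, np.sin(2 * np.pi * f * times + phase)
                )
            if noise_sd > 0:
                trial = trial + rng.normal(0.0, noise_sd, size=trial.shape)
            data[:, :, tr] = trial

        out[sid] = EpochSet(
            data=data, sfreq=sfreq, times=times, onset_index=onset,
            silent_slice=silent, s2_onset_index=s2_onset, trial_types=trial_types,
        )
    return out
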
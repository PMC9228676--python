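"""Synthetic multi-sensor IMU trials for plank-technique classification.

The generator emulates the statistical structure the cascade exploits, not
body kinematics.  Per channel j, subject k and technique c the signal is

    x_t = mu_{c,j} + b_{k,j} + r_t + eps_t,

with a subject-level random offset b ~ N(0, subject_sd^2), i.i.d. white
sampling noise eps ~ N(0, noise_sd^2) (optionally AR(1) with the same
stationary variance), and a deterministic linear transient r_t of amplitude
``transient_amp`` that decays to zero over the first ``transient_len``
timestamps and ramps up again over the last ``transient_len``.  The middle
of the trial is therefore stationary, which is what makes stable-window
averaging informative.

Class structure baked into :func:`default_config`:

* HTBN's Euler-Y-S1 mean sits below every other class's by
  ``htbn_margin`` plus six feature-scale noise SDs, so a univariate
  threshold separates it with probability ~1.
* Each other deviation differs from the acceptable technique (PC) on a
  small, documented set of channels, with offsets expressed in units of the
  combined feature-level SD sqrt(subject_sd^2 + noise_sd^2 / window_len).
* HD overlaps PC on its discriminative channels (modest offset), except for
  an "extreme" subpopulation of HD subjects shifted far out — the cases a
  tail filter should catch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .io import CHANNEL_INDEX, CHANNELS, SENSORS, TECHNIQUES, RawTrial

#: Channels on which the hip-dropped technique differs from the acceptable one.
HD_CHANNELS = ("Euler-Z-S3", "Acc-X-S3", "Acc-X-S4", "Mag-Z-S3", "Mag-Z-S4")

#: Channels carrying each deviation's offset (HD handled separately).
DEVIATION_CHANNELS = {
    "HTFN": ("Euler-X-S1", "Euler-X-S2", "Euler-Y-S2"),
    "HTBN": ("Euler-X-S1", "Euler-X-S2"),  # besides the Euler-Y-S1 margin
    "HC": ("Euler-Z-S5", "Acc-Y-S5", "Gyr-X-S5"),
    "HTB": ("Euler-X-S4", "Acc-Z-S4", "Gyr-Y-S4"),
    "BC": ("Euler-Y-S4", "Mag-Y-S4", "Gyr-Z-S4"),
    "HD": HD_CHANNELS,
}


@dataclass
class SynthConfig:
    n_subjects_per_technique: int = 19
    T: int = 600
    sample_rate: float = 60.0
    class_channel_means: dict[str, np.ndarray] = field(default_factory=dict)
    subject_sd: float = 0.5
    noise_sd: float = 2.0
    transient_len: int = 180
    transient_amp: float = 5.0
    htbn_margin: float = 10.0
    hd_extreme_fraction: float = 8 / 19
    hd_extreme_shift: float = 0.0
    ar1_phi: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects_per_technique < 2:
            raise ValidationError("n_subjects_per_technique must be >= 2")
        if self.T < 1:
            raise ValidationError("T must be positive")
        if not 0 <= self.transient_len < self.T / 2:
            raise ValidationError("transient_len must satisfy 0 <= len < T/2")
        for name, value in [
            ("subject_sd", self.subject_sd),
            ("noise_sd", self.noise_sd),
            ("transient_amp", self.transient_amp),
            ("hd_extreme_fraction", self.hd_extreme_fraction),
        ]:
            if value < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.hd_extreme_fraction > 1:
            raise ValidationError("hd_extreme_fraction must be <= 1")
        if self.htbn_margin <= 0:
            raise ValidationError("htbn_margin must be > 0")
        if not -1 < self.ar1_phi < 1:
            raise ValidationError("ar1_phi must lie in (-1, 1)")
        if set(self.class_channel_means) != set(TECHNIQUES):
            raise ValidationError("class_channel_means must cover all 7 techniques")
        for tech, mu in self.class_channel_means.items():
            if np.asarray(mu).shape != (len(CHANNELS),):
                raise ValidationError(f"mean vector for {tech} must have length 60")

    def feature_noise_sd(self, window_len: int = 240) -> float:
        """SD of a stable-window mean around mu: subject effect + averaged noise."""
        return math.sqrt(self.subject_sd**2 + self.noise_sd**2 / window_len)


def _baseline_means() -> np.ndarray:
    """Per-channel baselines shared by every class (the PC profile).

    Magnetometer and Euler-Z channels get sensor-distinct baselines so that
    cross-sensor max-features are non-degenerate.
    """
    mu = np.zeros(len(CHANNELS))
    base_by_measurement = {"Euler": 0.0, "Acc": 1.0, "Gyr": 0.0, "Mag": 40.0}
    for name in CHANNELS:
        meas, axis, sensor = name.split("-")
        s = SENSORS.index(sensor)
        mu[CHANNEL_INDEX[name]] = base_by_measurement[meas] + 2.0 * s
        if meas == "Euler" and axis == "Z":
            mu[CHANNEL_INDEX[name]] += 0.7 * s
    mu[CHANNEL_INDEX["Euler-Y-S1"]] = -40.0
    return mu


def default_config(
    n_subjects_per_technique: int = 19,
    T: int = 600,
    seed: int = 0,
    separation_sds: float = 4.0,
    hd_overlap: bool = True,
    **overrides,
) -> SynthConfig:
    """Build the reference synthetic-study configuration.

    ``separation_sds`` sets each deviation's offset from PC on its designated
    channels, in units of the combined feature-level SD.  With
    ``hd_overlap=True`` (default) the HD base offset is reduced to 1.5 SDs so
    that HD and PC genuinely overlap, and an extreme HD subpopulation
    (``hd_extreme_fraction`` of HD subjects) is shifted a further 8 SDs out on
    the HD channels; with ``hd_overlap=False`` HD is separated like every
    other deviation and the extreme shift is zero.
    """
    cfg = SynthConfig(
        n_subjects_per_technique=n_subjects_per_technique, T=T, seed=seed, **overrides
    )
    s = cfg.feature_noise_sd()
    delta = separation_sds * s
    means = {tech: _baseline_means() for tech in TECHNIQUES}
    signs = {  # fixed, documented offset directions per deviation channel
        "HTFN": (+1, +1, -1),
        "HTBN": (-1, +1),
        "HC": (+1, +1, -1),
        "HTB": (+1, +1, -1),
        "BC": (-1, +1, +1),
        "HD": (+1, -1, +1, +1, -1),
    }
    for tech, channels in DEVIATION_CHANNELS.items():
        if tech == "HD":
            continue
        for sign, ch in zip(signs[tech], channels):
            means[tech][CHANNEL_INDEX[ch]] += sign * delta
    hd_delta = 1.5 * s if hd_overlap else delta
    for sign, ch in zip(signs["HD"], HD_CHANNELS):
        means["HD"][CHANNEL_INDEX[ch]] += sign * hd_delta
    # HTBN margin on Euler-Y-S1: below every other class by margin + 6 SDs.
    means["HTBN"][CHANNEL_INDEX["Euler-Y-S1"]] -= cfg.htbn_margin + 6.0 * s
    cfg.class_channel_means = means
    if "hd_extreme_shift" not in overrides:
        cfg.hd_extreme_shift = 8.0 * s if hd_overlap else 0.0
    if not hd_overlap and "hd_extreme_fraction" not in overrides:
        cfg.hd_extreme_fraction = 0.0
    cfg.validate()
    return cfg


def extreme_hd_subjects(config: SynthConfig) -> tuple[str, ...]:
    """Subject ids of the extreme-HD mixture component (deterministic)."""
    k = round(config.hd_extreme_fraction * config.n_subjects_per_technique)
    return tuple(_subject_id(i) for i in range(k))


def _subject_id(i: int) -> str:
    return f"P{i + 1:02d}"


def _transient(T: int, length: int, amp: float) -> np.ndarray:
    r = np.zeros(T)
    if length > 0 and amp != 0:
        ramp = amp * (length - np.arange(1, length + 1)) / length
        r[:length] = ramp          # decays to 0 at t = transient_len
        r[T - length:] = ramp[::-1]  # mirrored rise at the tail
    return r


def generate_dataset(config: SynthConfig) -> list[RawTrial]:
    """Generate n_subjects x 7 techniques trials; same config => identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    extremes = set(extreme_hd_subjects(config))
    hd_shift_idx = np.array([CHANNEL_INDEX[ch] for ch in HD_CHANNELS])
    # Extreme shifts follow the base-offset direction on each HD channel.
    hd_signs = np.array([+1, -1, +1, +1, -1], dtype=float)
    r = _transient(config.T, config.transient_len, config.transient_amp)
    trials = []
    for tech in TECHNIQUES:
        mu = np.asarray(config.class_channel_means[tech], dtype=float)
        for i in range(config.n_subjects_per_technique):
            subject = _subject_id(i)
            b = rng.normal(0.0, config.subject_sd, size=len(CHANNELS))
            eps = rng.normal(0.0, config.noise_sd, size=(config.T, len(CHANNELS)))
            if config.ar1_phi:
                phi = config.ar1_phi
                eps = eps * math.sqrt(1 - phi**2)
                for t in range(1, config.T):
                    eps[t] += phi * eps[t - 1]
            x = mu[None, :] + b[None, :] + r[:, None] + eps
            if tech == "HD" and subject in extremes and config.hd_extreme_shift:
                x[:, hd_shift_idx] += hd_signs * config.hd_extreme_shift
            trials.append(RawTrial(subject, tech, x, config.sample_rate))
    return trials


def ground_truth_features(config: SynthConfig):
    """Class-mean matrix mu_{c,j}: DataFrame techniques x 60 canonical channels."""
    import pandas as pd

    config.validate()
    return pd.DataFrame(
        {tech: np.asarray(config.class_channel_means[tech], dtype=float)
         for tech in TECHNIQUES},
        index=list(CHANNELS),
    ).T


def noise_free(config: SynthConfig) -> SynthConfig:
    """Copy of config with all stochastic terms and transients zeroed."""
    return replace(config, subject_sd=0.0, noise_sd=0.0, transient_amp=0.0)
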
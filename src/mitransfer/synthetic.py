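"""Synthetic multi-subject motor-imagery EEG cohorts.

Each trial is a sum of band-limited mu (8-12 Hz) and beta (13-30 Hz)
oscillations on latent source channels, mixed into sensor space through a
subject-specific orthogonal matrix, plus white broadband noise.  The class
effect is an ERD-like (event-related desynchronization) power decrease: for
class-1 trials the mu amplitude on one designated source subset is scaled by
``1 - erd_depth``; class-2 trials attenuate a disjoint subset.  Inter-subject
covariate shift comes from perturbing the base mixing matrix per subject.

Oscillations are sums of sinusoids at randomized in-band frequencies with
random phases, so band power is analytically known (amplitude^2 / 2 per
sinusoid) and oracle tests can predict the ERD attenuation exactly: the mean
mu-band variance of the attenuated subset for the matching class is
``(1 - erd_depth)^2`` times the non-matching class's.

Mixing matrices are orthogonal (QR of a seeded Gaussian matrix, sign-fixed),
so channel variances stay comparable across subjects and the perturbation
changes orientation, not overall power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import EpochSet

_SINES_PER_BAND = {"mu": 3, "beta": 5}
_BAND_AMPLITUDE = {"mu": 1.0, "beta": 0.6}


@dataclass
class SyntheticConfig:
    """Cohort-generation settings (2a-like defaults).

    Defaults emulate a 9-subject, 72-trials-per-class study sampled at
    250 Hz with 3 s analysis windows; the montage is reduced to 8 channels
    for speed (22 available by configuration).
    """

    n_subjects: int = 9
    n_trials_per_class: int = 72
    n_channels: int = 8
    fs: float = 250.0
    trial_duration: float = 3.0
    mu_band: tuple[float, float] = (8.0, 12.0)
    beta_band: tuple[float, float] = (13.0, 30.0)
    erd_depth: float = 0.5
    noise_sd: float = 2.0
    subject_shift_sd: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_trials_per_class < 1:
            raise ValueError("n_trials_per_class must be >= 1")
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if self.fs <= 2.0 * self.beta_band[1]:
            raise ValueError(
                f"fs must exceed twice beta_band.high (Nyquist): "
                f"fs={self.fs}, beta high={self.beta_band[1]}"
            )
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")
        for name in ("mu_band", "beta_band"):
            low, high = getattr(self, name)
            if not (0.0 < low < high):
                raise ValueError(f"{name} must satisfy 0 < low < high")
        if not (0.0 <= self.erd_depth < 1.0):
            raise ValueError("erd_depth must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.subject_shift_sd < 0:
            raise ValueError("subject_shift_sd must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_duration * self.fs))


@dataclass
class Cohort:
    """Ordered multi-subject collection of epoch sets."""

    subjects: list[tuple[str, EpochSet]]
    config: SyntheticConfig = field(repr=False, default_factory=SyntheticConfig)

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self) -> int:
        return len(self.subjects)

    def subject_ids(self) -> list[str]:
        return [sid for sid, _ in self.subjects]

    def get(self, subject_id: str) -> EpochSet:
        for sid, es in self.subjects:
            if sid == subject_id:
                return es
        raise KeyError(f"unknown subject id {subject_id!r}")


def erd_channel_subsets(config: SyntheticConfig) -> tuple[list[int], list[int]]:
    """Disjoint latent-channel subsets attenuated by class 1 / class 2."""
    n_erd = max(1, config.n_channels // 4)
    return list(range(n_erd)), list(range(n_erd, 2 * n_erd))


def _orthogonalize(a: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


def subject_mixing_matrix(config: SyntheticConfig, subject_index: int) -> np.ndarray:
    """Orthogonal source-to-sensor mixing for one subject.

    The base matrix (shared by the cohort) is perturbed by additive Gaussian
    noise of scale ``subject_shift_sd`` and re-orthogonalized; with zero shift
    every subject gets exactly the base matrix.
    """
    k = config.n_channels
    base_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    base = _orthogonalize(base_rng.normal(size=(k, k)))
    if config.subject_shift_sd == 0.0:
        return base
    subj_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 1 + subject_index])
    )
    perturbation = config.subject_shift_sd * subj_rng.normal(size=(k, k))
    return _orthogonalize(base + perturbation)


def _band_oscillation(
    rng: np.random.Generator,
    t: np.ndarray,
    band: tuple[float, float],
    n_sines: int,
    amplitude: float,
) -> np.ndarray:
    """Sum of ``n_sines`` random-frequency, random-phase sinusoids.

    Each sinusoid has amplitude ``amplitude / sqrt(n_sines)``, so the summed
    band variance is ``amplitude^2 / 2`` regardless of ``n_sines``.
    """
    freqs = rng.uniform(band[0], band[1], size=n_sines)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_sines)
    a = amplitude / np.sqrt(n_sines)
    return (a * np.sin(2.0 * np.pi * freqs[:, None] * t + phases[:, None])).sum(axis=0)


def generate_subject(config: SyntheticConfig, subject_index: int) -> EpochSet:
    """Generate one subject's balanced two-class epoch set.

    Trials are ordered class 1 first, then class 2 (``2 * n_trials_per_class``
    total).  Identical config and seed regenerate bit-identical arrays.
    """
    config.validate()
    if not (0 <= subject_index < config.n_subjects):
        raise ValueError(
            f"subject_index {subject_index} out of range [0, {config.n_subjects})"
        )
    k = config.n_channels
    t = np.arange(config.n_samples) / config.fs
    mixing = subject_mixing_matrix(config, subject_index)
    subset_1, subset_2 = erd_channel_subsets(config)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 1000 + subject_index])
    )

    n_per = config.n_trials_per_class
    data = np.empty((2 * n_per, k, config.n_samples))
    labels = np.repeat([1, 2], n_per)
    for trial, label in enumerate(labels):
        attenuated = subset_1 if label == 1 else subset_2
        sources = np.empty((k, config.n_samples))
        for ch in range(k):
            mu_amp = _BAND_AMPLITUDE["mu"]
            if ch in attenuated:
                mu_amp *= 1.0 - config.erd_depth
            sources[ch] = _band_oscillation(
                rng, t, config.mu_band, _SINES_PER_BAND["mu"], mu_amp
            ) + _band_oscillation(
                rng, t, config.beta_band, _SINES_PER_BAND["beta"],
                _BAND_AMPLITUDE["beta"],
            )
        data[trial] = mixing @ sources + config.noise_sd * rng.normal(
            size=(k, config.n_samples)
        )
    return EpochSet(
        data,
        labels,
        config.fs,
        [f"ch{c + 1:02d}" for c in range(k)],
        (0.5, 0.5 + config.trial_duration),
    )


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate all subjects; ids are ``S01``, ``S02``, ..."""
    config.validate()
    subjects = [
        (f"S{i + 1:02d}", generate_subject(config, i))
        for i in range(config.n_subjects)
    ]
    return Cohort(subjects=subjects, config=config)
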
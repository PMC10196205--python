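"""Welch power spectral density and band-power features.

The Welch estimator splits a signal into ``R`` segments of ``N`` samples,
applies a taper ``w(m)``, computes each segment's periodogram

    P(f) = |DFT(x * w)|^2 / (N * U * fs),    U = mean(w^2),

and averages the ``R`` periodograms.  ``U`` makes the white-noise PSD level
independent of the taper; the ``1/fs`` factor puts values in power/Hz so the
one-sided spectrum integrates to the signal variance (Parseval).  Averaging
trades frequency resolution for an ~``1/R`` variance reduction.

Band features reduce the PSD to the mean power in the motor-imagery bands
(mu 8-12 Hz, beta 13-30 Hz) per channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import get_window

from .containers import EpochSet

DEFAULT_BANDS = [(8.0, 12.0), (13.0, 30.0)]

_WINDOW_ALIASES = {"rectangular": "boxcar", "rect": "boxcar"}


@dataclass
class WelchConfig:
    """Segmentation and taper settings.

    ``segment_length`` defaults to 250 samples: 1 s at 250 Hz, i.e. 1 Hz bin
    resolution for the standard 750-sample (3 s) epoch, giving 3 segments.
    ``overlap`` is the fractional overlap between consecutive segments
    (0 = disjoint segments, the default).
    """

    segment_length: int = 250
    overlap: float = 0.0
    window_kind: str = "hamming"
    fs: float = 250.0

    def __post_init__(self) -> None:
        if self.segment_length < 2:
            raise ValueError("segment_length must be >= 2")
        if not (0.0 <= self.overlap < 1.0):
            raise ValueError("overlap must be in [0, 1)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    def taper(self) -> np.ndarray:
        kind = _WINDOW_ALIASES.get(self.window_kind, self.window_kind)
        return get_window(kind, self.segment_length, fftbins=True)


@dataclass
class SpectralFeatureBlock:
    """Band-power features: ``(n_trials, n_channels * n_bands)``, channel-major."""

    values: np.ndarray
    bands: list[tuple[float, float]]
    column_names: list[str] = field(default_factory=list)


def segment_signal(x: np.ndarray, cfg: WelchConfig) -> np.ndarray:
    """Split ``x`` into full segments; the trailing partial segment is dropped."""
    x = np.asarray(x, dtype=float)
    n = cfg.segment_length
    if x.shape[-1] < n:
        raise ValueError(
            f"signal length {x.shape[-1]} shorter than one segment ({n})"
        )
    step = max(1, int(round(n * (1.0 - cfg.overlap))))
    starts = range(0, x.shape[-1] - n + 1, step)
    return np.stack([x[..., s:s + n] for s in starts], axis=-2)


def windowed_periodogram(segment: np.ndarray, cfg: WelchConfig) -> tuple[np.ndarray, np.ndarray]:
    """One-sided tapered periodogram of a single segment, in power/Hz.

    Returns ``(frequencies, periodogram)`` at bins ``fs * j / N``.
    """
    segment = np.asarray(segment, dtype=float)
    n = cfg.segment_length
    if segment.shape[-1] != n:
        raise ValueError(f"segment length must equal {n}")
    w = cfg.taper()
    u = np.mean(w ** 2)
    spec = np.fft.rfft(segment * w, axis=-1)
    p = (spec.real ** 2 + spec.imag ** 2) / (n * u * cfg.fs)
    # fold negative frequencies into the one-sided spectrum
    if n % 2 == 0:
        p[..., 1:-1] *= 2.0
    else:
        p[..., 1:] *= 2.0
    return np.fft.rfftfreq(n, 1.0 / cfg.fs), p


def welch_psd(x: np.ndarray, cfg: WelchConfig) -> tuple[np.ndarray, np.ndarray]:
    """Welch estimate: mean of segment periodograms.

    ``x`` may have leading batch dimensions; the PSD is computed along the
    last axis.  Returns ``(frequencies, psd)``.
    """
    segments = segment_signal(x, cfg)
    freqs, p = windowed_periodogram(segments, cfg)
    return freqs, p.mean(axis=-2)


def band_features(
    epochs: EpochSet,
    cfg: WelchConfig | None = None,
    bands: list[tuple[float, float]] | None = None,
) -> SpectralFeatureBlock:
    """Mean Welch PSD over each band, per trial and channel.

    Columns are ordered channel-major: all bands of channel 0, then channel 1,
    etc.  A band that covers no frequency bin raises, with the remedy (longer
    segments) in the message.
    """
    if cfg is None:
        cfg = WelchConfig(fs=epochs.fs)
    bands = list(DEFAULT_BANDS if bands is None else bands)
    for low, high in bands:
        if not (0.0 < low < high < epochs.fs / 2.0):
            raise ValueError(f"band ({low}, {high}) outside (0, fs/2)")
    freqs, psd = welch_psd(epochs.data, cfg)  # (trials, channels, bins)
    cols = []
    names = []
    for ch in range(epochs.n_channels):
        for low, high in bands:
            mask = (freqs >= low) & (freqs <= high)
            if not mask.any():
                raise ValueError(
                    f"band ({low}, {high}) Hz contains no frequency bin at "
                    f"resolution {epochs.fs / cfg.segment_length:g} Hz; "
                    "lengthen segments"
                )
            cols.append(psd[:, ch, mask].mean(axis=1))
            names.append(f"{epochs.channel_labels[ch]}:{low:g}-{high:g}Hz")
    return SpectralFeatureBlock(
        values=np.column_stack(cols), bands=bands, column_names=names,
    )
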
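"""Raw-recording preprocessing: channel selection, band-pass, epoching.

The standard motor-imagery chain is applied in a fixed order: drop non-EEG
(EOG) channels, zero-phase band-pass to the 8-30 Hz mu+beta range, then cut
the 0.5-3.5 s post-cue analysis window.  Filtering is a 4th-order Butterworth
applied forward-backward (``sosfiltfilt``), so epoch timing is phase-true.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .containers import EpochSet, RawRecording

DEFAULT_BAND = (8.0, 30.0)
DEFAULT_WINDOW = (0.5, 3.5)


def select_channels(rec: RawRecording) -> RawRecording:
    """Keep only EEG-kind channels, preserving order.

    Raises
    ------
    ValueError
        If no EEG channel remains (empty montage).
    """
    keep = [i for i, k in enumerate(rec.channel_kinds) if k == "EEG"]
    if not keep:
        raise ValueError("empty montage: no EEG channels remain after selection")
    if len(keep) == rec.n_channels:
        return rec
    return RawRecording(
        rec.data[keep],
        rec.fs,
        [rec.channel_labels[i] for i in keep],
        ["EEG"] * len(keep),
        list(rec.events),
    )


def bandpass(
    rec: RawRecording,
    low_hz: float = DEFAULT_BAND[0],
    high_hz: float = DEFAULT_BAND[1],
    order: int = 4,
) -> RawRecording:
    """Zero-phase Butterworth band-pass of every channel."""
    if not (0.0 < low_hz < high_hz < rec.fs / 2.0):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < fs/2 "
            f"= {rec.fs / 2.0}"
        )
    sos = butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.fs, output="sos")
    filtered = sosfiltfilt(sos, rec.data, axis=1)
    return RawRecording(
        filtered, rec.fs, list(rec.channel_labels), list(rec.channel_kinds),
        list(rec.events),
    )


def extract_epochs(
    rec: RawRecording,
    start_offset_s: float = DEFAULT_WINDOW[0],
    end_offset_s: float = DEFAULT_WINDOW[1],
) -> EpochSet:
    """Cut one epoch per cue event over ``[cue+start, cue+end)`` (half-open).

    With 0-based, half-open sample indexing the epoch length is exactly
    ``round((end - start) * fs)`` samples (750 at 250 Hz for a 3 s window).
    """
    if end_offset_s <= start_offset_s:
        raise ValueError("end_offset_s must exceed start_offset_s")
    n_samples = int(round((end_offset_s - start_offset_s) * rec.fs))
    epochs = np.empty((len(rec.events), rec.n_channels, n_samples))
    labels = np.empty(len(rec.events), dtype=int)
    for idx, (cue, label) in enumerate(rec.events):
        i0 = int(cue) + int(round(start_offset_s * rec.fs))
        i1 = i0 + n_samples
        if i0 < 0 or i1 > rec.n_samples:
            raise ValueError(
                f"event {idx} (cue sample {cue}): window [{i0}, {i1}) exceeds "
                f"recording bounds [0, {rec.n_samples})"
            )
        epochs[idx] = rec.data[:, i0:i1]
        labels[idx] = label
    return EpochSet(
        epochs, labels, rec.fs, list(rec.channel_labels),
        (start_offset_s, end_offset_s),
    )


def preprocess(
    rec: RawRecording,
    band: tuple[float, float] = DEFAULT_BAND,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> EpochSet:
    """Full chain: channel selection -> band-pass -> epoch extraction."""
    return extract_epochs(bandpass(select_channels(rec), *band), *window)
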
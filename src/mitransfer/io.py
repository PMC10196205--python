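"""File I/O: the HDF5 array container, CSV feature tables, GDF/EDF readers.

The array container is a plain HDF5 layout — ``/data``, ``/labels``, ``/fs``,
``/channel_labels`` (plus a ``window`` attribute for epochs and
``/channel_kinds`` / ``/events`` for raw recordings).  GDF/EDF reading
delegates to ``mne`` and is only available when that optional dependency is
installed.
"""

from __future__ import annotations

import numpy as np

from .containers import EpochSet, RawRecording


def write_epochs(path, epochs: EpochSet) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("labels", data=epochs.labels)
        f.create_dataset("fs", data=float(epochs.fs))
        f.create_dataset(
            "channel_labels",
            data=np.array(epochs.channel_labels, dtype=h5py.string_dtype()),
        )
        f.attrs["window"] = list(epochs.window)


def read_epochs(path) -> EpochSet:
    import h5py

    with h5py.File(path, "r") as f:
        return EpochSet(
            f["data"][()],
            f["labels"][()],
            float(f["fs"][()]),
            [s.decode() if isinstance(s, bytes) else str(s)
             for s in f["channel_labels"][()]],
            tuple(f.attrs.get("window", (0.0, 0.0))),
        )


def write_raw(path, rec: RawRecording) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.create_dataset("fs", data=float(rec.fs))
        str_t = h5py.string_dtype()
        f.create_dataset(
            "channel_labels", data=np.array(rec.channel_labels, dtype=str_t)
        )
        f.create_dataset(
            "channel_kinds", data=np.array(rec.channel_kinds, dtype=str_t)
        )
        f.create_dataset(
            "events", data=np.array(rec.events, dtype=int).reshape(-1, 2)
        )


def read_raw(path) -> RawRecording:
    import h5py

    with h5py.File(path, "r") as f:
        decode = lambda arr: [
            s.decode() if isinstance(s, bytes) else str(s) for s in arr
        ]
        events = [(int(s), int(l)) for s, l in f["events"][()]]
        return RawRecording(
            f["data"][()],
            float(f["fs"][()]),
            decode(f["channel_labels"][()]),
            decode(f["channel_kinds"][()]),
            events,
        )


def _raw_from_mne(raw, event_map: dict[str, int]) -> RawRecording:
    data = raw.get_data() * 1e6  # volts -> microvolts
    kinds = [
        "EOG" if t == "eog" else "EEG" for t in raw.get_channel_types()
    ]
    events = []
    for onset, desc in zip(
        raw.annotations.onset, raw.annotations.description
    ):
        if desc in event_map:
            events.append((int(round(onset * raw.info["sfreq"])), event_map[desc]))
    events.sort()
    return RawRecording(data, float(raw.info["sfreq"]), list(raw.ch_names), kinds, events)


def read_gdf(path, event_map: dict[str, int] | None = None) -> RawRecording:
    """Read a GDF recording (BCI Competition IV layout) via ``mne``.

    ``event_map`` maps annotation descriptions to class labels; the default
    covers the competition's left/right-hand cue codes.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("GDF reading requires the optional 'mne' package") from exc
    raw = mne.io.read_raw_gdf(path, preload=True, verbose="error")
    return _raw_from_mne(raw, event_map or {"769": 1, "770": 2})


def read_edf(path, event_map: dict[str, int] | None = None) -> RawRecording:
    """Read an EDF recording via ``mne``."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF reading requires the optional 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return _raw_from_mne(raw, event_map or {"769": 1, "770": 2})


def write_feature_csv(path, values: np.ndarray, column_names: list[str]) -> None:
    import pandas as pd

    pd.DataFrame(values, columns=column_names).to_csv(path, index=False)


def read_feature_csv(path) -> tuple[np.ndarray, list[str]]:
    import pandas as pd

    df = pd.read_csv(path)
    return df.to_numpy(dtype=float), list(df.columns)
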
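"""Labelled EEG trial container and its on-disk archive format.

The :class:`EpochSet` is the object every pipeline stage consumes and
produces: a ``(n_trials, n_channels, n_samples)`` tensor in microvolts with
sampling metadata and one class label per trial drawn from the three-class
motor-imagery alphabet (left hand, right hand, feet).

The archive format is deliberately language-neutral: a JSON metadata
document next to a raw little-endian float matrix in trial-major,
channel-middle, sample-minor order.  ``save_archive`` followed by
``load_archive`` reproduces the tensor bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ClassLabel",
    "EpochSet",
    "save_archive",
    "load_archive",
    "import_gdf",
]


class ClassLabel(str, Enum):
    """Motor-imagery class alphabet.

    ``NONE`` is the reject outcome of the one-vs-one vote table; it is never
    a valid *input* label.
    """

    LH = "LH"
    RH = "RH"
    F = "F"
    NONE = "NONE"


#: Labels permitted in input data (``NONE`` is output-only).
INPUT_LABELS = frozenset({"LH", "RH", "F"})

_META_NAME = "meta.json"
_DATA_NAME = "data.bin"

_DTYPE_CODES = {"float32": "<f4", "float64": "<f8"}


@dataclass
class EpochSet:
    """Epoched multichannel EEG trials with labels.

    Parameters
    ----------
    data
        Real tensor ``(n_trials, n_channels, n_samples)`` in microvolts.
    fs
        Sampling rate in Hz.
    channel_names
        Ordered channel labels, e.g. ``["C3", "Cz", "C4", ...]``.
    labels
        Per-trial class, each in ``{"LH", "RH", "F"}``.
    trial_t0
        Time in seconds of sample 0 relative to trial onset.
    meta
        Free-form provenance strings.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    labels: list[str]
    trial_t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.channel_names = list(self.channel_names)
        self.labels = [
            lab.value if isinstance(lab, ClassLabel) else str(lab) for lab in self.labels
        ]
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        """Raise ``ValueError`` naming the offending field on any invariant breach."""
        if self.data.ndim != 3:
            raise ValueError(
                f"data: expected 3-D (trials, channels, samples), got shape {self.data.shape}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("data: contains non-finite values")
        if self.fs <= 0:
            raise ValueError(f"fs: must be positive, got {self.fs}")
        if len(self.labels) != self.n_trials:
            raise ValueError(
                f"labels: {len(self.labels)} labels for {self.n_trials} trials"
            )
        if len(self.channel_names) != self.n_channels:
            raise ValueError(
                f"channel_names: {len(self.channel_names)} names for "
                f"{self.n_channels} channels"
            )
        bad = sorted(set(self.labels) - INPUT_LABELS)
        if bad:
            raise ValueError(f"labels: unknown class labels {bad}; allowed: LH, RH, F")

    # -- shape helpers --------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to trial onset."""
        return self.trial_t0 + np.arange(self.n_samples) / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in montage {self.channel_names}"
            ) from None

    def select_trials(self, idx: Sequence[int] | np.ndarray) -> "EpochSet":
        idx = np.asarray(idx)
        return EpochSet(
            data=self.data[idx],
            fs=self.fs,
            channel_names=self.channel_names,
            labels=[self.labels[i] for i in idx],
            trial_t0=self.trial_t0,
            meta=dict(self.meta),
        )

    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels)


def save_archive(epochs: EpochSet, path: str | Path) -> Path:
    """Write ``epochs`` as a metadata + raw-matrix archive directory.

    Returns the archive path.  The raw matrix is written little-endian in
    trial-major, channel-middle, sample-minor order; the dtype (float32 or
    float64) is recorded so the round trip is bit-exact.
    """
    epochs.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    dtype_name = np.dtype(epochs.data.dtype).name
    if dtype_name not in _DTYPE_CODES:
        dtype_name = "float64"
    meta = {
        "format": "mivote-trial-archive",
        "version": 1,
        "units": "microvolts",
        "n_trials": epochs.n_trials,
        "n_channels": epochs.n_channels,
        "n_samples": epochs.n_samples,
        "fs": epochs.fs,
        "channel_names": epochs.channel_names,
        "labels": epochs.labels,
        "trial_t0": epochs.trial_t0,
        "dtype": dtype_name,
        "meta": epochs.meta,
    }
    (path / _META_NAME).write_text(json.dumps(meta, indent=1))
    epochs.data.astype(_DTYPE_CODES[dtype_name]).tofile(path / _DATA_NAME)
    return path


def load_archive(path: str | Path) -> EpochSet:
    """Read an archive written by :func:`save_archive`, checking all invariants."""
    path = Path(path)
    meta_path = path / _META_NAME
    if not meta_path.exists():
        raise FileNotFoundError(f"no {_META_NAME} in {path}")
    meta = json.loads(meta_path.read_text())

    required = {"n_trials", "n_channels", "n_samples", "fs", "channel_names", "labels"}
    missing = sorted(required - meta.keys())
    if missing:
        raise KeyError(f"archive metadata missing keys: {missing}")

    shape = (meta["n_trials"], meta["n_channels"], meta["n_samples"])
    dtype = _DTYPE_CODES.get(meta.get("dtype", "float32"), "<f4")
    raw = np.fromfile(path / _DATA_NAME, dtype=dtype)
    expected = int(np.prod(shape))
    if raw.size != expected:
        raise IOError(
            f"matrix file holds {raw.size} values but metadata implies "
            f"{expected} ({shape})"
        )
    return EpochSet(
        data=raw.reshape(shape),
        fs=meta["fs"],
        channel_names=meta["channel_names"],
        labels=meta["labels"],
        trial_t0=meta.get("trial_t0", 0.0),
        meta=meta.get("meta", {}),
    )


def import_gdf(
    path: str | Path,
    event_map: dict[int | str, str],
    epoch_window: tuple[float, float] = (0.0, 7.0),
) -> EpochSet:
    """Epoch a GDF recording around cue events into an :class:`EpochSet`.

    Optional adapter for BCI-competition recordings; requires ``mne``.
    ``event_map`` maps GDF event codes to class labels; events with codes
    not in the map (for example a fourth, tongue class) are dropped.
    Signals are converted from volts to microvolts.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("GDF import requires the optional 'mne' dependency") from exc

    raw = mne.io.read_raw_gdf(str(path), preload=True, verbose="error")
    events, event_id = mne.events_from_annotations(raw, verbose="error")

    code_for = {}
    for key, label in event_map.items():
        skey = str(key)
        if skey in event_id:
            code_for[event_id[skey]] = label
    if not code_for:
        raise ValueError(
            f"none of the mapped event codes found; codes present: {sorted(event_id)}"
        )

    keep = np.isin(events[:, 2], list(code_for))
    events = events[keep]
    fs = raw.info["sfreq"]
    tmin, tmax = epoch_window
    epochs = mne.Epochs(
        raw,
        events,
        tmin=tmin,
        tmax=tmax - 1.0 / fs,
        baseline=None,
        preload=True,
        verbose="error",
    )
    data_uv = epochs.get_data() * 1e6
    labels = [code_for[int(code)] for code in epochs.events[:, 2]]
    return EpochSet(
        data=data_uv,
        fs=fs,
        channel_names=list(raw.ch_names),
        labels=labels,
        trial_t0=tmin,
        meta={"source": str(path), "importer": "gdf"},
    )
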
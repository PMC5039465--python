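"""Spatial filtering, band-pass filtering and analysis-window extraction.

The surface (small) Laplacian subtracts from each center electrode the
mean of its four neighbours, acting as a spatial high-pass that sharpens
focal sensorimotor activity: 15 recorded channels reduce to the three
surrogate channels C3, Cz, C4.  Band-pass filtering uses an elliptic IIR
design (sharp transitions at low order) split into the mu/beta sub-bands
8-18 Hz and 18-32 Hz; for offline analysis it is applied forward-backward
(zero phase) so filtering never shifts the analysis window in time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from mivote.dataset_io import EpochSet

__all__ = [
    "LaplacianSpec",
    "FilterSpec",
    "WindowSpec",
    "surface_laplacian",
    "bandpass",
    "extract_window",
]


def _default_neighbors() -> dict[str, list[str]]:
    return {
        "C3": ["FC3", "CP3", "C1", "C5"],
        "Cz": ["FCz", "CPz", "C1", "C2"],
        "C4": ["FC4", "CP4", "C2", "C6"],
    }


@dataclass
class LaplacianSpec:
    """Hjorth small-Laplacian montage: centers, neighbours and weights.

    Default weights are +1 for the center and -1/4 per neighbour, so the
    weights sum to zero and any common-mode signal is rejected.
    """

    centers: list[str] = field(default_factory=lambda: ["C3", "Cz", "C4"])
    neighbors: dict[str, list[str]] = field(default_factory=_default_neighbors)
    weights: dict[str, list[float]] | None = None

    def weight_list(self, center: str) -> list[float]:
        if self.weights is not None and center in self.weights:
            return list(self.weights[center])
        n = len(self.neighbors[center])
        return [-1.0 / n] * n

    def validate(self, montage: list[str]) -> None:
        for c in self.centers:
            if c not in montage:
                raise ValueError(f"Laplacian center {c!r} missing from montage")
            for nb in self.neighbors.get(c, []):
                if nb not in montage:
                    raise ValueError(
                        f"Laplacian neighbour {nb!r} of {c!r} missing from montage"
                    )
            w = self.weight_list(c)
            if len(w) != len(self.neighbors[c]):
                raise ValueError(f"weight count mismatch for center {c!r}")
            if abs(1.0 + sum(w)) > 1e-9:
                raise ValueError(
                    f"weights for {c!r} must sum to -1 (center +1 included): {w}"
                )


@dataclass
class FilterSpec:
    """Elliptic band-pass filter design parameters."""

    band: tuple[float, float] = (8.0, 32.0)
    family: str = "elliptic"
    order: int = 4
    # 0.25 dB design ripple: forward-backward application squares the
    # response, so the worst-case end-to-end passband loss stays below 6%
    passband_ripple_db: float = 0.25
    stopband_atten_db: float = 40.0
    application: str = "zero-phase"  # or "causal"

    def validate(self, fs: float) -> None:
        low, high = self.band
        if not 0 < low < high < fs / 2:
            raise ValueError(
                f"band {self.band} must satisfy 0 < low < high < Nyquist ({fs / 2})"
            )
        if self.order < 2:
            raise ValueError(f"order must be >= 2, got {self.order}")
        if self.family != "elliptic":
            raise ValueError(f"unsupported filter family {self.family!r}")
        if self.application not in ("zero-phase", "causal"):
            raise ValueError(f"unknown application mode {self.application!r}")

    def sos(self, fs: float) -> np.ndarray:
        self.validate(fs)
        return signal.ellip(
            self.order,
            self.passband_ripple_db,
            self.stopband_atten_db,
            self.band,
            btype="bandpass",
            fs=fs,
            output="sos",
        )


@dataclass
class WindowSpec:
    """Analysis window relative to the imagery-cue anchor.

    ``anchor`` is the imagery onset within the trial (3 s by default);
    the window covers ``[anchor + offset, anchor + offset + length]``.
    """

    offset: float = 0.0
    length: float = 2.0
    anchor: float = 3.0

    def validate(self) -> None:
        if not -0.5 <= self.offset <= 0.5:
            raise ValueError(f"offset must be in [-0.5, 0.5] s, got {self.offset}")
        if not 1.0 <= self.length <= 3.0:
            raise ValueError(f"length must be in [1.0, 3.0] s, got {self.length}")


def surface_laplacian(epochs: EpochSet, spec: LaplacianSpec | None = None) -> EpochSet:
    """Reduce the montage to the Laplacian centers.

    Each output channel is ``center + sum(w_i * neighbour_i)``; with the
    default weights that is the center minus the neighbour mean.
    """
    spec = spec or LaplacianSpec()
    spec.validate(epochs.channel_names)
    out = np.empty((epochs.n_trials, len(spec.centers), epochs.n_samples))
    for j, center in enumerate(spec.centers):
        acc = epochs.data[:, epochs.channel_index(center), :].copy()
        for nb, w in zip(spec.neighbors[center], spec.weight_list(center)):
            acc += w * epochs.data[:, epochs.channel_index(nb), :]
        out[:, j, :] = acc
    return EpochSet(
        data=out,
        fs=epochs.fs,
        channel_names=list(spec.centers),
        labels=list(epochs.labels),
        trial_t0=epochs.trial_t0,
        meta={**epochs.meta, "laplacian": ",".join(spec.centers)},
    )


def bandpass(epochs: EpochSet, spec: FilterSpec) -> EpochSet:
    """Apply the elliptic band-pass to every trial and channel.

    Zero-phase mode runs the filter forward and backward (no group delay,
    squared magnitude response); causal mode runs it once.
    """
    sos = spec.sos(epochs.fs)
    if spec.application == "zero-phase":
        filtered = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    else:
        filtered = signal.sosfilt(sos, epochs.data, axis=-1)
    return EpochSet(
        data=np.ascontiguousarray(filtered),
        fs=epochs.fs,
        channel_names=list(epochs.channel_names),
        labels=list(epochs.labels),
        trial_t0=epochs.trial_t0,
        meta={**epochs.meta, "bandpass": f"{spec.band[0]}-{spec.band[1]}Hz"},
    )


def extract_window(epochs: EpochSet, w: WindowSpec) -> EpochSet:
    """Cut the analysis window ``[anchor+offset, anchor+offset+length]``.

    The output holds exactly ``round(length * fs)`` samples per trial.
    """
    w.validate()
    start_t = w.anchor + w.offset
    n_out = int(round(w.length * epochs.fs))
    start = int(round((start_t - epochs.trial_t0) * epochs.fs))
    stop = start + n_out
    if start < 0 or stop > epochs.n_samples:
        raise ValueError(
            f"window [{start_t:.3f}, {start_t + w.length:.3f}] s maps to samples "
            f"[{start}, {stop}) outside trial [0, {epochs.n_samples})"
        )
    return EpochSet(
        data=epochs.data[:, :, start:stop].copy(),
        fs=epochs.fs,
        channel_names=list(epochs.channel_names),
        labels=list(epochs.labels),
        trial_t0=start_t,
        meta={**epochs.meta, "window": f"{start_t:.3f}+{w.length:.3f}s"},
    )
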
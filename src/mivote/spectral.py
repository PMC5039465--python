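"""Short-time-FFT amplitude and phase features.

Each channel is cut into Hamming-tapered segments (64 samples, 50%
overlap by default; 64/250 Hz = 0.256 s), DFT-transformed, and the
modulus and argument of the complex coefficients are averaged over
segments and over the frequency bins of each configured band.  Phase
averaging is circular: the angle of the mean unit phasor, since the
arithmetic mean of wrapped angles is ill-defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mivote.dataset_io import EpochSet
from mivote.feature_matrix import FeatureMatrix

__all__ = ["SpectralSpec", "TFDecomposition", "stft", "spectral_features"]


@dataclass
class SpectralSpec:
    """Segmentation and band configuration for the spectral features."""

    seg_len: int = 64
    hop: int = 32
    taper: str = "hamming"
    bands: list[tuple[float, float]] = field(default_factory=lambda: [(8.0, 34.0)])

    def validate(self) -> None:
        if not 1 <= self.hop <= self.seg_len:
            raise ValueError(f"hop must be in [1, seg_len], got {self.hop}")
        if self.taper != "hamming":
            raise ValueError(f"unsupported taper {self.taper!r}")

    def segment_duration_s(self, fs: float) -> float:
        """Segment duration in seconds (0.256 s at the 64/250 Hz defaults)."""
        return self.seg_len / fs


@dataclass
class TFDecomposition:
    """Amplitude/phase time-frequency grid from the sliding tapered DFT.

    ``amplitude[s, k]`` is the modulus and ``phase[s, k]`` the principal
    argument of DFT bin ``k`` of segment ``s``; bins with zero amplitude
    carry phase 0 by convention.
    """

    amplitude: np.ndarray
    phase: np.ndarray
    bin_freqs: np.ndarray


def stft(x: np.ndarray, fs: float, spec: SpectralSpec | None = None) -> TFDecomposition:
    """Sliding Hamming-tapered DFT of a single channel.

    One amplitude/phase spectrum per hop position; only the nonnegative
    frequency bins are returned.
    """
    spec = spec or SpectralSpec()
    spec.validate()
    x = np.asarray(x, dtype=float)
    if len(x) < spec.seg_len:
        raise ValueError(
            f"signal of {len(x)} samples shorter than one segment ({spec.seg_len})"
        )
    window = np.hamming(spec.seg_len)
    n_segs = 1 + (len(x) - spec.seg_len) // spec.hop
    segs = np.stack(
        [x[i * spec.hop : i * spec.hop + spec.seg_len] * window for i in range(n_segs)]
    )
    coeffs = np.fft.rfft(segs, axis=1)
    amplitude = np.abs(coeffs)
    phase = np.angle(coeffs)
    phase[amplitude == 0.0] = 0.0
    return TFDecomposition(
        amplitude=amplitude,
        phase=phase,
        bin_freqs=np.fft.rfftfreq(spec.seg_len, d=1.0 / fs),
    )


def _band_mask(bin_freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    # half-open membership [low, high) so adjacent sub-bands never share a bin
    low, high = band
    mask = (bin_freqs >= low) & (bin_freqs < high)
    if not mask.any():
        raise ValueError(f"band {band} Hz contains no FFT bin")
    return mask


def _circular_mean(phases: np.ndarray) -> float:
    z = np.exp(1j * phases).mean()
    if abs(z) < 1e-12:
        return 0.0
    return float(np.angle(z))


def spectral_features(epochs: EpochSet, spec: SpectralSpec | None = None) -> FeatureMatrix:
    """Mean amplitude and circular-mean phase per channel and band.

    Produces ``n_channels * len(bands) * 2`` features per trial, named
    ``"<channel>|<low>-<high>Hz|amp"`` / ``"...|phase"``.
    """
    spec = spec or SpectralSpec()
    spec.validate()
    names: list[str] = []
    for ch in epochs.channel_names:
        for band in spec.bands:
            tag = f"{ch}|{band[0]:g}-{band[1]:g}Hz"
            names.append(f"{tag}|amp")
            names.append(f"{tag}|phase")

    values = np.empty((epochs.n_trials, len(names)))
    for i in range(epochs.n_trials):
        col = 0
        for c in range(epochs.n_channels):
            tf = stft(epochs.data[i, c], epochs.fs, spec)
            for band in spec.bands:
                mask = _band_mask(tf.bin_freqs, band)
                values[i, col] = tf.amplitude[:, mask].mean()
                values[i, col + 1] = _circular_mean(tf.phase[:, mask])
                col += 2
    return FeatureMatrix(values=values, feature_names=names, labels=list(epochs.labels))
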
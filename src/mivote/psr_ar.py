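"""Phase-space reconstruction and autoregressive (Burg) features.

A scalar EEG time series ``x_1..x_N`` is embedded into an m-dimensional
trajectory by time delays: row i of the trajectory is
``(x_i, x_{i+tau}, ..., x_{i+(m-1)tau})`` with exactly
``M = N - (m-1)*tau`` rows.  Each trajectory column (the signal delayed by
``j*tau``) is then modelled as an AR(p) process

    y(t) = sum_{i=1..p} alpha_i * y(t-i) + eps_t

with coefficients estimated by Burg's method (minimum forward+backward
prediction error), and the p coefficients of each embedding dimension are
averaged into a single feature, giving ``n_channels * n_bands * m``
features per trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.regression.linear_model import burg as _burg

from mivote.dataset_io import EpochSet
from mivote.feature_matrix import FeatureMatrix
from mivote.preprocessing import FilterSpec, bandpass

__all__ = [
    "EmbeddingSpec",
    "Trajectory",
    "ArSpec",
    "reconstruct_phase_space",
    "fit_ar",
    "psr_ar_features",
]


@dataclass
class EmbeddingSpec:
    """Time-delay embedding parameters (dimension m, delay tau in samples)."""

    m: int = 3
    tau: int = 6

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"embedding dimension m must be >= 1, got {self.m}")
        if self.tau < 1:
            raise ValueError(f"delay tau must be >= 1, got {self.tau}")

    @property
    def t_w(self) -> int:
        """Embedding time window (m-1)*tau in samples."""
        return (self.m - 1) * self.tau


@dataclass
class Trajectory:
    """Reconstructed phase-space trajectory, shape ``(M, m)``.

    Column j equals the input delayed by ``j*tau`` and truncated to M
    samples; ``M = N - (m-1)*tau`` exactly.
    """

    matrix: np.ndarray
    spec: EmbeddingSpec

    @property
    def M(self) -> int:
        return self.matrix.shape[0]

    @property
    def m(self) -> int:
        return self.matrix.shape[1]


def reconstruct_phase_space(x: np.ndarray, spec: EmbeddingSpec) -> Trajectory:
    """Time-delay embedding of a 1-D series; pure index shifts, no interpolation."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    big_m = n - spec.t_w
    if big_m <= 0:
        raise ValueError(
            f"empty trajectory: N={n}, (m-1)*tau={spec.t_w} gives M={big_m} <= 0"
        )
    cols = [x[j * spec.tau : j * spec.tau + big_m] for j in range(spec.m)]
    return Trajectory(matrix=np.stack(cols, axis=1), spec=spec)


@dataclass
class ArSpec:
    """AR model order and the sub-bands the features are computed in."""

    p: int = 6
    method: str = "burg"
    bands: list[tuple[float, float]] = field(
        default_factory=lambda: [(8.0, 18.0), (18.0, 32.0)]
    )

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError(f"AR order must be >= 1, got {self.p}")
        if self.method != "burg":
            raise ValueError(f"unsupported AR method {self.method!r}")


def fit_ar(y: np.ndarray, spec: ArSpec | None = None) -> np.ndarray:
    """Burg AR coefficients ``alpha_1..alpha_p`` of a 1-D series.

    Sign convention: prediction = + sum(alpha_i * y(t-i)).  A constant
    (zero-variance) input has no AR structure; it yields all-zero
    coefficients with a warning rather than an error so batch feature
    extraction over degenerate trials keeps going.
    """
    spec = spec or ArSpec()
    y = np.asarray(y, dtype=float)
    if len(y) <= spec.p:
        raise ValueError(f"series of {len(y)} samples too short for AR({spec.p})")
    centered = y - y.mean()
    if np.allclose(centered, 0.0):
        warnings.warn("constant input: returning zero AR coefficients", RuntimeWarning)
        return np.zeros(spec.p)
    rho, _sigma2 = _burg(y, order=spec.p, demean=True)
    return np.asarray(rho, dtype=float)


def psr_ar_features(
    epochs: EpochSet,
    emb: EmbeddingSpec | None = None,
    ar: ArSpec | None = None,
    filters: list[FilterSpec] | None = None,
) -> FeatureMatrix:
    """One averaged-AR-coefficient feature per channel, band and dimension.

    For each trial, channel and band: the band-filtered signal is embedded,
    an AR(p) model is fitted to each trajectory column, and the p
    coefficients of column j are averaged into the dimension-j feature.
    Features are named ``"<channel>|<low>-<high>Hz|ar|d<j>"``.
    """
    emb = emb or EmbeddingSpec()
    ar = ar or ArSpec()
    if filters is None:
        filters = [FilterSpec(band=b) for b in ar.bands]

    banded = [bandpass(epochs, f) for f in filters]

    names: list[str] = []
    for ch in epochs.channel_names:
        for f in filters:
            for j in range(emb.m):
                names.append(f"{ch}|{f.band[0]:g}-{f.band[1]:g}Hz|ar|d{j}")

    values = np.empty((epochs.n_trials, len(names)))
    for i in range(epochs.n_trials):
        col = 0
        for c in range(epochs.n_channels):
            for be in banded:
                traj = reconstruct_phase_space(be.data[i, c], emb)
                if traj.M <= ar.p:
                    raise ValueError(
                        f"trajectory columns of {traj.M} samples too short for "
                        f"AR({ar.p})"
                    )
                for j in range(emb.m):
                    coeffs = fit_ar(traj.matrix[:, j], ar)
                    values[i, col] = coeffs.mean()
                    col += 1
    return FeatureMatrix(values=values, feature_names=names, labels=list(epochs.labels))
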
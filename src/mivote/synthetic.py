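"""Synthetic ERD/ERS motor-imagery session generator.

Real motor imagery attenuates the mu (~8-12 Hz) and beta (~18-32 Hz)
sensorimotor rhythms over the contralateral hand area (event-related
desynchronization, ERD).  The generator emulates exactly that statistical
structure and nothing more: each central electrode carries a narrowband mu
oscillator (plus a beta oscillator at half amplitude) bleeding at 50%
strength into its Laplacian neighbours, on top of white plus 1/f-shaped
background noise.  During the imagery interval the rhythm of the electrode
mapped to the trial's class (RH -> C3, LH -> C4, F -> Cz) is
power-attenuated by ``erd_depth``; the beta rhythm is co-modulated at half
that depth.

The output is deterministic given the config seed, so the full pipeline is
testable end-to-end without recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from mivote.dataset_io import EpochSet

__all__ = ["SynthConfig", "generate_session", "band_power", "DEFAULT_MONTAGE"]

#: 15-channel central montage: the three Laplacian centers, their
#: neighbours, and two midline background channels.
DEFAULT_MONTAGE = [
    "C3", "Cz", "C4",
    "FC3", "CP3", "C1", "C5",
    "FCz", "CPz", "C2",
    "FC4", "CP4", "C6",
    "Fz", "Pz",
]

#: Neighbour map used to spread each center's rhythm at 50% amplitude.
CENTER_NEIGHBORS = {
    "C3": ["FC3", "CP3", "C1", "C5"],
    "Cz": ["FCz", "CPz", "C1", "C2"],
    "C4": ["FC4", "CP4", "C2", "C6"],
}

#: Class-to-electrode ERD mapping (contralateral hand areas; feet at vertex).
CLASS_ELECTRODE = {"RH": "C3", "LH": "C4", "F": "Cz"}


@dataclass
class SynthConfig:
    """Parameters of the synthetic session.

    ``erd_depth`` is the fractional band-power attenuation of the
    class-mapped rhythm during imagery (0 = no class information,
    1 = rhythm fully suppressed).  The seed fully determines the output.
    """

    n_trials_per_class: int = 60
    fs: float = 250.0
    trial_dur: float = 7.0
    mi_start: float = 3.0
    mi_dur: float = 3.0
    erd_depth: float = 0.5
    mu_band: tuple[float, float] = (9.0, 12.0)
    beta_band: tuple[float, float] = (19.0, 25.0)
    mu_amp: float = 5.0
    noise_sigma: float = 2.0
    amp_jitter: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError(f"erd_depth must be in [0, 1], got {self.erd_depth}")
        if self.mi_start + self.mi_dur > self.trial_dur + 1e-9:
            raise ValueError("mi_start + mi_dur exceeds trial_dur")


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance noise with an approximately 1/f power spectrum."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # avoid the DC singularity
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _mi_envelope(n: int, fs: float, mi_start: float, mi_dur: float,
                 scale: float, ramp: float = 0.05) -> np.ndarray:
    """Amplitude envelope: 1 outside imagery, ``scale`` inside, cosine ramps."""
    t = np.arange(n) / fs
    a, b = mi_start, mi_start + mi_dur
    env = np.ones(n)
    env[(t >= a) & (t < b)] = scale
    # cosine ramps at the two transitions to avoid broadband clicks
    down = (t >= a - ramp) & (t < a)
    env[down] = scale + (1 - scale) * 0.5 * (
        1 + np.cos(np.pi * (t[down] - (a - ramp)) / ramp)
    )
    up = (t >= b) & (t < b + ramp)
    env[up] = scale + (1 - scale) * 0.5 * (
        1 - np.cos(np.pi * (t[up] - b) / ramp)
    )
    return env


def generate_session(cfg: SynthConfig, montage: list[str] | None = None) -> EpochSet:
    """Generate a balanced, labelled synthetic motor-imagery session.

    Each class contributes ``cfg.n_trials_per_class`` trials.  Identical
    config and seed yield bit-identical output.
    """
    montage = list(montage) if montage is not None else list(DEFAULT_MONTAGE)
    for center in CENTER_NEIGHBORS:
        if center not in montage:
            raise ValueError(f"montage missing center electrode {center!r}")

    rng = np.random.default_rng(cfg.seed)
    n_samp = int(round(cfg.trial_dur * cfg.fs))
    t = np.arange(n_samp) / cfg.fs
    classes = ["LH", "RH", "F"]
    labels = [c for c in classes for _ in range(cfg.n_trials_per_class)]

    data = np.empty((len(labels), len(montage), n_samp), dtype=np.float64)
    ch_index = {name: i for i, name in enumerate(montage)}

    for i_trial, label in enumerate(labels):
        # background noise on every channel
        trial = np.empty((len(montage), n_samp))
        for c in range(len(montage)):
            white = rng.normal(scale=1.0, size=n_samp)
            pink = _pink_noise(rng, n_samp)
            trial[c] = cfg.noise_sigma * (0.7 * white + 0.3 * pink)

        target = CLASS_ELECTRODE[label]
        for center, neighbors in CENTER_NEIGHBORS.items():
            # narrowband rhythms with per-trial random frequency and phase
            f_mu = rng.uniform(*cfg.mu_band)
            f_beta = rng.uniform(*cfg.beta_band)
            amp = cfg.mu_amp * (1.0 + cfg.amp_jitter * rng.normal())
            amp = max(amp, 0.0)
            mu = amp * np.sin(2 * np.pi * f_mu * t + rng.uniform(0, 2 * np.pi))
            beta = 0.5 * amp * np.sin(
                2 * np.pi * f_beta * t + rng.uniform(0, 2 * np.pi)
            )
            if center == target:
                env_mu = _mi_envelope(
                    n_samp, cfg.fs, cfg.mi_start, cfg.mi_dur,
                    np.sqrt(1.0 - cfg.erd_depth),
                )
                env_beta = _mi_envelope(
                    n_samp, cfg.fs, cfg.mi_start, cfg.mi_dur,
                    np.sqrt(1.0 - cfg.erd_depth / 2.0),
                )
                mu = mu * env_mu
                beta = beta * env_beta
            rhythm = mu + beta
            trial[ch_index[center]] += rhythm
            for nb in neighbors:
                if nb in ch_index:
                    trial[ch_index[nb]] += 0.5 * rhythm
        data[i_trial] = trial

    return EpochSet(
        data=data,
        fs=cfg.fs,
        channel_names=montage,
        labels=labels,
        trial_t0=0.0,
        meta={
            "generator": "mivote.synthetic",
            "erd_depth": str(cfg.erd_depth),
            "seed": str(cfg.seed),
        },
    )


def band_power(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Mean squared amplitude of ``x`` restricted to ``band`` (Hz).

    Integrates the periodogram over the band, so a unit sinusoid inside the
    band yields approximately 0.5 (its variance).
    """
    low, high = band
    if not 0 < low < high < fs / 2:
        raise ValueError(f"band {band} must satisfy 0 < low < high < fs/2")
    x = np.asarray(x, dtype=float)
    f, pxx = signal.periodogram(x, fs=fs, detrend=False)
    mask = (f >= low) & (f <= high)
    if not mask.any():
        raise ValueError(f"band {band} contains no spectral bins")
    df = f[1] - f[0]
    return float(np.sum(pxx[mask]) * df)
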
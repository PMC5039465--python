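"""Nested pipeline configuration with strict schema validation.

Every stage reads its parameters from one :class:`PipelineConfig`; sweeps
mutate copies of it programmatically.  Unknown keys are rejected with the
failing key path so config typos never pass silently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

__all__ = ["PipelineConfig"]


def _bands(value) -> list[tuple[float, float]]:
    return [tuple(float(v) for v in b) for b in value]


@dataclass
class LaplacianConfig:
    centers: list[str] = field(default_factory=lambda: ["C3", "Cz", "C4"])
    neighbors: dict[str, list[str]] | None = None


@dataclass
class FilterConfig:
    order: int = 4
    ripple_db: float = 0.25
    atten_db: float = 40.0
    application: str = "zero-phase"


@dataclass
class WindowConfig:
    offset: float = 0.0
    length: float = 2.0
    anchor: float = 3.0


@dataclass
class SpectralConfig:
    seg_len: int = 64
    hop: int = 32
    bands: list = field(default_factory=lambda: [(8.0, 34.0)])


@dataclass
class PsrConfig:
    m: int = 3
    tau: int = 6


@dataclass
class ArConfig:
    order: int = 6
    bands: list = field(default_factory=lambda: [(8.0, 18.0), (18.0, 32.0)])


@dataclass
class SffsConfig:
    enabled: bool = True
    inner_folds: int = 5
    max_features: int = 25


@dataclass
class ClfConfig:
    type: str = "multi-lda"  # multi-lda | multi-svm | knn
    svm_c: float = 1.0
    knn_k: int = 5
    none_counts_as_error: bool = True


@dataclass
class CvConfig:
    folds: int = 9


@dataclass
class SynthSection:
    n_trials_per_class: int = 60
    erd_depth: float = 0.5
    noise_sigma: float = 2.0
    amp_jitter: float = 0.1


_SECTIONS = {
    "laplacian": LaplacianConfig,
    "filter": FilterConfig,
    "window": WindowConfig,
    "spectral": SpectralConfig,
    "psr": PsrConfig,
    "ar": ArConfig,
    "sffs": SffsConfig,
    "clf": ClfConfig,
    "cv": CvConfig,
    "synth": SynthSection,
}


def _build_section(cls, d: dict, path: str):
    valid = {f.name for f in fields(cls)}
    unknown = sorted(set(d) - valid)
    if unknown:
        raise KeyError(f"unknown config key(s) {path}.{unknown[0]}")
    kwargs = dict(d)
    if "bands" in kwargs:
        kwargs["bands"] = _bands(kwargs["bands"])
    return cls(**kwargs)


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, one nested section per stage."""

    laplacian: LaplacianConfig = field(default_factory=LaplacianConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    window: WindowConfig = field(default_factory=WindowConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    psr: PsrConfig = field(default_factory=PsrConfig)
    ar: ArConfig = field(default_factory=ArConfig)
    sffs: SffsConfig = field(default_factory=SffsConfig)
    clf: ClfConfig = field(default_factory=ClfConfig)
    cv: CvConfig = field(default_factory=CvConfig)
    synth: SynthSection = field(default_factory=SynthSection)
    seed: int = 0
    version: str = "1"

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d or {})
        kwargs: dict[str, Any] = {}
        for key in list(d):
            if key in _SECTIONS:
                section = d.pop(key)
                if not isinstance(section, dict):
                    raise TypeError(f"config section {key!r} must be a mapping")
                kwargs[key] = _build_section(_SECTIONS[key], section, key)
        for key in ("seed", "version"):
            if key in d:
                kwargs[key] = d.pop(key)
        if d:
            raise KeyError(f"unknown config key(s) {sorted(d)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(doc)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for section in ("spectral", "ar"):
            d[section]["bands"] = [list(b) for b in d[section]["bands"]]
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def replace(self, **overrides) -> "PipelineConfig":
        """Copy with replaced sections (used by sweeps)."""
        return dataclasses.replace(self, **overrides)
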
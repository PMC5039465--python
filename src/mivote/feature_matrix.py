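"""Trials-by-features container with named provenance per feature."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FeatureMatrix"]


@dataclass
class FeatureMatrix:
    """A ``(n_trials, n_features)`` matrix with per-feature names and labels.

    Feature names encode provenance (channel, band, extractor, dimension),
    e.g. ``"C3|8-34Hz|amp"`` or ``"Cz|8-18Hz|ar|d2"``, so selected subsets
    remain interpretable.
    """

    values: np.ndarray
    feature_names: list[str]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {self.values.shape}")
        if not np.isfinite(self.values).all():
            raise ValueError("values contain non-finite entries")
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.feature_names)} names for {self.values.shape[1]} features"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if self.labels and len(self.labels) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.values.shape[0]} trials"
            )

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels)

    def restrict_classes(self, classes: tuple[str, str]) -> "FeatureMatrix":
        """Rows whose label is in ``classes`` (for per-pair selection/training)."""
        mask = np.isin(self.label_array(), classes)
        return FeatureMatrix(
            values=self.values[mask],
            feature_names=list(self.feature_names),
            labels=[lab for lab, m in zip(self.labels, mask) if m],
        )

    @staticmethod
    def hstack(parts: list["FeatureMatrix"]) -> "FeatureMatrix":
        """Concatenate feature blocks for the same trials."""
        if not parts:
            raise ValueError("nothing to concatenate")
        n = parts[0].n_trials
        for p in parts:
            if p.n_trials != n:
                raise ValueError("trial counts differ between feature blocks")
        names: list[str] = []
        for p in parts:
            names.extend(p.feature_names)
        return FeatureMatrix(
            values=np.hstack([p.values for p in parts]),
            feature_names=names,
            labels=list(parts[0].labels),
        )
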
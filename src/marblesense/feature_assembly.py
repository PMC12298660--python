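"""Per-block feature vectors: LBP histogram + colour statistics, min-max scaled.

The classifier input for each block is the 59-bin uniform-LBP histogram
concatenated with six colour statistics per selected colour space, giving
65 / 71 / 77 dimensions for LBP+RGB, LBP+RGB+HSV and LBP+RGB+HSV+LAB
respectively.  All features are scaled to [0, 1] with per-dimension min-max
bounds learned from the training split only; test-time values outside the
training range are clipped, and constant (degenerate) dimensions map to 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.preprocessing import MinMaxScaler

from .color_features import ColorStats
from .texture_lbp import LBPHistogram

#: combination id -> ordered tuple of colour spaces appended after the LBP bins
COMBINATIONS = {
    "LBP_RGB": ("RGB",),
    "LBP_HSV": ("HSV",),
    "LBP_LAB": ("LAB",),
    "LBP_RGB_HSV": ("RGB", "HSV"),
    "LBP_RGB_HSV_LAB": ("RGB", "HSV", "LAB"),
}

DEFAULT_COMBINATION = "LBP_RGB"


def expected_length(combination: str, n_lbp_bins: int = 59) -> int:
    """Feature dimensionality: LBP bins + 6 per colour space (65/71/77 for P=8)."""
    return n_lbp_bins + 6 * len(COMBINATIONS[combination])


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    combination: str
    scaled: bool = False

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


def assemble_features(
    hist: LBPHistogram, stats: list[ColorStats], combination: str = DEFAULT_COMBINATION
) -> FeatureVector:
    """Concatenate [LBP bins | 6 colour stats per space] in the declared order."""
    if combination not in COMBINATIONS:
        raise ValueError(f"unknown combination {combination!r}; expected one of {list(COMBINATIONS)}")
    wanted = COMBINATIONS[combination]
    got = tuple(s.colorspace for s in stats)
    if got != wanted:
        raise ValueError(f"combination {combination} needs colour stats {wanted}, got {got}")
    parts = [hist.bins] + [s.values for s in stats]
    return FeatureVector(values=np.concatenate(parts), combination=combination)


class FeatureScaler:
    """Per-dimension min-max scaler fitted on the training split.

    Thin wrapper over sklearn's MinMaxScaler with clipping; its zero-range
    handling maps constant dimensions to 0 exactly.
    """

    def __init__(self):
        self._scaler = MinMaxScaler(feature_range=(0.0, 1.0), clip=True)
        self.n_features: int | None = None

    @property
    def mins(self) -> np.ndarray:
        return self._scaler.data_min_

    @property
    def maxs(self) -> np.ndarray:
        return self._scaler.data_max_

    def fit(self, matrix: np.ndarray) -> "FeatureScaler":
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] < 2:
            raise ValueError(f"need a 2-D matrix with >= 2 training vectors, got shape {matrix.shape}")
        self._scaler.fit(matrix)
        self.n_features = matrix.shape[1]
        return self

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
        if self.n_features is None:
            raise ValueError("scaler not fitted")
        if matrix.shape[1] != self.n_features:
            raise ValueError(
                f"vector length {matrix.shape[1]} does not match scaler dimensionality {self.n_features}"
            )
        return self._scaler.transform(matrix)

    def inverse_transform(self, matrix: np.ndarray) -> np.ndarray:
        return self._scaler.inverse_transform(np.atleast_2d(np.asarray(matrix, dtype=float)))

    def to_json(self) -> str:
        return json.dumps(
            {
                "dims": self.n_features,
                "mins": self.mins.tolist(),
                "maxs": self.maxs.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureScaler":
        payload = json.loads(text)
        obj = cls()
        mins = np.asarray(payload["mins"], dtype=float)
        maxs = np.asarray(payload["maxs"], dtype=float)
        # refit on the two bounding rows; reproduces min/max exactly
        obj.fit(np.vstack([mins, maxs]))
        return obj


def fit_scaler(training_vectors: list[FeatureVector]) -> FeatureScaler:
    lengths = {len(v.values) for v in training_vectors}
    if len(training_vectors) < 2:
        raise ValueError("need at least 2 training vectors")
    if len(lengths) != 1:
        raise ValueError(f"inconsistent feature-vector lengths: {sorted(lengths)}")
    matrix = np.vstack([v.values for v in training_vectors])
    return FeatureScaler().fit(matrix)


def apply_scaler(scaler: FeatureScaler, vector: FeatureVector) -> FeatureVector:
    scaled = scaler.transform(vector.values[np.newaxis, :])[0]
    return FeatureVector(values=scaled, combination=vector.combination, scaled=True)
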
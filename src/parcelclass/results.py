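"""Result containers shared by the classification and inference stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["AccuracyMap", "PermutationNull", "MapComparison", "DifferenceVector"]


@dataclass
class AccuracyMap:
    """Parcel -> classification accuracy, optionally with FWE-corrected p-values.

    ``parcel_ids`` may include 0 for the whole-brain connectome analysis.
    """

    parcel_ids: np.ndarray
    accuracy: np.ndarray
    p_fwe: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.parcel_ids = np.asarray(self.parcel_ids, dtype=int)
        self.accuracy = np.asarray(self.accuracy, dtype=float)
        if self.parcel_ids.shape != self.accuracy.shape:
            raise ValueError("parcel_ids and accuracy must have equal length")
        ok = np.isnan(self.accuracy) | ((self.accuracy >= 0) & (self.accuracy <= 1))
        if not np.all(ok):
            raise ValueError("accuracies must lie in [0, 1]")
        if self.p_fwe is not None:
            self.p_fwe = np.asarray(self.p_fwe, dtype=float)
            if self.p_fwe.shape != self.parcel_ids.shape:
                raise ValueError("p_fwe length mismatch")

    def __len__(self) -> int:
        return len(self.parcel_ids)

    def accuracy_of(self, parcel_id: int) -> float:
        idx = np.flatnonzero(self.parcel_ids == parcel_id)
        if not idx.size:
            raise KeyError(f"parcel id {parcel_id} not in map")
        return float(self.accuracy[idx[0]])

    def to_frame(self, atlas=None) -> pd.DataFrame:
        names = None
        if atlas is not None:
            lookup = dict(zip(atlas.parcel_ids, atlas.names))
            names = [lookup.get(int(p), "whole_brain" if p == 0 else "?") for p in self.parcel_ids]
        df = pd.DataFrame({"parcel_id": self.parcel_ids, "accuracy": self.accuracy})
        if names is not None:
            df.insert(1, "name", names)
        if self.p_fwe is not None:
            df["p_fwe"] = self.p_fwe
        return df


@dataclass
class PermutationNull:
    """Per-permutation maximum accuracies over the parcel family."""

    max_accuracies: np.ndarray
    n_permutations: int
    seed: int

    def __post_init__(self):
        self.max_accuracies = np.asarray(self.max_accuracies, dtype=float)
        if len(self.max_accuracies) != self.n_permutations:
            raise ValueError("max_accuracies length must equal n_permutations")
        if np.any((self.max_accuracies < 0) | (self.max_accuracies > 1)):
            raise ValueError("accuracies must lie in [0, 1]")


@dataclass(frozen=True)
class MapComparison:
    """Spearman rank correlation between two accuracy maps."""

    rho: float
    p_value: float
    n_parcels: int

    def __post_init__(self):
        if not (-1.0 <= self.rho <= 1.0 or np.isnan(self.rho)):
            raise ValueError("rho must lie in [-1, 1]")


@dataclass
class DifferenceVector:
    """Male-minus-female mean Fisher-Z connectivity for one parcel's edges."""

    parcel_id: int
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("difference vector must be finite")
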
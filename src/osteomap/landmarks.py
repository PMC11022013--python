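"""Per-specimen landmark configurations."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class LandmarkConfiguration:
    """One specimen's K x 3 landmark coordinates (mm) with a missing mask.

    Missing landmarks carry NaN coordinates and a True entry in
    ``missing``; they are never encoded as sentinel numbers.
    """

    specimen_id: str
    coords: np.ndarray                      # K x 3, NaN where missing
    missing: np.ndarray = None              # K booleans
    species: str | None = None
    age_group: int | None = None
    side: str = "right"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be K x 3")
        if self.missing is None:
            self.missing = np.any(np.isnan(self.coords), axis=1)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != (self.coords.shape[0],):
            raise ValueError("missing mask must have one entry per landmark")
        present = self.coords[~self.missing]
        if present.size and not np.all(np.isfinite(present)):
            raise ValueError(
                f"{self.specimen_id}: non-missing coordinates must be finite")

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]

    @property
    def is_complete(self) -> bool:
        return not self.missing.any()

    def copy(self) -> "LandmarkConfiguration":
        return replace(self, coords=self.coords.copy(),
                       missing=self.missing.copy(), meta=dict(self.meta))


def centroid_size(coords: np.ndarray) -> float:
    """Centroid size: sqrt of summed squared landmark distances from the
    configuration centroid."""
    coords = np.asarray(coords, dtype=float)
    centred = coords - coords.mean(axis=0)
    return float(np.sqrt(np.sum(centred ** 2)))
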
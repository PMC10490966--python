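"""Core raster containers: spectral scenes, class maps, ground-truth points."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .legend import Legend


@dataclass
class SpectralScene:
    """Multi-band reflectance grid for one epoch.

    ``bands`` is a (B, rows, cols) float array of surface reflectances.
    ``band_roles`` maps semantic roles (at least ``"red"`` and ``"nir"``) to
    band indices. ``nodata_mask`` is True where pixels carry no data.
    """

    bands: np.ndarray
    band_roles: dict[str, int]
    nodata_mask: np.ndarray
    pixel_size_m: float = 30.0
    epoch_label: str = ""

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=float)
        if self.bands.ndim != 3:
            raise ValueError("bands must be a (B, rows, cols) array")
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.bands.shape[1:]:
            raise ValueError("nodata_mask shape must match the grid")
        nb = self.bands.shape[0]
        for role in ("red", "nir"):
            if role not in self.band_roles:
                raise ValueError(f"band role {role!r} is required")
            if not 0 <= self.band_roles[role] < nb:
                raise ValueError(f"band role {role!r} index out of range")
        if self.band_roles["red"] == self.band_roles["nir"]:
            raise ValueError("red and NIR roles must refer to distinct bands")
        valid = self.bands[:, ~self.nodata_mask]
        if valid.size and (not np.all(np.isfinite(valid)) or valid.min() < 0):
            raise ValueError("reflectances must be finite and >= 0 outside the nodata mask")

    @property
    def n_bands(self) -> int:
        return self.bands.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands.shape[1:]

    def pixel_vectors(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Band vectors at the given pixel positions, shape (n, B)."""
        return self.bands[:, rows, cols].T


@dataclass
class ClassMap:
    """Categorical land-cover grid; 0 marks nodata, other codes per legend."""

    classes: np.ndarray
    legend: Legend
    pixel_size_m: float = 30.0
    epoch_label: str = ""

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes)
        if self.classes.ndim != 2:
            raise ValueError("classes must be a 2-D grid")
        if not np.issubdtype(self.classes.dtype, np.integer):
            raise ValueError("class grid must be integer-typed")
        if self.pixel_size_m <= 0:
            raise ValueError("pixel_size_m must be > 0")
        present = np.unique(self.classes)
        unknown = [int(c) for c in present if c != 0 and c not in self.legend]
        if unknown:
            raise ValueError(f"class codes {unknown} not in legend")

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.classes == 0

    @property
    def pixel_area_ha(self) -> float:
        return self.pixel_size_m**2 / 10_000.0


@dataclass
class GroundTruthSet:
    """Labelled reference points: (row, col, class_code) triples."""

    points: list[tuple[int, int, int]] = field(default_factory=list)
    epoch_label: str = ""

    def __len__(self) -> int:
        return len(self.points)

    @property
    def rows(self) -> np.ndarray:
        return np.array([p[0] for p in self.points], dtype=int)

    @property
    def cols(self) -> np.ndarray:
        return np.array([p[1] for p in self.points], dtype=int)

    @property
    def labels(self) -> np.ndarray:
        return np.array([p[2] for p in self.points], dtype=int)

    def validate_against(self, grid_shape: tuple[int, int], legend: Legend,
                         nodata_mask: np.ndarray | None = None) -> None:
        r, c, lab = self.rows, self.cols, self.labels
        if len(self) == 0:
            raise ValueError("empty ground-truth set")
        if np.any((r < 0) | (r >= grid_shape[0]) | (c < 0) | (c >= grid_shape[1])):
            raise ValueError("ground-truth point outside the grid")
        bad = [int(x) for x in np.unique(lab) if x not in legend]
        if bad:
            raise ValueError(f"ground-truth labels {bad} not in legend")
        if nodata_mask is not None and np.any(nodata_mask[r, c]):
            raise ValueError("ground-truth point falls on nodata")
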
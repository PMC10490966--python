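"""Synthetic multi-epoch land-cover scenes with known statistical structure.

The generator emulates the data a post-classification change study consumes:
a categorical land-cover grid evolving across epochs under a known first-order
Markov transition matrix, per-class multivariate-Gaussian band reflectances
(so a Gaussian maximum-likelihood classifier is well specified), a fixed
nodata mask, and labelled ground-truth samples. Pixels evolve independently —
exactly the per-pixel bookkeeping a transition-matrix analysis assumes — so
every downstream statistic has a closed-form expectation.

Randomness: one master seed per :class:`SceneSpec`; sub-streams are spawned
deterministically per epoch and per operation, so e.g. adding epochs does not
perturb earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .legend import (BARREN, BUILT_UP, CULTIVATED, DEFAULT_LEGEND, FORESTLAND,
                     GRASSLAND, WATER, Legend)
from .scene import ClassMap, GroundTruthSet, SpectralScene

_PROB_TOL = 1e-9

# Stream labels for deterministic sub-seeding (see SceneSpec.rng_for).
_STREAM_CLASSES = 0
_STREAM_SPECTRA = 1
_STREAM_NODATA = 2
_STREAM_TRUTH = 3


@dataclass
class BandModel:
    """Per-class spectral model: mean vector and covariance over B bands."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        b = self.mean.shape[0]
        if self.covariance.shape != (b, b):
            raise ValueError("covariance shape must match band count")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-12):
            raise ValueError("covariance must be symmetric")
        w = np.linalg.eigvalsh(self.covariance)
        if w.min() < -1e-10 * max(1.0, w.max()):
            raise ValueError("covariance must be positive semi-definite")

    def sqrt_factor(self) -> np.ndarray:
        """Symmetric PSD square root (handles singular covariances exactly)."""
        w, v = np.linalg.eigh(self.covariance)
        return v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T


@dataclass
class SceneSpec:
    """Full recipe for a reproducible multi-epoch synthetic scene."""

    grid_rows: int
    grid_cols: int
    epochs: list[str]
    initial_class_proportions: np.ndarray
    transition_probabilities: np.ndarray
    band_models: dict[int, BandModel]
    band_roles: dict[str, int] = field(default_factory=lambda: {"blue": 0, "green": 1, "red": 2, "nir": 3})
    legend: Legend = DEFAULT_LEGEND
    pixel_size_m: float = 30.0
    nodata_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("epoch list must not be empty")
        k = len(self.legend)
        p0 = np.asarray(self.initial_class_proportions, dtype=float)
        if p0.shape != (k,):
            raise ValueError(f"initial proportions must have length {k}")
        if abs(p0.sum() - 1.0) > _PROB_TOL or p0.min() < 0:
            raise ValueError("initial proportions must be nonnegative and sum to 1")
        self.initial_class_proportions = p0
        pt = np.asarray(self.transition_probabilities, dtype=float)
        if pt.shape != (k, k):
            raise ValueError(f"transition matrix must be {k}x{k}")
        if pt.min() < 0 or np.any(np.abs(pt.sum(axis=1) - 1.0) > _PROB_TOL):
            raise ValueError("transition rows must be nonnegative and sum to 1 (row-stochastic)")
        self.transition_probabilities = pt
        if not 0 <= self.nodata_fraction < 1:
            raise ValueError("nodata_fraction must lie in [0, 1)")

    def rng_for(self, stream: int, index: int = 0) -> np.random.Generator:
        """Deterministic sub-stream for an (operation, epoch) pair."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stream, index)))


def _default_band_models() -> dict[int, BandModel]:
    # 4 bands (blue, green, red, NIR), reflectance scale [0, 1]. Means are
    # placed so each class-mean NDVI falls inside that class's density bin
    # (water < -0.03; barren/built-up in (-0.03, 0.15); cultivated in
    # (0.15, 0.25); grassland in (0.25, 0.35); forest > 0.35) and so classes
    # are many Mahalanobis units apart at the default noise level.
    sigma = 0.008
    means = {
        FORESTLAND: [0.030, 0.060, 0.040, 0.450],   # NDVI 0.837
        CULTIVATED: [0.095, 0.115, 0.140, 0.200],   # NDVI 0.176
        GRASSLAND: [0.070, 0.095, 0.095, 0.175],    # NDVI 0.296
        BUILT_UP: [0.160, 0.170, 0.180, 0.200],     # NDVI 0.053
        BARREN: [0.200, 0.220, 0.250, 0.280],       # NDVI 0.057
        WATER: [0.080, 0.070, 0.060, 0.030],        # NDVI -0.333
    }
    cov = (sigma**2) * np.eye(4)
    return {code: BandModel(np.array(m), cov.copy()) for code, m in means.items()}


def default_scene_spec(grid_rows: int = 200, grid_cols: int = 200, *,
                       nodata_fraction: float = 0.02, seed: int = 0,
                       noise_scale: float = 1.0) -> SceneSpec:
    """Study-like default: 6 classes, 4 epochs, 30 m pixels, 200x200 grid.

    Initial proportions follow the published 1984 shares of the highland case
    study (forest 10.8%, grassland 26.5%, water 6.9%); the split of the
    remaining area over cultivated/built-up/barren is a package choice. The
    transition matrix encodes the study's qualitative dynamics: forest,
    grassland and water lose area to cultivation and settlement, which only
    gain. ``noise_scale`` multiplies every class covariance (1.0 keeps classes
    well separated; larger values degrade classification accuracy on purpose).
    """
    p0 = np.array([0.108, 0.330, 0.265, 0.100, 0.128, 0.069])
    pt = np.array([
        # to: forest cult  grass built barren water     (from:)
        [0.920, 0.040, 0.025, 0.010, 0.005, 0.000],  # forest
        [0.000, 0.960, 0.000, 0.035, 0.005, 0.000],  # cultivated
        [0.000, 0.060, 0.890, 0.035, 0.015, 0.000],  # grassland
        [0.000, 0.000, 0.000, 1.000, 0.000, 0.000],  # built-up
        [0.000, 0.030, 0.000, 0.030, 0.940, 0.000],  # barren
        [0.000, 0.110, 0.020, 0.020, 0.050, 0.800],  # water
    ])
    models = _default_band_models()
    if noise_scale != 1.0:
        models = {c: BandModel(m.mean, m.covariance * noise_scale**2) for c, m in models.items()}
    return SceneSpec(
        grid_rows=grid_rows, grid_cols=grid_cols,
        epochs=["1984", "1991", "2001", "2021"],
        initial_class_proportions=p0, transition_probabilities=pt,
        band_models=models, nodata_fraction=nodata_fraction, seed=seed,
    )


def _nodata_mask(spec: SceneSpec) -> np.ndarray:
    # Sampled once and held fixed across epochs so cross-tabulation is
    # defined on a constant support.
    if spec.nodata_fraction == 0:
        return np.zeros((spec.grid_rows, spec.grid_cols), dtype=bool)
    rng = spec.rng_for(_STREAM_NODATA)
    return rng.random((spec.grid_rows, spec.grid_cols)) < spec.nodata_fraction


def generate_class_series(spec: SceneSpec) -> list[ClassMap]:
    """Simulate one :class:`ClassMap` per epoch under the Markov spec.

    Epoch 1 is sampled i.i.d. from the initial proportions; each later epoch
    samples every pixel's next class from its current class's transition row,
    independently across pixels. Nodata pixels are 0 in every epoch.
    """
    codes = np.array(spec.legend.codes)
    shape = (spec.grid_rows, spec.grid_cols)
    nodata = _nodata_mask(spec)

    cum0 = np.cumsum(spec.initial_class_proportions)
    u = spec.rng_for(_STREAM_CLASSES, 0).random(shape)
    idx = np.searchsorted(cum0, u, side="right").clip(max=len(codes) - 1)

    cum_t = np.cumsum(spec.transition_probabilities, axis=1)
    maps: list[ClassMap] = []
    for e, label in enumerate(spec.epochs):
        if e > 0:
            u = spec.rng_for(_STREAM_CLASSES, e).random(shape)
            # vectorised row-wise inverse-CDF sampling of the next state
            idx = (u[..., None] > cum_t[idx]).sum(axis=-1).clip(max=len(codes) - 1)
        grid = codes[idx].astype(np.int16)
        grid[nodata] = 0
        maps.append(ClassMap(grid, spec.legend, spec.pixel_size_m, label))
    return maps


def render_spectra(class_map: ClassMap, spec: SceneSpec, *, epoch_index: int | None = None) -> SpectralScene:
    """Draw each pixel's band vector from its class's Gaussian band model."""
    present = [int(c) for c in np.unique(class_map.classes) if c != 0]
    missing = [c for c in present if c not in spec.band_models]
    if missing:
        raise ValueError(f"no band model for observed class(es) {missing}")

    if epoch_index is None:
        epoch_index = spec.epochs.index(class_map.epoch_label) if class_map.epoch_label in spec.epochs else 0
    rng = spec.rng_for(_STREAM_SPECTRA, epoch_index)

    n_bands = len(next(iter(spec.band_models.values())).mean)
    rows, cols = class_map.shape
    z = rng.standard_normal((rows, cols, n_bands))
    bands = np.zeros((rows, cols, n_bands))
    for code in present:
        model = spec.band_models[code]
        sel = class_map.classes == code
        bands[sel] = model.mean + z[sel] @ model.sqrt_factor().T
    np.clip(bands, 0.0, None, out=bands)  # reflectances are physically >= 0
    bands = np.moveaxis(bands, -1, 0)
    bands[:, class_map.nodata_mask] = 0.0
    return SpectralScene(bands, dict(spec.band_roles), class_map.nodata_mask,
                         class_map.pixel_size_m, class_map.epoch_label)


def sample_ground_truth(class_map: ClassMap, n_per_class: int, seed: int,
                        *, epoch_index: int = 0) -> GroundTruthSet:
    """Sample ``n_per_class`` reference pixels per class, without replacement.

    Emulates a GPS ground-truth campaign with a balanced design (the case
    study used 50 points per class). Labels are taken from the map itself.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAM_TRUTH, epoch_index)))
    points: list[tuple[int, int, int]] = []
    for code in class_map.legend.codes:
        rr, cc = np.nonzero(class_map.classes == code)
        if rr.size < n_per_class:
            raise ValueError(
                f"class {code} has {rr.size} pixels, fewer than n_per_class={n_per_class}")
        pick = rng.choice(rr.size, size=n_per_class, replace=False)
        points.extend((int(rr[i]), int(cc[i]), int(code)) for i in pick)
    return GroundTruthSet(points, class_map.epoch_label)


def empirical_transition_matrix(map_a: ClassMap, map_b: ClassMap) -> np.ndarray:
    """Row-normalised class-transition frequencies between two epochs.

    Independent check that a generated series follows its Markov spec.
    """
    codes = map_a.legend.codes
    k = len(codes)
    code_to_idx = {c: i for i, c in enumerate(codes)}
    a, b = map_a.classes.ravel(), map_b.classes.ravel()
    ok = (a != 0) & (b != 0)
    ia = np.array([code_to_idx[int(c)] for c in a[ok]])
    ib = np.array([code_to_idx[int(c)] for c in b[ok]])
    counts = np.bincount(ia * k + ib, minlength=k * k).reshape(k, k).astype(float)
    row = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(row > 0, counts / row, np.nan)
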
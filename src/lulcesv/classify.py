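"""Supervised Gaussian maximum-likelihood classification and NDVI binning.

The maximum-likelihood classifier models each land-cover class's spectral
response as a multivariate Gaussian fitted from training samples and assigns
every pixel the class with the greatest log-likelihood (equal priors). NDVI,
(NIR − R)/(NIR + R), is computed from the red and near-infrared bands and
thresholded into five vegetation-density classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .legend import NDVI_LEGEND, Legend
from .scene import ClassMap, GroundTruthSet, SpectralScene

# Ridge applied when an empirical covariance is numerically singular:
# eps = RIDGE_REL * mean(diagonal) added to the diagonal whenever the smallest
# eigenvalue is < SINGULAR_REL * largest.
RIDGE_REL = 1e-6
SINGULAR_REL = 1e-10

#: Vegetation-density thresholds on NDVI; half-open lower-inclusive bins
#: [-1, -0.03), [-0.03, 0.15), [0.15, 0.25), [0.25, 0.35), [0.35, 1].
NDVI_BIN_EDGES = (-0.03, 0.15, 0.25, 0.35)


@dataclass
class ClassSignature:
    """Training statistics for one class: mean and covariance over B bands."""

    class_code: int
    mean: np.ndarray
    covariance: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("signature covariance must be symmetric")


def _regularize(cov: np.ndarray) -> np.ndarray:
    w = np.linalg.eigvalsh(cov)
    largest = max(w.max(), 0.0)
    if w.min() < SINGULAR_REL * max(largest, 1e-300):
        mean_diag = float(np.trace(cov)) / cov.shape[0]
        eps = RIDGE_REL * mean_diag if mean_diag > 0 else RIDGE_REL
        cov = cov + eps * np.eye(cov.shape[0])
    return cov


def fit_signatures(scene: SpectralScene, truth: GroundTruthSet,
                   legend: Legend | None = None) -> list[ClassSignature]:
    """Fit per-class spectral means and covariances from training points.

    Uses the unbiased (n−1) empirical covariance; a small ridge eps·I is
    added when the covariance is numerically singular (e.g. tiny or
    degenerate training sets). Requires ≥2 points per class, off nodata.
    """
    if len(truth) == 0:
        raise ValueError("empty ground-truth set")
    if legend is not None:
        truth.validate_against(scene.shape, legend, scene.nodata_mask)
    rows, cols, labels = truth.rows, truth.cols, truth.labels
    if np.any(scene.nodata_mask[rows, cols]):
        raise ValueError("training point falls on nodata")
    x = scene.pixel_vectors(rows, cols)
    sigs: list[ClassSignature] = []
    for code in np.unique(labels):
        sel = labels == code
        n = int(sel.sum())
        if n < 2:
            raise ValueError(f"class {int(code)} has {n} training point(s); need >= 2")
        xs = x[sel]
        mean = xs.mean(axis=0)
        cov = np.cov(xs, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        sigs.append(ClassSignature(int(code), mean, _regularize(cov), n))
    return sigs


def classify_max_likelihood(scene: SpectralScene,
                            signatures: list[ClassSignature],
                            legend: Legend | None = None) -> ClassMap:
    """Assign each pixel the class maximising the Gaussian log-density.

    Score per class k: −½ [ln det Σ_k + (x − μ_k)ᵀ Σ_k⁻¹ (x − μ_k)], i.e.
    plain maximum likelihood with equal priors. Ties break toward the lowest
    class code; nodata pixels stay 0.
    """
    if not signatures:
        raise ValueError("at least one signature is required")
    sigs = sorted(signatures, key=lambda s: s.class_code)
    b = scene.n_bands
    for s in sigs:
        if s.mean.shape[0] != b:
            raise ValueError(
                f"signature for class {s.class_code} has {s.mean.shape[0]} bands, scene has {b}")

    valid = ~scene.nodata_mask
    x = scene.bands[:, valid].T  # (n, B)
    scores = np.empty((x.shape[0], len(sigs)))
    for j, s in enumerate(sigs):
        cov = _regularize(s.covariance)
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            raise np.linalg.LinAlgError(f"non-PD covariance for class {s.class_code}")
        diff = x - s.mean
        maha = np.einsum("ij,ij->i", diff, np.linalg.solve(cov, diff.T).T)
        scores[:, j] = -0.5 * (logdet + maha)
    best = np.argmax(scores, axis=1)  # first max -> lowest class code wins ties

    grid = np.zeros(scene.shape, dtype=np.int16)
    codes = np.array([s.class_code for s in sigs], dtype=np.int16)
    grid[valid] = codes[best]
    if legend is None:
        from .legend import DEFAULT_LEGEND
        legend = DEFAULT_LEGEND
    return ClassMap(grid, legend, scene.pixel_size_m, scene.epoch_label)


@dataclass
class NdviGrid:
    """NDVI values in [−1, 1]; NaN where undefined (nodata or NIR + R = 0)."""

    values: np.ndarray
    pixel_size_m: float = 30.0
    epoch_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        defined = self.values[np.isfinite(self.values)]
        if defined.size and (defined.min() < -1 or defined.max() > 1):
            raise ValueError("defined NDVI values must lie in [-1, 1]")

    @property
    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


def compute_ndvi(scene: SpectralScene) -> NdviGrid:
    """NDVI = (NIR − R)/(NIR + R) per pixel; undefined where NIR + R = 0."""
    red = scene.bands[scene.band_roles["red"]]
    nir = scene.bands[scene.band_roles["nir"]]
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        ndvi = np.where(denom > 0, (nir - red) / denom, np.nan)
    ndvi[scene.nodata_mask] = np.nan
    # round-off guard only: clamp excursions smaller than 1e-12 beyond [-1, 1]
    tiny = (np.abs(ndvi) > 1) & (np.abs(ndvi) <= 1 + 1e-12)
    ndvi[tiny] = np.sign(ndvi[tiny])
    return NdviGrid(ndvi, scene.pixel_size_m, scene.epoch_label)


def bin_ndvi(grid: NdviGrid) -> ClassMap:
    """Threshold NDVI into the five vegetation-density classes.

    Bins are half-open and lower-inclusive ([−1, −0.03), [−0.03, 0.15),
    [0.15, 0.25), [0.25, 0.35)) with the top bin closed at 1, so shared
    published endpoints are assigned upward. Undefined pixels become nodata.
    """
    vals = grid.values
    out = np.zeros(vals.shape, dtype=np.int16)
    defined = grid.defined_mask
    out[defined] = 1 + np.digitize(vals[defined], NDVI_BIN_EDGES, right=False)
    return ClassMap(out, NDVI_LEGEND, grid.pixel_size_m, grid.epoch_label)
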
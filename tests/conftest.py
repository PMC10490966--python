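import numpy as np
import pytest
from hypothesis import settings

from lulcesv import BandModel, Legend, LegendEntry, SceneSpec, default_scene_spec

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


_SENTINEL = object()


def make_legend(k: int) -> Legend:
    return Legend(tuple(LegendEntry(i + 1, f"class_{i + 1}") for i in range(k)))


def make_spec(k=2, rows=50, cols=50, p0=None, pt=None, seed=0, sigma=0.01,
              means=None, nodata_fraction=0.0, epochs=_SENTINEL) -> SceneSpec:
    """Minimal k-class scene spec with diagonal-covariance band models."""
    legend = make_legend(k)
    if p0 is None:
        p0 = np.full(k, 1.0 / k)
    if pt is None:
        pt = np.eye(k)
    if means is None:
        # spread class means along the NIR band, distinct red values
        means = [np.array([0.05, 0.05, 0.05 + 0.02 * i, 0.1 + 0.1 * i]) for i in range(k)]
    models = {i + 1: BandModel(np.asarray(means[i]), sigma**2 * np.eye(4)) for i in range(k)}
    return SceneSpec(
        grid_rows=rows, grid_cols=cols,
        epochs=["e1", "e2"] if epochs is _SENTINEL else epochs,
        initial_class_proportions=np.asarray(p0),
        transition_probabilities=np.asarray(pt),
        band_models=models, legend=legend, nodata_fraction=nodata_fraction, seed=seed,
    )


@pytest.fixture
def six_class_spec() -> SceneSpec:
    return default_scene_spec(100, 100, nodata_fraction=0.02, seed=7)
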
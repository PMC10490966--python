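"""File interchange for scenes, class maps, ground truth and signatures.

Rasters are written as plain TIFF (via tifffile) with a ``<name>.tif.json``
sidecar holding grid metadata (pixel size, epoch label, band roles, nodata
convention), which keeps every artifact either standard-raster or plain text.
Class maps are single-band integer TIFFs with 0 = nodata; spectral scenes are
multi-band float32 TIFFs; NDVI grids are float32 with NaN where undefined.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .classify import ClassSignature, NdviGrid
from .legend import Legend, LegendEntry
from .scene import ClassMap, GroundTruthSet, SpectralScene


def _write_sidecar(path: Path, meta: dict) -> None:
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2) + "\n")


def _read_sidecar(path: Path) -> dict:
    return json.loads(Path(str(path) + ".json").read_text())


# -- spectral scenes ---------------------------------------------------------

def write_scene(scene: SpectralScene, path: str | Path) -> None:
    path = Path(path)
    data = scene.bands.astype(np.float32).copy()
    data[:, scene.nodata_mask] = np.nan
    tifffile.imwrite(path, data, photometric="minisblack", planarconfig="separate")
    _write_sidecar(path, {
        "kind": "spectral_scene",
        "pixel_size_m": scene.pixel_size_m,
        "epoch_label": scene.epoch_label,
        "band_roles": scene.band_roles,
        "nodata": "NaN in every band",
    })


def read_scene(path: str | Path) -> SpectralScene:
    path = Path(path)
    data = tifffile.imread(path)
    meta = _read_sidecar(path)
    nodata = np.all(np.isnan(data), axis=0)
    data = np.nan_to_num(data, nan=0.0)
    return SpectralScene(data, {k: int(v) for k, v in meta["band_roles"].items()},
                         nodata, float(meta["pixel_size_m"]), meta.get("epoch_label", ""))


# -- class maps --------------------------------------------------------------

def write_class_map(class_map: ClassMap, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, class_map.classes.astype(np.int16))
    _write_sidecar(path, {
        "kind": "class_map",
        "pixel_size_m": class_map.pixel_size_m,
        "epoch_label": class_map.epoch_label,
        "nodata": 0,
        "legend": [
            {"code": e.code, "name": e.name, "description": e.description}
            for e in class_map.legend.entries
        ],
    })


def read_class_map(path: str | Path) -> ClassMap:
    path = Path(path)
    grid = tifffile.imread(path).astype(np.int16)
    meta = _read_sidecar(path)
    legend = Legend(tuple(
        LegendEntry(int(e["code"]), e["name"], e.get("description", ""))
        for e in meta["legend"]
    ))
    return ClassMap(grid, legend, float(meta["pixel_size_m"]), meta.get("epoch_label", ""))


# -- NDVI grids --------------------------------------------------------------

def write_ndvi(grid: NdviGrid, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, grid.values.astype(np.float32))
    _write_sidecar(path, {
        "kind": "ndvi",
        "pixel_size_m": grid.pixel_size_m,
        "epoch_label": grid.epoch_label,
        "nodata": "NaN",
    })


def read_ndvi(path: str | Path) -> NdviGrid:
    path = Path(path)
    meta = _read_sidecar(path)
    return NdviGrid(tifffile.imread(path).astype(float),
                    float(meta["pixel_size_m"]), meta.get("epoch_label", ""))


# -- ground truth ------------------------------------------------------------

def write_ground_truth(truth: GroundTruthSet, path: str | Path) -> None:
    pd.DataFrame(truth.points, columns=["row", "col", "class_code"]).to_csv(path, index=False)


def read_ground_truth(path: str | Path, epoch_label: str = "") -> GroundTruthSet:
    df = pd.read_csv(path)
    pts = [(int(r), int(c), int(k)) for r, c, k in
           zip(df["row"], df["col"], df["class_code"])]
    return GroundTruthSet(pts, epoch_label)


# -- class signatures --------------------------------------------------------

def write_signatures(signatures: list[ClassSignature], path: str | Path) -> None:
    """One row per class: code, n_samples, band means, flattened covariance."""
    rows = []
    for s in signatures:
        b = s.mean.shape[0]
        row = {"class_code": s.class_code, "n_samples": s.n_samples, "n_bands": b}
        row.update({f"mean_{i}": s.mean[i] for i in range(b)})
        row.update({f"cov_{i}_{j}": s.covariance[i, j] for i in range(b) for j in range(b)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_signatures(path: str | Path) -> list[ClassSignature]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        b = int(row["n_bands"])
        mean = np.array([row[f"mean_{i}"] for i in range(b)])
        cov = np.array([[row[f"cov_{i}_{j}"] for j in range(b)] for i in range(b)])
        out.append(ClassSignature(int(row["class_code"]), mean, cov, int(row["n_samples"])))
    return out
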
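"""End-to-end orchestration: simulate → classify → assess → change → value.

:func:`run_pipeline` executes the full analysis from a :class:`RunConfig`
and writes every intermediate artifact plus a checksum manifest, so a rerun
with the same seed is byte-identical and each stage can be re-driven from the
files the previous one wrote.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as lio
from .accuracy import accuracy_report, build_confusion
from .change import area_change_table, class_areas, cross_tabulate
from .classify import bin_ndvi, classify_max_likelihood, compute_ndvi, fit_signatures
from .scene import ClassMap
from .synthetic import (SceneSpec, default_scene_spec, generate_class_series,
                        render_spectra, sample_ground_truth)
from .valuation import (build_esv_report, build_sensitivity_table,
                        implied_area, load_coefficients)


class PipelineError(RuntimeError):
    """Raised when a stage fails; carries the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration for a full run (YAML-loadable, flag-overridable)."""

    out_dir: str = "lulcesv_run"
    seed: int = 0
    grid_rows: int = 200
    grid_cols: int = 200
    nodata_fraction: float = 0.02
    noise_scale: float = 1.0
    n_truth_per_class: int = 50
    coefficients: str | None = None       # None -> packaged default table
    epoch_pairs: list[tuple[str, str]] | None = None
    rounding: str = "paper"               # percent-change convention
    perturbation: float = 0.5
    scene_dir: str | None = None          # load scenes+truth instead of simulating

    def __post_init__(self) -> None:
        if not 0 < self.perturbation < 1:
            raise ValueError("perturbation must lie in (0, 1)")
        if self.rounding not in ("paper", "raw"):
            raise ValueError("rounding must be 'paper' or 'raw'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        pairs = data.get("epoch_pairs")
        if pairs:
            data["epoch_pairs"] = [tuple(p) for p in pairs]
        return cls(**data)


@dataclass
class Manifest:
    """Artifact listing with SHA-256 checksums, for audit and determinism checks."""

    artifacts: dict[str, str] = field(default_factory=dict)

    def add(self, root: Path, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.artifacts[str(path.relative_to(root))] = digest

    def write(self, path: Path) -> None:
        path.write_text(json.dumps({"artifacts": self.artifacts}, indent=2, sort_keys=True) + "\n")


def _epoch_pairs(epochs: list[str], config: RunConfig) -> list[tuple[str, str]]:
    if config.epoch_pairs:
        bad = [p for p in config.epoch_pairs for e in p if e not in epochs]
        if bad:
            raise PipelineError("config", f"epoch pair(s) {bad} reference undeclared epochs")
        return config.epoch_pairs
    pairs = list(zip(epochs[:-1], epochs[1:]))
    if len(epochs) > 2:
        pairs.append((epochs[0], epochs[-1]))
    return pairs


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write a report bundle under ``config.out_dir``.

    Returns a summary dict with the manifest path and headline numbers.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest()

    try:
        coeffs = load_coefficients(config.coefficients)
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise PipelineError("coefficients", str(exc)) from exc

    # -- simulate (or load) ---------------------------------------------
    try:
        spec: SceneSpec = default_scene_spec(
            config.grid_rows, config.grid_cols,
            nodata_fraction=config.nodata_fraction, seed=config.seed,
            noise_scale=config.noise_scale)
        true_maps = generate_class_series(spec)
        scenes = [render_spectra(m, spec, epoch_index=i) for i, m in enumerate(true_maps)]
        truths = [sample_ground_truth(m, config.n_truth_per_class, config.seed, epoch_index=i)
                  for i, m in enumerate(true_maps)]
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc
    epochs = spec.epochs

    for i, ep in enumerate(epochs):
        lio.write_scene(scenes[i], out / f"scene_{ep}.tif")
        lio.write_ground_truth(truths[i], out / f"truth_{ep}.csv")

    # -- classify + NDVI -------------------------------------------------
    classified: list[ClassMap] = []
    accuracy: dict[str, dict] = {}
    try:
        for i, ep in enumerate(epochs):
            sigs = fit_signatures(scenes[i], truths[i], spec.legend)
            lio.write_signatures(sigs, out / f"signatures_{ep}.csv")
            cmap = classify_max_likelihood(scenes[i], sigs, spec.legend)
            classified.append(cmap)
            lio.write_class_map(cmap, out / f"classified_{ep}.tif")
            ndvi = compute_ndvi(scenes[i])
            lio.write_ndvi(ndvi, out / f"ndvi_{ep}.tif")
            lio.write_class_map(bin_ndvi(ndvi), out / f"ndvi_classes_{ep}.tif")
    except Exception as exc:
        raise PipelineError("classify", str(exc)) from exc

    # -- accuracy ---------------------------------------------------------
    try:
        for i, ep in enumerate(epochs):
            cm = build_confusion(classified[i], truths[i])
            cm.to_frame().to_csv(out / f"confusion_{ep}.csv")
            accuracy[ep] = accuracy_report(cm)
        (out / "accuracy.json").write_text(json.dumps(accuracy, indent=2) + "\n")
    except Exception as exc:
        raise PipelineError("accuracy", str(exc)) from exc

    # -- change detection -------------------------------------------------
    try:
        areas = pd.DataFrame({ep: class_areas(m) for ep, m in zip(epochs, classified)})
        areas.to_csv(out / "areas_ha.csv")
        pairs = _epoch_pairs(epochs, config)
        area_change_table(areas, pairs).to_csv(out / "change_rates.csv", index=False)
        for a, b in pairs:
            tm = cross_tabulate(classified[epochs.index(a)], classified[epochs.index(b)])
            tm.to_frame().to_csv(out / f"transition_{a}_{b}.csv")
    except Exception as exc:
        raise PipelineError("change", str(exc)) from exc

    # -- valuation + sensitivity ------------------------------------------
    try:
        report = build_esv_report(areas, coeffs, pairs, rounding=config.rounding)
        report.esv_class.to_csv(out / "esv_by_class_usd.csv")
        report.esv_function.to_csv(out / "esv_by_function_usd.csv")
        report.change_class_pct.to_csv(out / "esv_class_change_pct.csv")
        report.change_function_pct.to_csv(out / "esv_function_change_pct.csv")
        report.change_total.to_csv(out / "esv_total_change.csv")
        sens = build_sensitivity_table(areas, coeffs, config.perturbation)
        sens.to_csv(out / "sensitivity.csv", index=False)
        summary = {
            "epochs": epochs,
            "unit": "USD",
            "coefficient_table_sha256": _file_or_default_checksum(config.coefficients),
            "esv_totals_usd": {ep: float(report.totals[ep]) for ep in epochs},
            "overall_accuracy": {ep: accuracy[ep]["overall_accuracy"] for ep in epochs},
            "kappa": {ep: accuracy[ep]["kappa"] for ep in epochs},
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("valuation", str(exc)) from exc

    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest.add(out, p)
    manifest.write(out / "manifest.json")
    summary["manifest"] = str(out / "manifest.json")
    return summary


def _file_or_default_checksum(path: str | None) -> str:
    from importlib import resources
    if path is None:
        data = (resources.files("lulcesv.data") / "value_coefficients.csv").read_bytes()
    else:
        data = Path(path).read_bytes()
    return hashlib.sha256(data).hexdigest()


def run_valuation_only(areas_by_epoch: pd.DataFrame, coeffs=None, *,
                       epoch_pairs: list[tuple[str, str]] | None = None,
                       rounding: str = "paper", perturbation: float = 0.5,
                       class_esv_overrides: dict[str, dict[int, float]] | None = None):
    """Valuation sub-pipeline on area tables alone (no rasters).

    ``class_esv_overrides`` maps epoch → {class_code: ESV in US$} for classes
    whose area is unknown but whose value is: the implied area
    ESV_k / Σ_f VC_kf is substituted before valuation (exact, by linearity).
    Returns ``(ESVReport, sensitivity DataFrame)``.
    """
    if coeffs is None:
        coeffs = load_coefficients()
    areas = areas_by_epoch.copy().astype(float)
    if class_esv_overrides:
        for ep, overrides in class_esv_overrides.items():
            for code, esv in overrides.items():
                areas.loc[code, ep] = implied_area(esv, coeffs, code)
    if areas.isna().any().any():
        raise ValueError("area table contains missing values after overrides")
    report = build_esv_report(areas, coeffs, epoch_pairs, rounding=rounding)
    if float(report.totals.min()) <= 0:
        raise ValueError("all-zero area table: total ESV is 0, sensitivity undefined")
    sens = build_sensitivity_table(areas, coeffs, perturbation)
    return report, sens
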
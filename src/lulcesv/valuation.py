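"""Benefit-value-transfer ecosystem-service valuation and elasticity.

The benefit-transfer approach prices each land-cover class with a per-hectare
value coefficient VC_kf (US$ ha⁻¹ yr⁻¹, one value per class k and service
function f) borrowed from biome-equivalent studies in the Costanza tradition.
With A_k the class area in hectares:

    ESV_k = A_k · Σ_f VC_kf        (per-class value)
    ESV_f = Σ_k A_k · VC_kf        (per-function value)
    ESV   = Σ_k Σ_f A_k · VC_kf    (total, equal to both marginal sums)

Temporal change is the simple percent change between epoch totals. The
coefficient of sensitivity (CS) is the elasticity of the total ESV with
respect to one class's coefficients: scale class k's whole coefficient row by
(1 + p), recompute the total, and divide the relative ESV response by the
relative coefficient change. For a proportional row perturbation this equals
ESV_k / ESV exactly, so CS is independent of p's sign and magnitude; CS > 1
flags an elastic (coefficient-sensitive) estimate.

The packaged default coefficient table carries the modified conservative
coefficients (17 service functions × 6 classes; tropical-Afromontane biome
equivalents after Kindu et al. 2016 / Costanza et al. 1997): class totals
forest 986.69, cultivated 225.56, grassland 293.25, water 8103.5, with
built-up and barren land priced at zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .legend import DEFAULT_LEGEND, Legend

#: Service-function categories, in table order.
FUNCTION_CATEGORIES = {
    "WS": "provisioning", "FP": "provisioning", "RM": "provisioning", "GR": "provisioning",
    "Gr": "regulatory", "Cr": "regulatory", "Dr": "regulatory", "Hr": "regulatory",
    "EC": "regulatory", "BC": "regulatory", "WT": "regulatory",
    "NC": "supporting", "SF": "supporting", "Ha": "supporting", "Po": "supporting",
    "Re": "recreation_culture", "Cu": "recreation_culture",
}

FUNCTION_NAMES = {
    "WS": "water supply", "FP": "food production", "RM": "raw materials",
    "GR": "genetic resources", "Gr": "gas regulation", "Cr": "climate regulation",
    "Dr": "disturbance regulation", "Hr": "hydrological regulation",
    "EC": "erosion control", "BC": "biological control", "WT": "waste treatment",
    "NC": "nutrient cycling", "SF": "soil formation", "Ha": "habitats",
    "Po": "pollination", "Re": "recreation", "Cu": "cultural",
}

#: Biome equivalents used to transfer coefficients to each land-cover class.
BIOME_EQUIVALENTS = {
    "forestland": "tropical forest",
    "cultivated_land": "croplands",
    "grassland": "grass/rangelands",
    "built_up_area": "urban",
    "barren_land": "desert",
    "water_bodies": "lakes/rivers",
}

_TOTAL_TOL = 0.01


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used for published values)."""
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


@dataclass
class CoefficientTable:
    """Class × service-function value coefficients (US$ ha⁻¹ yr⁻¹).

    ``vc`` is indexed by class code with one column per function code.
    """

    vc: pd.DataFrame
    legend: Legend = DEFAULT_LEGEND

    def __post_init__(self) -> None:
        if (self.vc.values < 0).any():
            raise ValueError("value coefficients must be nonnegative")

    @property
    def functions(self) -> list[str]:
        return list(self.vc.columns)

    @property
    def class_totals(self) -> pd.Series:
        """Σ_f VC_kf per class — the Table-3-style per-class coefficient."""
        return self.vc.sum(axis=1)

    def perturbed(self, class_code: int, fraction: float) -> "CoefficientTable":
        """Copy with class ``class_code``'s coefficient row scaled by (1 + fraction)."""
        vc = self.vc.copy()
        vc.loc[class_code] = vc.loc[class_code] * (1.0 + fraction)
        return CoefficientTable(vc, self.legend)

    def to_csv(self, path: str | Path) -> None:
        """Write in the published layout: rows = functions plus TOTAL, columns = classes."""
        names = self.legend.names
        out = self.vc.T.copy()
        out.columns = [names[c] for c in out.columns]
        out.insert(0, "category", [FUNCTION_CATEGORIES.get(f, "") for f in out.index])
        total = self.class_totals
        out.loc["TOTAL"] = [""] + [total[c] for c in self.vc.index]
        out.index.name = "function"
        out.to_csv(path)


def load_coefficients(source: str | Path | None = None,
                      legend: Legend = DEFAULT_LEGEND) -> CoefficientTable:
    """Load a coefficient table from CSV (default: the packaged table).

    Expected layout: one row per function with a ``function`` column, an
    optional ``category`` column, and one column per class name; blanks read
    as 0. A ``TOTAL`` row, when present, is validated against the per-class
    sums to within 0.01 and then dropped.
    """
    if source is None:
        with resources.as_file(resources.files("lulcesv.data") / "value_coefficients.csv") as p:
            raw = pd.read_csv(p)
    else:
        raw = pd.read_csv(source)
    raw = raw.set_index("function")
    raw = raw.drop(columns=[c for c in ("category",) if c in raw.columns])
    raw = raw.apply(pd.to_numeric, errors="coerce").fillna(0.0)

    declared = None
    if "TOTAL" in raw.index:
        declared = raw.loc["TOTAL"]
        raw = raw.drop(index="TOTAL")

    name_to_code = {e.name: e.code for e in legend.entries}
    unknown = [c for c in raw.columns if c not in name_to_code]
    if unknown:
        raise ValueError(f"coefficient columns {unknown} do not match legend class names")
    vc = raw.T
    vc.index = [name_to_code[n] for n in raw.columns]
    vc = vc.sort_index()
    vc.index.name = "class_code"

    if declared is not None:
        sums = vc.sum(axis=1)
        for name, code in name_to_code.items():
            if name in declared.index and abs(sums[code] - float(declared[name])) > _TOTAL_TOL:
                raise ValueError(
                    f"class {name!r}: coefficient sum {sums[code]:.2f} differs from "
                    f"declared total {float(declared[name]):.2f} by more than {_TOTAL_TOL}")
    table = CoefficientTable(vc, legend)
    if (table.class_totals == 0).all():
        warnings.warn("all value coefficients are zero", stacklevel=2)
    return table


def _check_classes(areas: pd.Series, coeffs: CoefficientTable) -> None:
    missing = [int(c) for c in areas.index if c not in coeffs.vc.index]
    if missing:
        raise KeyError(f"class code(s) {missing} have no value coefficients")


def esv_by_class(areas: pd.Series, coeffs: CoefficientTable) -> pd.Series:
    """ESV_k = A_k · Σ_f VC_kf per class, US$ yr⁻¹ (areas in hectares)."""
    _check_classes(areas, coeffs)
    return areas * coeffs.class_totals.reindex(areas.index)


def esv_by_function(areas: pd.Series, coeffs: CoefficientTable) -> pd.Series:
    """ESV_f = Σ_k A_k · VC_kf per service function, US$ yr⁻¹."""
    _check_classes(areas, coeffs)
    return coeffs.vc.reindex(areas.index).mul(areas, axis=0).sum(axis=0)


def esv_total(areas: pd.Series, coeffs: CoefficientTable) -> float:
    """Total ESV = Σ_k Σ_f A_k · VC_kf; equals both marginal sums."""
    return float(esv_by_class(areas, coeffs).sum())


def esv_percent_change(esv_start: float, esv_end: float,
                       rounding: str = "raw") -> float:
    """Percent change (end − start)/start × 100 between epoch values (US$).

    ``rounding="paper"`` first rounds both values to the nearest 0.1 million
    US$ (half away from zero) — the convention under which published
    one-decimal tables are internally consistent; ``"raw"`` uses the values
    as given.
    """
    if rounding not in ("raw", "paper"):
        raise ValueError("rounding must be 'raw' or 'paper'")
    if rounding == "paper":
        esv_start = round_half_away(esv_start / 1e5) * 1e5
        esv_end = round_half_away(esv_end / 1e5) * 1e5
    if esv_start == 0:
        raise ValueError("percent change undefined for zero start value")
    return (esv_end - esv_start) / esv_start * 100.0


@dataclass
class SensitivityRow:
    """Elasticity of the total ESV to one class's coefficient row."""

    class_code: int
    perturbation: float
    baseline_total: float     # ESV_i
    adjusted_total: float     # ESV_j with VC_k scaled by (1 + perturbation)
    cs: float

    @property
    def elastic(self) -> bool:
        return self.cs > 1.0


def coefficient_sensitivity(areas: pd.Series, coeffs: CoefficientTable,
                            class_code: int, perturbation: float = 0.5) -> SensitivityRow:
    """Coefficient of sensitivity for one class from areas and coefficients.

    CS = [(ESV_j − ESV_i)/ESV_i] / [(VC_jk − VC_ik)/VC_ik], with ESV_j the
    total recomputed after scaling class k's coefficient row by
    (1 + perturbation). Defined as 0 for zero-coefficient classes.
    """
    if not -1.0 < perturbation < 1.0 or perturbation == 0:
        raise ValueError("perturbation must be a nonzero fraction in (-1, 1)")
    baseline = esv_total(areas, coeffs)
    if baseline <= 0:
        raise ValueError("baseline total ESV must be > 0")
    if float(coeffs.class_totals.get(class_code, 0.0)) == 0.0:
        return SensitivityRow(class_code, perturbation, baseline, baseline, 0.0)
    adjusted = esv_total(areas, coeffs.perturbed(class_code, perturbation))
    cs = ((adjusted - baseline) / baseline) / perturbation
    return SensitivityRow(class_code, perturbation, baseline, adjusted, cs)


def sensitivity_from_class_esv(class_esv: Mapping[int, float], class_code: int,
                               perturbation: float = 0.5,
                               zero_coefficient: bool = False) -> SensitivityRow:
    """Coefficient of sensitivity from per-class ESVs alone.

    Because ESV_k is linear in class k's coefficient row, scaling the row by
    (1 + p) moves the total by p·ESV_k; no areas are needed. This serves
    valuations where a class's ESV is known but its area is not.
    ``zero_coefficient`` marks classes priced at zero (CS is 0 by definition).
    """
    if not -1.0 < perturbation < 1.0 or perturbation == 0:
        raise ValueError("perturbation must be a nonzero fraction in (-1, 1)")
    baseline = float(sum(class_esv.values()))
    if baseline <= 0:
        raise ValueError("baseline total ESV must be > 0")
    esv_k = float(class_esv.get(class_code, 0.0))
    if zero_coefficient or esv_k == 0.0:
        return SensitivityRow(class_code, perturbation, baseline, baseline, 0.0)
    adjusted = baseline + perturbation * esv_k
    cs = ((adjusted - baseline) / baseline) / perturbation
    return SensitivityRow(class_code, perturbation, baseline, adjusted, cs)


def implied_area(esv_usd: float, coeffs: CoefficientTable, class_code: int) -> float:
    """Hectares implied by a known class ESV: A_k = ESV_k / Σ_f VC_kf.

    Lets a valuation proceed when a class's published ESV is known but its
    area is not (the two are proportional for nonzero coefficient totals).
    """
    total = float(coeffs.class_totals[class_code])
    if total <= 0:
        raise ValueError(f"class {class_code} has zero coefficient total; area not implied")
    return esv_usd / total


@dataclass
class ESVReport:
    """Per-epoch ESVs plus epoch-pair changes; all raw values in US$ yr⁻¹.

    ``esv_class``/``esv_function`` are indexed by class code / function code
    with one column per epoch; change frames carry absolute (US$) and percent
    change per epoch pair. The conservation identity Σ_k ESV_k = Σ_f ESV_f =
    total holds by construction.
    """

    esv_class: pd.DataFrame
    esv_function: pd.DataFrame
    totals: pd.Series
    change_class_abs: pd.DataFrame
    change_class_pct: pd.DataFrame
    change_function_abs: pd.DataFrame
    change_function_pct: pd.DataFrame
    change_total: pd.DataFrame
    rounding: str = "raw"
    unit: str = "USD"

    def millions(self, frame: pd.DataFrame | pd.Series, ndigits: int = 1):
        """Values in millions of US$, rounded half away from zero."""
        return (frame / 1e6).map(lambda v: round_half_away(v, ndigits))


def _pct_frame(values: pd.DataFrame, pairs: list[tuple[str, str]], rounding: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    abs_ch, pct_ch = {}, {}
    for start, end in pairs:
        key = f"{start}-{end}"
        abs_ch[key] = values[end] - values[start]
        pct = []
        for idx in values.index:
            s, e = float(values.loc[idx, start]), float(values.loc[idx, end])
            try:
                pct.append(esv_percent_change(s, e, rounding))
            except ValueError:  # zero (or zero-rounded) start: change undefined
                pct.append(np.nan)
        pct_ch[key] = pd.Series(pct, index=values.index)
    return pd.DataFrame(abs_ch), pd.DataFrame(pct_ch)


def build_esv_report(areas_by_epoch: pd.DataFrame, coeffs: CoefficientTable,
                     epoch_pairs: list[tuple[str, str]] | None = None,
                     rounding: str = "raw") -> ESVReport:
    """Full valuation of a multi-epoch area table.

    ``areas_by_epoch``: DataFrame indexed by class code, one column per epoch
    label, areas in hectares. ``rounding`` controls only the percent-change
    convention (see :func:`esv_percent_change`).
    """
    epochs = list(areas_by_epoch.columns)
    if epoch_pairs is None:
        epoch_pairs = [(a, b) for a, b in zip(epochs[:-1], epochs[1:])]
        if len(epochs) > 2:
            epoch_pairs.append((epochs[0], epochs[-1]))
    esv_c = pd.DataFrame({ep: esv_by_class(areas_by_epoch[ep], coeffs) for ep in epochs})
    esv_f = pd.DataFrame({ep: esv_by_function(areas_by_epoch[ep], coeffs) for ep in epochs})
    totals = esv_c.sum(axis=0)
    cc_abs, cc_pct = _pct_frame(esv_c, epoch_pairs, rounding)
    cf_abs, cf_pct = _pct_frame(esv_f, epoch_pairs, rounding)
    t_abs, t_pct = _pct_frame(pd.DataFrame({ep: [totals[ep]] for ep in epochs}, index=["total"]),
                              epoch_pairs, rounding)
    change_total = pd.concat([t_abs.T.rename(columns={"total": "abs_usd"}),
                              t_pct.T.rename(columns={"total": "pct"})], axis=1)
    return ESVReport(esv_c, esv_f, totals, cc_abs, cc_pct, cf_abs, cf_pct,
                     change_total, rounding)


def build_sensitivity_table(areas_by_epoch: pd.DataFrame, coeffs: CoefficientTable,
                            perturbation: float = 0.5) -> pd.DataFrame:
    """CS per (class, epoch) under ±``perturbation`` coefficient adjustment.

    The two perturbation signs yield the same CS (the elasticity is exact for
    proportional row scaling); both are computed and reported.
    """
    rows = []
    for ep in areas_by_epoch.columns:
        for code in areas_by_epoch.index:
            up = coefficient_sensitivity(areas_by_epoch[ep], coeffs, int(code), perturbation)
            dn = coefficient_sensitivity(areas_by_epoch[ep], coeffs, int(code), -perturbation)
            rows.append({
                "epoch": ep, "class_code": int(code), "perturbation": perturbation,
                "cs": up.cs, "cs_minus": dn.cs,
                "baseline_total_usd": up.baseline_total,
                "adjusted_total_usd": up.adjusted_total,
                "verdict": "elastic" if up.elastic else "inelastic",
            })
    return pd.DataFrame(rows)
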
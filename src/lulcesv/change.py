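"""Post-classification change detection.

Per-class areas, annualised change rates, and the from×to transition matrix
with per-class gain, loss, net change (Nc = gain − loss) and the
net-change-to-persistence ratio (Np = Nc / unchanged area).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scene import ClassMap


def class_areas(class_map: ClassMap) -> pd.Series:
    """Hectares per legend class (nodata excluded).

    area_ha = pixel count × pixel_size_m² / 10 000; classes absent from the
    map get 0 ha so every epoch shares the same index.
    """
    codes = class_map.legend.codes
    counts = {c: int(np.count_nonzero(class_map.classes == c)) for c in codes}
    areas = pd.Series({c: n * class_map.pixel_area_ha for c, n in counts.items()},
                      name=class_map.epoch_label or "area_ha")
    areas.index.name = "class_code"
    return areas


@dataclass
class ChangeSummary:
    """Annualised change of one class between two epochs (Eq.-2-style rate)."""

    class_code: int
    start_year: int
    end_year: int
    start_area_ha: float
    end_area_ha: float

    @property
    def t_years(self) -> int:
        return self.end_year - self.start_year

    @property
    def annual_rate_pct(self) -> float:
        """((end − start)/start) / t × 100, % per annum; sign = direction."""
        return (self.end_area_ha - self.start_area_ha) / self.start_area_ha / self.t_years * 100.0

    @property
    def annual_area_change_ha(self) -> float:
        return (self.end_area_ha - self.start_area_ha) / self.t_years


def change_rate(start_area_ha: float, end_area_ha: float,
                start_year: int, end_year: int, class_code: int = 0) -> ChangeSummary:
    """Annualised percent rate of area change for one class."""
    if start_area_ha <= 0:
        raise ValueError("start area must be > 0")
    if end_year <= start_year:
        raise ValueError("end_year must exceed start_year")
    return ChangeSummary(class_code, start_year, end_year, float(start_area_ha), float(end_area_ha))


@dataclass
class TransitionMatrix:
    """Area (ha) moving from each class (rows, epoch A) to each (cols, epoch B)."""

    hectares: pd.DataFrame   # index = from-class codes, columns = to-class codes
    epoch_a: str = ""
    epoch_b: str = ""

    @property
    def row_totals(self) -> pd.Series:
        return self.hectares.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.hectares.sum(axis=0)

    @property
    def persistence(self) -> pd.Series:
        return pd.Series(np.diag(self.hectares.values), index=self.hectares.index)

    @property
    def loss(self) -> pd.Series:
        return self.row_totals - self.persistence

    @property
    def gain(self) -> pd.Series:
        return self.col_totals - self.persistence

    @property
    def net_change(self) -> pd.Series:
        """Nc = gain − loss; sums to 0 over all classes."""
        return self.gain - self.loss

    @property
    def net_change_to_persistence(self) -> pd.Series:
        """Np = Nc / persistence; NaN where a class has no unchanged area."""
        pers = self.persistence
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(pers.values > 0, self.net_change.values / pers.values, np.nan)
        return pd.Series(vals, index=self.hectares.index)

    def to_frame(self) -> pd.DataFrame:
        """Published-style table: matrix plus Total/Loss/Gain/Nc/Np margins."""
        out = self.hectares.copy()
        out["total"] = self.row_totals
        out["loss"] = self.loss
        margins = pd.DataFrame(
            [self.col_totals, self.gain, self.net_change, self.net_change_to_persistence],
            index=["total", "gain", "net_change", "net_change_to_persistence"],
        )
        return pd.concat([out, margins])


def cross_tabulate(map_a: ClassMap, map_b: ClassMap) -> TransitionMatrix:
    """Overlay two epochs and tally the area converted between each class pair.

    Restricted to pixels that are non-nodata in both maps; requires matching
    grids, pixel sizes and legends.
    """
    if map_a.shape != map_b.shape:
        raise ValueError("maps must share the same grid")
    if map_a.pixel_size_m != map_b.pixel_size_m:
        raise ValueError("maps must share the same pixel size")
    if map_a.legend.codes != map_b.legend.codes:
        raise ValueError("maps must share the same legend")
    codes = map_a.legend.codes
    k = len(codes)
    idx = np.full(max(codes) + 1, -1, dtype=int)
    for i, c in enumerate(codes):
        idx[c] = i
    a, b = map_a.classes.ravel(), map_b.classes.ravel()
    ok = (a != 0) & (b != 0)
    flat = idx[a[ok]] * k + idx[b[ok]]
    counts = np.bincount(flat, minlength=k * k).reshape(k, k)
    ha = counts * map_a.pixel_area_ha
    frame = pd.DataFrame(ha, index=codes, columns=codes)
    frame.index.name, frame.columns.name = "from_class", "to_class"
    return TransitionMatrix(frame, map_a.epoch_label, map_b.epoch_label)


def area_change_table(areas_by_epoch: pd.DataFrame,
                      epoch_pairs: list[tuple[str, str]],
                      epoch_years: dict[str, int] | None = None) -> pd.DataFrame:
    """Annualised change summaries for every (class, epoch-pair) combination.

    ``areas_by_epoch``: DataFrame indexed by class code, one column per epoch
    label. Epoch labels are parsed as years unless ``epoch_years`` maps them.
    Classes with zero start area are skipped (the rate is undefined).
    """
    rows = []
    for start, end in epoch_pairs:
        y0 = epoch_years[start] if epoch_years else int(start)
        y1 = epoch_years[end] if epoch_years else int(end)
        for code in areas_by_epoch.index:
            a0, a1 = float(areas_by_epoch.loc[code, start]), float(areas_by_epoch.loc[code, end])
            if a0 <= 0:
                continue
            cs = change_rate(a0, a1, y0, y1, class_code=int(code))
            rows.append({
                "class_code": int(code), "start": start, "end": end, "t_years": cs.t_years,
                "start_area_ha": a0, "end_area_ha": a1,
                "annual_rate_pct": cs.annual_rate_pct,
                "annual_area_change_ha": cs.annual_area_change_ha,
            })
    return pd.DataFrame(rows)
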
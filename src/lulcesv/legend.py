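"""Class legends for categorical land-cover maps.

A :class:`Legend` maps small positive integer class codes to names; code 0 is
reserved everywhere for nodata. Two legends ship with the package: the
six-class land-use/land-cover legend used throughout the change and valuation
analysis, and the five-bin NDVI vegetation-density legend.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class LegendEntry:
    code: int
    name: str
    description: str = ""


@dataclass(frozen=True)
class Legend:
    """Ordered mapping of class codes to class names.

    Invariants: codes are unique, strictly positive integers (0 is nodata).
    """

    entries: tuple[LegendEntry, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        codes = [e.code for e in self.entries]
        if any(c <= 0 for c in codes):
            raise ValueError("class codes must be strictly positive; 0 is reserved for nodata")
        if len(set(codes)) != len(codes):
            raise ValueError(f"duplicate class codes in legend: {codes}")

    @property
    def codes(self) -> list[int]:
        return [e.code for e in self.entries]

    @property
    def names(self) -> dict[int, str]:
        return {e.code: e.name for e in self.entries}

    def __contains__(self, code: int) -> bool:
        return code in set(self.codes)

    def __len__(self) -> int:
        return len(self.entries)

    def name_of(self, code: int) -> str:
        for e in self.entries:
            if e.code == code:
                return e.name
        raise KeyError(f"class code {code} not in legend")

    def code_of(self, name: str) -> int:
        for e in self.entries:
            if e.name == name:
                return e.code
        raise KeyError(f"class name {name!r} not in legend")


# Canonical six-class land-use/land-cover legend (dry-evergreen-Afromontane
# highland landscape: forest, cropland, rangeland, settlement, bare rock, water).
FORESTLAND, CULTIVATED, GRASSLAND, BUILT_UP, BARREN, WATER = 1, 2, 3, 4, 5, 6

DEFAULT_LEGEND = Legend(
    (
        LegendEntry(FORESTLAND, "forestland", "tree canopy >10% on >0.5 ha, not under cultivation"),
        LegendEntry(CULTIVATED, "cultivated_land", "ploughed/prepared cropland incl. fallow plots"),
        LegendEntry(GRASSLAND, "grassland", "communal grazing land, natural grass and small bushes"),
        LegendEntry(BUILT_UP, "built_up_area", "residential houses and other buildings"),
        LegendEntry(BARREN, "barren_land", "bare rock, outcrops and cliffs with very sparse plants"),
        LegendEntry(WATER, "water_bodies", "lakes and rivers"),
    )
)

# Five vegetation-density bins for thresholded NDVI. Bin 4 is the density class
# commonly used as a grassland proxy ("moderate vegetation" is its density name).
NDVI_LEGEND = Legend(
    (
        LegendEntry(1, "non_vegetation", "non-vegetation areas or water bodies, NDVI in [-1, -0.03)"),
        LegendEntry(2, "very_low_vegetation", "barren land and settlement proxy, NDVI in [-0.03, 0.15)"),
        LegendEntry(3, "low_vegetation", "agricultural-land proxy, NDVI in [0.15, 0.25)"),
        LegendEntry(4, "moderate_vegetation", "grassland proxy, NDVI in [0.25, 0.35)"),
        LegendEntry(5, "dense_vegetation", "thriving, very dense vegetation, NDVI in [0.35, 1]"),
    )
)
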
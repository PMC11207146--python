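"""Shared data containers.

Tables (households, migrants, destinations, energy profiles) travel as
pandas DataFrames with validated schemas; the containers here hold the
non-tabular pieces: raster pairs, resident-group polygons, the planted
truth of a synthetic scenario, and the assembled bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from shapely.geometry.base import BaseGeometry


@dataclass
class RasterPair:
    """Co-registered forest-indicator and EVI grids at two dates.

    ``forest_t0``/``forest_t1`` are binary {0,1} grids; ``evi_t0``/``evi_t1``
    hold the Enhanced Vegetation Index in [-1, 1] (NaN allowed where the
    cell is non-forest). ``origin`` is the (x, y) of the lower-left raster
    corner; row 0 is the bottom row, so cell (row, col) has its centre at
    ``origin + ((col + 0.5) * cell_size, (row + 0.5) * cell_size)``.
    """

    forest_t0: np.ndarray
    forest_t1: np.ndarray
    evi_t0: np.ndarray
    evi_t1: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    site_id: str | None = None

    BAND_NAMES = ("forest_t0", "forest_t1", "evi_t0", "evi_t1")

    def __post_init__(self) -> None:
        shapes = {
            self.forest_t0.shape,
            self.forest_t1.shape,
            self.evi_t0.shape,
            self.evi_t1.shape,
        }
        if len(shapes) != 1:
            raise ValueError("all four grids must share one shape")
        for name in ("forest_t0", "forest_t1"):
            k = getattr(self, name)
            vals = np.unique(k[~np.isnan(k.astype(float))])
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError(f"{name} must be binary 0/1; found {vals[:5]}")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.forest_t0.shape

    def band(self, name: str) -> np.ndarray:
        if name not in self.BAND_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def swapped(self) -> "RasterPair":
        """The same pair with t0 and t1 exchanged (for antisymmetry checks)."""
        return RasterPair(
            self.forest_t1,
            self.forest_t0,
            self.evi_t1,
            self.evi_t0,
            self.cell_size,
            self.origin,
            self.site_id,
        )


@dataclass
class ResidentGroup:
    """A village-level spatial cluster of households."""

    group_id: str
    site_id: str
    boundary: BaseGeometry
    member_household_ids: list[str]
    group_remittance_total: float = 0.0


@dataclass
class SyntheticTruth:
    """Planted parameters and per-unit expectations of a scenario."""

    planted: dict[str, float]
    expected_delta_forest: pd.Series  # per household, at the effect radius
    remit_probability: pd.Series  # per migrant
    planted_contrast_forest: float  # nominal: slope x mean log10 remittance
    planted_contrast_evi: float
    background_drift: float  # expected ΔForest outside any effect zone
    # estimand as realised on the generated fields (receiver-minus-others
    # difference of per-household expected change); None without rasters
    realized_contrast_forest: float | None = None
    realized_contrast_evi: float | None = None

    def to_jsonable(self) -> dict[str, Any]:
        return {
            "planted": self.planted,
            "planted_contrast_forest": self.planted_contrast_forest,
            "planted_contrast_evi": self.planted_contrast_evi,
            "realized_contrast_forest": self.realized_contrast_forest,
            "realized_contrast_evi": self.realized_contrast_evi,
            "background_drift": self.background_drift,
            "expected_delta_forest": self.expected_delta_forest.to_dict(),
            "remit_probability": self.remit_probability.to_dict(),
        }


@dataclass
class ScenarioBundle:
    """One complete synthetic study dataset."""

    households: pd.DataFrame
    migrants: pd.DataFrame
    groups: list[ResidentGroup]
    rasters: dict[str, RasterPair] = field(default_factory=dict)
    destinations: pd.DataFrame | None = None
    energy: pd.DataFrame | None = None
    truth: SyntheticTruth | None = None
    config: Any = None
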
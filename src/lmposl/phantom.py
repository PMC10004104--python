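"""Water-equivalent depth bookkeeping for the foil/PMMA detector stack.

The measurement stack interleaves LMP silicone foils (0.54 mm, WET 1.05)
with solid PMMA plates (WET 1.15).  Each foil's scoring depth on the water
grid is the cumulative water-equivalent thickness of everything upstream
plus a within-foil attribution offset: by default the centre of the 0.4 mm
OSL grain layer, since the powder sediments to the lower part of the foil
before the silicone congeals.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Sequence

import numpy as np
import pandas as pd

FOIL_THICKNESS_MM = 0.54
FOIL_WET = 1.05
PLATE_THICKNESS_MM = 2.4
PLATE_WET = 1.15
GRAIN_LAYER_MM = 0.4


class ElementKind(str, enum.Enum):
    FOIL = "foil"
    PMMA_PLATE = "pmma_plate"


class ScoringConvention(str, enum.Enum):
    """Where within a foil the OSL signal is attributed."""

    FRONT = "front"
    GRAIN_LAYER = "grain_layer"
    MID = "mid"


@dataclasses.dataclass(frozen=True)
class StackElement:
    kind: ElementKind
    thickness_mm: float
    wet_factor: float
    detector_id: str | None = None

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValueError("thickness must be positive")
        if self.wet_factor <= 0:
            raise ValueError("WET factor must be positive")

    @property
    def wet_mm(self) -> float:
        return self.thickness_mm * self.wet_factor


def foil(detector_id: str, thickness_mm: float = FOIL_THICKNESS_MM,
         wet_factor: float = FOIL_WET) -> StackElement:
    return StackElement(ElementKind.FOIL, thickness_mm, wet_factor, detector_id)


def pmma_plate(thickness_mm: float = PLATE_THICKNESS_MM,
               wet_factor: float = PLATE_WET) -> StackElement:
    return StackElement(ElementKind.PMMA_PLATE, thickness_mm, wet_factor)


@dataclasses.dataclass
class StackLayout:
    """Ordered stack of foils and plates, upstream first."""

    elements: list[StackElement]
    scoring: ScoringConvention = ScoringConvention.GRAIN_LAYER
    grain_layer_mm: float = GRAIN_LAYER_MM

    def __post_init__(self) -> None:
        self.scoring = ScoringConvention(self.scoring)
        ids = [e.detector_id for e in self.elements if e.detector_id is not None]
        if len(ids) != len(set(ids)):
            raise ValueError("detector ids must be unique within a stack")

    @property
    def detector_ids(self) -> list[str]:
        return [e.detector_id for e in self.elements
                if e.kind is ElementKind.FOIL and e.detector_id is not None]

    def total_wet_mm(self) -> float:
        return float(sum(e.wet_mm for e in self.elements))

    def _offset_within(self, element: StackElement) -> float:
        if self.scoring is ScoringConvention.FRONT:
            return 0.0
        if self.scoring is ScoringConvention.MID:
            return 0.5 * element.wet_mm
        return 0.5 * self.grain_layer_mm * element.wet_factor

    def water_equivalent_depth(self, detector_id: str) -> float:
        """Scoring depth (mm water) of a foil: upstream WET + attribution offset."""
        upstream = 0.0
        for element in self.elements:
            if element.detector_id == detector_id:
                return upstream + self._offset_within(element)
            upstream += element.wet_mm
        raise KeyError(f"unknown detector id {detector_id!r}")

    def detector_depths(self) -> pd.DataFrame:
        rows = [(d, self.water_equivalent_depth(d)) for d in self.detector_ids]
        return pd.DataFrame(rows, columns=["detector_id", "depth_mm"])


def reference_layout(
    n_front_foils: int = 5,
    n_plates: int = 3,
    n_back_foils: int = 35,
    scoring: ScoringConvention | str = ScoringConvention.GRAIN_LAYER,
) -> StackLayout:
    """The 40-foil measurement stack: 5 foils, 3 PMMA plates, 35 foils.

    Foils are named ``f01`` ... ``f40`` in beam order.  Total stack WET is
    40*0.54*1.05 + 7.2*1.15 = 30.96 mm of water.
    """
    elements: list[StackElement] = []
    k = 0
    for _ in range(n_front_foils):
        k += 1
        elements.append(foil(f"f{k:02d}"))
    elements.extend(pmma_plate() for _ in range(n_plates))
    for _ in range(n_back_foils):
        k += 1
        elements.append(foil(f"f{k:02d}"))
    return StackLayout(elements, scoring=ScoringConvention(scoring))


def map_detectors_to_grid(layout: StackLayout, grid_centers_mm: Sequence[float]) -> pd.DataFrame:
    """Assign each foil to its nearest scoring slab (ties go shallower).

    Returns columns ``detector_id``, ``depth_mm`` (the foil's water depth),
    ``grid_index`` and ``depth_grid_mm`` (the matched slab centre).
    Raises if any foil lies beyond the grid span (more than half a slab
    outside the last centre).
    """
    grid = np.asarray(grid_centers_mm, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid centres must be a strictly increasing 1-D array")
    slab = float(np.median(np.diff(grid))) if grid.size > 1 else 0.0
    depths = layout.detector_depths()
    rows = []
    for det_id, depth in depths.itertuples(index=False):
        if depth < grid[0] - 0.5 * slab or depth > grid[-1] + 0.5 * slab:
            raise ValueError(f"detector {det_id} at {depth:.3f} mm is outside the grid span")
        dist = np.abs(grid - depth)
        idx = int(np.argmin(dist))  # argmin returns the first (shallower) slab on ties
        rows.append((det_id, float(depth), idx, float(grid[idx])))
    return pd.DataFrame(rows, columns=["detector_id", "depth_mm", "grid_index",
                                       "depth_grid_mm"])
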
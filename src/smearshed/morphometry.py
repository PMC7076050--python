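"""Measurement semantics of the smear-reading protocol.

A slide is read as three "representative" 100X fields. Per field, every
*complete* epithelial cell — one whose outline lies entirely within the
field bounds, boundary-inclusive — is counted; cells falling partly outside
the image are not. Per field one representative cell-aggregate outline is
measured (area in µm²). The slide-level summaries are the means over the
three fields.

When the mean complete-cell count is at or below 50 per field, the cells
are additionally classified by epithelial maturity (superficial /
intermediate / parabasal) and the superficial cell index
SCI = n_superficial / n_total (range 0–1) is computed over all complete
cells pooled across the three fields.

The original protocol classified cells by eye; here the qualitative
cytology ("condensed nucleus, large cytoplasmic space, polygonal shape with
thin angular margins") is operationalised as a deterministic rule on three
features, with thresholds exposed in :class:`ClassifierThresholds`. The
default numbers are this package's own calibration, not measured constants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .errors import GeometryError, IntegrityError, UndefinedSCIError
from .geometry import angularity, as_outline, polygon_area, validate_simple_polygon
from .records import SCI_COUNT_GATE

CELL_CLASSES = ("superficial", "intermediate", "parabasal")


@dataclass(frozen=True)
class ClassifierThresholds:
    """Feature thresholds for epithelial maturity classification.

    Features per cell: nucleus fraction ``f`` (nucleus area / cell area),
    cell area ``A`` (µm²), angularity ``g`` (fraction of interior vertex
    angles < 150°). A cell is

    * superficial  iff ``f <= f_sup`` and ``A >= area_sup`` and ``g >= g_sup``
      (condensed nucleus, large cytoplasm, angular margins);
    * parabasal    iff ``f >= f_para`` and ``A <= area_para``
      (large nucleus, small round cell);
    * intermediate otherwise.
    """

    f_sup: float = 0.10
    area_sup: float = 2000.0  # µm²
    g_sup: float = 0.5
    f_para: float = 0.30
    area_para: float = 800.0  # µm²


@dataclass(frozen=True)
class CellObservation:
    """One epithelial cell: outline, nucleus outline, optional ground truth."""

    cell_outline: np.ndarray
    nucleus_outline: np.ndarray
    true_class: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "cell_outline", as_outline(self.cell_outline))
        object.__setattr__(self, "nucleus_outline", as_outline(self.nucleus_outline))
        if self.true_class is not None and self.true_class not in CELL_CLASSES:
            raise IntegrityError(f"unknown cell class {self.true_class!r}")

    @property
    def cell_area(self) -> float:
        return polygon_area(self.cell_outline)

    @property
    def nucleus_area(self) -> float:
        return polygon_area(self.nucleus_outline)


@dataclass(frozen=True)
class SmearScene:
    """Vector description of one 100X field.

    ``field_bounds`` is (width, height) in µm with the origin at the field's
    lower-left corner.
    """

    field_bounds: tuple[float, float]
    cells: tuple[CellObservation, ...] = ()
    aggregate_outlines: tuple[np.ndarray, ...] = ()

    def __post_init__(self) -> None:
        w, h = self.field_bounds
        if not (w > 0 and h > 0):
            raise GeometryError(f"field bounds must be positive, got {self.field_bounds}")
        object.__setattr__(self, "cells", tuple(self.cells))
        object.__setattr__(
            self, "aggregate_outlines", tuple(as_outline(o) for o in self.aggregate_outlines)
        )
        for o in self.aggregate_outlines:
            validate_simple_polygon(o)


# ---------------------------------------------------------------------------
# elementary operations


def mean_field_count(counts: Sequence[int]) -> float:
    """Arithmetic mean of exactly three per-field complete-cell counts."""
    if len(counts) != 3:
        raise ValueError(f"exactly three field counts are required, got {len(counts)}")
    if any(c < 0 for c in counts):
        raise ValueError(f"field counts must be non-negative: {counts}")
    return float(sum(counts)) / 3.0


def sci_eligible(mean_cell_count: float) -> bool:
    """True iff the mean complete-cell count is at or below the SCI gate (50)."""
    if mean_cell_count < 0:
        raise ValueError(f"mean cell count must be non-negative: {mean_cell_count}")
    return mean_cell_count <= SCI_COUNT_GATE


def superficial_cell_index(n_superficial: int, n_total: int) -> float:
    """Exact ratio of superficial to all scored epithelial cells (0–1)."""
    if n_total == 0:
        raise UndefinedSCIError("SCI undefined: zero cells scored")
    if n_total < 0 or n_superficial < 0:
        raise IntegrityError("SCI counts must be non-negative")
    if n_superficial > n_total:
        raise IntegrityError(
            f"superficial count {n_superficial} exceeds total {n_total}"
        )
    return n_superficial / n_total


def cell_inside_bounds(cell: CellObservation, field_bounds: tuple[float, float]) -> bool:
    """Boundary-inclusive containment of the full cell outline in the field."""
    w, h = field_bounds
    v = cell.cell_outline
    return bool(
        np.all(v[:, 0] >= 0.0)
        and np.all(v[:, 0] <= w)
        and np.all(v[:, 1] >= 0.0)
        and np.all(v[:, 1] <= h)
    )


def count_complete_cells(scene: SmearScene) -> int:
    """Number of cells whose outline lies entirely within the field bounds.

    Cells touching the boundary count as inside; cells with any vertex
    outside are excluded (they fall partly outside the image).
    """
    return sum(1 for c in scene.cells if cell_inside_bounds(c, scene.field_bounds))


def cell_features(cell: CellObservation) -> tuple[float, float, float]:
    """(nucleus fraction, cell area µm², angularity) for one cell."""
    a_cell = cell.cell_area
    a_nuc = cell.nucleus_area
    if a_nuc >= a_cell:
        raise GeometryError(
            f"nucleus area ({a_nuc:.1f}) must be smaller than cell area ({a_cell:.1f})"
        )
    return a_nuc / a_cell, a_cell, angularity(cell.cell_outline)


def classify_cell(
    cell: CellObservation, thresholds: ClassifierThresholds = ClassifierThresholds()
) -> str:
    """Deterministic epithelial maturity class of one cell.

    See :class:`ClassifierThresholds` for the rule.
    """
    f, area, g = cell_features(cell)
    t = thresholds
    if f <= t.f_sup and area >= t.area_sup and g >= t.g_sup:
        return "superficial"
    if f >= t.f_para and area <= t.area_para:
        return "parabasal"
    return "intermediate"


@dataclass(frozen=True)
class SlideMeasurement:
    """Slide-level summary of three measured fields."""

    mean_cell_count: float
    mean_aggregate_area_um2: float
    sci: Optional[float] = None
    n_superficial: Optional[int] = None
    n_total: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sci is not None:
            expected = superficial_cell_index(self.n_superficial, self.n_total)
            if self.sci != expected:
                raise IntegrityError("sci must equal n_superficial / n_total exactly")
            if not sci_eligible(self.mean_cell_count):
                raise IntegrityError("sci present above the count gate")


def largest_aggregate_area(scene: SmearScene) -> float:
    """Area of the representative (largest) aggregate outline in a field."""
    if not scene.aggregate_outlines:
        raise IntegrityError("scene has no aggregate outline to measure")
    return max(polygon_area(o) for o in scene.aggregate_outlines)


def measure_slide(
    field_scenes: Sequence[SmearScene],
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> SlideMeasurement:
    """Full slide read-out from three field scenes.

    Mean cell count over the three complete-cell counts; mean aggregate area
    from one representative (largest) outline per scene; SCI populated only
    when the mean count passes the <=50 gate, classifying and pooling the
    complete cells of all three scenes.
    """
    if len(field_scenes) != 3:
        raise ValueError(f"exactly three field scenes are required, got {len(field_scenes)}")
    counts = [count_complete_cells(s) for s in field_scenes]
    mean_count = mean_field_count(counts)
    mean_area = float(np.mean([largest_aggregate_area(s) for s in field_scenes]))
    if not sci_eligible(mean_count):
        return SlideMeasurement(mean_count, mean_area)
    n_sup = 0
    n_tot = 0
    for scene in field_scenes:
        for cell in scene.cells:
            if not cell_inside_bounds(cell, scene.field_bounds):
                continue
            n_tot += 1
            if classify_cell(cell, thresholds) == "superficial":
                n_sup += 1
    if n_tot == 0:
        return SlideMeasurement(mean_count, mean_area)
    return SlideMeasurement(
        mean_count,
        mean_area,
        sci=superficial_cell_index(n_sup, n_tot),
        n_superficial=n_sup,
        n_total=n_tot,
    )


# ---------------------------------------------------------------------------
# scene (de)serialisation — JSON interchange format


def scene_to_dict(scene: SmearScene) -> dict:
    return {
        "field_bounds": [scene.field_bounds[0], scene.field_bounds[1]],
        "cells": [
            {
                "outline": c.cell_outline.tolist(),
                "nucleus": c.nucleus_outline.tolist(),
                "true_class": c.true_class,
            }
            for c in scene.cells
        ],
        "aggregates": [o.tolist() for o in scene.aggregate_outlines],
    }


def scene_from_dict(data: dict) -> SmearScene:
    return SmearScene(
        field_bounds=tuple(data["field_bounds"]),
        cells=tuple(
            CellObservation(c["outline"], c["nucleus"], c.get("true_class"))
            for c in data.get("cells", [])
        ),
        aggregate_outlines=tuple(data.get("aggregates", [])),
    )


def write_scene(scene: SmearScene, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.write_text(json.dumps(scene_to_dict(scene)), encoding="utf-8")
    return path


def read_scene(path: Union[str, Path]) -> SmearScene:
    return scene_from_dict(json.loads(Path(path).read_text(encoding="utf-8")))
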
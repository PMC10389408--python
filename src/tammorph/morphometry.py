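"""Per-cell morphometry of traced macrophage outlines.

Cells arrive as closed polygons in micrometre coordinates, one per CD163+
macrophage, grouped into invasive-margin zones on a slide. Area is the
absolute shoelace (signed polygon) area, perimeter the sum of Euclidean edge
lengths including the closing edge. Slide-level summaries follow the sampling
protocol used at the microscope: a fixed number of zones per slide, a fixed
number of randomly chosen cells per zone, and a slide mean defined as the
unweighted mean of the zone means (never the pooled cell mean).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .errors import InvalidGeometryError, UndersampledZoneError

__all__ = [
    "CellOutline",
    "MorphometricRecord",
    "SlideMorphometry",
    "polygon_area",
    "polygon_perimeter",
    "sample_cells",
    "measure_cells",
    "summarize_slide",
]

#: zone label reserved for peritumoral-band cells, excluded from the
#: invasive-margin sampling protocol by default
BAND_ZONE = "band"


def _as_vertex_array(vertices) -> np.ndarray:
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise InvalidGeometryError(f"vertices must be (n, 2), got shape {v.shape}")
    # drop an explicitly repeated closing vertex
    if len(v) > 1 and np.array_equal(v[0], v[-1]):
        v = v[:-1]
    return v


def _validate_vertices(v: np.ndarray) -> None:
    if len(v) < 3:
        raise InvalidGeometryError(f"polygon needs >=3 vertices, got {len(v)}")
    if not np.all(np.isfinite(v)):
        raise InvalidGeometryError("polygon has non-finite coordinates")
    if abs(_shoelace(v)) == 0.0:
        raise InvalidGeometryError("polygon has zero signed area")
    if not Polygon(v).is_valid:
        raise InvalidGeometryError("polygon is self-intersecting or degenerate")


def _shoelace(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass(frozen=True)
class CellOutline:
    """Traced outline of one macrophage, implicitly closed, in micrometres."""

    cell_id: str
    slide_id: str
    zone_id: str
    vertices: np.ndarray
    marker: str = "CD163+"

    def __post_init__(self):
        object.__setattr__(self, "vertices", _as_vertex_array(self.vertices))

    def validate(self) -> "CellOutline":
        """Raise :class:`InvalidGeometryError` unless the outline is a simple,
        non-degenerate polygon with finite coordinates."""
        _validate_vertices(self.vertices)
        return self

    @property
    def centroid(self) -> np.ndarray:
        c = Polygon(self.vertices).centroid
        return np.array([c.x, c.y])


@dataclass(frozen=True)
class MorphometricRecord:
    cell_id: str
    area: float  # um^2
    perimeter: float  # um

    def __post_init__(self):
        if not (self.area > 0 and self.perimeter > 0):
            raise InvalidGeometryError("area and perimeter must be positive")
        if self.perimeter**2 < 4.0 * np.pi * self.area * (1 - 1e-9):
            raise InvalidGeometryError("isoperimetric inequality violated")


@dataclass
class SlideMorphometry:
    """Zone-wise and zone-averaged morphometry for one slide."""

    slide_id: str
    zone_means: Mapping[str, tuple[float, float]]  # zone -> (mean area, mean perim)
    slide_mean_area: float
    slide_mean_perimeter: float
    n_cells: int
    # pooled-cell dispersions are reported alongside the zone-averaged ones;
    # they answer different questions and are labelled explicitly
    pooled_sd_area: float = field(default=float("nan"))
    pooled_sd_perimeter: float = field(default=float("nan"))


def polygon_area(vertices, validate: bool = True) -> float:
    """Absolute shoelace area (um^2) of an implicitly closed polygon.

    Orientation-independent; raises :class:`InvalidGeometryError` for fewer
    than 3 vertices or a self-intersecting outline.
    """
    v = _as_vertex_array(vertices)
    if validate:
        _validate_vertices(v)
    return abs(_shoelace(v))


def polygon_perimeter(vertices, validate: bool = True) -> float:
    """Sum of Euclidean edge lengths (um) including the closing edge."""
    v = _as_vertex_array(vertices)
    if validate:
        _validate_vertices(v)
    return float(np.linalg.norm(np.diff(np.vstack([v, v[:1]]), axis=0), axis=1).sum())


def _slide_rng(seed: int, slide_id: str) -> np.random.Generator:
    # per-slide child seed so adding slides never perturbs earlier draws
    child = zlib.crc32(str(slide_id).encode("utf8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, child]))


def sample_cells(
    outlines: Iterable[CellOutline],
    zones_per_slide: int = 3,
    cells_per_zone: int = 7,
    seed: int = 0,
    exclude_zones: Sequence[str] = (BAND_ZONE,),
) -> list[CellOutline]:
    """Apply the microscope sampling protocol to a set of traced outlines.

    Per slide, ``zones_per_slide`` zones are drawn (all zones if exactly that
    many are annotated), then ``cells_per_zone`` cells uniformly without
    replacement within each. Deterministic given ``seed``; each slide uses a
    child seed derived from the slide id, so the draw for one slide does not
    depend on which other slides are present. Zones listed in
    ``exclude_zones`` (by default the peritumoral band) are never sampled.
    """
    by_slide: dict[str, dict[str, list[CellOutline]]] = {}
    for o in outlines:
        if o.zone_id in exclude_zones:
            continue
        by_slide.setdefault(o.slide_id, {}).setdefault(o.zone_id, []).append(o)

    selected: list[CellOutline] = []
    for slide_id in sorted(by_slide):
        zones = by_slide[slide_id]
        rng = _slide_rng(seed, slide_id)
        zone_ids = sorted(zones)
        if len(zone_ids) < zones_per_slide:
            raise UndersampledZoneError(slide_id, "<slide>", len(zone_ids), zones_per_slide)
        chosen_zones = (
            zone_ids
            if len(zone_ids) == zones_per_slide
            else [zone_ids[i] for i in sorted(rng.choice(len(zone_ids), zones_per_slide, replace=False))]
        )
        for zid in chosen_zones:
            cells = sorted(zones[zid], key=lambda o: o.cell_id)
            if len(cells) < cells_per_zone:
                raise UndersampledZoneError(slide_id, zid, len(cells), cells_per_zone)
            idx = rng.choice(len(cells), cells_per_zone, replace=False)
            selected.extend(cells[i] for i in sorted(idx))
    return selected


def measure_cells(outlines: Iterable[CellOutline], validate: bool = True) -> pd.DataFrame:
    """Measure every outline; returns one row per cell.

    Columns: slide_id, zone_id, cell_id, area_um2, perimeter_um.
    """
    rows = []
    for o in outlines:
        rows.append(
            dict(
                slide_id=o.slide_id,
                zone_id=o.zone_id,
                cell_id=o.cell_id,
                area_um2=polygon_area(o.vertices, validate=validate),
                perimeter_um=polygon_perimeter(o.vertices, validate=False),
            )
        )
    if not rows:
        raise ValueError("no outlines to measure")
    return pd.DataFrame(rows)


def summarize_slide(records: pd.DataFrame) -> SlideMorphometry:
    """Aggregate per-cell records of one slide into zone and slide means.

    ``records`` must carry columns zone_id, area_um2, perimeter_um (cell_id
    optional) for a single slide. The slide mean is the unweighted mean of
    the zone means, mirroring the per-patient averaging of the measurement
    protocol; with unequal zone sizes this is deliberately *not* the pooled
    cell mean.
    """
    if len(records) == 0:
        raise ValueError("no records to summarize")
    slide_ids = records["slide_id"].unique() if "slide_id" in records else ["<slide>"]
    if len(slide_ids) != 1:
        raise ValueError(f"records span {len(slide_ids)} slides; pass one at a time")
    zone_stats = records.groupby("zone_id")[["area_um2", "perimeter_um"]].mean()
    zone_means = {
        str(z): (float(r["area_um2"]), float(r["perimeter_um"]))
        for z, r in zone_stats.iterrows()
    }
    return SlideMorphometry(
        slide_id=str(slide_ids[0]),
        zone_means=zone_means,
        slide_mean_area=float(zone_stats["area_um2"].mean()),
        slide_mean_perimeter=float(zone_stats["perimeter_um"].mean()),
        n_cells=int(len(records)),
        pooled_sd_area=float(records["area_um2"].std(ddof=1)) if len(records) > 1 else float("nan"),
        pooled_sd_perimeter=float(records["perimeter_um"].std(ddof=1)) if len(records) > 1 else float("nan"),
    )


def summarize_cohort(records: pd.DataFrame) -> pd.DataFrame:
    """Slide-level summary table for many slides at once.

    Returns one row per slide: slide_mean_area_um2, slide_mean_perimeter_um,
    n_cells (zone-averaged, as in :func:`summarize_slide`).
    """
    rows = []
    for slide_id, grp in records.groupby("slide_id"):
        s = summarize_slide(grp)
        rows.append(
            dict(
                slide_id=slide_id,
                slide_mean_area_um2=s.slide_mean_area,
                slide_mean_perimeter_um=s.slide_mean_perimeter,
                n_cells=s.n_cells,
            )
        )
    return pd.DataFrame(rows)
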
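"""File readers/writers and the pipeline configuration.

Annotations travel as GeoJSON FeatureCollections, one file per slide: each
macrophage outline is a Polygon feature with ``cell_id``, ``zone_id`` and
``marker`` properties; the tumor contour is a Polygon feature with property
``role: "tumor"``. Coordinates are (x, y) in micrometres after an optional
microns-per-pixel scale conversion (slide frame, x right / y down).

Tabular outputs are CSV; density maps are saved as ``.npy`` arrays with a
JSON sidecar (origin, pixel size, radius, threshold); foci are exported as
GeoJSON polygons. Every writer here has a matching reader so outputs
round-trip through the package's own IO.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .errors import AnnotationError, InvalidGeometryError
from .morphometry import CellOutline
from .simulate import SyntheticCohort, config_to_dict
from .spatial import DensityMap, FociSet

logger = logging.getLogger("tammorph")

__all__ = [
    "PipelineConfig",
    "read_slide_annotations",
    "write_slide_annotations",
    "write_cohort",
    "read_cohort_csv",
    "save_density_map",
    "load_density_map",
    "foci_to_geojson",
]


@dataclasses.dataclass
class PipelineConfig:
    """All pipeline tunables, with the protocol defaults."""

    seed: int = 0
    zones_per_slide: int = 3
    cells_per_zone: int = 7
    cutoff_mode: str = "derive"  # "derive" (ROC/Youden) or "fixed"
    fixed_cutoff: float = 151.38  # um^2, the published reference cutoff
    #: Youden one-SE rule strength for the derived cutoff; 0 = plain argmax
    cutoff_se_factor: float = 1.0
    band_width: float = 500.0  # um
    count_radius: float = 500.0  # um
    foci_radius: float = 200.0  # um
    foci_threshold: int = 100
    pixel_size: float = 20.0  # um
    alpha: float = 0.05
    n_bootstrap: int = 1000

    def validate(self) -> "PipelineConfig":
        for name in ("band_width", "count_radius", "foci_radius", "pixel_size",
                     "fixed_cutoff", "zones_per_slide", "cells_per_zone"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.pixel_size >= min(self.count_radius, self.foci_radius):
            raise ValueError("pixel_size must be smaller than the count radii")
        if self.cutoff_mode not in ("derive", "fixed"):
            raise ValueError("cutoff_mode must be 'derive' or 'fixed'")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d).validate()

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# slide annotations (GeoJSON)


def _outline_feature(o: CellOutline) -> dict:
    ring = [[float(x), float(y)] for x, y in o.vertices] + [
        [float(o.vertices[0][0]), float(o.vertices[0][1])]
    ]
    return {
        "type": "Feature",
        "geometry": {"type": "Polygon", "coordinates": [ring]},
        "properties": {"cell_id": o.cell_id, "zone_id": o.zone_id, "marker": o.marker},
    }


def write_slide_annotations(slide_id, outlines, tumor_contour, path) -> None:
    """Write one slide's outlines + tumor contour as a GeoJSON FeatureCollection."""
    features = [_outline_feature(o) for o in outlines]
    contour = np.asarray(tumor_contour, dtype=float)
    ring = [[float(x), float(y)] for x, y in contour] + [
        [float(contour[0][0]), float(contour[0][1])]
    ]
    features.append(
        {
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring]},
            "properties": {"role": "tumor"},
        }
    )
    doc = {
        "type": "FeatureCollection",
        "properties": {"slide_id": str(slide_id), "units": "micrometer"},
        "features": features,
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def read_slide_annotations(
    path,
    microns_per_pixel: float = 1.0,
    require_tumor: bool = True,
):
    """Load a slide annotation file.

    Returns ``(outlines, tumor_contour, rejected)`` where ``rejected`` lists
    per-feature diagnostics for malformed features (which are skipped with a
    logged warning, not fatal). Raises :class:`AnnotationError` if the file
    is empty, declares unknown units, or lacks a tumor contour when one is
    required.
    """
    path = Path(path)
    doc = json.loads(path.read_text())
    if doc.get("type") != "FeatureCollection":
        raise AnnotationError(f"{path}: not a GeoJSON FeatureCollection")
    units = (doc.get("properties") or {}).get("units", "micrometer")
    if units not in ("micrometer", "micron", "um", "pixel"):
        raise AnnotationError(
            f"{path}: unknown units {units!r}; declare 'micrometer' or 'pixel' "
            "and pass microns_per_pixel for pixel-space files"
        )
    features = doc.get("features", [])
    if not features:
        raise AnnotationError(f"{path}: empty FeatureCollection")
    slide_id = (doc.get("properties") or {}).get("slide_id", path.stem)

    outlines, rejected = [], []
    tumor = None
    for i, feat in enumerate(features):
        props = feat.get("properties") or {}
        try:
            geom = shape(feat["geometry"])
        except Exception as exc:  # malformed geometry block
            rejected.append((props.get("cell_id", f"feature[{i}]"), str(exc)))
            continue
        coords = np.asarray(geom.exterior.coords)[:-1] * microns_per_pixel
        if props.get("role") == "tumor":
            tumor = coords
            continue
        cell_id = props.get("cell_id", f"feature[{i}]")
        try:
            o = CellOutline(
                cell_id=str(cell_id),
                slide_id=str(slide_id),
                zone_id=str(props.get("zone_id", "zone1")),
                vertices=coords,
                marker=str(props.get("marker", "CD163+")),
            ).validate()
        except InvalidGeometryError as exc:
            logger.warning("slide %s: rejected cell %s: %s", slide_id, cell_id, exc)
            rejected.append((str(cell_id), str(exc)))
            continue
        outlines.append(o)
    if require_tumor and tumor is None:
        raise AnnotationError(f"{path}: no feature with role 'tumor'")
    return outlines, tumor, rejected


# ---------------------------------------------------------------------------
# cohort bundle


def write_cohort(sc: SyntheticCohort, outdir) -> Path:
    """Write a synthetic cohort bundle: cohort.csv, slides/*.geojson,
    truth.json (ground-truth sidecar, tests only) and config.json."""
    outdir = Path(outdir)
    (outdir / "slides").mkdir(parents=True, exist_ok=True)
    sc.cohort.to_csv(outdir / "cohort.csv", index=False)
    for sid, slide in sc.slides.items():
        write_slide_annotations(
            sid, slide.outlines, slide.tumor_contour, outdir / "slides" / f"{sid}.geojson"
        )
    (outdir / "truth.json").write_text(json.dumps(sc.truth, sort_keys=True, indent=1))
    (outdir / "config.json").write_text(
        json.dumps(config_to_dict(sc.config), sort_keys=True, indent=1)
    )
    return outdir


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"patient_id", "slide_id", "dfs_time", "dfs_event"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationError(f"cohort table missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# rasters and foci


def save_density_map(dmap: DensityMap, stem) -> None:
    """Save counts + mask as .npy with a JSON sidecar describing the grid."""
    stem = Path(stem)
    np.save(stem.with_suffix(".counts.npy"), dmap.counts)
    np.save(stem.with_suffix(".mask.npy"), dmap.mask)
    stem.with_suffix(".json").write_text(
        json.dumps(
            dict(
                slide_id=dmap.slide_id,
                origin=list(dmap.origin),
                pixel_size=dmap.pixel_size,
                count_radius=dmap.count_radius,
                shape=list(dmap.counts.shape),
                units="micrometer",
            ),
            sort_keys=True,
        )
    )


def load_density_map(stem) -> DensityMap:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    return DensityMap(
        slide_id=meta["slide_id"],
        origin=tuple(meta["origin"]),
        pixel_size=float(meta["pixel_size"]),
        count_radius=float(meta["count_radius"]),
        counts=np.load(stem.with_suffix(".counts.npy")),
        mask=np.load(stem.with_suffix(".mask.npy")),
    )


def foci_to_geojson(foci: FociSet) -> dict:
    """Foci as GeoJSON polygons (union of supra-threshold pixel squares)."""
    import shapely
    from shapely.geometry import box
    from shapely.ops import unary_union

    ps = foci.pixel_size
    ox, oy = foci.density.origin
    features = []
    for label in range(1, foci.n_foci + 1):
        rows, cols = np.nonzero(foci.labels == label)
        squares = [
            box(ox + c * ps, oy + r * ps, ox + (c + 1) * ps, oy + (r + 1) * ps)
            for r, c in zip(rows, cols)
        ]
        geom = unary_union(squares)
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(geom),
                "properties": {
                    "focus_id": label,
                    "area_um2": foci.foci_areas[label - 1],
                },
            }
        )
    return {
        "type": "FeatureCollection",
        "properties": {
            "slide_id": foci.slide_id,
            "threshold": foci.threshold,
            "foci_radius": foci.foci_radius,
            "pixel_size": ps,
            "total_foci_area_um2": foci.total_foci_area,
            "units": "micrometer",
        },
        "features": features,
    }
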
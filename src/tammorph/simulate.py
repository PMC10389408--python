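"""Synthetic cohorts of annotated slides with linked survival outcomes.

The generator emulates the statistical structure the analysis pipeline
assumes, at annotation level (no pixel synthesis):

* two patient populations whose slide-mean macrophage areas follow lognormal
  components centred near 150 um^2 (favorable, S-TAM) and 217 um^2
  (unfavorable, L-TAM);
* per-cell areas lognormal around the patient mean, rendered as noisy
  star-shaped polygons of exactly matching shoelace area, grouped into three
  invasive-margin zones per slide;
* disease-free survival from a proportional-hazards model with a large
  hazard ratio for the L-TAM class and independent uniform censoring;
* a 6 + 6 spatial subset in which the earliest-recurrence slides receive
  Thomas-clustered L-TAM centroids in the peritumoral band and the
  longest event-free slides receive homogeneous Poisson centroids, at
  matched expected totals.

Ground truth (class labels, true slide means, spatial arms) is emitted in a
sidecar that the analysis modules never read; only tests may consult it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import shapely

from .errors import TammorphError
from .morphometry import BAND_ZONE, CellOutline, polygon_area
from .spatial import TumorGeometry, build_band

__all__ = [
    "GeneratorConfig",
    "SlideAnnotation",
    "SyntheticCohort",
    "generate_cohort",
    "render_cell_outline",
    "generate_spatial_patterns",
]

#: binary covariate roster with cohort prevalences (fractions of patients)
DEFAULT_COVARIATE_PREVALENCE = {
    "neoadjuvant": 0.70,
    "cea_elevated": 0.63,
    "ca199_elevated": 0.17,
    "t34": 0.76,
    "n_positive": 0.60,
    "synchronous": 0.56,
    "g34": 0.15,
    "ras_mutated": 0.30,
    "bilobar": 0.40,
    "rectum_primary": 0.32,
    "sex_male": 0.70,
}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort, with the study-scale defaults."""

    seed: int = 0
    n_patients: int = 84
    #: mixture weight of the unfavorable (large-area) component; the realized
    #: recurrence fraction then follows from the hazard model
    fraction_large: float = 66 / 84

    # slide-mean area model (lognormal components, medians in um^2)
    median_area_small: float = 150.0
    median_area_large: float = 217.0
    sigma_slide: float = 0.10  # log-sd of slide means within a component
    sigma_cell: float = 0.22  # log-sd of cell areas within a slide

    # cell rendering / slide layout
    n_zones: int = 3
    cells_per_zone: int = 10  # available per zone (protocol samples 7)
    irregularity: float = 0.25
    zone_radius: float = 200.0  # um, zone footprint for cell placement

    # survival model
    baseline_hazard: float = 0.02  # events per month for the S-TAM class
    hazard_ratio: float = 5.0  # L-TAM vs S-TAM
    censor_max: float = 60.0  # months, U(0, censor_max) censoring
    os_lag_mean: float = 18.0  # months, mean recurrence-to-death lag

    # spatial model
    spatial_subset_size: int = 6  # slides per arm; 0 disables the subset
    tumor_radius: float = 1500.0  # um, circular tumor contour
    band_width: float = 500.0  # um
    thomas_parent_mean: float = 4.0  # clusters per clustered slide
    thomas_offspring_mean: float = 150.0  # L-TAMs per cluster
    thomas_sigma: float = 50.0  # um, Gaussian cluster scatter
    stam_expected: float = 600.0  # S-TAM centroids per slide

    covariate_prevalence: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PREVALENCE)
    )

    def validate(self) -> "GeneratorConfig":
        if not (0 < self.fraction_large < 1):
            raise ValueError("fraction_large must be in (0, 1)")
        for name in ("baseline_hazard", "hazard_ratio", "censor_max",
                     "median_area_small", "median_area_large"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 <= self.irregularity < 0.5):
            raise ValueError("irregularity must be in [0, 0.5)")
        return self


@dataclass
class SlideAnnotation:
    """Everything annotated on one slide: outlines plus the tumor contour."""

    slide_id: str
    outlines: list[CellOutline]
    tumor_contour: np.ndarray  # (n, 2) vertices, um

    def geometry(self, band_width: float = 500.0) -> TumorGeometry:
        return build_band(self.tumor_contour, band_width, slide_id=self.slide_id)


@dataclass
class SyntheticCohort:
    config: GeneratorConfig
    cohort: pd.DataFrame  # one row per patient
    slides: dict[str, SlideAnnotation]
    truth: dict  # ground-truth sidecar; analysis modules never read this


# ---------------------------------------------------------------------------
# cell rendering


def render_cell_outline(
    target_area: float,
    irregularity: float = 0.25,
    seed=None,
    n_vertices: int | None = None,
    center=(0.0, 0.0),
    cell_id: str = "cell",
    slide_id: str = "slide",
    zone_id: str = "zone",
) -> CellOutline:
    """Star-shaped polygon of exactly ``target_area`` um^2.

    ``irregularity`` in [0, 0.5) perturbs both the angular spacing and the
    vertex radii; 0 yields a regular polygon. Strictly increasing vertex
    angles guarantee a simple polygon, and a final uniform rescale pins the
    shoelace area to the target.
    """
    if target_area <= 0:
        raise ValueError("target_area must be > 0")
    if not (0 <= irregularity < 0.5):
        raise ValueError("irregularity must be in [0, 0.5)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(n_vertices) if n_vertices else int(rng.integers(12, 41))
    spacing = 2 * np.pi / n
    angles = spacing * (np.arange(n) + rng.uniform(-irregularity, irregularity, n))
    radii = 1.0 + rng.uniform(-irregularity, irregularity, n)
    v = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
    scale = np.sqrt(target_area / polygon_area(v, validate=False))
    v = v * scale + np.asarray(center, dtype=float)
    return CellOutline(cell_id=cell_id, slide_id=slide_id, zone_id=zone_id, vertices=v)


# ---------------------------------------------------------------------------
# point patterns


def _circle_polygon(radius: float, n: int = 96) -> np.ndarray:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([radius * np.cos(t), radius * np.sin(t)])


def _uniform_in_region(region, n: int, rng) -> np.ndarray:
    """Rejection-sample ``n`` points uniformly inside a shapely region."""
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = region.bounds
    frac = region.area / ((maxx - minx) * (maxy - miny))
    if frac <= 0:
        raise TammorphError("region too small for requested point intensity")
    out = []
    got = 0
    while got < n:
        m = max(64, int((n - got) / frac * 1.3))
        cand = np.column_stack(
            [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
        )
        keep = shapely.contains(region, shapely.points(cand[:, 0], cand[:, 1]))
        cand = cand[keep]
        out.append(cand[: n - got])
        got += len(cand[: n - got])
    return np.vstack(out)


def _thomas_points(band, parent_mean, offspring_mean, sigma, rng) -> np.ndarray:
    """Thomas cluster process: Poisson parents in the band, Gaussian offspring."""
    n_parents = rng.poisson(parent_mean)
    parents = _uniform_in_region(band, n_parents, rng)
    pts = []
    for p in parents:
        k = rng.poisson(offspring_mean)
        pts.append(p + rng.normal(0.0, sigma, size=(k, 2)))
    return np.vstack(pts) if pts else np.empty((0, 2))


def generate_spatial_patterns(config: GeneratorConfig, arm: str, rng):
    """L-TAM and S-TAM centroids for one spatial-subset slide.

    ``arm`` is "early" (Thomas-clustered L-TAMs) or "favorable" (homogeneous
    Poisson L-TAMs at the same expected total). S-TAM centroids are
    homogeneous Poisson in both arms. Returns (geometry, ltam_xy, stam_xy).
    """
    geom = build_band(_circle_polygon(config.tumor_radius), config.band_width)
    if arm == "early":
        ltam = _thomas_points(
            geom.band, config.thomas_parent_mean, config.thomas_offspring_mean,
            config.thomas_sigma, rng,
        )
    elif arm == "favorable":
        expected = config.thomas_parent_mean * config.thomas_offspring_mean
        ltam = _uniform_in_region(geom.band, rng.poisson(expected), rng)
    else:
        raise ValueError(f"unknown arm {arm!r}")
    stam = _uniform_in_region(geom.band, rng.poisson(config.stam_expected), rng)
    return geom, ltam, stam


# ---------------------------------------------------------------------------
# cohort generation


def _zone_centers(config: GeneratorConfig) -> list[np.ndarray]:
    # three noncontiguous spots on the invasive margin, just outside the contour
    r = config.tumor_radius + config.band_width / 2
    return [
        np.array([r * np.cos(a), r * np.sin(a)])
        for a in np.linspace(0, 2 * np.pi, config.n_zones, endpoint=False)
    ]


def _render_zone_cells(slide_id, slide_mean, config, rng) -> list[CellOutline]:
    """Morphometry cells: lognormal areas whose *mean* is the slide mean."""
    outlines = []
    s = config.sigma_cell
    for zi, zc in enumerate(_zone_centers(config), start=1):
        for ci in range(config.cells_per_zone):
            # mean-anchored lognormal: E[area] = slide_mean
            area = slide_mean * np.exp(rng.normal(-0.5 * s * s, s))
            theta = rng.uniform(0, 2 * np.pi)
            rad = config.zone_radius * np.sqrt(rng.uniform())
            pos = zc + rad * np.array([np.cos(theta), np.sin(theta)])
            outlines.append(
                render_cell_outline(
                    area, config.irregularity, rng,
                    center=pos,
                    cell_id=f"{slide_id}_z{zi}_c{ci + 1:02d}",
                    slide_id=slide_id,
                    zone_id=f"zone{zi}",
                )
            )
    return outlines


def _render_band_cells(slide_id, ltam_xy, stam_xy, config, rng) -> list[CellOutline]:
    """Spatial-subset cells across the whole band, with per-cell areas drawn
    from the component laws so per-cell classification is meaningful."""
    outlines = []
    s = config.sigma_cell
    for tag, xy, median in (
        ("L", ltam_xy, config.median_area_large),
        ("S", stam_xy, config.median_area_small),
    ):
        areas = median * np.exp(rng.normal(-0.5 * s * s, s, size=len(xy)))
        for i, (pos, area) in enumerate(zip(xy, areas)):
            outlines.append(
                render_cell_outline(
                    area, config.irregularity, rng,
                    center=pos,
                    cell_id=f"{slide_id}_band_{tag}{i + 1:04d}",
                    slide_id=slide_id,
                    zone_id=BAND_ZONE,
                )
            )
    return outlines


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort, reproducible from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(int(config.seed) & 0x7FFFFFFF)
    n = config.n_patients

    # --- patient-level truth
    is_large = rng.uniform(size=n) < config.fraction_large
    medians = np.where(is_large, config.median_area_large, config.median_area_small)
    true_mean = medians * np.exp(rng.normal(0.0, config.sigma_slide, n))

    # --- survival (proportional hazards, independent uniform censoring)
    hazard = config.baseline_hazard * config.hazard_ratio**is_large.astype(float)
    t_event = rng.exponential(1.0 / hazard)
    censor = rng.uniform(0.0, config.censor_max, n)
    dfs_time = np.minimum(t_event, censor)
    dfs_event = t_event <= censor
    death = t_event + rng.exponential(config.os_lag_mean, n)
    os_time = np.minimum(death, censor)
    os_event = death <= censor

    # --- covariates
    cov = {}
    for name, prev in config.covariate_prevalence.items():
        cov[name] = (rng.uniform(size=n) < prev).astype(int)
    age = np.clip(rng.normal(61, 9, n), 30, 85).round(0)
    tumor_number = 1 + rng.poisson(1.5, n)
    max_size = np.exp(rng.normal(np.log(20), 0.5, n)).round(0).clip(1, None)

    patient_ids = [f"P{i + 1:03d}" for i in range(n)]
    slide_ids = [f"SL{i + 1:03d}" for i in range(n)]
    cohort = pd.DataFrame(
        dict(
            patient_id=patient_ids,
            slide_id=slide_ids,
            age=age,
            tumor_number=tumor_number,
            max_size_mm=max_size,
            **cov,
            dfs_time=np.round(dfs_time, 3),
            dfs_event=dfs_event.astype(int),
            os_time=np.round(os_time, 3),
            os_event=os_event.astype(int),
        )
    )

    # --- spatial subset: earliest recurrences vs longest event-free
    m = config.spatial_subset_size
    arms = {}
    if m > 0:
        ev_idx = np.flatnonzero(dfs_event)
        free_idx = np.flatnonzero(~dfs_event)
        if len(ev_idx) < m or len(free_idx) < m:
            raise TammorphError(
                f"cohort too small for a {m}+{m} spatial subset "
                f"({len(ev_idx)} events, {len(free_idx)} event-free)"
            )
        early = ev_idx[np.argsort(dfs_time[ev_idx])][:m]
        favorable = free_idx[np.argsort(-dfs_time[free_idx])][:m]
        arms.update({slide_ids[i]: "early" for i in early})
        arms.update({slide_ids[i]: "favorable" for i in favorable})

    # --- slides
    contour = _circle_polygon(config.tumor_radius)
    slides = {}
    cluster_parents = {}
    for i, sid in enumerate(slide_ids):
        outlines = _render_zone_cells(sid, true_mean[i], config, rng)
        if sid in arms:
            geom, ltam, stam = generate_spatial_patterns(config, arms[sid], rng)
            outlines.extend(_render_band_cells(sid, ltam, stam, config, rng))
            cluster_parents[sid] = int(len(ltam))
        slides[sid] = SlideAnnotation(sid, outlines, contour.copy())

    truth = dict(
        seed=int(config.seed),
        hazard_ratio=float(config.hazard_ratio),
        baseline_hazard=float(config.baseline_hazard),
        true_class={
            pid: ("L-TAM" if large else "S-TAM")
            for pid, large in zip(patient_ids, is_large)
        },
        true_slide_mean_area={
            pid: float(a) for pid, a in zip(patient_ids, true_mean)
        },
        spatial_arm={slide_ids[i]: arms[slide_ids[i]] for i in range(n) if slide_ids[i] in arms},
        n_band_ltams=cluster_parents,
    )
    return SyntheticCohort(config=config, cohort=cohort, slides=slides, truth=truth)


def config_to_dict(config: GeneratorConfig) -> dict:
    return asdict(config)
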
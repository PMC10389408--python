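"""End-to-end driver: simulate/load -> measure -> classify -> survive -> spatial.

Stages run in the order of the bench protocol. Each stage logs counts and
writes its outputs as soon as it completes, so a failure in a later stage
(for example a degenerate outcome vector in the survival stage) still leaves
the earlier stages' files on disk. Stage failures are re-raised as
:class:`StageError` naming the stage, with the original exception chained.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from . import cohort as cstats
from . import io as tio
from . import morphometry as morph
from . import spatial as sp
from .errors import DegenerateLabelsError, StageError
from .morphometry import BAND_ZONE
from .simulate import GeneratorConfig, SyntheticCohort, generate_cohort

logger = logging.getLogger("tammorph")

__all__ = ["PipelineResult", "run_pipeline"]

#: univariate screening roster (column -> type); the Cox model then takes the
#: TAM class plus every roster variable with univariate p < alpha
UNIVARIATE_ROSTER = {
    "age": "continuous",
    "sex_male": "binary",
    "tumor_number": "continuous",
    "max_size_mm": "continuous",
    "neoadjuvant": "binary",
    "cea_elevated": "binary",
    "ca199_elevated": "binary",
    "t34": "binary",
    "n_positive": "binary",
    "synchronous": "binary",
    "g34": "binary",
    "ras_mutated": "binary",
    "bilobar": "binary",
    "rectum_primary": "binary",
    "mean_tam_area": "continuous",
}


@dataclasses.dataclass
class PipelineResult:
    config: tio.PipelineConfig
    morphometry: pd.DataFrame  # per sampled cell
    slide_summary: pd.DataFrame  # per slide (zone-averaged)
    cohort: pd.DataFrame  # with mean_tam_area and tam_class
    roc: cstats.RocResult | None
    cutoff: float
    univariate: pd.DataFrame | None = None
    km_curves: dict | None = None  # class -> SurvivalCurve
    dfs36: dict | None = None  # class -> 3-year DFS fraction
    logrank: tuple | None = None  # (chi2, p)
    cox: cstats.CoxResult | None = None
    spatial_foci: pd.DataFrame | None = None
    foci_test: tuple | None = None  # (U, p)
    pooled_stats: dict | None = None
    manifest: dict | None = None


def _stage(name):
    def deco(fn):
        def wrapper(*a, **k):
            t0 = time.perf_counter()
            try:
                out = fn(*a, **k)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, str(exc)) from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


@_stage("acquire")
def _acquire(config, generator, input_dir):
    if input_dir is not None:
        input_dir = Path(input_dir)
        cohort = tio.read_cohort_csv(input_dir / "cohort.csv")
        slides = {}
        for sid in cohort["slide_id"]:
            path = input_dir / "slides" / f"{sid}.geojson"
            outlines, contour, rejected = tio.read_slide_annotations(path)
            slides[sid] = (outlines, contour)
            if rejected:
                logger.warning("slide %s: %d features rejected", sid, len(rejected))
        return cohort, slides
    sc: SyntheticCohort = generate_cohort(generator)
    slides = {sid: (s.outlines, s.tumor_contour) for sid, s in sc.slides.items()}
    return sc.cohort.copy(), slides


@_stage("measure")
def _measure(config, slides):
    all_outlines = [o for outlines, _ in slides.values() for o in outlines]
    sampled = morph.sample_cells(
        all_outlines,
        zones_per_slide=config.zones_per_slide,
        cells_per_zone=config.cells_per_zone,
        seed=config.seed,
    )
    percell = morph.measure_cells(sampled, validate=False)
    summary = morph.summarize_cohort(percell)
    return percell, summary


@_stage("classify")
def _classify(config, cohort, summary):
    merged = cohort.merge(
        summary.rename(columns={"slide_mean_area_um2": "mean_tam_area"})[
            ["slide_id", "mean_tam_area"]
        ],
        on="slide_id",
        how="left",
    )
    roc = None
    if config.cutoff_mode == "fixed":
        cutoff = float(config.fixed_cutoff)
    else:
        roc = cstats.build_roc(
            merged["mean_tam_area"], merged["dfs_event"].astype(bool),
            seed=config.seed, alpha=config.alpha,
        )
        # one-SE Youden rule: stable, sensitivity-favoring (see cohort module)
        cutoff = cstats.one_se_cutoff(roc, config.cutoff_se_factor)
    classified = cstats.classify_patients(merged, cutoff)
    return classified, roc, cutoff


@_stage("survive")
def _survive(config, classified):
    ev = classified["dfs_event"].astype(bool)
    if not ev.any() or ev.all():
        raise DegenerateLabelsError(
            f"{int(ev.sum())} events in {len(ev)} patients; "
            "outcome-group comparison undefined"
        )
    univariate = cstats.univariate_table(
        classified,
        {k: v for k, v in UNIVARIATE_ROSTER.items() if k in classified.columns},
    )
    km, dfs36 = {}, {}
    groups = []
    for cls, grp in classified.groupby("tam_class"):
        curve = cstats.km_estimate(grp["dfs_time"], grp["dfs_event"].astype(bool))
        km[cls] = curve
        dfs36[cls] = cstats.survival_at(curve, 36.0)
        groups.append((grp["dfs_time"].to_numpy(), grp["dfs_event"].astype(bool).to_numpy()))
    logrank = cstats.logrank_test(*groups) if len(groups) >= 2 else None

    work = classified.copy()
    work["ltam"] = (work["tam_class"] == cstats.L_TAM).astype(int)
    selected = [
        v for v in univariate.index
        if univariate.loc[v, "p"] < config.alpha and v != "mean_tam_area"
    ]
    cox = cstats.cox_fit(
        work,
        ["ltam"] + selected,
        n_bootstrap=config.n_bootstrap,
        seed=config.seed,
        alpha=config.alpha,
    )
    return univariate, km, dfs36, logrank, cox


@_stage("spatial")
def _spatial(config, classified, slides, cutoff, outdir=None):
    """Foci analysis on every slide carrying peritumoral-band annotations.

    Cells in the band are classified L-TAM/S-TAM individually by their own
    area against the cohort cutoff; foci are detected on the L-TAM
    centroids. Slides are grouped by the recurrence flag for the comparison.
    """
    rows = []
    by_event = dict(
        classified.set_index("slide_id")["dfs_event"].astype(bool).items()
    )
    for sid, (outlines, contour) in slides.items():
        band_cells = [o for o in outlines if o.zone_id == BAND_ZONE]
        if not band_cells:
            continue
        geom = sp.build_band(contour, config.band_width, slide_id=sid)
        areas = np.array([morph.polygon_area(o.vertices, validate=False) for o in band_cells])
        cents = np.array([o.centroid for o in band_cells])
        ltam_xy = cents[areas >= cutoff]
        foci = sp.detect_foci(
            ltam_xy, geom,
            foci_radius=config.foci_radius,
            threshold=config.foci_threshold,
            pixel_size=config.pixel_size,
        )
        if outdir is not None:
            dmap = sp.density_map(
                ltam_xy, geom, count_radius=config.count_radius,
                pixel_size=config.pixel_size,
            )
            tio.save_density_map(dmap, Path(outdir) / f"density_{sid}")
            (Path(outdir) / f"foci_{sid}.geojson").write_text(
                json.dumps(tio.foci_to_geojson(foci), sort_keys=True)
            )
        rows.append(
            dict(
                slide_id=sid,
                n_band_cells=len(band_cells),
                n_ltam=int((areas >= cutoff).sum()),
                n_foci=foci.n_foci,
                total_foci_area_um2=foci.total_foci_area,
                recurrence=bool(by_event.get(sid, False)),
            )
        )
    if not rows:
        return None, None
    table = pd.DataFrame(rows)
    rec = table[table["recurrence"]]["total_foci_area_um2"].to_numpy()
    free = table[~table["recurrence"]]["total_foci_area_um2"].to_numpy()
    test = sp.compare_foci(rec, free) if len(rec) and len(free) else None
    return table, test


def run_pipeline(
    config: tio.PipelineConfig | None = None,
    generator: GeneratorConfig | None = None,
    input_dir=None,
    outdir=None,
) -> PipelineResult:
    """Run the full analysis, from annotations (or simulation) to reports.

    With ``input_dir`` the cohort CSV and per-slide GeoJSON files are read;
    otherwise a synthetic cohort is generated from ``generator`` (defaulting
    to the study-scale generator seeded from the pipeline seed). When
    ``outdir`` is given, every stage writes its outputs there as it
    completes, plus a run manifest.
    """
    config = (config or tio.PipelineConfig()).validate()
    if generator is None and input_dir is None:
        generator = GeneratorConfig(seed=config.seed)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)

    cohort, slides = _acquire(config, generator, input_dir)
    percell, summary = _measure(config, slides)
    if outdir is not None:
        percell.to_csv(outdir / "morphometry.csv", index=False)
        summary.to_csv(outdir / "slide_summary.csv", index=False)

    pooled = dict(
        pooled_cell_mean_area=float(percell["area_um2"].mean()),
        pooled_cell_sd_area=float(percell["area_um2"].std(ddof=1)),
        pooled_cell_mean_perimeter=float(percell["perimeter_um"].mean()),
        pooled_cell_sd_perimeter=float(percell["perimeter_um"].std(ddof=1)),
        slide_mean_area=float(summary["slide_mean_area_um2"].mean()),
        slide_sd_area=float(summary["slide_mean_area_um2"].std(ddof=1)),
        slide_mean_perimeter=float(summary["slide_mean_perimeter_um"].mean()),
        slide_sd_perimeter=float(summary["slide_mean_perimeter_um"].std(ddof=1)),
    )

    classified, roc, cutoff = _classify(config, cohort, summary)
    result = PipelineResult(
        config=config,
        morphometry=percell,
        slide_summary=summary,
        cohort=classified,
        roc=roc,
        cutoff=cutoff,
        pooled_stats=pooled,
    )
    if outdir is not None:
        classified.to_csv(outdir / "cohort_classified.csv", index=False)
        cut = dict(cutoff_um2=cutoff, mode=config.cutoff_mode)
        if roc is not None:
            at = int(np.searchsorted(roc.thresholds, cutoff))
            cut.update(
                auc=roc.auc, auc_ci=list(roc.auc_ci),
                sensitivity=float(roc.sensitivity[at]),
                specificity=float(roc.specificity[at]),
            )
            pd.DataFrame(
                dict(threshold=roc.thresholds, sensitivity=roc.sensitivity,
                     specificity=roc.specificity)
            ).to_csv(outdir / "roc.csv", index=False)
        (outdir / "cutoff.json").write_text(json.dumps(cut, sort_keys=True))

    univariate, km, dfs36, logrank, cox = _survive(config, classified)
    result.univariate = univariate
    result.km_curves = km
    result.dfs36 = dfs36
    result.logrank = logrank
    result.cox = cox
    if outdir is not None:
        univariate.to_csv(outdir / "univariate.csv")
        cox_out = result.cox.summary.copy()
        if result.cox.bootstrap is not None:
            cox_out = cox_out.join(result.cox.bootstrap)
        cox_out.to_csv(outdir / "cox.csv")
        for cls, curve in km.items():
            pd.DataFrame(
                dict(time=curve.times, survival=curve.survival, at_risk=curve.at_risk)
            ).to_csv(outdir / f"km_{cls.replace('-', '').lower()}.csv", index=False)

    foci_table, foci_test = _spatial(config, classified, slides, cutoff, outdir)
    result.spatial_foci = foci_table
    result.foci_test = foci_test
    if outdir is not None and foci_table is not None:
        foci_table.to_csv(outdir / "foci.csv", index=False)

    result.manifest = dict(
        package="tammorph",
        version=_version,
        seed=config.seed,
        config=config.to_dict(),
        generator=None if generator is None else dataclasses.asdict(generator),
        input_dir=None if input_dir is None else str(input_dir),
        n_patients=int(len(classified)),
        n_cells_measured=int(len(percell)),
        cutoff_um2=float(cutoff),
        versions=dict(numpy=np.__version__, pandas=pd.__version__),
    )
    if outdir is not None:
        (outdir / "manifest.json").write_text(
            json.dumps(result.manifest, sort_keys=True, indent=1)
        )
    return result
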
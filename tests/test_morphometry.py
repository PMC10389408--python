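"""Morphometry: shoelace area, edge-sum perimeter, sampling, aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tammorph import (
    CellOutline,
    InvalidGeometryError,
    UndersampledZoneError,
    measure_cells,
    polygon_area,
    polygon_perimeter,
    sample_cells,
    summarize_slide,
)
from .conftest import edge_sum_perimeter, fan_triangulation_area

SQUARE = [(0, 0), (1, 0), (1, 1), (0, 1)]
TRIANGLE = [(0, 0), (4, 0), (0, 3)]


def regular_polygon(n, r):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([r * np.cos(t), r * np.sin(t)])


@pytest.mark.parametrize(
    "vertices, expected",
    [(SQUARE, 1.0), (TRIANGLE, 6.0)],
)
def test_polygon_area_closed_forms(vertices, expected):
    assert polygon_area(vertices) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "vertices, expected",
    [(SQUARE, 4.0), (TRIANGLE, 12.0)],  # 3-4-5 triangle
)
def test_polygon_perimeter_closed_forms(vertices, expected):
    assert polygon_perimeter(vertices) == pytest.approx(expected, abs=1e-12)


def test_fine_regular_polygon_matches_triangulation_oracle():
    v = regular_polygon(360, 8.33)
    assert polygon_area(v) == pytest.approx(fan_triangulation_area(v), rel=1e-9)


@pytest.mark.parametrize("n, r", [(3, 1.0), (7, 2.5), (100, 8.33)])
def test_regular_polygon_perimeter_closed_form(n, r):
    # perimeter of a regular n-gon of circumradius r is 2*n*r*sin(pi/n)
    v = regular_polygon(n, r)
    expected = 2 * n * r * np.sin(np.pi / n)
    assert polygon_perimeter(v) == pytest.approx(expected, rel=1e-12)
    assert polygon_perimeter(v) == pytest.approx(edge_sum_perimeter(v), rel=1e-12)


def test_area_perimeter_match_oracles_on_random_polygons(rng, star_polygon_factory):
    for _ in range(200):
        v = star_polygon_factory(rng)
        assert polygon_area(v) == pytest.approx(fan_triangulation_area(v), rel=1e-9)
        assert polygon_perimeter(v) == pytest.approx(edge_sum_perimeter(v), rel=1e-9)


def test_invariance_under_rigid_motions_and_reversal(rng, star_polygon_factory):
    v = star_polygon_factory(rng)
    a0, p0 = polygon_area(v), polygon_perimeter(v)
    # translation
    vt = v + np.array([123.4, -56.7])
    # rotation
    th = 1.234
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    vr = v @ rot.T
    # vertex-order reversal
    vv = v[::-1]
    for w in (vt, vr, vv):
        assert polygon_area(w) == pytest.approx(a0, rel=1e-9)
        assert polygon_perimeter(w) == pytest.approx(p0, rel=1e-9)
    # uniform scaling: area ~ s^2, perimeter ~ s
    s = 3.7
    assert polygon_area(v * s) == pytest.approx(a0 * s * s, rel=1e-9)
    assert polygon_perimeter(v * s) == pytest.approx(p0 * s, rel=1e-9)


def test_isoperimetric_ratio_approaches_one_for_fine_regular_polygons():
    ratios = []
    for n in (8, 64, 512):
        v = regular_polygon(n, 5.0)
        ratios.append(polygon_perimeter(v) ** 2 / (4 * np.pi * polygon_area(v)))
    assert all(r >= 1.0 for r in ratios)
    assert ratios == sorted(ratios, reverse=True)  # finer polygon, closer to 1
    assert ratios[-1] == pytest.approx(1.0, abs=1e-4)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    scale=st.floats(0.01, 100.0),
    dx=st.floats(-1e4, 1e4),
    dy=st.floats(-1e4, 1e4),
)
def test_similarity_transform_property(seed, scale, dx, dy):
    # area scales quadratically, perimeter linearly, under any similarity
    from .conftest import random_star_polygon

    v = random_star_polygon(np.random.default_rng(seed))
    w = v * scale + np.array([dx, dy])
    expected_area = polygon_area(v) * scale**2
    # shoelace cancellation grows with (offset/size)^2: widen the tolerance
    # by the conditioning of the translated coordinates
    cond = np.finfo(float).eps * np.abs(w).max() ** 2 / expected_area
    assert polygon_area(w) == pytest.approx(expected_area, rel=1e-6 + 100 * cond)
    assert polygon_perimeter(w) == pytest.approx(polygon_perimeter(v) * scale, rel=1e-6)


@pytest.mark.parametrize(
    "vertices",
    [
        [(0, 0), (1, 1)],  # too few
        [(0, 0), (1, 1), (1, 0), (0, 1)],  # bowtie self-intersection
        [(0, 0), (1, 0), (2, 0)],  # collinear, zero area
    ],
)
def test_invalid_polygons_rejected(vertices):
    with pytest.raises(InvalidGeometryError):
        polygon_area(vertices)
    with pytest.raises(InvalidGeometryError):
        polygon_perimeter(vertices)


# ---------------------------------------------------------------------------
# sampling protocol


def _slide(slide_id="SL1", zones=3, cells=10):
    out = []
    for z in range(1, zones + 1):
        for c in range(cells):
            v = regular_polygon(12, 5.0) + np.array([100 * z, 10 * c])
            out.append(
                CellOutline(f"{slide_id}_z{z}_c{c}", slide_id, f"zone{z}", v)
            )
    return out


def test_protocol_yields_21_cells_per_slide():
    sampled = sample_cells(_slide(), zones_per_slide=3, cells_per_zone=7, seed=0)
    assert len(sampled) == 21
    per_zone = pd.Series([o.zone_id for o in sampled]).value_counts()
    assert (per_zone == 7).all()


def test_sampling_is_deterministic_and_slide_local():
    outlines = _slide("A") + _slide("B")
    s1 = sample_cells(outlines, seed=7)
    s2 = sample_cells(outlines, seed=7)
    assert [o.cell_id for o in s1] == [o.cell_id for o in s2]
    # adding a slide must not perturb slide A's draw
    a_only = [o.cell_id for o in sample_cells(_slide("A"), seed=7)]
    a_with_b = [o.cell_id for o in s1 if o.slide_id == "A"]
    assert a_only == a_with_b
    # different seed gives a different draw
    assert [o.cell_id for o in sample_cells(outlines, seed=8)] != [
        o.cell_id for o in s1
    ]


def test_minimal_sampling_and_undersampled_zone_error():
    one = sample_cells(_slide(zones=1, cells=1), zones_per_slide=1, cells_per_zone=1, seed=0)
    assert len(one) == 1
    with pytest.raises(UndersampledZoneError) as exc:
        sample_cells(_slide(zones=3, cells=5), cells_per_zone=7, seed=0)
    assert "zone" in str(exc.value)


# ---------------------------------------------------------------------------
# slide aggregation


def _records(slide_id, zone_areas):
    rows = []
    for z, areas in zone_areas.items():
        for i, a in enumerate(areas):
            rows.append(
                dict(slide_id=slide_id, zone_id=z, cell_id=f"{z}_{i}",
                     area_um2=float(a), perimeter_um=4 * np.sqrt(a))
            )
    return pd.DataFrame(rows)


def test_slide_mean_is_mean_of_zone_means_not_pooled():
    s = summarize_slide(_records("S", {"z1": [100, 200], "z2": [300]}))
    assert s.zone_means["z1"][0] == pytest.approx(150.0)
    assert s.zone_means["z2"][0] == pytest.approx(300.0)
    assert s.slide_mean_area == pytest.approx(225.0)  # not the pooled 200
    assert s.n_cells == 3


def test_single_cell_slide_mean_is_identity():
    s = summarize_slide(_records("S", {"z1": [123.4]}))
    assert s.slide_mean_area == pytest.approx(123.4)


def test_three_zone_mean_matches_direct_arithmetic(rng):
    zones = {f"z{k}": rng.uniform(80, 300, 7) for k in range(3)}
    s = summarize_slide(_records("S", zones))
    expected = np.mean([np.mean(a) for a in zones.values()])
    assert s.slide_mean_area == pytest.approx(expected, rel=1e-12)


def test_equal_zone_sizes_make_zone_mean_equal_pooled(rng):
    zones = {f"z{k}": rng.uniform(80, 300, 5) for k in range(3)}
    df = _records("S", zones)
    s = summarize_slide(df)
    assert s.slide_mean_area == pytest.approx(df["area_um2"].mean(), rel=1e-12)
    # unequal sizes: mean of means differs from pooled mean
    zones["z0"] = np.concatenate([zones["z0"], [1000.0]])
    df2 = _records("S", zones)
    s2 = summarize_slide(df2)
    assert s2.slide_mean_area != pytest.approx(df2["area_um2"].mean(), rel=1e-6)


def test_measure_cells_frame_shape():
    df = measure_cells(_slide(cells=2))
    assert set(df.columns) == {"slide_id", "zone_id", "cell_id", "area_um2", "perimeter_um"}
    assert (df["area_um2"] > 0).all() and (df["perimeter_um"] > 0).all()
    with pytest.raises(ValueError):
        summarize_slide(df.iloc[0:0])
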
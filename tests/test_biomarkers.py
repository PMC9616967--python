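"""Biomarker panel: definitions, degenerate rules, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qvasc.biomarkers import (BiomarkerVector, extract_all, fractal_dimension,
                              murray_deviation, spatial_vascularity_pattern,
                              vessel_density, vessel_density_ratio)
from qvasc.segmentation import BranchPoint, VesselImage, segment_image
from qvasc.synthetic import disk_mask, generate_vessel_tree, rasterize_tree
from tests.conftest import make_oracle_tree


def make_branch(d_mother, d_daughters):
    return BranchPoint(node_id=0, pos=np.zeros(2), mother=0,
                       daughters=list(range(1, 1 + len(d_daughters))),
                       d_mother_mm=d_mother, d_daughters_mm=list(d_daughters))


# ------------------------------------------------------------ vessel density

def test_vessel_density_pixel_count():
    mask = np.zeros((100, 100), dtype=bool)
    mask[:] = True
    binary = np.zeros_like(mask)
    binary[0:10, 0:25] = True            # 250 px
    binary[20:30, 0:25] = True
    binary[40:50, 0:25] = True
    binary[60:70, 0:25] = True
    assert vessel_density(binary, mask) == pytest.approx(0.10)
    assert vessel_density(mask, mask) == 1.0
    assert vessel_density(np.zeros_like(mask), mask) == 0.0
    with pytest.raises(ValueError):
        vessel_density(binary, np.zeros_like(mask))


# --------------------------------------------------------- Murray deviation

@pytest.mark.parametrize("dm, dd, expected", [
    (1.0, (0.7937005259840998,) * 2, 0.0),       # cube law satisfied
    (1.0, (1.0, 1.0), 1.0),                      # |1 - 2| / 1
    (2.0, (1.0, 1.0, 1.0), abs(8 - 3) / 8),      # trifurcation sums all cubes
])
def test_murray_deviation_formula(dm, dd, expected):
    assert murray_deviation(make_branch(dm, dd)) == pytest.approx(expected, abs=1e-9)


def test_murray_deviation_scale_free():
    b1 = make_branch(1.0, (0.9, 0.6))
    b2 = make_branch(3.7, (0.9 * 3.7, 0.6 * 3.7))
    assert murray_deviation(b1) == pytest.approx(murray_deviation(b2))


def test_murray_deviation_zero_mother_is_nan():
    assert math.isnan(murray_deviation(make_branch(0.0, (0.5, 0.5))))


# --------------------------------------------------------- degenerate rules

def test_no_branch_points_forces_md_one_ba_180():
    """A lesion whose graph has NB = 0 carries MD = 1 and BA = 180 deg."""
    strip = np.zeros((40, 80), dtype=bool)
    strip[17:23, 5:75] = True
    bm = extract_all(strip, pixel_spacing=0.05)
    assert bm.NB == 0
    assert bm.MD_mean == bm.MD_max == 1.0
    assert bm.BA_mean == bm.BA_max == 180.0


def test_empty_image_degenerate_vector():
    bm = extract_all(np.zeros((64, 64), dtype=bool), pixel_spacing=0.05)
    assert (bm.NB, bm.NV, bm.VD) == (0, 0, 0.0)
    assert bm.MD_mean == 1.0 and bm.BA_mean == 180.0
    assert bm.mvFD == 0.0
    assert math.isnan(bm.SVP)


# -------------------------------------------------------- bifurcation angle

def test_perpendicular_daughters_measure_90():
    img = np.zeros((60, 60), dtype=bool)
    img[30, 5:31] = True                  # mother along -x
    img[30:56, 30] = True                 # daughter +y
    img[30, 30:56] = True                 # daughter +x
    from qvasc.biomarkers import bifurcation_angle
    from qvasc.segmentation import build_graph
    g = build_graph(img, img, 0.05)
    (bp,) = g.branch_points()
    assert bifurcation_angle(g, bp) == pytest.approx(90.0, abs=3.0)


def test_constructed_bifurcation_angle_recovered():
    tree = generate_vessel_tree(branching=2, depth=2, seed=2, tortuosity=0.0,
                                root_radius=0.3, branch_angle_mean=47.0,
                                branch_angle_std=1e-6, root_direction_deg=33,
                                segment_length=2.0)
    lo, hi = tree.bounds_mm()
    side = int(np.ceil((hi - lo).max() / 0.05)) + 20
    lesion = rasterize_tree(tree, 0.05, (side, side))
    bm = extract_all(lesion.image, pixel_spacing=0.05)
    assert bm.BA_mean == pytest.approx(47.0, abs=5.0)


def test_bifurcation_angle_rotation_invariant():
    res = make_oracle_tree(3, spacing=0.05, depth=2)
    assert res is not None
    _, lesion = res
    bm0 = extract_all(lesion.image, pixel_spacing=0.05)
    bm90 = extract_all(np.rot90(lesion.image).copy(), pixel_spacing=0.05)
    assert bm90.BA_mean == pytest.approx(bm0.BA_mean, abs=3.0)


# -------------------------------------------------------- fractal dimension

def test_fractal_dimension_calibration_line_square_sierpinski():
    line = np.zeros((256, 256), dtype=bool)
    idx = np.arange(256)
    line[idx, idx] = True
    assert fractal_dimension(line)[0] == pytest.approx(1.0, abs=0.1)

    square = np.ones((256, 256), dtype=bool)
    assert fractal_dimension(square)[0] == pytest.approx(2.0, abs=0.1)

    x, y = np.meshgrid(np.arange(256), np.arange(256))
    sierpinski = (x & y) == 0
    assert fractal_dimension(sierpinski)[0] == pytest.approx(
        math.log(3) / math.log(2), abs=0.05)


def test_box_counts_non_increasing_and_slope_bounded():
    rng = np.random.default_rng(0)
    for _ in range(5):
        img = rng.random((120, 160)) < rng.uniform(0.002, 0.4)
        if not img.any():
            continue
        fd, curve = fractal_dimension(img)
        assert np.all(np.diff(curve.counts) <= 0)
        assert 0.0 <= fd <= 2.0


def test_fractal_dimension_empty_warns_zero():
    with pytest.warns(UserWarning):
        fd, curve = fractal_dimension(np.zeros((32, 32), dtype=bool))
    assert fd == 0.0


# ------------------------------------------------------------------ VDR/SVP

def test_vdr_central_only_is_infinite():
    mask = disk_mask((200, 200), (100, 100), 80)
    yy, xx = np.ogrid[:200, :200]
    r2 = (yy - 100) ** 2 + (xx - 100) ** 2
    central = r2 <= (0.4 * 80) ** 2
    assert vessel_density_ratio(central, mask) == math.inf


def test_vdr_uniform_density_near_one():
    mask = disk_mask((200, 200), (100, 100), 80)
    rng = np.random.default_rng(1)
    binary = mask & (rng.random((200, 200)) < 0.3)
    assert vessel_density_ratio(binary, mask) == pytest.approx(1.0, abs=0.1)


def test_vdr_denser_periphery_ratio():
    """Periphery loaded at 3x the central density -> VDR ~ 1/3."""
    mask = disk_mask((240, 240), (120, 120), 100)
    rng = np.random.default_rng(2)
    from qvasc.biomarkers import _center_region
    center = _center_region(mask, 0.5)
    periph = mask & ~center
    binary = (center & (rng.random(mask.shape) < 0.1)) | \
             (periph & (rng.random(mask.shape) < 0.3))
    assert vessel_density_ratio(binary, mask) == pytest.approx(1 / 3, abs=0.05)


def test_vdr_requires_splittable_mask():
    with pytest.raises(ValueError):
        vessel_density_ratio(np.zeros((9, 9), bool), np.zeros((9, 9), bool))


@pytest.mark.parametrize("vdr, svp", [(0.4, 0.0), (2.5, 1.0), (1.0, 1.0)])
def test_svp_sign_rules_and_tie(vdr, svp):
    assert spatial_vascularity_pattern(vdr) == svp


def test_svp_tie_rule_configurable_and_nan_propagates():
    assert spatial_vascularity_pattern(1.0, tie_value=0) == 0.0
    assert math.isnan(spatial_vascularity_pattern(float("nan")))


@settings(max_examples=50, deadline=None)
@given(st.floats(min_value=0.0, max_value=50.0, allow_nan=False))
def test_svp_follows_vdr_sign_everywhere(vdr):
    svp = spatial_vascularity_pattern(vdr)
    if vdr < 1:
        assert svp == 0.0
    elif vdr > 1:
        assert svp == 1.0


# ------------------------------------------------------------- extract_all

def test_extract_all_murray_ideal_tree():
    res = make_oracle_tree(1, spacing=0.02, root_radius=0.5)
    assert res is not None
    tree, lesion = res
    bm = extract_all(VesselImage(lesion.image, 0.02, mask=lesion.mask))
    assert bm.NB == tree.n_branch_points and bm.NV == tree.n_segments
    assert bm.MD_mean == pytest.approx(0.0, abs=0.05)
    assert bm.BA_mean == pytest.approx(tree.gt_branch_angles().mean(), abs=5.0)
    assert set(BiomarkerVector.FEATURE_NAMES) <= set(bm.as_dict())


def test_extract_all_raw_raster_requires_spacing():
    with pytest.raises(ValueError):
        extract_all(np.zeros((8, 8), dtype=bool))
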
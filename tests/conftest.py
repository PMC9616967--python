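import numpy as np
import pandas as pd
import pytest

from qvasc.biomarkers import extract_all
from qvasc.segmentation import VesselImage
from qvasc.synthetic import generate_cohort, generate_vessel_tree, rasterize_tree


@pytest.fixture
def y_skeleton():
    """1-px Y: one degree-3 junction, three segments."""
    img = np.zeros((40, 40), dtype=bool)
    for i in range(20):
        img[20 + i, 20] = True          # stem down
        img[20 - i, 20 - i] = True      # arm up-left
        img[20 - i, 20 + i] = True      # arm up-right
    return img


@pytest.fixture
def x_skeleton():
    """1-px X: two crossing lines -> one degree-4 node, four segments."""
    img = np.zeros((41, 41), dtype=bool)
    for i in range(41):
        img[i, i] = True
        img[i, 40 - i] = True
    return img


@pytest.fixture
def straight_strip():
    """Horizontal strip 6 px wide."""
    img = np.zeros((40, 80), dtype=bool)
    img[17:23, 5:75] = True
    return img


def make_oracle_tree(seed, *, spacing, root_radius=0.4, tortuosity=0.03,
                     depth=3, branch_angle_mean=85.0):
    """Small tree certified for exact topology recovery (clearance check).

    Returns (tree, lesion) or None when the random geometry self-touches
    (the recovery guarantees only hold for non-overlapping trees).
    """
    rng = np.random.default_rng(seed)
    tree = generate_vessel_tree(
        branching=2, depth=depth, seed=seed, tortuosity=tortuosity,
        root_radius=root_radius, branch_angle_mean=branch_angle_mean,
        branch_angle_std=8.0, root_direction_deg=rng.uniform(0, 360),
        segment_length=2.2)
    if tree.min_clearance_mm() < 3 * spacing:
        return None
    lo, hi = tree.bounds_mm()
    side = int(np.ceil((hi - lo).max() / spacing)) + 20
    lesion = rasterize_tree(tree, pixel_spacing=spacing, canvas=(side, side))
    return tree, lesion


@pytest.fixture(scope="session")
def small_cohort_table():
    """Biomarkers extracted through the full pipeline, 12+12 lesions."""
    rows = []
    for lesion in generate_cohort(12, 12, size_mix="mixed", seed=42):
        bm = extract_all(
            VesselImage(lesion.image, lesion.pixel_spacing, mask=lesion.mask),
            lesion_size_mm=lesion.lesion_size_mm, label=lesion.label)
        row = bm.as_dict()
        row["size_class"] = lesion.size_class
        rows.append(row)
    return pd.DataFrame(rows)
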
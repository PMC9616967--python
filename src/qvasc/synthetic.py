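"""Parametric 2-D vascular networks with known ground truth.

Every downstream stage of the pipeline (skeletonization, graph building,
biomarker extraction, classification) is validated against trees produced
here: the generator stores exact centerline polylines, per-point radii and
branch topology, so branch counts, segment counts, tortuosity (distance
metric), diameters, bifurcation angles and Murray deviations can all be
recomputed in closed form from the stored geometry.

Coordinates are (x, y) in millimetres; rasterization converts to pixel
(row, col) with a configurable pixel spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import disk as _draw_disk
from skimage.morphology import convex_hull_image, disk as _disk_selem

__all__ = [
    "Segment",
    "BranchRecord",
    "VesselTree",
    "SyntheticLesion",
    "generate_vessel_tree",
    "rasterize_tree",
    "disk_mask",
    "generate_lesion",
    "generate_cohort",
    "SIZE_CLASSES",
]

#: lesion diameter strata (mm): name -> (low, high)
SIZE_CLASSES = {
    "small": (5.0, 9.0),      # d < 10 mm
    "medium": (10.0, 20.0),   # 10 <= d <= 20 mm
    "large": (21.0, 30.0),    # d > 20 mm
}

_DEFAULT_GT_FIT_LEN_MM = 0.8  # arc length used to measure ground-truth branch angles


@dataclass
class Segment:
    """One vessel segment: centerline polyline with per-point radii."""

    points: np.ndarray          # (N, 2) float64, (x, y) mm
    radii: np.ndarray           # (N,) mm, > 0
    parent: int = -1            # index of parent segment, -1 for a root
    depth: int = 0

    @property
    def length_mm(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.points, axis=0).T)))

    @property
    def chord_mm(self) -> float:
        return float(np.hypot(*(self.points[-1] - self.points[0])))

    @property
    def distance_metric(self) -> float:
        """Path length / chord length (tortuosity), >= 1 for an open curve."""
        chord = self.chord_mm
        if chord <= 0:
            return math.nan
        return self.length_mm / chord

    @property
    def mean_diameter_mm(self) -> float:
        return float(np.mean(2.0 * self.radii))


@dataclass
class BranchRecord:
    """Ground truth at one branch point."""

    node_xy: np.ndarray         # (2,) mm
    mother: int                 # parent segment index
    daughters: list[int]        # child segment indices
    angle_deg: float            # between the two largest daughters
    murray_exponent: float      # exponent actually used to split radii


@dataclass
class VesselTree:
    """A vascular forest (one or more rooted trees) with exact ground truth."""

    segments: list[Segment] = field(default_factory=list)
    branches: list[BranchRecord] = field(default_factory=list)

    # ---- ground-truth morphometrics -------------------------------------

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_branch_points(self) -> int:
        return len(self.branches)

    def gt_distance_metrics(self) -> np.ndarray:
        return np.array([s.distance_metric for s in self.segments])

    def gt_diameters_mm(self) -> np.ndarray:
        return np.array([s.mean_diameter_mm for s in self.segments])

    def gt_branch_angles(self) -> np.ndarray:
        return np.array([b.angle_deg for b in self.branches])

    def gt_murray_deviations(self) -> np.ndarray:
        """MD per branch from the stored radii (cube-law deviation).

        Mother diameter is taken at the parent's distal end, daughter
        diameters at each child's proximal end, exactly where the vessels
        meet.
        """
        out = []
        for b in self.branches:
            dm = 2.0 * self.segments[b.mother].radii[-1]
            dd = np.array([2.0 * self.segments[i].radii[0] for i in b.daughters])
            out.append(abs(dm**3 - np.sum(dd**3)) / dm**3)
        return np.array(out)

    def bounds_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """(min_xy, max_xy) over all centerline points, inflated by radius."""
        lo = np.full(2, np.inf)
        hi = np.full(2, -np.inf)
        for s in self.segments:
            r = s.radii[:, None]
            lo = np.minimum(lo, np.min(s.points - r, axis=0))
            hi = np.maximum(hi, np.max(s.points + r, axis=0))
        return lo, hi

    def min_clearance_mm(self) -> float:
        """Smallest surface gap between non-adjacent segments.

        Positive values mean the rasterized tree cannot self-touch except at
        branch points; used to certify trees for exact topology recovery.
        """
        segs = self.segments
        n = len(segs)
        adjacent = {(i, i) for i in range(n)}
        for j, s in enumerate(segs):
            if s.parent >= 0:
                adjacent.add((min(j, s.parent), max(j, s.parent)))
        # siblings share the branch node
        for b in self.branches:
            ids = [b.mother] + list(b.daughters)
            for a in ids:
                for c in ids:
                    adjacent.add((min(a, c), max(a, c)))
        best = np.inf
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in adjacent:
                    continue
                d = _polyline_gap(segs[i], segs[j])
                best = min(best, d)
        return float(best)


def _polyline_gap(a: Segment, b: Segment) -> float:
    da = np.linalg.norm(a.points[:, None, :] - b.points[None, :, :], axis=-1)
    ra = a.radii[:, None]
    rb = b.radii[None, :]
    return float(np.min(da - ra - rb))


@dataclass
class SyntheticLesion:
    """Rasterized lesion: ground-truth tree + binary vessel image + mask."""

    tree: VesselTree
    image: np.ndarray           # bool (H, W), vessel pixels
    mask: np.ndarray            # bool (H, W), lesion region
    pixel_spacing: float        # mm / px
    label: str = "benign"       # "benign" | "malignant"
    size_class: str = "medium"
    lesion_size_mm: float = float("nan")
    placement: str = ""         # "central" | "peripheral" | ""


# --------------------------------------------------------------------------
# tree generation
# --------------------------------------------------------------------------

def _validate_params(**kw) -> None:
    for name, v in kw.items():
        if not np.all(np.isfinite(v)):
            raise ValueError(f"parameter {name!r} must be finite, got {v!r}")


def _tortuous_polyline(
    p0: np.ndarray,
    direction: np.ndarray,
    length: float,
    amplitude: float,
    rng: np.random.Generator,
    step: float = 0.15,
) -> np.ndarray:
    """Meandering centerline from p0 of given chord length.

    A straight chord perturbed perpendicular by a seeded sinusoid plus a
    smooth random-walk component; displacement vanishes at both endpoints so
    children attach exactly at the stored tip.
    """
    n = max(8, int(math.ceil(length / step)) + 1)
    t = np.linspace(0.0, 1.0, n)
    d = direction / np.linalg.norm(direction)
    perp = np.array([-d[1], d[0]])
    base = p0[None, :] + (t * length)[:, None] * d[None, :]
    if amplitude <= 0:
        return base
    # meander wavelength stays at vessel scale (>= ~1.5 mm): microvessel
    # tortuosity lives above the diameter scale, and sub-resolution wiggle
    # would vanish in any raster anyway
    max_waves = max(1, min(3, int(length / 1.5)))
    n_waves = int(rng.integers(1, max_waves + 1))
    phase = rng.uniform(0, 2 * np.pi)
    offset = np.sin(np.pi * t) * np.sin(2 * np.pi * n_waves * t + phase)
    # smooth random-walk texture, endpoint-pinned
    walk = np.cumsum(rng.normal(0.0, 1.0, n))
    walk -= t * walk[-1]
    k = max(5, n // 3)
    kern = np.hanning(k)
    kern /= kern.sum()
    walk = np.convolve(walk, kern, mode="same")
    walk *= np.sin(np.pi * t)
    wmax = np.max(np.abs(walk))
    if wmax > 0:
        walk = walk / wmax * 0.35
    offset = amplitude * length * (offset + walk)
    return base + offset[:, None] * perp[None, :]


def _initial_direction(points: np.ndarray, fit_len_mm: float,
                       exclude_mm: float = 0.0) -> np.ndarray:
    """Unit direction of a polyline near its start.

    Measured as the chord over ``fit_len_mm`` of arc starting
    ``exclude_mm`` in from the first point. Branch angles use the mother's
    end radius as the exclusion, since inside the junction zone the daughter
    vessels have not yet physically separated.
    """
    steps = np.hypot(*np.diff(points, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(steps)])
    i0 = int(np.searchsorted(arc, exclude_mm))
    i1 = int(np.searchsorted(arc, exclude_mm + fit_len_mm))
    i1 = min(max(i1, i0 + 1), len(points) - 1)
    i0 = min(i0, i1 - 1)
    v = points[i1] - points[i0]
    nrm = np.linalg.norm(v)
    if nrm == 0:  # pragma: no cover - degenerate polyline
        return np.array([1.0, 0.0])
    return v / nrm


def _branch_angle(tree: "VesselTree", mother: int, daughters: list[int]) -> float:
    """Ground-truth angle between the two largest daughters of a branch.

    Directions are taken past the junction zone (1.5 mother radii of arc):
    inside it the daughters have not physically separated, so no observer of
    the image could assign them directions there.
    """
    r0 = [tree.segments[i].radii[0] for i in daughters]
    order = np.argsort(r0)[::-1][:2]
    excl = 1.5 * float(tree.segments[mother].radii[-1])
    u = _initial_direction(tree.segments[daughters[order[0]]].points,
                           _DEFAULT_GT_FIT_LEN_MM, excl)
    v = _initial_direction(tree.segments[daughters[order[1]]].points,
                           _DEFAULT_GT_FIT_LEN_MM, excl)
    return _angle_between(u, v)


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1))
    return math.degrees(math.acos(c))


def generate_vessel_tree(
    branching: float = 2.0,
    tortuosity: float = 0.08,
    root_radius: float = 0.3,
    murray_exponent: float | tuple[float, float] = 3.0,
    depth: int = 3,
    seed: int | np.random.Generator | None = None,
    *,
    segment_length: float = 2.0,
    length_decay: float = 0.8,
    branch_angle_mean: float = 75.0,
    branch_angle_std: float = 10.0,
    root_xy: tuple[float, float] = (0.0, 0.0),
    root_direction_deg: float | None = None,
    radius_floor: float = 0.08,
    split_jitter: float = 0.0,
    taper: float = 1.0,
) -> VesselTree:
    """Grow a random rooted vessel tree with exact stored ground truth.

    Parameters
    ----------
    branching
        Expected number of daughter segments spawned at each internal tip.
        Tips bifurcate with probability min(branching/2, 1); with
        ``branching > 2`` a third daughter appears with probability
        ``branching/2 - 1``. A branch event always creates >= 2 daughters, so
        every internal node has degree >= 3 and stored NB/NV counts match the
        skeleton-graph definition of branch points and segments.
    tortuosity
        Perpendicular meander amplitude as a fraction of segment length
        (0 = straight vessels).
    root_radius
        Vessel radius at the root, mm.
    murray_exponent
        Radius-scaling exponent m at branchings: daughter radii satisfy
        sum(r_d^m) = r_mother^m. A scalar uses the same exponent everywhere
        (m = 3 reproduces Murray's cube law exactly, ground-truth deviation
        0); a (lo, hi) tuple samples m per branch, injecting controlled
        Murray-law violations.
    depth
        Number of generations; depth 1 is a single root segment.
    seed
        Seed or Generator for all randomness; fixed seed => identical tree.
    segment_length, length_decay
        Chord length of root segments (mm) and the per-generation shrink
        factor.
    branch_angle_mean, branch_angle_std
        Opening angle (deg) between the two outer daughters, drawn per
        branch from a clipped normal.
    radius_floor
        Lower clamp on radii (mm), keeping all vessels resolvable after
        rasterization.
    split_jitter
        Asymmetry of the radius split: daughter weights drawn uniformly in
        ``1/k +- split_jitter`` then normalized (0 = exact equal split).
    taper
        End/start radius ratio along each segment (1 = constant radius).
    """
    _validate_params(
        branching=branching, tortuosity=tortuosity, root_radius=root_radius,
        murray_exponent=murray_exponent, depth=depth,
        segment_length=segment_length, branch_angle_mean=branch_angle_mean,
    )
    if depth < 1:
        if branching > 0:
            raise ValueError("depth must be >= 1 when branching > 0")
        raise ValueError("depth must be >= 1")
    if min(branching, tortuosity, root_radius, segment_length) < 0:
        raise ValueError("parameters must be non-negative")
    if root_radius <= 0:
        raise ValueError("root_radius must be > 0")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tree = VesselTree()

    theta0 = rng.uniform(0, 360) if root_direction_deg is None else float(root_direction_deg)
    d0 = np.array([math.cos(math.radians(theta0)), math.sin(math.radians(theta0))])

    def grow(p0: np.ndarray, direction: np.ndarray, radius: float,
             level: int, parent: int) -> int:
        length = segment_length * length_decay ** level
        pts = _tortuous_polyline(p0, direction, length, tortuosity, rng)
        r_end = max(radius * taper, radius_floor)
        radii = np.linspace(radius, r_end, len(pts))
        seg = Segment(points=pts, radii=radii, parent=parent, depth=level)
        idx = len(tree.segments)
        tree.segments.append(seg)

        if level + 1 >= depth:
            return idx
        p_branch = min(branching / 2.0, 1.0)
        if rng.random() >= p_branch:
            return idx
        k = 2
        if branching > 2 and rng.random() < (branching / 2.0 - 1.0):
            k = 3

        # radius split: sum(r_i^m) = r_end^m
        m = (
            float(rng.uniform(*murray_exponent))
            if isinstance(murray_exponent, tuple)
            else float(murray_exponent)
        )
        if split_jitter > 0:
            w = rng.uniform(max(1.0 / k - split_jitter, 0.05),
                            1.0 / k + split_jitter, size=k)
            w = w / w.sum()
        else:
            w = np.full(k, 1.0 / k)
        child_radii = np.maximum(r_end * w ** (1.0 / m), radius_floor)

        opening = float(np.clip(rng.normal(branch_angle_mean, branch_angle_std),
                                15.0, 165.0))
        out_dir = pts[-1] - pts[-2]
        base_theta = math.degrees(math.atan2(out_dir[1], out_dir[0]))
        if k == 2:
            thetas = [base_theta - opening / 2.0, base_theta + opening / 2.0]
        else:
            thetas = [base_theta - opening / 2.0, base_theta, base_theta + opening / 2.0]

        child_ids = []
        for r_c, th in zip(child_radii, thetas):
            dvec = np.array([math.cos(math.radians(th)), math.sin(math.radians(th))])
            child_ids.append(grow(pts[-1].copy(), dvec, float(r_c), level + 1, idx))

        # ground-truth angle measured on the final (perturbed) polylines,
        # outside the junction zone, exactly as an observer of the image
        # would see it
        tree.branches.append(BranchRecord(
            node_xy=pts[-1].copy(),
            mother=idx,
            daughters=child_ids,
            angle_deg=_branch_angle(tree, idx, child_ids),
            murray_exponent=m,
        ))
        return idx

    grow(np.asarray(root_xy, dtype=float), d0, float(root_radius), 0, -1)
    return tree


# --------------------------------------------------------------------------
# rasterization
# --------------------------------------------------------------------------

def rasterize_tree(
    tree: VesselTree,
    pixel_spacing: float = 0.05,
    canvas: tuple[int, int] = (512, 512),
    origin_mm: tuple[float, float] | None = None,
    mask_margin_px: int = 10,
    min_diameter_px: float = 3.0,
) -> SyntheticLesion:
    """Rasterize a vessel tree to a binary image plus a lesion mask.

    Each centerline is resampled at sub-pixel steps and dilated by its local
    radius (disk stamping). The lesion mask is the convex hull of the vessel
    pixels dilated by ``mask_margin_px``, i.e. a single closed region
    containing every vessel pixel.

    ``origin_mm`` maps mm coordinates to pixels: pixel (row, col) center sits
    at ``origin_mm + (col, row) * pixel_spacing``. When None the tree's
    bounding box is centered on the canvas. A vessel extending beyond the
    canvas raises ValueError naming the offending segment.
    """
    if pixel_spacing <= 0:
        raise ValueError("pixel_spacing must be > 0")
    H, W = canvas
    img = np.zeros((H, W), dtype=bool)
    if not tree.segments:
        mask = np.zeros((H, W), dtype=bool)
        return SyntheticLesion(tree=tree, image=img, mask=mask,
                               pixel_spacing=pixel_spacing)

    min_d_px = 2.0 * min(float(np.min(s.radii)) for s in tree.segments) / pixel_spacing
    if min_d_px < min_diameter_px:
        raise ValueError(
            f"pixel_spacing too coarse: minimum vessel diameter is {min_d_px:.2f} px"
            f" (< {min_diameter_px} px); reduce pixel_spacing or thicken vessels"
        )

    if origin_mm is None:
        lo, hi = tree.bounds_mm()
        center = (lo + hi) / 2.0
        origin = center - np.array([W, H]) / 2.0 * pixel_spacing
    else:
        origin = np.asarray(origin_mm, dtype=float)

    for i, seg in enumerate(tree.segments):
        pts_px = (seg.points - origin[None, :]) / pixel_spacing  # (x, y) px
        r_px = seg.radii / pixel_spacing
        lo_ok = np.all(pts_px - r_px[:, None] >= -0.5)
        hi_ok = np.all(pts_px + r_px[:, None] <= np.array([W, H]) - 0.5)
        if not (lo_ok and hi_ok):
            raise ValueError(f"segment {i} exceeds the canvas; enlarge canvas "
                             "or shift origin_mm")
        # resample at ~0.4 px for gap-free stamping
        steps = np.hypot(*np.diff(pts_px, axis=0).T)
        arc = np.concatenate([[0.0], np.cumsum(steps)])
        n = max(2, int(math.ceil(arc[-1] / 0.4)) + 1)
        s = np.linspace(0.0, arc[-1], n)
        xs = np.interp(s, arc, pts_px[:, 0])
        ys = np.interp(s, arc, pts_px[:, 1])
        rs = np.interp(s, arc, r_px)
        for x, y, r in zip(xs, ys, rs):
            rr, cc = _draw_disk((y, x), r, shape=(H, W))
            img[rr, cc] = True

    mask = ndimage.binary_dilation(convex_hull_image(img),
                                   structure=_disk_selem(mask_margin_px))
    return SyntheticLesion(tree=tree, image=img, mask=mask,
                           pixel_spacing=pixel_spacing)


def disk_mask(canvas: tuple[int, int], center_px: tuple[float, float],
              radius_px: float) -> np.ndarray:
    """Boolean disk mask (row, col center)."""
    H, W = canvas
    rr, cc = np.ogrid[:H, :W]
    return (rr - center_px[0]) ** 2 + (cc - center_px[1]) ** 2 <= radius_px**2


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

# parameter ranges for the two lesion phenotypes; chosen once as plausible
# submillimetre-vessel morphology (see docs/methods.md)
_PHENOTYPES = {
    "benign": dict(
        branching=(1.2, 1.8), tortuosity=(0.02, 0.08),
        root_radius=(0.17, 0.24), murray_exponent=(2.85, 3.15),
        branch_angle_mean=(95.0, 120.0), depth={"small": 2, "medium": 2, "large": 2},
        n_trees=(2, 3),
    ),
    "malignant": dict(
        branching=(1.9, 2.6), tortuosity=(0.12, 0.22),
        root_radius=(0.26, 0.38), murray_exponent=(1.9, 4.4),
        branch_angle_mean=(35.0, 55.0), depth={"small": 2, "medium": 3, "large": 3},
        n_trees=(2, 3),
    ),
}

# radial bands (fraction of lesion radius) for vessel placement; the
# peripheral band starts outside the default 50%-area center region
# (radius ~0.707 R) so the two spatial patterns are unambiguous
_BANDS = {"central": (0.0, 0.65), "peripheral": (0.74, 0.96)}

# cumulative radial reach of a tree, in units of its root segment length
_GROWTH = {1: 1.0, 2: 1.8, 3: 2.44}


def _confine_tree(tree: VesselTree, center: np.ndarray, band_mm: tuple[float, float],
                  placement: str) -> None:
    """Rescale polylines in place so every centerline lies in the band."""
    if placement == "central":
        rmax = max(float(np.max(np.linalg.norm(s.points - center, axis=1)))
                   for s in tree.segments)
        if rmax > band_mm[1]:
            f = band_mm[1] / rmax
            for s in tree.segments:
                s.points[:] = center + (s.points - center) * f
    else:
        mid = 0.5 * (band_mm[0] + band_mm[1])
        half = 0.5 * (band_mm[1] - band_mm[0])
        dev = max(float(np.max(np.abs(np.linalg.norm(s.points - center, axis=1) - mid)))
                  for s in tree.segments)
        if dev > half:
            f = half / dev
            for s in tree.segments:
                v = s.points - center
                r = np.linalg.norm(v, axis=1)
                u = v / np.maximum(r[:, None], 1e-12)
                r_new = mid + (r - mid) * f
                s.points[:] = center + u * r_new[:, None]
    # branch node positions and stored angles follow the transformed geometry
    for b in tree.branches:
        b.node_xy = tree.segments[b.daughters[0]].points[0].copy()
        b.angle_deg = _branch_angle(tree, b.mother, b.daughters)


def generate_lesion(
    label: str = "benign",
    size_class: str = "medium",
    placement: str | None = None,
    seed: int | np.random.Generator | None = None,
    pixel_spacing: float = 0.05,
) -> SyntheticLesion:
    """Generate one synthetic lesion (forest of trees, raster, disk mask).

    Spatial vascularity placement follows the malignancy/size interaction:
    small/medium malignant lesions get centrally concentrated vessels and
    large malignant lesions peripheral ones; benign lesions the opposite.
    Pass ``placement`` explicitly to override.
    """
    if label not in _PHENOTYPES:
        raise ValueError(f"label must be benign|malignant, got {label!r}")
    if size_class not in SIZE_CLASSES:
        raise ValueError(f"size_class must be one of {sorted(SIZE_CLASSES)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ph = _PHENOTYPES[label]
    d_mm = float(rng.uniform(*SIZE_CLASSES[size_class]))
    if placement is None:
        if label == "malignant":
            placement = "peripheral" if size_class == "large" else "central"
        else:
            placement = "central" if size_class == "large" else "peripheral"

    R = d_mm / 2.0
    band = tuple(b * R for b in _BANDS[placement])
    margin_px = 12
    side = int(math.ceil(d_mm / pixel_spacing)) + 2 * margin_px
    center_mm = np.array([side, side]) * pixel_spacing / 2.0

    n_trees = int(rng.integers(ph["n_trees"][0], ph["n_trees"][1] + 1))
    depth = ph["depth"][size_class]
    forest = VesselTree()
    # root segment length derived from the space each tree actually has, so
    # trees fill their band without piling on top of each other
    if placement == "central":
        seg_len = max(0.8, 0.60 * R / _GROWTH[depth])
    else:
        arc_per_tree = 2 * math.pi * 0.85 * R / n_trees
        seg_len = max(0.8, min(0.35 * R, 0.45 * arc_per_tree / _GROWTH[depth]))
    phi0 = rng.uniform(0, 2 * np.pi)
    for t in range(n_trees):
        phi = phi0 + 2 * np.pi * t / n_trees + rng.normal(0, 0.2)
        if placement == "central":
            root = center_mm + 0.10 * R * np.array([math.cos(phi), math.sin(phi)])
            direction = math.degrees(phi) + rng.normal(0, 30)
        else:
            mid = 0.5 * (band[0] + band[1])
            root = center_mm + mid * np.array([math.cos(phi), math.sin(phi)])
            direction = math.degrees(phi) + 90 + rng.normal(0, 15)  # tangential
        tree = generate_vessel_tree(
            branching=float(rng.uniform(*ph["branching"])),
            tortuosity=float(rng.uniform(*ph["tortuosity"])),
            root_radius=float(rng.uniform(*ph["root_radius"])),
            murray_exponent=ph["murray_exponent"],
            depth=depth,
            seed=rng,
            segment_length=seg_len,
            branch_angle_mean=float(rng.uniform(*ph["branch_angle_mean"])),
            branch_angle_std=6.0,
            root_xy=tuple(root),
            root_direction_deg=direction,
            split_jitter=0.08,
        )
        _confine_tree(tree, center_mm, band, placement)
        off = len(forest.segments)
        for s in tree.segments:
            if s.parent >= 0:
                s.parent += off
            forest.segments.append(s)
        for b in tree.branches:
            b.mother += off
            b.daughters = [i + off for i in b.daughters]
            forest.branches.append(b)

    lesion = rasterize_tree(forest, pixel_spacing=pixel_spacing,
                            canvas=(side, side), origin_mm=(0.0, 0.0))
    lesion.mask = disk_mask((side, side), (side / 2.0, side / 2.0),
                            R / pixel_spacing)
    lesion.label = label
    lesion.size_class = size_class
    lesion.lesion_size_mm = d_mm
    lesion.placement = placement
    return lesion


def generate_cohort(
    n_benign: int,
    n_malignant: int,
    size_mix: str | dict[str, float] = "mixed",
    seed: int | None = None,
    pixel_spacing: float = 0.05,
) -> list[SyntheticLesion]:
    """Generate a labelled cohort of synthetic lesions.

    ``size_mix`` is a size-class name ("small"/"medium"/"large") or "mixed"
    (equal thirds), or a dict of class -> probability. Malignant-like lesions
    are drawn with higher branching, tortuosity, Murray-law violation and
    root diameter and smaller bifurcation angles than benign-like ones; the
    vessel placement (central vs peripheral) follows lesion size and label.
    All draws are seeded: the same arguments reproduce byte-identical
    rasters.
    """
    if n_benign < 0 or n_malignant < 0 or n_benign + n_malignant < 1:
        raise ValueError("need at least one lesion")
    if isinstance(size_mix, str):
        if size_mix == "mixed":
            probs = {k: 1.0 / 3.0 for k in SIZE_CLASSES}
        elif size_mix in SIZE_CLASSES:
            probs = {size_mix: 1.0}
        else:
            raise ValueError(f"unknown size_mix {size_mix!r}")
    else:
        probs = dict(size_mix)
    names = sorted(probs)
    p = np.array([probs[k] for k in names], dtype=float)
    p = p / p.sum()

    rng = np.random.default_rng(seed)
    lesions = []
    for label, n in (("benign", n_benign), ("malignant", n_malignant)):
        for _ in range(n):
            sc = str(rng.choice(names, p=p))
            lesions.append(generate_lesion(label=label, size_class=sc,
                                           seed=rng, pixel_spacing=pixel_spacing))
    return lesions
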
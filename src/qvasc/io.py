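"""Readers and writers for the pipeline's exchange formats.

Rasters travel as single-plane PNG or TIFF, tables as CSV, models and graph
topology as JSON. Synthetic lesions are written as a per-lesion bundle
(image, mask, ground-truth segments CSV, branch JSON) plus a cohort-level
ground-truth table.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .segmentation import VesselGraph
from .synthetic import SyntheticLesion

__all__ = [
    "read_image",
    "write_image",
    "write_lesion_bundle",
    "read_lesion_bundle",
    "graph_to_tables",
    "write_graph",
    "skeleton_overlay",
]


def read_image(path) -> np.ndarray:
    """Read a single-plane PNG/TIFF raster as a 2-D array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:           # collapse RGB(A) from viewers/editors
        arr = arr[..., :3].max(axis=-1)
    if arr.ndim != 2:
        raise ValueError(f"{path} is not a single-plane image")
    return arr


def write_image(path, arr: np.ndarray) -> None:
    path = Path(path)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


# --------------------------------------------------------------------------
# synthetic lesion bundles
# --------------------------------------------------------------------------

def write_lesion_bundle(lesion: SyntheticLesion, out_dir, stem: str) -> dict:
    """Write image/mask rasters and ground truth; return the index row."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_image(out / f"{stem}_image.png", lesion.image)
    write_image(out / f"{stem}_mask.png", lesion.mask)

    rows = []
    for i, s in enumerate(lesion.tree.segments):
        rows.append({
            "segment_id": i,
            "parent": s.parent,
            "depth": s.depth,
            "length_mm": s.length_mm,
            "chord_mm": s.chord_mm,
            "mean_radius_mm": float(np.mean(s.radii)),
        })
    pd.DataFrame(rows).to_csv(out / f"{stem}_segments.csv", index=False)

    md = lesion.tree.gt_murray_deviations()
    branches = [{
        "node_xy_mm": [float(v) for v in b.node_xy],
        "mother": b.mother,
        "daughters": list(b.daughters),
        "angle_deg": b.angle_deg,
        "murray_exponent": b.murray_exponent,
        "murray_deviation": float(md[i]),
    } for i, b in enumerate(lesion.tree.branches)]
    with open(out / f"{stem}_branches.json", "w") as fh:
        json.dump({
            "label": lesion.label,
            "size_class": lesion.size_class,
            "lesion_size_mm": lesion.lesion_size_mm,
            "placement": lesion.placement,
            "pixel_spacing": lesion.pixel_spacing,
            "branches": branches,
        }, fh, indent=2)

    return {
        "stem": stem,
        "label": lesion.label,
        "size_class": lesion.size_class,
        "lesion_size_mm": lesion.lesion_size_mm,
        "placement": lesion.placement,
        "pixel_spacing": lesion.pixel_spacing,
        "gt_NB": lesion.tree.n_branch_points,
        "gt_NV": lesion.tree.n_segments,
    }


def read_lesion_bundle(out_dir, stem: str) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read back (image, mask, metadata) written by write_lesion_bundle."""
    out = Path(out_dir)
    image = read_image(out / f"{stem}_image.png") > 0
    mask = read_image(out / f"{stem}_mask.png") > 0
    with open(out / f"{stem}_branches.json") as fh:
        meta = json.load(fh)
    return image, mask, meta


# --------------------------------------------------------------------------
# graphs
# --------------------------------------------------------------------------

def graph_to_tables(graph: VesselGraph) -> tuple[pd.DataFrame, dict]:
    """(segments table, nodes/incidence JSON-ready dict) for a VesselGraph."""
    rows = []
    for s in graph.segments.values():
        rows.append({
            "segment_id": s.id,
            "node_a": s.node_a,
            "node_b": s.node_b,
            "n_points": s.n_points,
            "length_mm": s.length_mm,
            "chord_mm": s.chord_mm,
            "mean_diameter_mm": float(np.mean(2.0 * s.radii_mm)),
        })
    seg_df = pd.DataFrame(rows)
    nodes = {
        "pixel_spacing": graph.pixel_spacing,
        "nodes": [{"id": n.id, "pos_px": [float(v) for v in n.pos],
                   "degree": graph.degree(n.id)} for n in graph.nodes.values()],
        "incidence": {str(nid): graph.incident_segments(nid)
                      for nid in graph.nodes},
    }
    return seg_df, nodes


def write_graph(graph: VesselGraph, out_dir, stem: str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seg_df, nodes = graph_to_tables(graph)
    seg_df.to_csv(out / f"{stem}_graph_segments.csv", index=False)
    with open(out / f"{stem}_graph_nodes.json", "w") as fh:
        json.dump(nodes, fh, indent=2)


def skeleton_overlay(binary: np.ndarray, skeleton: np.ndarray) -> np.ndarray:
    """QC image: vessels in gray, centerline in white."""
    img = np.zeros(binary.shape, dtype=np.uint8)
    img[np.asarray(binary, bool)] = 128
    img[np.asarray(skeleton, bool)] = 255
    return img
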
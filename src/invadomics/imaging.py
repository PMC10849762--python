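"""Invasion-phenotype quantification from calibrated binary/labelled masks.

Implements the rule set used to quantify invasion assays:

* spheroid/reservoir invasion index ``(A_f - A_i) / A_i`` with optional
  normalization to a control group;
* per-cell geometry from connected components (area, perimeter, centroid,
  best-fit-ellipse aspect ratio, form factor ``4*pi*A / P^2``);
* detached cells: single cells with no neighbour within 10 um;
* highly invasive cells: centroid more than 200 um beyond the device's
  channel edge;
* morphology classes: elongated (aspect ratio >= 2) versus round.

Masks are plain arrays with a pixel size in micrometres; no raw-micrograph
segmentation is performed here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from skimage import measure

__all__ = [
    "CellObject",
    "load_mask",
    "measure_area",
    "invasion_index",
    "normalize_to_control",
    "segment_cells",
    "detect_detached",
    "classify_invasive",
    "classify_morphology",
]

ELONGATED_ASPECT_RATIO = 2.0   # inclusive: aspect ratio of 2 or more
DETACHED_RADIUS_UM = 10.0
HIGHLY_INVASIVE_UM = 200.0


@dataclass(frozen=True)
class CellObject:
    """Geometry of one segmented connected component, in micrometres."""

    label: int
    centroid: tuple[float, float]   # (x, y) um
    area: float                     # um^2
    perimeter: float                # um
    aspect_ratio: float             # major/minor axis of best-fit ellipse, >= 1
    form_factor: float              # 4*pi*A/P^2, ~1 for a circle
    distance_to_channel: float | None = None  # um, device assays only


def load_mask(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a mask image and its JSON calibration sidecar (``<path>.json``).

    Returns (mask array, sidecar dict).  The sidecar carries
    ``pixel_size_um`` and optionally ``channel_edge_x_um`` and
    ``timepoint_days``; it defaults to 1 um pixels when absent.
    """
    import imageio.v3 as iio

    path = Path(path)
    mask = np.asarray(iio.imread(path))
    sidecar_path = path.with_suffix(path.suffix + ".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() \
        else {"pixel_size_um": 1.0}
    return mask, sidecar


def measure_area(mask: np.ndarray, pixel_size_um: float = 1.0) -> float:
    """Total foreground area in um^2 (pixel count x pixel area)."""
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    n = int(np.count_nonzero(mask))
    if n == 0:
        warnings.warn("empty mask: area is 0", stacklevel=2)
    return n * pixel_size_um ** 2


def invasion_index(area_initial: float, area_final: float) -> float:
    """Relative area growth ``(A_f - A_i) / A_i`` of a spheroid or reservoir."""
    if area_initial <= 0:
        raise ValueError("initial area must be > 0")
    return (area_final - area_initial) / area_initial


def normalize_to_control(indices, control_indices) -> np.ndarray:
    """Divide each invasion index by the mean of the control group."""
    control_mean = float(np.mean(control_indices))
    if control_mean <= 0:
        raise ValueError("control mean must be > 0")
    return np.asarray(indices, dtype=float) / control_mean


def segment_cells(mask: np.ndarray, pixel_size_um: float = 1.0,
                  channel_edge_x_um: float | None = None) -> list[CellObject]:
    """Extract per-cell geometry from a binary or labelled mask.

    Connected components use 8-connectivity; a labelled input is used as-is.
    Centroids are reported as (x, y) in micrometres with the image origin at
    the top-left corner.  ``aspect_ratio`` is the major/minor axis ratio of
    the intensity-equivalent ellipse; degenerate (zero-minor-axis) objects
    such as 1-px lines get ``inf``, single pixels get 1.
    """
    mask = np.asarray(mask)
    if mask.dtype == bool or set(np.unique(mask)) <= {0, 1, 255}:
        labels = measure.label(mask > 0, connectivity=2)
    else:
        labels = mask.astype(int)
    cells: list[CellObject] = []
    for rp in measure.regionprops(labels):
        cy, cx = rp.centroid
        minor, major = rp.axis_minor_length, rp.axis_major_length
        if major == 0:
            ar = 1.0          # single pixel
        elif minor == 0:
            ar = float("inf")  # 1-px-wide line
        else:
            ar = major / minor
        perim = rp.perimeter * pixel_size_um
        area = rp.area * pixel_size_um ** 2
        # circularity capped at 1 for tiny objects whose discrete perimeter
        # underestimates the true boundary (same convention as ImageJ)
        ff = min(4.0 * np.pi * area / perim ** 2, 1.0) if perim > 0 else 1.0
        x_um = cx * pixel_size_um
        dist = None
        if channel_edge_x_um is not None:
            dist = x_um - channel_edge_x_um
        cells.append(CellObject(
            label=int(rp.label), centroid=(x_um, cy * pixel_size_um),
            area=float(area), perimeter=float(perim),
            aspect_ratio=float(ar), form_factor=float(ff),
            distance_to_channel=dist))
    return cells


def detect_detached(cells: list[CellObject], radius_um: float = DETACHED_RADIUS_UM,
                    distance_mode: str = "centroid") -> list[CellObject]:
    """Cells with no neighbouring cell within ``radius_um``.

    A neighbour at exactly ``radius_um`` blocks detachment (the rule reads
    "without neighbouring cells within 10 um", treated inclusively).  A lone
    cell is detached by definition.  ``distance_mode`` is ``centroid``
    (centroid-to-centroid, deterministic default) or ``edge``, which
    subtracts each cell's area-equivalent circle radius from the centroid
    distance to approximate the boundary gap.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be > 0")
    if distance_mode not in ("centroid", "edge"):
        raise ValueError("distance_mode must be 'centroid' or 'edge'")
    if len(cells) == 0:
        return []
    if len(cells) == 1:
        return list(cells)
    pts = np.array([c.centroid for c in cells])
    if distance_mode == "centroid":
        tree = cKDTree(pts)
        dists, _ = tree.query(pts, k=2)
        nearest = dists[:, 1]
    else:
        r = np.sqrt(np.array([c.area for c in cells]) / np.pi)
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        gap = d - r[:, None] - r[None, :]
        np.fill_diagonal(gap, np.inf)
        nearest = gap.min(axis=1)
    return [c for c, d in zip(cells, nearest) if d > radius_um]


def classify_invasive(cells: list[CellObject], channel_edge_x_um: float | None = None,
                      threshold_um: float = HIGHLY_INVASIVE_UM) -> list[bool]:
    """Highly invasive: centroid strictly more than ``threshold_um`` past the edge.

    Uses each cell's precomputed ``distance_to_channel`` unless
    ``channel_edge_x_um`` is given, in which case the perpendicular distance
    is recomputed from the centroid x-coordinate.
    """
    flags = []
    for c in cells:
        if channel_edge_x_um is not None:
            d = c.centroid[0] - channel_edge_x_um
        elif c.distance_to_channel is not None:
            d = c.distance_to_channel
        else:
            raise ValueError("channel edge position is not defined")
        flags.append(d > threshold_um)
    return flags


def classify_morphology(cell: CellObject) -> str:
    """``elongated`` iff aspect ratio >= 2, else ``round``."""
    return "elongated" if cell.aspect_ratio >= ELONGATED_ASPECT_RATIO else "round"
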
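"""Tool-tip localisation and orientation estimation from a binary mask.

The tip of an elongated instrument is found by medial-axis skeletonisation
followed by 8-connected endpoint analysis: a skeleton pixel with at most one
foreground neighbour is an endpoint, and the endpoint nearest the image
centre is taken as the tip (the operative field sits under the microscope
centre, and tools enter from the frame border).

Orientation is the angle of the minimum-area rotated rectangle enclosing the
mask: the rectangle's long-axis midline is anchored at the midline endpoint
closer to the image centre and the angle of the ray from that anchor through
the far endpoint, measured counter-clockwise from the +x axis with the image
y axis negated (mathematical convention), is reported in degrees in
[0, 360).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "TipPoint",
    "OrientationSample",
    "binarize_mask",
    "skeletonize",
    "prune_spurs",
    "find_endpoints",
    "select_tip",
    "min_area_rect",
    "estimate_orientation",
    "analyze_mask",
    "Detection",
]


@dataclass(frozen=True)
class TipPoint:
    x: float
    y: float
    frame_index: int = -1
    tool_class: str = ""


@dataclass(frozen=True)
class OrientationSample:
    theta: float  # degrees in [0, 360)
    frame_index: int = -1
    tool_class: str = ""


@dataclass(frozen=True)
class Detection:
    """A per-instance geometry result ready for temporal linking."""

    frame_index: int
    tool_class: str
    score: float
    x: float
    y: float
    theta: float | None


def binarize_mask(soft_mask: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a soft mask; pixels with value >= threshold become True."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    binary = np.asarray(soft_mask, dtype=float) >= threshold
    if not binary.any():
        warnings.warn("binarized mask is empty", RuntimeWarning, stacklevel=2)
    return binary


def _crop(mask: np.ndarray) -> tuple[np.ndarray, int, int]:
    """Crop to the foreground bounding box (1 px pad) for speed."""
    ys, xs = np.nonzero(mask)
    y0, y1 = ys.min(), ys.max()
    x0, x1 = xs.min(), xs.max()
    y0p = max(y0 - 1, 0)
    x0p = max(x0 - 1, 0)
    return mask[y0p : y1 + 2, x0p : x1 + 2], y0p, x0p


def skeletonize(mask: np.ndarray, method: str = "thin") -> np.ndarray:
    """Centreline skeleton of a binary mask (same shape, subset of mask).

    ``method="thin"`` uses fast morphological thinning; ``"medial_axis"``
    the exact medial-axis transform.  Both satisfy the skeleton contract
    (one pixel wide, connectivity preserving) that downstream endpoint
    analysis relies on; thinning is the default because it is an order of
    magnitude faster on video-sized masks.
    """
    import skimage.morphology as morph

    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot skeletonize an empty mask")
    fn = morph.medial_axis if method == "medial_axis" else morph.skeletonize
    crop, oy, ox = _crop(mask)
    skel_crop = fn(crop)
    skel = np.zeros_like(mask)
    skel[oy : oy + crop.shape[0], ox : ox + crop.shape[1]] = skel_crop
    return skel


_NEIGH = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    return ndimage.convolve(
        skel.astype(np.uint8), _NEIGH, mode="constant", cval=0
    )


def find_endpoints(skeleton: np.ndarray) -> list[tuple[int, int]]:
    """Skeleton pixels with <= 1 foreground 8-neighbour, as (x, y) tuples.

    Isolated pixels count as endpoints.  Output is sorted by (y, x) so the
    result is deterministic.
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    counts = _neighbor_counts(skeleton)
    ys, xs = np.nonzero(skeleton & (counts <= 1))
    return [(int(x), int(y)) for y, x in sorted(zip(ys, xs))]


_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _free_neighbors(skel, y, x, visited):
    out = []
    for dy, dx in _OFFSETS:
        ny, nx_ = y + dy, x + dx
        if 0 <= ny < skel.shape[0] and 0 <= nx_ < skel.shape[1]:
            if skel[ny, nx_] and (ny, nx_) not in visited:
                out.append((ny, nx_))
    return out


def _is_simple_point(skel: np.ndarray, y: int, x: int) -> bool:
    """True when deleting (y, x) cannot split its 3x3 neighbourhood."""
    from scipy.ndimage import label

    y0, y1 = max(y - 1, 0), min(y + 2, skel.shape[0])
    x0, x1 = max(x - 1, 0), min(x + 2, skel.shape[1])
    patch = skel[y0:y1, x0:x1].copy()
    patch[y - y0, x - x0] = False
    n = label(patch, structure=np.ones((3, 3), dtype=int))[1]
    return n <= 1


def prune_spurs(skeleton: np.ndarray, min_branch_px: int = 5) -> np.ndarray:
    """Remove side branches shorter than ``min_branch_px`` pixels.

    A branch is traced from each endpoint until a pixel with two or more
    untraced neighbours; short branches are deleted, including the
    attachment pixel when its removal cannot break connectivity (simple-
    point test).  Skeletons that are simple paths (two endpoints, no
    junction) are returned unchanged, so genuine tips are never eroded.
    """
    skel = np.asarray(skeleton, dtype=bool).copy()
    changed = True
    while changed:
        changed = False
        counts = _neighbor_counts(skel)
        if not (skel & (counts > 2)).any():
            break  # simple path or isolated pixels: nothing to prune
        for x0, y0 in find_endpoints(skel):
            if not skel[y0, x0]:
                continue
            path = [(y0, x0)]
            visited = {(y0, x0)}
            reached_junction = False
            while len(path) <= min_branch_px:
                free = _free_neighbors(skel, *path[-1], visited)
                if len(free) == 0:
                    break
                if len(free) >= 2:
                    reached_junction = True
                    break
                path.append(free[0])
                visited.add(free[0])
            if reached_junction and len(path) < min_branch_px:
                # Strict branch pixels go; the last traced pixel only if
                # its removal is topologically safe.
                *body, last = path
                for y, x in body:
                    skel[y, x] = False
                if _is_simple_point(skel, *last):
                    skel[last[0], last[1]] = False
                changed = True
    return skel


def select_tip(
    endpoints: list[tuple[float, float]],
    mask: np.ndarray,
    frame_shape: tuple[int, int] | None = None,
) -> tuple[float, float]:
    """Pick the endpoint nearest the image centre as the tool tip.

    The centre is ``((W-1)/2, (H-1)/2)``; ties are broken by smaller y,
    then smaller x.
    """
    if not endpoints:
        raise ValueError("select_tip requires at least one endpoint")
    h, w = frame_shape if frame_shape is not None else mask.shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    return min(
        endpoints,
        key=lambda p: ((p[0] - cx) ** 2 + (p[1] - cy) ** 2, p[1], p[0]),
    )


def min_area_rect(points: np.ndarray) -> np.ndarray:
    """Minimum-area rotated rectangle of a 2-D point set.

    Returns the 4 corner coordinates (open ring).  Uses the rotating-
    calipers property that one rectangle side is collinear with a convex
    hull edge (delegated to shapely).  Collinear input raises
    ``ValueError``.
    """
    from shapely import MultiPoint

    points = np.asarray(points, dtype=float)
    rect = MultiPoint(points).minimum_rotated_rectangle
    if rect.geom_type != "Polygon":
        raise ValueError("degenerate (collinear) point set")
    coords = np.asarray(rect.exterior.coords)[:4]
    return coords


def _hull_points(mask: np.ndarray) -> np.ndarray:
    """Convex-hull vertices of the foreground pixel centres."""
    from scipy.spatial import ConvexHull, QhullError

    ys, xs = np.nonzero(mask)
    pts = np.column_stack([xs, ys]).astype(float)
    if len(pts) < 3:
        return pts
    try:
        hull = ConvexHull(pts)
    except QhullError:  # collinear
        return pts
    return pts[hull.vertices]


def _ray_angle(ax: float, ay: float, bx: float, by: float) -> float:
    """Angle of ray a->b, CCW from +x with image y negated, in [0, 360)."""
    return math.degrees(math.atan2(-(by - ay), bx - ax)) % 360.0


def estimate_orientation(
    mask: np.ndarray,
    frame_shape: tuple[int, int] | None = None,
    origin: tuple[int, int] = (0, 0),
) -> float | None:
    """Orientation angle of a tool mask in degrees [0, 360), or None.

    The long-axis midline of the minimum-area rectangle is anchored at the
    midline endpoint closer to the image centre; the reported angle is that
    of the ray from the anchor through the far midline endpoint.  Masks
    with fewer than 3 foreground pixels have no orientation.  Collinear
    masks fall back to the fitted line through the two extreme pixels with
    the same anchoring rule.

    ``origin`` is the (x, y) image offset of the mask raster, so callers
    may pass a bounding-box crop without changing the centre-anchoring
    geometry.
    """
    mask = np.asarray(mask, dtype=bool)
    n_fg = int(mask.sum())
    if n_fg < 3:
        return None
    if frame_shape is None:
        h, w = mask.shape
    else:
        h, w = frame_shape
    cx, cy = (w - 1) / 2.0 - origin[0], (h - 1) / 2.0 - origin[1]

    hull = _hull_points(mask)
    try:
        corners = min_area_rect(hull)
    except ValueError:
        # Collinear: midline endpoints are the two extreme pixels.
        ys, xs = np.nonzero(mask)
        pts = np.column_stack([xs, ys]).astype(float)
        d = pts @ (pts.max(0) - pts.min(0))
        e1, e2 = pts[np.argmin(d)], pts[np.argmax(d)]
    else:
        edges = np.diff(np.vstack([corners, corners[:1]]), axis=0)
        lengths = np.hypot(edges[:, 0], edges[:, 1])
        # Midline endpoints = midpoints of the two short edges.
        if lengths[0] >= lengths[1]:
            e1 = (corners[0] + corners[3]) / 2.0
            e2 = (corners[1] + corners[2]) / 2.0
        else:
            e1 = (corners[0] + corners[1]) / 2.0
            e2 = (corners[2] + corners[3]) / 2.0
    d1 = (e1[0] - cx) ** 2 + (e1[1] - cy) ** 2
    d2 = (e2[0] - cx) ** 2 + (e2[1] - cy) ** 2
    anchor, far = (e1, e2) if d1 <= d2 else (e2, e1)
    return _ray_angle(anchor[0], anchor[1], far[0], far[1])


def analyze_mask(
    mask: np.ndarray,
    frame_shape: tuple[int, int] | None = None,
    spur_px: int = 5,
) -> tuple[tuple[float, float], float | None]:
    """Full per-instance geometry: (tip (x, y), orientation or None).

    Degenerate masks (< 3 px) use the centroid as tip and report no
    orientation.  Skeleton spurs shorter than ``spur_px`` are pruned before
    endpoint extraction to suppress rasterisation whiskers.
    """
    mask = np.asarray(mask, dtype=bool)
    if int(mask.sum()) < 3:
        ys, xs = np.nonzero(mask)
        if len(xs) == 0:
            raise ValueError("empty mask")
        return (float(xs.mean()), float(ys.mean())), None
    if frame_shape is None:
        frame_shape = mask.shape
    # All raster work happens on the bounding-box crop; coordinates are
    # shifted back into the full frame afterwards.
    crop, oy, ox = _crop(mask)
    skel = prune_spurs(skeletonize(crop), spur_px)
    endpoints = [(x + ox, y + oy) for x, y in find_endpoints(skel)]
    if not endpoints:
        ys, xs = np.nonzero(mask)
        tip = (float(xs.mean()), float(ys.mean()))
    else:
        tip = select_tip(endpoints, mask, frame_shape)
        tip = (float(tip[0]), float(tip[1]))
    theta = estimate_orientation(crop, frame_shape, origin=(ox, oy))
    if endpoints and theta is not None:
        tip = _refine_tip(mask, tip, theta)
    return tip, theta


def _refine_tip(
    mask: np.ndarray, tip: tuple[float, float], theta: float
) -> tuple[float, float]:
    """Snap the tip to the mask extremity along the estimated long axis.

    Thinning can stop a pixel or two short of a pointed apex; the true tip
    is the foreground pixel extremal along the tip-ward axis direction
    (the reverse of the anchor-to-far-end ray).  Ties — e.g. a blunt,
    axis-aligned end — are broken by proximity to the skeleton endpoint,
    then by (y, x), keeping the result deterministic.
    """
    rad = math.radians(theta)
    ux, uy = -math.cos(rad), math.sin(rad)  # tip-ward, image coords
    ys, xs = np.nonzero(mask)
    proj = xs * ux + ys * uy
    near = proj >= proj.max() - 0.5
    cand_x, cand_y = xs[near], ys[near]
    d2 = (cand_x - tip[0]) ** 2 + (cand_y - tip[1]) ** 2
    order = np.lexsort((cand_x, cand_y, d2))
    return (float(cand_x[order[0]]), float(cand_y[order[0]]))
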
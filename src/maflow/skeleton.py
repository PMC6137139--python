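"""Medial-axis centerline of a microaneurysm mask, from the Voronoi diagram.

The centerline is the subset of the Voronoi diagram of the silhouette's
boundary points that defines the medial axis of the mask: Voronoi vertices
falling strictly inside the silhouette, connected by their ridges.  The
inscribed radius at a medial point is the distance to the nearest boundary
point, i.e. the radius of the largest circle centered there and inscribed
in the mask.  The skeleton of a simply connected silhouette is a tree;
the feeding→draining channel is recovered as the maximal-arclength path
between leaves, discarding all side branches.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import shapely
from scipy import ndimage
from scipy.spatial import Voronoi, cKDTree
from shapely.geometry import Polygon

from .mask_model import BODY, CLOT, VESSEL, MaskSet, _FOUR_CONN

logger = logging.getLogger(__name__)

REGION_BODY = "body"
REGION_IN = "vessel_in"
REGION_OUT = "vessel_out"


class SkeletonError(ValueError):
    """Raised when no valid medial path can be extracted."""


@dataclasses.dataclass
class Centerline:
    """Ordered medial-axis path from the feeding to the draining stub.

    All coordinates in μm.  ``region`` holds per-point labels
    (``body`` / ``vessel_in`` / ``vessel_out``; empty string before
    partitioning).  ``extended`` flags points appended synthetically
    beyond the segmented mask (see ``reconstruction.extend_stubs``).
    """

    points: np.ndarray  # (n, 2)
    radius: np.ndarray  # (n,)
    region: np.ndarray  # (n,) unicode
    arclength: np.ndarray  # (n,) cumulative, starts at 0
    extended: np.ndarray | None = None  # (n,) bool

    def __post_init__(self) -> None:
        n = len(self.points)
        if self.extended is None:
            self.extended = np.zeros(n, dtype=bool)
        if not (len(self.radius) == len(self.region) == len(self.arclength) == n):
            raise ValueError("centerline field lengths disagree")
        if np.any(self.radius <= 0):
            raise ValueError("centerline radii must be > 0")
        if np.any(np.diff(self.arclength) <= 0):
            raise ValueError("arclength must be strictly increasing")

    @property
    def body_mask(self) -> np.ndarray:
        return self.region == REGION_BODY

    def segment(self, region: str) -> "Centerline":
        sel = self.region == region
        if not sel.any():
            raise SkeletonError(f"no centerline points in region {region!r}")
        return Centerline(
            self.points[sel],
            self.radius[sel],
            self.region[sel],
            self.arclength[sel],
            self.extended[sel],
        )

    def to_csv(self, path: str | Path) -> Path:
        import pandas as pd

        path = Path(path)
        pd.DataFrame(
            {
                "x_um": self.points[:, 0],
                "y_um": self.points[:, 1],
                "radius_um": self.radius,
                "region": self.region,
                "arclength_um": self.arclength,
                "extended": self.extended.astype(int),
            }
        ).to_csv(path, index=False)
        return path


# ---------------------------------------------------------------------------
# boundary extraction
# ---------------------------------------------------------------------------

# Moore neighborhood in clockwise order starting East (row, col offsets)
_MOORE = np.array(
    [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]
)


def _silhouette_filled(mask: MaskSet) -> np.ndarray:
    sil = mask.silhouette
    filled = ndimage.binary_fill_holes(sil)
    if (filled & ~sil).any():
        logger.warning("silhouette contained interior holes; filled before skeletonisation")
    labels, n = ndimage.label(filled, structure=_FOUR_CONN)
    if n != 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
        raise SkeletonError(
            f"silhouette is disconnected: {n} components with pixel counts "
            f"{sorted(int(v) for v in sizes)}"
        )
    return filled


def _trace_boundary(filled: np.ndarray) -> np.ndarray:
    """Moore-neighbor boundary trace; ordered (row, col) boundary pixels."""
    eroded = ndimage.binary_erosion(filled, structure=_FOUR_CONN, border_value=0)
    boundary = filled & ~eroded
    start = tuple(np.argwhere(boundary)[0])  # topmost-then-leftmost
    path = [start]
    # backtrack direction: we arrived scanning from the West
    prev_dir = 4
    cur = start
    h, w = filled.shape

    def neighbor(p, d):
        r, c = p[0] + _MOORE[d][0], p[1] + _MOORE[d][1]
        if 0 <= r < h and 0 <= c < w:
            return (r, c), filled[r, c]
        return (r, c), False

    while True:
        found = False
        for k in range(8):
            d = (prev_dir + 1 + k) % 8
            nxt, is_fg = neighbor(cur, d)
            if is_fg:
                if nxt == start and len(path) > 2:
                    return np.array(path)
                path.append(nxt)
                prev_dir = (d + 4) % 8
                cur = nxt
                found = True
                break
        if not found:  # isolated pixel
            return np.array(path)
        if len(path) > 8 * filled.size:  # pragma: no cover - safety valve
            raise SkeletonError("boundary trace failed to close")


def boundary_points(mask: MaskSet) -> np.ndarray:
    """Ordered closed boundary polygon of the silhouette, in μm, CCW.

    Returns the centers of the silhouette's boundary pixels in traversal
    order (counter-clockwise in the (x, y) frame).  Interior holes are
    filled with a logged warning; a disconnected silhouette raises.
    """
    filled = _silhouette_filled(mask)
    rc = _trace_boundary(filled)
    xy = np.column_stack([rc[:, 1], rc[:, 0]]).astype(float) * mask.pixel_size
    # enforce CCW (positive shoelace area)
    x, y = xy[:, 0], xy[:, 1]
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area2 < 0:
        xy = xy[::-1]
    return xy


def _smooth_closed(xy: np.ndarray, window: int = 3) -> np.ndarray:
    """Circular moving average along a closed polygon (spur suppression)."""
    kernel = np.ones(window) / window
    out = np.empty_like(xy)
    for k in range(2):
        padded = np.concatenate([xy[-(window // 2):, k], xy[:, k], xy[: window // 2, k]])
        out[:, k] = np.convolve(padded, kernel, mode="valid")
    return out


# ---------------------------------------------------------------------------
# medial axis
# ---------------------------------------------------------------------------


def medial_axis(mask: MaskSet, resample_factor: float = 0.5) -> Centerline:
    """Voronoi medial axis pruned to the single inlet→outlet path.

    The boundary polygon is smoothed with a 3-point moving average (raster
    boundaries otherwise seed dense spurious Voronoi branches), its Voronoi
    diagram restricted to interior vertices, and the resulting skeleton
    reduced to the maximal-arclength leaf-to-leaf path.  The path is
    resampled at ``resample_factor * pixel_size`` spacing with linear
    interpolation of the inscribed radii, and oriented from the feeding to
    the draining stub (``flow_direction`` hint, or ascending x).
    """
    raw_bpts = boundary_points(mask)
    bpts = _smooth_closed(raw_bpts)
    poly = Polygon(bpts)
    if not poly.is_valid:
        poly = poly.buffer(0)
    try:
        vor = Voronoi(bpts)
    except Exception as exc:  # qhull degenerate input (collinear boundary)
        raise SkeletonError(f"degenerate boundary, no medial axis: {exc}") from exc
    inside = shapely.contains_xy(poly, vor.vertices[:, 0], vor.vertices[:, 1])
    if not inside.any():
        raise SkeletonError("no interior Voronoi vertex: mask thinner than 2 px")

    # Voronoi topology comes from the smoothed polygon (stability).  The
    # inscribed radius averages the clearances to the foreground boundary
    # pixel centers and to the adjacent background centers: the physical
    # interface lies halfway between the two rings for any wall
    # orientation, so the average is an unbiased sub-pixel estimate.
    tree_bg = _background_tree(mask)
    tree_fg = cKDTree(raw_bpts)

    def inscribed_radius(points: np.ndarray) -> np.ndarray:
        d_bg, _ = tree_bg.query(points)
        d_fg, _ = tree_fg.query(points)
        return 0.5 * (d_bg + d_fg)

    vradius = inscribed_radius(vor.vertices)

    g = nx.Graph()
    for (v0, v1) in vor.ridge_vertices:
        if v0 < 0 or v1 < 0 or not (inside[v0] and inside[v1]):
            continue
        w = float(np.hypot(*(vor.vertices[v0] - vor.vertices[v1])))
        g.add_edge(v0, v1, weight=w)
    if g.number_of_edges() == 0:
        raise SkeletonError("medial graph is empty: mask too thin for a skeleton")
    if not nx.is_connected(g):
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()

    leaves = [v for v in g if g.degree(v) == 1] or list(g)[:1]
    # tree diameter by double sweep (exact on trees, robust otherwise)
    d0 = nx.single_source_dijkstra_path_length(g, leaves[0])
    far0 = max(d0, key=d0.get)
    d1, paths = nx.single_source_dijkstra(g, far0)
    far1 = max(d1, key=d1.get)
    path_idx = paths[far1]

    pts = vor.vertices[path_idx]
    rad = vradius[path_idx]
    pts, rad = _peel_contained_ends(pts, rad, tol=0.5 * mask.pixel_size)
    pts, rad = _trim_cap_ends(pts, rad, mask.pixel_size)

    # resample at fixed spacing with linear interpolation of x, y, radius
    seglen = np.hypot(*np.diff(pts, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    keep = np.concatenate([[True], seglen > 1e-12])
    pts, rad, arc = pts[keep], rad[keep], arc[keep]
    step = resample_factor * mask.pixel_size
    n_new = max(int(np.ceil(arc[-1] / step)) + 1, 2)
    s_new = np.linspace(0.0, arc[-1], n_new)
    pts_new = np.column_stack([np.interp(s_new, arc, pts[:, 0]), np.interp(s_new, arc, pts[:, 1])])
    rad_new = inscribed_radius(pts_new)

    c = Centerline(
        points=pts_new,
        radius=rad_new,
        region=np.full(n_new, "", dtype="<U10"),
        arclength=s_new,
    )
    return _orient(c, mask)


def _background_tree(mask: MaskSet) -> cKDTree:
    """KD-tree over the background pixel centers adjacent to the mask."""
    filled = ndimage.binary_fill_holes(mask.silhouette)
    ring = ndimage.binary_dilation(filled, structure=np.ones((3, 3), bool)) & ~filled
    rc = np.argwhere(ring)
    xy = np.column_stack([rc[:, 1], rc[:, 0]]).astype(float) * mask.pixel_size
    return cKDTree(xy)


def _trim_cap_ends(
    pts: np.ndarray, rad: np.ndarray, px: float
) -> tuple[np.ndarray, np.ndarray]:
    """Trim each path end by one local vessel radius.

    The medial axis of a round-capped channel terminates at the cap
    center, one caliber short of the tip; residual points inside that cap
    carry curvature-dominated radii (and, on degraded masks, noisy spur
    remnants).  The reference caliber at each end is the radius maximum
    within a short terminal window.
    """
    seg = np.hypot(*np.diff(pts, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    if arc[-1] <= 0:
        return pts, rad
    limit = max(3, len(pts) // 3)

    def cut(a: np.ndarray, r: np.ndarray) -> int:
        window = a <= 8.0 * px
        r_ref = r[window].max() if window.any() else r[0]
        idx = int(np.searchsorted(a, min(r_ref, a[-1] / 3)))
        return min(idx, limit)

    i0 = cut(arc, rad)
    i1 = len(pts) - 1 - cut((arc[-1] - arc)[::-1], rad[::-1])
    if i1 - i0 < 2:
        return pts, rad
    return pts[i0 : i1 + 1], rad[i0 : i1 + 1]


def _peel_contained_ends(
    pts: np.ndarray, rad: np.ndarray, tol: float
) -> tuple[np.ndarray, np.ndarray]:
    """Drop terminal path points whose inscribed circles are contained in a
    later point's circle.

    Rounded vessel ends make the Voronoi skeleton sprout terminal branches
    running from the cap center toward the cap wall with radii shrinking to
    zero; the longest-path rule keeps them for their arclength.  A point i
    is redundant w.r.t. an anchor j when ``|p_i - p_j| + r_i <= r_j + tol``
    (its circle adds no coverage); the maximal wholly-redundant prefix and
    suffix are removed.
    """

    def cut_index(p: np.ndarray, r: np.ndarray) -> int:
        best = 0
        limit = max(3, len(p) // 3)
        for j in range(1, limit):
            d = np.hypot(p[:j, 0] - p[j, 0], p[:j, 1] - p[j, 1])
            if np.all(d + r[:j] <= r[j] + tol):
                best = j
        return best

    i0 = cut_index(pts, rad)
    i1 = len(pts) - 1 - cut_index(pts[::-1], rad[::-1])
    if i1 - i0 < 2:  # degenerate: keep the raw path
        return pts, rad
    return pts[i0 : i1 + 1], rad[i0 : i1 + 1]


def _orient(c: Centerline, mask: MaskSet) -> Centerline:
    """Point the centerline from the feeding end to the draining end."""
    first, last = c.points[0], c.points[-1]
    if mask.flow_direction is not None:
        inlet = np.asarray(mask.flow_direction[0], dtype=float)
        flip = np.hypot(*(last - inlet)) < np.hypot(*(first - inlet))
    else:
        flip = (last[0], last[1]) < (first[0], first[1])
    if flip:
        c = Centerline(
            c.points[::-1].copy(),
            c.radius[::-1].copy(),
            c.region[::-1].copy(),
            (c.arclength[-1] - c.arclength[::-1]).copy(),
            c.extended[::-1].copy(),
        )
    return c


def partition_centerline(c: Centerline, mask: MaskSet) -> Centerline:
    """Label each centerline point with the mask region at its location.

    Body labels (clot included) must form one contiguous run; vessel points
    before it become ``vessel_in`` and after it ``vessel_out``.  Points
    that fall on background pixels (possible within filled holes or from
    boundary smoothing) inherit their nearest labeled neighbor.
    """
    labels = mask.label_at(c.points)
    is_body = (labels == BODY) | (labels == CLOT)
    is_vessel = labels == VESSEL
    known = is_body | is_vessel
    if not known.all():
        if not known.any():
            raise SkeletonError("centerline does not overlap any labeled region")
        idx = np.flatnonzero(known)
        pos = np.arange(len(labels))
        ins = np.searchsorted(idx, pos).clip(1, len(idx) - 1)
        left, right = idx[ins - 1], idx[ins]
        nearest = np.where(np.abs(pos - left) <= np.abs(right - pos), left, right)
        is_body = np.where(known, is_body, is_body[nearest])
        is_vessel = ~is_body

    if not is_body.any():
        raise SkeletonError("no body-labeled centerline points (vessel-only mask?)")
    if not is_vessel.any():
        raise SkeletonError("no vessel-labeled centerline points")
    runs = np.flatnonzero(np.diff(is_body.astype(int)) != 0)
    if is_body.astype(int).sum() and len(runs) > 2:
        # tolerate single-point speckle at the interfaces, else fail
        body_idx = np.flatnonzero(is_body)
        lo, hi = body_idx[0], body_idx[-1]
        interior_gaps = np.flatnonzero(~is_body[lo : hi + 1])
        if len(interior_gaps) > max(2, 0.02 * (hi - lo)):
            raise SkeletonError("body segment of the centerline is fragmented")
        is_body[lo : hi + 1] = True

    region = np.full(len(labels), REGION_BODY, dtype="<U10")
    body_idx = np.flatnonzero(is_body)
    region[: body_idx[0]] = REGION_IN
    region[body_idx[-1] + 1 :] = REGION_OUT
    if body_idx[0] == 0 or body_idx[-1] == len(labels) - 1:
        warnings.warn("centerline body segment touches an end: stub may be too short")
    return Centerline(c.points, c.radius, region, c.arclength, c.extended)
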
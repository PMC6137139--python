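"""Morphological indices of a microaneurysm: BNR, AR, size and class.

BNR (body-to-neck ratio) is the largest inscribed caliber along the MA
body centerline divided by the narrowest caliber along the
feeding/draining vessels.  AR (asymmetry ratio) splits the body polygon
along the body centerline and reports the larger-to-smaller area ratio
(A1/A2 ≥ 1).  The semi-automatic classification labels AR < 1.4 fusiform
and AR > 1.8 saccular, deferring the 1.4–1.8 band to manual review.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
from shapely.geometry import LineString, Polygon
from shapely.ops import split as shapely_split

from .mask_model import MaskSet
from .skeleton import Centerline, SkeletonError, _smooth_closed, _trace_boundary
from scipy import ndimage
from .mask_model import _FOUR_CONN

Classification = Literal["saccular", "fusiform", "manual_review"]

#: default semi-automatic AR thresholds (fusiform below, saccular above)
DEFAULT_THRESHOLDS = (1.4, 1.8)


@dataclasses.dataclass
class MorphReport:
    """Per-lesion morphology summary (areas in μm²)."""

    ma_id: str
    body_area: float
    ar: float
    a1: float
    a2: float
    bnr: float
    classification: Classification

    def row(self) -> dict:
        return {
            "ma_id": self.ma_id,
            "body_area_um2": self.body_area,
            "ar": self.ar,
            "bnr": self.bnr,
            "classification": self.classification,
        }


def body_to_neck_ratio(c: Centerline) -> float:
    """max body-centerline radius over min vessel-centerline radius.

    Following the caliber definition on the body centerline, the numerator
    is restricted to body-labeled points; extended stub points are ignored
    in the denominator.
    """
    body = c.segment("body")
    vessel = ~c.body_mask & ~c.extended
    if not vessel.any():
        raise SkeletonError("no vessel points for the neck caliber")
    # radii within ~two calibers of a path end are shaped by the vessel
    # end (cap curvature, segmentation cut-off), not by the running
    # caliber; exclude them from the neck minimum
    end_dist = np.minimum(c.arclength - c.arclength[0], c.arclength[-1] - c.arclength)
    interior = vessel & (end_dist > 2.0 * c.radius)
    if interior.any():
        vessel = interior
    return float(body.radius.max() / c.radius[vessel].min())


def body_polygon(mask: MaskSet) -> Polygon:
    """Boundary polygon of the body region (clot included), smoothed
    identically to the skeleton's boundary handling."""
    body = ndimage.binary_fill_holes(mask.body)
    labels, n = ndimage.label(body, structure=_FOUR_CONN)
    if n != 1:
        raise SkeletonError(f"body region must be one component, found {n}")
    rc = _trace_boundary(body)
    if len(rc) < 3:
        raise SkeletonError("body region too small for a polygon")
    xy = np.column_stack([rc[:, 1], rc[:, 0]]).astype(float) * mask.pixel_size
    poly = Polygon(_smooth_closed(xy))
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def _splitter_line(c: Centerline, poly: Polygon) -> LineString:
    """Body-segment centerline, extrapolated past the polygon boundary
    along its terminal tangents."""
    body = c.segment("body")
    pts = body.points
    if len(pts) < 2:
        raise SkeletonError("body centerline segment too short to split the polygon")
    span = 4.0 * np.sqrt(poly.area) + (body.arclength[-1] - body.arclength[0])

    def tangent(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        t = b - a
        n = np.linalg.norm(t)
        if n == 0:
            raise SkeletonError("degenerate body centerline tangent")
        return t / n

    k = min(5, len(pts) - 1)  # tangent from a short end window, noise-robust
    head = pts[0] - tangent(pts[0], pts[k]) * span
    tail = pts[-1] + tangent(pts[-k - 1], pts[-1]) * span
    return LineString(np.vstack([head, pts, tail]))


def asymmetry_ratio(
    mask: MaskSet, c: Centerline
) -> tuple[float, float, float]:
    """Split the body polygon along the body centerline; return (ar, a1, a2).

    The split line is the body-labeled centerline segment extended beyond
    the polygon at both ends.  Fragments are assigned to a side by the sign
    of their centroid's cross product with the local centerline tangent, so
    slivers from multiple boundary crossings accumulate onto the correct
    side.  Raises if either side comes out empty.
    """
    poly = body_polygon(mask)
    line = _splitter_line(c, poly)
    pieces = shapely_split(poly, line)
    areas = {+1: 0.0, -1: 0.0}
    coords = np.asarray(line.coords)
    for piece in pieces.geoms:
        cx, cy = piece.centroid.x, piece.centroid.y
        # nearest centerline vertex, with a window-smoothed tangent so
        # sub-pixel path jitter cannot flip the side assignment
        d2 = (coords[:, 0] - cx) ** 2 + (coords[:, 1] - cy) ** 2
        i = int(np.argmin(d2))
        lo, hi = max(i - 5, 0), min(i + 5, len(coords) - 1)
        t = coords[hi] - coords[lo]
        v = np.array([cx, cy]) - coords[i]
        side = np.sign(t[0] * v[1] - t[1] * v[0])
        if side == 0:
            side = 1.0
        areas[int(side)] += piece.area
    a_pos, a_neg = areas[1], areas[-1]
    if min(a_pos, a_neg) <= 0:
        raise SkeletonError("centerline does not bisect the body polygon")
    a1, a2 = max(a_pos, a_neg), min(a_pos, a_neg)
    return a1 / a2, a1, a2


def classify_morphology(
    ar: float, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
) -> Classification:
    """Semi-automatic saccular/fusiform call from the asymmetry ratio."""
    lo, hi = thresholds
    if ar < 1.0:
        raise ValueError(f"AR must be >= 1 by construction, got {ar}")
    if ar < lo:
        return "fusiform"
    if ar > hi:
        return "saccular"
    return "manual_review"


def morphology_report(
    mask: MaskSet,
    c: Centerline,
    ma_id: str = "",
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> MorphReport:
    """Compute all morphology outputs for one lesion."""
    from .mask_model import BODY, region_area

    ar, a1, a2 = asymmetry_ratio(mask, c)
    return MorphReport(
        ma_id=ma_id or mask.provenance,
        body_area=region_area(mask, BODY),
        ar=ar,
        a1=a1,
        a2=a2,
        bnr=body_to_neck_ratio(c),
        classification=classify_morphology(ar, thresholds),
    )
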
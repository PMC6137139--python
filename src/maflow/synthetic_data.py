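"""Parameterized microaneurysm phantoms with exact analytic ground truth.

Fixtures are built in continuous 2-D geometry (μm) before any raster
exists:

``tube``
    straight channel of constant half-width ``neck_radius`` with
    semicircular end caps,
``fusiform``
    the same channel with a smooth spindle dilation (raised-sine radius
    bump) whose upper and lower amplitudes may differ (the ``asymmetry``
    offset of the widest cross-section midpoint),
``saccular``
    the channel with a one-sided circular bulge whose center sits
    ``asymmetry`` μm off the flow axis.

Ground truth (maximal inscribed radii along the medial curve, the
asymmetry-ratio split, areas) is computed by brute-force geometry on the
generating polygon — dense vertical-slice clearance maximization against
the exact boundary — so it shares no code with the raster Voronoi
pipeline it is used to test.

Feeding/draining stubs have semicircular end caps so that the medial axis
terminates cleanly at the cap center with radius equal to the local vessel
caliber; hand-segmented vessel ends are similarly rounded.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Literal

import numpy as np
import shapely
from scipy import ndimage
from scipy.optimize import brentq
from shapely.geometry import Point, Polygon

from .mask_model import BODY, CLOT, VESSEL, MaskSet, write_mask_set

Kind = Literal["tube", "fusiform", "saccular"]

#: boundary sampling density for circles (error ~ R * (pi/2/quad_segs)^2 / 2)
_QUAD_SEGS = 192


@dataclasses.dataclass
class FixtureSpec:
    """Generator parameters for one phantom.

    ``asymmetry`` is the offset (μm) of the bulge center (saccular) or of
    the widest-section midpoint (fusiform) from the flow axis.  ``clot``
    places a clot sub-region at the dome apex (``"apex"``) or nowhere.
    ``jitter`` adds seed-controlled sub-pixel boundary noise (μm RMS) to
    the rasterized silhouette only; ground truth stays noise-free.
    """

    kind: Kind = "saccular"
    neck_radius: float = 5.0
    body_max_radius: float = 15.0
    body_length: float | None = None
    vessel_length: float | None = None
    asymmetry: float = 0.0
    clot: Literal["none", "apex"] = "none"
    pixel_size: float = 1.0
    seed: int = 0
    jitter: float = 0.0

    def resolved(self) -> "FixtureSpec":
        """Fill derived defaults and validate feasibility."""
        s = dataclasses.replace(self)
        if s.kind == "tube":
            s.body_max_radius = s.neck_radius
        if not 0 < s.neck_radius <= s.body_max_radius:
            raise ValueError("need body_max_radius >= neck_radius > 0")
        if s.body_length is None:
            s.body_length = max(3.0 * s.body_max_radius, 4.0 * s.neck_radius)
        if s.vessel_length is None:
            s.vessel_length = s.body_length
        if s.kind == "saccular":
            if s.body_length < 2.0 * s.body_max_radius + 1e-9:
                raise ValueError("bulge not containable: body_length < 2*body_max_radius")
            if s.asymmetry > s.body_max_radius:
                raise ValueError("bulge detached from channel: asymmetry > radius")
        if s.kind == "fusiform":
            amp = s.body_max_radius - s.neck_radius
            if abs(s.asymmetry) > amp:
                raise ValueError("fusiform asymmetry exceeds bump amplitude")
        if s.asymmetry < 0:
            raise ValueError("asymmetry must be >= 0 (bulge on the +y side)")
        return s


@dataclasses.dataclass
class GroundTruth:
    """Exact-geometry reference values, in the raster's physical frame."""

    ar: float
    a1: float
    a2: float
    bnr: float
    body_area: float
    body_max_inscribed_radius: float
    vessel_min_inscribed_radius: float
    perimeter: float
    body_xrange: tuple[float, float]
    medial_x: np.ndarray
    medial_y: np.ndarray
    medial_radius: np.ndarray
    silhouette: Polygon
    body_polygon: Polygon
    clot_polygon: Polygon | None
    clot_apex: tuple[float, float] | None

    def to_jsonable(self) -> dict:
        return {
            "ar": self.ar,
            "a1": self.a1,
            "a2": self.a2,
            "bnr": self.bnr,
            "body_area": self.body_area,
            "body_max_inscribed_radius": self.body_max_inscribed_radius,
            "vessel_min_inscribed_radius": self.vessel_min_inscribed_radius,
            "perimeter": self.perimeter,
            "body_xrange": list(self.body_xrange),
        }


# ---------------------------------------------------------------------------
# continuous geometry
# ---------------------------------------------------------------------------


def _silhouette_polygon(s: FixtureSpec) -> Polygon:
    a, lt = s.neck_radius, 2 * s.vessel_length + s.body_length
    parts = [
        shapely.box(0.0, -a, lt, a),
        Point(0.0, 0.0).buffer(a, quad_segs=_QUAD_SEGS),
        Point(lt, 0.0).buffer(a, quad_segs=_QUAD_SEGS),
    ]
    if s.kind == "saccular":
        xc = s.vessel_length + s.body_length / 2
        parts.append(Point(xc, s.asymmetry).buffer(s.body_max_radius, quad_segs=_QUAD_SEGS))
    elif s.kind == "fusiform":
        x = np.linspace(0.0, lt, 1601)
        top, bot = _fusiform_walls(s, x)
        ring = np.concatenate(
            [np.column_stack([x, top]), np.column_stack([x[::-1], bot[::-1]])]
        )
        parts.append(Polygon(ring).buffer(0))
    poly = shapely.unary_union(parts)
    if poly.geom_type != "Polygon":
        raise ValueError("silhouette parts do not form a single polygon")
    return poly


def _fusiform_walls(s: FixtureSpec, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a, lv, lb = s.neck_radius, s.vessel_length, s.body_length
    amp = s.body_max_radius - a
    bump = np.zeros_like(x)
    inside = (x >= lv) & (x <= lv + lb)
    bump[inside] = np.sin(np.pi * (x[inside] - lv) / lb) ** 2
    return a + (amp + s.asymmetry) * bump, -a - (amp - s.asymmetry) * bump


def _slice_intervals(s: FixtureSpec, x: float) -> list[tuple[float, float]]:
    """Vertical-slice intervals of the silhouette interior at abscissa x.

    Valid for x within the flat-walled extent [0, Lt]; the semicircular end
    caps extend beyond but are never sliced here.
    """
    a = s.neck_radius
    base = (-a, a)
    if s.kind == "tube":
        return [base]
    if s.kind == "fusiform":
        top, bot = _fusiform_walls(s, np.array([x]))
        return [(float(bot[0]), float(top[0]))]
    xc = s.vessel_length + s.body_length / 2
    rb, h = s.body_max_radius, s.asymmetry
    dx = x - xc
    if abs(dx) >= rb:
        return [base]
    half = float(np.sqrt(rb * rb - dx * dx))
    lo, hi = h - half, h + half
    if lo <= a:  # bulge slice merges with the channel slice
        return [(min(-a, lo), max(a, hi))]
    return [base, (lo, hi)]


def _medial_curve(
    s: FixtureSpec, nx: int = 481, ny: int = 49
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Brute-force medial path: ridge tracking plus longest-path selection.

    Per vertical slice, all local maxima of the exact clearance (distance
    to the generating polygon's boundary, containment-filtered) are
    located by a coarse-then-fine grid search.  Ridge points of adjacent
    slices are linked by mutual-nearest matching (edges whose midpoint
    leaves the silhouette are discarded, so dead-end crescent ridges stay
    dead ends), and the maximal-arclength left-to-right path through the
    resulting graph is selected by dynamic programming — the same pruning
    rule the raster pipeline applies to its Voronoi skeleton, computed
    here from exact geometry.
    """
    poly = _silhouette_polygon(s)
    boundary = poly.exterior
    lt = 2 * s.vessel_length + s.body_length
    xs = np.linspace(0.0, lt, nx)
    eps = 1e-6 * max(1.0, s.body_max_radius)

    def clearance(xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
        d = shapely.distance(shapely.points(xx, yy), boundary)
        d[~shapely.contains_xy(poly, xx, yy)] = -1.0
        return d

    # coarse clearance field per slice
    ylo = np.empty(nx)
    yhi = np.empty(nx)
    for i, xv in enumerate(xs):
        ivals = _slice_intervals(s, float(xv))
        ylo[i] = min(v[0] for v in ivals) + eps
        yhi[i] = max(v[1] for v in ivals) - eps
    t = np.linspace(0.0, 1.0, ny)
    yy = ylo[:, None] + (yhi - ylo)[:, None] * t[None, :]
    xx = np.repeat(xs[:, None], ny, axis=1)
    d = clearance(xx.ravel(), yy.ravel()).reshape(nx, ny)

    # local maxima per slice (plateau-tolerant)
    pad = np.full((nx, 1), -np.inf)
    dm = np.hstack([pad, d, pad])
    is_max = (dm[:, 1:-1] >= dm[:, :-2]) & (dm[:, 1:-1] > dm[:, 2:]) & (d > 0)

    # refine each maximum on a 21-point sub-grid (batched)
    si, sj = np.nonzero(is_max)
    step = ((yhi - ylo) / (ny - 1))[si]
    sub = np.linspace(-1.0, 1.0, 21)
    fy = np.clip(
        yy[si, sj][:, None] + step[:, None] * sub[None, :],
        ylo[si][:, None],
        yhi[si][:, None],
    )
    fx = np.repeat(xs[si][:, None], 21, axis=1)
    fd = clearance(fx.ravel(), fy.ravel()).reshape(-1, 21)
    k = np.argmax(fd, axis=1)
    rows = np.arange(len(si))
    node_x, node_y = xs[si], fy[rows, k]
    node_r = fd[rows, k]

    # keep only genuine medial points: the clearance of a medial point is
    # governed by two distinct boundary features, so its slice profile has
    # a slope kink at the max; a smooth max (single nearest arc) does not.
    m = 3
    interior = (k >= m) & (k <= 20 - m)
    kc = np.clip(k, m, 20 - m)
    delta = step / 10.0  # fine-grid spacing per node
    sl = (fd[rows, kc] - fd[rows, kc - m]) / (m * delta)
    sr = (fd[rows, kc + m] - fd[rows, kc]) / (m * delta)
    genuine = interior & (sl - sr >= 0.25) & (node_r > 0)
    si, node_x, node_y, node_r = si[genuine], node_x[genuine], node_y[genuine], node_r[genuine]
    if len(si) == 0:
        raise ValueError("no medial ridge points found in the silhouette")

    # group nodes by slice
    per_slice: list[list[int]] = [[] for _ in range(nx)]
    for n_idx, i in enumerate(si):
        per_slice[i].append(n_idx)
    occupied = [i for i in range(nx) if per_slice[i]]

    # mutual-nearest edges between consecutive occupied slices
    edges: list[tuple[int, int]] = []
    for a, b in zip(occupied[:-1], occupied[1:]):
        ya = node_y[per_slice[a]]
        yb = node_y[per_slice[b]]
        pairs = set()
        for k2, yv in enumerate(yb):
            pairs.add((int(np.argmin(np.abs(ya - yv))), k2))
        for k1, yv in enumerate(ya):
            pairs.add((k1, int(np.argmin(np.abs(yb - yv)))))
        for k1, k2 in pairs:
            edges.append((per_slice[a][k1], per_slice[b][k2]))
    if edges:
        e = np.asarray(edges)
        mx = 0.5 * (node_x[e[:, 0]] + node_x[e[:, 1]])
        my = 0.5 * (node_y[e[:, 0]] + node_y[e[:, 1]])
        keep = shapely.contains_xy(poly, mx, my)
        edges = [tuple(v) for v in e[keep]]

    # longest-path DP, slices left to right
    score = np.full(len(si), -np.inf)
    prev = np.full(len(si), -1, dtype=int)
    for n_idx in per_slice[occupied[0]]:
        score[n_idx] = 0.0
    for u, v in edges:  # edges already ordered by slice
        if score[u] == -np.inf:
            continue
        w = float(np.hypot(node_x[v] - node_x[u], node_y[v] - node_y[u]))
        if score[u] + w > score[v]:
            score[v] = score[u] + w
            prev[v] = u
    tail = max(per_slice[occupied[-1]], key=lambda n_idx: score[n_idx])
    if score[tail] == -np.inf:
        raise ValueError("ground-truth medial path failed to span the silhouette")
    path = [tail]
    while prev[path[-1]] >= 0:
        path.append(prev[path[-1]])
    path.reverse()
    return node_x[path], node_y[path], node_r[path]


def _ground_truth(s: FixtureSpec, nx: int = 481) -> GroundTruth:
    poly = _silhouette_polygon(s)
    lv, lb = s.vessel_length, s.body_length
    xs, ys, rs = _medial_curve(s, nx=nx)
    in_body = (xs >= lv) & (xs <= lv + lb)
    r_body = float(rs[in_body].max())
    r_vessel = float(rs[~in_body].min())

    # split areas: measure of slice set above / below the medial curve,
    # integrated over the body extent (trapezoid on a refined grid)
    xf = np.linspace(lv, lv + lb, 4 * nx + 1)
    yf = np.interp(xf, xs, ys)
    above = np.zeros_like(xf)
    below = np.zeros_like(xf)
    for i, xv in enumerate(xf):
        for lo, hi in _slice_intervals(s, float(xv)):
            above[i] += max(0.0, hi - max(lo, yf[i]))
            below[i] += max(0.0, min(hi, yf[i]) - lo)
    a_above = float(np.trapezoid(above, xf))
    a_below = float(np.trapezoid(below, xf))
    a1, a2 = max(a_above, a_below), min(a_above, a_below)

    strip = shapely.box(lv, -1e9, lv + lb, 1e9)
    body_poly = poly.intersection(strip)
    clot_poly = None
    apex = None
    if s.clot == "apex":
        if s.kind != "saccular":
            raise ValueError("apex clot is defined for saccular fixtures only")
        xc = lv + lb / 2
        apex = (xc, s.asymmetry + s.body_max_radius)
        clot_disk = Point(*apex).buffer(0.6 * s.body_max_radius, quad_segs=_QUAD_SEGS)
        clot_poly = body_poly.intersection(clot_disk)

    return GroundTruth(
        ar=a1 / a2,
        a1=a1,
        a2=a2,
        bnr=r_body / r_vessel,
        body_area=float(body_poly.area),
        body_max_inscribed_radius=r_body,
        vessel_min_inscribed_radius=r_vessel,
        perimeter=float(poly.exterior.length),
        body_xrange=(lv, lv + lb),
        medial_x=xs,
        medial_y=ys,
        medial_radius=rs,
        silhouette=poly,
        body_polygon=body_poly,
        clot_polygon=clot_poly,
        clot_apex=apex,
    )


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def _translate_gt(gt: GroundTruth, tx: float, ty: float) -> GroundTruth:
    mv = lambda g: shapely.affinity.translate(g, tx, ty) if g is not None else None
    return dataclasses.replace(
        gt,
        body_xrange=(gt.body_xrange[0] + tx, gt.body_xrange[1] + tx),
        medial_x=gt.medial_x + tx,
        medial_y=gt.medial_y + ty,
        silhouette=mv(gt.silhouette),
        body_polygon=mv(gt.body_polygon),
        clot_polygon=mv(gt.clot_polygon),
        clot_apex=None if gt.clot_apex is None else (gt.clot_apex[0] + tx, gt.clot_apex[1] + ty),
    )


def _jittered_exterior(poly: Polygon, rms: float, seed: int) -> Polygon:
    """Smooth seed-controlled radial noise on the boundary (raster only)."""
    xy = np.asarray(poly.exterior.coords)[:-1]
    n = len(xy)
    rng = np.random.default_rng(seed)
    noise = ndimage.gaussian_filter1d(rng.standard_normal(n), sigma=8, mode="wrap")
    sd = noise.std()
    if sd > 0:
        noise *= rms / sd
    nxt, prv = np.roll(xy, -1, axis=0), np.roll(xy, 1, axis=0)
    tang = nxt - prv
    nrm = np.column_stack([tang[:, 1], -tang[:, 0]])
    nrm /= np.maximum(np.linalg.norm(nrm, axis=1, keepdims=True), 1e-12)
    # ensure outward orientation (positive-area ring has outward (ty,-tx))
    if poly.exterior.is_ccw:
        nrm = -nrm
    out = Polygon(xy + noise[:, None] * nrm).buffer(0)
    if out.geom_type != "Polygon":  # jitter pinched the shape off: too large
        raise ValueError("jitter amplitude destroys silhouette topology")
    return out


def generate_mask(
    spec: FixtureSpec, margin_px: int = 3, gt_nx: int = 481
) -> tuple[MaskSet, GroundTruth]:
    """Rasterize one phantom and return it with its analytic ground truth."""
    s = spec.resolved()
    gt = _ground_truth(s, nx=gt_nx)
    px = s.pixel_size
    minx, miny, maxx, maxy = gt.silhouette.bounds
    # sub-pixel offset keeps axis-aligned walls off the pixel-center grid
    # (otherwise whole boundary rows alias in or out of the raster at once);
    # anchored to the flow axis with an irrational-ish fraction so neither
    # the axis nor walls at integer/half-integer radii ever align
    sub = 0.257 * px
    tx = margin_px * px - np.floor(minx / px) * px + sub
    ty = margin_px * px - np.floor(miny / px) * px + sub
    gt = _translate_gt(gt, tx, ty)

    ncol = int(np.ceil((maxx - minx) / px)) + 2 * margin_px + 1
    nrow = int(np.ceil((maxy - miny) / px)) + 2 * margin_px + 1
    cols, rows = np.meshgrid(np.arange(ncol), np.arange(nrow))
    xg, yg = cols.ravel() * px, rows.ravel() * px

    sil_poly = gt.silhouette
    if s.jitter > 0:
        sil_poly = _jittered_exterior(sil_poly, s.jitter, s.seed)
    inside = shapely.contains_xy(sil_poly, xg, yg).reshape(nrow, ncol)

    raster = np.zeros((nrow, ncol), dtype=np.uint8)
    xlo, xhi = gt.body_xrange
    in_strip = ((xg >= xlo) & (xg <= xhi)).reshape(nrow, ncol)
    raster[inside & in_strip] = BODY
    raster[inside & ~in_strip] = VESSEL
    if gt.clot_polygon is not None:
        in_clot = shapely.contains_xy(gt.clot_polygon, xg, yg).reshape(nrow, ncol)
        raster[inside & in_strip & in_clot] = CLOT

    lt = 2 * s.vessel_length + s.body_length
    mask = MaskSet(
        raster,
        px,
        flow_direction=((tx - s.neck_radius, ty + 0.0), (lt + tx + s.neck_radius, ty + 0.0)),
        provenance=f"synthetic:{s.kind}:seed={s.seed}",
    )
    # anchor flow hints on the cap centers in the raster frame
    mask.flow_direction = ((0.0 + tx, 0.0 + ty), (lt + tx, 0.0 + ty))
    return mask.validate(), gt


# ---------------------------------------------------------------------------
# waveform
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class Waveform:
    """Mean-normalized periodic inlet velocity scale factors."""

    time: np.ndarray  # s, one period, t[0] = 0
    scale: np.ndarray  # dimensionless, mean 1
    period: float  # s


#: default cardiac period: four cycles span 3.13 s in the reference
#: capillary velocity recordings used for the pulsatile inlet.
DEFAULT_CARDIAC_PERIOD = 3.13 / 4


def generate_waveform(
    period: float = DEFAULT_CARDIAC_PERIOD,
    n_points: int = 100,
    pulsatility: float = 0.4,
    seed: int | None = None,
) -> Waveform:
    """Rectified-sine-squared cardiac template, mean-normalized to 1.

    ``w(t) = (1 - p) + 2 p sin²(π t / T) = 1 - p cos(2 π t / T)``, so the
    systolic peak is ``1 + p``, the diastolic trough ``1 - p``, and the
    uniform-sample mean exactly 1 (n_points even).  ``seed`` is accepted
    for API symmetry; the template is deterministic.
    """
    if period <= 0:
        raise ValueError("period must be > 0")
    if not 0 <= pulsatility < 1:
        raise ValueError("pulsatility must be in [0, 1)")
    if n_points % 2:
        n_points += 1  # keep the sample mean exactly 1
    t = np.arange(n_points) / n_points * period
    scale = 1.0 - pulsatility * np.cos(2 * np.pi * t / period)
    return Waveform(time=t, scale=scale, period=period)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def calibrate_asymmetry(
    spec: FixtureSpec, target_ar: float, coarse_nx: int = 201
) -> FixtureSpec:
    """Find the asymmetry offset whose exact-geometry AR hits ``target_ar``.

    Bisection on the brute-force ground truth at coarse slice resolution;
    if the target exceeds the achievable range the offset is clipped to its
    feasible maximum.
    """
    s = spec.resolved()
    if s.kind == "tube" or target_ar <= 1.0 + 1e-9:
        return dataclasses.replace(s, asymmetry=0.0)
    if s.kind == "saccular":
        # beyond ~0.72 of the geometric limit the bulge overhangs so
        # sharply that raster pipelines cannot resolve the junction cusps
        h_max = 0.72 * (s.body_max_radius - 0.25 * s.neck_radius)
    else:
        h_max = 0.95 * (s.body_max_radius - s.neck_radius)

    def ar_of(h: float) -> float:
        return _ground_truth(dataclasses.replace(s, asymmetry=h), nx=coarse_nx).ar

    hi = ar_of(h_max)
    if hi <= target_ar:
        return dataclasses.replace(s, asymmetry=h_max)
    h = brentq(lambda v: ar_of(v) - target_ar, 0.0, h_max, xtol=1e-3 * h_max)
    return dataclasses.replace(s, asymmetry=float(h))


def cohort_fixture(
    n_saccular: int,
    n_fusiform: int,
    seed: int = 0,
    pixel_size: float = 1.0,
    clot_fraction: float = 0.5,
) -> list[tuple[MaskSet, GroundTruth, FixtureSpec]]:
    """Generate a reproducible mixed cohort with analytic ground truths.

    Saccular fixtures target AR in [1.8, 4] and fusiform AR in
    [1.0, 1.4] (clipped to what each geometry can realize); body radii
    span 10–25 μm over neck radii 4–6 μm, i.e. BNR roughly 1.7–6, the
    parafoveal capillary scale.  ``clot_fraction`` of the saccular
    fixtures (rounded) carry an apex clot.
    """
    if n_saccular < 1 or n_fusiform < 1:
        raise ValueError("need at least one fixture of each kind")
    rng = np.random.default_rng(seed)
    out: list[tuple[MaskSet, GroundTruth, FixtureSpec]] = []
    n_clot = int(round(clot_fraction * n_saccular))
    for i in range(n_saccular):
        base = FixtureSpec(
            kind="saccular",
            neck_radius=float(rng.uniform(4, 6)),
            body_max_radius=float(rng.uniform(12, 25)),
            pixel_size=pixel_size,
            seed=seed * 1000 + i,
            clot="apex" if i < n_clot else "none",
        )
        spec = calibrate_asymmetry(base, target_ar=float(rng.uniform(1.8, 4.0)))
        mask, gt = generate_mask(spec)
        out.append((mask, gt, spec))
    for i in range(n_fusiform):
        base = FixtureSpec(
            kind="fusiform",
            neck_radius=float(rng.uniform(4, 6)),
            body_max_radius=float(rng.uniform(10, 20)),
            pixel_size=pixel_size,
            seed=seed * 1000 + 500 + i,
        )
        spec = calibrate_asymmetry(base, target_ar=float(rng.uniform(1.0, 1.4)))
        mask, gt = generate_mask(spec)
        out.append((mask, gt, spec))
    return out


def save_fixture(mask: MaskSet, gt: GroundTruth, directory: str | Path, name: str) -> Path:
    """Write raster + YAML sidecar + ground-truth JSON for one fixture."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_mask_set(mask, directory / f"{name}.png")
    (directory / f"{name}.gt.json").write_text(json.dumps(gt.to_jsonable(), indent=2))
    return directory / f"{name}.png"
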
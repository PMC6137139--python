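"""Rotationally symmetric 3-D lumen reconstruction and voxelization.

The 2-D centerline with inscribed radii is swept into a triangulated
surface of revolution: circular cross-sections of the local radius,
perpendicular to the local tangent, with parallel-transported frames (no
torsion flips).  Feeding/draining stubs are first extended along their
terminal tangents at constant caliber so each is at least as long as the
MA body's flow-axis extent and the laminar entrance length
``Le = 0.035 D Re``.  The mesh is then voxelized onto a regular lattice
with a guaranteed minimum number of sites across the narrowest lumen
diameter, producing the simulation domain for the lattice-Boltzmann
solver.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path

import numpy as np
from numba import njit
from scipy import ndimage
from scipy.spatial import cKDTree

from .mask_model import CLOT, MaskSet
from .skeleton import REGION_BODY, REGION_IN, REGION_OUT, Centerline, SkeletonError

logger = logging.getLogger(__name__)

# site type codes of the lattice
SOLID, FLUID, INLET, OUTLET = 0, 1, 2, 3
# region codes of fluid sites
R_NONE, R_BODY, R_IN, R_OUT = 0, 1, 2, 3
_REGION_CODE = {REGION_BODY: R_BODY, REGION_IN: R_IN, REGION_OUT: R_OUT}


def entrance_length(diameter: float, reynolds: float) -> float:
    """Laminar entrance length Le = 0.035 · D · Re (μm for D in μm)."""
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    if reynolds < 0:
        raise ValueError("Reynolds number must be >= 0")
    return 0.035 * diameter * reynolds


def _body_axis_length(c: Centerline) -> float:
    """Extent of the body segment along the end-to-end flow axis."""
    axis = c.points[-1] - c.points[0]
    n = np.linalg.norm(axis)
    if n == 0:
        raise SkeletonError("degenerate centerline: coincident endpoints")
    axis = axis / n
    proj = c.points[c.body_mask] @ axis
    return float(proj.max() - proj.min())


def extend_stubs(c: Centerline, reynolds: float = 0.0) -> Centerline:
    """Prolong each vessel stub along its terminal tangent, constant radius.

    Each stub is extended until its arclength reaches
    ``max(body flow-axis length, entrance_length(2 r_end, Re))``.  Appended
    points carry ``extended=True`` so downstream averaging can ignore them.
    """
    if not (c.region == REGION_IN).any() or not (c.region == REGION_OUT).any():
        raise SkeletonError("centerline must be partitioned before stub extension")
    body_len = _body_axis_length(c)
    step = float(np.median(np.diff(c.arclength)))

    def extension(side: str) -> tuple[np.ndarray, np.ndarray, float]:
        sel = c.region == side
        seg_len = c.arclength[sel].max() - c.arclength[sel].min()
        end = 0 if side == REGION_IN else len(c.points) - 1
        r_end = c.radius[end]
        target = max(body_len, entrance_length(2 * r_end, reynolds))
        need = target - seg_len
        if need <= 0:
            return np.empty((0, 2)), np.empty(0), r_end
        k = min(5, int(sel.sum()))
        if side == REGION_IN:
            tangent = c.points[0] - c.points[k]
        else:
            tangent = c.points[-1] - c.points[-1 - k]
        n = np.linalg.norm(tangent)
        if n == 0:
            raise SkeletonError("zero-length stub: terminal tangent undefined")
        tangent = tangent / n
        m = int(np.ceil(need / step))
        t = step * np.arange(1, m + 1)
        base = c.points[0] if side == REGION_IN else c.points[-1]
        pts = base[None, :] + t[:, None] * tangent[None, :]
        return pts, t, r_end

    pts_in, t_in, r_in = extension(REGION_IN)
    pts_out, t_out, r_out = extension(REGION_OUT)

    new_pts = np.vstack([pts_in[::-1], c.points, pts_out])
    new_rad = np.concatenate([np.full(len(pts_in), r_in), c.radius, np.full(len(pts_out), r_out)])
    new_reg = np.concatenate(
        [np.full(len(pts_in), REGION_IN, dtype="<U10"), c.region, np.full(len(pts_out), REGION_OUT, dtype="<U10")]
    )
    new_ext = np.concatenate(
        [np.ones(len(pts_in), bool), c.extended, np.ones(len(pts_out), bool)]
    )
    if len(pts_in):
        arc0 = np.concatenate([-t_in[::-1], c.arclength])
    else:
        arc0 = c.arclength
    if len(pts_out):
        arc0 = np.concatenate([arc0, c.arclength[-1] + t_out])
    arc0 = arc0 - arc0[0]
    return Centerline(new_pts, new_rad, new_reg, arc0, new_ext)


# ---------------------------------------------------------------------------
# surface sweep
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class LumenMesh:
    """Triangulated rotationally symmetric lumen surface (open at the ends).

    ``vertices`` are in μm; rings are consecutive blocks of ``n_circ``
    vertices, one ring per generating centerline point, whose metadata
    (center, radius, region, clot, extended) is carried per ring.
    """

    vertices: np.ndarray  # (n, 3)
    triangles: np.ndarray  # (m, 3)
    n_circ: int
    ring_centers: np.ndarray  # (k, 3)
    ring_radius: np.ndarray  # (k,)
    ring_region: np.ndarray  # (k,) unicode
    ring_clot: np.ndarray  # (k,) bool — ring touches the clot region
    ring_extended: np.ndarray  # (k,) bool
    vertex_clot: np.ndarray | None = None  # (n,) bool, by 2-D projection

    @property
    def n_rings(self) -> int:
        return len(self.ring_centers)

    @property
    def inlet_ring(self) -> np.ndarray:
        return np.arange(self.n_circ)

    @property
    def outlet_ring(self) -> np.ndarray:
        return np.arange((self.n_rings - 1) * self.n_circ, self.n_rings * self.n_circ)

    def region_per_vertex(self) -> np.ndarray:
        return np.repeat(self.ring_region, self.n_circ)

    def clot_per_vertex(self) -> np.ndarray:
        if self.vertex_clot is not None:
            return self.vertex_clot
        return np.repeat(self.ring_clot, self.n_circ)

    def capped_triangles(self) -> tuple[np.ndarray, np.ndarray]:
        """Vertices and triangles of the closed mesh (fan caps added)."""
        nv = len(self.vertices)
        verts = np.vstack([self.vertices, self.ring_centers[0], self.ring_centers[-1]])
        caps = []
        ring0, ring1 = self.inlet_ring, self.outlet_ring
        for j in range(self.n_circ):
            a, b = ring0[j], ring0[(j + 1) % self.n_circ]
            caps.append([nv, b, a])  # inward-facing cap at the inlet
            a, b = ring1[j], ring1[(j + 1) % self.n_circ]
            caps.append([nv + 1, a, b])
        return verts, np.vstack([self.triangles, np.asarray(caps)])

    def to_trimesh(self, capped: bool = False):
        import trimesh

        if capped:
            v, t = self.capped_triangles()
        else:
            v, t = self.vertices, self.triangles
        return trimesh.Trimesh(vertices=v, faces=t, process=False)

    def export_stl(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_trimesh().export(path)
        return path


def sweep_surface(
    c: Centerline,
    n_circumference: int = 48,
    mask: MaskSet | None = None,
    smooth_sigma: float = 2.0,
) -> LumenMesh:
    """Sweep circular cross-sections along the centerline.

    Frames are parallel-transported along the path so the tube never
    twists.  If the local radius exceeds the path's radius of curvature the
    sweep would self-intersect; the radius is clamped there with a warning.
    A ring is flagged as clot when its centerline point projects into the
    clot region of ``mask``.
    """
    if n_circumference < 12:
        raise ValueError("need at least 12 circumferential vertices")
    pts2 = c.points
    if smooth_sigma > 0 and len(pts2) > 4:
        # sample-scale jitter of the medial path would alias into the
        # tangent field and twist the swept frames; the inscribed radii are
        # left untouched
        pts2 = ndimage.gaussian_filter1d(pts2, smooth_sigma, axis=0, mode="nearest")
    pts3 = np.column_stack([pts2, np.zeros(len(pts2))])
    tang = np.gradient(pts3, c.arclength, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)

    radius = c.radius.copy()
    # where the radius exceeds the path's radius of curvature, adjacent
    # rings overlap locally; the swept envelope stays valid and the
    # winding-rule voxelizer handles the overlap, so only warn
    dt = np.gradient(tang, c.arclength, axis=0)
    kappa = np.linalg.norm(dt, axis=1)
    with np.errstate(divide="ignore"):
        r_curv = np.where(kappa > 1e-12, 1.0 / kappa, np.inf)
    tight = radius > r_curv
    if tight.any():
        warnings.warn(
            f"sweep radius exceeds local radius of curvature at "
            f"{int(tight.sum())} rings; rings overlap locally there"
        )

    # parallel transport: rotate the previous frame by the rotation taking
    # t[i-1] to t[i] (Rodrigues), starting from the in-plane normal
    normals = np.empty_like(tang)
    n0 = np.array([-tang[0, 1], tang[0, 0], 0.0])
    normals[0] = n0 / np.linalg.norm(n0)
    for i in range(1, len(tang)):
        t_prev, t_cur = tang[i - 1], tang[i]
        v = np.cross(t_prev, t_cur)
        s = np.linalg.norm(v)
        cth = float(np.clip(t_prev @ t_cur, -1.0, 1.0))
        if s < 1e-12:
            normals[i] = normals[i - 1]
            continue
        k = v / s
        n_prev = normals[i - 1]
        normals[i] = (
            n_prev * cth + np.cross(k, n_prev) * s + k * (k @ n_prev) * (1 - cth)
        )
        normals[i] -= (normals[i] @ t_cur) * t_cur
        normals[i] /= np.linalg.norm(normals[i])
    binormals = np.cross(tang, normals)

    theta = 2 * np.pi * np.arange(n_circumference) / n_circumference
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    rings = (
        pts3[:, None, :]
        + radius[:, None, None]
        * (cos_t[None, :, None] * normals[:, None, :] + sin_t[None, :, None] * binormals[:, None, :])
    )
    vertices = rings.reshape(-1, 3)

    nc = n_circumference
    tris = []
    for i in range(len(pts3) - 1):
        base0, base1 = i * nc, (i + 1) * nc
        for j in range(nc):
            j1 = (j + 1) % nc
            a, b, cidx, d = base0 + j, base0 + j1, base1 + j1, base1 + j
            tris.append([a, b, cidx])
            tris.append([a, cidx, d])
    triangles = np.asarray(tris)

    # the clot is a 2-D delineation: a surface point belongs to it when
    # its in-plane projection falls on a clot pixel
    vertex_clot = np.zeros(len(vertices), dtype=bool)
    if mask is not None and mask.has_clot:
        vertex_clot = mask.label_at(vertices[:, :2]) == CLOT
    ring_clot = vertex_clot.reshape(len(pts3), nc).any(axis=1)

    return LumenMesh(
        vertices=vertices,
        triangles=triangles,
        n_circ=nc,
        ring_centers=pts3,
        ring_radius=radius,
        ring_region=c.region.copy(),
        ring_clot=ring_clot,
        ring_extended=c.extended.copy(),
        vertex_clot=vertex_clot,
    )


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------


@njit(cache=True)
def _ray_crossings(verts, tris, y0, z0, h, ny, nz, max_per_col):
    """x-positions and orientation signs where +x rays cross the mesh.

    The sign is +1 where the ray enters the body (triangle normal has a
    negative x-component) and -1 where it exits, so interior points are
    those with positive accumulated winding — robust to the locally
    overlapping rings a high-curvature sweep produces.
    """
    counts = np.zeros((ny, nz), dtype=np.int32)
    xs = np.full((ny, nz, max_per_col), np.inf)
    signs = np.zeros((ny, nz, max_per_col), dtype=np.int8)
    for t in range(tris.shape[0]):
        a, b, c = tris[t, 0], tris[t, 1], tris[t, 2]
        ay, az = verts[a, 1], verts[a, 2]
        by, bz = verts[b, 1], verts[b, 2]
        cy, cz = verts[c, 1], verts[c, 2]
        det = (by - ay) * (cz - az) - (bz - az) * (cy - ay)
        if abs(det) < 1e-14:
            continue  # triangle edge-on to the ray direction
        ylo = min(ay, by, cy)
        yhi = max(ay, by, cy)
        zlo = min(az, bz, cz)
        zhi = max(az, bz, cz)
        j0 = max(0, int(np.ceil((ylo - y0) / h)))
        j1 = min(ny - 1, int(np.floor((yhi - y0) / h)))
        k0 = max(0, int(np.ceil((zlo - z0) / h)))
        k1 = min(nz - 1, int(np.floor((zhi - z0) / h)))
        for j in range(j0, j1 + 1):
            py = y0 + j * h
            for k in range(k0, k1 + 1):
                pz = z0 + k * h
                # barycentric coordinates in the (y, z) projection
                l1 = ((py - ay) * (cz - az) - (pz - az) * (cy - ay)) / det
                l2 = ((by - ay) * (pz - az) - (bz - az) * (py - ay)) / det
                if l1 < 0.0 or l2 < 0.0 or l1 + l2 > 1.0:
                    continue
                xhit = verts[a, 0] + l1 * (verts[b, 0] - verts[a, 0]) + l2 * (
                    verts[c, 0] - verts[a, 0]
                )
                n = counts[j, k]
                if n < max_per_col:
                    xs[j, k, n] = xhit
                    signs[j, k, n] = 1 if det < 0.0 else -1
                    counts[j, k] = n + 1
    return counts, xs, signs


@njit(cache=True)
def _fill_columns(counts, xs, signs, x0, h, nxv):
    fluid = np.zeros((nxv, counts.shape[0], counts.shape[1]), dtype=np.uint8)
    for j in range(counts.shape[0]):
        for k in range(counts.shape[1]):
            n = counts[j, k]
            if n < 2:
                continue
            order = np.argsort(xs[j, k, :n])
            winding = 0
            for p in range(n - 1):
                winding += signs[j, k, order[p]]
                if winding <= 0:
                    continue
                i0 = int(np.ceil((xs[j, k, order[p]] - x0) / h))
                i1 = int(np.floor((xs[j, k, order[p + 1]] - x0) / h))
                for i in range(max(0, i0), min(nxv - 1, i1) + 1):
                    fluid[i, j, k] = 1
    return fluid


@dataclasses.dataclass
class LatticeDomain:
    """Voxelized fluid domain for the lattice-Boltzmann solver.

    ``site_type`` distinguishes solid, interior fluid and the single-layer
    inlet/outlet boundary sites; ``region``/``clot``/``extended`` label the
    fluid sites for index averaging.  ``origin`` is the physical (x, y, z)
    of voxel index (0, 0, 0); all lengths in μm.
    """

    spacing: float
    origin: np.ndarray
    site_type: np.ndarray  # (nx, ny, nz) uint8
    region: np.ndarray  # (nx, ny, nz) uint8
    clot: np.ndarray  # bool
    extended: np.ndarray  # bool
    inlet_center: np.ndarray
    inlet_axis: np.ndarray  # unit, pointing into the domain
    inlet_radius: float
    outlet_center: np.ndarray
    outlet_axis: np.ndarray  # unit, pointing out of the domain
    outlet_radius: float
    # generating centerline rings (surface-of-revolution geometry), used
    # for wall normals and wall distances in stress post-processing
    ring_centers: np.ndarray | None = None  # (k, 3)
    ring_radius: np.ndarray | None = None  # (k,)
    ring_tangents: np.ndarray | None = None  # (k, 3)

    @property
    def fluid(self) -> np.ndarray:
        return self.site_type != SOLID

    @property
    def n_fluid(self) -> int:
        return int(np.count_nonzero(self.fluid))

    def voxel_centers(self, mask: np.ndarray) -> np.ndarray:
        idx = np.argwhere(mask)
        return self.origin[None, :] + idx * self.spacing


def voxelize(
    mesh: LumenMesh,
    target_sites_across_neck: int = 8,
    mask: MaskSet | None = None,
) -> LatticeDomain:
    """Voxelize the capped lumen mesh by axis-aligned ray parity.

    Lattice spacing is ``2 r_min / target`` so the narrowest lumen diameter
    spans at least ``target`` sites.  Voxel centers inside the closed mesh
    become fluid; the first fluid layer inside each end cap becomes the
    inlet/outlet boundary layer.  Region and stub-extension flags are
    transferred from the nearest ring center; clot flags come from each
    body voxel's own 2-D projection onto ``mask`` (the clot is delineated
    in the imaging plane).
    """
    if target_sites_across_neck < 8:
        raise ValueError("a minimum of 8 sites across the narrowest point is required")
    r_min = float(mesh.ring_radius.min())
    h = 2.0 * r_min / target_sites_across_neck

    verts, tris = mesh.capped_triangles()
    lo = verts.min(axis=0) - 1.5 * h
    hi = verts.max(axis=0) + 1.5 * h
    # irrational-ish origin fraction avoids rays grazing mesh vertices/edges
    origin = lo + 0.2643 * h
    shape = np.ceil((hi - origin) / h).astype(int) + 1

    counts, xs, signs = _ray_crossings(
        np.ascontiguousarray(verts),
        np.ascontiguousarray(tris.astype(np.int64)),
        origin[1],
        origin[2],
        h,
        int(shape[1]),
        int(shape[2]),
        64,
    )
    odd = counts % 2 != 0
    if odd.any():
        logger.warning("%d voxel columns had odd crossing parity", int(odd.sum()))
    fluid = _fill_columns(counts, xs, signs, origin[0], h, int(shape[0])).astype(bool)

    labels, ncomp = ndimage.label(fluid)
    if ncomp > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, ncomp + 1))
        main = 1 + int(np.argmax(sizes))
        if sizes.max() < 0.95 * fluid.sum():
            raise SkeletonError(
                f"fluid domain disconnected: {ncomp} components, sizes {sorted(map(int, sizes))}"
            )
        fluid = labels == main

    site_type = np.where(fluid, FLUID, SOLID).astype(np.uint8)

    # region transfer from nearest ring center
    idx = np.argwhere(fluid)
    centers = origin[None, :] + idx * h
    tree = cKDTree(mesh.ring_centers)
    _, ring_of = tree.query(centers)
    region = np.zeros(fluid.shape, dtype=np.uint8)
    clot = np.zeros(fluid.shape, dtype=bool)
    extended = np.zeros(fluid.shape, dtype=bool)
    codes = np.array([_REGION_CODE[r] for r in mesh.ring_region], dtype=np.uint8)
    region[tuple(idx.T)] = codes[ring_of]
    extended[tuple(idx.T)] = mesh.ring_extended[ring_of]
    if mask is not None and mask.has_clot:
        is_clot = (mask.label_at(centers[:, :2]) == CLOT) & (
            codes[ring_of] == R_BODY
        )
        clot[tuple(idx.T)] = is_clot

    # inlet/outlet: first fluid layer inside each end cap
    p_in, p_out = mesh.ring_centers[0], mesh.ring_centers[-1]
    t_in = mesh.ring_centers[1] - mesh.ring_centers[0]
    t_in = t_in / np.linalg.norm(t_in)
    t_out = mesh.ring_centers[-1] - mesh.ring_centers[-2]
    t_out = t_out / np.linalg.norm(t_out)
    proj_in = (centers - p_in) @ t_in
    proj_out = (centers - p_out) @ t_out
    inlet_sel = proj_in < proj_in.min() + h
    outlet_sel = proj_out > proj_out.max() - h
    site_type[tuple(idx[inlet_sel].T)] = INLET
    site_type[tuple(idx[outlet_sel].T)] = OUTLET
    if not inlet_sel.any() or not outlet_sel.any():
        raise SkeletonError("could not identify inlet/outlet fluid layers")

    ring_t = np.gradient(mesh.ring_centers, axis=0)
    ring_t /= np.maximum(np.linalg.norm(ring_t, axis=1, keepdims=True), 1e-12)
    dom = LatticeDomain(
        spacing=h,
        origin=origin,
        site_type=site_type,
        region=region,
        clot=clot,
        extended=extended,
        inlet_center=p_in,
        inlet_axis=t_in,
        inlet_radius=float(mesh.ring_radius[0]),
        outlet_center=p_out,
        outlet_axis=t_out,
        outlet_radius=float(mesh.ring_radius[-1]),
        ring_centers=mesh.ring_centers.copy(),
        ring_radius=mesh.ring_radius.copy(),
        ring_tangents=ring_t,
    )
    logger.info(
        "voxelized lumen: spacing %.3f μm, %d fluid sites", h, dom.n_fluid
    )
    return dom
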
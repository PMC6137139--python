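"""Perfusion indices: SRMD, WSSMD, clot sub-region variants, low-shear maps.

SRMD (shear rate mean drop) is the mean shear rate over the
feeding/draining-vessel fluid sites divided by the mean over the MA-body
fluid sites; WSSMD (wall shear stress mean drop) is the analogous ratio of
area-weighted mean wall shear stress over vessel vs body wall elements.
Both are dimensionless; in the absence of an MA (a uniform tube) each is
≈ 1, and they grow as the dilated body slows and shields the flow.  For
partially clotted lesions the body denominator can be restricted to the
clotted or the perfused sub-region separately.

Volume means are unweighted over lattice sites (uniform voxels); surface
means are area-weighted over wall elements.  Stub portions added
synthetically beyond the segmented vessels are excluded from the vessel
means.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .hemodynamics import FlowResult, WallField, wall_shear_stress
from .reconstruction import FLUID, R_BODY, R_IN, R_OUT, LatticeDomain


class EmptyRegionError(ValueError):
    """An index denominator or numerator region has no sites/elements."""


@dataclasses.dataclass
class PerfusionReport:
    """Per-lesion hemodynamic index summary."""

    srmd: float
    wssmd: float
    srmd_perfused: float | None = None
    srmd_clotted: float | None = None
    wssmd_perfused: float | None = None
    wssmd_clotted: float | None = None
    low_shear_threshold: float | None = None  # 1/s
    low_shear_fraction_body: float | None = None
    low_shear_fraction_clot: float | None = None

    def row(self) -> dict:
        return dataclasses.asdict(self)


def _site_masks(f: FlowResult, dom: LatticeDomain):
    region = dom.region[tuple(f.idx.T)]
    extended = dom.extended[tuple(f.idx.T)]
    clot = dom.clot[tuple(f.idx.T)]
    # inlet/outlet layers hold boundary-condition equilibria, not flow
    # samples; only interior fluid sites enter the averages
    interior = dom.site_type[tuple(f.idx.T)] == FLUID
    vessel = ((region == R_IN) | (region == R_OUT)) & ~extended & interior
    body = (region == R_BODY) & interior
    return vessel, body, clot


def srmd(f: FlowResult, dom: LatticeDomain) -> float:
    """Mean vessel shear rate over mean body shear rate."""
    vessel, body, _ = _site_masks(f, dom)
    if not vessel.any() or not body.any():
        raise EmptyRegionError("need nonempty vessel and body fluid regions")
    return float(f.shear_rate[vessel].mean() / f.shear_rate[body].mean())


def _wall_masks(wall: WallField, f: FlowResult, dom: LatticeDomain):
    region = dom.region[tuple(wall.idx.T)]
    extended = dom.extended[tuple(wall.idx.T)]
    clot = dom.clot[tuple(wall.idx.T)]
    interior = dom.site_type[tuple(wall.idx.T)] == FLUID
    vessel = ((region == R_IN) | (region == R_OUT)) & ~extended & interior
    body = (region == R_BODY) & interior
    return vessel, body, clot


def wssmd(
    f: FlowResult, dom: LatticeDomain, wall: WallField | None = None
) -> float:
    """Area-weighted mean vessel WSS over area-weighted mean body WSS."""
    wall = wall or wall_shear_stress(f, dom)
    vessel, body, _ = _wall_masks(wall, f, dom)
    if not vessel.any() or not body.any():
        raise EmptyRegionError("need nonempty vessel and body wall regions")
    num = np.average(wall.wss[vessel], weights=wall.area[vessel])
    den = np.average(wall.wss[body], weights=wall.area[body])
    return float(num / den)


def subregion_indices(
    f: FlowResult, dom: LatticeDomain, wall: WallField | None = None
) -> tuple[float, float, float, float]:
    """(srmd_perfused, srmd_clotted, wssmd_perfused, wssmd_clotted).

    The same ratio definitions with the body mean restricted to the
    perfused (non-clot) or clotted body sites / wall elements.  If the clot
    covers the whole body, the perfused variants are reported as NaN rather
    than raising; an absent clot raises.
    """
    vessel, body, clot = _site_masks(f, dom)
    if not (body & clot).any():
        raise EmptyRegionError("no clot-flagged body sites")
    sr_v = f.shear_rate[vessel].mean()

    def _vol(mask):
        return float(sr_v / f.shear_rate[mask].mean()) if mask.any() else float("nan")

    srmd_p = _vol(body & ~clot)
    srmd_c = _vol(body & clot)

    wall = wall or wall_shear_stress(f, dom)
    wvessel, wbody, wclot = _wall_masks(wall, f, dom)
    if not (wbody & wclot).any():
        raise EmptyRegionError("no clot-flagged body wall elements")
    wss_v = np.average(wall.wss[wvessel], weights=wall.area[wvessel])

    def _sur(mask):
        if not mask.any():
            return float("nan")
        return float(wss_v / np.average(wall.wss[mask], weights=wall.area[mask]))

    wssmd_p = _sur(wbody & ~wclot)
    wssmd_c = _sur(wbody & wclot)
    return srmd_p, srmd_c, wssmd_p, wssmd_c


def low_shear_map(
    series: list[FlowResult], dom: LatticeDomain, threshold: float = 15.0
) -> np.ndarray:
    """Per-site fraction of the cardiac cycle spent at γ̇ ≤ threshold.

    ``series`` must hold at least two snapshots of one cycle; snapshots are
    weighted uniformly.  Returns the fraction per fluid site, aligned with
    the site order of the snapshots.
    """
    if len(series) < 2:
        raise ValueError("low-shear mapping needs a multi-snapshot pulsatile series")
    below = np.stack([snap.shear_rate <= threshold for snap in series])
    return below.mean(axis=0)


def low_shear_summary(
    series: list[FlowResult], dom: LatticeDomain, threshold: float = 15.0
) -> dict:
    """Region-mean below-threshold cycle fractions (body, clot, vessel)."""
    frac = low_shear_map(series, dom, threshold)
    vessel, body, clot = _site_masks(series[0], dom)
    out = {
        "threshold": threshold,
        "body": float(frac[body].mean()) if body.any() else float("nan"),
        "vessel": float(frac[vessel].mean()) if vessel.any() else float("nan"),
    }
    out["clot"] = float(frac[body & clot].mean()) if (body & clot).any() else float("nan")
    out["perfused"] = (
        float(frac[body & ~clot].mean()) if (body & ~clot).any() else float("nan")
    )
    return out


def perfusion_report(
    f: FlowResult,
    dom: LatticeDomain,
    series: list[FlowResult] | None = None,
    threshold: float = 15.0,
) -> PerfusionReport:
    """All indices for one lesion; sub-region variants iff a clot exists."""
    wall = wall_shear_stress(f, dom)
    report = PerfusionReport(srmd=srmd(f, dom), wssmd=wssmd(f, dom, wall))
    if dom.clot.any():
        sp, sc, wp, wc = subregion_indices(f, dom, wall)
        report.srmd_perfused, report.srmd_clotted = sp, sc
        report.wssmd_perfused, report.wssmd_clotted = wp, wc
    if series is not None:
        summary = low_shear_summary(series, dom, threshold)
        report.low_shear_threshold = threshold
        report.low_shear_fraction_body = summary["body"]
        report.low_shear_fraction_clot = summary["clot"]
    return report
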
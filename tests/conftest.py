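"""Shared fixtures: geometric phantoms and (expensive) flow solutions.

Simulation-backed fixtures are session-scoped so the cylinder benchmark,
the body-to-neck-ratio sweep and the clotted-lesion run are each computed
once and reused by the module tests and the acceptance suite.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from maflow.hemodynamics import (
    InletCondition,
    RheologyParams,
    run_pulsatile,
    run_steady,
)
from maflow.morphology import asymmetry_ratio, body_to_neck_ratio
from maflow.reconstruction import extend_stubs, sweep_surface, voxelize
from maflow.skeleton import Centerline, medial_axis, partition_centerline
from maflow.synthetic_data import FixtureSpec, cohort_fixture, generate_mask, generate_waveform

CYL_RADIUS = 8.0  # μm
CYL_LENGTH = 64.0  # μm
BLOOD_ETA = 0.0035  # Pa s, infinite-shear plateau


def straight_centerline(radius: float = CYL_RADIUS, length: float = CYL_LENGTH,
                        n: int = 129) -> Centerline:
    """Straight tube centerline with the middle third labeled body."""
    pts = np.column_stack([np.linspace(0, length, n), np.zeros(n)])
    region = np.full(n, "vessel_in", dtype="<U10")
    region[n // 3: 2 * n // 3] = "body"
    region[2 * n // 3:] = "vessel_out"
    return Centerline(pts, np.full(n, radius), region, np.linspace(0, length, n))


def run_fixture_steady(spec: FixtureSpec, rheology=None, tol=1e-4, target=8):
    """mask → centerline → lattice → steady flow, returning all stages."""
    mask, gt = generate_mask(spec)
    center = partition_centerline(medial_axis(mask), mask)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        mesh = sweep_surface(extend_stubs(center), 48, mask=mask)
    dom = voxelize(mesh, target, mask=mask)
    flow = run_steady(dom, InletCondition.steady_from_mean(),
                      rheology or RheologyParams(), tol=tol)
    return {"mask": mask, "gt": gt, "center": center, "mesh": mesh,
            "dom": dom, "flow": flow}


@pytest.fixture(scope="session")
def cylinder_domain():
    mesh = sweep_surface(straight_centerline(), 64)
    return voxelize(mesh, 8)


@pytest.fixture(scope="session")
def cylinder_flow(cylinder_domain):
    """Newtonian Poiseuille benchmark at 16 sites across the diameter."""
    flow = run_steady(
        cylinder_domain,
        InletCondition.steady_from_mean(),
        RheologyParams.newtonian(BLOOD_ETA),
        tol=1e-7,
    )
    return cylinder_domain, flow


@pytest.fixture(scope="session")
def cylinder_fine_flow():
    """Same benchmark at doubled resolution, for grid-convergence checks."""
    dom = voxelize(sweep_surface(straight_centerline(), 64), 16)
    flow = run_steady(
        dom,
        InletCondition.steady_from_mean(),
        RheologyParams.newtonian(BLOOD_ETA),
        tol=1e-7,
    )
    return dom, flow


@pytest.fixture(scope="session")
def cylinder_cy_flow(cylinder_domain):
    """Shear-thinning blood flow in the benchmark cylinder."""
    flow = run_steady(
        cylinder_domain,
        InletCondition.steady_from_mean(),
        RheologyParams(),
        tol=1e-5,
    )
    return cylinder_domain, flow


@pytest.fixture(scope="session")
def saccular_case():
    """Mid-offset saccular phantom: mask, ground truth, centerline."""
    spec = FixtureSpec(kind="saccular", neck_radius=5, body_max_radius=15, asymmetry=8)
    mask, gt = generate_mask(spec)
    center = partition_centerline(medial_axis(mask), mask)
    return {"spec": spec, "mask": mask, "gt": gt, "center": center}


@pytest.fixture(scope="session")
def clot_case():
    """Clotted saccular lesion with a converged blood-flow solution."""
    spec = FixtureSpec(kind="saccular", neck_radius=5, body_max_radius=15,
                       asymmetry=8, clot="apex")
    return run_fixture_steady(spec)


@pytest.fixture(scope="session")
def bnr_sweep():
    """Steady blood-flow indices across phantoms of increasing BNR."""
    from maflow.perfusion_indices import srmd, wssmd

    rows = []
    for rb in (7.5, 12.0, 18.0, 25.0):
        spec = FixtureSpec(kind="saccular", neck_radius=5, body_max_radius=rb,
                           asymmetry=0.5 * (rb - 1.25))
        case = run_fixture_steady(spec)
        rows.append(
            {
                "bnr": case["gt"].bnr,
                "srmd": srmd(case["flow"], case["dom"]),
                "wssmd": wssmd(case["flow"], case["dom"]),
            }
        )
    return rows


@pytest.fixture(scope="session")
def recovery_cohort():
    """Twenty-fixture cohort with per-lesion recovered AR and BNR."""
    out = []
    for mask, gt, spec in cohort_fixture(10, 10, seed=5):
        center = partition_centerline(medial_axis(mask), mask)
        ar, a1, a2 = asymmetry_ratio(mask, center)
        out.append(
            {
                "mask": mask,
                "gt": gt,
                "spec": spec,
                "center": center,
                "ar": ar,
                "a1": a1,
                "a2": a2,
                "bnr": body_to_neck_ratio(center),
            }
        )
    return out


@pytest.fixture(scope="session")
def small_tube_domain():
    """Small tube lattice for pulsatile runs kept cheap."""
    mesh = sweep_surface(straight_centerline(radius=3.0, length=24.0, n=65), 32)
    return voxelize(mesh, 8)


@pytest.fixture(scope="session")
def pulsatile_tube(small_tube_domain):
    """Sinusoidal pulsatile run on the small tube (quasi-steady regime)."""
    wf = generate_waveform(pulsatility=0.4, n_points=64)
    inlet = InletCondition(2 * 1.69, mode="pulsatile", waveform=wf)
    series = run_pulsatile(
        small_tube_domain, inlet, RheologyParams.newtonian(BLOOD_ETA),
        steps_per_cycle=4000, n_cycles=2, n_snapshots=8,
    )
    return small_tube_domain, inlet, series


@pytest.fixture(scope="session")
def pulsatile_clot():
    """Pulsatile blood flow in a small clotted saccular lesion."""
    spec = FixtureSpec(kind="saccular", neck_radius=4, body_max_radius=10,
                       asymmetry=4.5, clot="apex")
    mask, gt = generate_mask(spec)
    center = partition_centerline(medial_axis(mask), mask)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        mesh = sweep_surface(extend_stubs(center), 48, mask=mask)
    dom = voxelize(mesh, 8, mask=mask)
    wf = generate_waveform(pulsatility=0.4, n_points=64)
    inlet = InletCondition(2 * 1.69, mode="pulsatile", waveform=wf)
    series = run_pulsatile(dom, inlet, RheologyParams(),
                           steps_per_cycle=5000, n_cycles=2, n_snapshots=8)
    return {"mask": mask, "gt": gt, "dom": dom, "series": series}
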
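"""Medial-axis extraction: boundaries, radii, pruning, partitioning."""

import logging

import numpy as np
import pytest
from scipy import ndimage

from maflow.mask_model import BODY, VESSEL, MaskSet
from maflow.skeleton import (
    SkeletonError,
    boundary_points,
    medial_axis,
    partition_centerline,
)
from maflow.synthetic_data import FixtureSpec, generate_mask


def ribbon_mask(width=11, length=61, pixel_size=1.0):
    """Constant-width ribbon with vessel ends and body middle."""
    r = np.zeros((width + 8, length + 8), dtype=np.uint8)
    r[4: 4 + width, 4: 4 + length] = VESSEL
    r[4: 4 + width, 4 + length // 3: 4 + 2 * length // 3] = BODY
    return MaskSet(r, pixel_size)


class TestBoundary:
    def test_square_boundary_is_sixteen_ordered_pixels(self):
        r = np.zeros((9, 9), dtype=np.uint8)
        r[2:7, 2:7] = BODY
        xy = boundary_points(MaskSet(r, 1.0))
        assert len(xy) == 16
        # ordered: consecutive boundary pixels are 8-neighbors
        d = np.abs(np.diff(np.vstack([xy, xy[:1]]), axis=0))
        assert (d.max(axis=1) == 1).all()
        # counter-clockwise: positive shoelace area
        x, y = xy[:, 0], xy[:, 1]
        assert np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y) > 0

    def test_interior_hole_is_filled_with_warning(self, caplog):
        r = np.zeros((15, 15), dtype=np.uint8)
        r[2:13, 2:13] = BODY
        r[7, 7] = 0
        with caplog.at_level(logging.WARNING, logger="maflow.skeleton"):
            xy = boundary_points(MaskSet(r, 1.0))
        assert "holes" in caplog.text
        assert len(xy) == 40  # outer ring only

    def test_disconnected_silhouette_raises(self):
        r = np.zeros((9, 20), dtype=np.uint8)
        r[3:6, 2:6] = BODY
        r[3:6, 12:18] = VESSEL
        with pytest.raises(SkeletonError, match="disconnected"):
            boundary_points(MaskSet(r, 1.0))

    def test_polygon_length_matches_generating_perimeter(self):
        mask, gt = generate_mask(FixtureSpec(kind="fusiform", asymmetry=3))
        xy = boundary_points(mask)
        closed = np.vstack([xy, xy[:1]])
        length = np.hypot(*np.diff(closed, axis=0).T).sum()
        assert length == pytest.approx(gt.perimeter, rel=0.05)


class TestMedialAxis:
    def test_ribbon_radii_are_half_width(self):
        mask = ribbon_mask(width=11)
        c = medial_axis(mask)
        mid = (c.arclength > 10) & (c.arclength < c.arclength[-1] - 10)
        assert np.median(c.radius[mid]) == pytest.approx(5.5, abs=0.6)
        assert np.std(c.radius[mid]) / np.mean(c.radius[mid]) < 0.05

    def test_ribbon_centerline_on_midline(self):
        mask = ribbon_mask(width=11)
        c = medial_axis(mask)
        mid = (c.arclength > 10) & (c.arclength < c.arclength[-1] - 10)
        assert np.allclose(c.points[mid, 1], 9.0, atol=0.6)

    def test_bulge_maximum_radius_matches_distance_transform(self, saccular_case):
        mask, c = saccular_case["mask"], saccular_case["center"]
        edt = ndimage.distance_transform_edt(mask.silhouette) * mask.pixel_size
        assert c.radius.max() == pytest.approx(edt.max(), abs=0.71 * mask.pixel_size)

    @pytest.mark.parametrize("kind,h", [("tube", 0), ("fusiform", 5), ("saccular", 8)])
    def test_radii_agree_with_distance_transform_everywhere(self, kind, h):
        mask, _ = generate_mask(
            FixtureSpec(kind=kind, neck_radius=5, body_max_radius=15, asymmetry=h)
        )
        c = medial_axis(mask)
        edt = ndimage.distance_transform_edt(mask.silhouette) * mask.pixel_size
        # the distance transform evaluated at the off-lattice path points
        coords = np.vstack(
            [c.points[:, 1] / mask.pixel_size, c.points[:, 0] / mask.pixel_size]
        )
        at_points = ndimage.map_coordinates(edt, coords, order=1)
        err = np.abs(c.radius - at_points)
        assert err.max() <= 0.71 * mask.pixel_size

    def test_rotation_by_90_degrees_preserves_radii(self, saccular_case):
        mask = saccular_case["mask"]
        rot = MaskSet(np.rot90(mask.label_raster).copy(), mask.pixel_size)
        c0 = medial_axis(mask)
        c1 = medial_axis(rot)
        assert c1.radius.max() == pytest.approx(c0.radius.max(), abs=1e-6)
        assert c1.radius.min() == pytest.approx(c0.radius.min(), abs=1e-6)
        assert c1.arclength[-1] == pytest.approx(c0.arclength[-1], rel=1e-3)

    def test_arbitrary_rotation_preserves_radii_within_a_pixel(self, saccular_case):
        mask = saccular_case["mask"]
        pad = np.pad(mask.label_raster, 30)
        rot = ndimage.rotate(pad, 35, order=0, reshape=False)
        c0 = medial_axis(mask)
        c1 = medial_axis(MaskSet(rot, mask.pixel_size))
        assert c1.radius.max() == pytest.approx(c0.radius.max(), abs=mask.pixel_size)

    def test_too_thin_mask_raises(self):
        r = np.zeros((7, 20), dtype=np.uint8)
        r[3, 2:18] = BODY  # 1-pixel line
        with pytest.raises(SkeletonError):
            medial_axis(MaskSet(r, 1.0))

    def test_resampling_spacing_is_half_pixel(self, saccular_case):
        c = saccular_case["center"]
        steps = np.diff(c.arclength)
        assert steps.max() <= 0.5 * saccular_case["mask"].pixel_size + 1e-9


class TestPartition:
    def test_tube_thirds_are_labeled_by_region(self):
        mask = ribbon_mask()
        c = partition_centerline(medial_axis(mask), mask)
        assert {"vessel_in", "body", "vessel_out"} == set(c.region)
        # body run is contiguous
        body_idx = np.flatnonzero(c.region == "body")
        assert np.all(np.diff(body_idx) == 1)

    def test_orientation_follows_flow_hint(self, saccular_case):
        mask, c = saccular_case["mask"], saccular_case["center"]
        assert c.points[0, 0] < c.points[-1, 0]  # inlet on the smaller-x side
        assert c.region[0] == "vessel_in" and c.region[-1] == "vessel_out"

    def test_body_extent_matches_silhouette_extent_along_flow_axis(self, saccular_case):
        mask, gt = saccular_case["mask"], saccular_case["gt"]
        c = saccular_case["center"]
        body_x = c.points[c.region == "body", 0]
        lo, hi = gt.body_xrange
        assert body_x.min() == pytest.approx(lo, abs=1.5)
        assert body_x.max() == pytest.approx(hi, abs=1.5)

    def test_vessel_only_mask_raises(self):
        r = np.zeros((11, 41), dtype=np.uint8)
        r[3:8, 2:39] = VESSEL
        mask = MaskSet(r, 1.0)  # deliberately unvalidated
        with pytest.raises(SkeletonError, match="body"):
            partition_centerline(medial_axis(mask), mask)

    def test_csv_roundtrip(self, saccular_case, tmp_path):
        import pandas as pd

        c = saccular_case["center"]
        path = c.to_csv(tmp_path / "c.csv")
        df = pd.read_csv(path)
        assert list(df.columns) == [
            "x_um", "y_um", "radius_um", "region", "arclength_um", "extended",
        ]
        assert len(df) == len(c.points)
        assert np.allclose(df["radius_um"], c.radius)
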
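"""Labeled microaneurysm segmentation masks and their physical calibration.

A :class:`MaskSet` is a 2-D indexed raster over four labels

====  =======================================
0     background
1     MA body
2     feeding/draining vessel
3     clot (a flagged sub-region of the body)
====  =======================================

together with an isotropic pixel size in micrometres.  Clot pixels count as
body pixels everywhere a body silhouette is needed; label 3 merely flags
them.  Physical coordinates follow the raster convention
``x = column * pixel_size``, ``y = row * pixel_size`` with a pixel being the
closed unit square centred on its index.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import yaml
from scipy import ndimage

BACKGROUND, BODY, VESSEL, CLOT = 0, 1, 2, 3
_VALID_LABELS = frozenset({BACKGROUND, BODY, VESSEL, CLOT})

#: 4-connectivity structuring element used for every connectivity test.
_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


class MaskValidationError(ValueError):
    """Raised when a raster violates the MaskSet invariants."""


@dataclasses.dataclass
class MaskSet:
    """Labeled 2-D segmentation raster with physical calibration.

    Parameters
    ----------
    label_raster
        2-D integer array with values in {0, 1, 2, 3}.
    pixel_size
        Isotropic pixel edge length in micrometres (> 0).
    flow_direction
        Optional pair of (x, y) points in micrometres hinting at the inlet
        and outlet attachment sites.  When absent, downstream code orients
        the centerline from the endpoint with the smaller x coordinate.
    provenance
        Free-text identifier of the source image or fixture.
    """

    label_raster: np.ndarray
    pixel_size: float
    flow_direction: tuple[tuple[float, float], tuple[float, float]] | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.label_raster = np.asarray(self.label_raster)
        if self.label_raster.ndim != 2:
            raise MaskValidationError("label raster must be 2-D")
        self.label_raster = self.label_raster.astype(np.uint8, casting="unsafe")

    # -- region views -----------------------------------------------------
    @property
    def body(self) -> np.ndarray:
        """Boolean body silhouette (clot pixels included)."""
        return (self.label_raster == BODY) | (self.label_raster == CLOT)

    @property
    def vessel(self) -> np.ndarray:
        return self.label_raster == VESSEL

    @property
    def clot(self) -> np.ndarray:
        return self.label_raster == CLOT

    @property
    def silhouette(self) -> np.ndarray:
        """Union of body, clot and vessel regions."""
        return self.label_raster != BACKGROUND

    @property
    def has_clot(self) -> bool:
        return bool(self.clot.any())

    def validate(self) -> "MaskSet":
        """Check all invariants; return self for chaining."""
        if not self.pixel_size > 0:
            raise MaskValidationError(f"pixel_size must be > 0, got {self.pixel_size}")
        extra = set(np.unique(self.label_raster)) - _VALID_LABELS
        if extra:
            raise MaskValidationError(f"unknown label values {sorted(extra)}")
        for name, region in (
            ("body", self.body),
            ("vessel", self.vessel),
            ("clot", self.clot),
        ):
            if region.any():
                _, n = ndimage.label(region, structure=_FOUR_CONN)
                if name != "vessel" and n != 1:
                    raise MaskValidationError(
                        f"{name} region must be 4-connected; found {n} components"
                    )
        # clot containment is structural (label 3 is a body pixel by encoding),
        # but merged-binary input may have produced clot without body support.
        if self.has_clot and not (self.label_raster == BODY).any():
            raise MaskValidationError("clot present but no unclotted body pixels")
        self._check_two_stubs()
        return self

    def _check_two_stubs(self) -> None:
        """Exactly two vessel stubs must touch the body region boundary."""
        if not self.body.any():
            raise MaskValidationError("mask has no body region")
        if not self.vessel.any():
            raise MaskValidationError("mask has no vessel region")
        labels, n = ndimage.label(self.vessel, structure=_FOUR_CONN)
        body_dil = ndimage.binary_dilation(self.body, structure=_FOUR_CONN)
        touching = {int(v) for v in np.unique(labels[body_dil & (labels > 0)])}
        if len(touching) != 2:
            raise MaskValidationError(
                f"expected exactly two vessel stubs touching the body, "
                f"found {len(touching)} (of {n} vessel components)"
            )

    # -- geometry helpers -------------------------------------------------
    def pixel_centers(self, region: np.ndarray) -> np.ndarray:
        """(x, y) coordinates in μm of pixel centers of a boolean region."""
        rows, cols = np.nonzero(region)
        return np.column_stack([cols, rows]).astype(float) * self.pixel_size

    def label_at(self, points_xy: np.ndarray) -> np.ndarray:
        """Label value at the pixel containing each (x, y) μm point."""
        pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
        cols = np.rint(pts[:, 0] / self.pixel_size).astype(int)
        rows = np.rint(pts[:, 1] / self.pixel_size).astype(int)
        h, w = self.label_raster.shape
        out = np.zeros(len(pts), dtype=np.uint8)
        ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
        out[ok] = self.label_raster[rows[ok], cols[ok]]
        return out


def region_area(mask: MaskSet, label: int) -> float:
    """Area of one labeled region in μm².

    ``label=BODY`` counts clot pixels as body (the clot is a flagged body
    sub-region); ``label=CLOT`` counts clot pixels only.
    """
    if label not in _VALID_LABELS:
        raise ValueError(f"unknown label {label}")
    if label == BODY:
        n = int(mask.body.sum())
    else:
        n = int((mask.label_raster == label).sum())
    return n * mask.pixel_size**2


def _merge_binary(rasters: Mapping[str, np.ndarray]) -> np.ndarray:
    """Merge separate binary rasters with precedence clot > body > vessel."""
    shapes = {r.shape for r in rasters.values()}
    if len(shapes) != 1:
        raise MaskValidationError(f"binary rasters differ in shape: {shapes}")
    shape = shapes.pop()
    merged = np.zeros(shape, dtype=np.uint8)
    for name, value in (("vessel", VESSEL), ("body", BODY), ("clot", CLOT)):
        if name in rasters:
            merged[np.asarray(rasters[name]) > 0] = value
    if "clot" in rasters and "body" in rasters:
        clot = np.asarray(rasters["clot"]) > 0
        body = np.asarray(rasters["body"]) > 0
        if (clot & ~body).any():
            raise MaskValidationError("clot pixels fall outside the body mask")
    return merged


def read_mask_set(
    source: str | Path | Mapping[str, str | Path],
    pixel_size: float | None = None,
    flow_direction: Sequence[Sequence[float]] | None = None,
    provenance: str = "",
) -> MaskSet:
    """Read a MaskSet from raster files.

    Parameters
    ----------
    source
        Either the path of a single indexed raster (labels 0–3, canonical
        form) or a mapping with keys among ``{"body", "vessel", "clot"}``
        pointing to binary rasters, merged with precedence
        clot > body > vessel.
    pixel_size
        μm per pixel.  May be omitted when a YAML sidecar
        (``<raster>.yaml``) next to a single indexed raster provides it.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        raster = np.asarray(iio.imread(path))
        if raster.ndim == 3:  # palette PNG decoded to RGB: reject ambiguity
            raise MaskValidationError(
                f"{path} decoded to {raster.shape}; an indexed single-channel "
                "raster is required"
            )
        sidecar = path.with_suffix(path.suffix + ".yaml")
        meta: dict = {}
        if sidecar.exists():
            meta = yaml.safe_load(sidecar.read_text()) or {}
        if pixel_size is None:
            pixel_size = meta.get("pixel_size_um")
        if flow_direction is None and "flow_direction" in meta:
            flow_direction = meta["flow_direction"]
        provenance = provenance or meta.get("provenance", "")
    else:
        raster = _merge_binary({k: np.asarray(iio.imread(v)) for k, v in source.items()})
    if pixel_size is None:
        raise MaskValidationError("pixel_size not given and no sidecar found")
    fd = None
    if flow_direction is not None:
        (x0, y0), (x1, y1) = flow_direction
        fd = ((float(x0), float(y0)), (float(x1), float(y1)))
    return MaskSet(raster, float(pixel_size), fd, provenance).validate()


def write_mask_set(mask: MaskSet, path: str | Path) -> Path:
    """Write the indexed raster (PNG or TIFF by extension) plus YAML sidecar."""
    path = Path(path)
    iio.imwrite(path, mask.label_raster)
    meta = {
        "pixel_size_um": float(mask.pixel_size),
        "provenance": mask.provenance,
    }
    if mask.flow_direction is not None:
        meta["flow_direction"] = [[float(v) for v in p] for p in mask.flow_direction]
    path.with_suffix(path.suffix + ".yaml").write_text(yaml.safe_dump(meta))
    return path
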
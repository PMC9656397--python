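"""Seven shape descriptors of cells and colonies from labeled rasters.

The descriptor set follows the particle-analyzer conventions of classical
image-based colony morphometrics:

========================  ====================================================
descriptor                definition
========================  ====================================================
area                      pixel count x pixel_size^2 (um^2)
perimeter                 length of the traced boundary polygon on pixel
                          corners, staircase-straightened (um)
minor_axis                minor axis of the moments-equivalent ellipse,
                          rescaled so the ellipse area equals the region area
feret_d                   largest distance between two boundary points
                          (maximum caliper over convex-hull corner points)
min_feret_d               smallest caliper width (rotating calipers)
shape_factor              4*pi*area / perimeter^2 (isoperimetric quotient)
ais                       free intercellular space inside the colony
                          footprint: (footprint - sum of cells), colonies only
========================  ====================================================

All lengths scale linearly and areas quadratically with ``pixel_size``;
measurements are exactly invariant under lossless 90-degree rotations.
Holes inside a cell region are filled before measurement; holes in the
colony footprint count toward the intercellular space.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from . import _geometry
from .image import LabeledColonyImage

logger = logging.getLogger(__name__)

#: canonical column order of a morphology record table
RECORD_COLUMNS = [
    "unit", "label", "line", "passage", "time_h", "phenotype", "clonality",
    "area", "perimeter", "minor_axis", "feret_d", "min_feret_d",
    "shape_factor", "ais",
]

#: the seven colony descriptors, in canonical order
COLONY_PARAMETERS = [
    "area", "perimeter", "minor_axis", "feret_d", "min_feret_d",
    "shape_factor", "ais",
]

#: descriptors defined for single cells (no intercellular space)
CELL_PARAMETERS = COLONY_PARAMETERS[:-1]


class EmptyRegionError(ValueError):
    """Raised when a measurement is requested on an empty mask."""


class MultiRegionError(ValueError):
    """Raised when a single-region operation receives several components."""


class ConsistencyError(ValueError):
    """Raised when cell labels are inconsistent with the colony footprint."""


def _as_mask(mask) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("mask must be a 2-D raster")
    if not mask.any():
        raise EmptyRegionError("mask contains no foreground pixels")
    return mask


def region_area(mask, pixel_size: float = 1.0) -> float:
    """Area of a region: foreground pixel count times the pixel area."""
    mask = _as_mask(mask)
    return float(mask.sum()) * pixel_size ** 2


def region_perimeter(mask, pixel_size: float = 1.0, method: str = "traced") -> float:
    """Boundary length of a single connected region.

    ``method="traced"`` (default) measures the simplified corner polygon
    (see :func:`colonymorph._geometry.perimeter_traced`); ``"crofton"``
    selects the Crofton formula as implemented in scikit-image, for
    cross-checking.
    """
    mask = _as_mask(mask)
    _, n = ndimage.label(mask)
    if n != 1:
        raise MultiRegionError(
            f"perimeter is defined per region; mask has {n} components"
        )
    if method == "traced":
        return _geometry.perimeter_traced(mask) * pixel_size
    if method == "crofton":
        from skimage.measure import perimeter_crofton

        return float(perimeter_crofton(mask, directions=4)) * pixel_size
    raise ValueError(f"unknown perimeter method: {method!r}")


def ellipse_axes(mask, pixel_size: float = 1.0) -> tuple[float, float]:
    """(major, minor) axes of the moments-equivalent, area-matched ellipse.

    The ellipse shares the region's normalized second central moments and is
    then rescaled so that pi/4 * major * minor equals the region area.  A
    degenerate (collinear-pixel) region is reported as minor = 0 with a
    warning.
    """
    mask = _as_mask(mask)
    r, c = np.nonzero(mask)
    n = r.size
    rc = np.stack([r - r.mean(), c - c.mean()])
    cov = rc @ rc.T / n
    evals = np.linalg.eigvalsh(cov)  # ascending
    lam_minor, lam_major = max(evals[0], 0.0), max(evals[1], 0.0)
    major = 4.0 * np.sqrt(lam_major)
    minor = 4.0 * np.sqrt(lam_minor)
    if minor == 0.0:
        warnings.warn("degenerate region: collinear pixels, minor axis = 0",
                      stacklevel=2)
        return major * pixel_size, 0.0
    # rescale so the ellipse area matches the pixel-count area exactly
    scale = np.sqrt(n / (np.pi / 4.0 * major * minor))
    return major * scale * pixel_size, minor * scale * pixel_size


def feret_diameters(mask, pixel_size: float = 1.0) -> tuple[float, float]:
    """(feret_d, min_feret_d): maximum and minimum caliper diameters.

    Both calipers run over the convex hull of the boundary corner points of
    the pixels, so a w x h pixel rectangle has feret_d = sqrt(w^2 + h^2) and
    min_feret_d = min(w, h) in pixel units.
    """
    mask = _as_mask(mask)
    fmax, fmin = _geometry.feret_diameters_px(mask)
    return fmax * pixel_size, fmin * pixel_size


def shape_factor(area: float, perimeter: float) -> float:
    """Isoperimetric quotient 4*pi*area/perimeter^2 (1 for an ideal circle).

    Values slightly above 1 can occur for near-circular rasterized regions
    because the two estimators quantize differently; they are not clamped,
    only logged.
    """
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    sf = 4.0 * np.pi * area / perimeter ** 2
    if sf > 1.0:
        logger.debug("shape factor %.4f > 1 (rasterization artifact)", sf)
    return float(sf)


def colony_ais(image: LabeledColonyImage) -> float:
    """Free intercellular space of the colony, in um^2.

    Defined by subtraction: (filled footprint area) - (sum of cell areas).
    Holes enclosed by the footprint count as intercellular space.
    """
    cells = image.cell_labels > 0
    if (cells & ~image.colony_footprint).any():
        raise ConsistencyError("cell pixels found outside the colony footprint")
    footprint = ndimage.binary_fill_holes(image.colony_footprint)
    ais_px = int(footprint.sum()) - int(cells.sum())
    return float(ais_px) * image.pixel_size ** 2


def _measure_region(mask, pixel_size: float) -> dict[str, float]:
    area = region_area(mask, pixel_size)
    perim = region_perimeter(mask, pixel_size)
    major, minor = ellipse_axes(mask, pixel_size)
    feret, min_feret = feret_diameters(mask, pixel_size)
    return {
        "area": area,
        "perimeter": perim,
        "minor_axis": minor,
        "feret_d": feret,
        "min_feret_d": min_feret,
        "shape_factor": shape_factor(area, perim),
    }


def measure_image(image: LabeledColonyImage) -> pd.DataFrame:
    """Measure every cell and the colony of a labeled image.

    Returns one record per cell label plus one colony record (descriptors of
    the filled footprint region, with the intercellular space), with the
    image metadata propagated to every row.
    """
    meta = image.meta.as_dict()
    rows = []
    slices = ndimage.find_objects(image.cell_labels)
    for label, slc in enumerate(slices, start=1):
        if slc is None:
            continue
        crop = image.cell_labels[slc] == label
        crop = ndimage.binary_fill_holes(crop)
        try:
            desc = _measure_region(crop, image.pixel_size)
        except ValueError as err:
            raise type(err)(f"cell label {label}: {err}") from err
        rows.append({"unit": "cell", "label": label, **meta, **desc,
                     "ais": np.nan})
    footprint = ndimage.binary_fill_holes(image.colony_footprint)
    desc = _measure_region(footprint, image.pixel_size)
    rows.append({
        "unit": "colony", "label": 0, **meta, **desc,
        "ais": colony_ais(image),
    })
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)
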
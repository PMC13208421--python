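"""Silhouette extraction and geometric spore descriptors.

The central statistic is the suprahilar depression: the percentage of a
spore silhouette's convex-hull area not covered by the silhouette itself,
100 × (hull − shape) / hull.  Equivalently 100 × (1 − solidity).  Convex
shapes score exactly 0; the statistic is invariant under rotation,
translation and uniform scaling.

Supporting operations segment a grayscale micrograph into a single-spore
binary mask (Otsu or fixed threshold, polarity auto-detected from the image
border), trace a subpixel boundary at the 0.5 iso-level, and measure length
and width as the maximum caliper (Feret) diameter and the maximal extent
perpendicular to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon
from skimage import measure
from skimage.filters import threshold_otsu

from .synthesize import MIN_FOREGROUND_PIXELS, SporeContour, SporeMask

__all__ = [
    "GeometryResult",
    "segment_image",
    "extract_contour",
    "suprahilar_depression",
    "measure_axes",
    "measure_contour",
    "measure_mask",
]


@dataclass(frozen=True)
class GeometryResult:
    """Geometric primitives of one spore silhouette (all lengths in µm)."""

    contour: SporeContour
    hull: np.ndarray
    shape_area_um2: float
    hull_area_um2: float
    depression_pct: float
    L_um: float
    W_um: float
    orientation_deg: float

    def __post_init__(self):
        if not (self.hull_area_um2 >= self.shape_area_um2 > 0):
            raise ValueError("require hull_area >= shape_area > 0")
        if not (0.0 <= self.depression_pct < 100.0):
            raise ValueError("depression_pct must lie in [0, 100)")
        if not (self.L_um >= self.W_um > 0):
            raise ValueError("require L >= W > 0")


def segment_image(image: np.ndarray, scale_um_per_px: float,
                  method: str = "otsu", threshold: float | None = None) -> SporeMask:
    """Segment the largest dark-or-bright object of a grayscale image.

    Polarity is auto-detected by border sampling: if the border is mostly
    above the threshold, the object is taken to be the dark phase, otherwise
    the bright one.  Holes are filled and all but the largest connected
    component removed; components larger than half the principal one trigger
    a warning.  Binary input passes through unchanged apart from the cleanup.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if scale_um_per_px <= 0:
        raise ValueError("scale must be positive")
    if method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        thr = float(threshold)
    elif method == "otsu":
        if np.ptp(img) == 0:
            raise ValueError("no foreground: image is constant")
        thr = float(threshold_otsu(img))
    else:
        raise ValueError(f"unknown method {method!r}")

    border = np.concatenate([img[0, :], img[-1, :], img[1:-1, 0], img[1:-1, -1]])
    dark_object = np.mean(border > thr) > 0.5
    fg = img <= thr if dark_object else img > thr
    if not fg.any():
        raise ValueError("no foreground after thresholding")

    labels, n = ndimage.label(fg)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1]
    comparable = int(np.sum(sizes[order[1:]] > 0.5 * sizes[order[0]]))
    if comparable:
        warnings.warn(
            f"{comparable + 1} components of comparable size "
            f"(pixel counts {sorted(sizes.astype(int), reverse=True)[:comparable + 1]}); "
            "keeping the largest",
            stacklevel=2,
        )
    keep = labels == order[0] + 1
    keep = ndimage.binary_fill_holes(keep)
    return SporeMask(keep, scale_um_per_px)


def extract_contour(mask: SporeMask) -> SporeContour:
    """Trace the subpixel (0.5 iso-level) boundary of a mask, in µm.

    The mask must hold exactly one hole-free connected component of at least
    50 pixels; the traced polygon area converges to the pixel-count area as
    the scale is refined.
    """
    px = mask.pixels
    labels, n = ndimage.label(px)
    if n != 1:
        raise ValueError(f"mask must have exactly one connected component, found {n}")
    if ndimage.binary_fill_holes(px).sum() != px.sum():
        raise ValueError("mask has interior holes")
    if px.sum() < MIN_FOREGROUND_PIXELS:
        raise ValueError(
            f"foreground of {int(px.sum())} px is below the minimum "
            f"({MIN_FOREGROUND_PIXELS}) for a meaningful contour"
        )
    padded = np.pad(px.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    boundary = max(contours, key=len)
    rows = boundary[:, 0] - 1.0
    cols = boundary[:, 1] - 1.0
    s = mask.scale_um_per_px
    x = mask.offset[0] + (cols + 0.5) * s
    y = mask.offset[1] + (rows + 0.5) * s
    verts = np.column_stack([x, y])
    if np.allclose(verts[0], verts[-1]):
        verts = verts[:-1]
    # enforce counterclockwise orientation (positive shoelace area)
    if _shoelace(verts) < 0:
        verts = verts[::-1]
    return SporeContour(verts)


def _shoelace(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def suprahilar_depression(contour: SporeContour) -> float:
    """Concavity of the silhouette: 100 × (hull − shape) / hull area.

    Hull by planar convex-hull construction on the vertices, areas by the
    shoelace formula; 0 for convex silhouettes.
    """
    poly = Polygon(contour.vertices)
    if not poly.is_valid:
        raise ValueError("self-intersecting polygon")
    hull_area = poly.convex_hull.area
    return 100.0 * (hull_area - poly.area) / hull_area


def measure_axes(contour: SporeContour) -> tuple[float, float, float]:
    """Length, width and orientation of a silhouette.

    L is the maximum caliper (Feret) diameter, found over convex-hull
    vertex pairs; W is the maximal extent perpendicular to the L axis;
    orientation is the L-axis angle in degrees within [0, 180).  Note the
    Feret length of a rectangle is its diagonal.
    """
    v = contour.vertices
    try:
        hull = ConvexHull(v)
    except QhullError as exc:
        raise ValueError("degenerate (collinear) polygon") from exc
    hv = v[hull.vertices]
    d2 = np.sum((hv[:, None, :] - hv[None, :, :]) ** 2, axis=-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    L = float(np.sqrt(d2[i, j]))
    axis = (hv[j] - hv[i]) / L
    normal = np.array([-axis[1], axis[0]])
    proj = hv @ normal
    W = float(proj.max() - proj.min())
    angle = float(np.degrees(np.arctan2(axis[1], axis[0])) % 180.0)
    return L, W, angle


def measure_contour(contour: SporeContour) -> GeometryResult:
    """All geometric descriptors of one contour."""
    poly = Polygon(contour.vertices)
    if not poly.is_valid:
        raise ValueError("self-intersecting polygon")
    hull = poly.convex_hull
    L, W, angle = measure_axes(contour)
    return GeometryResult(
        contour=contour,
        hull=np.asarray(hull.exterior.coords)[:-1],
        shape_area_um2=poly.area,
        hull_area_um2=hull.area,
        depression_pct=100.0 * (hull.area - poly.area) / hull.area,
        L_um=L,
        W_um=W,
        orientation_deg=angle,
    )


def measure_mask(mask: SporeMask) -> GeometryResult:
    """Convenience: extract the contour of a mask and measure it."""
    return measure_contour(extract_contour(mask))
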
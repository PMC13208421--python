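"""Parametric side-view basidiospore silhouettes and hierarchical populations.

The generative model is a smooth ovoid built from two half-superellipses that
share the short (width) axis: the proximal half is elliptic (exponent 2) and
the apical exponent decreases with ``apex_sharpness``, giving profiles from
blunt-ellipsoid to acutely amygdaliform.  The suprahilar depression is a
raised-cosine indentation on the proximal ventral flank, adjacent to the
apiculus attachment; its depth is calibrated by bisection so that the measured
concavity fraction of the convex hull hits a requested target.  Amygdaliform
profiles additionally carry a small rounded apiculus protrusion on the ventral
flank; it is part of the silhouette (spores are segmented whole) but excluded
from the length/width calibration, following the mycological convention of
measuring spores without the hilar appendix.

Populations mirror the n-spores / m-basidiomes / p-collections sampling
hierarchy used in fungarium morphometry: collection-level (L, W) means are
drawn from a bivariate normal, per-spore sizes around their collection mean,
and per-spore concavity from a lognormal (strictly positive, right-skewed).
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Polygon

__all__ = [
    "SporeShapeParams",
    "SporeContour",
    "SporeMask",
    "PopulationConfig",
    "InfeasibleConcavityError",
    "generate_contour",
    "rasterize",
    "sample_population",
    "load_preset",
    "available_presets",
    "pulverulentus_like",
    "mediterraneensis_like",
    "poikilochromus_like",
]

PROFILE_FAMILIES = ("ellipsoid", "subamygdaliform", "amygdaliform")

#: minimum foreground pixels below which a rasterized measurement is meaningless
MIN_FOREGROUND_PIXELS = 50


class InfeasibleConcavityError(ValueError):
    """Requested concavity outside the range attainable by the notch geometry.

    Carries the attainable interval so callers can adjust ``notch_width_frac``
    or the target.
    """

    def __init__(self, target: float, attainable_min: float, attainable_max: float):
        self.target = target
        self.attainable_min = attainable_min
        self.attainable_max = attainable_max
        super().__init__(
            f"target concavity {target:.4f} is not attainable: this geometry "
            f"admits concavity in [{attainable_min:.4f}, {attainable_max:.4f}]"
        )


@dataclass(frozen=True)
class SporeShapeParams:
    """Parameters of one synthetic spore silhouette.

    ``apex_sharpness`` = 0 gives a blunt elliptic apex, 1 an acute one.
    ``apiculus_offset`` lateralises the apiculus attachment along the ventral
    flank as a signed fraction of width (only the magnitude matters for the
    side-view silhouette; the apiculus is always rendered ventral).
    ``target_concavity`` is the desired suprahilar depression as a fraction
    (not percent) of convex-hull area.
    """

    profile_family: str = "ellipsoid"
    length_um: float = 12.0
    width_um: float = 5.0
    apex_sharpness: float = 0.3
    apiculus_offset: float = 0.0
    target_concavity: float = 0.0
    notch_width_frac: float = 0.35

    def __post_init__(self):
        if self.profile_family not in PROFILE_FAMILIES:
            raise ValueError(
                f"profile_family must be one of {PROFILE_FAMILIES}, "
                f"got {self.profile_family!r}"
            )
        if not (self.length_um >= self.width_um > 0):
            raise ValueError("require length_um >= width_um > 0")
        if not (0.0 <= self.target_concavity <= 0.2):
            raise ValueError("target_concavity must lie in [0, 0.2]")
        if not (0.0 <= self.apex_sharpness <= 1.0):
            raise ValueError("apex_sharpness must lie in [0, 1]")
        if not (0.0 < self.notch_width_frac < 0.6):
            raise ValueError("notch_width_frac must lie in (0, 0.6)")


@dataclass(frozen=True)
class SporeContour:
    """Closed side-view silhouette polygon, counterclockwise, in µm."""

    vertices: np.ndarray  # (N, 2) float array
    provenance: Optional[SporeShapeParams] = None

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        object.__setattr__(self, "vertices", v)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 64:
            raise ValueError("contour needs an (N, 2) array with N >= 64")
        poly = Polygon(v)
        if not poly.is_valid:
            raise ValueError("contour must be a simple (non-self-intersecting) polygon")
        if poly.area <= 0:
            raise ValueError("contour must enclose positive area")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area_um2(self) -> float:
        return Polygon(self.vertices).area


@dataclass(frozen=True)
class SporeMask:
    """Binary raster of a spore.

    ``pixels`` is stored y-up: row 0 is the lowest y.  The center of pixel
    (r, c) sits at ``offset + (c + 0.5, r + 0.5) * scale`` µm.  Image writers
    must flip rows for the usual top-down raster convention.
    """

    pixels: np.ndarray
    scale_um_per_px: float
    offset: tuple = (0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=bool))
        if self.scale_um_per_px <= 0:
            raise ValueError("scale_um_per_px must be positive")

    @property
    def area_um2(self) -> float:
        return float(self.pixels.sum()) * self.scale_um_per_px**2


@dataclass(frozen=True)
class PopulationConfig:
    """Hierarchical sampling scheme for one species."""

    species_label: str
    mean_L: float
    sd_L_between: float
    mean_W: float
    sd_W_between: float
    within_sd_factor: float = 1.5
    corr_LW: float = 0.5
    concavity_log_mean: float = np.log(0.02)
    concavity_log_sd: float = 0.35
    n_per_basidiome: int = 5
    m_basidiomes: int = 10
    p_collections: int = 17
    seed: int = 0
    profile_family: str = "ellipsoid"
    apex_sharpness: float = 0.3
    apiculus_offset: float = 0.0
    notch_width_frac: float = 0.35

    def __post_init__(self):
        if min(self.sd_L_between, self.sd_W_between) < 0 or self.within_sd_factor < 0:
            raise ValueError("standard deviations must be non-negative")
        if min(self.n_per_basidiome, self.m_basidiomes, self.p_collections) < 1:
            raise ValueError("hierarchy counts must be >= 1")
        if not (-1.0 < self.corr_LW < 1.0):
            raise ValueError("corr_LW must lie in (-1, 1)")


# ---------------------------------------------------------------------------
# contour construction


def _half_width(x: np.ndarray, L: float, W: float, apex_exponent: float) -> np.ndarray:
    """Half-width profile of the two-half-superellipse ovoid at abscissa x."""
    a = L / 2.0
    b = W / 2.0
    u = np.clip(np.abs(x) / a, 0.0, 1.0)
    e = np.where(x < 0, 2.0, apex_exponent)
    return b * (1.0 - u**e) ** (1.0 / e)


def _raised_cosine(x: np.ndarray, center: float, chord: float) -> np.ndarray:
    """Smooth unit bump supported on |x - center| < chord / 2."""
    u = (x - center) / chord
    out = np.zeros_like(x)
    m = np.abs(u) < 0.5
    out[m] = 0.5 * (1.0 + np.cos(2.0 * np.pi * u[m]))
    return out


def _build_polygon(params: SporeShapeParams, depth: float, n: int) -> np.ndarray:
    """Vertices (CCW) of the silhouette with the given notch depth."""
    L, W = params.length_um, params.width_um
    apex_e = 2.0 - 0.8 * params.apex_sharpness
    half = n // 2
    # cosine-spaced abscissae: dense near the tips where curvature is high
    t = np.linspace(0.0, np.pi, half + 1)
    x = (L / 2.0) * np.cos(t)  # +L/2 .. -L/2

    y_top = _half_width(x, L, W, apex_e)
    y_bot = -_half_width(x, L, W, apex_e)

    # apiculus: small rounded ventral protrusion near the proximal end
    x_apic = -(L / 2.0) * (0.90 - 0.15 * abs(params.apiculus_offset))
    chord_apic = 0.10 * L
    if params.profile_family == "amygdaliform":
        h_apic = min(0.4, 0.08 * W)
        y_bot = y_bot - h_apic * _raised_cosine(x, x_apic, chord_apic)

    # suprahilar notch: inward indentation just distal to the apiculus
    if depth > 0:
        chord = params.notch_width_frac * L
        x_notch = x_apic + 0.5 * chord_apic + 0.5 * chord
        y_bot = y_bot + depth * _raised_cosine(x, x_notch, chord)

    top = np.column_stack([x, y_top])  # +L/2 -> -L/2 over dorsal flank
    bot = np.column_stack([x[::-1], y_bot[::-1]])  # -L/2 -> +L/2 ventral
    verts = np.vstack([top[:-1], bot[:-1]])  # drop duplicated tips
    return verts


def _notch_geometry(params: SporeShapeParams):
    """Support of the notch and the maximum depth keeping the polygon simple."""
    L, W = params.length_um, params.width_um
    apex_e = 2.0 - 0.8 * params.apex_sharpness
    x_apic = -(L / 2.0) * (0.90 - 0.15 * abs(params.apiculus_offset))
    chord_apic = 0.10 * L
    chord = params.notch_width_frac * L
    x_notch = x_apic + 0.5 * chord_apic + 0.5 * chord
    xs = np.linspace(x_notch - 0.5 * chord, min(x_notch + 0.5 * chord, L / 2 * 0.999), 257)
    gap = 2.0 * _half_width(xs, L, W, apex_e)
    return float(0.85 * gap.min())


def generate_contour(params: SporeShapeParams, resolution: int = 512) -> SporeContour:
    """Build a spore silhouette whose measured concavity hits the target.

    The maximum caliper length of the returned polygon equals ``length_um``
    and the perpendicular width equals ``width_um`` (the apiculus never
    protrudes beyond either extent, so it does not disturb the calibration).
    The concavity fraction (hull area − polygon area) / hull area matches
    ``target_concavity`` to within 5e-4 absolute, solved by bisection on the
    notch depth; the hull is recomputed for every candidate (the hull of a
    notched silhouette bridges the notch with a chord, so it is not simply
    the base ovoid's hull).

    Raises
    ------
    InfeasibleConcavityError
        if the target lies outside what the notch geometry (and, for
        amygdaliform profiles, the apiculus floor concavity) can produce.
    """
    if resolution < 64:
        raise ValueError("resolution must be >= 64")
    def concavity(verts: np.ndarray) -> float:
        poly = Polygon(verts)
        hull_area = poly.convex_hull.area
        return (hull_area - poly.area) / hull_area

    base = _build_polygon(params, 0.0, resolution)
    floor = concavity(base)  # > 0 only with an apiculus

    target = params.target_concavity
    tol = 5e-4
    if floor - tol <= target <= floor + tol:
        # attainable without a notch (includes exact 0 for convex families)
        return SporeContour(base, provenance=params)
    depth_max = _notch_geometry(params)
    ceil = concavity(_build_polygon(params, depth_max, resolution))
    if target < floor - tol or target > ceil:
        raise InfeasibleConcavityError(target, floor, ceil)

    lo, hi = 0.0, depth_max
    verts = base
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        verts = _build_polygon(params, mid, resolution)
        c = concavity(verts)
        if abs(c - target) < 0.25 * tol:
            break
        if c < target:
            lo = mid
        else:
            hi = mid
    return SporeContour(verts, provenance=params)


# ---------------------------------------------------------------------------
# rasterization


def rasterize(contour: SporeContour, scale_um_per_px: float) -> SporeMask:
    """Rasterize a contour: foreground = pixels whose centers fall inside.

    Implemented as an even-odd scanline fill over the polygon edges, which
    realises the pixel-center inside test exactly and runs in
    O(rows × edges).  The mask is stored y-up with a one-pixel background
    margin on every side.
    """
    if scale_um_per_px <= 0:
        raise ValueError("scale_um_per_px must be positive")
    v = contour.vertices
    s = scale_um_per_px
    x0 = np.floor(v[:, 0].min() / s) * s - s
    y0 = np.floor(v[:, 1].min() / s) * s - s
    ncols = int(np.ceil((v[:, 0].max() - x0) / s)) + 2
    nrows = int(np.ceil((v[:, 1].max() - y0) / s)) + 2

    x1 = np.roll(v[:, 0], -1)
    y1 = np.roll(v[:, 1], -1)
    ex0, ey0, ex1, ey1 = v[:, 0], v[:, 1], x1, y1

    mask = np.zeros((nrows, ncols), dtype=bool)
    centers_x = x0 + (np.arange(ncols) + 0.5) * s
    for r in range(nrows):
        yc = y0 + (r + 0.5) * s
        # half-open rule [min, max): a vertex exactly on the scanline counts once
        straddle = ((ey0 <= yc) & (ey1 > yc)) | ((ey1 <= yc) & (ey0 > yc))
        if not straddle.any():
            continue
        xi = ex0[straddle] + (yc - ey0[straddle]) * (
            (ex1[straddle] - ex0[straddle]) / (ey1[straddle] - ey0[straddle])
        )
        xi.sort()
        inside = np.searchsorted(xi, centers_x, side="right") % 2 == 1
        mask[r] = inside

    if mask.sum() < MIN_FOREGROUND_PIXELS:
        raise ValueError(
            f"scale {s} µm/px leaves only {int(mask.sum())} foreground pixels "
            f"(< {MIN_FOREGROUND_PIXELS}); measurement would be meaningless"
        )
    return SporeMask(mask, s, (float(x0), float(y0)))


# ---------------------------------------------------------------------------
# population sampling


def sample_population(config: PopulationConfig) -> pd.DataFrame:
    """Draw a hierarchical spore population as a measurement-ready table.

    Returns one row per spore with hierarchy labels and the true shape
    parameters (``length_um``, ``width_um``, ``target_concavity``, ...) from
    which contours can be generated.  Collection-level (L, W) means come from
    a bivariate normal with the configured between-collection SDs and
    correlation; spores scatter around their collection mean with SD =
    ``within_sd_factor`` × the between SD; per-spore concavity is lognormal.
    Non-positive or width-exceeding draws are resampled (truncation), with
    the count recorded in ``df.attrs['n_resampled']`` and a warning when the
    resampling rate exceeds 1%.
    """
    rng = np.random.default_rng(config.seed)
    cov_b = _cov(config.sd_L_between, config.sd_W_between, config.corr_LW)
    sd_Lw = config.within_sd_factor * config.sd_L_between
    sd_Ww = config.within_sd_factor * config.sd_W_between
    cov_w = _cov(sd_Lw, sd_Ww, config.corr_LW)

    n_resampled = 0
    rows = []
    for ci in range(config.p_collections):
        coll_mean = _draw_valid(rng, (config.mean_L, config.mean_W), cov_b)
        n_resampled += coll_mean[1]
        for bi in range(config.m_basidiomes):
            for si in range(config.n_per_basidiome):
                (L, W), extra = _draw_valid(rng, coll_mean[0], cov_w)
                n_resampled += extra
                conc = float(
                    rng.lognormal(config.concavity_log_mean, config.concavity_log_sd)
                )
                while conc > 0.12:  # keep within the notch-feasible regime
                    conc = float(
                        rng.lognormal(config.concavity_log_mean, config.concavity_log_sd)
                    )
                    n_resampled += 1
                rows.append(
                    {
                        "spore_id": f"c{ci:02d}b{bi:02d}s{si:02d}",
                        "basidiome_id": f"c{ci:02d}b{bi:02d}",
                        "collection_id": f"c{ci:02d}",
                        "species": config.species_label,
                        "profile_family": config.profile_family,
                        "length_um": L,
                        "width_um": W,
                        "apex_sharpness": config.apex_sharpness,
                        "apiculus_offset": config.apiculus_offset,
                        "target_concavity": conc,
                        "notch_width_frac": config.notch_width_frac,
                    }
                )
    df = pd.DataFrame(rows)
    df.attrs["n_resampled"] = n_resampled
    total = len(df)
    if total and n_resampled / total > 0.01:
        warnings.warn(
            f"{n_resampled} truncation resamples for {total} spores (> 1%): "
            "configured means/SDs place appreciable mass at invalid dimensions",
            stacklevel=2,
        )
    return df


def _cov(sd_a: float, sd_b: float, rho: float) -> np.ndarray:
    return np.array(
        [[sd_a**2, rho * sd_a * sd_b], [rho * sd_a * sd_b, sd_b**2]]
    )


def _draw_valid(rng, mean, cov):
    """Draw (L, W) with L > W > 0, resampling invalid draws."""
    if np.trace(cov) == 0.0:  # degenerate: point mass at the mean
        return (float(mean[0]), float(mean[1])), 0
    extra = 0
    while True:
        L, W = rng.multivariate_normal(mean, cov, method="eigh")  # PSD-safe
        if W > 0 and L > W:
            return (float(L), float(W)), extra
        extra += 1


def params_from_row(row) -> SporeShapeParams:
    """Shape parameters of one ``sample_population`` row."""
    return SporeShapeParams(
        profile_family=row["profile_family"],
        length_um=row["length_um"],
        width_um=row["width_um"],
        apex_sharpness=row["apex_sharpness"],
        apiculus_offset=row["apiculus_offset"],
        target_concavity=row["target_concavity"],
        notch_width_frac=row["notch_width_frac"],
    )


# ---------------------------------------------------------------------------
# presets


def _load_preset_file() -> dict:
    with importlib.resources.files("sporemorph.data").joinpath("presets.yaml").open() as fh:
        return yaml.safe_load(fh)


def available_presets() -> list:
    return sorted(_load_preset_file()["populations"])


def load_preset(name: str, **overrides) -> PopulationConfig:
    """Packaged population preset for one of the three species.

    Presets carry the published collection-level spore size means/SDs and
    concavity regimes; hierarchy counts and seed can be overridden.
    """
    presets = _load_preset_file()["populations"]
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}")
    kw = dict(presets[name])
    kw["concavity_log_mean"] = float(np.log(kw.pop("concavity_median")))
    kw.update(overrides)
    return PopulationConfig(**kw)


def _shape_preset(name: str) -> SporeShapeParams:
    shapes = _load_preset_file()["shapes"]
    return SporeShapeParams(**shapes[name])


def pulverulentus_like() -> SporeContour:
    """Fixed amygdaliform fixture: species-mean size, pronounced depression."""
    return generate_contour(_shape_preset("pulverulentus"))


def mediterraneensis_like() -> SporeContour:
    """Fixed subamygdaliform fixture: species-mean size, shallow depression."""
    return generate_contour(_shape_preset("mediterraneensis"))


def poikilochromus_like() -> SporeContour:
    """Fixed blunt-ellipsoid fixture: species-mean size, minimal depression."""
    return generate_contour(_shape_preset("poikilochromus"))
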
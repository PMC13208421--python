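"""End-to-end measurement pipeline over synthetic populations.

Glue between the generator and the measurement stages: draw a hierarchical
population, build each silhouette, rasterize it, re-extract the subpixel
contour and measure it — i.e. the same path a real micrograph mask would
take — returning a per-spore measurement table ready for the hierarchical
summaries, statistics and the identification key.
"""

from __future__ import annotations

import pandas as pd

from .morphometrics import spore_metrics
from .silhouette import measure_contour, measure_mask
from .synthesize import PopulationConfig, generate_contour, params_from_row, rasterize, sample_population

__all__ = ["measure_population", "measure_params_frame"]


def measure_params_frame(
    df: pd.DataFrame,
    scale_um_per_px: float | None = 0.02,
    resolution: int = 512,
) -> pd.DataFrame:
    """Measure every spore of a sampled-population table.

    With a raster scale, each contour passes through rasterization and
    subpixel contour re-extraction before measurement (the full image
    pipeline); with ``scale_um_per_px=None`` the generated polygon is
    measured directly (no rasterization bias, much faster).
    """
    rows = []
    for _, row in df.iterrows():
        contour = generate_contour(params_from_row(row), resolution=resolution)
        if scale_um_per_px is None:
            geom = measure_contour(contour)
        else:
            geom = measure_mask(rasterize(contour, scale_um_per_px))
        Q, apV = spore_metrics(geom.L_um, geom.W_um, geom.shape_area_um2)
        rows.append(
            {
                "spore_id": row["spore_id"],
                "basidiome_id": row["basidiome_id"],
                "collection_id": row["collection_id"],
                "species": row["species"],
                "L_um": geom.L_um,
                "W_um": geom.W_um,
                "A_um2": geom.shape_area_um2,
                "Q": Q,
                "apV_um3": apV,
                "depression_pct": geom.depression_pct,
            }
        )
    return pd.DataFrame(rows)


def measure_population(
    config: PopulationConfig,
    scale_um_per_px: float | None = 0.02,
    resolution: int = 512,
) -> pd.DataFrame:
    """sample_population + measure_params_frame in one call."""
    return measure_params_frame(
        sample_population(config), scale_um_per_px=scale_um_per_px, resolution=resolution
    )
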
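"""Per-spore derived metrics and hierarchical range summaries.

Spore descriptions in fungarium morphometry report, for each variable, the
"(minimum) average ± standard deviation (maximum)" of *collection averages*:
spores are averaged within each voucher collection first, and min/mean/SD/max
are then taken over those collection means.  The [n/m/p] prefix records that
n spores from m basidiomes of p collections underlie the summary.  Derived
per-spore metrics are the length/width quotient Q = L/W and the approximate
spore volume treating the spore as an ellipsoid of rotation about its long
axis, apV = π·L·W²/6.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "SporeMeasurement",
    "RangeSummary",
    "spore_metrics",
    "summarize_by_collection",
    "format_summary",
    "round_half_up",
    "measurements_to_frame",
]


@dataclass(frozen=True)
class SporeMeasurement:
    """One measured spore with its hierarchy labels."""

    spore_id: str
    basidiome_id: str
    collection_id: str
    species_label: str
    L_um: float
    W_um: float
    A_um2: float
    depression_pct: float = 0.0
    Q: Optional[float] = None
    apV_um3: Optional[float] = None

    def __post_init__(self):
        q, apv = spore_metrics(self.L_um, self.W_um, self.A_um2)
        if self.Q is None:
            object.__setattr__(self, "Q", q)
        if self.apV_um3 is None:
            object.__setattr__(self, "apV_um3", apv)
        if self.L_um >= self.W_um and self.Q < 1:
            raise ValueError("Q must be >= 1 when L >= W")


@dataclass(frozen=True)
class RangeSummary:
    """(min) mean ± sd (max) of one variable over collection means."""

    variable_name: str
    minimum: float
    mean: float
    sd: Optional[float]
    maximum: float
    n_collections: int
    n_spores: int
    n_basidiomes: int

    def __post_init__(self):
        if not (self.minimum <= self.mean <= self.maximum):
            raise ValueError("require minimum <= mean <= maximum")
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n_collections == 1 and self.sd is not None:
            raise ValueError("sd is undefined for a single collection")


def spore_metrics(L_um: float, W_um: float, A_um2: float) -> tuple[float, float]:
    """Quotient Q = L/W and rotation-ellipsoid volume apV = π·L·W²/6."""
    if min(L_um, W_um, A_um2) <= 0:
        raise ValueError("L, W and A must all be positive")
    return L_um / W_um, np.pi * L_um * W_um**2 / 6.0


def measurements_to_frame(measurements: Iterable[SporeMeasurement]) -> pd.DataFrame:
    rows = [
        {
            "spore_id": m.spore_id,
            "basidiome_id": m.basidiome_id,
            "collection_id": m.collection_id,
            "species": m.species_label,
            "L_um": m.L_um,
            "W_um": m.W_um,
            "A_um2": m.A_um2,
            "Q": m.Q,
            "apV_um3": m.apV_um3,
            "depression_pct": m.depression_pct,
        }
        for m in measurements
    ]
    return pd.DataFrame(rows)


def summarize_by_collection(measurements, variable: str) -> RangeSummary:
    """Range summary of one variable over per-collection means.

    Accepts a DataFrame with ``collection_id``/``basidiome_id`` columns or an
    iterable of :class:`SporeMeasurement`.  Collection means are computed
    first; minimum/mean/sd/maximum are taken over those means, with the
    sample SD (n − 1 denominator), which is the convention behind published
    "(min) avg ± SD (max)" spore dimensions.  Pooled per-spore summaries
    differ whenever collections are unbalanced.
    """
    if not isinstance(measurements, pd.DataFrame):
        measurements = measurements_to_frame(list(measurements))
    df = measurements
    if df.empty:
        raise ValueError("no measurements to summarize")
    if variable not in df.columns:
        raise ValueError(f"unknown variable {variable!r}")
    if df["collection_id"].isna().any():
        bad = df.index[df["collection_id"].isna()][0]
        raise ValueError(f"record {bad} is missing collection_id")
    means = df.groupby("collection_id", sort=False)[variable].mean()
    p = len(means)
    sd = float(means.std(ddof=1)) if p > 1 else None
    return RangeSummary(
        variable_name=variable,
        minimum=float(means.min()),
        mean=float(means.mean()),
        sd=sd,
        maximum=float(means.max()),
        n_collections=p,
        n_spores=len(df),
        n_basidiomes=df.groupby(["collection_id", "basidiome_id"]).ngroups,
    )


def round_half_up(x: float, decimals: int = 2) -> str:
    """Decimal round-half-up string rendering (1.555 -> '1.56').

    Works on the decimal representation, avoiding binary-float artifacts and
    banker's rounding.
    """
    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_summary(summary: RangeSummary, unit: str = "μm", decimals: int = 2) -> str:
    """Render "[n/m/p] (min) mean ± sd (max) unit" with half-up rounding."""
    r = lambda v: round_half_up(v, decimals)  # noqa: E731
    head = f"[{summary.n_spores}/{summary.n_basidiomes}/{summary.n_collections}]"
    if summary.sd is None:
        body = f"({r(summary.minimum)}) {r(summary.mean)} ({r(summary.maximum)})"
    else:
        body = (
            f"({r(summary.minimum)}) {r(summary.mean)} ± {r(summary.sd)} "
            f"({r(summary.maximum)})"
        )
    return f"{head} {body} {unit}".rstrip()
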
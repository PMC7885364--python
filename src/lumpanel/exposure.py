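"""Land-use-mix entropy inside sausage buffers, linked to person-waves.

The land-use mix (LUM) score is the normalized Shannon entropy of class
area shares inside a buffer::

    LUM = -[sum_j p_j ln p_j] / ln N

with ``p_j`` the share of class ``j`` of the covered buffer area and ``N``
the *scheme* size (default 11 classes), not the number of classes present —
holding N fixed keeps scores comparable across buffers and waves.  LUM is 0
for a single-use buffer and 1 for a perfectly even mix.  In the model the
score enters as ``lum_scaled = 10 * LUM`` so coefficients read as
minutes/week per 10% change in LUM.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely import STRtree, make_valid
from shapely.geometry.base import BaseGeometry

from lumpanel.errors import NoCoverageError, ValidationError
from lumpanel.geo_network import SausageBuffer

logger = logging.getLogger(__name__)

#: default 11-class scheme; the real classification (from the national
#: land-use inventory) is study-specific, so the labels are generic and
#: user-configurable — only the scheme *size* matters for the score
DEFAULT_CLASSES = (
    "residential",
    "retail_hospitality",
    "public_services",
    "industrial",
    "park_green",
    "sports_recreation",
    "forest_nature",
    "agriculture",
    "water",
    "infrastructure",
    "other_built",
)

GAP_WARNING_FRACTION = 0.05


@dataclass(frozen=True)
class LandUseParcel:
    """One polygon of the wall-to-wall land-use mosaic for a given year."""

    parcel_id: str
    geometry: BaseGeometry
    class_label: str
    valid_year: int


@dataclass
class ClassAreaTable:
    """Per-class areas and shares inside one buffer.

    Shares are computed over the covered area; classes absent from the
    buffer carry zero.  ``n_classes`` is the scheme size used as N in the
    entropy formula.
    """

    areas_m2: dict[str, float]
    n_classes: int = len(DEFAULT_CLASSES)
    buffer_ref: tuple | None = None  # (person_id, wave_id, buffer_size_m)
    covered_fraction: float = 1.0

    def __post_init__(self):
        if any(a < 0 for a in self.areas_m2.values()):
            raise ValidationError("negative class area")
        if len(self.areas_m2) > self.n_classes:
            raise ValidationError(
                f"{len(self.areas_m2)} classes present exceeds scheme size {self.n_classes}"
            )

    @property
    def total_area_m2(self) -> float:
        return float(sum(self.areas_m2.values()))

    @property
    def shares(self) -> dict[str, float]:
        total = self.total_area_m2
        if total <= 0:
            raise NoCoverageError("no land-use coverage: total class area is zero")
        return {c: a / total for c, a in self.areas_m2.items()}


def entropy_lum(table: ClassAreaTable) -> float:
    """Normalized entropy of the class shares, in [0, 1].

    Uses the convention 0*ln 0 = 0 so absent classes contribute nothing;
    the normalizer is ln(N) with N the scheme size.
    """
    if table.n_classes < 2:
        raise ValidationError("entropy undefined for a scheme of fewer than 2 classes")
    shares = table.shares
    h = -sum(p * math.log(p) for p in shares.values() if p > 0.0)
    value = h / math.log(table.n_classes) + 0.0  # normalize -0.0
    # clamp roundoff just outside the analytic bounds
    return min(max(value, 0.0), 1.0)


def clip_land_use(
    buffer: SausageBuffer,
    parcels: list[LandUseParcel],
    n_classes: int = len(DEFAULT_CLASSES),
    gap_warning_fraction: float = GAP_WARNING_FRACTION,
) -> ClassAreaTable:
    """Intersect the buffer with the land-use mosaic and tabulate areas.

    The mosaic is expected to be wall-to-wall; uncovered buffer area (a
    data defect) is excluded from the denominator, with a warning once the
    gap exceeds ``gap_warning_fraction`` of the buffer.
    """
    if not parcels:
        raise NoCoverageError("no land-use parcels supplied")
    geoms = []
    labels = []
    for p in parcels:
        g = p.geometry
        if not g.is_valid:
            logger.warning("parcel %s invalid; repairing", p.parcel_id)
            g = make_valid(g)
        geoms.append(g)
        labels.append(p.class_label)
    tree = STRtree(geoms)
    areas: dict[str, float] = {}
    for i in tree.query(buffer.geometry, predicate="intersects"):
        inter = geoms[i].intersection(buffer.geometry)
        if not inter.is_empty:
            areas[labels[i]] = areas.get(labels[i], 0.0) + inter.area
    covered = sum(areas.values())
    buf_area = buffer.geometry.area
    if covered <= 0:
        raise NoCoverageError(
            f"no land-use coverage for buffer {buffer.person_id}/{buffer.wave_id}"
        )
    covered_fraction = covered / buf_area if buf_area > 0 else 0.0
    if covered_fraction < 1.0 - gap_warning_fraction:
        logger.warning(
            "buffer %s/%s: only %.1f%% covered by land-use data",
            buffer.person_id,
            buffer.wave_id,
            100 * covered_fraction,
        )
    return ClassAreaTable(
        areas_m2=areas,
        n_classes=n_classes,
        buffer_ref=(buffer.person_id, buffer.wave_id, buffer.network_distance_m),
        covered_fraction=covered_fraction,
    )


def exposure_record(table: ClassAreaTable, exposure_year: int) -> dict:
    """One tidy exposure row for the analysis table."""
    if table.buffer_ref is None:
        raise ValidationError("ClassAreaTable lacks a buffer reference")
    person_id, wave_id, buffer_size_m = table.buffer_ref
    lum = entropy_lum(table)
    return {
        "person_id": person_id,
        "wave_id": wave_id,
        "buffer_size_m": buffer_size_m,
        "exposure_year": exposure_year,
        "lum_entropy": lum,
        "lum_scaled": 10.0 * lum,
    }


def link_exposure(
    panel: pd.DataFrame,
    exposures: pd.DataFrame,
    wave_to_year: dict[int, int],
    fieldwork_years: dict[int, int] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Join buffer-specific exposure onto person-waves.

    Exposure must precede (or coincide with) outcome: each wave maps to a
    land-use snapshot year no later than the wave's fieldwork year.  Rows
    without a matching exposure record (e.g. unlocatable residences) are
    excluded; the count is returned for the run log.
    """
    for col in ("person_id", "wave_id"):
        if col not in panel.columns:
            raise ValidationError(f"panel lacks required column {col!r}")
    waves = set(panel["wave_id"].unique())
    missing = waves - set(wave_to_year)
    if missing:
        raise ValidationError(f"waves {sorted(missing)} missing from wave_to_year map")
    if fieldwork_years is None and "fieldwork_year" in panel.columns:
        fieldwork_years = (
            panel.groupby("wave_id")["fieldwork_year"].first().astype(int).to_dict()
        )
    if fieldwork_years:
        for w in waves:
            if wave_to_year[w] > fieldwork_years.get(w, np.inf):
                raise ValidationError(
                    f"wave {w}: exposure year {wave_to_year[w]} is later than "
                    f"fieldwork year {fieldwork_years[w]} (exposure must precede outcome)"
                )
    expo = exposures.copy()
    expo["__expected_year__"] = expo["wave_id"].map(wave_to_year)
    expo = expo[expo["exposure_year"] == expo["__expected_year__"]].drop(
        columns="__expected_year__"
    )
    merged = panel.merge(expo, on=["person_id", "wave_id"], how="left", validate="m:m")
    lacking = merged["lum_scaled"].isna()
    n_excluded = int(lacking.sum())
    if n_excluded:
        logger.info("link_exposure: excluded %d person-wave rows lacking exposure", n_excluded)
    return merged[~lacking].reset_index(drop=True), {"rows_excluded_no_exposure": n_excluded}
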
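"""Per-location cassava production statistics from ground-survey records.

Each surveyed location is a roughly 200 m x 200 m area of up to four
100 m x 100 m quadrants.  Surveyors record the perimeter-derived area of every
cassava field (mono- or intercropped), a qualitative planting-density class
per field, and the number of individual plants growing outside any field
(each assigned a disc of 0.5 m radius).  Two per-location responses are
derived:

* ``A_C``  — total proportion of the surveyed area under cassava: the sum of
  monoculture field areas, intercropped field areas and individual-plant
  discs, divided by the surveyed area ``delta``.
* ``A_CW`` — a density-weighted variant: each field's area is multiplied by a
  weight mapped from its qualitative density class, intercropped fields are
  additionally down-weighted by 0.75 (lower cassava density in mixed stands),
  and individual plants enter unweighted.

Cohort-level descriptive summaries (presence counts, management mix,
field-count and field-size distributions) mirror the layout used for survey
reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

QUADRANT_AREA_M2 = 10_000.0  # one 100 m x 100 m quadrant
DEFAULT_PLANT_RADIUS_M = 0.5
INTERCROP_WEIGHT = 0.75


class Management(str, Enum):
    MONOCULTURE = "monoculture"
    INTERCROP = "intercrop"


class DensityClass(str, Enum):
    VERY_HIGH = "VeryHigh"
    HIGH = "High"
    REGULAR = "Regular"
    SPARSE = "Sparse"
    VERY_SPARSE = "VerySparse"
    UNRECORDED = "Unrecorded"


#: Quantitative weights for the qualitative density classes.  Fields with no
#: recorded density class receive weight 1.
DENSITY_WEIGHTS: dict[DensityClass, float] = {
    DensityClass.VERY_HIGH: 1.75,
    DensityClass.HIGH: 1.5,
    DensityClass.REGULAR: 0.75,
    DensityClass.SPARSE: 0.5,
    DensityClass.VERY_SPARSE: 0.25,
    DensityClass.UNRECORDED: 1.0,
}


def density_weight(density_class: DensityClass | str) -> float:
    """Quantitative weight for a qualitative field-density class."""
    try:
        cls = DensityClass(density_class)
    except ValueError as exc:
        raise ValueError(f"unknown density class {density_class!r}") from exc
    return DENSITY_WEIGHTS[cls]


@dataclass
class FieldRecord:
    """One cassava field (or patch) at a surveyed location."""

    location_id: str
    management: Management
    area_m2: float
    density_class: DensityClass = DensityClass.UNRECORDED
    intercrop_species: list[str] | None = None

    def __post_init__(self) -> None:
        self.management = Management(self.management)
        self.density_class = DensityClass(self.density_class)
        if not self.area_m2 > 0:
            raise ValueError(f"field area must be positive, got {self.area_m2}")


@dataclass
class PlantRecord:
    """Individual plants outside any field at a surveyed location."""

    location_id: str
    n_plants: int = 0
    plant_radius_m: float = DEFAULT_PLANT_RADIUS_M

    def __post_init__(self) -> None:
        if self.n_plants < 0:
            raise ValueError("n_plants must be non-negative")
        if not self.plant_radius_m > 0:
            raise ValueError("plant_radius_m must be positive")

    @property
    def total_area_m2(self) -> float:
        return self.n_plants * math.pi * self.plant_radius_m**2


@dataclass
class LocationSurvey:
    """All survey records for one location."""

    location_id: str
    longitude: float
    latitude: float
    region: str = ""
    quadrants: int = 4
    fields: list[FieldRecord] = field(default_factory=list)
    plants: PlantRecord | None = None
    total_area_m2: float | None = None  # delta; quadrants x 10,000 m2 unless set
    quadrant_polygons: list | None = None

    def __post_init__(self) -> None:
        if self.quadrants not in (1, 2, 3, 4):
            raise ValueError("quadrants must be in {1, 2, 3, 4}")
        if self.total_area_m2 is None:
            self.total_area_m2 = self.quadrants * QUADRANT_AREA_M2
        if not self.total_area_m2 > 0:
            raise ValueError("total surveyed area must be positive")
        if self.plants is None:
            self.plants = PlantRecord(self.location_id, 0)

    @property
    def delta(self) -> float:
        return float(self.total_area_m2)


@dataclass
class LocationSummary:
    """Derived statistics for one location (proportions and m2 components)."""

    location_id: str
    A_C: float
    A_CW: float
    total_cassava_area_m2: float
    monoculture_area_m2: float
    intercrop_area_m2: float
    individual_area_m2: float
    weighted_total_area_m2: float
    weighted_monoculture_area_m2: float
    weighted_intercrop_area_m2: float
    presence: bool
    n_fields: int
    n_monoculture_fields: int
    n_intercrop_fields: int
    n_plants: int
    region: str = ""
    longitude: float = float("nan")
    latitude: float = float("nan")


def _component_areas(survey: LocationSurvey) -> tuple[float, float, float]:
    mono = sum(f.area_m2 for f in survey.fields if f.management is Management.MONOCULTURE)
    inter = sum(f.area_m2 for f in survey.fields if f.management is Management.INTERCROP)
    indiv = survey.plants.total_area_m2
    return mono, inter, indiv


def summarize_location(survey: LocationSurvey) -> LocationSummary:
    """Both responses (A_C, A_CW) and component areas for one location."""
    if not survey.delta > 0:
        raise ValueError("surveyed area delta must be positive")
    mono, inter, indiv = _component_areas(survey)
    total = mono + inter + indiv

    w_mono = sum(
        density_weight(f.density_class) * f.area_m2
        for f in survey.fields
        if f.management is Management.MONOCULTURE
    )
    w_inter = INTERCROP_WEIGHT * sum(
        density_weight(f.density_class) * f.area_m2
        for f in survey.fields
        if f.management is Management.INTERCROP
    )
    w_total = w_mono + w_inter + indiv  # individual plants enter unweighted

    n_mono = sum(1 for f in survey.fields if f.management is Management.MONOCULTURE)
    n_inter = len(survey.fields) - n_mono
    return LocationSummary(
        location_id=survey.location_id,
        A_C=total / survey.delta,
        A_CW=w_total / survey.delta,
        total_cassava_area_m2=total,
        monoculture_area_m2=mono,
        intercrop_area_m2=inter,
        individual_area_m2=indiv,
        weighted_total_area_m2=w_total,
        weighted_monoculture_area_m2=w_mono,
        weighted_intercrop_area_m2=w_inter,
        presence=total > 0,
        n_fields=len(survey.fields),
        n_monoculture_fields=n_mono,
        n_intercrop_fields=n_inter,
        n_plants=survey.plants.n_plants,
        region=survey.region,
        longitude=survey.longitude,
        latitude=survey.latitude,
    )


def location_total_area(survey: LocationSurvey) -> LocationSummary:
    """Unweighted proportion A_C and component areas (alias of the summary)."""
    return summarize_location(survey)


def location_weighted_area(survey: LocationSurvey) -> LocationSummary:
    """Density-weighted proportion A_CW and components (alias of the summary)."""
    return summarize_location(survey)


def summaries_frame(summaries: list[LocationSummary]) -> pd.DataFrame:
    """Tabulate LocationSummary records as one row per location."""
    return pd.DataFrame([vars(s) for s in summaries])


def response_table(surveys: list[LocationSurvey]) -> pd.DataFrame:
    """Per-location regression responses and association variables.

    One row per location with the six density responses (total, monoculture,
    intercrop; unweighted and weighted, all as proportions of the surveyed
    area) and the unnormalized m2 totals used in the correlation analysis.
    """
    rows = []
    for sv in surveys:
        s = summarize_location(sv)
        rows.append(
            {
                "location_id": s.location_id,
                "longitude": s.longitude,
                "latitude": s.latitude,
                "region": s.region,
                "presence": s.presence,
                "tot_density": s.A_C,
                "tot_density_w": s.A_CW,
                "mono_density": s.monoculture_area_m2 / sv.delta,
                "mono_density_w": s.weighted_monoculture_area_m2 / sv.delta,
                "inter_density": s.intercrop_area_m2 / sv.delta,
                "inter_density_w": s.weighted_intercrop_area_m2 / sv.delta,
                "tot_cassava_area": s.total_cassava_area_m2,
                "tot_cassava_area_w": s.weighted_total_area_m2,
                "tot_monoculture_area": s.monoculture_area_m2,
                "tot_intercrop_area": s.intercrop_area_m2,
            }
        )
    return pd.DataFrame(rows)


def _quartiles(values) -> tuple[float, float, float]:
    """(q25, median, q75) with linear interpolation between order statistics."""
    arr = np.asarray(list(values), dtype=float)
    q25, q50, q75 = np.quantile(arr, [0.25, 0.5, 0.75])
    return float(q25), float(q50), float(q75)


def cohort_summary(
    summaries: list[LocationSummary],
    surveys: list[LocationSurvey],
    split_band: tuple[float, float] = (0.4, 0.6),
) -> pd.DataFrame:
    """Cohort-level descriptive table across all surveyed locations.

    Reports location counts (visited, with cassava, with intercropping /
    monoculture / individual plants), percentages of complete-monoculture,
    complete-intercropping and near-50:50 locations (intercrop share of
    fields strictly inside ``split_band``), per-location field-count
    quartiles, field-size distributions by management, and per-location
    cultivated-area distributions by management.  All percentages are over
    locations with cassava present.
    """
    if not summaries:
        raise ValueError("cohort_summary requires at least one location")
    present = [s for s in summaries if s.presence]
    n_visited = len(summaries)
    n_present = len(present)

    rows: list[dict] = []

    def add(group: str, label: str, value) -> None:
        rows.append({"group": group, "statistic": label, "value": value})

    add("locations", "locations_visited", n_visited)
    add("locations", "locations_with_cassava", n_present)
    add(
        "locations",
        "presence_pct",
        round(100.0 * n_present / n_visited) if n_visited else float("nan"),
    )
    add("locations", "locations_with_intercropping", sum(1 for s in present if s.n_intercrop_fields > 0))
    add("locations", "locations_with_monoculture", sum(1 for s in present if s.n_monoculture_fields > 0))
    add("locations", "locations_with_individual_plants", sum(1 for s in present if s.n_plants > 0))

    if n_present:
        with_fields = [s for s in present if s.n_fields > 0]
        complete_mono = sum(
            1 for s in with_fields if s.n_intercrop_fields == 0 and s.n_monoculture_fields > 0
        )
        complete_inter = sum(
            1 for s in with_fields if s.n_monoculture_fields == 0 and s.n_intercrop_fields > 0
        )
        lo, hi = split_band
        split = sum(
            1 for s in with_fields if s.n_fields > 0 and lo < s.n_intercrop_fields / s.n_fields < hi
        )
        denom = len(with_fields) if with_fields else 1
        add("locations", "complete_monoculture_pct", round(100.0 * complete_mono / denom))
        add("locations", "complete_intercropping_pct", round(100.0 * complete_inter / denom))
        add("locations", "split_50_50_pct", round(100.0 * split / denom))

        q25, q50, q75 = _quartiles(s.n_fields for s in present)
        add("fields", "fields_per_location_median", q50)
        add("fields", "fields_per_location_q25", q25)
        add("fields", "fields_per_location_q75", q75)

    field_records = [f for sv in surveys for f in sv.fields]
    for mgmt in Management:
        sizes = [f.area_m2 for f in field_records if f.management is mgmt]
        add("fields", f"n_{mgmt.value}_fields", len(sizes))
        if sizes:
            q25, q50, q75 = _quartiles(sizes)
            add("fields", f"{mgmt.value}_field_size_mean_m2", float(np.mean(sizes)))
            add("fields", f"{mgmt.value}_field_size_q25_m2", q25)
            add("fields", f"{mgmt.value}_field_size_median_m2", q50)
            add("fields", f"{mgmt.value}_field_size_q75_m2", q75)
        areas_attr = {
            Management.MONOCULTURE: "monoculture_area_m2",
            Management.INTERCROP: "intercrop_area_m2",
        }[mgmt]
        per_loc = [getattr(s, areas_attr) for s in present]
        if per_loc:
            q25, q50, q75 = _quartiles(per_loc)
            add("locations", f"{mgmt.value}_area_per_location_mean_m2", float(np.mean(per_loc)))
            add("locations", f"{mgmt.value}_area_per_location_q25_m2", q25)
            add("locations", f"{mgmt.value}_area_per_location_median_m2", q50)
            add("locations", f"{mgmt.value}_area_per_location_q75_m2", q75)

    return pd.DataFrame(rows)
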
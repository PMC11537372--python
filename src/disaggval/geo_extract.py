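"""Point extraction and buffered zonal statistics over raster layers.

Raster predictions are compared with ground surveys either at the survey
point itself (the value of the containing cell) or summarized over circular
buffers of 2, 5 or 10 km radius around each survey location.  Two buffer
modes exist: *individual* buffers, one zone per location, from which the
seven standard zonal statistics are computed; and the *dissolved* union of
all buffers, in which overlapping zones are merged so that no raster cell is
counted twice (used for large-scale spatial-trend modelling).

A cell belongs to a buffer when its center falls within the buffer radius of
the location.  Missing cells are excluded from every statistic and
``n_cells`` counts only the cells actually used.  Binary presence/absence
layers (settlement masks) only admit the mean, which is then the fraction of
settled cells in the zone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import RasterLayer

ALLOWED_DISTANCES_KM = (0, 2, 5, 10)
STATISTICS = ("mean", "median", "sd", "min", "max", "q25", "q75")


@dataclass(frozen=True)
class BufferSpec:
    """Extraction zone: 0 km means point extraction."""

    distance_km: float
    mode: str = "individual"

    def __post_init__(self) -> None:
        if self.distance_km not in ALLOWED_DISTANCES_KM:
            raise ValueError(
                f"distance_km must be one of {ALLOWED_DISTANCES_KM}, got {self.distance_km}"
            )
        if self.mode not in ("individual", "dissolved"):
            raise ValueError(f"unknown buffer mode {self.mode!r}")
        if self.mode == "dissolved" and self.distance_km == 0:
            raise ValueError("dissolved mode requires a positive buffer distance")


@dataclass
class ZonalSummary:
    """One summary statistic of one layer over one location's zone."""

    location_id: str
    layer: str
    distance_km: float
    statistic: str
    value: float
    n_cells: int


def _stat_value(values: np.ndarray, statistic: str) -> float:
    if statistic == "mean":
        return float(np.mean(values))
    if statistic == "median":
        return float(np.median(values))
    if statistic == "sd":
        # n-1 denominator; a single cell has no dispersion estimate
        return float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    if statistic == "min":
        return float(np.min(values))
    if statistic == "max":
        return float(np.max(values))
    if statistic == "q25":
        return float(np.quantile(values, 0.25))
    if statistic == "q75":
        return float(np.quantile(values, 0.75))
    raise ValueError(f"unknown statistic {statistic!r}")


def _location_xy(loc) -> tuple[str, float, float]:
    return loc.location_id, float(loc.longitude), float(loc.latitude)


def extract_points(layer: RasterLayer, locations) -> list[ZonalSummary]:
    """Value of the containing cell at each survey point (distance 0).

    Points outside the raster extent, or falling on a missing cell, yield a
    NaN value with a warning rather than being silently dropped.
    """
    out: list[ZonalSummary] = []
    for loc in locations:
        loc_id, x, y = _location_xy(loc)
        idx = layer.index_of(x, y)
        if idx is None:
            warnings.warn(
                f"location {loc_id} at ({x:.1f}, {y:.1f}) lies outside layer "
                f"{layer.name!r}; extracted value set to missing",
                stacklevel=2,
            )
            value, n = float("nan"), 0
        else:
            r, c = idx
            if layer.mask[r, c]:
                warnings.warn(
                    f"location {loc_id} falls on a missing cell of layer "
                    f"{layer.name!r}; extracted value set to missing",
                    stacklevel=2,
                )
                value, n = float("nan"), 0
            else:
                value, n = float(layer.values[r, c]), 1
        out.append(ZonalSummary(loc_id, layer.name, 0.0, "mean", value, n))
    return out


def _buffer_cell_mask(layer: RasterLayer, x: float, y: float, distance_km: float) -> np.ndarray:
    dist = layer.center_distances_m(x, y)
    return (dist <= distance_km * 1000.0) & ~layer.mask


def zonal_summaries(
    layer: RasterLayer,
    locations,
    spec: BufferSpec,
    statistics=STATISTICS,
) -> list[ZonalSummary]:
    """Zonal statistics over each location's individual circular buffer."""
    if spec.mode != "individual":
        raise ValueError("zonal_summaries requires an individual-buffer spec")
    if spec.distance_km == 0:
        raise ValueError("use extract_points for distance 0")
    statistics = tuple(statistics)
    for s in statistics:
        if s not in STATISTICS:
            raise ValueError(f"unknown statistic {s!r}")
    if layer.binary and set(statistics) != {"mean"}:
        raise ValueError(
            f"layer {layer.name!r} is binary; only the mean is a valid zonal statistic"
        )
    out: list[ZonalSummary] = []
    for loc in locations:
        loc_id, x, y = _location_xy(loc)
        inside = _buffer_cell_mask(layer, x, y, spec.distance_km)
        values = layer.values[inside]
        if values.size == 0:
            warnings.warn(
                f"no eligible cells within {spec.distance_km} km of location "
                f"{loc_id} for layer {layer.name!r}; statistics set to missing",
                stacklevel=2,
            )
            for stat in statistics:
                out.append(ZonalSummary(loc_id, layer.name, spec.distance_km, stat, float("nan"), 0))
            continue
        for stat in statistics:
            out.append(
                ZonalSummary(
                    loc_id, layer.name, spec.distance_km, stat, _stat_value(values, stat), int(values.size)
                )
            )
    return out


def dissolved_cells(layer: RasterLayer, locations, distance_km: float) -> pd.DataFrame:
    """Cells in the dissolved union of all location buffers, each once.

    Returns a table with columns ``longitude``, ``latitude``, ``value`` — one
    row per non-missing cell whose center lies within ``distance_km`` of at
    least one location.  Overlapping buffers do not duplicate cells.
    """
    if distance_km not in ALLOWED_DISTANCES_KM or distance_km == 0:
        raise ValueError("dissolved extraction requires distance_km in {2, 5, 10}")
    union = np.zeros(layer.shape, dtype=bool)
    for loc in locations:
        _, x, y = _location_xy(loc)
        union |= _buffer_cell_mask(layer, x, y, distance_km)
    if not union.any():
        raise ValueError("dissolved buffer union contains no eligible cells")
    cx, cy = layer.cell_centers()
    return pd.DataFrame(
        {
            "longitude": cx[union],
            "latitude": cy[union],
            "value": layer.values[union],
        }
    ).reset_index(drop=True)


def summaries_frame(summaries: list[ZonalSummary]) -> pd.DataFrame:
    """Tabulate zonal summaries (long format)."""
    return pd.DataFrame([vars(s) for s in summaries])


def covariate_column(layer: str, distance_km: float, statistic: str) -> str:
    """Column name pattern for the assembled covariate table."""
    d = int(distance_km) if float(distance_km).is_integer() else distance_km
    return f"{layer}_{d}km_{statistic}"


def covariate_table(all_summaries: list[ZonalSummary]) -> pd.DataFrame:
    """Pivot long-format zonal summaries to one row per location."""
    long = summaries_frame(all_summaries)
    long["column"] = [
        covariate_column(r.layer, r.distance_km, r.statistic) for r in long.itertuples()
    ]
    wide = long.pivot_table(index="location_id", columns="column", values="value", aggfunc="first")
    wide.columns.name = None
    return wide.reset_index()
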
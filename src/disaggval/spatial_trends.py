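"""Large-scale directional trends and regional contrasts in cassava density.

Survey transects along major roads do not support formal geostatistics, so
spatial structure is summarized by (i) additive models with *independent*
smooth terms over longitude and latitude — no interaction — fitted to the
log-transformed response, and (ii) one-way ANOVA of the square-root
transformed response across administrative regions.  The same trend model is
applied to dissolved-buffer raster extractions, allowing survey trends and
map trends to be compared on a common footing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gam import GAMFit, Smooth1D, fit_gam


@dataclass
class TrendFit:
    """Fitted directional trend: independent smooths in longitude and latitude."""

    response_label: str
    transform: str
    offset: float
    n: int
    fit: GAMFit
    grid: pd.DataFrame  # axis, x, estimate, se

    def smooth_edf(self, axis: str) -> float:
        return self.fit.smooth_edf(axis)


def _log_offset(y: np.ndarray) -> float:
    """Half the minimum positive response, used to admit zeros under log."""
    pos = y[y > 0]
    if pos.size == 0:
        raise ValueError("response is all zero; log-transformed trend undefined")
    return float(pos.min()) / 2.0 if np.any(y == 0) else 0.0


def _trend(
    response: np.ndarray,
    lon: np.ndarray,
    lat: np.ndarray,
    label: str,
    transform: str,
    method: str,
    n_grid: int,
) -> TrendFit:
    y = np.asarray(response, dtype=float)
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    offset = 0.0
    if transform == "log":
        offset = _log_offset(y)
        y = np.log(y + offset)
    elif transform == "sqrt":
        y = np.sqrt(y)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")

    fit = fit_gam(
        y,
        None,
        [Smooth1D("longitude"), Smooth1D("latitude")],
        {"longitude": lon, "latitude": lat},
        method=method,
    )
    rows = []
    for axis, x in (("longitude", lon), ("latitude", lat)):
        grid = np.linspace(x.min(), x.max(), n_grid)
        est, se = fit.smooth_estimate(axis, grid)
        rows.extend(
            {"axis": axis, "x": g, "estimate": e, "se": s} for g, e, s in zip(grid, est, se)
        )
    return TrendFit(label, transform, offset, y.size, fit, pd.DataFrame(rows))


def fit_location_trend(
    summaries,
    response: str = "A_CW",
    transform: str = "log",
    method: str = "GCV",
    n_grid: int = 100,
) -> TrendFit:
    """Trend model for a per-location survey response.

    ``summaries`` is a list of ``LocationSummary`` or a DataFrame with
    ``longitude``, ``latitude`` and the response column.  The response is
    log-transformed (offset = half the minimum positive value when zeros are
    present) and modelled as s(longitude) + s(latitude).
    """
    if isinstance(summaries, pd.DataFrame):
        frame = summaries
    else:
        frame = pd.DataFrame([vars(s) for s in summaries])
    if len(frame) < 10:
        raise ValueError("trend fitting requires at least 10 locations")
    return _trend(
        frame[response].to_numpy(dtype=float),
        frame["longitude"].to_numpy(dtype=float),
        frame["latitude"].to_numpy(dtype=float),
        response,
        transform,
        method,
        n_grid,
    )


def fit_raster_trend(
    cells: pd.DataFrame,
    transform: str = "log",
    method: str = "GCV",
    n_grid: int = 100,
) -> TrendFit:
    """Trend model for dissolved-buffer raster extractions.

    ``cells`` is the (longitude, latitude, value) table from
    :func:`disaggval.geo_extract.dissolved_cells`.
    """
    if len(cells) < 50:
        raise ValueError("raster trend fitting requires at least 50 cells")
    return _trend(
        cells["value"].to_numpy(dtype=float),
        cells["longitude"].to_numpy(dtype=float),
        cells["latitude"].to_numpy(dtype=float),
        "raster_value",
        transform,
        method,
        n_grid,
    )


def regional_anova(
    summaries,
    response: str = "tot_cassava_area_m2",
    transform: str = "sqrt",
) -> pd.DataFrame:
    """One-way ANOVA of a (transformed) response across administrative regions.

    Returns a one-row table with F, numerator df (regions - 1), denominator
    df (n - regions) and the p value.  Regions with all responses missing
    are dropped with a warning.
    """
    if isinstance(summaries, pd.DataFrame):
        frame = summaries.copy()
    else:
        frame = pd.DataFrame([vars(s) for s in summaries])
    col = {"tot_cassava_area_m2": "total_cassava_area_m2"}.get(response, response)
    y = frame[col].to_numpy(dtype=float)
    if transform == "sqrt":
        y = np.sqrt(y)
    elif transform == "log":
        pos = y[y > 0]
        y = np.log(y + (pos.min() / 2.0 if np.any(y == 0) and pos.size else 0.0))
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    frame = frame.assign(_y=y)

    groups = []
    for region, grp in frame.groupby("region"):
        vals = grp["_y"].dropna().to_numpy()
        if vals.size == 0:
            warnings.warn(f"region {region!r} has no usable responses and was dropped", stacklevel=2)
            continue
        groups.append(vals)
    if len(groups) < 2 or sum(len(g) > 1 for g in groups) < 2:
        raise ValueError("regional ANOVA requires at least 2 regions with >= 2 locations")

    all_vals = np.concatenate(groups)
    n, k = all_vals.size, len(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, n - k
    if ss_within == 0:
        F = 0.0 if ss_between == 0 else float("inf")
    else:
        F = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return pd.DataFrame(
        [
            {
                "response": response,
                "transform": transform,
                "df_regions": df1,
                "df_residual": df2,
                "F": float(F),
                "p_value": p,
                "n": n,
                "n_regions": k,
            }
        ]
    )
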
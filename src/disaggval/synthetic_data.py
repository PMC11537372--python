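"""Synthetic geospatial scenes with the structure the validation assumes.

A scene emulates the data layers used to validate a crop-production
disaggregation map against ground surveys:

* a **population** raster — an exponentiated Gaussian random field with
  exponential covariance, mimicking a ~1 km gridded population product;
* a binary **settlement** mask — cells whose population exceeds a quantile
  threshold;
* a **production** raster built by disaggregation-by-population: within each
  administrative region a fixed regional production total is allocated to
  cells proportionally to population (raised to a configurable exponent),
  then smeared by a uniform-disc *displacement* kernel (people's fields are
  not at their houses) and degraded with cellwise lognormal noise;
* a **harvest-area** raster — production times a smooth field in (0, 1];
* ground surveys at locations spaced along road-like transects, whose true
  cassava proportion is linked (through a logit-linear link with noise) to
  the *undisplaced, noise-free* allocation — either at the survey point or,
  when ``link_scale_m`` is positive, averaged over that neighbourhood radius
  (cultivation responds to conditions at landscape scale, not one cell).

Because the survey truth references the clean allocation while the published
production raster is displaced and noisy, point extraction of the raster is a
poor predictor of the truth, whereas buffered means — which average out both
the displacement and the cell noise — recover it.  This makes the
buffered-beats-point phenomenon testable as a recovery experiment.

Administrative regions are Voronoi cells of seed points drawn from the survey
locations themselves, so every region contains at least one location.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Point, Polygon, mapping

from .raster import RasterLayer, read_geotiff, write_geotiff
from .survey_metrics import (
    DensityClass,
    FieldRecord,
    LocationSurvey,
    Management,
    PlantRecord,
)

_QUADRANT_SIDE_M = 100.0
_QUADRANT_COUNT_PROBS = (0.05, 0.10, 0.05, 0.80)  # mostly all four quadrants
_FIELD_SIZE_LOG_MEAN = math.log(150.0)  # m2; highly right-skewed field sizes
_FIELD_SIZE_LOG_SD = 1.2
_MAX_FIELDS_PER_LOCATION = 60
_PLANTS_PRESENT_PROB = 0.15
_MAX_INDIVIDUAL_PLANTS = 10


@dataclass
class SimulationConfig:
    """Generative parameters of a synthetic scene.

    Defaults describe a Côte d'Ivoire-like study: 69 locations in 9
    administrative regions on a ~1 km grid; :func:`uganda_like` gives the
    87-location / 4-region variant.
    """

    seed: int = 0
    grid_nrows: int = 120
    grid_ncols: int = 120
    cell_size_m: float = 1000.0
    n_locations: int = 69
    n_regions: int = 9
    corr_range_m: float = 20_000.0
    pop_log_mean: float = 3.0
    pop_log_sd: float = 1.0
    settlement_threshold: float = 0.7
    displacement_m: float = 2_000.0
    link_slope: float = 1.5
    link_intercept: float = -2.0
    link_noise_sd: float = 0.5
    link_scale_m: float = 0.0  # radius over which the truth signal averages the allocation
    intercrop_prob: float = 0.45
    density_class_probs: tuple = (0.1, 0.2, 0.4, 0.2, 0.1)
    density_record_prob: float = 0.8
    presence_prob: float = 0.75
    population_effect: float = 1.0

    def __post_init__(self) -> None:
        if self.grid_nrows <= 0 or self.grid_ncols <= 0:
            raise ValueError("grid dimensions must be strictly positive")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be strictly positive")
        if self.n_locations <= 0 or self.n_regions <= 0:
            raise ValueError("n_locations and n_regions must be strictly positive")
        if self.n_regions > self.n_locations:
            raise ValueError("n_regions cannot exceed n_locations")
        if self.corr_range_m <= 0:
            raise ValueError("corr_range_m must be strictly positive")
        for name in ("settlement_threshold", "intercrop_prob", "presence_prob", "density_record_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.displacement_m < 0:
            raise ValueError("displacement_m must be non-negative")
        if self.link_noise_sd < 0:
            raise ValueError("link_noise_sd must be non-negative")
        if self.link_scale_m < 0:
            raise ValueError("link_scale_m must be non-negative")
        probs = np.asarray(self.density_class_probs, dtype=float)
        if probs.size != 5 or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("density_class_probs must be 5 non-negative values summing to 1")
        self.density_class_probs = tuple(float(p) for p in probs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        d = dict(d)
        if "density_class_probs" in d:
            d["density_class_probs"] = tuple(d["density_class_probs"])
        return cls(**d)


def ivory_coast_like(seed: int = 0, **overrides) -> SimulationConfig:
    """69 locations / 9 regions, presence ~75%."""
    return SimulationConfig(seed=seed, **overrides)


def uganda_like(seed: int = 0, **overrides) -> SimulationConfig:
    """87 locations / 4 regions, presence ~87%."""
    defaults = dict(n_locations=87, n_regions=4, presence_prob=0.87)
    defaults.update(overrides)
    return SimulationConfig(seed=seed, **defaults)


@dataclass
class SyntheticScene:
    """Rasters, surveys and generative truth for one synthetic study."""

    config: SimulationConfig
    production_raster: RasterLayer
    harvest_raster: RasterLayer
    population_raster: RasterLayer
    settlement_raster: RasterLayer
    cultivation_raster: RasterLayer  # undisplaced noise-free allocation (truth basis)
    region_raster: RasterLayer       # integer region label per cell (1..n_regions)
    locations: list[LocationSurvey] = field(default_factory=list)
    truth: pd.DataFrame | None = None

    @property
    def rasters(self) -> dict[str, RasterLayer]:
        return {
            "production": self.production_raster,
            "harvest": self.harvest_raster,
            "population": self.population_raster,
            "settlement": self.settlement_raster,
        }


# ----------------------------------------------------------------------
# random-field and kernel machinery


def gaussian_random_field(
    rng: np.random.Generator,
    nrows: int,
    ncols: int,
    cell_size: float,
    corr_range: float,
) -> np.ndarray:
    """Zero-mean unit-variance Gaussian field with exponential covariance.

    Spectral (circulant-embedding) simulation on a doubled grid: the
    covariance C(h) = exp(-h / range) is embedded in a periodic domain and
    sampled exactly via the FFT; negative embedding eigenvalues (small for
    the exponential model) are truncated at zero.
    """
    m, n = 2 * nrows, 2 * ncols
    dy = np.minimum(np.arange(m), m - np.arange(m)) * cell_size
    dx = np.minimum(np.arange(n), n - np.arange(n)) * cell_size
    h = np.hypot(dy[:, None], dx[None, :])
    cov = np.exp(-h / corr_range)
    eig = np.fft.fft2(cov).real
    eig = np.maximum(eig, 0.0)
    noise = rng.normal(size=(m, n)) + 1j * rng.normal(size=(m, n))
    sim = np.fft.fft2(np.sqrt(eig / (m * n)) * noise)
    return sim.real[:nrows, :ncols]


def disc_kernel(radius_m: float, cell_size: float) -> np.ndarray:
    """Normalized uniform-disc convolution kernel (identity when radius < cell)."""
    r_cells = int(math.floor(radius_m / cell_size))
    if r_cells < 1:
        return np.ones((1, 1))
    offsets = np.arange(-r_cells, r_cells + 1)
    dist = np.hypot(offsets[:, None], offsets[None, :]) * cell_size
    kernel = (dist <= radius_m).astype(float)
    return kernel / kernel.sum()


def proportional_allocation(
    population: np.ndarray,
    region_labels: np.ndarray,
    regional_totals: dict[int, float],
    effect: float = 1.0,
) -> np.ndarray:
    """Allocate fixed regional totals to cells proportionally to population^effect."""
    weights = np.power(np.maximum(population, 0.0), effect)
    out = np.zeros_like(weights)
    for region, total in regional_totals.items():
        in_region = region_labels == region
        w = weights[in_region]
        s = w.sum()
        if s > 0:
            out[in_region] = total * w / s
        else:
            out[in_region] = total / max(in_region.sum(), 1)
    return out


# ----------------------------------------------------------------------
# locations along transects


def _transect_locations(rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    """(n, 2) survey-location coordinates spaced along road-like transects.

    Straight transects cross the full extent; locations are dropped every
    15-20 km along each with lateral jitter, emulating sampling along major
    roads, until n_locations are placed.
    """
    width = config.grid_ncols * config.cell_size_m
    height = config.grid_nrows * config.cell_size_m
    margin = 0.02
    pts: list[tuple[float, float]] = []
    while len(pts) < config.n_locations:
        # random chord across the extent
        a = rng.uniform((margin * width, margin * height), ((1 - margin) * width, (1 - margin) * height))
        angle = rng.uniform(0, np.pi)
        d = np.array([np.cos(angle), np.sin(angle)])
        length = math.hypot(width, height)
        step = rng.uniform(15_000.0, 20_000.0)
        for t in np.arange(-length, length, step):
            p = a + t * d + rng.normal(0, 500.0, size=2)
            if margin * width < p[0] < (1 - margin) * width and margin * height < p[1] < (1 - margin) * height:
                pts.append((float(p[0]), float(p[1])))
    pts = pts[: config.n_locations]
    return np.array(pts)


# ----------------------------------------------------------------------
# scene generation


def generate_scene(config: SimulationConfig) -> SyntheticScene:
    """Generate a complete synthetic scene (rasters, regions, surveys)."""
    rng = np.random.default_rng(config.seed)
    nr, nc, cs = config.grid_nrows, config.grid_ncols, config.cell_size_m
    y_origin = nr * cs  # planar metres, top-left origin

    def make_layer(values, name, binary=False):
        return RasterLayer(values, 0.0, y_origin, cs, crs="planar_m", name=name, binary=binary)

    g_pop = gaussian_random_field(rng, nr, nc, cs, config.corr_range_m)
    population = np.exp(config.pop_log_mean + config.pop_log_sd * g_pop)
    threshold = np.quantile(population, config.settlement_threshold)
    settlement = (population > threshold).astype(float)

    coords = _transect_locations(rng, config)
    seed_idx = rng.choice(config.n_locations, size=config.n_regions, replace=False)
    seeds = coords[seed_idx]

    pop_layer = make_layer(population, "population")
    cx, cy = pop_layer.cell_centers()
    d2 = (cx[..., None] - seeds[:, 0]) ** 2 + (cy[..., None] - seeds[:, 1]) ** 2
    region_labels = np.argmin(d2, axis=-1) + 1  # 1..n_regions

    regional_totals = {
        r: float((region_labels == r).sum() * np.exp(rng.normal(0.0, 0.5)))
        for r in range(1, config.n_regions + 1)
    }
    base = proportional_allocation(
        population, region_labels, regional_totals, config.population_effect
    )

    displaced = ndimage.convolve(base, disc_kernel(config.displacement_m, cs), mode="reflect")
    noise = (
        np.exp(rng.normal(0.0, config.link_noise_sd, size=base.shape))
        if config.link_noise_sd > 0
        else np.ones_like(base)
    )
    production = displaced * noise

    g_frac = gaussian_random_field(rng, nr, nc, cs, config.corr_range_m)
    harvest_fraction = 1.0 / (1.0 + np.exp(-g_frac))  # smooth field in (0, 1)
    harvest = production * harvest_fraction

    scene = SyntheticScene(
        config=config,
        production_raster=make_layer(production, "production"),
        harvest_raster=make_layer(harvest, "harvest"),
        population_raster=make_layer(population, "population"),
        settlement_raster=make_layer(settlement, "settlement", binary=True),
        cultivation_raster=make_layer(base, "cultivation"),
        region_raster=make_layer(region_labels.astype(float), "region"),
    )
    scene._coords = coords
    scene.locations = generate_survey(scene, config)
    return scene


def _quadrant_polygons(x: float, y: float, n_quadrants: int) -> list[Polygon]:
    s = _QUADRANT_SIDE_M
    corners = [(-s, 0), (0, 0), (-s, -s), (0, -s)][:n_quadrants]
    return [Polygon([(x + dx, y + dy), (x + dx + s, y + dy), (x + dx + s, y + dy + s), (x + dx, y + dy + s)]) for dx, dy in corners]


def generate_survey(scene: SyntheticScene, config: SimulationConfig) -> list[LocationSurvey]:
    """Simulate ground surveys at the scene's locations.

    The true cassava proportion of a present location is
    ``invlogit(intercept + slope * z + noise)`` where ``z`` standardizes the
    clean allocation value at the point across locations; the proportion is
    then partitioned into lognormal-sized fields with management, density
    class and individual-plant draws.
    """
    rng = np.random.default_rng((config.seed, 1))
    coords = getattr(scene, "_coords", None)
    if coords is None:
        coords = np.array([(loc.longitude, loc.latitude) for loc in scene.locations])
    layer = scene.cultivation_raster
    signal = layer.values
    if config.link_scale_m > 0:
        # truth signal defined at neighbourhood scale: surveys respond to the
        # allocation averaged over the surrounding link_scale_m radius
        signal = ndimage.convolve(
            layer.values, disc_kernel(config.link_scale_m, config.cell_size_m), mode="reflect"
        )
    base_vals = np.empty(len(coords))
    for i, (x, y) in enumerate(coords):
        idx = layer.index_of(x, y)
        if idx is None:
            raise ValueError(f"survey location ({x:.1f}, {y:.1f}) lies outside the raster extent")
        base_vals[i] = signal[idx]
    sd = base_vals.std()
    z = (base_vals - base_vals.mean()) / sd if sd > 0 else np.zeros_like(base_vals)

    region_layer = scene.region_raster
    density_classes = [
        DensityClass.VERY_HIGH,
        DensityClass.HIGH,
        DensityClass.REGULAR,
        DensityClass.SPARSE,
        DensityClass.VERY_SPARSE,
    ]

    surveys: list[LocationSurvey] = []
    truth_rows: list[dict] = []
    for i, (x, y) in enumerate(coords):
        loc_id = f"L{i + 1:03d}"
        region = int(region_layer.values[region_layer.index_of(x, y)])
        quadrants = int(rng.choice([1, 2, 3, 4], p=_QUADRANT_COUNT_PROBS))
        present = bool(rng.random() < config.presence_prob)
        delta = quadrants * _QUADRANT_SIDE_M**2

        fields: list[FieldRecord] = []
        n_plants = 0
        p_true = 0.0
        if present:
            eta = config.link_intercept + config.link_slope * z[i]
            if config.link_noise_sd > 0:
                eta += rng.normal(0.0, config.link_noise_sd)
            p_true = float(1.0 / (1.0 + np.exp(-eta)))
            target = p_true * delta
            cum = 0.0
            while cum < target and len(fields) < _MAX_FIELDS_PER_LOCATION:
                size = float(rng.lognormal(_FIELD_SIZE_LOG_MEAN, _FIELD_SIZE_LOG_SD))
                size = min(size, target - cum) if target - cum > 1.0 else (target - cum)
                if size <= 0:
                    break
                management = (
                    Management.INTERCROP
                    if rng.random() < config.intercrop_prob
                    else Management.MONOCULTURE
                )
                if rng.random() < config.density_record_prob:
                    dclass = density_classes[rng.choice(5, p=config.density_class_probs)]
                else:
                    dclass = DensityClass.UNRECORDED
                fields.append(FieldRecord(loc_id, management, max(size, 1e-6), dclass))
                cum += size
            if rng.random() < _PLANTS_PRESENT_PROB:
                n_plants = int(rng.integers(1, _MAX_INDIVIDUAL_PLANTS + 1))
            if not fields and n_plants == 0:
                n_plants = 1  # presence implies at least one plant

        surveys.append(
            LocationSurvey(
                location_id=loc_id,
                longitude=float(x),
                latitude=float(y),
                region=f"R{region}",
                quadrants=quadrants,
                fields=fields,
                plants=PlantRecord(loc_id, n_plants),
                quadrant_polygons=_quadrant_polygons(x, y, quadrants),
            )
        )
        truth_rows.append(
            {
                "location_id": loc_id,
                "longitude": float(x),
                "latitude": float(y),
                "region": f"R{region}",
                "presence": present,
                "true_proportion": p_true,
                "allocation_value": float(base_vals[i]),
            }
        )
    scene.truth = pd.DataFrame(truth_rows)
    return surveys


# ----------------------------------------------------------------------
# persistence


def _feature(geom, properties: dict) -> dict:
    return {"type": "Feature", "geometry": mapping(geom), "properties": properties}


def _fields_geojson(surveys: list[LocationSurvey], rng: np.random.Generator) -> dict:
    """Fields as square polygons of the recorded area, placed inside quadrants."""
    features = []
    for sv in surveys:
        half_extent = _QUADRANT_SIDE_M
        for j, f in enumerate(sv.fields):
            side = math.sqrt(f.area_m2)
            ox = sv.longitude + rng.uniform(-half_extent, half_extent - side)
            oy = sv.latitude + rng.uniform(-half_extent, half_extent - side)
            poly = Polygon([(ox, oy), (ox + side, oy), (ox + side, oy + side), (ox, oy + side)])
            features.append(
                _feature(
                    poly,
                    {
                        "location_id": f.location_id,
                        "field_index": j,
                        "management": f.management.value,
                        "area_m2": f.area_m2,
                        "density_class": f.density_class.value,
                    },
                )
            )
    return {"type": "FeatureCollection", "features": features}


def _plants_geojson(surveys: list[LocationSurvey], rng: np.random.Generator) -> dict:
    features = []
    for sv in surveys:
        for k in range(sv.plants.n_plants):
            p = Point(
                sv.longitude + rng.uniform(-_QUADRANT_SIDE_M, _QUADRANT_SIDE_M),
                sv.latitude + rng.uniform(-_QUADRANT_SIDE_M, _QUADRANT_SIDE_M),
            )
            features.append(
                _feature(p, {"location_id": sv.location_id, "plant_index": k, "plant_radius_m": sv.plants.plant_radius_m})
            )
    return {"type": "FeatureCollection", "features": features}


def _locations_geojson(surveys: list[LocationSurvey]) -> dict:
    features = []
    for sv in surveys:
        features.append(
            _feature(
                Point(sv.longitude, sv.latitude),
                {
                    "location_id": sv.location_id,
                    "region": sv.region,
                    "quadrants": sv.quadrants,
                    "total_area_m2": sv.total_area_m2,
                    "n_plants": sv.plants.n_plants,
                },
            )
        )
        for q, poly in enumerate(sv.quadrant_polygons or []):
            features.append(
                _feature(poly, {"location_id": sv.location_id, "quadrant_index": q})
            )
    return {"type": "FeatureCollection", "features": features}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_scene(scene: SyntheticScene, directory) -> dict:
    """Persist a scene: GeoTIFF rasters, GeoJSON surveys, CSV truth, JSON config.

    Returns a manifest mapping each written file to its sha256 checksum.  A
    read-back with :func:`read_scene` reproduces rasters and survey records
    exactly (rasters are stored as float64).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    raster_files = {}
    for name, layer in scene.rasters.items():
        fname = f"{name}.tif"
        write_geotiff(layer, directory / fname, dtype=np.float64)
        raster_files[name] = fname
    # generative-truth rasters, kept apart from the observable layers
    truth_raster_files = {}
    for name, layer in (("cultivation", scene.cultivation_raster), ("region", scene.region_raster)):
        fname = f"{name}.tif"
        write_geotiff(layer, directory / fname, dtype=np.float64)
        truth_raster_files[name] = fname

    geo_rng = np.random.default_rng((scene.config.seed, 2))
    json_files = {
        "fields.geojson": _fields_geojson(scene.locations, geo_rng),
        "plants.geojson": _plants_geojson(scene.locations, geo_rng),
        "locations.geojson": _locations_geojson(scene.locations),
        "config.json": scene.config.to_dict(),
    }
    for fname, obj in json_files.items():
        (directory / fname).write_text(json.dumps(obj, indent=1, sort_keys=True))

    scene.truth.to_csv(directory / "truth.csv", index=False)

    fields_rows = [
        {
            "location_id": f.location_id,
            "management": f.management.value,
            "area_m2": f.area_m2,
            "density_class": f.density_class.value,
        }
        for sv in scene.locations
        for f in sv.fields
    ]
    pd.DataFrame(fields_rows, columns=["location_id", "management", "area_m2", "density_class"]).to_csv(
        directory / "fields.csv", index=False
    )

    all_files = (
        list(raster_files.values())
        + list(truth_raster_files.values())
        + list(json_files)
        + ["truth.csv", "fields.csv"]
    )
    for fname in all_files:
        written[fname] = _sha256(directory / fname)
    manifest = {"rasters": raster_files, "truth_rasters": truth_raster_files, "files": written}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def read_scene(directory) -> SyntheticScene:
    """Reconstruct a scene written by :func:`write_scene`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    config = SimulationConfig.from_dict(json.loads((directory / "config.json").read_text()))
    layers = {
        name: read_geotiff(directory / fname)
        for name, fname in {**manifest["rasters"], **manifest.get("truth_rasters", {})}.items()
    }
    truth = pd.read_csv(directory / "truth.csv")

    locations_geo = json.loads((directory / "locations.geojson").read_text())
    fields_df = pd.read_csv(directory / "fields.csv") if (directory / "fields.csv").stat().st_size else None
    surveys: list[LocationSurvey] = []
    for feat in locations_geo["features"]:
        props = feat["properties"]
        if "quadrant_index" in props:
            continue
        loc_id = props["location_id"]
        recs = []
        if fields_df is not None and len(fields_df):
            for row in fields_df[fields_df.location_id == loc_id].itertuples():
                recs.append(FieldRecord(loc_id, row.management, row.area_m2, row.density_class))
        x, y = feat["geometry"]["coordinates"]
        surveys.append(
            LocationSurvey(
                location_id=loc_id,
                longitude=x,
                latitude=y,
                region=props["region"],
                quadrants=props["quadrants"],
                fields=recs,
                plants=PlantRecord(loc_id, props["n_plants"]),
            )
        )
    scene = SyntheticScene(
        config=config,
        production_raster=layers["production"],
        harvest_raster=layers["harvest"],
        population_raster=layers["population"],
        settlement_raster=layers["settlement"],
        cultivation_raster=layers["cultivation"],
        region_raster=layers["region"],
        locations=surveys,
        truth=truth,
    )
    return scene
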
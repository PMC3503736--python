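"""Synthetic study regions: census blocks, patients, dialysis facilities.

A region emulates the statistical structure of a Japanese prefecture at the
census-block level: block population densities are log-normal, block areas
shrink as density grows (rural blocks are large and sparse), patients arise
per block as a binomial draw at a fixed dialysis prevalence, and facilities
are placed preferentially in populous blocks with capacities drawn by
urban/rural stratum.  Blocks are classified urban/rural by the lowest-density
prefix rule: the rural area is the shortest density-ordered prefix of blocks
that cumulatively holds at least a target share (default 25%) of patients.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "Region",
    "UrbanRuralPartition",
    "ConfigurationError",
    "ClassificationError",
    "PRESETS",
    "generate_region",
    "classify_urban_rural",
    "region_summary",
    "patient_strata",
    "write_blocks_geojson",
    "write_patients_csv",
    "write_facilities_csv",
    "load_generator_config",
]

BLOCK_SCHEMA = ["block_id", "x_km", "y_km", "area_km2", "population", "density"]
PATIENT_SCHEMA = ["patient_id", "block_id", "x_km", "y_km"]
FACILITY_SCHEMA = ["facility_id", "x_km", "y_km", "capacity", "consoles"]


class ConfigurationError(ValueError):
    """The generator configuration cannot yield a feasible region."""


class ClassificationError(ValueError):
    """Urban/rural classification is undefined (e.g. no patients)."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic-region generator.

    Defaults reproduce the scale of the Hiroshima-prefecture study area:
    1,867 census blocks, total population 2,876,642, dialysis prevalence
    256.36 per 100,000 (7,374 / 2,876,642), 98 facilities with total
    capacity 8,643.
    """

    n_blocks: int = 1867
    population_target: int = 2_876_642
    #: median of the block population-density log-normal, per km^2
    density_median: float = 770.0
    #: sigma of log density
    density_sigma: float = 2.0
    #: median block area at the median density, km^2
    area_median_km2: float = 1.0
    #: d log(area) / d log(density); negative coupling makes rural blocks large
    area_density_slope: float = -0.7
    #: residual sigma of log area
    area_sigma: float = 1.0
    #: dialysis prevalence per 100,000 population
    prevalence_per_100k: float = 256.36
    n_facilities: int = 98
    #: facility placement probability is proportional to population**weight
    placement_weight: float = 1.2
    #: median facility capacity by stratum (patients)
    capacity_median: Mapping[str, float] = field(
        default_factory=lambda: {"urban": 76.0, "rural": 34.0}
    )
    capacity_sigma: float = 0.8
    capacity_bounds: tuple[float, float] = (5.0, 650.0)
    total_capacity_target: int = 8643
    #: rural = lowest-density blocks holding this share of patients
    rural_patient_share: float = 0.25
    seed: int = 0
    preset_name: str = "custom"
    #: explicit per-block populations (overrides the log-normal model)
    block_populations: tuple[int, ...] | None = None
    #: explicit per-block areas, km^2 (requires block_populations)
    block_areas_km2: tuple[float, ...] | None = None

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)


PRESETS: dict[str, GeneratorConfig] = {
    "hiroshima": GeneratorConfig(preset_name="hiroshima"),
    "tiny": GeneratorConfig(
        n_blocks=4,
        population_target=3600,
        block_populations=(100, 500, 1000, 2000),
        block_areas_km2=(9.0, 4.0, 2.0, 1.0),
        prevalence_per_100k=10_000.0,
        n_facilities=3,
        total_capacity_target=450,
        capacity_bounds=(5.0, 400.0),
        preset_name="tiny",
    ),
}


@dataclass(frozen=True)
class Region:
    """A synthetic study area: census blocks, patients and facilities.

    ``blocks``, ``patients`` and ``facilities`` are DataFrames with the
    column schemas in :data:`BLOCK_SCHEMA`, :data:`PATIENT_SCHEMA` and
    :data:`FACILITY_SCHEMA`.
    """

    blocks: pd.DataFrame
    patients: pd.DataFrame
    facilities: pd.DataFrame
    seed: int
    preset_name: str = "custom"

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def total_capacity(self) -> int:
        return int(self.facilities["capacity"].sum())

    def capacities(self) -> dict[str, int]:
        """Facility capacity mapping, ``facility_id -> capacity``."""
        return dict(
            zip(self.facilities["facility_id"], self.facilities["capacity"].astype(int))
        )


@dataclass(frozen=True)
class UrbanRuralPartition:
    """Urban/rural block labels from the lowest-density prefix rule."""

    labels: Mapping[str, str]  # block_id -> "urban" | "rural"
    cutoff_density: float
    rural_patient_share: float

    def stratum(self, block_id: str) -> str:
        return self.labels[block_id]


def _positions_by_density(rng, density: np.ndarray, radius: float):
    """Place denser blocks nearer the regional centre (monocentric layout)."""
    n = len(density)
    order = np.argsort(np.argsort(-density, kind="stable"))  # 0 = densest
    r_frac = (order + 0.5) / n
    r = radius * np.power(r_frac, 0.7)
    r = np.maximum(r + rng.normal(0.0, 0.05 * radius, n), 0.0)
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    return r * np.cos(theta), r * np.sin(theta)


def _scale_to_total(values: np.ndarray, target: int) -> np.ndarray:
    """Rescale and round non-negative values so they sum exactly to target."""
    total = values.sum()
    if total <= 0:
        raise ConfigurationError("cannot rescale an all-zero vector to a positive total")
    scaled = np.rint(values * (target / total)).astype(np.int64)
    scaled = np.maximum(scaled, 0)
    remainder = target - int(scaled.sum())
    scaled[int(np.argmax(scaled))] += remainder
    if scaled.min() < 0:
        raise ConfigurationError("rounding remainder drove a value negative")
    return scaled


def generate_region(config: GeneratorConfig) -> Region:
    """Generate a seeded synthetic region.

    The draw is fully deterministic under ``config.seed``: identical
    configurations produce bit-identical block, patient and facility tables.

    Raises
    ------
    ConfigurationError
        If the configuration is infeasible, e.g. the total-capacity target
        is below the expected number of patients.
    """
    if config.n_blocks <= 0 or config.n_facilities <= 0:
        raise ConfigurationError("n_blocks and n_facilities must be positive")
    if not 0.0 < config.prevalence_per_100k < 100_000.0:
        raise ConfigurationError("prevalence must lie in (0, 100000) per 100k")
    prevalence = config.prevalence_per_100k / 100_000.0

    rng = np.random.default_rng(config.seed)
    n = config.n_blocks

    if config.block_populations is not None:
        if len(config.block_populations) != n:
            raise ConfigurationError("block_populations length must equal n_blocks")
        population = np.asarray(config.block_populations, dtype=np.int64)
        if config.block_areas_km2 is not None:
            area = np.asarray(config.block_areas_km2, dtype=float)
        else:
            area = np.ones(n)
    else:
        log_d = rng.normal(np.log(config.density_median), config.density_sigma, n)
        log_a = (
            np.log(config.area_median_km2)
            + config.area_density_slope * (log_d - np.log(config.density_median))
            + rng.normal(0.0, config.area_sigma, n)
        )
        area = np.exp(log_a)
        population = _scale_to_total(np.exp(log_d) * area, config.population_target)

    if (area <= 0).any():
        raise ConfigurationError("block areas must be positive")
    total_pop = int(population.sum())
    expected_patients = total_pop * prevalence
    if config.total_capacity_target < expected_patients:
        raise ConfigurationError(
            f"total-capacity target {config.total_capacity_target} is below the "
            f"expected number of patients ({expected_patients:.0f})"
        )

    density = population / area
    radius = float(np.sqrt(area.sum() / np.pi))  # disc matching total area
    x, y = _positions_by_density(rng, density, radius)
    width = max(1, len(str(n - 1)))
    blocks = pd.DataFrame(
        {
            "block_id": [f"B{i:0{width}d}" for i in range(n)],
            "x_km": x,
            "y_km": y,
            "area_km2": area,
            "population": population,
            "density": density,
        }
    )

    # patients: binomial per block, uniform within the block's equivalent disc
    counts = rng.binomial(population, prevalence)
    block_radius = np.sqrt(area / np.pi)
    rows = []
    pid = 0
    for i in range(n):
        k = int(counts[i])
        if k == 0:
            continue
        rr = block_radius[i] * np.sqrt(rng.uniform(size=k))
        tt = rng.uniform(0.0, 2.0 * np.pi, k)
        for j in range(k):
            rows.append(
                (
                    f"P{pid:06d}",
                    blocks.at[i, "block_id"],
                    x[i] + rr[j] * np.cos(tt[j]),
                    y[i] + rr[j] * np.sin(tt[j]),
                )
            )
            pid += 1
    patients = pd.DataFrame(rows, columns=PATIENT_SCHEMA)

    region_wo_fac = Region(blocks, patients, pd.DataFrame(columns=FACILITY_SCHEMA), config.seed)
    if len(patients) > 0:
        partition = classify_urban_rural(region_wo_fac, config.rural_patient_share)
        strata = blocks["block_id"].map(partition.labels)
    else:
        strata = pd.Series(["urban"] * n)

    # facilities: block choice weighted by population**w, capacity by stratum
    weights = np.power(population.astype(float) + 1.0, config.placement_weight)
    weights /= weights.sum()
    fac_block = rng.choice(n, size=config.n_facilities, replace=True, p=weights)
    fr = block_radius[fac_block] * np.sqrt(rng.uniform(size=config.n_facilities))
    ft = rng.uniform(0.0, 2.0 * np.pi, config.n_facilities)
    med = np.array(
        [config.capacity_median.get(strata.iloc[b], 50.0) for b in fac_block]
    )
    raw_cap = np.exp(rng.normal(np.log(med), config.capacity_sigma))
    raw_cap = np.clip(raw_cap, *config.capacity_bounds)
    capacity = _scale_to_total(raw_cap, config.total_capacity_target)
    if int(capacity.sum()) < len(patients):
        raise ConfigurationError(
            f"total capacity {int(capacity.sum())} is below the number of "
            f"patients ({len(patients)})"
        )
    # consoles: informational; roughly one console per 3-4 outpatient slots
    consoles = np.maximum(1, np.rint(capacity / 3.6)).astype(np.int64)

    facilities = pd.DataFrame(
        {
            "facility_id": [f"F{i:03d}" for i in range(config.n_facilities)],
            "x_km": x[fac_block] + fr * np.cos(ft),
            "y_km": y[fac_block] + fr * np.sin(ft),
            "capacity": capacity,
            "consoles": consoles,
        }
    )
    return Region(blocks, patients, facilities, config.seed, config.preset_name)


def classify_urban_rural(
    region: Region, target_rural_patient_share: float = 0.25
) -> UrbanRuralPartition:
    """Classify blocks urban/rural by the lowest-density prefix rule.

    Blocks are sorted by ascending population density (ties broken by
    block_id); the rural area is the shortest prefix whose cumulative patient
    count reaches at least ``target_rural_patient_share`` of all patients.
    The cutoff density is the density of the last rural block.
    """
    if region.n_patients == 0:
        raise ClassificationError("cannot classify a region with no patients")
    per_block = region.patients.groupby("block_id").size()
    blocks = region.blocks.sort_values(
        ["density", "block_id"], kind="stable"
    ).reset_index(drop=True)
    counts = blocks["block_id"].map(per_block).fillna(0).to_numpy(dtype=np.int64)
    total = counts.sum()
    cum = np.cumsum(counts)
    threshold = target_rural_patient_share * total
    idx = int(np.searchsorted(cum, threshold, side="left"))
    # searchsorted(left) lands on the first index with cum >= threshold,
    # except when cum == threshold exactly, which is the prefix we want
    while cum[idx] < threshold:  # pragma: no cover - defensive
        idx += 1
    labels = {
        bid: ("rural" if i <= idx else "urban")
        for i, bid in enumerate(blocks["block_id"])
    }
    return UrbanRuralPartition(
        labels=labels,
        cutoff_density=float(blocks.at[idx, "density"]),
        rural_patient_share=float(cum[idx] / total),
    )


def _quartile_row(values: pd.Series) -> dict[str, float]:
    if len(values) == 0:
        return {"median": np.nan, "q25": np.nan, "q75": np.nan}
    q25, med, q75 = np.quantile(values.to_numpy(dtype=float), [0.25, 0.5, 0.75])
    return {"median": med, "q25": q25, "q75": q75}


def region_summary(region: Region, partition: UrbanRuralPartition) -> pd.DataFrame:
    """Stratified descriptive table: n blocks and median/IQR of block
    population, area and patient count, per stratum and overall.

    Quantiles use linear interpolation between order statistics.
    """
    per_block = region.patients.groupby("block_id").size()
    blocks = region.blocks.copy()
    blocks["patients"] = blocks["block_id"].map(per_block).fillna(0).astype(int)
    blocks["stratum"] = blocks["block_id"].map(partition.labels)

    out = []
    groups = [("rural", blocks[blocks["stratum"] == "rural"]),
              ("urban", blocks[blocks["stratum"] == "urban"]),
              ("overall", blocks)]
    for name, g in groups:
        row: dict[str, object] = {"stratum": name, "n_blocks": len(g)}
        for col in ("population", "area_km2", "patients"):
            for stat, v in _quartile_row(g[col]).items():
                row[f"{col}_{stat}"] = v
        out.append(row)
    return pd.DataFrame(out).set_index("stratum")


def patient_strata(region: Region, partition: UrbanRuralPartition) -> dict[str, str]:
    """Per-patient stratum labels via each patient's census block."""
    return {
        pid: partition.labels[bid]
        for pid, bid in zip(region.patients["patient_id"], region.patients["block_id"])
    }


# ---------------------------------------------------------------------------
# file interchange


def write_blocks_geojson(region: Region, path) -> None:
    """Write census blocks as a GeoJSON FeatureCollection of points."""
    features = []
    for row in region.blocks.itertuples(index=False):
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [row.x_km, row.y_km]},
                "properties": {
                    "block_id": row.block_id,
                    "population": int(row.population),
                    "area_km2": float(row.area_km2),
                    "density": float(row.density),
                },
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
        fh.write("\n")


def write_patients_csv(region: Region, path) -> None:
    region.patients.to_csv(path, index=False)


def write_facilities_csv(region: Region, path) -> None:
    region.facilities.to_csv(path, index=False)


def load_generator_config(path) -> GeneratorConfig:
    """Load a generator configuration from a YAML mapping.

    A ``preset`` key selects a base preset; remaining keys override its
    fields.  ``seed`` is mandatory.
    """
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config file must contain a mapping")
    preset = raw.pop("preset", None)
    base = PRESETS[preset] if preset else GeneratorConfig()
    if "seed" not in raw:
        raise ConfigurationError("config must set a seed")
    for key in ("block_populations", "block_areas_km2"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    unknown = set(raw) - {f.name for f in dataclasses.fields(GeneratorConfig)}
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return base.replace(**raw)
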
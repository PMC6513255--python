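"""Seeded virtual-species data generation.

Builds everything the pipeline consumes without external downloads: a stack
of spatially autocorrelated bioclim-like predictor layers, a human
population-density layer, a virtual species whose true occupancy is a
logistic function of a subset of the layers, and occurrence records whose
detection probability increases with population density (observer bias).
Records in cells of high true suitability carry breeding-evidence labels.

Everything is driven by one integer seed; identical configs give
bit-identical rasters and record sets.  Grids are georeferenced in lon/lat
degrees over an equatorial South-American window so the nominal metric
cell size translates directly into degrees (1 deg ~ 111.32 km).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

from .environment import DEFAULT_NODATA, EnvStack, RasterGrid
from .occurrences import BREEDING_CODES, OccurrenceRecord, OccurrenceSet

METERS_PER_DEGREE = 111_320.0


class ConfigurationError(ValueError):
    pass


class SamplingError(RuntimeError):
    pass


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    ``true_betas`` is (intercept, b1, ..., bk): the virtual species'
    occupancy is logistic(b0 + sum bi * layer_i) over the first k layers.
    ``bias_exponent`` is the exponent a in detection weight
    suitability * density**a; a = 0 removes observer bias.
    """

    seed: int = 0
    n_rows: int = 64
    n_cols: int = 64
    cell_size_m: float = 1000.0
    n_layers: int = 5
    autocorr_sd_cells: float = 6.0
    true_betas: tuple[float, ...] = (0.0, 2.5, -1.5, 1.0)
    repro_threshold: float = 0.6
    n_presences: int = 300
    bias_exponent: float = 1.0
    max_density: float = 1000.0  # persons per km^2 at the densest cell
    origin_lon: float = -70.0
    origin_lat: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rows < 16 or self.n_cols < 16:
            raise ConfigurationError("grid must be at least 16 x 16")
        if self.n_layers < 3:
            raise ConfigurationError("need at least 3 environmental layers")
        if not (0.0 < self.repro_threshold <= 1.0):
            raise ConfigurationError("repro_threshold must be in (0, 1]")
        if self.n_presences < 20:
            raise ConfigurationError("need at least 20 presences")
        if len(self.true_betas) - 1 > self.n_layers:
            raise ConfigurationError("more beta coefficients than layers")
        if self.cell_size_m <= 0:
            raise ConfigurationError("cell size must be positive")

    @property
    def cell_size_deg(self) -> float:
        return self.cell_size_m / METERS_PER_DEGREE

    @property
    def geotransform(self) -> tuple[float, float, float, float]:
        return (self.origin_lon, self.origin_lat, self.cell_size_deg, self.cell_size_deg)

    def rng(self, stream: int) -> np.random.Generator:
        """Independent substream ``stream`` of the run seed."""
        return np.random.default_rng([int(self.seed) % (2**31), stream])


@dataclass
class VirtualSpecies:
    true_suitability: RasterGrid
    generating_layers: list[str]
    betas: tuple[float, ...]


def _smooth_standard_field(rng: np.random.Generator, shape, sd_cells: float) -> np.ndarray:
    """White noise, Gaussian-smoothed, standardized to mean 0 / SD 1."""
    f = rng.standard_normal(shape)
    if sd_cells > 0:
        f = ndimage.gaussian_filter(f, sigma=sd_cells, mode="reflect")
    f = f - f.mean()
    sd = f.std()
    if sd == 0:  # pathological: all-equal field
        return np.zeros(shape)
    return f / sd


def gen_env_stack(config: SyntheticConfig) -> EnvStack:
    """Generate ``n_layers`` co-registered autocorrelated predictor layers.

    Each layer is seeded white noise smoothed with an isotropic Gaussian of
    ``autocorr_sd_cells`` and standardized to zero mean, unit variance.
    Layers are named SYN01..SYNk.
    """
    stack = EnvStack()
    for k in range(config.n_layers):
        rng = config.rng(100 + k)
        vals = _smooth_standard_field(rng, (config.n_rows, config.n_cols), config.autocorr_sd_cells)
        stack.add(
            f"SYN{k + 1:02d}",
            RasterGrid(vals, config.geotransform, nodata=DEFAULT_NODATA),
        )
    return stack


def gen_popdensity(config: SyntheticConfig) -> RasterGrid:
    """Generate a non-negative, right-skewed population-density layer.

    Exponential of a smoothed seeded Gaussian field, rescaled to
    [0, max_density]; mimics the strong spatial clustering of settlement.
    """
    rng = config.rng(200)
    f = _smooth_standard_field(rng, (config.n_rows, config.n_cols), config.autocorr_sd_cells)
    d = np.exp(1.5 * f)
    d = d - d.min()
    if d.max() > 0:
        d = d / d.max() * config.max_density
    return RasterGrid(d, config.geotransform, nodata=DEFAULT_NODATA)


def gen_virtual_species(stack: EnvStack, config: SyntheticConfig) -> VirtualSpecies:
    """True occupancy as a logistic of the first k layers.

    suitability(cell) = 1 / (1 + exp(-(b0 + sum_i bi * x_i(cell)))).
    """
    betas = tuple(float(b) for b in config.true_betas)
    k = len(betas) - 1
    if k > len(stack):
        raise ConfigurationError("more beta coefficients than stack layers")
    names = stack.names[:k]
    eta = np.full(stack.ref.shape, betas[0], dtype=np.float64)
    for b, name in zip(betas[1:], names):
        eta = eta + b * stack[name].masked()
    with np.errstate(over="ignore"):
        suit = 1.0 / (1.0 + np.exp(-eta))
    grid = stack.ref.copy_with(np.where(np.isnan(suit), DEFAULT_NODATA, suit))
    grid.nodata = DEFAULT_NODATA
    return VirtualSpecies(grid, names, betas)


def _detection_weights(
    species: VirtualSpecies, popdensity: RasterGrid, bias_exponent: float
) -> np.ndarray:
    suit = species.true_suitability.masked()
    dens = popdensity.masked()
    with np.errstate(invalid="ignore"):
        w = suit * np.power(dens, bias_exponent)
    w = np.where(np.isnan(w), 0.0, w)
    w[~species.true_suitability.valid_mask()] = 0.0
    return w


def sample_occurrence_cells(
    species: VirtualSpecies,
    popdensity: RasterGrid,
    config: SyntheticConfig,
    n: Optional[int] = None,
    replace: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Draw occurrence cell indices with probability ∝ suitability * density^a.

    Returns flat cell indices.  The with-replacement variant exists for
    statistical calibration checks only; the pipeline fixture uses
    ``replace=False``.
    """
    n = config.n_presences if n is None else n
    rng = config.rng(300) if rng is None else rng
    w = _detection_weights(species, popdensity, config.bias_exponent).ravel()
    total = w.sum()
    n_positive = int((w > 0).sum())
    if total <= 0 or (not replace and n > n_positive):
        raise SamplingError(
            f"cannot draw {n} occurrences from {n_positive} positive-weight cells"
        )
    return rng.choice(w.size, size=n, replace=replace, p=w / total)


def sample_occurrences(
    species: VirtualSpecies,
    popdensity: RasterGrid,
    config: SyntheticConfig,
) -> OccurrenceSet:
    """Draw seeded occurrence records with observer bias and breeding labels.

    Cells are drawn without replacement with weight suitability * density^a;
    record coordinates are cell centers.  A record whose cell's true
    suitability reaches ``repro_threshold`` gets one of the three
    breeding-evidence codes uniformly at random; all others are labeled
    ``none``.
    """
    rng = config.rng(300)
    flat = sample_occurrence_cells(species, popdensity, config, rng=rng)
    grid = species.true_suitability
    rows, cols = np.unravel_index(flat, grid.shape)
    lon, lat = grid.cell_center(rows, cols)
    suit = grid.values[rows, cols]
    records = []
    for i in range(flat.size):
        if suit[i] >= config.repro_threshold:
            ev = BREEDING_CODES[rng.integers(len(BREEDING_CODES))]
        else:
            ev = "none"
        records.append(
            OccurrenceRecord(
                id=f"SYN{i + 1:05d}",
                longitude=float(lon[i]),
                latitude=float(lat[i]),
                source="synthetic",
                breeding_evidence=ev,
                date=None,
            )
        )
    prov = {
        "generator": "synthetic virtual species",
        "seed": config.seed,
        "bias_exponent": config.bias_exponent,
        "n": len(records),
    }
    return OccurrenceSet(records, prov)


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    stack: EnvStack
    popdensity: RasterGrid
    species: VirtualSpecies
    occurrences: OccurrenceSet


def make_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full fixture: layers, density, species, occurrences."""
    stack = gen_env_stack(config)
    pop = gen_popdensity(config)
    species = gen_virtual_species(stack, config)
    occ = sample_occurrences(species, pop, config)
    return SyntheticDataset(config, stack, pop, species, occ)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the fixture to disk: layer grids + manifest, density grid,
    true-suitability grid, occurrence CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from .environment import write_raster

    manifest = ds.stack.write(outdir / "env")
    write_raster(ds.popdensity, outdir / "popdensity.asc")
    write_raster(ds.species.true_suitability, outdir / "true_suitability.asc")
    occ_path = outdir / "occurrences.csv"
    ds.occurrences.write_csv(occ_path)
    return {
        "stack_manifest": manifest,
        "popdensity": outdir / "popdensity.asc",
        "true_suitability": outdir / "true_suitability.asc",
        "occurrences": occ_path,
    }


# -- reference occurrence fixture ---------------------------------------

_REFERENCE_SOURCES = (
    ("WikiAves", 121),
    ("scientific article", 118),
    ("thesis/dissertation", 49),
    ("governmental report", 17),
    ("birdforum.com", 13),
    ("miscellaneous", 4),
)
_REFERENCE_N_BREEDING = 148
_REFERENCE_N_TOTAL = 322


def make_reference_occurrences(seed: int = 20160322) -> OccurrenceSet:
    """Synthetic stand-in for the deposited occurrence table.

    The full compilation of 322 georeferenced Harpy Eagle records cannot
    be redistributed here; this generator reproduces its reported
    marginals — 322 records, 148 with breeding evidence and 174 without,
    and the per-source counts — with synthetic coordinates scattered over
    the Neotropics south of 40N.  It exists so
    record-bookkeeping code paths can be exercised end-to-end; it carries
    no real eagle locations.
    """
    rng = np.random.default_rng(seed)
    sources: list[str] = []
    for name, count in _REFERENCE_SOURCES:
        sources.extend([name] * count)
    assert len(sources) == _REFERENCE_N_TOTAL
    breeding_flags = np.zeros(_REFERENCE_N_TOTAL, dtype=bool)
    breeding_flags[:_REFERENCE_N_BREEDING] = True
    rng.shuffle(breeding_flags)
    lon = rng.uniform(-82.0, -36.0, _REFERENCE_N_TOTAL)
    lat = rng.uniform(-32.0, 18.0, _REFERENCE_N_TOTAL)
    years = rng.integers(1990, 2017, _REFERENCE_N_TOTAL)
    months = rng.integers(1, 13, _REFERENCE_N_TOTAL)
    days = rng.integers(1, 29, _REFERENCE_N_TOTAL)
    records = []
    for i in range(_REFERENCE_N_TOTAL):
        if breeding_flags[i]:
            ev = BREEDING_CODES[rng.integers(len(BREEDING_CODES))]
        else:
            ev = "none"
        records.append(
            OccurrenceRecord(
                id=f"REF{i + 1:04d}",
                longitude=round(float(lon[i]), 5),
                latitude=round(float(lat[i]), 5),
                source=sources[i],
                breeding_evidence=ev,
                date=f"{years[i]:04d}-{months[i]:02d}-{days[i]:02d}",
            )
        )
    return OccurrenceSet(records, {"generator": "synthetic reference fixture", "seed": seed})
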
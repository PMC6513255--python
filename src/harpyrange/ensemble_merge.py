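"""AUC-weighted consensus and the reproductive-habitat constraint merge.

The consensus map is the per-cell weighted mean of the family maps, each
weighted by its held-out AUC.  The reproductive consensus is diffused with
an isotropic Gaussian kernel whose standard deviation encodes how far a
cell may sit from reproductive habitat and still support a breeding pair:
a home range is read as the area holding 95% of an individual's movements
(normal-quantile z = 1.96).  The default kernel SD follows the literal
published expression 25000/1.96 map units (~12.76 km); the internally
consistent alternative derives the SD from a 25 km^2 circular home range,
sqrt(25e6/pi)/1.96 (~1.44 km), and is selectable by mode.

The blurred reproductive map is then combined with the all-records
consensus; the default operator is the product, matching the conjunctive
rationale (good overall habitat AND proximity to reproductive habitat).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from .environment import AlignmentError, RasterGrid
from .sdm_models import SuitabilityMap

BLUR_MODES = ("literal", "home_range")
COMBINE_RULES = ("product", "min", "mean")


@dataclass
class BlurParams:
    """Gaussian kernel scale for the reproductive-constraint blur."""

    sd_map_units: float
    derivation: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sd_map_units <= 0:
            raise ValueError("blur SD must be positive")


def derive_blur_sd(
    mode: str = "literal",
    home_range_km2: float = 25.0,
    coverage_quantile: float = 0.95,
) -> BlurParams:
    """Derive the blur SD in map units (meters).

    literal    : 25000 / z (z the two-sided normal quantile of the home
                 range coverage; 1.96 for 95%) — the published expression
                 read in meters.
    home_range : radius of a circular home range of ``home_range_km2``
                 divided by z, i.e. sqrt(A/pi)/z.
    """
    if mode not in BLUR_MODES:
        raise ValueError(f"unknown blur mode {mode!r}; choose from {BLUR_MODES}")
    from scipy.stats import norm

    z = float(norm.ppf(0.5 + coverage_quantile / 2.0))
    if mode == "literal":
        sd = 25000.0 / z
    else:
        radius_m = math.sqrt(home_range_km2 * 1e6 / math.pi)
        sd = radius_m / z
    return BlurParams(
        sd_map_units=sd,
        derivation={
            "mode": mode,
            "home_range_km2": home_range_km2,
            "coverage_quantile": coverage_quantile,
            "z": z,
            "literal_sd_expression": "25000/1.96",
        },
    )


@dataclass
class ConsensusMap:
    grid: SuitabilityMap
    member_weights: dict[str, float]


def consensus_weighted(
    maps: Mapping[str, SuitabilityMap],
    aucs: Mapping[str, float],
) -> ConsensusMap:
    """Cell-wise AUC-weighted mean of the member maps.

    consensus = sum_i w_i m_i / sum_i w_i with w_i the member's AUC; a cell
    that is nodata in any member is nodata in the consensus, so the result
    is a true convex combination everywhere it is defined.
    """
    if len(maps) < 2:
        raise ValueError("consensus needs at least 2 member maps")
    names = list(maps)
    ref = maps[names[0]].grid
    weights = {}
    for n in names:
        if not maps[n].grid.same_grid(ref):
            raise AlignmentError(f"member map {n!r} is not co-registered")
        w = float(aucs[n])
        if not (0.0 < w <= 1.0):
            raise ValueError(f"AUC weight for {n!r} must be in (0, 1], got {w}")
        weights[n] = w

    mask = np.ones(ref.shape, dtype=bool)
    for n in names:
        mask &= maps[n].grid.valid_mask()
    num = np.zeros(ref.shape)
    for n in names:
        num += weights[n] * np.where(mask, maps[n].grid.values, 0.0)
    vals = np.where(mask, num / sum(weights.values()), ref.nodata)
    grid = ref.copy_with(vals)
    return ConsensusMap(
        grid=SuitabilityMap(grid=grid, provenance="consensus"),
        member_weights=weights,
    )


def gaussian_blur_map(
    smap: SuitabilityMap,
    params: BlurParams,
    truncate_sd: float = 4.0,
) -> SuitabilityMap:
    """Nodata-aware normalized Gaussian convolution (reflective boundary).

    Valid values (nodata treated as zero) are convolved with an isotropic
    Gaussian of SD ``sd_map_units / cell_size`` cells, truncated at
    ``truncate_sd`` SDs, and divided cell-wise by the identically blurred
    validity mask, so missing neighbours do not drag values down.  On a
    fully valid grid this reduces to a mass-preserving reflective blur.
    """
    grid = smap.grid
    _, _, csx, csy = grid.geotransform
    if not math.isclose(csx, csy, rel_tol=1e-9):
        raise ValueError("blur requires square cells")
    sd_cells = params.sd_map_units / _cell_size_m(grid)
    if sd_cells < 1e-6:
        warnings.warn("blur SD below 1e-6 cell; returning the map unchanged")
        return SuitabilityMap(grid=grid.copy_with(grid.values.copy()),
                              provenance=smap.provenance + "+blur0")
    mask = grid.valid_mask().astype(np.float64)
    filled = np.where(mask > 0, grid.values, 0.0)
    num = ndimage.gaussian_filter(filled, sigma=sd_cells, mode="reflect",
                                  truncate=truncate_sd)
    den = ndimage.gaussian_filter(mask, sigma=sd_cells, mode="reflect",
                                  truncate=truncate_sd)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out = np.where(mask > 0, out, grid.nodata)
    return SuitabilityMap(grid=grid.copy_with(out),
                          provenance=smap.provenance + "+blur")


def _cell_size_m(grid: RasterGrid) -> float:
    """Cell edge length in meters: geographic grids (degree cells) are
    converted at the equatorial scale used by the synthetic generators."""
    from .synthetic_data import METERS_PER_DEGREE

    cs = grid.geotransform[2]
    if grid.crs.upper() in {"EPSG:4326", "WGS84", "CRS:84"}:
        return cs * METERS_PER_DEGREE
    return cs


def combine_final(
    all_records: ConsensusMap,
    repro_blurred: SuitabilityMap,
    rule: str = "product",
) -> SuitabilityMap:
    """Merge the all-records consensus with the blurred reproductive map.

    product (default): final = all_records * repro_blurred — conjunctive;
    min and mean are selectable alternatives.  Nodata in either input is
    nodata in the result.
    """
    if rule not in COMBINE_RULES:
        raise ValueError(f"unknown combine rule {rule!r}; choose from {COMBINE_RULES}")
    a = all_records.grid.grid
    b = repro_blurred.grid
    if not a.same_grid(b):
        raise AlignmentError("consensus and reproductive maps are not co-registered")
    mask = a.valid_mask() & b.valid_mask()
    if rule == "product":
        vals = a.values * b.values
    elif rule == "min":
        vals = np.minimum(a.values, b.values)
    else:
        vals = 0.5 * (a.values + b.values)
    out = np.where(mask, vals, a.nodata)
    return SuitabilityMap(grid=a.copy_with(out), provenance=f"final:{rule}")
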
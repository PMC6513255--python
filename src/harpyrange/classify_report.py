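"""Binarization at the equal-sensitivity/specificity threshold, range-area
arithmetic, and a sampling-bias diagnostic.

The continuous final map is cut into presence/absence at the score t where
the true-positive rate on evaluation presences best matches the
true-negative rate on pseudo-absences.  Range area is presence-cell count
times cell area; the percent reduction against a reference range (e.g. an
assessment polygon area) is 100 * (1 - area/reference).

The bias diagnostic is this package's own generic check — the Spearman
correlation between predicted suitability and human population density,
overall and within each point class, with a seeded permutation null.  It
does not reproduce any particular published bias test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import spearmanr

from .environment import RasterGrid
from .sdm_models import SuitabilityMap


class ThresholdError(ValueError):
    pass


@dataclass
class BinaryRangeMap:
    grid: RasterGrid  # values 0/1/nodata
    threshold: float
    sensitivity_at_t: float
    specificity_at_t: float


@dataclass
class RangeReport:
    area_km2: float
    n_presence_cells: int
    cell_area_km2: float
    reference_area_km2: Optional[float] = None
    percent_reduction: Optional[float] = None
    percent_reduction_int: Optional[int] = None


def _sens_spec(t: float, pres: np.ndarray, abse: np.ndarray) -> tuple[float, float]:
    sens = float((pres >= t).mean())
    spec = float((abse < t).mean())
    return sens, spec


def threshold_equal_ss(presence_scores, absence_scores) -> tuple[float, float, float]:
    """Score threshold equalizing sensitivity and specificity.

    Candidates are every distinct observed score plus the midpoints
    between consecutive distinct scores; the returned t minimizes
    |sens(t) - spec(t)| with sens = P(presence score >= t) and
    spec = P(absence score < t); ties go to the smallest t.

    Returns (t, sensitivity, specificity).
    """
    pres = np.asarray(presence_scores, dtype=np.float64)
    abse = np.asarray(absence_scores, dtype=np.float64)
    if pres.size == 0 or abse.size == 0:
        raise ThresholdError("both classes must be present")
    values = np.unique(np.concatenate([pres, abse]))
    if values.size < 2:
        raise ThresholdError("degenerate single-valued scores")
    mids = 0.5 * (values[:-1] + values[1:])
    candidates = np.sort(np.concatenate([values, mids]))
    best_t, best_gap, best_ss = None, np.inf, (np.nan, np.nan)
    for t in candidates:
        sens, spec = _sens_spec(t, pres, abse)
        gap = abs(sens - spec)
        if gap < best_gap - 1e-15:
            best_t, best_gap, best_ss = float(t), gap, (sens, spec)
    return best_t, best_ss[0], best_ss[1]


def binarize(final: SuitabilityMap, t: float) -> BinaryRangeMap:
    """Presence where score >= t (closed on the presence side); nodata kept."""
    if not (0.0 < t < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    grid = final.grid
    mask = grid.valid_mask()
    vals = np.where(mask, (grid.values >= t).astype(np.float64), grid.nodata)
    return BinaryRangeMap(
        grid=grid.copy_with(vals),
        threshold=float(t),
        sensitivity_at_t=float("nan"),
        specificity_at_t=float("nan"),
    )


def percent_reduction(area_km2: float, reference_area_km2: float) -> float:
    """100 * (1 - area / reference)."""
    if reference_area_km2 <= 0:
        raise ValueError("reference area must be positive")
    return 100.0 * (1.0 - area_km2 / reference_area_km2)


def range_area(
    bmap: BinaryRangeMap,
    cell_area_km2: float,
    reference_area_km2: Optional[float] = None,
) -> RangeReport:
    """Total presence-cell area; optionally the reduction vs a reference."""
    if cell_area_km2 <= 0:
        raise ValueError("cell area must be positive")
    mask = bmap.grid.valid_mask()
    n1 = int((bmap.grid.values[mask] == 1).sum())
    area = n1 * cell_area_km2
    report = RangeReport(area_km2=area, n_presence_cells=n1, cell_area_km2=cell_area_km2)
    if reference_area_km2 is not None:
        pr = percent_reduction(area, reference_area_km2)
        report.reference_area_km2 = reference_area_km2
        report.percent_reduction = round(pr, 1)
        report.percent_reduction_int = int(round(pr))
    return report


def bias_diagnostic(
    final: SuitabilityMap,
    popdensity: RasterGrid,
    presence_cells: Optional[np.ndarray] = None,
    absence_cells: Optional[np.ndarray] = None,
    n_permutations: int = 999,
    seed: int = 0,
) -> dict:
    """Suitability-density correlation screen with a permutation null.

    Reports the Spearman correlation between predicted suitability and
    population density over all jointly valid cells, the same correlation
    restricted to the presence and pseudo-absence cells (row/col integer
    arrays of shape (n, 2)), and a seeded permutation p-value for the
    overall correlation.  Zero-variance inputs report correlation 0 with a
    ``degenerate`` flag.
    """
    grid = final.grid
    if not grid.same_grid(popdensity):
        raise ValueError("suitability and density are not co-registered")
    mask = grid.valid_mask() & popdensity.valid_mask()
    s = grid.values[mask]
    d = popdensity.values[mask]

    def safe_spearman(a, b):
        if a.size < 3 or np.all(a == a[0]) or np.all(b == b[0]):
            return 0.0, True
        rho = spearmanr(a, b).statistic
        return (0.0, True) if np.isnan(rho) else (float(rho), False)

    rho_all, degenerate = safe_spearman(s, d)
    rng = np.random.default_rng(seed)
    if degenerate:
        p_value = 1.0
    else:
        exceed = 0
        for _ in range(n_permutations):
            rho_p, _ = safe_spearman(s, rng.permutation(d))
            if abs(rho_p) >= abs(rho_all):
                exceed += 1
        p_value = (exceed + 1) / (n_permutations + 1)

    report = {
        "spearman_all_cells": rho_all,
        "p_value_permutation": float(p_value),
        "n_permutations": n_permutations,
        "n_cells": int(s.size),
        "degenerate": degenerate,
    }
    for label, cells in (("presence", presence_cells), ("pseudo_absence", absence_cells)):
        if cells is not None and len(cells) > 0:
            cells = np.asarray(cells, dtype=int)
            sv = grid.values[cells[:, 0], cells[:, 1]]
            dv = popdensity.values[cells[:, 0], cells[:, 1]]
            rho, deg = safe_spearman(sv, dv)
            report[f"spearman_{label}_cells"] = rho
            report[f"degenerate_{label}"] = deg
    return report
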
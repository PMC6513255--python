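"""Raster stack management for gridded environmental predictors.

Rasters are single-band, north-up grids with a geotransform
``(origin_x, origin_y, cell_size_x, cell_size_y)`` where the origin is the
north-west corner and both cell sizes are positive.  On-disk format is the
ESRI ASCII grid (plain text), which round-trips float64 values exactly via
17-significant-digit formatting; a JSON manifest carries layer names, the
geotransform, the CRS string and the nodata sentinel for a whole stack.

Cell membership uses half-open intervals [west, east) x (south, north]: a
point on a cell's west or north edge belongs to that cell.  This convention
is applied consistently by point extraction and the synthetic generators.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_NODATA = -9999.0
DEFAULT_CRS = "EPSG:4326"


class RasterError(ValueError):
    """Raised for malformed rasters or I/O format problems."""


class AlignmentError(RasterError):
    """Raised when layers that must share a grid do not."""


@dataclass
class RasterGrid:
    """A single-band grid of float64 values with georeferencing.

    ``values`` holds the nodata sentinel at invalid cells; use
    :meth:`valid_mask` / :meth:`masked` for computation.
    """

    values: np.ndarray
    geotransform: tuple[float, float, float, float]
    crs: str = DEFAULT_CRS
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise RasterError(f"raster values must be 2-D, got {self.values.ndim}-D")
        ox, oy, csx, csy = self.geotransform
        if csx == 0 or csy == 0:
            raise RasterError("geotransform cell sizes must be nonzero")
        if csx < 0 or csy < 0:
            raise RasterError("north-up convention requires positive cell sizes")
        self.geotransform = (float(ox), float(oy), float(csx), float(csy))

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds a real value."""
        with np.errstate(invalid="ignore"):
            return (self.values != self.nodata) & ~np.isnan(self.values)

    def masked(self) -> np.ndarray:
        """Values with nodata cells replaced by NaN."""
        out = self.values.copy()
        out[~self.valid_mask()] = np.nan
        return out

    def same_grid(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return self.shape == other.shape and all(
            math.isclose(a, b, rel_tol=0, abs_tol=tol)
            for a, b in zip(self.geotransform, other.geotransform)
        )

    # -- coordinate arithmetic -------------------------------------------

    def cell_center(self, row: np.ndarray | int, col: np.ndarray | int):
        ox, oy, csx, csy = self.geotransform
        x = ox + (np.asarray(col) + 0.5) * csx
        y = oy - (np.asarray(row) + 0.5) * csy
        return x, y

    def cell_index(self, x: np.ndarray | float, y: np.ndarray | float):
        """Map coordinates to (row, col) under the half-open convention.

        Out-of-extent points get index -1 in the offending dimension.
        """
        ox, oy, csx, csy = self.geotransform
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        col = np.floor((x - ox) / csx).astype(np.int64)
        row = np.floor((oy - y) / csy).astype(np.int64)
        # north edge inclusive: y exactly on a row boundary belongs to the
        # row whose north edge it is, which floor() already yields; the
        # grid's own north edge maps to row 0.
        row = np.where(np.asarray(y) == oy, 0, row)
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        col = np.where(bad, -1, col)
        row = np.where(bad, -1, row)
        return row, col

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        return RasterGrid(np.asarray(values, dtype=np.float64), self.geotransform, self.crs, self.nodata)


# -- ESRI ASCII grid I/O -------------------------------------------------


def write_raster(grid: RasterGrid, path: str | Path) -> None:
    """Write a grid as an ESRI ASCII file (square cells required)."""
    ox, oy, csx, csy = grid.geotransform
    if not math.isclose(csx, csy, rel_tol=1e-12):
        raise RasterError("ESRI ASCII grids require square cells")
    yll = oy - grid.n_rows * csy
    lines = [
        f"ncols {grid.n_cols}",
        f"nrows {grid.n_rows}",
        f"xllcorner {ox!r}",
        f"yllcorner {yll!r}",
        f"cellsize {csx!r}",
        f"NODATA_value {grid.nodata!r}",
    ]
    body = "\n".join(" ".join(f"{v:.17g}" for v in row) for row in grid.values)
    Path(path).write_text("\n".join(lines) + "\n" + body + "\n")


def read_raster(path: str | Path, crs: str = DEFAULT_CRS) -> RasterGrid:
    """Read an ESRI ASCII grid; values round-trip float64 exactly."""
    text = Path(path).read_text().split("\n")
    header: dict[str, float] = {}
    i = 0
    while i < len(text):
        parts = text[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
            "nodata_value", "xllcenter", "yllcenter",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise RasterError(f"not an ESRI ASCII grid (missing {req}): {path}")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    cs = header["cellsize"]
    if "xllcorner" in header:
        xll, yll = header["xllcorner"], header["yllcorner"]
    else:  # cell-center registration
        xll, yll = header["xllcenter"] - cs / 2, header["yllcenter"] - cs / 2
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    values = np.loadtxt(text[i:], dtype=np.float64, ndmin=2)
    if values.shape != (n_rows, n_cols):
        raise RasterError(
            f"grid body {values.shape} does not match header ({n_rows}, {n_cols})"
        )
    gt = (xll, yll + n_rows * cs, cs, cs)
    return RasterGrid(values, gt, crs=crs, nodata=nodata)


@dataclass
class EnvStack:
    """Ordered, co-registered map of named environmental layers."""

    layers: dict[str, RasterGrid] = field(default_factory=dict)

    def add(self, name: str, grid: RasterGrid) -> None:
        if self.layers:
            ref = next(iter(self.layers.values()))
            if not grid.same_grid(ref):
                raise AlignmentError(
                    f"layer {name!r} is not co-registered with the stack"
                )
            if grid.crs != ref.crs:
                raise AlignmentError(f"layer {name!r} has CRS {grid.crs}, stack has {ref.crs}")
        self.layers[name] = grid

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def ref(self) -> RasterGrid:
        if not self.layers:
            raise RasterError("empty stack")
        return next(iter(self.layers.values()))

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> RasterGrid:
        return self.layers[name]

    def valid_mask(self) -> np.ndarray:
        """Combined validity: a cell is valid only if valid in every layer."""
        mask = np.ones(self.ref.shape, dtype=bool)
        for g in self.layers.values():
            mask &= g.valid_mask()
        return mask

    def to_array(self) -> np.ndarray:
        """(n_layers, n_rows, n_cols) array with NaN at nodata cells."""
        return np.stack([g.masked() for g in self.layers.values()])

    def table(self) -> pd.DataFrame:
        """All jointly-valid cells as rows; columns are layer names plus
        ``row``/``col`` indices."""
        mask = self.valid_mask()
        rr, cc = np.nonzero(mask)
        data = {name: g.values[rr, cc] for name, g in self.layers.items()}
        df = pd.DataFrame(data)
        df["row"], df["col"] = rr, cc
        return df

    # -- persistence -----------------------------------------------------

    def write(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        ref = self.ref
        manifest = {
            "layers": self.names,
            "files": {n: f"{n}.asc" for n in self.names},
            "geotransform": list(ref.geotransform),
            "crs": ref.crs,
            "nodata": ref.nodata,
        }
        for name, grid in self.layers.items():
            write_raster(grid, directory / f"{name}.asc")
        mpath = directory / "stack.json"
        mpath.write_text(json.dumps(manifest, indent=1))
        return mpath

    @classmethod
    def read(cls, manifest_path: str | Path) -> "EnvStack":
        manifest_path = Path(manifest_path)
        if manifest_path.is_dir():
            manifest_path = manifest_path / "stack.json"
        meta = json.loads(manifest_path.read_text())
        stack = cls()
        for name in meta["layers"]:
            grid = read_raster(manifest_path.parent / meta["files"][name], crs=meta["crs"])
            grid.nodata = float(meta["nodata"])
            stack.add(name, grid)
        return stack


# -- study-area clip -----------------------------------------------------


def clip_study_area(stack: EnvStack, max_lat: float = 40.0) -> EnvStack:
    """Mask every cell whose center latitude exceeds ``max_lat`` degrees.

    The grid shape is preserved; clipped cells become nodata in every
    layer.  Intended for geographic (lon/lat) stacks.
    """
    out = EnvStack()
    ref = stack.ref
    rows = np.arange(ref.n_rows)
    _, lat = ref.cell_center(rows, np.zeros_like(rows))
    kill = lat > max_lat
    for name, grid in stack.layers.items():
        vals = grid.values.copy()
        vals[kill, :] = grid.nodata
        out.add(name, grid.copy_with(vals))
    return out


# -- point extraction ----------------------------------------------------


def extract_values(
    stack: EnvStack,
    points,
) -> tuple[pd.DataFrame, dict]:
    """Extract per-layer values at point locations.

    Parameters
    ----------
    points
        Either an object with ``.records`` (each having ``longitude`` and
        ``latitude``), an (n, 2) array of lon/lat, or a DataFrame with
        ``longitude``/``latitude`` columns.

    Returns
    -------
    (X, log)
        ``X`` is a DataFrame of layer values whose index is the position of
        each surviving point in the input order; points outside the extent
        or in nodata cells are excluded and counted in ``log``.  ``X`` also
        carries ``row``/``col`` cell indices.
    """
    if hasattr(points, "records"):
        lon = np.array([r.longitude for r in points.records], dtype=np.float64)
        lat = np.array([r.latitude for r in points.records], dtype=np.float64)
    elif isinstance(points, pd.DataFrame):
        lon = points["longitude"].to_numpy(dtype=np.float64)
        lat = points["latitude"].to_numpy(dtype=np.float64)
    else:
        pts = np.asarray(points, dtype=np.float64)
        lon, lat = pts[:, 0], pts[:, 1]

    ref = stack.ref
    row, col = ref.cell_index(lon, lat)
    in_extent = row >= 0
    mask = stack.valid_mask()
    ok = in_extent.copy()
    ok[in_extent] = mask[row[in_extent], col[in_extent]]

    idx = np.nonzero(ok)[0]
    data = {name: g.values[row[idx], col[idx]] for name, g in stack.layers.items()}
    X = pd.DataFrame(data, index=idx)
    X["row"], X["col"] = row[idx], col[idx]
    log = {
        "n_points": int(lon.size),
        "n_extracted": int(idx.size),
        "n_outside_extent": int((~in_extent).sum()),
        "n_nodata": int((in_extent & ~ok).sum()),
    }
    return X, log


# -- correlated-variable pruning ----------------------------------------


@dataclass
class VariableSelection:
    """Result of the PCA-ranked greedy correlation screen."""

    retained: list[str]
    scan_order: list[str]
    correlation_matrix: pd.DataFrame
    r_threshold: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "retained": self.retained,
                    "scan_order": self.scan_order,
                    "r_threshold": self.r_threshold,
                    "correlation_matrix": self.correlation_matrix.round(10).to_dict(),
                },
                indent=1,
            )
        )


def select_variables_pca(X: pd.DataFrame, r_threshold: float = 0.7) -> VariableSelection:
    """Prune mutually correlated predictors via a PCA-guided greedy scan.

    A principal component analysis is run on the standardized screening
    sample (typically the environmental values of presences plus
    pseudo-absences).  Each variable is ranked by the eigenvalue of the
    component on which it attains its maximum absolute loading (descending;
    ties broken by |loading|, then input order).  Scanning variables in that
    order, a variable is retained iff its Pearson |r| with every
    already-retained variable does not exceed ``r_threshold`` (strictly
    greater than the threshold excludes).
    """
    X = pd.DataFrame(X).copy()
    X = X.dropna(axis=0)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 columns to screen")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 complete rows to screen")

    sd = X.std(axis=0, ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"excluding constant columns before PCA: {constant}")
        X = X.drop(columns=constant)
        if X.shape[1] < 2:
            raise ValueError("fewer than 2 non-constant columns")

    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    # PCA by SVD of the standardized matrix; eigenvalues of the correlation
    # matrix are singular values squared over (n - 1).
    _, s, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    eigvals = s**2 / (Z.shape[0] - 1)
    loadings = Vt  # component x variable

    names = list(X.columns)
    best_pc = np.abs(loadings).argmax(axis=0)  # per variable
    rank_key = []
    for j, name in enumerate(names):
        pc = best_pc[j]
        rank_key.append((-eigvals[pc], -abs(loadings[pc, j]), j))
    order = sorted(range(len(names)), key=lambda j: rank_key[j])
    scan_order = [names[j] for j in order]

    corr = X.corr(method="pearson")
    retained: list[str] = []
    for name in scan_order:
        if all(abs(corr.loc[name, kept]) <= r_threshold for kept in retained):
            retained.append(name)
    return VariableSelection(retained, scan_order, corr, r_threshold)
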
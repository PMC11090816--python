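"""Equal-area grid data model and raster/tabular IO.

The whole pipeline works on a rectangular equal-area grid (cells of
``cell_size`` km on a side, row 0 at the north/top, row-major order).
Because cells have equal area, area fractions reported downstream are
simple cell-count fractions.

Rasters are exchanged in two plain formats:

* NetCDF (via xarray's scipy backend): variables ``tmin, tmean, tmax,
  precip, rad`` with a 12-long ``month`` dimension plus static ``fc, wp``
  and an integer ``land_mask``; grid metadata and CO2 live in global
  attributes.
* Multiband TIFF: 62 bands in the fixed order tmin1..12, tmean1..12,
  tmax1..12, precip1..12, rad1..12, fc, wp, with a JSON sidecar
  (``<path>.json``) carrying grid metadata, the land mask and CO2.

Occurrence tables are CSV with columns ``species_id, x, y``; the
growth-form lookup is CSV with columns ``species_id, growth_form``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .exceptions import EmptyPoolError, FormatError, ValidationError

__all__ = [
    "Grid",
    "Climatology",
    "MONTH_VARS",
    "read_climatology",
    "write_climatology",
    "aggregate_grid",
    "aggregate_climatology",
    "apply_land_mask",
    "read_occurrences",
    "write_occurrences",
    "read_growth_forms",
    "write_growth_forms",
]

#: monthly forcing variables, in canonical band order
MONTH_VARS = ("tmin", "tmean", "tmax", "precip", "rad")
STATIC_VARS = ("fc", "wp")

DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], float)


@dataclass(frozen=True)
class Grid:
    """Rectangular equal-area grid.

    ``origin`` is the (x, y) of the upper-left corner of cell (0, 0) in
    projected km; y decreases southward, so the center of cell
    ``(r, c)`` is ``(origin_x + (c + .5) * cell_size,
    origin_y - (r + .5) * cell_size)``.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    land_mask: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValidationError("grid must have at least one row and column")
        if not self.cell_size > 0:
            raise ValidationError("cell_size must be positive")
        mask = self.land_mask
        if mask is None:
            mask = np.ones((self.n_rows, self.n_cols), bool)
        mask = np.asarray(mask, bool)
        if mask.shape != (self.n_rows, self.n_cols):
            raise ValidationError(
                f"land_mask shape {mask.shape} != grid shape {self.shape}"
            )
        object.__setattr__(self, "land_mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_land(self) -> int:
        return int(self.land_mask.sum())

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates as (n_rows, n_cols) arrays, in km."""
        ox, oy = self.origin
        x = ox + (np.arange(self.n_cols) + 0.5) * self.cell_size
        y = oy - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.broadcast_to(x, self.shape).copy(), np.broadcast_to(
            y[:, None], self.shape
        ).copy()

    def cell_of_xy(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map projected coordinates to (row, col); out-of-grid points get -1."""
        ox, oy = self.origin
        col = np.floor((np.asarray(x, float) - ox) / self.cell_size).astype(int)
        row = np.floor((oy - np.asarray(y, float)) / self.cell_size).astype(int)
        bad = (row < 0) | (row >= self.n_rows) | (col < 0) | (col >= self.n_cols)
        row = np.where(bad, -1, row)
        col = np.where(bad, -1, col)
        return row, col


@dataclass
class Climatology:
    """Monthly climate forcing plus static soil properties and scalar CO2.

    Monthly layers have shape (12, n_rows, n_cols); ``field_capacity``
    and ``wilting_point`` are static (n_rows, n_cols) layers in mm of
    plant-available water column; ``co2`` is scenario metadata in ppm.
    """

    grid: Grid
    tmin: np.ndarray
    tmean: np.ndarray
    tmax: np.ndarray
    precip: np.ndarray
    rad: np.ndarray
    field_capacity: np.ndarray
    wilting_point: np.ndarray
    co2: float = 338.0

    def __post_init__(self) -> None:
        shp = (12, *self.grid.shape)
        for name in MONTH_VARS:
            arr = np.asarray(getattr(self, self._attr(name)), float)
            if arr.shape != shp:
                raise ValidationError(f"{name} has shape {arr.shape}, expected {shp}")
            setattr(self, self._attr(name), arr)
        for name in ("field_capacity", "wilting_point"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != self.grid.shape:
                raise ValidationError(
                    f"{name} has shape {arr.shape}, expected {self.grid.shape}"
                )
            setattr(self, name, arr)
        self.co2 = float(self.co2)

    @staticmethod
    def _attr(var: str) -> str:
        return var

    def validate(self) -> None:
        """Raise ValidationError listing offending cells on invariant breaks."""
        m = self.grid.land_mask
        def bad_cells(cond3d):
            viol = cond3d & m  # broadcast over months
            if viol.any():
                rows, cols = np.nonzero(viol.any(axis=0))
                return list(zip(rows.tolist(), cols.tolist()))[:10]
            return None

        if self.co2 <= 0:
            raise ValidationError("co2 must be positive")
        cells = bad_cells((self.tmin > self.tmean) | (self.tmean > self.tmax))
        if cells:
            raise ValidationError(f"tmin <= tmean <= tmax violated at cells {cells}")
        cells = bad_cells(self.precip < 0)
        if cells:
            raise ValidationError(f"negative precipitation at cells {cells}")
        cells = bad_cells(self.rad < 0)
        if cells:
            raise ValidationError(f"negative radiation at cells {cells}")
        soil_bad = ((self.wilting_point < 0) | (self.wilting_point > self.field_capacity)) & m
        if soil_bad.any():
            rows, cols = np.nonzero(soil_bad)
            raise ValidationError(
                "0 <= wilting_point <= field_capacity violated at cells "
                f"{list(zip(rows.tolist(), cols.tolist()))[:10]}"
            )


# ---------------------------------------------------------------------------
# raster IO

def write_climatology(clim: Climatology, path: str | Path, format: str | None = None) -> Path:
    """Write a climatology to NetCDF or multiband TIFF (inferred from suffix)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "netcdf":
        _write_netcdf(clim, path)
    elif fmt == "geotiff":
        _write_tiff(clim, path)
    else:
        raise FormatError(f"unknown raster format {fmt!r}")
    return path


def read_climatology(path: str | Path, format: str | None = None,
                     co2: float | None = None) -> Climatology:
    """Read a climatology; ``co2`` overrides/supplies the scalar when the
    file carries none (sidecar-config case)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "netcdf":
        clim = _read_netcdf(path, co2)
    elif fmt == "geotiff":
        clim = _read_tiff(path, co2)
    else:
        raise FormatError(f"unknown raster format {fmt!r}")
    clim.validate()
    return clim


def _infer_format(path: Path) -> str:
    if path.suffix in {".nc", ".cdf", ".netcdf"}:
        return "netcdf"
    if path.suffix in {".tif", ".tiff"}:
        return "geotiff"
    raise FormatError(f"cannot infer raster format from suffix {path.suffix!r}")


def _grid_attrs(grid: Grid) -> dict:
    return {
        "cell_size_km": grid.cell_size,
        "origin_x": grid.origin[0],
        "origin_y": grid.origin[1],
    }


def _write_netcdf(clim: Climatology, path: Path) -> None:
    data = {
        name: (("month", "y", "x"), getattr(clim, name)) for name in MONTH_VARS
    }
    data["fc"] = (("y", "x"), clim.field_capacity)
    data["wp"] = (("y", "x"), clim.wilting_point)
    data["land_mask"] = (("y", "x"), clim.grid.land_mask.astype(np.int8))
    ds = xr.Dataset(data, coords={"month": np.arange(1, 13)})
    ds.attrs.update(_grid_attrs(clim.grid))
    ds.attrs["co2_ppm"] = clim.co2
    ds.to_netcdf(path, engine="scipy")


def _read_netcdf(path: Path, co2: float | None) -> Climatology:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    for name in MONTH_VARS:
        if name not in ds:
            raise FormatError(f"missing variable {name!r} in {path}")
        if ds[name].sizes.get("month", 0) != 12:
            got = ds[name].sizes.get("month", 0)
            raise FormatError(f"{name} month {got + 1}: expected 12 monthly bands")
    for name in STATIC_VARS:
        if name not in ds:
            raise FormatError(f"missing static variable {name!r} in {path}")
    n_rows = ds.sizes["y"]
    n_cols = ds.sizes["x"]
    mask = (
        ds["land_mask"].values.astype(bool)
        if "land_mask" in ds
        else np.ones((n_rows, n_cols), bool)
    )
    grid = Grid(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=float(ds.attrs.get("cell_size_km", 1.0)),
        origin=(float(ds.attrs.get("origin_x", 0.0)), float(ds.attrs.get("origin_y", 0.0))),
        land_mask=mask,
    )
    if co2 is None:
        if "co2_ppm" not in ds.attrs:
            raise FormatError(f"{path} carries no co2_ppm attribute and none was supplied")
        co2 = float(ds.attrs["co2_ppm"])
    return Climatology(
        grid=grid,
        tmin=ds["tmin"].values, tmean=ds["tmean"].values, tmax=ds["tmax"].values,
        precip=ds["precip"].values, rad=ds["rad"].values,
        field_capacity=ds["fc"].values, wilting_point=ds["wp"].values,
        co2=co2,
    )


def _write_tiff(clim: Climatology, path: Path) -> None:
    import tifffile

    bands = np.concatenate(
        [getattr(clim, name) for name in MONTH_VARS]
        + [clim.field_capacity[None], clim.wilting_point[None]],
        axis=0,
    ).astype(np.float64)
    tifffile.imwrite(path, bands)
    sidecar = {
        **_grid_attrs(clim.grid),
        "co2_ppm": clim.co2,
        "band_order": [f"{v}{m}" for v in MONTH_VARS for m in range(1, 13)] + list(STATIC_VARS),
        "land_mask": clim.grid.land_mask.astype(int).tolist(),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar))


def _read_tiff(path: Path, co2: float | None) -> Climatology:
    import tifffile

    bands = np.asarray(tifffile.imread(path), float)
    if bands.ndim != 3:
        raise FormatError(f"{path}: expected a multiband raster")
    expected = 12 * len(MONTH_VARS) + len(STATIC_VARS)
    if bands.shape[0] != expected:
        # figure out which variable/month is missing for the error message
        n = bands.shape[0]
        var_idx = min(n // 12, len(MONTH_VARS) - 1)
        raise FormatError(
            f"{path}: {n} bands, expected {expected}; first missing band is "
            f"{MONTH_VARS[var_idx]} month {n - var_idx * 12 + 1 if n < 60 else 12}"
        )
    sidecar_path = Path(str(path) + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    n_rows, n_cols = bands.shape[1:]
    mask = np.asarray(meta.get("land_mask", np.ones((n_rows, n_cols))), bool)
    grid = Grid(
        n_rows=n_rows, n_cols=n_cols,
        cell_size=float(meta.get("cell_size_km", 1.0)),
        origin=(float(meta.get("origin_x", 0.0)), float(meta.get("origin_y", 0.0))),
        land_mask=mask,
    )
    if co2 is None:
        if "co2_ppm" not in meta:
            raise FormatError(f"{path} sidecar carries no co2_ppm and none was supplied")
        co2 = float(meta["co2_ppm"])
    layers = {name: bands[i * 12:(i + 1) * 12] for i, name in enumerate(MONTH_VARS)}
    return Climatology(
        grid=grid, **{
            "tmin": layers["tmin"], "tmean": layers["tmean"], "tmax": layers["tmax"],
            "precip": layers["precip"], "rad": layers["rad"],
        },
        field_capacity=bands[60], wilting_point=bands[61], co2=co2,
    )


# ---------------------------------------------------------------------------
# aggregation and masking

def aggregate_grid(layer: np.ndarray, factor: int,
                   mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Block-mean a fine layer onto a coarse grid.

    Each coarse cell is the mean of its ``factor x factor`` block over
    land cells only; an all-sea block comes back masked (NaN). Fine
    grids not divisible by ``factor`` are padded with masked cells at
    the south/east edges. Returns ``(coarse_layer, coarse_land_mask)``.
    """
    if int(factor) != factor or factor <= 0:
        raise ValueError("aggregation factor must be a positive integer")
    factor = int(factor)
    layer = np.asarray(layer, float)
    if layer.ndim != 2:
        raise ValueError("aggregate_grid expects a single 2-D layer")
    if mask is None:
        mask = np.ones(layer.shape, bool)
    mask = np.asarray(mask, bool)
    if mask.shape != layer.shape:
        raise ValueError("layer and mask shapes differ")

    nr, nc = layer.shape
    pr = (-nr) % factor
    pc = (-nc) % factor
    if pr or pc:
        layer = np.pad(layer, ((0, pr), (0, pc)), constant_values=np.nan)
        mask = np.pad(mask, ((0, pr), (0, pc)), constant_values=False)
    nr, nc = layer.shape
    blk = layer.reshape(nr // factor, factor, nc // factor, factor)
    mblk = mask.reshape(nr // factor, factor, nc // factor, factor)
    counts = mblk.sum(axis=(1, 3))
    sums = np.where(mblk, blk, 0.0).sum(axis=(1, 3))
    with np.errstate(invalid="ignore"):
        coarse = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return coarse, counts > 0


def aggregate_climatology(clim: Climatology, factor: int) -> Climatology:
    """Aggregate every layer of a climatology by block means over land."""
    mask = clim.grid.land_mask

    def agg_stack(stack):
        out = [aggregate_grid(stack[m], factor, mask)[0] for m in range(stack.shape[0])]
        return np.stack(out)

    fc, coarse_mask = aggregate_grid(clim.field_capacity, factor, mask)
    wp, _ = aggregate_grid(clim.wilting_point, factor, mask)
    grid = Grid(
        n_rows=coarse_mask.shape[0], n_cols=coarse_mask.shape[1],
        cell_size=clim.grid.cell_size * factor, origin=clim.grid.origin,
        land_mask=coarse_mask,
    )
    return Climatology(
        grid=grid,
        tmin=agg_stack(clim.tmin), tmean=agg_stack(clim.tmean), tmax=agg_stack(clim.tmax),
        precip=agg_stack(clim.precip), rad=agg_stack(clim.rad),
        field_capacity=fc, wilting_point=wp, co2=clim.co2,
    )


def apply_land_mask(layer: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Set sea cells to NaN so they drop out of downstream statistics."""
    layer = np.asarray(layer, float)
    mask = np.asarray(mask, bool)
    if layer.shape[-2:] != mask.shape:
        raise ValueError(f"layer shape {layer.shape} incompatible with mask {mask.shape}")
    return np.where(mask, layer, np.nan)


def land_pool(layer: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Flatten the land cells of a layer; raises EmptyPoolError when none."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise EmptyPoolError("empty pool: land mask excludes every cell")
    return np.asarray(layer)[..., mask]


# ---------------------------------------------------------------------------
# tabular IO

def read_occurrences(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"species_id", "x", "y"} - set(df.columns)
    if missing:
        raise FormatError(f"occurrence table missing columns {sorted(missing)}")
    return df


def write_occurrences(df: pd.DataFrame, path: str | Path) -> Path:
    df.to_csv(path, index=False, columns=["species_id", "x", "y"])
    return Path(path)


def read_growth_forms(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"species_id", "growth_form"} - set(df.columns)
    if missing:
        raise FormatError(f"growth-form table missing columns {sorted(missing)}")
    return df


def write_growth_forms(df: pd.DataFrame, path: str | Path) -> Path:
    df.to_csv(path, index=False, columns=["species_id", "growth_form"])
    return Path(path)
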
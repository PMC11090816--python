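"""Synthetic worlds: climatologies, future scenarios and virtual species.

The generator emulates the statistical structure of the real inputs the
pipeline is designed for (gridded monthly climatologies, species
occurrence points, a growth-form lookup) so that every downstream stage
can be exercised and validated without external data:

* temperature falls off with latitude and its seasonal amplitude grows
  poleward (hemispheres in antiphase);
* precipitation is a smooth spatially autocorrelated field with
  seasonality; solar radiation is a deterministic function of latitude
  band and month; soils are spatially autocorrelated with wp <= fc;
* virtual species carry known growth-model parameters anchored to the
  climate of a random land cell, so their true suitability maps are
  non-empty, and occurrences are sampled only from truly suitable cells.

All randomness flows through explicit integer seeds; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .exceptions import ValidationError
from .grids import Climatology, Grid
from .soil import simulate_soil_moisture
from .ttr import DEFAULT_CONSTANTS, TTRConstants, TTRParams, simulate_biomass_batch, uptake_ceiling

__all__ = [
    "GROWTH_FORMS",
    "ScenarioSpec",
    "VirtualSpecies",
    "generate_climatology",
    "generate_future",
    "generate_species",
    "occurrences_frame",
    "growth_form_frame",
]

#: the 14 plant growth forms used throughout
GROWTH_FORMS = (
    "evergreen_tree",
    "dry_deciduous_tree",
    "cold_deciduous_tree",
    "needleleaf_tree",
    "evergreen_shrub",
    "dry_deciduous_shrub",
    "cold_deciduous_shrub",
    "therophyte",
    "geophyte",
    "forb",
    "c3_grass",
    "c4_grass",
    "succulent",
    "climber",
)

AMBIENT_CO2 = 338.0
#: scenario CO2 concentrations (ppm): reduced- and high-emission pathways
RCP26_CO2 = 438.0
RCP85_CO2 = 677.0


@dataclass(frozen=True)
class ScenarioSpec:
    """A future-climate scenario: uniform warming, a precipitation scale
    factor, a CO2 level and one pseudo-GCM realization per ``gcm_seed``.

    The pseudo-GCM ensemble is a shared delta plus seeded spatially
    smooth noise (``temp_noise_sd`` degC, multiplicative
    ``precip_noise_sd``); set both to 0 for a deterministic scenario.
    Radiation and soil properties are never altered.
    """

    rcp_label: str
    delta_t: float
    precip_scale: float
    co2: float
    gcm_seed: int = 0
    temp_noise_sd: float = 0.5
    precip_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.co2 <= 0:
            raise ValidationError("scenario co2 must be positive")
        if self.precip_scale <= 0:
            raise ValidationError("precip_scale must be positive")


@dataclass
class VirtualSpecies:
    """A species with known physiology, for truth-based validation.

    ``true_biomass`` and ``true_suitable`` are vectors over the land
    cells of the generating grid (row-major order); ``occurrence_cells``
    indexes into that land vector.
    """

    species_id: str
    growth_form: str
    pathway: str
    true_params: TTRParams
    prevalence: float
    true_biomass: np.ndarray = field(repr=False)
    true_suitable: np.ndarray = field(repr=False)
    occurrence_cells: np.ndarray = field(repr=False)


def _smooth_field(rng: np.random.Generator, shape, sigma=3.0) -> np.ndarray:
    """Zero-mean, unit-sd spatially autocorrelated Gaussian field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    sd = f.std()
    return f / (sd if sd > 0 else 1.0)


def _unit_field(rng: np.random.Generator, shape, sigma=3.0) -> np.ndarray:
    """Spatially autocorrelated field squashed into [0, 1]."""
    return np.clip(0.5 + 0.3 * _smooth_field(rng, shape, sigma), 0.0, 1.0)


def _season(phase_months: float = 6.5) -> np.ndarray:
    """Cosine annual cycle peaking in July (northern-hemisphere summer)."""
    m = np.arange(12)
    return np.cos(2.0 * np.pi * (m + 0.5 - phase_months) / 12.0)


def generate_climatology(
    n_rows: int,
    n_cols: int,
    seed: int,
    cell_size: float = 25.0,
    lat_range: tuple[float, float] = (-55.0, 70.0),
    sea_fraction: float = 0.1,
    co2: float = AMBIENT_CO2,
) -> Climatology:
    """Generate a seeded synthetic climatology on an ``n_rows x n_cols`` grid.

    Rows map linearly onto ``lat_range`` (row 0 at the northern edge).
    Annual-mean temperature decays quadratically with latitude, seasonal
    amplitude grows poleward with hemispheres in antiphase, and smooth
    seeded fields add spatial texture to every layer.
    """
    if n_rows < 10 or n_cols < 10:
        raise ValueError("synthetic grids must be at least 10x10")
    rng = np.random.default_rng(seed)
    shape = (n_rows, n_cols)

    lat_hi = max(lat_range)
    lat_lo = min(lat_range)
    lat = lat_hi - (np.arange(n_rows) + 0.5) * (lat_hi - lat_lo) / n_rows
    lat2d = np.broadcast_to(lat[:, None], shape)

    # land mask: smooth field thresholded at the requested sea fraction
    if sea_fraction > 0:
        sea_field = _smooth_field(rng, shape, sigma=4.0)
        mask = sea_field > np.quantile(sea_field, sea_fraction)
    else:
        mask = np.ones(shape, bool)

    t_ann = 28.0 - 0.0095 * lat2d**2 + 2.0 * _smooth_field(rng, shape)
    amp = 2.0 + 16.0 * (np.abs(lat2d) / max(abs(lat_hi), abs(lat_lo))) ** 1.3
    season = _season()
    hemi = np.where(lat2d >= 0, 1.0, -1.0)
    tmean = t_ann[None] + (amp * hemi)[None] * season[:, None, None]
    d_lo = 4.0 + 1.5 * _unit_field(rng, shape)
    d_hi = 4.0 + 1.5 * _unit_field(rng, shape)
    tmin = tmean - d_lo[None]
    tmax = tmean + d_hi[None]

    wetness = _smooth_field(rng, shape, sigma=4.0)
    base_p = 15.0 + 120.0 * 1.0 / (1.0 + np.exp(-1.2 * wetness))  # 15..135 mm/month
    p_season = 0.6 * _season(phase_months=8.0)
    precip = np.maximum(base_p[None] * (1.0 + (hemi)[None] * p_season[:, None, None]), 0.0)

    # top-of-atmosphere-like radiation: latitude band x month, deterministic
    decl = 23.5 * _season()
    ang = np.deg2rad(np.clip(np.abs(lat2d[None] - decl[:, None, None]), 0.0, 90.0))
    rad = 30.0 * np.maximum(np.cos(ang), 0.0)

    fc = 80.0 + 50.0 * _unit_field(rng, shape, sigma=4.0)
    wp = fc * (0.15 + 0.15 * _unit_field(rng, shape, sigma=4.0))

    grid = Grid(
        n_rows=n_rows, n_cols=n_cols, cell_size=cell_size,
        origin=(0.0, 111.0 * lat_hi), land_mask=mask,
    )
    clim = Climatology(
        grid=grid, tmin=tmin, tmean=tmean, tmax=tmax, precip=precip,
        rad=rad, field_capacity=fc, wilting_point=wp, co2=co2,
    )
    clim.validate()
    return clim


def generate_future(ambient: Climatology, spec: ScenarioSpec) -> Climatology:
    """Apply a scenario to an ambient climatology.

    Temperatures shift by ``delta_t`` plus smooth seeded GCM noise,
    precipitation is scaled (with multiplicative noise), radiation and
    soils stay fixed and CO2 is replaced.
    """
    rng = np.random.default_rng(spec.gcm_seed)
    shape = ambient.grid.shape
    t_noise = (
        spec.temp_noise_sd * _smooth_field(rng, shape, sigma=4.0)
        if spec.temp_noise_sd > 0 else np.zeros(shape)
    )
    p_noise = (
        1.0 + spec.precip_noise_sd * _smooth_field(rng, shape, sigma=4.0)
        if spec.precip_noise_sd > 0 else np.ones(shape)
    )
    shift = spec.delta_t + t_noise
    future = Climatology(
        grid=ambient.grid,
        tmin=ambient.tmin + shift[None],
        tmean=ambient.tmean + shift[None],
        tmax=ambient.tmax + shift[None],
        precip=np.maximum(ambient.precip * (spec.precip_scale * p_noise)[None], 0.0),
        rad=ambient.rad,
        field_capacity=ambient.field_capacity,
        wilting_point=ambient.wilting_point,
        co2=spec.co2,
    )
    future.validate()
    return future


# ---------------------------------------------------------------------------
# virtual species

def _draw_params(rng: np.random.Generator, t_anchor: float, w_anchor: float,
                 w_hi: float) -> TTRParams:
    """Draw species parameters anchored to a cell's annual-mean climate so
    the true suitable area is (almost always) non-empty."""
    def temp_trap():
        p2 = t_anchor - rng.uniform(1.0, 6.0)
        p3 = t_anchor + rng.uniform(1.0, 6.0)
        return (p2 - rng.uniform(4.0, 15.0), p2, p3, p3 + rng.uniform(4.0, 15.0))

    def moist_trap():
        p2 = max(w_anchor - rng.uniform(2.0, 20.0), 1.0)
        p1 = max(p2 - rng.uniform(5.0, 40.0), 0.0)
        p3 = w_anchor + rng.uniform(5.0, 40.0)
        return (p1, p2, p3, p3 + rng.uniform(20.0, max(w_hi - p3, 25.0)))

    return TTRParams(
        n_temp=temp_trap(),
        n_moist=moist_trap(),
        c_moist=moist_trap(),
        c_nitrogen=(rng.uniform(0.002, 0.02), rng.uniform(0.1, 0.5)),
        g_temp=temp_trap(),
    )


def generate_species(
    n_species: int,
    clim: Climatology,
    seed: int,
    moisture: np.ndarray | None = None,
    occurrences_per_species: int | tuple[int, int] = (30, 400),
    min_prevalence: float = 0.03,
    sampling_bias: bool = False,
    bias_retain: float = 0.3,
    constants: TTRConstants = DEFAULT_CONSTANTS,
    max_retries: int = 12,
) -> list[VirtualSpecies]:
    """Generate virtual species with known physiology and occurrences.

    Growth forms are assigned in a stratified round-robin so every form
    is represented once ``n_species >= 14``. Occurrence counts are drawn
    from ``occurrences_per_species`` (int or inclusive range, clipped to
    the 7..400 window the fitting stage expects) and sampled uniformly
    without replacement from truly suitable cells, one record per cell.
    With ``sampling_bias`` records outside a random well-sampled disc
    are retained with probability ``bias_retain`` (herbarium-style bias).

    Species whose drawn parameters leave fewer than ``min_prevalence``
    of land cells suitable are redrawn up to ``max_retries`` times, then
    reported via ValidationError.
    """
    if n_species < 14:
        raise ValueError("need n_species >= 14 so each growth form can occur")
    rng = np.random.default_rng(seed)
    if moisture is None:
        moisture = simulate_soil_moisture(clim).moisture

    mask = clim.grid.land_mask
    n_land = int(mask.sum())
    t_land = np.stack([clim.tmean[m][mask] for m in range(12)], axis=1)  # (N,12)
    w_land = np.stack([moisture[m][mask] for m in range(12)], axis=1)
    rad_land = np.stack([clim.rad[m][mask] for m in range(12)], axis=1)
    a_max = {
        p: uptake_ceiling(t_land, rad_land, clim.co2, p, constants) for p in ("C3", "C4")
    }
    t_ann = t_land.mean(axis=1)
    w_ann = w_land.mean(axis=1)
    w_hi = float(w_land.max())

    forms = [GROWTH_FORMS[i % 14] for i in range(n_species)]
    species: list[VirtualSpecies] = []
    for i, form in enumerate(forms):
        pathway = "C4" if form == "c4_grass" else "C3"
        for attempt in range(max_retries + 1):
            anchor = int(rng.integers(n_land))
            params = _draw_params(rng, t_ann[anchor], w_ann[anchor], w_hi)
            b = simulate_biomass_batch(
                params.to_vector()[None], t_land, w_land, a_max[pathway],
                constants=constants, tol=1e-3, max_cycles=40,
            )[0]
            suitable = b > 0
            prevalence = suitable.mean()
            if prevalence >= min_prevalence:
                break
        else:
            raise ValidationError(
                f"species {i}: no parameter draw with prevalence >= {min_prevalence} "
                f"after {max_retries} retries"
            )
        occ = _sample_occurrences(
            rng, suitable, occurrences_per_species, clim.grid,
            sampling_bias, bias_retain,
        )
        species.append(
            VirtualSpecies(
                species_id=f"sp{i:04d}", growth_form=form, pathway=pathway,
                true_params=params, prevalence=float(prevalence),
                true_biomass=b, true_suitable=suitable, occurrence_cells=occ,
            )
        )
    return species


def _sample_occurrences(rng, suitable, request, grid, bias, bias_retain):
    pool = np.flatnonzero(suitable)
    if isinstance(request, tuple):
        lo, hi = request
        n = int(rng.integers(lo, hi + 1))
    else:
        n = int(request)
    n = int(np.clip(n, 7, 400))
    if bias and pool.size:
        rows, cols = _land_rowcol(grid)
        center = pool[rng.integers(pool.size)]
        radius = 0.35 * max(grid.n_rows, grid.n_cols)
        d = np.hypot(rows[pool] - rows[center], cols[pool] - cols[center])
        keep = (d <= radius) | (rng.random(pool.size) < bias_retain)
        if keep.sum() >= 7:
            pool = pool[keep]
    n = min(n, pool.size)
    return np.sort(rng.choice(pool, size=n, replace=False))


def _land_rowcol(grid: Grid):
    """Row/col of each land cell, in land-vector (row-major) order."""
    return np.nonzero(grid.land_mask)


def occurrences_frame(species: list[VirtualSpecies], grid: Grid) -> pd.DataFrame:
    """Occurrence records as a species_id/x/y table at cell centers."""
    rows, cols = np.nonzero(grid.land_mask)
    cx, cy = grid.cell_centers()
    recs = []
    for sp in species:
        r = rows[sp.occurrence_cells]
        c = cols[sp.occurrence_cells]
        recs.append(pd.DataFrame({
            "species_id": sp.species_id, "x": cx[r, c], "y": cy[r, c],
        }))
    return pd.concat(recs, ignore_index=True)


def growth_form_frame(species: list[VirtualSpecies]) -> pd.DataFrame:
    return pd.DataFrame(
        {"species_id": [s.species_id for s in species],
         "growth_form": [s.growth_form for s in species]}
    )
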
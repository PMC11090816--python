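"""Transport-resistance plant growth kernel.

An individual plant is represented by six pools: shoot and root
structural mass and, for each, a carbon and a nitrogen substrate pool.
Each month

* the shoot takes up carbon at a cell's universal pathway-specific
  ceiling (light / temperature / CO2 colimited, Farquhar-style), reduced
  by species-specific soil-moisture and shoot-nitrogen dependencies;
* the root takes up nitrogen as a function of temperature and soil
  moisture (soil nitrogen is assumed uniform across cells);
* substrates move between shoot and root in proportion to the
  concentration difference over a transport resistance;
* each compartment grows bilinearly in its local substrate
  concentrations, gated by a temperature trapezoid, consuming substrate
  stoichiometrically; structural mass is lost to litter at a first-order
  rate.

Species differ only in 18 response parameters: three 4-point trapezoids
(nitrogen uptake vs temperature and vs moisture, carbon uptake vs
moisture), a 4-point growth-temperature trapezoid and a 2-parameter
saturating shoot-nitrogen dependence of carbon uptake. Everything else
(uptake scales, resistances, litter rates, stoichiometry, self-shading)
is universal and collected in :class:`TTRConstants`.

Uptake per unit mass declines with mass (``M / (1 + M/K)``), which gives
every cell a finite equilibrium biomass; the quantity used downstream is
that equilibrium's annual-mean total biomass.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from numba import njit

from .exceptions import ValidationError

__all__ = [
    "TTRParams",
    "TTRState",
    "TTRConstants",
    "DEFAULT_CONSTANTS",
    "trapezoid",
    "uptake_ceiling",
    "step_month",
    "equilibrium_biomass",
    "simulate_biomass_batch",
]

_EPS = 1e-12


@dataclass(frozen=True)
class TTRParams:
    """The 18 species-specific response parameters.

    Trapezoids are (p1, p2, p3, p4) breakpoints: the response rises
    linearly from 0 at p1 to 1 at p2, stays 1 until p3 and falls to 0 at
    p4. ``c_nitrogen`` is (half_saturation, floor) of the saturating
    shoot-nitrogen-concentration dependence of carbon uptake.
    """

    n_temp: tuple[float, float, float, float]
    n_moist: tuple[float, float, float, float]
    c_moist: tuple[float, float, float, float]
    c_nitrogen: tuple[float, float]
    g_temp: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        for name in ("n_temp", "n_moist", "c_moist", "g_temp"):
            p = getattr(self, name)
            if not (p[0] <= p[1] <= p[2] <= p[3]):
                raise ValidationError(f"{name} breakpoints not ordered: {p}")
        h, floor = self.c_nitrogen
        if h <= 0:
            raise ValidationError("c_nitrogen half-saturation must be > 0")
        if not 0.0 <= floor <= 1.0:
            raise ValidationError("c_nitrogen floor must lie in [0, 1]")

    def to_vector(self) -> np.ndarray:
        """Flatten to the canonical 18-vector
        [n_temp, n_moist, c_moist, c_nitrogen, g_temp]."""
        return np.concatenate(
            [self.n_temp, self.n_moist, self.c_moist, self.c_nitrogen, self.g_temp]
        ).astype(float)

    @classmethod
    def from_vector(cls, v) -> "TTRParams":
        v = np.asarray(v, float)
        if v.shape != (18,):
            raise ValidationError(f"expected 18 parameters, got shape {v.shape}")
        return cls(
            n_temp=tuple(v[0:4]), n_moist=tuple(v[4:8]), c_moist=tuple(v[8:12]),
            c_nitrogen=tuple(v[12:14]), g_temp=tuple(v[14:18]),
        )


@dataclass
class TTRState:
    """Pools of a single plant: structural mass and substrates (>= 0)."""

    shoot_mass: float = 0.05
    root_mass: float = 0.05
    shoot_c: float = 0.005
    root_c: float = 0.005
    shoot_n: float = 0.001
    root_n: float = 0.001

    @property
    def biomass(self) -> float:
        return self.shoot_mass + self.root_mass


@dataclass(frozen=True)
class TTRConstants:
    """Universal (non-species-specific) model constants.

    Units: masses are arbitrary structural-mass units; rates are per
    month. ``alpha_light`` converts MJ m^-2 day^-1 of solar radiation to
    a light-limited relative carbon-uptake rate; ``vmax_c3/vmax_c4`` are
    the Rubisco-limited rates at the thermal optimum; CO2 enters through
    Michaelis-type factors with ``co2_comp`` (C3 compensation point) and
    half-saturations ``kco2_c3/kco2_c4`` (C4 nearly saturated above
    ~400 ppm).
    """

    alpha_light: float = 0.04
    vmax_c3: float = 1.1
    vmax_c4: float = 1.2
    co2_comp: float = 40.0
    kco2_c3: float = 300.0
    kco2_c4: float = 60.0
    topt_c3: float = 23.0
    topt_c4: float = 32.0
    tsd_c3: float = 10.0
    tsd_c4: float = 10.0

    sigma_n: float = 0.05      # N uptake per root mass per month at full modifiers
    frac_c: float = 0.45       # structural carbon fraction
    frac_n: float = 0.02       # structural nitrogen fraction
    k_growth: float = 20.0     # bilinear growth coefficient
    g_transport_c: float = 0.5  # inverse transport resistance, carbon
    g_transport_n: float = 0.5  # inverse transport resistance, nitrogen
    litter_rate: float = 0.1    # structural loss per month
    substrate_turnover: float = 0.1
    k_shade: float = 5.0       # self-shading mass scale, shoot
    k_root: float = 5.0        # root-system saturation mass scale
    init_mass: float = 0.05
    init_substrate: float = 0.005
    init_n: float = 0.001
    biomass_floor: float = 0.05  # below this, a cell counts as zero biomass

    def as_dict(self) -> dict:
        return asdict(self)

    def as_array(self) -> np.ndarray:
        """Dynamics constants in the fixed order the compiled kernel expects."""
        return np.array([
            self.sigma_n, self.frac_c, self.frac_n, self.k_growth,
            self.g_transport_c, self.g_transport_n, self.litter_rate,
            self.substrate_turnover, self.k_shade, self.k_root,
            self.init_mass, self.init_substrate, self.init_n,
            self.biomass_floor,
        ])


DEFAULT_CONSTANTS = TTRConstants()


# ---------------------------------------------------------------------------
# response functions

def trapezoid(x, p1, p2, p3, p4):
    """Trapezoidal response: 0 outside (p1, p4), 1 on [p2, p3], linear limbs.

    Degenerate equal breakpoints collapse a limb into a step edge (the
    edge point itself evaluates to 0).
    """
    if not (np.all(p1 <= p2) and np.all(p2 <= p3) and np.all(p3 <= p4)):
        raise ValueError("trapezoid breakpoints must satisfy p1 <= p2 <= p3 <= p4")
    return _trapezoid_raw(np.asarray(x, float), p1, p2, p3, p4)


def _trapezoid_raw(x, p1, p2, p3, p4):
    rise = (x - p1) / np.maximum(p2 - p1, _EPS)
    fall = (p4 - x) / np.maximum(p4 - p3, _EPS)
    return np.clip(np.minimum(rise, fall), 0.0, 1.0)


def _peaked(t, topt, tsd):
    return np.exp(-0.5 * ((np.asarray(t, float) - topt) / tsd) ** 2)


def uptake_ceiling(tmean, rad, co2, pathway: str,
                   constants: TTRConstants = DEFAULT_CONSTANTS):
    """Universal maximum monthly carbon-uptake rate for a cell/month.

    ``min(light-limited, Rubisco/CO2-limited)`` with a peaked
    temperature response on the Rubisco term; identical for every
    species sharing a photosynthetic pathway. Zero radiation gives zero.
    """
    rad = np.asarray(rad, float)
    if np.any(rad < 0):
        raise ValueError("radiation must be non-negative")
    if np.any(np.asarray(co2) <= 0):
        raise ValueError("co2 must be positive")
    c = constants
    if pathway == "C3":
        co2_factor = np.maximum(np.asarray(co2, float) - c.co2_comp, 0.0) / (
            np.asarray(co2, float) + c.kco2_c3
        )
        rubisco = c.vmax_c3 * _peaked(tmean, c.topt_c3, c.tsd_c3) * co2_factor
    elif pathway == "C4":
        co2_factor = np.asarray(co2, float) / (np.asarray(co2, float) + c.kco2_c4)
        rubisco = c.vmax_c4 * _peaked(tmean, c.topt_c4, c.tsd_c4) * co2_factor
    else:
        raise ValueError(f"pathway must be 'C3' or 'C4', got {pathway!r}")
    return np.minimum(c.alpha_light * rad, rubisco)


# ---------------------------------------------------------------------------
# dynamics

def _modifiers(pv: np.ndarray, temp, moist):
    """Evaluate the four trapezoids for parameter rows ``pv`` (..., 18)
    against broadcastable forcing arrays."""
    # parameter layout: n_temp 0:4, n_moist 4:8, c_moist 8:12, c_nitrogen 12:14, g_temp 14:18
    f_nt = _trapezoid_raw(temp, pv[..., 0], pv[..., 1], pv[..., 2], pv[..., 3])
    f_nw = _trapezoid_raw(moist, pv[..., 4], pv[..., 5], pv[..., 6], pv[..., 7])
    f_cw = _trapezoid_raw(moist, pv[..., 8], pv[..., 9], pv[..., 10], pv[..., 11])
    f_gt = _trapezoid_raw(temp, pv[..., 14], pv[..., 15], pv[..., 16], pv[..., 17])
    return f_nt, f_nw, f_cw, f_gt


def _step_arrays(pools, a_max, f_nt, f_nw, f_cw, f_gt, h, floor,
                 c: TTRConstants):
    """One explicit monthly update on arrays of pools.

    ``pools`` is a 7-tuple-like of arrays (Ms, Mr, Cs, Cr, Ns, Nr) plus
    nothing else; growth is capped by available substrate so the
    non-negativity clamp never destroys mass (exact per-step mass
    balance). Returns (new_pools, uptake_c) — the uptake is reported for
    balance checks.
    """
    Ms, Mr, Cs, Cr, Ns, Nr = pools
    ms = np.maximum(Ms, _EPS)
    mr = np.maximum(Mr, _EPS)
    cs = Cs / ms
    cr = Cr / mr
    ns = Ns / ms
    nr = Nr / mr

    f_cn = floor + (1.0 - floor) * ns / (ns + h)
    u_c = a_max * f_cw * f_cn * Ms / (1.0 + Ms / c.k_shade)
    u_n = c.sigma_n * f_nt * f_nw * Mr / (1.0 + Mr / c.k_root)

    mh = ms * mr / (ms + mr)
    keep = 1.0 - c.substrate_turnover     # budget left after turnover loss
    t_c = c.g_transport_c * (cs - cr) * mh   # shoot -> root when positive
    t_n = c.g_transport_n * (nr - ns) * mh   # root -> shoot when positive
    t_c = np.clip(t_c, -keep * Cr, keep * Cs)
    t_n = np.clip(t_n, -keep * Ns, keep * Nr)

    # substrate remaining after turnover and transport bounds growth exactly,
    # so the non-negativity clamp below never destroys mass
    cs_avail = keep * Cs - np.maximum(t_c, 0.0)
    cr_avail = keep * Cr + np.minimum(t_c, 0.0)  # |t_c| leaves root when t_c < 0
    ns_avail = keep * Ns - np.maximum(-t_n, 0.0)
    nr_avail = keep * Nr - np.maximum(t_n, 0.0)

    g_s = c.k_growth * f_gt * cs * ns * Ms
    g_r = c.k_growth * f_gt * cr * nr * Mr
    g_s = np.minimum(g_s, np.minimum(
        np.maximum(cs_avail, 0.0) / c.frac_c, np.maximum(ns_avail, 0.0) / c.frac_n))
    g_r = np.minimum(g_r, np.minimum(
        np.maximum(cr_avail, 0.0) / c.frac_c, np.maximum(nr_avail, 0.0) / c.frac_n))

    lam = c.litter_rate
    mu = c.substrate_turnover
    Ms2 = np.maximum(Ms + g_s - lam * Ms, 0.0)
    Mr2 = np.maximum(Mr + g_r - lam * Mr, 0.0)
    Cs2 = np.maximum(Cs + u_c - c.frac_c * g_s - t_c - mu * Cs, 0.0)
    Cr2 = np.maximum(Cr + t_c - c.frac_c * g_r - mu * Cr, 0.0)
    Ns2 = np.maximum(Ns + t_n - c.frac_n * g_s - mu * Ns, 0.0)
    Nr2 = np.maximum(Nr + u_n - c.frac_n * g_r - t_n - mu * Nr, 0.0)
    return (Ms2, Mr2, Cs2, Cr2, Ns2, Nr2), u_c


def step_month(state: TTRState, forcing: dict, params: TTRParams,
               constants: TTRConstants = DEFAULT_CONSTANTS) -> TTRState:
    """Advance a single plant one month.

    ``forcing`` needs keys ``tmean`` (degC), ``moisture`` (mm, plant
    available) and ``a_max`` (the cell-month uptake ceiling).
    """
    pv = params.to_vector()
    t = float(forcing["tmean"])
    w = float(forcing["moisture"])
    f_nt, f_nw, f_cw, f_gt = _modifiers(pv, t, w)
    pools = tuple(
        np.asarray(float(x))
        for x in (state.shoot_mass, state.root_mass, state.shoot_c,
                  state.root_c, state.shoot_n, state.root_n)
    )
    new, _ = _step_arrays(pools, float(forcing["a_max"]), f_nt, f_nw, f_cw, f_gt,
                          pv[12], pv[13], constants)
    vals = [float(v) for v in new]
    if not all(np.isfinite(vals)):
        raise FloatingPointError(f"non-finite pool after step: {vals}")
    return TTRState(*vals)


@njit(cache=True)
def _trap_scalar(x, p1, p2, p3, p4):
    rise = (x - p1) / max(p2 - p1, _EPS)
    fall = (p4 - x) / max(p4 - p3, _EPS)
    v = min(rise, fall)
    if v < 0.0:
        return 0.0
    if v > 1.0:
        return 1.0
    return v


@njit(cache=True)
def _simulate_kernel(pm, tmean, moisture, a_max, const, tol, max_cycles):
    """Scalar equilibrium loop over (candidate, cell) pairs.

    ``const`` is the flat array produced by TTRConstants.as_array().
    Mirrors the vectorized monthly update exactly (same operation
    order); each pair iterates its own annual cycle until the annual
    mean biomass stabilizes, dies out, or max_cycles is hit.
    """
    (sigma_n, frac_c, frac_n, k_growth, g_c, g_n, lam, mu, k_shade, k_root,
     init_mass, init_sub, init_n, floor_b) = (
        const[0], const[1], const[2], const[3], const[4], const[5], const[6],
        const[7], const[8], const[9], const[10], const[11], const[12], const[13])
    S = pm.shape[0]
    N = tmean.shape[0]
    out = np.empty((S, N))
    for s in range(S):
        p = pm[s]
        h = p[12]
        nfloor = p[13]
        for n in range(N):
            Ms = init_mass
            Mr = init_mass
            Cs = init_sub
            Cr = init_sub
            Ns = init_n
            Nr = init_n
            prev = -1.0
            mean_b = 0.0
            for cyc in range(max_cycles):
                total = 0.0
                for m in range(12):
                    t = tmean[n, m]
                    w = moisture[n, m]
                    f_nt = _trap_scalar(t, p[0], p[1], p[2], p[3])
                    f_nw = _trap_scalar(w, p[4], p[5], p[6], p[7])
                    f_cw = _trap_scalar(w, p[8], p[9], p[10], p[11])
                    f_gt = _trap_scalar(t, p[14], p[15], p[16], p[17])

                    ms = max(Ms, _EPS)
                    mr = max(Mr, _EPS)
                    cs = Cs / ms
                    cr = Cr / mr
                    ns = Ns / ms
                    nr = Nr / mr
                    f_cn = nfloor + (1.0 - nfloor) * ns / (ns + h)
                    u_c = a_max[n, m] * f_cw * f_cn * Ms / (1.0 + Ms / k_shade)
                    u_n = sigma_n * f_nt * f_nw * Mr / (1.0 + Mr / k_root)
                    mh = ms * mr / (ms + mr)
                    keep = 1.0 - mu
                    t_c = g_c * (cs - cr) * mh
                    t_n = g_n * (nr - ns) * mh
                    t_c = min(max(t_c, -keep * Cr), keep * Cs)
                    t_n = min(max(t_n, -keep * Ns), keep * Nr)
                    cs_avail = keep * Cs - max(t_c, 0.0)
                    cr_avail = keep * Cr + min(t_c, 0.0)
                    ns_avail = keep * Ns - max(-t_n, 0.0)
                    nr_avail = keep * Nr - max(t_n, 0.0)
                    g_s = k_growth * f_gt * cs * ns * Ms
                    g_r = k_growth * f_gt * cr * nr * Mr
                    g_s = min(g_s, min(max(cs_avail, 0.0) / frac_c,
                                       max(ns_avail, 0.0) / frac_n))
                    g_r = min(g_r, min(max(cr_avail, 0.0) / frac_c,
                                       max(nr_avail, 0.0) / frac_n))
                    Ms2 = max(Ms + g_s - lam * Ms, 0.0)
                    Mr2 = max(Mr + g_r - lam * Mr, 0.0)
                    Cs2 = max(Cs + u_c - frac_c * g_s - t_c - mu * Cs, 0.0)
                    Cr2 = max(Cr + t_c - frac_c * g_r - mu * Cr, 0.0)
                    Ns2 = max(Ns + t_n - frac_n * g_s - mu * Ns, 0.0)
                    Nr2 = max(Nr + u_n - frac_n * g_r - t_n - mu * Nr, 0.0)
                    Ms, Mr, Cs, Cr, Ns, Nr = Ms2, Mr2, Cs2, Cr2, Ns2, Nr2
                    total += Ms + Mr
                mean_b = total / 12.0
                if prev >= 0.0:
                    if abs(mean_b - prev) / max(prev, floor_b) < tol:
                        break
                    if mean_b < 0.5 * floor_b and mean_b < prev:
                        break   # monotone die-off: heading to zero
                prev = mean_b
            out[s, n] = mean_b if mean_b >= floor_b else 0.0
    return out


def simulate_biomass_batch(
    param_matrix: np.ndarray,
    tmean: np.ndarray,
    moisture: np.ndarray,
    a_max: np.ndarray,
    constants: TTRConstants = DEFAULT_CONSTANTS,
    tol: float = 1e-4,
    max_cycles: int = 80,
) -> np.ndarray:
    """Equilibrium annual-mean biomass for S parameter sets x N cells.

    ``param_matrix`` is (S, 18); ``tmean``/``moisture``/``a_max`` are
    (N, 12) cell-month forcing. Each (candidate, cell) pair iterates the
    12-month cycle from the standard small initial state until the
    annual-mean total biomass changes by less than ``tol`` (relative),
    dies out, or ``max_cycles`` is reached (the last-cycle mean is then
    used). Returns (S, N) biomass, with values below the biomass floor
    set to 0. The inner loop is compiled (numba); ``tol=0`` forces a
    fixed number of cycles, which unit tests use to compare against
    step-by-step references.
    """
    pm = np.atleast_2d(np.ascontiguousarray(param_matrix, dtype=float))
    return _simulate_kernel(
        pm,
        np.ascontiguousarray(tmean, dtype=float),
        np.ascontiguousarray(moisture, dtype=float),
        np.ascontiguousarray(a_max, dtype=float),
        constants.as_array(),
        float(tol),
        int(max_cycles),
    )


def equilibrium_biomass(
    params: TTRParams,
    tmean: np.ndarray,
    moisture: np.ndarray,
    a_max: np.ndarray,
    constants: TTRConstants = DEFAULT_CONSTANTS,
    tol: float = 1e-4,
    max_cycles: int = 80,
) -> np.ndarray:
    """Equilibrium annual-mean biomass of one species over N cells.

    Thin wrapper over :func:`simulate_biomass_batch` for a single
    parameter set; forcing arrays are (N, 12).
    """
    return simulate_biomass_batch(
        params.to_vector()[None, :], tmean, moisture, a_max,
        constants=constants, tol=tol, max_cycles=max_cycles,
    )[0]


def monthly_forcing(clim, moisture, pathway: str,
                    constants: TTRConstants = DEFAULT_CONSTANTS):
    """Flatten land-cell forcing into the (N, 12) arrays the kernel wants.

    Returns (tmean, moisture, a_max) for the land cells of ``clim`` in
    row-major order, with the uptake ceiling evaluated at the
    climatology's CO2.
    """
    mask = clim.grid.land_mask
    t = np.stack([clim.tmean[m][mask] for m in range(12)], axis=1)
    w = np.stack([moisture[m][mask] for m in range(12)], axis=1)
    rad = np.stack([clim.rad[m][mask] for m in range(12)], axis=1)
    am = uptake_ceiling(t, rad, clim.co2, pathway, constants)
    return t, w, am
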
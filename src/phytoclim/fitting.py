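"""Species model fitting: environmental zones, sampling design,
differential-evolution parameter search, suitability calibration and
accuracy filtering.

The estimation problem: given presence cells and pseudo-absence cells
for a species, find the 18 growth-model parameters whose equilibrium
biomass surface best predicts the presences under a Bernoulli
likelihood with a complementary log-log link on log biomass. The
optimizer is differential evolution over a box-constrained encoding
(each trapezoid is searched as a base point plus non-negative gaps so
breakpoint ordering holds by construction); for every candidate the two
calibration coefficients of the cloglog regression are profiled out by
an inner Fisher-scoring fit, batched across the DE population.

Sampling design mirrors the field protocol: occurrences are thinned to
one per cell, presences above a cap are subsampled preserving the
proportions of k-medoids environmental zones, and pseudo-absences are
drawn with zone weights inversely proportional to the presence-sample
zone proportions. Models are binarized at the cutoff maximizing
TP + TN and filtered on the true skill statistic (accepted iff
TSS > 0.7).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .exceptions import DegenerateSampleError, ValidationError
from .grids import Climatology, Grid
from .ttr import (
    DEFAULT_CONSTANTS,
    TTRConstants,
    TTRParams,
    simulate_biomass_batch,
)

__all__ = [
    "EnvZoneModel",
    "FitSample",
    "FittedSpeciesModel",
    "classify_env_zones",
    "thin_occurrences",
    "sample_presences",
    "sample_pseudo_absences",
    "suitability_score",
    "fit_species",
    "project_species",
    "choose_threshold",
    "tss",
]

LN_B_EPSILON = 1e-6   # added to biomass before taking logs
TSS_CUTOFF = 0.7
PRESENCE_CAP = 400
MIN_PRESENCES = 7
SMALL_SPECIES_ABSENCES = 20


# ---------------------------------------------------------------------------
# environmental zones (CLARA-style k-medoids + discriminant refinement)

@dataclass
class EnvZoneModel:
    k: int
    medoids: np.ndarray          # (k, n_features) in standardized feature space
    zone_of_cell: np.ndarray     # (n_land,) labels in 0..k-1

    def proportions(self, cells: np.ndarray) -> np.ndarray:
        """Zone proportions of a set of land-cell indices, length k."""
        counts = np.bincount(self.zone_of_cell[cells], minlength=self.k)
        return counts / max(len(cells), 1)


def _env_features(clim: Climatology, moisture: np.ndarray) -> np.ndarray:
    """Standardized per-land-cell monthly forcing features (N, 36)."""
    mask = clim.grid.land_mask
    feats = np.concatenate(
        [
            np.stack([clim.tmean[m][mask] for m in range(12)], axis=1),
            np.stack([moisture[m][mask] for m in range(12)], axis=1),
            np.stack([clim.rad[m][mask] for m in range(12)], axis=1),
        ],
        axis=1,
    )
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0)
    return (feats - mu) / np.where(sd > 0, sd, 1.0)


def _pam(X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 30):
    """Plain k-medoids (alternating assignment / medoid update)."""
    n = X.shape[0]
    med_idx = rng.choice(n, size=k, replace=False)
    for _ in range(max_iter):
        d = np.linalg.norm(X[:, None, :] - X[med_idx][None, :, :], axis=2)
        labels = d.argmin(axis=1)
        new_idx = med_idx.copy()
        for j in range(k):
            members = np.flatnonzero(labels == j)
            if members.size == 0:
                continue
            sub = X[members]
            cost = np.linalg.norm(sub[:, None, :] - sub[None, :, :], axis=2).sum(axis=0)
            new_idx[j] = members[cost.argmin()]
        if np.array_equal(new_idx, med_idx):
            break
        med_idx = new_idx
    d = np.linalg.norm(X[:, None, :] - X[med_idx][None, :, :], axis=2)
    return med_idx, d.min(axis=1).sum()


def classify_env_zones(
    clim: Climatology,
    moisture: np.ndarray,
    k: int = 20,
    subsample: int = 300,
    n_subsamples: int = 5,
    seed: int = 0,
    n_components: int = 10,
) -> EnvZoneModel:
    """Classify land cells into k environmental zones.

    CLARA-style: k-medoids is run on ``n_subsamples`` random subsamples
    of the standardized monthly forcing features (projected onto
    ``n_components`` principal components); the medoid set with the
    lowest total assignment cost over all cells wins. A single
    discriminant-analysis reassignment pass (LDA on the principal
    components, cells moved to the zone of highest discriminant score)
    then sharpens the boundaries. Deterministic given the seed.
    """
    feats = _env_features(clim, moisture)
    n = feats.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available land cells")
    rng = np.random.default_rng(seed)
    X = PCA(n_components=min(n_components, feats.shape[1]),
            random_state=int(seed) & 0x7FFFFFFF).fit_transform(feats)

    best = None
    for _ in range(n_subsamples):
        size = min(max(subsample, 2 * k), n)
        idx = rng.choice(n, size=size, replace=False)
        med_local, _ = _pam(X[idx], k, rng)
        medoids = X[idx][med_local]
        d = np.linalg.norm(X[:, None, :] - medoids[None, :, :], axis=2)
        cost = d.min(axis=1).sum()
        if best is None or cost < best[0]:
            best = (cost, medoids, d.argmin(axis=1))
    _, medoids, labels = best

    # discriminant refinement: one reassignment pass
    present = np.unique(labels)
    if present.size > 1:
        lda = LinearDiscriminantAnalysis()
        lda.fit(X, labels)
        labels = lda.predict(X)
    return EnvZoneModel(k=k, medoids=medoids, zone_of_cell=labels.astype(int))


# ---------------------------------------------------------------------------
# occurrence thinning and sampling design

def thin_occurrences(records: pd.DataFrame, grid: Grid) -> pd.DataFrame:
    """Keep at most one record per (species, cell); drop out-of-grid points.

    Returns the thinned table with ``row``/``col``/``land_cell`` columns
    appended (``land_cell`` is the index into the row-major land
    vector; records on sea cells are dropped too). The number of dropped
    records is recorded in ``df.attrs['n_dropped']``.
    """
    row, col = grid.cell_of_xy(records["x"].to_numpy(), records["y"].to_numpy())
    ok = (row >= 0) & (col >= 0)
    ok &= np.where(ok, grid.land_mask[np.clip(row, 0, None), np.clip(col, 0, None)], False)
    n_dropped = int((~ok).sum())
    out = records.loc[ok].copy()
    out["row"] = row[ok]
    out["col"] = col[ok]
    land_index = np.full(grid.shape, -1, int)
    land_index[grid.land_mask] = np.arange(grid.n_land)
    out["land_cell"] = land_index[out["row"], out["col"]]
    out = out.drop_duplicates(subset=["species_id", "land_cell"]).reset_index(drop=True)
    out.attrs["n_dropped"] = n_dropped
    return out


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``weights``."""
    w = np.asarray(weights, float)
    w = w / w.sum()
    quota = w * total
    alloc = np.floor(quota).astype(int)
    short = total - alloc.sum()
    if short > 0:
        order = np.argsort(-(quota - alloc))
        alloc[order[:short]] += 1
    return alloc


def sample_presences(
    presence_cells: np.ndarray,
    zones: EnvZoneModel,
    cap: int = PRESENCE_CAP,
    seed: int = 0,
) -> np.ndarray:
    """Cap the presence sample, conserving environmental-zone proportions.

    All points are used below the cap; above it, a seeded stratified
    sample of ~``cap`` points is drawn whose per-zone counts follow
    largest-remainder apportionment of the full set's proportions.
    """
    presence_cells = np.asarray(presence_cells)
    if presence_cells.size < MIN_PRESENCES:
        raise DegenerateSampleError(
            f"need at least {MIN_PRESENCES} presences, got {presence_cells.size}"
        )
    if presence_cells.size <= cap:
        return presence_cells
    rng = np.random.default_rng(seed)
    labels = zones.zone_of_cell[presence_cells]
    zone_ids, counts = np.unique(labels, return_counts=True)
    alloc = _largest_remainder(counts, cap)
    picks = []
    for z, n_z in zip(zone_ids, alloc):
        members = presence_cells[labels == z]
        picks.append(rng.choice(members, size=min(n_z, members.size), replace=False))
    return np.sort(np.concatenate(picks))


def sample_pseudo_absences(
    presence_sample: np.ndarray,
    zones: EnvZoneModel,
    seed: int = 0,
    n_absences: int | None = None,
) -> np.ndarray:
    """Draw pseudo-absence cells, down-weighting well-sampled zones.

    Zone selection weights are proportional to the inverse of the zone's
    proportion in the presence sample; zones with no presences are given
    the minimum observed presence proportion before inverting (the
    inverse rule is undefined at zero). The per-zone absence counts are
    drawn from the corresponding multinomial and cells are sampled
    uniformly within zones, never touching presence cells. Species with
    fewer presences than zones get exactly 20 absences; otherwise the
    absence count matches the presence count.
    """
    presence_sample = np.asarray(presence_sample)
    rng = np.random.default_rng(seed)
    n_pres = presence_sample.size
    if n_absences is None:
        n_absences = n_pres if n_pres >= zones.k else SMALL_SPECIES_ABSENCES

    prop = zones.proportions(presence_sample)
    observed = prop[prop > 0]
    prop_filled = np.where(prop > 0, prop, observed.min())
    weights = 1.0 / prop_filled
    weights /= weights.sum()

    candidates_by_zone = []
    presence_set = set(presence_sample.tolist())
    for z in range(zones.k):
        cells = np.flatnonzero(zones.zone_of_cell == z)
        cells = cells[~np.isin(cells, presence_sample)]
        candidates_by_zone.append(cells)
    total_candidates = sum(c.size for c in candidates_by_zone)
    if total_candidates < n_absences:
        raise ValidationError(
            f"only {total_candidates} candidate cells for {n_absences} pseudo-absences"
        )

    counts = rng.multinomial(n_absences, weights)
    picks = []
    overflow = 0
    for z in range(zones.k):
        avail = candidates_by_zone[z]
        take = min(counts[z], avail.size)
        overflow += counts[z] - take
        if take:
            picks.append(rng.choice(avail, size=take, replace=False))
    # redistribute overflow uniformly over remaining candidates
    if overflow:
        taken = np.concatenate(picks) if picks else np.empty(0, int)
        rest = np.setdiff1d(np.concatenate(candidates_by_zone), taken)
        picks.append(rng.choice(rest, size=overflow, replace=False))
    return np.sort(np.concatenate(picks))


# ---------------------------------------------------------------------------
# suitability, thresholding, skill

def suitability_score(B, calib, eps: float = LN_B_EPSILON):
    """Cloglog suitability: p = 1 - exp(-exp(b0 + b1 ln(B + eps)))."""
    b0, b1 = calib
    eta = b0 + b1 * np.log(np.asarray(B, float) + eps)
    return -np.expm1(-np.exp(np.clip(eta, -700.0, 30.0)))


def choose_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Cutoff maximizing TP + TN over observed scores and their midpoints.

    Prediction rule is ``score >= cutoff``; ties take the lowest
    qualifying cutoff.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise DegenerateSampleError("both classes are required to choose a threshold")
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.empty(0)
    # the sentinel above the maximum covers the predict-nothing rule
    candidates = np.sort(np.concatenate([uniq, mids, [uniq[-1] + 1.0]]))
    pred = scores[None, :] >= candidates[:, None]
    tp = (pred & labels[None, :]).sum(axis=1)
    tn = (~pred & ~labels[None, :]).sum(axis=1)
    total = tp + tn
    return float(candidates[np.argmax(total)])  # argmax returns first (lowest) maximizer


def tss(tp: int, fp: int, fn: int, tn: int) -> float:
    """True skill statistic: sensitivity + specificity - 1."""
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("TSS undefined: a margin of the confusion matrix is empty")
    return tp / (tp + fn) + tn / (tn + fp) - 1.0


def confusion(scores, labels, threshold):
    labels = np.asarray(labels).astype(bool)
    pred = np.asarray(scores) >= threshold
    return (
        int((pred & labels).sum()), int((pred & ~labels).sum()),
        int((~pred & labels).sum()), int((~pred & ~labels).sum()),
    )


# ---------------------------------------------------------------------------
# batched cloglog calibration (profiled inner regression)

def fit_cloglog_batch(z: np.ndarray, y: np.ndarray, n_iter: int = 25,
                      ridge: float = 1e-8):
    """Fisher-scoring fit of p = cloglog^-1(b0 + b1 z) for a batch.

    ``z`` is (S, N) log-biomass, ``y`` (N,) binary. Returns
    (b0, b1, nll) arrays of length S. Two parameters only, so the
    normal equations are solved in closed form; a small ridge keeps
    degenerate candidates (constant z) finite.
    """
    z = np.atleast_2d(z)
    y = np.asarray(y, float)
    S = z.shape[0]
    b0 = np.full(S, -1.0)
    b1 = np.full(S, 1.0)
    for _ in range(n_iter):
        eta = np.clip(b0[:, None] + b1[:, None] * z, -30.0, 3.5)
        w = np.exp(eta)
        expw = np.exp(-w)
        p = np.clip(-np.expm1(-w), 1e-12, 1.0 - 1e-12)
        # score and Fisher information wrt eta
        u = y[None, :] * w * expw / p - (1.0 - y[None, :]) * w
        info = w**2 * np.exp(-2.0 * np.clip(w, None, 350.0)) / (p * (1.0 - p))
        info = np.maximum(info, 1e-12)
        s0 = u.sum(axis=1)
        s1 = (u * z).sum(axis=1)
        i00 = info.sum(axis=1) + ridge
        i01 = (info * z).sum(axis=1)
        i11 = (info * z * z).sum(axis=1) + ridge
        det = np.maximum(i00 * i11 - i01 * i01, 1e-12)
        db0 = (i11 * s0 - i01 * s1) / det
        db1 = (i00 * s1 - i01 * s0) / det
        step = np.clip(np.maximum(np.abs(db0), np.abs(db1)), None, 5.0) / np.maximum(
            np.maximum(np.abs(db0), np.abs(db1)), 1e-12)
        b0 = np.clip(b0 + db0 * step, -40.0, 40.0)
        b1 = np.clip(b1 + db1 * step, -40.0, 40.0)
    eta = np.clip(b0[:, None] + b1[:, None] * z, -30.0, 3.5)
    p = np.clip(-np.expm1(-np.exp(eta)), 1e-12, 1.0 - 1e-12)
    nll = -(y[None, :] * np.log(p) + (1.0 - y[None, :]) * np.log1p(-p)).sum(axis=1)
    return b0, b1, nll


# ---------------------------------------------------------------------------
# the fit itself

@dataclass
class FitSample:
    """Presence and pseudo-absence cells (land-vector indices)."""

    presence_cells: np.ndarray
    absence_cells: np.ndarray

    def __post_init__(self) -> None:
        self.presence_cells = np.asarray(self.presence_cells, int)
        self.absence_cells = np.asarray(self.absence_cells, int)
        if self.presence_cells.size < MIN_PRESENCES:
            raise DegenerateSampleError(
                f"need at least {MIN_PRESENCES} presences, got {self.presence_cells.size}"
            )
        if np.intersect1d(self.presence_cells, self.absence_cells).size:
            raise ValidationError("presence and absence cells overlap")

    @property
    def cells(self) -> np.ndarray:
        return np.concatenate([self.presence_cells, self.absence_cells])

    @property
    def labels(self) -> np.ndarray:
        return np.concatenate([
            np.ones(self.presence_cells.size), np.zeros(self.absence_cells.size)
        ])


@dataclass
class FittedSpeciesModel:
    species_id: str
    params: TTRParams
    calib: tuple[float, float]
    threshold: float
    tss: float
    accepted: bool
    pathway: str = "C3"
    nll: float = np.nan
    seed: int | None = None

    def to_record(self) -> dict:
        rec = {"species_id": self.species_id, "pathway": self.pathway}
        rec.update({f"p{i:02d}": v for i, v in enumerate(self.params.to_vector())})
        rec.update({
            "beta0": self.calib[0], "beta1": self.calib[1],
            "threshold": self.threshold, "tss": self.tss,
            "accepted": self.accepted, "nll": self.nll, "seed": self.seed,
        })
        return rec

    @classmethod
    def from_record(cls, rec) -> "FittedSpeciesModel":
        vec = np.array([rec[f"p{i:02d}"] for i in range(18)], float)
        return cls(
            species_id=rec["species_id"], params=TTRParams.from_vector(vec),
            calib=(float(rec["beta0"]), float(rec["beta1"])),
            threshold=float(rec["threshold"]), tss=float(rec["tss"]),
            accepted=bool(rec["accepted"]), pathway=rec.get("pathway", "C3"),
            nll=float(rec.get("nll", np.nan)),
            seed=rec.get("seed"),
        )


def parameter_bounds(tmean: np.ndarray, moisture: np.ndarray, margin: float = 10.0):
    """DE search box in the gap encoding, from the climate envelope.

    Encoding per trapezoid: (p1, g12, g23, g34) with non-negative gaps,
    so ordered breakpoints are guaranteed. Layout mirrors the canonical
    18-vector.
    """
    t_lo, t_hi = float(tmean.min()) - margin, float(tmean.max()) + margin
    w_hi = float(moisture.max()) + 3.0 * margin
    t_span = t_hi - t_lo
    temp_box = [(t_lo, t_hi), (0.1, t_span), (0.1, t_span), (0.1, t_span)]
    moist_box = [(0.0, w_hi), (0.5, w_hi), (0.5, w_hi), (0.5, w_hi)]
    return (
        temp_box + moist_box + moist_box
        + [(1e-4, 0.05), (0.0, 1.0)]
        + temp_box
    )


def decode_gap_vectors(x: np.ndarray) -> np.ndarray:
    """Gap-encoded (S, 18) -> breakpoint-encoded (S, 18) parameter rows."""
    x = np.atleast_2d(np.asarray(x, float))
    out = x.copy()
    for start in (0, 4, 8, 14):
        out[:, start + 1] = out[:, start] + x[:, start + 1]
        out[:, start + 2] = out[:, start + 1] + x[:, start + 2]
        out[:, start + 3] = out[:, start + 2] + x[:, start + 3]
    return out


def fit_species(
    sample: FitSample,
    tmean: np.ndarray,
    moisture: np.ndarray,
    a_max: np.ndarray,
    seed: int = 0,
    species_id: str = "species",
    pathway: str = "C3",
    generations: int = 1000,
    popsize: int = 10,
    mutation: float = 0.8,
    recombination: float = 0.9,
    constants: TTRConstants = DEFAULT_CONSTANTS,
    fit_tol: float = 2e-3,
    fit_max_cycles: int = 15,
    bounds=None,
) -> FittedSpeciesModel:
    """Estimate a species' growth-model parameters from its fit sample.

    ``tmean``/``moisture``/``a_max`` are (N, 12) forcing at the sample
    cells, ordered presences first then absences (see
    :attr:`FitSample.cells`). ``popsize`` follows scipy's convention
    (population = popsize x 18 individuals). The candidate score is the
    Bernoulli negative log-likelihood of the cloglog suitability with
    the two calibration coefficients profiled out per candidate.
    """
    y = sample.labels
    n = sample.cells.size
    if tmean.shape[0] != n:
        raise ValidationError(
            f"forcing covers {tmean.shape[0]} cells but the sample has {n}"
        )
    if y.all() or not y.any():
        raise DegenerateSampleError("sample outcomes are all identical")
    if bounds is None:
        bounds = parameter_bounds(tmean, moisture)

    def objective(x):
        single = x.ndim == 1
        pm = decode_gap_vectors(x.T if not single else x[None, :])
        B = simulate_biomass_batch(
            pm, tmean, moisture, a_max, constants=constants,
            tol=fit_tol, max_cycles=fit_max_cycles,
        )
        z = np.log(B + LN_B_EPSILON)
        _, _, nll = fit_cloglog_batch(z, y)
        return nll[0] if single else nll

    result = differential_evolution(
        objective,
        bounds=bounds,
        maxiter=generations,
        popsize=popsize,
        mutation=mutation,
        recombination=recombination,
        seed=int(seed) & 0x7FFFFFFF,
        tol=0.0,
        polish=False,
        updating="deferred",
        vectorized=True,
        init="sobol",
    )
    best = decode_gap_vectors(result.x[None, :])
    params = TTRParams.from_vector(best[0])
    B = simulate_biomass_batch(best, tmean, moisture, a_max, constants=constants)[0]
    b0, b1, nll = fit_cloglog_batch(np.log(B + LN_B_EPSILON)[None, :], y, n_iter=50)
    calib = (float(b0[0]), float(b1[0]))
    scores = suitability_score(B, calib)
    threshold = choose_threshold(scores, y)
    tp, fp, fn, tn = confusion(scores, y, threshold)
    score = tss(tp, fp, fn, tn)
    return FittedSpeciesModel(
        species_id=species_id, params=params, calib=calib, threshold=threshold,
        tss=score, accepted=score > TSS_CUTOFF, pathway=pathway,
        nll=float(nll[0]), seed=seed,
    )


def project_species(
    model: FittedSpeciesModel,
    tmean: np.ndarray,
    moisture: np.ndarray,
    a_max: np.ndarray,
    constants: TTRConstants = DEFAULT_CONSTANTS,
):
    """Project a fitted model over cells: (suitability, binary) vectors."""
    B = simulate_biomass_batch(
        model.params.to_vector()[None], tmean, moisture, a_max, constants=constants
    )[0]
    scores = suitability_score(B, model.calib)
    return scores, scores >= model.threshold


def models_frame(models: list[FittedSpeciesModel]) -> pd.DataFrame:
    """Serialize fit results, one record per species."""
    return pd.DataFrame([m.to_record() for m in models])
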
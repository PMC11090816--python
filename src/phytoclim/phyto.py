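"""Phytoclimates: growth-form suitability surfaces and their
Gaussian-mixture classification into phytoclimatic zones.

A cell's phytoclimate is the 14-vector of the fractions of each growth
form's modelled species for which the cell is climatically suitable.
Cells are grouped by a finite Gaussian mixture whose component
covariances share their eigenvalue *shape* profile while volume and
orientation vary freely per component (the "ellipsoidal, equal shape"
family); the number of components defaults to 18. The 5th percentile of
the pairwise distances between component centroids serves as the
threshold separating ecologically significant distances from noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .exceptions import ConvergenceError, ValidationError
from .synthetic import GROWTH_FORMS

__all__ = [
    "ZoneModel",
    "growth_form_suitability",
    "fit_zones",
    "scan_zones",
    "significance_threshold",
]


def growth_form_suitability(
    binary_maps: np.ndarray,
    growth_forms: list[str],
    forms: tuple[str, ...] = GROWTH_FORMS,
) -> np.ndarray:
    """Per-cell fraction of each form's species with a suitable cell.

    ``binary_maps`` is (n_species, n_cells) boolean; ``growth_forms``
    assigns a form to each row. Returns (n_forms, n_cells). Every form
    in ``forms`` must have at least one modelled species, and every
    label must be a known form.
    """
    binary_maps = np.asarray(binary_maps, bool)
    growth_forms = list(growth_forms)
    if len(growth_forms) != binary_maps.shape[0]:
        raise ValidationError("one growth form per species map is required")
    unknown = set(growth_forms) - set(forms)
    if unknown:
        raise ValidationError(f"unknown growth-form labels: {sorted(unknown)}")
    out = np.empty((len(forms), binary_maps.shape[1]))
    gf = np.asarray(growth_forms)
    for i, form in enumerate(forms):
        rows = gf == form
        if not rows.any():
            raise ValidationError(f"no modelled species for growth form {form!r}")
        out[i] = binary_maps[rows].mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# constrained Gaussian mixture (equal shape, free volume and orientation)

@dataclass
class ZoneModel:
    k: int
    weights: np.ndarray
    means: np.ndarray            # (k, d) centroids in suitability space
    covariances: np.ndarray      # (k, d, d)
    labels: np.ndarray           # (n,) argmax-responsibility labels
    log_likelihood: float
    bic: float
    threshold: float             # 5th-percentile intercentroid distance
    responsibilities: np.ndarray = field(default=None, repr=False)  # type: ignore


def _estep(X, weights, means, covs):
    n, d = X.shape
    k = means.shape[0]
    log_r = np.empty((n, k))
    for j in range(k):
        try:
            chol = np.linalg.cholesky(covs[j])
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular component covariance") from exc
        dev = solve_triangular(chol, (X - means[j]).T, lower=True)
        maha = (dev**2).sum(axis=0)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        log_r[:, j] = np.log(weights[j] + 1e-300) - 0.5 * (
            d * np.log(2.0 * np.pi) + logdet + maha
        )
    m = log_r.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(log_r - m).sum(axis=1))
    resp = np.exp(log_r - lse[:, None])
    return resp, lse.sum()


def _mstep_vev(X, resp, reg, inner_iters=4):
    """M-step under shared covariance shape, free volume/orientation."""
    n, d = X.shape
    k = resp.shape[1]
    nk = resp.sum(axis=0) + 1e-12
    weights = nk / n
    means = (resp.T @ X) / nk[:, None]

    omegas = np.empty((k, d))     # eigenvalues of scatter matrices, descending
    rotations = np.empty((k, d, d))
    for j in range(k):
        dev = X - means[j]
        W = (resp[:, j, None] * dev).T @ dev + reg * np.eye(d)
        evals, evecs = np.linalg.eigh(W)
        omegas[j] = evals[::-1]
        rotations[j] = evecs[:, ::-1]

    lam = omegas.sum(axis=1) / (d * nk)          # initial volumes
    shape = np.ones(d)
    for _ in range(inner_iters):
        shape = (omegas / lam[:, None]).sum(axis=0)
        shape = np.maximum(shape, 1e-12)
        shape = shape / np.exp(np.log(shape).mean())   # det = 1
        lam = (omegas / shape[None, :]).sum(axis=1) / (d * nk)
    lam = np.maximum(lam, 1e-12)

    covs = np.empty((k, d, d))
    for j in range(k):
        covs[j] = (rotations[j] * (lam[j] * shape)) @ rotations[j].T + reg * np.eye(d)
    return weights, means, covs


def fit_zones(
    X: np.ndarray,
    k: int = 18,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
    reg: float = 1e-6,
    max_restarts: int = 3,
) -> ZoneModel:
    """Fit the constrained Gaussian mixture to phytoclimate vectors.

    ``X`` is (n_cells, 14). Initialization is seeded k-means
    (``n_init`` starts); EM runs until the per-observation
    log-likelihood changes by less than ``tol``. ``reg`` is added to covariance
    diagonals, which also handles degenerate synthetic surfaces with
    constant components. BIC uses the statistics convention
    (-2 logL + p log n: smaller is better).
    """
    X = np.asarray(X, float)
    n, d = X.shape
    if n < k:
        raise ValueError(f"k={k} exceeds the {n} available cells")
    rng_seed = int(seed) & 0x7FFFFFFF
    last_err: Exception | None = None
    for restart in range(max_restarts):
        try:
            km = KMeans(n_clusters=k, n_init=n_init, random_state=rng_seed + restart)
            labels0 = km.fit_predict(X + (restart > 0) * 1e-8 * np.random.default_rng(
                rng_seed + restart).standard_normal(X.shape))
            resp = np.zeros((n, k))
            resp[np.arange(n), labels0] = 1.0
            ll_prev = -np.inf
            for _ in range(max_iter):
                weights, means, covs = _mstep_vev(X, resp, reg)
                resp, ll = _estep(X, weights, means, covs)
                if abs(ll - ll_prev) < tol * n:
                    break
                ll_prev = ll
            break
        except ConvergenceError as exc:   # singular component: jitter and retry
            last_err = exc
    else:
        raise ConvergenceError(f"EM degenerate after {max_restarts} restarts") from last_err

    # free parameters: weights (k-1) + means (k d) + volumes (k)
    # + shape (d-1) + orientations (k d(d-1)/2)
    p = (k - 1) + k * d + k + (d - 1) + k * d * (d - 1) // 2
    bic = -2.0 * ll + p * np.log(n)
    labels = resp.argmax(axis=1)
    thr = significance_threshold(means) if k >= 2 else np.nan
    return ZoneModel(
        k=k, weights=weights, means=means, covariances=covs, labels=labels,
        log_likelihood=float(ll), bic=float(bic), threshold=float(thr),
        responsibilities=resp,
    )


def scan_zones(X, ks, seed: int = 0, **kwargs) -> dict[int, float]:
    """BIC per candidate component count (smaller is better)."""
    return {k: fit_zones(X, k=k, seed=seed, **kwargs).bic for k in ks}


def significance_threshold(centroids: np.ndarray) -> float:
    """5th percentile (linear interpolation) of pairwise centroid distances."""
    centroids = np.asarray(centroids, float)
    if centroids.shape[0] < 2:
        raise ValueError("need at least two centroids")
    return float(np.percentile(pdist(centroids), 5.0))
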
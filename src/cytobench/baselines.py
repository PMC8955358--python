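"""Built-in reference clusterers and the external-tool adapter.

The benchmark harness ships two deliberately simple, fully deterministic
baselines — Lloyd k-means with k-means++ seeding and a full-covariance
Gaussian-mixture EM — so the end-to-end pipeline is exercisable without
third-party cytometry software.  They are stand-ins for the classes of
algorithm found in production tools (k-means-family and model-based
clustering), not re-implementations of any particular tool.  Outputs from
real tools enter through :func:`load_external_assignments`, a CSV adapter
using the same ``event_index,label`` dialect as the ground-truth
sidecars.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import ConsistencyError, DegenerateFitError
from .evaluation import ClusteringResult


@dataclass(frozen=True)
class BaselineConfig:
    """Shared configuration of the built-in clusterers."""

    method: str = "kmeans"
    k: int = 2
    max_iter: int = 300
    tol: float = 1e-6
    n_restarts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("kmeans", "gmm_em"):
            raise ValueError("method must be 'kmeans' or 'gmm_em'")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


def _kmeans_pp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = len(x)
    centers = np.empty((k, x.shape[1]))
    centers[0] = x[rng.integers(n)]
    d2 = np.sum((x - centers[0]) ** 2, axis=1)
    for j in range(1, k):
        probs = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
        centers[j] = x[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, np.sum((x - centers[j]) ** 2, axis=1))
    return centers


def _lloyd(x: np.ndarray, centers: np.ndarray, max_iter: int, tol: float):
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1)
        new = centers.copy()
        for j in range(len(centers)):
            members = x[assign == j]
            if len(members) == 0:
                # re-seed an emptied centroid at the point farthest from
                # its current nearest centroid
                far = int(d2.min(axis=1).argmax())
                new[j] = x[far]
            else:
                new[j] = members.mean(axis=0)
        shift = np.linalg.norm(new - centers, axis=1).max()
        centers = new
        if shift < tol:
            break
    d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)
    inertia = float(d2[np.arange(len(x)), assign].sum())
    return centers, assign, inertia


def kmeans(points, config: BaselineConfig) -> ClusteringResult:
    """Lloyd k-means, k-means++ seeded, best of ``n_restarts`` by
    within-cluster sum of squares.  Deterministic given ``config.seed``."""
    x = np.asarray(points, dtype=float)
    if len(x) < config.k:
        raise ValueError("need at least k points")
    rng = np.random.default_rng(config.seed)
    best = None
    for _ in range(config.n_restarts):
        centers = _kmeans_pp_init(x, config.k, rng)
        centers, assign, inertia = _lloyd(x, centers, config.max_iter, config.tol)
        if best is None or inertia < best[2]:
            best = (centers, assign, inertia)
    _, assign, _ = best
    return ClusteringResult(labels=assign + 1, source="kmeans")


def _log_gauss(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = x.shape[1]
    chol = np.linalg.cholesky(cov)
    sol = np.linalg.solve(chol, (x - mean).T)
    maha = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


class GmmFit:
    """Converged mixture fit: parameters, responsibilities and the
    per-iteration log-likelihood trace (monotone non-decreasing)."""

    def __init__(self, weights, means, covs, log_likelihoods, labels):
        self.weights = weights
        self.means = means
        self.covariances = covs
        self.log_likelihoods = log_likelihoods
        self.labels = labels


def _em_run(x, k, rng, max_iter, tol, reg):
    n, d = x.shape
    km = kmeans(x, BaselineConfig(k=k, n_restarts=1, seed=int(rng.integers(2**31))))
    labels0 = km.labels - 1
    weights = np.array([max(np.mean(labels0 == j), 1e-6) for j in range(k)])
    weights /= weights.sum()
    means = np.array(
        [x[labels0 == j].mean(axis=0) if np.any(labels0 == j) else x[rng.integers(n)]
         for j in range(k)]
    )
    covs = []
    for j in range(k):
        members = x[labels0 == j]
        c = np.cov(members, rowvar=False) if len(members) > d else np.cov(x, rowvar=False)
        covs.append(np.atleast_2d(c) + reg * np.eye(d))
    covs = np.array(covs)
    ll_trace = []
    prev = -np.inf
    for _ in range(max_iter):
        log_comp = np.column_stack(
            [np.log(weights[j]) + _log_gauss(x, means[j], covs[j]) for j in range(k)]
        )
        log_norm = logsumexp(log_comp, axis=1)
        ll = float(log_norm.sum())
        ll_trace.append(ll)
        resp = np.exp(log_comp - log_norm[:, None])
        nk = resp.sum(axis=0) + 1e-12
        weights = nk / n
        means = (resp.T @ x) / nk[:, None]
        for j in range(k):
            diff = x - means[j]
            covs[j] = (resp[:, j][:, None] * diff).T @ diff / nk[j] + reg * np.eye(d)
        if ll - prev < tol and np.isfinite(prev):
            break
        prev = ll
    log_comp = np.column_stack(
        [np.log(weights[j]) + _log_gauss(x, means[j], covs[j]) for j in range(k)]
    )
    labels = log_comp.argmax(axis=1)
    return GmmFit(weights, means, covs, np.array(ll_trace), labels)


def gmm_em(points, config: BaselineConfig, return_fit: bool = False):
    """Full-covariance Gaussian-mixture EM with k-means initialisation.

    Covariances are regularised by ``+1e-6 I``; convergence when the
    log-likelihood gain drops below ``config.tol``.  Hard labels by
    maximum posterior (the accuracy statistic needs integer counts).
    Best of ``n_restarts`` by final log-likelihood.
    """
    x = np.asarray(points, dtype=float)
    n, d = x.shape
    if n < config.k * (d + 1):
        raise ValueError("need at least k (dim + 1) points for a full-cov fit")
    rng = np.random.default_rng(config.seed)
    best = None
    failures = 0
    for _ in range(config.n_restarts):
        try:
            fit = _em_run(x, config.k, rng, config.max_iter, config.tol, reg=1e-6)
        except np.linalg.LinAlgError:
            failures += 1
            continue
        if best is None or fit.log_likelihoods[-1] > best.log_likelihoods[-1]:
            best = fit
    if best is None:
        raise DegenerateFitError(
            f"all {failures} EM restarts collapsed to singular covariances"
        )
    result = ClusteringResult(labels=best.labels + 1, source="gmm_em")
    return (result, best) if return_fit else result


def run_baseline(points, config: BaselineConfig) -> ClusteringResult:
    """Dispatch on ``config.method``."""
    fn = {"kmeans": kmeans, "gmm_em": gmm_em}[config.method]
    return fn(points, config)


def load_external_assignments(path, expected_total: int) -> ClusteringResult:
    """Read a clustering tool's output CSV (``event_index,label``).

    Every event must appear exactly once; arbitrary label alphabets are
    re-coded to 1..k in sorted order.  ``source`` is the file stem.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != ["event_index", "label"]:
        raise ConsistencyError(
            f"assignment file must have columns event_index,label; got {list(df.columns)}"
        )
    idx = np.sort(df["event_index"].to_numpy())
    if len(df) != expected_total or not np.array_equal(idx, np.arange(expected_total)):
        raise ConsistencyError(
            f"assignment file must cover event_index 0..{expected_total - 1} "
            f"exactly once ({len(df)} rows found)"
        )
    ordered = df.sort_values("event_index")["label"].to_numpy()
    vals = np.unique(ordered)
    recode = {v: i + 1 for i, v in enumerate(vals)}
    labels = np.array([recode[v] for v in ordered])
    return ClusteringResult(labels=labels, source=path.stem)
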
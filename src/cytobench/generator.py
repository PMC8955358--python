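"""Single-cluster sampling: multivariate normal and skew-normal populations.

A cluster is described by a :class:`ClusterModel` — mean, SPD covariance,
skew shape ``alpha`` applied along the x-axis, skew side and event count.
Skew-normal clusters are drawn through the standard stochastic
representation of the multivariate skew-normal: with correlation matrix
``Obar`` and shape vector ``at = (alpha, 0, ...)``, set
``delta = Obar at / sqrt(1 + at' Obar at)``, sample ``(X0, X)`` jointly
Gaussian with ``cor(X0, Xj) = delta_j``, and keep ``X`` when ``X0 > 0``
else ``-X``.  The draw is then location-shifted so the *theoretical* mean
equals the model mean, and mirrored in x for left-skewed populations.

Applying skew shrinks the x-variance by the factor ``1 - 2 delta^2 / pi``;
:func:`rescale_to_preskew_width` undoes that shrinkage (restoring the
width the cluster would have had unskewed) without changing skewness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import DegenerateInputError, InvalidModelError

SkewSide = Literal["right", "left"]


@dataclass(frozen=True)
class ClusterModel:
    """Parametric description of one cell population.

    Attributes
    ----------
    mean : numpy.ndarray
        Population mean in channel intensity units (arbitrary scale).
    covariance : numpy.ndarray
        SPD covariance / scale matrix.
    shape_alpha : float
        Skew-normal shape parameter along x; 0 means normal.  Left skew
        is realised by mirroring, never by a negative alpha.
    skew_side : str
        ``"right"`` or ``"left"``.
    size : int
        Number of events to draw.
    """

    mean: np.ndarray
    covariance: np.ndarray
    shape_alpha: float = 0.0
    skew_side: SkewSide = "right"
    size: int = 1000

    def __post_init__(self) -> None:
        m = np.asarray(self.mean, dtype=float).ravel()
        c = np.asarray(self.covariance, dtype=float)
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "covariance", c)
        if c.shape != (len(m), len(m)):
            raise InvalidModelError("covariance shape must match mean length")
        if not np.allclose(c, c.T, atol=1e-10 * max(1.0, np.abs(c).max())):
            raise InvalidModelError("covariance must be symmetric")
        if np.linalg.eigvalsh(c)[0] <= 0.0:
            raise InvalidModelError("covariance must be positive definite")
        if self.shape_alpha < 0.0:
            raise InvalidModelError(
                "shape_alpha must be >= 0; use skew_side='left' for left skew"
            )
        if self.skew_side not in ("right", "left"):
            raise InvalidModelError("skew_side must be 'right' or 'left'")
        if self.size < 1:
            raise InvalidModelError("size must be a positive integer")

    @property
    def dim(self) -> int:
        return len(self.mean)


def _rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def random_covariance(dim: int, eig_low: float, eig_high: float, rng_seed) -> np.ndarray:
    """Random SPD matrix with eigenvalues uniform in ``[eig_low, eig_high]``.

    Builds ``Q L Q'`` from a uniformly random rotation ``Q`` (QR of a
    Gaussian matrix with the R-diagonal sign fixed) and i.i.d. uniform
    eigenvalues, so the spectrum is controlled exactly.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if not 0.0 < eig_low <= eig_high:
        raise ValueError("need 0 < eig_low <= eig_high")
    rng = _rng(rng_seed)
    eigs = rng.uniform(eig_low, eig_high, size=dim)
    q, r = np.linalg.qr(rng.standard_normal((dim, dim)))
    q = q * np.sign(np.diag(r))
    cov = (q * eigs) @ q.T
    return 0.5 * (cov + cov.T)


def sample_normal_cluster(model: ClusterModel, rng_seed) -> np.ndarray:
    """Draw ``model.size`` i.i.d. multivariate normal events."""
    if model.shape_alpha != 0.0:
        raise InvalidModelError(
            "sample_normal_cluster requires shape_alpha = 0; "
            "use sample_skew_normal_cluster"
        )
    rng = _rng(rng_seed)
    chol = np.linalg.cholesky(model.covariance)
    z = rng.standard_normal((model.size, model.dim))
    return model.mean + z @ chol.T


def _delta_vector(covariance: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    omega = np.sqrt(np.diag(covariance))
    obar = covariance / np.outer(omega, omega)
    shape = np.zeros(len(omega))
    shape[0] = alpha
    denom = np.sqrt(1.0 + shape @ obar @ shape)
    return obar @ shape / denom, omega


def sample_skew_normal_cluster(model: ClusterModel, rng_seed) -> np.ndarray:
    """Draw a multivariate skew-normal cluster (shape along x).

    Uses the selection representation described in the module docstring,
    then shifts location so the theoretical mean equals ``model.mean``
    (the skew-normal mean exceeds its location by
    ``omega * delta * sqrt(2/pi)``).  ``skew_side='left'`` mirrors x about
    the mean afterwards.
    """
    if model.shape_alpha <= 0.0:
        raise InvalidModelError(
            "sample_skew_normal_cluster requires shape_alpha > 0; "
            "use sample_normal_cluster for normal populations"
        )
    rng = _rng(rng_seed)
    delta, omega = _delta_vector(model.covariance, model.shape_alpha)
    dim = model.dim
    joint = np.empty((dim + 1, dim + 1))
    joint[0, 0] = 1.0
    joint[0, 1:] = delta
    joint[1:, 0] = delta
    joint[1:, 1:] = model.covariance / np.outer(omega, omega)
    chol = np.linalg.cholesky(joint)
    raw = rng.standard_normal((model.size, dim + 1)) @ chol.T
    x0 = raw[:, 0]
    z = np.where(x0[:, None] > 0.0, raw[:, 1:], -raw[:, 1:])
    xi = model.mean - omega * delta * np.sqrt(2.0 / np.pi)
    points = xi + z * omega
    if model.skew_side == "left":
        points = mirror_x(points, about=model.mean[0])
    return points


def mirror_x(points: np.ndarray, about: float = 0.0) -> np.ndarray:
    """Reflect the x-coordinate about ``about``; other axes untouched."""
    out = np.array(points, dtype=float, copy=True)
    out[:, 0] = 2.0 * about - out[:, 0]
    return out


def skew_delta(alpha: float) -> float:
    """Induced correlation parameter ``delta = alpha / sqrt(1 + alpha^2)``."""
    return alpha / np.sqrt(1.0 + alpha * alpha)


def skew_normal_skewness(alpha: float) -> float:
    """Closed-form skewness ``gamma_1`` of the skew-normal x-marginal."""
    d = skew_delta(alpha)
    b = d * np.sqrt(2.0 / np.pi)
    return float((4.0 - np.pi) / 2.0 * b**3 / (1.0 - 2.0 * d * d / np.pi) ** 1.5)


def rescale_to_preskew_width(points: np.ndarray, shape_alpha: float) -> np.ndarray:
    """Restore the x-width the cluster would have had without skew.

    Skewing deflates the x-variance to ``1 - 2 delta^2/pi`` of the scale
    variance; this multiplies mean-centered x by the inverse square root
    of that factor.  Skewness is exactly invariant under the operation.
    """
    if shape_alpha <= 0.0:
        raise ValueError("rescale_to_preskew_width requires shape_alpha > 0")
    d = skew_delta(shape_alpha)
    factor = 1.0 / np.sqrt(1.0 - 2.0 * d * d / np.pi)
    out = np.array(points, dtype=float, copy=True)
    cx = out[:, 0].mean()
    out[:, 0] = cx + factor * (out[:, 0] - cx)
    return out


def sample_skewness(values) -> float:
    """Moment-ratio sample skewness ``g1 = m3 / m2^(3/2)``.

    Invariant under positive affine maps of the data and negated by
    mirroring.  Requires at least three values with nonzero variance.
    """
    x = np.asarray(values, dtype=float).ravel()
    if len(x) < 3:
        raise DegenerateInputError("sample skewness needs at least 3 values")
    xc = x - x.mean()
    m2 = np.mean(xc**2)
    if m2 <= 0.0:
        raise DegenerateInputError("sample skewness undefined for constant input")
    m3 = np.mean(xc**3)
    return float(m3 / m2**1.5)
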
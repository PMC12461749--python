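"""Needle-deflection statistics.

Transperineal needles deflect from their planned path while traversing
tissue layers; the displacement between the planned and annotated tip is a
3D deflection vector.  This module filters a table of such vectors, fits a
multivariate Gaussian, and derives the confidence ellipsoid that the
planner uses to represent placement uncertainty around a candidate
location.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .io import ValidationError

__all__ = [
    "DeflectionModel",
    "Ellipsoid",
    "DegenerateModelError",
    "filter_deflections",
    "fit_deflection_gaussian",
    "confidence_ellipsoid",
    "orient_ellipsoid_to_deflection",
    "rotation_between",
]

# floor applied to covariance eigenvalues (mm^2) when the fit is rank
# deficient, so a thin sample still yields a usable (sliver) ellipsoid
EIGENVALUE_FLOOR = 1e-6


class DegenerateModelError(ValueError):
    """The deflection model carries no spread at all."""


@dataclass(frozen=True)
class DeflectionModel:
    """Multivariate-Gaussian model of tip deflection (mm / mm^2)."""

    mean: np.ndarray
    covariance: np.ndarray
    n: int
    confidence_level: float = 0.95
    rank_deficient: bool = False

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float).reshape(3)
        cov = np.asarray(self.covariance, dtype=float).reshape(3, 3)
        if not np.allclose(cov, cov.T, atol=1e-9):
            raise ValidationError("covariance must be symmetric")
        eigvals = np.linalg.eigvalsh(cov)
        if np.any(eigvals < -1e-9):
            raise ValidationError(f"covariance must be PSD, eigenvalues {eigvals}")
        if not (0 < self.confidence_level < 1):
            raise ValidationError("confidence_level must be in (0, 1)")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", (cov + cov.T) / 2.0)

    def to_json(self, path: str | Path) -> Path:
        doc = {
            "mean": self.mean.tolist(),
            "covariance": self.covariance.tolist(),
            "n": self.n,
            "confidence_level": self.confidence_level,
            "rank_deficient": self.rank_deficient,
        }
        Path(path).write_text(json.dumps(doc, indent=2), encoding="utf-8")
        return Path(path)

    @classmethod
    def from_json(cls, path: str | Path) -> "DeflectionModel":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            mean=np.asarray(doc["mean"], dtype=float),
            covariance=np.asarray(doc["covariance"], dtype=float),
            n=int(doc["n"]),
            confidence_level=float(doc["confidence_level"]),
            rank_deficient=bool(doc.get("rank_deficient", False)),
        )


@dataclass(frozen=True)
class Ellipsoid:
    """An ellipsoid in patient space (mm).

    ``rotation`` columns are the principal directions, ordered with
    ``semi_axes`` descending; a point p is inside iff
    ``|| diag(1/semi_axes) R^T (p - center) || <= 1``.
    """

    center: np.ndarray
    semi_axes: np.ndarray
    rotation: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.center, dtype=float).reshape(3)
        s = np.asarray(self.semi_axes, dtype=float).reshape(3)
        r = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        if np.any(s <= 0):
            raise ValidationError(f"semi_axes must be positive, got {s}")
        if np.any(np.diff(s) > 1e-12):
            raise ValidationError(f"semi_axes must be sorted descending, got {s}")
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-6):
            raise ValidationError("rotation must be orthonormal")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "semi_axes", s)
        object.__setattr__(self, "rotation", r)

    @property
    def major_axis(self) -> np.ndarray:
        return self.rotation[:, 0]

    @property
    def volume_mm3(self) -> float:
        return float(4.0 / 3.0 * np.pi * np.prod(self.semi_axes))

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorized membership test for (N, 3) points (boundary inclusive)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        local = (pts - self.center) @ self.rotation  # = R^T (p - c) rowwise
        normed = local / self.semi_axes
        return np.einsum("ij,ij->i", normed, normed) <= 1.0


def filter_deflections(
    vectors: Sequence[np.ndarray] | np.ndarray, max_norm: float
) -> np.ndarray:
    """Drop deflection vectors whose Euclidean norm exceeds ``max_norm``.

    The boundary is kept: a vector of exactly ``max_norm`` mm survives.
    Order is preserved.
    """
    if max_norm <= 0:
        raise ValidationError("max_norm must be positive")
    arr = np.asarray(vectors, dtype=float).reshape(-1, 3)
    if arr.size == 0:
        return arr.reshape(0, 3)
    keep = np.linalg.norm(arr, axis=1) <= max_norm
    return arr[keep]


def fit_deflection_gaussian(
    vectors: Sequence[np.ndarray] | np.ndarray, confidence_level: float = 0.95
) -> DeflectionModel:
    """Fit a multivariate Gaussian to deflection vectors.

    Uses the arithmetic mean and the unbiased (n-1) sample covariance.
    Requires at least 4 vectors for a full-rank 3D fit; a rank-deficient
    covariance (e.g. identical vectors) is flagged on the model and later
    floored when deriving the ellipsoid.
    """
    arr = np.asarray(vectors, dtype=float).reshape(-1, 3)
    if arr.shape[0] < 4:
        raise ValidationError(
            f"need at least 4 deflection vectors for a full-rank fit, got {arr.shape[0]}"
        )
    mean = arr.mean(axis=0)
    cov = np.cov(arr, rowvar=False, ddof=1)
    rank_deficient = bool(np.linalg.matrix_rank(cov, tol=1e-9) < 3)
    if rank_deficient:
        warnings.warn(
            "deflection covariance is rank deficient; confidence ellipsoid "
            "will use an eigenvalue floor",
            stacklevel=2,
        )
    return DeflectionModel(
        mean=mean, covariance=cov, n=arr.shape[0],
        confidence_level=confidence_level, rank_deficient=rank_deficient,
    )


def confidence_ellipsoid(model: DeflectionModel, level: float | None = None) -> Ellipsoid:
    """Gaussian confidence ellipsoid of the deflection distribution.

    Principal directions are the covariance eigenvectors; semi-axis i is
    ``sqrt(q * lambda_i)`` with q the chi-square quantile at ``level`` with
    3 degrees of freedom (the standard confidence region of a trivariate
    Gaussian).  Centered on the model mean.
    """
    if level is None:
        level = model.confidence_level
    if not (0 < level < 1):
        raise ValidationError("level must be in (0, 1)")
    eigvals, eigvecs = np.linalg.eigh(model.covariance)
    eigvals = np.clip(eigvals, 0.0, None)
    if np.all(eigvals <= 0):
        raise DegenerateModelError("all covariance eigenvalues are zero")
    eigvals = np.maximum(eigvals, EIGENVALUE_FLOOR)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    if np.linalg.det(eigvecs) < 0:  # keep a right-handed frame
        eigvecs = eigvecs.copy()
        eigvecs[:, 2] *= -1
    q = stats.chi2.ppf(level, df=3)
    return Ellipsoid(
        center=model.mean, semi_axes=np.sqrt(q * eigvals), rotation=eigvecs
    )


def rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix carrying unit vector u onto unit vector v."""
    u = np.asarray(u, dtype=float) / np.linalg.norm(u)
    v = np.asarray(v, dtype=float) / np.linalg.norm(v)
    w = np.cross(u, v)
    s = np.linalg.norm(w)
    c = float(u @ v)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any axis perpendicular to u
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    k = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])
    return np.eye(3) + k + k @ k * ((1 - c) / s**2)


def orient_ellipsoid_to_deflection(
    ellipsoid: Ellipsoid,
    center: np.ndarray,
    deflection: np.ndarray,
    fallback_rotation: np.ndarray | None = None,
) -> Ellipsoid:
    """Re-center an ellipsoid and align its major axis with a deflection.

    The returned ellipsoid keeps its semi-axes; its orientation is the
    original one composed with the minimal rotation that carries the
    original major axis onto the unit deflection direction.  A zero
    deflection falls back to a template-axis-aligned default orientation
    (``fallback_rotation``, identity if omitted) and emits a warning.
    """
    center = np.asarray(center, dtype=float).reshape(3)
    deflection = np.asarray(deflection, dtype=float).reshape(3)
    norm = np.linalg.norm(deflection)
    if norm < 1e-12:
        warnings.warn(
            "zero deflection: ellipsoid left in default template-aligned "
            "orientation",
            stacklevel=2,
        )
        rot = np.eye(3) if fallback_rotation is None else np.asarray(fallback_rotation, dtype=float)
        return Ellipsoid(center=center, semi_axes=ellipsoid.semi_axes, rotation=rot)
    target = deflection / norm
    align = rotation_between(ellipsoid.major_axis, target)
    return Ellipsoid(
        center=center,
        semi_axes=ellipsoid.semi_axes,
        rotation=align @ ellipsoid.rotation,
    )
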
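"""Synthetic phantom generator.

Produces every input the planner consumes — tumor/prostate/urethra masks,
a pseudo-MR image, a needle template and a table of deflection vectors —
from analytic shapes, so the full pipeline is exercisable and testable
without any clinical data.  One integer seed drives all randomness.

The default deflection distribution is shaped to the dispersion reported
for transperineal prostate insertions: its 95% confidence ellipsoid has
semi-axes of roughly 7.5, 6.4 and 1.0 mm (a flat, axially thin scatter),
with a small systematic bias.  The pseudo-MR mimics only gross tissue
contrast plus Gaussian noise; it carries no needle artifacts, bias fields
or anatomy beyond three nested shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .deflection import Ellipsoid
from .io import LabelVolume, TemplateGrid, ValidationError

__all__ = [
    "PhantomSpec",
    "DEFAULT_DEFLECTION_MEAN",
    "DEFAULT_DEFLECTION_COV",
    "make_phantom",
    "sample_deflections",
    "make_template",
]

# covariance whose 95% ellipsoid (chi2(3) quantile) has semi-axes
# ~(7.52, 6.41, 0.98) mm — a realistic transperineal deflection spread
_Q95 = float(stats.chi2.ppf(0.95, df=3))
DEFAULT_DEFLECTION_COV = np.diag(np.array([7.52, 6.41, 0.98]) ** 2 / _Q95)
DEFAULT_DEFLECTION_MEAN = np.array([0.5, 1.0, 1.5])


@dataclass(frozen=True)
class PhantomSpec:
    """Analytic description of the phantom anatomy and imaging grid.

    The default lesion is a small posterior peripheral-zone tumor
    (12 x 10 x 10 mm) clear of the urethral warmer — the typical
    indication for a two-needle focal cryoablation.
    """

    tumor_center: tuple[float, float, float] = (0.0, -13.0, 0.0)
    tumor_semi_axes: tuple[float, float, float] = (6.0, 5.0, 5.0)
    tumor_rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    prostate_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    prostate_semi_axes: tuple[float, float, float] = (24.0, 22.0, 22.0)
    urethra_radius_mm: float = 2.5
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing must be positive")
        if any(a <= 0 for a in self.tumor_semi_axes + self.prostate_semi_axes):
            raise ValidationError("semi-axes must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")


def _grid(spec: PhantomSpec) -> LabelVolume:
    shape = np.asarray(spec.shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    # center the grid on the prostate
    origin = np.asarray(spec.prostate_center) - (shape - 1) / 2.0 * spacing
    return LabelVolume(
        array=np.zeros(tuple(shape), dtype=np.uint8),
        spacing=spacing,
        origin=origin,
        directions=np.eye(3),
    )


def _sorted_ellipsoid(center, semi_axes, rotation) -> Ellipsoid:
    s = np.asarray(semi_axes, dtype=float)
    order = np.argsort(s)[::-1]
    return Ellipsoid(
        center=np.asarray(center, dtype=float),
        semi_axes=s[order],
        rotation=np.asarray(rotation, dtype=float)[:, order],
    )


def make_phantom(
    spec: PhantomSpec | None = None,
) -> tuple[LabelVolume, LabelVolume, LabelVolume, LabelVolume]:
    """Rasterize the phantom: (tumor, prostate, urethra, pseudo-MR).

    The urethra is a straight cylinder through the prostate center along
    the S axis.  Pseudo-MR intensities: background 100, prostate 140,
    tumor 180, urethra 120, plus a gentle S-gradient and N(0, noise_sd)
    noise from the spec seed.  Deterministic per seed.
    """
    spec = spec or PhantomSpec()
    grid = _grid(spec)
    centers = grid.voxel_centers()

    tumor_e = _sorted_ellipsoid(spec.tumor_center, spec.tumor_semi_axes, spec.tumor_rotation)
    prost_e = _sorted_ellipsoid(spec.prostate_center, spec.prostate_semi_axes, np.eye(3))
    tum = tumor_e.contains(centers)
    pro = prost_e.contains(centers)
    if np.any(tum & ~pro):
        raise ValidationError("tumor is not contained inside the prostate")
    c = np.asarray(spec.prostate_center, dtype=float)
    radial = np.linalg.norm(centers[:, :2] - c[:2], axis=1)
    ure = (radial <= spec.urethra_radius_mm) & pro

    shape = grid.shape
    tumor = grid.with_array(tum.reshape(shape).astype(np.uint8))
    prostate = grid.with_array(pro.reshape(shape).astype(np.uint8))
    urethra = grid.with_array(ure.reshape(shape).astype(np.uint8))

    rng = np.random.default_rng(spec.seed)
    intensity = np.full(centers.shape[0], 100.0)
    intensity[pro] = 140.0
    intensity[ure] = 120.0
    intensity[tum] = 180.0
    intensity += 0.1 * (centers[:, 2] - c[2])  # mild gradient, still "smooth"
    if spec.noise_sd > 0:
        intensity += rng.normal(0.0, spec.noise_sd, size=intensity.shape)
    mri = grid.with_array(intensity.reshape(shape))
    return tumor, prostate, urethra, mri


def sample_deflections(
    covariance: np.ndarray | None = None,
    mean: np.ndarray | None = None,
    n: int = 205,
    seed: int = 0,
) -> np.ndarray:
    """Draw n deflection vectors from a Gaussian, reproducibly per seed."""
    cov = DEFAULT_DEFLECTION_COV if covariance is None else np.asarray(covariance, dtype=float)
    mu = DEFAULT_DEFLECTION_MEAN if mean is None else np.asarray(mean, dtype=float)
    if n < 1:
        raise ValidationError("n must be >= 1")
    eigvals = np.linalg.eigvalsh((cov + cov.T) / 2.0)
    if np.any(eigvals < -1e-9):
        raise ValidationError(f"covariance must be PSD, eigenvalues {eigvals}")
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(mu, cov, size=n, method="eigh")


def make_template(
    pitch: float = 5.0,
    extent: tuple[int, int] = (13, 13),
    origin: tuple[float, float, float] | np.ndarray | None = None,
    tilt: np.ndarray | None = None,
) -> TemplateGrid:
    """A perineal template: a pitch-spaced hole lattice facing along +S.

    ``tilt`` (a rotation matrix) is applied to the default axes
    u=(1,0,0), v=(0,1,0), w=(0,0,1); with zero tilt the insertion axis is
    exactly +S.  ``origin`` defaults to centering the lattice on x=y=0 at
    z=-60 mm (well inferior of the phantom prostate).
    """
    if pitch <= 0:
        raise ValidationError("pitch must be positive")
    rot = np.eye(3) if tilt is None else np.asarray(tilt, dtype=float)
    u, v, w = rot[:, 0], rot[:, 1], rot[:, 2]
    if origin is None:
        half = (np.asarray(extent, dtype=float) - 1) / 2.0 * pitch
        origin = -half[0] * u - half[1] * v + np.array([0.0, 0.0, -60.0])
    return TemplateGrid(
        origin=np.asarray(origin, dtype=float),
        in_plane_axes=np.vstack([u, v]),
        insertion_axis=w,
        hole_spacing=float(pitch),
        extent=tuple(extent),
    )
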
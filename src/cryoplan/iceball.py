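"""Iceball volume estimation.

Two estimators are provided.  The *geometric* model places vendor-chart
isotherm ellipsoids around the needles: a single merged ellipsoid for a
two-needle configuration, one ellipsoid per needle otherwise.  It is fast
and is used to pre-rank candidate placements.

The *volumetric predictor* contract mirrors how a learned model would be
driven: it receives the planning image with the distal shaft of each needle
marked by an out-of-range constant, and returns a binary isotherm mask on
the same grid.  A deterministic surrogate predictor is bundled; it augments
the per-needle geometric union with a synergy closing when needle tips are
close and carves out a warm cylinder around the urethra (the heat-sink of
the urethral warmer catheter).  External predictors register under a string
name and can replace it without touching the planner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .deflection import Ellipsoid, rotation_between
from .io import IsothermSpec, LabelVolume, NeedlePose, ValidationError

__all__ = [
    "IceballPrediction",
    "UnsupportedConfigurationError",
    "GridMismatchError",
    "geometric_iceball",
    "needle_ellipsoids",
    "rasterize_ellipsoids",
    "mark_needles_on_image",
    "predict_iceball",
    "register_predictor",
    "get_predictor",
]


class UnsupportedConfigurationError(ValueError):
    """More needles than the iceball models support."""


class GridMismatchError(ValueError):
    """Volumes passed together do not share grid geometry."""


@dataclass(frozen=True)
class IceballPrediction:
    """A binary frozen-tissue mask (1 = at/below the 0 degree C isotherm)."""

    mask: LabelVolume
    provenance: str

    def __post_init__(self) -> None:
        vals = np.unique(self.mask.array)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValidationError("iceball mask must be binary")


def _axis_rotation(axis: np.ndarray) -> np.ndarray:
    """Orthonormal frame whose first column is the (unit) needle axis."""
    return rotation_between(np.array([1.0, 0.0, 0.0]), axis)


def _single_ellipsoid(needle: NeedlePose, triple: tuple[float, float, float]) -> Ellipsoid:
    length, diameter, tip_offset = triple
    center = needle.tip - tip_offset * needle.axis
    return Ellipsoid(
        center=center,
        semi_axes=np.array([length / 2.0, diameter / 2.0, diameter / 2.0]),
        rotation=_axis_rotation(needle.axis),
    )


def needle_ellipsoids(
    needles: Sequence[NeedlePose], spec: IsothermSpec, merged_pair: bool = True
) -> list[Ellipsoid]:
    """Analytic isotherm ellipsoids for a needle configuration.

    Exactly two needles with ``merged_pair`` produce the single merged
    ellipsoid: centered ``tip_offset`` proximal to the tip midpoint along
    the mean insertion axis, major axis along that mean axis.  One or three
    needles (or ``merged_pair=False``) produce one single-needle ellipsoid
    each.
    """
    if not 1 <= len(needles) <= 3:
        raise UnsupportedConfigurationError(
            f"geometric model supports 1-3 needles, got {len(needles)}"
        )
    for n in needles:
        if abs(np.linalg.norm(n.axis) - 1.0) > 1e-9:
            raise ValidationError("needle axes must be unit length")
    if len(needles) == 2 and merged_pair:
        length, diameter, tip_offset = spec.two_needle_merged
        mean_axis = needles[0].axis + needles[1].axis
        mean_axis = mean_axis / np.linalg.norm(mean_axis)
        midpoint = (needles[0].tip + needles[1].tip) / 2.0
        return [
            Ellipsoid(
                center=midpoint - tip_offset * mean_axis,
                semi_axes=np.array([length / 2.0, diameter / 2.0, diameter / 2.0]),
                rotation=_axis_rotation(mean_axis),
            )
        ]
    return [_single_ellipsoid(n, spec.single_needle) for n in needles]


def rasterize_ellipsoids(
    ellipsoids: Sequence[Ellipsoid],
    grid: LabelVolume,
    centers: np.ndarray | None = None,
) -> np.ndarray:
    """Binary array on ``grid``: voxel set iff its center is inside an ellipsoid."""
    if centers is None:
        centers = grid.voxel_centers()
    inside = np.zeros(centers.shape[0], dtype=bool)
    for e in ellipsoids:
        inside |= e.contains(centers)
    return inside.reshape(grid.shape).astype(np.uint8)


def geometric_iceball(
    needles: Sequence[NeedlePose], spec: IsothermSpec, grid: LabelVolume
) -> IceballPrediction:
    """Fast geometric iceball estimate rasterized on ``grid``."""
    ellipsoids = needle_ellipsoids(needles, spec)
    mask = rasterize_ellipsoids(ellipsoids, grid)
    return IceballPrediction(mask=grid.with_array(mask), provenance="geometric")


# ---------------------------------------------------------------------------
# needle marking (predictor input convention)
# ---------------------------------------------------------------------------


def mark_needles_on_image(
    image: LabelVolume,
    needles: Sequence[NeedlePose],
    marker_value: float,
    distal_len: float = 15.0,
) -> LabelVolume:
    """Burn the distal shaft of each needle into a scalar image.

    Voxels whose centers lie within half a voxel diagonal of the segment
    from ``tip - distal_len * axis`` to ``tip`` are set to ``marker_value``,
    which must lie strictly outside the image intensity range so a
    downstream predictor can identify the needles unambiguously.
    """
    arr = image.array.astype(float, copy=True)
    lo, hi = float(arr.min()), float(arr.max())
    if lo <= marker_value <= hi:
        raise ValidationError(
            f"marker_value {marker_value} lies inside image intensity range "
            f"[{lo}, {hi}]"
        )
    if distal_len < 0:
        raise ValidationError("distal_len must be non-negative")
    tol = 0.5 * float(np.linalg.norm(image.spacing))
    centers = image.voxel_centers()
    marked = np.zeros(centers.shape[0], dtype=bool)
    for n in needles:
        a = n.tip - distal_len * n.axis
        marked |= _dist_to_segment(centers, a, n.tip) <= tol
    arr.ravel()[marked] = marker_value
    return image.with_array(arr)


def _dist_to_segment(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-24:  # degenerate segment: a point
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


# ---------------------------------------------------------------------------
# predictor registry
# ---------------------------------------------------------------------------

Predictor = Callable[[LabelVolume, Sequence[NeedlePose], Mapping], IceballPrediction]

_PREDICTORS: dict[str, Predictor] = {}


def register_predictor(name: str) -> Callable[[Predictor], Predictor]:
    """Decorator registering a volumetric iceball predictor under ``name``."""

    def deco(fn: Predictor) -> Predictor:
        _PREDICTORS[name] = fn
        return fn

    return deco


def get_predictor(name: str) -> Predictor:
    try:
        return _PREDICTORS[name]
    except KeyError:
        raise KeyError(
            f"unknown predictor {name!r}; registered: {sorted(_PREDICTORS)}"
        ) from None


def predict_iceball(
    predictor: str | Predictor,
    marked_image: LabelVolume,
    needles: Sequence[NeedlePose],
    context: Mapping | None = None,
) -> IceballPrediction:
    """Run a registered (or callable) predictor on the planning grid.

    ``context`` may carry an ``isotherm_spec``, surrogate parameters
    (``synergy_distance_mm``, ``synergy_radius_mm``, ``urethra_radius_mm``)
    and a ``urethra`` mask, which must share the planning grid.
    """
    ctx = dict(context or {})
    urethra = ctx.get("urethra")
    if urethra is not None and not marked_image.same_grid(urethra):
        raise GridMismatchError("urethra mask is not on the planning grid")
    fn = get_predictor(predictor) if isinstance(predictor, str) else predictor
    pred = fn(marked_image, needles, ctx)
    if not pred.mask.same_grid(marked_image):
        raise GridMismatchError("predictor returned a mask on a different grid")
    return pred


def _ball_structure(radius_mm: float, spacing: np.ndarray) -> np.ndarray:
    r_vox = np.maximum(np.floor(radius_mm / spacing).astype(int), 0)
    grids = np.indices(2 * r_vox + 1).reshape(3, -1).T - r_vox
    dist = np.linalg.norm(grids * spacing, axis=1)
    return (dist <= radius_mm + 1e-9).reshape(tuple(2 * r_vox + 1))


@register_predictor("geometric")
def _geometric_predictor(
    image: LabelVolume, needles: Sequence[NeedlePose], ctx: Mapping
) -> IceballPrediction:
    spec = ctx.get("isotherm_spec", IsothermSpec())
    return geometric_iceball(needles, spec, image)


@register_predictor("surrogate")
def _surrogate_predictor(
    image: LabelVolume, needles: Sequence[NeedlePose], ctx: Mapping
) -> IceballPrediction:
    """Deterministic stand-in volumetric predictor.

    Union of per-needle single isotherm ellipsoids; when any two tips are
    within ``synergy_distance_mm`` the union is morphologically closed with
    a ball of radius ``synergy_radius_mm`` (freezing synergy between nearby
    needles); voxels within ``urethra_radius_mm`` of a supplied urethra
    mask are cleared (heat sink of the urethral warmer).
    """
    spec = ctx.get("isotherm_spec", IsothermSpec())
    ellipsoids = needle_ellipsoids(needles, spec, merged_pair=False)
    mask = rasterize_ellipsoids(ellipsoids, image, centers=ctx.get("_voxel_centers"))
    tips = np.array([n.tip for n in needles])
    synergy_dist = float(ctx.get("synergy_distance_mm", 20.0))
    if len(tips) >= 2:
        pair_d = np.linalg.norm(tips[:, None, :] - tips[None, :, :], axis=2)
        iu = np.triu_indices(len(tips), k=1)
        if np.any(pair_d[iu] <= synergy_dist):
            struct = _ball_structure(float(ctx.get("synergy_radius_mm", 3.0)), image.spacing)
            mask = ndimage.binary_closing(mask, structure=struct).astype(np.uint8)
    urethra = ctx.get("urethra")
    if urethra is not None and np.any(urethra.array > 0):
        r_u = float(ctx.get("urethra_radius_mm", 4.0))
        dist = ndimage.distance_transform_edt(
            urethra.array == 0, sampling=image.spacing
        )
        mask = np.where(dist <= r_u, 0, mask).astype(np.uint8)
    return IceballPrediction(mask=image.with_array(mask), provenance="surrogate")
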
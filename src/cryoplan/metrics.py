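"""Margin and agreement metrics between iceball and tumor masks.

The central quantity is the minimum ablation margin M: the smallest
Euclidean distance between the iceball boundary and the tumor boundary.
As a pure set distance M cannot distinguish an iceball that generously
covers the tumor from one that misses it, so the default here is a
*signed* margin: positive when the tumor is fully covered, negative
(penetration deficit) when part of it is not.  The literal unsigned value
is available via ``signed=False``.

Boundaries are foreground voxels with at least one six-connected
background neighbor (voxels on the volume edge count as boundary), and all
distances use the exact Euclidean distance transform on the physical mm
grid.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import LabelVolume, ValidationError

__all__ = [
    "MarginReport",
    "EmptyMaskError",
    "boundary_mask",
    "signed_margin_field",
    "min_ablation_margin",
    "margin_above_threshold_pct",
    "dice",
    "hausdorff",
    "margin_heatmap",
    "evaluate_masks",
]

_SIX = ndimage.generate_binary_structure(3, 1)


class EmptyMaskError(ValueError):
    """A metric was asked for on an empty mask."""


@dataclass(frozen=True)
class MarginReport:
    """Summary of the ablation margin between an iceball and a tumor."""

    min_margin_mm: float
    pct_above_threshold: float
    threshold_mm: float
    covered: bool
    per_vertex_margins: np.ndarray  # (n, 4): x, y, z, signed margin mm

    def to_dict(self) -> dict:
        return {
            "min_margin_mm": self.min_margin_mm,
            "pct_above_threshold": self.pct_above_threshold,
            "threshold_mm": self.threshold_mm,
            "covered": self.covered,
            "n_surface_points": int(self.per_vertex_margins.shape[0]),
        }


def _fg(v: LabelVolume) -> np.ndarray:
    return v.array > 0


def _check_pair(iceball: LabelVolume, tumor: LabelVolume) -> None:
    if not iceball.same_grid(tumor):
        raise ValidationError("iceball and tumor must share grid geometry")
    if not np.any(_fg(tumor)):
        raise EmptyMaskError("tumor mask is empty")
    if not np.any(_fg(iceball)):
        raise EmptyMaskError("iceball mask is empty: margin is undefined")


def boundary_mask(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with a six-connected background neighbor."""
    mask = mask.astype(bool)
    eroded = ndimage.binary_erosion(mask, structure=_SIX, border_value=0)
    return mask & ~eroded


def _dist_to_set(target: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """Exact EDT (mm) from every voxel to the nearest voxel of ``target``."""
    if not np.any(target):
        raise EmptyMaskError("distance target set is empty")
    return ndimage.distance_transform_edt(~target, sampling=tuple(spacing))


def signed_margin_field(iceball: LabelVolume, tumor: LabelVolume) -> np.ndarray:
    """Signed margin at every tumor boundary voxel.

    Returns (n, 4) rows (x, y, z, margin_mm): the distance from the voxel
    center to the iceball boundary, negated where the voxel lies outside
    the iceball.
    """
    _check_pair(iceball, tumor)
    ice = _fg(iceball)
    tum_bnd = boundary_mask(_fg(tumor))
    dist_ice_bnd = _dist_to_set(boundary_mask(ice), iceball.spacing)
    idx = np.argwhere(tum_bnd)
    margins = dist_ice_bnd[tuple(idx.T)]
    sign = np.where(ice[tuple(idx.T)], 1.0, -1.0)
    coords = tumor.indices_to_world(idx)
    return np.column_stack([coords, sign * margins])


def min_ablation_margin(
    iceball: LabelVolume, tumor: LabelVolume, signed: bool = True
) -> float:
    """Minimum ablation margin M in mm.

    Unsigned (``signed=False``): the literal minimum boundary-to-boundary
    distance, always >= 0.  Signed (default): identical when the tumor is
    fully covered; otherwise the negated maximum distance from an uncovered
    tumor voxel to the iceball boundary, so under-ablation depth is visible.
    """
    _check_pair(iceball, tumor)
    ice, tum = _fg(iceball), _fg(tumor)
    dist_ice_bnd = _dist_to_set(boundary_mask(ice), iceball.spacing)
    tum_bnd = boundary_mask(tum)
    unsigned = float(dist_ice_bnd[tum_bnd].min())
    if not signed:
        return unsigned
    uncovered = tum & ~ice
    if not np.any(uncovered):
        return unsigned
    return -float(dist_ice_bnd[uncovered].max())


def margin_above_threshold_pct(
    iceball: LabelVolume, tumor: LabelVolume, threshold: float = 5.0
) -> float:
    """Percentage of tumor surface with signed margin >= ``threshold`` mm."""
    field = signed_margin_field(iceball, tumor)
    return float(100.0 * np.mean(field[:, 3] >= threshold))


def dice(a: LabelVolume, b: LabelVolume) -> float:
    """Dice similarity 2|A n B| / (|A| + |B|) of two foreground masks."""
    if not a.same_grid(b):
        raise ValidationError("masks must share grid geometry")
    fa, fb = _fg(a), _fg(b)
    na, nb = int(fa.sum()), int(fb.sum())
    if na == 0 or nb == 0:
        raise EmptyMaskError("dice is undefined for an empty mask")
    return 2.0 * int((fa & fb).sum()) / (na + nb)


def hausdorff(a: LabelVolume, b: LabelVolume) -> float:
    """Symmetric Hausdorff distance (mm) between the two mask boundaries."""
    if not a.same_grid(b):
        raise ValidationError("masks must share grid geometry")
    ba, bb = boundary_mask(_fg(a)), boundary_mask(_fg(b))
    if not np.any(ba) or not np.any(bb):
        raise EmptyMaskError("hausdorff is undefined for an empty mask")
    d_to_b = _dist_to_set(bb, a.spacing)
    d_to_a = _dist_to_set(ba, a.spacing)
    return float(max(d_to_b[ba].max(), d_to_a[bb].max()))


def margin_heatmap(
    iceball: LabelVolume,
    tumor: LabelVolume,
    csv_path: str | Path | None = None,
    png_path: str | Path | None = None,
) -> np.ndarray:
    """Signed margin sampled on the tumor surface, optionally exported.

    The CSV holds one row (x, y, z, margin_mm) per tumor boundary voxel;
    the PNG shows the surface points colored blue (high margin) to red
    (low margin).
    """
    field = signed_margin_field(iceball, tumor)
    if csv_path is not None:
        with Path(csv_path).open("w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["x_mm", "y_mm", "z_mm", "margin_mm"])
            w.writerows(field.tolist())
    if png_path is not None:
        _export_heatmap_png(field, Path(png_path))
    return field


def _export_heatmap_png(field: np.ndarray, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    sc = ax.scatter(
        field[:, 0], field[:, 1], field[:, 2], c=field[:, 3],
        cmap="coolwarm_r", s=8,
    )
    fig.colorbar(sc, ax=ax, label="ablation margin (mm)")
    ax.set_xlabel("R (mm)")
    ax.set_ylabel("A (mm)")
    ax.set_zlabel("S (mm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def evaluate_masks(
    iceball: LabelVolume, tumor: LabelVolume, threshold: float = 5.0
) -> MarginReport:
    """Full margin report for an iceball/tumor pair."""
    field = signed_margin_field(iceball, tumor)
    covered = bool(np.all(_fg(iceball)[_fg(tumor)]))
    return MarginReport(
        min_margin_mm=min_ablation_margin(iceball, tumor),
        pct_above_threshold=float(100.0 * np.mean(field[:, 3] >= threshold)),
        threshold_mm=threshold,
        covered=covered,
        per_vertex_margins=field,
    )
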
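"""Independent brute-force oracles used to check the fast implementations.

Everything here is deliberately naive: boundaries by explicit neighbor
shifts, distances by exhaustive pairwise computation.  Nothing imports the
code paths under test.
"""

import numpy as np
from scipy.spatial.distance import cdist


def bf_boundary(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with >= 1 six-connected background neighbor."""
    mask = mask.astype(bool)
    padded = np.pad(mask, 1, constant_values=False)
    has_bg = np.zeros_like(mask)
    shifts = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    core = (slice(1, -1),) * 3
    for dx, dy, dz in shifts:
        neigh = np.roll(padded, (dx, dy, dz), axis=(0, 1, 2))[core]
        has_bg |= ~neigh
    return mask & has_bg


def _coords(mask: np.ndarray, spacing) -> np.ndarray:
    return np.argwhere(mask) * np.asarray(spacing, dtype=float)


def bf_min_margin(ice: np.ndarray, tum: np.ndarray, spacing, signed=True) -> float:
    """Exhaustive pairwise minimum boundary-to-boundary margin (mm)."""
    bi = _coords(bf_boundary(ice), spacing)
    bt = _coords(bf_boundary(tum), spacing)
    unsigned = float(cdist(bt, bi).min(axis=1).min())
    if not signed:
        return unsigned
    uncovered = tum.astype(bool) & ~ice.astype(bool)
    if not uncovered.any():
        return unsigned
    cu = _coords(uncovered, spacing)
    return -float(cdist(cu, bi).min(axis=1).max())


def bf_signed_margins(ice: np.ndarray, tum: np.ndarray, spacing) -> np.ndarray:
    """Signed margin per tumor boundary voxel."""
    bi = _coords(bf_boundary(ice), spacing)
    bt_idx = np.argwhere(bf_boundary(tum))
    bt = bt_idx * np.asarray(spacing, dtype=float)
    d = cdist(bt, bi).min(axis=1)
    inside = ice.astype(bool)[tuple(bt_idx.T)]
    return np.where(inside, d, -d)


def bf_pct_above(ice: np.ndarray, tum: np.ndarray, spacing, threshold: float) -> float:
    m = bf_signed_margins(ice, tum, spacing)
    return float(100.0 * np.mean(m >= threshold))


def bf_dice(a: np.ndarray, b: np.ndarray) -> float:
    a, b = a.astype(bool), b.astype(bool)
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())


def bf_hausdorff(a: np.ndarray, b: np.ndarray, spacing) -> float:
    ba = _coords(bf_boundary(a), spacing)
    bb = _coords(bf_boundary(b), spacing)
    d = cdist(ba, bb)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def in_ellipsoid(points: np.ndarray, center, semi_axes, rotation) -> np.ndarray:
    """Membership via the explicit quadratic form x^T A^{-1} x <= 1."""
    rotation = np.asarray(rotation, dtype=float)
    a_inv = rotation @ np.diag(1.0 / np.asarray(semi_axes, dtype=float) ** 2) @ rotation.T
    x = np.atleast_2d(points) - np.asarray(center, dtype=float)
    return np.einsum("ij,jk,ik->i", x, a_inv, x) <= 1.0 + 1e-12
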
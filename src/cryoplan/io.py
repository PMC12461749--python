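"""Spatial data model and file IO for the planning pipeline.

All coordinates in this package are physical-space millimeters in the RAS
(right-anterior-superior) convention.  SimpleITK reads both NRRD and NIfTI
into an LPS world frame; the first two world axes are negated on read and
write so that everything downstream is RAS.

Voxel model: the center of voxel (i, j, k) sits at

    world = origin + directions @ (spacing * (i, j, k))

with ``directions`` an orthonormal 3x3 matrix whose columns are the image
axes.  Masks are treated as half-open boxes around voxel centers; every
membership test in the package is a voxel-center test.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import SimpleITK as sitk

__all__ = [
    "LabelVolume",
    "NeedlePose",
    "TemplateGrid",
    "PlannerConfig",
    "IsothermSpec",
    "ValidationError",
    "FormatError",
    "read_label_volume",
    "write_label_volume",
    "read_needle_points",
    "write_needle_points",
    "read_deflection_table",
    "write_deflection_table",
    "read_planner_config",
    "write_planner_config",
]

_LPS_TO_RAS = np.diag([-1.0, -1.0, 1.0])


class ValidationError(ValueError):
    """An input violates a documented invariant."""


class FormatError(IOError):
    """A file could not be parsed as the requested format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabelVolume:
    """A 3D label map with physical geometry.

    ``array`` is indexed ``[i, j, k]`` with 0 = background and positive
    integers as labels; ``spacing`` (mm/voxel), ``origin`` (mm, RAS, center
    of voxel (0,0,0)) and ``directions`` (orthonormal columns) place it in
    patient space.
    """

    array: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    directions: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.array)
        if arr.ndim != 3 or arr.size == 0:
            raise ValidationError("volume array must be non-empty and 3D")
        sp = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(sp <= 0):
            raise ValidationError(f"spacing must be strictly positive, got {sp}")
        og = np.asarray(self.origin, dtype=float).reshape(3)
        dm = np.asarray(self.directions, dtype=float).reshape(3, 3)
        if abs(abs(np.linalg.det(dm)) - 1.0) > 1e-6 or not np.allclose(
            dm.T @ dm, np.eye(3), atol=1e-6
        ):
            raise ValidationError(f"direction matrix is not orthonormal:\n{dm}")
        object.__setattr__(self, "array", arr)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", og)
        object.__setattr__(self, "directions", dm)

    # -- geometry helpers ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.array.shape)  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "LabelVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.directions, other.directions, atol=atol)
        )

    def indices_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map an (N, 3) array of voxel indices to world mm coordinates."""
        idx = np.asarray(idx, dtype=float).reshape(-1, 3)
        return (idx * self.spacing) @ self.directions.T + self.origin

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel center, shape (N, 3), C order."""
        grids = np.indices(self.shape).reshape(3, -1).T
        return self.indices_to_world(grids)

    def foreground_indices(self, label: int | None = None) -> np.ndarray:
        mask = self.array == label if label is not None else self.array > 0
        return np.argwhere(mask)

    def with_array(self, array: np.ndarray) -> "LabelVolume":
        return replace(self, array=array)

    def __eq__(self, other: object) -> bool:  # voxelwise + header
        if not isinstance(other, LabelVolume):
            return NotImplemented
        return self.same_grid(other) and np.array_equal(self.array, other.array)


@dataclass(frozen=True)
class NeedlePose:
    """A needle tip location plus its (unit) insertion axis.

    ``role`` distinguishes the physician's intended target, the achieved
    placement annotated after insertion, and the planner's suggestion.
    """

    tip: np.ndarray
    axis: np.ndarray
    needle_id: int
    role: str = "achieved"

    _ROLES = ("intended", "achieved", "suggested")

    def __post_init__(self) -> None:
        tip = np.asarray(self.tip, dtype=float).reshape(3)
        axis = np.asarray(self.axis, dtype=float).reshape(3)
        if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
            raise ValidationError(f"needle axis must be unit length, got {axis}")
        if int(self.needle_id) < 1:
            raise ValidationError(f"needle_id must be >= 1, got {self.needle_id}")
        if self.role not in self._ROLES:
            raise ValidationError(f"role must be one of {self._ROLES}")
        object.__setattr__(self, "tip", tip)
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "needle_id", int(self.needle_id))


@dataclass(frozen=True)
class TemplateGrid:
    """A perineal needle-guiding template: a lattice of holes on a plane.

    Hole (i, j) sits at ``origin + i*hole_spacing*u + j*hole_spacing*v``
    where u, v are the in-plane axes; needles travel along
    ``insertion_axis``, the plane normal.
    """

    origin: np.ndarray
    in_plane_axes: np.ndarray  # 2x3, rows u and v
    insertion_axis: np.ndarray
    hole_spacing: float
    extent: tuple[int, int]

    def __post_init__(self) -> None:
        og = np.asarray(self.origin, dtype=float).reshape(3)
        ax = np.asarray(self.in_plane_axes, dtype=float).reshape(2, 3)
        w = np.asarray(self.insertion_axis, dtype=float).reshape(3)
        if self.hole_spacing <= 0:
            raise ValidationError("hole_spacing must be positive")
        gram = np.array(
            [
                [ax[0] @ ax[0], ax[0] @ ax[1], ax[0] @ w],
                [ax[1] @ ax[0], ax[1] @ ax[1], ax[1] @ w],
                [w @ ax[0], w @ ax[1], w @ w],
            ]
        )
        if not np.allclose(gram, np.eye(3), atol=1e-6):
            raise ValidationError("template axes must be mutually orthonormal")
        object.__setattr__(self, "origin", og)
        object.__setattr__(self, "in_plane_axes", ax)
        object.__setattr__(self, "insertion_axis", w)
        object.__setattr__(self, "extent", (int(self.extent[0]), int(self.extent[1])))

    def hole_position(self, i: int, j: int) -> np.ndarray:
        return (
            self.origin
            + i * self.hole_spacing * self.in_plane_axes[0]
            + j * self.hole_spacing * self.in_plane_axes[1]
        )

    def hole_indices(self) -> Iterable[tuple[int, int]]:
        for i in range(self.extent[0]):
            for j in range(self.extent[1]):
                yield (i, j)

    def to_dict(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "in_plane_axes": self.in_plane_axes.tolist(),
            "insertion_axis": self.insertion_axis.tolist(),
            "hole_spacing": self.hole_spacing,
            "extent": list(self.extent),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TemplateGrid":
        return cls(
            origin=np.asarray(d["origin"], dtype=float),
            in_plane_axes=np.asarray(d["in_plane_axes"], dtype=float),
            insertion_axis=np.asarray(d["insertion_axis"], dtype=float),
            hole_spacing=float(d["hole_spacing"]),
            extent=tuple(d["extent"]),
        )


@dataclass(frozen=True)
class IsothermSpec:
    """Dimensions of the 0 degree C isotherm used by the geometric iceball model.

    Each triple is (length_mm, diameter_mm, tip_offset_mm): the isotherm is a
    prolate spheroid of the given length along the needle axis and diameter
    across it, whose center sits tip_offset_mm proximal to the needle tip.

    The defaults are documented placeholders shaped like vendor planning-chart
    isotherms for a 1.5 mm straight cryo-needle; override them with the values
    from the chart for the needle actually in use.
    """

    single_needle: tuple[float, float, float] = (30.0, 16.0, 5.0)
    two_needle_merged: tuple[float, float, float] = (35.0, 24.0, 5.0)
    source: str = "placeholder defaults; override from vendor isotherm chart"

    def __post_init__(self) -> None:
        for name, (length, diameter, _off) in (
            ("single_needle", self.single_needle),
            ("two_needle_merged", self.two_needle_merged),
        ):
            if length <= 0 or diameter <= 0:
                raise ValidationError(f"{name}: lengths must be positive")
            if length < diameter:
                raise ValidationError(f"{name}: length must be >= diameter")

    def to_dict(self) -> dict:
        return {
            "single_needle": list(self.single_needle),
            "two_needle_merged": list(self.two_needle_merged),
            "source": self.source,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IsothermSpec":
        return cls(
            single_needle=tuple(d.get("single_needle", (30.0, 16.0, 5.0))),
            two_needle_merged=tuple(d.get("two_needle_merged", (35.0, 24.0, 5.0))),
            source=d.get("source", "unspecified"),
        )


@dataclass(frozen=True)
class PlannerConfig:
    """Tunable planning parameters.

    w1 weighs tumor coverage, w2 weighs placement uncertainty (stage 1) or
    ablation margin (stage 2); both default to 0.5 so the two objectives
    count equally.  Candidate holes must lie between ``min_dist_mm`` and
    ``max_dist_mm`` (inclusive) in-plane from every placed needle, and are
    replicated at ``depth_offsets_mm`` along the template insertion axis.
    """

    w1: float = 0.5
    w2: float = 0.5
    min_dist_mm: float = 10.0
    max_dist_mm: float = 20.0
    depth_offsets_mm: tuple[float, ...] = (-15.0, -10.0, -5.0, 0.0, 5.0, 10.0, 15.0)
    shortlist_size: int = 5
    deflection_filter_mm: float = 15.0
    confidence_level: float = 0.95
    isotherm_spec: IsothermSpec = field(default_factory=IsothermSpec)
    margin_threshold_mm: float = 5.0
    margin_cap_mm: float = 10.0
    normalize_scores: bool = True
    tie_tolerance: float = 1e-9
    synergy_distance_mm: float = 20.0
    synergy_radius_mm: float = 3.0
    urethra_radius_mm: float = 4.0

    def __post_init__(self) -> None:
        if not (0 < self.min_dist_mm < self.max_dist_mm):
            raise ValidationError("need 0 < min_dist_mm < max_dist_mm")
        if self.shortlist_size < 1:
            raise ValidationError("shortlist_size must be >= 1")
        if not (0 < self.confidence_level < 1):
            raise ValidationError("confidence_level must be in (0, 1)")
        if self.w1 < 0 or self.w2 < 0:
            raise ValidationError("weights must be non-negative")
        if self.margin_cap_mm <= 0:
            raise ValidationError("margin_cap_mm must be positive")
        if self.deflection_filter_mm <= 0:
            raise ValidationError("deflection_filter_mm must be positive")
        object.__setattr__(
            self, "depth_offsets_mm", tuple(float(d) for d in self.depth_offsets_mm)
        )

    def to_dict(self) -> dict:
        d = {
            "w1": self.w1,
            "w2": self.w2,
            "min_dist_mm": self.min_dist_mm,
            "max_dist_mm": self.max_dist_mm,
            "depth_offsets_mm": list(self.depth_offsets_mm),
            "shortlist_size": self.shortlist_size,
            "deflection_filter_mm": self.deflection_filter_mm,
            "confidence_level": self.confidence_level,
            "isotherm_spec": self.isotherm_spec.to_dict(),
            "margin_threshold_mm": self.margin_threshold_mm,
            "margin_cap_mm": self.margin_cap_mm,
            "normalize_scores": self.normalize_scores,
            "tie_tolerance": self.tie_tolerance,
            "synergy_distance_mm": self.synergy_distance_mm,
            "synergy_radius_mm": self.synergy_radius_mm,
            "urethra_radius_mm": self.urethra_radius_mm,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PlannerConfig":
        d = dict(d)
        known = {f for f in cls.__dataclass_fields__}  # noqa: C416
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "isotherm_spec" in d:
            d["isotherm_spec"] = IsothermSpec.from_dict(d["isotherm_spec"])
        if "depth_offsets_mm" in d:
            d["depth_offsets_mm"] = tuple(d["depth_offsets_mm"])
        try:
            return cls(**d)
        except TypeError as exc:
            raise ValidationError(str(exc)) from exc


# ---------------------------------------------------------------------------
# volume IO
# ---------------------------------------------------------------------------

_FMT_IO = {"nrrd": "NrrdImageIO", "nifti": "NiftiImageIO"}


def _check_fmt(fmt: str) -> str:
    if fmt not in _FMT_IO:
        raise ValidationError(f"fmt must be one of {sorted(_FMT_IO)}, got {fmt!r}")
    return _FMT_IO[fmt]


def read_label_volume(path: str | Path, fmt: str) -> LabelVolume:
    """Read a label volume from NRRD or NIfTI into the RAS data model.

    The file must actually be in the named format: an NRRD handed to
    ``fmt="nifti"`` raises :class:`FormatError` rather than being misread.
    """
    imageio = _check_fmt(fmt)
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    reader = sitk.ImageFileReader()
    reader.SetImageIO(imageio)
    reader.SetFileName(str(path))
    try:
        img = reader.Execute()
    except RuntimeError as exc:
        raise FormatError(f"could not read {path} as {fmt}: {exc}") from exc
    return _from_sitk(img)


def write_label_volume(volume: LabelVolume, path: str | Path, fmt: str) -> Path:
    imageio = _check_fmt(fmt)
    path = Path(path)
    img = _to_sitk(volume)
    writer = sitk.ImageFileWriter()
    writer.SetImageIO(imageio)
    writer.SetFileName(str(path))
    try:
        writer.Execute(img)
    except RuntimeError as exc:
        raise IOError(f"could not write {path}: {exc}") from exc
    return path


def _from_sitk(img: sitk.Image) -> LabelVolume:
    if img.GetDimension() != 3:
        raise ValidationError(f"expected a 3D volume, got {img.GetDimension()}D")
    arr = sitk.GetArrayFromImage(img)  # [k, j, i]
    arr = np.ascontiguousarray(arr.transpose(2, 1, 0))
    directions_lps = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    origin_lps = np.asarray(img.GetOrigin(), dtype=float)
    return LabelVolume(
        array=arr,
        spacing=np.asarray(img.GetSpacing(), dtype=float),
        origin=_LPS_TO_RAS @ origin_lps,
        directions=_LPS_TO_RAS @ directions_lps,
    )


def _to_sitk(volume: LabelVolume) -> sitk.Image:
    arr = np.ascontiguousarray(volume.array.transpose(2, 1, 0))
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    img.SetOrigin(tuple(_LPS_TO_RAS @ volume.origin))
    img.SetDirection(tuple((_LPS_TO_RAS @ volume.directions).ravel()))
    return img


# ---------------------------------------------------------------------------
# needle points
# ---------------------------------------------------------------------------


def read_needle_points(
    path: str | Path, default_axis: Sequence[float] = (0.0, 0.0, 1.0)
) -> list[NeedlePose]:
    """Read needle tip annotations from CSV or a markups-style JSON file.

    CSV columns: needle_id, role, x, y, z and optionally ax, ay, az.  A
    markups JSON (3D-Slicer dialect) is recognized by extension or content;
    only the control-point ``position`` triplets are consumed, needles are
    numbered in file order with role "achieved".
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json" or text.lstrip().startswith("{"):
        return _parse_markups_json(text, default_axis)
    return _parse_needle_csv(text, default_axis)


def _parse_needle_csv(text: str, default_axis: Sequence[float]) -> list[NeedlePose]:
    rows = list(csv.reader(text.splitlines()))
    if not rows:
        raise FormatError("empty needle CSV")
    header = [h.strip().lower() for h in rows[0]]
    required = ["needle_id", "role", "x", "y", "z"]
    if header[: len(required)] != required:
        raise FormatError(f"needle CSV must start with columns {required}, got {header}")
    has_axis = header[5:8] == ["ax", "ay", "az"]
    poses = []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or all(not c.strip() for c in row):
            continue
        try:
            nid = int(row[0])
            xyz = [float(v) for v in row[2:5]]
            axis = [float(v) for v in row[5:8]] if has_axis and len(row) >= 8 else list(default_axis)
        except ValueError as exc:
            raise FormatError(f"needle CSV row {lineno}: non-numeric value ({exc})") from exc
        poses.append(NeedlePose(tip=np.array(xyz), axis=np.array(axis), needle_id=nid, role=row[1].strip()))
    return poses


def _parse_markups_json(text: str, default_axis: Sequence[float]) -> list[NeedlePose]:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid markups JSON: {exc}") from exc
    points: list[list[float]] = []
    for markup in doc.get("markups", []):
        for cp in markup.get("controlPoints", []):
            pos = cp.get("position")
            if pos is None or len(pos) != 3:
                raise FormatError("markups control point without 3-element 'position'")
            points.append([float(v) for v in pos])
    return [
        NeedlePose(tip=np.array(p), axis=np.array(list(default_axis), dtype=float), needle_id=i + 1)
        for i, p in enumerate(points)
    ]


def write_needle_points(poses: Sequence[NeedlePose], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["needle_id", "role", "x", "y", "z", "ax", "ay", "az"])
        for p in poses:
            w.writerow([p.needle_id, p.role, *map(float, p.tip), *map(float, p.axis)])
    return path


# ---------------------------------------------------------------------------
# deflection tables and config
# ---------------------------------------------------------------------------


def read_deflection_table(path: str | Path) -> np.ndarray:
    """Read an (n, 3) array of deflection displacement vectors in mm.

    CSV with header columns dx_mm, dy_mm, dz_mm (optional leading case_id).
    """
    import pandas as pd

    df = pd.read_csv(path)
    cols = ["dx_mm", "dy_mm", "dz_mm"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"deflection table missing columns {missing}")
    vals = df[cols].to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)):
        bad = int(np.argwhere(~np.isfinite(vals))[0, 0]) + 2  # header + 1-based
        raise FormatError(f"deflection table row {bad}: non-numeric value")
    return vals


def write_deflection_table(vectors: np.ndarray, path: str | Path) -> Path:
    import pandas as pd

    arr = np.asarray(vectors, dtype=float).reshape(-1, 3)
    pd.DataFrame(arr, columns=["dx_mm", "dy_mm", "dz_mm"]).to_csv(path, index=False)
    return Path(path)


def read_planner_config(path: str | Path) -> PlannerConfig:
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid config JSON: {exc}") from exc
    return PlannerConfig.from_dict(doc)


def write_planner_config(config: PlannerConfig, path: str | Path) -> Path:
    Path(path).write_text(json.dumps(config.to_dict(), indent=2), encoding="utf-8")
    return Path(path)
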
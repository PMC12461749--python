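"""Adaptive needle-placement optimization.

After the first cryo-needle is in, the planner suggests where to put the
next one.  It enumerates every template hole within the allowed annulus of
the placed needle(s) at seven depths, ranks all candidates with a fast
overlap score

    O_S = W1 * |V_Geo n V_T| / |V_T| + W2 * <|V_C n V_T| / |V_T|>

(geometric-iceball coverage plus deflection-confidence-ellipsoid coverage,
the ellipsoid term averaged over the not-yet-final needles), shortlists
the best five, re-evaluates those with the volumetric iceball predictor
and scores them by

    P_S = W1 * coverage + W2 * clamp(M, 0, cap) / cap

where M is the signed minimum ablation margin.  The best candidate (both,
on an exact tie) is suggested together with a depth adjustment for the
first needle.

Intersection terms are normalized by tumor volume and the margin by
``margin_cap_mm`` so that both equations combine dimensionless quantities
in [0, 1]; set ``normalize_scores=False`` in the config to score with raw
mm^3 / mm instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .deflection import (
    DeflectionModel,
    Ellipsoid,
    confidence_ellipsoid,
    orient_ellipsoid_to_deflection,
)
from .iceball import (
    IceballPrediction,
    mark_needles_on_image,
    needle_ellipsoids,
    predict_iceball,
)
from .io import (
    LabelVolume,
    NeedlePose,
    PlannerConfig,
    TemplateGrid,
    ValidationError,
)
from .metrics import EmptyMaskError, min_ablation_margin

__all__ = [
    "Candidate",
    "CandidateScore",
    "PlanRecommendation",
    "EmptyCandidateError",
    "PlanningError",
    "enumerate_candidates",
    "overlap_score",
    "shortlist",
    "performance_score",
    "recommend_next_needle",
]


class EmptyCandidateError(ValueError):
    """No template hole satisfies the distance constraints."""


class PlanningError(RuntimeError):
    """The optimization loop could not produce a recommendation."""


@dataclass(frozen=True)
class Candidate:
    """A legal next-needle placement: a template hole at a depth offset."""

    hole_index: tuple[int, int]
    depth_offset_mm: float
    pose: NeedlePose
    in_plane_dist_mm: float


@dataclass(frozen=True)
class CandidateScore:
    """Scores attached to a candidate (p_s and m_mm only once shortlisted)."""

    candidate: Candidate
    o_s: float
    p_s: float | None = None
    m_mm: float | None = None

    def to_dict(self) -> dict:
        return {
            "hole_index": list(self.candidate.hole_index),
            "depth_offset_mm": self.candidate.depth_offset_mm,
            "tip": [float(v) for v in self.candidate.pose.tip],
            "in_plane_dist_mm": self.candidate.in_plane_dist_mm,
            "o_s": self.o_s,
            "p_s": self.p_s,
            "m_mm": self.m_mm,
        }


@dataclass(frozen=True)
class PlanRecommendation:
    """The planner's output: suggestion(s), depth advice, and the audit trail."""

    suggestions: tuple[CandidateScore, ...]
    needle1_depth_adjustment_mm: float
    audit: tuple[CandidateScore, ...] = field(default=(), repr=False)

    def to_dict(self) -> dict:
        return {
            "suggestions": [s.to_dict() for s in self.suggestions],
            "needle1_depth_adjustment_mm": self.needle1_depth_adjustment_mm,
            "audit": [s.to_dict() for s in self.audit],
        }


# ---------------------------------------------------------------------------
# candidate enumeration
# ---------------------------------------------------------------------------


def _in_plane_distance(p: np.ndarray, q: np.ndarray, normal: np.ndarray) -> float:
    d = np.asarray(p, dtype=float) - np.asarray(q, dtype=float)
    d = d - (d @ normal) * normal
    return float(np.linalg.norm(d))


def enumerate_candidates(
    template: TemplateGrid,
    needle1: NeedlePose,
    config: PlannerConfig,
    other_needles: Sequence[NeedlePose] = (),
) -> list[Candidate]:
    """All template holes in the annulus, replicated at the depth offsets.

    A hole qualifies when its in-plane distance (perpendicular to the
    template insertion axis, i.e. measured at tip depth) to ``needle1`` —
    and to every pose in ``other_needles`` — lies inclusively within
    ``[min_dist_mm, max_dist_mm]``.  Each qualifying hole yields one
    candidate per configured depth offset, with the tip placed along the
    template insertion axis relative to needle 1's depth.
    """
    w = template.insertion_axis
    depth1 = float((needle1.tip - template.origin) @ w)
    next_id = 1 + max([needle1.needle_id, *(n.needle_id for n in other_needles)])
    tol = 1e-9
    anchors = [needle1, *other_needles]
    candidates: list[Candidate] = []
    dists_n1: list[float] = []
    for i, j in template.hole_indices():
        hole = template.hole_position(i, j)
        d1 = _in_plane_distance(hole, needle1.tip, w)
        dists_n1.append(d1)
        ok = all(
            config.min_dist_mm - tol
            <= _in_plane_distance(hole, a.tip, w)
            <= config.max_dist_mm + tol
            for a in anchors
        )
        if not ok:
            continue
        for off in config.depth_offsets_mm:
            tip = hole + (depth1 + off) * w
            pose = NeedlePose(tip=tip, axis=w, needle_id=next_id, role="suggested")
            candidates.append(
                Candidate(
                    hole_index=(i, j),
                    depth_offset_mm=float(off),
                    pose=pose,
                    in_plane_dist_mm=d1,
                )
            )
    if not candidates:
        raise EmptyCandidateError(
            "no template hole lies within "
            f"[{config.min_dist_mm}, {config.max_dist_mm}] mm of all placed "
            f"needles (hole distances to needle 1 range "
            f"{min(dists_n1):.2f}-{max(dists_n1):.2f} mm)"
        )
    return candidates


# ---------------------------------------------------------------------------
# stage-1 overlap score
# ---------------------------------------------------------------------------


def _tumor_centers(tumor: LabelVolume) -> np.ndarray:
    idx = np.argwhere(tumor.array > 0)
    if idx.size == 0:
        raise EmptyMaskError("tumor mask is empty")
    return tumor.indices_to_world(idx)


def overlap_score(
    tumor: LabelVolume,
    geo: IceballPrediction,
    conf: Ellipsoid | Sequence[Ellipsoid],
    config: PlannerConfig,
) -> float:
    """Combined geometric-iceball / confidence-ellipsoid overlap score.

    With one ellipsoid this is the two-needle form; with several, the
    ellipsoid coverages are averaged (three-needle form).  Under the
    default normalization every term is a fraction of tumor volume.
    """
    if not geo.mask.same_grid(tumor):
        raise ValidationError("geometric iceball and tumor must share a grid")
    tum = tumor.array > 0
    n_t = int(tum.sum())
    if n_t == 0:
        raise EmptyMaskError("tumor mask is empty")
    ellipsoids = [conf] if isinstance(conf, Ellipsoid) else list(conf)
    centers = _tumor_centers(tumor)
    geo_count = int((geo.mask.array.astype(bool) & tum).sum())
    ell_counts = [int(e.contains(centers).sum()) for e in ellipsoids]
    if config.normalize_scores:
        geo_term = geo_count / n_t
        ell_term = float(np.mean([c / n_t for c in ell_counts]))
    else:
        vv = tumor.voxel_volume_mm3
        geo_term = geo_count * vv
        ell_term = float(np.mean([c * vv for c in ell_counts]))
    return config.w1 * geo_term + config.w2 * ell_term


def _overlap_terms_analytic(
    tumor_centers: np.ndarray,
    n_tumor: int,
    geo_ellipsoids: Sequence[Ellipsoid],
    conf_ellipsoids: Sequence[Ellipsoid],
    config: PlannerConfig,
    voxel_volume: float,
) -> float:
    """Overlap score via ellipsoid membership at tumor voxel centers.

    Exactly equivalent to rasterizing the geometric iceball and counting,
    because rasterization is itself a voxel-center membership test.
    """
    geo_in = np.zeros(n_tumor, dtype=bool)
    for e in geo_ellipsoids:
        geo_in |= e.contains(tumor_centers)
    geo_count = int(geo_in.sum())
    ell_counts = [int(e.contains(tumor_centers).sum()) for e in conf_ellipsoids]
    if config.normalize_scores:
        geo_term = geo_count / n_tumor
        ell_term = float(np.mean([c / n_tumor for c in ell_counts]))
    else:
        geo_term = geo_count * voxel_volume
        ell_term = float(np.mean([c * voxel_volume for c in ell_counts]))
    return config.w1 * geo_term + config.w2 * ell_term


# ---------------------------------------------------------------------------
# shortlist and stage-2 performance score
# ---------------------------------------------------------------------------


def _rank_key(s: CandidateScore) -> tuple:
    return (
        -s.o_s,
        abs(s.candidate.depth_offset_mm),
        s.candidate.in_plane_dist_mm,
        s.candidate.hole_index,
        s.candidate.depth_offset_mm,
    )


def shortlist(
    scored: Sequence[CandidateScore], k: int, tie_tolerance: float = 1e-9
) -> list[CandidateScore]:
    """The k candidates with the highest overlap score.

    Ties at the cut are broken by smaller |depth offset|, then smaller
    in-plane distance, then lexicographic hole index; candidates still
    indistinguishable from the k-th are all retained.
    """
    if k < 1:
        raise ValidationError("shortlist size must be >= 1")
    ordered = sorted(scored, key=_rank_key)
    if len(ordered) <= k:
        if len(ordered) < k:
            warnings.warn(
                f"only {len(ordered)} candidates available for a shortlist of {k}",
                stacklevel=2,
            )
        return ordered
    kept = ordered[:k]
    cut = kept[-1]
    for s in ordered[k:]:
        # hole index orders candidates deterministically but does not break a
        # tie for retention: equally-scored mirror holes are both kept
        same = (
            abs(s.o_s - cut.o_s) <= tie_tolerance
            and abs(s.candidate.depth_offset_mm) == abs(cut.candidate.depth_offset_mm)
            and s.candidate.in_plane_dist_mm == cut.candidate.in_plane_dist_mm
        )
        if same:
            kept.append(s)
        else:
            break
    return kept


def performance_score(
    iceball: IceballPrediction, tumor: LabelVolume, config: PlannerConfig
) -> tuple[float, float]:
    """Stage-2 score: predicted coverage combined with the ablation margin.

    Returns ``(p_s, m_mm)`` where ``m_mm`` is the signed minimum ablation
    margin.  Under the default normalization the margin is clamped to
    ``[0, margin_cap_mm]`` and divided by the cap.
    """
    tum = tumor.array > 0
    n_t = int(tum.sum())
    if n_t == 0:
        raise EmptyMaskError("tumor mask is empty")
    inter = int((iceball.mask.array.astype(bool) & tum).sum())
    m = min_ablation_margin(iceball.mask, tumor, signed=True)
    if config.normalize_scores:
        coverage = inter / n_t
        margin_term = float(np.clip(m, 0.0, config.margin_cap_mm)) / config.margin_cap_mm
    else:
        coverage = inter * tumor.voxel_volume_mm3
        margin_term = m
    return config.w1 * coverage + config.w2 * margin_term, m


# ---------------------------------------------------------------------------
# the full recommendation loop
# ---------------------------------------------------------------------------


def _split_roles(
    needles: Sequence[NeedlePose],
) -> tuple[dict[int, NeedlePose], dict[int, NeedlePose]]:
    achieved = {n.needle_id: n for n in needles if n.role == "achieved"}
    intended = {n.needle_id: n for n in needles if n.role == "intended"}
    return achieved, intended


def recommend_next_needle(
    tumor: LabelVolume,
    needles: Sequence[NeedlePose],
    template: TemplateGrid,
    defl_model: DeflectionModel,
    predictor: str = "surrogate",
    config: PlannerConfig | None = None,
    context: Mapping | None = None,
) -> PlanRecommendation:
    """Suggest the placement of the next needle.

    ``needles`` carries the achieved poses of the already-inserted
    needle(s) and at least needle 1's intended pose (the deflection
    direction is achieved minus intended).  With one achieved needle the
    second is planned; with two, the third.  ``context`` is forwarded to
    the predictor (urethra mask, isotherm override, background image under
    key "image").

    The loop: enumerate candidates -> overlap-score all -> shortlist ->
    predictor + performance-score each -> best candidate(s), then sweep
    the depth offsets on needle 1 (next needle fixed) for the depth
    adjustment suggestion.
    """
    config = config or PlannerConfig()
    ctx = dict(context or {})
    achieved, intended = _split_roles(needles)
    n_placed = len(achieved)
    if n_placed not in (1, 2):
        raise PlanningError(f"need 1 or 2 achieved needles, got {n_placed}")
    ids = sorted(achieved)
    needle1 = achieved[ids[0]]
    if ids[0] not in intended:
        raise PlanningError("needle 1 intended pose is required for the deflection direction")
    defl1 = needle1.tip - intended[ids[0]].tip
    deflections = [defl1]
    if n_placed == 2:
        n2 = achieved[ids[1]]
        defl2 = n2.tip - intended[ids[1]].tip if ids[1] in intended else defl1
        deflections.append(defl2)

    others = [achieved[i] for i in ids[1:]]
    candidates = enumerate_candidates(template, needle1, config, others)

    # stage 1: overlap score for every candidate --------------------------------
    # placement uncertainty: the fitted covariance shape, zero-mean (the mean
    # deflection is treated as correctable bias), centered on each candidate
    shape_model = DeflectionModel(
        mean=np.zeros(3),
        covariance=defl_model.covariance,
        n=defl_model.n,
        confidence_level=defl_model.confidence_level,
        rank_deficient=defl_model.rank_deficient,
    )
    base_ell = confidence_ellipsoid(shape_model, config.confidence_level)
    template_rot = np.column_stack(
        [template.insertion_axis, template.in_plane_axes[0], template.in_plane_axes[1]]
    )
    tum_centers = _tumor_centers(tumor)
    n_t = tum_centers.shape[0]
    vv = tumor.voxel_volume_mm3

    if n_placed == 2:
        # the placed second needle keeps its own uncertainty term (its
        # ellipsoid is oriented by needle 1's deflection); the new third
        # needle is oriented by the mean of the observed deflections
        ell_n2 = orient_ellipsoid_to_deflection(
            base_ell, achieved[ids[1]].tip, defl1, fallback_rotation=template_rot
        )
        new_defl = (deflections[0] + deflections[1]) / 2.0
    else:
        ell_n2 = None
        new_defl = defl1

    scored: list[CandidateScore] = []
    for cand in candidates:
        needle_set = [needle1, *others, cand.pose]
        geo_ells = needle_ellipsoids(needle_set, config.isotherm_spec)
        ell_new = orient_ellipsoid_to_deflection(
            base_ell, cand.pose.tip, new_defl, fallback_rotation=template_rot
        )
        conf_ells = [ell_new] if ell_n2 is None else [ell_n2, ell_new]
        o_s = _overlap_terms_analytic(tum_centers, n_t, geo_ells, conf_ells, config, vv)
        scored.append(CandidateScore(candidate=cand, o_s=o_s))

    short = shortlist(scored, config.shortlist_size, config.tie_tolerance)
    if not short:
        raise PlanningError("shortlist is empty")

    # stage 2: predictor + performance score for the shortlist ------------------
    base_image = ctx.pop("image", None)
    if base_image is None:
        base_image = tumor.with_array(np.zeros(tumor.shape, dtype=float))
    ctx.setdefault("isotherm_spec", config.isotherm_spec)
    ctx.setdefault("synergy_distance_mm", config.synergy_distance_mm)
    ctx.setdefault("synergy_radius_mm", config.synergy_radius_mm)
    ctx.setdefault("urethra_radius_mm", config.urethra_radius_mm)
    ctx.setdefault("_voxel_centers", tumor.voxel_centers())
    marker = float(np.max(base_image.array)) + 1024.0

    def _score_set(needle_set: list[NeedlePose]) -> tuple[float, float]:
        marked = mark_needles_on_image(base_image, needle_set, marker)
        pred = predict_iceball(predictor, marked, needle_set, ctx)
        return performance_score(pred, tumor, config)

    rescored: list[CandidateScore] = []
    for s in short:
        p_s, m = _score_set([needle1, *others, s.candidate.pose])
        rescored.append(CandidateScore(candidate=s.candidate, o_s=s.o_s, p_s=p_s, m_mm=m))

    ranked = sorted(
        rescored,
        key=lambda s: (
            -(s.p_s if s.p_s is not None else -np.inf),
            abs(s.candidate.depth_offset_mm),
            s.candidate.in_plane_dist_mm,
            s.candidate.hole_index,
            s.candidate.depth_offset_mm,
        ),
    )
    best = ranked[0]
    suggestions = [best]
    if len(ranked) > 1 and abs(ranked[1].p_s - best.p_s) <= config.tie_tolerance:
        suggestions.append(ranked[1])

    # depth adjustment for needle 1, next-needle choice held fixed --------------
    w = template.insertion_axis
    depth_scores: list[tuple[float, float]] = []
    for off in sorted(config.depth_offsets_mm, key=lambda o: (abs(o), o)):
        shifted1 = NeedlePose(
            tip=needle1.tip + off * w,
            axis=needle1.axis,
            needle_id=needle1.needle_id,
            role="achieved",
        )
        p_s, _ = _score_set([shifted1, *others, best.candidate.pose])
        depth_scores.append((float(off), p_s))
    best_off = max(depth_scores, key=lambda t: t[1])[0]

    # merge the shortlist scores back into the audit trail
    by_id = {id(s.candidate): s for s in rescored}
    audit = tuple(by_id.get(id(s.candidate), s) for s in scored)
    return PlanRecommendation(
        suggestions=tuple(suggestions),
        needle1_depth_adjustment_mm=best_off,
        audit=audit,
    )
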
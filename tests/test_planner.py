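import numpy as np
import pytest

from cryoplan import (
    DeflectionModel,
    Ellipsoid,
    IsothermSpec,
    NeedlePose,
    PlannerConfig,
    enumerate_candidates,
    make_template,
    overlap_score,
    performance_score,
    recommend_next_needle,
    shortlist,
)
from cryoplan.iceball import IceballPrediction, mark_needles_on_image, predict_iceball
from cryoplan.metrics import min_ablation_margin
from cryoplan.planner import Candidate, CandidateScore, EmptyCandidateError

from conftest import make_volume, sphere_volume

W = np.array([0.0, 0.0, 1.0])


def _pose(tip, nid=1, role="achieved", axis=W):
    return NeedlePose(tip=np.asarray(tip, dtype=float), axis=axis, needle_id=nid, role=role)


def _centered_template(pitch=5.0, extent=(13, 13)):
    half = (np.asarray(extent) - 1) / 2.0 * pitch
    return make_template(pitch=pitch, extent=extent, origin=(-half[0], -half[1], -60.0))


# ---------------------------------------------------------------------------
# candidate enumeration
# ---------------------------------------------------------------------------


def test_enumeration_matches_lattice_oracle():
    """Needle on a hole of a 5 mm lattice, annulus [10, 20]: exactly the 40
    lattice points with radius in {2..4} times 7 depths = 280 candidates."""
    tmpl = _centered_template()
    needle1 = _pose((0.0, 0.0, 0.0))
    cands = enumerate_candidates(tmpl, needle1, PlannerConfig())
    # independent oracle: exhaustive integer-lattice enumeration
    n_holes = sum(
        1
        for i in range(-6, 7)
        for j in range(-6, 7)
        if 10.0 <= 5.0 * np.hypot(i, j) <= 20.0
    )
    assert n_holes == 40
    assert len(cands) == n_holes * 7 == 280
    holes = {c.hole_index for c in cands}
    assert len(holes) == 40
    for c in cands:
        assert 10.0 - 1e-9 <= c.in_plane_dist_mm <= 20.0 + 1e-9
        assert c.depth_offset_mm in PlannerConfig().depth_offsets_mm
        # tip sits at needle-1 depth plus the offset, along the template axis
        assert np.isclose((c.pose.tip - needle1.tip) @ W, c.depth_offset_mm)


def test_depth_planes_per_hole():
    tmpl = _centered_template()
    cands = enumerate_candidates(tmpl, _pose((0, 0, 0)), PlannerConfig())
    per_hole: dict = {}
    for c in cands:
        per_hole.setdefault(c.hole_index, []).append(c.depth_offset_mm)
    for offs in per_hole.values():
        assert sorted(offs) == [-15.0, -10.0, -5.0, 0.0, 5.0, 10.0, 15.0]


def test_empty_annulus_is_diagnosed():
    tmpl = _centered_template(pitch=25.0, extent=(3, 3))
    with pytest.raises(EmptyCandidateError, match="mm"):
        enumerate_candidates(tmpl, _pose((0, 0, 0)), PlannerConfig())


def test_tilted_template_equivariance():
    """Tilting the template keeps the candidate count; tips displace along
    the tilted insertion axis."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.from_rotvec([0.3, 0.0, 0.0]).as_matrix()
    flat = _centered_template()
    half = 6 * 5.0
    tilted = make_template(pitch=5.0, extent=(13, 13),
                           origin=rot @ np.array([-half, -half, -60.0]), tilt=rot)
    n_flat = _pose((0.0, 0.0, 0.0))
    n_tilt = _pose(rot @ np.zeros(3), axis=rot @ W)
    c_flat = enumerate_candidates(flat, n_flat, PlannerConfig())
    c_tilt = enumerate_candidates(tilted, n_tilt, PlannerConfig())
    assert len(c_flat) == len(c_tilt)
    for a, b in zip(c_flat, c_tilt):
        assert a.hole_index == b.hole_index
        assert np.allclose(rot @ a.pose.tip, b.pose.tip, atol=1e-9)


def test_three_needle_annulus_respects_both_needles():
    tmpl = _centered_template()
    n1, n2 = _pose((0, 0, 0)), _pose((15.0, 0, 0), nid=2)
    cands = enumerate_candidates(tmpl, n1, PlannerConfig(), other_needles=[n2])
    for c in cands:
        for anchor in (n1, n2):
            d = np.linalg.norm((c.pose.tip - anchor.tip)[:2])
            assert 10.0 - 1e-9 <= d <= 20.0 + 1e-9


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def _block_tumor():
    """Ten tumor voxels along x at integer world coordinates 0..9."""
    arr = np.zeros((12, 3, 3), dtype=np.uint8)
    arr[0:10, 1, 1] = 1
    return make_volume(arr, origin=(0.0, -1.0, -1.0))


def test_overlap_score_saturation_and_fractions():
    tumor = _block_tumor()
    grid_all = tumor.with_array((tumor.array >= 0).astype(np.uint8))
    full = IceballPrediction(mask=grid_all, provenance="geometric")
    big = Ellipsoid(center=(4.5, 0, 0), semi_axes=(50.0, 49.0, 48.0), rotation=np.eye(3))
    assert overlap_score(tumor, full, big, PlannerConfig()) == 1.0

    # W1=1: iceball covering exactly half the tumor
    half_mask = np.zeros_like(tumor.array)
    half_mask[0:5] = 1
    half = IceballPrediction(mask=tumor.with_array(half_mask), provenance="geometric")
    cfg = PlannerConfig(w1=1.0, w2=0.0)
    assert np.isclose(overlap_score(tumor, half, big, cfg), 0.5)


def test_overlap_score_three_needle_arithmetic():
    """Geometric term 0.6, ellipsoid terms 0.8 and 0.4 at equal weights
    combine to 0.5*0.6 + 0.5*(0.8+0.4)/2 = 0.6."""
    tumor = _block_tumor()
    geo_mask = np.zeros_like(tumor.array)
    geo_mask[0:6] = 1  # 6 of 10 tumor voxels
    geo = IceballPrediction(mask=tumor.with_array(geo_mask), provenance="geometric")
    # spheres covering exactly 8 and 4 of the tumor voxel centers
    e_n2 = Ellipsoid(center=(3.5, 0, 0), semi_axes=(4.0, 4.0, 4.0), rotation=np.eye(3))
    e_n3 = Ellipsoid(center=(1.5, 0, 0), semi_axes=(2.0, 2.0, 2.0), rotation=np.eye(3))
    got = overlap_score(tumor, geo, [e_n2, e_n3], PlannerConfig())
    assert np.isclose(got, 0.6)


def _cand(o_s, hole=(0, 0), off=0.0, ip=12.0):
    pose = _pose((hole[0] * 5.0, hole[1] * 5.0, off), nid=2, role="suggested")
    return CandidateScore(
        candidate=Candidate(hole_index=hole, depth_offset_mm=off, pose=pose,
                            in_plane_dist_mm=ip),
        o_s=o_s,
    )


def test_shortlist_order_statistic_and_ties():
    scored = [_cand(0.1 + 0.001 * k, hole=(k, 0)) for k in range(280)]
    top = shortlist(scored, 5)
    assert len(top) == 5
    worst_kept = min(s.o_s for s in top)
    assert all(s.o_s <= worst_kept for s in scored if s not in top)

    with pytest.warns(UserWarning, match="only 3"):
        assert len(shortlist([_cand(0.1), _cand(0.2), _cand(0.3)], 5)) == 3

    # exact tie at the cut: both retained
    tied = [_cand(0.9 - 0.1 * k, hole=(k, 0)) for k in range(4)]
    tied += [_cand(0.4, hole=(9, 9), off=5.0), _cand(0.4, hole=(9, 9), off=-5.0)]
    kept = shortlist(tied, 5)
    assert len(kept) == 6


def test_performance_score_cases():
    cfg = PlannerConfig()
    tum = sphere_volume(4.0, shape=(40, 40, 40))
    # saturation: uniform margin beyond the cap
    huge = IceballPrediction(mask=sphere_volume(16.0, shape=(40, 40, 40)), provenance="surrogate")
    p, m = performance_score(huge, tum, cfg)
    assert p == 1.0 and m >= cfg.margin_cap_mm
    # iceball identical to tumor: coverage 1, margin 0
    same = IceballPrediction(mask=tum, provenance="surrogate")
    p, m = performance_score(same, tum, cfg)
    assert p == 0.5 and m == 0.0
    # general case follows the stated combination exactly
    part = IceballPrediction(mask=sphere_volume(5.0, shape=(40, 40, 40), center=(2.0, 0, 0)),
                             provenance="surrogate")
    p, m = performance_score(part, tum, cfg)
    cov = (part.mask.array.astype(bool) & (tum.array > 0)).sum() / (tum.array > 0).sum()
    assert np.isclose(p, 0.5 * cov + 0.5 * np.clip(m, 0, 10) / 10)
    assert m == min_ablation_margin(part.mask, tum)


# ---------------------------------------------------------------------------
# the full loop
# ---------------------------------------------------------------------------


def _model():
    cov = np.diag(np.array([7.52, 6.41, 0.98]) ** 2 / 7.8147)
    return DeflectionModel(mean=np.zeros(3), covariance=cov, n=205)


def _sym_scene(tumor_center=(2.5, 5.0, 0.0)):
    """Grid and template mirror-symmetric about the plane x = 2.5."""
    arr = np.zeros((32, 32, 32), dtype=np.uint8)
    vol = make_volume(arr, spacing=(1.0, 1.0, 1.0), origin=(-13.5, -13.5, -13.5))
    centers = vol.voxel_centers()
    tum = np.linalg.norm(centers - np.asarray(tumor_center), axis=1) <= 6.0
    tumor = vol.with_array(tum.reshape(vol.shape).astype(np.uint8))
    tmpl = make_template(pitch=5.0, extent=(13, 13), origin=(-30.0, -30.0, -60.0))
    intended = _pose((2.5, 0.0, 0.0), role="intended")
    achieved = _pose((2.5, 0.0, 2.0), role="achieved")  # purely axial deflection
    return tumor, tmpl, intended, achieved


def test_mirror_symmetric_phantom_yields_tie():
    tumor, tmpl, intended, achieved = _sym_scene()
    rec = recommend_next_needle(tumor, [intended, achieved], tmpl, _model(),
                                predictor="surrogate")
    assert len(rec.suggestions) == 2
    a, b = rec.suggestions
    assert abs(a.p_s - b.p_s) <= 1e-9
    # the two suggested holes are mirror images across x = 2.5 (x -> 5 - x)
    xa, xb = a.candidate.pose.tip[0], b.candidate.pose.tip[0]
    assert np.isclose(xa + xb, 5.0)
    assert np.isclose(a.candidate.pose.tip[1], b.candidate.pose.tip[1])


def test_shifted_tumor_selects_correct_half_plane():
    """A +5 mm tumor shift breaks the mirror tie toward the +x half-plane."""
    tumor, tmpl, intended, achieved = _sym_scene(tumor_center=(7.5, 5.0, 0.0))
    rec = recommend_next_needle(tumor, [intended, achieved], tmpl, _model(),
                                predictor="surrogate")
    best = rec.suggestions[0]
    assert best.candidate.pose.tip[0] > 2.5
    # and it beats its mirror image
    mirror_x = 5.0 - best.candidate.pose.tip[0]
    mirrors = [s for s in rec.audit
               if np.isclose(s.candidate.pose.tip[0], mirror_x)
               and np.isclose(s.candidate.pose.tip[1], best.candidate.pose.tip[1])
               and s.candidate.depth_offset_mm == best.candidate.depth_offset_mm]
    assert mirrors and all(best.o_s > m.o_s or best.p_s is not None for m in mirrors)


def _brute_force_best(tumor, needles, tmpl, model, config, context=None):
    """Independent exhaustive argmax of p_s over every candidate."""
    from cryoplan.deflection import confidence_ellipsoid, orient_ellipsoid_to_deflection

    achieved = [n for n in needles if n.role == "achieved"]
    intended = {n.needle_id: n for n in needles if n.role == "intended"}
    n1 = achieved[0]
    cands = enumerate_candidates(tmpl, n1, config, achieved[1:])
    base_img = tumor.with_array(np.zeros(tumor.shape, dtype=float))
    ctx = dict(context or {})
    ctx.setdefault("isotherm_spec", config.isotherm_spec)
    best, best_key = None, None
    for c in cands:
        needle_set = [*achieved, c.pose]
        marked = mark_needles_on_image(base_img, needle_set, 1024.0)
        pred = predict_iceball("surrogate", marked, needle_set, ctx)
        p_s, _ = performance_score(pred, tumor, config)
        key = (-p_s, abs(c.depth_offset_mm), c.in_plane_dist_mm, c.hole_index,
               c.depth_offset_mm)
        if best_key is None or key < best_key:
            best, best_key = c, key
    return best, -best_key[0]


def test_recommendation_equals_bruteforce_argmax():
    """With the shortlist widened to every candidate, the recommendation is
    the exhaustive argmax of the performance score."""
    tumor, tmpl, intended, achieved = _sym_scene(tumor_center=(7.5, 5.0, 0.0))
    config = PlannerConfig(shortlist_size=10_000)
    rec = recommend_next_needle(tumor, [intended, achieved], tmpl, _model(),
                                predictor="surrogate", config=config)
    best, best_ps = _brute_force_best(tumor, [intended, achieved], tmpl, _model(), config)
    got = rec.suggestions[0]
    assert got.candidate.hole_index == best.hole_index
    assert got.candidate.depth_offset_mm == best.depth_offset_mm
    assert np.isclose(got.p_s, best_ps, atol=1e-12)


def test_shallow_needle_gets_deeper_depth_suggestion():
    """Needle 1 placed 10 mm too shallow: the depth adjustment is positive
    and does not lower the performance score."""
    tumor, tmpl, _, _ = _sym_scene(tumor_center=(2.5, 5.0, 0.0))
    intended = _pose((2.5, 0.0, -10.0), role="intended")
    achieved = _pose((2.5, 0.0, -10.0 + 1e-6), role="achieved")
    rec = recommend_next_needle(tumor, [intended, achieved], tmpl, _model(),
                                predictor="surrogate")
    assert rec.needle1_depth_adjustment_mm in (5.0, 10.0, 15.0)


def test_determinism_and_annulus_invariant():
    tumor, tmpl, intended, achieved = _sym_scene(tumor_center=(7.5, 5.0, 0.0))
    r1 = recommend_next_needle(tumor, [intended, achieved], tmpl, _model())
    r2 = recommend_next_needle(tumor, [intended, achieved], tmpl, _model())
    assert r1.to_dict() == r2.to_dict()
    for s in r1.suggestions:
        d = np.linalg.norm((s.candidate.pose.tip - achieved.tip)[:2])
        assert 10.0 - 1e-9 <= d <= 20.0 + 1e-9


def test_weight_sensitivity():
    """w2=0 reduces the stage-2 choice to the pure-coverage argmax; w1=0 to
    the pure-margin argmax."""
    tumor, tmpl, intended, achieved = _sym_scene(tumor_center=(7.5, 5.0, 0.0))
    for w1, w2 in ((1.0, 0.0), (0.0, 1.0)):
        config = PlannerConfig(w1=w1, w2=w2, shortlist_size=10_000)
        rec = recommend_next_needle(tumor, [intended, achieved], tmpl, _model(),
                                    config=config)
        best, best_ps = _brute_force_best(tumor, [intended, achieved], tmpl,
                                          _model(), config)
        assert np.isclose(rec.suggestions[0].p_s, best_ps, atol=1e-12)
        assert rec.suggestions[0].candidate.hole_index == best.hole_index


def test_three_needle_planning_runs():
    tumor, tmpl, intended, achieved = _sym_scene()
    n2i = _pose((2.5, 12.5, 0.0), nid=2, role="intended")
    n2a = _pose((3.5, 12.0, 1.0), nid=2, role="achieved")
    rec = recommend_next_needle(tumor, [intended, achieved, n2i, n2a], tmpl, _model())
    s = rec.suggestions[0]
    assert s.p_s is not None
    for anchor in (achieved, n2a):
        d = np.linalg.norm((s.candidate.pose.tip - anchor.tip)[:2])
        assert 10.0 - 1e-9 <= d <= 20.0 + 1e-9
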
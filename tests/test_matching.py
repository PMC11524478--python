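"""Keypoint extraction, robust pair verification, content-sharing scores."""

import numpy as np
import pytest

from figprov.errors import ValidationError
from figprov.evidence import RetrievalConfig
from figprov.matching import (
    MatchResult,
    content_sharing_score,
    extract_keypoints,
    homography_similarity_params,
    hull_area,
    match_and_verify,
)
from figprov.synthetic import TransformOp, apply_chain, synth_panel

from conftest import make_panel


def monotone_chain_area(points):
    """Independent convex-hull area: Andrew's monotone chain + shoelace."""
    pts = sorted(map(tuple, points))
    if len(pts) < 3:
        return 0.0

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    def half(seq):
        out = []
        for p in seq:
            while len(out) >= 2 and cross(out[-2], out[-1], p) <= 0:
                out.pop()
            out.append(p)
        return out

    hull = half(pts)[:-1] + half(reversed(pts))[:-1]
    if len(hull) < 3:
        return 0.0
    x = np.array([p[0] for p in hull])
    y = np.array([p[1] for p in hull])
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class TestExtractKeypoints:
    def test_uniform_panel_has_no_keypoints(self):
        panel = make_panel(np.full((128, 128, 3), 128, np.uint8))
        assert len(extract_keypoints(panel)) == 0

    def test_textured_panel_is_keypoint_rich(self, textured_panel):
        assert len(extract_keypoints(textured_panel)) >= 20

    def test_deterministic(self, textured_panel):
        a = extract_keypoints(textured_panel)
        b = extract_keypoints(textured_panel)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)
        np.testing.assert_array_equal(a.descriptors, b.descriptors)

    def test_coordinates_within_bounds(self, textured_panel):
        kp = extract_keypoints(textured_panel)
        assert (kp.coordinates >= 0).all()
        assert (kp.coordinates[:, 0] < textured_panel.width).all()
        assert (kp.coordinates[:, 1] < textured_panel.height).all()


class TestMatchAndVerify:
    def test_identical_copy_recovers_identity(self, textured_panel):
        copy = make_panel(textured_panel.raster.copy(), "docB/fig0/p0")
        m = match_and_verify(textured_panel, copy)
        assert m.consistent and not m.mirrored
        scale, rot, (tx, ty) = homography_similarity_params(m.homography)
        assert scale == pytest.approx(1.0, rel=0.02)
        assert abs(rot) < 1.0
        assert abs(tx) < 2 and abs(ty) < 2

    def test_mirrored_and_rescaled_copy(self, rng):
        orig = synth_panel("microscopy", rng)
        chain = (TransformOp("hflip"), TransformOp("rescale", (0.75,)))
        P = make_panel(orig, "docA/fig0/p0")
        R = make_panel(apply_chain(orig, chain, rng), "docB/fig0/p0")
        m = match_and_verify(P, R)
        assert m.consistent and m.mirrored
        scale, rot, _ = homography_similarity_params(m.homography)
        # flipped-P frame vs R differ only by the planted rescale
        assert scale == pytest.approx(0.75, rel=0.05)
        assert abs(rot) <= 2.0

    def test_planted_scale_and_rotation_recovered(self, rng):
        orig = synth_panel("microscopy", rng)
        chain = (TransformOp("rotate", (10.0,)), TransformOp("rescale", (1.3,)))
        P = make_panel(orig, "docA/fig0/p0")
        R = make_panel(apply_chain(orig, chain, rng), "docB/fig0/p0")
        m = match_and_verify(P, R)
        assert m.consistent
        scale, rot, _ = homography_similarity_params(m.homography)
        assert scale == pytest.approx(1.3, rel=0.05)
        # rotate() is counter-clockwise; image y grows downward
        assert abs(abs(rot) - 10.0) <= 2.0

    def test_unrelated_noise_panels_inconsistent(self, noise_panel_pair):
        P, R = noise_panel_pair
        m = match_and_verify(P, R)
        assert not m.consistent
        assert m.homography is None and m.n_inliers == 0

    def test_symmetric_consistency(self, rng):
        orig = synth_panel("microscopy", rng)
        chain = (TransformOp("rescale", (0.8,)), TransformOp("jpeg_recompress", (80,)))
        P = make_panel(orig, "docA/fig0/p0")
        R = make_panel(apply_chain(orig, chain, rng), "docB/fig0/p0")
        assert match_and_verify(P, R).consistent == match_and_verify(R, P).consistent

    def test_blank_panels_inconsistent_not_error(self):
        a = make_panel(np.full((96, 96, 3), 200, np.uint8), "docA/f/p0")
        b = make_panel(np.full((96, 96, 3), 200, np.uint8), "docB/f/p0")
        assert not match_and_verify(a, b).consistent


def constructed_match(src_pts, dst_pts, mirrored=False):
    src, dst = np.asarray(src_pts, float), np.asarray(dst_pts, float)
    return MatchResult(("P", "R"), src, dst, np.eye(3), mirrored, consistent=True)


class TestContentSharingScore:
    def test_crop_covering_half_of_source(self):
        """A crop covering 50% of its source scores 1.0 from the crop's side
        and 0.5 from the source's side when matches span the whole crop."""
        P = make_panel(np.zeros((100, 100, 3), np.uint8), "a/f/p0")  # the crop
        R = make_panel(np.zeros((100, 200, 3), np.uint8), "b/f/p0")  # the source
        corners_P = [(0, 0), (100, 0), (100, 100), (0, 100)]
        corners_R = [(0, 0), (100, 0), (100, 100), (0, 100)]  # left half of R
        s = content_sharing_score(constructed_match(corners_P, corners_R), P, R)
        assert s.score_P_given_R == 1.0
        assert s.score_R_given_P == 0.5

    def test_full_overlap_scores_one_on_both_sides(self):
        P = make_panel(np.zeros((80, 80, 3), np.uint8), "a/f/p0")
        R = make_panel(np.zeros((80, 80, 3), np.uint8), "b/f/p0")
        corners = [(0, 0), (80, 0), (80, 80), (0, 80)]
        s = content_sharing_score(constructed_match(corners, corners), P, R)
        assert s.score_P_given_R == s.score_R_given_P == 1.0

    def test_hull_area_matches_shoelace_oracle(self, rng):
        for _ in range(25):
            pts = rng.uniform(0, 50, size=(rng.integers(3, 30), 2))
            assert hull_area(pts) == pytest.approx(monotone_chain_area(pts), abs=1e-9)

    def test_collinear_points_score_zero(self):
        P = make_panel(np.zeros((64, 64, 3), np.uint8), "a/f/p0")
        R = make_panel(np.zeros((64, 64, 3), np.uint8), "b/f/p0")
        line = [(0, 0), (10, 10), (20, 20), (30, 30)]
        square = [(0, 0), (64, 0), (64, 64), (0, 64)]
        s = content_sharing_score(constructed_match(line, square), P, R)
        assert s.score_P_given_R == 0.0
        assert s.score_R_given_P == 1.0

    def test_points_clipped_to_panel_bounds(self):
        P = make_panel(np.zeros((64, 64, 3), np.uint8), "a/f/p0")
        R = make_panel(np.zeros((64, 64, 3), np.uint8), "b/f/p0")
        wild = [(-50, -50), (200, 0), (200, 200), (-50, 200)]
        s = content_sharing_score(constructed_match(wild, wild), P, R)
        assert s.score_P_given_R == 1.0  # clipped hull is the whole panel
        assert s.score_R_given_P == 1.0

    def test_mirrored_points_mapped_back(self):
        P = make_panel(np.zeros((64, 128, 3), np.uint8), "a/f/p0")
        R = make_panel(np.zeros((64, 128, 3), np.uint8), "b/f/p0")
        # hull covering the left half in the flipped frame = right half of P
        half = [(0, 0), (64, 0), (64, 64), (0, 64)]
        s = content_sharing_score(constructed_match(half, half, mirrored=True), P, R)
        assert s.score_P_given_R == pytest.approx(0.5, abs=0.02)

    def test_inconsistent_match_is_contract_violation(self):
        P = make_panel(np.zeros((64, 64, 3), np.uint8), "a/f/p0")
        R = make_panel(np.zeros((64, 64, 3), np.uint8), "b/f/p0")
        bad = MatchResult(("P", "R"), np.empty((0, 2)), np.empty((0, 2)), None, False, False)
        with pytest.raises(ValidationError):
            content_sharing_score(bad, P, R)

    def test_scores_always_in_unit_interval(self, rng):
        P = make_panel(np.zeros((64, 64, 3), np.uint8), "a/f/p0")
        R = make_panel(np.zeros((64, 64, 3), np.uint8), "b/f/p0")
        for _ in range(20):
            pts_p = rng.uniform(-20, 90, size=(12, 2))
            pts_r = rng.uniform(-20, 90, size=(12, 2))
            s = content_sharing_score(constructed_match(pts_p, pts_r), P, R)
            assert 0.0 <= s.score_P_given_R <= 1.0
            assert 0.0 <= s.score_R_given_P <= 1.0
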
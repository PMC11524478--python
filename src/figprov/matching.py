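"""Pixel-level consistency check between two panels.

Given a probe panel P and a retrieved candidate R, the consistency check
matches SIFT interest points between them by brute force (with Lowe's ratio
filter), fits a robust homography H to the candidate correspondences, and
declares the pair consistent when at least ``min_inliers`` correspondences
survive. SIFT is not mirror-invariant, so a failed attempt is retried against
the horizontally flipped probe P'; success on the retry sets the ``mirrored``
flag.

A consistent pair is then quantified by the *content-sharing score*: the area
of the convex hull of the verified interest points on one panel, divided by
that panel's area. The score is directional — a small crop fully contained in
a larger panel scores 1.0 from the crop's side but only the covered fraction
from the source's side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage.feature import SIFT, match_descriptors
from skimage.measure import ransac
from skimage.transform import ProjectiveTransform

from .errors import ValidationError
from .evidence import RetrievalConfig
from .ingest import Panel


@dataclass(frozen=True)
class MatchConfig:
    """Interest-point matching and robust-fit settings.

    ratio: Lowe's ratio for brute-force descriptor matching (raw brute force
    floods the homography solver with false pairs). residual_threshold: max
    reprojection error in px for an inlier. flip_axis: which mirror axis the
    retry uses. rng_seed fixes the robust estimator's sampling so matches are
    reproducible.
    """

    ratio: float = 0.75
    residual_threshold: float = 3.0
    max_trials: int = 10_000
    stop_probability: float = 0.9999
    flip_axis: str = "horizontal"  # or "vertical"
    rng_seed: int = 0


@dataclass
class InterestPointSet:
    """SIFT keypoint coordinates (x, y, pixel centers) and 128-d descriptors."""

    coordinates: np.ndarray  # (N, 2) float, x then y
    descriptors: np.ndarray  # (N, 128)

    def __len__(self) -> int:
        return len(self.coordinates)


@dataclass
class MatchResult:
    pair: tuple[str, str]
    src_points: np.ndarray  # inlier coordinates on P (P' frame when mirrored)
    dst_points: np.ndarray  # matching inlier coordinates on R
    homography: np.ndarray | None  # maps P(')-frame points onto R
    mirrored: bool
    consistent: bool

    @property
    def n_inliers(self) -> int:
        return len(self.src_points)

    @property
    def inlier_pairs(self) -> list[tuple[tuple[float, float], tuple[float, float]]]:
        return [
            (tuple(s), tuple(d)) for s, d in zip(self.src_points, self.dst_points)
        ]


@dataclass(frozen=True)
class ContentShareScore:
    score_P_given_R: float
    score_R_given_P: float

    @property
    def max(self) -> float:
        return max(self.score_P_given_R, self.score_R_given_P)


def _gray(raster: np.ndarray) -> np.ndarray:
    if raster.ndim == 2:
        return raster.astype(np.float64) / 255.0
    return (raster.astype(np.float64) @ np.array([0.299, 0.587, 0.114])) / 255.0


_EMPTY = InterestPointSet(np.empty((0, 2)), np.empty((0, 128)))


def extract_keypoints(panel: Panel | np.ndarray) -> InterestPointSet:
    """Detect SIFT interest points on the grayscale panel.

    Zero keypoints (e.g. a uniform raster) is a valid outcome. Detection is
    deterministic for identical pixel input.
    """
    raster = panel.raster if isinstance(panel, Panel) else panel
    sift = SIFT()
    try:
        sift.detect_and_extract(_gray(raster))
    except RuntimeError:  # skimage raises when no features survive
        return _EMPTY
    coords = sift.keypoints[:, ::-1].astype(np.float64)  # (row, col) -> (x, y)
    return InterestPointSet(coords, sift.descriptors.astype(np.float64))


def _flip_raster(raster: np.ndarray, axis: str) -> np.ndarray:
    return raster[:, ::-1] if axis == "horizontal" else raster[::-1, :]


def _robust_homography(
    src: np.ndarray, dst: np.ndarray, mcfg: MatchConfig, min_inliers: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """RANSAC projective fit; None when no adequate model exists."""
    if len(src) < max(4, min_inliers):
        return None  # robust inliers can never reach the consistency bar
    try:
        model, inliers = ransac(
            (src, dst),
            ProjectiveTransform,
            min_samples=4,
            residual_threshold=mcfg.residual_threshold,
            max_trials=mcfg.max_trials,
            stop_probability=mcfg.stop_probability,
            rng=np.random.default_rng(mcfg.rng_seed),
        )
    except Exception:
        return None  # degenerate sample sets are an inconsistency, not a crash
    if model is None or inliers is None or not np.all(np.isfinite(model.params)):
        return None
    if inliers.sum() < min_inliers or abs(np.linalg.det(model.params)) < 1e-12:
        return None
    return model.params, src[inliers], dst[inliers]


def _match_attempt(
    kp_p: InterestPointSet,
    kp_r: InterestPointSet,
    mcfg: MatchConfig,
    min_inliers: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    if len(kp_p) < 4 or len(kp_r) < 4:
        return None
    pairs = match_descriptors(
        kp_p.descriptors, kp_r.descriptors, cross_check=True, max_ratio=mcfg.ratio
    )
    if len(pairs) == 0:
        return None
    return _robust_homography(
        kp_p.coordinates[pairs[:, 0]],
        kp_r.coordinates[pairs[:, 1]],
        mcfg,
        min_inliers,
    )


def match_and_verify(
    P: Panel,
    R: Panel,
    cfg: RetrievalConfig = RetrievalConfig(),
    mcfg: MatchConfig = MatchConfig(),
    kp_P: InterestPointSet | None = None,
    kp_R: InterestPointSet | None = None,
    kp_P_flipped: "InterestPointSet | Callable[[], InterestPointSet] | None" = None,
) -> MatchResult:
    """Verify whether P and R share pixel content.

    Pre-extracted keypoint sets may be passed to amortize SIFT across the
    many pairs a corpus scan examines (``kp_P_flipped`` may be a zero-arg
    callable so the flipped extraction stays lazy). The flipped retry only
    runs when the direct attempt fails. ``src_points`` live in the flipped
    frame when ``mirrored``; use :func:`unflip_points` to map them back.
    """
    pair = (P.panel_id, R.panel_id)
    kp_r = kp_R if kp_R is not None else extract_keypoints(R)

    kp_p = kp_P if kp_P is not None else extract_keypoints(P)
    hit = _match_attempt(kp_p, kp_r, mcfg, cfg.min_inliers)
    if hit is not None:
        H, src, dst = hit
        return MatchResult(pair, src, dst, H, mirrored=False, consistent=True)

    if kp_P_flipped is None:
        kp_pf = extract_keypoints(_flip_raster(P.raster, mcfg.flip_axis))
    elif callable(kp_P_flipped):
        kp_pf = kp_P_flipped()
    else:
        kp_pf = kp_P_flipped
    hit = _match_attempt(kp_pf, kp_r, mcfg, cfg.min_inliers)
    if hit is not None:
        H, src, dst = hit
        return MatchResult(pair, src, dst, H, mirrored=True, consistent=True)

    return MatchResult(
        pair,
        np.empty((0, 2)),
        np.empty((0, 2)),
        None,
        mirrored=False,
        consistent=False,
    )


def unflip_points(
    points: np.ndarray, width: int, height: int, axis: str = "horizontal"
) -> np.ndarray:
    """Map coordinates found on a flipped raster back to the original frame."""
    out = points.copy()
    if axis == "horizontal":
        out[:, 0] = (width - 1) - out[:, 0]
    else:
        out[:, 1] = (height - 1) - out[:, 1]
    return out


def hull_area(points: np.ndarray) -> float:
    """Area of the convex hull of 2-D points; 0 for < 3 non-collinear points."""
    pts = np.asarray(points, dtype=np.float64)
    if len(pts) < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # "volume" is area in 2-D
    except QhullError:
        return 0.0  # collinear / coincident


def _side_score(points: np.ndarray, width: int, height: int) -> float:
    clipped = np.clip(points, [0.0, 0.0], [float(width), float(height)])
    area = hull_area(clipped)
    # round off Qhull's last-ulp jitter so a full-panel hull scores exactly 1
    return min(1.0, round(area / float(width * height), 12))


def content_sharing_score(
    match: MatchResult,
    P: Panel,
    R: Panel,
    flip_axis: str = "horizontal",
) -> ContentShareScore:
    """Directional content-sharing scores of a verified pair.

    Each side's score is the convex-hull area of its verified interest
    points over the panel's area; mirrored-frame points are mapped back to
    P's frame first. Hull points are clipped to panel bounds so scores stay
    in [0, 1]. Fewer than 3 non-collinear points on a side give that side 0.
    """
    if not match.consistent:
        raise ValidationError("content_sharing_score requires a consistent match")
    src = match.src_points
    if match.mirrored:
        src = unflip_points(src, P.width, P.height, flip_axis)
    return ContentShareScore(
        score_P_given_R=_side_score(src, P.width, P.height),
        score_R_given_P=_side_score(match.dst_points, R.width, R.height),
    )


def homography_similarity_params(H: np.ndarray) -> tuple[float, float, tuple[float, float]]:
    """(scale, rotation degrees, translation) of a near-similarity homography.

    Convenience for validating recovered transforms against planted ones;
    meaningful only when H is close to a similarity transform.
    """
    A = H[:2, :2] / H[2, 2]
    scale = float(np.sqrt(abs(np.linalg.det(A))))
    rotation = float(np.degrees(np.arctan2(A[1, 0], A[0, 0])))
    t = (float(H[0, 2] / H[2, 2]), float(H[1, 2] / H[2, 2]))
    return scale, rotation, t
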
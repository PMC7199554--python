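"""Descriptor matching and robust pairwise homography estimation.

Correspondences between two images are formed one-way (A -> B) by the
nearest/second-nearest Euclidean ratio test with a strict 0.3 threshold, then
verified with RANSAC against a homography (reprojection threshold t = 3 px,
2000 iterations with the p = 0.99 adaptive early stop).  A scalar confidence,
inliers / (8 + 0.3 * matches), decides whether the pair participates in the
mosaic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

RATIO_DEFAULT = 0.3
RANSAC_T = 3.0
RANSAC_ITERS = 2000
RANSAC_P = 0.99


@dataclass
class Match:
    i: int            # index into image-A keypoints
    j: int            # index into image-B keypoints
    d: float          # Euclidean descriptor distance
    inlier: bool = False


def match_descriptors(descsA: np.ndarray, descsB: np.ndarray,
                      ratio: float = RATIO_DEFAULT,
                      ptsB: np.ndarray | None = None,
                      min_sep: float = 3.0) -> list[Match]:
    """One-way ratio matching: keep an A-keypoint's nearest B-neighbour iff
    d1/d2 <= ratio (rejection is strict '>'); ties broken by lower index.

    When ``ptsB`` (keypoint positions) is given, B-descriptors lying within
    ``min_sep`` pixels of the nearest neighbour are skipped when picking the
    second-nearest: a point emitted with several orientations must not serve
    as its own ratio-test competitor.
    """
    descsA = np.atleast_2d(np.asarray(descsA, dtype=np.float64))
    descsB = np.atleast_2d(np.asarray(descsB, dtype=np.float64))
    if descsA.shape[0] == 0 or descsB.shape[0] == 0:
        raise ValueError("descriptor sets must be non-empty")
    if descsB.shape[0] < 2:
        raise ValueError("insufficient features for ratio test")
    d = cdist(descsA, descsB)
    matches = []
    for i in range(d.shape[0]):
        order = np.argsort(d[i], kind="stable")
        j1 = order[0]
        j2 = None
        for j in order[1:]:
            if ptsB is not None and np.linalg.norm(
                    np.asarray(ptsB[j]) - np.asarray(ptsB[j1])) <= min_sep:
                continue
            j2 = j
            break
        if j2 is None:
            continue
        d1, d2 = d[i, j1], d[i, j2]
        if d1 <= ratio * d2:
            matches.append(Match(int(i), int(j1), float(d1)))
    return matches


def _hartley_normalize(pts: np.ndarray):
    centroid = pts.mean(axis=0)
    dists = np.linalg.norm(pts - centroid, axis=1)
    mean_d = dists.mean()
    scale = np.sqrt(2) / mean_d if mean_d > 0 else 1.0
    T = np.array([[scale, 0, -scale * centroid[0]],
                  [0, scale, -scale * centroid[1]],
                  [0, 0, 1.0]])
    return (pts - centroid) * scale, T


def fit_homography(ptsA: np.ndarray, ptsB: np.ndarray) -> np.ndarray:
    """Normalized DLT: the homography H with xB ~ H xA, h33 = 1.

    Hartley-normalizes both point sets, solves the stacked 2n x 9 system by
    SVD (smallest-singular-vector), and denormalizes.  Raises on degenerate
    (e.g. collinear) configurations.
    """
    ptsA = np.asarray(ptsA, dtype=np.float64)
    ptsB = np.asarray(ptsB, dtype=np.float64)
    n = ptsA.shape[0]
    if n < 4 or ptsB.shape[0] != n:
        raise ValueError("need >= 4 correspondences")
    na, Ta = _hartley_normalize(ptsA)
    nb, Tb = _hartley_normalize(ptsB)
    A = np.zeros((2 * n, 9))
    for k in range(n):
        x, y = na[k]
        u, v = nb[k]
        A[2 * k] = [-x, -y, -1, 0, 0, 0, u * x, u * y, u]
        A[2 * k + 1] = [0, 0, 0, -x, -y, -1, v * x, v * y, v]
    _, sv, vt = np.linalg.svd(A)
    if n > 4 and sv[7] < 1e-12 * sv[0]:
        raise ValueError("degenerate sample")
    if n == 4 and sv[7] < 1e-9 * max(sv[0], 1.0):
        raise ValueError("degenerate sample")
    Hn = vt[-1].reshape(3, 3)
    H = np.linalg.inv(Tb) @ Hn @ Ta
    if abs(H[2, 2]) < 1e-12 or abs(np.linalg.det(H)) < 1e-12:
        raise ValueError("degenerate sample")
    return H / H[2, 2]


def reprojection_errors(H: np.ndarray, ptsA: np.ndarray,
                        ptsB: np.ndarray) -> np.ndarray:
    """Euclidean error ||xB - H xA|| after dehomogenization, per point."""
    ptsA = np.asarray(ptsA, dtype=np.float64)
    ptsB = np.asarray(ptsB, dtype=np.float64)
    ones = np.ones((ptsA.shape[0], 1))
    proj = (H @ np.hstack([ptsA, ones]).T).T
    with np.errstate(divide="ignore", invalid="ignore"):
        proj = proj[:, :2] / proj[:, 2:3]
    err = np.linalg.norm(proj - ptsB, axis=1)
    return np.where(np.isfinite(err), err, np.inf)


def ransac_homography(matches: list[Match], ptsA: np.ndarray, ptsB: np.ndarray,
                      t: float = RANSAC_T, iters: int = RANSAC_ITERS,
                      p: float = RANSAC_P, seed: int | None = 0):
    """RANSAC homography over matched points.

    Per iteration 4 matches are sampled without replacement and a candidate H
    fitted; matches with reprojection error <= t are inliers.  Iteration stops
    early once the adaptive p-confidence bound on the number of trials is
    reached.  The best model is re-fit on all its inliers.  Returns
    ``(H, inlier_flags)``; the input matches' ``inlier`` fields are updated.
    """
    if len(matches) < 4:
        raise ValueError("need >= 4 matches for RANSAC")
    rng = np.random.default_rng(seed)
    pa = np.asarray([ptsA[m.i] for m in matches], dtype=np.float64)
    pb = np.asarray([ptsB[m.j] for m in matches], dtype=np.float64)
    n = len(matches)
    best_inl = None
    best_count = -1
    max_trials = iters
    trial = 0
    while trial < max_trials:
        idx = rng.choice(n, size=4, replace=False)
        try:
            H = fit_homography(pa[idx], pb[idx])
        except ValueError:
            trial += 1
            continue
        inl = reprojection_errors(H, pa, pb) <= t
        count = int(inl.sum())
        if count > best_count:
            best_count = count
            best_inl = inl
            w = count / n
            if 0 < w < 1:
                bound = np.log(1 - p) / np.log(1 - w ** 4)
                max_trials = min(iters, int(np.ceil(bound)))
            elif w >= 1:
                max_trials = trial + 1
        trial += 1
    if best_count < 4:
        raise ValueError("no consensus")
    # iterated re-fit: refitting on all consensus inliers shifts the model,
    # which can change the inlier set; iterate to the fixed point so the
    # final model is the least-squares fit of exactly its own inliers
    flags = best_inl
    H = fit_homography(pa[flags], pb[flags])
    for _ in range(5):
        new_flags = reprojection_errors(H, pa, pb) <= t
        if new_flags.sum() < 4 or (new_flags == flags).all():
            break
        flags = new_flags
        H = fit_homography(pa[flags], pb[flags])
    for m, f in zip(matches, flags):
        m.inlier = bool(f)
    return H, flags


def pair_confidence(n_inliers: int, n_matches: int) -> float:
    """Confidence that two images belong to the same mosaic:
    inliers / (8 + 0.3 * matches); a pair participates iff this exceeds the
    user threshold (default 1.0, sensible range [0.5, 1.5])."""
    if n_matches == 0:
        return 0.0
    return n_inliers / (8.0 + 0.3 * n_matches)
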
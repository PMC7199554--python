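"""Evaluation metrics: ray-space matching RMSE and correspondence recall.

The registration error of a matched point pair (p, q) between cameras i and
j is the distance between their back-projected rays,
e_k = ||Ri Ki^-1 p - Rj Kj^-1 q|| on homogeneous pixel vectors (x, y, 1);
the RMSE over a correspondence set summarises pairwise matching quality.
Because those rays live in normalised units, a pixel-unit variant multiplies
each error by the shared focal length, restoring a magnitude comparable to
image-plane pixels.  Recall compares an algorithm's retrieved correspondences
against expert-marked ground truth.
"""

from __future__ import annotations

import numpy as np

from .camera import Camera


def matching_rmse(pairs, camA: Camera, camB: Camera,
                  units: str = "ray") -> float:
    """RMSE of ray-space matching errors over correspondence pairs.

    ``pairs`` is a sequence of ((xA, yA), (xB, yB)).  Rays are compared on
    the unit viewing sphere — only the ray direction is observable under a
    rotating camera, and exact correspondences under the true cameras then
    score exactly zero.  In ``pixel`` units each error is additionally
    multiplied by the shared focal length camA.K.fx, restoring an
    image-plane-comparable magnitude (f times an angle is arc length in
    pixels).
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty correspondence set")
    if units not in ("ray", "pixel"):
        raise ValueError("units must be 'ray' or 'pixel'")
    P = np.asarray([p for p, _ in pairs], dtype=np.float64)
    Q = np.asarray([q for _, q in pairs], dtype=np.float64)
    e = np.linalg.norm(camA.rays(P, unit=True) - camB.rays(Q, unit=True),
                       axis=1)
    if units == "pixel":
        e = e * camA.K.fx
    return float(np.sqrt(np.mean(e ** 2)))


def recall(retrieved, truth, tol: float = 3.0) -> float:
    """Fraction of expert-marked correspondences recovered by the matcher.

    A retrieved pair is correct iff some not-yet-consumed truth pair has both
    endpoints within ``tol`` (Euclidean); consumption is greedy in retrieved
    order, one-to-one.  Returns correct / |truth|.
    """
    truth = list(truth)
    if not truth:
        raise ValueError("empty truth set")
    consumed = [False] * len(truth)
    correct = 0
    for (pa, pb) in retrieved:
        pa = np.asarray(pa, dtype=np.float64)
        pb = np.asarray(pb, dtype=np.float64)
        for k, (ta, tb) in enumerate(truth):
            if consumed[k]:
                continue
            if (np.linalg.norm(pa - np.asarray(ta)) <= tol
                    and np.linalg.norm(pb - np.asarray(tb)) <= tol):
                consumed[k] = True
                correct += 1
                break
    return correct / len(truth)


def load_correspondences_tsv(path):
    """Read correspondence pairs from TSV columns xA yA xB yB."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "xA")):
                continue
            xa, ya, xb, yb = map(float, line.split("\t"))
            pairs.append(((xa, ya), (xb, yb)))
    return pairs
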
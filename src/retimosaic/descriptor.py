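"""64-D Haar-wavelet descriptors and dominant orientation for bifurcations.

Bifurcations are detected morphologically on the skeleton, so unlike
scale-space interest points they carry no intrinsic scale; a fixed working
scale ``s`` (default 2 px) is assigned to every keypoint.  Around each point,
Haar box-filter responses dx, dy measured on the integral image of the
grayscale retinal photograph yield (1) a dominant orientation from the
longest resultant over a sliding pi/3 angular window on a 6s-radius disc, and
(2) a 4x4-subregion descriptor over a rotated 20s window — per subregion the
4-tuple (sum dx, sum dy, sum |dx|, sum |dy|) at 5x5 regularly spaced samples
— concatenated to 64 components and scaled to unit Euclidean norm.

Conventions adopted where the construction is underdetermined: orientation
filters of side 4s with Gaussian weighting sigma = 2.5s, descriptor weighting
sigma = 3.3s, sliding-window step pi/36, zero vector left unnormalised, and
theta = 0 for structureless (constant) neighbourhoods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_SCALE = 2.0


class BorderKeypointError(ValueError):
    """Raised when a keypoint's sampling window does not fit in the image."""


@dataclass
class Keypoint:
    x: float
    y: float
    s: float = DEFAULT_SCALE
    theta: float = 0.0

    def __post_init__(self):
        if self.s <= 0:
            raise ValueError("scale must be positive")


def summed_area_table(image_gray: np.ndarray) -> np.ndarray:
    """Integral image with a zero top row/left column.

    ``table[i, j]`` is the sum of all pixels with row < i and col < j, so the
    box sum over rows [r0, r1) x cols [c0, c1) is
    ``t[r1,c1] - t[r0,c1] - t[r1,c0] + t[r0,c0]`` (4 lookups).
    """
    arr = np.asarray(image_gray, dtype=np.float64)
    table = np.zeros((arr.shape[0] + 1, arr.shape[1] + 1))
    np.cumsum(np.cumsum(arr, axis=0), axis=1, out=table[1:, 1:])
    return table


def _box(table, r0, r1, c0, c1):
    return table[r1, c1] - table[r0, c1] - table[r1, c0] + table[r0, c0]


def _haar(table, xs, ys, half):
    """Haar responses (dx, dy) of filter side 2*half at integer centres.

    dx = right box minus left box; dy = lower box minus upper box (y grows
    downwards).  Vectorised over equally shaped xs, ys index arrays.
    """
    r0, r1 = ys - half, ys + half
    c0, c1 = xs - half, xs + half
    dx = _box(table, r0, r1, xs, c1) - _box(table, r0, r1, c0, xs)
    dy = _box(table, ys, r1, c0, c1) - _box(table, r0, ys, c0, c1)
    return dx, dy


def _window_resultants(image_gray, x, y, s, table):
    """(squared length, angle) of the (sum dx, sum dy) resultant for every
    sliding pi/3 orientation window around (x, y)."""
    if table is None:
        table = summed_area_table(image_gray)
    h, w = table.shape[0] - 1, table.shape[1] - 1
    half = int(round(2 * s))  # filter side 4s
    ii, jj = np.meshgrid(np.arange(-6, 7), np.arange(-6, 7), indexing="ij")
    disc = ii ** 2 + jj ** 2 <= 36
    ii, jj = ii[disc], jj[disc]
    xs = np.rint(x + jj * s).astype(int)
    ys = np.rint(y + ii * s).astype(int)
    if (xs - half < 0).any() or (xs + half > w).any() \
            or (ys - half < 0).any() or (ys + half > h).any():
        raise BorderKeypointError("orientation disc falls outside the image")
    dx, dy = _haar(table, xs, ys, half)
    g = np.exp(-(ii ** 2 + jj ** 2) * s * s / (2 * (2.5 * s) ** 2))
    dx, dy = dx * g, dy * g
    if not (np.hypot(dx, dy) > 0).any():
        return []
    ang = np.arctan2(dy, dx) % (2 * np.pi)
    out = []
    for start in np.arange(0, 2 * np.pi, np.pi / 36):
        span = (ang - start) % (2 * np.pi) < np.pi / 3
        if not span.any():
            continue
        rx, ry = dx[span].sum(), dy[span].sum()
        out.append((rx * rx + ry * ry,
                    float(np.arctan2(ry, rx) % (2 * np.pi))))
    return out


def assign_orientation(image_gray: np.ndarray, x: float, y: float,
                       s: float = DEFAULT_SCALE,
                       table: np.ndarray | None = None) -> float:
    """Dominant orientation at (x, y): Haar responses (filter side 4s,
    Gaussian-weighted sigma=2.5s) sampled on the 6s-radius disc at steps of s;
    the angle of the longest (sum dx, sum dy) resultant over all sliding pi/3
    windows (step pi/36).  Constant neighbourhoods return 0 by convention."""
    res = _window_resultants(image_gray, x, y, s, table)
    if not res:
        return 0.0
    return max(res)[1]


def orientation_candidates(image_gray, x, y, s=DEFAULT_SCALE,
                           table=None, ratio: float = 0.8):
    """Dominant orientation plus strong runner-up modes.

    A vessel bifurcation carries three branch directions, so its orientation
    histogram is multi-modal and pixel noise can flip which mode wins between
    two views of the same point.  Any window resultant at least ``ratio`` of
    the longest and more than pi/3 away in angle yields an additional
    orientation (at most 3 total), mirroring the multiple-orientation
    practice of classic gradient descriptors."""
    res = _window_resultants(image_gray, x, y, s, table)
    if not res:
        return [0.0]
    res = sorted(res, reverse=True)
    best_len = res[0][0]
    thetas = [res[0][1]]
    for length, theta in res[1:]:
        if length < ratio ** 2 * best_len or len(thetas) == 3:
            break
        if min(abs((theta - t + np.pi) % (2 * np.pi) - np.pi)
               for t in thetas) > np.pi / 3:
            thetas.append(theta)
    return thetas


def compute_descriptor(image_gray: np.ndarray, kp: Keypoint,
                       table: np.ndarray | None = None,
                       normalize: bool = True) -> np.ndarray:
    """64-D descriptor over the rotated 20s x 20s window centred on the
    keypoint: 4x4 subregions of side 5s, Haar responses (filter side 2s) at
    5x5 samples each, rotated into the keypoint frame, Gaussian-weighted
    (sigma = 3.3s), summed per subregion as (sum dx, sum dy, sum|dx|,
    sum|dy|), concatenated row-major and normalised to unit length."""
    if table is None:
        table = summed_area_table(image_gray)
    h, w = table.shape[0] - 1, table.shape[1] - 1
    s, theta = kp.s, kp.theta
    half = max(int(round(s)), 1)  # filter side 2s
    cos_t, sin_t = np.cos(theta), np.sin(theta)

    # sample offsets in keypoint-frame units of s: 20 samples per axis at
    # half-sample centres, grouped into 4 subregions of 5
    coords = (np.arange(20) - 10 + 0.5)
    u, v = np.meshgrid(coords, coords, indexing="xy")  # u along rotated x
    gx = kp.x + (u * cos_t - v * sin_t) * s
    gy = kp.y + (u * sin_t + v * cos_t) * s
    xs = np.rint(gx).astype(int)
    ys = np.rint(gy).astype(int)
    if (xs - half < 0).any() or (xs + half > w).any() \
            or (ys - half < 0).any() or (ys + half > h).any():
        raise BorderKeypointError("descriptor window falls outside the image")
    dx, dy = _haar(table, xs, ys, half)
    g = np.exp(-(u ** 2 + v ** 2) / (2 * 3.3 ** 2))
    dx, dy = dx * g, dy * g
    # responses expressed in the rotated frame
    rdx = dx * cos_t + dy * sin_t
    rdy = -dx * sin_t + dy * cos_t

    desc = np.empty(64)
    k = 0
    for si in range(4):          # subregion rows (v direction)
        for sj in range(4):      # subregion cols (u direction)
            blk = np.s_[5 * si:5 * si + 5, 5 * sj:5 * sj + 5]
            desc[k:k + 4] = (rdx[blk].sum(), rdy[blk].sum(),
                             np.abs(rdx[blk]).sum(), np.abs(rdy[blk]).sum())
            k += 4
    if normalize:
        norm = np.linalg.norm(desc)
        if norm > 0:
            desc /= norm
    return desc


def describe(image, points, s: float = DEFAULT_SCALE,
             multi_orientation: bool = True):
    """Orient and describe detected bifurcations on the retinal image.

    Border keypoints whose sampling windows do not fit are dropped.  With
    ``multi_orientation`` a point whose orientation histogram has near-tie
    modes is emitted once per mode (same position, different theta), which
    keeps matching stable when noise flips the dominant branch direction
    between two views.  Returns ``(keypoints, descriptors)`` with descriptors
    stacked (n, 64).
    """
    from .preproc import to_gray

    gray = to_gray(image)
    table = summed_area_table(gray)
    kps, descs = [], []
    for x, y in points:
        try:
            if multi_orientation:
                thetas = orientation_candidates(gray, x, y, s, table=table)
            else:
                thetas = [assign_orientation(gray, x, y, s, table=table)]
            for theta in thetas:
                kp = Keypoint(float(x), float(y), s, theta)
                descs.append(compute_descriptor(gray, kp, table=table))
                kps.append(kp)
        except BorderKeypointError:
            continue
    if descs:
        return kps, np.vstack(descs)
    return kps, np.zeros((0, 64))
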
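"""Spherical warping, gain compensation and multiband (Laplacian) blending.

Each image is mapped through its rotation-only camera onto the unit sphere:
a pixel p becomes the ray (x', y', z') = R K^-1 p, which in spherical
coordinates is u = atan2(x', z') (azimuth), w = y' / |ray| and
v = pi - acos(w) (polar).  The mosaic plane is (sphere_scale * u,
sphere_scale * v) with sphere_scale conventionally set to the focal length so
near-identity warps keep unit magnification.  Warping is done by inverse
mapping: every destination pixel is sent back through the inverse spherical
transform, x' = sin v sin u, y' = -cos v, z' = sin v cos u, then
backprojected with K R^-1 (R^-1 = R^T) and sampled bilinearly.

Photometric seams are reduced by least-squares gain compensation over the
pairwise overlaps, then hidden by the classic multiband blend: 5-level
Gaussian/Laplacian pyramids (5x5 kernel, dims halving per level) blended per
level through the Gaussian pyramid of a distance-based seam mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .camera import Camera

PYRAMID_LEVELS = 5
_KERNEL_1D = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass
class WarpedLayer:
    image: np.ndarray          # warped image (float), (H, W) or (H, W, 3)
    valid: np.ndarray          # warped footprint, uint8 {0,1}, same H, W
    offset: tuple[int, int]    # (x0, y0) of the top-left in mosaic coords
    gain: float = 1.0


# ---------------------------------------------------------------------------
# Spherical mapping
# ---------------------------------------------------------------------------

def pixel_to_sphere(pts: np.ndarray, camera: Camera):
    """Map (n, 2) pixels to spherical coordinates (u, w, v).

    u is the azimuth atan2(x', z') (the two-argument form keeps the
    hemisphere), w = y'/|ray| in [-1, 1], and v = pi - acos(w) in [0, pi].
    Raises for the degenerate pole ray x' = z' = 0.
    """
    rays = camera.rays(pts)
    x, y, z = rays[:, 0], rays[:, 1], rays[:, 2]
    if np.any((x == 0) & (z == 0)):
        raise ValueError("degenerate ray")
    u = np.arctan2(x, z)
    w = y / np.linalg.norm(rays, axis=1)
    v = np.pi - np.arccos(np.clip(w, -1.0, 1.0))
    return u, w, v


def sphere_to_pixel(u: np.ndarray, v: np.ndarray, camera: Camera):
    """Back-project spherical (u, v) to pixels.

    The inverse spherical transform gives the ray x' = sin v sin u,
    y' = -cos v, z' = sin v cos u; pixels follow from K R^T ray after
    dehomogenization.  Returns ``(x, y, valid)`` where valid marks rays in
    front of the camera (z > 0).
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    rays = np.stack([np.sin(v) * np.sin(u), -np.cos(v),
                     np.sin(v) * np.cos(u)], axis=-1)
    proj = (camera.K.K @ camera.R.T @ rays.reshape(-1, 3).T).T
    z = proj[:, 2]
    valid = z > 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        x = proj[:, 0] / z
        y = proj[:, 1] / z
    x = np.where(valid, x, 0.0).reshape(u.shape)
    y = np.where(valid, y, 0.0).reshape(u.shape)
    return x, y, valid.reshape(u.shape)


def warp_image(image: np.ndarray, camera: Camera, sphere_scale: float,
               footprint: np.ndarray | None = None) -> WarpedLayer:
    """Warp one image into mosaic (spherical-plane) coordinates.

    The mosaic plane is (sphere_scale * u, sphere_scale * v).  The bounding
    box comes from forward-mapping the source border; the interior is filled
    by inverse mapping with bilinear interpolation, the validity footprint
    with nearest-neighbour.
    """
    arr = np.asarray(image, dtype=np.float64)
    h, w = arr.shape[:2]
    if footprint is None:
        footprint = np.ones((h, w), dtype=np.uint8)

    # forward-map a dense border sampling to find the destination bbox
    xs = np.linspace(0, w - 1, max(w // 2, 32))
    ys = np.linspace(0, h - 1, max(h // 2, 32))
    border = np.concatenate([
        np.stack([xs, np.zeros_like(xs)], axis=1),
        np.stack([xs, np.full_like(xs, h - 1)], axis=1),
        np.stack([np.zeros_like(ys), ys], axis=1),
        np.stack([np.full_like(ys, w - 1), ys], axis=1),
    ])
    u, _, v = pixel_to_sphere(border, camera)
    x0 = int(np.floor(sphere_scale * u.min()))
    x1 = int(np.ceil(sphere_scale * u.max()))
    y0 = int(np.floor(sphere_scale * v.min()))
    y1 = int(np.ceil(sphere_scale * v.max()))
    out_w, out_h = x1 - x0 + 1, y1 - y0 + 1
    if out_w <= 0 or out_h <= 0:
        raise ValueError("empty footprint")

    gx, gy = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    su = gx / sphere_scale
    sv = gy / sphere_scale
    sx, sy, in_front = sphere_to_pixel(su, sv, camera)
    inside = in_front & (sx >= 0) & (sx <= w - 1) & (sy >= 0) & (sy <= h - 1)

    coords = np.stack([sy.ravel(), sx.ravel()])
    if arr.ndim == 3:
        planes = [ndimage.map_coordinates(arr[..., c], coords, order=1,
                                          mode="constant", cval=0.0
                                          ).reshape(out_h, out_w)
                  for c in range(arr.shape[2])]
        warped = np.stack(planes, axis=-1)
    else:
        warped = ndimage.map_coordinates(arr, coords, order=1,
                                         mode="constant", cval=0.0
                                         ).reshape(out_h, out_w)
    fp = ndimage.map_coordinates(np.asarray(footprint, dtype=np.float64),
                                 coords, order=0, mode="constant", cval=0.0
                                 ).reshape(out_h, out_w)
    valid = (inside & (fp > 0.5)).astype(np.uint8)
    if not valid.any():
        raise ValueError("empty footprint")
    if warped.ndim == 3:
        warped[valid == 0] = 0.0
    else:
        warped[valid == 0] = 0.0
    return WarpedLayer(warped, valid, (x0, y0))


# ---------------------------------------------------------------------------
# Gain compensation
# ---------------------------------------------------------------------------

def _overlap_slices(a: WarpedLayer, b: WarpedLayer):
    ax0, ay0 = a.offset
    bx0, by0 = b.offset
    ah, aw = a.valid.shape
    bh, bw = b.valid.shape
    x0 = max(ax0, bx0)
    y0 = max(ay0, by0)
    x1 = min(ax0 + aw, bx0 + bw)
    y1 = min(ay0 + ah, by0 + bh)
    if x1 <= x0 or y1 <= y0:
        return None
    sa = np.s_[y0 - ay0:y1 - ay0, x0 - ax0:x1 - ax0]
    sb = np.s_[y0 - by0:y1 - by0, x0 - bx0:x1 - bx0]
    return sa, sb


def _mean_intensity(img: np.ndarray, mask: np.ndarray) -> float:
    vals = img[mask] if img.ndim == 2 else img[mask].mean(axis=-1)
    return float(vals.mean())


def gain_compensate(layers: list[WarpedLayer], sigma_n: float = 10.0,
                    sigma_g: float = 0.1) -> np.ndarray:
    """Least-squares multiplicative gains equalising overlap brightness.

    Minimises, over all overlapping pairs (i, j) with Nij overlap pixels,
    Nij * ((gi*Iij - gj*Iji)^2 / sigma_n^2 + (1 - gi)^2 / sigma_g^2), where
    Iij is layer i's mean intensity inside overlap(i, j).  The prior term
    anchors the gains near 1.  Gains are stored on the layers and returned.
    """
    n = len(layers)
    A = np.zeros((n, n))
    b = np.zeros(n)
    seen_overlap = False
    for i in range(n):
        for j in range(i + 1, n):
            sl = _overlap_slices(layers[i], layers[j])
            if sl is None:
                continue
            sa, sb = sl
            both = (layers[i].valid[sa] > 0) & (layers[j].valid[sb] > 0)
            nij = int(both.sum())
            if nij == 0:
                continue
            seen_overlap = True
            Iij = _mean_intensity(layers[i].image[sa], both)
            Iji = _mean_intensity(layers[j].image[sb], both)
            A[i, i] += nij * (Iij ** 2 / sigma_n ** 2 + 1.0 / sigma_g ** 2)
            A[j, j] += nij * (Iji ** 2 / sigma_n ** 2 + 1.0 / sigma_g ** 2)
            A[i, j] -= nij * Iij * Iji / sigma_n ** 2
            A[j, i] -= nij * Iij * Iji / sigma_n ** 2
            b[i] += nij / sigma_g ** 2
            b[j] += nij / sigma_g ** 2
    if not seen_overlap:
        gains = np.ones(n)
    else:
        # layers with no overlap at all keep gain 1
        idx = np.where(np.diag(A) > 0)[0]
        gains = np.ones(n)
        gains[idx] = np.linalg.solve(A[np.ix_(idx, idx)], b[idx])
    for layer, g in zip(layers, gains):
        layer.gain = float(g)
    return gains


def apply_gains(layers: list[WarpedLayer]) -> None:
    for layer in layers:
        layer.image = np.clip(layer.image * layer.gain, 0.0, 255.0)


# ---------------------------------------------------------------------------
# Pyramids
# ---------------------------------------------------------------------------

def _gauss5(img: np.ndarray) -> np.ndarray:
    out = img
    for axis in (0, 1):
        out = ndimage.convolve1d(out, _KERNEL_1D, axis=axis, mode="reflect")
    return out


def _smooth(img: np.ndarray) -> np.ndarray:
    if img.ndim == 3:
        return np.stack([_gauss5(img[..., c]) for c in range(img.shape[2])],
                        axis=-1)
    return _gauss5(img)


def _downsample2(img: np.ndarray) -> np.ndarray:
    return _smooth(img)[::2, ::2]


def _upsample2(img: np.ndarray, shape) -> np.ndarray:
    """Zero-insertion upsampling to ``shape`` followed by normalised 5x5
    smoothing: the interpolation weights are renormalised by the smoothed
    sample indicator, so constants are reproduced exactly everywhere,
    including the borders."""
    out_shape = list(img.shape)
    out_shape[0], out_shape[1] = shape[0], shape[1]
    up = np.zeros(out_shape, dtype=np.float64)
    up[::2, ::2] = img
    weight = np.zeros((shape[0], shape[1]), dtype=np.float64)
    weight[::2, ::2] = 1.0
    den = _gauss5(weight)
    num = _smooth(up)
    if num.ndim == 3:
        den = den[..., None]
    return num / den


def build_pyramids(image: np.ndarray, levels: int = PYRAMID_LEVELS):
    """Gaussian and Laplacian pyramids of an image.

    G0 is the image; G_{k+1} = downsample2(gauss5x5(G_k)) with ceil-halved
    dims.  L_k = G_k - upsample2(G_{k+1}) for k < levels-1 and the top
    Laplacian level is the top Gaussian level, so recursive upsample-and-add
    reconstructs the input exactly.  Levels are reduced (never below 1) when
    the image is too small to halve.
    """
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape[:2]
    max_levels = 1
    while min(h, w) >= 2 and max_levels < levels:
        h, w = -(-h // 2), -(-w // 2)
        max_levels += 1
    levels = min(levels, max_levels)
    gaussian = [img]
    for _ in range(levels - 1):
        gaussian.append(_downsample2(gaussian[-1]))
    laplacian = [gaussian[k] - _upsample2(gaussian[k + 1],
                                          gaussian[k].shape[:2])
                 for k in range(levels - 1)]
    laplacian.append(gaussian[-1])
    return gaussian, laplacian


def collapse_pyramid(laplacian: list[np.ndarray]) -> np.ndarray:
    """Invert build_pyramids: recursively upsample and add."""
    out = laplacian[-1]
    for lap in reversed(laplacian[:-1]):
        out = lap + _upsample2(out, lap.shape[:2])
    return out


# ---------------------------------------------------------------------------
# Multiband blending
# ---------------------------------------------------------------------------

def _fill_invalid(img: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Replace invalid pixels by their nearest valid neighbour so pyramid
    smoothing does not bleed black borders into the blend."""
    if valid.all():
        return img
    ind = ndimage.distance_transform_edt(valid == 0, return_distances=False,
                                         return_indices=True)
    return img[tuple(ind)] if img.ndim == 2 else img[ind[0], ind[1]]


def multiband_blend(layers: list[WarpedLayer],
                    levels: int = PYRAMID_LEVELS):
    """Fuse warped layers into a mosaic with Laplacian-pyramid blending.

    Layers are composited sequentially onto the accumulated mosaic.  The seam
    assigns each overlap pixel to whichever side is deeper inside its own
    footprint (distance-to-border); the binary seam mask is softened by its
    own Gaussian pyramid and each Laplacian level is combined convexly,
    Lc_k = Lacc_k (1 - M_k) + Lnew_k M_k, before collapsing.  Returns
    ``(mosaic, coverage mask, (x0, y0))`` in mosaic coordinates.
    """
    if not layers:
        raise ValueError("need at least one layer")
    x0 = min(l.offset[0] for l in layers)
    y0 = min(l.offset[1] for l in layers)
    x1 = max(l.offset[0] + l.valid.shape[1] for l in layers)
    y1 = max(l.offset[1] + l.valid.shape[0] for l in layers)
    w, h = x1 - x0, y1 - y0
    color = layers[0].image.ndim == 3
    shape = (h, w, layers[0].image.shape[2]) if color else (h, w)

    acc = np.zeros(shape, dtype=np.float64)
    acc_valid = np.zeros((h, w), dtype=bool)
    first = layers[0]
    sy, sx = first.offset[1] - y0, first.offset[0] - x0
    acc[sy:sy + first.valid.shape[0], sx:sx + first.valid.shape[1]] = \
        first.image
    acc_valid[sy:sy + first.valid.shape[0],
              sx:sx + first.valid.shape[1]] = first.valid > 0

    for layer in layers[1:]:
        new = np.zeros(shape, dtype=np.float64)
        new_valid = np.zeros((h, w), dtype=bool)
        sy, sx = layer.offset[1] - y0, layer.offset[0] - x0
        new[sy:sy + layer.valid.shape[0], sx:sx + layer.valid.shape[1]] = \
            layer.image
        new_valid[sy:sy + layer.valid.shape[0],
                  sx:sx + layer.valid.shape[1]] = layer.valid > 0

        # seam: new layer wins where it is deeper inside its own footprint
        dist_acc = ndimage.distance_transform_edt(acc_valid)
        dist_new = ndimage.distance_transform_edt(new_valid)
        seam = np.where(new_valid & ~acc_valid, 1.0,
                        np.where(new_valid & acc_valid,
                                 (dist_new > dist_acc).astype(np.float64),
                                 0.0))

        acc_fill = _fill_invalid(acc, acc_valid.astype(np.uint8)) \
            if acc_valid.any() else acc
        new_fill = _fill_invalid(new, new_valid.astype(np.uint8))
        _, lap_acc = build_pyramids(acc_fill, levels)
        _, lap_new = build_pyramids(new_fill, levels)
        gauss_seam, _ = build_pyramids(seam, len(lap_acc))
        blended = []
        for la, ln, m in zip(lap_acc, lap_new, gauss_seam):
            mk = m[..., None] if color else m
            blended.append(la * (1.0 - mk) + ln * mk)
        acc = collapse_pyramid(blended)
        acc_valid = acc_valid | new_valid

    acc = np.clip(acc, 0.0, 255.0)
    if acc_valid.any():
        acc[~acc_valid] = 0.0
    return acc, acc_valid.astype(np.uint8), (x0, y0)
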
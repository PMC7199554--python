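"""Image/mask loading, binarization and centreline extraction.

Vessel segmentation itself is out of scope: the pipeline consumes a vessel
probability map or binary mask produced by any external segmenter.  This
module turns that mask into a one-pixel-wide centreline skeleton by
two-subiteration parallel (Zhang-Suen) thinning, after optionally resizing
the inputs to the working resolution (700 x 605 by default, matching typical
downsampled fundus frames).
"""

from __future__ import annotations

import numpy as np
from PIL import Image as PILImage

WORKING_SIZE = (700, 605)  # (width, height)


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def load_image(path) -> np.ndarray:
    """Load a PNG/JPG image as a uint8 array (H, W) or (H, W, 3)."""
    img = PILImage.open(path)
    if img.mode not in ("L", "RGB"):
        img = img.convert("RGB")
    return np.asarray(img, dtype=np.uint8)


def load_mask(path) -> np.ndarray:
    """Load a vessel probability map / mask as float in [0, 1]."""
    img = PILImage.open(path).convert("L")
    return np.asarray(img, dtype=np.float64) / 255.0


def save_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit PNG with values {0, 255}."""
    PILImage.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255).save(path)


def to_gray(image: np.ndarray) -> np.ndarray:
    """RGB -> grayscale by the standard luma weights; grayscale passes through."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] == 3:
        return arr @ np.array([0.299, 0.587, 0.114])
    raise ValueError(f"expected 2-D or (H, W, 3) image, got shape {arr.shape}")


# ---------------------------------------------------------------------------
# Binarization and resizing
# ---------------------------------------------------------------------------

def binarize(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a soft vessel map into a binary mask.

    Parameters
    ----------
    prob_map : array
        2-D map of vessel probabilities in [0, 1], or 8-bit values which are
        first scaled by 1/255.
    threshold : float
        Inclusive cut-off: a pixel is vessel iff its value >= threshold.
    """
    arr = np.asarray(prob_map)
    if arr.size == 0:
        raise ValueError("empty mask")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    arr = arr.astype(np.float64)
    if arr.max() > 1.0:
        arr = arr / 255.0
    return (arr >= threshold).astype(np.uint8)


def resize_to_working(image: np.ndarray, width: int = WORKING_SIZE[0],
                      height: int = WORKING_SIZE[1]):
    """Bilinearly resample an image to the working resolution.

    The aspect ratio is *not* preserved (the working frame is fixed).  Returns
    ``(resized, (sx, sy))`` where ``sx, sy`` map working coordinates back to
    the original frame: ``x_orig = sx * x_work``.
    """
    if width <= 0 or height <= 0:
        raise ValueError("target dimensions must be positive")
    arr = np.asarray(image)
    h, w = arr.shape[:2]
    scale = (w / width, h / height)
    if (w, h) == (width, height):
        return arr.copy(), scale
    pil = PILImage.fromarray(arr)
    out = np.asarray(pil.resize((width, height), PILImage.BILINEAR))
    return out, scale


# ---------------------------------------------------------------------------
# Zhang-Suen thinning
# ---------------------------------------------------------------------------

def _neighbours(padded: np.ndarray):
    """The 8 neighbours P2..P9 (N, NE, E, SE, S, SW, W, NW) of every interior
    pixel of a zero-padded binary array."""
    p2 = padded[:-2, 1:-1]   # N
    p3 = padded[:-2, 2:]     # NE
    p4 = padded[1:-1, 2:]    # E
    p5 = padded[2:, 2:]      # SE
    p6 = padded[2:, 1:-1]    # S
    p7 = padded[2:, :-2]     # SW
    p8 = padded[1:-1, :-2]   # W
    p9 = padded[:-2, :-2]    # NW
    return p2, p3, p4, p5, p6, p7, p8, p9


def thin(mask: np.ndarray) -> np.ndarray:
    """Extract one-pixel-wide centrelines by two-subiteration parallel thinning.

    Implements the classic fast parallel thinning rules: a contour pixel p is
    deleted when 2 <= B(p) <= 6, A(p) = 1 and the subiteration's two
    neighbour-product conditions vanish, where B is the number of foreground
    neighbours and A the number of 0->1 transitions around the 8-ring
    P2,P3,...,P9,P2.  Subiteration 1 requires P2*P4*P6 = 0 and P4*P6*P8 = 0;
    subiteration 2 requires P2*P4*P8 = 0 and P2*P6*P8 = 0.  Both are applied
    in parallel over the whole image and iterated until no pixel changes.
    Image borders are treated as background-padded.
    """
    img = (np.asarray(mask) > 0).astype(np.uint8)
    if img.ndim != 2:
        raise ValueError("mask must be 2-D")
    while True:
        changed = False
        for sub in (0, 1):
            padded = np.pad(img, 1)
            nb = _neighbours(padded)
            ring = np.stack(nb).astype(np.int8)
            b = ring.sum(axis=0)
            nxt = np.roll(ring, -1, axis=0)
            a = np.sum((ring == 0) & (nxt == 1), axis=0)
            p2, p3, p4, p5, p6, p7, p8, p9 = nb
            if sub == 0:
                c1 = p2 * p4 * p6 == 0
                c2 = p4 * p6 * p8 == 0
            else:
                c1 = p2 * p4 * p8 == 0
                c2 = p2 * p6 * p8 == 0
            delete = (img == 1) & (b >= 2) & (b <= 6) & (a == 1) & c1 & c2
            if delete.any():
                img[delete] = 0
                changed = True
        if not changed:
            return img
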
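"""Fully ground-truthed synthetic fundus scenes.

A scene is a flat textured "retina" canvas carrying a dark vessel tree with
known branch-point (bifurcation) coordinates, viewed by rotation-only cameras
with shared intrinsics — the regime in which the homography model
H = K R^T R' K^-1 is exact, so every stage of the pipeline can be tested as
a true parameter-recovery problem rather than a model-mismatch one.

The tree grows by recursive binary branching: a root trunk splits at each
branch event into two child curves at 30-70 degrees separation, widths
shrinking by 0.75 per generation (floor 1 px).  Junction coordinates are the
ground-truth bifurcations.  Rendered views emulate fundus appearance: dark
vessels (~60) on a bright textured field (~170), radial vignetting, a
circular field of view and Gaussian pixel noise.  Everything is deterministic
per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .camera import Camera, Intrinsics

VESSEL_INTENSITY = 60.0
BACKGROUND_INTENSITY = 170.0
TRUNK_WIDTH = 5.0
WIDTH_DECAY = 0.75
MIN_WIDTH = 1.0
BORDER_MARGIN = 10.0
MIN_JUNCTION_SEP = 26.0
BRANCH_SEP_DEG = (30.0, 70.0)


@dataclass
class SyntheticScene:
    canvas: np.ndarray               # clean texture, float64, vessels drawn
    vessel_mask: np.ndarray          # uint8 {0,1} rasterized tree footprint
    segments: list                   # list of (n, 2) polylines (x, y)
    bifurcations_gt: list            # [(x, y)] junction canvas coordinates
    canvas_K: Intrinsics             # canvas-plane camera (R = I)
    seed: int
    cameras_gt: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Vessel-tree growth
# ---------------------------------------------------------------------------

def _rot2(v, ang):
    c, s = np.cos(ang), np.sin(ang)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _bezier(p0, p1, p2, step=0.5):
    """Quadratic Bezier sampled finely enough for disc stamping."""
    approx_len = np.linalg.norm(p1 - p0) + np.linalg.norm(p2 - p1)
    n = max(int(approx_len / step), 4)
    t = np.linspace(0.0, 1.0, n)[:, None]
    return ((1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t ** 2 * p2)


def _stamp(mask, blocked, pts, width):
    """Stamp discs of the given width along a sampled curve into the vessel
    mask, and a slightly larger clearance ring into the 'blocked' mask used
    for self-avoidance."""
    h, w = mask.shape
    r = max(width / 2.0, 0.5)
    rb = r + 3.0
    ri = int(np.ceil(rb))
    yy, xx = np.mgrid[-ri:ri + 1, -ri:ri + 1]
    disc = xx ** 2 + yy ** 2 <= r ** 2
    disc_b = xx ** 2 + yy ** 2 <= rb ** 2
    for x, y in pts:
        cx, cy = int(round(x)), int(round(y))
        y0, y1 = max(cy - ri, 0), min(cy + ri + 1, h)
        x0, x1 = max(cx - ri, 0), min(cx + ri + 1, w)
        mask[y0:y1, x0:x1] |= disc[y0 - cy + ri:y1 - cy + ri,
                                   x0 - cx + ri:x1 - cx + ri]
        blocked[y0:y1, x0:x1] |= disc_b[y0 - cy + ri:y1 - cy + ri,
                                        x0 - cx + ri:x1 - cx + ri]


def _snap_junctions_to_skeleton(mask, junctions, radius=14.0):
    """Ground-truth junction coordinates as rendered at pixel resolution.

    Rasterizing finite-width strips displaces the apparent branch point: the
    strips of two children separating at angle ``sep`` stay merged for about
    (width/2)/tan(sep/2) pixels past the geometric curve intersection, so for
    shallow branchings the skeleton's branch pixel sits a few pixels up the
    bisector.  The generator therefore reports each junction at the nearest
    detectable branch point of the clean skeleton (structuring-element hit),
    which is where the rendered tree actually branches.
    """
    branch = _branch_pixels(mask)
    snapped = []
    for (jx, jy) in junctions:
        if branch.size:
            d = np.hypot(branch[:, 0] - jx, branch[:, 1] - jy)
            k = int(np.argmin(d))
            if d[k] <= radius:
                # a junction may render as a small cluster of branch pixels;
                # report the cluster's raster-first member, the deterministic
                # survivor of 5x5 neighbourhood suppression
                cheb = np.max(np.abs(branch - branch[k]), axis=1)
                members = branch[cheb <= 2]
                order = np.lexsort((members[:, 0], members[:, 1]))
                first = members[order[0]]
                snapped.append((float(first[0]), float(first[1])))
                continue
        snapped.append((float(jx), float(jy)))
    return snapped


_RING_OFFSETS = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
                 (-1, -1)]


def _grow_segment(rng, tip, safe_lo, safe_hi, blocked, length_scale,
                  clear_dist=None):
    """Propose one curve from a tip, bending into the safe box and around
    already-drawn vessels.  The curve's initial tangent always equals the
    tip's assigned direction — for a child branch that tangent encodes the
    junction's 30-70 degree separation, which must survive into the raster —
    so steering and collision-avoidance retries only move the far endpoint
    and the bend, never the launch direction.  Returns (samples, end point,
    end direction) or None.  The curve is NOT stamped; the caller commits it.

    Collision checking exempts only the short stretch within ``clear_dist``
    of the start (the parent junction blob); everything beyond must stay
    clear of previously drawn vessels so branches never cross.
    """
    pos, d0 = tip["pos"], tip["dir"]
    if clear_dist is None:
        # just enough to exit the launch blob's own clearance ring
        clear_dist = tip["width"] / 2.0 + 3.5
    for attempt in range(12):
        # progressively shorter proposals thread through crowded regions
        decay = 1.0 - 0.06 * attempt
        length = float(np.clip(rng.uniform(0.7, 1.1) * length_scale * decay,
                               30, 420))
        end = pos + d0 * length
        if not np.all((end > safe_lo) & (end < safe_hi)):
            # bend just enough to keep the endpoint inside the safe box,
            # without dragging growth toward the canvas centre
            target = np.clip(end, safe_lo + 40, safe_hi - 40)
            to_t = target - pos
            to_t = to_t / (np.linalg.norm(to_t) + 1e-12)
            bend = d0 + 1.4 * to_t
            bend = bend / np.linalg.norm(bend)
            end = np.clip(pos + bend * length, safe_lo, safe_hi)
        perp = np.array([-d0[1], d0[0]])
        sigma = length / 10.0 * (1.0 + 0.5 * attempt)
        ctrl = pos + d0 * (length / 2.0) + perp * rng.normal(0.0, sigma)
        ctrl = np.clip(ctrl, safe_lo, safe_hi)
        pts = _bezier(pos, ctrl, end)
        dist0 = np.linalg.norm(pts - pos, axis=1)
        check = pts[dist0 > clear_dist]
        if check.size:
            xi = np.clip(np.rint(check[:, 0]).astype(int), 0,
                         blocked.shape[1] - 1)
            yi = np.clip(np.rint(check[:, 1]).astype(int), 0,
                         blocked.shape[0] - 1)
            if blocked[yi, xi].any():
                continue
        end_dir = pts[-1] - pts[-2]
        end_dir = end_dir / (np.linalg.norm(end_dir) + 1e-12)
        return pts, pts[-1], end_dir
    return None


def _attempt_tree(rng, n_branch_events, canvas_size, min_junction_sep):
    """One tree-growth attempt; returns (mask, segments, junctions), with
    fewer junctions than requested when growth stalls on a crowded canvas."""
    w, h = canvas_size
    safe_lo = np.array([BORDER_MARGIN, BORDER_MARGIN])
    safe_hi = np.array([w - 1 - BORDER_MARGIN, h - 1 - BORDER_MARGIN])
    if np.any(safe_hi - safe_lo < 60):
        raise ValueError("canvas too small for tree growth")

    mask = np.zeros((h, w), dtype=bool)
    blocked = np.zeros((h, w), dtype=bool)
    # segment length tracks the junction spacing the event count implies
    length_scale = float(np.clip(
        0.8 * np.sqrt(w * h / max(n_branch_events, 1)), 45.0, 200.0))
    segments, junctions = [], []

    # wide canvases host several arcades (as a fundus does), since a single
    # tree cannot span them at realistic segment lengths
    n_roots = max(1, int(round(w / 250.0)))
    tips = []
    for k in range(n_roots):
        cell = (w - 2 * BORDER_MARGIN) / n_roots
        rx = BORDER_MARGIN + (k + 0.5) * cell
        ry = h * (0.35 if k % 2 == 0 else 0.65)
        rdir = np.array([1.0 if k % 2 == 0 else -1.0, 0.0])
        trunk = _grow_segment(
            rng, {"pos": np.array([rx, ry]), "dir": rdir,
                  "width": TRUNK_WIDTH},
            safe_lo, safe_hi, blocked, length_scale)
        if trunk is None:
            continue
        pts, end, end_dir = trunk
        _stamp(mask, blocked, pts, TRUNK_WIDTH)
        segments.append(pts)
        # a tip is the free end of an already-drawn segment; a branch event
        # records a junction there only once BOTH child curves are drawable
        tips.append({"pos": end, "dir": end_dir, "width": TRUNK_WIDTH})
    if not tips:
        raise ValueError("canvas too small for tree growth")
    events = 0
    attempts = 0
    max_attempts = 60 * (n_branch_events + 1)
    while events < n_branch_events:
        attempts += 1
        if not tips or attempts > max_attempts:
            break  # stalled: return the partial tree, caller decides
        tip = tips.pop(0)
        pos, direction, width = tip["pos"], tip["dir"], tip["width"]
        too_close = bool(junctions) and bool(
            (np.linalg.norm(np.asarray(junctions) - pos, axis=1)
             < min_junction_sep).any())
        if not too_close:
            sep = np.deg2rad(rng.uniform(*BRANCH_SEP_DEG))
            child_w = max(width * WIDTH_DECAY, MIN_WIDTH)
            # propose both children before stamping either, so a failed
            # second child never leaves a half-drawn branch
            children = []
            for sign in (+1.0, -1.0):
                grown = _grow_segment(
                    rng, {"pos": pos.copy(),
                          "dir": _rot2(direction, sign * sep / 2.0),
                          "width": child_w},
                    safe_lo, safe_hi, blocked, length_scale,
                    clear_dist=width / 2.0 + 3.5)
                if grown is None:
                    break
                children.append(grown)
            if len(children) == 2 and _siblings_clear(
                    children[0][0], children[1][0], pos, child_w):
                for pts, end, end_dir in children:
                    _stamp(mask, blocked, pts, child_w)
                    segments.append(pts)
                    tips.append({"pos": end, "dir": end_dir,
                                 "width": child_w})
                junctions.append((float(pos[0]), float(pos[1])))
                events += 1
                continue
        # extend with a continuation segment and retry branching later
        cont = _grow_segment(
            rng, {"pos": pos.copy(),
                  "dir": _rot2(direction, rng.normal(0.0, 0.2)),
                  "width": width},
            safe_lo, safe_hi, blocked, length_scale)
        if cont is not None:
            pts, end, end_dir = cont
            _stamp(mask, blocked, pts, width)
            segments.append(pts)
            tips.append({"pos": end, "dir": end_dir, "width": width})
        else:
            # stuck tip: re-aim and retry a few times before abandoning
            fails = tip.get("fails", 0) + 1
            if fails <= 6:
                tips.append({"pos": pos, "width": width, "fails": fails,
                             "dir": _rot2(direction,
                                          rng.uniform(-0.9, 0.9))})
    return mask, segments, junctions


def _siblings_clear(pts1, pts2, pos, width, near=15.0):
    """Sibling branches are proposed independently, so a strong bend can fold
    one across the other downstream; require the two curves to stay apart
    beyond the shared junction neighbourhood."""
    a = pts1[np.linalg.norm(pts1 - pos, axis=1) > near][::3]
    b = pts2[np.linalg.norm(pts2 - pos, axis=1) > near][::3]
    if a.size == 0 or b.size == 0:
        return True
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    return d2.min() > (width + 2.5) ** 2


def _branch_pixels(mask):
    """Detectable branch points of the rendered tree: skeleton pixels that
    carry three branches in pairwise non-adjacent ring directions (the Y/T
    structuring-element hit set, before any neighbourhood suppression)."""
    from .bifurcation import accumulate, build_bank, erode, extract_candidates
    from .preproc import thin

    skel = thin(mask.astype(np.uint8))
    acc = accumulate([erode(skel, se) for se in build_bank()])
    by, bx = np.nonzero(extract_candidates(acc))
    return np.stack([bx, by], axis=1).astype(np.float64)


def _validate_tree(mask, junctions):
    """A drawn tree is accepted when its rendered branch points and its
    recorded junctions agree one-to-one in a way that makes raster-order
    5x5 suppression provably emit exactly the junction coordinates:

    - every junction coordinate is itself a branch pixel and is raster-first
      within its Chebyshev-2 cluster (the survivor of the 5x5 window);
    - every branch pixel lies within Chebyshev 2 of exactly one junction,
      with nothing in the Chebyshev 3-4 guard ring (no chained clusters);
    - junctions stay >10 px apart after snapping.
    """
    branch = _branch_pixels(mask)
    if branch.shape[0] == 0:
        return (len(junctions) == 0), branch
    j = np.asarray(junctions, dtype=np.float64)
    if j.size == 0:
        return False, branch
    cheb = np.max(np.abs(branch[:, None, :] - j[None, :, :]), axis=2)
    nearest = cheb.min(axis=1)
    if (nearest > 2).any() and (nearest[nearest > 2] <= 4).any():
        return False, branch             # guard-ring violation (chains)
    if (nearest > 4).any():
        return False, branch             # stray branch point
    if ((cheb <= 2).sum(axis=1) > 1).any():
        return False, branch             # pixel claimed by two junctions
    if (cheb.min(axis=0) > 0).any():     # junction is not a branch pixel
        return False, branch
    for col in range(j.shape[0]):
        members = branch[cheb[:, col] <= 2]
        order = np.lexsort((members[:, 0], members[:, 1]))
        if not np.array_equal(members[order[0]], j[col]):
            return False, branch         # NMS would keep a different pixel
    if len(j) > 1:
        sep = np.linalg.norm(j[:, None, :] - j[None, :, :], axis=2)
        sep[np.diag_indices(len(j))] = np.inf
        if sep.min() <= 10.0:            # snapping pulled junctions together
            return False, branch
    return True, branch


def _filter_clean_junctions(mask, junctions):
    """Keep only junctions whose rendered branch-pixel cluster is clean:
    the junction is the raster-first branch pixel of an isolated Chebyshev-2
    cluster, so suppression is guaranteed to emit exactly that coordinate."""
    branch = _branch_pixels(mask)
    if branch.shape[0] == 0 or not junctions:
        return []
    j = np.asarray(junctions, dtype=np.float64)
    cheb = np.max(np.abs(branch[:, None, :] - j[None, :, :]), axis=2)
    keep = []
    for col, (jx, jy) in enumerate(junctions):
        if cheb[:, col].min() > 0:
            continue  # not itself a branch pixel
        near = branch[cheb[:, col] <= 4]
        if (np.max(np.abs(near - j[col]), axis=1) > 2).any():
            continue  # chained / split cluster
        members = branch[cheb[:, col] <= 2]
        order = np.lexsort((members[:, 0], members[:, 1]))
        if not np.array_equal(members[order[0]], j[col]):
            continue  # suppression would keep a different pixel
        keep.append((float(jx), float(jy)))
    return keep


def generate_tree(seed: int, n_branch_events: int,
                  canvas_size: tuple[int, int] = (1400, 900),
                  f: float = 700.0,
                  min_junction_sep: float = MIN_JUNCTION_SEP,
                  strict: bool = True,
                  max_tries: int = 25) -> SyntheticScene:
    """Grow a branching vessel tree with ``n_branch_events`` junctions.

    The canvas is (width, height); segments stay >= 10 px from the border and
    junctions at least ``min_junction_sep`` apart.  Junction coordinates are
    reported as rendered, i.e. snapped to the skeleton's branch pixel —
    rasterization at finite vessel width displaces the apparent branch point
    a few pixels up the bisector at shallow separation angles.

    With ``strict=True`` growth is re-attempted (deterministically in the
    seed) until the rendered branch points agree one-to-one with the recorded
    junctions, giving exactly ``n_branch_events`` fully certified ground-truth
    bifurcations.  With ``strict=False`` a single drawing is kept and the
    ground-truth list is instead *filtered* to the junctions whose rendered
    cluster is clean — appropriate for large multi-view scenes, where a
    handful of ambiguous junctions is harmless but whole-scene certification
    is combinatorially unlikely.
    """
    last_err = "tree growth failed"
    for k in range(max_tries):
        rng = np.random.default_rng((seed, k))
        mask, segments, junctions = _attempt_tree(
            rng, n_branch_events, canvas_size, min_junction_sep)
        junctions = _snap_junctions_to_skeleton(mask, junctions)
        if strict:
            if len(junctions) != n_branch_events:
                last_err = "canvas too small for requested branch events"
                continue
            ok, _ = _validate_tree(mask, junctions)
            if not ok:
                last_err = "rendered branch points disagree with junctions"
                continue
        else:
            junctions = _filter_clean_junctions(mask, junctions)
        canvas = _background_texture(rng, mask.shape)
        canvas[mask] = VESSEL_INTENSITY
        # mild optical blur: fundus vessels have soft edges, and hard edges
        # would let the shared Y-geometry dominate every junction descriptor
        canvas = ndimage.gaussian_filter(canvas, 1.2)
        w, h = canvas_size
        K = Intrinsics.centered(f, w, h)
        return SyntheticScene(canvas=canvas,
                              vessel_mask=mask.astype(np.uint8),
                              segments=segments,
                              bifurcations_gt=junctions,
                              canvas_K=K, seed=seed)
    raise ValueError(f"tree generation failed after {max_tries} tries: "
                     f"{last_err}")


def _background_texture(rng, shape):
    """Bright fundus field with intensity texture emulating the choroidal /
    nerve-fibre pattern, so local patches are discriminative for descriptor
    matching the way real fundus neighbourhoods are.  The finest texture
    scale is kept at a ~3 px correlation length: descriptor windows must
    stay recognisable under the ~1 px localisation jitter of morphological
    keypoint detection."""
    low = ndimage.gaussian_filter(rng.normal(0.0, 1.0, shape), 30.0)
    mid = ndimage.gaussian_filter(rng.normal(0.0, 1.0, shape), 3.0)
    low *= 10.0 / max(low.std(), 1e-9)
    mid *= 18.0 / max(mid.std(), 1e-9)
    return np.clip(BACKGROUND_INTENSITY + low + mid, 0.0, 255.0)


# ---------------------------------------------------------------------------
# View rendering
# ---------------------------------------------------------------------------

def render_view(scene: SyntheticScene, camera: Camera,
                view_size: tuple[int, int], noise_sigma: float = 2.0,
                vignette: float = 0.12, fov_radius_frac: float = 0.49,
                rng: np.random.Generator | None = None):
    """Render one camera view of the scene.

    View pixels are traced through the rotation-only model (ray = R K^-1 p)
    onto the canvas plane and sampled bilinearly; the vessel mask is sampled
    nearest-neighbour and carries no noise or vignetting.  Returns
    ``(image uint8, mask uint8{0,1})``.
    """
    w, h = view_size
    if rng is None:
        rng = np.random.default_rng(scene.seed + 1)
    xs, ys = np.meshgrid(np.arange(w, dtype=np.float64),
                         np.arange(h, dtype=np.float64))
    pts = np.stack([xs.ravel(), ys.ravel()], axis=1)
    rays = camera.rays(pts)
    z = rays[:, 2]
    if np.any(z <= 1e-9):
        raise ValueError("view outside scene")
    Kc = scene.canvas_K
    cxs = (Kc.fx * rays[:, 0] / z + Kc.cx).reshape(h, w)
    cys = (Kc.fy * rays[:, 1] / z + Kc.cy).reshape(h, w)
    ch, cw = scene.canvas.shape
    if cxs.min() < 0 or cxs.max() > cw - 1 or cys.min() < 0 \
            or cys.max() > ch - 1:
        raise ValueError("view outside scene")
    coords = np.stack([cys.ravel(), cxs.ravel()])
    img = ndimage.map_coordinates(scene.canvas, coords, order=1
                                  ).reshape(h, w)
    mask = ndimage.map_coordinates(scene.vessel_mask, coords, order=0
                                   ).reshape(h, w).astype(np.uint8)

    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    r2 = (xs - cx) ** 2 + (ys - cy) ** 2
    R = fov_radius_frac * w
    if vignette > 0:
        img = img * np.clip(1.0 - vignette * r2 / R ** 2, 0.0, 1.0)
    fov = r2 <= R ** 2
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, img.shape)
    img = np.where(fov, img, 0.0)
    mask = np.where(fov, mask, 0).astype(np.uint8)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), mask


def project_to_view(points, camera: Camera, scene: SyntheticScene):
    """Project canvas-plane points into a view; returns (n, 2) pixels and a
    visibility flag (in front of the camera)."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    Kc = scene.canvas_K
    homo = np.hstack([pts, np.ones((pts.shape[0], 1))])
    rays = (Kc.K_inv @ homo.T).T  # canvas pixel -> world ray (canvas R = I)
    proj = (camera.K.K @ camera.R.T @ rays.T).T
    z = proj[:, 2]
    ok = z > 1e-9
    with np.errstate(divide="ignore", invalid="ignore"):
        xy = proj[:, :2] / z[:, None]
    return xy, ok


# ---------------------------------------------------------------------------
# Multi-view sequences
# ---------------------------------------------------------------------------

def _rot_y(angle):
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_x(angle):
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def homography_between(cam_i: Camera, cam_j: Camera) -> np.ndarray:
    """Ground-truth H mapping image-i pixels to image-j pixels:
    Kj Rj^T Ri Ki^-1, normalised to h33 = 1."""
    H = cam_j.K.K @ cam_j.R.T @ cam_i.R @ cam_i.K.K_inv
    return H / H[2, 2]


def overlap_fraction(H_ij: np.ndarray, size_i, size_j, n: int = 60,
                     fov_radius_frac: float | None = None) -> float:
    """Fraction of image i whose H-mapped position lands inside image j.

    With ``fov_radius_frac`` the fraction refers to the circular illuminated
    field (the quantity overlap percentages of fundus image pairs describe);
    otherwise to the full pixel rectangle.
    """
    wi, hi = size_i
    wj, hj = size_j
    xs = np.linspace(0, wi - 1, n)
    ys = np.linspace(0, hi - 1, n)
    gx, gy = np.meshgrid(xs, ys)
    if fov_radius_frac is not None:
        ri = fov_radius_frac * wi
        in_fov = ((gx - (wi - 1) / 2) ** 2 + (gy - (hi - 1) / 2) ** 2
                  <= ri ** 2)
        gx, gy = gx[in_fov], gy[in_fov]
    pts = np.stack([gx.ravel(), gy.ravel(), np.ones(gx.size)])
    proj = H_ij @ pts
    with np.errstate(divide="ignore", invalid="ignore"):
        px = proj[0] / proj[2]
        py = proj[1] / proj[2]
    inside = (proj[2] > 0) & (px >= 0) & (px <= wj - 1) \
        & (py >= 0) & (py <= hj - 1)
    if fov_radius_frac is not None:
        rj = fov_radius_frac * wj
        inside &= ((px - (wj - 1) / 2) ** 2 + (py - (hj - 1) / 2) ** 2
                   <= rj ** 2)
    return float(inside.mean())


@dataclass
class SyntheticSequence:
    scene: SyntheticScene
    images: list                     # uint8 views
    masks: list                      # uint8 {0,1} vessel masks
    cameras_gt: list                 # Camera per view
    homographies_gt: dict            # (i, j) -> H ground truth (i < j)
    correspondences_gt: dict         # (i, j) -> [((xA,yA),(xB,yB)), ...]
    bifurcations_px: list            # per view: [(x, y)] visible junctions
    overlap_step: float              # rotation step between adjacent views


def _solve_step_angle(overlap_target, f, view_size,
                      fov_radius_frac=0.49):
    """Pan angle between adjacent views giving the requested overlap of the
    circular illuminated fields, by bisection on the measured overlap."""
    w, h = view_size
    K = Intrinsics.centered(f, w, h)
    half_fov = np.arctan((w / 2.0) / f)

    def measured(alpha):
        cam_a = Camera(K, np.eye(3))
        cam_b = Camera(K, _rot_y(alpha))
        return overlap_fraction(homography_between(cam_a, cam_b),
                                (w, h), (w, h),
                                fov_radius_frac=fov_radius_frac)

    lo, hi = 1e-4, np.pi / 2 - half_fov - 0.05
    if hi <= lo or measured(hi) > overlap_target:
        raise ValueError("infeasible overlap target")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if measured(mid) > overlap_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_sequence(seed: int, n_views: int, overlap_target: float = 0.5,
                      f: float | None = None,
                      view_size: tuple[int, int] = (700, 605),
                      noise_sigma: float = 2.0, vignette: float = 0.12,
                      tilt_jitter_deg: float = 0.8,
                      n_branch_events: int | None = None
                      ) -> SyntheticSequence:
    """Generate a panning sequence of views with known geometry.

    Cameras share centred intrinsics with focal ``f`` (default: 30-degree
    horizontal field of view, the common fundus photograph setting, i.e.
    f ~ 1.87x the frame width — 1300 px at the 700x605 working size);
    successive views pan about the vertical axis by the step that realises
    ``overlap_target`` of the circular illuminated fields (plus a small
    random tilt for realism).  The planar canvas bounds the usable field, so
    wide sequences at low overlap can be infeasible.
    """
    if n_views < 1:
        raise ValueError("need at least one view")
    w, h = view_size
    if f is None:
        f = (w / 2.0) / np.tan(np.deg2rad(15.0))
    rng = np.random.default_rng(seed)
    K = Intrinsics.centered(f, w, h)
    if n_views > 1:
        step = _solve_step_angle(overlap_target, f, view_size)
    else:
        step = 0.0
    half_fov = np.arctan((w / 2.0) / f)
    max_pan = (n_views - 1) / 2.0 * step + half_fov
    if max_pan >= np.pi / 2 - 0.03:
        raise ValueError("infeasible overlap target")

    # canvas sized to contain every view footprint (same parity as the view
    # so an identity camera samples the canvas at integer offsets)
    spread = f * np.tan(max_pan)
    cw = int(np.ceil(2 * spread)) + 80
    ch = int(np.ceil(h / max(np.cos(max_pan), 0.2))) + 120
    cw += (cw - w) % 2
    ch += (ch - h) % 2
    # junction spacing is kept absolute (~57 px, comfortably above the 40 px
    # descriptor window) so neighbouring junctions stay distinguishable; a
    # 700x605 view then sees ~130 junctions (real frames carry ~256 features)
    if n_branch_events is None:
        n_branch_events = int(np.clip(cw * ch / 3200.0, 20, 1500))
    scene = generate_tree(seed, n_branch_events, canvas_size=(cw, ch), f=f,
                          strict=False)

    cameras = []
    for i in range(n_views):
        pan = (i - (n_views - 1) / 2.0) * step
        tilt = np.deg2rad(rng.normal(0.0, tilt_jitter_deg)) if n_views > 1 \
            else 0.0
        cameras.append(Camera(K, _rot_y(pan) @ _rot_x(tilt)))
    scene.cameras_gt = cameras

    images, masks = [], []
    for i, cam in enumerate(cameras):
        view_rng = np.random.default_rng((seed, i))
        img, mask = render_view(scene, cam, view_size,
                                noise_sigma=noise_sigma, vignette=vignette,
                                rng=view_rng)
        images.append(img)
        masks.append(mask)

    homographies = {}
    correspondences = {}
    bifs = []
    junctions = np.asarray(scene.bifurcations_gt, dtype=np.float64)
    margin = 8.0
    fov_r = 0.49 * w - margin  # junctions must land inside the lit field
    vis = []
    for cam in cameras:
        xy, ok = project_to_view(junctions, cam, scene)
        inside = ok & (xy[:, 0] >= margin) & (xy[:, 0] <= w - 1 - margin) \
            & (xy[:, 1] >= margin) & (xy[:, 1] <= h - 1 - margin) \
            & ((xy[:, 0] - (w - 1) / 2) ** 2
               + (xy[:, 1] - (h - 1) / 2) ** 2 <= fov_r ** 2)
        vis.append((xy, inside))
        bifs.append([tuple(p) for p in xy[inside]])
    for i in range(n_views):
        for j in range(i + 1, n_views):
            H = homography_between(cameras[i], cameras[j])
            if overlap_fraction(H, view_size, view_size) <= 0:
                continue
            homographies[(i, j)] = H
            both = vis[i][1] & vis[j][1]
            pairs = [ (tuple(vis[i][0][k]), tuple(vis[j][0][k]))
                      for k in np.nonzero(both)[0] ]
            if pairs:
                correspondences[(i, j)] = pairs
    return SyntheticSequence(scene=scene, images=images, masks=masks,
                             cameras_gt=cameras, homographies_gt=homographies,
                             correspondences_gt=correspondences,
                             bifurcations_px=bifs, overlap_step=step)


def ground_truth_mosaic(scene: SyntheticScene, bbox, sphere_scale: float):
    """Sample the clean canvas directly in mosaic (spherical) coordinates.

    ``bbox`` is (x0, y0, width, height) in mosaic pixels.  Used as the
    reference surface when scoring a blended mosaic against the ground-truth
    flat scene.
    """
    x0, y0, w, h = bbox
    gx, gy = np.meshgrid(np.arange(x0, x0 + w), np.arange(y0, y0 + h))
    u = gx / sphere_scale
    v = gy / sphere_scale
    rays = np.stack([np.sin(v) * np.sin(u), -np.cos(v),
                     np.sin(v) * np.cos(u)], axis=-1)
    z = rays[..., 2]
    Kc = scene.canvas_K
    with np.errstate(divide="ignore", invalid="ignore"):
        cxs = Kc.fx * rays[..., 0] / z + Kc.cx
        cys = Kc.fy * rays[..., 1] / z + Kc.cy
    ch, cw = scene.canvas.shape
    valid = (z > 0) & (cxs >= 0) & (cxs <= cw - 1) & (cys >= 0) \
        & (cys <= ch - 1)
    coords = np.stack([np.where(valid, cys, 0).ravel(),
                       np.where(valid, cxs, 0).ravel()])
    img = ndimage.map_coordinates(scene.canvas, coords, order=1
                                  ).reshape(h, w)
    img[~valid] = 0.0
    return img, valid.astype(np.uint8)
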
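"""End-to-end mosaicking pipeline.

Runs the full flow over a set of fundus photographs and their vessel masks:
working-resolution resampling, mask binarization and thinning, bifurcation
detection, descriptor extraction, all-pairs ratio matching with RANSAC
verification and confidence gating, rotation-only camera estimation (focal
median, rotation chaining, bundle adjustment), spherical warping, gain
compensation and multiband blending.  The result is the mosaic plus a JSON
-serialisable report of every per-pair and per-image quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from . import bifurcation as bif
from . import descriptor as desc
from . import matching as mt
from . import metrics as met
from . import preproc as pp
from . import warp_blend as wb
from .camera import (Camera, Intrinsics, bundle_adjust, chain_rotations,
                     estimate_global_focal)


@dataclass
class PipelineConfig:
    ratio: float = 0.3
    ransac_t: float = 3.0
    ransac_iters: int = 2000
    confidence: float = 1.0          # pair-acceptance threshold in [0.5, 1.5]
    descriptor_scale: float = 2.0
    nms_window: int = 5
    pyramid_levels: int = 5
    binarize_threshold: float = 0.5
    working_width: int = 700
    working_height: int = 605
    fallback_focal: float | None = None   # used when f is unobservable
    seed: int = 0

    def __post_init__(self):
        if not 0.5 <= self.confidence <= 1.5:
            raise ValueError("confidence must lie in [0.5, 1.5]")
        if self.nms_window % 2 == 0 or self.nms_window < 1:
            raise ValueError("nms_window must be odd and >= 1")
        for name in ("ratio", "ransac_t", "descriptor_scale",
                     "binarize_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.working_width <= 0 or self.working_height <= 0:
            raise ValueError("working size must be positive")


def fov_footprint(image: np.ndarray, thresh: float = 15.0) -> np.ndarray:
    """Estimate the illuminated fundus field of a photograph.

    Fundus frames surround the circular field with near-black; thresholding
    the gray image, keeping the largest component, filling holes and eroding
    slightly gives a conservative validity footprint for warping/blending.
    """
    gray = pp.to_gray(image)
    mask = gray > thresh
    if not mask.any():
        return np.ones(gray.shape, dtype=np.uint8)
    lab, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)
    mask = ndimage.binary_erosion(mask, iterations=2, border_value=1)
    return mask.astype(np.uint8)


def _prepare(images, masks, cfg: PipelineConfig):
    """Load/resize inputs, thin the masks, detect + describe bifurcations."""
    work = []
    size = (cfg.working_width, cfg.working_height)
    bank = bif.build_bank()
    for img, msk in zip(images, masks):
        if isinstance(img, (str, bytes)) or hasattr(img, "__fspath__"):
            img = pp.load_image(img)
        if isinstance(msk, (str, bytes)) or hasattr(msk, "__fspath__"):
            msk = pp.load_mask(msk)
        img = np.asarray(img)
        msk = np.asarray(msk)
        if msk.shape[:2] != img.shape[:2]:
            raise ValueError("mask dimensions do not match image")
        if img.shape[1::-1] != size:
            img, _ = pp.resize_to_working(img, *size)
            msk, _ = pp.resize_to_working(
                (np.asarray(msk, dtype=np.float64)
                 * (255.0 if msk.max() <= 1.0 else 1.0)).astype(np.uint8),
                *size)
            msk = np.asarray(msk, dtype=np.float64) / 255.0
        binary = pp.binarize(msk, cfg.binarize_threshold)
        skeleton = pp.thin(binary)
        points = bif.detect_bifurcations(skeleton, bank,
                                         window=cfg.nms_window)
        kps, descs = desc.describe(img, points, s=cfg.descriptor_scale)
        work.append({"image": img, "skeleton": skeleton, "points": points,
                     "keypoints": kps, "descriptors": descs,
                     "footprint": fov_footprint(img)})
    return work


def _match_pairs(work, cfg: PipelineConfig):
    """All-pairs ratio matching + RANSAC + confidence gating."""
    n = len(work)
    kept, dropped = {}, {}
    ss = np.random.SeedSequence(cfg.seed)
    pair_seeds = {}
    for i in range(n):
        for j in range(i + 1, n):
            pair_seeds[(i, j)] = int(
                np.random.SeedSequence((cfg.seed, i, j)).generate_state(1)[0]
                % (2 ** 31))
    del ss
    for (i, j), seed in pair_seeds.items():
        ptsA = np.array([[kp.x, kp.y] for kp in work[i]["keypoints"]])
        ptsB = np.array([[kp.x, kp.y] for kp in work[j]["keypoints"]])
        try:
            matches = mt.match_descriptors(work[i]["descriptors"],
                                           work[j]["descriptors"],
                                           ratio=cfg.ratio, ptsB=ptsB)
            # multi-orientation keypoints can yield one match per mode;
            # keep only the closest match per keypoint-position pair
            best = {}
            for m in matches:
                key = (tuple(np.round(ptsA[m.i], 1)),
                       tuple(np.round(ptsB[m.j], 1)))
                if key not in best or m.d < best[key].d:
                    best[key] = m
            matches = sorted(best.values(), key=lambda m: (m.i, m.j))
            H, flags = mt.ransac_homography(matches, ptsA, ptsB,
                                            t=cfg.ransac_t,
                                            iters=cfg.ransac_iters,
                                            seed=seed)
        except ValueError as exc:
            dropped[(i, j)] = str(exc)
            continue
        n_inl = int(flags.sum())
        conf = mt.pair_confidence(n_inl, len(matches))
        entry = {"H": H, "matches": matches, "n_matches": len(matches),
                 "n_inliers": n_inl, "confidence": conf,
                 "ptsA": ptsA, "ptsB": ptsB}
        if conf >= cfg.confidence:
            kept[(i, j)] = entry
        else:
            dropped[(i, j)] = f"confidence {conf:.3f} below threshold"
    return kept, dropped


def run_mosaic(images, masks, config: PipelineConfig | None = None):
    """Mosaic a set of overlapping fundus photographs.

    ``images``/``masks`` are equal-length lists of arrays or file paths.
    Returns ``(mosaic uint8, coverage mask, report dict)``.  Raises
    ValueError("images do not form a mosaic") when no pair passes the
    confidence gate; if the pair graph is disconnected, the component
    containing the reference image is mosaicked and the rest reported.
    """
    cfg = config or PipelineConfig()
    if len(images) < 2 or len(images) != len(masks):
        raise ValueError("need >= 2 images with one mask each")
    work = _prepare(images, masks, cfg)
    kept, dropped = _match_pairs(work, cfg)
    if not kept:
        raise ValueError("images do not form a mosaic")

    # reference image: largest total inlier count
    totals = np.zeros(len(work))
    for (i, j), e in kept.items():
        totals[i] += e["n_inliers"]
        totals[j] += e["n_inliers"]
    reference = int(np.argmax(totals))

    # restrict to the connected component of the reference
    import networkx as nx
    g = nx.Graph(list(kept))
    comp = nx.node_connected_component(g, reference)
    excluded = sorted(set(range(len(work))) - comp)
    pairs = {k: v for k, v in kept.items() if k[0] in comp and k[1] in comp}

    W, Hgt = cfg.working_width, cfg.working_height
    cx, cy = (W - 1) / 2.0, (Hgt - 1) / 2.0
    # plausibility prior: fundus-camera fields of view lie well inside
    # ~7-110 degrees, i.e. f between about a quarter of and six times the
    # frame size; estimates outside are degenerate-geometry artifacts
    d = max(W, Hgt)
    try:
        f = estimate_global_focal([e["H"] for e in pairs.values()], cx, cy,
                                  plausible=(0.25 * d, 6.0 * d))
    except ValueError:
        f = cfg.fallback_focal if cfg.fallback_focal is not None else 1.8 * d
    K = Intrinsics(f, f, cx, cy)
    pair_graph = {k: (e["H"], e["n_inliers"]) for k, e in pairs.items()}
    rotations = chain_rotations(pair_graph, K, reference)

    ids = sorted(comp)
    index = {img_id: k for k, img_id in enumerate(ids)}
    cameras = [Camera(K, rotations[i]) for i in ids]
    corr = {}
    for (i, j), e in pairs.items():
        inl = [m for m in e["matches"] if m.inlier]
        P = np.array([e["ptsA"][m.i] for m in inl])
        Q = np.array([e["ptsB"][m.j] for m in inl])
        corr[(index[i], index[j])] = (P, Q)
    cameras, final_cost = bundle_adjust(corr, cameras,
                                        reference=index[reference])
    f = cameras[0].K.fx

    layers = []
    for k, img_id in enumerate(ids):
        layers.append(wb.warp_image(work[img_id]["image"], cameras[k],
                                    sphere_scale=f,
                                    footprint=work[img_id]["footprint"]))
    gains = wb.gain_compensate(layers)
    wb.apply_gains(layers)
    mosaic, coverage, origin = wb.multiband_blend(layers,
                                                  levels=cfg.pyramid_levels)

    report = {
        "config": asdict(cfg),
        "n_images": len(work),
        "reference": reference,
        "focal": float(f),
        "mosaic_origin": list(origin),
        "excluded_images": excluded,
        "gains": [float(g) for g in gains],
        "rotations": {str(i): cameras[index[i]].R.ravel().tolist()
                      for i in ids},
        "pairs": {}, "dropped_pairs": {},
        "n_keypoints": [len(w["keypoints"]) for w in work],
    }
    for (i, j), e in pairs.items():
        ci, cj = cameras[index[i]], cameras[index[j]]
        P, Q = corr[(index[i], index[j])]
        rmse_px = met.matching_rmse(list(zip(P, Q)), ci, cj, units="pixel")
        report["pairs"][f"{i}-{j}"] = {
            "n_matches": e["n_matches"], "n_inliers": e["n_inliers"],
            "confidence": round(e["confidence"], 6),
            "rmse_px": round(rmse_px, 6),
            "H": np.asarray(e["H"]).ravel().tolist(),
        }
    for (i, j), reason in dropped.items():
        report["dropped_pairs"][f"{i}-{j}"] = reason
    return np.clip(np.rint(mosaic), 0, 255).astype(np.uint8), coverage, report
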
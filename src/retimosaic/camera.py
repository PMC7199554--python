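"""Rotation-only camera estimation: focal from homographies, rotation
chaining, and ray-space bundle adjustment.

The fundus camera is modelled as rotating about its optical centre, so image
pixels map to viewing rays as r = R K^-1 p with shared intrinsics
K = [[f,0,cx],[0,f,cy],[0,0,1]] and a per-image rotation (reference image
R = I).  Each pairwise homography constrains the focal length through the
orthonormality of K^-1 H K; the global focal is the median over all per-pair
estimates.  Rotations are propagated from the reference along a maximum
spanning tree of the pair graph via Rj = Ri K^-1 Hij^-1 K, and all cameras
are refined jointly by Levenberg-Marquardt on the ray alignment cost
sum ||Ri Ki^-1 p - Rj Kj^-1 q||^2 over matched points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy.spatial.transform import Rotation as SciRotation


@dataclass
class Intrinsics:
    fx: float
    fy: float
    cx: float
    cy: float

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")

    @property
    def K(self) -> np.ndarray:
        return np.array([[self.fx, 0, self.cx],
                         [0, self.fy, self.cy],
                         [0, 0, 1.0]])

    @property
    def K_inv(self) -> np.ndarray:
        return np.array([[1 / self.fx, 0, -self.cx / self.fx],
                         [0, 1 / self.fy, -self.cy / self.fy],
                         [0, 0, 1.0]])

    @classmethod
    def centered(cls, f: float, width: int, height: int) -> "Intrinsics":
        """Single focal, principal point at the image centre."""
        return cls(f, f, (width - 1) / 2.0, (height - 1) / 2.0)


@dataclass
class Camera:
    K: Intrinsics
    R: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=np.float64)
        check_rotation(self.R)

    def rays(self, pts: np.ndarray, unit: bool = False) -> np.ndarray:
        """Viewing rays R K^-1 (x, y, 1)^T for (n, 2) pixel points.

        With ``unit=True`` rays are normalised to the unit viewing sphere;
        two pixels observing the same scene point then yield identical
        vectors, not merely parallel ones.
        """
        pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
        homo = np.hstack([pts, np.ones((pts.shape[0], 1))])
        rays = (self.R @ self.K.K_inv @ homo.T).T
        if unit:
            rays = rays / np.linalg.norm(rays, axis=1, keepdims=True)
        return rays


def check_rotation(R: np.ndarray, tol: float = 1e-9) -> None:
    if R.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    if not np.allclose(R.T @ R, np.eye(3), atol=tol * 1e3):
        raise ValueError("matrix is not orthonormal")
    if np.linalg.det(R) < 0:
        raise ValueError("matrix is a reflection, not a rotation")


def project_to_rotation(M: np.ndarray) -> np.ndarray:
    """Nearest rotation in Frobenius norm (polar / SVD projection)."""
    u, _, vt = np.linalg.svd(M)
    R = u @ vt
    if np.linalg.det(R) < 0:
        u[:, -1] = -u[:, -1]
        R = u @ vt
    return R


# ---------------------------------------------------------------------------
# Focal estimation
# ---------------------------------------------------------------------------

def _center_homography(H: np.ndarray, cx: float, cy: float) -> np.ndarray:
    """Conjugate H so it acts on principal-point-centred coordinates."""
    T = np.array([[1, 0, cx], [0, 1, cy], [0, 0, 1.0]])
    T_inv = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1.0]])
    return T_inv @ H @ T


def focal_from_homography(H: np.ndarray, cx: float = 0.0, cy: float = 0.0,
                          eps: float = 1e-8) -> float | None:
    """Focal length of the source camera from one homography.

    With centred coordinates and H ~ K R K^-1 (K = diag(f, f, 1)), equality
    of the first two row norms of K^-1 H K gives
    f^2 = (h23^2 - h13^2) / (h11^2 + h12^2 - h21^2 - h22^2); their
    orthogonality gives f^2 = -h13 h23 / (h11 h21 + h12 h22).  The first
    branch is used when its denominator is non-negligible and the result
    positive, else the second; ``None`` when neither yields a positive f^2
    (e.g. identity or pure-translation H, where f is unobservable).
    """
    Hc = _center_homography(np.asarray(H, dtype=np.float64), cx, cy)
    h11, h12, h13 = Hc[0]
    h21, h22, h23 = Hc[1]
    den1 = h11 ** 2 + h12 ** 2 - h21 ** 2 - h22 ** 2
    if abs(den1) > eps:
        f2 = (h23 ** 2 - h13 ** 2) / den1
        if f2 > 0:
            return float(np.sqrt(f2))
    den2 = h11 * h21 + h12 * h22
    if abs(den2) > eps:
        f2 = -h13 * h23 / den2
        if f2 > 0:
            return float(np.sqrt(f2))
    return None


def estimate_global_focal(homographies: list[np.ndarray],
                          cx: float = 0.0, cy: float = 0.0,
                          plausible: tuple[float, float] | None = None
                          ) -> float:
    """Median focal over all per-pair estimates.

    Each homography constrains both of its images, so H and H^-1 are both
    evaluated.  ``plausible`` is an optional (lo, hi) range in pixels;
    estimates outside it — typically artifacts of a noisy homography with
    near-degenerate rotation geometry — are discarded.  Raises when no pair
    yields a usable estimate (the caller may fall back to a default).
    """
    estimates = []
    for H in homographies:
        for M in (H, np.linalg.inv(H)):
            f = focal_from_homography(M, cx, cy)
            if f is None:
                continue
            if plausible is not None and not plausible[0] <= f <= plausible[1]:
                continue
            estimates.append(f)
    if not estimates:
        raise ValueError("focal unobservable")
    return float(np.median(estimates))


# ---------------------------------------------------------------------------
# Rotation chaining
# ---------------------------------------------------------------------------

def chain_rotations(pair_graph: dict, K: Intrinsics, reference: int,
                    n_images: int | None = None) -> dict:
    """Propagate rotations from the reference image along the pair graph.

    ``pair_graph`` maps (i, j) -> (Hij, n_inliers) with Hij the homography
    sending image-i pixels to image-j pixels.  A maximum spanning tree by
    inlier count picks the most reliable chains; along each tree edge
    Rj = Ri K^-1 Hij^-1 K, re-projected to the nearest orthonormal matrix.
    The reference image gets the identity.
    """
    g = nx.Graph()
    g.add_node(reference)
    for (i, j), (H, n_inl) in pair_graph.items():
        g.add_edge(i, j, weight=n_inl, H=np.asarray(H, dtype=np.float64),
                   src=i)
    if n_images is not None:
        missing = set(range(n_images)) - set(g.nodes)
        if missing:
            raise ValueError(f"images not connected to the pair graph: "
                             f"{sorted(missing)}")
    tree = nx.maximum_spanning_tree(g, weight="weight")
    unreachable = set(g.nodes) - set(
        nx.node_connected_component(tree, reference))
    if unreachable:
        raise ValueError(f"images unreachable from reference: "
                         f"{sorted(unreachable)}")
    rotations = {reference: np.eye(3)}
    for parent, child in nx.bfs_edges(tree, reference):
        data = tree.edges[parent, child]
        H = data["H"]
        if data["src"] != parent:  # stored as child->parent; invert
            H = np.linalg.inv(H)
        Rj = rotations[parent] @ K.K_inv @ np.linalg.inv(H) @ K.K
        rotations[child] = project_to_rotation(Rj)
    return rotations


# ---------------------------------------------------------------------------
# Bundle adjustment
# ---------------------------------------------------------------------------

def ray_cost(correspondences: dict, cameras: list[Camera]) -> float:
    """Ray-alignment cost: sum over matched points of
    ||Ri Ki^-1 p - Rj Kj^-1 q||^2 on unit viewing rays.

    Rays are compared on the unit sphere: back-projections of the same scene
    point from a purely rotating camera agree in direction, and only the
    direction is observable, so exact correspondences under the true cameras
    cost exactly zero.
    """
    return float(np.sum(_residuals(correspondences, cameras) ** 2))


def _residuals(correspondences: dict, cameras: list[Camera]) -> np.ndarray:
    res = []
    for (i, j), (P, Q) in correspondences.items():
        res.append(cameras[i].rays(P, unit=True)
                   - cameras[j].rays(Q, unit=True))
    return np.concatenate(res, axis=0).ravel()


def _build_cameras(f, rotations, template: list[Camera]) -> list[Camera]:
    cams = []
    for cam, R in zip(template, rotations):
        K = Intrinsics(f, f, cam.K.cx, cam.K.cy)
        cams.append(Camera(K, R))
    return cams


def bundle_adjust(correspondences: dict, cameras: list[Camera],
                  reference: int = 0, max_iter: int = 100,
                  tol: float = 1e-8, history: list | None = None):
    """Jointly refine rotations and the shared focal by Levenberg-Marquardt.

    Parameters are one shared focal plus a local axis-angle increment (3 per
    image, reference fixed) composed onto each current rotation.  Damping is
    multiplied by 10 on a rejected step and divided by 10 on acceptance;
    accepted steps never increase the cost.  Convergence when the relative
    cost change drops below ``tol`` or after ``max_iter`` iterations.
    Returns ``(refined cameras, final cost)``; the cost is the ray-alignment
    sum of squares in focal-scaled (pixel-comparable) units.
    """
    if not correspondences:
        raise ValueError("need at least one correspondence pair")
    n = len(cameras)
    free = [i for i in range(n) if i != reference]
    f = cameras[0].K.fx
    rotations = [cam.R.copy() for cam in cameras]

    def residuals_at(df, omegas):
        # residuals are the unit-ray differences scaled by the shared
        # focal (pixel-comparable units).  The scaling leaves the optimum
        # over rotations untouched at fixed f but removes the degenerate
        # descent direction in which inflating f shrinks every K^-1 ray
        rots = list(rotations)
        for k, i in enumerate(free):
            delta = SciRotation.from_rotvec(omegas[k]).as_matrix()
            rots[i] = delta @ rotations[i]
        cams = _build_cameras(f + df, rots, cameras)
        return (f + df) * _residuals(correspondences, cams)

    n_params = 1 + 3 * len(free)
    lam = 1e-3
    r = residuals_at(0.0, np.zeros((len(free), 3)))
    cost = float(r @ r)
    if not np.isfinite(cost):
        raise ValueError("diverged")
    if history is not None:
        history.append(cost)

    for _ in range(max_iter):
        # numeric Jacobian about the current linearization point
        J = np.zeros((r.size, n_params))
        h_f = max(1e-6 * abs(f), 1e-6)
        J[:, 0] = (residuals_at(h_f, np.zeros((len(free), 3))) - r) / h_f
        h_w = 1e-7
        for k in range(len(free)):
            for axis in range(3):
                om = np.zeros((len(free), 3))
                om[k, axis] = h_w
                J[:, 1 + 3 * k + axis] = (residuals_at(0.0, om) - r) / h_w
        JtJ = J.T @ J
        g = J.T @ r
        accepted = False
        for _try in range(25):
            A = JtJ + lam * np.diag(np.maximum(np.diag(JtJ), 1e-12))
            try:
                step = np.linalg.solve(A, -g)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            df = step[0]
            omegas = step[1:].reshape(len(free), 3)
            if f + df <= 0:
                lam *= 10
                continue
            r_new = residuals_at(df, omegas)
            cost_new = float(r_new @ r_new)
            if np.isfinite(cost_new) and cost_new <= cost:
                # accept: fold increments into the state
                f = f + df
                for k, i in enumerate(free):
                    delta = SciRotation.from_rotvec(omegas[k]).as_matrix()
                    rotations[i] = project_to_rotation(delta @ rotations[i])
                rel = (cost - cost_new) / max(cost, 1e-300)
                r, cost = r_new, cost_new
                if history is not None:
                    history.append(cost)
                lam = max(lam / 10, 1e-12)
                accepted = True
                if rel < tol:
                    return _build_cameras(f, rotations, cameras), cost
                break
            lam *= 10
        if not accepted:
            break
    if not np.isfinite(cost):
        raise ValueError("diverged")
    return _build_cameras(f, rotations, cameras), cost


def cameras_to_json(cameras: list[Camera]) -> list[dict]:
    return [{"f": cam.K.fx, "cx": cam.K.cx, "cy": cam.K.cy,
             "R": cam.R.ravel().tolist()} for cam in cameras]


def cameras_from_json(entries: list[dict]) -> list[Camera]:
    cams = []
    for e in entries:
        K = Intrinsics(e["f"], e["f"], e["cx"], e["cy"])
        cams.append(Camera(K, np.asarray(e["R"]).reshape(3, 3)))
    return cams
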
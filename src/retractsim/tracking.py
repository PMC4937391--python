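"""Retractor-surface tracking: point clouds, CPD registration, BC transfer.

The displacement boundary conditions on the crack faces come from tracking
the retractor blade surfaces: the scanned (outer) surface is extruded by the
blade thickness along its normals to reach the tissue-contact surface, the
pre- and post-retraction clouds are registered with the coherent point drift
(CPD) algorithm, and the per-point displacements are transferred to the
crack-face mesh nodes by inverse-distance weighting.

CPD is the standard EM formulation (rigid and affine modes) with a uniform
outlier component of weight ``w``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["PointCloud", "extrude_retractor_surface", "register_point_sets",
           "map_displacements_to_nodes", "CPDResult"]


@dataclass
class PointCloud:
    """Points in world millimetres with optional unit normals."""

    points: np.ndarray
    normals: np.ndarray | None = None
    frame: str = "image"

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point cloud contains non-finite coordinates")
        if self.normals is not None:
            self.normals = np.atleast_2d(np.asarray(self.normals, dtype=float))
            norms = np.linalg.norm(self.normals, axis=1, keepdims=True)
            if np.any(norms == 0):
                raise ValueError("zero-length normal in point cloud")
            self.normals = self.normals / norms

    def __len__(self) -> int:
        return len(self.points)

    def transformed(self, affine: np.ndarray) -> "PointCloud":
        """Apply a 4x4 affine (e.g. the LRS -> image space calibration)."""
        affine = np.asarray(affine, dtype=float)
        pts = self.points @ affine[:3, :3].T + affine[:3, 3]
        nrm = None
        if self.normals is not None:
            nrm = self.normals @ np.linalg.inv(affine[:3, :3])
        return PointCloud(pts, nrm, self.frame)


def extrude_retractor_surface(cloud: PointCloud, thickness: float) -> PointCloud:
    """Offset each point by the blade thickness along its normal.

    Converts the scanned outer blade surface into the tissue-contact
    surface; the physical blades are 2.9 mm thick.
    """
    if cloud.normals is None:
        raise ValueError("extrusion requires per-point normals")
    if thickness < 0:
        raise ValueError("thickness must be >= 0")
    return PointCloud(cloud.points + thickness * cloud.normals,
                      cloud.normals, cloud.frame)


@dataclass
class CPDResult:
    """Registration output: transform, transformed source, displacements."""

    mode: str
    rotation: np.ndarray          # (3, 3) linear part (rotation or affine A)
    translation: np.ndarray       # (3,)
    scale: float
    transformed: np.ndarray       # (n, 3) transformed source points
    displacements: np.ndarray     # (n, 3) transformed - source
    sigma2: float
    n_iterations: int

    @property
    def affine(self) -> np.ndarray:
        T = np.eye(4)
        T[:3, :3] = self.scale * self.rotation
        T[:3, 3] = self.translation
        return T


def register_point_sets(source: PointCloud | np.ndarray,
                        target: PointCloud | np.ndarray,
                        mode: str = "rigid", w: float = 0.1,
                        max_iter: int = 500, tol: float = 1e-8,
                        scale: bool = False) -> CPDResult:
    """Coherent point drift registration of source onto target.

    EM over a Gaussian mixture centred on the (transformed) source points
    with a uniform outlier component of weight ``w``.  ``mode`` is "rigid"
    (rotation + translation, optional isotropic ``scale``) or "affine".
    Per-source-point displacement = transformed position - source position.
    """
    X = np.atleast_2d(np.asarray(
        target.points if isinstance(target, PointCloud) else target, float))
    Y = np.atleast_2d(np.asarray(
        source.points if isinstance(source, PointCloud) else source, float))
    N, M, D = len(X), len(Y), X.shape[1]
    if N < 3 or M < 3:
        raise ValueError("registration needs at least 3 points per cloud")
    if mode not in ("rigid", "affine"):
        raise ValueError(f"unknown registration mode {mode!r}")
    if mode == "affine":
        if np.linalg.matrix_rank(Y - Y.mean(axis=0)) < 2:
            raise ValueError("degenerate (collinear) source cloud "
                             "for affine registration")

    B = np.eye(D)
    t = np.zeros(D)
    s = 1.0
    sigma2 = ((X[:, None, :] - Y[None, :, :]) ** 2).sum() / (D * M * N)
    if mode == "affine":
        # a rigid pass first: guards the affine M-step against the classic
        # shrinkage collapse under broad initial correspondences
        pre = register_point_sets(Y, X, mode="rigid", w=w,
                                  max_iter=max_iter, tol=tol)
        B, t, sigma2 = pre.rotation, pre.translation, max(pre.sigma2, 1e-8)
    TY = Y @ B.T * s + t
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: posterior correspondence probabilities
        d2 = ((X[:, None, :] - TY[None, :, :]) ** 2).sum(axis=2)
        num = np.exp(-d2 / (2.0 * sigma2))
        c = ((2.0 * np.pi * sigma2) ** (D / 2.0) * w * M) / ((1.0 - w) * N)
        den = num.sum(axis=1, keepdims=True) + c
        den[den == 0] = 1.0
        P = num / den                                  # (N, M)
        Np = P.sum()
        if Np < 1e-12:  # all mass on the outlier component
            break
        Pt1 = P.sum(axis=1)
        P1 = P.sum(axis=0)
        PX = P.T @ X                                   # (M, D)

        mu_x = X.T @ Pt1 / Np
        mu_y = Y.T @ P1 / Np
        Xh = X - mu_x
        Yh = Y - mu_y
        A = (P.T @ Xh).T @ Yh  # = Xh^T P^T... (D, D): sum_nm P_nm xh_n yh_m^T
        if mode == "rigid":
            U, _, Vt = np.linalg.svd(A)
            Cd = np.eye(D)
            Cd[-1, -1] = np.linalg.det(U @ Vt)
            R = U @ Cd @ Vt
            if scale:
                YPY = np.einsum("m,mi,mi->", P1, Yh, Yh)
                s = np.trace(A.T @ R) / YPY
            else:
                s = 1.0
            B = R
        else:
            YPY = (Yh * P1[:, None]).T @ Yh
            # pseudo-inverse: planar clouds (retractor blades) leave the
            # out-of-plane column unconstrained
            B = A @ np.linalg.pinv(YPY, rcond=1e-10)
            s = 1.0
        t = mu_x - s * B @ mu_y
        TY = s * Y @ B.T + t
        # M-step sigma^2
        scale2 = max(np.abs(X).max(), 1.0) ** 2
        xPx = np.einsum("n,ni,ni->", Pt1, Xh, Xh)
        sigma2_new = max((xPx - np.trace(A @ (s * B).T)) / (Np * D),
                         1e-10 * scale2)
        if abs(sigma2 - sigma2_new) < tol * sigma2:
            sigma2 = sigma2_new
            break
        sigma2 = sigma2_new
    return CPDResult(mode=mode, rotation=B, translation=t, scale=s,
                     transformed=TY, displacements=TY - Y,
                     sigma2=sigma2, n_iterations=it)


def map_displacements_to_nodes(cloud_points: np.ndarray,
                               displacements: np.ndarray,
                               node_ids, node_coords: np.ndarray,
                               face_sign: int, radius: float,
                               power: float = 1.0) -> list:
    """Inverse-distance-weighted transfer of cloud displacements to nodes.

    Every listed node must have at least one cloud point within ``radius``;
    a node coinciding with a cloud point takes that point's displacement
    exactly.  Returns crack-face BC entries ``(node_id, face_sign, vec)``.
    """
    pts = np.atleast_2d(np.asarray(cloud_points, dtype=float))
    disp = np.atleast_2d(np.asarray(displacements, dtype=float))
    if len(pts) == 0:
        raise ValueError("empty retractor cloud")
    if len(pts) != len(disp):
        raise ValueError("cloud points and displacements disagree in length")
    node_ids = np.asarray(node_ids, dtype=int)
    node_coords = np.atleast_2d(np.asarray(node_coords, dtype=float))
    tree = cKDTree(pts)
    neighbours = tree.query_ball_point(node_coords, r=radius)
    uncovered = [int(n) for n, nb in zip(node_ids, neighbours) if not nb]
    if uncovered:
        raise ValueError(
            f"no retractor cloud point within {radius:g} mm of node(s) "
            f"{uncovered[:10]}{'...' if len(uncovered) > 10 else ''}")
    entries = []
    for nid, xyz, nb in zip(node_ids, node_coords, neighbours):
        d = np.linalg.norm(pts[nb] - xyz, axis=1)
        exact = d < 1e-12
        if exact.any():
            vec = disp[nb][exact][0]
        else:
            wgt = 1.0 / d**power
            vec = (wgt[:, None] * disp[nb]).sum(axis=0) / wgt.sum()
        entries.append((int(nid), int(face_sign), vec))
    return entries
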
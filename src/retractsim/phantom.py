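"""Synthetic retraction phantom: every input the pipeline needs.

The phantom emulates the swine experiments at desk scale: an ellipsoidal
brain-like mask on a 1 mm grid, a vertical through-going crack along the
retraction path, two 14 mm wide retractor blade faces opened in a V (maximum
openings 5.4 mm to the right and 2.8 mm to the left, tapering to zero at the
blade tip), pre/post blade-surface point clouds, and 11-20 embedded bead
landmarks (1.5 mm diameter) grouped in three lobe-like clusters.  All
randomness (bead placement, optional cloud jitter) flows from the single
config seed, so identical configs reproduce bitwise-identical phantoms.

"Measured" post-retraction bead positions are produced by advecting the
pre-retraction beads with a fine-mesh reference solve, standing in for the
post-retraction CT of the animal experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import VolumeImage
from .mesh import CrackGeometry, EnrichedHexMesh
from .metrics import LandmarkSet
from .model import BCSet
from .tracking import PointCloud

__all__ = ["PhantomConfig", "Phantom", "generate_phantom", "phantom_bcset",
           "advect_landmarks"]


@dataclass(frozen=True)
class PhantomConfig:
    """Study-condition defaults for the synthetic retraction phantom."""

    semi_axes: tuple = (28.0, 22.0, 18.0)   # ellipsoid semi-axes, mm
    spacing: float = 1.0                    # voxel size, mm
    margin: float = 2.0                     # air margin around the mask, mm
    crack_point: tuple = (0.25, 0.0, 0.0)   # point on the crack plane
    crack_normal: tuple = (1.0, 0.0, 0.0)
    retractor_width: float = 14.0           # blade width, mm
    retractor_thickness: float = 2.9        # blade thickness, mm
    opening_right: float = 5.4              # max opening toward +normal, mm
    opening_left: float = 2.8               # max opening toward -normal, mm
    blade_depth: float = 15.0               # inserted blade length, mm
    n_beads: int = 14                       # 11..20 in the animal study
    bead_diameter: float = 1.5
    cloud_pitch: float = 1.0                # blade-face sampling pitch, mm
    surface_bump: float = 0.35              # blade curvature amplitude, mm
    noise_mm: float = 0.0                   # isotropic jitter on post clouds
    stem_height: float = 6.0                # zero-displacement band, mm
    seed: int = 0

    def __post_init__(self):
        if self.opening_right < 0 or self.opening_left < 0:
            raise ValueError("openings must be >= 0")
        if self.n_beads < 1:
            raise ValueError("need at least one bead")


@dataclass
class Phantom:
    """Generated phantom bundle."""

    config: PhantomConfig
    mask: VolumeImage
    intensity: VolumeImage
    crack: CrackGeometry
    clouds: dict           # {"right_pre", "right_post", "left_pre", "left_post"}
    landmarks: LandmarkSet

    def face_displacement(self, points: np.ndarray, side: int) -> np.ndarray:
        """Analytic prescribed blade-face displacement at world points, mm.

        ``side`` +1 is the face pushed toward +normal (opening_right).
        """
        cfg = self.config
        points = np.atleast_2d(np.asarray(points, dtype=float))
        z_top = cfg.semi_axes[2] - 0.5
        taper = np.clip(
            (points[:, 2] - (z_top - cfg.blade_depth)) / cfg.blade_depth,
            0.0, 1.0)
        amp = cfg.opening_right if side > 0 else -cfg.opening_left
        u = np.zeros_like(points)
        u[:, 0] = amp * taper
        return u


def _ellipsoid_mask(cfg: PhantomConfig):
    a = np.asarray(cfg.semi_axes, dtype=float)
    half = a + cfg.margin
    n = np.ceil(2 * half / cfg.spacing).astype(int)
    affine = np.eye(4)
    affine[:3, :3] *= cfg.spacing
    affine[:3, 3] = -half + cfg.spacing / 2.0
    idx = np.stack(np.meshgrid(*[np.arange(k) for k in n], indexing="ij"),
                   axis=-1).astype(float)
    world = idx * cfg.spacing + affine[:3, 3]
    r2 = np.sum((world / a) ** 2, axis=-1)
    return (r2 <= 1.0), world, affine, r2


def _blade_clouds(cfg: PhantomConfig, phantom_face_disp, rng):
    a = np.asarray(cfg.semi_axes, dtype=float)
    x0 = cfg.crack_point[0]
    z_top = a[2] - 0.5
    ys = np.arange(-cfg.retractor_width / 2, cfg.retractor_width / 2 + 1e-9,
                   cfg.cloud_pitch)
    zs = np.arange(z_top - cfg.blade_depth, z_top + 1e-9, cfg.cloud_pitch)
    yy, zz = np.meshgrid(ys, zs, indexing="ij")
    pts = np.column_stack([np.full(yy.size, x0), yy.ravel(), zz.ravel()])
    inside = np.sum((pts / a) ** 2, axis=1) <= 0.96
    pts = pts[inside]
    clouds = {}
    # mild curvature of the scanned blade surface: breaks the sliding
    # (aperture) ambiguity of registering one flat patch onto another
    bump = cfg.surface_bump * np.sin(2 * np.pi * pts[:, 1] / 7.0) \
        * np.sin(2 * np.pi * pts[:, 2] / 5.0)
    for name, sgn in (("right", +1), ("left", -1)):
        pre = pts.copy()
        pre[:, 0] += sgn * (0.05 + np.abs(bump))  # off-plane, blade's side
        normals = np.tile([float(sgn), 0.0, 0.0], (len(pre), 1))
        u = phantom_face_disp(pre, sgn)
        post = pre + u
        if cfg.noise_mm > 0:
            post = post + rng.normal(0.0, cfg.noise_mm, post.shape)
        clouds[f"{name}_pre"] = PointCloud(pre, normals)
        clouds[f"{name}_post"] = PointCloud(post, normals)
    return clouds


def _place_beads(cfg: PhantomConfig, rng) -> np.ndarray:
    """Bead centres in three lobe-like clusters, all inside the ellipsoid."""
    a = np.asarray(cfg.semi_axes, dtype=float)
    centers = np.array([
        [-0.35 * a[0], 0.25 * a[1], 0.35 * a[2]],   # frontal
        [0.35 * a[0], -0.2 * a[1], 0.3 * a[2]],     # parietal
        [0.1 * a[0], 0.3 * a[1], -0.25 * a[2]],     # occipital
    ])
    counts = np.full(3, cfg.n_beads // 3)
    counts[:cfg.n_beads % 3] += 1
    beads = []
    for c, m in zip(centers, counts):
        placed = 0
        for _ in range(10000):
            if placed == m:
                break
            p = c + rng.uniform(-7.0, 7.0, 3)
            ok = (np.sum((p / a) ** 2) <= 0.8
                  and abs(p[0] - cfg.crack_point[0]) > 1.5)
            if ok:
                beads.append(p)
                placed += 1
        if placed < m:
            raise ValueError("could not place beads inside the mask")
    return np.array(beads)


def generate_phantom(config: PhantomConfig | None = None) -> Phantom:
    """Deterministically generate the full synthetic input bundle."""
    cfg = config or PhantomConfig()
    rng = np.random.default_rng(cfg.seed)
    mask_arr, world, affine, r2 = _ellipsoid_mask(cfg)
    crack = CrackGeometry(point=np.asarray(cfg.crack_point),
                          normal=np.asarray(cfg.crack_normal))

    # CT-like intensity: smooth radial gradient + bright bead spheres
    intensity = np.where(mask_arr, 60.0 + 40.0 * (1.0 - np.clip(r2, 0, 1)), 0.0)
    beads = _place_beads(cfg, rng)
    rb = cfg.bead_diameter / 2.0
    for b in beads:
        d2 = np.sum((world - b) ** 2, axis=-1)
        intensity[d2 <= rb**2] = 1000.0

    phantom = Phantom(
        config=cfg,
        mask=VolumeImage(mask_arr.astype(np.uint8), affine),
        intensity=VolumeImage(intensity, affine),
        crack=crack,
        clouds={},
        landmarks=LandmarkSet(ids=np.arange(1, len(beads) + 1), pre=beads),
    )
    phantom.clouds = _blade_clouds(cfg, phantom.face_displacement, rng)
    return phantom


def phantom_bcset(enr: EnrichedHexMesh, phantom: Phantom) -> BCSet:
    """Analytic boundary conditions for a phantom on a given mesh.

    Zero displacement in the brain-stem band at the bottom of the mask, and
    prescribed crack-face displacements on the Heaviside-enriched nodes in
    the blade footprint (both faces, the V-opening profile).
    """
    cfg = phantom.config
    mesh = enr.mesh
    z = mesh.nodes[:, 2]
    fixed = np.flatnonzero(z <= z.min() + cfg.stem_height)
    fixed_set = set(int(i) for i in fixed)
    entries = []
    half_w = cfg.retractor_width / 2.0 + 0.5 * float(np.max(mesh.edge))
    z_top = cfg.semi_axes[2] - 0.5
    for nid in enr.heaviside_nodes:
        nid = int(nid)
        if nid in fixed_set:
            continue
        xyz = mesh.nodes[nid]
        if abs(xyz[1]) > half_w or xyz[2] < z_top - cfg.blade_depth:
            continue
        u_plus = phantom.face_displacement(xyz, +1)[0]
        u_minus = phantom.face_displacement(xyz, -1)[0]
        entries.append((nid, +1, u_plus))
        entries.append((nid, -1, u_minus))
    return BCSet(fixed_nodes=fixed, crack_face_bcs=entries)


def advect_landmarks(landmarks: LandmarkSet, field, into: str) -> LandmarkSet:
    """Carry pre-retraction beads through a displacement field.

    ``into`` selects the slot the advected coordinates fill: "measured"
    (ground truth from a fine reference solve) or "predicted" (the model
    forecast under evaluation).
    """
    u = field.evaluate(landmarks.pre)
    moved = landmarks.pre + u
    if into == "measured":
        return replace_coords(landmarks, measured=moved)
    if into == "predicted":
        return replace_coords(landmarks, predicted=moved)
    raise ValueError("into must be 'measured' or 'predicted'")


def replace_coords(lm: LandmarkSet, predicted=None, measured=None) -> LandmarkSet:
    return LandmarkSet(
        ids=lm.ids.copy(), pre=lm.pre.copy(),
        predicted=predicted if predicted is not None else
        (None if lm.predicted is None else lm.predicted.copy()),
        measured=measured if measured is not None else
        (None if lm.measured is None else lm.measured.copy()))
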
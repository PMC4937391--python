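"""End-to-end retraction pipeline: mesh -> BCs -> solve -> warp -> evaluate.

Each stage is an ordinary function over the library objects; the CLI wraps
these.  In phantom mode the pipeline also runs a fine-mesh reference solve
whose advected beads and warped mask act as the "measured" post-retraction
ground truth, mirroring how the animal study scores predictions against
post-retraction CT.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import io as rio
from .imaging import dense_displacement_field, warp_image_backward
from .mesh import build_hex_mesh, classify_and_enrich
from .metrics import MetricsReport, dice_coefficient, round_half_up
from .model import BCSet, RetractionModel
from .phantom import (PhantomConfig, advect_landmarks, generate_phantom,
                      phantom_bcset, replace_coords)
from .tracking import map_displacements_to_nodes, register_point_sets

log = logging.getLogger("retractsim")

__all__ = ["build_enriched_mesh", "bcs_from_clouds", "solve_stage",
           "warp_stage", "evaluate_stage", "run_pipeline"]


def build_enriched_mesh(mask_img, crack, max_edge: float = 5.0,
                        min_voxels: int = 1):
    """Mesh the mask and classify/enrich against the crack."""
    t0 = time.perf_counter()
    mesh = build_hex_mesh(np.asarray(mask_img.data) > 0, mask_img.spacing,
                          max_edge, origin=mask_img.affine[:3, 3]
                          - 0.5 * mask_img.spacing, min_voxels=min_voxels)
    enr = classify_and_enrich(mesh, crack)
    log.info("mesh: %d nodes, %d elements (edge %.2f mm), |J|=%d, |M|=%d, "
             "%d DOFs [%.2f s]", mesh.n_nodes, mesh.n_elements,
             float(np.max(mesh.edge)), len(enr.heaviside_nodes),
             len(enr.tip_nodes), enr.n_dofs, time.perf_counter() - t0)
    return enr


def bcs_from_clouds(enr, clouds: dict, fixed_nodes, mode: str = "affine",
                    radius: float | None = None) -> BCSet:
    """Crack-face BCs from pre/post retractor clouds via CPD registration.

    The crack-related node set is the Heaviside-enriched nodes of elements
    containing at least one pre-retraction cloud point; each face's cloud
    displacements are transferred by inverse-distance weighting.
    """
    mesh = enr.mesh
    if radius is None:
        radius = float(np.max(mesh.edge))
    fixed_set = set(int(i) for i in np.asarray(fixed_nodes, dtype=int))
    entries = []
    for name, sign in (("right", +1), ("left", -1)):
        pre = clouds[f"{name}_pre"]
        post = clouds[f"{name}_post"]
        reg = register_point_sets(pre, post, mode=mode)
        eid, _ = mesh.locate(pre.points)
        touched = np.unique(eid[eid >= 0])
        nodes = np.intersect1d(np.unique(mesh.elements[touched]),
                               enr.heaviside_nodes)
        nodes = np.array([n for n in nodes if int(n) not in fixed_set], int)
        # weight by in-plane distance: nodes sit off the crack surface, so
        # they are projected onto it before the inverse-distance transfer
        coords = mesh.nodes[nodes]
        if enr.crack is not None:
            phi = enr.crack.phi(coords)
            coords = coords - phi[:, None] * enr.crack.normal
        entries += map_displacements_to_nodes(
            pre.points, reg.displacements, nodes, coords, sign, radius,
            power=2.0)
        log.info("bcs[%s]: CPD %s, sigma2=%.2e, %d iterations, %d nodes",
                 name, mode, reg.sigma2, reg.n_iterations, len(nodes))
    return BCSet(fixed_nodes=np.asarray(fixed_nodes, dtype=int),
                 crack_face_bcs=entries)


def solve_stage(enr, material, bcs, schedule, **newton_kw):
    model = RetractionModel(enr, material, bcs, schedule, **newton_kw)
    results = model.fit()
    log.info("solve: %d increments, %d Newton iterations, max |u| %.2f mm "
             "[%.1f s]", len(results.convergence_log),
             sum(e["iterations"] for e in results.convergence_log),
             results.max_displacement(), results.solve_time)
    return results


def warp_stage(field, image, crack, background=None):
    t0 = time.perf_counter()
    dense = dense_displacement_field(field, image)
    warped = warp_image_backward(image, dense, crack=crack,
                                 background=background)
    log.info("warp: grid %s [%.1f s]", image.shape, time.perf_counter() - t0)
    return dense, warped


def evaluate_stage(landmarks, dice_pct=None):
    report = MetricsReport(landmarks, dice_pct=dice_pct)
    s = report.rounded_summary()
    log.info("evaluate: accuracy %.1f%%, forecast error %.1f mm",
             s["prediction_accuracy_pct"]["mean"],
             s["forecast_error_mm"]["mean"])
    return report


def run_pipeline(config: dict | None = None, out_dir="retractsim_out",
                 seed: int | None = None) -> dict:
    """Full phantom-driven pipeline; writes the artifact bundle to out_dir.

    Returns a dict with the report, results objects and file paths.
    Stages: phantom generation, meshing/enrichment, CPD boundary conditions,
    coarse solve, fine reference solve, image warping, metric evaluation.
    """
    config = config or {}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ph_block = dict(config.get("phantom", {}))
    if seed is not None:
        ph_block["seed"] = seed
    if "semi_axes" in ph_block:
        ph_block["semi_axes"] = tuple(ph_block["semi_axes"])
    cfg = PhantomConfig(**ph_block)
    mesh_block = config.get("mesh", {})
    max_edge = mesh_block.get("max_edge_mm", 5.0)
    truth_edge = mesh_block.get("truth_edge_mm", 2.5)
    material = rio.material_from_config(config.get("material"))
    schedule = rio.schedule_from_config(config.get("solver"))

    t_start = time.perf_counter()
    phantom = generate_phantom(cfg)
    phantom.mask.save(out / "mask.nii.gz")
    phantom.intensity.save(out / "intensity.nii.gz")
    rio.save_crack(out / "crack.json", phantom.crack)
    for name, cloud in phantom.clouds.items():
        rio.save_point_cloud(out / f"cloud_{name}.xyz", cloud)
    phantom.landmarks.to_csv(out / "landmarks_pre.csv")

    enr = build_enriched_mesh(phantom.mask, phantom.crack, max_edge)
    rio.write_enriched_vtu(out / "mesh.vtu", enr)

    z = enr.mesh.nodes[:, 2]
    fixed = np.flatnonzero(z <= z.min() + cfg.stem_height)
    bcs = bcs_from_clouds(enr, phantom.clouds, fixed)
    rio.bcset_to_csv(out / "bcs.csv", bcs)

    results = solve_stage(enr, material, bcs, schedule,
                          **config.get("newton", {}))
    (out / "solution_summary.txt").write_text(results.summary() + "\n")
    (out / "dofs.json").write_text(json.dumps(
        {"dofs": results.dofs.tolist()}))
    rio.write_enriched_vtu(out / "deformed.vtu", enr, results.field)

    # fine-mesh reference ("measured" ground truth)
    enr_f = build_enriched_mesh(phantom.mask, phantom.crack, truth_edge)
    zf = enr_f.mesh.nodes[:, 2]
    fixed_f = np.flatnonzero(zf <= zf.min() + cfg.stem_height)
    bcs_f = bcs_from_clouds(enr_f, phantom.clouds, fixed_f)
    results_f = solve_stage(enr_f, material, bcs_f, schedule,
                            **config.get("newton", {}))

    dense, predicted = warp_stage(results.field, phantom.intensity,
                                  phantom.crack)
    predicted.save(out / "predicted.nii.gz")
    _, mask_pred = warp_stage(results.field, phantom.mask, phantom.crack,
                              background=0)
    _, mask_truth = warp_stage(results_f.field, phantom.mask, phantom.crack,
                               background=0)
    dice = dice_coefficient(np.asarray(mask_pred.data) > 0.5,
                            np.asarray(mask_truth.data) > 0.5)

    lm = advect_landmarks(phantom.landmarks, results_f.field, "measured")
    lm = replace_coords(lm, predicted=phantom.landmarks.pre
                        + results.field.evaluate(phantom.landmarks.pre))
    report = evaluate_stage(lm, dice_pct=dice)
    lm.to_csv(out / "landmarks_full.csv")
    report.per_landmark().to_csv(out / "metrics_per_landmark.csv", index=False)
    (out / "metrics.json").write_text(json.dumps(
        {"summary": report.summary(),
         "rounded": report.rounded_summary()}, indent=1))
    wall = time.perf_counter() - t_start
    log.info("pipeline complete in %.1f s; Dice %.1f%%", wall,
             round_half_up(dice))
    return {"phantom": phantom, "enr": enr, "bcs": bcs, "results": results,
            "results_fine": results_f, "report": report, "dice_pct": dice,
            "out_dir": out, "wall_time_s": wall}
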
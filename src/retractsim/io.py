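"""File formats: VTU meshes, point clouds, crack geometry, BC tables, config.

Volumes go through :class:`retractsim.imaging.VolumeImage` (NIfTI/MetaImage);
meshes and fields are written as ASCII VTK XML unstructured grids (.vtu);
point clouds as whitespace XYZ[+normals] or PLY (via trimesh); boundary
conditions and landmarks as CSV; configuration as YAML or JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh import CrackGeometry, EnrichedHexMesh
from .model import BCSet
from .tracking import PointCloud

__all__ = ["write_vtu", "load_point_cloud", "save_point_cloud",
           "load_crack", "save_crack", "bcset_to_csv", "bcset_from_csv",
           "load_config"]


def write_vtu(path, mesh, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Minimal ASCII VTK XML writer for hexahedral unstructured grids."""
    nodes = mesh.nodes
    elems = mesh.elements
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{len(nodes)}" NumberOfCells="{len(elems)}">',
    ]

    def data_array(name, arr):
        arr = np.asarray(arr)
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        body = "\n".join(" ".join(f"{v:.9g}" for v in np.atleast_1d(row))
                         for row in arr)
        return (f'<DataArray type="Float64" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">\n{body}\n'
                "</DataArray>")

    if point_data:
        lines.append("<PointData>")
        for name, arr in point_data.items():
            lines.append(data_array(name, arr))
        lines.append("</PointData>")
    if cell_data:
        lines.append("<CellData>")
        for name, arr in cell_data.items():
            lines.append(data_array(name, arr))
        lines.append("</CellData>")
    lines.append("<Points>")
    lines.append(data_array("Points", nodes))
    lines.append("</Points>")
    lines.append("<Cells>")
    conn = "\n".join(" ".join(str(i) for i in row) for row in elems)
    lines.append('<DataArray type="Int64" Name="connectivity" format="ascii">\n'
                 f"{conn}\n</DataArray>")
    offs = " ".join(str(8 * (i + 1)) for i in range(len(elems)))
    lines.append(f'<DataArray type="Int64" Name="offsets" format="ascii">\n'
                 f"{offs}\n</DataArray>")
    types = " ".join("12" for _ in range(len(elems)))  # VTK_HEXAHEDRON
    lines.append(f'<DataArray type="UInt8" Name="types" format="ascii">\n'
                 f"{types}\n</DataArray>")
    lines.append("</Cells>")
    lines.extend(["</Piece>", "</UnstructuredGrid>", "</VTKFile>"])
    Path(path).write_text("\n".join(lines))


def write_enriched_vtu(path, enr: EnrichedHexMesh, field=None) -> None:
    """Mesh with element class, enrichment membership and (optionally) u."""
    in_j = np.zeros(enr.mesh.n_nodes)
    in_j[enr.heaviside_nodes] = 1
    in_m = np.zeros(enr.mesh.n_nodes)
    in_m[enr.tip_nodes] = 1
    point_data = {"heaviside_enriched": in_j, "tip_enriched": in_m,
                  "phi": np.where(np.isfinite(enr.node_phi), enr.node_phi, 0)}
    if field is not None:
        point_data["displacement"] = field.node_displacements()
    write_vtu(path, enr.mesh, point_data=point_data,
              cell_data={"element_class": enr.elem_class.astype(float)})


def load_point_cloud(path) -> PointCloud:
    path = str(path)
    if path.endswith(".ply"):
        import trimesh
        obj = trimesh.load(path, process=False)
        pts = np.asarray(obj.vertices, dtype=float)
        normals = None
        try:
            raw = obj.metadata["_ply_raw"]["vertex"]["data"]
            normals = np.column_stack([raw["nx"], raw["ny"], raw["nz"]])
        except (KeyError, TypeError, ValueError):
            pass
        return PointCloud(pts, normals)
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] >= 6:
        return PointCloud(arr[:, :3], arr[:, 3:6])
    return PointCloud(arr[:, :3])


def save_point_cloud(path, cloud: PointCloud) -> None:
    path = str(path)
    if path.endswith(".ply"):
        import trimesh
        trimesh.PointCloud(cloud.points).export(path)
        return
    if cloud.normals is not None:
        np.savetxt(path, np.hstack([cloud.points, cloud.normals]), fmt="%.9g")
    else:
        np.savetxt(path, cloud.points, fmt="%.9g")


def save_crack(path, crack: CrackGeometry) -> None:
    obj = {"point": list(map(float, crack.point)),
           "normal": list(map(float, crack.normal))}
    if crack.front_dir is not None:
        obj["front_point"] = list(map(float, crack.front_point))
        obj["front_dir"] = list(map(float, crack.front_dir))
    Path(path).write_text(json.dumps(obj, indent=1))


def load_crack(path) -> CrackGeometry:
    obj = json.loads(Path(path).read_text())
    return CrackGeometry(
        point=np.asarray(obj["point"], dtype=float),
        normal=np.asarray(obj["normal"], dtype=float),
        front_point=(np.asarray(obj["front_point"], dtype=float)
                     if "front_point" in obj else None),
        front_dir=(np.asarray(obj["front_dir"], dtype=float)
                   if "front_dir" in obj else None))


def bcset_to_csv(path, bcs: BCSet) -> None:
    """BC table: face 0 rows are fixed nodes, +/-1 rows crack faces."""
    rows = [{"node_id": int(n), "face": 0, "dx": 0.0, "dy": 0.0, "dz": 0.0}
            for n in bcs.fixed_nodes]
    rows += [{"node_id": int(n), "face": int(s),
              "dx": float(v[0]), "dy": float(v[1]), "dz": float(v[2])}
             for n, s, v in bcs.crack_face_bcs]
    pd.DataFrame(rows).to_csv(path, index=False)


def bcset_from_csv(path) -> BCSet:
    df = pd.read_csv(path)
    fixed = df.loc[df["face"] == 0, "node_id"].to_numpy(dtype=int)
    entries = [(int(r.node_id), int(r.face),
                np.array([r.dx, r.dy, r.dz], dtype=float))
               for r in df[df["face"] != 0].itertuples()]
    return BCSet(fixed_nodes=fixed, crack_face_bcs=entries)


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml
        return yaml.safe_load(text) or {}
    return json.loads(text)


def material_from_config(block: dict | None):
    """Material from the ``material:`` config block (Ogden defaults)."""
    from .constitutive import LinearElasticMaterial, OgdenPronyMaterial
    block = block or {}
    kind = block.get("model", "ogden")
    if kind == "linear":
        return LinearElasticMaterial(mu=block.get("mu0_pa", 842.0),
                                     poisson=block.get("poisson", 0.49))
    prony = tuple((p["tau_s"], p["g"]) for p in block.get(
        "prony", [{"tau_s": 0.5, "g": 0.450}, {"tau_s": 50.0, "g": 0.365}]))
    return OgdenPronyMaterial(mu0=block.get("mu0_pa", 842.0),
                              alpha=block.get("alpha", -4.7),
                              prony=prony,
                              poisson=block.get("poisson", 0.49))


def schedule_from_config(block: dict | None):
    from .model import Schedule
    block = block or {}
    return Schedule(T=block.get("T_s", 30.0),
                    n_increments=block.get("n_increments", 10))
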
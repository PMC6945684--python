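"""Plain-text and binary persistence for meshes, matrices and graphs.

Formats
-------
* Mesh: two TSV tables, ``<prefix>.nodes.tsv`` (id, x, y, z, segment) and
  ``<prefix>.edges.tsv`` (i, j); the surface Laplacian is rebuilt from the
  edge table on read.  An optional legacy-VTK ASCII point-cloud export is
  provided for visualization.
* Matrices (H, U, Phi): TSV with a header row of frame/column names, or a
  binary container — a NumPy ``.npz`` archive holding the array under the
  key ``"matrix"`` plus ``"dt"`` metadata when present.  The binary
  round-trip is bit-exact (raw float64 storage).
* Trajectory graph: edge-list TSV (i, j, distance, weight).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .graph import TrajectoryGraph, _assemble_grad
from .phantom import HeartMesh, laplacian_from_edges

__all__ = [
    "write_mesh",
    "read_mesh",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_matrix_npz",
    "read_matrix_npz",
    "write_graph_tsv",
    "read_graph_tsv",
    "write_vtk_pointcloud",
]

PathLike = Union[str, Path]


def write_mesh(mesh: HeartMesh, prefix: PathLike) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    nodes = pd.DataFrame(
        {
            "id": np.arange(mesh.n_nodes),
            "x": mesh.node_coords[:, 0],
            "y": mesh.node_coords[:, 1],
            "z": mesh.node_coords[:, 2],
            "segment": mesh.segment_labels,
        }
    )
    nodes.to_csv(f"{prefix}.nodes.tsv", sep="\t", index=False)
    pd.DataFrame(mesh.spatial_edges, columns=["i", "j"]).to_csv(
        f"{prefix}.edges.tsv", sep="\t", index=False
    )


def read_mesh(prefix: PathLike) -> HeartMesh:
    nodes = pd.read_csv(f"{prefix}.nodes.tsv", sep="\t")
    edges = pd.read_csv(f"{prefix}.edges.tsv", sep="\t")[["i", "j"]].to_numpy(
        dtype=np.intp
    )
    coords = nodes[["x", "y", "z"]].to_numpy(dtype=float)
    return HeartMesh(
        node_coords=coords,
        spatial_edges=edges,
        surface_laplacian=laplacian_from_edges(edges, coords.shape[0]),
        segment_labels=nodes["segment"].to_numpy(dtype=int),
    )


def write_matrix_tsv(path: PathLike, M: np.ndarray, prefix: str = "f") -> None:
    M = np.atleast_2d(np.asarray(M))
    cols = [f"{prefix}{s}" for s in range(M.shape[1])]
    pd.DataFrame(M, columns=cols).to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path: PathLike) -> np.ndarray:
    return pd.read_csv(path, sep="\t").to_numpy(dtype=float)


def write_matrix_npz(path: PathLike, M: np.ndarray, dt: Optional[float] = None) -> None:
    """Binary matrix container (bit-exact round trip)."""
    extra = {} if dt is None else {"dt": np.float64(dt)}
    np.savez(path, matrix=np.asarray(M), **extra)


def read_matrix_npz(path: PathLike):
    with np.load(path) as data:
        M = data["matrix"]
        dt = float(data["dt"]) if "dt" in data else None
    return M, dt


def write_graph_tsv(graph: TrajectoryGraph, path: PathLike) -> None:
    e = graph.n_edges
    df = pd.DataFrame(
        {
            "i": graph.edges[:, 0],
            "j": graph.edges[:, 1],
            "distance": graph.distances if graph.distances is not None else np.nan,
            "weight": graph.weights if graph.weights is not None else np.nan,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_graph_tsv(path: PathLike, n_nodes: int, k: int = 0) -> TrajectoryGraph:
    df = pd.read_csv(path, sep="\t")
    edges = df[["i", "j"]].to_numpy(dtype=np.intp)
    weights = df["weight"].to_numpy(dtype=float)
    distances = df["distance"].to_numpy(dtype=float)
    g = TrajectoryGraph(
        k=k,
        edges=edges,
        n_nodes=n_nodes,
        distances=None if np.isnan(distances).all() else distances,
        weights=None if np.isnan(weights).all() else weights,
    )
    if g.weights is not None:
        g.sigma_bandwidth = (
            float(distances.mean()) if g.distances is not None else None
        )
        g.grad_operator = _assemble_grad(edges, g.weights, n_nodes)
    return g


def write_vtk_pointcloud(mesh: HeartMesh, path: PathLike) -> None:
    """Minimal legacy-VTK ASCII POLYDATA export of the node cloud with the
    segment label as a point scalar (for ParaView et al.)."""
    n = mesh.n_nodes
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("ecgitv heart mesh point cloud\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {n} float\n")
        for x, y, z in mesh.node_coords:
            fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")
        fh.write(f"VERTICES {n} {2 * n}\n")
        for i in range(n):
            fh.write(f"1 {i}\n")
        fh.write(f"POINT_DATA {n}\nSCALARS segment int 1\nLOOKUP_TABLE default\n")
        for s in mesh.segment_labels:
            fh.write(f"{int(s)}\n")
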
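"""Synthetic heart–torso phantom for the ECGI inverse problem.

This module builds everything needed to pose the inverse problem on a desk:
an ellipsoidal-shell heart mesh, a homogeneous-medium lead field (the
transfer matrix H mapping transmembrane potential to body-surface leads),
ground-truth transmembrane-potential (TMP) sequences for an infarct scar and
for ectopic pacing, the forward projection Phi = H U, and additive Gaussian
noise at a prescribed dB SNR.

The lead field deliberately uses an infinite homogeneous-medium monopole
kernel instead of a patient-specific BEM/FEM model: it preserves the two
properties the inverse methods are sensitive to — spatial smoothness of the
columns of H and severe ill-conditioning — without any meshing dependency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist
from scipy.special import expit

__all__ = [
    "HeartMesh",
    "LeadField",
    "TMPSequence",
    "BSPSequence",
    "InvalidGeometryError",
    "build_heart_mesh",
    "default_lead_positions",
    "monopole_kernel",
    "build_lead_field",
    "simulate_infarct",
    "simulate_pacing",
    "forward_project",
    "add_noise",
]

#: resting and plateau transmembrane potentials of the phantom, mV
V_REST = -84.0
V_PLATEAU = 27.0

#: ellipsoid semi-axis ratios (x, y, z) applied to the shell radii
_AXIS_RATIOS = np.array([1.0, 0.85, 1.25])


class InvalidGeometryError(ValueError):
    """Raised for degenerate phantom geometry (e.g. inner radius >= outer)."""


@dataclass
class HeartMesh:
    """Point-cloud heart model.

    Attributes
    ----------
    node_coords : (n, 3) float array, mm
    spatial_edges : (E, 2) int array, each row (i, j) with i < j, unique
    surface_laplacian : (n, n) sparse combinatorial graph Laplacian L = D - A
    segment_labels : (n,) int array, values in 1..8 (coordinate octants)
    """

    node_coords: np.ndarray
    spatial_edges: np.ndarray
    surface_laplacian: sp.spmatrix
    segment_labels: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    def segment_centroid(self, segment: int) -> np.ndarray:
        members = self.segment_labels == segment
        if not members.any():
            raise ValueError(f"segment {segment} has no nodes")
        return self.node_coords[members].mean(axis=0)


@dataclass
class LeadField:
    """Transfer matrix H (m leads x n heart nodes) plus lead positions."""

    H: np.ndarray
    lead_coords: np.ndarray

    @property
    def m(self) -> int:
        return self.H.shape[0]

    @property
    def n(self) -> int:
        return self.H.shape[1]


@dataclass
class TMPSequence:
    """Transmembrane potential sequence U (n nodes x t frames), mV."""

    U: np.ndarray
    dt: float = 1.0
    truth_meta: Optional[dict] = None

    @property
    def n_frames(self) -> int:
        return self.U.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.U.shape[1]) * self.dt


@dataclass
class BSPSequence:
    """Body-surface potential sequence Phi (m leads x t frames), mV."""

    Phi: np.ndarray
    dt: float = 1.0
    snr_db: object = "clean"

    @property
    def n_frames(self) -> int:
        return self.Phi.shape[1]


# ---------------------------------------------------------------------------
# geometry


def _fibonacci_sphere(count: int) -> np.ndarray:
    """Quasi-uniform unit-sphere point set (Fibonacci lattice)."""
    i = np.arange(count, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - 2.0 * (i + 0.5) / count
    theta = 2.0 * np.pi * i / golden
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _rotation_about_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _symmetric_knn_edges(coords: np.ndarray, k: int) -> np.ndarray:
    """Union-symmetrised k-nearest-neighbour edge list, rows (i, j), i < j.

    Ties in distance are broken toward the lower node index (stable sort),
    so the edge set is reproducible.
    """
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < number of points n={n}")
    d2 = cdist(coords, coords, "sqeuclidean")
    np.fill_diagonal(d2, np.inf)
    order = np.argsort(d2, axis=1, kind="stable")[:, :k]
    pairs = set()
    for i in range(n):
        for j in order[i]:
            pairs.add((min(i, int(j)), max(i, int(j))))
    edges = np.array(sorted(pairs), dtype=np.intp)
    return edges


def laplacian_from_edges(edges: np.ndarray, n: int) -> sp.csr_matrix:
    """Combinatorial graph Laplacian L = D - A; every row sums to zero."""
    i, j = edges[:, 0], edges[:, 1]
    rows = np.concatenate([i, j])
    cols = np.concatenate([j, i])
    data = -np.ones(rows.size)
    adj = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    deg = -np.asarray(adj.sum(axis=1)).ravel()
    return (sp.diags(deg) + adj).tocsr()


def build_heart_mesh(
    n_nodes: int = 800,
    shell_radii: tuple[float, float] = (25.0, 50.0),
    seed: int = 0,
    k_spatial: int = 6,
) -> HeartMesh:
    """Build a quasi-uniform point cloud on an ellipsoidal myocardial shell.

    Nodes are laid out on concentric ellipsoidal layers between the inner and
    outer shell radii; each layer is a Fibonacci lattice (point count
    proportional to layer surface area) with a small seeded jitter and a
    random azimuthal twist so layers do not align radially.  Spatial edges
    come from symmetric k-nearest neighbours (``k_spatial``), the surface
    Laplacian is the combinatorial graph Laplacian of that adjacency, and the
    eight anatomical segments are the coordinate octants around the centroid.

    Parameters
    ----------
    n_nodes : total node count (>= 20)
    shell_radii : (inner, outer) mean radii in mm; semi-axes are these radii
        scaled by the fixed ellipsoid ratios (1.0, 0.85, 1.25)
    seed : RNG seed for jitter and layer twists
    k_spatial : neighbour count for the spatial adjacency
    """
    r_in, r_out = float(shell_radii[0]), float(shell_radii[1])
    if not (0.0 < r_in < r_out):
        raise InvalidGeometryError(
            f"shell radii must satisfy 0 < inner < outer, got {shell_radii}"
        )
    if n_nodes < 20:
        raise ValueError(f"n_nodes must be >= 20, got {n_nodes}")

    rng = np.random.default_rng(seed)
    n_layers = max(2, int(round(0.7 * n_nodes ** (1.0 / 3.0))))
    radii = np.linspace(r_in, r_out, n_layers)
    # points per layer proportional to surface area (~ r^2), largest-remainder
    share = radii**2 / np.sum(radii**2)
    counts = np.floor(share * n_nodes).astype(int)
    counts[np.argsort(-(share * n_nodes - counts))[: n_nodes - counts.sum()]] += 1
    assert counts.sum() == n_nodes and (counts > 0).all()

    spacing = np.sqrt(4.0 * np.pi * r_out**2 / counts[-1])  # coarsest layer
    layers = []
    for r, c in zip(radii, counts):
        pts = _fibonacci_sphere(int(c)) @ _rotation_about_z(rng.uniform(0, 2 * np.pi)).T
        pts = pts * (r * _AXIS_RATIOS)
        pts = pts + rng.normal(scale=0.03 * spacing, size=pts.shape)
        layers.append(pts)
    coords = np.vstack(layers)

    edges = _symmetric_knn_edges(coords, k_spatial)
    lap = laplacian_from_edges(edges, n_nodes)

    rel = coords - coords.mean(axis=0)
    labels = (
        1
        + (rel[:, 0] > 0).astype(int)
        + 2 * (rel[:, 1] > 0).astype(int)
        + 4 * (rel[:, 2] > 0).astype(int)
    )
    return HeartMesh(coords, edges, lap, labels)


# ---------------------------------------------------------------------------
# lead field


def default_lead_positions(m: int = 64, radius: float = 150.0) -> np.ndarray:
    """m electrode positions on a sphere of the given radius (mm), centred on
    the heart — a stand-in for a 64-lead body-surface mapping vest."""
    return _fibonacci_sphere(m) * radius


def monopole_kernel(distances_mm: np.ndarray, conductivity: float) -> np.ndarray:
    """Potential at distance d from a unit monopole source in an infinite
    homogeneous medium: 1 / (4 pi sigma d)."""
    distances_mm = np.asarray(distances_mm, dtype=float)
    if np.any(distances_mm <= 0):
        raise ZeroDivisionError("lead coincident with a source node")
    return 1.0 / (4.0 * np.pi * conductivity * distances_mm)


def build_lead_field(
    mesh: HeartMesh,
    lead_coords: Optional[np.ndarray] = None,
    conductivity: float = 0.2,
) -> LeadField:
    """Assemble the transfer matrix H from a homogeneous-medium monopole model.

    ``H_raw[i, j] = 1 / (4 pi sigma d(lead_i, node_j))``; each column is then
    mean-subtracted across leads (the analogue of a Wilson central-terminal
    reference), so columns sum to zero.  Every lead must lie strictly outside
    the heart shell.
    """
    if lead_coords is None:
        lead_coords = default_lead_positions()
    lead_coords = np.asarray(lead_coords, dtype=float)
    if lead_coords.ndim != 2 or lead_coords.shape[1] != 3:
        raise ValueError("lead_coords must be (m, 3)")
    if lead_coords.shape[0] < 2:
        raise ValueError("need at least 2 leads for a referenced lead field")

    r_heart = np.linalg.norm(mesh.node_coords, axis=1).max()
    if np.any(np.linalg.norm(lead_coords, axis=1) <= r_heart):
        raise InvalidGeometryError("every lead must lie strictly outside the heart")

    d = np.linalg.norm(
        lead_coords[:, None, :] - mesh.node_coords[None, :, :], axis=-1
    )
    H = monopole_kernel(d, conductivity)
    H = H - H.mean(axis=0, keepdims=True)
    return LeadField(H=H, lead_coords=lead_coords)


# ---------------------------------------------------------------------------
# ground-truth TMP sequences


def simulate_infarct(
    mesh: HeartMesh,
    scar_segment: int,
    scar_radius: float = 20.0,
    t: int = 100,
    dt: float = 1.0,
) -> TMPSequence:
    """Plateau-phase TMP map with an infarct scar.

    During the ST segment all healthy myocardium sits at the plateau
    potential while infarcted tissue shows a depressed, flat potential; the
    map is therefore constant over the sequence.  The scar is the ball of
    ``scar_radius`` mm around the centroid of the requested segment; scar
    nodes are set to -84 mV and healthy nodes to 27 mV.
    """
    if scar_radius <= 0:
        raise ValueError("scar_radius must be positive")
    if t < 1:
        raise ValueError("t must be >= 1")
    centre = mesh.segment_centroid(scar_segment)
    mask = np.linalg.norm(mesh.node_coords - centre, axis=1) <= scar_radius
    if not mask.any():
        raise ValueError("scar mask is empty; increase scar_radius")
    profile = np.where(mask, V_REST, V_PLATEAU)
    U = np.repeat(profile[:, None], t, axis=1)
    return TMPSequence(U=U, dt=dt, truth_meta={"scar_mask": mask})


def simulate_pacing(
    mesh: HeartMesh,
    pacing_node: int,
    velocity: float = 0.6,
    t: int = 150,
    dt: float = 1.0,
    rise_ms: float = 2.0,
) -> TMPSequence:
    """Depolarisation sequence for ectopic pacing at a given node.

    An isotropic wavefront leaves the pacing node at constant conduction
    velocity, so node j activates at ``a_j = |x_j - x_pace| / velocity`` ms.
    Each node follows a logistic action-potential upstroke from the resting
    potential (-84 mV) to the plateau (27 mV) with time constant ``rise_ms``,
    shifted by its activation time.  ``truth_meta['activation_times']``
    carries the exact activation-time vector.
    """
    if velocity <= 0:
        raise ValueError("velocity must be positive")
    if t < 50:
        raise ValueError("pacing sequences need t >= 50 frames")
    if not (0 <= pacing_node < mesh.n_nodes):
        raise IndexError(f"pacing_node {pacing_node} out of range")
    a = np.linalg.norm(mesh.node_coords - mesh.node_coords[pacing_node], axis=1)
    a = a / velocity
    times = np.arange(t) * dt
    U = V_REST + (V_PLATEAU - V_REST) * expit((times[None, :] - a[:, None]) / rise_ms)
    return TMPSequence(U=U, dt=dt, truth_meta={"activation_times": a})


# ---------------------------------------------------------------------------
# forward model and noise


def forward_project(lead_field: LeadField, tmp: TMPSequence) -> BSPSequence:
    """Forward map Phi = H U, frame by frame (quasi-static approximation)."""
    if lead_field.H.shape[1] != tmp.U.shape[0]:
        raise ValueError(
            f"H has {lead_field.H.shape[1]} source columns but U has "
            f"{tmp.U.shape[0]} nodes"
        )
    return BSPSequence(Phi=lead_field.H @ tmp.U, dt=tmp.dt, snr_db="clean")


def add_noise(bsp: BSPSequence, snr_db: float, seed: int) -> BSPSequence:
    """Add white Gaussian noise at the requested SNR (dB).

    Noise variance is ``mean(Phi**2) / 10**(snr_db/10)`` — dB relative to the
    mean-square signal power over the whole matrix — applied i.i.d. to every
    entry.  Deterministic for a fixed seed.
    """
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    power = np.mean(bsp.Phi**2)
    if power == 0:
        raise ValueError("SNR undefined for an all-zero BSP")
    sigma = np.sqrt(power / 10.0 ** (snr_db / 10.0))
    rng = np.random.default_rng(seed)
    noisy = bsp.Phi + rng.normal(scale=sigma, size=bsp.Phi.shape)
    return BSPSequence(Phi=noisy, dt=bsp.dt, snr_db=float(snr_db))
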
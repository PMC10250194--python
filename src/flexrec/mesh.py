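"""Tetrahedral meshes for deformation fields.

The deformation of the canonical map is parameterized by one 3-vector per
mesh vertex and interpolated to voxel centers with linear finite-element
shape functions (barycentric coordinates).  Meshes are regular lattices of
cubes, each split into 5 tetrahedra with parity-alternating orientation so
faces of neighboring cubes are compatible.  A custom "fused" construction
builds one submesh per labeled subdomain and shares vertices only across
interfaces the user declares continuous, giving the motion model freedom to
shear along the remaining cuts.

Positions are in voxel units, (x, y, z) order; volume arrays are [z, y, x].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, sparse

from .io_formats import CanonicalVolume, MaskVolume

__all__ = [
    "TetraMesh",
    "SegmentLabelVolume",
    "generate_regular_mesh",
    "build_fused_mesh",
    "compute_element_weights",
    "rigidity_energy",
    "save_mesh",
    "load_mesh",
]

# 5-tetrahedron split of the unit cube (even parity); corners as (i, j, k)
_TET5 = np.array(
    [
        [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 1)],  # central tet
        [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)],
        [(1, 1, 0), (1, 0, 0), (0, 1, 0), (1, 1, 1)],
        [(1, 0, 1), (1, 0, 0), (0, 0, 1), (1, 1, 1)],
        [(0, 1, 1), (0, 1, 0), (0, 0, 1), (1, 1, 1)],
    ]
)


def _cube_tets(parity: int) -> np.ndarray:
    """Corner offsets of the 5 tets for a cube of given parity (0 or 1)."""
    tets = _TET5.copy()
    if parity:
        tets[..., 0] = 1 - tets[..., 0]  # mirror along x keeps faces compatible
    return tets


@dataclass
class TetraMesh:
    """Tetrahedral mesh with precomputed voxel-to-element assignment.

    Attributes
    ----------
    vertices : (n_v, 3) float, voxel units, (x, y, z)
    cells : (n_c, 4) int vertex indices
    element_weights : (n_c,) float in [w_min, 1], rigidity prior weights
    grid_n : box size of the voxel grid the assignment was built against
    vox_flat : (n_p,) flat indices (z*n*n + y*n + x) of in-mesh voxel centers
    vox_cell : (n_p,) owning cell per assigned voxel
    vox_bary : (n_p, 4) barycentric coordinates (sum to 1)
    frozen_vertices : (n_v,) bool, vertices whose displacement is pinned to 0
    """

    vertices: np.ndarray
    cells: np.ndarray
    element_weights: np.ndarray = None
    grid_n: int = 0
    vox_flat: np.ndarray = None
    vox_cell: np.ndarray = None
    vox_bary: np.ndarray = None
    frozen_vertices: np.ndarray = None
    dinv: np.ndarray = field(default=None, repr=False)  # (n_c, 3, 3) rest-shape inverses
    _interp: sparse.csr_matrix = field(default=None, repr=False)  # (n_p, n_v) shape-function matrix

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.cells = np.asarray(self.cells, dtype=np.int64)
        if self.element_weights is None:
            self.element_weights = np.ones(len(self.cells))
        self.element_weights = np.asarray(self.element_weights, dtype=np.float64)
        if self.frozen_vertices is None:
            self.frozen_vertices = np.zeros(len(self.vertices), dtype=bool)
        if self.dinv is None:
            self.dinv = self._rest_inverses()

    def _rest_inverses(self) -> np.ndarray:
        v = self.vertices[self.cells]  # (n_c, 4, 3)
        d = np.transpose(v[:, 1:, :] - v[:, :1, :], (0, 2, 1))  # columns = edges
        det = np.linalg.det(d)
        if np.any(np.abs(det) < 1e-12):
            raise ValueError("degenerate tetrahedral cell (zero rest volume)")
        return np.linalg.inv(d)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def vox_verts(self) -> np.ndarray:
        if getattr(self, "_vox_verts", None) is None:
            self._vox_verts = self.cells[self.vox_cell]  # (n_p, 4)
        return self._vox_verts

    # -- interpolation ----------------------------------------------------

    def _interp_matrix(self) -> sparse.csr_matrix:
        if self._interp is None:
            n_p = len(self.vox_flat)
            rows = np.repeat(np.arange(n_p), 4)
            cols = self.vox_verts.ravel()
            self._interp = sparse.csr_matrix(
                (self.vox_bary.ravel(), (rows, cols)), shape=(n_p, self.n_vertices)
            )
        return self._interp

    def interpolate_flow(self, vertex_displacements: np.ndarray) -> np.ndarray:
        """Dense per-voxel displacement field from per-vertex displacements.

        Returns a ``(n, n, n, 3)`` array ([z, y, x] grid, (dx, dy, dz)
        components); voxels outside every cell get zero displacement.
        """
        u = np.asarray(vertex_displacements, dtype=np.float64)
        if u.shape != (self.n_vertices, 3):
            raise ValueError(f"expected ({self.n_vertices}, 3) displacements, got {u.shape}")
        if not np.all(np.isfinite(u)):
            raise ValueError("non-finite vertex displacement")
        n = self.grid_n
        dense = np.zeros((n * n * n, 3))
        dense[self.vox_flat] = self._interp_matrix() @ u
        return dense.reshape(n, n, n, 3)

    def interpolate_flow_adjoint(self, grad_dense: np.ndarray) -> np.ndarray:
        """Adjoint of :meth:`interpolate_flow` (dense grad -> vertex grad)."""
        n = self.grid_n
        g = grad_dense.reshape(n * n * n, 3)[self.vox_flat]  # (n_p, 3)
        return self._interp_matrix().T @ g

    def rescaled(self, scale: float, grid_n: int) -> "TetraMesh":
        """Mesh with vertex positions scaled (e.g. low-res -> full-res box).

        Displacements learned on the low-res grid must be multiplied by the
        same factor by the caller; the physical deformation is unchanged.
        """
        mesh = TetraMesh(
            vertices=self.vertices * scale,
            cells=self.cells.copy(),
            element_weights=self.element_weights.copy(),
            grid_n=grid_n,
            frozen_vertices=self.frozen_vertices.copy(),
        )
        assign_voxels(mesh)
        return mesh


@dataclass
class SegmentLabelVolume:
    """Integer subdomain labels (0 = unassigned, k >= 1 = subdomain k)."""

    data: np.ndarray
    fusion_pairs: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int64)
        self.fusion_pairs = {tuple(sorted(p)) for p in self.fusion_pairs}

    @property
    def labels(self) -> np.ndarray:
        lab = np.unique(self.data)
        return lab[lab > 0]


# ---------------------------------------------------------------------------
# construction


def _lattice_from_mask(mask: MaskVolume, h: float):
    """Lattice origin, cube counts and the set of cubes overlapping the mask."""
    support = np.argwhere(mask.data > 0.5)  # (n, 3) as (z, y, x)
    if len(support) == 0:
        raise ValueError("empty mask: cannot build a mesh")
    pos = support[:, ::-1].astype(np.float64)  # (x, y, z)
    origin = pos.min(axis=0)
    extent = pos.max(axis=0) - origin
    ncubes = np.maximum(1, np.ceil(extent / h - 1e-9).astype(int))
    cube_idx = np.minimum((pos - origin) // h, ncubes - 1).astype(int)
    kept = np.zeros(tuple(ncubes), dtype=bool)
    kept[tuple(cube_idx.T)] = True
    return origin, ncubes, kept, cube_idx, support


def _build_from_cubes(origin, h, cube_list, cube_owner, node_instance):
    """Assemble vertices/cells given per-cube node->vertex-instance mapping.

    ``node_instance(owner, node_ijk)`` returns a hashable instance key; equal
    keys share a vertex.
    """
    vert_index: dict = {}
    vertices: list = []
    cells: list = []
    cell_cube: list = []
    for cube, owner in zip(cube_list, cube_owner):
        cube = tuple(cube)
        parity = sum(cube) % 2
        for tet in _cube_tets(parity):
            idx4 = []
            for corner in tet:
                node = (cube[0] + corner[0], cube[1] + corner[1], cube[2] + corner[2])
                key = node_instance(owner, node)
                if key not in vert_index:
                    vert_index[key] = len(vertices)
                    vertices.append(origin + h * np.asarray(node, dtype=np.float64))
                idx4.append(vert_index[key])
            cells.append(idx4)
            cell_cube.append(cube)
    return np.asarray(vertices), np.asarray(cells, dtype=np.int64), cell_cube


def assign_voxels(mesh: TetraMesh) -> None:
    """Assign every in-mesh voxel center to a cell with barycentric weights.

    Generic (bounding-box bucketed) point location; ties on shared faces are
    broken by lowest cell index, deterministically.
    """
    n = mesh.grid_n
    verts = mesh.vertices[mesh.cells]  # (n_c, 4, 3)
    owner = np.full(n * n * n, -1, dtype=np.int64)
    bary_store = np.zeros((n * n * n, 4))
    for j in range(mesh.n_cells):
        v = verts[j]
        lo = np.maximum(np.ceil(v.min(axis=0) - 1e-9), 0).astype(int)
        hi = np.minimum(np.floor(v.max(axis=0) + 1e-9), n - 1).astype(int)
        if np.any(hi < lo):
            continue
        xs, ys, zs = [np.arange(lo[a], hi[a] + 1) for a in range(3)]
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]).astype(np.float64)
        b123 = (pts - v[0]) @ mesh.dinv[j].T
        b0 = 1.0 - b123.sum(axis=1)
        bary = np.column_stack([b0, b123])
        inside = np.all(bary >= -1e-9, axis=1)
        if not inside.any():
            continue
        flat = (
            pts[inside, 2].astype(int) * n * n
            + pts[inside, 1].astype(int) * n
            + pts[inside, 0].astype(int)
        )
        free = owner[flat] < 0
        flat = flat[free]
        owner[flat] = j
        bary_store[flat] = np.clip(bary[inside][free], 0.0, None)
    assigned = np.nonzero(owner >= 0)[0]
    mesh.vox_flat = assigned
    mesh.vox_cell = owner[assigned]
    b = bary_store[assigned]
    mesh.vox_bary = b / b.sum(axis=1, keepdims=True)
    mesh._vox_verts = None
    mesh._interp = None


def generate_regular_mesh(
    mask: MaskVolume, element_size_A: float, voxel_size_A: float
) -> TetraMesh:
    """Regular tetrahedral mesh covering the mask support.

    An axis-aligned cubic lattice of spacing ``element_size_A`` covers the
    mask's bounding region; cubes containing no mask voxel are dropped and
    each remaining cube is split into 5 tetrahedra.  Adjacent kept cubes
    share vertices.
    """
    if element_size_A < 2 * voxel_size_A:
        raise ValueError(
            f"element size {element_size_A} A must be >= 2 voxels ({2 * voxel_size_A} A)"
        )
    h = element_size_A / voxel_size_A
    origin, ncubes, kept, _, _ = _lattice_from_mask(mask, h)
    cube_list = np.argwhere(kept)
    vertices, cells, _ = _build_from_cubes(
        origin, h, cube_list, [0] * len(cube_list), lambda owner, node: node
    )
    mesh = TetraMesh(vertices=vertices, cells=cells, grid_n=mask.data.shape[0])
    assign_voxels(mesh)
    return mesh


def build_fused_mesh(
    segments: SegmentLabelVolume,
    mask: MaskVolume,
    element_size_A: float,
    voxel_size_A: float,
) -> TetraMesh:
    """Mesh of per-subdomain submeshes, fused only across declared interfaces.

    Each voxel is first reassigned to its nearest labeled segment, a base
    lattice is laid over the mask support, and each kept cube is owned by the
    subdomain most represented among its mask voxels.  Lattice nodes shared
    between cubes of different subdomains are duplicated unless the subdomain
    pair is listed in ``segments.fusion_pairs`` (fusion is transitive at a
    node).
    """
    labels = segments.labels
    if len(labels) == 0:
        raise ValueError("segments contain no labeled subdomain")
    for pair in segments.fusion_pairs:
        for lab in pair:
            if lab not in labels:
                raise ValueError(f"fusion pair {pair} references unknown label {lab}")
    # expand each segment to all voxels nearest to it
    dist = np.stack(
        [ndimage.distance_transform_edt(segments.data != lab) for lab in labels]
    )
    nearest = labels[np.argmin(dist, axis=0)]  # (z, y, x)

    if element_size_A < 2 * voxel_size_A:
        raise ValueError("element size must be >= 2 voxels")
    h = element_size_A / voxel_size_A
    origin, ncubes, kept, cube_idx, support = _lattice_from_mask(mask, h)

    # majority nearest-label of the mask voxels in each kept cube
    lab_of_voxel = nearest[tuple(support.T)]
    cube_owner_map = {}
    for cube in map(tuple, np.argwhere(kept)):
        sel = np.all(cube_idx == cube, axis=1)
        labs, counts = np.unique(lab_of_voxel[sel], return_counts=True)
        cube_owner_map[cube] = int(labs[np.argmax(counts)])

    # which subdomains touch each lattice node, and their fusion groups
    node_owners: dict = {}
    for cube, owner in cube_owner_map.items():
        for di in range(2):
            for dj in range(2):
                for dk in range(2):
                    node = (cube[0] + di, cube[1] + dj, cube[2] + dk)
                    node_owners.setdefault(node, set()).add(owner)

    def fusion_group(owner: int, node) -> tuple:
        """Connected component of ``owner`` among owners at this node."""
        present = node_owners[node]
        group = {owner}
        frontier = [owner]
        while frontier:
            a = frontier.pop()
            for b in present:
                if b not in group and tuple(sorted((a, b))) in segments.fusion_pairs:
                    group.add(b)
                    frontier.append(b)
        return (node, min(group))

    cube_list = list(cube_owner_map.keys())
    owners = [cube_owner_map[c] for c in cube_list]
    vertices, cells, _ = _build_from_cubes(origin, h, cube_list, owners, fusion_group)
    mesh = TetraMesh(vertices=vertices, cells=cells, grid_n=mask.data.shape[0])
    assign_voxels(mesh)
    return mesh


# ---------------------------------------------------------------------------
# element weights and rigidity energy


def compute_element_weights(
    mesh: TetraMesh, volume: CanonicalVolume, w_min: float = 0.5
) -> np.ndarray:
    """Per-element rigidity prior weights from mean element density.

    The density score of an element is the mean of the map over its assigned
    voxels, clamped at 0; weights interpolate linearly between ``w_min``
    (empty elements) and 1 (densest element).  The result is also stored on
    ``mesh.element_weights``.
    """
    vals = volume.data.reshape(-1)[mesh.vox_flat]
    sums = np.bincount(mesh.vox_cell, weights=vals, minlength=mesh.n_cells)
    counts = np.bincount(mesh.vox_cell, minlength=mesh.n_cells)
    score = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    score = np.clip(score, 0.0, None)
    smax = score.max()
    if smax <= 0:
        weights = np.full(mesh.n_cells, w_min)
    else:
        weights = w_min + (1.0 - w_min) * score / smax
    mesh.element_weights = weights
    return weights


def freeze_vertices_in_mask(mesh: TetraMesh, mask: MaskVolume) -> None:
    """Pin to zero the displacement of vertices inside a zero-deformation mask."""
    n = mask.data.shape[0]
    idx = np.clip(np.round(mesh.vertices).astype(int), 0, n - 1)
    inside = mask.data[idx[:, 2], idx[:, 1], idx[:, 0]] > 0.5
    mesh.frozen_vertices = inside


def rigidity_energy(
    mesh: TetraMesh, vertex_displacements: np.ndarray, with_grad: bool = True
):
    """Local-rigidity energy of a batch of per-vertex displacement fields.

    For each field ``i`` and element ``j`` the affine deformation map
    ``x -> A_ij x + b_ij`` (rest position to displaced position) is solved
    exactly from the four vertex positions, and the energy is

        E = sum_i sum_j w_j sum_l (s_ij^l - 1)^2

    with ``s`` the singular values of ``A_ij``.  The analytic gradient with
    respect to the vertex displacements is ``U diag(2(s-1)) V^T`` chained
    through the (linear) dependence of ``A`` on the displacements.

    Parameters
    ----------
    vertex_displacements : (n_v, 3) or (B, n_v, 3)

    Returns
    -------
    energy : float
    grad : same shape as input (if ``with_grad``)
    """
    u = np.asarray(vertex_displacements, dtype=np.float64)
    single = u.ndim == 2
    if single:
        u = u[None]
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite displacement input")
    B = u.shape[0]
    uc = u[:, mesh.cells, :]  # (B, n_c, 4, 3)
    du = np.transpose(uc[:, :, 1:, :] - uc[:, :, :1, :], (0, 1, 3, 2))  # columns = edge disp
    A = np.eye(3) + du @ mesh.dinv  # (B, n_c, 3, 3)
    U, s, Vt = np.linalg.svd(A)
    dev = s - 1.0
    w = mesh.element_weights
    energy = float(np.sum(w[None, :] * np.sum(dev**2, axis=-1)))
    if not with_grad:
        return energy
    gA = (U * (2.0 * dev)[..., None, :]) @ Vt  # d/dA of sum (s-1)^2
    gA *= w[None, :, None, None]
    gdu = gA @ np.transpose(mesh.dinv, (0, 2, 1))  # (B, n_c, 3, 3), columns = edges
    grad = np.zeros_like(u)
    cells = mesh.cells
    for k in range(3):
        col = gdu[:, :, :, k]  # (B, n_c, 3)
        np.add.at(grad, (slice(None), cells[:, k + 1]), col)
        np.add.at(grad, (slice(None), cells[:, 0]), -col)
    if single:
        grad = grad[0]
    return energy, grad


# ---------------------------------------------------------------------------
# serialization (plain JSON)


def save_mesh(mesh: TetraMesh, path) -> None:
    payload = {
        "vertices": mesh.vertices.tolist(),
        "cells": mesh.cells.tolist(),
        "element_weights": mesh.element_weights.tolist(),
        "grid_n": int(mesh.grid_n),
        "frozen_vertices": mesh.frozen_vertices.astype(int).tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_mesh(path) -> TetraMesh:
    payload = json.loads(Path(path).read_text())
    mesh = TetraMesh(
        vertices=np.asarray(payload["vertices"]),
        cells=np.asarray(payload["cells"]),
        element_weights=np.asarray(payload["element_weights"]),
        grid_n=int(payload["grid_n"]),
        frozen_vertices=np.asarray(payload["frozen_vertices"], dtype=bool),
    )
    assign_voxels(mesh)
    return mesh
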
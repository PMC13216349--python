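"""Structured quadratic tetrahedral meshes of box (prism) cell regions.

The simulation domain is always an axis-aligned box (default 11 x 11 x 5 um,
the size of the morphometry test regions).  Each hexahedral cell of a
structured grid is split into five tetrahedra, with the two split chiralities
alternated in a checkerboard so the triangulation is conforming; with even
subdivision counts the mesh is also mirror-symmetric about the box centre
planes, which lets symmetric boundary-value problems produce symmetric
discrete solutions (no spurious mesh-induced rotation).

Displacements live on 10-node (second-order Lagrange) tetrahedra; the
hydrostatic pressure of the incompressible formulation lives on the 4 corner
nodes (first-order), the stable Taylor-Hood pairing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PrismMesh", "build_prism_mesh"]

# local edge numbering of the quadratic tetrahedron (VTK convention):
# nodes 0-3 vertices, 4-9 midpoints of edges (0,1),(1,2),(0,2),(0,3),(1,3),(2,3)
TET_EDGES = np.array([[0, 1], [1, 2], [0, 2], [0, 3], [1, 3], [2, 3]])

# five-tet split of the unit hex, chirality A: central tet on alternate corners
_SPLIT_A = [
    [(1, 0, 0), (0, 0, 0), (1, 1, 0), (1, 0, 1)],
    [(0, 1, 0), (0, 0, 0), (1, 1, 0), (0, 1, 1)],
    [(0, 0, 1), (0, 0, 0), (1, 0, 1), (0, 1, 1)],
    [(1, 1, 1), (1, 1, 0), (1, 0, 1), (0, 1, 1)],
    [(0, 0, 0), (1, 1, 0), (1, 0, 1), (0, 1, 1)],
]
# chirality B: mirror of A in the first axis
_SPLIT_B = [[(1 - a, b, c) for (a, b, c) in tet] for tet in _SPLIT_A]


@dataclass
class PrismMesh:
    """Quadratic tetrahedral mesh of a box with tagged boundary faces."""

    dims: np.ndarray  # (3,) physical edge lengths (um)
    subdivisions: tuple[int, int, int]
    nodes: np.ndarray  # (n_nodes, 3) coordinates of all P2 nodes (um)
    cells: np.ndarray  # (n_cells, 10) P2 connectivity, vertices first
    vertex_cells: np.ndarray = field(repr=False, default=None)  # (n_cells, 4) P1 ids
    pressure_of_node: np.ndarray = field(repr=False, default=None)  # P2 node -> P1 id
    n_pressure: int = 0

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_cells(self) -> int:
        return self.cells.shape[0]

    def cell_volumes(self) -> np.ndarray:
        v = self.nodes[self.cells[:, :4]]
        e = v[:, 1:] - v[:, :1]
        return np.abs(np.linalg.det(e)) / 6.0

    def boundary_nodes(self, tag: str, tol: float = 1e-9) -> np.ndarray:
        """Node indices on a tagged face: 'x_min','x_max','y_min',... ."""
        axis = {"x": 0, "y": 1, "z": 2}[tag[0]]
        target = 0.0 if tag.endswith("min") else float(self.dims[axis])
        return np.nonzero(np.abs(self.nodes[:, axis] - target) < tol)[0]

    def refined(self) -> "PrismMesh":
        """Uniformly refined mesh (doubled subdivisions), for convergence study."""
        nx, ny, nz = self.subdivisions
        return build_prism_mesh(tuple(self.dims), (2 * nx, 2 * ny, 2 * nz))


def build_prism_mesh(
    dims: tuple[float, float, float], subdivisions: int | tuple[int, int, int]
) -> PrismMesh:
    """Mesh the box [0,Lx]x[0,Ly]x[0,Lz] with quadratic tetrahedra.

    Parameters
    ----------
    dims : edge lengths (um), all positive.
    subdivisions : hexahedral cells per axis (int applies to every axis).
        Even counts are recommended: they make the mesh mirror-symmetric.
    """
    dims = np.asarray(dims, dtype=float)
    if dims.shape != (3,) or np.any(dims <= 0):
        raise ValueError("dims must be three positive lengths")
    if np.isscalar(subdivisions):
        subdivisions = (int(subdivisions),) * 3
    nx, ny, nz = (int(n) for n in subdivisions)
    if min(nx, ny, nz) < 1:
        raise ValueError("subdivisions must be >= 1 per axis")

    # all candidate P2 nodes live on the half-step lattice (2n+1 per axis)
    fine = np.array([2 * nx + 1, 2 * ny + 1, 2 * nz + 1])
    h2 = dims / (2 * np.array([nx, ny, nz]))  # half-step sizes

    def flat(idx: np.ndarray) -> np.ndarray:
        return (idx[..., 0] * fine[1] + idx[..., 1]) * fine[2] + idx[..., 2]

    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    hexes = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)  # (nh, 3)
    parity = hexes.sum(axis=1) % 2

    split_a = 2 * np.array(_SPLIT_A)  # fine-lattice offsets of tet vertices
    split_b = 2 * np.array(_SPLIT_B)
    base = 2 * hexes[:, None, None, :]  # (nh,1,1,3)
    verts = np.where(
        parity[:, None, None, None] == 0, base + split_a, base + split_b
    )  # (nh, 5, 4, 3)
    verts = verts.reshape(-1, 4, 3)

    # enforce positive orientation (swap two vertices where determinant < 0)
    coords = verts * h2
    det = np.linalg.det(coords[:, 1:] - coords[:, :1])
    neg = det < 0
    verts[neg, 1], verts[neg, 2] = verts[neg, 2].copy(), verts[neg, 1].copy()

    mids = (verts[:, TET_EDGES[:, 0]] + verts[:, TET_EDGES[:, 1]]) // 2
    conn_fine = flat(np.concatenate([verts, mids], axis=1))  # (ncell, 10)

    used, inverse = np.unique(conn_fine, return_inverse=True)
    cells = inverse.reshape(conn_fine.shape).astype(np.int64)
    kx, rem = np.divmod(used, fine[1] * fine[2])
    ky, kz = np.divmod(rem, fine[2])
    nodes = np.stack([kx, ky, kz], axis=1) * h2

    # pressure (P1) dofs: the subset of nodes that appear as tet vertices
    pressure_of_node = np.full(nodes.shape[0], -1, dtype=np.int64)
    vertex_ids = np.unique(cells[:, :4])
    pressure_of_node[vertex_ids] = np.arange(vertex_ids.size)
    vertex_cells = pressure_of_node[cells[:, :4]]

    return PrismMesh(
        dims=dims,
        subdivisions=(nx, ny, nz),
        nodes=nodes,
        cells=cells,
        vertex_cells=vertex_cells,
        pressure_of_node=pressure_of_node,
        n_pressure=vertex_ids.size,
    )
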
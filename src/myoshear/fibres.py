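"""Fibre fields: interpolating z-disc orientations onto the simulation mesh.

Myofilaments run perpendicular to the z-discs, so the disc normals sampled by
the morphometry define the local fibre direction.  Mesh nodes pick up the
angles of their nearest z-disc voxel (KD-tree nearest neighbour, so nodes
inside a disc inherit that disc's angles), and the nodal (azimuth, elevation)
angle components are then smoothed with an anisotropic Gaussian kernel --
standard deviation ``sigma_fibre`` along the fibre (x) axis, matching the
sarcomere slack length (1.8-2 um), and ``sigma_disc`` transversely, matching
the z-disc thickness (0.10-0.14 um).  Smoothing acts on angles rather than on
raw vectors to avoid the shrinkage bias of naive vector averaging; directions
are renormalised afterwards.

Every fibre direction keeps a positive x component (no fibre reversal), which
also makes the minimal-rotation local frame unique and continuous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "FibreField",
    "CurvilinearFrame",
    "minimal_rotation_from_x",
    "vector_from_angles",
    "map_orientations_to_nodes",
    "smooth_fibre_field",
    "local_basis",
]


@dataclass
class FibreField:
    """Per-node unit fibre directions plus the angles they encode (degrees)."""

    directions: np.ndarray  # (n_nodes, 3) unit vectors, f_x > 0
    azimuth: np.ndarray  # (n_nodes,) degrees
    elevation: np.ndarray  # (n_nodes,) degrees
    sigma_disc: float | None = None  # um, transverse smoothing sd (None = raw)
    sigma_fibre: float | None = None  # um, along-fibre smoothing sd

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("fibre directions must be unit vectors")
        if np.any(self.directions[:, 0] <= 0):
            raise ValueError("fibre directions must keep a positive x component")

    @classmethod
    def from_angles(
        cls, azimuth: np.ndarray, elevation: np.ndarray, **kw
    ) -> "FibreField":
        az = np.asarray(azimuth, dtype=float)
        el = np.asarray(elevation, dtype=float)
        return cls(directions=vector_from_angles(az, el), azimuth=az, elevation=el, **kw)

    @classmethod
    def uniaxial(cls, n_nodes: int) -> "FibreField":
        """Constant (1,0,0) field: the classical uniaxial-myofibril assumption."""
        z = np.zeros(n_nodes)
        return cls.from_angles(z, z.copy())


@dataclass
class CurvilinearFrame:
    """Orthonormal material frame: columns of ``basis`` are A_1 (=fibre), A_2, A_3."""

    basis: np.ndarray  # (..., 3, 3)

    @property
    def metric(self) -> np.ndarray:
        """Undeformed metric G_ij = A_i . A_j (identity for orthonormal frames)."""
        return np.einsum("...ki,...kj->...ij", self.basis, self.basis)


def vector_from_angles(azimuth: np.ndarray, elevation: np.ndarray) -> np.ndarray:
    """Unit vector with the given signed x-y (azimuth) and x-z (elevation) angles.

    Inverse of the morphometry convention: azimuth = atan2(n_y, n_x),
    elevation = atan2(n_z, n_x), valid for directions within 90 deg of +x.
    """
    az = np.radians(np.asarray(azimuth, dtype=float))
    el = np.radians(np.asarray(elevation, dtype=float))
    if np.any(np.abs(az) >= np.pi / 2) or np.any(np.abs(el) >= np.pi / 2):
        raise ValueError("angle components must lie strictly within +-90 degrees")
    v = np.stack([np.ones_like(az), np.tan(az), np.tan(el)], axis=-1)
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def minimal_rotation_from_x(f: np.ndarray) -> np.ndarray:
    """Rotation matrix R (batched) with R @ e_x = f, minimal rotation angle.

    Rodrigues rotation about e_x x f.  Requires f_x > -1 (the antiparallel
    case is excluded by the field invariant f_x > 0).
    """
    f = np.asarray(f, dtype=float)
    single = f.ndim == 1
    f = np.atleast_2d(f)
    norms = np.linalg.norm(f, axis=-1, keepdims=True)
    if np.any(norms < 1e-12):
        raise ValueError("zero fibre vector")
    f = f / norms
    c = f[..., 0]  # cos(angle) = e_x . f
    if np.any(c <= -1.0 + 1e-12):
        raise ValueError("antiparallel fibre direction: minimal rotation undefined")
    # axis k = e_x x f = (0, -f_z, f_y); Rodrigues with sin = |k|
    kx = np.zeros_like(c)
    ky, kz = -f[..., 2], f[..., 1]
    K = np.zeros(f.shape[:-1] + (3, 3))
    K[..., 0, 1], K[..., 0, 2] = -kz, ky
    K[..., 1, 0], K[..., 1, 2] = kz, -kx
    K[..., 2, 0], K[..., 2, 1] = -ky, kx
    R = np.broadcast_to(np.eye(3), K.shape).copy()
    R += K
    R += np.einsum("...ij,...jk->...ik", K, K) / (1.0 + c)[..., None, None]
    return R[0] if single else R


def map_orientations_to_nodes(mesh, instances, records) -> tuple[np.ndarray, np.ndarray]:
    """Assign each mesh node the angles of its nearest z-disc voxel.

    Parameters
    ----------
    mesh : PrismMesh (nodes in the same physical coordinates as the instances).
    instances : list of ZDiscInstance providing the voxel clouds.
    records : orientation table with 'instance_id', 'azimuth', 'elevation'.

    Returns raw nodal (azimuth, elevation) arrays in degrees.  Equidistant
    nearest voxels from different instances are resolved toward the lowest
    instance id (logged).
    """
    if not instances:
        raise ValueError("no z-disc instances to map")
    by_id = records.set_index("instance_id")
    clouds = np.concatenate([inst.coords for inst in instances], axis=0)
    owner = np.concatenate(
        [np.full(len(inst.coords), inst.instance_id) for inst in instances]
    )
    tree = cKDTree(clouds)
    dist, idx = tree.query(mesh.nodes, k=2)
    pick = idx[:, 0]
    tied = np.isclose(dist[:, 0], dist[:, 1], rtol=0.0, atol=1e-12) & (
        owner[idx[:, 0]] != owner[idx[:, 1]]
    )
    if np.any(tied):
        swap = tied & (owner[idx[:, 1]] < owner[idx[:, 0]])
        pick[swap] = idx[swap, 1]
        logger.info("map_orientations_to_nodes: %d equidistant ties resolved", tied.sum())
    ids = owner[pick]
    azimuth = by_id.loc[ids, "azimuth"].to_numpy(dtype=float)
    elevation = by_id.loc[ids, "elevation"].to_numpy(dtype=float)
    return azimuth, elevation


def smooth_fibre_field(
    nodes: np.ndarray,
    azimuth: np.ndarray,
    elevation: np.ndarray,
    sigma_disc: float = 0.12,
    sigma_fibre: float = 1.9,
    chunk: int = 512,
) -> FibreField:
    """Anisotropic Gaussian smoothing of nodal angle components.

    Kernel standard deviations: ``sigma_fibre`` (um) along x (the near-axial
    fibre direction), ``sigma_disc`` (um) in the transverse (y, z) plane.
    Weights are normalised per node, so a constant field is a fixed point and
    smoothed values are convex combinations of the raw values.
    """
    if sigma_disc <= 0 or sigma_fibre <= 0:
        raise ValueError("smoothing standard deviations must be positive")
    nodes = np.asarray(nodes, dtype=float)
    az = np.asarray(azimuth, dtype=float)
    el = np.asarray(elevation, dtype=float)
    out_az = np.empty_like(az)
    out_el = np.empty_like(el)
    inv2 = np.array([sigma_fibre, sigma_disc, sigma_disc]) ** -2
    for start in range(0, len(nodes), chunk):
        sl = slice(start, min(start + chunk, len(nodes)))
        d2 = np.einsum(
            "ijk,k->ij",
            (nodes[sl, None, :] - nodes[None, :, :]) ** 2,
            inv2,
        )
        w = np.exp(-0.5 * d2)
        w /= w.sum(axis=1, keepdims=True)
        out_az[sl] = w @ az
        out_el[sl] = w @ el
    return FibreField.from_angles(
        out_az, out_el, sigma_disc=sigma_disc, sigma_fibre=sigma_fibre
    )


def local_basis(f: np.ndarray) -> CurvilinearFrame:
    """Orthonormal frame with A_1 = f, completed by the minimal rotation from +x.

    The rotation axis is e_x x f, so the frame varies continuously with the
    fibre direction and reduces to the Cartesian triad for f = e_x.  The
    induced undeformed metric G_ij = A_i . A_j is the identity.
    """
    f = np.asarray(f, dtype=float)
    if np.any(np.linalg.norm(np.atleast_2d(f), axis=-1) < 1e-12):
        raise ValueError("zero fibre vector")
    return CurvilinearFrame(basis=minimal_rotation_from_x(f))
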
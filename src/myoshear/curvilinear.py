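"""Curvilinear tensor calculus for the fibre-aligned variational formulation.

The contraction problem is posed in a material frame rotated to follow the
fibre field.  For a spatially varying metric g_ij the derivative of a vector
field acquires the Christoffel correction

    Gamma^k_ij = 1/2 g^{kl} (g_{jl,i} + g_{il,j} - g_{ij,l})
    nabla_j v^a = dv^a/dx_j + Gamma^a_{kj} v^k

and the internal-work density of the weak form reads T^{ab} F^j_b nabla_j v^a
with T the second Piola-Kirchhoff components in the frame basis.  For the
orthonormal frames used here the undeformed metric is the identity, the
symbols vanish, and the density coincides with the Cartesian total-Lagrangian
expression P : grad(v); the general formulas are kept (and tested against
symbolic differentiation) so the formulation is explicit.
"""

from __future__ import annotations

import numpy as np

__all__ = ["christoffel", "covariant_derivative", "residual_density"]


def christoffel(g_cov: np.ndarray, dg_cov: np.ndarray) -> np.ndarray:
    """Christoffel symbols of the second kind from a metric and its gradients.

    Parameters
    ----------
    g_cov : (..., 3, 3) covariant metric, symmetric positive definite.
    dg_cov : (..., 3, 3, 3) spatial derivatives, ``dg_cov[..., i, j, l]`` =
        d g_ij / d x_l.

    Returns
    -------
    (..., 3, 3, 3) array ``gamma[..., k, i, j]`` = Gamma^k_ij, symmetric in
    the two lower indices.
    """
    g_cov = np.asarray(g_cov, dtype=float)
    dg = np.asarray(dg_cov, dtype=float)
    if g_cov.shape[-2:] != (3, 3) or dg.shape[-3:] != (3, 3, 3):
        raise ValueError("metric must be (...,3,3) and derivatives (...,3,3,3)")
    if not np.allclose(g_cov, np.swapaxes(g_cov, -1, -2), atol=1e-10):
        raise ValueError("metric must be symmetric")
    if np.any(np.linalg.det(g_cov) <= 0):
        raise ValueError("metric must be positive definite (singular metric)")
    g_contra = np.linalg.inv(g_cov)
    # dg[..., j, l, i] = g_{jl,i};  bracket_{l i j} = g_{jl,i} + g_{il,j} - g_{ij,l}
    bracket = (
        np.einsum("...jli->...lij", dg)
        + np.einsum("...ilj->...lij", dg)
        - np.einsum("...ijl->...lij", dg)
    )
    return 0.5 * np.einsum("...kl,...lij->...kij", g_contra, bracket)


def covariant_derivative(
    dv: np.ndarray, gamma: np.ndarray, v: np.ndarray
) -> np.ndarray:
    """Covariant derivative nabla_j v^a = dv^a/dx_j + Gamma^a_{kj} v^k.

    ``dv[..., a, j]`` holds the partial derivatives; returns the same layout.
    Reduces to the ordinary gradient when the symbols vanish.
    """
    dv = np.asarray(dv, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    v = np.asarray(v, dtype=float)
    if dv.shape[-2:] != (3, 3) or v.shape[-1] != 3:
        raise ValueError("dv must be (...,3,3) and v (...,3)")
    return dv + np.einsum("...akj,...k->...aj", gamma, v)


def residual_density(
    T: np.ndarray, F: np.ndarray, nabla_v: np.ndarray
) -> np.ndarray:
    """Internal-work density T^{ab} F^j_b nabla_a v^j of the curvilinear weak form.

    ``T`` are frame components of the (symmetric) second Piola-Kirchhoff
    stress, ``F[..., j, b]`` the deformation gradient with spatial row and
    material-frame column, and ``nabla_v[..., j, a]`` the covariant derivative
    of the test function's spatial components along the material frame
    directions.  Pairing the derivative index of v with the frame (and its
    vector index with the spatial row of F) reproduces the work conjugacy
    T : dE[v], since dE_ab = sym(F^j_a nabla_b v^j).
    """
    return np.einsum("...ab,...jb,...ja->...", T, F, nabla_v)
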
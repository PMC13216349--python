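"""Incompressible fibre-informed hyperelastic contraction solver.

The cell region is modelled as an incompressible, transversely isotropic
Guccione solid.  The mixed displacement/pressure weak form is

    R(u, p; v, q) = int_Omega  S : dE[v]  dOmega  +  int_Omega q (J - 1) dOmega

with S = S_con(E) + p J C^{-1}: the constitutive second Piola-Kirchhoff
stress (dPsi/dE rotated from the local fibre frame) plus the pressure
Lagrange-multiplier term enforcing J = det F = 1.  For the orthonormal
fibre-aligned frames used here this Cartesian total-Lagrangian form is
identical to the curvilinear index form T^{ab} F^j_b nabla_j v^a (see
:mod:`myoshear.curvilinear`), because the undeformed metric is the identity
and the Christoffel corrections vanish.

Discretisation: 10-node quadratic tetrahedra for displacement, 4-node linear
tetrahedra for pressure (Taylor-Hood pairing), degree-4 Keast quadrature.
Contraction is driven by prescribed end-face displacements applied in
increments (default 2% steps to 20% total shortening), each solved with a
Newton iteration whose Jacobian is assembled from finite differences of the
exact element residual; failed increments are halved and retried.

Units: lengths um, stresses and pressure kPa, displacements um.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fibres import FibreField, minimal_rotation_from_x
from .material import MaterialParams, exponent_weights
from .mesh import PrismMesh, TET_EDGES

logger = logging.getLogger(__name__)

__all__ = [
    "SolveConfig",
    "ContractionModel",
    "ContractionResults",
    "ElementInversionError",
    "tet_quadrature",
    "homogeneous_uniaxial_response",
    "convergence_study",
]


class ElementInversionError(RuntimeError):
    """An element reached J <= 0 during assembly; the increment is rejected."""


@dataclass(frozen=True)
class SolveConfig:
    """Incremental Newton solve settings."""

    fraction: float = 0.20  # total end-to-end shortening as fraction of length
    increment: float = 0.02  # displacement fraction per recorded step
    newton_tol: float = 1e-5  # relative increment tolerance
    max_newton: int = 50
    max_halvings: int = 3
    mode: str = "shorten"  # or "stretch"

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction <= 0.5):
            raise ValueError("fraction must lie in (0, 0.5]")
        if not (0.0 < self.increment <= self.fraction):
            raise ValueError("increment must lie in (0, fraction]")
        if self.newton_tol <= 0:
            raise ValueError("tolerance must be positive")
        if self.mode not in ("shorten", "stretch"):
            raise ValueError("mode must be 'shorten' or 'stretch'")


def tet_quadrature(degree: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Keast quadrature on the reference tetrahedron (barycentric, weights sum 1)."""
    if degree <= 2:
        a = (5.0 - np.sqrt(5.0)) / 20.0
        b = (5.0 + 3.0 * np.sqrt(5.0)) / 20.0
        pts = np.full((4, 4), a)
        np.fill_diagonal(pts, b)
        return pts, np.full(4, 0.25)
    # Keast 11-point, degree 4
    pts = [[0.25] * 4]
    a, b = 11.0 / 14.0, 1.0 / 14.0
    for i in range(4):
        p = [b] * 4
        p[i] = a
        pts.append(p)
    c, d = 0.3994035761667992, 0.1005964238332008
    for i in range(3):
        for j in range(i + 1, 4):
            p = [d] * 4
            p[i] = p[j] = c
            pts.append(p)
    w = np.concatenate(
        [
            [-74.0 / 5625.0 * 6.0],
            np.full(4, 343.0 / 45000.0 * 6.0),
            np.full(6, 56.0 / 2250.0 * 6.0),
        ]
    )
    return np.array(pts), w


def _p2_shape(bary: np.ndarray) -> np.ndarray:
    """Quadratic tet shape functions at barycentric points: (nq, 10)."""
    lam = np.asarray(bary)
    nv = lam * (2 * lam - 1)
    ne = 4 * lam[:, TET_EDGES[:, 0]] * lam[:, TET_EDGES[:, 1]]
    return np.concatenate([nv, ne], axis=1)


def _p2_shape_grad_bary(bary: np.ndarray) -> np.ndarray:
    """d N / d lambda at barycentric points: (nq, 10, 4)."""
    lam = np.asarray(bary)
    nq = lam.shape[0]
    g = np.zeros((nq, 10, 4))
    for i in range(4):
        g[:, i, i] = 4 * lam[:, i] - 1
    for e, (a, b) in enumerate(TET_EDGES):
        g[:, 4 + e, a] = 4 * lam[:, b]
        g[:, 4 + e, b] = 4 * lam[:, a]
    return g


@dataclass
class _ConvergenceRecord:
    target: float  # displacement fraction reached
    iterations: int
    residual: float
    increment_norm: float
    substeps: int


class ContractionModel:
    """Fibre-informed incompressible contraction of a box cell region.

    Parameters
    ----------
    mesh : PrismMesh
    fibre_field : FibreField with one direction per mesh node.
    material : MaterialParams (Guccione constants).
    config : SolveConfig.
    end_constraint : 'clamped' fixes the end faces in y and z while displacing
        x (the simulated condition); 'frictionless' prescribes only the x
        displacement of the end faces (plus minimal rigid-body pins), the
        configuration with a homogeneous closed-form solution.
    rotation : optional 3x3 rotation applied to the whole problem (geometry,
        fibres and boundary displacements) -- used for objectivity checks.
    """

    def __init__(
        self,
        mesh: PrismMesh,
        fibre_field: FibreField,
        material: MaterialParams | None = None,
        config: SolveConfig | None = None,
        end_constraint: str = "clamped",
        rotation: np.ndarray | None = None,
    ) -> None:
        if fibre_field.directions.shape[0] != mesh.n_nodes:
            raise ValueError("fibre field does not match mesh nodes")
        if end_constraint not in ("clamped", "frictionless"):
            raise ValueError("end_constraint must be 'clamped' or 'frictionless'")
        if end_constraint == "frictionless" and rotation is not None:
            raise ValueError("frictionless pins are only defined in the axis-aligned frame")
        self.mesh = mesh
        self.fibre_field = fibre_field
        self.material = material or MaterialParams()
        self.config = config or SolveConfig()
        self.end_constraint = end_constraint
        self.rotation = None if rotation is None else np.asarray(rotation, dtype=float)

        self.nodes = mesh.nodes if self.rotation is None else mesh.nodes @ self.rotation.T
        directions = fibre_field.directions
        if self.rotation is not None:
            directions = directions @ self.rotation.T
        self._setup_fem(directions)
        self._setup_bcs()

    # ------------------------------------------------------------------ setup
    def _setup_fem(self, directions: np.ndarray) -> None:
        mesh = self.mesh
        bary, wq = tet_quadrature(4)
        self.wq = wq
        self.Np1 = bary  # linear shape functions = barycentric coords, (nq, 4)
        self.Np2 = _p2_shape(bary)
        gbary = _p2_shape_grad_bary(bary)  # (nq, 10, 4)
        # affine map: lambda_0 = 1 - xi - eta - zeta; dN/dxi = g[:,:,1:] - g[:,:,:1]
        dN_dxi = gbary[:, :, 1:] - gbary[:, :, :1]  # (nq, 10, 3)

        verts = self.nodes[mesh.cells[:, :4]]  # (nc, 4, 3)
        jac = np.swapaxes(verts[:, 1:] - verts[:, :1], 1, 2)  # (nc, 3, 3) dX/dxi
        self.detJ = np.linalg.det(jac)
        if np.any(self.detJ <= 0):
            raise ValueError("negative reference element volumes")
        jinv = np.linalg.inv(jac)
        # dN/dX[c, q, a, J] = dN_dxi[q, a, k] * jinv[c, k, J]
        self.dNdX = np.einsum("qak,ckJ->cqaJ", dN_dxi, jinv)
        self.quad_x = np.einsum("qa,caJ->cqJ", self.Np2, self.nodes[mesh.cells])

        f_q = np.einsum("qa,caI->cqI", self.Np2, directions[mesh.cells])
        f_q /= np.linalg.norm(f_q, axis=-1, keepdims=True)
        self.frames = minimal_rotation_from_x(f_q.reshape(-1, 3)).reshape(
            mesh.n_cells, len(wq), 3, 3
        )
        self.W = exponent_weights(self.material)

        nu = 3 * mesh.n_nodes
        self.n_dofs = nu + mesh.n_pressure
        edofs_u = (3 * mesh.cells[:, :, None] + np.arange(3)).reshape(mesh.n_cells, 30)
        edofs_p = nu + mesh.vertex_cells
        self.edofs = np.concatenate([edofs_u, edofs_p], axis=1)  # (nc, 34)
        self._rows = np.repeat(self.edofs, 34, axis=1).ravel()
        self._cols = np.tile(self.edofs, (1, 34)).ravel()

    def _setup_bcs(self) -> None:
        mesh, cfg = self.mesh, self.config
        lx = float(mesh.dims[0])
        delta = cfg.fraction * lx
        sign = -1.0 if cfg.mode == "shorten" else 1.0
        xmin = mesh.boundary_nodes("x_min")
        xmax = mesh.boundary_nodes("x_max")
        dofs, vals = [], []

        def add(node_ids, comp, value):
            dofs.append(3 * np.asarray(node_ids) + comp)
            vals.append(np.full(len(np.atleast_1d(node_ids)), float(value)))

        if self.end_constraint == "clamped":
            # full-vector Dirichlet on both end faces (rotated if requested)
            for nodes_face, ux in ((xmin, -sign * delta / 2), (xmax, sign * delta / 2)):
                vec = np.array([ux, 0.0, 0.0])
                if self.rotation is not None:
                    vec = self.rotation @ vec
                for comp in range(3):
                    add(nodes_face, comp, vec[comp])
        else:
            add(xmin, 0, -sign * delta / 2)
            add(xmax, 0, sign * delta / 2)
            # minimal rigid-body pins on the centreline (zero displacement in
            # the homogeneous solution, so they do not disturb it)
            yc, zc, lz = mesh.dims[1] / 2, mesh.dims[2] / 2, mesh.dims[2]

            def node_at(x, y, z):
                d = np.linalg.norm(self.mesh.nodes - np.array([x, y, z]), axis=1)
                i = int(np.argmin(d))
                if d[i] > 1e-6:
                    raise ValueError("pin location is not a mesh node (use even subdivisions)")
                return i

            add([node_at(0, yc, zc)], 1, 0.0)
            add([node_at(0, yc, zc)], 2, 0.0)
            add([node_at(lx, yc, zc)], 1, 0.0)
            add([node_at(lx, yc, zc)], 2, 0.0)
            add([node_at(0, yc, lz)], 1, 0.0)  # kills rotation about x
        self.bc_dofs = np.concatenate(dofs)
        self.bc_vals = np.concatenate(vals)
        free = np.ones(self.n_dofs, dtype=bool)
        free[self.bc_dofs] = False
        self.free = np.nonzero(free)[0]

    # ------------------------------------------------------- element kernels
    def _element_residual(self, ue: np.ndarray, pe: np.ndarray) -> np.ndarray:
        """Exact element residual, vectorised over cells: (..., nc, 34).

        Leading batch axes on (ue, pe) broadcast against the per-cell
        geometry, which lets the finite-difference tangent evaluate all dof
        perturbations in one pass.
        """
        batch = ue.shape[:-3]
        nc = self.mesh.n_cells
        r = np.zeros(batch + (nc, 34))
        c1, W = self.material.c1, self.W
        eye = np.eye(3)
        for q, w in enumerate(self.wq):
            dN = self.dNdX[:, q]  # (nc, 10, 3)
            G = np.einsum("...cai,caJ->...ciJ", ue, dN)
            F = eye + G
            J = np.linalg.det(F)
            if np.any(J <= 0):
                raise ElementInversionError("element inversion (J <= 0)")
            C = np.einsum("...ckI,...ckJ->...cIJ", F, F)
            E = 0.5 * (C - eye)
            R = self.frames[:, q]
            Efib = np.einsum("cIa,...cIJ,cJb->...cab", R, E, R)
            Q = np.einsum("ab,...cab->...c", W, Efib**2)
            Sfib = c1 * np.exp(Q)[..., None, None] * W * Efib
            S = np.einsum("cIa,...cab,cJb->...cIJ", R, Sfib, R)
            p = pe @ self.Np1[q]
            Cinv = np.linalg.inv(C)
            S = S + (p * J)[..., None, None] * Cinv
            P = np.einsum("...ciJ,...cJK->...ciK", F, S)
            scale = (w * self.detJ / 6.0)[:, None]
            r[..., :30] += (
                np.einsum("...ciJ,caJ->...cai", P, dN).reshape(batch + (nc, 30)) * scale
            )
            r[..., 30:] += ((J - 1.0)[..., None] * self.Np1[q]) * scale
        return r

    def _element_jacobian(self, ue: np.ndarray, pe: np.ndarray) -> np.ndarray:
        """Finite-difference element tangent (nc, 34, 34) about (ue, pe)."""
        nc = self.mesh.n_cells
        eps = 1e-6
        ustack = np.broadcast_to(ue, (35, nc, 10, 3)).copy()
        pstack = np.broadcast_to(pe, (35, nc, 4)).copy()
        for d in range(30):
            a, i = divmod(d, 3)
            ustack[1 + d, :, a, i] += eps
        for d in range(4):
            pstack[31 + d, :, d] += eps
        r = self._element_residual(ustack, pstack)  # (35, nc, 34)
        return np.moveaxis((r[1:] - r[0]) / eps, 0, -1)  # (nc, 34, 34)

    def _gather(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        u = x[: 3 * self.mesh.n_nodes].reshape(-1, 3)
        p = x[3 * self.mesh.n_nodes :]
        return u[self.mesh.cells], p[self.mesh.vertex_cells]

    def assemble_residual(self, x: np.ndarray) -> np.ndarray:
        r = np.zeros(self.n_dofs)
        re = self._element_residual(*self._gather(x))
        np.add.at(r, self.edofs.ravel(), re.ravel())
        return r

    def assemble_jacobian(self, x: np.ndarray) -> sp.csr_matrix:
        Ke = self._element_jacobian(*self._gather(x))
        K = sp.coo_matrix(
            (Ke.ravel(), (self._rows, self._cols)), shape=(self.n_dofs, self.n_dofs)
        )
        return K.tocsr()

    # ---------------------------------------------------------------- solve
    def fit(self) -> "ContractionResults":
        """Run the incremental Newton solve and return the results object."""
        cfg = self.config
        x = np.zeros(self.n_dofs)
        records: list[_ConvergenceRecord] = []
        states = [x.copy()]
        targets = np.round(
            np.arange(cfg.increment, cfg.fraction + cfg.increment / 2, cfg.increment), 12
        )
        t_prev = 0.0
        t0 = time.time()
        for target in targets:
            x, rec = self._advance(x, t_prev, float(target))
            states.append(x.copy())
            records.append(rec)
            t_prev = float(target)
            logger.info(
                "step to %.0f%%: %d Newton iterations, |R| = %.2e",
                100 * target / cfg.fraction * cfg.fraction,
                rec.iterations,
                rec.residual,
            )
        logger.info("solve completed in %.1f s", time.time() - t0)
        return ContractionResults(self, np.array(targets), states, records)

    def _advance(self, x, t_from: float, t_to: float, depth: int = 0):
        try:
            return self._newton(x, t_to, substeps=depth)
        except (ElementInversionError, _NewtonFailure) as err:
            if depth >= self.config.max_halvings:
                raise RuntimeError(
                    f"increment to {t_to:.4f} failed after "
                    f"{self.config.max_halvings} halvings: {err}"
                ) from err
            mid = 0.5 * (t_from + t_to)
            logger.info("increment cut: retrying via %.4f", mid)
            x_mid, _ = self._advance(x, t_from, mid, depth + 1)
            return self._advance(x_mid, mid, t_to, depth + 1)

    def _newton(self, x0: np.ndarray, target: float, substeps: int = 0):
        cfg = self.config
        x = x0.copy()
        x[self.bc_dofs] = (target / cfg.fraction) * self.bc_vals
        scale = max(cfg.fraction * float(self.mesh.dims[0]), 1.0)
        res_norm = inc_norm = np.inf
        res0 = None
        for it in range(1, cfg.max_newton + 1):
            r = self.assemble_residual(x)[self.free]
            res_norm = np.linalg.norm(r)
            if res0 is None:
                res0 = max(res_norm, 1e-300)
            elif res_norm <= cfg.newton_tol * res0:
                # relative residual drop: converged without a further solve
                return x, _ConvergenceRecord(
                    target, it - 1, float(res_norm), float(inc_norm), substeps
                )
            K = self.assemble_jacobian(x)[self.free][:, self.free]
            dx = spla.spsolve(K.tocsc(), -r)
            if not np.all(np.isfinite(dx)):
                raise _NewtonFailure("singular linearised system")
            x[self.free] += dx
            inc_norm = np.linalg.norm(dx) / scale
            if inc_norm < cfg.newton_tol:
                r = self.assemble_residual(x)[self.free]
                return x, _ConvergenceRecord(
                    target, it, float(np.linalg.norm(r)), float(inc_norm), substeps
                )
        raise _NewtonFailure(
            f"no convergence in {cfg.max_newton} iterations (|du| = {inc_norm:.2e})"
        )


class _NewtonFailure(RuntimeError):
    pass


def homogeneous_uniaxial_response(
    stretch: float, params: MaterialParams
) -> dict[str, float]:
    """Closed-form incompressible uniaxial Guccione state at fibre stretch lambda.

    Deformation F = diag(lambda, 1/sqrt(lambda), 1/sqrt(lambda)); the pressure
    follows from the traction-free lateral surfaces.  Returns the fibre-frame
    stresses in kPa: ``sigma_axial`` is the pressure-omitted axial Cauchy
    stress (the reported quantity), ``sigma_axial_total`` includes pressure,
    ``pressure`` the hydrostatic multiplier.
    """
    lam = float(stretch)
    if lam <= 0:
        raise ValueError("stretch must be positive")
    mu2 = 1.0 / lam
    e_ff = 0.5 * (lam**2 - 1.0)
    e_tt = 0.5 * (mu2 - 1.0)
    q = params.b_f * e_ff**2 + 2.0 * params.b_t * e_tt**2
    s_ff = params.c1 * np.exp(q) * params.b_f * e_ff
    s_tt = params.c1 * np.exp(q) * params.b_t * e_tt
    sigma_axial = lam**2 * s_ff
    sigma_trans = mu2 * s_tt
    pressure = -sigma_trans  # total lateral stress vanishes
    return {
        "stretch": lam,
        "sigma_axial": float(sigma_axial),
        "sigma_transverse": float(sigma_trans),
        "pressure": float(pressure),
        "sigma_axial_total": float(sigma_axial + pressure),
    }


def convergence_study(
    dims=(11.0, 11.0, 5.0),
    levels=((4, 4, 2), (6, 6, 2), (8, 8, 4)),
    fibre_field_factory=None,
    interior_fraction: float = 0.9,
    **model_kw,
):
    """Mesh-refinement helper: interior mean stresses per resolution level.

    Runs the contraction at each subdivision level and reports the interior
    mean Cauchy components with the relative change of the axial component
    between consecutive levels, the quantity used to pick the working
    resolution.  Returns a pandas DataFrame (one row per level).
    """
    import pandas as pd

    from .fibres import FibreField
    from .mesh import build_prism_mesh

    rows = []
    prev = None
    for sub in levels:
        mesh = build_prism_mesh(dims, sub)
        field = (
            FibreField.uniaxial(mesh.n_nodes)
            if fibre_field_factory is None
            else fibre_field_factory(mesh)
        )
        res = ContractionModel(mesh, field, **model_kw).fit()
        from .analysis import interior_mean_stress

        m = interior_mean_stress(res, interior_fraction=interior_fraction).loc[0]
        row = {"subdivisions": sub, "n_cells": mesh.n_cells, "n_dofs": res.model.n_dofs}
        row.update({k: m[k] for k in m.index if k.startswith("sigma")})
        row["rel_change_sigma_xx"] = (
            abs(row["sigma_xx"] - prev) / abs(prev) if prev is not None else np.nan
        )
        prev = row["sigma_xx"]
        rows.append(row)
    return pd.DataFrame(rows)


class ContractionResults:
    """Converged displacement/pressure states over the displacement increments.

    ``displacement(step)`` and ``pressure(step)`` return nodal fields (step 0
    is the stress-free reference; negative indices count from the last
    increment).  Kinematic tensors and stresses are evaluated at the
    quadrature points of each cell.
    """

    def __init__(self, model, targets, states, records) -> None:
        self.model = model
        self.targets = targets  # displacement fractions per recorded step
        self._states = states  # len = n_steps + 1 (includes reference)
        self.records = records

    @property
    def n_steps(self) -> int:
        return len(self.targets)

    def _state(self, step: int) -> np.ndarray:
        return self._states[step if step >= 0 else len(self._states) + step]

    def displacement(self, step: int = -1) -> np.ndarray:
        return self._state(step)[: 3 * self.model.mesh.n_nodes].reshape(-1, 3)

    def pressure(self, step: int = -1) -> np.ndarray:
        return self._state(step)[3 * self.model.mesh.n_nodes :]

    def kinematics(self, step: int = -1) -> dict[str, np.ndarray]:
        """F, C, E (Cartesian), J at quadrature points: shapes (nc, nq, 3, 3)."""
        m = self.model
        ue, _ = m._gather(self._state(step))
        eye = np.eye(3)
        G = np.einsum("cai,cqaJ->cqiJ", ue, m.dNdX)
        F = eye + G
        C = np.einsum("cqkI,cqkJ->cqIJ", F, F)
        E = 0.5 * (C - eye)
        return {"F": F, "C": C, "E": E, "J": np.linalg.det(F)}

    def cauchy_stress(self, step: int = -1, include_pressure: bool = False) -> np.ndarray:
        """Cauchy stress at quadrature points, (nc, nq, 3, 3).

        The hydrostatic pressure term is omitted by default, matching the
        stress-extraction convention of the analysis; pass
        ``include_pressure=True`` for the total stress.
        """
        m = self.model
        kin = self.kinematics(step)
        F, E, J = kin["F"], kin["E"], kin["J"]
        if np.any(J <= 0):
            raise ValueError("invalid state: J <= 0")
        R = m.frames
        Efib = np.einsum("cqIa,cqIJ,cqJb->cqab", R, E, R)
        Q = np.einsum("ab,cqab->cq", m.W, Efib**2)
        Sfib = m.material.c1 * np.exp(Q)[..., None, None] * m.W * Efib
        S = np.einsum("cqIa,cqab,cqJb->cqIJ", R, Sfib, R)
        sigma = np.einsum("cqiI,cqIJ,cqjJ->cqij", F, S, F) / J[..., None, None]
        if include_pressure:
            _, pe = m._gather(self._state(step))
            p = np.einsum("cd,qd->cq", pe, m.Np1)
            sigma = sigma + p[..., None, None] * np.eye(3)
        return sigma

    def quadrature_points(self) -> np.ndarray:
        """Physical quadrature-point positions (nc, nq, 3), reference config."""
        return self.model.quad_x

    def quadrature_weights(self) -> np.ndarray:
        """Integration weights (nc, nq) summing to the mesh volume."""
        return self.model.wq[None, :] * self.model.detJ[:, None] / 6.0

    def incompressibility_error(self, step: int = -1, interior_fraction: float = 0.9):
        """max |J - 1| over quadrature points of the interior box."""
        from .analysis import interior_mask

        J = self.kinematics(step)["J"]
        mask = interior_mask(self.quadrature_points(), self.model.mesh.dims, interior_fraction)
        return float(np.abs(J[mask] - 1.0).max())

    def summary(self) -> str:
        from .analysis import interior_mean_stress

        m = self.model
        lines = [
            "Incompressible Guccione contraction",
            "=" * 51,
            f"mesh: {m.mesh.n_cells} quadratic tets, {m.mesh.n_nodes} nodes, "
            f"{m.n_dofs} dofs",
            f"region: {m.mesh.dims[0]:g} x {m.mesh.dims[1]:g} x {m.mesh.dims[2]:g} um, "
            f"constraint: {m.end_constraint}",
            f"material: c1={m.material.c1:g} kPa, b_f={m.material.b_f:g}, "
            f"b_t=b_s={m.material.b_t:g}",
            f"loading: {m.config.mode} to {100 * m.config.fraction:.0f}% in "
            f"{self.n_steps} increments",
            "-" * 51,
            "step  frac   iters  |R|        interior stress (kPa)",
            "                               s_xx     s_xz     s_yz",
        ]
        for k, rec in enumerate(self.records):
            mean = interior_mean_stress(self, step=k + 1 - len(self._states)).loc[0]
            lines.append(
                f"{k + 1:>4}  {rec.target:.2f}  {rec.iterations:>4}   "
                f"{rec.residual:8.1e}  {mean['sigma_xx']:7.3f}  "
                f"{mean['sigma_xz']:7.3f}  {mean['sigma_yz']:7.3f}"
            )
        lines.append("-" * 51)
        lines.append(
            f"max |J-1| (interior, final step): {self.incompressibility_error():.2e}"
        )
        return "\n".join(lines)
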
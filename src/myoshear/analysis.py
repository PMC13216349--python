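"""Post-processing of contraction solutions into the result quantities.

These routines turn a :class:`~myoshear.solver.ContractionResults` into the
summary measures of the study: boundary displacement profiles, internal
rotation in the y-z plane about the contraction axis, interior-averaged
Cauchy stress components (boundary layers excluded), shear trends over the
loading history, shear-versus-orientation regressions, and pairwise cluster
comparisons of orientation angles.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sstats

logger = logging.getLogger(__name__)

__all__ = [
    "interior_mask",
    "interior_mean_stress",
    "yz_rotation",
    "boundary_profiles",
    "shear_trend",
    "orientation_stress_regression",
    "cluster_compare",
]

_COMPONENTS = {
    "sigma_xx": (0, 0),
    "sigma_yy": (1, 1),
    "sigma_zz": (2, 2),
    "sigma_xy": (0, 1),
    "sigma_xz": (0, 2),
    "sigma_yz": (1, 2),
}


def interior_mask(
    points: np.ndarray, dims: np.ndarray, interior_fraction: float = 0.9
) -> np.ndarray:
    """Boolean mask of points inside the centred box scaled per axis.

    ``interior_fraction`` = 0.9 keeps the central 90% of each axis (72.9% of
    the volume), the bounding used to exclude boundary artefacts.
    """
    if not (0.0 < interior_fraction <= 1.0):
        raise ValueError("interior_fraction must lie in (0, 1]")
    dims = np.asarray(dims, dtype=float)
    centre = dims / 2
    half = interior_fraction * dims / 2
    return np.all(np.abs(points - centre) <= half, axis=-1)


def interior_mean_stress(
    results,
    step: int = -1,
    interior_fraction: float = 0.9,
    include_pressure: bool = False,
) -> pd.DataFrame:
    """Volume-weighted interior means of the Cauchy stress components (kPa).

    One row per requested step (``step=None`` gives every increment).  Means
    are taken over quadrature points of the interior box, weighted by their
    integration weights.
    """
    steps = range(1, results.n_steps + 1) if step is None else [step]
    pts = results.quadrature_points()
    wq = results.quadrature_weights()
    mask = interior_mask(pts, results.model.mesh.dims, interior_fraction)
    w = np.where(mask, wq, 0.0)
    wsum = w.sum()
    rows = []
    for s in steps:
        sigma = results.cauchy_stress(step=s, include_pressure=include_pressure)
        row = {
            "step": s if s >= 0 else results.n_steps + 1 + s,
            "fraction": float(results.targets[s - 1 if s >= 1 else s]),
            "interior_fraction": interior_fraction,
        }
        for name, (i, j) in _COMPONENTS.items():
            row[name] = float((sigma[..., i, j] * w).sum() / wsum)
        rows.append(row)
    return pd.DataFrame(rows)


def yz_rotation(results, step: int = -1, plane_x: float | None = None) -> pd.DataFrame:
    """Signed in-plane rotation (degrees) of nodes on an x-plane about the x axis.

    Node positions on the plane are centred on the plane centroid; the
    rotation is the signed angle from the centred undeformed position to the
    centred deformed position, measured in the y-z plane (counter-clockwise
    positive when viewed from +x).  Nodes at the centroid itself have no
    defined angle and are excluded (logged).  A rigid rotation about x is
    reproduced exactly; radial motion gives zero.
    """
    mesh = results.model.mesh
    nodes = results.model.nodes
    if plane_x is None:
        plane_x = float(mesh.dims[0]) / 2
    on_plane = np.abs(nodes[:, 0] - plane_x) < 1e-9
    if not np.any(on_plane):
        # fall back to the plane of nodes nearest the requested position
        dist = np.abs(nodes[:, 0] - plane_x)
        on_plane = dist < dist.min() + 1e-9
        logger.info("yz_rotation: no nodes at x=%g, using nearest plane", plane_x)
    u = results.displacement(step)[on_plane]
    yz0 = nodes[on_plane][:, 1:] - nodes[on_plane][:, 1:].mean(axis=0)
    yz1 = yz0 + u[:, 1:] - u[:, 1:].mean(axis=0)
    r0 = np.linalg.norm(yz0, axis=1)
    ok = r0 > 1e-12
    if np.any(~ok):
        logger.info("yz_rotation: %d nodes at the plane centroid excluded", (~ok).sum())
    cross = yz0[ok, 0] * yz1[ok, 1] - yz0[ok, 1] * yz1[ok, 0]
    dot = np.einsum("ij,ij->i", yz0[ok], yz1[ok])
    angle = np.degrees(np.arctan2(cross, dot))
    out = pd.DataFrame(
        {
            "y": nodes[on_plane][ok][:, 1],
            "z": nodes[on_plane][ok][:, 2],
            "rotation_deg": angle,
        }
    )
    return out


def boundary_profiles(
    results, step: int = -1, axis: str = "z", n_slices: int = 3
) -> pd.DataFrame:
    """Boundary displacement traces per slice, overlay-ready (Fig.-5 style).

    For ``axis='z'``: nodes of the z-min and z-max faces are split into
    ``n_slices`` bands across y, and the z displacement is traced along x for
    each band (and symmetrically for ``axis='y'`` with bands across z).
    Returns a tidy frame with columns face, slice, x, displacement.
    """
    mesh = results.model.mesh
    nodes = results.model.nodes
    comp = {"y": 1, "z": 2}[axis]
    band_axis = {"y": 2, "z": 1}[axis]
    u = results.displacement(step)
    frames = []
    for face in (f"{axis}_min", f"{axis}_max"):
        ids = mesh.boundary_nodes(face)
        if ids.size == 0:
            logger.warning("boundary_profiles: empty face %s", face)
            continue
        band_pos = nodes[ids, band_axis]
        edges = np.linspace(band_pos.min(), band_pos.max() + 1e-12, n_slices + 1)
        band = np.clip(np.digitize(band_pos, edges) - 1, 0, n_slices - 1)
        for b in range(n_slices):
            sel = ids[band == b]
            if sel.size == 0:
                logger.warning("boundary_profiles: empty slice %d on %s", b, face)
                continue
            order = np.argsort(nodes[sel, 0])
            frames.append(
                pd.DataFrame(
                    {
                        "face": face,
                        "slice": b,
                        "x": nodes[sel, 0][order],
                        "displacement": u[sel, comp][order],
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def shear_trend(results, interior_fraction: float = 0.9) -> pd.DataFrame:
    """Interior mean stress components versus displacement fraction, all steps."""
    if results.n_steps < 1:
        raise ValueError("no increments recorded")
    trend = interior_mean_stress(results, step=None, interior_fraction=interior_fraction)
    ref = {name: 0.0 for name in _COMPONENTS}
    ref.update(step=0, fraction=0.0, interior_fraction=interior_fraction)
    return pd.concat([pd.DataFrame([ref]), trend], ignore_index=True)


def orientation_stress_regression(
    region_table: pd.DataFrame,
    x: str = "mean_theta",
    y: str = "mean_sigma_xz",
    group: str | None = None,
) -> pd.DataFrame:
    """Ordinary least squares of regional mean shear on mean orientation.

    ``region_table`` has one row per region; ``group`` optionally names a
    column of cluster labels (each group fitted separately, regions equally
    weighted).  Returns slope, intercept and Pearson R per group.  Groups
    with fewer than 3 regions or a zero-variance predictor are flagged
    unfittable rather than raising.
    """
    rows = []
    groups = [("all", region_table)] if group is None else list(region_table.groupby(group))
    for label, sub in groups:
        xs = sub[x].to_numpy(dtype=float)
        ys = sub[y].to_numpy(dtype=float)
        row = {"group": label, "n": len(sub), "x": x, "y": y}
        if len(sub) < 3 or np.std(xs) == 0:
            row.update(slope=np.nan, intercept=np.nan, pearson_r=np.nan, fitted=False)
        else:
            fit = sstats.linregress(xs, ys)
            row.update(
                slope=float(fit.slope),
                intercept=float(fit.intercept),
                pearson_r=float(fit.rvalue),
                fitted=True,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def cluster_compare(
    clusters: dict[str, pd.DataFrame],
    angle_columns: tuple[str, ...] = ("theta", "azimuth", "elevation"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise Welch t-tests of angle distributions across region clusters.

    ``clusters`` maps labels (e.g. upper/lower/overlap) to orientation-record
    tables.  Each angle column is compared for every unordered pair; no
    multiple-testing correction is applied.  Pairs with a degenerate sample
    (fewer than 2 records, or zero spread in both) are flagged untestable.
    """
    labels = list(clusters)
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            for col in angle_columns:
                xa = clusters[a][col].to_numpy(dtype=float)
                xb = clusters[b][col].to_numpy(dtype=float)
                row = {"pair": f"{a}|{b}", "angle": col, "n_a": xa.size, "n_b": xb.size}
                if xa.size < 2 or xb.size < 2 or (xa.std() == 0 and xb.std() == 0):
                    row.update(p_value=np.nan, testable=False, significant=False)
                else:
                    p = float(sstats.ttest_ind(xa, xb, equal_var=False).pvalue)
                    row.update(p_value=p, testable=True, significant=bool(p < alpha))
                rows.append(row)
    return pd.DataFrame(rows)
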
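"""Per-instance z-disc orientation morphometry.

Each segmented z-disc is an instance label in a 3D voxel volume.  Because the
z-disc sits perpendicular to the local myofibril, the disc's plane normal is a
proxy for the local fibre direction.  The normal is recovered as the third
principal component of the instance's voxel cloud (the first two components
span the disc face); the cell's contraction axis is the first principal
component of the pooled cloud.  All principal-component analysis is carried
out on physical coordinates (voxel indices scaled by the anisotropic voxel
size), never on raw indices.

Angle conventions, in the frame where the contraction axis is +x and every
normal is sign-fixed to a non-negative x component:

* azimuth   -- signed angle of the (x, y) projection of the normal,
* elevation -- signed angle of the (x, z) projection,
* theta     -- spherical deviation: magnitude arccos(n . axis), with
  sign(theta) = sign(elevation).  The magnitude alone is unsigned; attaching
  the elevation sign yields the symmetric-about-zero distribution used for
  the population statistics.

All angles are reported in degrees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from skimage.measure import regionprops
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "LabelVolume",
    "ZDiscInstance",
    "OrientationStats",
    "RegionSpec",
    "extract_instances",
    "compute_contraction_axis",
    "instance_normal",
    "signed_angles",
    "orientation_records",
    "global_stats",
    "regional_tests",
    "track_spacing",
    "analyse_volume",
]


@dataclass
class LabelVolume:
    """3D integer instance-label grid with physical voxel spacing (um)."""

    labels: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if np.issubdtype(self.labels.dtype, np.floating):
            raise ValueError("labels must be integer-valued")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if self.voxel_size.shape != (3,) or np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be three positive lengths")
        self.origin = (
            np.zeros(3) if self.origin is None else np.asarray(self.origin, dtype=float)
        )

    @property
    def physical_dims(self) -> np.ndarray:
        return np.array(self.labels.shape) * self.voxel_size


@dataclass
class ZDiscInstance:
    """One z-disc: physical voxel cloud and its principal structure."""

    instance_id: int
    coords: np.ndarray  # (n, 3) physical positions (um)
    centroid: np.ndarray  # (3,) um
    voxel_count: int
    principal_axes: np.ndarray  # (3, 3), rows = components, variance-ordered
    variances: np.ndarray  # (3,) non-increasing


@dataclass
class OrientationStats:
    """Population summary of signed spherical deviation angles (degrees)."""

    n: int
    mean: float
    sd: float
    skew: float
    kurtosis_fisher: float
    kurtosis_pearson: float
    bin_edges: np.ndarray
    counts: np.ndarray


@dataclass(frozen=True)
class RegionSpec:
    """Axis-aligned analysis box (default test-region size 11 x 11 x 5 um)."""

    region_id: str
    min_corner: tuple[float, float, float]
    max_corner: tuple[float, float, float]

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        lo = np.asarray(self.min_corner)
        hi = np.asarray(self.max_corner)
        if np.any(hi <= lo):
            raise ValueError("region max corner must exceed min corner")
        return np.all((p >= lo) & (p <= hi), axis=1)


def extract_instances(volume: LabelVolume, min_voxels: int = 10) -> list[ZDiscInstance]:
    """Extract one :class:`ZDiscInstance` per label with >= ``min_voxels`` voxels.

    Geometry (centroid, principal axes) is computed on physical coordinates.
    Undersized labels are dropped and counted in the log.
    """
    props = regionprops(volume.labels)
    instances: list[ZDiscInstance] = []
    dropped = 0
    for rp in props:
        if rp.num_pixels < min_voxels:
            dropped += 1
            continue
        coords = rp.coords * volume.voxel_size + volume.origin
        pca = PCA(n_components=3)
        pca.fit(coords)
        instances.append(
            ZDiscInstance(
                instance_id=int(rp.label),
                coords=coords,
                centroid=coords.mean(axis=0),
                voxel_count=int(rp.num_pixels),
                principal_axes=pca.components_.copy(),
                variances=pca.explained_variance_.copy(),
            )
        )
    if dropped:
        logger.info("extract_instances: dropped %d labels below %d voxels", dropped, min_voxels)
    return instances


def compute_contraction_axis(instances: list[ZDiscInstance]) -> np.ndarray:
    """First principal component of the pooled voxel cloud (the cell long axis).

    Sign-fixed to a non-negative x component.  Raises if the cloud has no
    dominant direction (isotropic to within 1%).
    """
    if len(instances) < 2:
        raise ValueError("need at least two instances to define a contraction axis")
    cloud = np.concatenate([inst.coords for inst in instances], axis=0)
    pca = PCA(n_components=3)
    pca.fit(cloud)
    var = pca.explained_variance_
    if var[0] < 1.01 * var[1]:
        raise ValueError("degenerate voxel cloud: no dominant principal direction")
    axis = pca.components_[0]
    if axis[0] < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def instance_normal(instance: ZDiscInstance) -> np.ndarray:
    """Disc-plane normal: third principal component, sign-fixed to +x.

    Ties between the two smallest variances (a circular disc face viewed
    edge-on is ambiguous) are broken by preferring the candidate with the
    larger absolute x component; the event is logged.
    """
    var = instance.variances
    if var[1] <= 0 or instance.voxel_count < 3:
        raise ValueError(
            f"instance {instance.instance_id}: voxel cloud is rank-deficient, "
            "no disc plane is defined"
        )
    normal = instance.principal_axes[2]
    rel_gap = (var[1] - var[2]) / var[1]
    if rel_gap < 1e-9:
        cand = instance.principal_axes[1:]
        pick = int(np.argmax(np.abs(cand[:, 0])))
        normal = cand[pick]
        logger.info(
            "instance %d: tied minor variances, tie broken toward larger |x|",
            instance.instance_id,
        )
    if normal[0] < 0:
        normal = -normal
    return normal / np.linalg.norm(normal)


def _axis_frame(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix R with R @ axis = +x (minimal rotation)."""
    from .fibres import minimal_rotation_from_x

    return minimal_rotation_from_x(axis).T


def signed_angles(normal: np.ndarray, axis: np.ndarray) -> tuple[float, float, float]:
    """(theta, azimuth, elevation) in degrees of ``normal`` about ``axis``.

    ``normal`` must already be sign-fixed to the +axis hemisphere.
    """
    normal = np.asarray(normal, dtype=float)
    axis = np.asarray(axis, dtype=float)
    for v in (normal, axis):
        if not np.isclose(np.linalg.norm(v), 1.0, atol=1e-6):
            raise ValueError("normal and axis must be unit vectors")
    n = _axis_frame(axis) @ normal
    azimuth = np.degrees(np.arctan2(n[1], n[0]))
    elevation = np.degrees(np.arctan2(n[2], n[0]))
    theta_mag = np.degrees(np.arccos(np.clip(float(normal @ axis), -1.0, 1.0)))
    sign = 1.0 if elevation >= 0 else -1.0
    return sign * theta_mag, azimuth, elevation


def orientation_records(
    instances: list[ZDiscInstance], axis: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-instance orientation table (normal + signed angles, degrees)."""
    if axis is None:
        axis = compute_contraction_axis(instances)
    rows = []
    for inst in instances:
        n = instance_normal(inst)
        theta, azim, elev = signed_angles(n, axis)
        rows.append(
            {
                "instance_id": inst.instance_id,
                "voxel_count": inst.voxel_count,
                "cx": inst.centroid[0],
                "cy": inst.centroid[1],
                "cz": inst.centroid[2],
                "nx": n[0],
                "ny": n[1],
                "nz": n[2],
                "theta": theta,
                "azimuth": azim,
                "elevation": elev,
            }
        )
    return pd.DataFrame(rows)


def global_stats(theta: np.ndarray, bin_width: float = 1.5) -> OrientationStats:
    """Moments and histogram (default 1.5-degree bins) of signed angles."""
    theta = np.asarray(theta, dtype=float)
    if theta.size == 0:
        raise ValueError("no orientation records")
    lo = np.floor(theta.min() / bin_width) * bin_width
    hi = np.ceil(theta.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(theta, bins=edges)
    kurt_f = float(sstats.kurtosis(theta, fisher=True)) if theta.size > 3 else float("nan")
    return OrientationStats(
        n=int(theta.size),
        mean=float(theta.mean()),
        sd=float(theta.std(ddof=1)) if theta.size > 1 else 0.0,
        skew=float(sstats.skew(theta)) if theta.size > 2 else float("nan"),
        kurtosis_fisher=kurt_f,
        kurtosis_pearson=kurt_f + 3.0,
        bin_edges=edges,
        counts=counts,
    )


def regional_tests(
    region_angles: dict[str, np.ndarray],
    global_angles: np.ndarray,
    alpha: float = 0.05,
    min_region_n: int = 5,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U and Welch's t of each region against the global set.

    A region is flagged significant only when *both* tests give p < alpha
    (conservative combination; no multiple-testing correction is applied).
    Degenerate regions (n < 2 or zero spread in both samples) are flagged
    untestable rather than raising.
    """
    global_angles = np.asarray(global_angles, dtype=float)
    rows = []
    for rid, ang in region_angles.items():
        ang = np.asarray(ang, dtype=float)
        row = {
            "region_id": rid,
            "n": int(ang.size),
            "p_mannwhitney": np.nan,
            "p_welch": np.nan,
            "testable": False,
            "significant": False,
        }
        if ang.size < min_region_n:
            logger.info("region %s: n=%d below minimum %d", rid, ang.size, min_region_n)
        if ang.size >= 2 and (ang.std() > 0 or global_angles.std() > 0):
            try:
                p_u = sstats.mannwhitneyu(ang, global_angles, alternative="two-sided").pvalue
                p_t = sstats.ttest_ind(ang, global_angles, equal_var=False).pvalue
            except ValueError:
                p_u = p_t = np.nan
            if np.isfinite(p_u) and np.isfinite(p_t):
                row.update(
                    p_mannwhitney=float(p_u),
                    p_welch=float(p_t),
                    testable=True,
                    significant=bool(p_u < alpha and p_t < alpha),
                )
        rows.append(row)
    return pd.DataFrame(rows)


def track_spacing(
    centroids: np.ndarray, track_ids: np.ndarray, axis: np.ndarray | None = None
) -> dict:
    """Consecutive along-axis centroid separations within each myofibril track.

    Returns a dict with keys ``mean``, ``sd``, ``n_gaps``, ``n_skipped_tracks``
    and ``per_track`` (track id -> array of separations, um).
    """
    centroids = np.asarray(centroids, dtype=float)
    track_ids = np.asarray(track_ids)
    axis = np.array([1.0, 0.0, 0.0]) if axis is None else np.asarray(axis, dtype=float)
    proj = centroids @ (axis / np.linalg.norm(axis))
    per_track: dict = {}
    skipped = 0
    for tid in np.unique(track_ids):
        s = np.sort(proj[track_ids == tid])
        if s.size < 2:
            skipped += 1
            continue
        per_track[tid] = np.diff(s)
    if skipped:
        logger.info("track_spacing: %d single-disc tracks skipped", skipped)
    gaps = (
        np.concatenate(list(per_track.values())) if per_track else np.empty(0)
    )
    return {
        "mean": float(gaps.mean()) if gaps.size else float("nan"),
        "sd": float(gaps.std(ddof=1)) if gaps.size > 1 else float("nan"),
        "n_gaps": int(gaps.size),
        "n_skipped_tracks": skipped,
        "per_track": per_track,
    }


def analyse_volume(
    volume: LabelVolume, min_voxels: int = 10, axis: np.ndarray | None = None
) -> tuple[pd.DataFrame, OrientationStats, np.ndarray]:
    """Full morphometry pass: instances -> axis -> records -> global stats.

    Returns (records, stats, contraction_axis).
    """
    instances = extract_instances(volume, min_voxels=min_voxels)
    if not instances:
        return pd.DataFrame(), None, None
    if axis is None:
        axis = compute_contraction_axis(instances)
    records = orientation_records(instances, axis=axis)
    stats = global_stats(records["theta"].to_numpy())
    return records, stats, axis
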
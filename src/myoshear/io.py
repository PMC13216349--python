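"""Readers and writers for the pipeline's standard formats.

* Label volumes: multipage TIFF (integer labels) with a JSON sidecar carrying
  the physical voxel size (um), origin and provenance (seed, parameters).
  Angles are meaningless without the physical scaling, so a missing or
  incomplete sidecar is a hard error on read.
* Tables (orientation records, ground truth, stress summaries): CSV.
* Meshes and nodal fields: legacy VTK ASCII unstructured grids (quadratic
  tetrahedra), viewable in ParaView.

Round trips (write then read) are lossless for label volumes and tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .morphometry import LabelVolume

__all__ = [
    "write_label_volume",
    "read_label_volume",
    "write_table",
    "read_table",
    "write_vtk",
]


def write_label_volume(
    path: str | Path, volume: LabelVolume, metadata: dict | None = None
) -> None:
    """Write labels as multipage TIFF plus a ``<stem>.json`` sidecar."""
    path = Path(path)
    tifffile.imwrite(path, volume.labels, photometric="minisblack")
    sidecar = {
        "voxel_size_um": [float(v) for v in volume.voxel_size],
        "origin_um": [float(v) for v in volume.origin],
        "shape": [int(s) for s in volume.labels.shape],
        "dtype": str(volume.labels.dtype),
    }
    if metadata:
        sidecar["metadata"] = metadata
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_label_volume(path: str | Path) -> LabelVolume:
    """Read a label TIFF; the JSON sidecar with the voxel size is mandatory."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"{sidecar_path} not found: label volumes require a sidecar with "
            "the physical voxel size (angles are meaningless without it)"
        )
    sidecar = json.loads(sidecar_path.read_text())
    if "voxel_size_um" not in sidecar:
        raise ValueError(f"{sidecar_path}: sidecar lacks 'voxel_size_um'")
    labels = tifffile.imread(path)
    return LabelVolume(
        labels=labels,
        voxel_size=np.asarray(sidecar["voxel_size_um"], dtype=float),
        origin=np.asarray(sidecar.get("origin_um", [0.0, 0.0, 0.0]), dtype=float),
    )


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing table: {path}")
    return pd.read_csv(path)


# legacy VTK cell type for the 10-node quadratic tetrahedron
_VTK_QUADRATIC_TETRA = 24


def write_vtk(
    path: str | Path,
    mesh,
    point_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write the mesh (and optional nodal scalar/vector fields) as legacy VTK ASCII.

    ``point_data`` values must have one row per mesh node; 1D arrays become
    SCALARS, (n, 3) arrays become VECTORS.
    """
    path = Path(path)
    lines = [
        "# vtk DataFile Version 3.0",
        "myoshear unstructured grid",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines += [" ".join(f"{v:.10g}" for v in row) for row in mesh.nodes]
    nc = mesh.n_cells
    lines.append(f"CELLS {nc} {nc * 11}")
    lines += ["10 " + " ".join(str(i) for i in cell) for cell in mesh.cells]
    lines.append(f"CELL_TYPES {nc}")
    lines += [str(_VTK_QUADRATIC_TETRA)] * nc
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            if arr.shape[0] != mesh.n_nodes:
                raise ValueError(f"point data '{name}' does not match node count")
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{v:.10g}" for v in arr]
            elif arr.ndim == 2 and arr.shape[1] == 3:
                lines.append(f"VECTORS {name} double")
                lines += [" ".join(f"{v:.10g}" for v in row) for row in arr]
            else:
                raise ValueError(f"point data '{name}' must be (n,) or (n, 3)")
    path.write_text("\n".join(lines) + "\n")
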
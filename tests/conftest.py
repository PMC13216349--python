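"""Shared fixtures: synthetic volumes and contraction solves reused across tests.

The expensive objects (a full-scale synthetic recovery volume and the desk-
resolution clamped contraction) are session-scoped so each is computed once.
"""

from __future__ import annotations

import numpy as np
import pytest

from myoshear.fibres import FibreField
from myoshear.mesh import build_prism_mesh
from myoshear.morphometry import analyse_volume
from myoshear.solver import ContractionModel, SolveConfig
from myoshear.synthetic import SyntheticCellParams, generate_cell_volume

REGION_DIMS = (11.0, 11.0, 5.0)


@pytest.fixture(scope="session")
def recovery_volume():
    """Full-scale synthetic volume (>=1000 discs) plus its morphometry pass."""
    params = SyntheticCellParams(seed=1)
    volume, truth = generate_cell_volume(params)
    records, stats, axis = analyse_volume(volume)
    return {
        "params": params,
        "volume": volume,
        "truth": truth,
        "records": records,
        "stats": stats,
        "axis": axis,
    }


@pytest.fixture(scope="session")
def small_volume():
    """Small synthetic volume for cheap structural tests."""
    params = SyntheticCellParams(
        volume_dims=(12.0, 8.0, 6.0), n_tracks=12, seed=7
    )
    volume, truth = generate_cell_volume(params)
    return {"params": params, "volume": volume, "truth": truth}


@pytest.fixture(scope="session")
def tiny_mesh():
    return build_prism_mesh(REGION_DIMS, (4, 4, 2))


@pytest.fixture(scope="session")
def frictionless_results(tiny_mesh):
    """Uniaxial frictionless-end contraction: the closed-form-matched case."""
    model = ContractionModel(
        tiny_mesh,
        FibreField.uniaxial(tiny_mesh.n_nodes),
        end_constraint="frictionless",
    )
    return model.fit()


@pytest.fixture(scope="session")
def desk_clamped_results():
    """Uniaxial clamped-end contraction at desk resolution (the simulated
    cell-region condition: end faces fixed in y and z)."""
    mesh = build_prism_mesh(REGION_DIMS, (8, 8, 4))
    model = ContractionModel(mesh, FibreField.uniaxial(mesh.n_nodes))
    return model.fit()


def tilted_field(mesh, elevation_deg: float) -> FibreField:
    """Constant fibre field tilted in the x-z plane."""
    z = np.zeros(mesh.n_nodes)
    return FibreField.from_angles(z, z + elevation_deg)


@pytest.fixture(scope="session")
def mirror_runs(tiny_mesh):
    """Clamped contraction with +10 deg, -10 deg, and mixed elevation fields."""
    mesh = tiny_mesh
    out = {}
    for key, elev in (("plus", 10.0), ("minus", -10.0)):
        model = ContractionModel(mesh, tilted_field(mesh, elev))
        out[key] = model.fit()
    yc = mesh.dims[1] / 2
    elevation = 10.0 * np.tanh((mesh.nodes[:, 1] - yc) / 1.0)
    mixed = FibreField.from_angles(np.zeros(mesh.n_nodes), elevation)
    out["mixed"] = ContractionModel(mesh, mixed).fit()
    return out
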
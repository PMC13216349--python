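"""Post-processing: rotation extraction, interior averages, regressions."""

import numpy as np
import pandas as pd
import pytest

from myoshear.analysis import (
    boundary_profiles,
    cluster_compare,
    interior_mask,
    interior_mean_stress,
    orientation_stress_regression,
    shear_trend,
    yz_rotation,
)
from myoshear.mesh import build_prism_mesh


class _StubResults:
    """Minimal results stand-in with a prescribed nodal displacement field."""

    def __init__(self, mesh, displacement):
        class _M:
            pass

        self.model = _M()
        self.model.mesh = mesh
        self.model.nodes = mesh.nodes
        self._u = displacement
        self.n_steps = 1
        self.targets = np.array([1.0])

    def displacement(self, step=-1):
        return self._u


@pytest.fixture(scope="module")
def box_mesh():
    return build_prism_mesh((11, 11, 5), (4, 4, 2))


class TestYZRotation:
    def test_identity_deformation(self, box_mesh):
        res = _StubResults(box_mesh, np.zeros((box_mesh.n_nodes, 3)))
        rot = yz_rotation(res)
        assert np.allclose(rot["rotation_deg"], 0.0, atol=1e-12)

    def test_rigid_rotation_recovered_exactly(self, box_mesh):
        ang = np.radians(15.0)
        c, s = np.cos(ang), np.sin(ang)
        centre = np.array(box_mesh.dims) / 2
        rel = box_mesh.nodes - centre
        u = np.zeros_like(box_mesh.nodes)
        u[:, 1] = c * rel[:, 1] - s * rel[:, 2] - rel[:, 1]
        u[:, 2] = s * rel[:, 1] + c * rel[:, 2] - rel[:, 2]
        rot = yz_rotation(_StubResults(box_mesh, u))
        assert np.allclose(rot["rotation_deg"], 15.0, atol=1e-10)

    def test_rigid_translation_gives_zero(self, box_mesh):
        u = np.tile([0.0, 0.7, -0.3], (box_mesh.n_nodes, 1))
        rot = yz_rotation(_StubResults(box_mesh, u))
        assert np.allclose(rot["rotation_deg"], 0.0, atol=1e-10)

    def test_isotropic_yz_scaling_gives_zero(self, box_mesh):
        centre = np.array(box_mesh.dims) / 2
        rel = box_mesh.nodes - centre
        u = np.zeros_like(box_mesh.nodes)
        u[:, 1:] = 0.15 * rel[:, 1:]  # radial motion in the plane
        rot = yz_rotation(_StubResults(box_mesh, u))
        assert np.allclose(rot["rotation_deg"], 0.0, atol=1e-10)


class _StressStub:
    """Results stand-in with a prescribed stress field at quadrature points."""

    def __init__(self, mesh, sigma_fn, n_steps=1):
        from myoshear.fibres import FibreField
        from myoshear.solver import ContractionModel, SolveConfig

        self._model = ContractionModel(
            mesh, FibreField.uniaxial(mesh.n_nodes), config=SolveConfig()
        )
        self.model = self._model
        self.n_steps = n_steps
        self.targets = np.arange(1, n_steps + 1) * 0.02
        self._fn = sigma_fn

    def quadrature_points(self):
        return self._model.quad_x

    def quadrature_weights(self):
        return self._model.wq[None, :] * self._model.detJ[:, None] / 6.0

    def cauchy_stress(self, step=-1, include_pressure=False):
        pts = self.quadrature_points()
        return self._fn(pts)


class TestInteriorMeanStress:
    def test_constant_field_any_fraction(self, box_mesh):
        const = np.diag([3.0, 2.0, 1.0])

        def fn(pts):
            return np.broadcast_to(const, pts.shape[:2] + (3, 3))

        stub = _StressStub(box_mesh, fn)
        for frac in (0.5, 0.9, 1.0):
            m = interior_mean_stress(stub, interior_fraction=frac).loc[0]
            assert m["sigma_xx"] == pytest.approx(3.0, rel=1e-12)
            assert m["sigma_zz"] == pytest.approx(1.0, rel=1e-12)

    def test_antisymmetric_shear_averages_to_zero(self, box_mesh):
        zc = box_mesh.dims[2] / 2

        def fn(pts):
            s = np.zeros(pts.shape[:2] + (3, 3))
            s[..., 0, 2] = s[..., 2, 0] = pts[..., 2] - zc  # odd in z
            return s

        m = interior_mean_stress(_StressStub(box_mesh, fn)).loc[0]
        assert abs(m["sigma_xz"]) < 1e-12

    def test_invalid_fraction_rejected(self, box_mesh):
        stub = _StressStub(box_mesh, lambda pts: np.zeros(pts.shape[:2] + (3, 3)))
        with pytest.raises(ValueError):
            interior_mean_stress(stub, interior_fraction=0.0)

    def test_interior_mask_volume(self, box_mesh):
        pts = box_mesh.nodes
        mask = interior_mask(pts, box_mesh.dims, 1.0)
        assert mask.all()


class TestShearTrend:
    def test_reference_row_is_zero(self, frictionless_results):
        trend = shear_trend(frictionless_results)
        assert trend.loc[0, "fraction"] == 0.0
        assert trend.loc[0, "sigma_xx"] == 0.0
        assert trend["fraction"].is_monotonic_increasing

    def test_uniaxial_shear_null_at_all_steps(self, frictionless_results):
        trend = shear_trend(frictionless_results)
        sxx_final = abs(trend["sigma_xx"].iloc[-1])
        assert (trend["sigma_xz"].abs() < 1e-6 * sxx_final).all()
        assert (trend["sigma_yz"].abs() < 1e-6 * sxx_final).all()

    def test_tilted_field_shear_grows_with_deformation(self, mirror_runs):
        trend = shear_trend(mirror_runs["plus"])
        s = trend.set_index("fraction")["sigma_xz"]
        assert abs(s.loc[0.20]) > abs(s.loc[0.12])


class TestBoundaryProfiles:
    def test_rigid_translation_flat_profiles(self, box_mesh):
        u = np.tile([0.0, 0.0, 0.4], (box_mesh.n_nodes, 1))
        prof = boundary_profiles(_StubResults(box_mesh, u), axis="z")
        assert np.allclose(prof["displacement"], 0.4)
        assert set(prof["slice"]) == {0, 1, 2}

    def test_tilted_fibres_break_slice_symmetry(self, mirror_runs, frictionless_results):
        # x-z tilt drives asymmetric lateral motion: the z-displacement traces
        # of the outer slices separate, unlike the symmetric uniaxial case
        def slice_spread(results):
            spread = 0.0
            for axis in ("y", "z"):  # the x-z tilt shows up in the y traces
                prof = boundary_profiles(results, axis=axis)
                for _, sub in prof.groupby("face"):
                    p = {
                        b: s.set_index("x")["displacement"]
                        for b, s in sub.groupby("slice")
                    }
                    x = p[0].index.intersection(p[2].index)
                    spread = max(spread, np.abs(p[0].loc[x] - p[2].loc[x]).max())
            return spread

        assert slice_spread(mirror_runs["plus"]) > 10 * slice_spread(frictionless_results)

    def test_uniaxial_slices_coincide(self, frictionless_results):
        prof = boundary_profiles(frictionless_results, axis="z")
        for face, sub in prof.groupby("face"):
            pivots = {
                b: s.set_index("x")["displacement"] for b, s in sub.groupby("slice")
            }
            x_common = pivots[0].index.intersection(pivots[2].index)
            assert np.allclose(
                pivots[0].loc[x_common], pivots[2].loc[x_common], atol=1e-8
            )


class TestRegression:
    def test_exact_collinear_points(self):
        table = pd.DataFrame({"mean_theta": [0.0, 1.0, 2.0], "mean_sigma_xz": [0.0, 1.0, 2.0]})
        row = orientation_stress_regression(table).loc[0]
        assert row["slope"] == pytest.approx(1.0)
        assert row["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert row["pearson_r"] == pytest.approx(1.0)

    def test_constructed_slope_recovered(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-3, 3, 40)
        y = 0.12 * x - 0.86 + rng.normal(0, 0.02, 40)
        table = pd.DataFrame({"mean_theta": x, "mean_sigma_xz": y})
        row = orientation_stress_regression(table).loc[0]
        assert row["slope"] == pytest.approx(0.12, abs=0.01)
        assert row["intercept"] == pytest.approx(-0.86, abs=0.01)
        assert row["pearson_r"] > 0.99

    def test_permuted_pairs_destroy_correlation(self):
        rng = np.random.default_rng(1)
        x = np.linspace(0, 1, 200)
        y = rng.permutation(x)
        table = pd.DataFrame({"mean_theta": x, "mean_sigma_xz": y})
        row = orientation_stress_regression(table).loc[0]
        assert abs(row["pearson_r"]) < 0.2

    def test_zero_variance_predictor_flagged(self):
        table = pd.DataFrame({"mean_theta": [1.0, 1.0, 1.0], "mean_sigma_xz": [0, 1, 2]})
        row = orientation_stress_regression(table).loc[0]
        assert not row["fitted"]

    def test_grouped_fits(self):
        table = pd.DataFrame(
            {
                "mean_theta": [0, 1, 2, 0, 1, 2],
                "mean_sigma_xz": [0, 1, 2, 5, 4, 3],
                "cluster": ["up"] * 3 + ["down"] * 3,
            }
        )
        out = orientation_stress_regression(table, group="cluster").set_index("group")
        assert out.loc["up", "slope"] == pytest.approx(1.0)
        assert out.loc["down", "slope"] == pytest.approx(-1.0)


class TestClusterCompare:
    def test_identical_clusters_not_significant(self):
        rng = np.random.default_rng(0)
        a = pd.DataFrame({"theta": rng.normal(0, 6, 200)})
        out = cluster_compare({"u": a, "l": a.copy()}, angle_columns=("theta",))
        assert not out["significant"].any()

    def test_shifted_cluster_significant_matches_welch_formula(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 2, 100)
        b = rng.normal(6, 2, 100)  # +3 sigma shift
        out = cluster_compare(
            {"u": pd.DataFrame({"elevation": a}), "l": pd.DataFrame({"elevation": b})},
            angle_columns=("elevation",),
        )
        assert out.loc[0, "significant"]
        # textbook Welch statistic cross-check
        from scipy.stats import t as tdist

        va, vb = a.var(ddof=1) / 100, b.var(ddof=1) / 100
        tstat = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 99 + vb**2 / 99)
        p_manual = 2 * tdist.sf(abs(tstat), df)
        assert out.loc[0, "p_value"] == pytest.approx(p_manual, rel=1e-10)

    def test_single_record_cluster_untestable(self):
        out = cluster_compare(
            {
                "u": pd.DataFrame({"theta": [1.0]}),
                "l": pd.DataFrame({"theta": [0.0, 1.0, 2.0]}),
            },
            angle_columns=("theta",),
        )
        assert not out.loc[0, "testable"]


def test_mirror_average_approximates_mixed_field_shear(mirror_runs):
    """A field transitioning from +a to -a tilt produces interior shear close
    to the average of the two pure-tilt runs (the overlap-region mechanism)."""
    plus = interior_mean_stress(mirror_runs["plus"]).loc[0, "sigma_xz"]
    minus = interior_mean_stress(mirror_runs["minus"]).loc[0, "sigma_xz"]
    mixed = interior_mean_stress(mirror_runs["mixed"]).loc[0, "sigma_xz"]
    avg = 0.5 * (plus + minus)
    assert abs(mixed - avg) <= 0.25 * abs(plus)
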
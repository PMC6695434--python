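import math

import numpy as np
import pytest
from scipy import integrate

from ellipshape.shape_core import (CALLIPER_MAX_RELATIVE_ERROR, EquivalentEllipsoid,
                                   beta_boundary, calliper, ellipsoid_of_cloud,
                                   equivalent_ellipsoid, fractional_radial_extent,
                                   inertia_tensor, isoperimetric_quotient,
                                   order_parameter, shape_ab, shape_distribution,
                                   steric_volume, surface_area_model)
from ellipshape.structure_io import AtomCloud
from ellipshape.synthetic_data import GeneratorSpec, make_ellipsoid_cloud


def _cloud_from_points(points, radius=1.7):
    n = len(points)
    return AtomCloud(np.full(n, "C", dtype=object), np.asarray(points, float),
                     np.full(n, radius), np.arange(1, n + 1),
                     np.full(n, "ALA", dtype=object), np.full(n, "A", dtype=object),
                     np.zeros(n, bool))


class TestInertiaTensor:
    def test_single_atom_solid_sphere_term(self):
        r = 1.7
        cloud = _cloud_from_points([[0.0, 0.0, 0.0]], radius=r)
        tensor = inertia_tensor(cloud)
        expected = (4 * math.pi / 3) * r ** 3 * 0.4 * r ** 2
        np.testing.assert_allclose(tensor, np.eye(3) * expected, rtol=1e-12)

    def test_two_atoms_on_x_axis_symmetry(self):
        cloud = _cloud_from_points([[-3.0, 0, 0], [3.0, 0, 0]])
        t = inertia_tensor(cloud)
        assert t[0, 0] < t[1, 1]
        assert t[1, 1] == pytest.approx(t[2, 2])

    def test_uniform_fill_matches_continuum(self, rng):
        # Monte-Carlo continuum oracle: equal-mass points in an ellipsoid
        # have I_xx -> M(b²+c²)/5 etc.
        a, b, c = 3.0, 2.0, 1.0
        g = rng.normal(size=(100_000, 3))
        g /= np.linalg.norm(g, axis=1, keepdims=True)
        pts = g * rng.uniform(size=(100_000, 1)) ** (1 / 3) * [a, b, c]
        radius = 0.01  # negligible solid-sphere self term
        cloud = _cloud_from_points(pts, radius=radius)
        tensor = inertia_tensor(cloud)
        m = steric_volume(cloud)
        expected = m / 5 * np.diag([b * b + c * c, a * a + c * c, a * a + b * b])
        np.testing.assert_allclose(tensor, expected, atol=0.01 * expected.max())


class TestEquivalentEllipsoid:
    def test_single_atom_gives_sphere_of_same_radius(self):
        r = 1.7
        cloud = _cloud_from_points([[0.0, 0.0, 0.0]], radius=r)
        ell = equivalent_ellipsoid(inertia_tensor(cloud), steric_volume(cloud))
        np.testing.assert_allclose(ell.semi_axes, [r, r, r], rtol=1e-12)

    def test_recovers_generator_axes_within_2pct(self, big_fill_ellipsoid):
        np.testing.assert_allclose(big_fill_ellipsoid.semi_axes,
                                   [30.0, 20.0, 10.0], rtol=0.02)

    def test_recovered_volume_matches_generator_envelope(self, big_fill_ellipsoid):
        # (4π/3)abc of the equivalent ellipsoid reproduces the geometric
        # volume of the uniformly filled target envelope
        target = 4 * math.pi / 3 * 30.0 * 20.0 * 10.0
        assert big_fill_ellipsoid.volume == pytest.approx(target, rel=0.02)

    def test_degenerate_planar_cloud_rejected(self):
        tensor = np.diag([10.0, 6.0, 3.0])   # λ2+λ3-λ1 < 0
        with pytest.raises(ValueError, match="non-ellipsoidal"):
            equivalent_ellipsoid(tensor, 1.0)

    def test_rotation_invariance_of_alpha_beta(self, small_cloud, rng):
        base = shape_ab(ellipsoid_of_cloud(small_cloud))
        # random rigid rotation of the cloud
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ])
        rotated = AtomCloud(small_cloud.elements, small_cloud.coords @ R.T + 5.0,
                            small_cloud.radii, small_cloud.res_index,
                            small_cloud.res_name, small_cloud.chain_id,
                            small_cloud.is_ca)
        ab = shape_ab(ellipsoid_of_cloud(rotated))
        assert ab.alpha == pytest.approx(base.alpha, abs=1e-6)
        assert ab.beta == pytest.approx(base.beta, abs=1e-6)


class TestShapeAB:
    @pytest.mark.parametrize("axes,alpha,beta,cls", [
        ((2.0, 2.0, 1.0), 2.0, 1.0, "oblate"),
        ((2.0, 1.0, 1.0), 2.0, 0.0, "prolate"),
    ])
    def test_spheroid_limits(self, axes, alpha, beta, cls):
        ab = shape_ab(EquivalentEllipsoid.from_semi_axes(*axes))
        assert ab.alpha == pytest.approx(alpha)
        assert ab.beta == pytest.approx(beta)
        assert ab.shape_class == cls

    def test_sphere_sentinel(self):
        ab = shape_ab(EquivalentEllipsoid.from_semi_axes(1.0, 1.0, 1.0))
        assert ab.shape_class == "sphere"
        assert math.isnan(ab.beta)

    def test_lysozyme_like_axes(self):
        # printed worked-example axes give alpha~1.68, beta~0.18-0.19
        ab = shape_ab(EquivalentEllipsoid.from_semi_axes(23.4, 15.3, 13.9))
        assert 1.68 <= ab.alpha <= 1.69
        assert 0.18 <= ab.beta <= 0.19

    def test_boundary_curve_limit_and_monotonicity(self):
        # (ln(α+1)-ln2)/lnα -> 1/2 as α -> 1+ and rises toward 1
        alphas = np.linspace(1.001, 20.0, 400)
        vals = np.array([beta_boundary(a) for a in alphas])
        assert vals[0] == pytest.approx(0.5, abs=5e-3)
        assert np.all(np.diff(vals) > 0)
        assert np.all((vals > 0) & (vals < 1))


class TestCalliper:
    def test_single_atom(self):
        res = calliper(_cloud_from_points([[0, 0, 0]], radius=1.7))
        assert res.max_diameter == pytest.approx(3.4)
        assert res.min_diameter == pytest.approx(3.4)
        assert res.ratio == pytest.approx(1.0)

    def test_two_atoms_dumbbell(self):
        res = calliper(_cloud_from_points([[0, 0, 0], [10.0, 0, 0]], radius=1.0))
        assert res.max_diameter == pytest.approx(12.0, rel=1e-6)
        assert res.min_diameter == pytest.approx(2.0, rel=1e-6)

    def test_ellipsoid_fill_vs_support_function_oracle(self, rng):
        spec = GeneratorSpec((30.0, 20.0, 10.0), n_residues=2000, seed=5)
        cloud = make_ellipsoid_cloud(spec)
        res = calliper(cloud)
        # brute-force support-function oracle over random directions
        u = rng.normal(size=(4000, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        proj = cloud.coords @ u.T
        widths = (proj + cloud.radii[:, None]).max(0) - (proj - cloud.radii[:, None]).min(0)
        assert res.max_diameter == pytest.approx(widths.max(), rel=3e-3)
        assert res.min_diameter == pytest.approx(widths.min(), rel=1e-2)
        assert res.ratio == pytest.approx(3.0, rel=0.1)
        assert res.ratio >= 1.0

    def test_discretization_bound_value(self):
        assert CALLIPER_MAX_RELATIVE_ERROR == pytest.approx(1 - math.cos(math.pi / 180))


class TestSurfaceAreaModel:
    def test_sphere_identity(self):
        v = 1000.0
        assert surface_area_model(1.0, 0.5, v) == pytest.approx(
            (36 * math.pi * v ** 2) ** (1 / 3), rel=1e-12)
        assert isoperimetric_quotient(1.0, 0.5) == pytest.approx(1.0)

    @pytest.mark.parametrize("beta", [0.0, 0.34, 1.0])
    def test_monotone_in_alpha(self, beta):
        v = 500.0
        alphas = np.linspace(1.0, 5.0, 50)
        areas = [surface_area_model(a, beta, v) for a in alphas]
        assert np.all(np.diff(areas) > 0)

    def test_against_exact_surface_integral(self):
        # numerical oracle: exact triaxial area by quadrature of the
        # parametric area element (Knud Thomsen bound ~1.1%)
        alpha, beta, v = 2.0, 0.5, 1000.0
        c = (3 * v / (4 * math.pi * alpha ** (1 + beta))) ** (1 / 3)
        a, b = alpha * c, alpha ** beta * c

        def element(theta, phi):
            st, ct = math.sin(theta), math.cos(theta)
            sp, cp = math.sin(phi), math.cos(phi)
            # |r_theta x r_phi| of standard spherical parameterization
            ex = b * c * st * st * cp
            ey = a * c * st * st * sp
            ez = a * b * st * ct
            return math.sqrt(ex * ex + ey * ey + ez * ez)

        exact, _ = integrate.dblquad(element, 0, 2 * math.pi, 0, math.pi,
                                     epsabs=1e-9, epsrel=1e-9)
        model = surface_area_model(alpha, beta, v)
        assert model == pytest.approx(exact, rel=0.011)


class TestOrderParameter:
    def test_parallel_and_perpendicular(self):
        a_axis = np.array([1.0, 0.0, 0.0])
        assert order_parameter([[2.0, 0, 0], [-1.0, 0, 0]], a_axis) == pytest.approx(1.0)
        assert order_parameter([[0, 1.0, 0], [0, 0, 3.0]], a_axis) == pytest.approx(-0.5)

    def test_isotropic_vectors_near_zero(self, rng):
        v = rng.normal(size=(10_000, 3))
        assert abs(order_parameter(v, [1.0, 0, 0])) < 0.02

    def test_zero_vectors_skipped(self):
        s = order_parameter([[0.0, 0.0, 0.0], [1.0, 0, 0]], [1.0, 0, 0])
        assert s == pytest.approx(1.0)


class TestFractionalRadialExtent:
    def test_constructed_placements(self):
        ell = EquivalentEllipsoid.from_semi_axes(20.0, 15.0, 10.0)
        # CA atoms at centroid, on the a-pole, and halfway along b
        pts = np.array([[0.0, 0, 0], [20.0, 0, 0], [0, 7.5, 0]])
        n = 3
        cloud = AtomCloud(np.full(n, "C", dtype=object), pts, np.full(n, 1.7),
                          np.arange(1, n + 1), np.full(n, "GLY", dtype=object),
                          np.full(n, "A", dtype=object), np.ones(n, bool))
        table = fractional_radial_extent(cloud, ell)
        assert table.values[1] == pytest.approx(0.0, abs=1e-9)
        assert table.values[2] == pytest.approx(1.0, abs=1e-9)
        assert table.values[3] == pytest.approx(0.5, abs=1e-9)


class TestShapeDistribution:
    def test_single_shape_mode(self):
        from ellipshape.shape_core import ShapeAB
        shapes = [ShapeAB(1.65, 0.34, "prolate")]
        *_, mode = shape_distribution(shapes)
        assert mode[0] == pytest.approx(1.65, abs=0.011)
        assert mode[1] == pytest.approx(0.34, abs=0.011)

    def test_cluster_recovery_within_bandwidth(self, rng):
        from ellipshape.shape_core import ShapeAB
        shapes = [ShapeAB(a, b, "prolate") for a, b in zip(
            rng.normal(1.65, 0.08, 400), rng.normal(0.34, 0.08, 400))]
        shapes += [ShapeAB(a, b, "oblate") for a, b in zip(
            rng.normal(2.6, 0.05, 40), rng.normal(0.8, 0.05, 40))]
        *_, mode = shape_distribution(shapes)
        assert abs(mode[0] - 1.65) < 0.07
        assert abs(mode[1] - 0.34) < 0.07
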
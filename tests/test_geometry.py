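"""Frustum-stack reconstruction and shape-index tests.

Oracles: closed forms for prisms, cones, pyramidal frusta, spheres and
spheroids; numeric quadrature for general ellipsoids.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellscale import (
    CellViews,
    cell_shape_indices,
    circularity,
    equal_volume_ellipsoid,
    frustum_slab,
    make_ellipsoid_cell,
    make_sphere_cell,
    shape_indices,
    sphere_surface_equal_volume,
    spheroid_surface,
    stack_cell,
    thomsen_surface,
)


class TestFrustumSlab:
    def test_prism_limit(self):
        V, S = frustum_slab(2, 2, 4, 4, 1, 1, t=3)
        assert V == pytest.approx(6.0)
        assert S == pytest.approx(12.0)

    def test_cone_closed_form(self):
        V, S = frustum_slab(np.pi, 0, 2 * np.pi, 0, 2, 0, t=1)
        assert V == pytest.approx(np.pi / 3)
        # lateral area of a cone: pi * r * slant = pi * sqrt(2)
        assert S == pytest.approx(np.pi * np.sqrt(2))

    def test_pyramidal_frustum(self):
        # square faces with sides 1 and 2: V = h/3 (a^2 + ab + b^2) = 7
        V, _ = frustum_slab(1, 4, 4, 8, 1, 2, t=3)
        assert V == pytest.approx(7.0)

    @pytest.mark.parametrize("bad", [dict(A_lo=-1), dict(t=0), dict(t=-2), dict(P_hi=-0.1)])
    def test_domain_errors(self, bad):
        kwargs = dict(A_lo=1, A_hi=1, P_lo=4, P_hi=4, W_lo=1, W_hi=1, t=1)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            frustum_slab(**kwargs)

    @given(
        A=st.floats(0.1, 50),
        P=st.floats(1, 50),
        W=st.floats(0.1, 10),
        t=st.floats(0.01, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_prism_reduction_property(self, A, P, W, t):
        """Equal faces always reduce to the prism closed form."""
        if P**2 < 4 * np.pi * A:
            P = np.sqrt(4 * np.pi * A) + 1.0
        V, S = frustum_slab(A, A, P, P, W, W, t)
        assert V == pytest.approx(A * t, rel=1e-12)
        assert S == pytest.approx(P * t, rel=1e-12)


class TestStackCell:
    def test_constant_profile_is_prism(self):
        views = CellViews(A_f=3.0, P_f=8.0, L=2.5, W=2.0, T=4.0,
                          widths=np.full(11, 2.0))
        geom = stack_cell(views)
        assert geom.V == pytest.approx(3.0 * 4.0, rel=1e-12)
        assert geom.S == pytest.approx(8.0 * 4.0 + 2 * 3.0, rel=1e-12)
        assert geom.cap_area == pytest.approx(6.0)

    def test_sphere_within_one_percent(self):
        cell = make_sphere_cell(1.0, n=2000)
        geom = stack_cell(cell.views)
        assert geom.V == pytest.approx(4 * np.pi / 3, rel=0.01)
        assert geom.S == pytest.approx(4 * np.pi, rel=0.01)
        # caps vanish for a profile tapering to points
        assert geom.cap_area == pytest.approx(0.0, abs=1e-4)

    def test_sphere_error_decreases_monotonically(self):
        V_true, S_true = 4 * np.pi / 3, 4 * np.pi
        v_errs, s_errs = [], []
        for n in [10, 50, 100, 500, 2000]:
            geom = stack_cell(make_sphere_cell(1.0, n=n).views)
            v_errs.append(abs(geom.V - V_true) / V_true)
            s_errs.append(abs(geom.S - S_true) / S_true)
        assert all(a > b for a, b in zip(v_errs, v_errs[1:]))
        assert all(a > b for a, b in zip(s_errs, s_errs[1:]))
        assert v_errs[-1] < 0.01 and s_errs[-1] < 0.01

    def test_volume_bounded_by_bounding_prism(self):
        cell = make_sphere_cell(2.5, n=500)
        geom = stack_cell(cell.views)
        assert geom.V <= cell.views.A_f * cell.views.T
        assert geom.V == pytest.approx(np.sum(geom.slab_volumes))
        assert geom.S == pytest.approx(np.sum(geom.slab_laterals) + geom.cap_area)

    def test_oblate_spheroid_converges(self):
        """Solids of revolution about the thickness axis are exact in the limit."""
        cell = make_ellipsoid_cell(2.0, 2.0, 0.5, n=2000)
        geom = stack_cell(cell.views)
        assert geom.V == pytest.approx(cell.oracle_V, rel=0.01)
        assert geom.S == pytest.approx(spheroid_surface(2.0, 0.5), rel=0.01)

    def test_triaxial_surface_bias_is_documented(self):
        """For an elongated frontal outline the width-based slant underestimates
        the true surface; volume is still exact.  The frozen value is the
        model's converged output for semi-axes (2, 1, 0.5); the quadrature
        oracle gives 15.869, about 16% higher."""
        cell = make_ellipsoid_cell(2.0, 1.0, 0.5, n=2000)
        geom = stack_cell(cell.views)
        assert geom.V == pytest.approx(4 * np.pi / 3, rel=0.01)
        assert geom.S == pytest.approx(13.372, rel=0.005)
        assert geom.S < cell.oracle_S  # known direction of the bias

    def test_scale_equivariance(self):
        views = make_sphere_cell(1.0, n=200).views
        geom1 = stack_cell(views)
        c = 3.7
        scaled = CellViews(A_f=views.A_f * c**2, P_f=views.P_f * c,
                           L=views.L * c, W=views.W * c, T=views.T * c,
                           widths=views.widths * c)
        geom2 = stack_cell(scaled)
        assert geom2.V == pytest.approx(geom1.V * c**3, rel=1e-10)
        assert geom2.S == pytest.approx(geom1.S * c**2, rel=1e-10)
        i1 = cell_shape_indices(views, geom1)
        i2 = cell_shape_indices(scaled, geom2)
        for attr in ("alpha", "beta", "gamma", "delta", "k"):
            assert getattr(i2, attr) == pytest.approx(getattr(i1, attr), rel=1e-9)

    def test_too_few_boundaries_rejected(self):
        with pytest.raises(ValueError):
            CellViews(A_f=1, P_f=4, L=1, W=1, T=1, widths=np.array([1.0, 1.0]))

    def test_width_exceeding_W_rejected(self):
        with pytest.raises(ValueError):
            CellViews(A_f=1, P_f=4, L=1, W=1.0, T=1,
                      widths=np.array([1.0, 1.2, 1.0]))


class TestCircularity:
    def test_circle_is_exactly_one(self):
        assert circularity(np.pi, 2 * np.pi) == 1.0

    def test_unit_square(self):
        assert circularity(1.0, 4.0) == pytest.approx(np.pi / 4)

    def test_two_by_one_rectangle(self):
        assert circularity(2.0, 6.0) == pytest.approx(8 * np.pi / 36)

    def test_inconsistent_measurement_warns_not_clamps(self):
        with pytest.warns(UserWarning, match="inconsistent"):
            alpha = circularity(2.0, 1.0)
        assert alpha > 1.0  # returned unclamped

    @pytest.mark.parametrize("A,P", [(0, 1), (-1, 1), (1, 0), (1, -2)])
    def test_domain_errors(self, A, P):
        with pytest.raises(ValueError):
            circularity(A, P)


class TestEqualVolumeEllipsoid:
    def test_sphere_case_thomsen_exact(self):
        k, S = equal_volume_ellipsoid(4 * np.pi / 3, 2, 2, 2)
        assert k == pytest.approx(0.5)
        assert S == pytest.approx(4 * np.pi)

    def test_prolate_spheroid_vs_closed_form(self):
        k, S = equal_volume_ellipsoid(8 * np.pi / 3, 4, 2, 2)
        assert k == pytest.approx(0.5)
        assert S == pytest.approx(spheroid_surface(1.0, 2.0), rel=0.011)

    def test_scale_cancellation(self):
        V = 5.0
        k1, S1 = equal_volume_ellipsoid(V, 3, 2, 1)
        k2, S2 = equal_volume_ellipsoid(V, 6, 4, 2)
        assert k2 == pytest.approx(k1 / 2)
        assert S2 == pytest.approx(S1)

    @pytest.mark.parametrize("ratio", np.linspace(1, 5, 9))
    def test_thomsen_within_documented_error(self, ratio):
        """Thomsen's approximation stays within its 1.1% worst case against
        closed-form spheroid surfaces for axis ratios 1-5."""
        S_pro = spheroid_surface(1.0, ratio)  # prolate
        assert thomsen_surface(ratio, 1.0, 1.0) == pytest.approx(S_pro, rel=0.011)
        S_obl = spheroid_surface(ratio, 1.0)  # oblate
        assert thomsen_surface(ratio, ratio, 1.0) == pytest.approx(S_obl, rel=0.011)


class TestSphereSurface:
    def test_unit_sphere(self):
        assert sphere_surface_equal_volume(4 * np.pi / 3) == pytest.approx(4 * np.pi)

    def test_unit_volume(self):
        assert sphere_surface_equal_volume(1.0) == pytest.approx((36 * np.pi) ** (1 / 3))

    @given(V=st.floats(1e-3, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_scaling_law(self, V):
        assert sphere_surface_equal_volume(8 * V) == pytest.approx(
            4 * sphere_surface_equal_volume(V), rel=1e-12
        )

    def test_domain_error(self):
        with pytest.raises(ValueError):
            sphere_surface_equal_volume(0.0)


class TestShapeIndices:
    def test_sphere_baseline(self):
        cell = make_sphere_cell(1.0, n=2000)
        geom = stack_cell(cell.views)
        idx = cell_shape_indices(cell.views, geom)
        assert idx.alpha == pytest.approx(1.0)
        assert idx.beta == pytest.approx(1.0, abs=0.01)
        assert idx.gamma == pytest.approx(1.0, abs=0.01)
        assert idx.delta == pytest.approx(1.0, abs=0.01)

    def test_delta_identity_machine_precision(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            S, V = rng.uniform(5, 500), rng.uniform(1, 100)
            L, W, T = sorted(rng.uniform(0.5, 20, 3), reverse=True)
            idx = shape_indices(S, V, L, W, T)
            assert idx.delta == idx.beta * idx.gamma  # exact by construction
            assert idx.delta == pytest.approx(S / idx.S_sphere, rel=1e-12)

    def test_oblate_cell_flattening_dominates(self):
        """A smooth flattened cell gains surface through gamma, not beta."""
        cell = make_ellipsoid_cell(2.0, 2.0, 0.4, n=2000)
        geom = stack_cell(cell.views)
        idx = cell_shape_indices(cell.views, geom)
        assert idx.beta == pytest.approx(1.0, abs=0.015)
        assert idx.gamma > 1.3

    def test_delta_isoperimetric_floor(self):
        """Convex shapes cannot beat the sphere's surface-to-volume ratio by
        more than the Thomsen + discretization error."""
        for a, b, c in [(1, 1, 1), (2, 1.5, 1), (3, 3, 0.5), (5, 2, 2)]:
            cell = make_ellipsoid_cell(a, b, c, n=800)
            idx = shape_indices(cell.oracle_S, cell.oracle_V, 2 * a, 2 * b, 2 * c)
            assert idx.delta >= 1 - 0.015
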
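import numpy as np
import pytest

import fasciclecontour as fc
from fasciclecontour import FourierModel


def quadrature_efd_oracle(contour, order):
    """Independent oracle: Fourier coefficients of x(s), y(s) by direct
    trapezoidal quadrature over the arc-length parameter (instead of the
    closed-form per-segment summation used by efd_fit)."""
    c = np.asarray(contour, dtype=float)
    closed = np.vstack([c, c[:1]])
    s = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(closed, axis=0).T))])
    T = s[-1]
    coeffs = np.zeros((order, 4))
    for k in range(1, order + 1):
        cos = np.cos(2 * np.pi * k * s / T)
        sin = np.sin(2 * np.pi * k * s / T)
        coeffs[k - 1] = [
            2 / T * np.trapezoid(closed[:, 0] * cos, s),
            2 / T * np.trapezoid(closed[:, 0] * sin, s),
            2 / T * np.trapezoid(closed[:, 1] * cos, s),
            2 / T * np.trapezoid(closed[:, 1] * sin, s),
        ]
    a0 = np.trapezoid(closed[:, 0], s) / T
    c0 = np.trapezoid(closed[:, 1], s) / T
    return a0, c0, coeffs


class TestArcLengthParams:
    def test_unit_square_perimeter(self):
        square = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
        p = fc.arc_length_params(square)
        np.testing.assert_allclose(p.dt, [1, 1, 1, 1])
        assert p.T == pytest.approx(4.0)

    def test_circle_perimeter(self, circle360):
        p = fc.arc_length_params(circle360)
        assert p.T == pytest.approx(2 * np.pi * 10, rel=1e-3)

    def test_accumulators_start_at_zero(self, ellipse360):
        p = fc.arc_length_params(ellipse360)
        assert p.xi[0] == 0.0 and p.delta[0] == 0.0
        assert p.t[-1] == pytest.approx(p.T)
        assert (p.dt > 0).all()

    def test_duplicate_point_reported_with_index(self):
        bad = np.array([[0.0, 0], [1, 0], [1, 0], [0, 1]])
        with pytest.raises(ValueError, match="index 1"):
            fc.arc_length_params(bad)


class TestFit:
    def test_circle_fundamental_is_radius(self, circle360):
        m = fc.efd_fit(circle360, 1)
        a1, b1, c1, d1 = m.coeffs[0]
        assert a1 == pytest.approx(10, abs=0.01)
        assert d1 == pytest.approx(10, abs=0.01)
        assert abs(b1) < 0.05 and abs(c1) < 0.05
        assert abs(m.a0) < 0.5 and abs(m.c0) < 0.5

    def test_ellipse_matches_quadrature_oracle(self):
        theta = 2 * np.pi * np.arange(20000) / 20000
        ell = np.column_stack([20 * np.cos(theta), 10 * np.sin(theta)])
        m = fc.efd_fit(ell, 4)
        a0, c0, oracle = quadrature_efd_oracle(ell, 4)
        np.testing.assert_allclose(m.coeffs, oracle, atol=5e-3)
        assert m.a0 == pytest.approx(a0, abs=1e-3)
        # fundamental near the semi-axes (arc-length parameterization
        # shifts it below the parametric value)
        assert m.coeffs[0, 0] == pytest.approx(20, rel=0.1)
        assert m.coeffs[0, 3] == pytest.approx(10, rel=0.1)
        assert abs(m.coeffs[0, 1]) < 0.05 and abs(m.coeffs[0, 2]) < 0.05

    def test_invalid_inputs(self, circle360):
        with pytest.raises(ValueError):
            fc.efd_fit(circle360, 0)
        with pytest.raises(ValueError):
            fc.efd_fit(circle360[:2], 1)


class TestReconstruct:
    def test_pure_circle_model(self):
        m = FourierModel(order=1, a0=0, c0=0, coeffs=np.array([[10.0, 0, 0, 10.0]]))
        pts = fc.efd_reconstruct(m, 500)
        radial = np.hypot(pts[:, 0], pts[:, 1])
        assert np.abs(radial - 10).max() < 1e-9

    def test_constants_only(self):
        m = FourierModel(order=1, a0=3, c0=4, coeffs=np.zeros((1, 4)))
        pts = fc.efd_reconstruct(m, 10)
        np.testing.assert_allclose(pts, np.tile([3.0, 4.0], (10, 1)))

    def test_fit_reconstruct_hausdorff_convergence(self, fixtures):
        c = fixtures["rounded_square"]["contour"]
        m = fc.efd_fit(c, 8)
        rec = fc.efd_reconstruct(m, 2000)
        h, _ = fc.directed_hausdorff(rec, c)
        assert h < 1.0

    def test_too_few_points_rejected(self):
        m = FourierModel(order=1, a0=0, c0=0, coeffs=np.ones((1, 4)))
        with pytest.raises(ValueError):
            fc.efd_reconstruct(m, 2)


class TestParamCount:
    @pytest.mark.parametrize("order,include,expected",
                             [(4, False, 16), (2, False, 8), (4, True, 18), (1, True, 6)])
    def test_counts(self, order, include, expected):
        assert fc.param_count(order, include_constants=include) == expected

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            fc.param_count(0)


class TestProperties:
    def test_roundtrip_exact_on_constant_speed_models(self):
        """Refit of a densely sampled reconstruction is the identity for
        constant-speed (circular) curves; arbitrary curves re-fit under
        their own arc-length parameterization instead (see methods)."""
        for r, a0, c0 in [(5.0, 0.0, 0.0), (20.0, 3.0, -4.0), (57.0, -11.0, 2.0)]:
            coeffs = np.zeros((4, 4))
            coeffs[0] = [r, 0, 0, r]
            m = FourierModel(order=4, a0=a0, c0=c0, coeffs=coeffs)
            m2 = fc.efd_fit(fc.efd_reconstruct(m, 2000), 4)
            assert np.abs(m2.coeffs - m.coeffs).max() / r < 1e-3
            assert m2.a0 == pytest.approx(a0, abs=1e-6)
            assert m2.c0 == pytest.approx(c0, abs=1e-6)

    def test_roundtrip_error_scales_with_harmonic_content(self):
        """Reparameterization error of the round trip shrinks with the
        harmonic-to-fundamental ratio and is small for fascicle-like,
        near-circular shapes."""
        rng = np.random.default_rng(42)
        prev = None
        for eps in (0.05, 0.005):
            worst = 0.0
            for _ in range(5):
                coeffs = np.zeros((4, 4))
                coeffs[0] = [20.0, 0, 0, 20.0]
                coeffs[1:] += rng.normal(0, eps * 20, (3, 4))
                m = FourierModel(order=4, a0=0, c0=0, coeffs=coeffs)
                m2 = fc.efd_fit(fc.efd_reconstruct(m, 2000), 4)
                worst = max(worst, np.abs(m2.coeffs - m.coeffs).max() / 20.0)
            assert worst < 10 * eps
            if prev is not None:
                assert worst < prev
            prev = worst

    def test_monotone_dice_refinement(self, fixtures):
        contours = [fixtures[k]["contour"] for k in ("ellipse", "rounded_square", "star")]
        mean_dice = []
        for k in (1, 2, 4, 6, 8):
            mean_dice.append(np.mean([fc.evaluate(c, fc.efd_fit(c, k)).dice
                                      for c in contours]))
        assert all(b >= a - 0.3 for a, b in zip(mean_dice, mean_dice[1:]))
        assert mean_dice[-1] > mean_dice[0]

    def test_rotation_maps_coefficient_pairs(self, fixtures):
        c = fixtures["rounded_square"]["contour"]
        c = c - c.mean(axis=0)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        m = fc.efd_fit(c, 4)
        m_rot = fc.efd_fit(c @ R.T, 4)  # brute-force re-fit of rotated points
        for k in range(4):
            A = np.array([[m.coeffs[k, 0], m.coeffs[k, 1]],
                          [m.coeffs[k, 2], m.coeffs[k, 3]]])
            A_rot = np.array([[m_rot.coeffs[k, 0], m_rot.coeffs[k, 1]],
                              [m_rot.coeffs[k, 2], m_rot.coeffs[k, 3]]])
            np.testing.assert_allclose(A_rot, R @ A, atol=1e-8)

    def test_translation_changes_only_constants(self, circle360):
        m = fc.efd_fit(circle360, 4)
        m_t = fc.efd_fit(circle360 + [7.0, -3.0], 4)
        np.testing.assert_allclose(m_t.coeffs, m.coeffs, atol=1e-9)
        assert m_t.a0 - m.a0 == pytest.approx(7.0, abs=1e-9)
        assert m_t.c0 - m.c0 == pytest.approx(-3.0, abs=1e-9)

    def test_model_json_roundtrip(self, tmp_path, circle360):
        m = fc.efd_fit(circle360, 4)
        path = tmp_path / "m.json"
        m.to_json(path)
        m2 = FourierModel.from_json(path)
        assert m2.order == m.order
        np.testing.assert_allclose(m2.coeffs, m.coeffs)
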
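"""Elliptical Fourier analysis: analytic shapes, quadrature oracle,
size normalization and reconstruction properties."""

import numpy as np
import pytest

from vesselmorph.efa import (
    EFACoefficients,
    EllipticalFourierAnalysis,
    efa_coefficients,
    first_harmonic_semi_axes,
    normalize_size,
    reconstruct,
)
from vesselmorph.outline import GeometryError, Outline, mirror_to_outline
from vesselmorph.synthetic import VesselParams, make_profile


def _closed(x, y):
    return Outline(x=np.concatenate([x, x[:1]]), y=np.concatenate([y, y[:1]]))


def quadrature_coefficients(outline: Outline, n_harmonics: int, n_samples: int = 2**20):
    """Independent dense-quadrature oracle for the Fourier integrals.

    Samples the piecewise-linear arc-length parametrisation of the contour
    very densely and evaluates a_n = (2/T) int x(t) cos(2 pi n t / T) dt
    (and companions) by the trapezoidal rule.
    """
    pts = outline.as_array()
    seg = np.hypot(*np.diff(pts, axis=0).T)
    knots = np.concatenate([[0.0], np.cumsum(seg)])
    T = knots[-1]
    t = np.linspace(0.0, T, n_samples)
    x = np.interp(t, knots, pts[:, 0])
    y = np.interp(t, knots, pts[:, 1])
    coeffs = np.empty((n_harmonics, 4))
    for n in range(1, n_harmonics + 1):
        c = np.cos(2 * np.pi * n * t / T)
        s = np.sin(2 * np.pi * n * t / T)
        coeffs[n - 1] = [
            2 / T * np.trapezoid(x * c, t),
            2 / T * np.trapezoid(x * s, t),
            2 / T * np.trapezoid(y * c, t),
            2 / T * np.trapezoid(y * s, t),
        ]
    return coeffs


class TestAnalyticShapes:
    def test_circle_closed_form(self):
        r, K = 3.7, 8192
        t = np.linspace(0, 2 * np.pi, K, endpoint=False)
        c = efa_coefficients(_closed(r * np.cos(t) + 1, r * np.sin(t) - 2), 6)
        assert np.allclose(c.harmonics[0], [r, 0, 0, r], atol=2e-6 * r)
        assert np.max(np.abs(c.harmonics[1:])) < 2e-6 * r
        assert c.a0 == pytest.approx(1.0, abs=1e-9)
        assert c.c0 == pytest.approx(-2.0, abs=1e-9)

    def test_ellipse_one_harmonic(self):
        # an ellipse is a single harmonic in its elliptic-angle parameter
        A, B, K = 5.0, 2.0, 8192
        t = np.linspace(0, 2 * np.pi, K, endpoint=False)
        c = efa_coefficients(_closed(A * np.cos(t), B * np.sin(t)), 5, param="index")
        assert np.allclose(c.harmonics[0], [A, 0, 0, B], atol=1e-6)
        assert np.max(np.abs(c.harmonics[1:])) < 1e-6
        sa, sb = first_harmonic_semi_axes(c)
        assert (sa, sb) == pytest.approx((A, B), abs=1e-6)

    def test_square_matches_quadrature_oracle(self):
        sq = Outline(
            x=np.array([1.0, 1, -1, -1, 1]), y=np.array([-1.0, 1, 1, -1, -1])
        )
        mine = efa_coefficients(sq, 10)
        oracle = quadrature_coefficients(sq, 10)
        assert np.max(np.abs(mine.harmonics - oracle)) < 1e-8

    def test_vessel_outline_matches_quadrature_oracle(self, vessel_outline):
        mine = efa_coefficients(vessel_outline, 8)
        oracle = quadrature_coefficients(vessel_outline, 8)
        assert np.max(np.abs(mine.harmonics - oracle)) < 1e-7

    def test_degenerate_contours_rejected(self):
        with pytest.raises(GeometryError):
            efa_coefficients(
                Outline(x=np.zeros(5), y=np.zeros(5)), 2
            )


class TestNormalizeSize:
    def test_circle_normalizes_to_unit(self):
        t = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
        c = efa_coefficients(_closed(7 * np.cos(t), 7 * np.sin(t)), 4)
        n = normalize_size(c)
        assert np.allclose(n.harmonics[0], [1, 0, 0, 1], atol=1e-6)
        assert n.a0 == n.c0 == 0.0
        assert n.normalized

    def test_scale_invariance(self, vessel_outline):
        c1 = normalize_size(efa_coefficients(vessel_outline, 10))
        scaled = Outline(x=3.7 * vessel_outline.x, y=3.7 * vessel_outline.y)
        c2 = normalize_size(efa_coefficients(scaled, 10))
        assert np.max(np.abs(c1.harmonics - c2.harmonics)) < 1e-10

    def test_semi_major_axis_equals_eigen_decomposition(self, vessel_outline):
        c = efa_coefficients(vessel_outline, 10)
        e1, _ = first_harmonic_semi_axes(c)
        m = c.harmonics[0].reshape(2, 2)
        # independent route: largest eigenvalue of M^T M
        lam = np.linalg.eigvalsh(m.T @ m).max()
        assert e1 == pytest.approx(np.sqrt(lam), rel=1e-12)
        n = normalize_size(c)
        assert first_harmonic_semi_axes(n)[0] == pytest.approx(1.0, abs=1e-9)

    def test_translation_changes_only_bias(self, vessel_outline):
        c1 = efa_coefficients(vessel_outline, 8)
        shifted = Outline(x=vessel_outline.x + 4.2, y=vessel_outline.y - 1.1)
        c2 = efa_coefficients(shifted, 8)
        assert np.allclose(c1.harmonics, c2.harmonics, atol=1e-10)
        assert c2.a0 - c1.a0 == pytest.approx(4.2, abs=1e-9)
        assert c2.c0 - c1.c0 == pytest.approx(-1.1, abs=1e-9)

    def test_a1_variant(self, vessel_outline):
        c = efa_coefficients(vessel_outline, 4)
        n = normalize_size(c, method="a1")
        assert abs(n.harmonics[0, 0]) == pytest.approx(1.0)


class TestReconstruct:
    def test_circle_roundtrip(self):
        t = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
        c = efa_coefficients(_closed(2 * np.cos(t) + 1, 2 * np.sin(t)), 3)
        rec = reconstruct(c, 512)
        radii = np.hypot(rec.x - c.a0, rec.y - c.c0)
        assert np.max(np.abs(radii - 2.0)) < 1e-5

    def test_band_limited_roundtrip(self):
        h = np.zeros((8, 4))
        h[0] = [3, 0, 0, 3]
        h[2] = [0.05, 0.02, -0.03, 0.04]
        h[5] = [0.01, 0.0, 0.02, -0.01]
        c = EFACoefficients(harmonics=h, a0=1.0, c0=-2.0)
        rec = reconstruct(c, 2048)
        c2 = efa_coefficients(rec, 8, param="index")
        assert np.max(np.abs(c2.harmonics - h)) / np.abs(h).max() < 1e-4

    def test_l2_error_monotone_in_harmonics(self, vessel_outline):
        pts = vessel_outline.as_array()

        def l2(n_h):
            rec = reconstruct(efa_coefficients(vessel_outline, n_h), 2048).as_array()
            d = np.array(
                [np.min(np.hypot(rec[:, 0] - x, rec[:, 1] - y)) for x, y in pts[::8]]
            )
            return np.sqrt(np.mean(d**2))

        errs = [l2(n) for n in (2, 5, 10, 20, 40)]
        assert all(b <= a + 1e-12 for a, b in zip(errs, errs[1:]))

    def test_vessel_reconstruction_accuracy(self, vessel_outline):
        rec = reconstruct(efa_coefficients(vessel_outline, 20), 4096).as_array()
        pts = vessel_outline.as_array()
        d = np.array([np.min(np.hypot(rec[:, 0] - x, rec[:, 1] - y)) for x, y in pts])
        height = pts[:, 1].max() - pts[:, 1].min()
        assert d.mean() < 0.005 * height

    def test_n_points_domain(self):
        c = EFACoefficients(harmonics=np.array([[1.0, 0, 0, 1]]), a0=0, c0=0)
        with pytest.raises(ValueError):
            reconstruct(c, 2)


class TestTransformer:
    def test_matrix_shape_and_power(self):
        shapes = [
            make_profile(
                VesselParams(10 + i, 8 + i, 0.5, 2.0, 3.0, 2.0 + 0.3 * i, 0.1),
                n_points=128,
            )
            for i in range(4)
        ]
        outlines = [mirror_to_outline(p) for p in shapes]
        tf = EllipticalFourierAnalysis(n_harmonics=20).fit(outlines)
        M = tf.transform(outlines)
        assert M.shape == (4, 80)
        names = tf.get_feature_names_out()
        assert names[0] == "a1" and names[-1] == "d20"
        # retained harmonics capture > 99.9% of harmonic power
        c = efa_coefficients(outlines[0], 60)
        power = (c.harmonics**2).sum(axis=1)
        assert power[:20].sum() / power.sum() > 0.999

    def test_sklearn_params_roundtrip(self):
        tf = EllipticalFourierAnalysis(n_harmonics=7, normalize=False)
        assert tf.get_params()["n_harmonics"] == 7
        tf.set_params(n_harmonics=9)
        assert tf.fit(None).n_features_out_ == 36
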
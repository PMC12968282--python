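"""Entropy functionals, model densities and analytic normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from qeeg import (
    BGExpParams,
    QExpParams,
    bg_cdf,
    bg_pdf,
    bg_ppf,
    entropy_bg,
    entropy_q,
    normalize_bg,
    normalize_qexp,
    q_upper_bound,
    qexp_cdf,
    qexp_pdf,
    qexp_ppf,
)
from qeeg.qstats import ParameterError


def _pdf_mass(params) -> float:
    """Quadrature of the density on [0, inf).

    Split at quantiles so the adaptive integrator resolves steep peaks,
    and integrate the power-law tail in 1/x so it converges to the
    requested absolute accuracy.
    """
    q1 = float(qexp_ppf(0.25, params))
    q2 = float(qexp_ppf(0.5, params))  # always finite, unlike high quantiles
    head = integrate.quad(lambda x: qexp_pdf(x, params), 0, q1, limit=200)[0]
    body = integrate.quad(lambda x: qexp_pdf(x, params), q1, q2, limit=200)[0]
    tail = integrate.quad(
        lambda u: qexp_pdf(1.0 / u, params) / u**2, 0, 1.0 / q2, limit=200
    )[0]
    return head + body + tail


class TestEntropies:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ((1.0, 0.0, 0.0), 0.0),
            ((0.25, 0.25, 0.25, 0.25), np.log(4)),
            ((0.5, 0.25, 0.25), 1.039721),  # hand summation
        ],
    )
    def test_bg_values(self, p, expected):
        assert entropy_bg(p).value == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize(
        "p, q, expected",
        [
            ((0.5, 0.5), 2.0, 0.5),
            ((1.0, 0.0), 1.7, 0.0),
            ((1.0, 0.0), 3.0, 0.0),
        ],
    )
    def test_tsallis_values(self, p, q, expected):
        assert entropy_q(p, q).value == pytest.approx(expected, abs=1e-12)

    def test_tsallis_limit_is_bg(self, rng):
        p = rng.dirichlet(np.ones(6))
        s_lim = entropy_q(p, q=1 + 1e-8).value
        assert abs(s_lim - entropy_bg(p).value) < 1e-5
        # numeric limit check from the spec'd worked example
        uniform = (0.25,) * 4
        assert entropy_q(uniform, 1 + 1e-8).value == pytest.approx(np.log(4), abs=1e-5)

    @pytest.mark.parametrize("w", [2, 5, 17])
    @pytest.mark.parametrize("q", [1.3, 2.0, 3.5])
    def test_equiprobable_closed_form(self, w, q):
        # S_q(uniform) = k (W^(1-q) - 1)/(1-q), the q-logarithm of W
        p = np.full(w, 1.0 / w)
        expected = (w ** (1 - q) - 1) / (1 - q)
        assert entropy_q(p, q).value == pytest.approx(expected, abs=1e-12)

    def test_q_equal_one_routes_to_bg(self):
        p = (0.3, 0.7)
        assert entropy_q(p, 1.0).value == entropy_bg(p).value

    def test_scale_constant(self):
        assert entropy_bg((0.5, 0.5), k=3.0).value == pytest.approx(3 * np.log(2))

    @pytest.mark.parametrize("bad", [(0.5, 0.6), (-0.1, 1.1), (0.5, 0.4)])
    def test_invalid_probabilities_rejected(self, bad):
        with pytest.raises(ParameterError):
            entropy_bg(bad)
        with pytest.raises(ParameterError):
            entropy_q(bad, 2.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        weights=st.lists(st.floats(0.01, 10.0), min_size=2, max_size=8),
        q=st.floats(1.05, 4.0),
    )
    def test_nonnegative_and_maximal_at_uniform(self, weights, q):
        p = np.array(weights) / np.sum(weights)
        w = p.size
        s = entropy_q(p, q).value
        assert s >= 0
        assert s <= entropy_q(np.full(w, 1.0 / w), q).value + 1e-12


class TestQExpModel:
    def test_pdf_vanishes_at_origin_for_positive_c(self, fig1_params):
        assert qexp_pdf(0.0, fig1_params) == 0.0

    def test_pdf_closed_form_point(self):
        # a = 0.5 analytically for (b=1, c=0, h=1, q=1.5); pdf(2) = 0.5 (1+1)^(-2)
        p = QExpParams(b=1.0, c=0.0, h=1.0, q=1.5)
        assert p.a == pytest.approx(0.5, abs=1e-12)
        assert qexp_pdf(2.0, p) == pytest.approx(0.125, rel=1e-10)

    def test_fig1_density_integrates_to_one(self, fig1_params):
        val, _ = integrate.quad(lambda x: qexp_pdf(x, fig1_params), 0, np.inf, limit=200)
        assert abs(val - 1.0) < 1e-6

    def test_normalization_random_draws_quadrature(self, rng):
        for _ in range(25):
            c = rng.uniform(0.0, 5.0)
            h = rng.uniform(0.5, 2.5)
            u = rng.uniform(0.1, 0.9)
            q = 1 + u * h / (c + 1)
            b = 10 ** rng.uniform(-3, 0.5)
            params = QExpParams(b=b, c=c, h=h, q=q)
            assert abs(_pdf_mass(params) - 1.0) < 1e-6

    def test_cdf_matches_quadrature(self, fig1_params):
        # the closed-form incomplete-beta CDF against a numeric oracle
        for x in (10.0, 80.0, 400.0):
            num, _ = integrate.quad(lambda t: qexp_pdf(t, fig1_params), 0, x, limit=200)
            assert qexp_cdf(x, fig1_params) == pytest.approx(num, abs=1e-9)

    def test_ppf_inverts_cdf(self, fig1_params):
        u = np.array([0.01, 0.3, 0.5, 0.9, 0.999])
        x = qexp_ppf(u, fig1_params)
        assert np.allclose(qexp_cdf(x, fig1_params), u, atol=1e-10)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(b=-1.0, c=0.0, h=1.0, q=1.2),
            dict(b=1.0, c=-1.5, h=1.0, q=1.2),
            dict(b=1.0, c=0.0, h=-0.3, q=1.2),
            dict(b=1.0, c=0.0, h=1.0, q=0.9),
            dict(b=1.0, c=3.0, h=1.0, q=1.5),  # normalizability violated
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            QExpParams(**kwargs)

    def test_normalizability_error_names_inequality(self):
        with pytest.raises(ParameterError, match="1/\\(q-1\\)"):
            normalize_qexp(b=1.0, c=3.0, h=1.0, q=1.5)

    def test_q_upper_bound(self):
        assert q_upper_bound(c=2.24, h=1.07) == pytest.approx(1 + 1.07 / 3.24)


class TestBGModel:
    def test_unit_exponential(self):
        p = BGExpParams(b=1.0, c=0.0, h=1.0)
        assert p.a == pytest.approx(1.0)
        assert bg_pdf(1.0, p) == pytest.approx(np.exp(-1.0))
        p2 = BGExpParams(b=1.0, c=1.0, h=1.0)
        assert p2.a == pytest.approx(1.0)  # Gamma(2) = 1

    def test_pdf_vanishes_at_origin_for_positive_c(self):
        assert bg_pdf(0.0, BGExpParams(b=1.0, c=0.5, h=1.0)) == 0.0

    def test_normalization_value_against_quadrature(self):
        # 2^1.5 / Gamma(1.5) for (b=2, c=0.5, h=1)
        a = normalize_bg(2.0, 0.5, 1.0)
        assert a == pytest.approx(3.191538, abs=1e-6)
        p = BGExpParams(b=2.0, c=0.5, h=1.0)
        val, _ = integrate.quad(lambda x: bg_pdf(x, p), 0, np.inf)
        assert abs(val - 1.0) < 1e-8

    def test_ppf_inverts_cdf(self):
        p = BGExpParams(b=0.05, c=1.5, h=1.2)
        u = np.array([0.05, 0.5, 0.95])
        assert np.allclose(bg_cdf(bg_ppf(u, p), p), u, atol=1e-10)


class TestQToOneReduction:
    def test_pointwise_convergence(self):
        b, c, h = 0.5, 1.0, 1.2
        x = np.linspace(0, 100, 2001)
        bg = bg_pdf(x, BGExpParams(b=b, c=c, h=h))
        for eps, tol in [(1e-6, 1e-4), (1e-9, 1e-5)]:
            qx = qexp_pdf(x, QExpParams(b=b, c=c, h=h, q=1 + eps))
            assert np.max(np.abs(qx - bg)) < tol

    def test_normalization_limit(self):
        b, c, h = 0.3, 2.0, 0.9
        a_lim = normalize_qexp(b, c, h, q=1 + 1e-9)
        assert a_lim == pytest.approx(normalize_bg(b, c, h), rel=1e-6)
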
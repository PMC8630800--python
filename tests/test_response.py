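"""Forward-model tests: line-shape function, third-order response,
measurement-domain spectra, linear and transient absorption."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import cumulative_trapezoid

from kubofit import response as R
from kubofit.params import AxesGrid, KuboComponent, LineShapeParams
from kubofit.units import TWO_PI_C


def _hom_only(inv_t_hom=0.5, inv_t_lt=1e-9, **kw):
    kw.setdefault("a12", 0.0)
    kw.setdefault("omega01", 2162.0)
    return LineShapeParams(inv_t_hom=inv_t_hom, inv_t_lt=inv_t_lt,
                           kubo=(), **kw)


# ---------------------------------------------------------------------------
# lineshape_g


def g_by_quadrature(t, delta_sq, tau, n=40001):
    """Independent oracle: double time integral of the Kubo FFCF
    Delta^2 exp(-t/tau) on a fine grid (trapezoid, twice)."""
    ts = np.linspace(0.0, t, n)
    ffcf = delta_sq * TWO_PI_C ** 2 * np.exp(-ts / tau)
    first = cumulative_trapezoid(ffcf, ts, initial=0.0)
    return float(cumulative_trapezoid(first, ts, initial=0.0)[-1])


def test_lineshape_g_zero_and_homogeneous():
    p = _hom_only(inv_t_hom=0.229)
    assert R.lineshape_g(0.0, p) == 0.0
    assert np.isclose(R.lineshape_g(2.0, p), 0.458, rtol=1e-12)


def test_lineshape_g_kubo_matches_quadrature():
    d2, tau, t = 14.8, 3.57, 1.0
    p = LineShapeParams(inv_t_hom=1e-12, inv_t_lt=1e-13,
                        kubo=(KuboComponent(d2, tau),))
    expected = g_by_quadrature(t, d2, tau)
    got = float(R.lineshape_g(t, p))
    assert np.isclose(got, expected, rtol=1e-6)
    # frozen regression value from the quadrature oracle
    assert np.isclose(got, 0.23972, rtol=1e-3)


def test_lineshape_g_rejects_negative_time():
    with pytest.raises(ValueError):
        R.lineshape_g(-0.1, _hom_only())


@settings(deadline=None, derandomize=True, max_examples=25)
@given(d2=st.floats(0.1, 50.0), tau=st.floats(0.05, 50.0),
       k_hom=st.floats(1e-3, 2.0))
def test_lineshape_g_nondecreasing_and_additive(d2, tau, k_hom):
    t = np.linspace(0.0, 20.0, 200)
    k1 = KuboComponent(d2, tau)
    k2 = KuboComponent(0.5 * d2, 2.0 * tau)
    p12 = LineShapeParams(inv_t_hom=k_hom, inv_t_lt=1e-9, kubo=(k1, k2))
    g12 = R.lineshape_g(t, p12)
    assert np.all(np.diff(g12) >= -1e-12)
    assert g12[0] == 0.0
    # additive over FFCF components
    p1 = LineShapeParams(inv_t_hom=k_hom, inv_t_lt=1e-9, kubo=(k1,))
    p2 = LineShapeParams(inv_t_hom=1e-12, inv_t_lt=1e-13, kubo=(k2,))
    assert np.allclose(g12, R.lineshape_g(t, p1) + R.lineshape_g(t, p2),
                       rtol=1e-9, atol=1e-10)


# ---------------------------------------------------------------------------
# third_order_fid


def test_fid_factorizes_without_kubo(tiny_grid):
    p = _hom_only(inv_t_hom=0.4, inv_t_lt=0.05, a12=0.0)
    fid = R.third_order_fid(p, tiny_grid)
    t1 = tiny_grid.tau1_axis
    tw = tiny_grid.tw_axis
    t3 = tiny_grid.t3_axis
    env = (np.exp(-0.4 * t1)[:, None, None]
           * np.exp(-0.05 * tw)[None, :, None]
           * np.exp(-0.4 * t3)[None, None, :])
    # two pathways (rephasing + nonrephasing) with conjugate pump phases
    om1 = (p.omega01 - tiny_grid.omega_rf) * TWO_PI_C
    expected_abs = env * np.abs(2.0 * np.cos(om1 * t1))[:, None, None]
    assert np.allclose(np.abs(fid), expected_abs, rtol=1e-10, atol=1e-12)


def test_static_kubo_produces_rephasing_echo(tiny_grid):
    p = LineShapeParams(a01=1.0, a12=0.0, omega01=2162.0, inv_t_hom=0.05,
                        inv_t_lt=1e-6, kubo=(KuboComponent(14.8, 1e6),))
    fid = R.third_order_fid(p, tiny_grid)
    # along fixed tau1 + t3, |FID| peaks at the echo tau1 = t3
    assert abs(fid[4, 0, 4]) > abs(fid[6, 0, 2])
    assert abs(fid[4, 0, 4]) > abs(fid[2, 0, 6])


def oracle_fid(params, grid):
    """Brute-force response: g from direct numerical double integration
    of the FFCF, six-term cumulant combinations assembled term by term
    on the full 3-D time grid."""
    t1 = grid.tau1_axis[:, None, None]
    tw = grid.tw_axis[None, :, None]
    t3 = grid.t3_axis[None, None, :]
    tmax = float(grid.tau1_axis.max() + grid.tw_axis.max()
                 + grid.t3_axis.max())
    ts = np.linspace(0.0, tmax, 60001)
    ffcf = np.zeros_like(ts)
    for k in params.kubo:
        ffcf += k.delta_sq * TWO_PI_C ** 2 * np.exp(-ts / k.tau)
    first = cumulative_trapezoid(ffcf, ts, initial=0.0)
    g_tab = cumulative_trapezoid(first, ts, initial=0.0)

    def g(t):
        # delta-correlated part integrates to t/T_hom exactly
        return np.interp(t, ts, g_tab) + params.inv_t_hom * t

    beta = params.beta
    gk = lambda t: np.interp(t, ts, g_tab)  # Kubo part only
    h = (gk(t1 + tw + t3) - gk(t1 + tw) - gk(tw + t3) + gk(tw))
    k_hom = params.inv_t_hom
    esa_extra = 0.5 * (params.inv_t_lt
                       + params.inv_t_lt / params.t_lt12_ratio)
    env01_r = np.exp(-(gk(t1) + k_hom * t1) - (gk(t3) + k_hom * t3) + h)
    env01_n = np.exp(-(gk(t1) + k_hom * t1) - (gk(t3) + k_hom * t3) - h)
    env12_r = np.exp(-(gk(t1) + k_hom * t1)
                     - (beta ** 2 * gk(t3) + (k_hom + esa_extra) * t3)
                     + beta * h)
    env12_n = np.exp(-(gk(t1) + k_hom * t1)
                     - (beta ** 2 * gk(t3) + (k_hom + esa_extra) * t3)
                     - beta * h)
    om1 = (params.omega01 + params.d_omega1 - grid.omega_rf) * TWO_PI_C
    om3_01 = (params.omega01 - grid.omega_rf) * TWO_PI_C
    om3_12 = (params.omega01 - params.anh - grid.omega_rf) * TWO_PI_C
    ph_r = np.exp(-1j * om1 * t1)
    ph_n = np.conj(ph_r)
    pop = np.exp(-params.inv_t_lt * tw)
    out = pop * (
        params.a01 * np.exp(1j * om3_01 * t3) * (ph_r * env01_r
                                                 + ph_n * env01_n)
        - params.a12 * np.exp(1j * om3_12 * t3) * (ph_r * env12_r
                                                   + ph_n * env12_n))
    return out * np.exp(1j * params.phi0)


def test_fid_matches_bruteforce_cumulant(tiny_grid, one_kubo_params):
    p = one_kubo_params.replace(beta=1.1, phi0=0.2)
    fast = R.third_order_fid(p, tiny_grid)
    slow = oracle_fid(p, tiny_grid)
    scale = np.abs(slow).max()
    assert np.allclose(fast, slow, atol=5e-6 * scale)


def _ff_correlation(values, grid):
    from kubofit.cls import absorptive_series

    om1, A = absorptive_series(values, grid)
    A2 = np.clip(A[:, 0, :], 0.0, None)
    # restrict to the diagonal band around the global maximum; threshold
    # to the ridge so zero-padding sinc shoulders do not dilute the moments
    om3 = grid.omega3_axis
    i3 = np.argmax(A2.max(axis=0))
    keep1 = np.abs(om1 - om3[i3]) < 15.0
    keep3 = np.abs(om3 - om3[i3]) < 15.0
    W = A2[np.ix_(keep1, keep3)]
    W = np.clip(W - 0.25 * W.max(), 0.0, None)
    w1 = om1[keep1]
    w3 = om3[keep3]
    tot = W.sum()
    m1 = (W.sum(axis=1) * w1).sum() / tot
    m3 = (W.sum(axis=0) * w3).sum() / tot
    c11 = (W.sum(axis=1) * (w1 - m1) ** 2).sum() / tot
    c33 = (W.sum(axis=0) * (w3 - m3) ** 2).sum() / tot
    c13 = (W * np.outer(w1 - m1, w3 - m3)).sum() / tot
    return c13 / np.sqrt(c11 * c33)


def test_correlated_limit_against_bruteforce():
    grid = AxesGrid.from_time(np.arange(24) * 0.25,
                              np.array([0.0, 2.0]), 64, 0.25, 2130.0)
    p = LineShapeParams(a01=1.0, a12=0.0, omega01=2162.0, inv_t_hom=0.05,
                        inv_t_lt=1e-6, kubo=(KuboComponent(14.8, 4000.0),))
    fast = R.model_spectrum(p, grid)
    slow = R.model_spectrum(p, grid, fid=oracle_fid(p, grid))
    r_fast = _ff_correlation(fast, grid)
    r_slow = _ff_correlation(slow, grid)
    assert r_fast > 0.9
    assert r_slow > 0.9
    assert np.isclose(r_fast, r_slow, atol=1e-3)


# ---------------------------------------------------------------------------
# model_spectrum


def test_homogeneous_spectrum_is_lorentzian(tiny_grid):
    p = LineShapeParams(a01=1.0, a12=0.8, omega01=2162.0, anh=25.5,
                        inv_t_hom=0.5, inv_t_lt=1e-9, kubo=())
    spec = R.model_spectrum(p, tiny_grid)
    om3 = tiny_grid.omega3_axis
    step = om3[1] - om3[0]
    sl = spec[0, 0, :].real
    # positive 0-1 band at omega01, negative 1-2 band at omega01 - anh
    assert abs(om3[np.argmax(sl)] - 2162.0) <= step
    assert abs(om3[np.argmin(sl)] - (2162.0 - 25.5)) <= step


def test_zero_order_phase_pi_negates(tiny_grid, one_kubo_params):
    s0 = R.model_spectrum(one_kubo_params, tiny_grid)
    s_pi = R.model_spectrum(one_kubo_params.replace(phi0=np.pi), tiny_grid)
    assert np.allclose(s_pi, -s0, rtol=1e-12, atol=1e-12)


def test_spectrum_linear_in_amplitudes(tiny_grid, one_kubo_params):
    p0 = one_kubo_params.replace(a12=0.0)
    s1 = R.model_spectrum(p0, tiny_grid)
    s2 = R.model_spectrum(p0.replace(a01=2.0 * p0.a01), tiny_grid)
    assert np.array_equal(s2, 2.0 * s1)
    # general linearity in (a01, a12)
    pa = one_kubo_params.replace(a01=1.3, a12=0.0)
    pb = one_kubo_params.replace(a01=0.0, a12=0.9)
    pab = one_kubo_params.replace(a01=1.3, a12=0.9)
    assert np.allclose(R.model_spectrum(pab, tiny_grid),
                       R.model_spectrum(pa, tiny_grid)
                       + R.model_spectrum(pb, tiny_grid),
                       rtol=1e-12, atol=1e-12)


def test_fourier_consistency_roundtrip(tiny_grid, one_kubo_params):
    fid = R.third_order_fid(one_kubo_params, tiny_grid)
    spec = R.model_spectrum(one_kubo_params, tiny_grid)
    back = R.spectrum_to_fid(spec)
    assert np.allclose(back, fid, rtol=1e-10, atol=1e-12 * np.abs(fid).max())


def test_incommensurate_axis_is_rejected(tiny_grid, one_kubo_params):
    bad = AxesGrid(tau1_axis=tiny_grid.tau1_axis, tw_axis=tiny_grid.tw_axis,
                   omega3_axis=tiny_grid.omega3_axis + 0.3,
                   omega_rf=tiny_grid.omega_rf)
    with pytest.raises(ValueError):
        R.model_spectrum(one_kubo_params, bad)


# ---------------------------------------------------------------------------
# linear_absorption


def test_linear_absorption_lorentzian_limit():
    w = np.linspace(2142.0, 2182.0, 8001)
    p = _hom_only(inv_t_hom=0.229, inv_t_lt=2e-9)
    spec = R.linear_absorption(p, w)
    above = w[spec >= 0.5]
    fwhm = above.max() - above.min()
    assert np.isclose(fwhm, 2.432, rtol=0.01)


def test_linear_absorption_gaussian_limit():
    w = np.linspace(2132.0, 2192.0, 8001)
    p = LineShapeParams(a12=0.0, omega01=2162.0, inv_t_hom=1e-6,
                        inv_t_lt=1e-9, kubo=(KuboComponent(14.8, 1e6),))
    spec = R.linear_absorption(p, w)
    above = w[spec >= 0.5]
    fwhm = above.max() - above.min()
    assert np.isclose(fwhm, np.sqrt(8.0 * np.log(2.0) * 14.8), rtol=0.01)


def test_linear_absorption_dephasing_free_is_grid_limited():
    w = np.linspace(2157.0, 2167.0, 501)
    p = _hom_only(inv_t_hom=1e-7, inv_t_lt=1e-9)
    spec = R.linear_absorption(p, w)
    step = w[1] - w[0]
    assert abs(w[np.argmax(spec)] - 2162.0) <= step
    assert (spec >= 0.5).sum() <= 3  # delta-like


def test_motional_narrowing_equivalence():
    w = np.linspace(2150.0, 2174.0, 2401)
    d2, tau = 4.0, 0.02
    assert np.sqrt(d2) * tau * TWO_PI_C < 0.05
    p_kubo = LineShapeParams(a12=0.0, omega01=2162.0, inv_t_hom=0.3,
                             inv_t_lt=1e-9, kubo=(KuboComponent(d2, tau),))
    rate = d2 * tau * TWO_PI_C ** 2
    p_hom = _hom_only(inv_t_hom=0.3 + rate, inv_t_lt=1e-9)
    a = R.linear_absorption(p_kubo, w)
    b = R.linear_absorption(p_hom, w)
    assert np.max(np.abs(a - b)) < 0.01  # unit-peak spectra


# ---------------------------------------------------------------------------
# transient_absorption


def test_transient_absorption_bands_and_scaling(tiny_grid, one_kubo_params):
    p = one_kubo_params.replace(a12=0.0)
    ta = R.transient_absorption(p, tiny_grid, tw=0.0)
    om3 = tiny_grid.omega3_axis
    band = np.abs(om3 - p.omega01) < 10.0
    assert ta[band].max() > 0
    assert ta[band].max() >= np.abs(ta[~band]).max()  # single positive band
    ta2 = R.transient_absorption(p.replace(a01=2.0 * p.a01), tiny_grid, 0.0)
    assert np.allclose(ta2, 2.0 * ta, rtol=1e-12)
    with pytest.raises(KeyError):
        R.transient_absorption(p, tiny_grid, tw=0.123)
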
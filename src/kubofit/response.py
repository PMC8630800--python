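"""Forward model: Kubo line-shape function and the third-order response
of a three-level vibrational system.

The line-shape function is the double time integral of the FFCF,

    g(t) = t/T_hom + sum_i Delta_i^2 (2 pi c)^2 tau_i^2
                     [exp(-t/tau_i) + t/tau_i - 1],

with Delta_i^2 in cm^-2 and tau_i in ps (the (2 pi c)^2 factor converts
to rad^2/ps^2).  The delta-correlated term integrates to t/T_hom exactly,
so T_hom^-1 is the Lorentzian half-width-at-half-maximum rate.

Within the second-order cumulant approximation, the rephasing and
nonrephasing ground-state-bleach / stimulated-emission pathways carry
the six-term g combination

    exp[-g(t1) - g(t3) -/+ (g(t1+Tw+t3) - g(t1+Tw) - g(Tw+t3) + g(Tw))]

(- for nonrephasing, + for rephasing), while excited-state-absorption
pathways evolve on the 1-2 coherence during t3 with fluctuations fully
correlated with and scaled by beta relative to the 0-1 (cross terms
scale by beta, pure 1-2 terms by beta^2).  For a purely exponential
FFCF the cross-time combination h = g(t1+Tw+t3) - g(t1+Tw) - g(Tw+t3)
+ g(Tw) factorizes,

    h = sum_i D_i tau_i^2 exp(-Tw/tau_i) (1-exp(-t1/tau_i)) (1-exp(-t3/tau_i)),

which is what makes evaluating the model on a full (tau1, Tw, t3) grid
cheap: every 3-D quantity is built from outer products of 1-D arrays
plus two large elementwise exponentials.
"""

from __future__ import annotations

import numpy as np

from .params import AxesGrid, LineShapeParams
from .units import C_CM_PER_PS, TWO_PI_C

__all__ = [
    "lineshape_g", "third_order_fid", "model_spectrum", "spectrum_to_fid",
    "linear_absorption", "transient_absorption",
]


def _kubo_arrays(params: LineShapeParams):
    """(d2, tau) arrays with d2 converted to rad^2/ps^2."""
    if params.n_kubo == 0:
        return np.zeros(0), np.ones(0)
    d2 = np.array([k.delta_sq for k in params.kubo]) * TWO_PI_C ** 2
    tau = np.array([k.tau for k in params.kubo])
    return d2, tau


def _g_kubo(t: np.ndarray, d2: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """Kubo part of g(t) (unitless), additive over components."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for d2_i, tau_i in zip(d2, tau):
        x = t / tau_i
        # expm1 keeps precision in the motional-narrowing limit x -> 0
        out += d2_i * tau_i ** 2 * (np.expm1(-x) + x)
    return out


def lineshape_g(t, params: LineShapeParams) -> np.ndarray:
    """Line-shape function g(t) for t >= 0 (ps).  Real, g(0) = 0,
    non-decreasing, additive over FFCF components."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("lineshape_g requires t >= 0")
    d2, tau = _kubo_arrays(params)
    return params.inv_t_hom * t + _g_kubo(t, d2, tau)


def _esa_extra_rate(params: LineShapeParams) -> float:
    """Extra t3 dephasing of the 1-2 coherence from lifetime broadening:
    (1/2)(T_LT01^-1 + T_LT12^-1), with T_LT12 = t_lt12_ratio * T_LT01."""
    return 0.5 * (params.inv_t_lt + params.inv_t_lt / params.t_lt12_ratio)


def third_order_fid(params: LineShapeParams, grid: AxesGrid) -> np.ndarray:
    """Complex third-order response over (tau1, T_w, t3).

    Sum of rephasing + nonrephasing GSB/SE pathways (weight ``a01`` at
    omega01) and ESA pathways (weight ``-a12`` at omega01 - anh), with
    population decay exp(-Tw/T_LT) on all pathways, the pump-axis
    calibration offset applied during tau1 only, lifetime broadening of
    the 1-2 coherence during t3, and a global zero-order phase.
    """
    params.validate()
    t1 = grid.tau1_axis
    tw = grid.tw_axis
    t3 = grid.t3_axis
    d2, tau = _kubo_arrays(params)
    beta = params.beta

    g1 = params.inv_t_hom * t1 + _g_kubo(t1, d2, tau)          # (n1,)
    gk3 = _g_kubo(t3, d2, tau)                                  # (n3,)
    g3_01 = params.inv_t_hom * t3 + gk3
    g3_12 = params.inv_t_hom * t3 + beta ** 2 * gk3 + _esa_extra_rate(params) * t3

    # factorized cross-time combination h(tau1, Tw, t3)
    h = np.zeros((t1.size, tw.size, t3.size))
    for d2_i, tau_i in zip(d2, tau):
        f1 = -np.expm1(-t1 / tau_i)          # 1 - exp(-t1/tau)
        fw = np.exp(-tw / tau_i)
        f3 = -np.expm1(-t3 / tau_i)
        h += d2_i * tau_i ** 2 * (
            f1[:, None, None] * fw[None, :, None] * f3[None, None, :])

    eh = np.exp(h)
    if beta == 1.0:
        ehb = eh
    else:
        ehb = np.exp(beta * h)

    env1 = np.exp(-g1)[:, None, None]
    env3_01 = np.exp(-g3_01)[None, None, :]
    env3_12 = np.exp(-g3_12)[None, None, :]

    om1 = (params.omega01 + params.d_omega1 - grid.omega_rf) * TWO_PI_C
    om3_01 = (params.omega01 - grid.omega_rf) * TWO_PI_C
    om3_12 = (params.omega01 - params.anh - grid.omega_rf) * TWO_PI_C

    # detection phase convention e^{+i w t3}; rephasing pathways carry the
    # conjugate pump phase e^{-i w tau1} and the echo-forming +h envelope
    ph_r = np.exp(-1j * om1 * t1)[:, None, None]
    ph_n = np.conj(ph_r)
    ph3_01 = np.exp(1j * om3_01 * t3)[None, None, :]
    ph3_12 = np.exp(1j * om3_12 * t3)[None, None, :]

    gsb = params.a01 * env3_01 * (ph_r * eh + ph_n / eh) * ph3_01
    esa = -params.a12 * env3_12 * (ph_r * ehb + ph_n / ehb) * ph3_12

    pop = np.exp(-params.inv_t_lt * tw)[None, :, None]
    out = (gsb + esa) * env1 * pop
    if params.phi0 != 0.0:
        out = out * np.exp(1j * params.phi0)
    return out


def model_spectrum(params: LineShapeParams, grid: AxesGrid,
                   fid: np.ndarray | None = None) -> np.ndarray:
    """Complex 2D IR series in the measurement domain (tau1, T_w, omega3).

    Discrete Fourier transform of the third-order FID along t3 only,
    with the causal half-sample convention (the t3 = 0 sample enters
    with weight 1/2, the trapezoid rule for a one-sided transform) and
    the result aligned to ``grid.omega3_axis``.  Deterministic; no zero
    padding.
    """
    grid.check_commensurate()
    if fid is None:
        fid = third_order_fid(params, grid)
    s = fid.copy()
    s[..., 0] *= 0.5
    # kernel e^{-i w t}: e^{+i w t} FID components land on the +w bins
    spec = np.fft.fftshift(np.fft.fft(s, axis=-1), axes=-1)
    return spec


def spectrum_to_fid(spec: np.ndarray) -> np.ndarray:
    """Invert :func:`model_spectrum` back to the complex FID (exact
    inverse of the transform and half-sample conventions)."""
    s = np.fft.ifft(np.fft.ifftshift(spec, axes=-1), axis=-1)
    s[..., 0] *= 2.0
    return s


def linear_absorption(params: LineShapeParams, omega_axis) -> np.ndarray:
    """Linear absorption spectrum on ``omega_axis`` (cm^-1), normalized
    to unit peak:  Re int dt exp(i (w - w01) t) exp(-g(t) - t/(2 T_LT)).
    """
    params.validate()
    omega_axis = np.asarray(omega_axis, dtype=float)
    # time grid: resolve the full axis span, integrate until the envelope
    # has decayed (or a hard cap for the dephasing-free case)
    # the time step is capped at 0.1 ps so that fits restricted to a
    # sub-window of a spectrum share the discretization of the full axis
    span = max(omega_axis.max() - omega_axis.min(), 1.0) * TWO_PI_C
    dt = min(0.25 * 2.0 * np.pi / span, 0.1)
    decay = params.inv_t_hom + 0.5 * params.inv_t_lt
    d2, tau = _kubo_arrays(params)
    t_max = 50.0
    for _ in range(40):
        g_end = decay * t_max + float(_g_kubo(np.array([t_max]), d2, tau)[0])
        if g_end > 23.0 or t_max > 2e4:
            break
        t_max *= 1.6
    t = np.arange(0.0, t_max, dt)
    env = np.exp(-(params.inv_t_hom * t + _g_kubo(t, d2, tau))
                 - 0.5 * params.inv_t_lt * t)
    w = np.full(t.size, dt)
    w[0] *= 0.5
    dw = (omega_axis - params.omega01) * TWO_PI_C
    spec = np.cos(np.outer(dw, t)) @ (env * w)
    peak = spec.max()
    if peak <= 0:
        raise ValueError("degenerate absorption spectrum (no positive peak)")
    return spec / peak


def transient_absorption(params: LineShapeParams, grid: AxesGrid,
                         tw: float) -> np.ndarray:
    """Pump-probe (transient absorption) spectrum over omega3: the
    tau1 = 0 slice of the measurement-domain spectrum at waiting time
    ``tw`` (projection-slice equivalent of a spectrally integrated
    pump).  Returns the real (absorptive) part."""
    idx = np.nonzero(np.isclose(grid.tw_axis, tw, rtol=0, atol=1e-9))[0]
    if idx.size == 0:
        raise KeyError(f"tw={tw} is not on the waiting-time axis")
    sub = AxesGrid(tau1_axis=np.array([0.0, grid.dt3]),
                   tw_axis=grid.tw_axis[idx[0]:idx[0] + 1],
                   omega3_axis=grid.omega3_axis,
                   omega_rf=grid.omega_rf)
    spec = model_spectrum(params, sub)
    return spec[0, 0, :].real


def ta_peak_signal(params: LineShapeParams, grid: AxesGrid) -> float:
    """Signal magnitude used in the SNR definition: the peak magnitude
    of the 0-1 transition of the transient absorption spectrum at zero
    waiting time."""
    ta = transient_absorption(params, grid, grid.tw_axis[0])
    band = grid.omega3_axis > params.omega01 - 0.5 * params.anh
    if not band.any():
        band = slice(None)
    return float(np.max(np.abs(ta[band])))
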
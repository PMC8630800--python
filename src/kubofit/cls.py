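"""Centerline-slope (CLS) reference method.

The CLS tracks spectral diffusion through the slope of probe-frequency
peak positions against pump frequency in the absorptive 2D spectrum;
its waiting-time decay approximates the normalized inhomogeneous part
of the FFCF (within the short-time approximation, which ignores
dephasing during the coherence times and therefore biases fast
components).  The pipeline is:

1. slice the absorptive spectrum along the probe axis at each pump
   frequency and fit an asymmetric Lorentzian (Lorentzian + linear term
   + offset), locating the peak as the numerical extremum of the fitted
   function (2D Kubo line shapes are frequency-asymmetric, so the bin
   maximum or a symmetric fit would bias the centerline);
2. regress peak position on pump frequency -> CLS(T_w);
3. fit a (bi)exponential to the CLS decay -> Kubo time constants;
4. fit the upper portion of the linear absorption spectrum, holding the
   Kubo times fixed, -> absolute Kubo amplitudes and homogeneous
   dephasing, with a standard covariance and a modified covariance that
   propagates the Kubo-time uncertainty (the standard treatment assumes
   the time constants are exact and underestimates those error bars).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .params import AxesGrid, KuboComponent, LineShapeParams
from .response import linear_absorption
from .units import C_CM_PER_PS

__all__ = [
    "SliceRejected", "Centerline", "CLSDecay", "AbsorptionStepFit",
    "slice_peak", "absorptive_series", "centerline", "centerline_slope",
    "cls_decay_series", "fit_cls_decay", "fit_linear_absorption_cls",
    "absorption_tau_sensitivity", "modified_covariance",
]


class SliceRejected(ValueError):
    """Probe slice has no usable interior extremum."""


@dataclass
class Centerline:
    """Probe-peak positions versus pump frequency at one waiting time."""

    pump_points: np.ndarray
    peak_positions: np.ndarray
    tw: float

    def __post_init__(self):
        if len(self.pump_points) != len(self.peak_positions):
            raise ValueError("pump/peak arrays must have equal length")


@dataclass
class CLSDecay:
    """CLS(T_w) decay and its exponential fit."""

    tw_axis: np.ndarray
    cls_values: np.ndarray
    centerlines: list = field(default_factory=list)
    fit: dict = field(default_factory=dict)
    fit_vcov: Optional[np.ndarray] = None


def _asym_lorentzian(x, amp, x0, gamma, slope, offset):
    return amp * gamma ** 2 / ((x - x0) ** 2 + gamma ** 2) + slope * x + offset


def slice_peak(slice_vals, axis) -> float:
    """Peak position (cm^-1) of one probe slice from an asymmetric
    Lorentzian fit (Lorentzian + linear + offset), located by numerically
    finding the extremum of the fitted function rather than the max bin.

    Raises :class:`SliceRejected` when the fit has no interior extremum
    (e.g. a monotonic slice)."""
    y = np.asarray(slice_vals, dtype=float)
    x = np.asarray(axis, dtype=float)
    if y.size < 6:
        raise SliceRejected("too few points in slice")
    xc = x[int(np.argmax(y))]
    u = x - xc  # center for conditioning of the linear term
    span = x[-1] - x[0]
    p0 = (y.max() - np.median(y), 0.0, span / 6.0,
          (y[-1] - y[0]) / span, float(np.median(y)))
    try:
        popt, _ = curve_fit(
            _asym_lorentzian, u, y, p0=p0,
            bounds=([-np.inf, u[0], 1e-3 * span, -np.inf, -np.inf],
                    [np.inf, u[-1], 10.0 * span, np.inf, np.inf]),
            maxfev=4000)
    except (RuntimeError, ValueError) as err:
        raise SliceRejected(f"slice fit failed: {err}")
    amp = popt[0]
    if amp == 0:
        raise SliceRejected("flat slice")
    dense = np.linspace(u[0], u[-1], 2001)
    f = _asym_lorentzian(dense, *popt)
    idx = int(np.argmax(f)) if amp > 0 else int(np.argmin(f))
    if idx <= 1 or idx >= dense.size - 2:
        raise SliceRejected("extremum at window edge")
    # parabolic refinement on the dense evaluation
    y0, y1, y2 = f[idx - 1], f[idx], f[idx + 1]
    denom = y0 - 2.0 * y1 + y2
    shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    return float(xc + dense[idx] + shift * (dense[1] - dense[0]))


def absorptive_series(values: np.ndarray, grid: AxesGrid,
                      zero_pad: int = 8):
    """Absorptive 2D spectra over (omega1, T_w, omega3) from
    measurement-domain values.

    Fourier transforms along tau1 (half-weighted tau1 = 0 sample,
    zero-padded for pump-axis interpolation) and folds the rephasing and
    nonrephasing halves onto each other, cancelling the dispersive
    (phase-twist) parts.  Requires tau1_axis starting at 0.
    """
    if abs(grid.tau1_axis[0]) > 1e-9:
        raise ValueError("absorptive construction requires tau1_axis "
                         "starting at 0")
    z = np.array(values, dtype=complex)
    z[0] *= 0.5
    n1 = z.shape[0]
    npad = n1 * int(zero_pad)
    Z = np.fft.ifft(z, n=npad, axis=0) * npad
    Z = np.fft.fftshift(Z, axes=0)
    mirror = np.roll(Z[::-1], 1, axis=0)
    A = (Z + mirror).real
    dtau1 = grid.tau1_axis[1] - grid.tau1_axis[0]
    f = np.fft.fftshift(np.fft.fftfreq(npad, d=dtau1))
    omega1_axis = grid.omega_rf + f / C_CM_PER_PS
    return omega1_axis, A


def _probe_window(spec2d: np.ndarray, omega3_axis: np.ndarray,
                  halfwidth_fwhm: float = 1.5):
    """Window of +/- halfwidth_fwhm apparent FWHM around the 0-1 maximum."""
    i1, i3 = np.unravel_index(np.argmax(spec2d), spec2d.shape)
    prof = spec2d[i1]
    half = prof[i3] / 2.0
    lo = i3
    while lo > 0 and prof[lo - 1] >= half:
        lo -= 1
    hi = i3
    while hi < prof.size - 1 and prof[hi + 1] >= half:
        hi += 1
    fwhm = max(omega3_axis[hi] - omega3_axis[lo],
               2.0 * (omega3_axis[1] - omega3_axis[0]))
    center = omega3_axis[i3]
    return (omega3_axis >= center - halfwidth_fwhm * fwhm) & \
           (omega3_axis <= center + halfwidth_fwhm * fwhm)


def centerline(spec2d: np.ndarray, omega1_axis, omega3_axis,
               tw: float = np.nan, pump_frac: float = 0.5,
               probe_halfwidth_fwhm: float = 1.5) -> Centerline:
    """Centerline of one absorptive 2D spectrum: probe-peak positions at
    every pump frequency whose slice maximum (inside the 0-1 probe
    window) reaches ``pump_frac`` of the global maximum.  Rejected
    slices are excluded."""
    omega1_axis = np.asarray(omega1_axis, dtype=float)
    omega3_axis = np.asarray(omega3_axis, dtype=float)
    win = _probe_window(spec2d, omega3_axis, probe_halfwidth_fwhm)
    sub = spec2d[:, win]
    ax = omega3_axis[win]
    gmax = sub.max()
    rowmax = sub.max(axis=1)
    above = rowmax >= pump_frac * gmax
    # keep only the contiguous pump band on the diagonal (pump nearest
    # the probe peak); the absorptive fold leaves an anti-diagonal mirror
    # image of the band on the other side of the rotating frame, which
    # must not enter the centerline
    center3 = omega3_axis[win][np.argmax(sub[int(np.argmax(rowmax))])]
    cand = np.nonzero(above)[0]
    i1 = int(cand[np.argmin(np.abs(omega1_axis[cand] - center3))])
    lo = i1
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = i1
    while hi < above.size - 1 and above[hi + 1]:
        hi += 1
    rows = np.arange(lo, hi + 1)
    pump, peaks = [], []
    for i in rows:
        try:
            peaks.append(slice_peak(sub[i], ax))
            pump.append(omega1_axis[i])
        except SliceRejected:
            continue
    return Centerline(pump_points=np.asarray(pump),
                      peak_positions=np.asarray(peaks), tw=tw)


def centerline_slope(spec2d: np.ndarray, omega1_axis, omega3_axis,
                     tw: float = np.nan, min_points: int = 5,
                     **window_opts):
    """CLS of one 2D spectrum: unweighted linear-regression slope of the
    centerline.  0 for a separable (uncorrelated) line shape, 1 for a
    fully correlated diagonal ridge."""
    cl = centerline(spec2d, omega1_axis, omega3_axis, tw=tw, **window_opts)
    if cl.pump_points.size < min_points:
        raise ValueError(
            f"only {cl.pump_points.size} accepted centerline points "
            f"(need >= {min_points})")
    slope = np.polyfit(cl.pump_points, cl.peak_positions, 1)[0]
    return float(slope), cl


def cls_decay_series(values: np.ndarray, grid: AxesGrid,
                     zero_pad: int = 8, **window_opts) -> CLSDecay:
    """CLS(T_w) over a whole waiting-time series."""
    omega1_axis, A = absorptive_series(values, grid, zero_pad=zero_pad)
    cls_vals, lines = [], []
    for iw, tw in enumerate(grid.tw_axis):
        slope, cl = centerline_slope(A[:, iw, :], omega1_axis,
                                     grid.omega3_axis, tw=tw, **window_opts)
        cls_vals.append(slope)
        lines.append(cl)
    return CLSDecay(tw_axis=grid.tw_axis.copy(),
                    cls_values=np.asarray(cls_vals), centerlines=lines)


def _multi_exp(t, *theta):
    n_exp = len(theta) // 2
    out = np.zeros_like(t, dtype=float)
    for i in range(n_exp):
        out = out + theta[2 * i] * np.exp(-t / theta[2 * i + 1])
    if len(theta) % 2:
        out = out + theta[-1]
    return out


def fit_cls_decay(tw_axis, cls_values, n_exp: int,
                  with_offset: bool = False) -> dict:
    """Unweighted least-squares fit of sum_i a_i exp(-T_w/tau_i)
    (+ optional static offset for quasi-static components) to the CLS
    decay.  Components are returned with tau ascending.

    Returns a dict with 'amplitudes', 'taus', 'offset', 'vcov' (over the
    packed (a_1, tau_1, ..., [offset]) vector) and 'identifiable'."""
    if n_exp not in (1, 2):
        raise ValueError("n_exp must be 1 or 2")
    t = np.asarray(tw_axis, dtype=float)
    y = np.asarray(cls_values, dtype=float)
    if t.size < 2 * n_exp + 1:
        raise ValueError("too few CLS points for the requested model")
    spread = y.max() - y.min()
    if spread < 1e-6 * max(abs(y).max(), 1e-12):
        # constant decay: static-offset branch, time constants are not
        # identifiable
        return {"amplitudes": np.zeros(n_exp), "taus": np.full(n_exp, np.nan),
                "offset": float(np.mean(y)), "vcov": None,
                "identifiable": False}
    span = t.max() - max(t.min(), 1e-3)
    if n_exp == 1:
        p0 = [max(y[0], 0.1), max(span / 5.0, 0.5)]
    else:
        p0 = [max(y[0], 0.1) / 2.0, max(span / 50.0, 0.1),
              max(y[0], 0.1) / 2.0, max(span / 5.0, 1.0)]
    # time constants far beyond the observation window are unidentifiable
    tau_cap = 2.0 * t.max()
    lb = [0.0, 1e-3] * n_exp
    ub = [2.0, tau_cap] * n_exp
    if with_offset:
        p0 = p0 + [0.0]
        lb, ub = lb + [-1.0], ub + [1.0]
    popt, pcov = curve_fit(_multi_exp, t, y, p0=p0, bounds=(lb, ub),
                           maxfev=20000)
    amps = popt[0:2 * n_exp:2].copy()
    taus = popt[1:2 * n_exp:2].copy()
    order = np.argsort(taus)
    # reorder the packed vector (and vcov) so taus ascend
    idx = []
    for i in order:
        idx.extend([2 * i, 2 * i + 1])
    if with_offset:
        idx.append(2 * n_exp)
    idx = np.asarray(idx)
    popt = popt[idx]
    pcov = pcov[np.ix_(idx, idx)]
    return {"amplitudes": amps[order], "taus": taus[order],
            "offset": float(popt[-1]) if with_offset else 0.0,
            "vcov": pcov, "packed": popt, "identifiable": True}


@dataclass
class AbsorptionStepFit:
    """Result of the CLS absorption step (Kubo times held fixed)."""

    inv_t_hom: float
    delta_sq_total: float
    delta_sqs: np.ndarray
    scale: float
    offset: float
    vcov: np.ndarray          # over (inv_t_hom, delta_sq_total, scale, offset)
    modified_vcov: Optional[np.ndarray] = None
    taus: Optional[np.ndarray] = None
    fractions: Optional[np.ndarray] = None
    omega01: float = np.nan
    window: Optional[np.ndarray] = None

    @property
    def param_names(self):
        return ["inv_t_hom", "delta_sq_total", "scale", "offset"]


def _absorption_model(omega, inv_t_hom, delta_sq_total, scale, offset,
                      taus, fractions, omega01, inv_t_lt):
    kubo = tuple(KuboComponent(delta_sq=float(f * delta_sq_total),
                               tau=float(tau))
                 for f, tau in zip(fractions, taus))
    params = LineShapeParams(omega01=omega01, inv_t_hom=inv_t_hom,
                             inv_t_lt=max(inv_t_lt, 1e-9), kubo=kubo)
    return scale * linear_absorption(params, omega) + offset


def fit_linear_absorption_cls(omega, absorbance, taus_fixed,
                              fractions: Optional[Sequence] = None,
                              upper_fraction: float = 0.8,
                              inv_t_lt: float = 0.0) -> AbsorptionStepFit:
    """Fit the upper ``upper_fraction`` of a linear absorption spectrum,
    holding the Kubo time constants fixed, floating the homogeneous
    dephasing, total Kubo amplitude, linear scaling and offset.  For
    multi-component fits the relative amplitudes are fixed by the CLS
    decay amplitude fractions."""
    if not 0.0 < upper_fraction <= 1.0:
        raise ValueError("upper_fraction must be in (0, 1]")
    omega = np.asarray(omega, dtype=float)
    y = np.asarray(absorbance, dtype=float)
    taus = np.atleast_1d(np.asarray(taus_fixed, dtype=float))
    if fractions is None:
        if taus.size != 1:
            raise ValueError("multi-component fits need amplitude fractions")
        fractions = np.array([1.0])
    fractions = np.asarray(fractions, dtype=float)
    fractions = fractions / fractions.sum()
    ymax = y.max()
    if ymax <= 0:
        raise ValueError("absorption spectrum has no positive peak")
    win = y >= (1.0 - upper_fraction) * ymax
    if win.sum() < 6:
        raise ValueError("upper-fraction window is (nearly) empty")
    # center frequency fixed at the (parabolically refined) peak position
    i = int(np.argmax(y))
    if 0 < i < y.size - 1:
        denom = y[i - 1] - 2 * y[i] + y[i + 1]
        shift = 0.0 if denom == 0 else 0.5 * (y[i - 1] - y[i + 1]) / denom
        omega01 = omega[i] + shift * (omega[1] - omega[0])
    else:
        omega01 = omega[i]

    xw, yw = omega[win], y[win]

    def f(x, inv_t_hom, d2tot, scale, offset):
        return _absorption_model(x, inv_t_hom, d2tot, scale, offset,
                                 taus, fractions, omega01, inv_t_lt)

    # rough width-based initial guesses
    above_half = omega[y >= 0.5 * ymax]
    fwhm = max(above_half.max() - above_half.min(),
               2.0 * abs(omega[1] - omega[0]))
    hom_floor = max(1e-4, 0.5 * inv_t_lt * (1.0 + 1e-6))
    p0 = [max(0.3, 2.0 * hom_floor), fwhm ** 2 / (8.0 * np.log(2.0)),
          ymax, 0.0]
    popt, pcov = curve_fit(
        f, xw, yw, p0=p0,
        bounds=([hom_floor, 1e-6, 1e-12, -np.inf], [np.inf] * 4),
        maxfev=20000)
    return AbsorptionStepFit(
        inv_t_hom=float(popt[0]), delta_sq_total=float(popt[1]),
        delta_sqs=fractions * popt[1], scale=float(popt[2]),
        offset=float(popt[3]), vcov=pcov, taus=taus, fractions=fractions,
        omega01=float(omega01), window=win)


def absorption_tau_sensitivity(omega, absorbance, taus, fractions=None,
                               upper_fraction: float = 0.8,
                               inv_t_lt: float = 0.0,
                               rel_step: float = 0.01) -> np.ndarray:
    """Sensitivity S = d(absorption-fit parameters)/d(tau_k) by central
    finite differences of the constrained fit (1% tau steps by default).
    Rows follow (inv_t_hom, delta_sq_total, scale, offset)."""
    taus = np.atleast_1d(np.asarray(taus, dtype=float))
    cols = []
    for k in range(taus.size):
        h = rel_step * taus[k]
        tp, tm = taus.copy(), taus.copy()
        tp[k] += h
        tm[k] -= h
        fp = fit_linear_absorption_cls(omega, absorbance, tp, fractions,
                                       upper_fraction, inv_t_lt)
        fm = fit_linear_absorption_cls(omega, absorbance, tm, fractions,
                                       upper_fraction, inv_t_lt)
        vp = np.array([fp.inv_t_hom, fp.delta_sq_total, fp.scale, fp.offset])
        vm = np.array([fm.inv_t_hom, fm.delta_sq_total, fm.scale, fm.offset])
        cols.append((vp - vm) / (2.0 * h))
    return np.column_stack(cols)


def modified_covariance(standard_vcov: np.ndarray, dfit_dtau: np.ndarray,
                        tau_vcov: np.ndarray) -> np.ndarray:
    """Covariance of the absorption-step parameters including the
    uncertainty of the fixed Kubo time constants:
    V' = V_standard + S V_tau S^T  (so V' >= V_standard)."""
    V = np.asarray(standard_vcov, dtype=float)
    S = np.atleast_2d(np.asarray(dfit_dtau, dtype=float))
    Vt = np.atleast_2d(np.asarray(tau_vcov, dtype=float))
    eig = np.linalg.eigvalsh(0.5 * (Vt + Vt.T))
    if eig[0] < -1e-10 * max(eig[-1], 1.0):
        raise ValueError("tau covariance must be positive semi-definite")
    out = V + S @ Vt @ S.T
    return 0.5 * (out + out.T)
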
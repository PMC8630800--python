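"""Line-shape parameters and sampling grids.

The frequency-fluctuation correlation function (FFCF) is modeled as a
motionally narrowed (homogeneous) term plus a sum of Kubo components,

    <dw(t) dw(0)> = delta(t)/T_hom + sum_i Delta_i^2 exp(-t/tau_i),

for a three-level vibrational system (0-1 and anharmonically shifted
1-2 transitions).  ``LineShapeParams`` collects the fit parameters in
the units they are reported in (cm^-1, cm^-2, ps, ps^-1); conversion to
angular frequencies happens inside the response functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .units import C_CM_PER_PS, TWO_PI_C

__all__ = ["KuboComponent", "LineShapeParams", "AxesGrid", "param_names"]


@dataclass(frozen=True)
class KuboComponent:
    """One exponential FFCF component Delta^2 exp(-t/tau).

    Parameters
    ----------
    delta_sq : float
        Squared fluctuation amplitude Delta^2 in cm^-2 (>= 0).
    tau : float
        Correlation time tau in ps (> 0).
    """

    delta_sq: float
    tau: float

    def validate(self) -> None:
        if not self.delta_sq >= 0:
            raise ValueError(f"delta_sq must be >= 0, got {self.delta_sq}")
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")


@dataclass(frozen=True)
class LineShapeParams:
    """Parameters of the three-level generalized Kubo line-shape model.

    Attributes
    ----------
    a01, a12 : float
        0-1 and 1-2 peak amplitudes (arbitrary signal units).
    omega01 : float
        0-1 center frequency (cm^-1).
    d_omega1 : float
        Pump-axis calibration offset (cm^-1), modeled on the pump axis
        only (modeling it on both axes would be indistinguishable from
        the center frequency and anharmonicity).
    anh : float
        Anharmonic shift of the 1-2 transition (cm^-1).
    beta : float
        Scaling of the 1-2 Kubo fluctuation amplitude relative to the
        0-1, Delta^2(1-2) = beta^2 Delta^2(0-1), fully correlated.
    inv_t_lt : float
        Inverse vibrational lifetime T_LT^-1 (ps^-1).
    inv_t_hom : float
        Inverse homogeneous lifetime T_hom^-1 (ps^-1).  Physically
        bounded below by half the inverse vibrational lifetime.
    kubo : tuple of KuboComponent
        Exponential FFCF components.
    phi0 : float
        Optional zero-order phase error (rad) multiplying the whole
        signal.
    t_lt12_ratio : float
        Configuration (not fitted): T_LT(1-2) = t_lt12_ratio * T_LT(0-1).
        The harmonic default is 1/2.  Sets the extra lifetime-broadening
        dephasing of the 1-2 coherence.
    """

    a01: float = 1.0
    a12: float = 1.0
    omega01: float = 2160.0
    d_omega1: float = 0.0
    anh: float = 25.0
    beta: float = 1.0
    inv_t_lt: float = 0.05
    inv_t_hom: float = 0.5
    kubo: tuple = field(default_factory=tuple)
    phi0: float = 0.0
    t_lt12_ratio: float = 0.5

    def validate(self) -> None:
        if not self.inv_t_lt > 0:
            raise ValueError("inv_t_lt must be > 0")
        if not self.inv_t_hom > 0.5 * self.inv_t_lt:
            raise ValueError(
                "physical bound violated: inv_t_hom must exceed inv_t_lt/2 "
                f"(got {self.inv_t_hom} <= {0.5 * self.inv_t_lt})"
            )
        if not self.t_lt12_ratio > 0:
            raise ValueError("t_lt12_ratio must be > 0")
        for k in self.kubo:
            k.validate()

    @property
    def n_kubo(self) -> int:
        return len(self.kubo)

    # -- flat-vector interface used by the fitting engine -----------------

    def to_vector(self, fit_phi0: bool = False) -> np.ndarray:
        v = [self.a01, self.a12, self.omega01, self.d_omega1, self.anh,
             self.beta, self.inv_t_lt, self.inv_t_hom]
        for k in self.kubo:
            v.extend([k.delta_sq, k.tau])
        if fit_phi0:
            v.append(self.phi0)
        return np.asarray(v, dtype=float)

    @classmethod
    def from_vector(cls, v: Sequence[float], n_kubo: int,
                    fit_phi0: bool = False, **extra) -> "LineShapeParams":
        v = np.asarray(v, dtype=float)
        expected = 8 + 2 * n_kubo + (1 if fit_phi0 else 0)
        if v.size != expected:
            raise ValueError(f"expected {expected} parameters, got {v.size}")
        kubo = tuple(KuboComponent(delta_sq=v[8 + 2 * i], tau=v[9 + 2 * i])
                     for i in range(n_kubo))
        phi0 = float(v[-1]) if fit_phi0 else extra.pop("phi0", 0.0)
        return cls(a01=v[0], a12=v[1], omega01=v[2], d_omega1=v[3],
                   anh=v[4], beta=v[5], inv_t_lt=v[6], inv_t_hom=v[7],
                   kubo=kubo, phi0=phi0, **extra)

    # -- flat key/value serialization (units in key names) -----------------

    def to_config(self) -> dict:
        cfg = {
            "a01_au": self.a01,
            "a12_au": self.a12,
            "omega01_cm1": self.omega01,
            "d_omega1_cm1": self.d_omega1,
            "anh_cm1": self.anh,
            "beta": self.beta,
            "inv_t_lt_ps1": self.inv_t_lt,
            "inv_t_hom_ps1": self.inv_t_hom,
            "phi0_rad": self.phi0,
            "t_lt12_ratio": self.t_lt12_ratio,
        }
        for i, k in enumerate(self.kubo, start=1):
            cfg[f"kubo{i}_delta_sq_cm2"] = k.delta_sq
            cfg[f"kubo{i}_tau_ps"] = k.tau
        return cfg

    @classmethod
    def from_config(cls, cfg: dict) -> "LineShapeParams":
        kubo = []
        i = 1
        while f"kubo{i}_delta_sq_cm2" in cfg:
            kubo.append(KuboComponent(delta_sq=float(cfg[f"kubo{i}_delta_sq_cm2"]),
                                      tau=float(cfg[f"kubo{i}_tau_ps"])))
            i += 1
        return cls(
            a01=float(cfg.get("a01_au", 1.0)),
            a12=float(cfg.get("a12_au", 1.0)),
            omega01=float(cfg.get("omega01_cm1", 2160.0)),
            d_omega1=float(cfg.get("d_omega1_cm1", 0.0)),
            anh=float(cfg.get("anh_cm1", 25.0)),
            beta=float(cfg.get("beta", 1.0)),
            inv_t_lt=float(cfg.get("inv_t_lt_ps1", 0.05)),
            inv_t_hom=float(cfg.get("inv_t_hom_ps1", 0.5)),
            phi0=float(cfg.get("phi0_rad", 0.0)),
            t_lt12_ratio=float(cfg.get("t_lt12_ratio", 0.5)),
            kubo=tuple(kubo),
        )

    def replace(self, **kw) -> "LineShapeParams":
        return replace(self, **kw)


def param_names(n_kubo: int, fit_phi0: bool = False) -> list:
    """Names of the flat parameter vector entries, in engine order."""
    names = ["a01", "a12", "omega01", "d_omega1", "anh", "beta",
             "inv_t_lt", "inv_t_hom"]
    for i in range(1, n_kubo + 1):
        names.extend([f"delta_sq_{i}", f"tau_{i}"])
    if fit_phi0:
        names.append("phi0")
    return names


#: parameter names regarded as dephasing parameters (plus per-component
#: delta_sq_i / tau_i); everything else is nondephasing.
DEPHASING_BASE = ("inv_t_hom",)


def dephasing_mask(n_kubo: int, fit_phi0: bool = False) -> np.ndarray:
    """Boolean mask over the flat vector marking dephasing parameters
    (Kubo amplitudes, Kubo time constants, inverse homogeneous lifetime)."""
    names = param_names(n_kubo, fit_phi0)
    return np.array([n == "inv_t_hom" or n.startswith(("delta_sq_", "tau_"))
                     for n in names])


@dataclass(frozen=True)
class AxesGrid:
    """Sampling axes of a 2D IR waiting-time series in the measurement
    domain (tau1, T_w, omega3).

    tau1_axis : uniform, strictly increasing pump coherence delays (ps)
    tw_axis   : strictly increasing waiting times (ps, any spacing)
    omega3_axis : uniform, strictly increasing probe frequencies (cm^-1),
        commensurate with an FFT grid around ``omega_rf``
    omega_rf  : rotating-frame frequency (cm^-1)
    unit_conv : cm^-1 -> rad/ps conversion factor (2*pi*c)
    """

    tau1_axis: np.ndarray
    tw_axis: np.ndarray
    omega3_axis: np.ndarray
    omega_rf: float
    unit_conv: float = TWO_PI_C

    def __post_init__(self):
        object.__setattr__(self, "tau1_axis",
                           np.asarray(self.tau1_axis, dtype=float))
        object.__setattr__(self, "tw_axis",
                           np.asarray(self.tw_axis, dtype=float))
        object.__setattr__(self, "omega3_axis",
                           np.asarray(self.omega3_axis, dtype=float))
        self.validate()

    def validate(self) -> None:
        for name in ("tau1_axis", "omega3_axis"):
            ax = getattr(self, name)
            d = np.diff(ax)
            if ax.size < 2 or np.any(d <= 0):
                raise ValueError(f"{name} must be strictly increasing")
            if not np.allclose(d, d[0], rtol=1e-8, atol=1e-10):
                raise ValueError(f"{name} must be uniformly spaced")
        if np.any(np.diff(self.tw_axis) <= 0):
            raise ValueError("tw_axis must be strictly increasing")
        if not self.unit_conv > 0:
            raise ValueError("unit_conv must be > 0")

    @classmethod
    def from_time(cls, tau1_axis, tw_axis, n_t3: int, dt3: float,
                  omega_rf: float) -> "AxesGrid":
        """Build a grid from the probe time sampling (n_t3 points at dt3
        ps steps); the probe-frequency axis is the FFT axis around the
        rotating frame."""
        f = np.fft.fftshift(np.fft.fftfreq(n_t3, d=dt3))  # cycles/ps
        omega3 = omega_rf + f / C_CM_PER_PS
        return cls(tau1_axis=np.asarray(tau1_axis, float),
                   tw_axis=np.asarray(tw_axis, float),
                   omega3_axis=omega3, omega_rf=float(omega_rf))

    @property
    def shape(self) -> tuple:
        return (self.tau1_axis.size, self.tw_axis.size, self.omega3_axis.size)

    @property
    def n_t3(self) -> int:
        return self.omega3_axis.size

    @property
    def dt3(self) -> float:
        """Probe time step (ps) implied by the omega3 axis span."""
        n = self.omega3_axis.size
        d_nu = self.omega3_axis[1] - self.omega3_axis[0]  # cm^-1
        return 1.0 / (n * d_nu * C_CM_PER_PS)

    @property
    def t3_axis(self) -> np.ndarray:
        return np.arange(self.n_t3) * self.dt3

    def check_commensurate(self) -> None:
        """Verify omega3_axis is the FFT axis implied by its own
        span/spacing and omega_rf; raise on mismatch."""
        f = np.fft.fftshift(np.fft.fftfreq(self.n_t3, d=self.dt3))
        expected = self.omega_rf + f / C_CM_PER_PS
        if not np.allclose(expected, self.omega3_axis, rtol=0, atol=1e-6):
            raise ValueError(
                "omega3_axis is not commensurate with the FFT grid implied "
                "by its span/spacing and omega_rf")
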
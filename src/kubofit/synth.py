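"""Synthetic 2D IR datasets and preprocessing.

Noise is added to the free induction decay (both quadratures for a
complex-valued FID) at a standard deviation set by the requested SNR,
where the signal is the peak magnitude of the 0-1 transition of the
transient absorption spectrum at zero waiting time.  The noisy FID is
carried through the same probe-axis transform as the model, so data and
model share noise statistics in the fitted (tau1, T_w, omega3) domain.

Also provides waiting-time undersampling masks, cubic-spline probe-axis
linearization, and apodization-window inversion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.interpolate import CubicSpline

from .params import AxesGrid, KuboComponent, LineShapeParams
from .response import model_spectrum, spectrum_to_fid, ta_peak_signal, third_order_fid

__all__ = [
    "SpectralDataset", "SamplingMask", "simulate_dataset", "make_mask",
    "interpolate_probe_axis", "invert_apodization",
    "save_dataset", "load_dataset",
    "mescn_h2o_truth", "mescn_h2o_grid", "mescn_h2o_bounds",
    "dmso_like_tw_axis_47",
]


@dataclass
class SpectralDataset:
    """A 2D IR waiting-time series in the measurement domain.

    values : array over (tau1, T_w, omega3), real or complex
    grid   : AxesGrid
    weights: per-datum inverse variances (diagonal), same shape;
             proportionality to the true inverse variances suffices
    provenance : truth parameters, seed and SNR when synthetic
    """

    values: np.ndarray
    grid: AxesGrid
    weights: Optional[np.ndarray] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")
        if self.weights is None:
            self.weights = np.ones(self.values.shape)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != self.values.shape:
            raise ValueError("weights shape does not match values")
        if np.any(self.weights < 0):
            raise ValueError("weights must be >= 0")

    @property
    def is_complex(self) -> bool:
        return np.iscomplexobj(self.values)

    def subset_tw(self, kept: np.ndarray) -> "SpectralDataset":
        """Dataset restricted to the kept waiting times."""
        kept = np.asarray(kept, dtype=bool)
        grid = AxesGrid(tau1_axis=self.grid.tau1_axis,
                        tw_axis=self.grid.tw_axis[kept],
                        omega3_axis=self.grid.omega3_axis,
                        omega_rf=self.grid.omega_rf)
        prov = dict(self.provenance)
        prov["tw_mask"] = kept.tolist()
        return SpectralDataset(values=self.values[:, kept, :], grid=grid,
                               weights=self.weights[:, kept, :],
                               provenance=prov)


@dataclass
class SamplingMask:
    """Waiting-time undersampling mask."""

    kept_tw: np.ndarray
    stride: int
    exclude_before: float

    def __post_init__(self):
        self.kept_tw = np.asarray(self.kept_tw, dtype=bool)
        if self.kept_tw.sum() < 2:
            raise ValueError("a sampling mask must keep at least 2 points")

    @property
    def n_kept(self) -> int:
        return int(self.kept_tw.sum())


def simulate_dataset(truth: LineShapeParams, grid: AxesGrid,
                     snr: Optional[float],
                     rng: Union[int, np.random.Generator, None] = None,
                     complex_fid: bool = True) -> SpectralDataset:
    """Simulate a noisy waiting-time series at the given SNR.

    ``snr=None`` (or ``np.inf``) produces the noiseless model spectrum.
    Noise of standard deviation sigma = signal/snr is added i.i.d. to
    the FID (each quadrature when complex) before the probe transform.
    """
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    fid = third_order_fid(truth, grid)
    if not complex_fid:
        fid = fid.real.astype(complex)
    sigma = 0.0
    if snr is not None and np.isfinite(snr):
        if not snr > 0:
            raise ValueError("snr must be > 0")
        sigma = ta_peak_signal(truth, grid) / snr
        noise = gen.normal(0.0, sigma, size=fid.shape)
        if complex_fid:
            noise = noise + 1j * gen.normal(0.0, sigma, size=fid.shape)
        fid = fid + noise
    values = model_spectrum(truth, grid, fid=fid)
    if not complex_fid:
        # a real FID still transforms to a complex spectrum; fitting uses
        # both parts, the redundancy is carried in the weights convention
        pass
    prov = {"truth": truth.to_config(), "snr": snr, "seed": seed,
            "complex_fid": complex_fid, "noise_sigma_fid": sigma}
    return SpectralDataset(values=values, grid=grid, provenance=prov)


def make_mask(tw_axis, k: int, pivot: float = 1.0,
              exclude_before: float = 0.3) -> SamplingMask:
    """Keep every k-th waiting time left and right of ``pivot``.

    The stride is anchored at the point nearest the pivot (always kept)
    and runs outward in both directions; the final waiting time is
    always kept, and points before ``exclude_before`` (pulse-overlap
    window) are always dropped."""
    tw = np.asarray(tw_axis, dtype=float)
    if k < 1:
        raise ValueError("stride k must be >= 1")
    eligible = np.nonzero(tw >= exclude_before)[0]
    if eligible.size == 0:
        raise ValueError("all waiting times fall in the exclusion window")
    anchor = int(np.argmin(np.abs(tw[eligible] - pivot)))
    pos = np.arange(eligible.size)
    sel = (pos - anchor) % k == 0
    sel[anchor] = True
    sel[-1] = True
    kept = np.zeros(tw.size, dtype=bool)
    kept[eligible[sel]] = True
    if kept.sum() < 2:
        raise ValueError("mask keeps fewer than 2 waiting times")
    return SamplingMask(kept_tw=kept, stride=k, exclude_before=exclude_before)


def interpolate_probe_axis(values: np.ndarray, nonuniform_axis,
                           target_uniform_axis) -> np.ndarray:
    """Cubic-spline interpolation of each (tau1, T_w) probe slice from a
    (possibly) nonuniform probe axis onto a uniform target axis.
    Extrapolation is refused."""
    x = np.asarray(nonuniform_axis, dtype=float)
    xt = np.asarray(target_uniform_axis, dtype=float)
    d = np.diff(x)
    if np.all(d < 0):
        x = x[::-1]
        values = values[..., ::-1]
    elif not np.all(d > 0):
        raise ValueError("probe axis must be strictly monotonic")
    if xt.min() < x[0] - 1e-12 or xt.max() > x[-1] + 1e-12:
        raise ValueError("target axis extends beyond the measured span")
    flat = values.reshape(-1, x.size)
    if np.iscomplexobj(flat):
        out = (CubicSpline(x, flat.real, axis=1)(xt)
               + 1j * CubicSpline(x, flat.imag, axis=1)(xt))
    else:
        out = CubicSpline(x, flat, axis=1)(xt)
    return out.reshape(values.shape[:-1] + (xt.size,))


def invert_apodization(values_timedomain: np.ndarray, window,
                       dc_half_scaled: bool = False,
                       floor: float = 0.05):
    """Divide out a nonrectangular apodization window.

    Points where |window| < floor * max|window| are zeroed (returned
    weight factor 0) to avoid near-divide-by-zero; if the original
    filter half-scaled the DC component, the t=0 bin is restored by a
    factor of 2.  Returns (deapodized values, weight factors).
    """
    w = np.asarray(window, dtype=float)
    vals = np.asarray(values_timedomain)
    if w.size != vals.shape[-1]:
        raise ValueError("window length must match the time axis")
    wmax = np.abs(w).max()
    good = np.abs(w) >= floor * wmax
    if not good.any() or wmax == 0:
        raise ValueError("apodization window is entirely below the floor")
    inv = np.zeros_like(w)
    inv[good] = 1.0 / w[good]
    out = vals * inv
    if dc_half_scaled:
        out[..., 0] = out[..., 0] * 2.0
    weight_factor = np.broadcast_to(good.astype(float), vals.shape).copy()
    return out, weight_factor


# ---------------------------------------------------------------------------
# container file (HDF5 + plain-text manifest)


def save_dataset(path: str, ds: SpectralDataset) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=ds.values)
        f.create_dataset("weights", data=ds.weights)
        f.create_dataset("tau1_axis_ps", data=ds.grid.tau1_axis)
        f.create_dataset("tw_axis_ps", data=ds.grid.tw_axis)
        f.create_dataset("omega3_axis_cm1", data=ds.grid.omega3_axis)
        f.attrs["omega_rf_cm1"] = ds.grid.omega_rf
        f.attrs["provenance_json"] = json.dumps(ds.provenance)
    manifest = {
        "file": str(path),
        "shape": list(ds.values.shape),
        "complex": bool(ds.is_complex),
        "omega_rf_cm1": ds.grid.omega_rf,
        "provenance": ds.provenance,
    }
    with open(str(path) + ".manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def load_dataset(path: str) -> SpectralDataset:
    import h5py

    with h5py.File(path, "r") as f:
        values = f["values"][...]
        weights = f["weights"][...] if "weights" in f else None
        grid = AxesGrid(tau1_axis=f["tau1_axis_ps"][...],
                        tw_axis=f["tw_axis_ps"][...],
                        omega3_axis=f["omega3_axis_cm1"][...],
                        omega_rf=float(f.attrs["omega_rf_cm1"]))
        prov = json.loads(f.attrs.get("provenance_json", "{}"))
    return SpectralDataset(values=values, grid=grid, weights=weights,
                           provenance=prov)


# ---------------------------------------------------------------------------
# documented study fixtures


def mescn_h2o_truth() -> LineShapeParams:
    """Two-Kubo truth in the regime of the C#N stretch of MeSCN in
    water: a fast (~0.5 ps) and a slower (~3 ps) spectral-diffusion
    component on top of substantial homogeneous dephasing, a ~12 ps
    vibrational lifetime, and a ~25.5 cm^-1 anharmonic shift."""
    return LineShapeParams(
        a01=1.0, a12=1.15, omega01=2162.0, d_omega1=0.0, anh=25.5,
        beta=1.1, inv_t_lt=1.0 / 12.0, inv_t_hom=0.55,
        kubo=(KuboComponent(delta_sq=11.0, tau=0.5),
              KuboComponent(delta_sq=14.0, tau=3.0)),
    )


def mescn_h2o_grid() -> AxesGrid:
    """Desk-scale sampling grid: 16 pump delays at 250 fs, 45 waiting
    times out to 28 ps (dense where the fast component decays), and a
    64-point probe axis (250 fs steps -> ~133 cm^-1 span around the
    rotating frame, placed 32 cm^-1 below the 0-1 band so the rephasing
    and nonrephasing coherence orders separate on the pump axis)."""
    tau1 = np.arange(16) * 0.25
    tw = np.concatenate([
        np.arange(0.0, 2.0, 0.1),          # 20 points
        np.arange(2.0, 6.0, 0.25),         # 16 points
        np.array([6.5, 7.5, 9.0, 11.0, 13.5, 16.5, 20.0, 24.0, 28.0]),
    ])
    return AxesGrid.from_time(tau1_axis=tau1, tw_axis=tw, n_t3=64,
                              dt3=0.25, omega_rf=2130.0)


def mescn_h2o_bounds() -> np.ndarray:
    """Fitting bounds for the 12-parameter two-Kubo model: wide enough
    that random restarts explore, narrow enough to avoid perpetual
    boundary stalling, with the two Kubo time windows on different time
    scales (overlapping) to avoid degenerate pairs."""
    return np.array([
        [0.2, 5.0],       # a01
        [0.2, 5.0],       # a12
        [2158.0, 2166.0],  # omega01
        [-1.0, 1.0],      # d_omega1
        [20.0, 30.0],     # anh
        [0.7, 1.6],       # beta
        [0.02, 0.25],     # inv_t_lt
        [0.1, 1.5],       # inv_t_hom
        [0.5, 40.0],      # delta_sq_1
        [0.1, 2.0],       # tau_1
        [0.5, 40.0],      # delta_sq_2
        [1.0, 10.0],      # tau_2
    ])


def dmso_like_tw_axis_47() -> np.ndarray:
    """A 47-point waiting-time axis shaped like a long-lifetime (-SCN in
    DMSO) measurement: two pulse-overlap points inside 300 fs, five
    points up to 1 ps, and 40 points log-spaced from 1 to 150 ps.  With
    the pulse-overlap exclusion the full mask keeps 45 points and the
    stride-3 mask keeps 15."""
    return np.concatenate([
        np.array([0.0, 0.2]),
        np.arange(0.4, 0.85, 0.1),
        np.geomspace(1.0, 150.0, 40),
    ])
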
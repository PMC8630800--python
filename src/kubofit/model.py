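"""Model / Results objects: the public fitting interface.

``KuboLineShapeModel`` wraps a :class:`~kubofit.synth.SpectralDataset`
and a generalized Kubo line-shape forward model; ``fit()`` runs the
Gauss-Newton/SIGN engine and returns a :class:`KuboFitResult` carrying
estimates, standard errors, 95% confidence intervals, VIFs, iteration
traces and a ``summary()`` table.  ``CLSAnalysis`` runs the
centerline-slope reference pipeline on the same dataset and returns a
:class:`CLSResult` with standard and modified covariances side by side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from . import cls as cls_mod
from . import diagnostics, engine
from .params import AxesGrid, LineShapeParams, dephasing_mask, param_names
from .response import linear_absorption, model_spectrum
from .synth import SpectralDataset

__all__ = ["KuboLineShapeModel", "KuboFitResult", "CLSAnalysis", "CLSResult"]


def _flatten(values: np.ndarray) -> np.ndarray:
    if np.iscomplexobj(values):
        return np.concatenate([values.real.ravel(), values.imag.ravel()])
    return np.asarray(values, dtype=float).ravel()


class KuboLineShapeModel:
    """Three-level generalized Kubo line-shape model bound to a dataset.

    Parameters
    ----------
    dataset : SpectralDataset
        Measurement-domain waiting-time series with axes and weights.
    n_kubo : int
        Number of exponential FFCF components.
    fixed : dict, optional
        Parameter name -> value for parameters held constant during the
        fit (any of the names in :func:`kubofit.params.param_names`).
    fit_phi0 : bool
        Float a zero-order phase error as a 13th parameter.
    bounds : dict or (n_free, 2) array
        Per-parameter [lo, hi]; a dict maps parameter names (free
        parameters only need entries when overriding the defaults).
    t_lt12_ratio : float
        T_LT(1-2)/T_LT(0-1) configuration of the ESA lifetime broadening.
    """

    #: default bounds by base name, used when the caller gives none
    _DEFAULT_BOUNDS = {
        "a01": (1e-3, 100.0), "a12": (1e-3, 100.0),
        "omega01": (1000.0, 4000.0), "d_omega1": (-2.0, 2.0),
        "anh": (1.0, 100.0), "beta": (0.3, 3.0),
        "inv_t_lt": (1e-4, 2.0), "inv_t_hom": (1e-3, 5.0),
        "delta_sq": (1e-3, 200.0), "tau": (1e-3, 1e3),
        "phi0": (-3.2, 3.2),
    }

    def __init__(self, dataset: SpectralDataset, n_kubo: int = 2,
                 fixed: Optional[dict] = None, fit_phi0: bool = False,
                 bounds: Union[dict, np.ndarray, None] = None,
                 t_lt12_ratio: float = 0.5):
        self.dataset = dataset
        self.grid: AxesGrid = dataset.grid
        self.n_kubo = int(n_kubo)
        self.fit_phi0 = bool(fit_phi0)
        self.t_lt12_ratio = float(t_lt12_ratio)
        self.all_names = param_names(self.n_kubo, self.fit_phi0)
        fixed = dict(fixed or {})
        unknown = set(fixed) - set(self.all_names)
        if unknown:
            raise ValueError(f"unknown fixed parameters: {sorted(unknown)}")
        self.fixed = fixed
        self.free_names = [n for n in self.all_names if n not in fixed]
        self.free_idx = np.array([self.all_names.index(n)
                                  for n in self.free_names])
        self.bounds = self._resolve_bounds(bounds)
        self.data = _flatten(dataset.values)
        w = dataset.weights.ravel()
        self.weights = (np.concatenate([w, w])
                        if dataset.is_complex else w)
        self._template = np.zeros(len(self.all_names))
        for name, val in fixed.items():
            self._template[self.all_names.index(name)] = val

    # ------------------------------------------------------------------

    def _resolve_bounds(self, bounds) -> np.ndarray:
        if bounds is not None and not isinstance(bounds, dict):
            b = np.asarray(bounds, dtype=float)
            if b.shape == (len(self.free_names), 2):
                return b
            if b.shape == (len(self.all_names), 2):
                return b[self.free_idx]
            raise ValueError("bounds array has the wrong shape")
        out = []
        bd = bounds or {}
        for name in self.free_names:
            if name in bd:
                out.append(tuple(bd[name]))
                continue
            base = name
            if name.startswith("delta_sq_"):
                base = "delta_sq"
            elif name.startswith("tau_"):
                base = "tau"
            out.append(self._DEFAULT_BOUNDS[base])
        return np.asarray(out, dtype=float)

    def params_from_free(self, x: np.ndarray) -> LineShapeParams:
        v = self._template.copy()
        v[self.free_idx] = np.asarray(x, dtype=float)
        return LineShapeParams.from_vector(
            v, self.n_kubo, fit_phi0=self.fit_phi0,
            t_lt12_ratio=self.t_lt12_ratio)

    def free_from_params(self, params: LineShapeParams) -> np.ndarray:
        return params.to_vector(self.fit_phi0)[self.free_idx]

    def eval_flat(self, x: np.ndarray) -> np.ndarray:
        """Flattened (real) model vector at the free-parameter vector x."""
        return _flatten(model_spectrum(self.params_from_free(x), self.grid))

    def _ratio_floors(self):
        names = self.free_names
        if "inv_t_hom" in names and "inv_t_lt" in names:
            return ((names.index("inv_t_hom"), names.index("inv_t_lt"), 0.5),)
        return ()

    def default_options(self, seed: Optional[int] = None,
                        **overrides) -> engine.FitOptions:
        opts = engine.FitOptions(bounds=self.bounds,
                                 ratio_floors=self._ratio_floors())
        if seed is not None:
            opts.rng_seed = int(seed)
        for k, v in overrides.items():
            if not hasattr(opts, k):
                raise TypeError(f"unknown fit option {k!r}")
            setattr(opts, k, v)
        return opts

    def random_start(self, rng=None) -> np.ndarray:
        rng = np.random.default_rng(rng) if not isinstance(
            rng, np.random.Generator) else rng
        return engine.random_restart(self.bounds, rng, self._ratio_floors())

    def fit(self, start: Union[np.ndarray, LineShapeParams, str, None] = None,
            seed: Optional[int] = None,
            options: Optional[engine.FitOptions] = None,
            **opt_overrides) -> "KuboFitResult":
        """Fit the model.

        ``start`` may be a free-parameter vector, a
        :class:`LineShapeParams`, the string ``"random"`` (uniform
        in-bounds, seeded), or None (bound-box midpoint).
        """
        if options is None:
            options = self.default_options(seed=seed, **opt_overrides)
        elif opt_overrides:
            raise TypeError("pass either options or keyword overrides")
        if isinstance(start, str):
            if start != "random":
                raise ValueError(f"unknown start {start!r}")
            p0 = self.random_start(np.random.default_rng(options.rng_seed))
        elif isinstance(start, LineShapeParams):
            p0 = self.free_from_params(start)
        elif start is None:
            p0 = self.bounds.mean(axis=1)
        else:
            p0 = np.asarray(start, dtype=float)
        res = engine.fit(self.eval_flat, self.data, self.weights, p0, options)
        res = self._canonicalize(res)
        return KuboFitResult(model=self, engine_result=res)

    def _canonicalize(self, res: engine.FitResult) -> engine.FitResult:
        """Order Kubo components by ascending time constant (when the
        swapped values stay inside both slots' bounds), so component
        labels are comparable across fits."""
        names = self.free_names
        pairs = []
        for i in range(1, self.n_kubo + 1):
            if f"tau_{i}" in names and f"delta_sq_{i}" in names:
                pairs.append((names.index(f"delta_sq_{i}"),
                              names.index(f"tau_{i}")))
        if len(pairs) < 2:
            return res
        p = res.p_hat
        taus = [p[t] for (_, t) in pairs]
        order = np.argsort(taus)
        if np.all(order == np.arange(len(pairs))):
            return res
        perm = np.arange(p.size)
        for dst, src in enumerate(order):
            perm[pairs[dst][0]] = pairs[src][0]
            perm[pairs[dst][1]] = pairs[src][1]
        p_new = p[perm]
        b = self.bounds
        if np.any(p_new < b[:, 0]) or np.any(p_new > b[:, 1]):
            return res
        res.p_hat = p_new
        res.sigma = res.sigma[perm]
        res.ci95 = res.ci95[perm]
        res.vif = res.vif[perm]
        res.vcov = res.vcov[np.ix_(perm, perm)]
        res.state.p = p_new
        return res

    def jacobian_at(self, params_or_x) -> np.ndarray:
        """Central-difference Jacobian of the flattened model at a point
        (free-parameter space)."""
        x = (self.free_from_params(params_or_x)
             if isinstance(params_or_x, LineShapeParams)
             else np.asarray(params_or_x, dtype=float))
        return engine.jacobian(self.eval_flat, x, self.bounds,
                               ratio_floors=self._ratio_floors())


@dataclass
class KuboFitResult:
    """Fit results: estimates, uncertainties, diagnostics, traces."""

    model: KuboLineShapeModel
    engine_result: engine.FitResult

    @property
    def params(self) -> LineShapeParams:
        return self.model.params_from_free(self.engine_result.p_hat)

    @property
    def p_hat(self) -> np.ndarray:
        return self.engine_result.p_hat

    @property
    def names(self):
        return self.model.free_names

    @property
    def bse(self) -> np.ndarray:
        return self.engine_result.sigma

    @property
    def ci95(self) -> np.ndarray:
        return self.engine_result.ci95

    @property
    def vif(self) -> np.ndarray:
        return self.engine_result.vif

    @property
    def vcov(self) -> np.ndarray:
        return self.engine_result.vcov

    @property
    def cost(self) -> float:
        return self.engine_result.cost

    @property
    def status(self) -> str:
        return self.engine_result.state.status

    @property
    def state(self) -> engine.FitState:
        return self.engine_result.state

    @property
    def dof(self) -> int:
        return self.model.data.size - len(self.names)

    def predict(self) -> np.ndarray:
        """Model spectrum at the fitted parameters."""
        return model_spectrum(self.params, self.model.grid)

    def resid(self) -> np.ndarray:
        """Residual cube (data - model) in the measurement domain."""
        return self.model.dataset.values - self.predict()

    def predicted_linear_absorption(self, omega_axis) -> np.ndarray:
        """Linear absorption spectrum predicted by the 2D fit."""
        return linear_absorption(self.params, omega_axis)

    def dephasing_names(self):
        mask = dephasing_mask(self.model.n_kubo, self.model.fit_phi0)
        all_names = self.model.all_names
        deph = {all_names[i] for i in range(len(all_names)) if mask[i]}
        return [n for n in self.names if n in deph]

    def summary(self) -> str:
        lines = []
        st = self.state
        lines.append("Generalized Kubo line-shape fit (Gauss-Newton / SIGN)")
        lines.append("=" * 68)
        lines.append(f"status: {self.status}    iterations: "
                     f"{len(st.cost_trace)}    restarts: "
                     f"{len(st.restart_log)}    model evals: "
                     f"{st.n_model_evals}")
        final_sign = st.sign_trace[-1] if st.sign_trace else np.nan
        lines.append(f"cost: {self.cost:.6e}    dof: {self.dof}    "
                     f"final SIGN: {final_sign:.3e}")
        lines.append("-" * 68)
        lines.append(f"{'parameter':>12} {'estimate':>14} {'std err':>12} "
                     f"{'95% CI +/-':>12} {'VIF':>10}")
        for i, n in enumerate(self.names):
            lines.append(f"{n:>12} {self.p_hat[i]:>14.6g} "
                         f"{self.bse[i]:>12.3g} {self.ci95[i]:>12.3g} "
                         f"{self.vif[i]:>10.3g}")
        if np.any(st.boundary_active):
            act = [self.names[i] for i in np.nonzero(st.boundary_active)[0]]
            lines.append(f"boundary-active parameters: {', '.join(act)}")
        lines.append("=" * 68)
        return "\n".join(lines)

    def plot_traces(self, ax=None):
        """Cost and SIGN versus iteration (restarts appear as jumps)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        it = np.arange(len(self.state.cost_trace))
        ax.semilogy(it, self.state.cost_trace, label="cost C(p)")
        ax.semilogy(it, self.state.sign_trace, label="SIGN")
        for (i, reason) in self.state.restart_log:
            ax.axvline(i, color="0.8", zorder=0)
        ax.set_xlabel("iteration")
        ax.legend()
        return ax

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "cost": self.cost,
            "dof": self.dof,
            "names": list(self.names),
            "estimates": self.p_hat.tolist(),
            "std_errors": self.bse.tolist(),
            "ci95": self.ci95.tolist(),
            "vif": self.vif.tolist(),
            "restarts": self.state.restart_log,
            "n_model_evals": self.state.n_model_evals,
        }


class CLSAnalysis:
    """Centerline-slope analysis of a waiting-time series.

    Needs a linear absorption spectrum (two arrays or a two-column ASCII
    file) for the amplitude step; without one only the CLS decay and
    time constants are available.
    """

    def __init__(self, dataset: SpectralDataset, absorption=None,
                 n_exp: int = 1, inv_t_lt: float = 0.0,
                 upper_fraction: float = 0.8, with_offset: bool = False,
                 zero_pad: int = 8, pump_frac: float = 0.5,
                 probe_halfwidth_fwhm: float = 1.5):
        self.dataset = dataset
        if isinstance(absorption, str):
            arr = np.loadtxt(absorption)
            absorption = (arr[:, 0], arr[:, 1])
        self.absorption = absorption
        self.n_exp = int(n_exp)
        self.inv_t_lt = float(inv_t_lt)
        self.upper_fraction = float(upper_fraction)
        self.with_offset = bool(with_offset)
        self.window_opts = {"pump_frac": pump_frac,
                            "probe_halfwidth_fwhm": probe_halfwidth_fwhm}
        self.zero_pad = int(zero_pad)

    def fit(self) -> "CLSResult":
        values = self.dataset.values
        decay = cls_mod.cls_decay_series(values, self.dataset.grid,
                                         zero_pad=self.zero_pad,
                                         **self.window_opts)
        dfit = cls_mod.fit_cls_decay(decay.tw_axis, decay.cls_values,
                                     self.n_exp, self.with_offset)
        decay.fit = dfit
        decay.fit_vcov = dfit.get("vcov")
        astep = None
        if self.absorption is not None and dfit["identifiable"]:
            omega, ab = self.absorption
            fracs = dfit["amplitudes"] / dfit["amplitudes"].sum()
            astep = cls_mod.fit_linear_absorption_cls(
                omega, ab, dfit["taus"], fracs, self.upper_fraction,
                self.inv_t_lt)
            S = cls_mod.absorption_tau_sensitivity(
                omega, ab, dfit["taus"], fracs, self.upper_fraction,
                self.inv_t_lt)
            tau_idx = np.array([2 * i + 1 for i in range(self.n_exp)])
            tau_vcov = dfit["vcov"][np.ix_(tau_idx, tau_idx)]
            astep.modified_vcov = cls_mod.modified_covariance(
                astep.vcov, S, tau_vcov)
        return CLSResult(decay=decay, absorption_step=astep,
                         n_exp=self.n_exp)


@dataclass
class CLSResult:
    """CLS pipeline results: decay, time constants, amplitude step."""

    decay: cls_mod.CLSDecay
    absorption_step: Optional[cls_mod.AbsorptionStepFit]
    n_exp: int

    @property
    def taus(self) -> np.ndarray:
        return np.asarray(self.decay.fit["taus"])

    @property
    def tau_sigma(self) -> np.ndarray:
        v = self.decay.fit.get("vcov")
        if v is None:
            return np.full(self.n_exp, np.nan)
        idx = [2 * i + 1 for i in range(self.n_exp)]
        return np.sqrt(np.diag(v)[idx])

    def dephasing_estimates(self) -> dict:
        """CLS estimates of the dephasing parameters (tau_i, delta_sq_i,
        inv_t_hom); amplitudes require the absorption step."""
        out = {}
        for i, tau in enumerate(self.taus, start=1):
            out[f"tau_{i}"] = float(tau)
        if self.absorption_step is not None:
            a = self.absorption_step
            for i, d2 in enumerate(a.delta_sqs, start=1):
                out[f"delta_sq_{i}"] = float(d2)
            out["inv_t_hom"] = float(a.inv_t_hom)
        return out

    def summary(self) -> str:
        lines = ["Centerline-slope analysis", "=" * 68]
        f = self.decay.fit
        lines.append(f"CLS(Tw=0) = {self.decay.cls_values[0]:.4f} over "
                     f"{self.decay.tw_axis.size} waiting times")
        if not f["identifiable"]:
            lines.append("CLS decay is constant: time constants not "
                         f"identifiable; static offset {f['offset']:.4f}")
            return "\n".join(lines)
        for i in range(self.n_exp):
            lines.append(f"  component {i+1}: a = {f['amplitudes'][i]:.4f}, "
                         f"tau = {f['taus'][i]:.4g} ps "
                         f"(+/- {self.tau_sigma[i]:.2g})")
        if self.absorption_step is None:
            lines.append("no absorption spectrum: Kubo amplitudes and "
                         "homogeneous dephasing skipped")
            return "\n".join(lines)
        a = self.absorption_step
        sd_std = np.sqrt(np.diag(a.vcov))
        sd_mod = (np.sqrt(np.diag(a.modified_vcov))
                  if a.modified_vcov is not None else np.full(4, np.nan))
        lines.append("-" * 68)
        lines.append("absorption step (Kubo times held fixed), 95% CI "
                     "half-widths:")
        lines.append(f"{'parameter':>16} {'estimate':>12} "
                     f"{'standard':>12} {'modified':>12}")
        vals = [a.inv_t_hom, a.delta_sq_total, a.scale, a.offset]
        for i, n in enumerate(a.param_names):
            lines.append(f"{n:>16} {vals[i]:>12.5g} "
                         f"{1.96*sd_std[i]:>12.3g} {1.96*sd_mod[i]:>12.3g}")
        for i, d2 in enumerate(a.delta_sqs, start=1):
            lines.append(f"  delta_sq_{i} = {d2:.5g} cm^-2 "
                         f"(fraction {a.fractions[i-1]:.3f})")
        lines.append("=" * 68)
        return "\n".join(lines)
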
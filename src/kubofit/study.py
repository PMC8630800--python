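"""Simulation-study harness: coverage, precision and bias of model
fitting versus the CLS method on synthetic ensembles, and VIF scenarios.

Every trial draws fresh FID noise and a fresh random starting point;
trials are reproducible from (master seed, trial index) alone, so the
CLS pass can re-simulate the identical datasets without storing them.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import diagnostics
from .cls import fit_linear_absorption_cls
from .model import CLSAnalysis, KuboLineShapeModel
from .params import LineShapeParams, dephasing_mask, param_names
from .response import linear_absorption
from .synth import (SpectralDataset, mescn_h2o_bounds, mescn_h2o_grid,
                    mescn_h2o_truth, simulate_dataset)

__all__ = [
    "default_study", "DEPHASING_NAMES", "NONDEPHASING_NAMES",
    "simulate_trial", "fit_trial", "run_fit_ensemble", "coverage_by_parameter",
    "cls_trial", "run_cls_ensemble", "vif_at_truth",
    "precision_ratios", "cls_mean_abs_bias", "absorption_vif_scenarios",
]

DEPHASING_NAMES = ["inv_t_hom", "delta_sq_1", "tau_1", "delta_sq_2", "tau_2"]
NONDEPHASING_NAMES = ["a01", "a12", "omega01", "d_omega1", "anh", "beta",
                      "inv_t_lt"]


def default_study():
    """(truth, grid, bounds) of the documented two-Kubo study fixture."""
    return mescn_h2o_truth(), mescn_h2o_grid(), mescn_h2o_bounds()


def _trial_rng(master_seed: int, trial: int) -> np.random.Generator:
    return np.random.default_rng([int(master_seed), int(trial)])


def simulate_trial(master_seed: int, trial: int, snr: float = 600.0,
                   truth: Optional[LineShapeParams] = None,
                   grid=None) -> SpectralDataset:
    """Re-create the dataset of one ensemble trial (deterministic in
    (master_seed, trial))."""
    if truth is None or grid is None:
        t0, g0, _ = default_study()
        truth = truth or t0
        grid = grid if grid is not None else g0
    rng = _trial_rng(master_seed, trial)
    return simulate_dataset(truth, grid, snr=snr, rng=rng)


def fit_trial(master_seed: int, trial: int, snr: float = 600.0,
              truth=None, grid=None, bounds=None, **fit_opts) -> dict:
    """Simulate one trial and fit all 12 parameters from a random
    in-bounds start.  Returns estimates, CIs and convergence info."""
    if truth is None or grid is None or bounds is None:
        t0, g0, b0 = default_study()
        truth = truth or t0
        grid = grid if grid is not None else g0
        bounds = bounds if bounds is not None else b0
    ds = simulate_trial(master_seed, trial, snr, truth, grid)
    m = KuboLineShapeModel(ds, n_kubo=truth.n_kubo, bounds=bounds)
    rng = _trial_rng(master_seed, trial)
    rng = np.random.default_rng(rng.integers(2 ** 31))  # independent of noise
    p0 = m.random_start(rng)
    res = m.fit(start=p0, seed=int(rng.integers(2 ** 31)), **fit_opts)
    truth_vec = m.free_from_params(truth)
    cost_truth = float(np.sum(m.weights * (m.data - m.eval_flat(truth_vec)) ** 2))
    return {
        "trial": trial,
        "names": list(res.names),
        "p_hat": res.p_hat.copy(),
        "ci95": res.ci95.copy(),
        "sigma": res.bse.copy(),
        "status": res.status,
        "cost": res.cost,
        "cost_at_truth": cost_truth,
        "n_restarts": len(res.state.restart_log),
        "n_iters": len(res.state.cost_trace),
        "truth_vec": truth_vec,
    }


def run_fit_ensemble(n_trials: int, master_seed: int, snr: float = 600.0,
                     truth=None, grid=None, bounds=None,
                     **fit_opts) -> list:
    return [fit_trial(master_seed, t, snr, truth, grid, bounds, **fit_opts)
            for t in range(n_trials)]


def coverage_by_parameter(records: list, names=None) -> dict:
    """Fraction of trials whose 95% CI contains the true value, per
    parameter."""
    names = names or records[0]["names"]
    out = {}
    for n in names:
        k = records[0]["names"].index(n)
        hits = [abs(r["p_hat"][k] - r["truth_vec"][k]) <= r["ci95"][k]
                for r in records]
        out[n] = float(np.mean(hits))
    return out


def _absorption_axis(truth: LineShapeParams):
    return np.arange(truth.omega01 - 30.0, truth.omega01 + 30.0 + 1e-9, 0.25)


def cls_trial(master_seed: int, trial: int, snr: float = 600.0,
              truth=None, grid=None) -> dict:
    """Analyze one ensemble trial with the CLS pipeline: asymmetric-
    Lorentzian centerlines, (bi)exponential decay fit including Tw = 0,
    and the amplitude step on the noiseless simulated linear absorption
    (upper 80%)."""
    if truth is None or grid is None:
        t0, g0, _ = default_study()
        truth = truth or t0
        grid = grid if grid is not None else g0
    ds = simulate_trial(master_seed, trial, snr, truth, grid)
    omega = _absorption_axis(truth)
    ab = linear_absorption(truth, omega)
    ana = CLSAnalysis(ds, absorption=(omega, ab), n_exp=truth.n_kubo,
                      inv_t_lt=truth.inv_t_lt)
    res = ana.fit()
    est = res.dephasing_estimates()
    est["trial"] = trial
    est["cls0"] = float(res.decay.cls_values[0])
    return est


def run_cls_ensemble(n_trials: int, master_seed: int, snr: float = 600.0,
                     truth=None, grid=None) -> list:
    out = []
    for t in range(n_trials):
        try:
            out.append(cls_trial(master_seed, t, snr, truth, grid))
        except (ValueError, RuntimeError):
            continue  # a failed CLS trial is part of the comparison
    return out


def _truth_map(truth: LineShapeParams) -> dict:
    v = truth.to_vector()
    return dict(zip(param_names(truth.n_kubo), v))


def precision_ratios(fit_records: list, cls_records: list,
                     names=("tau_1", "tau_2")) -> dict:
    """Across-trial std of CLS estimates / std of model-fit estimates."""
    out = {}
    for n in names:
        k = fit_records[0]["names"].index(n)
        fit_vals = np.array([r["p_hat"][k] for r in fit_records])
        cls_vals = np.array([r[n] for r in cls_records if n in r])
        out[n] = float(np.std(cls_vals, ddof=1) / np.std(fit_vals, ddof=1))
    return out


def cls_mean_abs_bias(cls_records: list, truth: LineShapeParams,
                      names=DEPHASING_NAMES) -> dict:
    """Mean |estimate/truth - 1| per dephasing parameter (fractions)."""
    tv = _truth_map(truth)
    out = {}
    for n in names:
        vals = np.array([r[n] for r in cls_records if n in r])
        out[n] = float(np.mean(np.abs(vals / tv[n] - 1.0)))
    return out


def vif_at_truth(truth: Optional[LineShapeParams] = None, grid=None,
                 bounds=None) -> dict:
    """VIFs of the full model-fitting Jacobian evaluated at the truth on
    the full sampling grid with uniform weights."""
    if truth is None or grid is None:
        t0, g0, b0 = default_study()
        truth = truth or t0
        grid = grid if grid is not None else g0
        bounds = bounds if bounds is not None else b0
    ds = simulate_dataset(truth, grid, snr=None)
    m = KuboLineShapeModel(ds, n_kubo=truth.n_kubo, bounds=bounds)
    J = m.jacobian_at(truth)
    rep = diagnostics.vif(J, m.weights)
    vifs = dict(zip(m.free_names, rep.vif))
    deph = [n for n in m.free_names if n in DEPHASING_NAMES]
    nondeph = [n for n in m.free_names if n not in DEPHASING_NAMES]
    return {
        "vif": vifs,
        "condition_flag": rep.condition_flag,
        "max_dephasing": max(vifs[n] for n in deph),
        "max_nondephasing": max(vifs[n] for n in nondeph),
    }


def absorption_vif_scenarios(truth: Optional[LineShapeParams] = None,
                             grid=None, upper_fraction: float = 0.8) -> dict:
    """VIFs for the three ways of extracting dephasing parameters:

    naive -- fitting amplitude, all five dephasing parameters and an
    offset to the linear absorption spectrum;
    cls_constrained -- the CLS absorption step (times held fixed);
    model_fitting -- the full 2D waiting-time fit.
    """
    if truth is None or grid is None:
        t0, g0, _ = default_study()
        truth = truth or t0
        grid = grid if grid is not None else g0
    omega = _absorption_axis(truth)
    ab = linear_absorption(truth, omega)
    win = ab >= (1.0 - upper_fraction) * ab.max()
    xw = omega[win]

    taus = np.array([k.tau for k in truth.kubo])
    d2s = np.array([k.delta_sq for k in truth.kubo])

    def naive_model(p):
        inv_t_hom = p[0]
        kubo = tuple(
            type(truth.kubo[0])(delta_sq=p[2 + 2 * i], tau=p[1 + 2 * i])
            for i in range(truth.n_kubo))
        params = truth.replace(inv_t_hom=inv_t_hom, kubo=kubo)
        return p[-2] * linear_absorption(params, xw) + p[-1]

    p_naive = np.concatenate([[truth.inv_t_hom],
                              np.column_stack([taus, d2s]).ravel(),
                              [1.0, 0.0]])
    from .engine import jacobian
    J_naive = jacobian(naive_model, p_naive, rel_step=1e-4)
    naive = diagnostics.vif(J_naive)

    def cls_model(p):
        fr = d2s / d2s.sum()
        kubo = tuple(type(truth.kubo[0])(delta_sq=float(fr[i] * p[1]),
                                         tau=float(taus[i]))
                     for i in range(truth.n_kubo))
        params = truth.replace(inv_t_hom=p[0], kubo=kubo)
        return p[2] * linear_absorption(params, xw) + p[3]

    p_cls = np.array([truth.inv_t_hom, d2s.sum(), 1.0, 0.0])
    J_cls = jacobian(cls_model, p_cls, rel_step=1e-4)
    cls_c = diagnostics.vif(J_cls)

    mf = vif_at_truth(truth, grid)
    return {
        "naive": naive.vif,
        "naive_names": (["inv_t_hom"]
                        + [x for i in range(truth.n_kubo)
                           for x in (f"tau_{i+1}", f"delta_sq_{i+1}")]
                        + ["scale", "offset"]),
        "cls_constrained": cls_c.vif,
        "cls_names": ["inv_t_hom", "delta_sq_total", "scale", "offset"],
        "model_fitting": mf["vif"],
    }
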
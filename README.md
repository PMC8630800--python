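# kubofit

Least-squares fitting of two-dimensional infrared (2D IR) waiting-time
series to generalized Kubo line-shape models.

2D IR spectroscopy tracks spectral diffusion of a vibrational probe
(e.g. the C≡N stretch of a thiocyanate label) through the evolution of
the 2D line shape with waiting time T_w.  The statistical object of
interest is the frequency-fluctuation correlation function (FFCF),

    ⟨δω(t) δω(0)⟩ = δ(t)/T_hom + Σᵢ Δᵢ² exp(−t/τᵢ),

a motionally narrowed (homogeneous) term plus one or more Kubo
components with amplitudes Δᵢ² (cm⁻²) and correlation times τᵢ (ps).
The dominant practice is the centerline-slope (CLS) method: measure the
slope of probe-frequency peak positions against pump frequency at each
waiting time, fit its decay for the τᵢ, then fit the linear absorption
spectrum for absolute amplitudes and homogeneous dephasing.  `kubofit`
implements the alternative: fit the full waiting-time series directly to
the response function of a three-level vibrational system, in the
measurement domain (τ₁, T_w, ω₃), by Gauss–Newton least squares — and
implements the CLS pipeline beside it as the reference method, including
the usually-neglected propagation of Kubo-time uncertainty into the
absorption-step error bars.

The package provides:

- **`response`** — the forward model: line-shape function g(t) (double
  time integral of the FFCF), rephasing/nonrephasing ground-state
  bleach/stimulated emission and excited-state absorption pathways of a
  three-level system with anharmonic shift and β-scaled 1–2
  fluctuations, measurement-domain 2D spectra, linear and transient
  absorption.
- **`engine`** — Gauss–Newton iteration with finite-difference
  Jacobians, Armijo backtracking, box bounds (plus the physical bound
  T_hom⁻¹ > ½T_LT⁻¹), and convergence/stall control through the **scale
  invariant gradient norm** SIGN = ‖∇C ⊙ σ_p‖ / C_prev, a stopping
  metric invariant to the scaling of data, weights and problem size
  (threshold 10⁻⁹).  Stalls — step collapse at boundaries or from
  multicollinearity — are detected from flat SIGN/cost windows and
  resolved by random restarts.
- **`diagnostics`** — parameter covariance V_p = [C/(N_D−N_p)](JᵀWJ)⁻¹,
  normal-quantile confidence intervals, variance inflation factors
  (VIFs) from the column-normalized Jacobian, and first-order
  data-perturbation propagation dp = (JᵀWJ)⁻¹JᵀW dD.
- **`cls`** — the CLS reference method: asymmetric-Lorentzian
  (Lorentzian + linear + offset) slice fits, centerline regression,
  (bi)exponential decay fits, the constrained linear-absorption
  amplitude step, and the modified covariance
  V′ = V + S V_τ Sᵀ that propagates Kubo-time uncertainty.
- **`synth`** — synthetic datasets with Gaussian noise added to the
  free induction decay at a defined SNR, waiting-time undersampling
  masks, probe-axis spline linearization, apodization-window inversion,
  and an HDF5 container with a plain-text manifest.
- **`kubofit`** (CLI) — `simulate` / `fit` / `cls` / `vif` subcommands
  driven by YAML configs, with plain-text + JSON reports.

## Worked example

Simulate a one-Kubo waiting-time series at 600:1 SNR, fit all ten
parameters from a random in-bounds start, and compare with the CLS
analysis of the same data:

```python
import numpy as np
from kubofit import (AxesGrid, KuboComponent, LineShapeParams,
                     KuboLineShapeModel, CLSAnalysis, simulate_dataset)

truth = LineShapeParams(
    a01=1.0, a12=1.1, omega01=2162.0, anh=25.5, beta=1.0,
    inv_t_lt=0.0833, inv_t_hom=0.5,
    kubo=(KuboComponent(delta_sq=12.0, tau=2.5),))
grid = AxesGrid.from_time(
    tau1_axis=np.arange(16) * 0.25,
    tw_axis=np.array([0.0, 0.3, 0.6, 1.0, 1.5, 2.2, 3.2,
                      4.7, 7.0, 10.0, 15.0, 22.0]),
    n_t3=64, dt3=0.25, omega_rf=2130.0)

data = simulate_dataset(truth, grid, snr=600.0, rng=7)
model = KuboLineShapeModel(data, n_kubo=1, bounds={
    "a01": (0.2, 5), "a12": (0.2, 5), "omega01": (2158, 2166),
    "d_omega1": (-1, 1), "anh": (20, 30), "beta": (0.7, 1.6),
    "inv_t_lt": (0.02, 0.25), "inv_t_hom": (0.1, 1.5),
    "delta_sq_1": (0.5, 40), "tau_1": (0.5, 10)})
result = model.fit(start="random", seed=3)
print(result.summary())
```

```
Generalized Kubo line-shape fit (Gauss-Newton / SIGN)
====================================================================
status: converged    iterations: 11    restarts: 0    model evals: 262
cost: 3.765907e+02    dof: 24566    final SIGN: 2.383e-10
--------------------------------------------------------------------
   parameter       estimate      std err   95% CI +/-        VIF
         a01       0.997354      0.00246      0.00482       3.58
         a12        1.09667      0.00278      0.00544       3.92
     omega01           2162      0.00834       0.0163       2.83
    d_omega1    -0.00168189       0.0102       0.0201       2.17
         anh         25.492       0.0124       0.0244       1.95
        beta       0.996372      0.00455      0.00893       1.77
    inv_t_lt      0.0829736     0.000314     0.000615       1.83
   inv_t_hom       0.498427      0.00352       0.0069         26
  delta_sq_1        12.0212        0.179        0.352       23.5
       tau_1        2.52646       0.0602        0.118       4.67
```

Every estimate sits within its 95% confidence interval of the truth
(e.g. Δ² = 12.02 ± 0.35 cm⁻² against a true 12, τ = 2.53 ± 0.12 ps
against 2.5), the final SIGN has dropped below the 10⁻⁹ stopping
threshold, and the VIF column shows the characteristic pattern:
near-orthogonal nondephasing parameters (VIF 2–4) and moderately
collinear dephasing parameters (VIF ~25).

The CLS analysis of the same dataset (with a noiseless simulated linear
absorption spectrum for the amplitude step):

```python
from kubofit.response import linear_absorption
omega = np.arange(2132.0, 2192.01, 0.25)
cls_res = CLSAnalysis(data, absorption=(omega, linear_absorption(truth, omega)),
                      n_exp=1, inv_t_lt=truth.inv_t_lt).fit()
print(cls_res.summary())
```

```
Centerline-slope analysis
====================================================================
CLS(Tw=0) = 0.3153 over 12 waiting times
  component 1: a = 0.3255, tau = 2.564 ps (+/- 0.35)
--------------------------------------------------------------------
absorption step (Kubo times held fixed), 95% CI half-widths:
       parameter     estimate     standard     modified
       inv_t_hom      0.50832     0.000174       0.0868
  delta_sq_total       11.716      0.00353         2.95
           scale       1.0011     4.18e-05       0.0117
          offset   -0.0011166     4.09e-05       0.0117
```

The CLS time constant carries a ~3× wider confidence interval than the
model fit (0.35 vs 0.12 ps), and the "standard" absorption-step error
bars — computed as if the Kubo time were known exactly — are hundreds of
times smaller than the "modified" ones that propagate the time-constant
uncertainty: the standard treatment drastically overstates the
precision of CLS-derived Kubo amplitudes and homogeneous dephasing.

The same workflow is available from the shell:

```sh
kubofit simulate --config config.yaml --seed 7 --out data.h5
kubofit fit --config config.yaml --dataset data.h5 --seed 3 --out run/
kubofit cls --dataset data.h5 --components 1 --out run/
```

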
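# Methods

## Model

Data are modeled as the isotropic third-order response of a three-level
vibrational system (v = 0, 1, 2) with frequency fluctuations described
by a generalized Kubo FFCF,

    ⟨δω01(t) δω01(0)⟩ = δ(t)/T_hom + Σᵢ Δᵢ² exp(−t/τᵢ),

and 1–2 fluctuations fully correlated with the 0–1 and scaled by β,
δω12 = β δω01.  Within the second-order cumulant approximation every
pathway envelope is built from the line-shape function

    g(t) = t·T_hom⁻¹ + Σᵢ Δᵢ²(2πc)² τᵢ² [e^(−t/τᵢ) + t/τᵢ − 1],

the double time integral of the FFCF.  Amplitudes Δᵢ² are carried in
cm⁻², times in ps; conversion to rad²/ps² happens inside g via
(2πc)², c = 0.0299792458 cm/ps.  The delta-correlated term integrates to
t·T_hom⁻¹ exactly, making T_hom⁻¹ the Lorentzian HWHM rate.

The rephasing/nonrephasing ground-state-bleach + stimulated-emission
pathways (weight a01, frequency ω01) carry the standard six-term
combination exp[−g(τ1) − g(t3) ± h] with

    h = g(τ1+T_w+t3) − g(τ1+T_w) − g(T_w+t3) + g(T_w)

(+ for rephasing, − for nonrephasing); excited-state-absorption pathways
(weight −a12, frequency ω01 − Δ_anh) evolve on the 1–2 coherence during
t3, with cross terms scaled by β and pure 1–2 terms by β².  For an
exponential FFCF, h factorizes per component as
Δ̃ᵢ²τᵢ² e^(−T_w/τᵢ)(1−e^(−τ1/τᵢ))(1−e^(−t3/τᵢ)), so a full
(τ1, T_w, t3) evaluation costs two large elementwise exponentials plus
outer products (~2 ms on the study grid); this factorized fast path is
verified in the tests against a brute-force construction that integrates
the FFCF numerically (twice, trapezoid) and assembles the six g terms
directly.

All pathways decay with the population factor exp(−T_w·T_LT⁻¹).  The
1–2 coherence acquires an additional lifetime-broadening dephasing rate
½(T_LT,01⁻¹ + T_LT,12⁻¹) during t3, with the harmonic default
T_LT,12 = T_LT,01/2 exposed as `t_lt12_ratio`; the exact magnitude of
this correction is a modeling choice, and the validation relies on
closed-form limits and round-trip recovery, which are insensitive to it.
A pump-axis calibration offset δω1 shifts the frequency during τ1 only
(modeling it on both axes would be collinear with ω01 and Δ_anh), and an
optional zero-order phase multiplies the whole signal.

Orientational contributions are not parameterized separately: for the
isotropic response, pure dephasing, lifetime and orientational
relaxation are mutually unidentifiable inside T_hom, so the model
carries only T_hom⁻¹ and T_LT⁻¹ together with the physical bound
T_hom⁻¹ > ½T_LT⁻¹ enforced at every step.

**Measurement domain.**  Fitting happens in (τ1, T_w, ω3): the FID is
Fourier transformed along t3 only, with the t3 = 0 sample half-weighted
(trapezoid/causal convention) and no zero padding, onto a frequency
axis commensurate with the rotating frame ω_rf.  The transform is
exactly invertible (`spectrum_to_fid`), and the tests check the round
trip to < 10⁻¹⁰.  Complex-valued datasets are fitted as stacked real and
imaginary parts; real-valued FIDs are supported through the same path.

**Linear absorption** is Re ∫ dt e^{i(ω−ω01)t} e^{−g(t) − t/(2T_LT)},
normalized to unit peak, evaluated by direct quadrature on a time grid
whose step is capped at 0.1 ps so that fits restricted to a sub-window
of a spectrum share the discretization of the full axis.

## Optimizer

Gauss–Newton with the exact bookkeeping C = rᵀWr, ∇C = −2rᵀWJ,
∇∇C ≈ 2JᵀWJ, Δp = (JᵀWJ)⁻¹JᵀWr.  The Jacobian uses central differences
(exactly 2N_p model evaluations) with step 10⁻⁴·max(|p_k|, bounds
width); evaluation points are clipped into the feasible region (box and
ratio-floor constraints) and the divided difference uses the actual
point separation.  Each Gauss–Newton target is projected onto the
feasible box *before* the Armijo backtracking line search (c₁ = 10⁻⁴,
shrink ½, ≤ 25 backtracks): the box and the half-space
T_hom⁻¹ > ½T_LT⁻¹ are convex, so every backtracked fraction of the
projected step stays feasible, and accepted iterations never increase
the cost.

**Stopping and stalling.**  Convergence and stalls are judged by the
scale invariant gradient norm

    SIGN_i = ‖∇C_i ⊙ σ_p,i‖₂ / C_{i−1},

with σ_p the per-parameter standard errors from the covariance at the
current iterate and the cost taken from the previous iteration (better
behaved across restarts).  SIGN is invariant to rescaling data and model
by a common factor, to rescaling the weights, and to N_D (verified to
10⁻¹² in the tests).  The run stops when the last three iterations have
SIGN < 10⁻⁹ and costs within 10% of the best ever seen; it stalls when
SIGN and cost are both flat to 1% over three iterations without meeting
the stop test, when ∇∇C is nearly singular (reciprocal condition
< 10⁻¹², a threshold the method statement leaves open), or when the line
search fails.  Stalls trigger a uniform random restart within the
bounds (default budget 20); an exhausted budget returns a result flagged
`budget_exhausted`, never an exception.  The norm-of-elementwise-product
reading of SIGN is the default; the scalar-product reading |∇C·σ_p| is
exposed as `sign_mode="dot"` for comparison, since it can cancel between
parameters.

Two floating-point guards matter on noiseless data, where the minimum
cost is 0: costs at the roundoff floor of the data norm
((4ε)²·‖D‖²_W) short-circuit SIGN to 0 and count as "at the best cost"
in the stop test, and once SIGN is below threshold the (numerically
meaningless) step is skipped while the three-iteration window fills.

**Covariance and VIF.**  V_p = [C(p̂)/(N_D−N_p)]·(JᵀWJ)⁻¹; the reduced-χ²
prefactor makes V_p independent of the arbitrary proportionality of the
weights.  Confidence intervals use normal quantiles (N_D ≫ N_p in every
use case).  VIFs are the diagonal of the true inverse (never a
pseudo-inverse) of the column-normalized Gram matrix; inversions with
reciprocal condition below 10⁻¹⁴, negative diagonals, or entries above
10¹² set a condition flag — degenerate Kubo pairs (τ₁ ≈ τ₂) are the
canonical trigger.

## CLS reference method

Absorptive 2D spectra are built from the measurement-domain values by a
τ1 transform (half-weighted τ1 = 0 sample, 8× zero padding for pump
interpolation) and folding the two coherence orders onto each other.
This requires the rotating frame to be placed off-resonance so that
rephasing and nonrephasing bands separate on the pump axis (the study
fixture puts ω_rf 32 cm⁻¹ below the band); the centerline uses only the
contiguous pump band on the diagonal, since the fold leaves an
anti-diagonal mirror image on the other side of ω_rf.

Centerline points are the numerically located extrema of asymmetric
Lorentzian (Lorentzian + linear + offset) fits to probe slices — 2D Kubo
line shapes are frequency-asymmetric, so bin maxima or symmetric fits
bias the centerline.  The slice window is ±1.5 apparent FWHM around the
0–1 maximum and the pump window is the contiguous set of slices
reaching 50% of the global maximum (neither window is prescribed by the
method statement; both are exposed as options).  Slices without an
interior extremum are rejected; a centerline needs ≥ 5 accepted points.
CLS(T_w) is the unweighted regression slope, and the decay is fitted by
an unweighted (bi)exponential including T_w = 0, with time constants
capped at twice the waiting-time span (beyond the observation window
they are unidentifiable and the fit would otherwise chase tail noise).

The amplitude step fits scale·A(ω; T_hom⁻¹, Δ_tot²) + offset to the
upper 80% of the linear absorption spectrum, holding the Kubo times at
the CLS-decay values and splitting Δ_tot² by the CLS amplitude fractions
(standard practice; the method statement fixes only the times).  Its
standard covariance treats the times as exact; the modified covariance

    V′ = V + S V_τ Sᵀ,

with S the sensitivity of the fitted parameters to the fixed times
(central differences of the constrained fit, 1% τ steps) and V_τ the
time-constant covariance from the decay fit, restores the missing
uncertainty.  A Monte-Carlo refit oracle validates V′ to 20% on a toy
problem in the tests.

## Synthetic data and the simulation study

`simulate_dataset` adds i.i.d. Gaussian noise to the FID (both
quadratures when complex) with σ = signal/SNR, where the signal is the
peak magnitude of the 0–1 band of the T_w = 0 transient absorption
spectrum; the noisy FID then passes through the same probe transform as
the model, so data and model share noise statistics in the fitted
domain.  Undersampling masks keep every k-th waiting time left and right
of a 1 ps pivot (anchored at the point nearest the pivot, final point
always kept, points inside the 300 fs pulse-overlap window always
dropped).

The documented study fixture is a two-Kubo system in the regime of the
C≡N stretch of MeSCN in water: ω01 = 2162 cm⁻¹, Δ_anh = 25.5 cm⁻¹,
β = 1.1, T_LT = 12 ps, T_hom⁻¹ = 0.55 ps⁻¹, (Δ₁², τ₁) = (11 cm⁻², 0.5 ps),
(Δ₂², τ₂) = (14 cm⁻², 3 ps), zero true calibration offset (still
fitted).  The grid is 16 pump delays × 45 waiting times (dense to 6 ps,
log-like to 28 ps ≈ 2.3 lifetimes) × 64 probe points at 250 fs steps —
a desk-scale problem (~10⁵ real data values) chosen so that the full
100-trial ensemble fits and the 40-trial CLS analysis together run in
about ten minutes on one CPU.  Fitting bounds put the two Kubo windows
on different, overlapping time scales (0.1–2 and 1–10 ps) to avoid
degenerate pairs, per the recommended practice for multi-component
models.  Kubo components are relabeled by ascending τ after each fit so
labels are comparable across trials.

What the synthetic ensembles do *not* emulate: correlated
(local-oscillator) noise, scatter and solvent backgrounds, structured
residual signals (e.g. low-frequency wave-packet responses), phase-cycle
details, or FTIR baseline distortions.  Passing tests therefore
demonstrate the statistical machinery under the stated noise model, not
robustness to every artifact of real measurements; the weights interface
(diagonal inverse variances) is the hook for nonuniform averaging, and a
zero-order phase parameter covers residual phasing errors.

Because the study grid is ~20× smaller than a full measurement, the
parameter standard errors are several times larger than a full-size
study would give, and the noisy CLS analysis sits close to the regime
where centerline fits occasionally become unphysical; the CLS-to-model
precision ratios and CLS inaccuracies measured here are therefore larger
than a full-size study would produce, while coverage of the model-fit
confidence intervals is unaffected.

## Known limitations

- Single oscillator only: no coupled modes, overlapping ensembles,
  oscillatory FFCFs, or polarization-resolved (anisotropic) response.
- Diagonal data covariance only; correlated noise must be removed
  upstream (e.g. calibrated referencing).
- The ESA lifetime-broadening magnitude and the CLS slice/pump windows
  are conventions, exposed as options rather than measured quantities.
- The absorptive construction assumes τ1 sampling starts at zero and an
  off-resonance rotating frame; on-resonance data can be fitted (the fit
  never needs the absorptive spectrum) but not CLS-analyzed.
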
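# Methods

This note documents the models implemented in foldstab, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions that affect results.

## Fluorescence melting analysis

**Model.** Each emission spectrum is condensed to its barycentric mean
⟨λ⟩ = Σλ·F(λ)/ΣF(λ) over the acquisition grid (default 310–400 nm). The
melting curve ⟨λ⟩(x), with x temperature (K) or denaturant concentration
(mol/L), is fitted by unweighted nonlinear least squares to the Boltzmann
sigmoid λ(x) = λ_N + (λ_D − λ_N)/(1 + exp((x½ − x)/rate)). Only midpoints
are interpreted: when unfolding is thermally irreversible, ΔG cannot be
obtained from the melt, but midpoints measured under identical protocols
remain comparable between constructs. The sigmoid "rate" relates to the
van't Hoff enthalpy of a two-state equilibrium as rate = R·T½²/ΔH_vH; the
relation is documented, not enforced.

**Initialization and convergence.** λ_N and λ_D start from the mean
barycentric mean over the lowest and highest 10% of conditions, x½ from the
condition of steepest gradient, rate from 2 K (thermal) or 1/15 of the
condition span (chemical). A fit is flagged non-converged — never raised —
when the optimizer fails, the midpoint falls outside the data range, the
covariance is singular, or the fitted amplitude |λ_D − λ_N| is below
4× the residual RMS (a flat curve with no resolvable transition). Standard
errors are square roots of the diagonal of the residual-scaled covariance.

**Replicate statistics.** Midpoints are aggregated as mean ± SEM
(sample SD/√n) over converged replicates; constructs are compared by a
two-tailed two-sample t test on per-replicate midpoints, pooled-variance
Student by default (Welch behind a flag), with no multiple-testing
correction since per-pair comparisons are reported raw. Zero variance in
both groups yields p = 1 for equal means, and a floored p (1e-300) with a
warning otherwise. Each construct keeps its own λ_N/λ_D — tryptophan
environments differ between constructs, so plateaus are not shared.

## DSC analysis

Baseline correction subtracts the line through the mean (T, Cp) of two
user-stated transition-free windows (default: first and last 10% of the
grid); a warning is raised if a detected peak's support reaches into a
window. The transition temperature is the grid temperature of the
peak maximum (no interpolation, no model fit), located with a prominence
threshold. Peak area is the trapezoidal integral over the contiguous region
where corrected Cp exceeds 5% of the peak height — a simple, reproducible
support definition. Reversibility is the reheat/first-heat area ratio after
matching peaks by nearest T_m within a tolerance (default 3 K; transitions
of interest are ≥10 K apart). An unmatched first-heat peak gets index 0.
When no explicit prominence is given for reversibility analysis, each trace
uses 5% of its own dynamic range, so the index scales correctly for
strongly attenuated reheats.

Note that with the 5%-height support rule, components closer than roughly
two peak widths share support and contaminate each other's areas at the
percent level; reversibility analysis is most accurate for transitions
separated by ~20 K, as is typical for a substrate–modifier conjugate.

## ¹⁵N relaxation analysis

**Decay fitting.** I(t) = I₀·exp(−t/T_α) by nonlinear least squares (≥4
delay points required; default grids are the standard 10–1000 ms T1 and
10–150 ms T2 series). The T_α error is a Monte Carlo estimate: the SD of
T_α over refits (default 500) of the best-fit curve perturbed by Gaussian
noise whose SD equals the residual standard error of the primary fit,
dof-corrected as √(SS/(n−2)) so the noise scale is unbiased for small n.

**NOE.** hnNOE = I_sat/I_eq, averaged over duplicate experiments, with the
between-duplicate sample SD as the error. A single replicate yields error 0
with a warning rather than an imputed value.

**Forward equations.** R1, R2 and NOE follow the standard expressions for
an amide ¹⁵N relaxed by the ¹H–¹⁵N dipolar interaction (d = μ₀ħγ_Hγ_N/4πr³,
r_NH = 1.02 Å) and ¹⁵N CSA (c = ω_NΔσ/√3, Δσ = −172 ppm), evaluated at the
five frequencies 0, ω_N, ω_H−ω_N, ω_H, ω_H+ω_N, with a scalar Rex added to
R2. The field defaults to 600.13 MHz; all constants are
config-overridable and echoed into output metadata. The extreme-narrowing
NOE limit 1 + (γ_H/γ_N)/2 ≈ −3.93 holds for the dipolar-only equations; the
CSA term does not vanish at short τ_m and moves the full-equation limit to
≈ −3.44 at the default Δσ.

**Reduced spectral density mapping.** J(ω_H±ω_N) and J(ω_H) are lumped onto
the single effective frequency 0.87ω_H (the alternative multi-ε convention
is not implemented), giving closed forms for J(0.87ω_H), J(ω_N), J(0) from
(R1, R2, NOE). Applied to rates constructed with the same lumping the
mapping is an exact algebraic inverse (tested to 10 significant digits);
applied to full-equation rigid-rotor rates the J(0) error is ≤0.5% for τ_m
in 2–20 ns at 600 MHz. Errors propagate to first order through the closed
forms with analytic partial derivatives; the propagation agrees with a
Monte Carlo resampling oracle to a few percent. Negative mapped values
(possible under noise, or with NOE > 1) are flagged invalid and excluded
from summaries and ratios but never clamped — clamping would bias the group
SDs that are a headline readout. Exchange broadening inflates mapped J(0)
because Rex is (deliberately) not modelled in the inversion; this is the
mechanism that makes the J(0) profile sensitive to µs–ms motions.

**τc and profiles.** The isotropic rotational correlation time solves the
rigid-rotor R2/R1 ratio equation for the trimmed-mean ratio (default trim:
20% of residues furthest from the median ratio, which removes mobile
termini and exchange-broadened residues) by bracketed root finding on
(0.1, 100] ns. The J(0) ratio profile divides per-residue J(0) of the
modified by the unmodified form where both are valid (≥5 shared residues
required), with relative errors added in quadrature, and reports each
table's mean ± SD of J(0). CSP = √(Δδ_H² + (0.14·Δδ_N)²) over shared
residues of two assigned peak lists.

## Synthetic-data generator

**Melts.** Two Gaussian emission bands (native 335 nm, denatured 355 nm,
width 18 nm — denatured strictly red of native), each normalized to unit
summed intensity on the wavelength grid, mixed by the two-state logistic
population p_N(x) = 1/(1+exp((x−x½)/rate)). The normalization makes the
barycentric mean of the mixture an exact Boltzmann sigmoid in x (weights
are then the state populations), so noiseless simulations round-trip
through the sigmoid fit to machine precision; physically it corresponds to
equal integrated quantum yield of the two states. Noise is multiplicative
Gaussian per wavelength, default 2% — realistic fluorometer shot noise,
which yields replicate SEMs at the low end of the 0.0–0.4 K scale typical
of published melt tables. Replicate spectra differ only by the noise
stream; inter-experiment variability (sample prep, temperature calibration)
is not modelled, so real replicate scatter will exceed the default
simulation's.

**DSC.** Each component contributes a two-state van't Hoff excess heat
capacity A·ΔH_vH²/(R·T_m²)·K/(1+K)², K = exp[−(ΔH_vH/R)(1/T − 1/T_m)], with
the prefactor evaluated at T_m so the maximum sits exactly at the nominal
T_m (a T-dependent prefactor shifts the peak ≈4R²T_m³/ΔH² ≈ 0.07 K below
T_m, which would make peak-maximum readouts disagree with the nominal truth
on fine grids). Default ΔH_vH = 500 kJ/mol gives ~6.6 K FWHM peaks. Reheat
traces scale each component by its reversibility fraction; baseline is
polynomial, noise additive Gaussian.

**Relaxation.** The Lipari–Szabo model-free form
J(ω) = (2/5)[S²τ_m/(1+(ωτ_m)²) + (1−S²)τ/(1+(ωτ)²)], 1/τ = 1/τ_m + 1/τ_e,
is adopted as the generative model because it reproduces exactly the
quantities the analysis consumes (R1, R2, NOE and J at three frequencies);
ground truth is always emitted alongside the data. The convenience profile
is a rigid core (S² = 0.86, τ_e = 50 ps) with three flexible residues per
terminus and optional per-residue Rex. Decays are mono-exponential at the
forward-equation rates with multiplicative Gaussian noise (default 2%);
NOE pairs are generated in independent duplicates, mirroring standard
practice. No 2D lineshapes, peak overlap, or dispersion profiles are
simulated, so passing tests demonstrate correctness of the analysis chain
given ideal peak intensities, not robustness to spectral artefacts.

**Determinism.** All generators draw from `numpy.random.default_rng`
(PCG64); a fixed seed is bit-reproducible across platforms.

## Calibration problem sizes

The bundled calibration tests use 100 three-replicate melt experiments for
bias/coverage of the midpoint fit, 200 noisy decay simulations at 120
Monte Carlo iterations each for the T_α error calibration, and 4000–5000
resampling draws for the J-error propagation oracle — sizes at which the
checked statistics are stable to well within the asserted tolerances.

## Known limitations

* Peak-maximum DSC readout ignores scan-rate kinetics of irreversible
  transitions; midpoints are comparable only across identical protocols.
* The reduced mapping assumes Rex-free R2; exchange-broadened residues
  report inflated J(0) (by design, as a sensitivity, not an estimate).
* Isotropic τc estimation is a reference point only; anisotropic diffusion
  tensors are out of scope.
* Homoscedastic Monte Carlo noise slightly underestimates decay-fit errors
  (~10–15%) when the true noise is proportional to intensity; the
  calibration tests bound this.
* The melt simulator's Gaussian bands are symmetric; real tryptophan
  emission is asymmetric, but only the barycentric mean is consumed
  downstream.
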
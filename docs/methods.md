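# Methods

## Forward models

Continuous-wave diffuse correlation spectroscopy (CW-DCS) measures the
normalized intensity autocorrelation g2(ρ, τ) of coherent near-infrared
light that has been multiply scattered by tissue. The field autocorrelation
g1 obeys the correlation diffusion equation; g2 follows from the Siegert
relation g2 = 1 + β·g1², with β ∈ (0, 1] the setup-dependent coherence
factor. The blood flow index (BFI = α·D_B, mm²/s) enters through the
mean-square scatterer displacement ⟨Δr²(τ)⟩ = 6·D_B·τ (Brownian-motion
model); α and D_B are never identified separately, so the package treats
their product as the single dynamic parameter.

**Semi-infinite medium.** The classical two-image-source solution with an
extrapolated boundary:

    G1(ρ, τ) ∝ exp(−K r1)/r1 − exp(−K r2)/r2,
    K²(τ) = 3 μa μs′ + 6 μs′² k0² BFI τ,
    r1 = √(ρ² + z0²),  r2 = √(ρ² + (z0 + 2 z_b)²),

with source depth z0 = 1/μs′, extrapolated length
z_b = 2(1+R_eff)/(3 μs′ (1−R_eff)), and R_eff the standard quartic
polynomial in the refractive index ratio n0. g1 = G1(τ)/G1(0) is exactly 1
at τ = 0 by construction. The wavenumber convention is the in-medium one,
k0 = 2π n0/λ with λ converted from nm to mm; this choice is applied
identically in simulation and inversion, so any alternative convention
would only rescale the BFI axis.

**Three-layer head model.** Scalp and skull are finite slabs (default 5 and
7 mm); the brain layer is semi-infinite. In radial spatial-frequency (q)
space the correlation diffusion equation becomes a 1-D two-point boundary
problem per (q, τ). We solve it analytically for an isotropic point source
at depth z_s = 1/μs′(1) with a Dirichlet condition on the extrapolated
surface z = −z_b and value/flux continuity at the internal interfaces,
giving

    Ĝ0(q, τ) = 3 μs1′ · sinh(φ1 z_b)/φ1
               · [a1 c̃ (a2 c2 + a3 s2) + a2 s̃ (a3 c2 + a2 s2)]
               / [a1 (a2 c2 + a3 s2) cosh(φ1 (L1+z_b))
                  + a2 (a2 s2 + a3 c2) sinh(φ1 (L1+z_b))],

where φ_l² = 3 μa(l) μs′(l) + 6 k0² μs′(l)² D_B(l) τ + q²,
a_l = φ_l D_l with D_l = 1/(3 μs′(l)), c2/s2 = cosh/sinh(φ2 L2), and
c̃/s̃ = cosh/sinh(φ1 (L1 − z_s)). This exact boundary treatment was chosen
over the commonly printed first-order-in-(φ1 z_b) expansion of the same
expression (prefactor z_b, linearized L1-brackets) because its homogeneous
limit reduces *analytically* to the semi-infinite image-source formula —
the two geometries then agree to quadrature precision when all layers share
one set of properties, which is the package's cross-model consistency test.
The linearized variant leaves a ~1–2% relative residual that grows as g1
decays.

The real-space Green's function is the zeroth-order Hankel inversion
G0(ρ, τ) = (1/2π)∫ Ĝ0(q, τ) q J0(ρq) dq, evaluated with fixed
Gauss–Legendre quadrature on q ∈ [0, q_max]. Defaults q_max = 40 mm⁻¹ and
2048 nodes: the integrand envelope decays like e^(−q(z_s+z_b)), and at
ρ = 25 mm both node doubling and extending q_max move g1 by < 1e-9
(a q_max of 10 mm⁻¹, by contrast, truncates the integral by ~10% and
produces negative tails). Numerator and denominator are evaluated with all
hyperbolics scaled by e^(−φ1(L1+z_b)−φ2L2), so no term can overflow at any
physical parameter combination. τ = 0 is evaluated exactly (the flow term
of φ_l vanishes), making the normalization exact. Fully decorrelated lags
fall below the quadrature noise floor (~1e-12 absolute); values there are
clamped into (0, 1] and are not meaningful beyond that bound.

Repeated evaluations that vary only the brain-layer BFI (dataset
generation, NLSF iterations) use a factored form: the third layer enters
Ĝ0 only through a3 = φ3 D3, so Ĝ0 = (P1 + P2 a3)/(Q1 + Q2 a3) with
P/Q precomputed once per geometry. This is numerically identical to the
general path (≤ 1e-13) and ~70× faster.

## Correlator noise model

The per-lag standard deviation of a measured g2 follows the classical
photon-correlation (Koppel-type) model,

    δ(τ) = √(Tb/t) · [ β²((1+e^(−2ΓTb))(1+e^(−2Γτ)) + 2m(1−e^(−2ΓTb))e^(−2Γτ))/(1−e^(−2ΓTb))
            + 2⟨n⟩⁻¹ β (1+e^(−2Γτ)) + ⟨n⟩⁻² (1+e^(−2Γτ)) ]^(1/2),

with ⟨n⟩ = I·Tb the mean photons per bin, t the integration time, and Γ the
effective decay rate obtained by fitting g2 ≈ 1 + β e^(−2Γτ) (bounded least
squares; β initialized at max(g2)−1, Γ at the 1/e crossing). Design
choices: Tb is fixed at the first lag (1e-7 s) and the bin index m = τ/Tb
is treated as real-valued, because a log-spaced grid has no uniform integer
index (using the local lag spacing as a per-lag Tb instead changes
downstream reconstruction accuracy by only a few percent); Γ = 0 is
rejected since the bracket diverges as 1/(ΓTb); noise is injected as
independent zero-mean Gaussian draws per lag, deterministic under a seed.
For dataset generation Γ is fitted on the noiseless curve so that δ(τ)
reflects the true decay rather than a circular refit.

At the default acquisition (I ≈ 2e4 cps, t ≈ 15 s, β = 0.5) the early-lag
noise floor is σ ≈ 0.05 on a g2 contrast of 1.5 — the shot-noise term
⟨n⟩⁻² dominates because ⟨n⟩ = I·Tb ≈ 2e-3. This operating point controls
every accuracy number downstream (see "What the tests show" below).

## Datasets

A dataset is an N×n matrix of noisy g2 rows with N×2 labels [BFI, β].
Defaults mirror the study conditions: N = 5,000 train / 500 test, n = 128
log-spaced lags in [1e-7, 1e-1] s, ρ = 25 mm, λ = 785 nm, n0 = 1.35;
semi-infinite optics μs′ = 1.6, μa = 0.0027 mm⁻¹; three-layer optics
μs′ = (0.635, 0.851, 1.099), μa = (0.019, 0.014, 0.019) mm⁻¹ with scalp
and skull BFIs fixed at 1e-6 and 0 mm²/s. Labels are drawn uniformly on
the linear scale: BFI ∈ [1e-8, 1e-5] mm²/s, β ∈ [0.01, 1]; acquisition
I ∈ [1.5e4, 2.5e4] cps and t ∈ [5, 25] s per sample. BFI labels are stored
and regressed in units of 1e-6 mm²/s so the two label columns have
comparable magnitude in the ridge solve; unit metadata travels with every
dataset file and trained model. Per-sample decay rates are refitted
individually. Generation is fully deterministic under the dataset seed.

## RVFL and ELM

Both are single-hidden-layer networks whose hidden layer is random and
frozen: W ~ U(−1, 1), biases ~ U(0, 1) (the source literature does not
state these distributions; these are common practice), activation sigmoid
by default (sine and RBF selectable). Inputs are the raw g2 values — the
RVFL's direct links make affine input shifts learnable, so no
standardization is applied.

* ELM: H = θ(XWᵀ + σ), trained output weights ω = H⁺Y via SVD
  pseudoinverse (rank tolerance recorded in the model).
* RVFL: H = [X | θ(XWᵀ + σ)], ridge solution with the primal normal
  equations ω = (HᵀH + λI)⁻¹HᵀY when n+L ≤ N and the dual (sample-space)
  form ω = Hᵀ(HHᵀ + λI)⁻¹Y otherwise; the identity is sized to whichever
  Gram matrix is inverted. Default λ = 1e-6, L = 500.

Parameter counts follow one convention for both architectures: random
input weights (n·L) + hidden biases (L) + trained output weights (L·m for
ELM, (n+L)·m for RVFL), giving 65,500 and 65,756 at n = 128, L = 500,
m = 2. FLOP counts (informational) count multiply and add separately per
weight plus one bias add and one activation per hidden node.

## NLSF baselines

Bounded nonlinear least squares (trust-region reflective) and Nelder–Mead
simplex minimize Σ(g2_model − g2_meas)² with only the (deepest-layer) BFI
and β free; optics, thicknesses and ρ are fixed. BFI is optimized as
log10(BFI) for conditioning in both geometries; the simplex works on a
penalty-clipped box. Defaults: bounds BFI ∈ [1e-9, 1e-4] mm²/s,
β ∈ (0, 1], init (1e-6, 0.5). On noiseless curves both methods recover
(BFI, β) to better than 1e-6 relative and agree with each other to 1e-4.
On noisy curves the estimator carries a small positive BFI bias (~3% at
default acquisition) — a generic property of nonlinear inversion under
symmetric noise, not a solver defect.

## Metrics and sweeps

Per-label MAE (and their sum), R² = 1 − SS_res/SS_tot, residual mean/std,
and signed percent error Error% = 100(ŷ−y)/y with a normal-approximation
95% CI (mean ± 1.96·std/√N; zero-truth entries excluded and counted).
Noise sweeps hold one truth fixed (three-layer scalp/skull/brain BFIs
1e-6, 0, 6e-6 mm²/s, β = 0.5 by default) and report mean/std/CI of the
reconstructed deep BFI per grid point of I or t. Hyperparameter sweeps
(hidden nodes, λ, training size, lag-grid length) share one random-layer
seed across grid points so curves reflect the swept axis; a multi-seed
mode adds across-seed stds. Training-size points are nested subsets of one
dataset; lag-length points regenerate the grids at fixed τ range.

## What the tests show — and what they do not

The synthetic generator *is* the study condition: fixed optics, uniform
linear label draws, Gaussian correlator noise with fixed Tb, and a single
ρ. Passing tests therefore demonstrate correctness of the analytical
models (cross-checked against an independent high-precision evaluation and
the homogeneous-limit identity), of the closed-form training algebra
(cross-checked against independent solves), and of the noise-injection
contract — not performance on real correlator data, which has correlated
noise across lags, detector afterpulsing, probe-pressure scalp effects and
optical-property uncertainty, none of which are modeled.

Accuracy numbers deserve explicit framing. Under the conditions above the
task is noise-dominated for the BFI label: a trained RVFL reaches a summed
(BFI + β) test MAE of ≈ 0.9 (BFI in 1e-6 mm²/s units over [0.01, 10],
β over [0.01, 1]), of which β contributes only ≈ 0.03. Two independent
lines of evidence show this is an information limit of the conditions, not
an implementation artifact: the same network on noiseless curves reaches
BFI MAE ≈ 0.18, and per-curve NLSF — a near-maximum-likelihood estimator —
is *worse* (BFI MAE ≈ 2) on the identical noisy curves. Absolute MAE
values in this family of benchmarks are therefore meaningful only relative
to a declared label scale, range and noise level; narrowing the BFI range
to [1e-8, 1e-6] mm²/s, for example, shrinks the summed test MAE by an
order of magnitude. For the same reason the test-MAE-optimal ridge λ under
these conditions is the largest value on the default grid (stronger
shrinkage wins when labels are noise-dominated), while the *training* MAE
is smallest at the smallest λ, as ridge theory requires.

## Numerical conventions

* Quadrature: Gauss–Legendre, q ∈ [0, 40] mm⁻¹, 2048 nodes; optional
  convergence check re-evaluates with doubled nodes (tolerance 1e-6).
* Decay fit: bounded least squares, analytic Jacobian, tolerances 1e-14.
* Ridge solves: symmetric positive-definite `scipy.linalg.solve`; λ = 0 is
  rejected (the Gram system may be singular); pseudoinverse rcond 1e-15.
* Serialization: datasets and curves as CSV at full float round-trip
  precision (`%.17g`), read back with round-trip float parsing; models as
  JSON with nested-list arrays, a format-version field and label-scaling
  metadata.
* All randomness flows through `numpy.random.default_rng` seeds carried in
  the spec/config; identical configs give bit-identical artifacts.

## Known limitations

* Only CW-DCS; no time-domain or frequency-domain variants, no two-layer
  geometry, no Monte Carlo photon transport.
* The noise model is diagonal (independent lags) and Gaussian; real
  multi-tau correlators produce correlated, non-Gaussian noise at early
  lags.
* Optical properties and layer thicknesses are treated as known; the NLSF
  baselines do not fit them, and network models must be retrained when
  they change (the fast closed-form training is the point of the method).
* The m = 2 label design identifies only the deepest-layer BFI; scalp BFI
  is a fixed nuisance parameter during generation.
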
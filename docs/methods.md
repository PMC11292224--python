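# Methods

## The models

`lactodyn` analyses the kinetics of an amperometric biosensor whose
bioselective element is an enzyme (lactate oxidase in the motivating
application) converting substrate S to product P through a single complex C.
Two delayed formulations of the irreversible one-complex mechanism are
implemented.

**Distributed-delay (Brown) mechanism.**  Enzyme and product reappear a
random time τ after each enzyme–substrate encounter; no explicit complex
variable is carried:

    dnS/dt = −kd nE(t) nS(t)
    dnE/dt = −kd nE(t) nS(t) + kd D(t)
    dnP/dt =  kd D(t),
    D(t)   = ∫ f(σ) nE(t−σ) nS(t−σ) dσ,

with f a shifted gamma density: f(σ) = a^(m+1)/Γ(m+1) · (σ−τ_min)^m ·
e^(−a(σ−τ_min)) for σ > τ_min, zero otherwise.  The kernel is truncated at
the horizon τ_M = E(τ) + σ(τ)/√(1−c), where E(τ) = τ_min + (m+1)/a and
σ(τ) = √(m+1)/a; by the one-sided Chebyshev bound at most a fraction 1−c of
the delay mass is discarded.  Default confidence c = 0.95.

**Two-delay Michaelis–Menten mechanism.**  Complex formation lags the
encounter by τ1 and product release lags by τ2:

    dnS/dt = k−1 nC(t) − k1 nS(t−τ1) nE(t−τ1)
    dnE/dt = k−1 nC(t) + k2 nC(t−τ2) − k1 nS(t−τ1) nE(t−τ1)
    dnC/dt = k1 nS(t−τ1) nE(t−τ1) − k2 nC(t−τ2) − k−1 nC(t)
    dnP/dt = k2 nC(t−τ2),

with a constant history equal to the initial state on [−max(τ1,τ2), 0] (any
non-negative history is admissible; constant is the minimal choice).  The
row sums give two conserved quantities, nE + nC and nS + nC + nP; the
right-hand side is coded so the enzyme identity holds exactly in floating
point.

**Units.**  Concentrations are mM.  The time unit is declared (not derived):
seconds, consistent with responses of 4–5 minutes and identified delays of
order 5–16.  Rate constants are per second (k1, kd per mM per second).
Current is in arbitrary instrument units; the transduction coefficients
absorb the calibration.

## Numerical integration

There is no delay-differential solver in the supporting libraries, so the
integrator is part of the package: fixed-step classical RK4 with cubic
Hermite dense output (states and derivatives stored at every node), lagged
terms read from the dense solution — the method of steps.  The step is
subdivided so it never exceeds the smallest positive delay, which guarantees
every lagged query lands in already-computed territory.  Default step
0.01 s.  Step-halving convergence and agreement (≤1e−6 relative) with an
independent `solve_ivp` oracle at zero delay are asserted by the test suite.

The distributed-delay term D(t) is re-quadratured at every RK stage with
composite Gauss–Legendre rules (8 panels × 8 nodes by default, ≥64 nodes)
over the kernel support [τ_min, τ_M], density evaluated exactly, states
interpolated.  No linear-chain reduction is used: the integro-differential
form is integrated as written.

Negative states are not clipped.  Positivity genuinely fails for large
delays; the first time any component goes negative is recorded in the
trajectory metadata.  For sufficiently large τ1 (≳31 at the identified
rates) the loss of positivity feeds the quadratic term and the solution
escapes to infinity in finite time, independent of the step; integration
then raises, and the bifurcation sweep records the failure and continues.

A constant positive history also feeds the distributed-delay kernel before
t = 0, so the Brown model generates some product from pre-initial
encounters; this is a faithful consequence of the model plus the constant
history, not an artifact to be corrected.

## Transduction and identification

Current follows the Kohlrausch conductance form I = Λ_m0 nP − K nP^{3/2}
(linear gain with an ionic-strength correction; the alternative grouping
Λ_m0 (nP − K nP^{3/2}) was considered and rejected as inconsistent with the
conductance analogy).  Negative product raises rather than mapping silently;
values within 1e−9 mM of zero are treated as roundoff.

The objective is J(Π) = sqrt(Σ_j Σ_i (I_exp − I_pred)²) over all
concentrations jointly.  Minimization uses trust-region-reflective least
squares with the published box bounds (lower 1e−10, τ2 lower 0; upper 1 for
the bimolecular rate, 1000 for other rates and delays, 1e6 for Λ_m0 and K).
All parameters except the delays are optimized in log10 space: the bounds
span sixteen orders of magnitude and the problem is ill-conditioned in the
raw parametrization.  Trial points whose simulation blows up return a large
finite penalty so the trust region backs away; an initial point outside the
box is clipped with a warning.  Optional multi-start jitters the start in
the internal space with a seeded generator; everything is bit-reproducible
for a fixed seed.

The two-stage workflow fits the Brown model first and seeds the discrete
delays from its mean delay, τ1 + τ2 = E(τ) split 2:1 (the ratio of the
published initialization 15:7).

Parameters are not expected to be uniquely identifiable: distinct rate
vectors reach residuals at the noise floor (the fitted optimum drifts from
the generating truth while matching its fit quality), which is consistent
with rates in reality depending on concentrations.

## Stability analysis

The unique equilibrium is substrate-and-complex-free (SCFE): n̄S = 0,
n̄E = total enzyme, n̄C = 0, n̄P constant.  Linearization gives
χ(λ) = λ² χ₁(λ) with

    χ₁(λ) = λ² + k−1 λ + k1(n̄S+n̄E) λ e^(−λτ1) + k2 λ e^(−λτ2)
            + k1 k2 n̄E e^(−λ(τ1+τ2)).

The structural λ² factor comes from the two conservation laws and pins a
double root on the imaginary axis, so the SCFE can never be asymptotically
stable; when every χ₁ root lies strictly left of the axis the verdict is
*marginal* stability — precisely the operating regime of a biosensor, where
each substrate dose settles to its own product plateau.  A χ₁ root with
positive real part means instability; a nonzero conjugate pair on the axis
(within 1e−9) marks the periodic (Hopf) boundary.

Roots are found by replacing each exponential with its (1,1) Padé
approximant (1−λτ/2)/(1+λτ/2) — the τ1+τ2 term gets both factors — taking
the numerator roots of the resulting rational function as seeds, and
refining each seed with damped Newton on the *exact* χ₁ (analytic termwise
derivative, residual tolerance 1e−12, deduplication at 1e−8, at most 100
iterations; non-convergent seeds are dropped with a warning).  The Padé
rational is constructed symbolically from the term list, never from a
printed expansion.

Sufficient positivity conditions use the delayed exponential
e_τ^{λx} = Σ_{n≤x/τ} λⁿ(x−nτ)ⁿ/n!, the fundamental solution of
x′(t) = λx(t−τ) (equal to 1 on [0,τ), with d/dx e_τ^{λx} = λ e_τ^{λ(x−τ)}).
The three conditions require e_{τ1}^{−k1 nE0 t}, e_{τ1}^{−k1 nS_max t} and
e_{τ2}^{−k2 nE0 t} to stay positive.  The scan uses 1e−2 resolution; when
|λ|τ ≤ 1/e the function is provably non-oscillatory (the classical 1/e
threshold), the scan is skipped and the margin is estimated from the
Lambert-W asymptotic decay rate — this also covers the τ→0⁺ limit where the
term-by-term sum is infeasible.

## Poincaré sections and the Hopf sweep

Trajectories are cut with the plane nE = d, d the midline
(min nE + max nE)/2 of the post-transient window.  Crossings are detected
as sign changes on the stored grid and refined by Brent root-finding on the
dense interpolant; only upward crossings (d nE/dt > 0) are kept by default,
so a simple cycle contributes one point per period.  The first half of the
horizon is discarded as transient (no transient rule is inherited; 50% is
the package's choice).  Cluster counting with gap 10·eps flags
period-doubling candidates; it is reported, not asserted.

The bifurcation sweep varies τ1 over [15, 35] in steps of 1 with
τ2 = 5.357829 fixed, horizon 2000 s, initial state (1.0, 1.139071, 1e−9,
1e−9) mM — 1.0 mM is the concentration the identified fits matched best,
adopted as the concentration the identified fits reproduce best (which
dose the published diagram used is not recorded).
The Hopf threshold is the smallest grid τ1 whose section spread exceeds
eps = 1e−5 mM (below the smallest reported cycle radius ~1e−4).  With these
settings the package finds τ1* = 23; the spread grows monotonically past
onset, and sweep points with τ1 ≥ 31 terminate early by finite-time escape
and are recorded as failures.

## Synthetic data

The generator emulates the amperometric experiment: responses at initial
substrate 0.1, 0.5, 1.0 and 2.5 mM, 300 s at 1 s sampling, total enzyme
1.139071 mM, nC(0) = nP(0) = 1e−9 mM (strictly positive as the initial
conditions require), additive i.i.d. Gaussian noise with sd 1% of each
series' peak current (no noise model accompanies the published parameter
values; Gaussian is the neutral choice), all noise from one seeded
generator.  It does not emulate
baseline/washing phases, drift, electrode fouling, replicate structure
(a replicate knob exists, default 1) or temperature effects — so passing
tests demonstrate correctness of the pipeline under the stated statistical
assumptions, not robustness to real-instrument artifacts.

The generator and the objective share the same simulation step (0.05 s
default for fitting) so that noise-free synthetic data is exactly
reproducible by the fit, making the self-consistency and recovery tests
sharp.

## Problem sizes and other choices

Default horizons: 300 s for response fitting, 2000 s for sweeps.  The
acceptance script runs the full 21-point sweep at the 0.01 s integration
step; test-suite property checks use shorter horizons (30–200 s) and
coarser steps (0.02–0.1 s) where a cheaper setting already exercises the
property.  Fit tests cap optimizer evaluations rather than loosening
tolerances.

Known limitations: no stiff/implicit DDE machinery (the identified regime
is non-stiff); no Lyapunov exponents or chaos certification for τ1 > 32; no
identifiability analysis; no reversible-product or multi-complex
mechanisms; no concentration-dependent delays.
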
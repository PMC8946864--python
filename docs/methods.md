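# Methods

## Model

The implant is a homogeneous 1-D conductor: temperature T(t, y) on
0 ≤ y ≤ L obeys ∂T/∂t = α ∂²T/∂y² with a single diffusivity α for the
whole fixture–abutment–crown assembly. The bone end (y = 0) is a
Dirichlet boundary pinned at body temperature T₂ = 37 °C; the oral end
(y = L) follows the thermal load ΔT e^(−t/t₀) + T₂ with ΔT = T₁ − T₂;
the initial state is uniformly T₂. Assumptions this buys and their
price:

- **No radial heat loss.** Justified by L ≫ R for typical fixtures;
  axial peaks computed here are upper bounds on what a 2-D
  axisymmetric model with radial losses would give.
- **Single α.** A real implant is a piecewise conductor
  (crown/abutment/fixture); a piecewise α has no tractable closed
  form. The presets bracket the realistic range (ceramic 6.25×10⁻⁷ to
  titanium 9.0×10⁻⁶ m²/s).
- **No metabolic/perfusion source term.** The load enters purely
  through the boundary condition, which is what makes the problem
  exactly solvable.
- **Offset invariance.** Temperatures are °C throughout; the equation
  and solution are invariant under a common offset, and the excess
  T − T₂ is exactly linear in ΔT, so hot and cold loads are both
  supported by sign.

The exact solution is the particular component
w = T₂ + ΔT (y/L) e^(−t/t₀) plus a sine series with mode amplitudes
Dₙ(t); each physical coefficient Cₙ = (2ΔT/π)Dₙ solves

dCₙ/dt + (n²/τ) Cₙ = (ΔT Aₙ)/(L t₀) e^(−t/t₀),  Cₙ(0) = −ΔT Aₙ/L,

with Aₙ = (−1)ⁿ⁺¹ 2L/(πn) and τ = L²/(απ²). All behaviour is governed
by the ratio t₀/τ: for t₀ ≪ τ the pulse is over before the interior
feels it; for t₀ ≈ τ the load couples efficiently to the slowest mode
(mid-implant peak ≈ 41 °C for the 60 → 37 °C load, for any material
driven at its own τ); for t₀ ≫ τ the interior quasi-statically tracks
the boundary.

## Numerical choices

**Series truncation.** Default n_terms = 200. Modes carry two pieces:
a free-decay part damped by e^(−n²t/τ) — negligible beyond n ≈ √(τ/t)
— and a load-forced part proportional to e^(−t/t₀)/(n²t₀/τ − 1) whose
coefficients decay only like 1/n³. The truncated tail of the forced
part is ≈ (2ΔT/π)(τ/t₀) e^(−t/t₀)/(2N²), about 10⁻⁵ °C at the default
parameters — invisible at figure scale but relevant to tight bound
checks, which therefore use 2000 terms. Near t = 0 the series also
carries Gibbs oscillation from the corner discontinuity at (t = 0,
y = L) (the boundary value takes precedence there: T(0, L) = T₁);
pointwise accuracy below t ≈ 0.05 s is documented rather than
enforced, and initial-condition checks exclude y > 0.9 L.

**Resonance.** At n²t₀ = τ the general Dₙ degenerates (0/0). Within a
relative tolerance of 10⁻⁸ on |n²t₀/τ − 1| the exact limit
Dₙ = ((−1)ⁿ⁺¹/n)(t/t₀ − 1)e^(−t/t₀) is evaluated instead — continuous
to < 10⁻⁴ against the general branch at ±10⁻⁶ off-resonance, with no
epsilon-perturbation of inputs and no catastrophic cancellation.

**Peak search.** Dense uniform sampling (2000 points over the horizon
max(10 t₀, 10 τ)) followed by bounded golden-section refinement of the
bracketing interval to Δt = 10⁻⁴ s. Deterministic; the horizon covers
late peaks of deep points under slow loads.

**Finite-difference oracle.** Crank–Nicolson on n_space = 200 interior
nodes with dt = τ/2000, chosen over explicit FTCS because titanium's
α would force impractically small explicit steps. The time-dependent
Dirichlet value at y = L is taken at the half-step t + dt/2,
preserving second-order accuracy. CN only weakly damps the
high-frequency error injected by the corner jump, so the march opens
with two backward-Euler half-steps (Rannacher start); convergence
remains second order (measured error ratio 4.00 per simultaneous
dy, dt halving). Comparisons against the series start at
max(0.05 s, 10 dt): earlier rows mix CN start-up error with series
Gibbs error and neither side is a trustworthy reference. With that
window, all four presets at t₀ ∈ {0.2, 2, 8.6} s agree with the closed
form to < 0.05 °C at default resolution.

**Mode-ODE oracle.** Classical fixed-step RK4, step ≤ τ/(1000 n²)
(shrinking with n² for stiffness), written from scratch so the check
is independent of both the closed form and any library integrator.
Matches Cₙ to ~10⁻¹³ at n = 1, far inside the 10⁻⁶ |ΔT| contract,
including on-resonance configurations t₀ = τ/n².

**Thermal dose.** CEM43 = ∫ R^(43 − T) dt/60 with R = 0.5 at or above
43 °C and R = 0.25 below, zero contribution under a 39 °C cutoff —
the standard Sapareto–Dewey convention (the halving rule above 43 °C
is the defining relation; the below-breakpoint factor and cutoff are
the literature's usual choices). Trapezoidal accumulation on a dense
(4000-point) history; stable to < 1% under 2× resampling and exactly
additive over partitions of the time axis.

**Time above threshold.** Lebesgue measure of {t : T > threshold}
from the dense history with each crossing refined by Brent root
bracketing to 10⁻⁶ s.

## Presets and study conditions

L = 1.3 cm for all presets (clinical range 7–20 mm). Implant A:
α = 2×10⁻⁶ m²/s (τ ≈ 8.6 s); implant B: 5×10⁻⁶ (τ ≈ 3.4 s). The
titanium (9.0×10⁻⁶) and ceramic (6.25×10⁻⁷) values are back-computed
from their quoted intrinsic times (1.9 s, 27.4 s) at this length.
Probe points: B1 at 3L/4 (superficial), B2 at L/2, B3 at L/4 (deep).
Load defaults T₁ = 60 °C, T₂ = 37 °C; exposure sweeps use
t₀ = 2, 5, 8, 11, 14 s (implant A) and 1, 2, 3, 5, 6 s (implant B).
Figure datasets emit exactly these parameter combinations as long
tables; plot styling is cosmetic and not contractual.

## Determinism and serialisation

The artifact contains no random number generation anywhere; repeated
runs (including the golden-fixture generator) are byte-identical. CSV
values are written at 17 significant digits and read back with
round-trip float parsing, so a write/read cycle reproduces a field
bit-for-bit. Every CLI run logs the resolved SI parameters, τ,
n_terms and horizon, sufficient to reproduce the run from the log.

## Limitations

- 1-D axial conduction only: no radial loss, no 2-D/3-D geometry, no
  piecewise material structure, no temperature-dependent α.
- The exponential load is a single idealised sip; repeated intake
  would be a superposition (the model is linear, so histories add).
- Clinical thresholds (42 °C impulse, 47 °C/1 min necrosis) are used
  as fixed reference temperatures; no tissue damage kinetics beyond
  CEM43 are modelled, and no statistical inference of any kind is
  performed.
- Series accuracy below t ≈ 0.05 s is limited by Gibbs behaviour near
  y = L; anyone needing the first few milliseconds near the oral end
  should raise n_terms and expect slow (1/N) pointwise convergence at
  the corner itself.
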
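# implant-heat

Transient heat conduction in dental implants during hot-liquid intake:
an exact analytical solution of the 1-D heat equation under an
exponentially decaying oral thermal load, with an independent
finite-difference oracle and clinical threshold/thermal-dose analyses.

## The problem

A titanium implant is an excellent thermal conductor compared with the
enamel and dentin it replaces, so a sip of hot coffee delivers a
thermal pulse straight toward the bone–implant interface. Osteoblasts
are damaged by sustained exposure around 42 °C and cortical bone
necroses at 47 °C (1 min), so the transient temperature along the
implant axis matters for osseointegration and implant survival.

The implant is modelled as a homogeneous 1-D conductor of length *L*
(bone end at *y* = 0 held at body temperature *T₂*, oral end at
*y* = *L*) obeying

∂T/∂t = α ∂²T/∂y²,  T(0, y) = T₂,  T(t, 0) = T₂,
T(t, L) = ΔT e^(−t/t₀) + T₂,  ΔT = T₁ − T₂,

where α is the thermal diffusivity and *t₀* the exposure time of the
load (effective duration ≈ 5 t₀). Splitting off the particular
component w(t, y) = T₂ + ΔT (y/L) e^(−t/t₀) and expanding the rest in
the sine eigenbasis gives the exact solution

T(t, y) = w(t, y) + (2ΔT/π) Σₙ Dₙ(t) sin(nπy/L),

Dₙ(t) = ((−1)ⁿ⁺¹/n) [ e^(−t/t₀)/(n²t₀/τ − 1) − (1 + 1/(n²t₀/τ − 1)) e^(−n²t/τ) ],

where τ = L²/(απ²) is the implant's **intrinsic time** — the decay time
of its slowest spatial mode. The solution depends on (L, α) only
through τ; the physics is the interplay between t₀ and τ. When
n²t₀ = τ the denominator vanishes and the exact resonance limit
Dₙ = ((−1)ⁿ⁺¹/n)(t/t₀ − 1)e^(−t/t₀) is used instead.

For the reference geometry (L = 1.3 cm): implant A (α = 2×10⁻⁶ m²/s,
moderate conductor) has τ ≈ 8.6 s; implant B (α = 5×10⁻⁶ m²/s, good
conductor) has τ ≈ 3.4 s; titanium ≈ 1.9 s; ceramic ≈ 27.4 s.

## Worked example

```python
import implant_heat as ih

model = ih.preset_model("implant_A")
print(f"intrinsic time tau = {model.intrinsic_time:.2f} s")

# drive the implant at its own intrinsic time
load = ih.ThermalLoad(t_hot=60.0, t_body=37.0, exposure_time=8.6)
t_peak, T_peak = ih.peak_temperature(model, load, model.length / 2, horizon=60.0)
print(f"peak at B2: {T_peak:.2f} degC at t = {t_peak:.2f} s")

report = ih.threshold_report(model, load, ih.LocationPoint.named("B2"), threshold=42.0)
print(f"time above 42 degC: {report.time_above:.2f} s, CEM43: {report.cem43_minutes:.4f} min")
```

prints

```
intrinsic time tau = 8.56 s
peak at B2: 41.20 degC at t = 10.72 s
time above 42 degC: 0.00 s, CEM43: 0.0133 min
```

The mid-implant peak when the exposure time matches the intrinsic time
is ≈ 41 °C — just below the 42 °C osteoblast-injury threshold, and the
same for both materials driven at their own τ. The CEM43 thermal dose
(cumulative equivalent minutes at 43 °C, Sapareto–Dewey halving rule)
is negligible here: the history never approaches 43 °C.

## Command line

```sh
implant-heat simulate --config run.yaml --out out/     # field CSV + provenance
implant-heat sweep --config run.yaml --t0 2 --t0 5 --point B2
implant-heat figure --id 4 --plot --out out/           # standard study datasets
implant-heat dose --config run.yaml --point B2 --threshold 47
implant-heat compare-oracle --config run.yaml          # CN vs closed form, JSON
```

A minimal config:

```yaml
implant: {preset: implant_A}     # or {length: 13 mm, diffusivity: 2.0e-6}
load: {t_hot: 60, t_body: 37, exposure_time: 2}
```

Exit code 2 flags configuration errors; every run logs the resolved SI
parameters, τ and the horizon.

## Verification

Two independent numerical oracles back the closed form: a
Crank–Nicolson finite-difference solver (agrees to < 0.05 °C at default
resolution, with the expected fourfold error reduction per grid
refinement) and a classical RK4 integration of each mode's ODE (agrees
to < 10⁻⁶ ΔT, including the resonant configurations).

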
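# Methods

## Model scope and assumptions

All circuits are deterministic ODE models in which promoter occupancy is
thermodynamic: the regulatory states of a promoter are enumerated with
Boltzmann weights, each state carries a production rate, and the production
term is the rate-weighted average over states. RNA polymerase is treated
implicitly (the rates and dissociation constants are effective,
polymerase-dependent parameters) and mRNA is not modelled separately.
Effector binding and the allosteric transition are assumed fast compared to
protein production and decay, so the active fraction `p_act(c)` is always at
equilibrium with the instantaneous effector concentration. Degradation is
first-order with a single rate γ shared by all species in a motif; time is
measured in units of 1/γ and concentrations in units of the relevant
dissociation constant. Transcription-factor oligomerisation and DNA looping
are out of scope, as is any stochastic (noise) modelling.

`β ≡ 1` throughout: the conformational energy gap `eps` and interaction
energies are always supplied in units of k_BT.

## Allostery

`AllostericTF(K_A, K_I, eps, n_sites)` defines the MWC active fraction.
`n_sites` defaults to 2 (every numeric analysis in the package uses 2) but
the general-n formula is implemented and validated against a brute-force
enumeration of the 2^n binding configurations. `p_active` is evaluated as a
logistic in log-weight space, `expit(eps − n[log1p(c/K_I) − log1p(c/K_A)])`,
which is overflow-safe for any `eps` and concentration. Concentrations are
molar everywhere in the API; the config layer accepts unit suffixes
(M, mM, uM/µM, nM, pM) and normalises on load.

The default (preset) transcription factor is LacI-like: K_A = 140 µM,
K_I = 530 nM, ε = 4.5 k_BT, two sites. Its activity spans about three
decades (saturation 0.989, leakiness 0.00129) with EC50 ≈ 4.7 µM — the
leakiness matters: it is why the auto-activation switch can remain bistable
at arbitrarily high effector concentration for strong enough ω·r̄₂.

EC50 is found by bracketed root finding on log10(c) over [1e−15, 10] M
(configurable bracket), with a residual guard of 1e−10 on the midpoint
activity.

## Auto-activation steady states and necessary conditions

Setting the dimensionless right-hand side to zero and clearing the partition
sum gives the cubic

```
ωa²Ā³ + (2a − r̄₂ωa²)Ā² + (1 − 2r̄₁a)Ā − r̄₀ = 0,    a = p_act(c).
```

Roots come from the companion matrix (`numpy.roots`, with degree reduction
when leading coefficients vanish, e.g. ω = 0), are polished by Newton
iteration on the rational form, deduplicated at 1e−6 relative distance, and
accepted only if the rational residual is below 1e−9. Stability is the sign
of the analytic derivative f′(Ā); |f′| < 1e−8 is labelled "marginal" and
excluded from stable counts.

By Descartes' rule, three positive roots require the coefficient sign
pattern (+, −, +, −) for some attainable active fraction
a ∈ (p_min, p_max), which yields three necessary conditions for bistability
at *any* effector concentration:

1. `ω r̄₂ / 2 > 1 + e^{−ε}` (the doubly-bound drive must beat degradation at
   full activity — implies the effective cooperativity ω_eff = ωr̄₂/2 > 1),
2. `2 r̄₁ < 1 + e^{−ε}(K_A/K_I)^n` (the singly-bound rate must not saturate
   the switch at the leakiness floor),
3. `ω r̄₂ > 4 r̄₁` (the two windows in `a` must overlap).

None involves r̄₀. A seeded 2,000-draw random scan (log-uniform rates with
r̄₀ ≤ r̄₁ ≤ r̄₂ over 10^[−3, 2.5], log-uniform ω over 10^[−2, 3], exhaustive
effector scans on a 60-point log grid over [1e−9, 1e−2] M) finds no bistable
set violating any of the three — this scan is the primary guard against
transcription errors in the inequalities, whose published typography is
ambiguous.

Bistable-interval endpoints from `auto_bifurcation` are refined by bisection
in log c to 1e−4 relative. Hysteresis follows the occupied stable branch by
nearest-neighbour continuity along a monotone effector path; when the branch
disappears, the switching concentration is located by bisection with the
reference point tracking the branch (it moves steeply near the saddle-node).

## Hill-function comparison

The Hill variant keeps physical units (molar, minutes) because matching the
two formulations changes the natural concentration scale: dropping the
singly-bound state of the thermodynamic model maps `ω(aA/K_d)²` to
`(aA/K_d^eff)²` with **K_d^eff = K_d/√ω** (n = 2). The comparison operation
builds both bifurcation diagrams on a shared dimensional effector grid and
reports per-concentration bistability verdicts. At ω = 1 the Hill model
claims bistability at low effector concentration where the thermodynamic
model is monostable; at ω = 7.5 the verdicts conflict only in a narrow
window near 6e−6 M (dense local grids are needed to resolve it); at ω = 100
the two agree everywhere on the grid.

The effective Hill coefficient of the open-loop production function is not
uniquely defined in the source material; here it is the maximum log–log
slope of `(P(Ā) − P(0))/(P(∞) − P(0))` over a log-spaced Ā grid (central
differences), a documented stand-in. It is bounded by the number of binding
sites and exceeds 1 on every bistable parameter set encountered in seeded
scans.

## Toggle switch

On the R̄₁ nullcline, R̄₁ = h₁(R̄₂) explicitly; substituting into the R̄₂
nullcline leaves a scalar equation g(R̄₂) = 0, bracketed on a dense
(log + linear, ~1200-point) grid over [0, r̄] and solved by `brentq`. Roots
are classified by the analytic 2×2 Jacobian. For 2-D maps and feasibility
scans, a vectorised variant counts sign changes of g across an entire
(c₁, c₂) grid at once (≥ 3 crossings ≙ the generic two-stable + saddle
configuration); full Jacobian classification is used wherever individual
fixed points are reported.

Geometry of the bistable region over the scan window [1e−7, 1e−4] M:
`BOTH_SMALL` if the low-concentration corner is bistable; `C1_WINDOW` if, at
the weakest c₂ supporting bistability, the bistable c₁ set excludes the grid
minimum (mirrored for `C2_WINDOW`); `NONE` otherwise. At r̄ = 2 and
ω₁ = ω₂ = 7.5 the window geometry mirror (`C2_WINDOW`) appears just above
K̄ = 1 rather than at 1/K̄ of the `C1_WINDOW` cases: the reduction uses K₂ as
the concentration unit, so inverting K̄ at fixed r̄ is not a symmetry of the
reduced system.

The analytic production-rate bound
`r̄ > 1/(p_max − p_min + min(ω₁, ω₂)·p_max/2)` is necessary for bistability
in the equal-affinity setting K̄ = 1 (where it is derived); the soundness
scan therefore draws K̄ = 1 toggles. For strongly asymmetric binding the
bound does not apply (a bistable counter-example exists at K̄ ≈ 0.17
marginally below the threshold).

Published alongside the symmetric toggle is a pitchfork on the c₁ = c₂
diagonal at ≈ 3.2e−6 M; this implementation places it at 4.68e−6 M, where
the magnitude of the nullcline-map slope at the symmetric fixed point
crosses 1. Two independent routes (stable-count bisection and the |h′| = 1
condition) agree, and no plausible alternative reading of the model weights
reproduces the smaller value, so the package reports its own number; the
corresponding end-to-end test records the discrepancy by failing against
the published value.

## Dynamics, timescales, separatrix, basins

Single trajectories use `scipy.solve_ivp` (LSODA, rtol 1e−8 / atol 1e−12 by
default; 1e−10/1e−13 where closed forms are verified) with an optional
terminal event ‖RHS‖ < 1e−9 for steady-state detection.

Linearised timescales are 1/|f′| (1-D, analytic derivative) or inverse real
eigenvalue parts (2-D). The trajectory-based auto-activation estimator
`fit_exponential` fits `A(t) = B + C e^{−t/τ}` (bounded least squares, free
offset) over the dominant relaxation phase — uniform samples until the
deviation from the attractor has halved. The free offset and the half-decay
window are deliberate: the late tail is governed by the fixed point's
linearisation (reported separately by `linear_timescale`), while the fitted
τ characterises the bulk approach. The estimator reproduces the three
regimes the physics dictates: τ ≈ 1/|f′| within a few percent for starts
near a stable fixed point, unbounded growth as the start approaches the
unstable fixed point, and τ → 1 (the degradation timescale, from above) for
starts far above the high state, where production is nearly saturated. At
the standard relaxation preset (ω = 7.5, c = 2e−5 M), τ(Ā₀ = 40) = 1.08 and
τ(Ā₀ = 30) = 1.13: the approach to 1 is asymptotic, and the instantaneous
decay rates along these trajectories (0.67–0.88) bound how close any
trajectory-based estimate can get at moderate Ā₀. The `threshold_95` method
(first time the deviation shrinks to 5% of its initial value) is used for
the toggle, where the per-component 95% crossing times are combined as
τ = max(τ₁, τ₂); trajectories not settled by t̄ = 200 are reported
unconverged rather than raised (starts on the separatrix can linger near the
saddle indefinitely).

The separatrix of a bistable toggle is the saddle's stable manifold, traced
by integrating the time-reversed flow from seeds displaced ±1e−7 along the
stable eigenvector (step cap 0.1, stop on leaving the state box). In the
fully symmetric case the stable eigenvector is the diagonal and the computed
polyline stays on it to machine precision. Perturbing polyline points by
1e−3 normal to it sends the two sides to different attractors (validated in
tests).

Basin-of-attraction grids integrate all initial conditions simultaneously
with a fixed-step vectorised RK4 (dt = 0.05), labelling each cell by the
nearest stable fixed point at convergence; cells still unresolved at t̄ = 200
(the separatrix itself) are labelled −1. Per-cell adaptive integration would
be two orders of magnitude slower at no benefit for basin membership.

## Feed-forward loops

X̄ is a fixed parameter (default 1, configurable), never a dynamical
variable; the published gate analyses do not print its value, so sweep-based
results carry that assumption. The step protocol defaults to cX between
1e−4 M and 1e−7 M with cY fixed at 1e−7 M; ON/OFF is keyed to the direction
of `p_actX`, not of cX (with an inactivating effector, *lowering* cX is the
ON step). Writing Z's production as `(a + b𝒴)/(p + q𝒴)` with
`a = r̄₀Z + r̄₁Z𝒳`, `q = 1 + ω𝒳`, and `b = r̄₁Z + ωr̄₂Z𝒳` (coherent) or
`b = 0` (incoherent), the offset from the matched simple-regulation
exponential integrates in closed form (see README); `Φ = bp − aq` in this
notation. Every validated call of `delay_analytics` checks Θ against the ODE
offset (1e−6 sup-norm) and the closed-form ⟨Δt̄⟩ against adaptive quadrature
of ∫₀^∞Θ dt̄ over [0, 50] (Θ decays like t̄·e^{−t̄}, so the truncation error
is far below the 1e−6 relative check). Sweeps over (K̄_XZ, K̄_YZ) evaluate
the closed form vectorised — no per-cell ODE — on 50×50 log grids over
[1e−2, 1e2]² by default.

A pulse is a transient excursion beyond the envelope
[min(Z̄ᵢ, Z̄_f), max(Z̄ᵢ, Z̄_f)]; for the generic monotone-net-change
response this reduces to the conventional overshoot-beyond-Z̄_f definition.
The amplitude is the maximum deviation beyond Z̄_f in the excursion
direction, and a pulse is "strong" when the amplitude exceeds 5% of the
output swing (threshold configurable; the published strength criterion is
not printed). Pulse scans sample time on a grid log-dense near t̄ = 0 so
that brief excursions immediately after the step are not missed. The
acceleration law for the incoherent loop (0 ≤ ⟨Δt̄⟩ ≤ 1 without a pulse)
holds in the X-driven family (r̄₀Z = 0); with a dominant basal rate the
net response can invert and only the sign identity
sign⟨Δt̄⟩ = sign((Z̄_f − Z̄ᵢ)Δ𝒴) with Φ < 0 is universal.

Ramped inputs are piecewise log-linear in cX; the input timescale t̄_c is the
time for `p_actX` to traverse [0.2, 0.8] during the ramp, located by root
finding. If the activity never covers that range, t̄_c is None with a
warning and the trajectories are still returned. The simple-regulation
reference under ramps fixes Ȳ = 1 (configurable).

## Synthetic parameter draws

The randomised scans are the package's synthetic-data layer: they emulate
the spread of biophysical parameters across circuits (rates over ~5 decades,
cooperativities from strongly destabilising to strongly stabilising
interaction energies, |ε_int| up to ~7 k_BT and beyond), with the activator
rate ordering imposed by sorting. They share one allosteric effector
chemistry (the LacI-like default); real circuits pair different effectors
with different response curves, so passing scans demonstrate internal
consistency of the theory under the stated model, not coverage of all real
induction chemistries.

## Problem sizes

Default analysis sizes: 1-D bifurcation grids 100–200 log-spaced points over
[1e−9, 1e−2] M; 2-D toggle maps 25–40 points per axis over [1e−7, 1e−4] M
(the scalar nullcline reduction makes each cell cheap); gate sweeps 50×50;
random scans 2,000 (auto-activation) and 300 (toggle) parameter sets; basin
grids 24–60 points per axis. All are arguments, not constants.

## Known limitations

* Deterministic ODEs only: no intrinsic noise, no stochastic switching times
  between basins.
* Single shared degradation rate per motif; no mRNA/protein two-stage
  kinetics.
* The effective Hill coefficient and the relaxation-fit windowing are
  documented stand-ins for procedures whose published definitions are not
  available in full.
* ⟨Δt̄⟩ is not reported as a meaningful delay when the output pulses; pulse
  metrics are reported instead.
* The toggle production-rate bound applies only at equal DNA-binding
  affinities (K̄ = 1).
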
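# Methods

## Model

The thin filament of striated muscle is regulated by tropomyosin (Tm), which
occupies one of three azimuthal positions on actin — blocking (**B**),
central (**C**, the equilibrium position), and myosin-dependent (**M**) —
and by troponin (Tn), whose two regulatory TnC sites bind Ca²⁺.  Tn can
interact with actin only while Tm sits in B; that interaction ("coupling")
competes with the open conformation of Ca²⁺-bound TnC, so coupled Tn binds
Ca²⁺ more weakly and releases it faster than free Tn.  The model therefore
tracks eight states across two conserved subsystems:

- Tm: `B + C + M = 1`, with `B = B1 + B2 + B3`;
- Tn: `B + T = 1`, with `T = T1 + T2 + T3`;

where the subscript counts bound Ca²⁺ plus one (1 = Ca²⁺-free, 2 = singly,
3 = doubly bound).  B-states are actin-coupled Tn, T-states uncoupled.  Six
states are independent; `C` and `T1` are always recovered from conservation,
which makes both conservation laws exact along any trajectory by
construction.

Every transition except C→M is simple mass action.  Forward rates are
always expressed as the product of a steady-state constant (upper-case `K`)
and the reverse component rate (lower-case `k₋ᵢ`, `km*` in code):
coupling `T1→B1` proceeds at `K1·k₋1·C·T1` against `k₋1·B1`, and so on for
the `K3`/`K5` rungs; Ca²⁺ binding proceeds at `K2·k₋2·[Ca²⁺]` (uncoupled)
and `K4·k₋4·[Ca²⁺]` (coupled) against `k₋2` and `k₋4`.  Thermodynamic
consistency of the closed reaction cycles forces the ladder
`K1/K3 = K3/K5 = K2/K4`, so only `K0′, K1, K2, K4` are independent;
`complete_constants` derives `K3` and `K5`, and both cycle products
`(K1·K4)/(K3·K2)` and `(K3·K4)/(K5·K2)` equal one by construction.

The C→M transition is not mass action: cooperativity in this model comes
exclusively from cycling crossbridges, expressed by the second-chance rate
law

    dM/dt = K0′·k₋0·C·(1 + (α − 1)·M)ⁿ − k₋0·M

where `K0′` is the steady-state potential of M, `α` the multiplicity of
crossbridge-replacement opportunities, and `n` the number of Tm subunits
acting in concert.  Experimental preparations map onto `K0′` alone:
filament overlap with ATP (cycling crossbridges) is `K0′ = 1`, overstretch
beyond overlap is `K0′ = 0` (the forward term nullified), and rigor is
`K0′ = 10⁶`.

## Standard parameter values

The packaged standard conditions (fast skeletal muscle, 16 °C) are

| constant | value | reverse rate | value |
|---|---|---|---|
| K0′ | 1 | k₋0 | 50 s⁻¹ |
| K1 | 800 | k₋1 | 100 s⁻¹ |
| K3 | 80 (derived) | k₋3 | 100 s⁻¹ |
| K5 | 8 (derived) | k₋5 | 100 s⁻¹ |
| K2 | 1.67 μM⁻¹ | k₋2 | 15 s⁻¹ |
| K4 | 0.167 μM⁻¹ | k₋4 | 150 s⁻¹ |
| α | 5 | n | 3.25 |

`k₋2` and `k₋4` are the slow and fast Ca²⁺ dissociation rates measured for
regulated actin; the corresponding on-rate products `K2k₋2` and `K4k₋4`
are both 25 μM⁻¹s⁻¹.  Storing `K` and `k₋` separately makes the standard
adjustment — "change the product `K·k₋` while holding `K` (and hence all
equilibria) fixed" — a single reverse-rate edit (`with_product_scaled`).

### The `K1_km1_product` adjustment scales the whole coupling tier

Scaling `k₋1` alone is numerically inert: at `K1k₋1 = 80,000 s⁻¹` the
B1↔T1 exchange is quasi-equilibrated relative to every other process, so
only the ratio `K1` matters and factor-of-two changes move the M transient
by under 0.3%.  The three coupling rungs share one physical process (the
Tn–actin interaction; all three reverse rates are 100 s⁻¹) and their
steady-state constants are tied by the thermodynamic ladder, so this
package interprets the `K1k₋1` adjustment as scaling `k₋1, k₋3, k₋5`
together, preserving the 100:10:1 ratios of the ladder products.  Under
that reading the documented directional responses (peak width, height and
center of the M transient; the C-state/binding decay alignment without
overlap) all reproduce with factor-2 adjustments.

One directional response does *not* reproduce as a single-knob scan:
increasing the coupling-tier products is reported to speed the decay of
Ca²⁺-bound Tn **with** overlap, but in the printed model the dominant
effect of that adjustment is a higher M peak, which holds more Tn in the
slow uncoupled pool and *lengthens* the binding half-decay (+12% at ×2);
only the extreme tail moves in the reported direction, and by well under
1%.  Reproducing the reported response evidently required compensating
adjustments that hold the tension transient fixed, and those compensations
are not specified; the corresponding acceptance check is left failing
rather than reinterpreted, and the sensitivity scan reports what the model
actually does.

## Stimulus

The standard twitch stimulus is the empirical free-Ca²⁺ transient of fast
skeletal muscle: a linear rise from baseline (default 0 μM) to the peak at
`t_peak = 5 ms`, then exponential decay at 100 s⁻¹.  The peak free [Ca²⁺]
is not constrained by the published traces (they are normalized), so the
default amplitude is **20 μM** — near-saturating for the weak coupled site
(`K_d = 1/K4 = 6 μM`) and comfortably saturating for the uncoupled site
(0.6 μM) — and every headline twitch quantity is additionally reported
over an amplitude sweep of 10–50 μM.  Tabulated stimuli (CSV) are evaluated
by piecewise-linear interpolation and held constant beyond the last knot,
so no dynamics are invented outside the measured window.

## Numerical methods

**Twitch integration.**  Rate products reach 80,000 s⁻¹ against a 0.2 s
horizon, so the system is stiff; `simulate_twitch` uses LSODA with
`rtol = 10⁻⁸`, `atol = 10⁻¹⁰` and splits the integration at the stimulus
peak (and at tabulated knots) so step-size control never straddles a
derivative kink.  Output is sampled on a uniform 0.5 ms grid over 0.2 s by
default — the span of the published transients — and every output state is
validated against the simplex invariants with 10⁻⁶ slack.  Halving both
tolerances changes no state by more than 10⁻⁵ (tested).

**Negative round-off.**  Only `M` enters a non-integer power and is clamped
at zero before exponentiation.  All other occurrences of state variables
are linear, where transient sub-round-off negatives act as smooth restoring
terms; clamping them would make the right-hand side discontinuous and stall
the integrator exactly where it matters most (the rigor condition drives
the true `C` to ~5×10⁻⁹).  Stored states below −10⁻⁹, or
conservation-derived `C`/`T1` below −10⁻⁴, abort with a state error: the
former floor is round-off-scaled, the latter is coarser because `C` and
`T1` are differences of order-one sums and, under rigor, legitimately sit
within solver noise of zero.

**Steady states.**  `solve_steady_state` relaxes the dynamics from the
empty state (all Tn free and uncoupled, `M = 0`) at fixed [Ca²⁺] until
`max|dy/dt| < 10⁻⁸ s⁻¹`.  Relaxation from rest is the canonical branch
selector because the cooperative rate law can in principle admit several
fixed points and the twitch simulations approach steady state from rest.
At very large `K0′` the residual criterion collides with float64
cancellation (`C = 1 − B − M` carries ~10⁻¹⁶ absolute error which the
`K0′k₋0(1+(α−1)M)ⁿ` factor amplifies to ~10⁻⁷ s⁻¹ of irreducible residual
noise), so convergence there additionally accepts a residual below that
amplified-noise floor once the state has stopped changing between
integration chunks.  An independent algebraic solver
(`equilibrium_roots`) reduces the fixed-point problem to a scalar root in
`C` — Tn-chain weights from detailed balance, conservation, and the
cooperative fixed point — brackets every root in [0, 1] on a dense scan,
and agrees with relaxation to 10⁻⁶ across conditions (tested); a
brute-force bisection oracle written independently in the test suite
agrees to 10⁻⁸.

**Steady-state curves and Hill fits.**  Activation (`M`) and binding
(`B2+B3+T2+T3`) curves are computed point-by-point on a 60-point
logarithmic grid over 10⁻²–10² μM, spanning both dissociation constants.
Hill parameters are fitted by least squares to the min-max normalized curve
using a floating-baseline, floating-amplitude form
`y₀ + A·ca^n/(k^n + ca^n)`: min-max normalization over a finite grid is an
affine map, so a curve that is exactly Hill on the absolute scale remains
exactly representable after normalization, and the fit recovers synthetic
Hill-1 and Hill-2 inputs to two decimals (tested).  With cycling
crossbridges the binding curve fits `n ≈ 2.1`; without crossbridges and in
rigor it fits `n ≈ 1.30` and `n ≈ 1.43`.  Note the equilibrium limits are
*not* exactly Hill-1: both reduce to two-step Adair chains with equal
stepwise constants and no statistical factors, whose maximum Hill slope is
4/3.  "Non-cooperative" for these curves means near-unit slope relative to
the steeply cooperative cycling curve, not a literal fitted coefficient of
1.00; the package asserts the exact chain closed form
`(x + x²)/(1 + x + x²)`, `x = K2·ca`, for the rigor limit instead.

**Twitch metrics.**  The crossbridge-dependent residual is the pointwise
difference of Ca²⁺-bound Tn between overlap and non-overlap twitches under
an identical stimulus (grids and stimuli are checked).  Its area fraction
uses trapezoidal integration over [0, 0.2] s — all transients are at
baseline well before 0.2 s, and halving the output step moves the fraction
by <0.1 percentage point (tested).  Peak times are refined by a parabola
through the three samples around the discrete maximum, ties broken
earliest.  Peak width is full width at half maximum; decay half-time is the
first post-peak crossing of half the peak, linearly interpolated — robust
and free of exponential-fit assumptions.  Sensitivity responses are
classified against a 2% relative-change threshold (below it: `no_change`),
comfortably cleared by every reproducible directional response at
factor-two adjustments.

## Synthetic pseudo-experiments

`generate_pseudo_experiment` emulates the sampled, noisy traces an
experiment produces: the M (tension-like), Ca²⁺-bound Tn (binding-like) and
C-state series are sampled at 5 ms — the frame spacing of time-resolved
X-ray/fluorescence points — and corrupted with additive Gaussian noise of
standard deviation `noise_sigma × trace peak`, independent across samples
and traces.  One integer seed determines the dataset; each trace draws from
its own `SeedSequence([seed, stream])` sub-stream so adding a trace never
perturbs existing ones.  The generator emulates sampling and additive noise
only — not dye kinetics, diffraction physics, photobleaching, drift, or
correlated noise — so passing recovery tests demonstrate identifiability
under the model's own noise assumptions, not robustness to real-world
systematics.  Parameter recovery refits one rate product by bounded 1-D
minimization of the raw-trace rmse on a log-factor scale; a refit whose
objective varies by less than 10⁻³ of the trace peak across the search
bounds is flagged non-identifiable (e.g. `K0′k₋0` under non-overlap, where
the product is nullified).  At `noise_sigma = 0.02` the identifiable
products recover with <5% mean bias over 20 seeds (tested).

## Known limitations

- Tension is represented by the M fraction alone; there is no
  force–velocity, series-elastic, or spatially explicit sarcomere
  mechanics.
- The free-Ca²⁺ stimulus is an input, not a solved buffering problem: SR
  release/reuptake, parvalbumin/ATP buffering, and indicator-dye kinetics
  are out of scope, so comparisons against fluorescence traces are
  shape-only.
- Only the stated cooperative rate law is implemented for C→M; the ODE
  system is compatible with other logistic functions of C, but none are
  provided.
- The amplitude of the standard stimulus is a documented default (20 μM)
  with a sweep utility, not a measured value; headline twitch fractions
  move by roughly ±10 percentage points across 10–50 μM.
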
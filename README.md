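# thinfil

Kinetic simulation of thin-filament regulation in striated muscle: the
coupled dynamics of tropomyosin position (blocking **B**, central **C**,
myosin-dependent **M**) and Ca²⁺ binding to troponin, driven by a free-Ca²⁺
twitch transient.

## The problem

During a twitch, cytosolic Ca²⁺ indicators (fluo-3) decay far more slowly
than the structural signal of troponin relaxation in overstretched fibers —
so which one reports Ca²⁺ actually bound to troponin?  This package
implements an eight-state mass-action model that answers the question
mechanistically: troponin coupled to actin (Tm in the blocking position)
binds Ca²⁺ weakly and releases it fast, uncoupled troponin binds tightly
and releases slowly, and cycling crossbridges — by holding tropomyosin in
the open M position — move troponin into the slow-releasing pool.  The
model predicts a **crossbridge-dependent pool of Ca²⁺-bound troponin**: the
extra Ca²⁺ retained on troponin when thick and thin filaments overlap,
revealed by simulating the same Ca²⁺ transient with and without overlap and
subtracting the Ca²⁺-bound troponin transients.

It is written for muscle biophysicists and modelers who want reproducible
steady-state activation/binding curves, twitch transients under
overlap/non-overlap/rigor conditions, directional sensitivity analyses, and
synthetic noisy "pseudo-experiments" for testing fitting pipelines.

## The model

Six independent ODEs (states B₁, B₂, B₃, T₂, T₃, M; C and T₁ follow from
`B + C + M = 1` and `B + T = 1`) with mass-action transitions whose forward
rates are products of a steady-state constant and a reverse rate (e.g.
coupling flux `K₁k₋₁·C·T₁` against `k₋₁·B₁`; Ca²⁺ binding `K₄k₋₄[Ca²⁺]`
against `k₋₄`).  Thermodynamics fixes `K₁/K₃ = K₃/K₅ = K₂/K₄`.  The single
non-mass-action step is the cooperative, crossbridge-driven C→M transition

    dM/dt = K₀′k₋₀ C (1 + (α−1)M)ⁿ − k₋₀ M

with experimental conditions expressed through K₀′ alone: overlap
(cycling crossbridges) K₀′ = 1, non-overlap K₀′ = 0, rigor K₀′ = 10⁶.
See `docs/methods.md` for the full account, parameter table and numerics.

## Worked example

```python
import thinfil as tf

constants = tf.standard_conditions()
stim = tf.make_standard_transient()          # 20 uM peak at 5 ms, decay 100/s

overlap = tf.simulate_twitch(constants, stim, tf.Condition.overlap())
nonoverlap = tf.simulate_twitch(constants, stim, tf.Condition.non_overlap())
residual = tf.crossbridge_dependent_residual(overlap, nonoverlap)

frac = tf.auc_fraction(residual, tf.trajectory_series(overlap, "ca_bound_tn"))
print(f"M (tension-like) peak:        {overlap.M.max():.3f} at "
      f"{1e3*tf.peak_time(tf.trajectory_series(overlap,'M')):.1f} ms")
print(f"residual pool peak:           {residual.values.max():.3f} at "
      f"{1e3*tf.peak_time(residual):.1f} ms")
print(f"residual area / overlap area: {frac:.1f} %")

fit = tf.hill_fit(tf.compute_curve(constants, quantity="ca_bound_tn"))
print(f"cycling binding curve:        n_Hill = {fit.n_hill:.2f}, "
      f"K_half = {fit.k_half:.2f} uM")
```

prints

```
M (tension-like) peak:        0.461 at 37.5 ms
residual pool peak:           0.259 at 57.8 ms
residual area / overlap area: 37.8 %
cycling binding curve:        n_Hill = 2.12, K_half = 1.69 uM
```

Reading: the M fraction (proportional to tension) peaks ~33 ms after the
Ca²⁺ peak; the crossbridge-held pool of Ca²⁺-bound troponin appears as the
stimulus ends and peaks near 60 ms, holding roughly a third of the total
Ca²⁺-binding signal; and cycling crossbridges make steady-state binding
steeply cooperative (n ≈ 2) where the no-crossbridge and rigor limits are
near mass action.

## Command line

```sh
thinfil simulate     --config run.yaml --condition overlap --out out/ov
thinfil simulate     --config run.yaml --condition non_overlap --out out/no
thinfil analyze      --overlap out/ov --nonoverlap out/no --out out
thinfil steady-state --k0p 0 --quantity binding --out out
thinfil sensitivity  --config run.yaml --out out
thinfil synth        --config run.yaml --seed 7 --noise 0.02 --out out/ds
```

Configs are single JSON/YAML documents; every omitted field falls back to
the standard conditions, the standard stimulus and the overlap condition.

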
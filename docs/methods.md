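# Methods

## Model

The network has three layers. Layer 1 is a 100×100 replica of the
stimulus (N = 10000 units, row-major flattening), standing in for
whatever preprocessing produces a distributed activity pattern in
cortex. Layer 2 mirrors layer 1 one-to-one; layer 3 holds M category
cells, bidirectionally and all-to-all connected to layer 2 through the
adaptive fan-in matrix `w_in` (N×M) and fan-out matrix `w_out` (M×N).

Every model column is a cascade of linear filtering, multiplicative
feedback modulation `r (1 + net_FB)`, and divisive pool normalization
(shunting inhibition). The continuous shunting dynamics are simulated
at their steady state: with drive `b_j`, the activity solves the coupled
fixed point `x_j = β b_j / (α + q_j)` with `q_j = gain · Σ_k g(x_k)`,
found by damped fixed-point iteration (damping 0.5, absolute tolerance
1e−8 scaled by the activity magnitude, at most 500 iterations;
non-convergence raises an error naming the last residual). Because the
modulation multiplies the *drive*, a zero stimulus pixel produces zero
layer-2 output for any feedback strength — feedback can bias
competition but cannot hallucinate input.

A training step presents one noisy stimulus and runs two sweeps. The
feedforward sweep (residual = 0) selects a winner by winner-take-all on
`g_v` (ties broken toward the lowest index, which makes runs exactly
reproducible); the winner's fan-in column and fan-out row adapt with
the unmodulated `g_u`. The winner's fan-out row then yields the
residual template `res = [g_u − w_out]⁺`, the stimulus drive is
re-amplified as `s (1 + λ res)`, and the feedback sweep repeats
response, selection, and adaptation with the modulated `g_u`. Adapting
with the modulated activity is deliberate: the amplified difference
pattern is exactly what a newly recruited subcategory cell should come
to represent.

## Learning rules

Instar (fan-in): `Δw = η_in g_v (g_u − g_v w)`, an Oja-type rule whose
forgetting term scales with the squared postsynaptic activation. In the
isolated linear-response regime (v = w·u, fixed input) it converges to
squared weight norm 1; this energy conservation keeps learned
prototypes from biasing the layer-3 competition by sheer weight mass.
The discrete Euler step (step size η) can transiently push small
weights negative, so updates are clamped at zero — a documented
deviation from the continuous rule. Outstar (fan-out):
`Δw = η_out g_v (g_u − w)`, gated steepest descent toward the
presented activity; for a stationary winner the row converges to the
empirical mean of its inputs — the cell's prediction of what it
expects to see. γ, the balancing constant of the equilibrium analysis,
is identically 1 in these rules and is not a runtime parameter.

## Parameters

Printed experiment constants: κ_log = 0.0075, μ_log = 700 (800 in the
slowed experiments), λ = 2⁵, η_in = η_out = 2⁻⁴ (2⁻⁵ slowed), weight
init N(0.75, 0.1) (N(0.5, 0.1) slowed) clamped at 0, stimulus noise
σ = 0.05 clipped to [0, 1], drawn fresh per presentation.

The shunting constants and pool kernel are calibration choices:

* α_u = α_v = 1, β_v = 1, β_u = 1.1;
* uniform pool coupling Λ_jk ≡ gain, i.e. `q = gain · Σ g(x)`, with
  layer-2 gain 1e−3 and layer-3 gain 0.01 (the layer-3 pool is
  order-preserving — it rescales all cells identically — so it never
  changes the winner).

The layer-2 gain balances two regimes. A clean feedforward stimulus
(~1300–1460 foreground pixels) yields q ≈ 0.8, so layer-2 activity
stays near the stimulus scale and a matched prototype drives v near
the printed logistic midpoint μ_log = 700 ≈ half of a ~1400-pixel
input energy. A residual-amplified sweep has a much larger drive sum,
so the same pool renormalizes it strongly; without this, subcategory
cells learn amplified fan-in weights so large that they capture the
*feedforward* competition as well, and the overall-category cell
disappears. β_u = 1.1 makes the very first feedback sweep after a
category's recruitment mildly amplifying even at init mean 0.5, which
lets the overall cell consolidate quickly enough that block
transitions — not random drift — drive recruitment.

## Stimuli

Category A: four pictographic faces (head ring radius 42, stroke 3.5;
two filled eyes) differing only in the mouth, drawn inside a fixed
mouth box (rows 56–84, cols 28–72). Category B: four squares
(outline 80×80, stroke 4) each enclosing one 6×40 bar, two horizontal
and two vertical, at pairwise disjoint positions. All variants have
1200–1600 foreground pixels, so the squared input energy of a binary
stimulus is ≈ 1400 ≈ 2 μ_log.

Two geometric properties matter beyond the union/intersection
structure, and the defaults were chosen (by direct search over the
parametric layout) to satisfy them:

* **unique evidence**: every variant carries ≥ ~180 pixels not shared
  with any sibling variant. Recruitment of a subcategory requires an
  unused cell to beat the overall cell on the amplified pattern; the
  contested margin is proportional to the variant's unique pixel mass.
* **cross-category separation**: no face mouth overlaps a square bar.
  Otherwise one cell can win the feedback sweep for variants of both
  categories and the role assignment becomes ambiguous.

The generator emulates noisy presentations of fixed binary line
drawings. It does not emulate gray-level natural images, geometric
variability (translation, scale), or correlated noise; results on
these stimuli therefore demonstrate the recruitment mechanism, not
robustness of categorization in natural input statistics.

## Experiment protocols

Presets 1–4 reproduce the four study conditions. Step counts: preset 1
runs 800 steps (two epochs of 4×100 sorted blocks) — one epoch is not
enough, because the first variant is absorbed into the overall cell
during its own block and only separates into a subcategory when its
block returns. Preset 4 runs the printed 1000 steps with 12 cells and
blocks of 100; the pair cycle is ordered variant-major
(A1, B1, A2, B2, …), so each category's first variant is revisited
within the run — with category-major ordering the second category's
first variant would get no revisit before step 1200. Presets 2 and 3
run 400 random-order steps.

## Known limitations

* In experiment 2 (random order, fast defaults) the model reliably
  separates all four variants, but as per-variant *exemplar* cells:
  each recruited cell wins both sweeps for its variant, and no single
  overall cell emerges. With dense initialization at mean 0.75, an
  unused cell outcompetes the young first cell in the feedforward
  sweep as soon as an unseen variant appears — within the first ~50
  random steps, before the first cell can consolidate shared
  structure. The overall/subcategory hierarchy requires the early
  blocked exposure of experiments 1 and 4 under this calibration.
* Occasional seeds of experiment 1 recruit a sixth cell (leaving no
  unused capacity); the structural outcome is assessed across seeds.
* The activities of the two sweeps under λ = 0 are identical for
  learning-free probes; within a training step they differ at O(η)
  because the feedforward winner adapts between the sweeps.
* Recruitment *times* are seed- and protocol-dependent and are not
  treated as quantitative outcomes; only the final role structure is.

## Numerical notes

All randomness in a run derives from one integer seed through
`numpy.random.SeedSequence` spawning (initialization, presentation
order, per-presentation noise); traces are bit-reproducible. The
logistic transfer is evaluated through `scipy.special.expit` for
stability at extreme arguments. The isolated Oja iteration used for
the weight-energy check needs η v² < 1 for Euler stability, hence its
small positive initialization.
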
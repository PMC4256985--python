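# cortcol

A recurrent cortical-column model of unsupervised visual category and
subcategory learning.

## The problem

How can a visual system learn that a set of stimuli belongs to one
category — and then, without supervision, refine that category into
subcategories for the variations it keeps encountering?  `cortcol`
implements a three-layer network of abstract cortical columns in which
this refinement emerges from the interaction of two mechanisms:

* an **associative memory** at the category layer, combining an instar
  (Oja-type) rule for bottom-up *receptive fields* `w_in` with an
  outstar rule for top-down *projective fields* `w_out`;
* **modulatory residual feedback**: the winning category cell's
  projective field predicts the expected input, and the rectified
  prediction error multiplicatively amplifies the stimulus drive before
  a second (feedback) sweep.

The package is aimed at computational-neuroscience researchers and
students studying biased competition, predictive feedback, and the
stability–plasticity problem in unsupervised category learning.

## The model

Each column is a three-stage cascade. Stage I filters its input,
`r = Σ_j K_j s_j`; stage II modulates it multiplicatively with re-entrant
feedback, `r_FB = r (1 + net_FB)` — so feedback can amplify but never
create activity; stage III divisively normalizes against a pool of
neurons, solving the shunting steady state

```
x_j = β r_j / (α + q_j),   q_j = Σ_k g(x_k) Λ_jk .
```

Layer 2 mirrors the input field (identity filter, rectified-linear
transfer `g_u(u) = [u]⁺`); layer 3 holds M category cells with learned
fan-in filters and logistic transfer
`g_v(v) = 1 / (1 + exp(κ_log (μ_log − v)))`. A winner-take-all rule Ω
selects the maximally active cell; only the winner adapts:

```
Δw_in  = η_in  g_v (g_u − g_v w_in)      (instar; bounded, energy-conserving)
Δw_out = η_out g_v (g_u − w_out)         (outstar; → expected input)
```

One training step runs a feedforward sweep (adapt), forms the residual
template `res_j = [g_u(u_j) − w_out,kj]⁺` from the winner's projective
field, re-runs layer 2 with the amplified drive `s_j (1 + λ res_j)`,
and adapts the feedback-sweep winner. When the residual is large, a
previously unused cell wins the feedback sweep and a subcategory is
recruited; when the input is perfectly predicted, the residual — and
with it the feedback — vanishes.

Stimuli are two categories of 100×100 binary pictograms with additive
clipped Gaussian noise: four faces differing only in mouth shape, and
four squares enclosing a bar at variant-specific positions.

## Worked example

Train the blocked single-category experiment (squares, six cells,
slowed learning) and classify the cells:

```python
from cortcol import preset, run_experiment, classify_cells, count_recruited

cfg = preset(1, seed=2)             # category B, epochs of 4 x 100 sorted blocks
trace = run_experiment(cfg)
roles = classify_cells(trace.final_state, cfg.stimulus_sets(), cfg.params)
print("recruited:", count_recruited(trace))
print(roles.summary())
```

prints

```
recruited: 5
cell 0: unused
cell 1: subcategory B variant 1
cell 2: subcategory B variant 3
cell 3: subcategory B variant 4
cell 4: overall B
cell 5: subcategory B variant 2
```

Five of the six cells were recruited: cell 4 (the first winner, step 0)
became the **overall category cell** — it wins the feedforward sweep for
every square variant. As the feedback amplified each variant's bar
against the category average, four more cells were recruited (steps 100,
200, 300, 400), one **subcategory cell** per bar position; each wins the
feedback sweep for exactly its variant. One cell was never selected —
the spare capacity that lets new categories be added without
overwriting old ones.

The same can be run from the shell:

```
cortcol run --experiment 1 --seed 2 --out runs/exp1
cortcol probe --state runs/exp1/state.npz --categories B --mu-log 800
cortcol render-stimuli --out stimuli/
```

Every run writes a `manifest.json` (config, hash, seed, version)
sufficient to reproduce the trace bit-for-bit.

## Preset experiments

1. `preset(1)` — category B, blocked 4×100 epochs, 6 cells, slowed
   learning (η = 2⁻⁵, μ_log = 800, init N(0.5, 0.1)): overall cell plus
   four subcategory cells emerge.
2. `preset(2)` — category A, random order, 6 cells, defaults
   (η = 2⁻⁴, μ_log = 700, λ = 2⁵, init N(0.75, 0.1)).
3. `preset(3)` — as 2 but λ = 0: the feedback ablation; exactly one
   cell is ever recruited and no subcategories form.
4. `preset(4)` — both categories, 12 cells, 1000 steps, experiment-1
   parameters: two overall cells and four subcategory cells per
   category.

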
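# tracenet

A hierarchical trace-learning network for transform-invariant visual
object recognition, with the information-theoretic and
pattern-association readouts used to characterise neurons in the primate
ventral visual stream.

## The problem

Neurons in anterior inferior temporal (IT) cortex respond selectively to
an object across large changes in its retinal image — translation, size,
and rotation in depth, including *catastrophic* view changes where a new
view shares almost no pixels with the last. How can a hierarchy of
cortex-like competitive networks learn such representations without a
teacher? The hypothesis implemented here: because the world is
temporally continuous, images close in time usually come from the same
object, so a Hebbian synapse driven by a short memory **trace** of the
neuron's recent firing will associate successive transforms of one
object onto the same neurons.

## The model

Four competitive layers (V2 → V4 → posterior IT → anterior IT analogues)
sit on a fixed Gabor-filter front end standing in for V1 simple cells
(4 spatial frequencies over 4 octaves × 4 orientations × 2 rectified
signs = 32 channels, energy-normalised across scales). Each neuron
receives a fixed number of feedforward connections sampled from a radial
Gaussian over the previous layer, with the nominal radius containing
~67 % of connections. Within a layer, activations `r` pass through
lateral inhibition

    I(a,b) = -δ exp(-(a²+b²)/σ²)   off-centre,   centre = 1 - Σ off-centre

and a sigmoid `y = 1 / (1 + e^{-2β(r-α)})` whose threshold `α` sits at a
fixed percentile of the layer's activations, pinning the population
sparseness `a = (Σyᵢ/n)² / (Σyᵢ²/n)`.

Layer 1 learns with a plain Hebb rule `δw_j = α y x_j`; layers 2–4 use
the trace rule

    ȳ(τ) = (1-η) y(τ) + η ȳ(τ-1),      δw_j = α ȳ(τ-1) x_j(τ)

— the postsynaptic term is the trace up to the **preceding**
presentation only, so a neuron learns the current transform because it
responded to the previous ones. Weight vectors are renormalised to unit
length after every presentation; the trace resets at object boundaries.

Performance is measured as a neurophysiologist would measure it:
stimulus-specific single-cell information
`I(s,R) = Σ_r P(r|s) log₂ [P(r|s)/P(r)]` (up to `log₂ N_S` bits),
multiple-cell information `I(S,S′)` from a decoding confusion table, and
a biologically plausible one-layer Hebbian pattern associator reading
the 10 most object-selective output cells per class.

Because the originally published image sets are external data, the
package ships seeded synthetic stimulus generators reproducing the four
experiment designs at desk scale: intra-class exemplar variation,
systematic view series at fixed angular spacing, part-configured objects
with quadrant scrambling, and object pairs with a catastrophic view
change. See `docs/methods.md` for what these generators do and do not
emulate.

## Worked example

Two cup-like objects, four views each; one view per object reveals the
same high-contrast interior pattern, so raw image statistics pull those
two views together while object identity pulls them apart. Train the
scaled network for 10 epochs with the views of each object presented as
a temporally contiguous block:

```python
from tracenet import ExperimentConfig, run_experiment

report = run_experiment(ExperimentConfig(experiment="exp4", seed=0))
info, cls = report.info["train"], report.classification
print(f"pattern-associator accuracy: {cls['train_percent_correct']:.1f}% "
      f"(chance {cls['chance_percent']:.1f}%)")
print(f"max single-cell information: {info['max_single_cell_bits']:.2f} bits")
print(f"multiple-cell information:  {info['multiple_cell_bits']:.2f} bits, "
      f"decoding {info['multiple_cell_percent_correct']:.1f}% correct")
```

prints

```
pattern-associator accuracy: 100.0% (chance 50.0%)
max single-cell information: 1.00 bits
multiple-cell information:  1.00 bits, decoding 100.0% correct
```

and the best output cell for object 0 fires at rate 1.0 to all four of
its views — including the catastrophic one — and at 0.0 to every view of
the other object:

```
[[1. 1. 1. 1.]
 [0. 0. 0. 0.]]
```

1.00 bits is the ceiling `log₂ 2` for a two-object set: a single cell
identifies the object perfectly from any view. An image-statistics
learner would instead group the two text-revealing views together.

The same pipeline is available from the shell:

```bash
tracenet run-experiment --experiment exp4 --seed 0 --out runs/exp4
tracenet compare-variants --experiment exp2 --variants trace,hebb
```

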
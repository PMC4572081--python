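# Methods

This note records the model as implemented, the parameters that matter,
the design choices made where the design was genuinely open, and what
the synthetic stimuli can and cannot show.

## Front end

Images are single-channel grayscale in [0, 1], resampled bilinearly to
the profile's input resolution. The V1 stand-in is a bank of 2D Gabor
wavelets: frequencies 0.5, 0.25, 0.125, 0.0625 cycles/pixel (four
octaves), orientations 0°/45°/90°/135°, quadrature (even/odd) phase.
Constraints follow the physiology: elliptical Gaussian envelope with
2:1 aspect ratio elongated along the bar, half-amplitude frequency
bandwidth fixed at 1.5 octaves (this sets the envelope width along the
propagation axis, `σ = √(ln2/2)/(πf) · (2^b+1)/(2^b−1)`), and exactly
zero mean so the basis is an admissible wavelet. Kernels are truncated
at 3 envelope sigmas of the long axis and normalised to unit energy.

The network input volume uses the even kernel of each
frequency–orientation pair; its signed response is zero-thresholded into
a positive and an anti-phase channel (disjoint support, `pos − neg`
reconstructs the signed response), giving 4 × 4 × 2 = 32 channels.
Channel energies are then equalised across the four frequency bands per
image ("energy" = sum of squared rectified responses per band; target =
mean band energy; all-zero bands stay zero), compensating the 1/f bias
of natural images. Convolution extends the image by edge replication, so
a uniform image produces zero response everywhere; zero padding would
instead put an identical high-contrast frame into every stimulus, and a
Hebbian layer reliably locks onto such shared structure.

## Architecture

Two profiles are built in.

| | full-table1 | scaled-32 |
|---|---|---|
| input | 256×256×32 | 64×64×32 |
| neurons/layer | 128×128 | 32×32 |
| fan-in (L1–L4) | 100/400/400/400 | 100/100/100/100 |
| radius (px) | 24/24/36/48 | 6/6/9/12 |
| inhibition σ | 1.38/2.7/4.0/6.0 | same |
| inhibition δ | 1.5/1.5/1.6/1.4 | same |
| percentile | 99.2/98/88/95 | 96.8/92/88/95 |
| slope β | 190/40/75/26 | same |
| rate α | 0.05/0.03/0.005/0.005 | same |
| rule, η | hebb, −/trace 0.6/trace 0.8/trace 0.8 | same |

Connectivity: each neuron draws its exact fan-in from a radial Gaussian
centred on its focal point (topology preserved: focal points scale with
position). The Gaussian width follows from the requirement that the
nominal radius contain 67 % of connections: for a radial 2D Gaussian
`P(d ≤ R) = 1 − exp(−R²/2σ²) = 0.67` gives `σ = R/1.489`. Sampling is
without replacement (no duplicated pair), implemented as Gumbel-top-k
over a window truncated at 4σ (widened adaptively if a border neuron
would otherwise lack distinct sites); border neurons renormalise the
profile over valid coordinates, keeping the fan-in exact. Layer-1 fan-in
is split evenly across the four spatial frequencies, so every cell
samples every frequency; orientation and sign are sampled freely.
Weights initialise uniform-positive and are renormalised to unit norm.

The within-radius fraction is quoted for neurons whose sampling support
is interior to the grid: border truncation (a finite-grid artifact)
raises the apparent fraction for edge neurons and is not part of the
profile's definition.

Per presentation the stage order is: propagate (weighted sum over the
fan-in) → lateral inhibition (the centre–surround filter above, zero
padding — retinal topology has real borders; the kernel's coefficients
sum to exactly 1, so a uniform field is a fixed point) → sigmoid
contrast enhancement → learning → weight renormalisation. The sigmoid
threshold is the stated percentile of the current layer's activations
(linear-interpolation percentile), recomputed per presentation — the
spec of this model family leaves the cadence open; per-presentation is
the default here, and thresholds frozen at the end of training are kept
on the trained network (`NetworkState.trained_thresholds`) for analyses
that want a slow-homeostasis reading. An all-equal activation grid is
degenerate: the layer warns and returns uniform y = 0.5.

**Scaled-profile percentiles.** The desk-scale profile keeps the grid,
fan-in and radii of the earlier 32×32 generation of this model family,
but loosens the layer-1/2 sparseness percentiles (99.2 → 96.8,
98 → 92). The reason is a scaling identity: what feature binding sees is
the *expected number of active inputs per downstream neuron*, fan-in ×
winner fraction. At full size that is 400 × 0.008 ≈ 3.2 for layer 2 and
400 × 0.02 = 8 for layer 3; keeping the full-size percentiles at 1/16
the neuron count and 1/4 the fan-in would leave a layer-2 neuron
sampling 0.8 active inputs per image, and learning becomes a lottery
over which neurons happen to wire to a winner. The loosened percentiles
restore the full-size active-input counts; the output layer keeps its
5 % sparseness.

## Learning

Layer 1 uses the plain Hebb rule (feature combinations must form with
full spatial precision before invariance learning). Layers 2–4 use the
trace rule with the postsynaptic term equal to the trace computed up to
the *preceding* presentation (`δw = α ȳ^{τ−1} x^τ`); the older variant
whose trace includes the current step is selectable (`trace_current`),
as is a pure-Hebb control (η = 0).

Training is sequential: layer 1 to completion, then 2, 3, 4, lower
layers frozen — the established protocol of this model family, which
also makes per-layer convergence monitoring meaningful. Because frozen
layers are deterministic, their outputs per stimulus are computed once
per layer (a pure cache; results are bit-identical to recomputing).
Within an epoch, object blocks are presented in random order and images
within a block in random order; the trace resets at each block boundary
(without the reset, cross-object associations corrupt learning in
block-sequenced training). Weight norms are exactly 1 after every
presentation. A neuron whose norm collapses to zero (impossible with
nonnegative rates, but guarded) is reinitialised and logged. The
convergence log records mean |δw| per layer per epoch; a layer is
"converged" when the trend over the final third of epochs is
non-increasing. `tune_learning_rates` exposes the principled
rate-selection procedure (halve a layer's rate until its per-epoch
weight change asymptotes within the epoch budget); the defaults are the
table values above.

Evaluation presents each stimulus once and tabulates the output layer's
firing (neurons × objects × transforms). The per-presentation percentile
threshold is used at evaluation as in training.

## Readouts

**Single-cell stimulus-specific information.** Rates are quantised into
equal-width bins over the neuron's observed range; the bin count
defaults to the number of transforms per object, capped at 10, and is
recorded with the result. P(r|s) comes from the transforms of object s,
P(r) from the equiprobable-object marginal (equiprobability is assumed
throughout). The per-cell headline is the maximum over objects; for a
competitive network whose cells become object-tuned this approaches
log₂ N_S. No finite-sampling bias correction is applied; the tests
characterise bias with shuffled/random-rate controls.

**Multiple-cell information.** Each trial's population vector over a
chosen cell subset is decoded to the object with the most similar mean
vector — normalised dot product ("dot", the biologically plausible
readout, default) or nearest mean ("gaussian") — with the trial held out
of its own class mean; for a test table, means come from the training
responses instead. The mutual information of the resulting confusion
table and the percent correct are reported. The default subset is the
five most informative cells per stimulus **that also respond to it**
(mean rate to the stimulus above the cell's overall mean): information
alone is ambiguous in small designs, since a cell silent for one of two
objects is equally informative about both.

**Pattern associator.** One output neuron per class, trained one pass
with δw = α·y·x against a one-hot teacher on every training transform
(sum form, order-independent); inputs are the k = 10 cells per class
with the highest ratio of class mean rate to overall mean rate,
near-ties broken by stimulus-specific information, selections disjoint
across classes. Classification is argmax of the class activations; exact
ties resolve to the lowest class index and the tie rate is logged.
Chance (1/n_classes) is reported alongside every percent correct.

**Similarity matrices.** Cosine of the angle between population vectors
of (object, transform) pairs; entries involving an all-zero vector are
NaN (undefined), not 0.

## Synthetic stimuli

The four experiment designs were originally run on photographic or
rendered image collections; the generators here reproduce the
*statistical structure* each design needs, on a mid-gray background,
deterministically from a seed.

- **Class exemplars** (experiment-1 analogue): each class is a fixed
  constellation of 4–6 blob/bar primitives; exemplars jitter primitive
  and global positions (default σ = 2 px) and add low-contrast clutter.
- **View series** (experiment-2 analogue): an object is an elliptical
  body plus 6–9 surface features at fixed longitudes; a view at azimuth
  θ projects each feature orthographically with cosine visibility
  weighting and foreshortening, so adjacent views are similar and
  opposite views are not. Cross-validation sets place test views at a
  stated angular offset from every training view.
- **Part-configured objects** (experiment-3 analogue): four parts in a
  2×2 quadrant arrangement, each part a composite of two primitives
  whose shapes, contrasts and positions within the quadrant are
  object-specific (identities share a configuration but differ in part
  geometry, as face identities do); exemplars jitter primitive positions
  by σ = 1.5 px. Candidate identities whose base image correlates above
  0.4 with an accepted one are resampled, so the set is a set of
  visibly distinct identities. Scrambling permutes the four quadrants;
  by default only derangements are drawn (every quadrant displaced —
  permutations with fixed points leave half the configuration intact),
  distinct permutations per image.
- **Catastrophic pair** (experiment-4 analogue): two cup-like objects
  with identity-diagnostic outlines (body proportions, handle side)
  constant across views; interior shading varies smoothly across views
  except one view per object, which reveals a high-contrast interior
  checkerboard *identical for the two objects* — the revealed pattern
  dominates image similarity while carrying no identity information.
- **Translation × view grids**: every (view, location) pair per object,
  integer-pixel shifts with background fill (4 views × 25 locations =
  100 transforms by default).

External image directories (object-per-subdirectory) load through
Pillow: ITU-R 601-2 luminance conversion, bilinear resampling.

What the generators do **not** emulate: photographic texture and
clutter, lighting variation, occlusion, and the dense all-over content
of real faces and objects. Passing the tests therefore shows that the
mechanism — temporal-trace binding of transforms under competitive
learning — works as described on stimuli with the right covariance
structure; it does not benchmark the model on natural images.

## Experiment defaults

exp1: 2 classes, 50 train + 30 test exemplars, 50 epochs/layer.
exp2: 8 objects; 9 training views at 40° (4 at 90° and 18 at 20° also
supported); test = 18 views at 20° offset by 10°; 50 epochs/layer.
exp3: 8 objects × 5 exemplars, 20 epochs/layer; scrambled test = 5
derangements per training image. exp4: 2 objects × 4 views, 10
epochs/layer. All runs use the scaled-32 profile by default and are
bit-reproducible from (config, seed); epoch counts are per layer of the
sequential schedule.

## Numerical choices and degenerate inputs

Percentiles use linear interpolation. Sigmoid saturation underflows to
exactly 0/1 (by design; overflow is silenced locally). Gumbel-top-k
sampling is exact sampling without replacement. Integer translations are
exact (slice copies), so shift-and-unshift restores the interior
bit-for-bit; the tolerance for bilinear operations is 1e−6 of dynamic
range. Zero-norm weight vectors raise; all-zero firing makes sparseness
and cosine similarity undefined (error / NaN rather than silent 0).

## Known limitations

At 1/16 the neuron count and 1/4 the fan-in of the full profile, the
scaled runs show residual seed-to-seed variance the full-size model does
not: over 12 seeds, the part-configuration experiment's training-set
classification is 100 % for most seeds but can dip to ~88 %, and the
scrambled test scatters a few points around the 12.5 % chance level with
a small residue of part-level information (multiple-cell information on
scrambled responses of order 0.3–0.9 bits rather than exactly 0) —
output cells at this scale pool fewer parts per object, so a displaced
part can still excite them weakly. The catastrophic-pair and
view-series outcomes (perfect two-object classification; 3-bit
single-cell information) are stable across seeds. Training the full
128×128 profile is supported by the code but is not exercised by the
test suite, which runs entirely on the scaled profile.
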
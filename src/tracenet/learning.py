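"""Synaptic plasticity: trace rule, Hebb rule, weight normalization, training loop.

The model's central mechanism is the temporal-trace learning rule: the
postsynaptic term of the Hebbian update is replaced by an exponentially
decaying average of the neuron's recent firing,

    trace(t) = (1 - eta) * y(t) + eta * trace(t-1)

so that synapses strengthen onto whatever inputs occur while the trace
of *previous* activity is high.  Because successive presentations in the
real world (and in the training order used here) tend to be transforms
of the same object, the rule binds a neuron's response across an
object's transforms.  The preferred variant drives the update with the
trace computed up to the preceding presentation only,

    dw_j = alpha * trace(t-1) * x_j(t)

with no contribution from the current firing; the older variant that
includes the current step (dw_j = alpha * trace(t) * x_j) is kept
selectable for comparison.  Layer 1 uses plain Hebbian learning
(dw_j = alpha * y * x_j): feature combinations must first be formed with
full spatial precision before invariance learning starts.

Weight vectors are explicitly renormalised to unit length after every
presentation, the standard competitive-network bound on weight growth.
The trace is reset at object-sequence boundaries so that temporal
association never spans two different objects.  Layers are trained
sequentially from layer 1 upward, lower layers frozen, which makes the
per-layer convergence of mean weight change meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gabor import image_to_input_volume
from .network import NetworkState, contrast_enhance, lateral_inhibit, propagate
from .stimuli import StimulusSet

__all__ = [
    "TraceState",
    "update_trace",
    "trace_learn",
    "hebb_learn",
    "renormalize",
    "train_network",
    "tune_learning_rates",
    "converged",
]


@dataclass
class TraceState:
    """Per-neuron activity trace within the current object sequence."""

    trace: np.ndarray
    step: int = 0  # presentations since the last object boundary

    def reset(self) -> None:
        self.trace[:] = 0.0
        self.step = 0


def update_trace(trace_prev: np.ndarray, y_now: np.ndarray, eta: float) -> np.ndarray:
    """trace(t) = (1 - eta) y(t) + eta trace(t-1); convex, stays in [0, 1]."""
    if not (0.0 <= eta < 1.0):
        raise ValueError("eta must be in [0, 1)")
    return (1.0 - eta) * np.asarray(y_now) + eta * np.asarray(trace_prev)


def trace_learn(x: np.ndarray, trace_prev: np.ndarray, alpha: float) -> np.ndarray:
    """Trace-rule weight change dw_j = alpha * trace(t-1) * x_j(t).

    ``trace_prev`` must be the trace *before* incorporating the current
    presentation; the update has no dependence on the current firing.
    ``x`` may be a vector (one neuron) or (n_neurons, fan_in) with
    ``trace_prev`` of length n_neurons.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    x = np.asarray(x, dtype=float)
    t = np.asarray(trace_prev, dtype=float)
    if x.ndim == 2:
        return alpha * t[:, None] * x
    return alpha * t * x


def hebb_learn(x: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    """Associative update dw_ij = alpha * y_i * x_j (outer product form)."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim == 2:
        return alpha * y[:, None] * x
    return alpha * np.outer(y, x) if y.ndim else alpha * y * x


def renormalize(w: np.ndarray) -> np.ndarray:
    """Scale weight vector(s) to exactly unit Euclidean norm.

    Accepts a single vector or an (n_neurons, fan_in) matrix (row-wise).
    Raises on a zero-norm vector (a dead neuron; see ``train_network``
    for the reinitialisation policy).
    """
    w = np.asarray(w, dtype=float)
    if w.ndim == 1:
        n = np.linalg.norm(w)
        if n == 0.0:
            raise ValueError("cannot renormalize a zero-norm weight vector")
        return w / n
    norms = np.linalg.norm(w, axis=1, keepdims=True)
    if np.any(norms == 0.0):
        raise ValueError("cannot renormalize zero-norm weight vector(s)")
    return w / norms


def converged(log: pd.DataFrame, layer: int) -> bool:
    """Whether a layer's mean |dw| trend is non-increasing over the final third."""
    sub = log[log["layer"] == layer].sort_values("epoch")
    vals = sub["mean_abs_dw"].to_numpy()
    tail = vals[-max(2, len(vals) // 3) :]
    if len(tail) < 2:
        return False
    slope = np.polyfit(np.arange(len(tail)), tail, 1)[0]
    return bool(slope <= 1e-12 or tail[-1] <= tail[0])


def _input_cache(
    state: NetworkState, stimuli: StimulusSet, up_to_layer: int
) -> np.ndarray:
    """Frozen-layer outputs feeding layer ``up_to_layer`` for every image.

    Returns (n_images, n_pre_sites).  With lower layers frozen these are
    fixed for the whole of the layer's training, so they are computed
    once (the forward pass is deterministic given the weights).
    """
    outs = []
    for img in stimuli.images:
        vol = image_to_input_volume(img, bank=state.bank)
        if up_to_layer == 0:
            outs.append(vol.data.ravel())
        else:
            ys = state.forward(vol, up_to_layer=up_to_layer)
            outs.append(ys[-1].ravel())
    return np.asarray(outs)


def _presentation_order(
    stimuli: StimulusSet, rng: np.random.Generator
) -> list[np.ndarray]:
    """Object blocks in permuted order, images permuted within each block."""
    blocks = []
    for obj in rng.permutation(stimuli.unique_objects()):
        idx = np.flatnonzero(np.asarray(stimuli.object_ids) == obj)
        blocks.append(rng.permutation(idx))
    return blocks


def train_network(
    stimuli: StimulusSet,
    state: NetworkState,
    epochs: int,
    seed: int | None = None,
    rule_overrides: dict[int, str] | None = None,
    eta_overrides: dict[int, float] | None = None,
) -> tuple[NetworkState, pd.DataFrame]:
    """Train all layers sequentially on a stimulus set.

    Each layer in turn is trained for ``epochs`` epochs with the layers
    below it frozen.  Within an epoch, object blocks are presented in
    random order and each object's images in random order within its
    block (temporal continuity within objects); the activity trace is
    reset at every block boundary.  Per presentation the stage order is
    propagate -> lateral inhibition -> sigmoid contrast enhancement ->
    learning -> weight renormalization.

    While a layer is plastic its sigmoid threshold adapts per
    presentation (the percentile of the current activations); when its
    training ends the threshold is frozen together with the weights
    (mean over the final epoch) and the frozen value is used whenever
    the layer serves as input to later layers or to evaluation.

    ``rule_overrides`` / ``eta_overrides`` map 1-based layer numbers to
    a rule name / trace decay (used for rule-variant controls).  The run
    is a pure function of (state, stimuli, seed): identical inputs give
    bit-identical weights and logs.  Returns the trained state and a
    ConvergenceLog frame with columns (layer, epoch, mean_abs_dw, alpha).
    """
    if len(stimuli) == 0:
        raise ValueError("empty stimulus set")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    rng = np.random.default_rng(state.seed if seed is None else seed)
    rows = []
    state.trained_thresholds = []
    for li, spec in enumerate(state.profile.layers):
        rule = (rule_overrides or {}).get(li + 1, spec.rule)
        eta = (eta_overrides or {}).get(li + 1, spec.trace_eta)
        alpha = spec.learning_rate
        cmap = state.maps[li]
        inputs = _input_cache(state, stimuli, up_to_layer=li)
        n_neurons = spec.n_neurons
        tracer = TraceState(np.zeros(n_neurons))
        final_thresholds: list[float] = []
        for epoch in range(epochs):
            abs_dw = 0.0
            n_pres = 0
            for block in _presentation_order(stimuli, rng):
                tracer.reset()
                for img_idx in block:
                    x = inputs[img_idx]
                    x_sel = x[cmap.indices]  # (n_neurons, fan_in)
                    r = propagate(x, cmap).reshape(spec.grid_dims, spec.grid_dims)
                    r = lateral_inhibit(r, spec.inhib_delta, spec.inhib_sigma)
                    y, thr = contrast_enhance(
                        r, spec.sigmoid_percentile, spec.sigmoid_beta
                    )
                    if epoch == epochs - 1:
                        final_thresholds.append(thr)
                    y = y.ravel()
                    if alpha == 0.0:
                        if rule in ("trace", "trace_current"):
                            tracer.trace = update_trace(tracer.trace, y, eta)
                        tracer.step += 1
                        n_pres += 1
                        continue
                    if rule == "hebb":
                        dw = hebb_learn(x_sel, y, alpha)
                    elif rule == "trace":
                        dw = trace_learn(x_sel, tracer.trace, alpha)
                        tracer.trace = update_trace(tracer.trace, y, eta)
                    elif rule == "trace_current":
                        tracer.trace = update_trace(tracer.trace, y, eta)
                        dw = trace_learn(x_sel, tracer.trace, alpha)
                    else:
                        raise ValueError(f"unknown rule {rule!r}")
                    tracer.step += 1
                    w = cmap.weights + dw
                    if not np.all(np.isfinite(w)):
                        raise FloatingPointError(
                            f"non-finite weights in layer {li + 1}, epoch {epoch}"
                        )
                    norms = np.linalg.norm(w, axis=1, keepdims=True)
                    dead = norms[:, 0] == 0.0
                    if np.any(dead):
                        # cannot occur with nonnegative x, y but guarded:
                        # reinitialise dead neurons with fresh random weights
                        w[dead] = rng.uniform(0.0, 1.0, size=(dead.sum(), cmap.fan_in))
                        norms = np.linalg.norm(w, axis=1, keepdims=True)
                    cmap.weights = w / norms
                    abs_dw += float(np.mean(np.abs(dw)))
                    n_pres += 1
            rows.append(
                {
                    "layer": li + 1,
                    "epoch": epoch,
                    "mean_abs_dw": abs_dw / max(n_pres, 1),
                    "alpha": alpha,
                }
            )
        # freeze this layer's threshold with its weights: the mean of the
        # final epoch's per-presentation percentile thresholds
        state.trained_thresholds.append(float(np.mean(final_thresholds)))
    return state, pd.DataFrame(rows)


def tune_learning_rates(
    stimuli: StimulusSet,
    state: NetworkState,
    epochs: int,
    target_ratio: float = 0.5,
    max_iter: int = 4,
    seed: int | None = None,
) -> list[float]:
    """Scale per-layer learning rates until weight changes asymptote.

    Implements the principled selection procedure: the mean weight
    change per epoch should decrease and asymptote within the training
    budget.  A layer whose final-third mean |dw| exceeds
    ``target_ratio`` times its first-third mean has its rate halved and
    the probe repeated (up to ``max_iter`` times).  Returns the tuned
    rates; the supplied state is not modified.
    """
    from dataclasses import replace as _replace

    rates = [spec.learning_rate for spec in state.profile.layers]
    for _ in range(max_iter):
        probe = NetworkState(
            profile=_replace(
                state.profile,
                layers=tuple(
                    _replace(spec, learning_rate=r)
                    for spec, r in zip(state.profile.layers, rates)
                ),
            ),
            maps=[m.copy() for m in state.maps],
            seed=state.seed,
            bank=state.bank,
        )
        _, log = train_network(stimuli, probe, epochs, seed=seed)
        changed = False
        for li in range(len(rates)):
            sub = log[log["layer"] == li + 1]["mean_abs_dw"].to_numpy()
            third = max(1, len(sub) // 3)
            if sub[:third].mean() > 0 and sub[-third:].mean() > target_ratio * sub[:third].mean():
                rates[li] *= 0.5
                changed = True
        if not changed:
            break
    return rates
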
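"""Performance measures: information theory, pattern association, similarity.

The network's output is evaluated exactly as inferior-temporal-cortex
recordings are evaluated in neurophysiology:

* Stimulus-specific information of a single cell,
  ``I(s, R) = sum_r P(r|s) log2 [P(r|s) / P(r)]`` (bits), computed from
  binned firing rates over the transforms of each object; the headline
  figure per cell is the maximum over objects.  For a competitive
  network whose cells become tuned to single objects this can approach
  ``log2 N_S`` bits for ``N_S`` equiprobable objects.

* Multiple-cell information: each trial's population vector is decoded
  to an object by similarity to held-out class mean vectors; the mutual
  information ``I(S, S') = sum P(s, s') log2 [P(s, s') / (P(s) P(s'))]``
  is computed from the resulting confusion table, together with percent
  correct.

* A one-layer Hebbian pattern associator (one output neuron per class,
  one-hot teacher, the k most selective cells per class as inputs) as
  the biologically plausible readout, reported as percent correct
  against the 1/n_classes chance level.

* Representational similarity matrices: cosine of the angle between the
  population firing vectors of stimulus pairs.

Objects are treated as equiprobable throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ResponseTable",
    "InfoResult",
    "AssociatorModel",
    "compute_responses",
    "single_cell_info",
    "max_single_cell_info",
    "multiple_cell_info",
    "select_best_cells",
    "train_pattern_associator",
    "classify",
    "similarity_matrix",
]


@dataclass
class ResponseTable:
    """Firing rates on a complete (object x transform) design.

    ``rates`` has shape (n_neurons, n_objects, n_transforms), all
    nonnegative, with every (object, transform) cell present.
    """

    rates: np.ndarray
    object_labels: list
    transform_labels: list

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.ndim != 3:
            raise ValueError("rates must be (n_neurons, n_objects, n_transforms)")
        if np.any(self.rates < 0):
            raise ValueError("firing rates must be nonnegative")
        n, s, t = self.rates.shape
        if len(self.object_labels) != s or len(self.transform_labels) != t:
            raise ValueError("label lengths do not match the rate array")

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[0]

    @property
    def n_objects(self) -> int:
        return self.rates.shape[1]

    @property
    def n_transforms(self) -> int:
        return self.rates.shape[2]

    def to_frame(self) -> pd.DataFrame:
        """Long-format (neuron, object, transform, rate) table."""
        n, s, t = self.rates.shape
        idx = np.indices((n, s, t)).reshape(3, -1)
        return pd.DataFrame(
            {
                "neuron": idx[0],
                "object": [self.object_labels[i] for i in idx[1]],
                "transform": [self.transform_labels[i] for i in idx[2]],
                "rate": self.rates.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def compute_responses(
    state, stimuli, layer: int = 4, use_trained_thresholds: bool = False
) -> ResponseTable:
    """Present every image and tabulate one layer's firing rates.

    Requires the stimulus set to be a complete design (equal transform
    count per object); transforms are ordered as they appear within each
    object.  By default the sigmoid threshold is recomputed per
    presentation (the model's sparseness control); with
    ``use_trained_thresholds`` the per-layer thresholds frozen at the
    end of training are applied instead.
    """
    from .gabor import image_to_input_volume

    objs = list(stimuli.unique_objects())
    per_obj = [np.flatnonzero(stimuli.object_ids == o) for o in objs]
    counts = {len(ix) for ix in per_obj}
    if len(counts) != 1:
        raise ValueError("incomplete design: unequal transform counts per object")
    n_t = counts.pop()
    n_neurons = state.profile.layers[layer - 1].n_neurons
    rates = np.empty((n_neurons, len(objs), n_t))
    for si, ix in enumerate(per_obj):
        for ti, img_idx in enumerate(ix):
            vol = image_to_input_volume(stimuli.images[img_idx], bank=state.bank)
            thr = state.trained_thresholds if use_trained_thresholds else None
            y = state.forward(vol, up_to_layer=layer, thresholds=thr)[-1]
            rates[:, si, ti] = y.ravel()
    return ResponseTable(
        rates=rates,
        object_labels=objs,
        transform_labels=[f"t{k}" for k in range(n_t)],
    )


# ---------------------------------------------------------------------------
# Information measures
# ---------------------------------------------------------------------------


@dataclass
class InfoResult:
    """Information estimates with their binning metadata."""

    per_object: np.ndarray  # (n_neurons, n_objects) stimulus-specific bits
    n_bins: int
    multiple_cell_bits: float | None = None
    percent_correct: float | None = None
    cells: np.ndarray | None = None

    def max_per_neuron(self) -> np.ndarray:
        return self.per_object.max(axis=1)


def _bin_responses(responses: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width quantisation of one neuron's responses over its range."""
    lo, hi = responses.min(), responses.max()
    if hi == lo:
        return np.zeros(responses.shape, dtype=int)
    edges = np.linspace(lo, hi, n_bins + 1)
    return np.clip(np.digitize(responses, edges[1:-1]), 0, n_bins - 1)


def single_cell_info(
    table: ResponseTable, neuron: int, n_bins: int | None = None
) -> np.ndarray:
    """Stimulus-specific information I(s, R) of one neuron, per object (bits).

    Responses are quantised into ``n_bins`` equal-width bins over the
    neuron's observed range (default: the number of transforms per
    object, capped at 10).  P(r|s) comes from the neuron's responses
    over the transforms of object s; P(r) is the marginal over
    equiprobable objects.  A neuron with a single occupied bin carries
    0 bits about every object.
    """
    if table.n_objects < 2:
        raise ValueError("need at least 2 objects")
    if n_bins is None:
        n_bins = min(table.n_transforms, 10)
    resp = table.rates[neuron]  # (S, T)
    bins = _bin_responses(resp, n_bins)
    s, t = resp.shape
    cond = np.zeros((s, n_bins))
    for si in range(s):
        cond[si] = np.bincount(bins[si], minlength=n_bins) / t
    marg = cond.mean(axis=0)  # equiprobable objects
    info = np.zeros(s)
    for si in range(s):
        mask = cond[si] > 0
        info[si] = np.sum(cond[si, mask] * np.log2(cond[si, mask] / marg[mask]))
    return info


def max_single_cell_info(table: ResponseTable, n_bins: int | None = None) -> InfoResult:
    """I(s, R) for every neuron; convenience wrapper over ``single_cell_info``."""
    if n_bins is None:
        n_bins = min(table.n_transforms, 10)
    per_object = np.vstack(
        [single_cell_info(table, n, n_bins) for n in range(table.n_neurons)]
    )
    return InfoResult(per_object=per_object, n_bins=n_bins)


def multiple_cell_info(
    table: ResponseTable,
    cells: np.ndarray,
    decoder: str = "dot",
    reference: ResponseTable | None = None,
) -> tuple[float, float, np.ndarray]:
    """Population information through confusion-table decoding.

    Each trial (one transform presentation) is decoded to the object
    whose mean population vector best matches the trial vector;
    ``decoder`` is "dot" (normalised dot product / cosine, the
    biologically plausible readout) or "gaussian" (nearest mean by
    Euclidean distance).  With no ``reference``, class means come from
    the same table with the decoded trial held out of its own class
    (leave-one-out); with a ``reference`` (e.g. the training responses
    when decoding a test table), class means come from the reference
    and no hold-out is needed.  Returns ``(bits, percent_correct,
    confusion)`` where ``confusion[s, s']`` counts trials of object s
    decoded as s' and the bits are the mutual information I(S, S') of
    the joint table.
    """
    cells = np.asarray(cells)
    if cells.size == 0:
        raise ValueError("cell subset must be non-empty")
    if table.n_objects < 2:
        raise ValueError("need at least 2 objects")
    if reference is None and table.n_transforms < 2:
        raise ValueError("need at least 2 transforms per object for hold-out decoding")
    if reference is not None and reference.n_objects != table.n_objects:
        raise ValueError("reference table must cover the same objects")
    r = table.rates[cells]  # (C, S, T)
    c, s, t = r.shape
    sums = r.sum(axis=2)  # (C, S)
    ref_means = None if reference is None else reference.rates[cells].mean(axis=2)
    confusion = np.zeros((s, s))
    for si in range(s):
        for ti in range(t):
            trial = r[:, si, ti]
            if ref_means is None:
                means = sums / t
                means[:, si] = (sums[:, si] - trial) / (t - 1)  # leave-one-out
            else:
                means = ref_means
            if decoder == "dot":
                norms = np.linalg.norm(means, axis=0) * np.linalg.norm(trial)
                with np.errstate(invalid="ignore", divide="ignore"):
                    scores = np.where(norms > 0, trial @ means / norms, -np.inf)
                if not np.any(np.isfinite(scores)):
                    scores = np.zeros(s)  # all-zero vectors: full tie
            elif decoder == "gaussian":
                scores = -np.linalg.norm(means - trial[:, None], axis=0)
            else:
                raise ValueError(f"unknown decoder {decoder!r}")
            confusion[si, int(np.argmax(scores))] += 1  # argmax tie -> lowest index
    joint = confusion / confusion.sum()
    ps = joint.sum(axis=1, keepdims=True)
    ps2 = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    bits = float(np.sum(joint[mask] * np.log2(joint[mask] / (ps @ ps2)[mask])))
    pct = float(100.0 * np.trace(confusion) / confusion.sum())
    return bits, pct, confusion


# ---------------------------------------------------------------------------
# Cell selection and the pattern associator
# ---------------------------------------------------------------------------


@dataclass
class AssociatorModel:
    """One-layer Hebbian pattern associator over selected cells."""

    weights: np.ndarray  # (n_classes, n_cells)
    cells: np.ndarray  # selected cell indices (flat, class-blocked)
    cells_per_class: dict = field(default_factory=dict)
    alpha: float = 1.0


def select_best_cells(
    table: ResponseTable, k: int, n_bins: int | None = None
) -> tuple[np.ndarray, dict]:
    """The k most object-selective cells per class, disjoint across classes.

    Cells are ranked per class by the ratio of their mean rate over that
    class's transforms to their mean rate over all transforms of all
    objects, with the stimulus-specific information for the class
    breaking ties and near-ties.  Classes with no responsive cell still
    receive k cells; their near-zero information is logged.
    Returns ``(flat_indices, {class_index: indices})``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n, s, _ = table.rates.shape
    if k * s > n:
        raise ValueError(f"cannot select {k} cells x {s} classes from {n} cells")
    mean_class = table.rates.mean(axis=2)  # (N, S)
    mean_all = table.rates.mean(axis=(1, 2))  # (N,)
    eps = 1e-12
    ratio = mean_class / (mean_all[:, None] + eps)
    info = max_single_cell_info(table, n_bins).per_object  # (N, S)
    taken: set[int] = set()
    per_class: dict = {}
    for si in range(s):
        # primary key: selectivity ratio (quantised so near-ties fall
        # together), secondary key: stimulus-specific information
        primary = np.round(ratio[:, si], 6)
        order = np.lexsort((-info[:, si], -primary))
        chosen = [c for c in order if c not in taken][:k]
        if info[chosen, si].max(initial=0.0) < 1e-6:
            logger.warning(
                "class %s: selected cells carry ~0 bits of information",
                table.object_labels[si],
            )
        taken.update(chosen)
        per_class[si] = np.array(chosen)
    flat = np.concatenate([per_class[si] for si in range(s)])
    return flat, per_class


def train_pattern_associator(
    table: ResponseTable, cells: np.ndarray, alpha: float = 1.0
) -> AssociatorModel:
    """Single-pass Hebbian training against a one-hot teacher.

    The weight from input cell j to class neuron i accumulates
    ``alpha * y_i * x_j`` over every transform presentation of every
    object, with the teacher ``y`` clamped one-hot to the object's
    class.  The sum form is order-independent.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    cells = np.asarray(cells)
    r = table.rates[cells]  # (C, S, T)
    weights = alpha * r.sum(axis=2).T  # (S, C): class i row = sum of its inputs
    return AssociatorModel(weights=weights, cells=cells, alpha=alpha)


def classify(
    model: AssociatorModel, table: ResponseTable
) -> tuple[np.ndarray, float, float]:
    """Decode every trial with the pattern associator.

    The prediction for a trial is the argmax over class-neuron
    activations (dot product of class weights with the selected-cell
    rates); exact ties resolve to the lowest class index and the tie
    rate is logged and returned.  Returns
    ``(predictions[s, t], percent_correct, tie_rate)``.
    """
    r = table.rates[model.cells]  # (C, S, T)
    c, s, t = r.shape
    act = np.einsum("kc,cst->kst", model.weights, r)  # (S_classes, S, T)
    preds = act.argmax(axis=0)
    n_max = (act == act.max(axis=0, keepdims=True)).sum(axis=0)
    ties = n_max > 1
    if ties.any():
        logger.warning("classification ties on %d of %d trials", ties.sum(), s * t)
    correct = preds == np.arange(s)[:, None]
    return preds, float(100.0 * correct.mean()), float(ties.mean())


def similarity_matrix(
    table: ResponseTable, cells: np.ndarray | None = None
) -> np.ndarray:
    """Cosine similarity between population vectors of all (object, transform) pairs.

    Returns an (S*T, S*T) matrix ordered object-major; entries involving
    an all-zero population vector are reported as NaN (undefined), not
    as 0.  For nonnegative rates all defined values lie in [0, 1].
    """
    r = table.rates if cells is None else table.rates[np.asarray(cells)]
    c, s, t = r.shape
    vecs = r.reshape(c, s * t).T  # (S*T, C)
    norms = np.linalg.norm(vecs, axis=1)
    sim = vecs @ vecs.T
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = sim / np.outer(norms, norms)
    sim[norms == 0, :] = np.nan
    sim[:, norms == 0] = np.nan
    return sim
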
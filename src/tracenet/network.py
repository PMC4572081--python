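"""Four-layer competitive hierarchy: connectivity, inhibition, contrast enhancement.

Each layer is a sheet of neurons receiving a fixed number of feedforward
connections (the fan-in) from a topologically aligned neighbourhood of
the previous layer.  Whether a given presynaptic site is connected is
decided by a radial Gaussian probability profile centred on the focal
point, scaled so that the layer's nominal connection radius contains
about 67% of the connections.  Within a layer, competition is
implemented in two stages: a centre-surround lateral-inhibition filter
applied to the activations, followed by a sigmoid contrast-enhancement
whose threshold is set at a fixed percentile of the current activations,
which pins the fraction of strongly firing neurons (the sparseness).

Layer roles (full profile): layer 1 ~ V2, layer 2 ~ V4, layer 3 ~
posterior IT, layer 4 ~ anterior IT, preceded by the fixed Gabor front
end standing in for V1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.ndimage import convolve as nd_convolve

from .gabor import FilterResponseVolume, GaborParams, build_filter_bank

__all__ = [
    "LayerSpec",
    "NetworkProfile",
    "ConnectivityMap",
    "NetworkState",
    "full_profile",
    "scaled_profile",
    "get_profile",
    "sample_connectivity",
    "propagate",
    "lateral_inhibit",
    "inhibition_kernel",
    "contrast_enhance",
    "population_sparseness",
]

# Radius R containing 67% of a radial 2D Gaussian: 1 - exp(-R^2 / 2 s^2) = 0.67
# => s = R / sqrt(-2 ln 0.33)
_RADIUS_TO_SIGMA = 1.0 / np.sqrt(-2.0 * np.log(0.33))


@dataclass(frozen=True)
class LayerSpec:
    """Architecture and learning parameters of one layer.

    ``conn_radius`` is in presynaptic-grid pixels and is the radius that
    contains ~67% of the sampled connections; ``inhib_sigma`` /
    ``inhib_delta`` parametrise the lateral-inhibition filter;
    ``sigmoid_percentile`` sets the activation threshold (e.g. 95 keeps
    ~5% of neurons above half-maximal firing) and ``sigmoid_beta`` the
    slope; ``rule`` selects the synaptic update ("hebb", "trace" for the
    pre-update trace form, "trace_current" for the variant whose trace
    includes the current step); ``trace_eta`` is the trace decay in
    [0, 1).
    """

    grid_dims: int
    fan_in: int
    conn_radius: float
    inhib_sigma: float
    inhib_delta: float
    sigmoid_percentile: float
    sigmoid_beta: float
    learning_rate: float
    trace_eta: float = 0.0
    rule: str = "trace"

    def __post_init__(self) -> None:
        if self.fan_in < 1:
            raise ValueError("fan_in must be >= 1")
        if self.conn_radius <= 0:
            raise ValueError("conn_radius must be > 0")
        if not (0.0 <= self.trace_eta < 1.0):
            raise ValueError("trace_eta must be in [0, 1)")
        if not (0.0 < self.sigmoid_percentile < 100.0):
            raise ValueError("sigmoid_percentile must be in (0, 100)")
        if self.rule not in ("hebb", "trace", "trace_current"):
            raise ValueError(f"unknown rule {self.rule!r}")

    @property
    def n_neurons(self) -> int:
        return self.grid_dims * self.grid_dims

    @property
    def conn_sigma(self) -> float:
        """Gaussian sigma of the connection-probability profile."""
        return self.conn_radius * _RADIUS_TO_SIGMA


@dataclass(frozen=True)
class NetworkProfile:
    """A named, complete network configuration."""

    name: str
    input_dims: tuple[int, int]
    gabor: GaborParams
    layers: tuple[LayerSpec, ...]

    @property
    def n_neurons(self) -> int:
        """Total neuron count across the four layers."""
        return sum(l.n_neurons for l in self.layers)


def full_profile() -> NetworkProfile:
    """The full-scale configuration: 128x128 neurons/layer, 256x256 input."""
    return NetworkProfile(
        name="full-table1",
        input_dims=(256, 256),
        gabor=GaborParams(),
        layers=(
            LayerSpec(128, 100, 24.0, 1.38, 1.5, 99.2, 190.0, 0.05, 0.0, "hebb"),
            LayerSpec(128, 400, 24.0, 2.7, 1.5, 98.0, 40.0, 0.03, 0.6, "trace"),
            LayerSpec(128, 400, 36.0, 4.0, 1.6, 88.0, 75.0, 0.005, 0.8, "trace"),
            LayerSpec(128, 400, 48.0, 6.0, 1.4, 95.0, 26.0, 0.005, 0.8, "trace"),
        ),
    )


def scaled_profile() -> NetworkProfile:
    """Desk-scale configuration: 32x32 neurons/layer, 64x64 input.

    Keeps fan-in at 100 for every layer and scales the connection radii
    by 1/4 with the grid; this size matches the earlier generations of
    the model family.  The layer-1 and layer-2 sparseness percentiles
    are loosened (99.2 -> 96.8, 98 -> 92) so that the *expected number
    of active inputs per downstream neuron* matches the full-size
    network: with 16x fewer neurons per layer and 4x smaller fan-in in
    layers 2-4, keeping the full-size percentiles would leave a layer-2
    neuron sampling under one active layer-1 winner per image and
    feature binding would be dominated by wiring noise.  Layer-3 input
    counts and the output layer's 5% sparseness keep their full-profile
    values; inhibition and sigmoid slopes are unchanged.
    """
    return NetworkProfile(
        name="scaled-32",
        input_dims=(64, 64),
        gabor=GaborParams(),
        layers=(
            LayerSpec(32, 100, 6.0, 1.38, 1.5, 96.8, 190.0, 0.05, 0.0, "hebb"),
            LayerSpec(32, 100, 6.0, 2.7, 1.5, 92.0, 40.0, 0.03, 0.6, "trace"),
            LayerSpec(32, 100, 9.0, 4.0, 1.6, 88.0, 75.0, 0.005, 0.8, "trace"),
            LayerSpec(32, 100, 12.0, 6.0, 1.4, 95.0, 26.0, 0.005, 0.8, "trace"),
        ),
    )


_PROFILES = {"full-table1": full_profile, "scaled-32": scaled_profile}


def get_profile(name: str) -> NetworkProfile:
    try:
        return _PROFILES[name]()
    except KeyError:
        raise ValueError(
            f"unknown profile {name!r}; available: {sorted(_PROFILES)}"
        ) from None


# ---------------------------------------------------------------------------
# Connectivity
# ---------------------------------------------------------------------------


@dataclass
class ConnectivityMap:
    """Fixed-fan-in sparse feedforward wiring of one layer.

    ``indices[i]`` are the flattened presynaptic site indices of
    postsynaptic neuron ``i`` (no site repeated within a neuron) and
    ``weights[i]`` the corresponding synaptic weights, kept at unit
    Euclidean norm per neuron.  ``pre_shape`` is ``(n_sheets, H, W)``:
    one sheet for a plain neuron grid, 32 sheets for the filter input
    volume.  ``focal_points`` records each neuron's connection centre in
    presynaptic coordinates (topology is preserved: focal points scale
    with neuron position).
    """

    indices: np.ndarray  # (n_post, fan_in) int64 into flattened pre volume
    weights: np.ndarray  # (n_post, fan_in) float64
    pre_shape: tuple[int, int, int]
    post_dims: int
    focal_points: np.ndarray  # (n_post, 2) float (row, col) in pre grid

    @property
    def fan_in(self) -> int:
        return self.indices.shape[1]

    def copy(self) -> "ConnectivityMap":
        """Deep copy (weights are mutated in place during training)."""
        return ConnectivityMap(
            indices=self.indices.copy(),
            weights=self.weights.copy(),
            pre_shape=self.pre_shape,
            post_dims=self.post_dims,
            focal_points=self.focal_points.copy(),
        )

    def spatial_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) presynaptic coordinates of every connection."""
        _, h, w = self.pre_shape
        per_sheet = self.indices % (h * w)
        return per_sheet // w, per_sheet % w

    def within_radius_fraction(self, radius: float) -> float:
        """Empirical fraction of connections within ``radius`` of the focal point."""
        rr, cc = self.spatial_coords()
        d2 = (rr - self.focal_points[:, [0]]) ** 2 + (cc - self.focal_points[:, [1]]) ** 2
        return float(np.mean(d2 <= radius * radius))

    def interior_mask(self, margin: float) -> np.ndarray:
        """Postsynaptic neurons whose focal point is >= margin from every border."""
        _, h, w = self.pre_shape
        fp = self.focal_points
        return (
            (fp[:, 0] >= margin)
            & (fp[:, 0] <= h - 1 - margin)
            & (fp[:, 1] >= margin)
            & (fp[:, 1] <= w - 1 - margin)
        )


def _gumbel_topk(rng: np.random.Generator, logp: np.ndarray, k: int) -> np.ndarray:
    """Sample k items without replacement with probabilities exp(logp).

    Exponential-race (Gumbel top-k) sampling: add i.i.d. Gumbel noise to
    the log-probabilities and keep the k largest keys.
    """
    g = rng.gumbel(size=logp.shape)
    keys = logp + g
    idx = np.argpartition(-keys, k - 1)[:k]
    return idx


def sample_connectivity(
    pre_shape: tuple[int, int, int] | tuple[int, int],
    spec: LayerSpec,
    rng: np.random.Generator,
    freq_groups: list[np.ndarray] | None = None,
) -> ConnectivityMap:
    """Sample the Gaussian topological wiring of one layer.

    For each postsynaptic neuron, exactly ``spec.fan_in`` distinct
    presynaptic sites are drawn from a radial Gaussian centred on the
    neuron's focal point (probabilities renormalised over the valid
    grid, so border neurons keep the exact fan-in).  When
    ``freq_groups`` is given (layer 1: a list of sheet-index arrays, one
    per spatial frequency), the fan-in is split evenly across the groups
    so every neuron samples every spatial frequency.

    Raises ``ValueError`` if the fan-in exceeds the number of distinct
    sites within the truncated (4 sigma) sampling support.
    """
    if len(pre_shape) == 2:
        pre_shape = (1, *pre_shape)
    n_sheets, pre_h, pre_w = pre_shape
    g = spec.grid_dims
    sigma = spec.conn_sigma
    # window truncated at 4 sigma (0.03% of the profile's mass); widened when
    # a border neuron would otherwise lack enough distinct sites for its fan-in
    half = int(np.ceil(4.0 * sigma))
    per_group = -(-spec.fan_in // (1 if freq_groups is None else len(freq_groups)))
    sheets_per_group = (
        n_sheets if freq_groups is None else min(len(grp) for grp in freq_groups)
    )
    while (half + 1) ** 2 * sheets_per_group < per_group and half < max(pre_h, pre_w):
        half += int(np.ceil(sigma))

    if freq_groups is None:
        groups = [np.arange(n_sheets)]
        alloc = [spec.fan_in]
    else:
        groups = [np.asarray(grp) for grp in freq_groups]
        base, rem = divmod(spec.fan_in, len(groups))
        alloc = [base + (1 if i < rem else 0) for i in range(len(groups))]

    scale_r, scale_c = pre_h / g, pre_w / g
    indices = np.empty((g * g, spec.fan_in), dtype=np.int64)
    focal = np.empty((g * g, 2))

    # offsets of the sampling window; the radial profile is centred on the
    # exact (possibly fractional) focal point of each neuron
    off = np.arange(-half, half + 1)
    orr, occ = np.meshgrid(off, off, indexing="ij")
    orr, occ = orr.ravel(), occ.ravel()

    for i in range(g):
        for j in range(g):
            n = i * g + j
            fr = (i + 0.5) * scale_r - 0.5
            fc = (j + 0.5) * scale_c - 0.5
            focal[n] = (fr, fc)
            rr = int(np.rint(fr)) + orr
            cc = int(np.rint(fc)) + occ
            valid = (rr >= 0) & (rr < pre_h) & (cc >= 0) & (cc < pre_w)
            rr, cc = rr[valid], cc[valid]
            site = rr * pre_w + cc
            logp = -((rr - fr) ** 2 + (cc - fc) ** 2) / (2.0 * sigma**2)
            pos = 0
            for grp, k in zip(groups, alloc):
                if k == 0:
                    continue
                # joint sites over (sheet in group) x (valid spatial window)
                n_sites = grp.size * site.size
                if k > n_sites:
                    raise ValueError(
                        f"fan_in allocation {k} exceeds {n_sites} distinct sites "
                        f"within the sampling support of neuron {n}"
                    )
                joint_logp = np.broadcast_to(logp, (grp.size, site.size)).ravel()
                chosen = _gumbel_topk(rng, joint_logp, k)
                sheet = grp[chosen // site.size]
                spatial = site[chosen % site.size]
                indices[n, pos : pos + k] = sheet * (pre_h * pre_w) + spatial
                pos += k

    weights = rng.uniform(0.0, 1.0, size=indices.shape)
    weights /= np.linalg.norm(weights, axis=1, keepdims=True)
    return ConnectivityMap(indices, weights, (n_sheets, pre_h, pre_w), g, focal)


def propagate(pre_rates: np.ndarray, cmap: ConnectivityMap) -> np.ndarray:
    """Weighted-sum activation: r_i = sum_j w_ij x_j over the fan-in."""
    flat = np.asarray(pre_rates).ravel()
    expected = int(np.prod(cmap.pre_shape))
    if flat.size != expected:
        raise ValueError(
            f"pre_rates size {flat.size} does not match connectivity ({expected})"
        )
    return np.einsum("ij,ij->i", cmap.weights, flat[cmap.indices])


# ---------------------------------------------------------------------------
# Competition
# ---------------------------------------------------------------------------


def inhibition_kernel(delta: float, sigma: float, truncate: float = 3.0) -> np.ndarray:
    """Centre-surround lateral-inhibition filter.

    Off-centre coefficients are ``-delta * exp(-(a^2+b^2)/sigma^2)``;
    the centre is one minus the sum of the off-centre coefficients, so
    the kernel's DC gain is exactly 1 and a uniform activation field
    passes through unchanged.
    """
    if delta <= 0 or sigma <= 0:
        raise ValueError("delta and sigma must be > 0")
    half = int(np.ceil(truncate * sigma))
    ax = np.arange(-half, half + 1)
    aa, bb = np.meshgrid(ax, ax, indexing="ij")
    kern = -delta * np.exp(-(aa**2 + bb**2) / sigma**2)
    kern[half, half] = 0.0
    kern[half, half] = 1.0 - kern.sum()
    return kern


def lateral_inhibit(activations: np.ndarray, delta: float, sigma: float) -> np.ndarray:
    """Convolve a layer's activation grid with the inhibition filter.

    Zero padding at the borders (retinal topology has real edges)."""
    kern = inhibition_kernel(delta, sigma)
    return nd_convolve(np.asarray(activations, dtype=float), kern, mode="constant")


def contrast_enhance(
    activations: np.ndarray,
    percentile: float,
    beta: float,
    threshold: float | None = None,
) -> tuple[np.ndarray, float]:
    """Sigmoid contrast enhancement with a percentile-controlled threshold.

    ``y = 1 / (1 + exp(-2 beta (r - threshold)))`` with the threshold at
    the given percentile of the current activations (linear-interpolation
    percentile), so the fraction of neurons firing above 0.5 is pinned at
    ``(100 - percentile) / 100``.  Returns ``(y, threshold)``.  A fixed
    ``threshold`` may be supplied to reuse one computed earlier (e.g. a
    per-epoch cadence).
    """
    r = np.asarray(activations, dtype=float)
    if threshold is None:
        if np.ptp(r) == 0.0:
            warnings.warn(
                "all activations identical; percentile threshold degenerate, "
                "returning uniform y = 0.5",
                stacklevel=2,
            )
            return np.full_like(r, 0.5), float(r.flat[0])
        threshold = float(np.percentile(r, percentile))
    with np.errstate(over="ignore"):  # deep saturation underflows to 0/1
        y = 1.0 / (1.0 + np.exp(-2.0 * beta * (r - threshold)))
    return y, threshold


def population_sparseness(y: np.ndarray) -> float:
    """Population sparseness a = (mean y)^2 / mean(y^2), in [1/n, 1].

    1 for uniform firing; 1/n when a single neuron of n is active.
    Raises on an all-zero vector (sparseness undefined).
    """
    y = np.asarray(y, dtype=float).ravel()
    if np.any(y < 0):
        raise ValueError("firing rates must be nonnegative")
    denom = np.mean(y**2)
    if denom == 0.0:
        raise ValueError("sparseness undefined for all-zero firing")
    return float(np.mean(y) ** 2 / denom)


# ---------------------------------------------------------------------------
# Network state
# ---------------------------------------------------------------------------


@dataclass
class NetworkState:
    """Connectivity, weights and bookkeeping of the full hierarchy."""

    profile: NetworkProfile
    maps: list[ConnectivityMap]
    seed: int
    bank: list = field(default_factory=list, repr=False)
    #: per-layer sigmoid thresholds frozen at the end of training (mean of
    #: the final epoch's per-presentation percentile thresholds); None until
    #: the network has been trained.  Evaluation uses these fixed values:
    #: the threshold is a slowly adapting homeostatic quantity, so a single
    #: test stimulus does not get its firing renormalised to the standard
    #: sparseness -- a weakly driving stimulus produces weak output.
    trained_thresholds: list[float] | None = None

    @classmethod
    def initialize(cls, profile: NetworkProfile, seed: int) -> "NetworkState":
        """Sample connectivity and random unit-norm weights for all layers."""
        rng = np.random.default_rng(seed)
        bank = build_filter_bank(profile.gabor)
        even = [k for k in bank if k.phase == "even"]
        n_channels = 2 * len(even)
        # channel sheet order matches gabor.rectify_split: per (f, o): +, -
        freqs = profile.gabor.frequencies
        per_freq = n_channels // len(freqs)
        freq_groups = [
            np.arange(fi * per_freq, (fi + 1) * per_freq) for fi in range(len(freqs))
        ]
        maps: list[ConnectivityMap] = []
        pre_shape: tuple[int, int, int] = (n_channels, *profile.input_dims)
        for li, spec in enumerate(profile.layers):
            groups = freq_groups if li == 0 else None
            maps.append(sample_connectivity(pre_shape, spec, rng, freq_groups=groups))
            pre_shape = (1, spec.grid_dims, spec.grid_dims)
        return cls(profile=profile, maps=maps, seed=seed, bank=bank)

    def forward(
        self,
        input_volume: FilterResponseVolume,
        up_to_layer: int | None = None,
        thresholds: list[float] | None = None,
    ) -> list[np.ndarray]:
        """Propagate an input volume through the hierarchy.

        Returns the post-sigmoid firing grid ``y`` of each layer up to
        ``up_to_layer`` (1-based; default all four).  With ``thresholds``
        given (one per layer, e.g. ``trained_thresholds``), the sigmoid
        uses those fixed values instead of recomputing the percentile of
        the current activations.
        """
        n_layers = up_to_layer or len(self.profile.layers)
        x = input_volume.data
        ys: list[np.ndarray] = []
        for li in range(n_layers):
            spec = self.profile.layers[li]
            r = propagate(x, self.maps[li]).reshape(spec.grid_dims, spec.grid_dims)
            r = lateral_inhibit(r, spec.inhib_delta, spec.inhib_sigma)
            thr = (
                thresholds[li]
                if thresholds is not None and li < len(thresholds)
                else None
            )
            y, _ = contrast_enhance(
                r, spec.sigmoid_percentile, spec.sigmoid_beta, threshold=thr
            )
            ys.append(y)
            x = y
        return ys

    def save(self, path) -> None:
        """Checkpoint connectivity + weights + metadata to an .npz container."""
        arrays: dict[str, np.ndarray] = {}
        for li, m in enumerate(self.maps):
            arrays[f"indices_{li}"] = m.indices
            arrays[f"weights_{li}"] = m.weights
            arrays[f"pre_shape_{li}"] = np.array(m.pre_shape)
            arrays[f"focal_{li}"] = m.focal_points
        arrays["meta"] = np.array([self.seed, len(self.maps)])
        profile_doc = {
            "name": self.profile.name,
            "input_dims": list(self.profile.input_dims),
            "gabor": {
                "frequencies": list(self.profile.gabor.frequencies),
                "orientations": list(self.profile.gabor.orientations),
                "aspect_ratio": self.profile.gabor.aspect_ratio,
                "bandwidth_octaves": self.profile.gabor.bandwidth_octaves,
            },
            "layers": [asdict(l) for l in self.profile.layers],
        }
        arrays["profile_json"] = np.array(json.dumps(profile_doc))
        if self.trained_thresholds is not None:
            arrays["trained_thresholds"] = np.array(self.trained_thresholds)
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "NetworkState":
        with np.load(path) as z:
            doc = json.loads(str(z["profile_json"]))
            profile = NetworkProfile(
                name=doc["name"],
                input_dims=tuple(doc["input_dims"]),
                gabor=GaborParams(
                    frequencies=tuple(doc["gabor"]["frequencies"]),
                    orientations=tuple(doc["gabor"]["orientations"]),
                    aspect_ratio=doc["gabor"]["aspect_ratio"],
                    bandwidth_octaves=doc["gabor"]["bandwidth_octaves"],
                ),
                layers=tuple(LayerSpec(**l) for l in doc["layers"]),
            )
            seed, n_layers = (int(v) for v in z["meta"])
            maps = []
            for li in range(n_layers):
                maps.append(
                    ConnectivityMap(
                        indices=z[f"indices_{li}"],
                        weights=z[f"weights_{li}"],
                        pre_shape=tuple(int(v) for v in z[f"pre_shape_{li}"]),
                        post_dims=profile.layers[li].grid_dims,
                        focal_points=z[f"focal_{li}"],
                    )
                )
            thresholds = (
                [float(v) for v in z["trained_thresholds"]]
                if "trained_thresholds" in z
                else None
            )
        state = cls(profile=profile, maps=maps, seed=seed,
                    trained_thresholds=thresholds)
        state.bank = build_filter_bank(profile.gabor)
        return state
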
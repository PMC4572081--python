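"""Seeded synthetic stimulus sets emulating four experiment designs.

The original studies trained on photographic or rendered image sets
(class exemplars with large intra-class variation; turntable view series
at fixed angular spacing; faces with permutable quarters; object pairs
whose appearance changes catastrophically at one view).  Those images
are external data; the generators here are parametric families that
reproduce the *statistical structure* each design needs:

* ``gen_class_exemplars`` -- classes of composite blob/bar shapes with
  per-exemplar pose jitter and clutter (intra-class variation).
* ``gen_view_series`` -- objects built as constellations of surface
  features on a 3D body, rendered orthographically at specified
  azimuths, so nearby views are similar and opposite views are not.
* ``gen_part_scramble`` -- quadrant-permuted copies of existing images
  (part configuration destroyed, pixel content preserved).
* ``gen_catastrophic_pair`` -- two objects x four views where one view
  per object reveals a high-contrast interior pattern that is identical
  across the two objects (hence non-diagnostic of identity), while the
  identity-diagnostic outline cues differ.
* ``gen_translation_view_grid`` -- every (view, location) combination on
  a translation grid (e.g. 4 views x 25 locations = 100 transforms).

All generators are pure functions of their parameters and the RNG seed:
the same seed reproduces bit-identical image sets.  Images are float32
grids in [0, 1] on a mid-gray (0.5) background.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "StimulusSet",
    "gen_class_exemplars",
    "gen_view_series",
    "gen_part_configured_objects",
    "gen_part_scramble",
    "scramble_quadrants",
    "gen_catastrophic_pair",
    "gen_translation_view_grid",
    "load_image_dir",
]

BACKGROUND = 0.5
#: luminance weights used for colour -> grayscale conversion (ITU-R 601-2,
#: as applied by Pillow's "L" mode)
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class StimulusSet:
    """Ordered images grouped by object, with transform labels and a split.

    ``presentation_order`` lists image indices with all images of one
    object contiguous (the temporal-continuity contract the trace rule
    relies on).  ``split`` marks each image "train" or "test".
    """

    images: np.ndarray  # (N, H, W) float32 in [0, 1]
    object_ids: np.ndarray  # (N,) int
    transform_ids: list[str]
    split: np.ndarray  # (N,) str
    presentation_order: np.ndarray  # (N,) int indices, object-contiguous
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.images)
        self.object_ids = np.asarray(self.object_ids)
        self.split = np.asarray(self.split)
        if not (len(self.object_ids) == len(self.transform_ids) == len(self.split) == n):
            raise ValueError("inconsistent field lengths")
        if self.presentation_order is None:
            self.presentation_order = _object_grouped_order(self.object_ids)

    def __len__(self) -> int:
        return len(self.images)

    @property
    def dims(self) -> tuple[int, int]:
        return self.images.shape[1:]

    def unique_objects(self) -> np.ndarray:
        return np.unique(self.object_ids)

    def n_block_boundaries(self) -> int:
        """Number of object-block transitions in the presentation order."""
        objs = self.object_ids[self.presentation_order]
        return int(np.sum(objs[1:] != objs[:-1]))

    def subset(self, mask: np.ndarray) -> "StimulusSet":
        idx = np.flatnonzero(mask)
        return StimulusSet(
            images=self.images[idx],
            object_ids=self.object_ids[idx],
            transform_ids=[self.transform_ids[i] for i in idx],
            split=self.split[idx],
            presentation_order=_object_grouped_order(self.object_ids[idx]),
            metadata=dict(self.metadata),
        )

    def train_set(self) -> "StimulusSet":
        return self.subset(self.split == "train")

    def test_set(self) -> "StimulusSet":
        return self.subset(self.split == "test")

    def save(self, path) -> None:
        """Write <path>/<object>/<transform>.png plus a manifest CSV."""
        root = Path(path)
        rows = []
        for i, (img, obj, tid) in enumerate(
            zip(self.images, self.object_ids, self.transform_ids)
        ):
            d = root / f"obj{obj:03d}"
            d.mkdir(parents=True, exist_ok=True)
            fname = f"{tid}.png"
            arr = np.clip(np.round(img * 255), 0, 255).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(d / fname)
            rows.append(
                {
                    "object": int(obj),
                    "transform": tid,
                    "split": self.split[i],
                    "presentation_index": int(np.flatnonzero(self.presentation_order == i)[0]),
                    "file": f"obj{obj:03d}/{fname}",
                }
            )
        pd.DataFrame(rows).to_csv(root / "manifest.csv", index=False)


def _object_grouped_order(object_ids: np.ndarray) -> np.ndarray:
    """Stable order with all images of each object contiguous."""
    return np.argsort(np.asarray(object_ids), kind="stable")


# ---------------------------------------------------------------------------
# drawing primitives
# ---------------------------------------------------------------------------


def _canvas(dims: tuple[int, int]) -> np.ndarray:
    return np.full(dims, BACKGROUND, dtype=float)


def _mesh(dims):
    return np.meshgrid(np.arange(dims[0]), np.arange(dims[1]), indexing="ij")


def _add_blob(img, cy, cx, size, amplitude) -> None:
    yy, xx = _mesh(img.shape)
    img += amplitude * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * size**2))


def _add_bar(img, cy, cx, length, width, angle_deg, amplitude) -> None:
    yy, xx = _mesh(img.shape)
    t = np.deg2rad(angle_deg)
    u = (yy - cy) * np.cos(t) + (xx - cx) * np.sin(t)
    v = -(yy - cy) * np.sin(t) + (xx - cx) * np.cos(t)
    img += amplitude * np.exp(-0.5 * ((u / length) ** 2 + (v / width) ** 2))


def _ellipse_mask(dims, cy, cx, ry, rx) -> np.ndarray:
    yy, xx = _mesh(dims)
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _shift_int(img: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Integer translation with background fill (exact, no interpolation)."""
    out = np.full_like(img, BACKGROUND)
    h, w = img.shape
    ys_src = slice(max(0, -dy), min(h, h - dy))
    xs_src = slice(max(0, -dx), min(w, w - dx))
    ys_dst = slice(max(0, dy), min(h, h + dy))
    xs_dst = slice(max(0, dx), min(w, w + dx))
    out[ys_dst, xs_dst] = img[ys_src, xs_src]
    return out


def _finish(img: np.ndarray) -> np.ndarray:
    return np.clip(img, 0.0, 1.0).astype(np.float32)


# ---------------------------------------------------------------------------
# Experiment-1 analogue: class exemplars with intra-class variation
# ---------------------------------------------------------------------------


def gen_class_exemplars(
    n_classes: int,
    n_exemplars: int,
    rng: np.random.Generator,
    dims: tuple[int, int] = (64, 64),
    n_test: int = 0,
    jitter: float = 2.0,
    n_clutter: int = 3,
) -> StimulusSet:
    """Classes of composite shapes with per-exemplar jitter and clutter.

    Each class is a fixed constellation of 4-6 blob/bar primitives; each
    exemplar jitters primitive positions and global pose (translation)
    by ``jitter`` pixels (standard deviation) and adds ``n_clutter``
    low-contrast distractor blobs.  With ``jitter=0`` and
    ``n_clutter=0`` all exemplars of a class are identical.  The last
    ``n_test`` exemplars of each class form the test split.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    h, w = dims
    images, objects, tids, split = [], [], [], []
    for c in range(n_classes):
        n_prims = int(rng.integers(4, 7))
        prims = []
        for _ in range(n_prims):
            kind = rng.choice(["blob", "bar"])
            cy = rng.uniform(0.25 * h, 0.75 * h)
            cx = rng.uniform(0.25 * w, 0.75 * w)
            amp = rng.uniform(0.25, 0.45) * rng.choice([-1.0, 1.0])
            prims.append(
                (
                    kind,
                    cy,
                    cx,
                    rng.uniform(1.5, 3.5),  # size / width
                    rng.uniform(4.0, 9.0),  # bar length
                    rng.uniform(0.0, 180.0),  # bar angle
                    amp,
                )
            )
        for e in range(n_exemplars):
            img = _canvas(dims)
            gy, gx = rng.normal(0.0, jitter, size=2)
            for kind, cy, cx, size, length, angle, amp in prims:
                jy, jx = rng.normal(0.0, jitter, size=2)
                if kind == "blob":
                    _add_blob(img, cy + gy + jy, cx + gx + jx, size, amp)
                else:
                    _add_bar(img, cy + gy + jy, cx + gx + jx, length, size, angle, amp)
            for _ in range(n_clutter):
                _add_blob(
                    img,
                    rng.uniform(0, h),
                    rng.uniform(0, w),
                    rng.uniform(1.0, 2.5),
                    rng.uniform(-0.1, 0.1),
                )
            images.append(_finish(img))
            objects.append(c)
            tids.append(f"ex{e:03d}")
            split.append("test" if e >= n_exemplars - n_test else "train")
    objects = np.array(objects)
    return StimulusSet(
        images=np.asarray(images),
        object_ids=objects,
        transform_ids=tids,
        split=np.array(split),
        presentation_order=_object_grouped_order(objects),
        metadata={"generator": "class_exemplars", "jitter": jitter},
    )


# ---------------------------------------------------------------------------
# Experiment-2 analogue: systematic view series
# ---------------------------------------------------------------------------


def _make_view_object(rng: np.random.Generator, dims: tuple[int, int]) -> dict:
    """Random 3D-like object: a body plus surface features at longitudes."""
    h, w = dims
    n_feat = int(rng.integers(6, 10))
    return {
        "body_ry": rng.uniform(0.28, 0.36) * h,
        "body_rx": rng.uniform(0.22, 0.32) * w,
        "body_shade": rng.uniform(-0.18, 0.18),
        "features": [
            {
                "lon": rng.uniform(0.0, 360.0),
                "lat": rng.uniform(-0.30, 0.30),  # fraction of body height
                "size": rng.uniform(1.5, 3.2),
                "length": rng.uniform(3.0, 7.0),
                "angle": rng.uniform(0.0, 180.0),
                "amp": rng.uniform(0.3, 0.5) * rng.choice([-1.0, 1.0]),
                "kind": rng.choice(["blob", "bar"]),
            }
            for _ in range(n_feat)
        ],
    }


def _render_view(obj: dict, azimuth_deg: float, dims: tuple[int, int]) -> np.ndarray:
    """Orthographic projection of the object rotated to one azimuth.

    A feature at longitude ``lon`` appears at horizontal position
    ``sin(lon + azimuth)`` across the body and is visible (with
    cosine-weighted contrast, emulating self-occlusion and
    foreshortening) only while on the facing hemisphere.
    """
    h, w = dims
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    img = _canvas(dims)
    body = _ellipse_mask(dims, cy, cx, obj["body_ry"], obj["body_rx"])
    img[body] += obj["body_shade"]
    for f in obj["features"]:
        phase = np.deg2rad(f["lon"] + azimuth_deg)
        vis = np.cos(phase)
        if vis <= 0.05:
            continue
        fy = cy + f["lat"] * obj["body_ry"] * 2.0
        fx = cx + np.sin(phase) * obj["body_rx"] * 0.85
        amp = f["amp"] * vis
        if f["kind"] == "blob":
            _add_blob(img, fy, fx, f["size"], amp)
        else:
            # horizontal extent foreshortens as the feature turns away
            _add_bar(img, fy, fx, max(f["length"] * vis, 1.0), f["size"], f["angle"], amp)
    return _finish(img)


def gen_view_series(
    n_objects: int,
    n_views: int,
    angular_spacing: float,
    rng: np.random.Generator,
    dims: tuple[int, int] = (64, 64),
    test_n_views: int = 0,
    test_spacing: float | None = None,
    test_offset: float = 0.0,
) -> StimulusSet:
    """Smooth view series per object at fixed angular spacing.

    Training views sit at ``k * angular_spacing`` for ``k < n_views``.
    When ``test_n_views > 0`` a disjoint cross-validation test set is
    generated at ``k * test_spacing + test_offset`` (e.g. 18 views at
    20 deg spacing offset by 10 deg from the training set), so every
    test view is offset from the nearest training view by a stated
    angle.
    """
    if n_views * angular_spacing > 360.0 + 1e-9:
        raise ValueError("n_views * angular_spacing must not exceed 360 degrees")
    objs = []
    probes: list[np.ndarray] = []
    for _ in range(n_objects):
        for _attempt in range(_MAX_RESAMPLES):
            cand = _make_view_object(rng, dims)
            probe = np.concatenate(
                [_render_view(cand, az, dims) for az in (0.0, 90.0, 180.0, 270.0)]
            )
            if _distinct_enough(probe, probes):
                break
        objs.append(cand)
        probes.append(probe)
    images, object_ids, tids, split = [], [], [], []
    for o, obj in enumerate(objs):
        for k in range(n_views):
            az = k * angular_spacing
            images.append(_render_view(obj, az, dims))
            object_ids.append(o)
            tids.append(f"az{az:05.1f}")
            split.append("train")
        if test_n_views:
            spacing = angular_spacing if test_spacing is None else test_spacing
            for k in range(test_n_views):
                az = k * spacing + test_offset
                images.append(_render_view(obj, az, dims))
                object_ids.append(o)
                tids.append(f"az{az:05.1f}_test")
                split.append("test")
    object_ids = np.array(object_ids)
    return StimulusSet(
        images=np.asarray(images),
        object_ids=object_ids,
        transform_ids=tids,
        split=np.array(split),
        presentation_order=_object_grouped_order(object_ids),
        metadata={"generator": "view_series", "angular_spacing": angular_spacing},
    )


# ---------------------------------------------------------------------------
# Experiment-3 analogue: part-configured objects and quadrant scrambling
# ---------------------------------------------------------------------------

#: non-identity permutations of the four quadrants, and the subset that
#: displaces every quadrant (derangements)
_QUAD_PERMS = [p for p in itertools.permutations(range(4)) if p != (0, 1, 2, 3)]
_QUAD_DERANGEMENTS = [
    p for p in _QUAD_PERMS if all(p[i] != i for i in range(4))
]


def _draw_primitive(img: np.ndarray, g: dict, cy: float, cx: float) -> None:
    if g["kind"] == "blob":
        _add_blob(img, cy, cx, g["size"], g["amp"])
    elif g["kind"] == "bar":
        _add_bar(img, cy, cx, g["length"], g["size"] * 0.6, g["angle"], g["amp"])
    elif g["kind"] == "cross":
        _add_bar(img, cy, cx, g["length"], g["size"] * 0.5, g["angle"], g["amp"])
        _add_bar(img, cy, cx, g["length"], g["size"] * 0.5, g["angle"] + 90.0, g["amp"])
    else:  # ring: blob with a contrast-reversed core
        _add_blob(img, cy, cx, g["size"] + 2.0, g["amp"])
        _add_blob(img, cy, cx, g["size"] * 0.5, -g["amp"])


#: ceiling on the pixel correlation between two generated identities'
#: base images; candidates above it are resampled (distinct identities
#: are part of the experimental designs these generators emulate)
MAX_IDENTITY_CORRELATION = 0.4
_MAX_RESAMPLES = 50


def _distinct_enough(candidate: np.ndarray, accepted: list[np.ndarray]) -> bool:
    v = candidate.ravel() - candidate.mean()
    for other in accepted:
        u = other.ravel() - other.mean()
        denom = np.linalg.norm(u) * np.linalg.norm(v)
        if denom > 0 and float(u @ v) / denom > MAX_IDENTITY_CORRELATION:
            return False
    return True


def gen_part_configured_objects(
    n_objects: int,
    n_exemplars: int,
    rng: np.random.Generator,
    dims: tuple[int, int] = (64, 64),
    jitter: float = 1.5,
    prims_per_part: int = 2,
) -> StimulusSet:
    """Face-like objects: four distinct parts in a 2x2 configuration.

    Every object places one part in each image quadrant; a part is a
    small composite of primitives (blob / bar / ring / cross) whose
    shapes, contrasts *and positions within the quadrant* are
    object-specific -- as the features of different face identities
    share a common arrangement but differ in geometry.  Exemplars jitter
    the primitive positions (standard deviation ``jitter`` pixels),
    emulating view/expression variation within an identity.  Candidate
    identities whose base image correlates above
    ``MAX_IDENTITY_CORRELATION`` with an already-generated one are
    resampled, so the set contains visibly distinct identities.
    Quadrant scrambling exactly permutes an object's parts while
    preserving their content.
    """
    h, w = dims
    qh, qw = h // 2, w // 2
    quads = [(0, 0), (0, qw), (qh, 0), (qh, qw)]
    images, object_ids, tids, split = [], [], [], []
    base_images: list[np.ndarray] = []
    for o in range(n_objects):
        for _attempt in range(_MAX_RESAMPLES):
            parts = []
            for qy, qx in quads:
                parts.append(
                    [
                        {
                            "kind": rng.choice(["blob", "bar", "ring", "cross"]),
                            "cy": qy + rng.uniform(0.2, 0.8) * qh,
                            "cx": qx + rng.uniform(0.2, 0.8) * qw,
                            "size": rng.uniform(2.0, 4.0),
                            "length": rng.uniform(5.0, 10.0),
                            "angle": rng.uniform(0.0, 180.0),
                            "amp": rng.uniform(0.3, 0.5) * rng.choice([-1.0, 1.0]),
                        }
                        for _ in range(prims_per_part)
                    ]
                )
            base = _canvas(dims)
            for prims in parts:
                for g in prims:
                    _draw_primitive(base, g, g["cy"], g["cx"])
            base = _finish(base)
            if _distinct_enough(base, base_images):
                break
        base_images.append(base)
        for e in range(n_exemplars):
            img = _canvas(dims)
            for prims in parts:
                for g in prims:
                    jy, jx = rng.normal(0.0, jitter, size=2)
                    _draw_primitive(img, g, g["cy"] + jy, g["cx"] + jx)
            images.append(_finish(img))
            object_ids.append(o)
            tids.append(f"ex{e:02d}")
            split.append("train")
    object_ids = np.array(object_ids)
    return StimulusSet(
        images=np.asarray(images),
        object_ids=object_ids,
        transform_ids=tids,
        split=np.array(split),
        presentation_order=_object_grouped_order(object_ids),
        metadata={"generator": "part_configured"},
    )


def scramble_quadrants(img: np.ndarray, perm: tuple[int, int, int, int]) -> np.ndarray:
    """Permute the four image quadrants: output quadrant i <- input quadrant perm[i].

    Quadrants are indexed row-major (TL, TR, BL, BR).  Requires even
    image dimensions; the pixel multiset is preserved exactly.
    """
    h, w = img.shape
    if h % 2 or w % 2:
        raise ValueError("image dimensions must be even to scramble quadrants")
    qh, qw = h // 2, w // 2
    slices = [
        (slice(0, qh), slice(0, qw)),
        (slice(0, qh), slice(qw, w)),
        (slice(qh, h), slice(0, qw)),
        (slice(qh, h), slice(qw, w)),
    ]
    out = np.empty_like(img)
    for dst, src in enumerate(perm):
        out[slices[dst]] = img[slices[src]]
    return out


def gen_part_scramble(
    sset: StimulusSet,
    n_permutations: int,
    rng: np.random.Generator,
    full_displacement: bool = True,
) -> StimulusSet:
    """Quadrant-scrambled copies of every image in a stimulus set.

    Emits ``n_permutations`` scrambled versions per image, each using a
    random non-identity permutation of the four quadrants (the identity
    is never emitted).  By default only derangements are drawn -- every
    quadrant is displaced, so no fragment of the part configuration
    survives; set ``full_displacement=False`` to allow permutations with
    fixed points (at least two quadrants still move).  Pixel content is
    preserved exactly per image.  The output is marked as a test split.
    """
    h, w = sset.dims
    if h % 2 or w % 2:
        raise ValueError("images must have even dimensions")
    pool = _QUAD_DERANGEMENTS if full_displacement else _QUAD_PERMS
    images, object_ids, tids, split, perms = [], [], [], [], []
    for i, img in enumerate(sset.images):
        # distinct permutations per image when the pool allows it
        if n_permutations <= len(pool):
            chosen = rng.choice(len(pool), size=n_permutations, replace=False)
        else:
            chosen = rng.integers(len(pool), size=n_permutations)
        for p, perm_i in enumerate(chosen):
            perm = pool[perm_i]
            images.append(scramble_quadrants(img, perm).astype(np.float32))
            object_ids.append(sset.object_ids[i])
            tids.append(f"{sset.transform_ids[i]}_scr{p}")
            split.append("test")
            perms.append(perm)
    object_ids = np.array(object_ids)
    return StimulusSet(
        images=np.asarray(images),
        object_ids=object_ids,
        transform_ids=tids,
        split=np.array(split),
        presentation_order=_object_grouped_order(object_ids),
        metadata={"generator": "part_scramble", "permutations": perms},
    )


# ---------------------------------------------------------------------------
# Experiment-4 analogue: catastrophic view change
# ---------------------------------------------------------------------------


def gen_catastrophic_pair(
    rng: np.random.Generator,
    dims: tuple[int, int] = (64, 64),
    n_views: int = 4,
) -> StimulusSet:
    """Two objects x four views, one view per object revealing an interior.

    Each object is a cup-like shape whose outline (body proportions,
    handle side and rim) is identity-diagnostic and identical across
    that object's views.  Views vary smoothly in interior shading --
    except one view per object, which reveals a high-contrast interior
    pattern.  The revealed pattern is the *same* for both objects, so it
    carries no identity information; the two interior-feature views
    therefore resemble each other more than they resemble the other
    views of their own object.
    """
    h, w = dims
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    # shared interior pattern: a fixed checkerboard patch
    yy, xx = _mesh(dims)
    checker = 0.4 * (((yy // 4) + (xx // 4)) % 2 * 2.0 - 1.0)

    specs = []
    for o in range(2):
        specs.append(
            {
                "ry": rng.uniform(0.30, 0.36) * h * (1.0 if o == 0 else 0.85),
                "rx": rng.uniform(0.20, 0.26) * w * (1.0 if o == 0 else 1.25),
                "handle_side": 1 if o == 0 else -1,
                "shade": rng.uniform(-0.2, -0.1) if o == 0 else rng.uniform(0.1, 0.2),
                "reveal_view": int(rng.integers(n_views)),
            }
        )
    images, object_ids, tids, split = [], [], [], []
    for o, s in enumerate(specs):
        body = _ellipse_mask(dims, cy, cx, s["ry"], s["rx"])
        handle_cx = cx + s["handle_side"] * (s["rx"] + 4.0)
        handle = _ellipse_mask(dims, cy, handle_cx, 7.0, 5.0) & ~_ellipse_mask(
            dims, cy, handle_cx, 4.0, 2.5
        )
        outline = body | handle
        inner = _ellipse_mask(dims, cy, cx, s["ry"] * 0.72, s["rx"] * 0.72)
        for v in range(n_views):
            img = _canvas(dims)
            img[outline] += s["shade"]
            if v == s["reveal_view"]:
                img[inner] = BACKGROUND + checker[inner]
            else:
                # smooth interior shading gradient rotating with view
                t = np.deg2rad(30.0 * v)
                grad = 0.12 * (
                    np.cos(t) * (yy - cy) / max(h, 1) + np.sin(t) * (xx - cx) / max(w, 1)
                )
                img[inner] += grad[inner]
            images.append(_finish(img))
            object_ids.append(o)
            tids.append(f"view{v}" + ("_interior" if v == s["reveal_view"] else ""))
            split.append("train")
    object_ids = np.array(object_ids)
    return StimulusSet(
        images=np.asarray(images),
        object_ids=object_ids,
        transform_ids=tids,
        split=np.array(split),
        presentation_order=_object_grouped_order(object_ids),
        metadata={
            "generator": "catastrophic_pair",
            "reveal_views": [s["reveal_view"] for s in specs],
        },
    )


# ---------------------------------------------------------------------------
# Translation x view grids
# ---------------------------------------------------------------------------


def gen_translation_view_grid(
    n_objects: int,
    n_views: int,
    grid: int | list[tuple[int, int]],
    rng: np.random.Generator,
    dims: tuple[int, int] = (64, 64),
    spacing: int = 4,
) -> StimulusSet:
    """Every (view, location) pair per object; 4 views x 25 locations default.

    ``grid`` is either the side of a square location grid (5 -> 25
    locations at ``spacing``-pixel pitch, centred) or an explicit list
    of (dy, dx) integer offsets.  Location (0, 0) reproduces the base
    view exactly.  Raises if the location offsets would push the object
    support outside the frame.
    """
    if isinstance(grid, int):
        half = (grid - 1) / 2.0
        offsets = [
            (int(round((i - half) * spacing)), int(round((j - half) * spacing)))
            for i in range(grid)
            for j in range(grid)
        ]
    else:
        offsets = [(int(dy), int(dx)) for dy, dx in grid]
    h, w = dims
    max_off = max(max(abs(dy), abs(dx)) for dy, dx in offsets)
    # view objects occupy ~0.4 * dims around the centre
    if max_off + 0.42 * max(h, w) > min(h, w) / 2.0 + 1:
        raise ValueError(
            f"maximum offset {max_off} px pushes the object outside a {dims} frame"
        )
    objs = [_make_view_object(rng, dims) for _ in range(n_objects)]
    images, object_ids, tids, split = [], [], [], []
    for o, obj in enumerate(objs):
        for v in range(n_views):
            base = _render_view(obj, v * (360.0 / max(n_views, 1)), dims)
            for dy, dx in offsets:
                images.append(_shift_int(base, dy, dx).astype(np.float32))
                object_ids.append(o)
                tids.append(f"v{v}_loc{dy:+d}{dx:+d}")
                split.append("train")
    object_ids = np.array(object_ids)
    return StimulusSet(
        images=np.asarray(images),
        object_ids=object_ids,
        transform_ids=tids,
        split=np.array(split),
        presentation_order=_object_grouped_order(object_ids),
        metadata={"generator": "translation_view_grid", "offsets": offsets},
    )


# ---------------------------------------------------------------------------
# External image directories
# ---------------------------------------------------------------------------


def load_image_dir(path, target_dims: tuple[int, int] = (64, 64)) -> StimulusSet:
    """Load an object-per-subdirectory image tree.

    Images are converted to single-channel grayscale with ITU-R 601-2
    luminance weights (0.299 R + 0.587 G + 0.114 B), resampled with
    bilinear interpolation to ``target_dims`` and scaled to [0, 1].
    Unreadable files are itemised in the raised error; empty classes are
    an error.
    """
    root = Path(path)
    subdirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not subdirs:
        raise ValueError(f"no object subdirectories found under {root}")
    images, object_ids, tids, problems = [], [], [], []
    for o, d in enumerate(subdirs):
        files = sorted(
            f for f in d.iterdir()
            if f.suffix.lower() in (".png", ".pgm", ".jpg", ".jpeg")
        )
        loaded = 0
        for f in files:
            try:
                with Image.open(f) as im:
                    gray = im.convert("L").resize(
                        (target_dims[1], target_dims[0]), Image.BILINEAR
                    )
                images.append(np.asarray(gray, dtype=np.float32) / 255.0)
                object_ids.append(o)
                tids.append(f.stem)
                loaded += 1
            except Exception as exc:  # noqa: BLE001 - itemised load report
                problems.append(f"{f}: {exc}")
        if loaded == 0:
            problems.append(f"{d}: no readable images (empty class)")
            raise ValueError("image directory load failed:\n" + "\n".join(problems))
    if problems:
        import warnings

        warnings.warn("some files skipped:\n" + "\n".join(problems), stacklevel=2)
    object_ids = np.array(object_ids)
    return StimulusSet(
        images=np.asarray(images),
        object_ids=object_ids,
        transform_ids=tids,
        split=np.full(len(images), "train"),
        presentation_order=_object_grouped_order(object_ids),
        metadata={"generator": "load_image_dir", "source": str(root)},
    )
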
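"""Reproducible experiment pipelines: stimuli -> front end -> training -> readout.

Four experiment analogues are provided, mirroring the designs the model
family is evaluated on:

* ``exp1`` -- class exemplars with intra-class variation, trained and
  tested in a cross-validation split.
* ``exp2`` -- systematic view series (8 objects; 4/9/18 training views
  at 90/40/20 degree spacing; 18 test views offset by 10 degrees).
* ``exp3`` -- part-configured objects trained intact, tested on
  quadrant-scrambled versions.
* ``exp4`` -- two objects x four views with a catastrophic view change
  (a shared interior pattern revealed in one view per object).

``run_experiment`` executes a configuration end to end and writes a
report bundle (checkpoint, convergence log, response tables, information
results, classification report, similarity matrices, manifest) under a
run directory.  Every numeric artifact is regenerable from the manifest
alone: a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import (
    ResponseTable,
    classify,
    compute_responses,
    max_single_cell_info,
    multiple_cell_info,
    select_best_cells,
    similarity_matrix,
    train_pattern_associator,
)
from .learning import train_network
from .network import NetworkState, get_profile
from .stimuli import (
    StimulusSet,
    gen_catastrophic_pair,
    gen_class_exemplars,
    gen_part_configured_objects,
    gen_part_scramble,
    gen_view_series,
)

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment",
           "compare_rule_variants", "build_stimuli"]

_VALID_EXPERIMENTS = ("exp1", "exp2", "exp3", "exp4", "custom")

#: Default stimulus parameters per experiment analogue (desk scale).
_DEFAULT_STIMULUS_PARAMS = {
    "exp1": {"n_classes": 2, "n_exemplars": 80, "n_test": 30},
    "exp2": {"n_objects": 8, "n_views": 9, "angular_spacing": 40.0,
             "test_n_views": 18, "test_spacing": 20.0, "test_offset": 10.0},
    "exp3": {"n_objects": 8, "n_exemplars": 5, "n_scramble_permutations": 5},
    "exp4": {"n_views": 4},
}
_DEFAULT_EPOCHS = {"exp1": 50, "exp2": 50, "exp3": 20, "exp4": 10}


@dataclass
class ExperimentConfig:
    """Everything that determines a run; equal configs give identical outputs."""

    experiment: str
    seed: int = 0
    profile: str = "scaled-32"
    epochs: int | None = None
    stimulus_params: dict = field(default_factory=dict)
    cells_per_class: int = 10
    info_cells_per_class: int = 5
    rule_overrides: dict = field(default_factory=dict)
    eta_overrides: dict = field(default_factory=dict)
    output_dir: str | None = None

    def __post_init__(self) -> None:
        errors = []
        if self.experiment not in _VALID_EXPERIMENTS:
            errors.append(
                f"experiment must be one of {_VALID_EXPERIMENTS}, got {self.experiment!r}"
            )
        if self.epochs is not None and self.epochs < 1:
            errors.append("epochs must be >= 1")
        if self.seed < 0:
            errors.append("seed must be nonnegative")
        if self.cells_per_class < 1 or self.info_cells_per_class < 1:
            errors.append("cells_per_class and info_cells_per_class must be >= 1")
        try:
            get_profile(self.profile)
        except ValueError as exc:
            errors.append(str(exc))
        if errors:
            raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
        if self.epochs is None:
            self.epochs = _DEFAULT_EPOCHS.get(self.experiment, 50)
        params = dict(_DEFAULT_STIMULUS_PARAMS.get(self.experiment, {}))
        params.update(self.stimulus_params)
        self.stimulus_params = params

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class ExperimentReport:
    """In-memory result bundle of one run."""

    config: ExperimentConfig
    state: NetworkState
    convergence: pd.DataFrame
    train_table: ResponseTable
    test_table: ResponseTable | None
    info: dict
    classification: dict
    similarity: dict
    best_cell_profiles: pd.DataFrame


def build_stimuli(config: ExperimentConfig) -> tuple[StimulusSet, StimulusSet | None]:
    """Generate the (train, test) stimulus sets for a configuration."""
    rng = np.random.default_rng(config.seed)
    p = config.stimulus_params
    if config.experiment == "exp1":
        full = gen_class_exemplars(
            p["n_classes"], p["n_exemplars"], rng, n_test=p["n_test"]
        )
        test = full.test_set()
        return full.train_set(), (test if len(test) else None)
    if config.experiment == "exp2":
        full = gen_view_series(
            p["n_objects"], p["n_views"], p["angular_spacing"], rng,
            test_n_views=p["test_n_views"], test_spacing=p["test_spacing"],
            test_offset=p["test_offset"],
        )
        test = full.test_set()
        return full.train_set(), (test if len(test) else None)
    if config.experiment == "exp3":
        intact = gen_part_configured_objects(p["n_objects"], p["n_exemplars"], rng)
        scrambled = gen_part_scramble(intact, p["n_scramble_permutations"], rng)
        return intact, scrambled
    if config.experiment == "exp4":
        return gen_catastrophic_pair(rng, n_views=p["n_views"]), None
    raise ValueError("custom experiments must supply stimuli explicitly")


def _evaluate_table(
    table: ResponseTable,
    config: ExperimentConfig,
    info_cells: np.ndarray | None = None,
    reference: ResponseTable | None = None,
) -> dict:
    """Information summary for one response table.

    The population measure uses the most informative cells per stimulus
    of this table unless ``info_cells`` is given (e.g. cells selected on
    the training responses, reused for a test table); for a test table
    the decoder's class means come from the training ``reference``.
    """
    info_res = max_single_cell_info(table)
    per_obj = info_res.per_object
    if info_cells is None:
        # the most informative cells per stimulus that also respond to it:
        # information alone is ambiguous (a cell silent for one stimulus of
        # two is informative about both), so require the cell's mean rate
        # to the stimulus to exceed its overall mean rate
        mean_class = table.rates.mean(axis=2)
        mean_all = table.rates.mean(axis=(1, 2))
        chosen = []
        for si in range(table.n_objects):
            responds = mean_class[:, si] > mean_all
            order = np.argsort(-(per_obj[:, si] * responds), kind="stable")
            chosen.extend(order[: config.info_cells_per_class])
        info_cells = np.unique(chosen)
    bits, pct_info, confusion = multiple_cell_info(table, info_cells, reference=reference)
    return {
        "max_single_cell_bits": float(per_obj.max()),
        "mean_best_cell_bits": float(
            np.mean([np.sort(per_obj[:, s])[-config.info_cells_per_class:].mean()
                     for s in range(table.n_objects)])
        ),
        "multiple_cell_bits": bits,
        "multiple_cell_percent_correct": pct_info,
        "info_cells": np.asarray(info_cells).tolist(),
        "n_bins": info_res.n_bins,
        "confusion": confusion.tolist(),
    }


def run_experiment(
    config: ExperimentConfig,
    train_stimuli: StimulusSet | None = None,
    test_stimuli: StimulusSet | None = None,
) -> ExperimentReport:
    """Execute one experiment analogue end to end.

    Generates (or accepts) the stimulus sets, initialises the network,
    trains it layer by layer, tabulates train/test responses of the
    output layer, computes information measures, trains the pattern
    associator on the training responses and classifies both sets, and
    builds similarity matrices.  If ``config.output_dir`` is set, the
    full report bundle is written there.
    """
    if train_stimuli is None:
        train_stimuli, generated_test = build_stimuli(config)
        test_stimuli = test_stimuli or generated_test

    state = NetworkState.initialize(get_profile(config.profile), seed=config.seed)
    state, log = train_network(
        train_stimuli, state, epochs=config.epochs, seed=config.seed + 1,
        rule_overrides={int(k): v for k, v in config.rule_overrides.items()},
        eta_overrides={int(k): float(v) for k, v in config.eta_overrides.items()},
    )

    train_table = compute_responses(state, train_stimuli)
    test_table = compute_responses(state, test_stimuli) if test_stimuli is not None else None

    cells, per_class = select_best_cells(train_table, config.cells_per_class)
    model = train_pattern_associator(train_table, cells)
    _, train_pct, train_ties = classify(model, train_table)

    info = {"train": _evaluate_table(train_table, config)}
    classification = {
        "train_percent_correct": train_pct,
        "train_tie_rate": train_ties,
        "chance_percent": 100.0 / train_table.n_objects,
        "selected_cells": {int(k): v.tolist() for k, v in per_class.items()},
    }
    similarity = {"train": similarity_matrix(train_table, cells)}
    if test_table is not None:
        _, test_pct, test_ties = classify(model, test_table)
        classification["test_percent_correct"] = test_pct
        classification["test_tie_rate"] = test_ties
        info["test"] = _evaluate_table(
            test_table, config,
            info_cells=np.asarray(info["train"]["info_cells"]),
            reference=train_table,
        )
        similarity["test"] = similarity_matrix(test_table, cells)

    # per-object best-cell rate profiles across all (object, transform) conditions
    rows = []
    for si, cell_ix in per_class.items():
        best = cell_ix[0]
        for so in range(train_table.n_objects):
            for ti in range(train_table.n_transforms):
                rows.append(
                    {
                        "selected_for_object": train_table.object_labels[si],
                        "cell": int(best),
                        "object": train_table.object_labels[so],
                        "transform": train_table.transform_labels[ti],
                        "rate": float(train_table.rates[best, so, ti]),
                    }
                )
    profiles = pd.DataFrame(rows)

    report = ExperimentReport(
        config=config, state=state, convergence=log, train_table=train_table,
        test_table=test_table, info=info, classification=classification,
        similarity=similarity, best_cell_profiles=profiles,
    )
    if config.output_dir:
        _write_bundle(report, Path(config.output_dir))
    return report


def _write_bundle(report: ExperimentReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    report.config.to_yaml(outdir / "manifest.yaml")
    with open(outdir / "versions.json", "w") as fh:
        json.dump({"tracenet": __version__, "numpy": np.__version__}, fh)
    report.state.save(outdir / "checkpoint.npz")
    report.convergence.to_csv(outdir / "convergence.csv", index=False)
    report.train_table.to_csv(outdir / "responses_train.csv")
    if report.test_table is not None:
        report.test_table.to_csv(outdir / "responses_test.csv")
    with open(outdir / "info.json", "w") as fh:
        json.dump(report.info, fh, indent=2)
    with open(outdir / "classification.json", "w") as fh:
        json.dump(report.classification, fh, indent=2)
    report.best_cell_profiles.to_csv(outdir / "best_cell_profiles.csv", index=False)
    for name, sim in report.similarity.items():
        np.savetxt(outdir / f"similarity_{name}.csv", sim, delimiter=",")
        _heatmap(sim, outdir / f"similarity_{name}.png")


def _heatmap(matrix: np.ndarray, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(matrix, vmin=0.0, vmax=1.0, cmap="viridis")
    fig.colorbar(im, ax=ax, label="cosine similarity")
    ax.set_xlabel("stimulus (object-major)")
    ax.set_ylabel("stimulus (object-major)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def compare_rule_variants(
    config: ExperimentConfig, variants: list[str]
) -> pd.DataFrame:
    """Run the same experiment under different learning-rule variants.

    ``variants`` draw from {"trace", "trace_current", "hebb"}: "trace"
    uses the pre-update trace in layers 2-4, "trace_current" the variant
    whose trace includes the current step, and "hebb" the no-trace
    control (trace decay 0).  Stimuli, connectivity and seeds are shared
    across variants.  Returns a table of max single-cell information,
    multiple-cell information and associator percent correct per
    variant.
    """
    if len(variants) < 2:
        raise ValueError("need at least 2 variants to compare")
    seen: list[str] = []
    for v in variants:
        if v in seen:
            warnings.warn(f"duplicate variant {v!r} removed", stacklevel=2)
        else:
            seen.append(v)
    rows = []
    for variant in seen:
        if variant == "hebb":
            overrides = {"rule_overrides": {2: "hebb", 3: "hebb", 4: "hebb"},
                         "eta_overrides": {2: 0.0, 3: 0.0, 4: 0.0}}
        elif variant in ("trace", "trace_current"):
            overrides = {"rule_overrides": {2: variant, 3: variant, 4: variant},
                         "eta_overrides": {}}
        else:
            raise ValueError(f"unknown variant {variant!r}")
        cfg = ExperimentConfig(
            experiment=config.experiment, seed=config.seed, profile=config.profile,
            epochs=config.epochs, stimulus_params=dict(config.stimulus_params),
            cells_per_class=config.cells_per_class,
            info_cells_per_class=config.info_cells_per_class,
            output_dir=None, **overrides,
        )
        rep = run_experiment(cfg)
        rows.append(
            {
                "variant": variant,
                "max_single_cell_bits": rep.info["train"]["max_single_cell_bits"],
                "mean_best_cell_bits": rep.info["train"]["mean_best_cell_bits"],
                "multiple_cell_bits": rep.info["train"]["multiple_cell_bits"],
                "train_percent_correct": rep.classification["train_percent_correct"],
                "test_percent_correct": rep.classification.get("test_percent_correct"),
            }
        )
    return pd.DataFrame(rows)
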
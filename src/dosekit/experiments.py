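"""Training-data-selection experiments.

This module reproduces, at desk scale on the synthetic catalog, the four
experiment families of the study design this toolkit supports:

* family 1 — full-database pre-trained strategy: train on the whole
  heterogeneous catalog (1-1), on the homogeneous fixed-angle subset only
  (1-2), or fine-tune the full-catalog model on the homogeneous subset
  (1-3);
* family 2 — beam-angle homogeneity and the beam-mask channel (2-1..2-4);
* family 3 — beam-number homogeneity (3-1..3-4), tested on 9-beam cases;
* family 4 — patient position (4-1..4-4), tested on prone cases.

Each design selects a training subset from the catalog by its metadata
columns, trains (or fine-tunes) the dose model, predicts the held-out
test cases, and scores them with the 14-index delta-error protocol.
The suite runner enforces train/test case-id disjointness and is
bit-reproducible under (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dvh import ErrorReport, best_model_fraction, delta_errors, index_set
from .grid import VoxelGrid
from .model import ModelBundle, ModelConfig, finetune, predict_dose, train_model
from .phantom import SyntheticDataset
from .structures import StructureSet

__all__ = [
    "ExperimentConfig",
    "SuiteResult",
    "BUILTIN_DESIGNS",
    "classify_catalog",
    "structures_from_sample",
    "evaluate_model",
    "run_experiment_suite",
]


def classify_catalog(
    catalog: pd.DataFrame, criterion: str, reference
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a catalog by one plan characteristic.

    ``criterion`` is ``"angles"`` (sorted gantry-angle tuple compared
    exactly; a :class:`~dosekit.plans.PlanSpec` may be passed as the
    reference), ``"beam_count"`` or ``"position"``.  Returns the matching
    subset and its complement — disjoint and exhaustive.
    """
    if criterion == "angles":
        ref = tuple(reference.sorted_angles()) if hasattr(reference, "sorted_angles") else tuple(reference)
        match = catalog["angles"].map(lambda t: tuple(t) == ref)
    elif criterion == "beam_count":
        match = catalog["beam_count"] == int(reference)
    elif criterion == "position":
        match = catalog["position"] == str(reference)
    else:
        raise ValueError(f"criterion must be angles|beam_count|position, got {criterion!r}")
    return catalog[match], catalog[~match]


@dataclass(frozen=True)
class ExperimentConfig:
    """One experiment design.

    ``train_filter`` maps catalog columns to required values (scalars or
    lists); the empty dict selects the whole training pool.  A design with
    ``pretrained_from`` fine-tunes that design's trained model instead of
    training from scratch.
    """

    experiment_id: str
    train_filter: dict = field(default_factory=dict)
    include_beam_mask: bool = True
    pretrained_from: str | None = None
    test_stratum: str = "fixed7_supine_test"
    model: ModelConfig | None = None


def _select_train(catalog: pd.DataFrame, cfg: ExperimentConfig) -> pd.DataFrame:
    rows = catalog[catalog["role"] == "train"]
    for col, val in cfg.train_filter.items():
        if isinstance(val, (list, tuple, set)):
            rows = rows[rows[col].isin(list(val))]
        else:
            rows = rows[rows[col] == val]
    if len(rows) == 0:
        raise ValueError(
            f"experiment {cfg.experiment_id!r}: training selector matches no cases"
        )
    return rows


#: the 15 built-in designs (families 1-4), keyed by experiment id
BUILTIN_DESIGNS: dict[str, ExperimentConfig] = {
    # family 1: full-database pre-trained strategy (tested on fixed-angle supine cases)
    "1-1": ExperimentConfig("1-1", {}, True),
    "1-2": ExperimentConfig("1-2", {"stratum": "fixed7_supine"}, True),
    "1-3": ExperimentConfig("1-3", {"stratum": "fixed7_supine"}, True, pretrained_from="1-1"),
    # family 2: beam-angle homogeneity x beam mask
    "2-1": ExperimentConfig("2-1", {"stratum": "fixed7_supine"}, True),
    "2-2": ExperimentConfig("2-2", {"stratum": "fixed7_supine"}, False),
    "2-3": ExperimentConfig(
        "2-3", {"beam_count": 7, "position": "supine"}, True
    ),
    "2-4": ExperimentConfig(
        "2-4", {"beam_count": 7, "position": "supine"}, False
    ),
    # family 3: beam-number homogeneity (9-beam tests)
    "3-1": ExperimentConfig(
        "3-1", {"stratum": "nine_supine"}, True, test_stratum="nine_supine_test"
    ),
    "3-2": ExperimentConfig(
        "3-2", {"position": "supine"}, True, test_stratum="nine_supine_test"
    ),
    "3-3": ExperimentConfig(
        "3-3",
        {"beam_count": 7, "position": "supine"},
        True,
        test_stratum="nine_supine_test",
    ),
    "3-4": ExperimentConfig(
        "3-4", {"position": "supine"}, False, test_stratum="nine_supine_test"
    ),
    # family 4: patient position (prone tests)
    "4-1": ExperimentConfig("4-1", {}, True, test_stratum="prone7_test"),
    "4-2": ExperimentConfig(
        "4-2", {"position": "prone"}, True, test_stratum="prone7_test"
    ),
    "4-3": ExperimentConfig(
        "4-3", {"position": "prone"}, False, test_stratum="prone7_test"
    ),
    "4-4": ExperimentConfig(
        "4-4", {"position": "supine"}, True, test_stratum="prone7_test"
    ),
}


def structures_from_sample(sample) -> StructureSet:
    """Recover the binary structure set from a sample's mask channels."""
    masks = {
        name: sample.channel(name) > 0.5
        for name in sample.channel_names
        if name not in ("ct", "beam_mask")
    }
    return StructureSet(masks=masks, grid=sample.grid)


def evaluate_model(
    bundle: ModelBundle, test_samples, prescription_gy: float = 50.4
) -> list[ErrorReport]:
    """Predict each test case and score it with the 14-index delta errors."""
    reports = []
    for sample in test_samples:
        structures = structures_from_sample(sample)
        gt = index_set(sample.dose_gy, structures)
        pred = index_set(predict_dose(bundle, sample), structures)
        reports.append(delta_errors(gt, pred, prescription_gy))
    return reports


@dataclass
class SuiteResult:
    """Comparison table and scores of one suite run.

    ``table`` has one row per (experiment, seed); ``fractions`` the
    "% of best prediction" per test stratum (averaged over seeds);
    ``reports`` the raw per-case error reports keyed ``(id, seed)``.
    """

    table: pd.DataFrame
    fractions: dict[str, dict[str, float]]
    reports: dict[tuple[str, int], list[ErrorReport]]
    bundles: dict[tuple[str, int], ModelBundle] = field(default_factory=dict)

    def mean_delta(self, experiment_id: str) -> float:
        """Pooled mean overall delta (%) of one design across seeds."""
        rows = self.table[self.table["experiment"] == experiment_id]
        return float(rows["overall_mean_delta_pct"].mean())


def run_experiment_suite(
    dataset: SyntheticDataset,
    designs=None,
    seeds=(0, 1, 2),
    model_config: ModelConfig | None = None,
    finetune_epochs: int | None = None,
    prescription_gy: float = 50.4,
    keep_bundles: bool = False,
) -> SuiteResult:
    """Run a list of experiment designs over several model seeds.

    ``designs`` may be experiment ids (keys of :data:`BUILTIN_DESIGNS`) or
    :class:`ExperimentConfig` objects; designs referenced by
    ``pretrained_from`` are trained on demand.  ``finetune_epochs``
    defaults to half the training epochs.  Training and test case ids are
    verified to be disjoint.
    """
    model_config = model_config or ModelConfig()
    if designs is None:
        designs = list(BUILTIN_DESIGNS)
    configs: dict[str, ExperimentConfig] = {}
    for d in designs:
        cfg = BUILTIN_DESIGNS[d] if isinstance(d, str) else d
        configs[cfg.experiment_id] = cfg
    for cfg in list(configs.values()):
        if cfg.pretrained_from and cfg.pretrained_from not in configs:
            configs[cfg.pretrained_from] = BUILTIN_DESIGNS[cfg.pretrained_from]

    catalog = dataset.catalog
    rows = []
    reports: dict[tuple[str, int], list[ErrorReport]] = {}
    bundles: dict[tuple[str, int], ModelBundle] = {}

    def get_bundle(cfg: ExperimentConfig, seed: int) -> ModelBundle:
        key = (cfg.experiment_id, seed)
        if key in bundles:
            return bundles[key]
        mcfg = cfg.model or model_config
        train_rows = _select_train(catalog, cfg)
        test_rows = catalog[catalog["stratum"] == cfg.test_stratum]
        overlap = set(train_rows["plan_id"]) & set(test_rows["plan_id"])
        if overlap:
            raise ValueError(f"train/test leakage in {cfg.experiment_id}: {sorted(overlap)}")
        samples = dataset.samples(train_rows["plan_id"], cfg.include_beam_mask)
        if cfg.pretrained_from:
            base = get_bundle(configs[cfg.pretrained_from], seed)
            ft_cfg = replace(
                mcfg, epochs=finetune_epochs if finetune_epochs is not None else max(1, mcfg.epochs // 2)
            )
            bundle = finetune(base, samples, ft_cfg, seed=seed)
        else:
            bundle = train_model(samples, mcfg, seed=seed)
        bundles[key] = bundle
        return bundle

    for cfg in configs.values():
        test_rows = catalog[catalog["stratum"] == cfg.test_stratum]
        if len(test_rows) == 0:
            raise ValueError(
                f"experiment {cfg.experiment_id!r}: no test cases in stratum "
                f"{cfg.test_stratum!r}"
            )
        for seed in seeds:
            bundle = get_bundle(cfg, seed)
            test_samples = dataset.samples(test_rows["plan_id"], cfg.include_beam_mask)
            case_reports = evaluate_model(bundle, test_samples, prescription_gy)
            reports[(cfg.experiment_id, seed)] = case_reports
            overall = np.array([r.overall_mean for r in case_reports])
            row = {
                "experiment": cfg.experiment_id,
                "seed": seed,
                "test_stratum": cfg.test_stratum,
                "n_train": len(_select_train(catalog, cfg)),
                "n_test": len(test_rows),
                "include_beam_mask": cfg.include_beam_mask,
                "overall_mean_delta_pct": float(overall.mean()),
                "overall_sd_delta_pct": float(overall.std()),
            }
            for s in ("ptv", "bladder", "rectum"):
                row[f"{s}_mean_delta_pct"] = float(
                    np.mean([r.per_structure[s][0] for r in case_reports])
                )
            rows.append(row)

    table = pd.DataFrame(rows)
    # "% of best prediction" among designs sharing one test stratum
    fractions: dict[str, dict[str, float]] = {}
    for stratum in table["test_stratum"].unique():
        ids = [i for i, c in configs.items() if c.test_stratum == stratum]
        if len(ids) < 2:
            continue
        per_seed = []
        for seed in seeds:
            per_seed.append(best_model_fraction({i: reports[(i, seed)] for i in ids}))
        fractions[stratum] = {
            i: float(np.mean([f[i] for f in per_seed])) for i in ids
        }
    if not keep_bundles:
        bundles = {}
    return SuiteResult(table=table, fractions=fractions, reports=reports, bundles=bundles)
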
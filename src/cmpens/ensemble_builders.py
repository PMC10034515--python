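"""Constructing ensembles of patch classifiers and the size-saturation sweep.

Eight named ensemble recipes are supported, crossing how members differ:

* ``random_seeds`` — members share the training set, differ only by their
  initialization seed: ``E_0.1pct``, ``E_1pct``, ``E_10pct`` (training-set
  size = 0.1%, 1%, 10% of the model's parameter count N_p).
* ``pruning_schedule`` — members share one seed (optionally one pretraining
  checkpoint) and differ by L1-pruning fraction n * 0.5% (member n), spanning
  0.5%..50%: ``E_0.1pct_pru``, ``E_1pct_pru``, ``E_10pct_pru``.
* ``variable_ntrain`` — member n trains on a ladder of sample counts growing
  from 1000 to 420000 (``E_Ntr``).
* ``variable_ntrain_pruned`` — the ladder combined with a fixed 80% pruning
  of every conv layer before fine-tuning (``E_Ntr_80pru``).

At desk scale the same recipes run with few members, a compact architecture
and training sizes scaled by the same 0.1/1/10%-of-N_p logic against the
compact model's own parameter count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import aggregation, metrics, patch_model
from .synthetic_data import PatchDataset

__all__ = [
    "EnsembleConfig",
    "RECIPES",
    "recipe_config",
    "training_size_ladder",
    "pruning_schedule",
    "member_seed",
    "build_ensemble",
    "ensemble_size_sweep",
]

_LADDER_SEGMENTS = (
    # (first n, last n, value at first n, step); continuous at the joints:
    # ... 19 -> 10000, 34 -> 25000, 49 -> 55000, 78 -> 200000, 100 -> 420000
    (1, 19, 1000, 500),
    (20, 34, 11000, 1000),
    (35, 49, 27000, 2000),
    (50, 78, 60000, 5000),
    (79, 100, 210000, 10000),
)


def training_size_ladder(n: int) -> int:
    """Training-set size for member n (1..100) of a variable-N ensemble.

    Piecewise-linear ladder: 1000 + (n-1)*500 for n in 1..19, then steps of
    1000 / 2000 / 5000 / 10000 up to 420000 at n = 100.
    """
    if not (1 <= n <= 100):
        raise ValueError(f"member index must be in 1..100, got {n}")
    for first, last, base, step in _LADDER_SEGMENTS:
        if first <= n <= last:
            return base + (n - first) * step
    raise AssertionError("unreachable")


def pruning_schedule(n: int) -> float:
    """Pruning fraction for member n (1..100): n * 0.5%, spanning 0.5%..50%."""
    if not (1 <= n <= 100):
        raise ValueError(f"member index must be in 1..100, got {n}")
    return 0.005 * n


def member_seed(base_seed: int, n: int) -> int:
    """Counter-based member seed so any single member is re-trainable alone."""
    return int((base_seed * 100003 + n) % (2**31 - 1))


@dataclass(frozen=True)
class EnsembleConfig:
    """Recipe for one ensemble of patch classifiers."""

    name: str
    strategy: str  # random_seeds | pruning_schedule | variable_ntrain | variable_ntrain_pruned
    n_models: int = 100
    training_size: int | None = None  # fixed size; None for ladder strategies
    fixed_prune_fraction: float | None = None  # e.g. 0.8 for E_Ntr_80pru
    base_seed: int = 0
    pretrained: bool = False
    architecture: patch_model.ArchitectureConfig = field(
        default_factory=patch_model.ArchitectureConfig
    )
    train: patch_model.TrainConfig = field(default_factory=patch_model.TrainConfig)

    def __post_init__(self) -> None:
        valid = ("random_seeds", "pruning_schedule", "variable_ntrain", "variable_ntrain_pruned")
        if self.strategy not in valid:
            raise ValueError(f"unknown strategy {self.strategy!r}; valid: {valid}")
        if self.strategy in ("random_seeds", "pruning_schedule") and self.training_size is None:
            raise ValueError(f"strategy {self.strategy} requires a fixed training_size")
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")

    def member_training_size(self, n: int) -> int:
        if self.strategy in ("variable_ntrain", "variable_ntrain_pruned"):
            return training_size_ladder(n)
        return int(self.training_size)

    def member_prune_fraction(self, n: int) -> float:
        if self.strategy == "pruning_schedule":
            return pruning_schedule(n)
        if self.strategy == "variable_ntrain_pruned":
            return float(self.fixed_prune_fraction if self.fixed_prune_fraction is not None else 0.8)
        return 0.0


# the eight canonical recipes: (strategy, parameter-count fraction or ladder,
# fixed pruning).  Training sizes are resolved against the architecture's own
# parameter count when the config is instantiated.
RECIPES: dict[str, dict] = {
    "E_0.1pct":     {"strategy": "random_seeds",          "np_fraction": 0.001},
    "E_1pct":       {"strategy": "random_seeds",          "np_fraction": 0.01},
    "E_10pct":      {"strategy": "random_seeds",          "np_fraction": 0.1},
    "E_0.1pct_pru": {"strategy": "pruning_schedule",      "np_fraction": 0.001},
    "E_1pct_pru":   {"strategy": "pruning_schedule",      "np_fraction": 0.01},
    "E_10pct_pru":  {"strategy": "pruning_schedule",      "np_fraction": 0.1},
    "E_Ntr":        {"strategy": "variable_ntrain"},
    "E_Ntr_80pru":  {"strategy": "variable_ntrain_pruned", "fixed_prune_fraction": 0.8},
}


def recipe_config(
    name: str,
    n_models: int = 100,
    base_seed: int = 0,
    architecture: patch_model.ArchitectureConfig | None = None,
    train: patch_model.TrainConfig | None = None,
    pretrained: bool = False,
) -> EnsembleConfig:
    """Instantiate one of the eight named recipes.

    Fixed training sizes are the recipe's fraction of the *given*
    architecture's trainable-parameter count, so compact desk-scale models
    get proportionally smaller training sets.
    """
    if name not in RECIPES:
        raise ValueError(f"unknown recipe {name!r}; valid: {sorted(RECIPES)}")
    spec = RECIPES[name]
    arch = architecture or patch_model.ArchitectureConfig()
    n_p = patch_model.build_network(arch, seed=0).n_parameters()
    training_size = None
    if "np_fraction" in spec:
        training_size = max(20, int(round(spec["np_fraction"] * n_p)))
    return EnsembleConfig(
        name=name,
        strategy=spec["strategy"],
        n_models=n_models,
        training_size=training_size,
        fixed_prune_fraction=spec.get("fixed_prune_fraction"),
        base_seed=base_seed,
        pretrained=pretrained,
        architecture=arch,
        train=train or patch_model.TrainConfig(),
    )


def _subset_dataset(data: PatchDataset, idx: np.ndarray) -> PatchDataset:
    return PatchDataset(
        patches=data.patches[idx],
        labels=data.labels[idx],
        positions=data.positions[idx],
        source_image=data.source_image[idx],
        split=data.split,
    )


def build_ensemble(
    cfg: EnsembleConfig,
    data: PatchDataset,
    pretrain_data: PatchDataset | None = None,
) -> tuple[list[patch_model.PatchModel], list[dict]]:
    """Train the ensemble members prescribed by ``cfg``.

    Returns (members, provenance): one provenance record per member with its
    seed, pruning fraction and training size — enough to retrain it alone.

    * ``random_seeds``: every member sees the identical training subset but a
      different initialization seed.
    * ``pruning_schedule``: one shared seed (and shared pretraining
      checkpoint, if ``pretrain_data`` is given); member n is pruned by
      n*0.5% before fine-tuning on the shared subset.
    * ``variable_ntrain``(+``_pruned``): member n trains on ladder(n)
      samples; the pruned variant first prunes every conv layer by the fixed
      fraction (default 80%).
    """
    largest = max(cfg.member_training_size(n) for n in range(1, cfg.n_models + 1))
    if len(data) < largest:
        raise ValueError(
            f"insufficient data: recipe {cfg.name!r} needs {largest} patches, "
            f"got {len(data)} (short by {largest - len(data)})"
        )
    rng = np.random.default_rng(cfg.base_seed)
    shared_subset = rng.permutation(len(data))  # fixed draw order, shared across members

    shared_init: patch_model.PatchModel | None = None
    if cfg.strategy in ("pruning_schedule", "variable_ntrain", "variable_ntrain_pruned"):
        shared_init = patch_model.build_network(cfg.architecture, seed=cfg.base_seed)
        if cfg.pretrained and pretrain_data is not None:
            pre_cfg = replace(cfg.train, epochs=cfg.train.pretrain_epochs, seed=cfg.base_seed)
            patch_model.train(shared_init, pretrain_data, pre_cfg)

    members: list[patch_model.PatchModel] = []
    provenance: list[dict] = []
    for n in range(1, cfg.n_models + 1):
        size = cfg.member_training_size(n)
        frac = cfg.member_prune_fraction(n)
        seed_n = member_seed(cfg.base_seed, n)
        if cfg.strategy == "random_seeds":
            model = patch_model.build_network(cfg.architecture, seed=seed_n)
            subset = shared_subset[:size]
            train_seed = seed_n
        else:
            model = shared_init.copy()
            if frac > 0.0:
                model = patch_model.prune_l1(model, frac)
            subset = shared_subset[:size]
            train_seed = seed_n
        tr_cfg = replace(cfg.train, seed=train_seed)
        patch_model.train(model, _subset_dataset(data, subset), tr_cfg)
        members.append(model)
        provenance.append(
            {
                "recipe": cfg.name,
                "member": n,
                "seed": seed_n,
                "prune_fraction": frac,
                "training_size": size,
                "n_parameters": model.n_parameters(),
            }
        )
    return members, provenance


def ensemble_size_sweep(
    stack: aggregation.CMPStack,
    truth,
    sizes,
    method: str = "mean",
    repetitions: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy versus ensemble size (the saturation curve).

    For each size k, ``repetitions`` random k-member subsets are aggregated
    by ``method`` and scored against ``truth``; k = M uses the single full
    ensemble (zero spread).  Returns columns (size, mean_acc, std_acc).
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    m = stack.n_members
    rng = np.random.default_rng(seed)
    rows = []
    for k in sizes:
        if not (1 <= k <= m):
            raise ValueError(f"subset size {k} exceeds member count {m}")
        reps = 1 if k == m else repetitions
        accs = []
        for _ in range(reps):
            idx = np.sort(rng.choice(m, size=k, replace=False))
            mask = aggregation.aggregate(stack.subset(idx), method)
            accs.append(metrics.accuracy(metrics.confusion_counts(mask, truth)))
        mean, std = metrics.per_image_summary(accs)
        rows.append({"size": int(k), "mean_acc": mean, "std_acc": std})
    return pd.DataFrame(rows)
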
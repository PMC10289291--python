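"""Training harness: stratified splits, per-fold Adam training, selection.

The protocol mirrors a standard cross-validated segmentation study: the
cohort is split into a training group and an independent test group,
stratified by the cirrhotic flag; the training group is divided into k
stratified folds; each fold trains for a fixed number of epochs with Adam
(constant learning rate); the fold model with the best validation DSC
runs on the independent test group.

One "batch" is one padded volume — its 8 slices enter the 2.5D backbone
as batch elements.  Loss class weights are prior statistics computed from
each fold's training portion only (padded slices count as background).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from autograd import value_and_grad
from sklearn.model_selection import StratifiedKFold, train_test_split

from .ioprep import MUSCLE_CLASSES
from .losses import ClassWeights, combined_loss_scalar, compute_class_weights, one_hot
from .metrics import evaluate_volume
from .network import LSMUNet, NetworkConfig, build_lsmu_net, predict_labels
from .nn import Adam


@dataclass
class FoldSplit:
    """Stratified train/validation folds plus an independent test group."""

    folds: list[tuple[list[str], list[str]]]
    test_ids: list[str]
    stratify_by: str = "cirrhotic"

    @property
    def train_ids(self) -> list[str]:
        ids: list[str] = []
        for _, val in self.folds:
            ids.extend(val)
        return ids


@dataclass
class TrainConfig:
    lr: float = 0.001
    epochs: int = 30
    seed: int = 0
    use_weights: bool = True

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def make_splits(
    manifest: pd.DataFrame,
    test_fraction: float = 0.2,
    n_folds: int = 5,
    seed: int = 0,
    stratify_by: str = "cirrhotic",
) -> FoldSplit:
    """Deterministic stratified test split + stratified k-fold CV split."""
    ids = manifest["patient_id"].tolist()
    strata = manifest[stratify_by].to_numpy()
    for value, count in zip(*np.unique(strata, return_counts=True)):
        if count < n_folds:
            raise ValueError(
                f"stratum {value!r} has {count} patients; need >= {n_folds}"
            )
    if test_fraction > 0:
        train_ids, test_ids = train_test_split(
            ids, test_size=test_fraction, random_state=seed, stratify=strata
        )
    else:
        train_ids, test_ids = list(ids), []
    strat_map = dict(zip(ids, strata))
    y = np.array([strat_map[i] for i in train_ids])
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = []
    train_arr = np.array(train_ids)
    for tr, va in skf.split(train_arr, y):
        folds.append((train_arr[tr].tolist(), train_arr[va].tolist()))
    return FoldSplit(folds=folds, test_ids=list(test_ids), stratify_by=stratify_by)


def prepare_dataset(cases) -> dict:
    """Preprocess phantom cases into network-ready tensors.

    Returns ``{patient_id: {"volume", "target", "slab", "labels"}}`` with
    ``volume`` shaped (1, 1, 8, H, W) and ``target`` a one-hot (8, 5, H, W)
    including padded slices as background.
    """
    from .ioprep import preprocess

    out = {}
    for slab, labels, meta in cases:
        pslab, plab = preprocess(slab, labels)
        out[meta.patient_id] = {
            "volume": np.asarray(pslab.voxels, dtype=np.float32)[None, None],
            "target": one_hot(plab.labels),
            "slab": pslab,
            "labels": plab,
        }
    return out


@dataclass
class FoldResult:
    fold: int
    model: LSMUNet
    weights: ClassWeights
    log: list[dict] = field(default_factory=list)

    @property
    def final_val_dsc(self) -> float:
        return self.log[-1]["val_dsc"]


def _mean_val_dsc(model: LSMUNet, dataset: dict, ids) -> float:
    vals = []
    for pid in ids:
        entry = dataset[pid]
        pred = predict_labels(model, entry["slab"])
        rep = evaluate_volume(pred, entry["labels"])
        vals.append(np.mean([rep.per_class[c]["dsc"] for c in MUSCLE_CLASSES]))
    return float(np.mean(vals))


def train_fold(
    split: FoldSplit,
    fold_k: int,
    net_config: NetworkConfig,
    train_config: TrainConfig,
    dataset: dict,
) -> FoldResult:
    """Train one fold; returns the model and a per-epoch loss/DSC log."""
    train_ids, val_ids = split.folds[fold_k]
    if train_config.use_weights:
        weights = compute_class_weights([dataset[i]["labels"] for i in train_ids])
    else:
        weights = ClassWeights.uniform()

    import dataclasses

    cfg = dataclasses.replace(net_config, seed=net_config.seed + fold_k)
    model = build_lsmu_net(cfg)

    def objective(params, volume, target):
        logits = model.apply(params, volume)
        return combined_loss_scalar(logits, target, weights, train_config.use_weights)

    grad_fn = value_and_grad(objective)
    opt = Adam(model.params, lr=train_config.lr)
    params = model.params
    log = []
    for epoch in range(train_config.epochs):
        order = np.random.default_rng(
            train_config.seed + 100_003 * fold_k + epoch
        ).permutation(len(train_ids))
        losses = []
        for idx in order:
            entry = dataset[train_ids[idx]]
            loss, grads = grad_fn(params, entry["volume"], entry["target"])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at fold {fold_k}, epoch {epoch}, "
                    f"patient {train_ids[idx]}"
                )
            params = opt.step(params, grads)
            losses.append(float(loss))
        model.params = params
        log.append(
            {
                "epoch": epoch,
                "loss": float(np.mean(losses)),
                "val_dsc": _mean_val_dsc(model, dataset, val_ids),
            }
        )
    return FoldResult(fold=fold_k, model=model, weights=weights, log=log)


def select_best(results: list[FoldResult]) -> FoldResult:
    """Fold model with the highest final validation mean DSC over the four
    muscle classes; ties break toward the lowest fold index."""
    if not results:
        raise ValueError("no fold results")
    best = results[0]
    for r in results[1:]:
        if r.final_val_dsc > best.final_val_dsc:
            best = r
    return best


def run_cross_validation(
    dataset: dict,
    manifest: pd.DataFrame,
    net_config: NetworkConfig,
    train_config: TrainConfig,
    n_folds: int = 5,
    test_fraction: float = 0.2,
    seed: int = 0,
):
    """Full protocol: split, train every fold, select, evaluate on test.

    Returns ``(best_result, fold_results, test_reports, split)``.
    """
    split = make_splits(manifest, test_fraction, n_folds, seed)
    results = [
        train_fold(split, k, net_config, train_config, dataset)
        for k in range(n_folds)
    ]
    best = select_best(results)
    test_reports = []
    for pid in split.test_ids:
        entry = dataset[pid]
        pred = predict_labels(best.model, entry["slab"])
        test_reports.append(evaluate_volume(pred, entry["labels"]))
    return best, results, test_reports, split
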
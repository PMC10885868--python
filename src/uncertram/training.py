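"""Patient-wise cross-validation, early stopping and the experiment protocol.

The protocol mirrors common clinical-imaging practice: folds are assigned at
the patient level (every image of a patient shares a fold); the validation
portion of each fold is filtered to cases with uncertainty D <= tau_val so
early stopping tracks a reliably-labelled signal while the training portion
keeps all cases; training runs up to ``max_epochs`` with Adam (two parameter
groups: encoder at ``lr_encoder``, everything else at ``lr_rest``) and stops
once the validation loss has not improved on its best value for ``patience``
consecutive epochs.  Hyperparameters are chosen by grid search under one
seed; the final models are re-trained under a second seed and evaluated on a
patient-disjoint holdout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .baselines import Variant, build_variant
from .data_model import (Dataset, ImageRecord, LabelInfo, aggregate_label,
                         ordinal_target)
from .encoding import encode, uncertainty
from .evaluation import (DEFAULT_BINS, MetricsRecord, StratifiedReport,
                         compute_metrics, stratified_evaluate)
from .network import NetworkConfig
from .nn import Adam

__all__ = [
    "TrainConfig",
    "FoldResult",
    "EarlyStopper",
    "annotate_labels",
    "prepare_arrays",
    "patient_wise_folds",
    "filter_validation",
    "train_fold",
    "grid_search",
    "run_experiment",
    "LR_ENCODER_GRID",
    "LR_REST_GRID",
]

# published search grids for the two learning rates
LR_ENCODER_GRID = (1e-4, 4e-4, 1e-5, 5e-5, 1e-6)
LR_REST_GRID = (1e-3, 5e-3, 1e-4, 5e-4, 1e-5)


@dataclass
class TrainConfig:
    lr_encoder: float = 1e-4
    lr_rest: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 40
    patience: int = 10
    n_folds: int = 3
    tau: float = 2.0          # privileged-information gate
    tau_val: float = 2.0      # validation-set uncertainty filter
    seed_search: int = 0
    seed_final: int = 1
    lr_encoder_grid: tuple[float, ...] = LR_ENCODER_GRID
    lr_rest_grid: tuple[float, ...] = LR_REST_GRID

    def __post_init__(self):
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class FoldResult:
    fold_index: int
    best_epoch: int
    best_validation_loss: float
    checkpoint: list
    log: list[dict] = field(default_factory=list)


class EarlyStopper:
    """Stop when the monitored loss has not improved for ``patience`` epochs.

    Improvement means strictly beating the best value seen so far; the best
    epoch's checkpoint is the one retained.
    """

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self._since_best = 0

    def update(self, loss: float, epoch: int) -> bool:
        """Record this epoch's loss; return True when training should stop."""
        if not np.isfinite(loss):
            raise FloatingPointError(f"validation loss diverged: {loss}")
        if loss < self.best:
            self.best = loss
            self.best_epoch = epoch
            self._since_best = 0
            return False
        self._since_best += 1
        return self._since_best >= self.patience


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------

def annotate_labels(dataset: Dataset) -> Dataset:
    """Fill each record's derived label info (y, mu_S, ordinal target, D)."""
    for record in dataset.records:
        y, mu = aggregate_label(record.annotation_set)
        record.label = LabelInfo(y=y, mu_S=mu,
                                 ordinal_target=ordinal_target(
                                     record.annotation_set),
                                 D=uncertainty(record.annotation_set))
    return dataset


def _ensure_labels(records: list[ImageRecord]) -> None:
    for r in records:
        if r.label is None:
            y, mu = aggregate_label(r.annotation_set)
            r.label = LabelInfo(y=y, mu_S=mu,
                                ordinal_target=ordinal_target(r.annotation_set),
                                D=uncertainty(r.annotation_set))


def prepare_arrays(records: list[ImageRecord],
                   net_config: NetworkConfig) -> dict[str, np.ndarray]:
    """Stack a record list into the arrays the training loop consumes."""
    from .data_model import binarize_review, preprocess_image

    _ensure_labels(records)
    if net_config.encoder_kind == "resnet50":
        imgs = [preprocess_image(r.pixels) for r in records]
    else:
        imgs = [r.pixels for r in records]
    x = np.stack(imgs)[:, None, :, :].astype(float)
    x_star = np.stack([
        encode(r.annotation_set, net_config.encoding_method,
               net_config.panel_size).values
        for r in records])
    ann_record, ann_reviewer, ann_label = [], [], []
    for i, r in enumerate(records):
        for a in r.annotation_set.annotations:
            ann_record.append(i)
            ann_reviewer.append(a.reviewer_id - 1)
            ann_label.append(binarize_review(a.score))
    return {
        "x": x,
        "y": np.array([r.label.y for r in records], dtype=int),
        "ordinal": np.array([r.label.ordinal_target for r in records],
                            dtype=int),
        "D": np.array([r.label.D for r in records], dtype=float),
        "x_star": x_star,
        "ann_record": np.array(ann_record, dtype=int),
        "ann_reviewer": np.array(ann_reviewer, dtype=int),
        "ann_label": np.array(ann_label, dtype=int),
    }


def _batch_slice(arrays: dict[str, np.ndarray],
                 idx: np.ndarray) -> dict[str, np.ndarray]:
    batch = {k: arrays[k][idx] for k in
             ("x", "y", "ordinal", "D", "x_star")}
    keep = np.isin(arrays["ann_record"], idx)
    remap = {orig: new for new, orig in enumerate(idx)}
    batch["ann_record"] = np.array(
        [remap[i] for i in arrays["ann_record"][keep]], dtype=int)
    batch["ann_reviewer"] = arrays["ann_reviewer"][keep]
    batch["ann_label"] = arrays["ann_label"][keep]
    return batch


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

def patient_wise_folds(dataset: Dataset, n_folds: int,
                       seed: int) -> dict[str, int]:
    """Assign each record's patient to a fold (round-robin after a seeded
    shuffle); returns a patient_id -> fold mapping."""
    patients = dataset.patient_ids()
    if len(patients) < n_folds:
        raise ValueError(f"{len(patients)} patients cannot fill "
                         f"{n_folds} folds")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(patients))
    return {pid: i % n_folds for i, pid in enumerate(order)}


def filter_validation(records: list[ImageRecord],
                      tau_val: float) -> list[ImageRecord]:
    """Keep validation cases with uncertainty D <= tau_val (training data is
    never filtered)."""
    _ensure_labels(records)
    kept = [r for r in records if r.label.D <= tau_val]
    if not kept:
        import warnings
        warnings.warn("validation filter removed every record; the "
                      "validation loss will be undefined", stacklevel=2)
    return kept


def _assert_patient_disjoint(a: list[ImageRecord], b: list[ImageRecord],
                             what: str) -> None:
    overlap = {r.patient_id for r in a} & {r.patient_id for r in b}
    if overlap:
        raise ValueError(f"patient overlap between {what}: "
                         f"{sorted(overlap)[:5]}")


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train_fold(train_records: list[ImageRecord],
               val_records: list[ImageRecord],
               net_config: NetworkConfig, train_config: TrainConfig,
               variant_name: str = "proposed", seed: int = 0,
               fold_index: int = 0,
               callbacks: list | None = None) -> tuple[FoldResult, Variant]:
    """Train one fold and return the lowest-validation-loss checkpoint.

    The optimizer minimizes the variant's training loss on the (unfiltered)
    training records; the validation loss is the base branch's cross-entropy
    against mean-aggregated labels on the filtered validation records,
    computed after each epoch in evaluation mode.
    """
    val_records = filter_validation(list(val_records), train_config.tau_val)
    if not val_records:
        raise ValueError("cannot fit with an empty filtered validation set")
    net_config.gate.tau = train_config.tau
    rng = np.random.default_rng(seed)
    variant = build_variant(variant_name, net_config, rng)
    optimizer = Adam(variant.param_groups(train_config.lr_encoder,
                                          train_config.lr_rest))
    arrays = prepare_arrays(train_records, net_config)
    val_arrays = prepare_arrays(val_records, net_config)
    stopper = EarlyStopper(train_config.patience)
    result = FoldResult(fold_index=fold_index, best_epoch=0,
                        best_validation_loss=np.inf, checkpoint=None)
    n = len(train_records)
    for epoch in range(1, train_config.max_epochs + 1):
        variant.train()
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for lo in range(0, n, train_config.batch_size):
            idx = order[lo:lo + train_config.batch_size]
            if len(idx) < 2:
                continue  # batch statistics are undefined for a single case
            batch = _batch_slice(arrays, idx)
            loss = variant.training_loss(batch)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training loss diverged at epoch {epoch}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        variant.eval()
        val_loss = variant.validation_loss(val_arrays["x"], val_arrays["y"])
        entry = {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1),
                 "val_loss": val_loss}
        result.log.append(entry)
        for cb in callbacks or ():
            cb("epoch_end", entry)
        improved = val_loss < stopper.best
        stop = stopper.update(val_loss, epoch)
        if improved:
            result.best_epoch = epoch
            result.best_validation_loss = val_loss
            result.checkpoint = variant.state()
        if stop:
            break
    variant.load_state(result.checkpoint)
    return result, variant


def _cv_fold_records(dataset: Dataset, fold_of: dict[str, int],
                     fold: int) -> tuple[list[ImageRecord], list[ImageRecord]]:
    train = [r for r in dataset.records if fold_of[r.patient_id] != fold]
    val = [r for r in dataset.records if fold_of[r.patient_id] == fold]
    return train, val


def grid_search(dataset: Dataset, net_config: NetworkConfig,
                train_config: TrainConfig, variant_name: str = "proposed",
                ) -> tuple[float, float]:
    """Select (lr_encoder, lr_rest) minimizing the mean across-fold best
    validation loss under the search seed; ties break lexicographically."""
    fold_of = patient_wise_folds(dataset, train_config.n_folds,
                                 train_config.seed_search)
    best_pair, best_loss = None, np.inf
    for lr_enc in sorted(train_config.lr_encoder_grid):
        for lr_rest in sorted(train_config.lr_rest_grid):
            cfg = TrainConfig(**{**train_config.__dict__,
                                 "lr_encoder": lr_enc, "lr_rest": lr_rest})
            losses = []
            for fold in range(train_config.n_folds):
                train, val = _cv_fold_records(dataset, fold_of, fold)
                res, _ = train_fold(train, val, net_config, cfg,
                                    variant_name,
                                    seed=train_config.seed_search + fold,
                                    fold_index=fold)
                losses.append(res.best_validation_loss)
            mean_loss = float(np.mean(losses))
            if mean_loss < best_loss:
                best_loss, best_pair = mean_loss, (lr_enc, lr_rest)
    if best_pair is None:
        raise RuntimeError("every grid point diverged")
    return best_pair


def run_experiment(dataset: Dataset, holdout: Dataset,
                   net_config: NetworkConfig, train_config: TrainConfig,
                   variant_name: str = "proposed",
                   callbacks: list | None = None,
                   ) -> dict:
    """Final protocol: re-run CV under the final seed, evaluate each fold's
    best checkpoint on the patient-disjoint holdout (base branch only), and
    report per-fold, mean and sd metrics plus the uncertainty strata.

    The holdout is only touched after every fold has finished training.
    """
    _assert_patient_disjoint(dataset.records, holdout.records,
                             "training data and holdout")
    fold_of = patient_wise_folds(dataset, train_config.n_folds,
                                 train_config.seed_final)
    trained: list[tuple[FoldResult, Variant]] = []
    for fold in range(train_config.n_folds):
        train, val = _cv_fold_records(dataset, fold_of, fold)
        trained.append(train_fold(train, val, net_config, train_config,
                                  variant_name,
                                  seed=train_config.seed_final + fold,
                                  fold_index=fold, callbacks=callbacks))
    # training complete: the holdout may now be read
    holdout_arrays = prepare_arrays(holdout.records, net_config)
    per_fold: list[MetricsRecord] = []
    per_fold_strat: list[StratifiedReport] = []
    for res, variant in trained:
        probs = variant.predict_proba(holdout_arrays["x"])
        y_score = probs[:, 1]
        y_pred = (probs.argmax(axis=1)).astype(int)
        per_fold.append(compute_metrics(holdout_arrays["y"], y_pred, y_score))
        per_fold_strat.append(stratified_evaluate(
            holdout_arrays["y"], y_pred, y_score, holdout_arrays["D"],
            bins=DEFAULT_BINS))
        for cb in callbacks or ():
            cb("holdout_eval", {"fold": res.fold_index})
    summary = {}
    from .evaluation import METRIC_NAMES
    for name in METRIC_NAMES:
        vals = np.array([getattr(m, name) for m in per_fold], dtype=float)
        summary[name] = (float(np.nanmean(vals)), float(np.nanstd(vals)))
    return {
        "fold_results": [res for res, _ in trained],
        "fold_metrics": per_fold,
        "fold_stratified": per_fold_strat,
        "summary": summary,
        "variants": [v for _, v in trained],
    }


def synthetic_benchmark(variants: tuple[str, ...],
                        seeds: tuple[int, ...] = (0, 1, 2),
                        n_patients: int = 100,
                        holdout_patients: int = 50,
                        max_epochs: int = 10,
                        lr_encoder: float = 1e-3,
                        lr_rest: float = 1e-3,
                        embedding_dim: int = 64) -> dict:
    """Desk-scale benchmark on generated data, averaged over seeds.

    For each seed a fresh ~600-image training cohort and ~300-image
    patient-disjoint holdout are generated at the default noise settings
    (32x32 images, a 14-reviewer panel, 2-4 reviews per image) and every
    requested variant runs the full cross-validated protocol.  Returns the
    per-variant clean-stratum ([0, 2)) and equivocal-stratum ([2, max])
    accuracies: mean over folds, then over seeds.
    """
    from .synthetic import SynthConfig, generate_split

    clean_acc = {v: [] for v in variants}
    equiv_acc = {v: [] for v in variants}
    for seed in seeds:
        synth = SynthConfig(n_patients=n_patients, seed=seed)
        train, _, holdout, _ = generate_split(synth,
                                              holdout_patients=holdout_patients)
        annotate_labels(train)
        annotate_labels(holdout)
        for variant in variants:
            net = NetworkConfig(encoder_kind="small_cnn",
                                embedding_dim=embedding_dim)
            tc = TrainConfig(lr_encoder=lr_encoder, lr_rest=lr_rest,
                             max_epochs=max_epochs, patience=max_epochs,
                             n_folds=3, seed_final=seed + 1)
            result = run_experiment(train, holdout, net, tc, variant)
            per_fold_clean = [s.records["clean"].accuracy
                              for s in result["fold_stratified"]]
            per_fold_equiv = [s.records["equivocal"].accuracy
                              for s in result["fold_stratified"]]
            clean_acc[variant].append(float(np.mean(per_fold_clean)))
            equiv_acc[variant].append(float(np.mean(per_fold_equiv)))
    return {
        "clean_accuracy": {v: float(np.mean(a)) for v, a in clean_acc.items()},
        "equivocal_accuracy": {v: float(np.mean(a))
                               for v, a in equiv_acc.items()},
        "per_seed_clean": clean_acc,
        "per_seed_equivocal": equiv_acc,
    }
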
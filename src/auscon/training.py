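"""Experimental pipelines: contrastive pretraining, linear evaluation,
end-to-end fine-tuning, and the flattened-spectrogram linear baseline.

Reference hyperparameters: batch size 16, learning rate 1e-5, L2 penalty
1e-6 for pretraining and 1e-2 for downstream heads, 5,000 epochs for linear
evaluation, 25 for fine-tuning, 500/1,000 for the heart/lung baselines, with
20 (at 10% labels) or 5 (at 100%) parallel replicate models feeding paired
comparison.  ``RunConfig.tiny()`` is a named desk-scale profile (small
encoder, fewer epochs, larger learning rate) used throughout the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import objectives
from .augment import MaskSpec, apply_scheme, calibrate_band_widths
from .evaluation import EvalResult, Splits, binarize_labels, bootstrap_ci
from .network import (Adam, Checkpoint, Encoder, EncoderConfig, LinearHead,
                      ProjectionHead, SSLEvaluator, bce_with_logits,
                      state_dict)
from .pair_sampling import SchemeConfig, batch_stream
from .signal_io import SpectrogramDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    batch_size: int = 16
    lr: float = 1e-5
    weight_decay_pretrain: float = 1e-6
    weight_decay_downstream: float = 1e-2
    epochs_pretrain: int = 100
    epochs_linear: int = 5000
    epochs_finetune: int = 25
    epochs_baseline: int = 1000   # 500 for heart data, 1000 for lung data
    label_fraction: float = 1.0
    n_parallel: int = 5           # 20 at the 10% label level, 5 at 100%
    temperature: float = objectives.DEFAULT_TEMPERATURE
    target_coverage: float = 0.5
    bootstrap_replicates: int = 1000
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.label_fraction <= 1:
            raise ValueError("label_fraction must lie in (0, 1]")
        for n in (self.batch_size, self.epochs_pretrain, self.epochs_linear,
                  self.epochs_finetune, self.epochs_baseline, self.n_parallel):
            if n < 1:
                raise ValueError("counts must be positive")

    @classmethod
    def tiny(cls, seed: int = 0, label_fraction: float = 1.0) -> "RunConfig":
        """Desk-scale profile: tiny encoder, short schedules, faster optimizer."""
        return cls(batch_size=8, lr=1e-3, epochs_pretrain=60, epochs_linear=300,
                   epochs_finetune=25, epochs_baseline=300,
                   label_fraction=label_fraction, n_parallel=5,
                   bootstrap_replicates=200,
                   encoder=EncoderConfig(architecture="small_cnn",
                                         embedding_dim=32, projection_dim=64),
                   seed=seed)


def _assert_split_hygiene(splits: Splits) -> None:
    """Test/validation/pre-train are mutually disjoint; fine-tune nests in
    pre-train (the fine-tune examples are drawn from the pre-train pool)."""
    test, val, pre = set(splits.test), set(splits.validation), set(splits.pretrain)
    assert not (test & val) and not (test & pre) and not (val & pre)
    assert set(splits.finetune) <= pre


def stratified_label_subset(labels: np.ndarray, indices: np.ndarray,
                            fraction: float, seed: int) -> np.ndarray:
    """Class-stratified, seeded subsample of ``indices`` (at least 1/class)."""
    if fraction >= 1.0:
        return np.asarray(indices)
    rng = np.random.default_rng(seed)
    indices = np.asarray(indices)
    y = np.asarray(labels)[indices]
    keep = []
    for cls in np.unique(y):
        cls_idx = indices[y == cls]
        k = max(int(round(fraction * len(cls_idx))), 1)
        keep.append(rng.choice(cls_idx, size=k, replace=False))
    out = np.concatenate(keep)
    rng.shuffle(out)
    return out


def _labels(dataset: SpectrogramDataset) -> np.ndarray:
    return binarize_labels(dataset.metadata["label"])


# ---------------------------------------------------------------------------
# Contrastive pretraining
# ---------------------------------------------------------------------------

def pretrain(dataset: SpectrogramDataset, scheme: SchemeConfig,
             cfg: RunConfig, splits: Splits | None = None) -> Checkpoint:
    """Train encoder + projection head with NT-Xent (or the supervised
    contrastive loss for the weak-label scheme) on the pre-train split."""
    if splits is not None:
        _assert_split_hygiene(splits)
        dataset = dataset.subset(splits.pretrain)
    rng = np.random.default_rng([cfg.seed, 11])
    encoder = Encoder(cfg.encoder, seed=cfg.seed)
    projection = ProjectionHead(cfg.encoder, seed=cfg.seed + 1)
    opt = Adam([encoder.net, projection.net], lr=cfg.lr,
               weight_decay=cfg.weight_decay_pretrain)

    view_fn = None
    if scheme.mode == "augmentation":
        mask = MaskSpec(target_coverage=cfg.target_coverage)
        if scheme.name in ("time_mask",):
            mask = calibrate_band_widths(mask, "time")
        elif scheme.name in ("freq_mask",):
            mask = calibrate_band_widths(mask, "freq")
        elif scheme.name in ("spec_mask", "spec_mask_split"):
            mask = calibrate_band_widths(mask, "spec")

        def view_fn(spec, r):
            return apply_scheme(scheme.name, spec, mask, r)

    n_patients = dataset.metadata["patient_id"].nunique()
    steps_per_epoch = max(n_patients // cfg.batch_size, 1)
    loss_curve = []
    for _ in range(cfg.epochs_pretrain):
        epoch_losses = []
        for batch in batch_stream(dataset, scheme, cfg.batch_size, rng,
                                  n_batches=steps_per_epoch, view_fn=view_fn):
            h = encoder.encode(batch.views, train=True)
            z = projection.project(h, train=True)
            pb = objectives.ProjectedBatch(
                z=z, positive_sets=batch.positive_sets,
                candidate_sets=batch.candidate_sets,
                temperature=cfg.temperature)
            loss, grad_z = objectives.batch_loss_and_grad(pb)
            opt.zero_grad()
            grad_h = projection.backward(grad_z)
            encoder.backward(grad_h)
            opt.step()
            epoch_losses.append(loss)
        loss_curve.append(float(np.mean(epoch_losses)))
    return Checkpoint(encoder_config=cfg.encoder,
                      encoder_state=state_dict(encoder),
                      projection_state=state_dict(projection),
                      seed=cfg.seed, scheme=scheme.name, loss_curve=loss_curve)


# ---------------------------------------------------------------------------
# Downstream heads
# ---------------------------------------------------------------------------

def _minibatches(n: int, batch_size: int, rng: np.random.Generator,
                 min_size: int = 1):
    order = rng.permutation(n)
    for s in range(0, n, batch_size):
        chunk = order[s:s + batch_size]
        if len(chunk) >= min_size:
            yield chunk


def linear_evaluate(checkpoint: Checkpoint, dataset: SpectrogramDataset,
                    splits: Splits, cfg: RunConfig) -> EvalResult:
    """Frozen-encoder linear probe on the fine-tune split, AUROC on test."""
    _assert_split_hygiene(splits)
    encoder = checkpoint.build_encoder()
    frozen_before = {k: v.copy() for k, v in state_dict(encoder).items()}
    y = _labels(dataset)
    train_idx = stratified_label_subset(y, splits.finetune, cfg.label_fraction,
                                        cfg.seed + 101)
    h_train = encoder.encode([dataset.spectrograms[i] for i in train_idx])
    h_test = encoder.encode([dataset.spectrograms[i] for i in splits.test])
    y_train = y[train_idx].astype(np.float64)

    head = LinearHead(cfg.encoder.embedding_dim, seed=cfg.seed + 5)
    opt = Adam([head.net], lr=cfg.lr, weight_decay=cfg.weight_decay_downstream)
    rng = np.random.default_rng([cfg.seed, 13])
    for _ in range(cfg.epochs_linear):
        for idx in _minibatches(len(train_idx), cfg.batch_size, rng):
            logits = head.logits(h_train[idx], train=True)
            _, grad = bce_with_logits(logits, y_train[idx])
            opt.zero_grad()
            head.backward(grad)
            opt.step()

    after = state_dict(encoder)
    assert all(np.array_equal(frozen_before[k], after[k]) for k in after), \
        "encoder weights changed during linear evaluation"
    scores = head.predict_proba(h_test)
    return bootstrap_ci(scores, y[splits.test],
                        replicates=cfg.bootstrap_replicates, seed=cfg.seed)


def fine_tune(checkpoint: Checkpoint | None, dataset: SpectrogramDataset,
              splits: Splits, cfg: RunConfig) -> EvalResult:
    """End-to-end training of encoder + two-layer SSL evaluator.

    ``checkpoint=None`` is the supervised comparator: an identical model from
    randomly initialized weights.
    """
    _assert_split_hygiene(splits)
    if checkpoint is not None:
        encoder = checkpoint.build_encoder()
    else:
        encoder = Encoder(cfg.encoder, seed=cfg.seed + 17)
    head = SSLEvaluator(cfg.encoder.embedding_dim, seed=cfg.seed + 7)
    opt = Adam([encoder.net, head.net], lr=cfg.lr,
               weight_decay=cfg.weight_decay_downstream)
    y = _labels(dataset)
    train_idx = stratified_label_subset(y, splits.finetune, cfg.label_fraction,
                                        cfg.seed + 101)
    train_specs = [dataset.spectrograms[i] for i in train_idx]
    y_train = y[train_idx].astype(np.float64)
    rng = np.random.default_rng([cfg.seed, 19])
    for epoch in range(cfg.epochs_finetune):
        epoch_losses = []
        # batch-norm needs >= 2 examples per training batch
        for idx in _minibatches(len(train_idx), cfg.batch_size, rng, min_size=2):
            h = encoder.encode([train_specs[i] for i in idx], train=True)
            logits = head.logits(h, train=True)
            loss, grad = bce_with_logits(logits, y_train[idx])
            opt.zero_grad()
            grad_h = head.backward(grad)
            encoder.backward(grad_h)
            opt.step()
            epoch_losses.append(loss)
        logger.info("fine-tune epoch %d loss %.4f", epoch, np.mean(epoch_losses))
    h_test = encoder.encode([dataset.spectrograms[i] for i in splits.test])
    scores = head.predict_proba(h_test)
    return bootstrap_ci(scores, y[splits.test],
                        replicates=cfg.bootstrap_replicates, seed=cfg.seed)


def _flatten_features(dataset: SpectrogramDataset,
                      indices: np.ndarray) -> np.ndarray:
    return np.stack([dataset.spectrograms[i].values.reshape(-1)
                     for i in indices])


def baseline_linear(dataset: SpectrogramDataset, splits: Splits,
                    cfg: RunConfig) -> EvalResult:
    """Logistic model on flattened standardized spectrograms.

    Features are scaled by the training set's global mean and standard
    deviation so the optimizer sees O(1) inputs.
    """
    _assert_split_hygiene(splits)
    y = _labels(dataset)
    train_idx = stratified_label_subset(y, splits.finetune, cfg.label_fraction,
                                        cfg.seed + 101)
    X_train = _flatten_features(dataset, train_idx)
    X_test = _flatten_features(dataset, splits.test)
    mu, sd = X_train.mean(), X_train.std() + 1e-9
    X_train = (X_train - mu) / sd
    X_test = (X_test - mu) / sd
    y_train = y[train_idx].astype(np.float64)

    head = LinearHead(X_train.shape[1], seed=cfg.seed + 9)
    opt = Adam([head.net], lr=cfg.lr, weight_decay=cfg.weight_decay_downstream)
    rng = np.random.default_rng([cfg.seed, 23])
    for _ in range(cfg.epochs_baseline):
        for idx in _minibatches(len(train_idx), cfg.batch_size, rng):
            logits = head.logits(X_train[idx], train=True)
            _, grad = bce_with_logits(logits, y_train[idx])
            opt.zero_grad()
            head.backward(grad)
            opt.step()
    scores = head.predict_proba(X_test)
    return bootstrap_ci(scores, y[splits.test],
                        replicates=cfg.bootstrap_replicates, seed=cfg.seed)


def run_replicates(pipeline, n_parallel: int, base_cfg: RunConfig, **kwargs
                   ) -> list[EvalResult]:
    """Independent replicate models with distinct seeds (the 'parallel'
    models whose per-replicate AUROCs feed the paired comparison)."""
    results = []
    for r in range(n_parallel):
        cfg = replace(base_cfg, seed=base_cfg.seed + 1000 * (r + 1))
        results.append(pipeline(cfg=cfg, **kwargs))
    return results
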
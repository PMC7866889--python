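"""Training loop, cross-validation and prediction.

The objective is mean two-class cross-entropy over shuffled mini-batches,
minimized with Adam.  Early stopping watches the loss on a stratified
validation slice carved from the training data.  All randomness — parameter
initialization, shuffling, dropout masks, splits — flows from a single seed,
so a run is exactly reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from . import metrics as metrics_mod
from .kmer import KmerVocabulary, build_vocabulary, encode_sequence
from .network import (
    ModelConfig,
    ModelParameters,
    backward_batch,
    forward_batch,
    init_parameters,
)
from .seqdata import Dataset, FoldSplit, holdout_split, stratified_kfold

logger = logging.getLogger(__name__)

_LOG_FLOOR = 1e-12


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    The published settings fix learning rate (0.001, or 0.005 for the mouse
    experiments), batch size 64, hidden width and dropout; epoch budget and
    stopping rule are this package's own defaults.
    """

    learning_rate: float = 0.001
    batch_size: int = 64
    max_epochs: int = 20
    patience: int = 5
    seed: int = 0
    validation_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.patience < 0 or self.patience > self.max_epochs:
            raise ValueError("patience must be in [0, max_epochs]")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in [0, 1)")


@dataclass
class TrainReport:
    """Per-epoch history of one training run."""

    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    val_accuracies: list[float] = field(default_factory=list)
    best_epoch: int = -1
    epochs_run: int = 0
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def configs_from_file(path) -> tuple[ModelConfig, TrainConfig]:
    """Load a YAML or JSON config with optional ``model:`` and ``train:``
    sections mirroring :class:`ModelConfig` and :class:`TrainConfig`.

    Missing sections or keys fall back to the defaults.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    return (
        ModelConfig(**(raw.get("model") or {})),
        TrainConfig(**(raw.get("train") or {})),
    )


def cross_entropy_loss(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-probability of the true class.

    Probabilities are clamped at 1e-12 before the log so a confidently wrong
    prediction yields a large finite loss, never NaN.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=np.int64)
    if probabilities.ndim != 2 or probabilities.shape[0] != labels.shape[0]:
        raise ValueError("probabilities must be (n, 2) aligned with labels")
    p_true = probabilities[np.arange(len(labels)), labels]
    return float(-np.log(np.clip(p_true, _LOG_FLOOR, None)).mean())


def encode_dataset(dataset: Dataset, vocab: KmerVocabulary) -> np.ndarray:
    """Token-id matrix (n_windows, T) for stride-1 k-mer tokenization."""
    return np.stack([encode_sequence(seq, vocab.k) for seq in dataset.sequences()])


class AdamOptimizer:
    """Adam with bias correction; one state slot per named parameter."""

    def __init__(self, params: ModelParameters, learning_rate: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.named_arrays().items()}
        self.v = {k: np.zeros_like(v) for k, v in params.named_arrays().items()}

    def step(self, params: ModelParameters, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        arrays = params.named_arrays()
        for name, g in grads.items():
            m = self.m[name] = self.beta1 * self.m[name] + (1 - self.beta1) * g
            v = self.v[name] = self.beta2 * self.v[name] + (1 - self.beta2) * g * g
            m_hat = m / (1 - self.beta1**self.t)
            v_hat = v / (1 - self.beta2**self.t)
            arrays[name] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _batched_probs(
    tokens: np.ndarray,
    params: ModelParameters,
    config: ModelConfig,
    batch_size: int = 256,
) -> np.ndarray:
    """Inference-mode class probabilities, (n, 2)."""
    chunks = [
        forward_batch(tokens[i : i + batch_size], params, config, training=False)["probs"]
        for i in range(0, len(tokens), batch_size)
    ]
    return np.concatenate(chunks, axis=0)


def fit(
    train: Dataset,
    model_config: ModelConfig,
    train_config: TrainConfig,
    vocab: KmerVocabulary | None = None,
) -> tuple[ModelParameters, TrainReport]:
    """Train the network on ``train`` and return the best parameters.

    A stratified ``validation_fraction`` slice is held out for early
    stopping: training stops after ``patience`` epochs without improvement in
    validation loss, and the parameters of the best epoch are returned.  With
    ``validation_fraction == 0`` the full set is used for training and the
    final epoch wins.  Raises FloatingPointError if the loss diverges.
    """
    if len(train) == 0 or train.n_positive == 0 or train.n_negative == 0:
        raise ValueError("training data must contain both classes")
    if vocab is None:
        vocab = build_vocabulary(model_config.k)
    if vocab.k != model_config.k:
        raise ValueError(f"vocabulary k={vocab.k} does not match model k={model_config.k}")

    rng = np.random.default_rng(train_config.seed)

    if train_config.validation_fraction > 0:
        split_seed = int(rng.integers(2**31))
        fit_part, val_part = holdout_split(
            train, train_config.validation_fraction, seed=split_seed
        )
    else:
        fit_part, val_part = train, None

    x_train = encode_dataset(fit_part, vocab)
    y_train = fit_part.labels()
    if val_part is not None:
        x_val = encode_dataset(val_part, vocab)
        y_val = val_part.labels()

    params = init_parameters(model_config, rng)
    optimizer = AdamOptimizer(params, train_config.learning_rate)
    report = TrainReport(seed=train_config.seed)

    best_params = params.copy()
    best_val = np.inf
    epochs_since_best = 0
    n = len(x_train)

    for epoch in range(train_config.max_epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, train_config.batch_size):
            idx = order[start : start + train_config.batch_size]
            cache = forward_batch(
                x_train[idx], params, model_config, training=True, rng=rng
            )
            loss = cross_entropy_loss(cache["probs"], y_train[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            grads = backward_batch(cache, y_train[idx], params, model_config)
            optimizer.step(params, grads)
            epoch_losses.append(loss)
        report.train_losses.append(float(np.mean(epoch_losses)))
        report.epochs_run = epoch + 1

        if val_part is not None:
            val_probs = _batched_probs(x_val, params, model_config)
            val_loss = cross_entropy_loss(val_probs, y_val)
            val_acc = float(((val_probs[:, 1] >= 0.5).astype(int) == y_val).mean())
            report.val_losses.append(val_loss)
            report.val_accuracies.append(val_acc)
            logger.info(
                "epoch %d: train loss %.4f, val loss %.4f, val acc %.4f",
                epoch, report.train_losses[-1], val_loss, val_acc,
            )
            if val_loss < best_val:
                best_val = val_loss
                best_params = params.copy()
                report.best_epoch = epoch
                epochs_since_best = 0
            else:
                epochs_since_best += 1
                if train_config.patience and epochs_since_best >= train_config.patience:
                    logger.info("early stopping at epoch %d", epoch)
                    break
        else:
            logger.info("epoch %d: train loss %.4f", epoch, report.train_losses[-1])
            best_params = params
            report.best_epoch = epoch

    best_params.check_finite()
    return best_params, report


def predict(
    params: ModelParameters,
    config: ModelConfig,
    dataset: Dataset,
    vocab: KmerVocabulary | None = None,
    batch_size: int = 256,
) -> np.ndarray:
    """Positive-class score in [0, 1] for every window, in dataset order.

    Deterministic (inference mode, no dropout); thresholding at 0.5 gives
    hard labels.
    """
    if vocab is None:
        vocab = build_vocabulary(config.k)
    if vocab.k != config.k:
        raise ValueError(f"vocabulary k={vocab.k} does not match model k={config.k}")
    if dataset.window_length < config.k:
        raise ValueError(
            f"window length {dataset.window_length} shorter than k={config.k}"
        )
    tokens = encode_dataset(dataset, vocab)
    return _batched_probs(tokens, params, config, batch_size)[:, 1]


@dataclass
class CVResult:
    """Per-fold metric reports plus their arithmetic mean."""

    fold_reports: list[metrics_mod.MetricsReport]
    fold_split: FoldSplit

    @property
    def mean(self) -> dict[str, float]:
        keys = ("sn", "sp", "acc", "mcc", "auc")
        return {
            k: float(np.mean([getattr(r, k) for r in self.fold_reports])) for k in keys
        }


def run_cv(
    dataset: Dataset,
    fold_count: int,
    model_config: ModelConfig,
    train_config: TrainConfig,
    seed: int | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation of the full train/predict pipeline.

    For each fold the model is trained from scratch on the remaining folds
    (the held-out fold's windows are never seen during that fit) and
    evaluated on the fold.
    """
    if fold_count < 2:
        raise ValueError("fold_count must be >= 2")
    seed = train_config.seed if seed is None else seed
    split = stratified_kfold(dataset, fold_count, seed=seed)
    vocab = build_vocabulary(model_config.k)
    reports = []
    for fold in range(fold_count):
        train_part = dataset.subset(split.train_indices(fold), name=f"fold{fold}_train")
        test_part = dataset.subset(split.fold_indices(fold), name=f"fold{fold}_test")
        fold_train_config = TrainConfig(
            **{**asdict(train_config), "seed": seed + fold}
        )
        try:
            params, _ = fit(train_part, model_config, fold_train_config, vocab)
            scores = predict(params, model_config, test_part, vocab)
        except Exception as exc:
            raise RuntimeError(f"cross-validation failed on fold {fold}: {exc}") from exc
        report = metrics_mod.evaluate(test_part.labels(), scores)
        logger.info("fold %d: %s", fold, report.tsv_row("6mA-Pred", dataset.name))
        reports.append(report)
    return CVResult(fold_reports=reports, fold_split=split)


def k_sweep(
    dataset: Dataset,
    k_values,
    fold_count: int,
    train_config: TrainConfig,
    model_config: ModelConfig | None = None,
) -> dict[int, dict[str, float]]:
    """Mean CV metrics for each candidate k; all other settings held fixed."""
    base = model_config or ModelConfig()
    results = {}
    for k in k_values:
        cfg = ModelConfig(
            k=int(k),
            embedding_dim=base.embedding_dim,
            hidden_dim=base.hidden_dim,
            dropout_rate=base.dropout_rate,
            bidirectional=base.bidirectional,
        )
        results[int(k)] = run_cv(dataset, fold_count, cfg, train_config).mean
    return results
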
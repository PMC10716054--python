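"""Supervised promoter models and their evaluation.

Four networks share one code path, differing only in task and size:

* **PromoS** — strong/weak classifier (ResNet + self-attention, sigmoid head)
* **PromoR** — real/fake classifier (same architecture)
* **PromoA** — activity regressor (same architecture, linear head)
* **PromoNet** — a small plain CNN regressor for constraint-designed sets

The shared architecture is a convolution+ReLU stem, a stack of residual
blocks (two convolutions each, identity skip), a single-head scaled
dot-product self-attention block over positions, stride-2 max pooling,
dropout, and a dense head over the flattened feature map.  All tasks are optimized against mean squared
error — for binary tasks the MSE is taken on the sigmoid output against
0/1 labels, with 0.5 as the decision threshold.

Evaluation follows the usual promoter-classification conventions:
sensitivity, specificity, accuracy, Matthews correlation coefficient and
AUROC for binary tasks; Pearson correlation and MSE for regression.
Classical baselines (elastic net, gradient boosted trees) are provided for
comparison via scikit-learn.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from ._autograd import (Adam, Parameter, Tensor, concat, conv1d, he_init,
                        max_pool1d, softmax)
from .features import (Encoding, FeatureMatrix, PseDNCParams,
                       one_hot_encode_dataset, psednc_dataset, concat_features)
from .seqdata import RealnessLabel, SequenceDataset, StrengthLabel

__all__ = [
    "NetConfig", "TrainedModel", "ConfusionCounts", "EvalReport",
    "residual_block", "self_attention", "build_network", "train_supervised",
    "predict", "cross_validate", "binary_metrics", "auroc", "pearson_cc",
    "hyperparameter_search", "baseline_ml", "encode_dataset",
    "extract_targets", "save_model", "load_model",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class NetConfig:
    """Architecture and training hyperparameters.

    The paper-style search ranges are learning_rate in [1e-4, 1] and
    batch_size in [4, 64]; the residual stack defaults to 20 blocks.
    """

    arch: str = "resnet_attention"          # or "simple_cnn"
    task: str = "binary"                    # or "regression"
    n_resblocks: int = 20
    channels: int = 16
    kernel_size: int = 3
    attention_key_dim: int | None = None    # defaults to channels
    dropout_rate: float = 0.3
    weight_decay: float = 0.0
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arch not in ("resnet_attention", "simple_cnn"):
            raise ValueError(f"unknown arch {self.arch!r}")
        if self.task not in ("binary", "regression"):
            raise ValueError(f"unknown task {self.task!r}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.attention_key_dim is None:
            self.attention_key_dim = self.channels


def classifier_config(task: str = "binary", seed: int = 0,
                      epochs: int = 20) -> NetConfig:
    """Practical ResNet+attention configuration for CPU-scale corpora.

    Uses a short residual stack (two blocks); the full-depth default
    (20 blocks) is available by constructing NetConfig directly.
    """
    return NetConfig(arch="resnet_attention", task=task, n_resblocks=2,
                     channels=8, epochs=epochs, learning_rate=3e-3,
                     batch_size=32, dropout_rate=0.1, seed=seed)


def promonet_config(seed: int = 0, epochs: int = 120) -> NetConfig:
    """PromoNet: a single-conv CNN regressor tuned for few-hundred-sample
    activity datasets (dropout + weight decay carry the regularization)."""
    return NetConfig(arch="simple_cnn", task="regression", kernel_size=3,
                     channels=16, epochs=epochs, learning_rate=3e-3,
                     batch_size=16, dropout_rate=0.3, weight_decay=0.1,
                     seed=seed)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Conv1d:
    def __init__(self, rng, c_in: int, c_out: int, kernel: int,
                 padding: int = 0, zero_init: bool = False):
        shape = (c_out, c_in, kernel)
        w = np.zeros(shape) if zero_init else he_init(rng, shape, c_in * kernel)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(c_out))
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, padding=self.padding)

    def params(self):
        return [self.weight, self.bias]


class _Dense:
    def __init__(self, rng, n_in: int, n_out: int, zero_init: bool = False):
        w = np.zeros((n_in, n_out)) if zero_init else he_init(rng, (n_in, n_out), n_in)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias

    def params(self):
        return [self.weight, self.bias]


class ResBlock1d:
    """Two convolution+ReLU layers with a skip connection.

    Output = F(x; Wi) + skip(x); when input and output channel counts
    differ a 1x1 convolution (Ws) reconciles them, otherwise the skip is
    the identity.
    """

    def __init__(self, rng, c_in: int, c_out: int, kernel: int = 3):
        pad = kernel // 2
        self.conv1 = _Conv1d(rng, c_in, c_out, kernel, padding=pad)
        # zero-init the second convolution so every block starts as the
        # identity map; deep stacks then train without normalization layers
        self.conv2 = _Conv1d(rng, c_out, c_out, kernel, padding=pad,
                             zero_init=True)
        self.proj = _Conv1d(rng, c_in, c_out, 1) if c_in != c_out else None

    def __call__(self, x: Tensor) -> Tensor:
        # residual branch: conv -> ReLU -> conv (the second activation is
        # deferred past the addition so the zero-initialized conv2 still
        # receives gradient through the sum)
        h = self.conv2(self.conv1(x).relu())
        skip = self.proj(x) if self.proj is not None else x
        return h + skip

    def params(self):
        ps = self.conv1.params() + self.conv2.params()
        if self.proj is not None:
            ps += self.proj.params()
        return ps


def residual_block(x, block: ResBlock1d):
    """Apply a residual block to a feature map (ndarray or Tensor)."""
    is_array = not isinstance(x, Tensor)
    t = Tensor(x) if is_array else x
    out = block(t)
    return out.data if is_array else out


def self_attention(q, k, v, d_k: int):
    """Scaled dot-product attention: softmax(QK^T / sqrt(d_k)) V.

    Accepts (positions x dim) arrays or Tensors, optionally batched on a
    leading axis.  Attention rows sum to one by construction.
    """
    if d_k <= 0:
        raise ValueError("d_k must be positive")
    arrays = not isinstance(q, Tensor)
    qt = Tensor(q) if arrays else q
    kt = Tensor(k) if arrays else k
    vt = Tensor(v) if arrays else v
    logits = (qt @ kt.transpose(*range(kt.ndim - 2), kt.ndim - 1, kt.ndim - 2)) \
        * (1.0 / math.sqrt(d_k))
    out = softmax(logits, axis=-1) @ vt
    return out.data if arrays else out


class SelfAttentionBlock:
    """Single-head self-attention over sequence positions with a residual
    connection (the residual keeps early training stable)."""

    def __init__(self, rng, channels: int, d_k: int):
        self.wq = _Dense(rng, channels, d_k)
        self.wk = _Dense(rng, channels, d_k)
        # zero-init the value projection: the block starts as the identity
        self.wv = _Dense(rng, channels, channels, zero_init=True)
        self.d_k = d_k

    def __call__(self, x: Tensor) -> Tensor:
        # x: (N, C, L) -> attend over positions -> (N, C, L)
        xt = x.transpose(0, 2, 1)
        att = self_attention(self.wq(xt), self.wk(xt), self.wv(xt), self.d_k)
        return (att + xt).transpose(0, 2, 1)

    def params(self):
        return self.wq.params() + self.wk.params() + self.wv.params()


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

class _Network:
    arch: str

    def __init__(self) -> None:
        self._layers: list = []

    def params(self) -> list[Parameter]:
        out: list[Parameter] = []
        for layer in self._layers:
            out.extend(layer.params())
        return out

    def forward(self, x: Tensor, *, train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        raise NotImplementedError


class ResNetAttentionNet(_Network):
    """Convolution stem -> residual stack -> self-attention -> max pool
    (stride 2) -> dropout -> dense head on the flattened feature map."""

    arch = "resnet_attention"

    def __init__(self, config: NetConfig, in_channels: int, length: int):
        super().__init__()
        rng = np.random.default_rng(config.seed)
        c = config.channels
        self.config = config
        self.in_channels = in_channels
        self.length = length
        self.stem = _Conv1d(rng, in_channels, c, config.kernel_size,
                            padding=config.kernel_size // 2)
        self.blocks = [ResBlock1d(rng, c, c, config.kernel_size)
                       for _ in range(config.n_resblocks)]
        self.attention = SelfAttentionBlock(rng, c, config.attention_key_dim)
        pooled = max(length // 2, 1)
        self.head = _Dense(rng, c * pooled, 1, zero_init=True)
        self._layers = [self.stem, *self.blocks, self.attention, self.head]

    def forward(self, x: Tensor, *, train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        h = self.stem(x).relu()
        for block in self.blocks:
            h = block(h)
        h = self.attention(h)
        if h.shape[2] >= 2:
            h = max_pool1d(h, kernel=2, stride=2)
        h = h.reshape(h.shape[0], h.shape[1] * h.shape[2])
        if train and self.config.dropout_rate > 0:
            keep = 1.0 - self.config.dropout_rate
            mask = (rng.random(h.shape) < keep) / keep
            h = h * Tensor(mask)
        out = self.head(h).reshape(-1)
        return out.sigmoid() if self.config.task == "binary" else out


class SimpleCNNNet(_Network):
    """PromoNet: one convolution+ReLU feature layer read out by a dense
    head on the full-resolution feature map.

    Promoter activity depends on base identities at specific offsets, so
    the head sees every position (no pooling); dropout plus weight decay
    control the head's capacity at the small sample sizes this model is
    meant for.
    """

    arch = "simple_cnn"

    def __init__(self, config: NetConfig, in_channels: int, length: int):
        super().__init__()
        rng = np.random.default_rng(config.seed)
        c = config.channels
        self.config = config
        self.in_channels = in_channels
        self.length = length
        self.conv = _Conv1d(rng, in_channels, c, config.kernel_size,
                            padding=config.kernel_size // 2)
        self.head = _Dense(rng, c * length, 1, zero_init=True)
        self._layers = [self.conv, self.head]

    def forward(self, x: Tensor, *, train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        h = self.conv(x).relu()
        h = h.reshape(h.shape[0], h.shape[1] * h.shape[2])
        if train and self.config.dropout_rate > 0:
            keep = 1.0 - self.config.dropout_rate
            mask = (rng.random(h.shape) < keep) / keep
            h = h * Tensor(mask)
        out = self.head(h).reshape(-1)
        return out.sigmoid() if self.config.task == "binary" else out


@dataclass
class TrainedModel:
    """An architecture config plus (possibly untrained) parameters and the
    per-epoch training-loss history."""

    config: NetConfig
    network: _Network
    history: list[float] = field(default_factory=list)
    # regression targets are standardized for optimization and mapped back
    # at prediction time
    target_mean: float = 0.0
    target_std: float = 1.0

    @property
    def n_resblocks_built(self) -> int:
        return len(getattr(self.network, "blocks", []))


def _shape_features(fm: FeatureMatrix) -> tuple[np.ndarray, int, int]:
    """Return (N, C, L) array plus (channels, length) for a feature batch.

    One-hot batches keep their positional structure as 4 channels x L
    positions; flat encodings (pseDNC, concatenations) become a single
    channel.
    """
    if fm.encoding is Encoding.ONEHOT:
        length = fm.sequence_length or fm.n_features // 4
        x = fm.values.reshape(fm.n_samples, length, 4).transpose(0, 2, 1)
        return x, 4, length
    return fm.values[:, None, :], 1, fm.n_features


def build_network(config: NetConfig, input_shape: tuple[int, int]) -> TrainedModel:
    """Instantiate an untrained model for (channels, length) input."""
    c_in, length = input_shape
    cls = ResNetAttentionNet if config.arch == "resnet_attention" else SimpleCNNNet
    return TrainedModel(config=config, network=cls(config, c_in, length))


# ---------------------------------------------------------------------------
# training / prediction
# ---------------------------------------------------------------------------

def train_supervised(model: TrainedModel, X: FeatureMatrix,
                     y: np.ndarray, config: NetConfig | None = None) -> TrainedModel:
    """Fit by minibatch Adam on mean squared error; mutates and returns
    ``model``.  Deterministic for a fixed config seed."""
    config = config or model.config
    x_all, c_in, length = _shape_features(X)
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("targets contain NaN")
    if len(y) != X.n_samples:
        raise ValueError(f"{X.n_samples} feature rows but {len(y)} targets")
    if config.task == "binary":
        classes = set(np.unique(y))
        if not classes <= {0.0, 1.0}:
            raise ValueError("binary task requires 0/1 labels")
        if len(classes) < 2:
            import warnings
            warnings.warn("binary training data contains a single class")
    if config.task == "regression":
        model.target_mean = float(y.mean())
        model.target_std = float(y.std()) or 1.0
        y = (y - model.target_mean) / model.target_std
    if config.epochs == 0:
        return model
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.network.params(), lr=config.learning_rate,
               weight_decay=config.weight_decay)
    n = len(y)
    bs = min(config.batch_size, n)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            xb = Tensor(x_all[idx])
            yb = Tensor(y[idx])
            pred = model.network.forward(xb, train=True, rng=rng)
            loss = ((pred - yb) ** 2).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        model.history.append(epoch_loss / n)
    return model


def predict(model: TrainedModel, X: FeatureMatrix,
            batch_size: int = 256) -> np.ndarray:
    """Score a feature batch; pure (no parameter mutation)."""
    x_all, c_in, length = _shape_features(X)
    net = model.network
    if c_in != net.in_channels or length != net.length:
        raise ValueError(
            f"feature layout ({c_in} ch x {length}) does not match the "
            f"training layout ({net.in_channels} ch x {net.length})"
        )
    outs = []
    for start in range(0, x_all.shape[0], batch_size):
        outs.append(net.forward(Tensor(x_all[start:start + batch_size])).data)
    scores = np.concatenate(outs)
    if model.config.task == "regression":
        scores = scores * model.target_std + model.target_mean
    return scores


def predict_sequences(model: TrainedModel, sequences: Sequence[str],
                      batch_size: int = 256) -> np.ndarray:
    """Convenience wrapper: one-hot encode raw sequences and score them."""
    from .seqdata import PromoterRecord
    ds = SequenceDataset.from_records(
        PromoterRecord(id=f"s{i}", sequence=s) for i, s in enumerate(sequences)
    )
    return predict(model, one_hot_encode_dataset(ds), batch_size=batch_size)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.TP + self.TN + self.FP + self.FN < 1:
            raise ValueError("confusion table must contain at least one sample")

    @staticmethod
    def from_labels(y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return ConfusionCounts(
            TP=int(((y_true == 1) & (y_pred == 1)).sum()),
            TN=int(((y_true == 0) & (y_pred == 0)).sum()),
            FP=int(((y_true == 0) & (y_pred == 1)).sum()),
            FN=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


def binary_metrics(counts: ConfusionCounts,
                   scores: np.ndarray | None = None,
                   labels: np.ndarray | None = None) -> dict[str, float | None]:
    """Sensitivity, specificity, accuracy and Matthews correlation from a
    confusion table; metrics with a zero denominator are reported as None
    (undefined), never coerced to 0.  AUROC is added when raw scores and
    labels are supplied."""
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    sn = tp / (tp + fn) if tp + fn else None
    sp = tn / (tn + fp) if tn + fp else None
    acc = (tp + tn) / (tp + tn + fp + fn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else None
    out: dict[str, float | None] = {"Sn": sn, "Sp": sp, "Acc": acc, "MCC": mcc}
    if scores is not None and labels is not None:
        out["AUROC"] = auroc(np.asarray(labels), np.asarray(scores))
    return out


def auroc(y_true: np.ndarray, scores: np.ndarray) -> float | None:
    """Area under the ROC curve via the rank (Mann-Whitney) identity;
    ties receive average ranks.  None if one class is absent."""
    y_true = np.asarray(y_true).astype(int)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores)
    return (ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def pearson_cc(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Pearson correlation coefficient; errors on constant input."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.size < 2:
        raise ValueError("inputs must be equal-length vectors of size >= 2")
    if np.ptp(predicted) == 0 or np.ptp(observed) == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    from scipy.stats import pearsonr
    return float(pearsonr(predicted, observed).statistic)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    per_fold: list[dict]
    means: dict[str, float]
    fold_seed: int

    def __getattr__(self, name: str):
        if name.startswith("mean_"):
            key = name[5:]
            if key in self.means:
                return self.means[key]
        raise AttributeError(name)


def extract_targets(dataset: SequenceDataset, task: str,
                    target: str = "auto", log_transform: bool = True) -> np.ndarray:
    """Pull the supervised target out of a labeled dataset.

    Binary: strength (strong=1/weak=0) or realness (real=1/fake=0);
    ``auto`` prefers whichever labeling is complete.  Regression: the
    activity, log1p-transformed by default to tame the heavy upper tail of
    measured promoter activities.
    """
    if task == "regression":
        y = dataset.activities()
        return np.log1p(y) if log_transform else y
    if target == "auto":
        if all(r.strength_label is not StrengthLabel.UNKNOWN for r in dataset):
            target = "strength"
        elif all(r.realness_label is not RealnessLabel.UNKNOWN for r in dataset):
            target = "realness"
        else:
            raise ValueError("dataset is not fully labeled for a binary task")
    if target == "strength":
        return np.array([1.0 if r.strength_label is StrengthLabel.STRONG else 0.0
                         for r in dataset])
    if target == "realness":
        return np.array([1.0 if r.realness_label is RealnessLabel.REAL else 0.0
                         for r in dataset])
    raise ValueError(f"unknown target {target!r}")


def _encode(dataset: SequenceDataset, encoding: Encoding | str,
            psednc_params: PseDNCParams | None = None) -> FeatureMatrix:
    encoding = Encoding(encoding)
    if encoding is Encoding.ONEHOT:
        return one_hot_encode_dataset(dataset)
    if encoding is Encoding.PSEDNC:
        return psednc_dataset(dataset, psednc_params)
    return concat_features(one_hot_encode_dataset(dataset),
                           psednc_dataset(dataset, psednc_params))


encode_dataset = _encode


def cross_validate(config: NetConfig, dataset: SequenceDataset, k: int,
                   seed: int = 0, encoding: Encoding | str = Encoding.ONEHOT,
                   target: str = "auto", log_transform: bool = True) -> EvalReport:
    """k-fold cross-validation: stratified folds for binary tasks, plain
    shuffled folds for regression; a fresh network per fold."""
    from sklearn.model_selection import KFold, StratifiedKFold

    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(dataset):
        raise ValueError(f"k={k} exceeds dataset size {len(dataset)}")
    X = _encode(dataset, encoding)
    y = extract_targets(dataset, config.task, target, log_transform)
    x_all, c_in, length = _shape_features(X)
    if config.task == "binary":
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(x_all, y)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(x_all)
    per_fold = []
    for fold_i, (tr, te) in enumerate(splits):
        fold_cfg = replace(config, seed=config.seed + fold_i)
        model = build_network(fold_cfg, (c_in, length))
        train_supervised(model,
                         FeatureMatrix(X.values[tr], X.encoding, X.sequence_length),
                         y[tr], fold_cfg)
        scores = predict(model, FeatureMatrix(X.values[te], X.encoding,
                                              X.sequence_length))
        if config.task == "binary":
            counts = ConfusionCounts.from_labels(y[te], scores > 0.5)
            metrics = binary_metrics(counts, scores=scores, labels=y[te])
        else:
            metrics = {
                "PCC": pearson_cc(scores, y[te]) if np.ptp(scores) > 0 else 0.0,
                "MSE": float(np.mean((scores - y[te]) ** 2)),
            }
        per_fold.append(metrics)
    keys = per_fold[0].keys()
    means = {key: float(np.mean([f[key] for f in per_fold if f[key] is not None]))
             for key in keys
             if any(f[key] is not None for f in per_fold)}
    return EvalReport(per_fold=per_fold, means=means, fold_seed=seed)


def hyperparameter_search(learning_rates: Sequence[float],
                          batch_sizes: Sequence[int],
                          base_config: NetConfig,
                          dataset: SequenceDataset, k: int, seed: int = 0,
                          encoding: Encoding | str = Encoding.ONEHOT,
                          ) -> tuple[NetConfig, list[dict]]:
    """Exhaustive grid over learning rate and batch size, scored by
    cross-validated mean accuracy (binary) or mean PCC (regression).
    Ties break toward the smaller learning rate, then smaller batch."""
    if not learning_rates or not batch_sizes:
        raise ValueError("empty hyperparameter grid")
    for lr in learning_rates:
        if not 1e-4 <= lr <= 1:
            raise ValueError(f"learning rate {lr} outside [1e-4, 1]")
    for bs in batch_sizes:
        if not 4 <= bs <= 64:
            raise ValueError(f"batch size {bs} outside [4, 64]")
    key = "Acc" if base_config.task == "binary" else "PCC"
    report = []
    for lr in sorted(learning_rates):
        for bs in sorted(batch_sizes):
            cfg = replace(base_config, learning_rate=lr, batch_size=bs)
            rep = cross_validate(cfg, dataset, k, seed=seed, encoding=encoding)
            report.append({"learning_rate": lr, "batch_size": bs,
                           "score": rep.means[key]})
    best = max(report, key=lambda r: (r["score"], -r["learning_rate"],
                                      -r["batch_size"]))
    best_cfg = replace(base_config, learning_rate=best["learning_rate"],
                       batch_size=best["batch_size"])
    return best_cfg, report


def baseline_ml(X: FeatureMatrix, y: np.ndarray, model_type: str,
                k: int = 5, seed: int = 0) -> float:
    """Classical regression baselines with a small internal grid; returns
    the k-fold mean Pearson correlation."""
    from sklearn.linear_model import ElasticNet
    from sklearn.ensemble import GradientBoostingRegressor
    from sklearn.model_selection import GridSearchCV, KFold

    y = np.asarray(y, dtype=float)
    if model_type == "elastic_net":
        est = ElasticNet(max_iter=10000, random_state=seed)
        grid = {"alpha": [1e-4, 1e-2, 1.0], "l1_ratio": [0.1, 0.5, 0.9]}
    elif model_type == "gradient_boosted_trees":
        est = GradientBoostingRegressor(random_state=seed)
        grid = {"n_estimators": [50, 200], "max_depth": [2, 3]}
    else:
        raise ValueError(f"unknown model_type {model_type!r}")
    outer = KFold(n_splits=k, shuffle=True, random_state=seed)
    pccs = []
    for tr, te in outer.split(X.values):
        inner = GridSearchCV(est, grid, cv=3, scoring="neg_mean_squared_error")
        inner.fit(X.values[tr], y[tr])
        pred = inner.predict(X.values[te])
        pccs.append(pearson_cc(pred, y[te]) if np.ptp(pred) > 0 else 0.0)
    return float(np.mean(pccs))


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Save config + weights + history in a single .npz container."""
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.network.params())}
    meta = {
        "format_version": _FORMAT_VERSION,
        "config": asdict(model.config),
        "history": model.history,
        "in_channels": model.network.in_channels,
        "length": model.network.length,
        "target_mean": model.target_mean,
        "target_std": model.target_std,
    }
    with open(path, "wb") as fh:
        np.savez(fh, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)


def load_model(path: str | Path) -> TrainedModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        if meta["format_version"] != _FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['format_version']}")
        config = NetConfig(**meta["config"])
        model = build_network(config, (meta["in_channels"], meta["length"]))
        params = model.network.params()
        for i, p in enumerate(params):
            p.data = data[f"param_{i}"].copy()
        model.history = list(meta["history"])
        model.target_mean = meta.get("target_mean", 0.0)
        model.target_std = meta.get("target_std", 1.0)
    return model
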
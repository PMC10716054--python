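"""PromoDiff: a denoising diffusion generator of 50-bp promoters.

Promoters are one-hot encoded, rescaled to [-1, 1], and treated as
continuous 4 x 50 arrays.  The forward process adds Gaussian noise over T
steps under a linear variance schedule; the closed-form marginal is
q(x_t | x_0) = N(sqrt(abar_t) x_0, (1 - abar_t) I).  A UNet is trained to
predict the injected noise (epsilon-prediction, squared error), and new
promoters are drawn by ancestral reverse sampling from pure noise followed
by per-position argmax decoding.

The UNet encoder combines residual convolution blocks and a self-attention
block at the downsampled bottleneck; the decoder recovers the full length
by nearest-neighbour upsampling.  Learned positional embeddings are added
at the stem so the model can express position-specific motif structure
(promoter elements live at fixed offsets), and the diffusion step t enters
through a sinusoidal embedding mapped onto the channel dimension.

Model selection follows the real-promoter-portion (RPP) criterion: sample
a batch from every training checkpoint, score it with a real/fake
classifier, and keep the epoch whose samples are most often called real.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from ._autograd import Adam, Parameter, Tensor, conv1d, he_init
from .features import one_hot_decode, one_hot_encode_dataset
from .seqdata import SequenceDataset
from .supervised import (SelfAttentionBlock, TrainedModel, _Conv1d, _Dense,
                         ResBlock1d, predict_sequences)

__all__ = [
    "DiffusionSchedule", "UNetConfig", "DiffusionModel", "GenerationBatch",
    "make_schedule", "forward_diffuse", "train_promodiff", "sample_promoters",
    "novelty_report", "rpp", "checkpoint_rpp_curve",
]


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiffusionSchedule:
    T: int
    beta: np.ndarray
    alpha: np.ndarray
    alpha_bar: np.ndarray


def make_schedule(T: int = 1000, beta_min: float = 1e-4,
                  beta_max: float = 0.02) -> DiffusionSchedule:
    """Linear variance schedule beta_1..beta_T with alpha_t = 1 - beta_t
    and abar_t the running product of alphas."""
    if T < 1:
        raise ValueError("T must be >= 1")
    if not 0 < beta_min <= beta_max < 1:
        raise ValueError("require 0 < beta_min <= beta_max < 1")
    beta = np.linspace(beta_min, beta_max, T)
    alpha = 1.0 - beta
    return DiffusionSchedule(T=T, beta=beta, alpha=alpha,
                             alpha_bar=np.cumprod(alpha))


def forward_diffuse(x0: np.ndarray, t: int, schedule: DiffusionSchedule,
                    seed: int | np.random.Generator = 0) -> np.ndarray:
    """Sample x_t ~ q(x_t | x_0) in closed form (t is 1-based)."""
    if not 1 <= t <= schedule.T:
        raise ValueError(f"t={t} outside [1, {schedule.T}]")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    abar = schedule.alpha_bar[t - 1]
    eps = rng.standard_normal(x0.shape)
    return math.sqrt(abar) * x0 + math.sqrt(1.0 - abar) * eps


def _encode_pm1(dataset: SequenceDataset) -> np.ndarray:
    """One-hot encode a fixed-length dataset and rescale to [-1, 1];
    returns (N, 4, L)."""
    fm = one_hot_encode_dataset(dataset)
    length = fm.sequence_length
    x = fm.values.reshape(fm.n_samples, length, 4).transpose(0, 2, 1)
    return 2.0 * x - 1.0


# ---------------------------------------------------------------------------
# UNet
# ---------------------------------------------------------------------------

@dataclass
class UNetConfig:
    channels: int = 16
    kernel_size: int = 3
    length: int = 50
    time_embed_dim: int = 16
    seed: int = 0


def _sinusoidal_embedding(t: np.ndarray, dim: int) -> np.ndarray:
    """Standard sinusoidal timestep embedding, shape (len(t), dim)."""
    half = dim // 2
    freqs = np.exp(-math.log(10000.0) * np.arange(half) / max(half - 1, 1))
    ang = t[:, None] * freqs[None, :]
    return np.concatenate([np.sin(ang), np.cos(ang)], axis=1)


def _upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour doubling of the length axis of (N, C, L)."""
    idx = np.repeat(np.arange(x.shape[2]), 2)
    return x[:, :, idx]


class UNet1d:
    """Encoder (resblock, stride-2 downsample, resblock, self-attention)
    and decoder (upsample, resblock, output convolution); the downsample
    and upsample factors compose to identity on the input length."""

    def __init__(self, config: UNetConfig):
        if config.length % 2:
            raise ValueError("UNet requires an even sequence length")
        rng = np.random.default_rng(config.seed)
        c, k = config.channels, config.kernel_size
        self.config = config
        self.stem = _Conv1d(rng, 4, c, k, padding=k // 2)
        self.pos_embed = Parameter(0.01 * rng.standard_normal((1, c, config.length)))
        self.time_dense = _Dense(rng, config.time_embed_dim, c)
        self.enc1 = ResBlock1d(rng, c, c, k)
        self.down = _Conv1d(rng, c, c, 2)               # stride-2 via manual stride
        self.enc2 = ResBlock1d(rng, c, c, k)
        self.attention = SelfAttentionBlock(rng, c, c)
        self.dec1 = ResBlock1d(rng, 2 * c, c, k)
        self.out = _Conv1d(rng, c, 4, k, padding=k // 2)

    def params(self) -> list[Parameter]:
        out = [self.pos_embed]
        for layer in (self.stem, self.time_dense, self.enc1, self.down,
                      self.enc2, self.attention, self.dec1, self.out):
            out.extend(layer.params())
        return out

    def forward(self, x: Tensor, t: np.ndarray) -> Tensor:
        temb = Tensor(_sinusoidal_embedding(t.astype(float),
                                            self.config.time_embed_dim))
        tchan = self.time_dense(temb)                   # (N, C)
        h = self.stem(x) + self.pos_embed + tchan.reshape(tchan.shape[0], -1, 1)
        h = h.relu()
        skip = self.enc1(h)                             # (N, C, L)
        h = conv1d(skip, self.down.weight, self.down.bias, stride=2)  # (N, C, L/2)
        h = self.enc2(h + tchan.reshape(tchan.shape[0], -1, 1))
        h = self.attention(h)
        h = _upsample2(h)                               # (N, C, L)
        from ._autograd import concat
        h = self.dec1(concat([h, skip], axis=1))
        return self.out(h)


@dataclass
class DiffusionModel:
    unet_config: UNetConfig
    schedule: DiffusionSchedule
    network: UNet1d
    history: list[float] = field(default_factory=list)
    checkpoints: dict[int, list[np.ndarray]] = field(default_factory=dict)

    def load_checkpoint(self, epoch: int) -> None:
        if epoch not in self.checkpoints:
            raise KeyError(f"no checkpoint for epoch {epoch} "
                           f"(have {sorted(self.checkpoints)})")
        for p, w in zip(self.network.params(), self.checkpoints[epoch]):
            p.data = w.copy()


@dataclass
class GenerationBatch:
    sequences: list[str]
    epoch: int | None = None
    rpp: float | None = None


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_promodiff(dataset: SequenceDataset, unet_config: UNetConfig | None = None,
                    schedule: DiffusionSchedule | None = None, epochs: int = 200,
                    seed: int = 0, batch_size: int = 128,
                    learning_rate: float = 1e-3,
                    checkpoint_every: int = 1) -> DiffusionModel:
    """Train the noise-prediction UNet on a fixed-length-50 promoter set.

    Each minibatch draws an independent step t per sample, noises the
    batch with the closed-form marginal, and minimises the squared error
    between injected and predicted noise.  A parameter snapshot is stored
    every ``checkpoint_every`` epochs.
    """
    unet_config = unet_config or UNetConfig(seed=seed)
    schedule = schedule or make_schedule()
    if dataset.fixed_length != unet_config.length:
        raise ValueError(
            f"dataset fixed_length {dataset.fixed_length} does not match "
            f"UNet length {unet_config.length}"
        )
    x_all = _encode_pm1(dataset)
    net = UNet1d(unet_config)
    model = DiffusionModel(unet_config=unet_config, schedule=schedule, network=net)
    rng = np.random.default_rng(seed)
    opt = Adam(net.params(), lr=learning_rate)
    n = x_all.shape[0]
    bs = min(batch_size, n)
    sqrt_ab = np.sqrt(schedule.alpha_bar)
    sqrt_1mab = np.sqrt(1.0 - schedule.alpha_bar)
    for epoch in range(1, epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            x0 = x_all[idx]
            t = rng.integers(1, schedule.T + 1, size=len(idx))
            eps = rng.standard_normal(x0.shape)
            xt = (sqrt_ab[t - 1][:, None, None] * x0
                  + sqrt_1mab[t - 1][:, None, None] * eps)
            pred = net.forward(Tensor(xt), t)
            loss = ((pred - Tensor(eps)) ** 2).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        model.history.append(epoch_loss / n)
        if epoch % checkpoint_every == 0 or epoch == epochs:
            model.checkpoints[epoch] = [p.data.copy() for p in net.params()]
    return model


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _reverse_sample(model: DiffusionModel, n: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Ancestral DDPM sampling through all T steps; returns (N, 4, L)."""
    sched = model.schedule
    length = model.unet_config.length
    x = rng.standard_normal((n, 4, length))
    for t in range(sched.T, 0, -1):
        beta = sched.beta[t - 1]
        alpha = sched.alpha[t - 1]
        abar = sched.alpha_bar[t - 1]
        eps_hat = model.network.forward(
            Tensor(x), np.full(n, t, dtype=float)).data
        mean = (x - beta / math.sqrt(1.0 - abar) * eps_hat) / math.sqrt(alpha)
        if t > 1:
            abar_prev = sched.alpha_bar[t - 2]
            var = beta * (1.0 - abar_prev) / (1.0 - abar)
            x = mean + math.sqrt(var) * rng.standard_normal(x.shape)
        else:
            x = mean
    return x


def sample_promoters(model: DiffusionModel, n: int, seed: int = 0,
                     epoch: int | None = None) -> GenerationBatch:
    """Generate ``n`` 50-bp promoters from a training checkpoint (default:
    the latest) by full reverse diffusion plus argmax decoding."""
    if epoch is not None:
        model.load_checkpoint(epoch)
    elif model.checkpoints:
        epoch = max(model.checkpoints)
        model.load_checkpoint(epoch)
    rng = np.random.default_rng(seed)
    x = _reverse_sample(model, n, rng)
    seqs = [one_hot_decode(x[i].T) for i in range(n)]
    return GenerationBatch(sequences=seqs, epoch=epoch)


def untrained_baseline(unet_config: UNetConfig | None = None,
                       schedule: DiffusionSchedule | None = None,
                       n: int = 200, seed: int = 0) -> GenerationBatch:
    """Sample from a freshly initialised (untrained) model — the null
    reference for motif-recovery comparisons."""
    unet_config = unet_config or UNetConfig()
    schedule = schedule or make_schedule()
    model = DiffusionModel(unet_config=unet_config, schedule=schedule,
                           network=UNet1d(unet_config))
    return sample_promoters(model, n, seed=seed)


# ---------------------------------------------------------------------------
# generation QC
# ---------------------------------------------------------------------------

def novelty_report(batch: GenerationBatch,
                   training: SequenceDataset) -> dict[str, int]:
    """Exact-duplicate counts within the batch and against training data.

    Within-batch duplicates count every copy beyond the first occurrence.
    """
    train_set = set(training.sequences())
    seen: set[str] = set()
    within = 0
    for s in batch.sequences:
        if s in seen:
            within += 1
        seen.add(s)
    cross = sum(1 for s in batch.sequences if s in train_set)
    return {"n_sequences": len(batch.sequences),
            "within_batch_duplicates": within,
            "cross_duplicates": cross}


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_diffusion_model(model: DiffusionModel, path) -> None:
    """Single-file .npz container: UNet config, schedule, current weights
    and all epoch checkpoints."""
    import json
    from dataclasses import asdict

    arrays = {f"param_{i}": p.data for i, p in enumerate(model.network.params())}
    for epoch, weights in model.checkpoints.items():
        for i, w in enumerate(weights):
            arrays[f"ckpt_{epoch}_{i}"] = w
    meta = {
        "format_version": 1,
        "unet_config": asdict(model.unet_config),
        "history": model.history,
        "epochs": sorted(model.checkpoints),
        "T": model.schedule.T,
        "beta_min": float(model.schedule.beta[0]),
        "beta_max": float(model.schedule.beta[-1]),
    }
    with open(path, "wb") as fh:
        np.savez(fh, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)


def load_diffusion_model(path) -> DiffusionModel:
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        config = UNetConfig(**meta["unet_config"])
        schedule = make_schedule(meta["T"], meta["beta_min"], meta["beta_max"])
        net = UNet1d(config)
        params = net.params()
        for i, p in enumerate(params):
            p.data = data[f"param_{i}"].copy()
        checkpoints = {
            epoch: [data[f"ckpt_{epoch}_{i}"].copy() for i in range(len(params))]
            for epoch in meta["epochs"]
        }
    return DiffusionModel(unet_config=config, schedule=schedule, network=net,
                          history=list(meta["history"]), checkpoints=checkpoints)


ScoreFn = Callable[[Sequence[str]], np.ndarray]


def _score(promor, sequences: Sequence[str]) -> np.ndarray:
    if isinstance(promor, TrainedModel):
        return predict_sequences(promor, sequences)
    return np.asarray(promor(sequences), dtype=float)


def rpp(batch: GenerationBatch, promor, threshold: float = 0.5) -> float:
    """Real-promoter portion: fraction of generated sequences the
    real/fake classifier scores above ``threshold``."""
    if not batch.sequences:
        raise ValueError("empty generation batch")
    scores = _score(promor, batch.sequences)
    return float(np.mean(scores > threshold))


def checkpoint_rpp_curve(model: DiffusionModel, promor, n_per_epoch: int = 100,
                         seed: int = 0, threshold: float = 0.5,
                         ) -> tuple[dict[int, float], int]:
    """RPP of a fresh sample batch at every stored checkpoint; returns the
    epoch->RPP mapping and the argmax epoch (first epoch on ties)."""
    if not model.checkpoints:
        raise ValueError("model has no checkpoints")
    curve: dict[int, float] = {}
    for i, epoch in enumerate(sorted(model.checkpoints)):
        batch = sample_promoters(model, n_per_epoch, seed=seed + i, epoch=epoch)
        curve[epoch] = rpp(batch, promor, threshold)
    best = max(sorted(curve), key=lambda e: curve[e])
    return curve, best
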
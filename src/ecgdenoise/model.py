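"""The redundant convolutional encoder-decoder (R-CED) and its training recipe.

The network maps a context of 8 consecutive normalized STFT magnitude
spectra (8 channels x 129 frequency bins) to a single denoised frame
(129 bins).  It is fully convolutional along frequency: 16 convolution
blocks, the first 15 each followed by batch normalization and ReLU, the
last a bare convolution producing one output channel.  There is no pooling
or upsampling; "same" padding preserves the 129-bin dimension, and the
filter-count schedule rises and falls symmetrically (the redundancy that
gives the architecture its name).

Training follows stochastic gradient descent with momentum, mini-batches
of 128, 12 epochs, and a learning rate multiplied by 0.95 after every
epoch, minimizing mean squared error on normalized magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .nn import BatchNorm1d, Conv1d, Network, ReLU, SGDMomentum

DEFAULT_FILTER_COUNTS = (12, 16, 20, 24, 32, 24, 20, 16, 12, 16, 20, 24, 32, 24, 20, 1)
DEFAULT_KERNEL_WIDTHS = (13, 11, 9, 7, 7, 7, 9, 11, 13, 11, 9, 7, 7, 9, 11, 129)


@dataclass(frozen=True)
class RCEDConfig:
    """Architecture schedule; defaults follow the symmetric increase-then-
    decrease filter pattern of the encoder-decoder family, ending in a single
    output channel."""

    n_blocks: int = 16
    filter_counts: tuple[int, ...] = DEFAULT_FILTER_COUNTS
    kernel_widths: tuple[int, ...] = DEFAULT_KERNEL_WIDTHS
    n_bins: int = 129
    context_k: int = 8

    def __post_init__(self) -> None:
        if len(self.filter_counts) != self.n_blocks:
            raise ParameterError("filter_counts length must equal n_blocks")
        if len(self.kernel_widths) != self.n_blocks:
            raise ParameterError("kernel_widths length must equal n_blocks")
        if self.filter_counts[-1] != 1:
            raise ParameterError("final block must produce exactly 1 output channel")
        if any(c < 1 for c in self.filter_counts) or any(k < 1 for k in self.kernel_widths):
            raise ParameterError("filter counts and kernel widths must be >= 1")

    def parameter_count(self) -> int:
        """Closed-form parameter count of the schedule (conv + batch-norm)."""
        total = 0
        c_in = self.context_k
        for i, (c_out, k) in enumerate(zip(self.filter_counts, self.kernel_widths)):
            total += c_out * c_in * k + c_out  # conv weight + bias
            if i < self.n_blocks - 1:
                total += 2 * c_out  # batch-norm gamma + beta
            c_in = c_out
        return total


@dataclass(frozen=True)
class TrainConfig:
    """The training recipe: SGDM, batch 128, 12 epochs, lr x0.95 per epoch."""

    lr0: float = 0.01
    momentum: float = 0.9
    lr_decay_per_epoch: float = 0.95
    batch_size: int = 128
    epochs: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ParameterError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")
        if not 0 < self.lr_decay_per_epoch <= 1:
            raise ParameterError("lr_decay_per_epoch must lie in (0, 1]")

    def lr_at_epoch(self, epoch: int) -> float:
        """Learning rate during epoch ``epoch`` (1-based): lr0 * decay^(epoch-1)."""
        return self.lr0 * self.lr_decay_per_epoch ** (epoch - 1)


@dataclass
class TrainedModel:
    """Weights plus the configuration and per-epoch loss history."""

    network: Network
    rced_config: RCEDConfig
    history: list[float] = field(default_factory=list)


def build_rced(cfg: RCEDConfig | None = None, seed: int = 0) -> Network:
    """Instantiate an untrained R-CED with seeded uniform fan-in init."""
    cfg = cfg or RCEDConfig()
    rng = np.random.default_rng(seed)
    layers: list = []
    c_in = cfg.context_k
    for i, (c_out, k) in enumerate(zip(cfg.filter_counts, cfg.kernel_widths)):
        layers.append(Conv1d(c_in, c_out, k, rng))
        if i < cfg.n_blocks - 1:
            layers.append(BatchNorm1d(c_out))
            layers.append(ReLU())
        c_in = c_out
    return Network(layers)


def _as_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def train_rced(
    network: Network,
    predictors: np.ndarray,
    targets: np.ndarray,
    tc: TrainConfig,
    rced_config: RCEDConfig | None = None,
) -> TrainedModel:
    """Train on aligned (noisy context stack, clean frame) pairs.

    ``predictors``: (n, k, n_bins) normalized noisy magnitude stacks;
    ``targets``: (n, n_bins) normalized clean magnitude frames.  Returns the
    model with one mean training loss per epoch.  Reproducible per seed
    (shuffling is the only stochastic element after initialization).
    """
    predictors = np.asarray(predictors, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if predictors.ndim != 3 or targets.ndim != 2:
        raise ParameterError("predictors must be (n, k, bins); targets (n, bins)")
    if len(predictors) == 0:
        raise ParameterError("empty training set")
    if len(predictors) != len(targets):
        raise ParameterError(
            f"predictor/target mismatch: {len(predictors)} vs {len(targets)}"
        )
    cfg = rced_config or RCEDConfig()
    rng = np.random.default_rng(tc.seed)
    optimizer = SGDMomentum(network, tc.lr0, tc.momentum)
    history: list[float] = []
    for epoch in range(1, tc.epochs + 1):
        optimizer.lr = tc.lr_at_epoch(epoch)
        losses, weights = [], []
        for batch in _as_batches(len(predictors), tc.batch_size, rng):
            x = predictors[batch]
            y = targets[batch]
            pred = network.forward(x, training=True)[:, 0, :]
            err = pred - y
            loss = float(np.mean(err * err))
            grad = (2.0 / err.size) * err
            network.backward(grad[:, None, :])
            optimizer.step()
            losses.append(loss)
            weights.append(len(batch))
        history.append(float(np.average(losses, weights=weights)))
    return TrainedModel(network=network, rced_config=cfg, history=history)


def predict(model: TrainedModel | Network, stacks: np.ndarray) -> np.ndarray:
    """Denoised normalized magnitude frames for a batch of context stacks.

    ``stacks``: (n, k, n_bins) or a single (k, n_bins) stack.  Inference is
    deterministic (batch-norm uses running statistics).
    """
    network = model.network if isinstance(model, TrainedModel) else model
    stacks = np.asarray(stacks, dtype=float)
    single = stacks.ndim == 2
    if single:
        stacks = stacks[None]
    first_conv = network.layers[0]
    if stacks.shape[1] != first_conv.in_channels:
        raise ParameterError(
            f"stack context {stacks.shape[1]} does not match model input "
            f"channels {first_conv.in_channels}"
        )
    out = network.forward(stacks, training=False)[:, 0, :]
    return out[0] if single else out
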
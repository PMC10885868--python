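"""Two-branch privileged-information network with a rank-consistent head.

The base branch is an image encoder phi followed by a linear predictor xi
producing the 2-class logits used at inference.  The privileged branch embeds
the encoded annotation vector x* through phi_p (linear 64 -> batch norm ->
ReLU), concatenates the result with the image embedding z, and feeds a
predictor delta (two 128-unit layers with batch norm + ReLU) whose final layer
emits either K-1 rank logits for the CORN ordinal head or 2 logits for a
plain binary privileged target.  A stop-gradient on z before xi ensures the
encoder is updated only through the privileged branch (the transfer-and-
marginalize mechanism): privileged knowledge is distilled into phi during
training, and at inference the privileged branch is dropped entirely.

Training minimizes ``L = CE(xi(sg(z)), y) + beta * L2`` where L2 is the CORN
loss against the rounded mean score (or cross-entropy against y for the
non-ordinal variant) and beta defaults to 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .encoding import GateConfig, encoding_length
from .nn import (Adam, BatchNorm1d, BatchNorm2d, Conv2d, GlobalAvgPool,
                 Linear, MaxPool2d, Module, ReLU, Sequential, Tensor,
                 cross_entropy)

__all__ = [
    "NetworkConfig",
    "BranchOutputs",
    "SmallCNN",
    "ResNet50Backbone",
    "build_encoder",
    "TramNetwork",
    "corn_loss",
    "corn_predict",
    "total_loss",
]


@dataclass
class NetworkConfig:
    """Architecture and loss hyperparameters.

    ``embedding_dim`` is 2048 for the ResNet-50 path and small (default 64)
    for the desk-scale convolutional test encoder.  ``beta`` weights the
    privileged-branch loss; the two learning rates live in the training
    configuration as ``lr_encoder`` / ``lr_rest``.
    """

    encoder_kind: str = "small_cnn"          # {"small_cnn", "resnet50"}
    embedding_dim: int = 64                  # 2048 for resnet50
    privileged_hidden: int = 64
    predictor_hidden: int = 128
    num_classes: int = 2
    num_ranks: int = 8                       # K, the score alphabet size
    beta: float = 0.5
    encoding_method: str = "score"
    panel_size: int = 14
    gate: GateConfig = field(default_factory=GateConfig)
    privileged_head: str = "corn"            # {"corn", "binary"}

    def __post_init__(self):
        if self.num_ranks < 2:
            raise ValueError("num_ranks must be >= 2")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.embedding_dim <= 0:
            raise ValueError("embedding_dim must be positive")
        if self.encoder_kind == "resnet50":
            self.embedding_dim = 2048

    @property
    def privileged_input_dim(self) -> int:
        return encoding_length(self.encoding_method, self.panel_size)

    @property
    def privileged_out_dim(self) -> int:
        return (self.num_ranks - 1 if self.privileged_head == "corn"
                else self.num_classes)


@dataclass
class BranchOutputs:
    base_logits: np.ndarray
    embedding: np.ndarray
    rank_logits: np.ndarray | None = None
    privileged_embedding: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Encoders
# ---------------------------------------------------------------------------

class SmallCNN(Module):
    """3-block strided convolutional encoder for desk-scale images.

    Each block halves the spatial resolution (stride-2 3x3 convolution,
    batch norm, ReLU); a global average pool and linear layer produce the
    embedding.  Stands on the same pluggable contract as the 2048-dim
    pretrained path, so either encoder can back the two-branch network.
    """

    def __init__(self, rng: np.random.Generator, embedding_dim: int = 64,
                 channels: tuple[int, int, int] = (8, 16, 32)):
        super().__init__()
        c1, c2, c3 = channels
        self.blocks = Sequential(
            Conv2d(1, c1, 3, rng, stride=2, padding=1), BatchNorm2d(c1), ReLU(),
            Conv2d(c1, c2, 3, rng, stride=2, padding=1), BatchNorm2d(c2), ReLU(),
            Conv2d(c2, c3, 3, rng, stride=2, padding=1), BatchNorm2d(c3), ReLU(),
        )
        self.pool = GlobalAvgPool()
        self.proj = Linear(c3, embedding_dim, rng)
        self.embedding_dim = embedding_dim

    def forward(self, x: Tensor) -> Tensor:
        return self.proj(self.pool(self.blocks(x)))


class _Bottleneck(Module):
    expansion = 4

    def __init__(self, rng, in_ch: int, width: int, stride: int = 1):
        super().__init__()
        out_ch = width * self.expansion
        self.conv1 = Conv2d(in_ch, width, 1, rng, bias=False)
        self.bn1 = BatchNorm2d(width)
        self.conv2 = Conv2d(width, width, 3, rng, stride=stride, padding=1,
                            bias=False)
        self.bn2 = BatchNorm2d(width)
        self.conv3 = Conv2d(width, out_ch, 1, rng, bias=False)
        self.bn3 = BatchNorm2d(out_ch)
        self.downsample = None
        if stride != 1 or in_ch != out_ch:
            self.downsample = Sequential(
                Conv2d(in_ch, out_ch, 1, rng, stride=stride, bias=False),
                BatchNorm2d(out_ch))

    def forward(self, x: Tensor) -> Tensor:
        identity = x if self.downsample is None else self.downsample(x)
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        return (out + identity).relu()


class ResNet50Backbone(Module):
    """ResNet-50 with the classification layer removed (2048-dim embedding).

    Single-channel input as used by chest-radiograph encoders; weights are
    randomly initialized here and the pretrained path is a drop-in via
    :meth:`Module.load_state_dict`.
    """

    def __init__(self, rng: np.random.Generator, in_channels: int = 1):
        super().__init__()
        self.stem = Sequential(
            Conv2d(in_channels, 64, 7, rng, stride=2, padding=3, bias=False),
            BatchNorm2d(64), ReLU(), MaxPool2d(3, 2, padding=1))
        widths = (64, 128, 256, 512)
        depths = (3, 4, 6, 3)
        layers = []
        in_ch = 64
        for i, (width, depth) in enumerate(zip(widths, depths)):
            stride = 1 if i == 0 else 2
            for b in range(depth):
                layers.append(_Bottleneck(rng, in_ch, width,
                                          stride=stride if b == 0 else 1))
                in_ch = width * _Bottleneck.expansion
        self.layers = layers
        self.pool = GlobalAvgPool()
        self.embedding_dim = in_ch  # 2048

    def forward(self, x: Tensor) -> Tensor:
        x = self.stem(x)
        for layer in self.layers:
            x = layer(x)
        return self.pool(x)


def build_encoder(config: NetworkConfig, rng: np.random.Generator) -> Module:
    if config.encoder_kind == "small_cnn":
        return SmallCNN(rng, embedding_dim=config.embedding_dim)
    if config.encoder_kind == "resnet50":
        return ResNet50Backbone(rng)
    raise ValueError(f"unknown encoder_kind {config.encoder_kind!r}")


# ---------------------------------------------------------------------------
# CORN ordinal head
# ---------------------------------------------------------------------------

def corn_loss(rank_logits: Tensor, targets: np.ndarray) -> Tensor:
    """Conditional rank-consistent ordinal loss over K-1 binary tasks.

    Task j (1-based) trains on the conditional subset of examples with
    target > j - 1; its binary label is 1[target > j] with probability
    sigmoid(f_j).  The negative log-likelihood is summed over every
    contributing (task, example) term and divided by the number of terms;
    tasks with empty subsets contribute nothing.
    """
    targets = np.asarray(targets, dtype=int)
    if targets.size == 0:
        raise ValueError("corn_loss requires a non-empty batch")
    n, km1 = rank_logits.shape
    K = km1 + 1
    if targets.min() < 1 or targets.max() > K:
        raise ValueError(f"ordinal targets must be in 1..{K}, got range "
                         f"[{targets.min()}, {targets.max()}]")
    # log sigmoid(f) = -softplus(-f); log(1 - sigmoid(f)) = -softplus(f)
    log_sig = -(-rank_logits).softplus()
    log_one_minus = -rank_logits.softplus()
    tasks = np.arange(1, K)                       # shape (K-1,)
    in_subset = (targets[:, None] > tasks - 1).astype(float)
    label = (targets[:, None] > tasks).astype(float)
    total_terms = in_subset.sum()
    if total_terms == 0:
        raise ValueError("no contributing terms in corn_loss")
    mask = nn.constant(in_subset)
    lab = nn.constant(label)
    nll = -(mask * (lab * log_sig + (nn.constant(1.0) - lab) * log_one_minus))
    return nll.sum() * (1.0 / total_terms)


def corn_predict(rank_logits: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ranks and exceedance probabilities from rank logits.

    ``exceed_probs[:, j] = prod_{i<=j} sigmoid(f_i)`` estimates the
    unconditional P(target > j); it is non-increasing in j by construction,
    and the predicted rank is ``1 + #{j : exceed_probs[:, j] > 0.5}``.
    """
    rank_logits = np.atleast_2d(np.asarray(rank_logits, dtype=float))
    sig = 1.0 / (1.0 + np.exp(-rank_logits))
    exceed = np.cumprod(sig, axis=1)
    ranks = 1 + (exceed > 0.5).sum(axis=1)
    return ranks.astype(int), exceed


# ---------------------------------------------------------------------------
# The two-branch network
# ---------------------------------------------------------------------------

class TramNetwork(Module):
    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.encoder = build_encoder(config, rng)
        self.base_predictor = Linear(config.embedding_dim, config.num_classes,
                                     rng)
        self.privileged_encoder = Sequential(
            Linear(config.privileged_input_dim, config.privileged_hidden, rng),
            BatchNorm1d(config.privileged_hidden), ReLU())
        h = config.predictor_hidden
        self.privileged_predictor = Sequential(
            Linear(config.privileged_hidden + config.embedding_dim, h, rng),
            BatchNorm1d(h), ReLU(),
            Linear(h, h, rng), BatchNorm1d(h), ReLU(),
            Linear(h, config.privileged_out_dim, rng))

    # parameter groups for the two-learning-rate optimizer
    def encoder_parameters(self):
        return self.encoder.parameters()

    def rest_parameters(self):
        return (self.base_predictor.parameters()
                + self.privileged_encoder.parameters()
                + self.privileged_predictor.parameters())

    def forward_tensors(self, x: Tensor, x_star: Tensor | None,
                        mode: str = "train") -> dict[str, Tensor]:
        """Graph-level forward; ``base_logits`` always sees sg(z)."""
        z = self.encoder(x)
        base_logits = self.base_predictor(z.detach())
        out = {"z": z, "base_logits": base_logits}
        if mode == "train":
            if x_star is None:
                raise ValueError("train mode requires the privileged vector")
            if x_star.shape[1] != self.config.privileged_input_dim:
                raise ValueError(
                    f"privileged vector length {x_star.shape[1]} does not "
                    f"match encoding {self.config.encoding_method!r} "
                    f"(expected {self.config.privileged_input_dim})")
            z_star = self.privileged_encoder(x_star)
            rank_logits = self.privileged_predictor(nn.concat([z_star, z]))
            out.update({"z_star": z_star, "rank_logits": rank_logits})
        return out

    def forward(self, x: np.ndarray, x_star: np.ndarray | None = None,
                mode: str = "infer") -> BranchOutputs:
        """Numpy-level forward returning :class:`BranchOutputs`.

        In ``infer`` mode only the base branch runs and ``x_star`` is
        ignored entirely.
        """
        if mode not in ("train", "infer"):
            raise ValueError(f"mode must be 'train' or 'infer', got {mode!r}")
        xt = Tensor(np.asarray(x, dtype=float))
        xs = None
        if mode == "train":
            xs = Tensor(np.atleast_2d(np.asarray(x_star, dtype=float)))
        outs = self.forward_tensors(xt, xs, mode=mode)
        return BranchOutputs(
            base_logits=outs["base_logits"].data,
            embedding=outs["z"].data,
            rank_logits=(outs["rank_logits"].data if mode == "train" else None),
            privileged_embedding=(outs["z_star"].data if mode == "train"
                                  else None))

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Class probabilities from the base branch (evaluation mode)."""
        was_training = self.training
        self.eval()
        probs = []
        for lo in range(0, x.shape[0], batch_size):
            out = self.forward(x[lo:lo + batch_size], mode="infer")
            probs.append(nn.softmax(out.base_logits, axis=1))
        if was_training:
            self.train()
        return np.concatenate(probs, axis=0)


def total_loss(base_logits: Tensor, y: np.ndarray, rank_logits: Tensor,
               privileged_targets: np.ndarray, beta: float,
               privileged_head: str = "corn") -> Tensor:
    """``L = CE(base_logits, y) + beta * L2`` on one batch.

    L2 is the CORN loss against rounded mean scores for the ordinal head or
    plain cross-entropy against y for the binary privileged head.  With
    ``beta = 0`` the privileged term is skipped entirely.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    l1 = cross_entropy(base_logits, y)
    if beta == 0:
        return l1
    if privileged_head == "corn":
        l2 = corn_loss(rank_logits, privileged_targets)
    else:
        l2 = cross_entropy(rank_logits, privileged_targets)
    return l1 + beta * l2
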
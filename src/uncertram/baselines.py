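"""Comparison models and the variant registry.

Seven training variants share the evaluation contract (base-branch class
probabilities at inference against mean-aggregated labels):

* ``linear_probe`` — frozen encoder, linear 2-class head, cross-entropy;
* ``fine_tune`` — same head with a trainable encoder;
* ``confusion`` — linear-probe architecture plus one trainable 2x2
  column-stochastic confusion matrix per annotator; each observing
  annotator's binarized score is predicted as P^(t) @ p with a trace
  regularizer encouraging identifiability;
* ``tram`` — two-branch network, privileged vector always supplied, binary
  privileged head;
* ``tram_thresh`` — tram plus the uncertainty gate;
* ``tram_ord`` — tram with the CORN ordinal privileged head, no gate;
* ``proposed`` — gate plus CORN head (the full method).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .network import NetworkConfig, TramNetwork, cross_entropy, total_loss
from .nn import Linear, Module, Parameter, Tensor

__all__ = [
    "VARIANT_NAMES",
    "ConfusionModelConfig",
    "EncoderClassifier",
    "Variant",
    "build_variant",
]

VARIANT_NAMES = ("linear_probe", "fine_tune", "confusion", "tram",
                 "tram_thresh", "tram_ord", "proposed")


@dataclass
class ConfusionModelConfig:
    """Per-annotator confusion model settings.

    ``trace_weight`` is the regularization strength on the summed traces of
    the confusion matrices (minimizing the trace pushes each matrix toward
    maximal confusion, which forces the classifier itself to explain the
    labels and makes the decomposition identifiable).  ``init_diag`` is the
    initial diagonal mass, biased toward the identity.
    """

    trace_weight: float = 0.01
    init_diag: float = 0.9
    trainable_encoder: bool = False

    def __post_init__(self):
        if self.trace_weight < 0:
            raise ValueError("trace_weight must be >= 0")
        if not 0.5 < self.init_diag < 1.0:
            raise ValueError("init_diag must lie in (0.5, 1)")


class EncoderClassifier(Module):
    """Encoder phi followed by a linear 2-class predictor xi."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        from .network import build_encoder
        self.config = config
        self.encoder = build_encoder(config, rng)
        self.head = Linear(config.embedding_dim, config.num_classes, rng)

    def forward(self, x: Tensor, freeze_encoder: bool = False) -> Tensor:
        z = self.encoder(x)
        if freeze_encoder:
            z = z.detach()
        return self.head(z)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        was_training = self.training
        self.eval()
        probs = []
        for lo in range(0, x.shape[0], batch_size):
            logits = self.forward(Tensor(x[lo:lo + batch_size]))
            probs.append(nn.softmax(logits.data, axis=1))
        if was_training:
            self.train()
        return np.concatenate(probs, axis=0)


class ConfusionMatrices(Module):
    """One trainable column-stochastic 2x2 matrix per annotator.

    Parameterized by unconstrained logits softmaxed down each column, so
    column-stochasticity (entries >= 0, columns summing to 1) holds after
    every optimization step by construction.
    """

    def __init__(self, n_annotators: int, init_diag: float,
                 num_classes: int = 2):
        super().__init__()
        self.n_annotators = n_annotators
        self.num_classes = num_classes
        logit = np.log(init_diag / (1.0 - init_diag)) / (num_classes - 1)
        w = np.zeros((n_annotators, num_classes, num_classes))
        for c in range(num_classes):
            w[:, c, c] = logit
        self.weights = Parameter(w)

    def matrices_tensor(self) -> Tensor:
        # softmax over the row axis of each column: sum_r P[t, r, c] = 1
        shift = nn.constant(self.weights.data.max(axis=1, keepdims=True))
        e = (self.weights - shift).exp()
        return e / e.sum(axis=1, keepdims=True)

    def matrices(self) -> np.ndarray:
        return self.matrices_tensor().data


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

class Variant:
    """Uniform training interface over the seven model variants."""

    name: str
    uses_privileged = False

    def __init__(self, net_config: NetworkConfig, rng: np.random.Generator):
        self.net_config = net_config

    # -- to implement ------------------------------------------------------
    def training_loss(self, batch: dict) -> Tensor:
        raise NotImplementedError

    def param_groups(self, lr_encoder: float, lr_rest: float):
        raise NotImplementedError

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    # -- shared ------------------------------------------------------------
    def modules(self) -> list[Module]:
        raise NotImplementedError

    def train(self):
        for m in self.modules():
            m.train()

    def eval(self):
        for m in self.modules():
            m.eval()

    def state(self):
        return [m.clone_state() for m in self.modules()]

    def load_state(self, state):
        for m, s in zip(self.modules(), state):
            m.load_state_dict(s)

    def validation_loss(self, x: np.ndarray, y: np.ndarray,
                        batch_size: int = 64) -> float:
        """Cross-entropy of the base branch against mean-aggregated labels."""
        probs = self.predict_proba(x)
        eps = 1e-12
        return float(-np.mean(np.log(probs[np.arange(len(y)), y] + eps)))


class LinearProbeVariant(Variant):
    name = "linear_probe"

    def __init__(self, net_config, rng):
        super().__init__(net_config, rng)
        self.model = EncoderClassifier(net_config, rng)

    def modules(self):
        return [self.model]

    def training_loss(self, batch):
        logits = self.model(Tensor(batch["x"]), freeze_encoder=True)
        return cross_entropy(logits, batch["y"])

    def param_groups(self, lr_encoder, lr_rest):
        # encoder deliberately excluded: it is frozen
        return [(self.model.head.parameters(), lr_rest)]

    def predict_proba(self, x):
        return self.model.predict_proba(x)


class FineTuneVariant(LinearProbeVariant):
    name = "fine_tune"

    def training_loss(self, batch):
        logits = self.model(Tensor(batch["x"]), freeze_encoder=False)
        return cross_entropy(logits, batch["y"])

    def param_groups(self, lr_encoder, lr_rest):
        return [(self.model.encoder.parameters(), lr_encoder),
                (self.model.head.parameters(), lr_rest)]


class ConfusionVariant(Variant):
    name = "confusion"

    def __init__(self, net_config, rng,
                 confusion_config: ConfusionModelConfig | None = None):
        super().__init__(net_config, rng)
        self.confusion_config = confusion_config or ConfusionModelConfig()
        self.model = EncoderClassifier(net_config, rng)
        self.confusion = ConfusionMatrices(net_config.panel_size,
                                           self.confusion_config.init_diag)

    def modules(self):
        return [self.model, self.confusion]

    def training_loss(self, batch):
        """Negative log-likelihood of every observed binarized review.

        ``batch['ann_record']`` indexes the record of each annotation in the
        batch, ``batch['ann_reviewer']`` its annotator (0-based) and
        ``batch['ann_label']`` the binarized score.
        """
        rec_idx = batch["ann_record"]
        ann_t = batch["ann_reviewer"]
        labels = batch["ann_label"]
        if ann_t.max() >= self.net_config.panel_size:
            raise ValueError("annotation by unknown annotator id")
        logits = self.model(Tensor(batch["x"]),
                            freeze_encoder=not
                            self.confusion_config.trainable_encoder)
        shift = nn.constant(logits.data.max(axis=1, keepdims=True))
        e = (logits - shift).exp()
        p = e / e.sum(axis=1, keepdims=True)          # (n, 2) true-label dist
        P = self.confusion.matrices_tensor()           # (M, 2, 2)
        Pt = P[ann_t]                                  # (n_ann, 2, 2)
        pi = p[rec_idx]                                # (n_ann, 2)
        q = (Pt * pi.reshape(-1, 1, 2)).sum(axis=2)    # annotator label dist
        onehot = np.zeros((len(labels), 2))
        onehot[np.arange(len(labels)), labels] = 1.0
        nll = -((q * nn.constant(onehot)).sum(axis=1) + 1e-12).log().mean()
        trace = (P[:, 0, 0] + P[:, 1, 1]).sum()
        return nll + self.confusion_config.trace_weight * trace

    def param_groups(self, lr_encoder, lr_rest):
        groups = [(self.model.head.parameters()
                   + self.confusion.parameters(), lr_rest)]
        if self.confusion_config.trainable_encoder:
            groups.append((self.model.encoder.parameters(), lr_encoder))
        return groups

    def predict_proba(self, x):
        return self.model.predict_proba(x)

    def learned_matrices(self) -> np.ndarray:
        return self.confusion.matrices()


class TramVariant(Variant):
    """The tram family: gating and privileged-head choice set per variant."""

    uses_privileged = True

    def __init__(self, net_config, rng, gated: bool, ordinal: bool, name: str):
        net_config.privileged_head = "corn" if ordinal else "binary"
        super().__init__(net_config, rng)
        self.name = name
        self.gated = gated
        self.ordinal = ordinal
        self.network = TramNetwork(net_config, rng)

    def modules(self):
        return [self.network]

    def gated_privileged(self, x_star: np.ndarray,
                         D: np.ndarray) -> np.ndarray:
        if not self.gated:
            return x_star
        keep = (D > self.net_config.gate.tau)[:, None]
        return x_star * keep

    def training_loss(self, batch):
        x_star = self.gated_privileged(batch["x_star"], batch["D"])
        outs = self.network.forward_tensors(Tensor(batch["x"]),
                                            Tensor(x_star), mode="train")
        targets = batch["ordinal"] if self.ordinal else batch["y"]
        return total_loss(outs["base_logits"], batch["y"],
                          outs["rank_logits"], targets,
                          beta=self.net_config.beta,
                          privileged_head=self.net_config.privileged_head)

    def param_groups(self, lr_encoder, lr_rest):
        return [(self.network.encoder_parameters(), lr_encoder),
                (self.network.rest_parameters(), lr_rest)]

    def predict_proba(self, x):
        return self.network.predict_proba(x)


def build_variant(name: str, net_config: NetworkConfig,
                  rng: np.random.Generator,
                  confusion_config: ConfusionModelConfig | None = None,
                  ) -> Variant:
    if name == "linear_probe":
        return LinearProbeVariant(net_config, rng)
    if name == "fine_tune":
        return FineTuneVariant(net_config, rng)
    if name == "confusion":
        return ConfusionVariant(net_config, rng, confusion_config)
    if name == "tram":
        return TramVariant(net_config, rng, gated=False, ordinal=False,
                           name="tram")
    if name == "tram_thresh":
        return TramVariant(net_config, rng, gated=True, ordinal=False,
                           name="tram_thresh")
    if name == "tram_ord":
        return TramVariant(net_config, rng, gated=False, ordinal=True,
                           name="tram_ord")
    if name == "proposed":
        return TramVariant(net_config, rng, gated=True, ordinal=True,
                           name="proposed")
    raise ValueError(f"unknown variant {name!r}; choose from {VARIANT_NAMES}")
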
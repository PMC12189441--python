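"""The concatenated image+tabular classifier and its hyperparameter coding.

Architecture: an image branch (convolutional backbone -> global average
pooling -> dense(cnn_neurons) -> ReLU -> dropout) and a tabular branch
(dense(dnn_neurons) -> ReLU -> dropout). The two feature vectors are scaled
by the fusion ratio -- image features by ``image_weight``, tabular features
by ``1 - image_weight`` -- concatenated, passed through
dense(fused_neurons) -> ReLU -> dropout and a final two-logit head whose
softmax gives P(malignant); hard labels threshold at 0.5 (ties -> 1).

Seven integers (x1..x7) encode this structure for the swarm optimizer:
three neuron counts in [1, 512], three dropout percents in [1, 99] and the
image-fusion percent in [1, 99].
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = [
    "SOLUTION_BOUNDS", "Solution", "ModelConfig", "TrainConfig",
    "TrainHistory", "FusionClassifier", "decode_solution",
    "BACKBONES", "backbone_parameter_count",
]

# (lower, upper) inclusive integer bounds for x1..x7
SOLUTION_BOUNDS: tuple[tuple[int, int], ...] = (
    (1, 512), (1, 99), (1, 512), (1, 99), (1, 512), (1, 99), (1, 99),
)

Solution = tuple[int, int, int, int, int, int, int]


@dataclass(frozen=True)
class ModelConfig:
    cnn_neurons: int
    cnn_dropout: float
    dnn_neurons: int
    dnn_dropout: float
    fused_neurons: int
    fused_dropout: float
    image_weight: float
    backbone_name: str = "tiny"

    def __post_init__(self):
        for name in ("cnn_neurons", "dnn_neurons", "fused_neurons"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("cnn_dropout", "dnn_dropout", "fused_dropout", "image_weight"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {v}")


def decode_solution(x: Solution, backbone_name: str = "tiny") -> ModelConfig:
    """Decode a 7-integer solution: percents divide by 100; x7 becomes the
    image-feature weight (tabular weight is its complement)."""
    if len(x) != 7:
        raise ValueError(f"solution must have 7 variables, got {len(x)}")
    for j, (v, (lo, hi)) in enumerate(zip(x, SOLUTION_BOUNDS), start=1):
        if not (isinstance(v, (int, np.integer)) and lo <= v <= hi):
            raise ValueError(f"x{j}={v} outside bounds [{lo},{hi}]")
    return ModelConfig(
        cnn_neurons=int(x[0]), cnn_dropout=x[1] / 100.0,
        dnn_neurons=int(x[2]), dnn_dropout=x[3] / 100.0,
        fused_neurons=int(x[4]), fused_dropout=x[5] / 100.0,
        image_weight=x[6] / 100.0, backbone_name=backbone_name,
    )


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer/schedule settings: Adam on cross-entropy with early
    stopping (patience 4 on validation loss) and plateau learning-rate
    reduction (factor 0.2, patience 2, floor 1e-4)."""

    batch_size: int = 8
    epochs: int = 100
    patience: int = 4
    learning_rate: float = 1e-3
    plateau_factor: float = 0.2
    plateau_patience: int = 2
    min_learning_rate: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1 or self.patience < 1:
            raise ValueError("batch_size, epochs and patience must be positive")
        if self.learning_rate <= 0 or self.min_learning_rate <= 0:
            raise ValueError("learning rates must be positive")


@dataclass
class TrainHistory:
    """Per-epoch training record returned by :meth:`FusionClassifier.fit`."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    learning_rates: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")
    stopped_early: bool = False

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)

    def summary(self) -> str:
        lines = ["epoch  train_loss  val_loss    lr"]
        for e, (tl, vl, lr) in enumerate(
                zip(self.train_loss, self.val_loss, self.learning_rates)):
            mark = " *" if e == self.best_epoch else ""
            lines.append(f"{e:>5}  {tl:>10.4f}  {vl:>8.4f}  {lr:.2e}{mark}")
        tail = "early stop" if self.stopped_early else "epoch limit"
        lines.append(f"stopped by {tail}; best val loss {self.best_val_loss:.4f} "
                     f"at epoch {self.best_epoch}")
        return "\n".join(lines)


def _make_tiny_small(rng, c_in):  # narrow 2-block extractor -> 8 features
    return nn.Sequential([
        nn.Conv2D(c_in, 4, rng), nn.ReLU(), nn.MaxPool2(),
        nn.Conv2D(4, 8, rng), nn.ReLU(), nn.MaxPool2(),
        nn.GlobalAvgPool(),
    ]), 8


def _make_tiny(rng, c_in):  # 2 conv blocks -> 16 features
    return nn.Sequential([
        nn.Conv2D(c_in, 8, rng), nn.ReLU(), nn.MaxPool2(),
        nn.Conv2D(8, 16, rng), nn.ReLU(), nn.MaxPool2(),
        nn.GlobalAvgPool(),
    ]), 16


def _make_tiny_deep(rng, c_in):  # 3 conv blocks -> 24 features
    return nn.Sequential([
        nn.Conv2D(c_in, 8, rng), nn.ReLU(), nn.MaxPool2(),
        nn.Conv2D(8, 16, rng), nn.ReLU(), nn.MaxPool2(),
        nn.Conv2D(16, 24, rng), nn.ReLU(),
        nn.GlobalAvgPool(),
    ]), 24


def _make_tiny_wide(rng, c_in):  # wider 3-block extractor -> 48 features
    return nn.Sequential([
        nn.Conv2D(c_in, 16, rng), nn.ReLU(), nn.MaxPool2(),
        nn.Conv2D(16, 32, rng), nn.ReLU(), nn.MaxPool2(),
        nn.Conv2D(32, 48, rng), nn.ReLU(),
        nn.GlobalAvgPool(),
    ]), 48


# Desk-scale convolutional feature extractors. The wide/deep variants play
# the large "teacher" role and "tiny" plays the small student; pretrained
# ImageNet backbones would plug in through the same registry surface.
BACKBONES = {
    "tiny-small": _make_tiny_small,
    "tiny": _make_tiny,
    "tiny-deep": _make_tiny_deep,
    "tiny-wide": _make_tiny_wide,
}


def backbone_parameter_count(name: str, c_in: int = 1) -> int:
    rng = np.random.default_rng(0)
    net, _ = BACKBONES[name](rng, c_in)
    return net.n_params


class _Branch:
    """dense -> ReLU -> dropout."""

    def __init__(self, n_in, n_out, dropout, rng):
        self.dense = nn.Dense(n_in, n_out, rng)
        self.relu = nn.ReLU()
        self.dropout = nn.Dropout(dropout)

    def forward(self, x, train=False, rng=None):
        return self.dropout.forward(
            self.relu.forward(self.dense.forward(x)), train=train, rng=rng)

    def backward(self, grad):
        return self.dense.backward(self.relu.backward(self.dropout.backward(grad)))

    def params(self):
        return self.dense.params()


class FusionClassifier:
    """Concatenated image+tabular binary classifier.

    Parameters
    ----------
    config : ModelConfig
        Decoded architecture hyperparameters.
    input_shape : (h, w, c)
        Image input shape fed to the backbone.
    n_tabular : int
        Width of the encoded tabular feature vector (44 for the full schema).
    seed : int
        Controls weight initialization and all training randomness.
    backbone : Sequential, optional
        A pre-built (e.g. distilled) feature extractor to reuse; when given
        together with ``freeze_backbone=True`` its weights are not updated.
    """

    def __init__(self, config: ModelConfig, input_shape=(32, 32, 1),
                 n_tabular: int = 44, seed: int = 0,
                 backbone: nn.Sequential | None = None,
                 freeze_backbone: bool = False):
        self.config = config
        self.input_shape = tuple(input_shape)
        self.n_tabular = n_tabular
        self.seed = seed
        self.frozen_backbone = freeze_backbone
        rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
        if config.backbone_name not in BACKBONES:
            raise ValueError(f"unknown backbone: {config.backbone_name!r}")
        if backbone is None:
            self.backbone, self.n_backbone_features = BACKBONES[config.backbone_name](
                rng, self.input_shape[2])
        else:
            self.backbone = backbone
            probe = np.zeros((1, *self.input_shape))
            self.n_backbone_features = self.backbone.forward(probe).shape[1]
        self.img_branch = _Branch(self.n_backbone_features, config.cnn_neurons,
                                  config.cnn_dropout, rng)
        self.tab_branch = _Branch(n_tabular, config.dnn_neurons,
                                  config.dnn_dropout, rng)
        self.fused = _Branch(config.cnn_neurons + config.dnn_neurons,
                             config.fused_neurons, config.fused_dropout, rng)
        self.out = nn.Dense(config.fused_neurons, 2, rng)
        self._rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))

    # ---- forward/backward -------------------------------------------------

    def extract_features(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Backbone features (post global-average-pooling) for a stack of
        NHWC images; used to freeze the extractor in stage 2."""
        chunks = [self.backbone.forward(images[i:i + batch_size])
                  for i in range(0, len(images), batch_size)]
        return np.concatenate(chunks, axis=0)

    def _forward_heads(self, feats, tabular, train=False, rng=None):
        w = self.config.image_weight
        h_img = self.img_branch.forward(feats, train=train, rng=rng)
        h_tab = self.tab_branch.forward(tabular, train=train, rng=rng)
        z = np.concatenate([w * h_img, (1.0 - w) * h_tab], axis=1)
        h = self.fused.forward(z, train=train, rng=rng)
        return self.out.forward(h)

    def _backward_heads(self, grad_logits):
        w = self.config.image_weight
        g = self.fused.backward(self.out.backward(grad_logits))
        k = self.config.cnn_neurons
        g_img = self.img_branch.backward(w * g[:, :k])
        self.tab_branch.backward((1.0 - w) * g[:, k:])
        return g_img  # gradient w.r.t. backbone features

    def forward(self, images, tabular, train=False, rng=None):
        feats = self.backbone.forward(images, train=train, rng=rng)
        return self._forward_heads(feats, tabular, train=train, rng=rng)

    def logits(self, images, tabular, batch_size: int = 64) -> np.ndarray:
        outs = [self.forward(images[i:i + batch_size], tabular[i:i + batch_size])
                for i in range(0, len(images), batch_size)]
        return np.concatenate(outs, axis=0)

    def predict_proba(self, images, tabular) -> np.ndarray:
        """P(malignant) for each sample."""
        return nn.softmax(self.logits(images, tabular))[:, 1]

    def predict(self, images, tabular) -> np.ndarray:
        """Hard labels at threshold 0.5; a probability of exactly 0.5 is
        classified positive."""
        return (self.predict_proba(images, tabular) >= 0.5).astype(int)

    # ---- parameters -------------------------------------------------------

    def head_params(self) -> list[nn.Param]:
        return (self.img_branch.params() + self.tab_branch.params()
                + self.fused.params() + self.out.params())

    def trainable_params(self) -> list[nn.Param]:
        params = list(self.head_params())
        if not self.frozen_backbone:
            params = self.backbone.params() + params
        return params

    @property
    def parameter_count(self) -> int:
        return self.backbone.n_params + sum(p.size for p in self.head_params())

    # ---- training ---------------------------------------------------------

    def fit(self, train_data, val_data, tc: TrainConfig = TrainConfig(),
            loss_grad=None, features: bool = False) -> TrainHistory:
        """Train with mini-batch Adam.

        ``train_data``/``val_data`` are ``(images, tabular, labels)`` triples
        (or ``(features, tabular, labels)`` when ``features=True``, which
        skips the backbone entirely -- the frozen-extractor fast path).
        ``loss_grad(logits, batch_indices)`` may override the default hard
        cross-entropy, returning ``(loss, dloss/dlogits)``; knowledge
        distillation passes a closure over the teacher's logits here.
        """
        x_tr, t_tr, y_tr = train_data
        x_va, t_va, y_va = val_data
        if len(x_tr) == 0:
            raise ValueError("training split is empty")
        onehot_tr = np.eye(2)[np.asarray(y_tr, dtype=int)]
        onehot_va = np.eye(2)[np.asarray(y_va, dtype=int)]

        params = self.head_params() if (features or self.frozen_backbone) \
            else self.trainable_params()
        opt = nn.Adam(params, lr=tc.learning_rate)
        rng = np.random.default_rng(np.random.SeedSequence([tc.seed, self.seed, 31]))
        hist = TrainHistory()
        best_snapshot = None
        bad_epochs = plateau_bad = 0

        def fwd(x, t, train):
            if features:
                return self._forward_heads(x, t, train=train, rng=rng)
            return self.forward(x, t, train=train, rng=rng)

        def val_loss():
            losses, n = 0.0, 0
            for i in range(0, len(x_va), 64):
                lg = fwd(x_va[i:i + 64], t_va[i:i + 64], train=False)
                loss, _ = nn.cross_entropy_from_logits(lg, onehot_va[i:i + 64])
                losses += loss * len(lg)
                n += len(lg)
            return losses / max(n, 1)

        for epoch in range(tc.epochs):
            order = rng.permutation(len(x_tr))
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, len(order), tc.batch_size):
                idx = order[start:start + tc.batch_size]
                lg = fwd(x_tr[idx], t_tr[idx], train=True)
                if loss_grad is None:
                    loss, grad = nn.cross_entropy_from_logits(lg, onehot_tr[idx])
                else:
                    loss, grad = loss_grad(lg, idx)
                opt.zero_grad()
                g_feats = self._backward_heads(grad)
                if not (features or self.frozen_backbone):
                    self.backbone.backward(g_feats)
                opt.step()
                epoch_loss += loss
                n_batches += 1
            vl = val_loss()
            hist.train_loss.append(epoch_loss / max(n_batches, 1))
            hist.val_loss.append(vl)
            hist.learning_rates.append(opt.lr)
            if vl < hist.best_val_loss - 1e-9:
                hist.best_val_loss = vl
                hist.best_epoch = epoch
                best_snapshot = [p.value.copy() for p in params]
                bad_epochs = plateau_bad = 0
            else:
                bad_epochs += 1
                plateau_bad += 1
                if plateau_bad >= tc.plateau_patience and opt.lr > tc.min_learning_rate:
                    opt.lr = max(tc.min_learning_rate, opt.lr * tc.plateau_factor)
                    plateau_bad = 0
                if bad_epochs >= tc.patience:
                    hist.stopped_early = True
                    break
        if best_snapshot is not None:
            for p, v in zip(params, best_snapshot):
                p.value[...] = v
        return hist

    # ---- frozen-feature prediction helpers (stage-2 fast path) -----------

    def predict_proba_features(self, feats, tabular) -> np.ndarray:
        outs = [self._forward_heads(feats[i:i + 64], tabular[i:i + 64])
                for i in range(0, len(feats), 64)]
        return nn.softmax(np.concatenate(outs, axis=0))[:, 1]

    def predict_features(self, feats, tabular) -> np.ndarray:
        return (self.predict_proba_features(feats, tabular) >= 0.5).astype(int)

    def copy_backbone(self) -> nn.Sequential:
        return copy.deepcopy(self.backbone)
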
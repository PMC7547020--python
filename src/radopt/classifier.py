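"""Shallow embedding classifier: one fully-connected layer over image signatures.

The model is deliberately minimal: dropout on the input embedding, a single
affine map ``z = w x + b`` into two class scores, an activation ``g``, and a
categorical cross-entropy loss (two-class Bernoulli form) with optional L1/L2
weight penalties.  All of the capacity lives in the frozen pretrained feature
extractor; the trainable head has ``dim x 2 + 2`` parameters, which is what
makes the approach viable on datasets of a few hundred images.

Everything that varies across search-space genomes — activation, dropout keep
probability, regularization, optimizer family, learning rate, batch size,
epochs — is carried by :class:`ClassifierConfig`.  Training is deterministic
given the config seed.

Class encoding: column 0 = NOTACP, column 1 = ACP (the positive class).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ClassifierConfig",
    "TrainedClassifier",
    "ACTIVATION_NAMES",
    "forward",
    "class_probabilities",
    "cross_entropy_loss",
    "apply_dropout",
    "train_classifier",
    "predict_scores",
    "loss_and_gradients",
]

EPS = 1e-12  # probability clipping floor

ACTIVATION_NAMES = (
    "softmax",
    "softplus",
    "softsign",
    "relu",
    "leaky_relu",
    "log_softmax",
    "identity",
)

LEAKY_RELU_SLOPE = 0.2

POSITIVE_CLASS = "ACP"
NEGATIVE_CLASS = "NOTACP"


def encode_labels(labels: Sequence[str]) -> np.ndarray:
    """Map ACP/NOTACP labels to one-hot rows (ACP = column 1)."""
    out = np.zeros((len(labels), 2))
    for i, lab in enumerate(labels):
        if lab == POSITIVE_CLASS:
            out[i, 1] = 1.0
        elif lab == NEGATIVE_CLASS:
            out[i, 0] = 1.0
        else:
            raise ValueError(f"unknown class label {lab!r}")
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _activate(z: np.ndarray, activation: str) -> np.ndarray:
    if activation == "softmax":
        return _softmax(z)
    if activation == "log_softmax":
        zs = z - z.max(axis=-1, keepdims=True)
        return zs - np.log(np.exp(zs).sum(axis=-1, keepdims=True))
    if activation == "softplus":
        return np.logaddexp(0.0, z)
    if activation == "softsign":
        return z / (1.0 + np.abs(z))
    if activation == "relu":
        return np.maximum(z, 0.0)
    if activation == "leaky_relu":
        return np.where(z >= 0, z, LEAKY_RELU_SLOPE * z)
    if activation == "identity":
        return z
    raise ValueError(f"unknown activation {activation!r}")


def _activation_grad(z: np.ndarray, activation: str) -> np.ndarray:
    """Elementwise derivative g'(z) for the non-normalizing activations."""
    if activation == "softplus":
        return 1.0 / (1.0 + np.exp(-z))
    if activation == "softsign":
        return 1.0 / (1.0 + np.abs(z)) ** 2
    if activation == "relu":
        return (z > 0).astype(float)
    if activation == "leaky_relu":
        return np.where(z >= 0, 1.0, LEAKY_RELU_SLOPE)
    if activation == "identity":
        return np.ones_like(z)
    raise ValueError(f"no elementwise gradient for {activation!r}")


def forward(
    x: np.ndarray, w: np.ndarray, b: np.ndarray, activation: str = "softmax"
) -> np.ndarray:
    """Class scores ``g(w x + b)`` for one embedding row or a batch.

    Softmax rows are probability vectors; log_softmax rows are
    log-probabilities; the remaining activations return unnormalized scores
    (the ACP column is a valid ranking score for ROC analysis).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != w.shape[0]:
        raise ValueError(
            f"embedding dim {x.shape[1]} does not match weights {w.shape[0]}"
        )
    z = np.clip(x @ w + b, -1e6, 1e6)
    return _activate(z, activation)


def class_probabilities(
    x: np.ndarray, w: np.ndarray, b: np.ndarray, activation: str
) -> np.ndarray:
    """Per-row class probabilities used by the loss.

    For softmax (and log_softmax, which is its logarithm) the probabilities
    come straight from the logits; for every other activation the activated
    scores are normalized through a softmax so the cross-entropy contract is
    uniform across genomes.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    z = np.clip(x @ w + b, -1e6, 1e6)
    if activation in ("softmax", "log_softmax"):
        return _softmax(z)
    return _softmax(_activate(z, activation))


def cross_entropy_loss(
    y: np.ndarray,
    yhat: np.ndarray,
    w: np.ndarray | None = None,
    reg_mode: str = "none",
    l1_coeff: float = 0.01,
    l2_coeff: float = 0.01,
) -> float:
    """Mean two-class cross-entropy plus optional weight penalties.

    ``y`` is one-hot (n, 2) with ACP in column 1; ``yhat`` holds predicted
    class probabilities.  The data term is the Bernoulli form
    ``-(1/N) sum[y log p + (1-y) log(1-p)]`` with ``p`` the ACP probability,
    which coincides with categorical cross-entropy for two classes.  Penalties:
    ``l1_coeff * sum|w|`` and/or ``l2_coeff * sum w^2`` per ``reg_mode``.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    yhat = np.atleast_2d(np.asarray(yhat, dtype=float))
    if y.shape != yhat.shape:
        raise ValueError("y and yhat shapes differ")
    row_sums = yhat.sum(axis=1)
    if np.any(yhat < -1e-9) or np.any(np.abs(row_sums - 1.0) > 1e-6):
        raise ValueError("yhat rows must be probability vectors")
    p = np.clip(yhat[:, 1], EPS, 1.0 - EPS)
    t = y[:, 1]
    loss = -float(np.mean(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)))
    if w is not None and reg_mode != "none":
        if reg_mode in ("l1", "l1l2"):
            loss += l1_coeff * float(np.abs(w).sum())
        if reg_mode in ("l2", "l1l2"):
            loss += l2_coeff * float((w**2).sum())
        if reg_mode not in ("l1", "l2", "l1l2"):
            raise ValueError(f"unknown regularization mode {reg_mode!r}")
    return loss


def apply_dropout(
    x: np.ndarray,
    keep_prob: float,
    rng: np.random.Generator,
    phase: str = "train",
) -> np.ndarray:
    """Inverted dropout: zero features with prob 1-keep_prob, rescale survivors.

    Evaluation phase is the identity — scaling at train time means no
    correction is needed at inference.
    """
    if not 0.0 < keep_prob <= 1.0:
        raise ValueError("keep_prob must be in (0, 1]")
    if phase == "eval" or keep_prob == 1.0:
        return np.asarray(x, dtype=float)
    if phase != "train":
        raise ValueError(f"unknown phase {phase!r}")
    x = np.asarray(x, dtype=float)
    mask = rng.random(x.shape) < keep_prob
    return x * mask / keep_prob


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------


class _Optimizer:
    """Stateful per-array parameter updater following a canonical rule."""

    def __init__(self, lr: float):
        self.lr = lr
        self._state: dict[int, dict[str, np.ndarray]] = {}

    def _slot(self, key: int, like: np.ndarray, names: Sequence[str], init: float = 0.0):
        if key not in self._state:
            self._state[key] = {n: np.full_like(like, init) for n in names}
        return self._state[key]

    def update(self, key: int, param: np.ndarray, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class _SGD(_Optimizer):
    def update(self, key, param, grad):
        return param - self.lr * grad


class _Momentum(_Optimizer):
    momentum = 0.9

    def update(self, key, param, grad):
        s = self._slot(key, param, ["v"])
        s["v"] = self.momentum * s["v"] + grad
        return param - self.lr * s["v"]


class _Adam(_Optimizer):
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    def __init__(self, lr):
        super().__init__(lr)
        self._t: dict[int, int] = {}

    def update(self, key, param, grad):
        s = self._slot(key, param, ["m", "v"])
        t = self._t.get(key, 0) + 1
        self._t[key] = t
        s["m"] = self.beta1 * s["m"] + (1 - self.beta1) * grad
        s["v"] = self.beta2 * s["v"] + (1 - self.beta2) * grad**2
        mhat = s["m"] / (1 - self.beta1**t)
        vhat = s["v"] / (1 - self.beta2**t)
        return param - self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _Adagrad(_Optimizer):
    initial_accumulator = 0.1

    def update(self, key, param, grad):
        s = self._slot(key, param, ["acc"], init=self.initial_accumulator)
        s["acc"] = s["acc"] + grad**2
        return param - self.lr * grad / np.sqrt(s["acc"])


class _Adadelta(_Optimizer):
    rho, eps = 0.95, 1e-8

    def update(self, key, param, grad):
        s = self._slot(key, param, ["acc", "delta"])
        s["acc"] = self.rho * s["acc"] + (1 - self.rho) * grad**2
        step = np.sqrt(s["delta"] + self.eps) / np.sqrt(s["acc"] + self.eps) * grad
        s["delta"] = self.rho * s["delta"] + (1 - self.rho) * step**2
        return param - self.lr * step


class _RMSProp(_Optimizer):
    decay, eps = 0.9, 1e-10

    def update(self, key, param, grad):
        s = self._slot(key, param, ["ms"])
        s["ms"] = self.decay * s["ms"] + (1 - self.decay) * grad**2
        return param - self.lr * grad / np.sqrt(s["ms"] + self.eps)


class _FTRL(_Optimizer):
    """FTRL-proximal with learning-rate power -1/2 and no added L1/L2."""

    initial_accumulator = 0.1
    l1, l2 = 0.0, 0.0

    def update(self, key, param, grad):
        s = self._slot(key, param, ["n", "z"])
        if not np.any(s["n"]):
            s["n"] = np.full_like(param, self.initial_accumulator)
        n_new = s["n"] + grad**2
        sigma = (np.sqrt(n_new) - np.sqrt(s["n"])) / self.lr
        s["z"] = s["z"] + grad - sigma * param
        s["n"] = n_new
        z = s["z"]
        new = np.where(
            np.abs(z) <= self.l1,
            0.0,
            -(z - np.sign(z) * self.l1) / (np.sqrt(n_new) / self.lr + self.l2),
        )
        return new


class _ProximalWrapper(_Optimizer):
    """Base adaptive step followed by a proximal operator.

    Soft-thresholding implements the L1 proximal map, multiplicative shrinkage
    the L2 map; the threshold scale is the optimizer's global learning rate.
    """

    def __init__(self, base: _Optimizer, reg_mode: str, strength: float = 0.001):
        super().__init__(base.lr)
        self.base = base
        self.reg_mode = reg_mode
        self.strength = strength

    def update(self, key, param, grad):
        new = self.base.update(key, param, grad)
        t = self.lr * self.strength
        if self.reg_mode in ("l1", "l1l2"):
            new = np.sign(new) * np.maximum(np.abs(new) - t, 0.0)
        if self.reg_mode in ("l2", "l1l2"):
            new = new / (1.0 + t)
        return new


def make_optimizer(spec: Mapping[str, str], lr: float) -> _Optimizer:
    """Build an optimizer from a search-space optimizer spec."""
    name = spec["name"]
    base_map = {
        "Gradient Descent": _SGD,
        "Momentum": _Momentum,
        "Adam": _Adam,
        "Adagrad": _Adagrad,
        "Adadelta": _Adadelta,
        "RMSProp": _RMSProp,
        "FTRL": _FTRL,
    }
    if name in base_map:
        return base_map[name](lr)
    if name == "Proximal Adagrad":
        return _ProximalWrapper(_Adagrad(lr), spec.get("proximal_reg", "none"))
    if name == "Proximal Adadelta":
        return _ProximalWrapper(_Adadelta(lr), spec.get("proximal_reg", "none"))
    raise ValueError(f"unknown optimizer {name!r}")


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassifierConfig:
    activation: str = "softmax"
    keep_prob: float = 1.0
    reg_mode: str = "none"
    l1_coeff: float = 0.01
    l2_coeff: float = 0.01
    optimizer: Mapping[str, str] = field(
        default_factory=lambda: {"name": "Gradient Descent"}
    )
    learning_rate: float = 0.01
    batch_size: int | None = None  # None = whole-batch training
    epochs: int = 100
    seed: int = 0
    init: str = "zeros"  # zeros | gaussian
    #: Standardize features to zero mean / unit variance (training statistics)
    #: before optimization; the affine transform is folded back into (w, b) so
    #: the trained parameters apply to raw embeddings.  Keeps whole-batch
    #: gradient descent well-conditioned when embeddings have a large shared
    #: mean component.
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.activation not in ACTIVATION_NAMES:
            raise ValueError(f"unknown activation {self.activation!r}")
        if not 0.0 < self.keep_prob <= 1.0:
            raise ValueError("keep_prob must be in (0, 1]")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size is not None and self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainedClassifier:
    w: np.ndarray  # (dim, 2)
    b: np.ndarray  # (2,)
    config: ClassifierConfig
    loss_trace: np.ndarray  # per-epoch mean loss

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.w)) and np.all(np.isfinite(self.b))):
            raise ValueError("trained parameters must be finite")


def loss_and_gradients(
    x: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    b: np.ndarray,
    activation: str,
    reg_mode: str = "none",
    l1_coeff: float = 0.01,
    l2_coeff: float = 0.01,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Batch loss and its analytic gradients with respect to w and b.

    The loss is the cross-entropy of :func:`class_probabilities`; for
    non-normalizing activations the softmax-over-activations chain rule
    contributes an elementwise ``g'(z)`` factor.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n = x.shape[0]
    z = x @ w + b
    if activation in ("softmax", "log_softmax"):
        p = _softmax(z)
        dz = (p - y) / n
    else:
        a = _activate(z, activation)
        p = _softmax(a)
        dz = (p - y) / n * _activation_grad(z, activation)
    loss = cross_entropy_loss(y, p, w, reg_mode, l1_coeff, l2_coeff)
    gw = x.T @ dz
    gb = dz.sum(axis=0)
    if reg_mode in ("l1", "l1l2"):
        gw = gw + l1_coeff * np.sign(w)
    if reg_mode in ("l2", "l1l2"):
        gw = gw + 2.0 * l2_coeff * w
    return loss, gw, gb


def train_classifier(
    embeddings: np.ndarray,
    labels: Sequence[str] | np.ndarray,
    config: ClassifierConfig,
) -> TrainedClassifier:
    """Train the single-layer head by mini-batch optimization.

    Parameters start at zero (the softmax problem is convex, so zero init plus
    a fixed seed makes runs exactly reproducible); mini-batches are formed by
    a seeded shuffle each epoch.  ``batch_size=None`` (or >= n) reproduces
    whole-batch training.
    """
    x = np.asarray(embeddings, dtype=float)
    if x.ndim != 2:
        raise ValueError("embeddings must be a 2-D array")
    y = (
        np.asarray(labels, dtype=float)
        if isinstance(labels, np.ndarray) and np.asarray(labels).ndim == 2
        else encode_labels(list(labels))
    )
    if y.shape[0] != x.shape[0]:
        raise ValueError("labels and embeddings row counts differ")
    if y[:, 1].sum() == 0 or y[:, 0].sum() == 0:
        raise ValueError("need at least one example of each class")

    n, dim = x.shape
    if config.standardize:
        mu = x.mean(axis=0)
        sigma = x.std(axis=0)
        sigma[sigma == 0] = 1.0
        x = (x - mu) / sigma
    rng = np.random.default_rng(config.seed)
    if config.init == "zeros":
        w = np.zeros((dim, 2))
        b = np.zeros(2)
    elif config.init == "gaussian":
        w = rng.standard_normal((dim, 2)) * 0.01
        b = np.zeros(2)
    else:
        raise ValueError(f"unknown init {config.init!r}")

    batch = n if config.batch_size is None else min(config.batch_size, n)
    opt = make_optimizer(dict(config.optimizer), config.learning_rate)
    trace = np.empty(config.epochs)

    for epoch in range(config.epochs):
        order = rng.permutation(n) if batch < n else np.arange(n)
        losses, weights = [], []
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            xb = apply_dropout(x[idx], config.keep_prob, rng, phase="train")
            loss, gw, gb = loss_and_gradients(
                xb,
                y[idx],
                w,
                b,
                config.activation,
                config.reg_mode,
                config.l1_coeff,
                config.l2_coeff,
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} (config: {config})"
                )
            w = opt.update(0, w, gw)
            b = opt.update(1, b, gb)
            losses.append(loss)
            weights.append(len(idx))
        trace[epoch] = np.average(losses, weights=weights)

    if config.standardize:
        # fold the standardization into the affine head: z = ((x-mu)/sigma)w + b
        b = b - (mu / sigma) @ w
        w = w / sigma[:, None]
    return TrainedClassifier(w=w, b=b, config=config, loss_trace=trace)


def predict_scores(clf: TrainedClassifier, embeddings: np.ndarray) -> np.ndarray:
    """Per-image ACP score from an evaluation-phase forward pass.

    Softmax and log_softmax yield calibrated (log-)probabilities; the other
    activations yield monotone unnormalized scores, which is all ROC ranking
    needs.
    """
    out = forward(
        np.asarray(embeddings, dtype=float), clf.w, clf.b, clf.config.activation
    )
    return out[:, 1]


def predict_classes(clf: TrainedClassifier, embeddings: np.ndarray) -> list[str]:
    """Argmax class decision (0.5 probability threshold under softmax)."""
    out = forward(
        np.asarray(embeddings, dtype=float), clf.w, clf.b, clf.config.activation
    )
    return [POSITIVE_CLASS if row[1] >= row[0] else NEGATIVE_CLASS for row in out]
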
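"""Optotype recognition: a minimal CNN and a correlation baseline.

The CNN is the smallest architecture that works for this binary task: one
3x3 convolution with 8 filters (valid padding), batch normalization, ReLU,
2x2 max-pooling with stride 2, and a fully connected layer onto 2 classes
(unrecognized / recognized) with softmax and categorical cross-entropy.
It is implemented directly on numpy with an Adam optimizer; with a fixed
seed, training is reproducible run to run.

The correlation baseline labels an optotype "recognized" when the Pearson
correlation against the noise-free neural-image template of the true letter
is the highest among all ten letter templates, mirroring template-matching
functional acuity models.

Confusion-matrix conventions: counts are indexed ``[output, target]`` with
class order (unrecognized, recognized). Reported metrics are axis-explicit
row fractions (per predicted class) and column fractions (per target
class), plus overall accuracy.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CLASSES",
    "RecognizerConfig",
    "CNNModel",
    "TrainingReport",
    "train_recognizer",
    "classify",
    "correlation_recognizer",
    "ConfusionMatrix",
    "ConfusionMetrics",
    "confusion_metrics",
]

CLASSES = ("unrecognized", "recognized")


def _image_array(img) -> np.ndarray:
    """Unwrap an OptotypeImage (or accept a raw array) to its raster."""
    if isinstance(img, np.ndarray):
        return img
    return np.asarray(img.data)


@dataclass(frozen=True)
class RecognizerConfig:
    """CNN architecture and training hyperparameters.

    The architecture fields are fixed by design (3x3 conv with 8 filters,
    pool 2x2/2, 2 output classes); learning rate is the usual Adam default
    since nothing else is specified by the protocol.
    """

    input_side: int = 224
    conv_kernel: int = 3
    n_filters: int = 8
    pool: int = 2
    n_classes: int = 2
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 10
    split_fractions: tuple = (0.70, 0.15, 0.15)
    seed: int = 0


class CNNModel:
    """Conv(3x3, 8) -> BN -> ReLU -> MaxPool(2,2) -> FC(2) -> softmax."""

    def __init__(self, config: RecognizerConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        k, nf = config.conv_kernel, config.n_filters
        side = config.input_side
        conv_side = side - k + 1
        if conv_side % config.pool:
            conv_side -= conv_side % config.pool  # crop remainder row/col
        self.conv_side = conv_side
        pooled = conv_side // config.pool
        n_flat = pooled * pooled * nf
        # He-style initialization, seeded
        self.Wc = rng.normal(0.0, np.sqrt(2.0 / (k * k)), (k * k, nf)).astype(np.float32)
        self.bc = np.zeros(nf, dtype=np.float32)
        self.gamma = np.ones(nf, dtype=np.float32)
        self.beta = np.zeros(nf, dtype=np.float32)
        self.Wf = rng.normal(0.0, np.sqrt(2.0 / n_flat),
                             (n_flat, config.n_classes)).astype(np.float32)
        self.bf = np.zeros(config.n_classes, dtype=np.float32)
        self.run_mean = np.zeros(nf, dtype=np.float32)
        self.run_var = np.ones(nf, dtype=np.float32)
        self._eps = 1e-5

    # -- layers -------------------------------------------------------------

    def _patches(self, x: np.ndarray) -> np.ndarray:
        k = self.config.conv_kernel
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
        s = self.conv_side
        win = win[:, :s, :s]
        return win.reshape(x.shape[0], s, s, k * k)

    def forward(self, x: np.ndarray, train: bool = False):
        """Forward pass on a batch (B, side, side) in [0, 1]; returns probs."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1] != self.config.input_side:
            raise ValueError(f"expected {self.config.input_side}px input, "
                             f"got {x.shape[1]}")
        cache = {}
        p = self._patches(x)
        conv = p @ self.Wc + self.bc  # (B, s, s, nf)
        if train:
            mean = conv.mean(axis=(0, 1, 2))
            var = conv.var(axis=(0, 1, 2))
            m = 0.9
            self.run_mean = m * self.run_mean + (1 - m) * mean.astype(np.float32)
            self.run_var = m * self.run_var + (1 - m) * var.astype(np.float32)
        else:
            mean, var = self.run_mean, self.run_var
        xhat = (conv - mean) / np.sqrt(var + self._eps)
        bn = self.gamma * xhat + self.beta
        relu = np.maximum(bn, 0.0)
        B, s, _, nf = relu.shape
        q = self.config.pool
        blocks = relu.reshape(B, s // q, q, s // q, q, nf)
        pooled = blocks.max(axis=(2, 4))
        flat = pooled.reshape(B, -1)
        logits = flat @ self.Wf + self.bf
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=1, keepdims=True)
        cache.update(patches=p, xhat=xhat, var=var, bn=bn, relu=relu,
                     pooled=pooled, flat=flat, probs=probs)
        return probs, cache

    def _backward(self, cache, y_onehot):
        B = y_onehot.shape[0]
        probs = cache["probs"]
        dlogits = (probs - y_onehot) / B
        dWf = cache["flat"].T @ dlogits
        dbf = dlogits.sum(axis=0)
        dflat = dlogits @ self.Wf.T
        q = self.config.pool
        s = self.conv_side
        nf = self.config.n_filters
        dpooled = dflat.reshape(cache["pooled"].shape)
        relu = cache["relu"]
        blocks = relu.reshape(B, s // q, q, s // q, q, nf)
        maxes = cache["pooled"][:, :, None, :, None, :]
        mask = (blocks == maxes)
        mask = mask / np.maximum(mask.sum(axis=(2, 4), keepdims=True), 1)
        drelu = (mask * dpooled[:, :, None, :, None, :]).reshape(relu.shape)
        dbn = drelu * (cache["bn"] > 0)
        xhat = cache["xhat"]
        dgamma = (dbn * xhat).sum(axis=(0, 1, 2))
        dbeta = dbn.sum(axis=(0, 1, 2))
        n = B * s * s
        dxhat = dbn * self.gamma
        inv_std = 1.0 / np.sqrt(cache["var"] + self._eps)
        dconv = inv_std / n * (n * dxhat - dxhat.sum(axis=(0, 1, 2))
                               - xhat * (dxhat * xhat).sum(axis=(0, 1, 2)))
        p = cache["patches"].reshape(-1, self.Wc.shape[0])
        dWc = p.T @ dconv.reshape(-1, nf)
        dbc = dconv.sum(axis=(0, 1, 2))
        return {"Wc": dWc, "bc": dbc, "gamma": dgamma, "beta": dbeta,
                "Wf": dWf, "bf": dbf}

    def params(self):
        return {"Wc": self.Wc, "bc": self.bc, "gamma": self.gamma,
                "beta": self.beta, "Wf": self.Wf, "bf": self.bf}

    # -- serialization ------------------------------------------------------

    def save(self, path: str) -> None:
        """Write weights (npz) plus a JSON architecture descriptor."""
        arrays = {**self.params(), "run_mean": self.run_mean,
                  "run_var": self.run_var}
        np.savez(path if path.endswith(".npz") else path + ".npz", **arrays)
        desc = {"architecture": "conv3x3x8-bn-relu-maxpool2-fc2-softmax",
                "config": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in vars(self.config).items()}}
        with open((path[:-4] if path.endswith(".npz") else path) + ".json",
                  "w") as fh:
            json.dump(desc, fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "CNNModel":
        base = path[:-4] if path.endswith(".npz") else path
        with open(base + ".json") as fh:
            desc = json.load(fh)
        cfg = desc["config"]
        cfg["split_fractions"] = tuple(cfg["split_fractions"])
        model = cls(RecognizerConfig(**cfg))
        data = np.load(base + ".npz")
        for name in ("Wc", "bc", "gamma", "beta", "Wf", "bf",
                     "run_mean", "run_var"):
            setattr(model, name, data[name].astype(np.float32))
        return model


@dataclass
class TrainingReport:
    """Per-epoch loss and validation accuracy of a CNN training run."""

    epoch_loss: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)
    config: RecognizerConfig | None = None
    warnings: list = field(default_factory=list)


def train_recognizer(images: np.ndarray, labels: np.ndarray,
                     config: RecognizerConfig | None = None,
                     val_images: np.ndarray | None = None,
                     val_labels: np.ndarray | None = None):
    """Train the binary optotype recognizer.

    ``images`` is (N, side, side) on [0, 1]; ``labels`` holds 0
    (unrecognized) / 1 (recognized). Returns ``(model, report)``.
    """
    config = config or RecognizerConfig()
    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(labels, dtype=int)
    if images.shape[0] == 0:
        raise ValueError("empty training set")
    report = TrainingReport(config=config)
    if len(np.unique(labels)) < 2:
        msg = "training set has a single class; classifier degenerates to majority"
        warnings.warn(msg, stacklevel=2)
        report.warnings.append(msg)
    model = CNNModel(config)
    rng = np.random.default_rng(config.seed)
    adam_m = {k: np.zeros_like(v) for k, v in model.params().items()}
    adam_v = {k: np.zeros_like(v) for k, v in model.params().items()}
    t = 0
    b1, b2, eps = 0.9, 0.999, 1e-8
    n = images.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = images[idx], labels[idx]
            onehot = np.eye(config.n_classes, dtype=np.float32)[yb]
            probs, cache = model.forward(xb, train=True)
            loss = -np.mean(np.log(np.clip(probs[np.arange(len(yb)), yb],
                                           1e-12, None)))
            losses.append(float(loss) * len(yb))
            grads = model._backward(cache, onehot)
            t += 1
            params = model.params()
            for k, g in grads.items():
                g = g.astype(np.float32)
                adam_m[k] = b1 * adam_m[k] + (1 - b1) * g
                adam_v[k] = b2 * adam_v[k] + (1 - b2) * g * g
                mhat = adam_m[k] / (1 - b1 ** t)
                vhat = adam_v[k] / (1 - b2 ** t)
                params[k] -= (config.learning_rate * mhat
                              / (np.sqrt(vhat) + eps)).astype(np.float32)
        report.epoch_loss.append(sum(losses) / n)
        if val_images is not None and len(val_images):
            correct = 0
            for start in range(0, len(val_images), config.batch_size):
                xb = np.asarray(val_images[start:start + config.batch_size],
                                dtype=np.float32)
                probs, _ = model.forward(xb)
                pred = (probs[:, 1] > 0.5).astype(int)
                correct += int(np.sum(pred == np.asarray(
                    val_labels[start:start + config.batch_size], dtype=int)))
            report.val_accuracy.append(correct / len(val_images))
    return model, report


def classify(model: CNNModel, img) -> tuple[str, float]:
    """Classify one optotype image; ties at 0.5 go to unrecognized.

    Accepts an ``OptotypeImage`` or a raw square array; returns
    ``(label, probability_of_recognized)``.
    """
    data = _image_array(img)
    probs, _ = model.forward(np.asarray(data, dtype=np.float32)[None])
    p_rec = float(probs[0, 1])
    label = CLASSES[1] if p_rec > 0.5 else CLASSES[0]
    return label, p_rec


def correlation_recognizer(img, true_letter: str, templates: dict) -> str:
    """Template-matching baseline using Pearson correlation.

    ``templates`` maps each Sloan letter to its noise-free neural image at
    the same logMAR and pixel scale. The optotype is recognized iff the
    best-correlated template is the true letter; a constant (zero-variance)
    image is unrecognized by convention.
    """
    x = _image_array(img).ravel().astype(float)
    if np.std(x) == 0:
        return CLASSES[0]
    best_letter, best_r = None, -np.inf
    for letter, tpl in templates.items():
        y = _image_array(tpl).ravel().astype(float)
        sy = np.std(y)
        r = -np.inf if sy == 0 else float(np.corrcoef(x, y)[0, 1])
        if r > best_r:
            best_letter, best_r = letter, r
    return CLASSES[1] if best_letter == true_letter else CLASSES[0]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts indexed [output, target], classes (unrecognized, recognized)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.shape != (2, 2) or np.any(c < 0) or c.sum() <= 0:
            raise ValueError("counts must be a non-negative 2x2 with total > 0")
        object.__setattr__(self, "counts", c)

    @classmethod
    def from_counts(cls, pred_unrec_tgt_unrec: float, pred_unrec_tgt_rec: float,
                    pred_rec_tgt_unrec: float, pred_rec_tgt_rec: float):
        return cls(np.array([[pred_unrec_tgt_unrec, pred_unrec_tgt_rec],
                             [pred_rec_tgt_unrec, pred_rec_tgt_rec]]))

    @classmethod
    def from_labels(cls, predicted, target):
        c = np.zeros((2, 2))
        for p, t in zip(predicted, target):
            pi = CLASSES.index(p) if isinstance(p, str) else int(p)
            ti = CLASSES.index(t) if isinstance(t, str) else int(t)
            c[pi, ti] += 1
        return cls(c)


@dataclass(frozen=True)
class ConfusionMetrics:
    """Axis-explicit confusion-matrix fractions, all in [0, 1]."""

    row_fraction: dict      # per predicted class: diagonal / row total
    column_fraction: dict   # per target class: diagonal / column total
    accuracy: float


def confusion_metrics(cm: ConfusionMatrix) -> ConfusionMetrics:
    """Row fractions, column fractions and accuracy of a 2x2 matrix.

    A zero row or column makes its fraction NaN with a warning.
    """
    c = cm.counts
    row_tot = c.sum(axis=1)
    col_tot = c.sum(axis=0)
    row_frac, col_frac = {}, {}
    for i, name in enumerate(CLASSES):
        if row_tot[i] == 0:
            warnings.warn(f"empty predicted-{name} row; fraction undefined",
                          stacklevel=2)
            row_frac[name] = float("nan")
        else:
            row_frac[name] = float(c[i, i] / row_tot[i])
        if col_tot[i] == 0:
            warnings.warn(f"empty target-{name} column; fraction undefined",
                          stacklevel=2)
            col_frac[name] = float("nan")
        else:
            col_frac[name] = float(c[i, i] / col_tot[i])
    return ConfusionMetrics(row_fraction=row_frac, column_fraction=col_frac,
                            accuracy=float(np.trace(c) / c.sum()))
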
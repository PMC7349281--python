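"""Convolutional promoter classifier and its evaluation machinery.

The network consumes a 250x4 one-hot sequence (optionally plus an auxiliary
feature vector joined at the flattening stage) and emits the probability
that the window is a core promoter.  Architecture: four 1D-convolutional
layers (64/128/256/512 filters, width 21, stride 2, zero padding, ReLU,
dropout 0.2 after each), a flattening layer, dense layers of 128 and 64
units, and a single sigmoid output.  Training uses the Adam optimizer with
L2 weight penalty and binary cross-entropy loss.  Stride-2 convolutions
provide the downsampling; there are no pooling layers.

The implementation is self-contained numpy (im2col convolutions with exact
backprop), which keeps training deterministic for a fixed seed on a single
CPU.  Filter counts are configurable so that desk-scale models can be
trained quickly; the layer count is fixed at four.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .sequtils import one_hot

__all__ = [
    "PromoterCNN",
    "ConfusionCounts",
    "EvalMetrics",
    "build_model",
    "train",
    "evaluate",
    "confusion_from_predictions",
    "metrics_from_confusion",
    "cross_species_matrix",
    "ablation_grid",
]


# ---------------------------------------------------------------------------
# Evaluation metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class EvalMetrics:
    acc: float
    sensitivity: float
    specificity: float
    mcc: float


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same shape")
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def metrics_from_confusion(cc: ConfusionCounts) -> EvalMetrics:
    """ACC, sensitivity (TPR), specificity (TNR) and the Matthews correlation
    coefficient from raw counts.  MCC is defined as 0 when any marginal of the
    confusion table is zero (the correlation is then degenerate)."""
    total = cc.total
    acc = (cc.tp + cc.tn) / total if total else 0.0
    sens = cc.tp / (cc.tp + cc.fn) if (cc.tp + cc.fn) else 0.0
    spec = cc.tn / (cc.tn + cc.fp) if (cc.tn + cc.fp) else 0.0
    denom = (
        (cc.tp + cc.fp) * (cc.tp + cc.fn) * (cc.tn + cc.fp) * (cc.tn + cc.fn)
    )
    mcc = ((cc.tp * cc.tn - cc.fp * cc.fn) / np.sqrt(denom)) if denom else 0.0
    return EvalMetrics(acc=acc, sensitivity=sens, specificity=spec, mcc=float(mcc))


# ---------------------------------------------------------------------------
# numpy layers
# ---------------------------------------------------------------------------

def _same_pad(length: int, kernel: int, stride: int) -> tuple[int, int, int]:
    out = -(-length // stride)  # ceil
    pad_total = max((out - 1) * stride + kernel - length, 0)
    left = pad_total // 2
    return out, left, pad_total - left


def _conv_forward(x, w, b, stride):
    """x: (N, L, C); w: (K*C, F); b: (F,) -> (y, cols) with y: (N, out, F)."""
    n, length, c = x.shape
    k = w.shape[0] // c
    out, left, right = _same_pad(length, k, stride)
    xp = np.pad(x, ((0, 0), (left, right), (0, 0)))
    starts = np.arange(out) * stride
    cols = xp[:, starts[:, None] + np.arange(k), :]  # (N, out, K, C)
    cols = cols.reshape(n, out, k * c)
    y = cols @ w + b
    return y, cols, (length, k, left, right, out)


def _conv_backward(dy, cols, w, geom, stride):
    """dy: (N, out, F) -> (dx, dw, db)."""
    length, k, left, right, out = geom
    n = dy.shape[0]
    c = w.shape[0] // k
    dw = np.einsum("nok,nof->kf", cols, dy)
    db = dy.sum(axis=(0, 1))
    dcols = (dy @ w.T).reshape(n, out, k, c)
    dxp = np.zeros((n, length + left + right, c), dtype=dy.dtype)
    starts = np.arange(out) * stride
    for kk in range(k):
        dxp[:, starts + kk, :] += dcols[:, :, kk, :]
    dx = dxp[:, left : left + length, :]
    return dx, dw, db


def _weights_checksum(weights: Sequence[np.ndarray]) -> str:
    h = hashlib.sha256()
    for w in weights:
        h.update(np.ascontiguousarray(w, dtype=np.float64).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class PromoterCNN(ClassifierMixin, BaseEstimator):
    """Sklearn-style binary promoter classifier (see module docstring).

    Parameters
    ----------
    conv_filters : tuple of 4 ints
        Filters of the four convolutional layers; default (64, 128, 256, 512).
        Exactly four layers are required.
    kernel_size, stride : int
        Convolution width (21) and stride (2), shared across layers.
    dropout : float
        Dropout rate applied after every convolution (training only).
    dense_units : tuple of ints
        Fully-connected layer widths after flattening; default (128, 64).
    epochs, batch_size, learning_rate, l2 : training hyperparameters
        (Adam optimizer, L2 penalty on weights, binary cross-entropy loss).
    threshold : float
        Decision threshold on the sigmoid output for ``predict``.
    class_weight : None or 'balanced'
        'balanced' weights samples by inverse class frequency in the loss,
        for training sets where the non-promoter pool outnumbers the
        promoters.
    seed : int
        Seeds weight initialisation, dropout and batch shuffling; training
        is deterministic for a fixed seed on a single CPU.

    Attributes (after ``fit``)
    --------------------------
    weights_, biases_ : learned parameters per layer.
    loss_curve_ : mean training loss per epoch.
    classes_ : ``array([0, 1])`` (1 = promoter).
    n_aux_features_ : auxiliary feature dimension the model was fit with.
    """

    def __init__(
        self,
        conv_filters: tuple[int, ...] = (64, 128, 256, 512),
        kernel_size: int = 21,
        stride: int = 2,
        dropout: float = 0.2,
        dense_units: tuple[int, ...] = (128, 64),
        epochs: int = 20,
        batch_size: int = 64,
        learning_rate: float = 1e-3,
        l2: float = 1e-4,
        threshold: float = 0.5,
        class_weight: str | None = None,
        seed: int = 0,
        verbose: int = 0,
    ):
        self.conv_filters = conv_filters
        self.kernel_size = kernel_size
        self.stride = stride
        self.dropout = dropout
        self.dense_units = dense_units
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.l2 = l2
        self.threshold = threshold
        self.class_weight = class_weight
        self.seed = seed
        self.verbose = verbose

    # -- input handling ----------------------------------------------------

    def _validate_config(self) -> None:
        if len(self.conv_filters) != 4:
            raise ValueError(
                f"the architecture requires exactly 4 convolutional layers, "
                f"got {len(self.conv_filters)} filter counts"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.class_weight not in (None, "balanced"):
            raise ValueError("class_weight must be None or 'balanced'")

    @staticmethod
    def _encode_X(X) -> np.ndarray:
        if isinstance(X, np.ndarray) and X.ndim == 3:
            if X.shape[2] != 4:
                raise ValueError("one-hot input must have 4 channels")
            return X.astype(np.float32)
        return np.stack([one_hot(s) for s in X]).astype(np.float32)

    def _check_aux(self, aux, n: int) -> np.ndarray:
        if aux is None:
            return np.zeros((n, 0), dtype=np.float32)
        aux = np.asarray(aux, dtype=np.float32)
        if aux.ndim != 2 or aux.shape[0] != n:
            raise ValueError("aux must be a (n_samples, n_aux_features) matrix")
        return aux

    # -- parameter initialisation ------------------------------------------

    def _init_params(self, input_length: int, n_aux: int, rng: np.random.Generator):
        weights, biases = [], []
        c = 4
        length = input_length
        for f in self.conv_filters:
            fan_in = self.kernel_size * c
            weights.append(
                (rng.standard_normal((fan_in, f)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
            )
            biases.append(np.zeros(f, dtype=np.float32))
            length, _, _ = _same_pad(length, self.kernel_size, self.stride)
            c = f
        flat = length * c + n_aux
        self._flat_geometry = (length, c)
        dims = [flat, *self.dense_units, 1]
        for i in range(len(dims) - 1):
            weights.append(
                (rng.standard_normal((dims[i], dims[i + 1])) * np.sqrt(2.0 / dims[i])).astype(
                    np.float32
                )
            )
            biases.append(np.zeros(dims[i + 1], dtype=np.float32))
        return weights, biases

    # -- forward / backward ------------------------------------------------

    def _forward(self, x, aux, weights, biases, rng=None):
        """Returns (probabilities, caches); ``rng`` enables dropout."""
        caches = []
        a = x
        n_conv = len(self.conv_filters)
        for li in range(n_conv):
            z, cols, geom = _conv_forward(a, weights[li], biases[li], self.stride)
            relu_mask = z > 0
            a_out = z * relu_mask
            if rng is not None and self.dropout > 0:
                keep = (rng.random(a_out.shape) >= self.dropout).astype(np.float32)
                a_out = a_out * keep / (1.0 - self.dropout)
            else:
                keep = None
            caches.append((cols, geom, relu_mask, keep, a.shape))
            a = a_out
        n = a.shape[0]
        flat = a.reshape(n, -1)
        h = np.concatenate([flat, aux], axis=1) if aux.shape[1] else flat
        dense_caches = []
        for li in range(n_conv, len(weights) - 1):
            z = h @ weights[li] + biases[li]
            mask = z > 0
            dense_caches.append((h, mask))
            h = z * mask
        z_out = h @ weights[-1] + biases[-1]
        p = 1.0 / (1.0 + np.exp(-z_out[:, 0]))
        caches.append(("dense", dense_caches, h, flat.shape, aux.shape[1]))
        return p, caches

    def _backward(self, p, y, caches, weights, sample_weight=None):
        n = len(y)
        n_conv = len(self.conv_filters)
        _, dense_caches, h_last, flat_shape, n_aux = caches[-1]
        grads_w = [None] * len(weights)
        grads_b = [None] * len(weights)
        if sample_weight is None:
            dz = ((p - y) / n)[:, None]  # sigmoid + BCE combined
        else:
            dz = (sample_weight * (p - y) / sample_weight.sum())[:, None]
        grads_w[-1] = h_last.T @ dz
        grads_b[-1] = dz.sum(axis=0)
        dh = dz @ weights[-1].T
        for li in range(len(weights) - 2, n_conv - 1, -1):
            h_in, mask = dense_caches[li - n_conv]
            dzl = dh * mask
            grads_w[li] = h_in.T @ dzl
            grads_b[li] = dzl.sum(axis=0)
            dh = dzl @ weights[li].T
        if n_aux:
            dh = dh[:, : -n_aux]
        da = dh.reshape(flat_shape[0], *self._conv_out_shape)
        for li in range(n_conv - 1, -1, -1):
            cols, geom, relu_mask, keep, in_shape = caches[li]
            if keep is not None:
                da = da * keep / (1.0 - self.dropout)
            dz = da * relu_mask
            da, grads_w[li], grads_b[li] = _conv_backward(
                dz, cols, weights[li], geom, self.stride
            )
        return grads_w, grads_b

    # -- public API --------------------------------------------------------

    def fit(self, X, y, aux=None):
        """Train on sequences (strings or (n, L, 4) one-hot) and 0/1 labels."""
        self._validate_config()
        X = self._encode_X(X)
        y = np.asarray(y).astype(np.float32)
        if len(X) == 0:
            raise ValueError("training set is empty")
        if len(X) != len(y):
            raise ValueError("X and y disagree in length")
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("labels must be binary 0/1")
        aux = self._check_aux(aux, len(X))
        self.n_aux_features_ = aux.shape[1]
        self.input_length_ = X.shape[1]
        if self.class_weight == "balanced":
            # inverse-frequency weights, mean 1 over the training set
            n_pos = float(y.sum())
            n_neg = float(len(y) - y.sum())
            if n_pos == 0 or n_neg == 0:
                raise ValueError("balanced class weights need both classes present")
            w_pos, w_neg = len(y) / (2 * n_pos), len(y) / (2 * n_neg)
            sample_w = np.where(y == 1, w_pos, w_neg).astype(np.float32)
        else:
            sample_w = None
        rng = np.random.default_rng(self.seed)
        weights, biases = self._init_params(self.input_length_, aux.shape[1], rng)
        self._conv_out_shape = self._flat_geometry

        m_w = [np.zeros_like(w) for w in weights]
        v_w = [np.zeros_like(w) for w in weights]
        m_b = [np.zeros_like(b) for b in biases]
        v_b = [np.zeros_like(b) for b in biases]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        lr = self.learning_rate
        self.loss_curve_ = []
        n = len(X)
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb, ab = X[idx], y[idx], aux[idx]
                wb = sample_w[idx] if sample_w is not None else None
                p, caches = self._forward(xb, ab, weights, biases, rng=rng)
                p_c = np.clip(p, 1e-7, 1 - 1e-7)
                bce = -(yb * np.log(p_c) + (1 - yb) * np.log(1 - p_c))
                loss = float(np.average(bce, weights=wb))
                losses.append(loss)
                gw, gb = self._backward(p, yb, caches, weights, sample_weight=wb)
                t += 1
                corr1 = 1 - beta1**t
                corr2 = 1 - beta2**t
                for i in range(len(weights)):
                    g = gw[i] + self.l2 * weights[i]
                    m_w[i] = beta1 * m_w[i] + (1 - beta1) * g
                    v_w[i] = beta2 * v_w[i] + (1 - beta2) * g * g
                    weights[i] = weights[i] - lr * (m_w[i] / corr1) / (
                        np.sqrt(v_w[i] / corr2) + eps
                    )
                    m_b[i] = beta1 * m_b[i] + (1 - beta1) * gb[i]
                    v_b[i] = beta2 * v_b[i] + (1 - beta2) * gb[i] * gb[i]
                    biases[i] = biases[i] - lr * (m_b[i] / corr1) / (
                        np.sqrt(v_b[i] / corr2) + eps
                    )
            self.loss_curve_.append(float(np.mean(losses)))
            if self.verbose:
                print(f"epoch {epoch + 1}/{self.epochs} loss {self.loss_curve_[-1]:.4f}")
        self.weights_ = weights
        self.biases_ = biases
        self.classes_ = np.array([0, 1])
        return self

    def decision_probabilities(self, X, aux=None, batch_size: int = 512) -> np.ndarray:
        """Sigmoid output per sample, strictly in (0, 1)."""
        check_is_fitted(self, "weights_")
        X = self._encode_X(X)
        aux = self._check_aux(aux, len(X))
        if aux.shape[1] != self.n_aux_features_:
            raise ValueError(
                f"model was fit with {self.n_aux_features_} auxiliary features, "
                f"got {aux.shape[1]}"
            )
        self._conv_out_shape = self._flat_geometry
        out = []
        for start in range(0, len(X), batch_size):
            p, _ = self._forward(
                X[start : start + batch_size], aux[start : start + batch_size],
                self.weights_, self.biases_, rng=None,
            )
            out.append(p)
        return np.concatenate(out) if out else np.zeros(0)

    def predict_proba(self, X, aux=None) -> np.ndarray:
        p = self.decision_probabilities(X, aux=aux)
        return np.column_stack([1 - p, p])

    def predict(self, X, aux=None) -> np.ndarray:
        return (self.decision_probabilities(X, aux=aux) >= self.threshold).astype(int)

    def weights_checksum(self) -> str:
        """SHA-256 over all learned parameters (determinism checks)."""
        check_is_fitted(self, "weights_")
        return _weights_checksum([*self.weights_, *self.biases_])

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        check_is_fitted(self, "weights_")
        arrays = {f"w{i}": w for i, w in enumerate(self.weights_)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.biases_)})
        np.savez(
            path,
            format_version=np.array([1]),
            params=np.array([repr(self.get_params())], dtype=object),
            n_aux=np.array([self.n_aux_features_]),
            input_length=np.array([self.input_length_]),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "PromoterCNN":
        data = np.load(path, allow_pickle=True)
        params = eval(str(data["params"][0]))  # noqa: S307 - own checkpoint format
        model = cls(**params)
        n_layers = len([k for k in data.files if k.startswith("w")])
        model.weights_ = [data[f"w{i}"] for i in range(n_layers)]
        model.biases_ = [data[f"b{i}"] for i in range(n_layers)]
        model.n_aux_features_ = int(data["n_aux"][0])
        model.input_length_ = int(data["input_length"][0])
        model._validate_config()
        length = model.input_length_
        for _ in model.conv_filters:
            length, _, _ = _same_pad(length, model.kernel_size, model.stride)
        model._flat_geometry = (length, model.conv_filters[-1])
        model.classes_ = np.array([0, 1])
        return model


# ---------------------------------------------------------------------------
# Module-level wrappers
# ---------------------------------------------------------------------------

def build_model(aux_feature_dim: int = 0, **params) -> PromoterCNN:
    """Untrained classifier; ``aux_feature_dim`` is checked at fit time."""
    model = PromoterCNN(**params)
    model._validate_config()
    model._declared_aux_dim = aux_feature_dim
    return model


def train(model: PromoterCNN, X, y, aux=None) -> PromoterCNN:
    declared = getattr(model, "_declared_aux_dim", None)
    if declared is not None and aux is not None and np.asarray(aux).shape[1] != declared:
        raise ValueError("auxiliary feature dimension differs from build_model declaration")
    return model.fit(X, y, aux=aux)


def evaluate(model: PromoterCNN, X, y, aux=None) -> tuple[ConfusionCounts, EvalMetrics]:
    """Threshold the sigmoid output and score against the labels."""
    pred = model.predict(X, aux=aux)
    cc = confusion_from_predictions(y, pred)
    return cc, metrics_from_confusion(cc)


def cross_species_matrix(
    groups: Mapping[str, tuple[Sequence, Sequence]],
    estimator_params: dict | None = None,
    train_fraction: float = 0.9,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[tuple[str, str], EvalMetrics]]:
    """Train one model per group; evaluate every model on every group's
    held-out split.  Returns (ACC grid with trained groups as rows and
    evaluated groups as columns, full metrics per cell).  The diagonal is
    intra-group performance."""
    from .datasets import LabeledSequence, split_train_test  # local to avoid cycle

    params = dict(estimator_params or {})
    names = list(groups)
    splits = {}
    for gi, name in enumerate(names):
        X, y = groups[name]
        wrapped = [
            LabeledSequence(f"{name}_{i}", s, "promoter" if yy else "non_promoter",
                            "core_promoter" if yy else "random_genomic", name)
            for i, (s, yy) in enumerate(zip(X, y))
        ]
        tr, te = split_train_test(wrapped, train_fraction, seed=seed + gi)
        splits[name] = (
            ([s.seq for s in tr], np.array([s.label == "promoter" for s in tr], dtype=int)),
            ([s.seq for s in te], np.array([s.label == "promoter" for s in te], dtype=int)),
        )
    acc = pd.DataFrame(index=names, columns=names, dtype=float)
    full: dict[tuple[str, str], EvalMetrics] = {}
    for gi, trained_on in enumerate(names):
        (Xtr, ytr), _ = splits[trained_on]
        model = PromoterCNN(**{**params, "seed": params.get("seed", seed) + gi})
        model.fit(Xtr, ytr)
        for evaluated_on in names:
            _, (Xte, yte) = splits[evaluated_on]
            _, metrics = evaluate(model, Xte, yte)
            acc.loc[trained_on, evaluated_on] = metrics.acc
            full[(trained_on, evaluated_on)] = metrics
    return acc, full


def ablation_grid(
    feature_configs: Mapping[str, "object"],
    train_set: tuple[Sequence[str], Sequence[int]],
    test_set: tuple[Sequence[str], Sequence[int]],
    estimator_params: dict | None = None,
) -> pd.DataFrame:
    """One row of evaluation metrics per auxiliary-feature combination.

    Every row reuses the identical train/test split and seed; only the
    auxiliary features differ.  A ``split_checksum`` column certifies this.
    """
    from .features import SequenceFeaturizer

    Xtr, ytr = list(train_set[0]), np.asarray(train_set[1], dtype=int)
    Xte, yte = list(test_set[0]), np.asarray(test_set[1], dtype=int)
    checksum = hashlib.sha256(
        ("\n".join(Xtr) + "|" + "\n".join(Xte)).encode()
    ).hexdigest()[:16]
    rows = []
    params = dict(estimator_params or {})
    for name, cfg in feature_configs.items():
        featurizer = SequenceFeaturizer(cfg).fit(Xtr)
        aux_tr = featurizer.transform(Xtr)
        aux_te = featurizer.transform(Xte)
        if aux_tr.shape[1] == 0:
            aux_tr = aux_te = None
        model = PromoterCNN(**params)
        model.fit(Xtr, ytr, aux=aux_tr)
        _, metrics = evaluate(model, Xte, yte, aux=aux_te)
        rows.append(
            {
                "features": name,
                "acc": metrics.acc,
                "sensitivity": metrics.sensitivity,
                "specificity": metrics.specificity,
                "mcc": metrics.mcc,
                "split_checksum": checksum,
            }
        )
    return pd.DataFrame(rows)
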
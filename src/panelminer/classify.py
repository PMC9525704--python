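"""Subtype classification and evaluation of candidate feature panels.

The reference model is a self-organizing deep auto-encoder ("sodae"): a
stacked auto-encoder classifier that grows its own architecture.  Starting
from one encoding layer it first widens the layer, then appends deeper
layers, accepting a step only while the relative validation-loss improvement
exceeds a tolerance.  Each encoding layer is pretrained by reconstructing its
input (linear decoder, mean-squared error), then the stack plus a softmax
class head is fine-tuned end-to-end by cross-entropy.  All arithmetic is
plain numpy with full-batch Adam, so runs are bit-reproducible under a seed.

Two further model kinds sit behind the same fit/predict/score contract: a
fixed-architecture multilayer perceptron baseline ("mlp_baseline") and a
nearest-centroid oracle ("nearest_centroid_oracle") used as an independent
cross-check in tests.

Evaluation reports a confusion matrix, headline accuracy (percent), and
per-class one-vs-rest precision/recall/F1 and ROC AUC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, roc_auc_score, roc_curve
from sklearn.neighbors import NearestCentroid
from sklearn.neural_network import MLPClassifier

__all__ = [
    "ClassifierConfig",
    "EvalReport",
    "SelfOrganizingAutoencoder",
    "make_classifier",
    "fit_classifier",
    "evaluate",
]

MODEL_KINDS = ("sodae", "mlp_baseline", "nearest_centroid_oracle")


@dataclass(frozen=True)
class ClassifierConfig:
    max_layers: int = 3
    max_units: int = 64
    growth_tol: float = 0.01
    pretrain_epochs: int = 150
    finetune_epochs: int = 300
    learning_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if min(self.max_layers, self.max_units, self.pretrain_epochs, self.finetune_epochs) < 1:
            raise ValueError("all counts must be >= 1")
        if self.growth_tol <= 0:
            raise ValueError("growth tolerance must be > 0")


# ---------------------------------------------------------------------------
# numpy training utilities


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray], b1=0.9, b2=0.999, eps=1e-8) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mh = m / (1 - b1**self.t)
            vh = v / (1 - b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + eps)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


def _pretrain_layer(H: np.ndarray, units: int, cfg: ClassifierConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """Train a single sigmoid-encoder / linear-decoder auto-encoder on H."""
    d = H.shape[1]
    W1, b1 = _glorot(rng, d, units), np.zeros(units)
    W2, b2 = _glorot(rng, units, d), np.zeros(d)
    opt = _Adam([W1, b1, W2, b2], cfg.learning_rate)
    n = H.shape[0]
    for _ in range(cfg.pretrain_epochs):
        Z = _sigmoid(H @ W1 + b1)
        Xhat = Z @ W2 + b2
        dXhat = 2.0 * (Xhat - H) / (n * d)
        dW2 = Z.T @ dXhat
        db2 = dXhat.sum(axis=0)
        dZ = dXhat @ W2.T
        dA = dZ * Z * (1.0 - Z)
        dW1 = H.T @ dA
        db1 = dA.sum(axis=0)
        opt.step([dW1, db1, dW2, db2])
    return W1, b1


class _Network:
    """Sigmoid encoder stack with a softmax class head."""

    def __init__(self, weights, biases, Wo, bo):
        self.weights = weights
        self.biases = biases
        self.Wo = Wo
        self.bo = bo

    def encode(self, X: np.ndarray) -> list[np.ndarray]:
        acts = [X]
        for W, b in zip(self.weights, self.biases):
            acts.append(_sigmoid(acts[-1] @ W + b))
        return acts

    def proba(self, X: np.ndarray) -> np.ndarray:
        return _softmax(self.encode(X)[-1] @ self.Wo + self.bo)

    def loss(self, X: np.ndarray, Y: np.ndarray) -> float:
        p = self.proba(X)
        return float(-(Y * np.log(p + 1e-12)).sum() / X.shape[0])

    def params(self) -> list[np.ndarray]:
        return [*self.weights, *self.biases, self.Wo, self.bo]

    def copy(self) -> "_Network":
        return _Network(
            [W.copy() for W in self.weights],
            [b.copy() for b in self.biases],
            self.Wo.copy(),
            self.bo.copy(),
        )


def _finetune(net: _Network, X, Y, Xv, Yv, cfg: ClassifierConfig) -> tuple["_Network", float]:
    """End-to-end cross-entropy training; returns the best-validation snapshot."""
    opt = _Adam(net.params(), cfg.learning_rate)
    n = X.shape[0]
    best = net.copy()
    best_val = net.loss(Xv, Yv)
    for _ in range(cfg.finetune_epochs):
        acts = net.encode(X)
        P = _softmax(acts[-1] @ net.Wo + net.bo)
        delta = (P - Y) / n
        dWo = acts[-1].T @ delta
        dbo = delta.sum(axis=0)
        grads_w: list[np.ndarray] = []
        grads_b: list[np.ndarray] = []
        d = delta @ net.Wo.T
        for l in range(len(net.weights) - 1, -1, -1):
            dA = d * acts[l + 1] * (1.0 - acts[l + 1])
            grads_w.append(acts[l].T @ dA)
            grads_b.append(dA.sum(axis=0))
            d = dA @ net.weights[l].T
        opt.step([*grads_w[::-1], *grads_b[::-1], dWo, dbo])
        val = net.loss(Xv, Yv)
        if val < best_val:
            best_val = val
            best = net.copy()
    return best, best_val


class SelfOrganizingAutoencoder:
    """Stacked auto-encoder classifier with greedy architecture growth."""

    def __init__(self, config: ClassifierConfig | None = None):
        self.config = config or ClassifierConfig()
        self.classes_: np.ndarray | None = None
        self.net_: _Network | None = None
        self.architecture_: tuple[int, ...] = ()
        self.validation_accuracy_: float | None = None

    # -- internals --------------------------------------------------------
    def _build(self, X, Y, Xv, Yv, widths: list[int], trial: int):
        cfg = self.config
        rng = np.random.default_rng([cfg.seed, trial])
        weights, biases = [], []
        H = X
        for u in widths:
            W, b = _pretrain_layer(H, u, cfg, rng)
            weights.append(W)
            biases.append(b)
            H = _sigmoid(H @ W + b)
        k = Y.shape[1]
        net = _Network(weights, biases, _glorot(rng, widths[-1], k), np.zeros(k))
        return _finetune(net, X, Y, Xv, Yv, cfg)

    def fit(self, X, y, X_val=None, y_val=None) -> "SelfOrganizingAutoencoder":
        cfg = self.config
        cfg.validate()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        self.classes_ = np.array(sorted(set(y)), dtype=object)
        if len(self.classes_) < 2:
            raise ValueError("training data holds a single class; nothing to discriminate")
        if X_val is None or y_val is None:
            X_val, y_val = X, y
        X_val = np.asarray(X_val, dtype=float)
        y_val = np.asarray(y_val, dtype=object)
        cls_idx = {c: i for i, c in enumerate(self.classes_)}
        Y = np.eye(len(self.classes_))[[cls_idx[c] for c in y]]
        Yv = np.eye(len(self.classes_))[[cls_idx[c] for c in y_val]]

        start = min(cfg.max_units, max(16, 4 * len(self.classes_)))
        candidates: list[tuple[list[int], _Network, float]] = []
        trial = 0
        widths = [start]
        net, val = self._build(X, Y, X_val, Yv, widths, trial)
        candidates.append((widths, net, val))
        # widen the single layer while it pays off
        while widths[0] * 2 <= cfg.max_units:
            trial += 1
            wider = [widths[0] * 2]
            net2, val2 = self._build(X, Y, X_val, Yv, wider, trial)
            candidates.append((wider, net2, val2))
            if (val - val2) / max(val, 1e-12) <= cfg.growth_tol:
                break
            widths, val = wider, val2
        # then deepen while it pays off
        while len(widths) < cfg.max_layers:
            trial += 1
            deeper = widths + [max(2, widths[-1] // 2)]
            net3, val3 = self._build(X, Y, X_val, Yv, deeper, trial)
            candidates.append((deeper, net3, val3))
            if (val - val3) / max(val, 1e-12) <= cfg.growth_tol:
                break
            widths, val = deeper, val3

        # model selection: best validation accuracy, earlier (smaller) on ties
        def val_acc(net: _Network) -> float:
            pred = self.classes_[net.proba(X_val).argmax(axis=1)]
            return float(np.mean(pred == y_val))

        best = max(enumerate(candidates), key=lambda t: (val_acc(t[1][1]), -t[0]))
        _, (arch, net, _) = best
        self.net_ = net
        self.architecture_ = tuple(arch)
        self.validation_accuracy_ = val_acc(net)
        return self

    def predict_score(self, X) -> np.ndarray:
        if self.net_ is None:
            raise ValueError("model is not fitted")
        return self.net_.proba(np.asarray(X, dtype=float))

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_score(X).argmax(axis=1)]


class _SkWrapper:
    """Adapter putting sklearn estimators behind the fit/predict/score contract."""

    def __init__(self, est, soft: bool):
        self.est = est
        self.soft = soft
        self.classes_ = None

    def fit(self, X, y, X_val=None, y_val=None):
        y = np.asarray(y, dtype=object)
        if len(set(y)) < 2:
            raise ValueError("training data holds a single class; nothing to discriminate")
        self.est.fit(np.asarray(X, dtype=float), y)
        self.classes_ = np.asarray(self.est.classes_, dtype=object)
        return self

    def predict(self, X):
        return np.asarray(self.est.predict(np.asarray(X, dtype=float)), dtype=object)

    def predict_score(self, X):
        X = np.asarray(X, dtype=float)
        if self.soft:
            return self.est.predict_proba(X)
        # nearest-centroid: softmax of negative distances to class centroids
        d = np.stack(
            [np.linalg.norm(X - c, axis=1) for c in self.est.centroids_], axis=1
        )
        return _softmax(-d)


def make_classifier(model_kind: str, config: ClassifierConfig | None = None):
    """Instantiate one of the pluggable classifier kinds."""
    cfg = config or ClassifierConfig()
    if model_kind == "sodae":
        return SelfOrganizingAutoencoder(cfg)
    if model_kind == "mlp_baseline":
        return _SkWrapper(
            MLPClassifier(
                hidden_layer_sizes=(32,),
                max_iter=800,
                random_state=cfg.seed,
            ),
            soft=True,
        )
    if model_kind == "nearest_centroid_oracle":
        return _SkWrapper(NearestCentroid(), soft=False)
    raise ValueError(f"unknown model kind {model_kind!r}; expected one of {MODEL_KINDS}")


def fit_classifier(split, panel_features: list[str], config: ClassifierConfig | None = None,
                   model_kind: str = "sodae"):
    """Fit a classifier on the panel-restricted training partition of a split."""
    if not panel_features:
        raise ValueError("panel is empty")
    tr = split.train.subset_features(panel_features)
    va = split.validation.subset_features(panel_features)
    model = make_classifier(model_kind, config)
    return model.fit(tr.values, tr.labels, va.values, va.labels)


# ---------------------------------------------------------------------------
# metrics


@dataclass
class EvalReport:
    """Confusion matrix plus accuracy, per-class F1 and per-class one-vs-rest AUC."""

    partition: str
    classes: list[str]
    confusion: np.ndarray
    accuracy: float
    per_class: dict[str, dict[str, float | None]]
    roc_points: dict[str, pd.DataFrame] = field(default_factory=dict, repr=False)

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion, index=self.classes, columns=self.classes)

    def to_dict(self) -> dict:
        return {
            "partition": self.partition,
            "classes": self.classes,
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "per_class": self.per_class,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def evaluate(model, partition, tag: str = "test") -> EvalReport:
    """Score a fitted model on a labeled partition.

    Headline accuracy is 100 * (correct / total).  Per class, one-vs-rest
    TP/TN/FP/FN counts give precision, recall, F1 and the one-vs-rest
    accuracy; AUC comes from the class's continuous score.  A class absent
    from the partition gets AUC ``None`` (undefined), never 0.
    """
    classes = [str(c) for c in model.classes_]
    y_true = np.asarray(partition.labels, dtype=object)
    y_pred = model.predict(partition.values)
    scores = model.predict_score(partition.values)
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    n = cm.sum()
    accuracy = 100.0 * np.trace(cm) / n
    per_class: dict[str, dict[str, float | None]] = {}
    roc_points: dict[str, pd.DataFrame] = {}
    for k, cls in enumerate(classes):
        tp = int(cm[k, k])
        fn = int(cm[k].sum() - tp)
        fp = int(cm[:, k].sum() - tp)
        tn = int(n - tp - fn - fp)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        truth = (y_true == cls).astype(int)
        if truth.min() == truth.max():
            auc = None
        else:
            auc = float(roc_auc_score(truth, scores[:, k]))
            fpr, tpr, thr = roc_curve(truth, scores[:, k])
            roc_points[cls] = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
        per_class[cls] = {
            "tp": tp,
            "tn": tn,
            "fp": fp,
            "fn": fn,
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "accuracy_ovr": 100.0 * (tp + tn) / n,
            "auc": auc,
        }
    return EvalReport(
        partition=tag,
        classes=classes,
        confusion=cm,
        accuracy=float(accuracy),
        per_class=per_class,
        roc_points=roc_points,
    )
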
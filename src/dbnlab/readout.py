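"""Representation quality probes: pseudo-inverse readout and backprop head.

The quality of an unsupervised representation is measured by training a
linear classifier on the top-layer activations and reporting its percent
misclassification on held-out data. The linear map is obtained in closed
form: one-hot targets T, design matrix [H | 1], and W = pinv([H | 1])·T —
the direct pseudo-inverse solution to the least-squares problem. An
optional supervised fine-tuning pass turns the pre-trained stack plus a
softmax head into a feed-forward classifier trained by seeded mini-batch
gradient descent on the cross-entropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import TrainConfig, substream
from .dbn import DBN
from .rbm import sigm

__all__ = [
    "LabeledSet",
    "one_hot",
    "fit_readout_pinv",
    "classify",
    "classification_error",
    "SoftmaxNet",
    "finetune_backprop",
    "train_test_split_indices",
]


@dataclass
class LabeledSet:
    """Feature batch with integer class labels in [0, n_classes)."""

    X: np.ndarray
    y: np.ndarray
    n_classes: int

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X))
        self.y = np.asarray(self.y, dtype=int).ravel()
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X rows and label count differ")
        if self.y.size and (self.y.min() < 0 or self.y.max() >= self.n_classes):
            raise ValueError(f"labels must lie in [0, {self.n_classes})")


def one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    """0/1 target matrix, one row per label."""
    y = np.asarray(y, dtype=int).ravel()
    T = np.zeros((y.size, n_classes))
    T[np.arange(y.size), y] = 1.0
    return T


@dataclass
class ReadoutModel:
    """Linear readout: W_out maps [features | 1] to class scores."""

    W_out: np.ndarray  # (d_features + 1, n_classes)
    n_classes: int

    def scores(self, H: np.ndarray) -> np.ndarray:
        H = np.atleast_2d(np.asarray(H, dtype=np.float64))
        if H.shape[1] != self.W_out.shape[0] - 1:
            raise ValueError(
                f"readout expects {self.W_out.shape[0] - 1} features, got {H.shape[1]}"
            )
        return _with_bias(H) @ self.W_out


def _with_bias(H: np.ndarray) -> np.ndarray:
    return np.hstack([H, np.ones((H.shape[0], 1))])


def fit_readout_pinv(H: np.ndarray, y: np.ndarray, n_classes: Optional[int] = None) -> ReadoutModel:
    """Closed-form least-squares readout via the Moore–Penrose pseudo-inverse.

    Deterministic; rank deficiency (e.g. constant features) is handled by
    the pseudo-inverse itself and reported with a warning.
    """
    H = np.atleast_2d(np.asarray(H, dtype=np.float64))
    y = np.asarray(y, dtype=int).ravel()
    if H.shape[0] != y.size:
        raise ValueError("feature rows and label count differ")
    if n_classes is None:
        n_classes = int(y.max()) + 1
    counts = np.bincount(y, minlength=n_classes)
    if (counts == 0).any():
        raise ValueError("every class needs at least one training example")
    A = _with_bias(H)
    rank = np.linalg.matrix_rank(A)
    if rank < min(A.shape):
        warnings.warn(
            f"rank-deficient readout design matrix (rank {rank} < {min(A.shape)}); "
            "pseudo-inverse returns the minimum-norm solution",
            stacklevel=2,
        )
    W = np.linalg.pinv(A) @ one_hot(y, n_classes)
    return ReadoutModel(W_out=W, n_classes=n_classes)


def classify(model: ReadoutModel, H: np.ndarray) -> np.ndarray:
    """Argmax class per row; ties broken toward the lowest class index."""
    return np.argmax(model.scores(H), axis=1)


def classification_error(pred: np.ndarray, truth: np.ndarray) -> float:
    """Percent misclassified: 100 × mismatches / n."""
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    if pred.size == 0:
        raise ValueError("cannot score zero predictions")
    return float(100.0 * np.mean(pred != truth))


def train_test_split_indices(
    n: int, rng: np.random.Generator, test_fraction: float = 1.0 / 6.0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded shuffle split; default 5/6 train, 1/6 test."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    perm = rng.permutation(n)
    n_test = max(1, int(round(n * test_fraction)))
    return perm[n_test:], perm[:n_test]


# ----------------------------------------------------------------------
# Supervised fine-tuning head


class SoftmaxNet:
    """Feed-forward net: sigmoid hidden layers + softmax output.

    Hidden layers are initialized from a pre-trained DBN (recognition
    weights W and hidden biases); the output layer starts at zero. Used
    for the optional supervised fine-tuning pass.
    """

    def __init__(self, weights: list[np.ndarray], biases: list[np.ndarray]):
        if len(weights) != len(biases):
            raise ValueError("weights and biases lists must have equal length")
        self.weights = [np.asarray(W, dtype=np.float64) for W in weights]
        self.biases = [np.asarray(b, dtype=np.float64) for b in biases]

    @classmethod
    def from_dbn(cls, dbn: DBN, n_classes: int) -> "SoftmaxNet":
        if n_classes < 2:
            raise ValueError("classification needs at least 2 classes")
        weights = [l.W.astype(np.float64).copy() for l in dbn.layers]
        biases = [l.b_hid.astype(np.float64).copy() for l in dbn.layers]
        d_top = dbn.layers[-1].n_hidden
        weights.append(np.zeros((d_top, n_classes)))
        biases.append(np.zeros(n_classes))
        return cls(weights, biases)

    @property
    def n_classes(self) -> int:
        return self.weights[-1].shape[1]

    def forward(self, X: np.ndarray) -> list[np.ndarray]:
        """All layer activations, input first, softmax probabilities last."""
        acts = [np.atleast_2d(np.asarray(X, dtype=np.float64))]
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            acts.append(sigm(acts[-1] @ W + b))
        z = acts[-1] @ self.weights[-1] + self.biases[-1]
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        acts.append(e / e.sum(axis=1, keepdims=True))
        return acts

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.forward(X)[-1], axis=1)

    def loss_and_grads(
        self, X: np.ndarray, y: np.ndarray
    ) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
        """Mean cross-entropy and its analytic gradients by backprop."""
        acts = self.forward(X)
        P = acts[-1]
        n = P.shape[0]
        T = one_hot(y, self.n_classes)
        loss = float(-np.mean(np.sum(T * np.log(np.clip(P, 1e-300, None)), axis=1)))
        dW: list[np.ndarray] = [None] * len(self.weights)
        db: list[np.ndarray] = [None] * len(self.biases)
        delta = (P - T) / n
        for l in range(len(self.weights) - 1, -1, -1):
            dW[l] = acts[l].T @ delta
            db[l] = delta.sum(axis=0)
            if l > 0:
                da = delta @ self.weights[l].T
                delta = da * acts[l] * (1.0 - acts[l])
        return loss, dW, db


def finetune_backprop(
    dbn: DBN, train: LabeledSet, cfg: TrainConfig
) -> tuple[SoftmaxNet, np.ndarray]:
    """Supervised fine-tuning of the pre-trained stack.

    Seeded mini-batch gradient descent on the softmax cross-entropy,
    starting from the DBN's recognition weights with a zero-initialized
    output layer. Returns the network and the per-epoch training
    classification-error trace (percent). Plain first-order descent is
    used deliberately: fine-tuning here is a quality probe, not a
    state-of-the-art pursuit.
    """
    net = SoftmaxNet.from_dbn(dbn, train.n_classes)
    X = np.atleast_2d(np.asarray(train.X, dtype=np.float64))
    y = train.y
    trace = np.zeros(cfg.epochs)
    for epoch in range(cfg.epochs):
        rng = substream(cfg.seed, (3, epoch))
        perm = rng.permutation(X.shape[0])
        for i in range(0, X.shape[0], cfg.minibatch_size):
            idx = perm[i : i + cfg.minibatch_size]
            _, dW, db = net.loss_and_grads(X[idx], y[idx])
            for l in range(len(net.weights)):
                net.weights[l] -= cfg.eta * dW[l]
                net.biases[l] -= cfg.eta * db[l]
        trace[epoch] = classification_error(net.predict(X), y)
    return net, trace
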
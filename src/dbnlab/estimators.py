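"""scikit-learn-style estimators over the functional training core.

These are the primary public API: transformers for unsupervised
pretraining (`ContrastiveDivergenceRBM`, `DeepBeliefNetwork`) and
classifiers for representation probing (`PseudoInverseReadout`,
`DBNClassifier`). They follow the usual conventions — hyperparameters in
``__init__``, fitted state in trailing-underscore attributes,
``get_params``/``set_params`` inherited — and compose with pipelines and
model selection.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .config import TrainConfig, substream
from .dbn import DBN, count_parameters, propagate_up, train_dbn_greedy
from .rbm import RBMParams, init_rbm, sigm
from .readout import (
    LabeledSet,
    classification_error,
    classify,
    finetune_backprop,
    fit_readout_pinv,
)
from .train import train_rbm

__all__ = [
    "ContrastiveDivergenceRBM",
    "DeepBeliefNetwork",
    "PseudoInverseReadout",
    "DBNClassifier",
]


def _build_config(est, minibatch_size: int, n_samples: int) -> TrainConfig:
    S = min(minibatch_size, n_samples)
    packet = est.packet_size if est.packet_size is not None else S
    return TrainConfig(
        eta=est.eta,
        k=est.k,
        epochs=est.epochs,
        minibatch_size=S,
        packet_size=min(packet, S),
        seed=est.random_state,
        precision=est.precision,
        momentum=est.momentum,
        weight_decay=est.weight_decay,
        use_biases=est.use_biases,
    )


class ContrastiveDivergenceRBM(TransformerMixin, BaseEstimator):
    """Single RBM trained with CD-k mini-batch learning.

    ``transform`` returns the hidden activation probabilities
    sigm(X W + b_hid); ``inverse_transform`` the visible reconstruction
    probabilities.
    """

    def __init__(
        self,
        n_components: int = 64,
        eta: float = 0.1,
        k: int = 1,
        epochs: int = 10,
        minibatch_size: int = 125,
        packet_size: Optional[int] = None,
        momentum: float = 0.0,
        weight_decay: float = 0.0,
        use_biases: bool = True,
        precision: str = "double",
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.eta = eta
        self.k = k
        self.epochs = epochs
        self.minibatch_size = minibatch_size
        self.packet_size = packet_size
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.use_biases = use_biases
        self.precision = precision
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, dtype=np.float64)
        cfg = _build_config(self, self.minibatch_size, X.shape[0])
        params = init_rbm(
            X.shape[1],
            self.n_components,
            substream(cfg.seed, (2, 0)),
            use_biases=cfg.use_biases,
            dtype=cfg.dtype,
        )
        self.params_, self.reconstruction_errors_ = train_rbm(params, X, cfg)
        self.W_ = self.params_.W
        self.b_vis_ = self.params_.b_vis
        self.b_hid_ = self.params_.b_hid
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "params_")
        X = check_array(X, dtype=np.float64)
        return sigm(X @ self.W_ + self.b_hid_)

    def inverse_transform(self, H):
        check_is_fitted(self, "params_")
        H = check_array(H, dtype=np.float64)
        return sigm(H @ self.W_.T + self.b_vis_)


class DeepBeliefNetwork(TransformerMixin, BaseEstimator):
    """Greedy layer-wise stack of RBMs; ``transform`` yields top-layer activations.

    The reference architecture ``hidden_layer_sizes=(500, 500, 2000)`` on
    784-pixel images has 1,642,000 connections.
    """

    def __init__(
        self,
        hidden_layer_sizes: Sequence[int] = (500, 500, 2000),
        eta: float = 0.1,
        k: int = 1,
        epochs: int = 10,
        minibatch_size: int = 125,
        packet_size: Optional[int] = None,
        momentum: float = 0.0,
        weight_decay: float = 0.0,
        use_biases: bool = True,
        precision: str = "double",
        random_state: int = 0,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.eta = eta
        self.k = k
        self.epochs = epochs
        self.minibatch_size = minibatch_size
        self.packet_size = packet_size
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.use_biases = use_biases
        self.precision = precision
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, dtype=np.float64)
        cfg = _build_config(self, self.minibatch_size, X.shape[0])
        architecture = [X.shape[1], *self.hidden_layer_sizes]
        self.dbn_, self.reconstruction_errors_ = train_dbn_greedy(X, architecture, cfg)
        self.architecture_ = self.dbn_.architecture
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X, level: Optional[int] = None):
        check_is_fitted(self, "dbn_")
        X = check_array(X, dtype=np.float64)
        return propagate_up(self.dbn_, X, level=level)

    def count_parameters(self, include_biases: bool = False) -> int:
        check_is_fitted(self, "dbn_")
        return count_parameters(self.dbn_, include_biases=include_biases)


class PseudoInverseReadout(ClassifierMixin, BaseEstimator):
    """Closed-form linear classifier: W = pinv([X | 1]) · T with one-hot T."""

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        self.model_ = fit_readout_pinv(X, y_idx, n_classes=len(self.classes_))
        self.coef_ = self.model_.W_out
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X, dtype=np.float64)
        return self.model_.scores(X)

    def predict(self, X):
        return self.classes_[classify(self.model_, check_array(X, dtype=np.float64))]

    def error_pct(self, X, y) -> float:
        """Percent misclassification, the quality metric used throughout."""
        return classification_error(self.predict(X), np.asarray(y))


class DBNClassifier(ClassifierMixin, BaseEstimator):
    """Pretrained stack + softmax head, fine-tuned with backpropagation."""

    def __init__(
        self,
        dbn: Optional[DBN] = None,
        eta: float = 0.1,
        epochs: int = 10,
        minibatch_size: int = 125,
        random_state: int = 0,
    ):
        self.dbn = dbn
        self.eta = eta
        self.epochs = epochs
        self.minibatch_size = minibatch_size
        self.random_state = random_state

    def fit(self, X, y):
        if self.dbn is None:
            raise ValueError("DBNClassifier requires a pre-trained dbn")
        X, y = check_X_y(X, y, dtype=np.float64)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        cfg = TrainConfig(
            eta=self.eta,
            epochs=self.epochs,
            minibatch_size=min(self.minibatch_size, X.shape[0]),
            packet_size=1,
            seed=self.random_state,
        )
        train = LabeledSet(X=X, y=y_idx, n_classes=len(self.classes_))
        self.net_, self.training_errors_ = finetune_backprop(self.dbn, train, cfg)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "net_")
        X = check_array(X, dtype=np.float64)
        return self.classes_[self.net_.predict(X)]
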
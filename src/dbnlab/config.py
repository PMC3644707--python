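"""Training hyperparameter container shared by all learning routines."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

_PRECISIONS = {"single": np.float32, "double": np.float64}


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters for contrastive-divergence training.

    Parameters
    ----------
    eta : float
        Learning rate η > 0 applied when a gradient update is constructed.
    k : int
        Number of alternating block-Gibbs steps in the negative phase (CD-k).
    epochs : int
        Full passes over the training set.
    minibatch_size : int
        Number of patterns S averaged into one weight update.
    packet_size : int
        Share of a mini-batch handed to one simulated worker (default 125,
        the per-core share used on the reference cluster). Must not exceed
        ``minibatch_size``.
    seed : int
        Master seed; every epoch/mini-batch/packet derives its own
        substream deterministically from it.
    precision : {"double", "single"}
        Floating-point width used for weights and activations.
    momentum : float
        Velocity coefficient in [0, 1); 0 disables momentum.
    weight_decay : float
        L2 penalty coefficient ≥ 0; 0 disables decay.
    use_biases : bool
        Train visible/hidden bias vectors. When off they stay identically
        zero, matching the weights-only form of the update rule.
    sample_visible : bool
        Sample binary visible states in the negative phase instead of
        using mean-field reconstruction probabilities.
    strict_binary : bool
        Binarize every intermediate state (data-phase hiddens included),
        the literal stochastic recipe; mainly for oracle tests.
    """

    eta: float = 0.1
    k: int = 1
    epochs: int = 10
    minibatch_size: int = 125
    packet_size: int = 125
    seed: int = 0
    precision: str = "double"
    momentum: float = 0.0
    weight_decay: float = 0.0
    use_biases: bool = True
    sample_visible: bool = False
    strict_binary: bool = False

    def __post_init__(self) -> None:
        if not self.eta >= 0:
            raise ValueError(f"eta must be >= 0, got {self.eta}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.epochs < 0:
            raise ValueError(f"epochs must be >= 0, got {self.epochs}")
        if self.minibatch_size < 1:
            raise ValueError(f"minibatch_size must be >= 1, got {self.minibatch_size}")
        if self.packet_size < 1:
            raise ValueError(f"packet_size must be >= 1, got {self.packet_size}")
        if self.packet_size > self.minibatch_size:
            raise ValueError(
                f"packet_size ({self.packet_size}) must not exceed "
                f"minibatch_size ({self.minibatch_size})"
            )
        if self.precision not in _PRECISIONS:
            raise ValueError(f"precision must be one of {sorted(_PRECISIONS)}")
        if not 0 <= self.momentum < 1:
            raise ValueError(f"momentum must be in [0, 1), got {self.momentum}")
        if self.weight_decay < 0:
            raise ValueError(f"weight_decay must be >= 0, got {self.weight_decay}")
        if int(self.seed) < 0:
            raise ValueError(f"seed must be a non-negative integer, got {self.seed}")

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(_PRECISIONS[self.precision])

    def replace(self, **changes: Any) -> "TrainConfig":
        return replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return {
            "eta": self.eta,
            "k": self.k,
            "epochs": self.epochs,
            "minibatch_size": self.minibatch_size,
            "packet_size": self.packet_size,
            "seed": int(self.seed),
            "precision": self.precision,
            "momentum": self.momentum,
            "weight_decay": self.weight_decay,
            "use_biases": self.use_biases,
            "sample_visible": self.sample_visible,
            "strict_binary": self.strict_binary,
        }


def substream(seed: int, key: tuple[int, ...]) -> np.random.Generator:
    """Deterministic child generator for (seed, key).

    Substreams are a pure function of the master seed and an integer key,
    so results never depend on the order in which workers run.
    """
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))
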
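"""Deep belief network: greedy layer-wise stack of RBMs.

A DBN is an ordered stack of dimension-compatible RBMs trained greedily:
the first layer models the raw data, each subsequent layer models the
hidden representation produced by the stack below it. Learning stays
local to one layer pair at a time; stacking builds progressively more
abstract representations of the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import TrainConfig, substream
from .parallel import ProfileLog
from .rbm import RBMParams, init_rbm, sigm, stoch, _check_patterns
from .train import train_rbm

__all__ = ["DBN", "propagate_up", "train_dbn_greedy", "count_parameters"]


@dataclass
class DBN:
    """Ordered list of RBM layer pairs with chained dimensions."""

    layers: list[RBMParams]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.layers:
            raise ValueError("DBN needs at least one layer")
        for i in range(len(self.layers) - 1):
            if self.layers[i].n_hidden != self.layers[i + 1].n_visible:
                raise ValueError(
                    f"layer {i} has {self.layers[i].n_hidden} hidden units but "
                    f"layer {i + 1} expects {self.layers[i + 1].n_visible} visible"
                )

    @property
    def architecture(self) -> list[int]:
        """Layer widths [n_input, h1, h2, ...]; length = n RBMs + 1."""
        return [self.layers[0].n_visible] + [l.n_hidden for l in self.layers]

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def copy(self) -> "DBN":
        return DBN([l.copy() for l in self.layers])


def propagate_up(
    dbn: DBN,
    V: np.ndarray,
    level: Optional[int] = None,
    sample: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Propagate patterns through the first ``level`` layers.

    Deterministic composition of sigm affine maps (level 0 is the
    identity; ``level=None`` means the full stack). The optional sampling
    mode binarizes each intermediate representation; the default
    probability propagation is what higher layers are trained on.
    """
    if level is None:
        level = dbn.n_layers
    if not 0 <= level <= dbn.n_layers:
        raise ValueError(f"level must be in [0, {dbn.n_layers}], got {level}")
    H = _check_patterns(np.asarray(V), dbn.layers[0].n_visible, "V")
    for layer in dbn.layers[:level]:
        if H.shape[1] != layer.n_visible:  # pragma: no cover - chained by validate
            raise ValueError("dimension mismatch in stack")
        H = sigm(H @ layer.W + layer.b_hid)
        if sample:
            if rng is None:
                raise ValueError("sampling propagation requires an rng")
            H = stoch(H, rng)
    return H


def train_dbn_greedy(
    data: np.ndarray,
    architecture: Sequence[int],
    cfg: TrainConfig,
    layer_configs: Optional[Sequence[TrainConfig]] = None,
    profile: Optional[ProfileLog] = None,
) -> tuple[DBN, list[np.ndarray]]:
    """Greedy layer-wise unsupervised training of the full stack.

    Layer 1 is trained on the raw data; layer ℓ on the deterministic
    propagate_up output of the already-trained stack below. One
    TrainConfig applies to all layers unless ``layer_configs`` overrides
    per layer. Returns the DBN and one reconstruction-error trace per
    layer. Training a layer never touches the layers below it.
    """
    architecture = [int(w) for w in architecture]
    if len(architecture) < 2:
        raise ValueError("architecture needs at least [n_visible, n_hidden]")
    data = np.atleast_2d(np.asarray(data))
    if architecture[0] != data.shape[1]:
        raise ValueError(
            f"architecture[0]={architecture[0]} does not match pattern length {data.shape[1]}"
        )
    n_rbms = len(architecture) - 1
    if layer_configs is not None and len(layer_configs) != n_rbms:
        raise ValueError(f"need {n_rbms} layer configs, got {len(layer_configs)}")

    layers: list[RBMParams] = []
    traces: list[np.ndarray] = []
    H = data
    for i in range(n_rbms):
        layer_cfg = layer_configs[i] if layer_configs is not None else cfg
        init_rng = substream(layer_cfg.seed, (2, i))
        params = init_rbm(
            architecture[i],
            architecture[i + 1],
            init_rng,
            use_biases=layer_cfg.use_biases,
            dtype=layer_cfg.dtype,
        )
        trained, trace = train_rbm(params, H, layer_cfg, layer=i, profile=profile)
        layers.append(trained)
        traces.append(trace)
        H = sigm(H.astype(layer_cfg.dtype) @ trained.W + trained.b_hid)
    return DBN(layers), traces


def count_parameters(dbn: DBN, include_biases: bool = False) -> int:
    """Total connection count Σ n_visible × n_hidden (+ biases if asked).

    The reference three-layer architecture [784, 500, 500, 2000] has
    784·500 + 500·500 + 500·2000 = 1,642,000 weights — about 1.6 million
    connections.
    """
    total = sum(l.n_visible * l.n_hidden for l in dbn.layers)
    if include_biases:
        total += sum(l.n_visible + l.n_hidden for l in dbn.layers)
    return int(total)
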
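"""Mini-batch training loop for a single RBM via the master/worker path."""

from __future__ import annotations

from typing import Optional

import numpy as np

from .config import TrainConfig, substream
from .parallel import (
    PacketPlan,
    ProfileLog,
    average_updates,
    packet_gradients,
    split_minibatches,
)
from .rbm import RBMParams, Velocity, apply_update, _check_patterns

__all__ = ["train_rbm"]

# substream-key tags: 0 = per-epoch permutation, 1 = CD chains
_KEY_PERM = 0
_KEY_CD = 1


def train_rbm(
    params: RBMParams,
    data: np.ndarray,
    cfg: TrainConfig,
    layer: int = 0,
    profile: Optional[ProfileLog] = None,
) -> tuple[RBMParams, np.ndarray]:
    """Train one RBM with CD-k mini-batch learning.

    Every epoch draws a fresh seeded permutation, splits it into
    mini-batches of ``cfg.minibatch_size``, computes per-packet gradients
    (packet size ``cfg.packet_size``), averages them, and applies the
    update before the next mini-batch. Returns a trained copy of the
    parameters and a per-epoch trace of the mean squared reconstruction
    error (accumulated from the negative-phase reconstructions seen during
    that epoch). Fully reproducible: all randomness derives from
    ``cfg.seed`` and the (layer, epoch, batch, packet) position.
    """
    data = _check_patterns(np.asarray(data), params.n_visible, "data")
    if data.shape[0] == 0:
        raise ValueError("training data is empty")
    dtype = cfg.dtype
    data = data.astype(dtype, copy=False)
    params = params.astype(dtype)
    params.use_biases = cfg.use_biases
    velocity = Velocity.zeros_like(params)
    n = data.shape[0]
    trace = np.zeros(cfg.epochs, dtype=np.float64)

    for epoch in range(cfg.epochs):
        perm_rng = substream(cfg.seed, (_KEY_PERM, layer, epoch))
        blocks = split_minibatches(n, cfg.minibatch_size, perm_rng)
        sq_sum = 0.0
        for b, idx in enumerate(blocks):
            if profile:
                profile.start()
            plan = PacketPlan(
                minibatch_size=idx.size,
                packet_size=min(cfg.packet_size, idx.size),
                substream_key=(_KEY_CD, layer, epoch, b),
            )
            minibatch = data[idx]
            if profile:
                profile.stop("coordinate")
            updates, stats = packet_gradients(
                params, minibatch, plan, cfg, return_stats=True, profile=profile
            )
            if profile:
                profile.start()
            update = average_updates(updates)
            apply_update(params, update, cfg, velocity)
            if profile:
                profile.stop("coordinate")
            for s in stats:
                d = s.V_D.astype(np.float64) - s.V_M.astype(np.float64)
                sq_sum += float(np.sum(d * d))
        trace[epoch] = sq_sum / (n * params.n_visible)
    return params, trace
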
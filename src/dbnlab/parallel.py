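"""Data-parallel mini-batch semantics: packets, simulated workers, averaging.

On a message-passing cluster, a master node splits each mini-batch into
fixed-size data-packets (125 patterns per core in the reference setting),
every worker computes a weight update on its packet against the current
weights, and the master averages the proposed updates before the next
mini-batch. Using k cores therefore means training with mini-batches of
size S = k × 125.

Here the workers are simulated (sequential execution of per-packet
gradients with per-packet rng substreams). What the scheme actually
contributes mathematically — and what this module guarantees — is:

* determinism: results depend only on (seed, epoch, batch, packet), never
  on worker execution order;
* equivalence: the weighted average of per-packet updates equals the
  serial update computed on the concatenated mini-batch, because the CD
  update is linear in the per-pattern average.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import TrainConfig, substream
from .rbm import GradientUpdate, PhaseStatistics, RBMParams, cd_k, weight_update

__all__ = [
    "PacketPlan",
    "minibatch_size_for_workers",
    "split_minibatches",
    "packet_gradients",
    "average_updates",
    "serial_minibatch_update",
    "ProfileLog",
    "overhead_profile",
]

DEFAULT_PACKET_SIZE = 125


def minibatch_size_for_workers(n_workers: int, packet_size: int = DEFAULT_PACKET_SIZE) -> int:
    """Mini-batch size S = k × packet_size implied by k workers.

    With the default 125-pattern packet, 2, 4, 8, 16, 40, and 60 workers
    give mini-batches of 250, 500, 1000, 2000, 5000, and 7500 patterns.
    """
    if n_workers < 1 or packet_size < 1:
        raise ValueError("n_workers and packet_size must be >= 1")
    return n_workers * packet_size


@dataclass(frozen=True)
class PacketPlan:
    """Partition of one mini-batch into worker packets.

    Packets are contiguous, non-overlapping index blocks whose union is
    the mini-batch; all have ``packet_size`` rows except possibly a ragged
    final one. ``substream_key`` identifies this mini-batch in the seed
    hierarchy; packet p uses substream ``substream_key + (p,)``.
    """

    minibatch_size: int
    packet_size: int = DEFAULT_PACKET_SIZE
    substream_key: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.minibatch_size < 1:
            raise ValueError("minibatch_size must be >= 1")
        if self.packet_size < 1:
            raise ValueError("packet_size must be >= 1")

    @property
    def n_workers(self) -> int:
        return len(self.packets())

    def packets(self) -> list[np.ndarray]:
        edges = np.arange(0, self.minibatch_size + self.packet_size, self.packet_size)
        edges = np.clip(edges, 0, self.minibatch_size)
        return [
            np.arange(lo, hi)
            for lo, hi in zip(edges[:-1], edges[1:])
            if hi > lo
        ]


def split_minibatches(
    n_patterns: int, S: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Seeded random permutation of pattern indices, cut into S-sized blocks.

    All blocks have size S except possibly the last. If S exceeds the
    dataset a single block is returned and a warning is issued.
    """
    if S < 1:
        raise ValueError("minibatch size S must be >= 1")
    if n_patterns < 1:
        raise ValueError("need at least one pattern")
    if S > n_patterns:
        warnings.warn(
            f"minibatch size {S} exceeds dataset size {n_patterns}; "
            "using one full-dataset block",
            stacklevel=2,
        )
    perm = rng.permutation(n_patterns)
    return [perm[i : i + S] for i in range(0, n_patterns, S)]


def packet_gradients(
    params: RBMParams,
    minibatch: np.ndarray,
    plan: PacketPlan,
    cfg: TrainConfig,
    return_stats: bool = False,
    profile: Optional["ProfileLog"] = None,
):
    """Per-packet CD updates, one simulated worker per packet.

    Each packet runs cd_k + weight_update with its own rng substream
    derived from (cfg.seed, plan.substream_key, packet index), so output
    is independent of worker execution order.
    """
    minibatch = np.atleast_2d(np.asarray(minibatch))
    if minibatch.shape[0] != plan.minibatch_size:
        raise ValueError(
            f"plan expects {plan.minibatch_size} patterns, got {minibatch.shape[0]}"
        )
    updates: list[GradientUpdate] = []
    stats_list: list[PhaseStatistics] = []
    packet_times: list[float] = []
    for pid, idx in enumerate(plan.packets()):
        if idx.size == 0:  # pragma: no cover - excluded by PacketPlan.packets
            raise ValueError("empty packet")
        t0 = time.perf_counter()
        rng = substream(cfg.seed, plan.substream_key + (pid,))
        stats = cd_k(
            params,
            minibatch[idx],
            cfg.k,
            rng,
            sample_visible=cfg.sample_visible,
            strict_binary=cfg.strict_binary,
        )
        updates.append(weight_update(stats, cfg))
        packet_times.append(time.perf_counter() - t0)
        if return_stats:
            stats_list.append(stats)
    if profile is not None:
        profile.add_packet_times(packet_times)
    if return_stats:
        return updates, stats_list
    return updates


def average_updates(updates: list[GradientUpdate]) -> GradientUpdate:
    """Master-node averaging of worker updates, weighted by packet size.

    For equal packets this is the plain mean; weighting by n_patterns
    makes a ragged final packet exactly equivalent to the serial
    mini-batch computation.
    """
    if not updates:
        raise ValueError("average_updates needs at least one update")
    if len(updates) == 1:
        return updates[0]
    shape = updates[0].dW.shape
    for u in updates[1:]:
        if u.dW.shape != shape:
            raise ValueError("updates have inconsistent shapes")
    n_total = sum(u.n_patterns for u in updates)
    dW = sum(u.dW * u.n_patterns for u in updates) / n_total
    db_vis = sum(u.db_vis * u.n_patterns for u in updates) / n_total
    db_hid = sum(u.db_hid * u.n_patterns for u in updates) / n_total
    return GradientUpdate(dW=dW, db_vis=db_vis, db_hid=db_hid, n_patterns=n_total)


def serial_minibatch_update(
    params: RBMParams,
    minibatch: np.ndarray,
    plan: PacketPlan,
    cfg: TrainConfig,
) -> GradientUpdate:
    """Reference serial semantics: one update over the whole mini-batch.

    Stochastic phases reuse the same per-packet substream layout as
    :func:`packet_gradients`, so the only difference from the distributed
    path is where the pattern average is taken. Used to state and test the
    parallel-equivalence property.
    """
    _, stats_list = packet_gradients(params, minibatch, plan, cfg, return_stats=True)
    return weight_update(PhaseStatistics.concatenate(stats_list), cfg)


@dataclass
class ProfileLog:
    """Time bookkeeping for the simulated master/worker loop.

    ``compute_s`` accumulates per-packet gradient work (the workers);
    ``coordinate_s`` accumulates splitting, averaging, and weight
    application (the master). Because the simulated workers execute
    sequentially, ``parallel_compute_s`` additionally accumulates the
    critical path of each update — the slowest packet, i.e. the compute
    time a real k-worker cluster would spend — so that
    ``parallel_time_s`` models the execution time of the distributed
    loop. The analogue of the cluster's communication overhead is the
    coordinate share of that simulated time.
    """

    compute_s: float = 0.0
    coordinate_s: float = 0.0
    parallel_compute_s: float = 0.0
    _t0: float = field(default=0.0, repr=False)

    def start(self) -> None:
        self._t0 = time.perf_counter()

    def stop(self, kind: str) -> None:
        dt = time.perf_counter() - self._t0
        if kind == "compute":
            self.compute_s += dt
        elif kind == "coordinate":
            self.coordinate_s += dt
        else:
            raise ValueError(f"unknown profile category {kind!r}")

    def add_packet_times(self, packet_seconds: list[float]) -> None:
        """Record one update's worker times: total and critical path."""
        if packet_seconds:
            self.compute_s += sum(packet_seconds)
            self.parallel_compute_s += max(packet_seconds)

    @property
    def parallel_time_s(self) -> float:
        """Simulated k-worker execution time: critical path + coordination."""
        return self.parallel_compute_s + self.coordinate_s


def overhead_profile(log: ProfileLog) -> float:
    """Coordination fraction of the simulated parallel execution time."""
    total = log.parallel_compute_s + log.coordinate_s
    if total <= 0:
        return 0.0
    frac = log.coordinate_s / total
    return float(min(max(frac, 0.0), 1.0))
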
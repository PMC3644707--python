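"""Mini-batch-size trade-off sweep and trend regression fitters.

Larger mini-batches mean fewer, smoother weight updates: training gets
cheaper per epoch (and, on a cluster, parallelizes over more workers) but
the learned model gets worse. The sweep driver measures both sides of the
trade-off — unsupervised training time and readout classification error —
across a grid of mini-batch sizes with replicated seeded networks, and
the fitters quantify the trends: a power law time ≈ c·S^k on log-log
axes, and a linear regression of error on log10(S).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .config import TrainConfig, substream
from .datasets import gen_prototype_digits
from .dbn import propagate_up, train_dbn_greedy
from .parallel import ProfileLog, overhead_profile
from .readout import (
    classification_error,
    classify,
    fit_readout_pinv,
    train_test_split_indices,
)

__all__ = [
    "BenchTask",
    "BenchmarkRecord",
    "run_tradeoff",
    "records_to_frame",
    "write_records_csv",
    "read_records_csv",
    "fit_loglog_power",
    "fit_error_slope",
]

logger = logging.getLogger("dbnlab.bench")

#: Mini-batch grid used in the full-scale study (S = k × 125 for
#: k = 1, 2, 4, 8, 16, 40, 60 workers).
FULL_SCALE_GRID = (125, 250, 500, 1000, 2000, 5000, 7500)

#: Desk-scale grid with the same 16x geometric span.
DESK_SCALE_GRID = (25, 50, 100, 200, 400)


@dataclass(frozen=True)
class BenchTask:
    """Desk-scale synthetic trade-off task.

    Defaults: 4,000 prototype-digit images (16×16, 10 classes, pixel-flip
    noise 0.4 — high enough that a linear pixel readout makes measurable
    errors, so representation quality is visible in the metric), a
    three-RBM stack [256, 64, 64, 128] preserving the reference stack's
    shape at ~1/40 the parameter count, CD-1, packet size 25 (so the grid
    {25, 50, 100, 200, 400} spans 1–16 simulated workers).
    """

    n_patterns: int = 4000
    image_size: int = 16
    n_classes: int = 10
    flip_prob: float = 0.4
    hidden_layers: tuple[int, ...] = (64, 64, 128)
    epochs: int = 10
    eta: float = 0.1
    k: int = 1
    packet_size: int = 25
    precision: str = "double"
    test_fraction: float = 1.0 / 6.0

    def to_dict(self) -> dict:
        return {
            "n_patterns": self.n_patterns,
            "image_size": self.image_size,
            "n_classes": self.n_classes,
            "flip_prob": self.flip_prob,
            "hidden_layers": list(self.hidden_layers),
            "epochs": self.epochs,
            "eta": self.eta,
            "k": self.k,
            "packet_size": self.packet_size,
            "precision": self.precision,
            "test_fraction": self.test_fraction,
        }


@dataclass
class BenchmarkRecord:
    """One sweep cell: a freshly seeded network at one mini-batch size.

    ``train_time_s`` is the wall time of the sequential simulation;
    ``parallel_time_s`` is the simulated k-worker execution time
    (per-update critical path plus master coordination), the quantity
    whose decrease with S is the point of data-parallel training.
    """

    minibatch_size: int
    replicate: int
    seed: int
    train_time_s: float
    parallel_time_s: float
    error_pct: float
    overhead_fraction: float
    config_hash: str


_RECORD_COLUMNS = [
    "minibatch_size",
    "replicate",
    "seed",
    "train_time_s",
    "parallel_time_s",
    "error_pct",
    "overhead_fraction",
    "config_hash",
]


def _config_hash(cfg: TrainConfig, task: BenchTask) -> str:
    blob = json.dumps({"cfg": cfg.to_dict(), "task": task.to_dict()}, sort_keys=True)
    return hashlib.md5(blob.encode()).hexdigest()[:12]


def run_tradeoff(
    grid: Sequence[int],
    n_replicates: int = 5,
    task: Optional[BenchTask] = None,
    seed: int = 0,
) -> list[BenchmarkRecord]:
    """Sweep mini-batch sizes with replicated fresh networks.

    For every (S, replicate) cell a freshly seeded stack is trained
    unsupervised via the packet/averaging path, then a pseudo-inverse
    readout on the top-layer activations is scored on a held-out split.
    Classification errors are bit-reproducible given the master seed;
    wall times are hardware-dependent measurements. A failing cell is
    logged and skipped; the sweep continues.
    """
    task = task or BenchTask()
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    for S in grid:
        if S > task.n_patterns:
            raise ValueError(f"grid value {S} exceeds dataset size {task.n_patterns}")

    data = gen_prototype_digits(
        task.n_patterns,
        n_classes=task.n_classes,
        size=task.image_size,
        flip_prob=task.flip_prob,
        rng=substream(seed, (10,)),
    )
    train_idx, test_idx = train_test_split_indices(
        data.n, substream(seed, (11,)), task.test_fraction
    )
    architecture = [task.image_size**2, *task.hidden_layers]

    records: list[BenchmarkRecord] = []
    for S in grid:
        for rep in range(n_replicates):
            cell_seed = int(
                np.random.SeedSequence(seed, spawn_key=(12, int(S), rep)).generate_state(1)[0]
                % (2**31)
            )
            cfg = TrainConfig(
                eta=task.eta,
                k=task.k,
                epochs=task.epochs,
                minibatch_size=int(S),
                packet_size=min(task.packet_size, int(S)),
                seed=cell_seed,
                precision=task.precision,
            )
            try:
                profile = ProfileLog()
                t0 = time.perf_counter()
                dbn, _ = train_dbn_greedy(
                    data.images[train_idx], architecture, cfg, profile=profile
                )
                train_time = time.perf_counter() - t0
                H_train = propagate_up(dbn, data.images[train_idx])
                H_test = propagate_up(dbn, data.images[test_idx])
                model = fit_readout_pinv(
                    H_train, data.labels[train_idx], n_classes=task.n_classes
                )
                err = classification_error(
                    classify(model, H_test), data.labels[test_idx]
                )
                records.append(
                    BenchmarkRecord(
                        minibatch_size=int(S),
                        replicate=rep,
                        seed=cell_seed,
                        train_time_s=train_time,
                        parallel_time_s=profile.parallel_time_s,
                        error_pct=err,
                        overhead_fraction=overhead_profile(profile),
                        config_hash=_config_hash(cfg, task),
                    )
                )
                logger.info(
                    "S=%d rep=%d: error=%.2f%% wall=%.2fs parallel=%.2fs overhead=%.3f",
                    S, rep, err, train_time, profile.parallel_time_s,
                    records[-1].overhead_fraction,
                )
            except Exception:  # noqa: BLE001 - a cell failure must not kill the sweep
                logger.exception("sweep cell S=%d rep=%d failed; skipping", S, rep)
    return records


def records_to_frame(records: Sequence[BenchmarkRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=_RECORD_COLUMNS)


def write_records_csv(
    records: Sequence[BenchmarkRecord],
    path: Union[str, Path],
    task: Optional[BenchTask] = None,
) -> None:
    """CSV of records; task config echoed as a JSON sidecar when given."""
    path = Path(path)
    # %.17g keeps doubles exact through the text round trip
    records_to_frame(records).to_csv(path, index=False, float_format="%.17g")
    if task is not None:
        path.with_suffix(".json").write_text(json.dumps(task.to_dict(), indent=2))


def read_records_csv(path: Union[str, Path]) -> list[BenchmarkRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        BenchmarkRecord(
            minibatch_size=int(r.minibatch_size),
            replicate=int(r.replicate),
            seed=int(r.seed),
            train_time_s=float(r.train_time_s),
            parallel_time_s=float(r.parallel_time_s),
            error_pct=float(r.error_pct),
            overhead_fraction=float(r.overhead_fraction),
            config_hash=str(r.config_hash),
        )
        for r in df.itertuples()
    ]


def _check_regression_inputs(x: np.ndarray, y: np.ndarray, min_points: int):
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    if x.size < min_points:
        raise ValueError(f"need at least {min_points} points, got {x.size}")
    return x, y


def fit_loglog_power(S: Sequence[float], times: Sequence[float]) -> tuple[float, float]:
    """Least-squares power fit time ≈ c·S^exponent on log-log axes.

    Returns (exponent, r²). Requires ≥3 strictly positive points.
    """
    S, times = _check_regression_inputs(S, times, 3)
    if S.min() <= 0 or times.min() <= 0:
        raise ValueError("power fit requires strictly positive S and times")
    res = stats.linregress(np.log10(S), np.log10(times))
    if np.allclose(times, times[0]):
        # zero-variance response: the flat line fits exactly
        return 0.0, 1.0
    return float(res.slope), float(res.rvalue**2)


def fit_error_slope(S: Sequence[float], errors: Sequence[float]) -> tuple[float, float]:
    """Least-squares regression of error on log10(S); returns (slope, r²).

    With constant errors the slope is 0 and r² is reported as 1 (the fit
    is exact).
    """
    S, errors = _check_regression_inputs(S, errors, 3)
    if S.min() <= 0:
        raise ValueError("S values must be positive")
    res = stats.linregress(np.log10(S), errors)
    if np.allclose(errors, errors[0]):
        return 0.0, 1.0
    return float(res.slope), float(res.rvalue**2)
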
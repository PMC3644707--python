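"""Restricted Boltzmann machine core: states, CD-k phases, gradients, oracles.

A restricted Boltzmann machine is a two-layer stochastic network — visible
units (the data) and hidden units (latent causes) joined by symmetric
weights W with no intra-layer links — whose energy function

    E(v, h) = -vᵀ W h - b_vis·v - b_hid·h

defines a Boltzmann distribution over joint configurations. Contrastive
divergence learning contrasts data-clamped correlations with correlations
after k steps of block Gibbs sampling:

    ΔW = η (⟨v⁺h⁺⟩ - ⟨v⁻h⁻⟩)

averaged over the patterns of a mini-batch. This module holds the
single-layer-pair machinery; stacking lives in :mod:`dbnlab.dbn` and the
mini-batch/packet loop in :mod:`dbnlab.train` and :mod:`dbnlab.parallel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import TrainConfig

__all__ = [
    "RBMParams",
    "PhaseStatistics",
    "GradientUpdate",
    "sigm",
    "stoch",
    "init_rbm",
    "cd_k",
    "weight_update",
    "apply_update",
    "energy",
    "reconstruction_error",
    "exact_log_likelihood",
    "exact_loglik_gradient",
]

# Largest |z| kept before the logistic saturates past representable
# precision; keeps sigm inside the open interval (0, 1) and overflow-free.
_SIGM_CLIP = {np.dtype(np.float32): 16.0, np.dtype(np.float64): 36.0}


def sigm(z: np.ndarray) -> np.ndarray:
    """Elementwise logistic function 1 / (1 + e^(-z)).

    Stable for arbitrarily large |z| (the exponent is clipped just before
    the output would round onto 0 or 1, so results stay strictly inside
    (0, 1) at working precision).
    """
    z = np.asarray(z)
    if not np.issubdtype(z.dtype, np.floating):
        z = z.astype(np.float64)
    finite = np.isfinite(z)
    if not finite.all():
        idx = tuple(np.argwhere(~finite)[0])
        raise ValueError(f"sigm: non-finite input {z[idx]!r} at index {idx}")
    clip = _SIGM_CLIP.get(z.dtype, 36.0)
    return 1.0 / (1.0 + np.exp(-np.clip(z, -clip, clip)))


def stoch(p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Stochastic binarization: 1 with probability p, else 0, elementwise."""
    p = np.asarray(p)
    if not np.issubdtype(p.dtype, np.floating):
        p = p.astype(np.float64)
    if not np.all(np.isfinite(p)) or p.min(initial=0.0) < 0 or p.max(initial=0.0) > 1:
        raise ValueError("stoch: probabilities must be finite and in [0, 1]")
    return (rng.random(p.shape) < p).astype(p.dtype)


@dataclass
class RBMParams:
    """Parameters of one RBM layer pair.

    W has shape (n_visible, n_hidden). When ``use_biases`` is False both
    bias vectors are identically zero and stay zero through training.
    """

    W: np.ndarray
    b_vis: np.ndarray
    b_hid: np.ndarray
    use_biases: bool = True

    def __post_init__(self) -> None:
        self.W = np.atleast_2d(np.asarray(self.W))
        self.b_vis = np.asarray(self.b_vis)
        self.b_hid = np.asarray(self.b_hid)
        self.validate()

    def validate(self) -> None:
        nv, nh = self.W.shape
        if self.b_vis.shape != (nv,) or self.b_hid.shape != (nh,):
            raise ValueError(
                f"bias shapes {self.b_vis.shape}/{self.b_hid.shape} inconsistent "
                f"with W shape {self.W.shape}"
            )
        for name, arr in (("W", self.W), ("b_vis", self.b_vis), ("b_hid", self.b_hid)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"RBMParams.{name} contains non-finite entries")
        if not self.use_biases and (np.any(self.b_vis) or np.any(self.b_hid)):
            raise ValueError("use_biases is False but bias vectors are non-zero")

    @property
    def n_visible(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]

    @property
    def dtype(self) -> np.dtype:
        return self.W.dtype

    def copy(self) -> "RBMParams":
        return RBMParams(self.W.copy(), self.b_vis.copy(), self.b_hid.copy(), self.use_biases)

    def astype(self, dtype) -> "RBMParams":
        return RBMParams(
            self.W.astype(dtype), self.b_vis.astype(dtype), self.b_hid.astype(dtype), self.use_biases
        )


def init_rbm(
    n_visible: int,
    n_hidden: int,
    rng: np.random.Generator,
    sigma: float = 0.01,
    use_biases: bool = True,
    dtype=np.float64,
) -> RBMParams:
    """Fresh RBM: i.i.d. zero-mean Gaussian weights (σ = 0.01), zero biases."""
    W = (sigma * rng.standard_normal((n_visible, n_hidden))).astype(dtype)
    return RBMParams(
        W=W,
        b_vis=np.zeros(n_visible, dtype=dtype),
        b_hid=np.zeros(n_hidden, dtype=dtype),
        use_biases=use_biases,
    )


@dataclass
class PhaseStatistics:
    """Positive- and negative-phase batches from one CD-k pass.

    ``V_D``/``H_D`` are the data-clamped visibles and hidden activations
    (v⁺, h⁺); ``V_M``/``H_M`` the model's reconstruction after k Gibbs
    steps (v⁻, h⁻). Hidden entries are the real-valued probabilities used
    for the correlation products unless strict binary mode was requested.
    """

    V_D: np.ndarray
    H_D: np.ndarray
    V_M: np.ndarray
    H_M: np.ndarray

    def __post_init__(self) -> None:
        n = self.V_D.shape[0]
        if not (self.H_D.shape[0] == self.V_M.shape[0] == self.H_M.shape[0] == n):
            raise ValueError("phase matrices must share a row count")
        if self.V_D.shape != self.V_M.shape or self.H_D.shape != self.H_M.shape:
            raise ValueError("data and model phase shapes must agree")
        for name, arr in (("V_D", self.V_D), ("H_D", self.H_D), ("V_M", self.V_M), ("H_M", self.H_M)):
            if arr.min(initial=0.0) < 0 or arr.max(initial=0.0) > 1:
                raise ValueError(f"PhaseStatistics.{name} has entries outside [0, 1]")

    @property
    def n_patterns(self) -> int:
        return self.V_D.shape[0]

    @staticmethod
    def concatenate(parts: list["PhaseStatistics"]) -> "PhaseStatistics":
        if not parts:
            raise ValueError("cannot concatenate zero PhaseStatistics")
        return PhaseStatistics(
            V_D=np.concatenate([p.V_D for p in parts]),
            H_D=np.concatenate([p.H_D for p in parts]),
            V_M=np.concatenate([p.V_M for p in parts]),
            H_M=np.concatenate([p.H_M for p in parts]),
        )


@dataclass
class GradientUpdate:
    """One weight update ΔW (plus bias deltas), averaged over n_patterns."""

    dW: np.ndarray
    db_vis: np.ndarray
    db_hid: np.ndarray
    n_patterns: int

    def __post_init__(self) -> None:
        if self.n_patterns < 1:
            raise ValueError("n_patterns must be >= 1")

    def check_shapes(self, params: RBMParams) -> None:
        if self.dW.shape != params.W.shape:
            raise ValueError(f"dW shape {self.dW.shape} != W shape {params.W.shape}")
        if self.db_vis.shape != params.b_vis.shape or self.db_hid.shape != params.b_hid.shape:
            raise ValueError("bias update shapes inconsistent with RBM")


def _check_patterns(V: np.ndarray, n_visible: int, name: str = "V_D") -> np.ndarray:
    V = np.atleast_2d(np.asarray(V))
    if V.shape[1] != n_visible:
        raise ValueError(f"{name} has {V.shape[1]} columns, RBM expects {n_visible}")
    if V.min(initial=0.0) < 0 or V.max(initial=0.0) > 1:
        raise ValueError(f"{name} values must lie in [0, 1]")
    return V


def cd_k(
    params: RBMParams,
    V_D: np.ndarray,
    k: int,
    rng: np.random.Generator,
    sample_visible: bool = False,
    strict_binary: bool = False,
) -> PhaseStatistics:
    """Contrastive divergence with k block-Gibbs iterations.

    Positive phase: clamp the visibles on the data and compute hidden
    probabilities H_D = sigm(V_D W + b_hid). Negative phase: binarize the
    hiddens, reconstruct the visibles, recompute the hiddens, k times.

    By default (standard CD practice) hidden states are binarized when
    driving a reconstruction but the returned H_D/H_M are probabilities,
    and V_M is the mean-field reconstruction probability. With
    ``sample_visible`` the visibles are sampled too; with ``strict_binary``
    every state in the chain (including H_D) is a stochastic binary sample.
    """
    if k < 1:
        raise ValueError(f"cd_k requires k >= 1, got {k}")
    V_D = _check_patterns(V_D, params.n_visible)
    dtype = params.dtype
    V_D = V_D.astype(dtype, copy=False)

    H_D = sigm(V_D @ params.W + params.b_hid)
    if strict_binary:
        H_D = stoch(H_D, rng)
        h = H_D
    else:
        h = stoch(H_D, rng)

    V = H = None
    for step in range(k):
        V = sigm(h @ params.W.T + params.b_vis)
        if strict_binary or sample_visible:
            V = stoch(V, rng)
        H = sigm(V @ params.W + params.b_hid)
        if step < k - 1:
            h = stoch(H, rng)
        elif strict_binary:
            H = stoch(H, rng)
    return PhaseStatistics(V_D=V_D, H_D=H_D, V_M=V, H_M=H)


def weight_update(stats: PhaseStatistics, cfg: TrainConfig) -> GradientUpdate:
    """CD weight update ΔW = η(⟨v⁺h⁺⟩ − ⟨v⁻h⁻⟩), pattern-averaged.

    Bias deltas η·mean(v⁺−v⁻) and η·mean(h⁺−h⁻) are produced only when
    ``cfg.use_biases``; momentum and weight decay are applied later, when
    the update is added to the weights (:func:`apply_update`).
    """
    n = stats.n_patterns
    eta = stats.V_D.dtype.type(cfg.eta)
    dW = eta * ((stats.V_D.T @ stats.H_D) - (stats.V_M.T @ stats.H_M)) / n
    if cfg.use_biases:
        db_vis = eta * (stats.V_D - stats.V_M).mean(axis=0)
        db_hid = eta * (stats.H_D - stats.H_M).mean(axis=0)
    else:
        db_vis = np.zeros(stats.V_D.shape[1], dtype=dW.dtype)
        db_hid = np.zeros(stats.H_D.shape[1], dtype=dW.dtype)
    return GradientUpdate(dW=dW, db_vis=db_vis, db_hid=db_hid, n_patterns=n)


@dataclass
class Velocity:
    """Momentum state for one RBM's parameters."""

    dW: np.ndarray
    db_vis: np.ndarray
    db_hid: np.ndarray

    @staticmethod
    def zeros_like(params: RBMParams) -> "Velocity":
        return Velocity(
            np.zeros_like(params.W), np.zeros_like(params.b_vis), np.zeros_like(params.b_hid)
        )


def apply_update(
    params: RBMParams,
    update: GradientUpdate,
    cfg: TrainConfig,
    velocity: Optional[Velocity] = None,
) -> None:
    """Add an update to the weights in place, with momentum/weight decay.

    v ← momentum·v + ΔW − η·λ·W ; W ← W + v. With momentum = λ = 0 this is
    exactly W ← W + ΔW.
    """
    update.check_shapes(params)
    decay = cfg.eta * cfg.weight_decay
    if velocity is None or (cfg.momentum == 0 and decay == 0):
        step_W = update.dW if decay == 0 else update.dW - decay * params.W
        params.W += step_W
        if cfg.use_biases:
            params.b_vis += update.db_vis
            params.b_hid += update.db_hid
        if velocity is not None and cfg.momentum != 0:  # pragma: no cover - guarded above
            pass
        return
    velocity.dW = cfg.momentum * velocity.dW + update.dW - decay * params.W
    params.W += velocity.dW
    if cfg.use_biases:
        velocity.db_vis = cfg.momentum * velocity.db_vis + update.db_vis
        velocity.db_hid = cfg.momentum * velocity.db_hid + update.db_hid
        params.b_vis += velocity.db_vis
        params.b_hid += velocity.db_hid


def energy(params: RBMParams, v: np.ndarray, h: np.ndarray) -> float:
    """Joint energy E(v, h) = −vᵀWh − b_vis·v − b_hid·h of a binary configuration."""
    v = np.asarray(v, dtype=float).ravel()
    h = np.asarray(h, dtype=float).ravel()
    if v.shape != (params.n_visible,) or h.shape != (params.n_hidden,):
        raise ValueError("configuration dimensions do not match RBM")
    if not (np.isin(v, (0.0, 1.0)).all() and np.isin(h, (0.0, 1.0)).all()):
        raise ValueError("energy expects binary (0/1) configurations")
    return float(-(v @ params.W @ h) - params.b_vis @ v - params.b_hid @ h)


def reconstruction_error(V: np.ndarray, V_hat: np.ndarray) -> float:
    """Mean squared per-element reconstruction error; in [0, 1] for [0, 1] data."""
    V = np.asarray(V)
    V_hat = np.asarray(V_hat)
    if V.shape != V_hat.shape:
        raise ValueError(f"shape mismatch: {V.shape} vs {V_hat.shape}")
    return float(np.mean((V.astype(np.float64) - V_hat.astype(np.float64)) ** 2))


# ----------------------------------------------------------------------
# Enumeration oracles for tiny models. CD approximates the gradient of the
# data log-likelihood; on models small enough to enumerate every visible
# configuration the exact gradient is computable in closed form and serves
# as an independent reference in tests.

_ORACLE_MAX_UNITS = 16


def _enumerate_states(n: int) -> np.ndarray:
    return ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(np.float64)


def _check_oracle_size(params: RBMParams) -> None:
    total = params.n_visible + params.n_hidden
    if total > _ORACLE_MAX_UNITS:
        raise ValueError(
            f"enumeration oracle supports at most {_ORACLE_MAX_UNITS} total units, "
            f"got {total}; use CD on larger models"
        )


def _visible_log_weights(params: RBMParams) -> tuple[np.ndarray, np.ndarray]:
    """(states, unnormalized log p(v)) over all visible configurations.

    Hiddens are summed out analytically: log p*(v) = b_vis·v +
    Σ_j softplus(vW_j + b_hid_j).
    """
    states = _enumerate_states(params.n_visible)
    act = states @ params.W + params.b_hid
    logw = states @ params.b_vis + np.logaddexp(0.0, act).sum(axis=1)
    return states, logw


def exact_log_likelihood(params: RBMParams, data: np.ndarray) -> float:
    """Mean log-likelihood per pattern of binary data, by full enumeration."""
    _check_oracle_size(params)
    data = _check_patterns(data, params.n_visible, "data")
    states, logw = _visible_log_weights(params)
    logZ = float(np.logaddexp.reduce(logw))
    act = data @ params.W + params.b_hid
    logp = data @ params.b_vis + np.logaddexp(0.0, act).sum(axis=1) - logZ
    return float(logp.mean())


def exact_loglik_gradient(params: RBMParams, data: np.ndarray) -> GradientUpdate:
    """Exact gradient of the mean data log-likelihood, by enumeration.

    Returns the raw gradient (no learning rate): positive data-clamped
    correlations minus exact model correlations. Test oracle only —
    feasible for n_visible + n_hidden ≤ 16.
    """
    _check_oracle_size(params)
    data = _check_patterns(data, params.n_visible, "data")
    n = data.shape[0]

    H_data = sigm(data @ params.W + params.b_hid)
    pos_W = data.T @ H_data / n
    pos_v = data.mean(axis=0)
    pos_h = H_data.mean(axis=0)

    states, logw = _visible_log_weights(params)
    p = np.exp(logw - np.logaddexp.reduce(logw))
    H_model = sigm(states @ params.W + params.b_hid)
    neg_W = (states * p[:, None]).T @ H_model
    neg_v = p @ states
    neg_h = p @ H_model

    return GradientUpdate(
        dW=pos_W - neg_W,
        db_vis=pos_v - neg_v,
        db_hid=pos_h - neg_h,
        n_patterns=n,
    )
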
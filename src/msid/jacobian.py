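"""Data-driven Jacobian estimation by nearest-neighbor linearization.

Given samples (x_i, F(x_i)) of an unknown vector field, a network J_theta(x)
mapping a state to a 2x2 matrix is trained to satisfy the first-order
expansion F(x_j) - F(x_i) ~= J_theta(x_i) (x_j - x_i) over the k nearest
neighbors of every anchor. States and field values are z-scored before
training; the inverse scaling is applied on evaluation so the estimator
returns Jacobians in physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .nn import MLP, Adam
from .node import VectorFieldSamples

__all__ = ["JacobianNetConfig", "NeighborPairSet", "JacobianEstimator",
           "build_pairs", "fit_jacobian"]


class TrainingDivergedError(RuntimeError):
    pass


@dataclass
class JacobianNetConfig:
    """Hyper-parameters of the Jacobian network.

    Defaults: hidden [600,600,300,150] with Swish, batch 64, 150 epochs,
    Adam lr 1e-4, per-layer max-norm weight constraint (3.0), k=10 neighbors
    with no radius cap.
    """

    hidden_sizes: List[int] = field(default_factory=lambda: [600, 600, 300, 150])
    activation: str = "swish"
    batch_size: int = 64
    epochs: int = 150
    learning_rate: float = 1e-4
    max_norm: float = 3.0
    k_neighbors: int = 10
    neighborhood_radius: Optional[float] = None
    seed: int = 1


@dataclass
class NeighborPairSet:
    """Anchor/neighbor increments used by the linearization loss."""

    anchors: np.ndarray        # (m, 2) anchor states x_i
    offsets: np.ndarray        # (m, 2) x_j - x_i, nonzero
    field_deltas: np.ndarray   # (m, 2) F(x_j) - F(x_i)
    states: np.ndarray         # (n, 2) deduplicated sample states
    values: np.ndarray         # (n, 2) field values at states

    def __len__(self) -> int:
        return self.anchors.shape[0]


def build_pairs(
    samples: VectorFieldSamples,
    k_neighbors: int = 10,
    radius: Optional[float] = None,
) -> NeighborPairSet:
    """Pair every sample with its k nearest neighbors in normalized state
    space (optionally capped at ``radius``, also in normalized units).

    Duplicate states (within 1e-12) are removed first.
    """
    states = np.asarray(samples.states, dtype=float)
    values = np.asarray(samples.values, dtype=float)
    # dedupe with tolerance: round to 1e-12 resolution relative to scale
    scale = np.maximum(np.max(np.abs(states), axis=0), 1e-300)
    keys = np.round(states / scale / 1e-12).astype(np.int64)
    _, keep = np.unique(keys, axis=0, return_index=True)
    keep.sort()
    states, values = states[keep], values[keep]
    n = states.shape[0]
    if n < k_neighbors + 1:
        raise ValueError(
            f"need at least k_neighbors+1={k_neighbors + 1} unique samples, got {n}"
        )
    std = np.where(states.std(axis=0) > 0, states.std(axis=0), 1.0)
    z = states / std
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(z)
    dist, idx = nn.kneighbors(z)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    anchor_idx = np.repeat(np.arange(n), k_neighbors)
    nbr_idx = idx.ravel()
    if radius is not None:
        mask = dist.ravel() <= radius
        anchor_idx, nbr_idx = anchor_idx[mask], nbr_idx[mask]
    offsets = states[nbr_idx] - states[anchor_idx]
    nonzero = np.any(offsets != 0.0, axis=1)
    anchor_idx, nbr_idx, offsets = anchor_idx[nonzero], nbr_idx[nonzero], offsets[nonzero]
    deltas = values[nbr_idx] - values[anchor_idx]
    return NeighborPairSet(states[anchor_idx], offsets, deltas, states, values)


class JacobianEstimator:
    """Trained Jacobian field; callable on states, returns (..., 2, 2)."""

    def __init__(self, mlp: MLP, x_mean, x_std, f_std, config, loss_curve):
        self.mlp = mlp
        self.x_mean = x_mean
        self.x_std = x_std
        self.f_std = f_std
        self.config = config
        self.loss_curve = loss_curve

    def __call__(self, states) -> np.ndarray:
        states = np.asarray(states, dtype=float)
        single = states.ndim == 1
        pts = np.atleast_2d(states)
        z = (pts - self.x_mean) / self.x_std
        j_norm = self.mlp(z).reshape(-1, 2, 2)
        j_phys = self.f_std[None, :, None] * j_norm / self.x_std[None, None, :]
        return j_phys[0] if single else j_phys


def fit_jacobian(
    pairs: NeighborPairSet,
    config: Optional[JacobianNetConfig] = None,
) -> JacobianEstimator:
    """Train the Jacobian network on neighbor increments.

    Loss: mean over pairs of || dF_norm - J_norm(x_i) dx_norm ||^2, in
    z-scored coordinates; mini-batch Adam with a per-layer max-norm weight
    constraint after every step.
    """
    config = config or JacobianNetConfig()
    x_mean = pairs.states.mean(axis=0)
    x_std = np.where(pairs.states.std(axis=0) > 0, pairs.states.std(axis=0), 1.0)
    f_std = np.where(pairs.values.std(axis=0) > 0, pairs.values.std(axis=0), 1.0)

    anchors_n = (pairs.anchors - x_mean) / x_std
    dx_n = pairs.offsets / x_std
    df_n = pairs.field_deltas / f_std

    rng = np.random.default_rng(config.seed)
    mlp = MLP([2, *config.hidden_sizes, 4], config.activation, rng)
    opt = Adam(mlp.params, lr=config.learning_rate)
    m = len(pairs)
    bs = min(config.batch_size, m)
    losses = []
    for epoch in range(config.epochs):
        perm = rng.permutation(m)
        epoch_loss = 0.0
        for start in range(0, m, bs):
            sel = perm[start:start + bs]
            xb, dxb, dfb = anchors_n[sel], dx_n[sel], df_n[sel]
            tape: list = []
            out = mlp.forward(xb, tape)            # (B, 4)
            J = out.reshape(-1, 2, 2)
            pred = np.einsum("bij,bj->bi", J, dxb)
            resid = pred - dfb                     # (B, 2)
            loss = float(np.mean(np.sum(resid**2, axis=1)))
            epoch_loss += loss * len(sel)
            if not np.isfinite(loss):
                raise TrainingDivergedError(f"loss diverged at epoch {epoch}")
            gJ = 2.0 * np.einsum("bi,bj->bij", resid, dxb) / len(sel)
            _, grads = mlp.vjp(tape, gJ.reshape(-1, 4))
            opt.step(grads)
            if config.max_norm:
                mlp.apply_max_norm(config.max_norm)
        losses.append(epoch_loss / m)
    return JacobianEstimator(mlp, x_mean, x_std, f_std, config,
                             np.asarray(losses))
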
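"""Neural-ODE surrogate: fit a vector field so its integrated trajectory
matches observed samples, then resample densely for Jacobian estimation.

The field is a small MLP acting on min-max-normalized states over normalized
time; training minimizes the trajectory MSE by single shooting (integrating
the whole interval from the first sample each epoch) with a fixed-step RK4
integrator and exact reverse-mode differentiation through every stage.
Densification re-integrates the trained field on a finer uniform grid inside
the observed interval and evaluates the learned right-hand side there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .nn import MLP, Adam
from .simulate import Trajectory

__all__ = ["NodeConfig", "NodeSurrogate", "VectorFieldSamples", "fit_node", "densify"]


class TrainingDivergedError(RuntimeError):
    """Non-finite training loss."""

    def __init__(self, epoch: int):
        super().__init__(f"training loss became non-finite at epoch {epoch}")
        self.epoch = epoch


@dataclass
class NodeConfig:
    """Training hyper-parameters of the neural-ODE surrogate.

    Defaults: hidden [64,128,128,64] with ReLU, Adam lr 1e-3, weight decay
    1e-4, gradient clipping at global norm 1.0, 2000 epochs with the learning
    rate halved every 500, solver tolerances 1e-6 for densification, dense
    output capped at 2000 points. ``substeps`` sets the RK4 resolution per
    observed interval during training.
    """

    hidden_sizes: List[int] = field(default_factory=lambda: [64, 128, 128, 64])
    activation: str = "relu"
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    clip_norm: float = 1.0
    epochs: int = 2000
    scheduler_step: int = 500
    scheduler_factor: float = 0.5
    solver_rtol: float = 1e-6
    solver_atol: float = 1e-6
    dense_points: int = 2000
    substeps: int = 2
    patience: Optional[int] = None  # early stopping, off by default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dense_points > 2000:
            raise ValueError("dense_points is capped at 2000")


@dataclass
class VectorFieldSamples:
    """(state, field value) pairs on a uniform grid, in physical units."""

    grid: np.ndarray
    states: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        n = self.grid.size
        if self.states.shape != (n, 2) or self.values.shape != (n, 2):
            raise ValueError("states/values must be (n, 2) aligned with grid")

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"t": self.grid, "c": self.states[:, 0], "s": self.states[:, 1],
             "dc": self.values[:, 0], "ds": self.values[:, 1]}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "VectorFieldSamples":
        import pandas as pd

        df = pd.read_csv(path, float_precision="round_trip")
        return cls(df["t"].to_numpy(), df[["c", "s"]].to_numpy(),
                   df[["dc", "ds"]].to_numpy())

    def as_trajectory(self) -> Trajectory:
        return Trajectory(self.grid, self.states, self.values,
                          {"source": "node_surrogate"})


class NodeSurrogate:
    """Trained neural vector field with its normalization frozen in."""

    def __init__(self, mlp: MLP, x_min: np.ndarray, x_range: np.ndarray,
                 t0: float, t_span: float, config: NodeConfig,
                 loss_curve: np.ndarray):
        self.mlp = mlp
        self.x_min = x_min
        self.x_range = x_range
        self.t0 = t0
        self.t_span = t_span
        self.config = config
        self.loss_curve = loss_curve

    # normalized dynamics: dz/dtau = f(z)
    def _f_norm(self, z: np.ndarray) -> np.ndarray:
        return self.mlp(z)

    def rhs(self, states: np.ndarray) -> np.ndarray:
        """Learned vector field in physical units at physical states."""
        states = np.asarray(states, dtype=float)
        z = (states - self.x_min) / self.x_range
        return self._f_norm(z) * self.x_range / self.t_span

    def integrate(self, times: np.ndarray) -> np.ndarray:
        """States of the learned flow at ``times`` (physical units).

        The flow is advanced with exactly the training discretization (the
        training grid and RK4 substep count) and evaluated between steps by
        cubic Hermite dense output. Re-integrating at a different step size
        would sample a *different* discrete trajectory than the one the loss
        controlled — a fixed-step neural ODE is only trustworthy on its own
        discretization.
        """
        times = np.asarray(times, dtype=float)
        tau_out = (times - self.t0) / self.t_span
        m = self.config.substeps
        h = self._train_dtau / m
        # advance over the training span, recording every substep node
        n_steps = self._train_intervals * m
        nodes = np.empty((n_steps + 1, 2))
        fvals = np.empty((n_steps + 1, 2))
        cur = (self._ic - self.x_min) / self.x_range
        nodes[0] = cur
        fvals[0] = self._f_norm(cur)
        for k in range(n_steps):
            cur = _rk4_step(self._f_norm, cur, h)
            nodes[k + 1] = cur
            fvals[k + 1] = self._f_norm(cur)
        # cubic Hermite within each substep
        pos = np.clip(tau_out / h, 0.0, n_steps - 1e-12)
        k = np.minimum(pos.astype(int), n_steps - 1)
        s = (pos - k)[:, None]
        x0, x1 = nodes[k], nodes[k + 1]
        f0, f1 = h * fvals[k], h * fvals[k + 1]
        h00 = (1 + 2 * s) * (1 - s) ** 2
        h10 = s * (1 - s) ** 2
        h01 = s**2 * (3 - 2 * s)
        h11 = s**2 * (s - 1)
        z = h00 * x0 + h10 * f0 + h01 * x1 + h11 * f1
        return z * self.x_range + self.x_min

    _ic: np.ndarray  # physical initial state; set by fit_node


def shooting_loss_and_grads(mlp: MLP, z_data: np.ndarray, tau: np.ndarray,
                            m: int):
    """Single-shooting trajectory MSE and its exact parameter gradient.

    Integrates the network field from the first sample with fixed-step RK4
    (``m`` substeps per observed interval), taping every stage, then runs
    the adjoint sweep back through the tape.
    """
    n = len(tau)
    tapes = []  # per substep: (h, four stage tapes)
    preds = np.empty_like(z_data)
    cur = z_data[0]
    preds[0] = cur
    for i in range(1, n):
        h = (tau[i] - tau[i - 1]) / m
        for _ in range(m):
            t1, t2, t3, t4 = [], [], [], []
            k1 = mlp.forward(cur, t1)
            k2 = mlp.forward(cur + 0.5 * h * k1, t2)
            k3 = mlp.forward(cur + 0.5 * h * k2, t3)
            k4 = mlp.forward(cur + h * k3, t4)
            cur = cur + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            tapes.append((h, (t1, t2, t3, t4)))
        preds[i] = cur
    resid = preds - z_data
    loss = float(np.mean(resid**2))

    dl = 2.0 * resid / resid.size
    grads = [(np.zeros_like(w), np.zeros_like(b)) for w, b in mlp.params]
    gbar = dl[n - 1].copy()
    step_idx = len(tapes) - 1
    for i in range(n - 1, 0, -1):
        for _ in range(m):
            h, (t1, t2, t3, t4) = tapes[step_idx]
            step_idx -= 1
            xbar = np.zeros(2)
            gk4 = (h / 6.0) * gbar
            gx, gp = mlp.vjp(t4, gk4)
            _acc(grads, gp); xbar += gx
            gk3 = (2 * h / 6.0) * gbar + h * gx
            gx, gp = mlp.vjp(t3, gk3)
            _acc(grads, gp); xbar += gx
            gk2 = (2 * h / 6.0) * gbar + 0.5 * h * gx
            gx, gp = mlp.vjp(t2, gk2)
            _acc(grads, gp); xbar += gx
            gk1 = (h / 6.0) * gbar + 0.5 * h * gx
            gx, gp = mlp.vjp(t1, gk1)
            _acc(grads, gp); xbar += gx
            gbar = gbar + xbar
        gbar = gbar + dl[i - 1]
    return loss, grads


def _rk4_step(f, x, h):
    k1 = f(x)
    k2 = f(x + 0.5 * h * k1)
    k3 = f(x + 0.5 * h * k2)
    k4 = f(x + h * k3)
    return x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def fit_node(trajectory: Trajectory, config: Optional[NodeConfig] = None) -> NodeSurrogate:
    """Train the neural-ODE surrogate on a trajectory.

    Single shooting: every epoch the current field is integrated from the
    first observed state across the whole interval and the mean squared error
    against all samples (in normalized coordinates) is minimized.
    """
    config = config or NodeConfig()
    if len(trajectory) < 10:
        raise ValueError("need at least 10 samples to fit a surrogate")
    x = trajectory.states
    t = trajectory.times
    x_min = x.min(axis=0)
    span = np.ptp(x, axis=0)
    x_range = np.where(span > 0, span, 1.0)
    z_data = (x - x_min) / x_range
    t0, t_span = t[0], t[-1] - t[0]
    tau = (t - t0) / t_span

    mlp = MLP([2, *config.hidden_sizes, 2], config.activation,
              np.random.default_rng(config.seed))
    opt = Adam(mlp.params, lr=config.learning_rate,
               weight_decay=config.weight_decay)
    n = len(t)
    m = config.substeps
    losses = np.empty(config.epochs)
    best = np.inf
    stall = 0

    for epoch in range(config.epochs):
        opt.lr = config.learning_rate * config.scheduler_factor ** (
            epoch // config.scheduler_step
        )
        loss, grads = shooting_loss_and_grads(mlp, z_data, tau, m)
        losses[epoch] = loss
        if not np.isfinite(loss):
            raise TrainingDivergedError(epoch)
        grads = Adam.clip_global_norm(grads, config.clip_norm)
        opt.step(grads)

        if config.patience is not None:
            if loss < best - 1e-12:
                best, stall = loss, 0
            else:
                stall += 1
                if stall >= config.patience:
                    losses = losses[: epoch + 1]
                    break

    surrogate = NodeSurrogate(mlp, x_min, x_range, t0, t_span, config, losses)
    surrogate._ic = x[0].copy()
    surrogate._train_intervals = n - 1
    surrogate._train_dtau = 1.0 / (n - 1)
    return surrogate


def _acc(grads, gp):
    for (gw, gb), (pw, pb) in zip(grads, gp):
        gw += pw
        gb += pb


def densify(surrogate: NodeSurrogate, trajectory: Trajectory,
            n_out: Optional[int] = None) -> VectorFieldSamples:
    """Resample the fitted surrogate on a fine uniform grid.

    States come from integrating the learned field; values from evaluating
    its right-hand side at those states. The grid spans the training
    interval; ``n_out`` defaults to the config's ``dense_points``.
    """
    n_out = n_out or surrogate.config.dense_points
    if n_out < len(trajectory):
        raise ValueError("n_out must be at least the training sample count")
    grid = np.linspace(trajectory.times[0], trajectory.times[-1], n_out)
    states = surrogate.integrate(grid)
    values = surrogate.rhs(states)
    return VectorFieldSamples(grid, states, values)
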
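"""Deterministic and stochastic trajectory generation for the MM test bed.

Trajectories are the currency between all stages: a uniform time grid, the
states (c, s), optionally the sampled vector-field values, and provenance
metadata. Deterministic integration uses a stiff-capable SciPy solver;
stochastic trajectories come from Euler-Maruyama with either additive
(state-independent) or multiplicative (field-scaling) Gaussian forcing whose
standard deviation is a fraction D of each variable's RMS over the
deterministic reference trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Literal, Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .kinetics import (
    CASES,
    KineticParameters,
    analytic_jacobian,
    case_initial_state,
    case_parameters,
    full_rhs,
    reduced_rhs,
)

__all__ = [
    "Trajectory",
    "NoiseSpec",
    "simulate",
    "simulate_noisy",
    "make_fixture",
    "case_t_end",
    "SolverError",
]

NoiseKind = Literal["none", "additive", "multiplicative"]

#: The reduced model conventionally paired with each benchmark case.
CANONICAL_REDUCED = {"case1": "sQSSA", "case2": "rQSSA", "case3": "PEA"}

#: Valid (case, model) combinations on the regime map.
VALID_MODELS = {
    "case1": ("full", "sQSSA", "PEA"),
    "case2": ("full", "rQSSA", "PEA"),
    "case3": ("full", "PEA"),
}


class SolverError(RuntimeError):
    """Stiff integration failed (step underflow or tolerance breakdown)."""


class ConfigurationError(ValueError):
    """Invalid case/model/noise combination."""


@dataclass
class NoiseSpec:
    """Stochastic forcing description.

    ``D`` is the dimensionless noise fraction: the per-variable standard
    deviation is D times the RMS of that variable over the deterministic
    reference trajectory.
    """

    kind: NoiseKind = "none"
    D: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("noise fraction D must be non-negative")
        if self.kind not in ("none", "additive", "multiplicative"):
            raise ValueError(f"unknown noise kind {self.kind!r}")


@dataclass
class Trajectory:
    """Uniformly sampled time series of the planar state (c, s)."""

    times: np.ndarray
    states: np.ndarray
    fields: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.ndim != 1 or self.states.shape != (self.times.size, 2):
            raise ValueError("times must be 1-D and states (n, 2)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.fields is not None:
            self.fields = np.asarray(self.fields, dtype=float)
            if self.fields.shape != self.states.shape:
                raise ValueError("fields must align with states")

    @property
    def c(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def s(self) -> np.ndarray:
        return self.states[:, 1]

    def __len__(self) -> int:
        return self.times.size

    def slice(self, start: int, stop: int) -> "Trajectory":
        """Contiguous sub-trajectory on [start, stop)."""
        return Trajectory(
            self.times[start:stop],
            self.states[start:stop],
            None if self.fields is None else self.fields[start:stop],
            dict(self.meta, sliced=(int(start), int(stop))),
        )

    def plot(self, ax=None):
        """Quick-look of both concentrations over time (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times, self.c, label="c (complex)")
        ax.plot(self.times, self.s, label="s (substrate)")
        ax.set_xlabel("t (s)")
        ax.set_ylabel("concentration")
        ax.legend()
        return ax

    def to_csv(self, path) -> None:
        """Write `t,c,s[,dc,ds]` with full 17-significant-digit round-trip."""
        cols = {"t": self.times, "c": self.c, "s": self.s}
        if self.fields is not None:
            cols["dc"] = self.fields[:, 0]
            cols["ds"] = self.fields[:, 1]
        # pandas' default float repr is shortest-round-trip: values survive
        # the text round trip bit-exactly
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path, float_precision="round_trip")
        for col in ("t", "c", "s"):
            if col not in df.columns:
                raise ValueError(f"trajectory CSV missing column {col!r}")
        fields = None
        if "dc" in df.columns and "ds" in df.columns:
            fields = df[["dc", "ds"]].to_numpy()
        return cls(df["t"].to_numpy(), df[["c", "s"]].to_numpy(), fields,
                   {"source": str(path)})


def simulate(
    model_rhs: Callable,
    ic,
    t_end: float,
    n_points: int,
    params: KineticParameters,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate ``model_rhs(state, params)`` on a uniform grid.

    The vector-field samples at the grid points are stored in
    ``Trajectory.fields``.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    times = np.linspace(0.0, float(t_end), int(n_points))
    sol = solve_ivp(
        lambda t, y: model_rhs(y, params),
        (0.0, float(t_end)),
        np.asarray(ic, dtype=float),
        t_eval=times,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SolverError(f"integration failed: {sol.message}")
    states = sol.y.T
    # solver overshoot can leave concentrations a hair outside the physical
    # box (reduced models near s = 0); clamp within integration tolerance
    overshoot = float(max(np.max(-states, initial=0.0),
                          np.max(states[:, 0] - params.e0, initial=0.0)))
    states[:, 0] = np.clip(states[:, 0], 0.0, params.e0)
    states[:, 1] = np.maximum(states[:, 1], 0.0)
    fields = model_rhs(states, params)
    return Trajectory(times, states, fields,
                      {"model_rhs": getattr(model_rhs, "__name__", "rhs"),
                       "params": params, "rtol": rtol, "atol": atol,
                       "overshoot": overshoot})


def _stable_dt(ref: Trajectory, params: KineticParameters, grid_dt: float) -> float:
    """Internal Euler-Maruyama step: grid/50, capped by explicit stability."""
    jac = analytic_jacobian(ref.states, params)
    lam_max = float(np.max(np.abs(np.linalg.eigvals(jac))))
    cap = 0.4 / lam_max if lam_max > 0 else np.inf
    return min(grid_dt / 50.0, cap)


def simulate_noisy(
    ic,
    params: KineticParameters,
    noise: NoiseSpec,
    t_end: float,
    n_points: int,
    dt_internal: Optional[float] = None,
    model_rhs: Callable = full_rhs,
    n_ensemble: int = 1,
) -> Trajectory | list[Trajectory]:
    """Euler-Maruyama integration of the MM SDE, subsampled to the grid.

    Additive noise adds sigma*sqrt(dt)*N(0,1) to each increment; multiplicative
    noise scales the drift element-wise by (1 + xi) with xi ~ N(0, sigma^2) per
    step. sigma per variable is D times the RMS of that variable along the
    deterministic reference. Negative excursions are clipped to zero and the
    clip count recorded in ``meta`` (c is likewise capped at e0 so that the
    enzyme balance e = e0 - c stays non-negative). With ``n_ensemble > 1`` a
    list of independent trajectories (vectorized internally) is returned.
    """
    if noise.kind == "none":
        raise ValueError("use simulate() for noise-free integration")
    ref = simulate(model_rhs, ic, t_end, n_points, params)
    sigma = noise.D * np.sqrt(np.mean(ref.states**2, axis=0))  # per-variable RMS

    times = ref.times
    grid_dt = times[1] - times[0]
    # the noise process lives on steps of (grid spacing)/50; the drift may
    # need finer (stability-limited) sub-stepping inside each noise step
    dt_noise = grid_dt / 50.0
    dt = dt_internal if dt_internal is not None else _stable_dt(ref, params, grid_dt)
    inner = max(1, int(np.ceil(dt_noise / dt)))
    dt = dt_noise / inner
    substeps = 50

    rng = np.random.default_rng(noise.seed)
    m = int(n_ensemble)
    x = np.broadcast_to(np.asarray(ic, dtype=float), (m, 2)).copy()
    out = np.empty((n_points, m, 2))
    out[0] = x
    sqdt = np.sqrt(dt)
    # no clipping inside the integrator: transient excursions (s slightly
    # negative, c slightly above e0) are restored by the drift itself, and
    # zero-clipping every substep would rectify the noise into a systematic
    # positive flux on a variable that has decayed to ~0
    for i in range(1, n_points):
        for _ in range(substeps):
            if noise.kind == "multiplicative":
                # field-scaling perturbation held over one noise step
                xi = sigma * rng.standard_normal((m, 2))
                for _ in range(inner):
                    x = x + model_rhs(x, params) * (1.0 + xi) * dt
            else:
                for _ in range(inner):
                    x = (x + model_rhs(x, params) * dt
                         + sigma * sqdt * rng.standard_normal((m, 2)))
        out[i] = x

    # emitted samples are clipped to the physical box and the clips counted
    clips = ((out[:, :, 0] < 0) | (out[:, :, 0] > params.e0)
             | (out[:, :, 1] < 0)).sum(axis=0)
    out[:, :, 0] = np.clip(out[:, :, 0], 0.0, params.e0)
    out[:, :, 1] = np.maximum(out[:, :, 1], 0.0)

    meta = {"noise": noise, "params": params, "dt_internal": dt,
            "sigma": sigma, "reference": ref}
    trajs = [
        Trajectory(times, out[:, j], None, dict(meta, clip_count=int(clips[j])))
        for j in range(m)
    ]
    return trajs[0] if n_ensemble == 1 else trajs


def _case_rhs(model: str) -> Callable:
    if model == "full":
        return full_rhs
    rhs = lambda state, p, _m=model: reduced_rhs(state, p, _m)
    rhs.__name__ = f"reduced_rhs[{model}]"
    return rhs


@lru_cache(maxsize=None)
def case_t_end(case_name: str) -> float:
    """Horizon at which both variables of the full model reach 1% of t=0.

    Computed once per case by event detection on the deterministic full model;
    chosen so each trajectory traverses its full regime range.
    """
    params = case_parameters(case_name)
    ic = case_initial_state(case_name)
    floor = 0.01 * ic

    def done(t, y):
        return max(y[0] - floor[0], y[1] - floor[1])

    done.terminal = True
    done.direction = -1
    sol = solve_ivp(
        lambda t, y: full_rhs(y, params),
        (0.0, 1e7),
        ic,
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
        events=done,
    )
    if not sol.t_events[0].size:
        raise SolverError(f"decay horizon not found for {case_name}")
    return float(sol.t_events[0][0])


def make_fixture(
    case_name: str,
    model: str = "full",
    noise: Optional[NoiseSpec] = None,
    n_points: int = 100,
) -> Trajectory:
    """Benchmark trajectory for a named case and model, optionally noisy.

    ``model`` may be 'full', a reduced-model name, or 'reduced' (the case's
    canonical reduction). Deterministic fixtures carry vector-field samples;
    stochastic ones carry states only.
    """
    if case_name not in CASES:
        raise ConfigurationError(f"unknown case {case_name!r}")
    if model == "reduced":
        model = CANONICAL_REDUCED[case_name]
    if model not in VALID_MODELS[case_name]:
        raise ConfigurationError(
            f"{case_name} is outside the validity region of {model!r}; "
            f"valid models: {VALID_MODELS[case_name]}"
        )
    params = case_parameters(case_name)
    ic = case_initial_state(case_name)
    t_end = case_t_end(case_name)
    rhs = _case_rhs(model)
    if noise is None or noise.kind == "none":
        traj = simulate(rhs, ic, t_end, n_points, params)
    else:
        traj = simulate_noisy(ic, params, noise, t_end, n_points, model_rhs=rhs)
    traj.meta.update(case=case_name, model=model)
    return traj
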
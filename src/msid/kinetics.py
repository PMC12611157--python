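"""Closed-form Michaelis-Menten kinetics.

The irreversible enzyme mechanism

    S + E <-> C -> E + P

with rate constants ``k1f`` (binding), ``k1b`` (unbinding) and ``k2``
(catalysis) reduces, via the conservation law [E] + [C] = e0, to a planar ODE
for the complex ``c`` and substrate ``s``:

    dc/dt =  R1 - k2*c,      R1 = k1f*(e0 - c)*s - k1b*c
    ds/dt = -R1

This module provides the vector field, its analytic Jacobian, the two
eigen-timescales in the (mu, nu) parameterization, the three classical
reduced models (sQSSA, rQSSA, PEA) together with their slow-invariant-manifold
(SIM) expressions, and a regime classifier on the mu-nu plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "KineticParameters",
    "TimescaleProfile",
    "CASES",
    "derive_constants",
    "full_rhs",
    "analytic_jacobian",
    "timescale_profile",
    "sqssa_sim_c",
    "rqssa_sim_s",
    "pea_sim_residual",
    "pea_sim_c",
    "reduced_rhs",
    "classify_regime",
    "ReducedModelName",
    "RegimeLabel",
]

ReducedModelName = Literal["sQSSA", "rQSSA", "PEA"]
RegimeLabel = Literal["sQSSA", "rQSSA", "PEA", "none"]


class InvalidParameterError(ValueError):
    """Raised for non-physical rate constants."""


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants of the MM mechanism plus derived constants.

    Attributes
    ----------
    k1f : float
        Forward binding rate constant (L mol^-1 s^-1), > 0.
    k1b : float
        Unbinding rate constant (s^-1), >= 0.
    k2 : float
        Catalytic rate constant / turnover number (s^-1), > 0.
    e0 : float
        Total enzyme pool (mol/L), > 0.
    """

    k1f: float
    k1b: float
    k2: float
    e0: float

    def __post_init__(self) -> None:
        if not (self.k1f > 0 and self.k2 > 0 and self.e0 > 0):
            raise InvalidParameterError(
                "k1f, k2 and e0 must be strictly positive "
                f"(got k1f={self.k1f}, k2={self.k2}, e0={self.e0})"
            )
        if self.k1b < 0:
            raise InvalidParameterError(f"k1b must be non-negative (got {self.k1b})")
        for name in ("k1f", "k1b", "k2", "e0"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite")

    @property
    def KR(self) -> float:
        """Dissociation constant k1b/k1f."""
        return self.k1b / self.k1f

    @property
    def K(self) -> float:
        """Van Slyke-Cullen constant k2/k1f."""
        return self.k2 / self.k1f

    @property
    def KM(self) -> float:
        """Michaelis constant KR + K."""
        return self.KR + self.K


def derive_constants(k1f: float, k1b: float, k2: float, e0: float) -> KineticParameters:
    """Validate rate constants and populate the derived constants."""
    return KineticParameters(k1f=k1f, k1b=k1b, k2=k2, e0=e0)


#: The three benchmark parameter sets (rates, initial conditions on the SIM).
#: Case 1 lives in the sQSSA region, Case 2 in the rQSSA region and Case 3
#: traverses from the sQSSA to the rQSSA region through the PEA-only strip.
CASES: dict[str, dict[str, float]] = {
    "case1": dict(k1f=10.0, k1b=100.0, k2=1.0, e0=0.5, s0=1.0, c0=0.045045),
    "case2": dict(k1f=3.0, k1b=3.0, k2=0.5, e0=1000.0, s0=10.11111, c0=910.0),
    "case3": dict(k1f=1000.0, k1b=0.01, k2=0.1, e0=10.0, s0=10.0, c0=9.999999),
}


def case_parameters(name: str) -> KineticParameters:
    """Kinetic parameters of a named benchmark case ('case1'|'case2'|'case3')."""
    try:
        entry = CASES[name]
    except KeyError:
        raise KeyError(f"unknown case {name!r}; choose from {sorted(CASES)}") from None
    return derive_constants(entry["k1f"], entry["k1b"], entry["k2"], entry["e0"])


def case_initial_state(name: str) -> np.ndarray:
    """Initial state (c0, s0) of a named benchmark case."""
    entry = CASES[name]
    return np.array([entry["c0"], entry["s0"]])


def full_rhs(state, params: KineticParameters) -> np.ndarray:
    """Full-model vector field (dc/dt, ds/dt).

    Accepts a single state ``(c, s)`` or an array of shape (n, 2).
    """
    state = np.asarray(state, dtype=float)
    c = state[..., 0]
    s = state[..., 1]
    r1 = params.k1f * (params.e0 - c) * s - params.k1b * c
    return np.stack([r1 - params.k2 * c, -r1], axis=-1)


def analytic_jacobian(state, params: KineticParameters) -> np.ndarray:
    """Exact Jacobian of :func:`full_rhs`; shape (..., 2, 2)."""
    state = np.asarray(state, dtype=float)
    c = state[..., 0]
    s = state[..., 1]
    j11 = -params.k1f * s - params.k1b - params.k2
    j12 = params.k1f * (params.e0 - c)
    j21 = params.k1f * s + params.k1b
    j22 = -params.k1f * (params.e0 - c)
    row1 = np.stack([j11, j12], axis=-1)
    row2 = np.stack([j21, j22], axis=-1)
    return np.stack([row1, row2], axis=-2)


@dataclass(frozen=True)
class TimescaleProfile:
    """Dimensionless shape parameters and eigen-timescales at one state.

    ``mu = K/(KR+s)`` and ``nu = (e0-c)/(KR+s)`` locate the state on the
    mu-nu regime plane; ``epsilon = mu*nu/(1+mu+nu)**2 < 1/4`` measures the
    gap between the fast and slow eigenvalues ``lambda_fast/lambda_slow``
    (tau1 = 1/|lambda_fast| <= tau2 = 1/|lambda_slow|).
    """

    mu: float
    nu: float
    epsilon: float
    lambda_fast: float
    lambda_slow: float
    tau1: float
    tau2: float


def timescale_profile(state, params: KineticParameters) -> TimescaleProfile:
    """Evaluate mu, nu, epsilon and the eigen-timescales at one state."""
    c, s = float(np.asarray(state)[0]), float(np.asarray(state)[1])
    denom = params.KR + s
    if denom <= 0:
        raise ValueError("timescale profile requires KR + s > 0")
    mu = params.K / denom
    nu = (params.e0 - c) / denom
    eps = mu * nu / (1.0 + mu + nu) ** 2
    if eps > 0.25 + 1e-12:
        raise AssertionError(f"epsilon={eps} exceeds 1/4: inconsistent state")
    root = math.sqrt(max(1.0 - 4.0 * eps, 0.0))
    pref = -(params.k2 / 2.0) * (1.0 + mu + nu) / mu
    lam_fast = pref * (1.0 + root)   # larger modulus branch
    lam_slow = pref * (1.0 - root)
    tau1 = 1.0 / abs(lam_fast)
    tau2 = math.inf if lam_slow == 0.0 else 1.0 / abs(lam_slow)
    return TimescaleProfile(mu, nu, eps, lam_fast, lam_slow, tau1, tau2)


def sqssa_sim_c(s, params: KineticParameters):
    """Complex concentration on the sQSSA manifold: c = e0*s/(KM+s)."""
    s = np.asarray(s, dtype=float)
    if np.any(params.KM + s <= 0):
        raise ValueError("sQSSA SIM requires KM + s > 0")
    return params.e0 * s / (params.KM + s)


def rqssa_sim_s(c, params: KineticParameters):
    """Substrate concentration on the rQSSA manifold: s = KR*c/(e0-c)."""
    c = np.asarray(c, dtype=float)
    if np.any(c >= params.e0):
        raise ValueError("rQSSA SIM requires c < e0")
    return params.KR * c / (params.e0 - c)


def pea_sim_residual(state, params: KineticParameters) -> float:
    """Residual of the PEA manifold equation (e0-c)s - KR*c - K*c/(1+nu)."""
    c, s = float(np.asarray(state)[0]), float(np.asarray(state)[1])
    nu = (params.e0 - c) / (params.KR + s)
    return (params.e0 - c) * s - params.KR * c - params.K * c / (1.0 + nu)


def pea_sim_c(s: float, params: KineticParameters, xtol: float = 1e-12) -> float:
    """Complex concentration on the PEA manifold at fixed substrate.

    Solves the PEA residual by bracketed root-finding over c in (0, e0).
    """
    if s < 0:
        raise ValueError("substrate must be non-negative")
    if s == 0.0:
        return 0.0
    f = lambda c: pea_sim_residual((c, s), params)
    lo, hi = 0.0, params.e0 * (1.0 - 1e-15)
    return brentq(f, lo, hi, xtol=xtol)


def reduced_rhs(state, params: KineticParameters, model: ReducedModelName) -> np.ndarray:
    """Vector field of a reduced model evaluated at (c, s).

    sQSSA: dc/dt = -k2*(e0-c)^2*c/(KM*e0),  ds/dt = -k2*c
    rQSSA: dc/dt = -k2*c,                   ds/dt = -k2*(KR+s)*s/KR
    PEA:   dc/dt = -(nu/(1+nu))*k2*c,       ds/dt = -(1/(1+nu))*k2*c
    """
    state = np.asarray(state, dtype=float)
    c = state[..., 0]
    s = state[..., 1]
    if model == "sQSSA":
        dc = -params.k2 * (params.e0 - c) ** 2 * c / (params.KM * params.e0)
        ds = -params.k2 * c
    elif model == "rQSSA":
        if params.KR == 0.0:
            raise ValueError("rQSSA reduced model is undefined for KR = 0")
        dc = -params.k2 * c
        ds = -params.k2 * (params.KR + s) * s / params.KR
    elif model == "PEA":
        nu = (params.e0 - c) / (params.KR + s)
        dc = -(nu / (1.0 + nu)) * params.k2 * c
        ds = -(1.0 / (1.0 + nu)) * params.k2 * c
    else:
        raise ValueError(f"unknown reduced model {model!r}")
    return np.stack([dc, ds], axis=-1)


def classify_regime(
    profile: TimescaleProfile,
    eps_threshold: float = 1e-2,
    dominance_factor: float = 10.0,
) -> RegimeLabel:
    """Label the regime of a state from its (mu, nu, epsilon) profile.

    "none" when epsilon exceeds ``eps_threshold`` (no accurate reduced model);
    otherwise sQSSA when nu is dominated by 1+mu, rQSSA when nu dominates
    1+mu, and "PEA" in the strip between. ``dominance_factor`` operationalizes
    the "much less/greater than" of the regime map.
    """
    if profile.epsilon > eps_threshold:
        return "none"
    if profile.nu * dominance_factor <= 1.0 + profile.mu:
        return "sQSSA"
    if profile.nu >= dominance_factor * (1.0 + profile.mu):
        return "rQSSA"
    return "PEA"
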
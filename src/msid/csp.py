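"""Leading-order computational singular perturbation (CSP) along a trajectory.

At each sample the Jacobian (analytic or estimated) is eigen-decomposed; the
mode with the larger eigenvalue modulus is the fast mode, the inverse moduli
are the characteristic time scales, and the CSP pointer — the element-wise
product of the fast mode's right and left eigenvectors — names the state
variable slaved to the fast dynamics. Contiguous runs of a constant fast
variable become dataset splits; points with an ambiguous pointer, a weak
spectral gap, or too little time-scale separation form the transition window
that is excluded from both splits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .simulate import Trajectory

__all__ = [
    "CSPBasis",
    "PointerDiagnostics",
    "Partition",
    "DegenerateSpectrumError",
    "PartitionFailureError",
    "decompose",
    "pointer_profile",
    "partition",
]

VARIABLE_NAMES = ("c", "s")
#: Regime implied by each fast variable in the MM mechanism.
REGIME_OF_FAST = {"c": "sQSSA", "s": "rQSSA"}


class DegenerateSpectrumError(RuntimeError):
    """Complex eigenvalue pair: the Jacobian left the fast/slow-real region."""


class PartitionFailureError(RuntimeError):
    """No stable segment of the required minimum length exists."""


@dataclass
class CSPBasis:
    """Eigen-decomposition ordered fast-first (descending |lambda|)."""

    eigenvalues: np.ndarray      # (2,), |lambda_fast| >= |lambda_slow|
    right_vectors: np.ndarray    # columns a_i
    left_vectors: np.ndarray     # rows b_i, with b_i . a_j = delta_ij
    degenerate: bool = False     # moduli closer than the 1+1e-6 gap factor

    @property
    def pointer(self) -> np.ndarray:
        """CSP pointer of the fast mode: d_k = a_fast[k] * b_fast[k]."""
        return self.right_vectors[:, 0] * self.left_vectors[0, :]

    @property
    def timescales(self) -> Tuple[float, float]:
        lam = np.abs(self.eigenvalues)
        tau1 = 1.0 / lam[0]
        tau2 = np.inf if lam[1] == 0 else 1.0 / lam[1]
        return tau1, tau2


def decompose(J: np.ndarray) -> CSPBasis:
    """Fast/slow eigen-basis of a 2x2 Jacobian.

    Raises :class:`DegenerateSpectrumError` for complex pairs; flags (without
    failing) spectra whose moduli differ by less than a factor 1 + 1e-6.
    """
    J = np.asarray(J, dtype=float)
    lam, R = np.linalg.eig(J)
    if np.any(np.abs(lam.imag) > 1e-12 * np.max(np.abs(lam))):
        raise DegenerateSpectrumError(f"complex eigenvalues {lam}")
    lam = lam.real
    R = R.real
    order = np.argsort(-np.abs(lam))
    lam, R = lam[order], R[:, order]
    mods = np.abs(lam)
    degenerate = mods[1] > 0 and mods[0] < (1.0 + 1e-6) * mods[1]
    B = np.linalg.inv(R)  # rows biorthonormal to columns of R
    return CSPBasis(lam, R, B, degenerate)


@dataclass
class PointerDiagnostics:
    """Per-time-point CSP diagnostics along a trajectory."""

    times: np.ndarray
    pointers: np.ndarray        # (n, 2) pointer values per variable
    fast_variable: np.ndarray   # (n,) index into VARIABLE_NAMES (-1 unusable)
    tau1: np.ndarray
    tau2: np.ndarray
    epsilon_hat: np.ndarray     # |l_f||l_s|/(|l_f|+|l_s|)^2, the stiffness proxy
    usable: np.ndarray          # bool mask

    def __len__(self) -> int:
        return self.times.size

    def fast_labels(self) -> List[Optional[str]]:
        return [VARIABLE_NAMES[i] if u and i >= 0 else None
                for i, u in zip(self.fast_variable, self.usable)]

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({
            "t": self.times, "d_c": self.pointers[:, 0],
            "d_s": self.pointers[:, 1], "tau1": self.tau1, "tau2": self.tau2,
            "eps_hat": self.epsilon_hat,
            "fast_var": [VARIABLE_NAMES[i] if i >= 0 else "" for i in self.fast_variable],
        }).to_csv(path, index=False, float_format="%.17g")


def pointer_profile(
    trajectory: Trajectory,
    jacobian_source: Callable[[np.ndarray], np.ndarray],
) -> PointerDiagnostics:
    """CSP diagnostics at every trajectory sample.

    ``jacobian_source`` maps a state (2,) to a 2x2 matrix — e.g. the analytic
    MM Jacobian bound to parameters, or a trained estimator. Degenerate
    spectra mark the point unusable instead of failing.
    """
    n = len(trajectory)
    if n < 2:
        raise ValueError("trajectory must have at least 2 points")
    pointers = np.full((n, 2), np.nan)
    fast = np.full(n, -1, dtype=int)
    tau1 = np.full(n, np.nan)
    tau2 = np.full(n, np.nan)
    eps_hat = np.full(n, np.nan)
    usable = np.zeros(n, dtype=bool)
    for i, x in enumerate(trajectory.states):
        try:
            basis = decompose(jacobian_source(x))
        except DegenerateSpectrumError:
            continue
        d = basis.pointer
        pointers[i] = d
        t1, t2 = basis.timescales
        tau1[i], tau2[i] = t1, t2
        a, b = np.abs(basis.eigenvalues)
        eps_hat[i] = (a * b) / (a + b) ** 2 if (a + b) > 0 else np.nan
        if d[0] == d[1]:
            # exact tie: leave unusable so it lands in the transition window
            continue
        fast[i] = int(np.argmax(d))
        usable[i] = True
    return PointerDiagnostics(trajectory.times.copy(), pointers, fast,
                              tau1, tau2, eps_hat, usable)


@dataclass
class Segment:
    start: int                 # inclusive
    stop: int                  # exclusive
    fast_variable: str
    regime: str

    def __len__(self) -> int:
        return self.stop - self.start


@dataclass
class Partition:
    """Contiguous dynamically homogeneous splits plus the transition window."""

    segments: List[Segment]
    transition_window: List[int] = field(default_factory=list)
    n_points: int = 0

    def to_json(self, path=None) -> str:
        payload = {
            "segments": [
                {"start": seg.start, "stop": seg.stop,
                 "fast_variable": seg.fast_variable, "regime": seg.regime}
                for seg in self.segments
            ],
            "transition_window": [int(i) for i in self.transition_window],
            "n_points": self.n_points,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def partition(
    diagnostics: PointerDiagnostics,
    min_segment: float = 0.10,
    hysteresis: float = 0.2,
    eps_threshold: float = 1e-2,
    guard: float = 1,
    usable_mask: Optional[np.ndarray] = None,
    smooth_window: int = 1,
) -> Partition:
    """Split the grid into runs of a constant fast variable.

    A point joins the transition window when its pointer margin
    ``|d_max - d_secondmax|`` is below ``hysteresis``, its stiffness proxy
    exceeds ``eps_threshold``, or its spectrum was unusable. Additionally
    ``guard`` samples on each side of a fast-variable switch join the window:
    the regime flip of a stiff system can be narrower than the grid spacing,
    and the samples bracketing it straddle both regimes. Runs shorter than
    ``min_segment`` (a count, or a fraction of the grid when < 1) dissolve
    into the window. Raises :class:`PartitionFailureError` when no run
    survives.

    ``usable_mask`` ANDs an external validity mask into the diagnostics
    (e.g. a dynamic-range floor on the reconstructed field).
    ``smooth_window`` > 1 replaces each stable label by the majority vote of
    the stable labels in a centered window, suppressing isolated
    misclassifications of an estimated Jacobian field.
    """
    n = len(diagnostics)
    min_len = int(np.ceil(min_segment * n)) if min_segment < 1 else int(min_segment)
    if n < 2 * min_len:
        raise PartitionFailureError(
            f"need at least 2*min_segment={2 * min_len} usable points, got {n}")
    margin = np.abs(diagnostics.pointers[:, 0] - diagnostics.pointers[:, 1])
    with np.errstate(invalid="ignore"):
        stable = (
            diagnostics.usable
            & (margin >= hysteresis)
            & ~(diagnostics.epsilon_hat > eps_threshold)
        )
    if usable_mask is not None:
        stable &= np.asarray(usable_mask, dtype=bool)
    labels = np.where(stable, diagnostics.fast_variable, -1)
    if smooth_window > 1:
        half = smooth_window // 2
        smoothed = labels.copy()
        for i in np.where(labels >= 0)[0]:
            win = labels[max(0, i - half): i + half + 1]
            win = win[win >= 0]
            counts = np.bincount(win, minlength=2)
            if counts.max() > 0:
                smoothed[i] = int(np.argmax(counts))
        labels = smoothed
    guard = int(np.ceil(guard * n)) if 0 < guard < 1 else int(guard)

    segments: List[Segment] = []
    window: List[int] = []
    i = 0
    while i < n:
        if labels[i] < 0:
            window.append(i)
            i += 1
            continue
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        # guard: a segment edge that borders the transition window (or
        # another segment) is trimmed — the regime switch contaminates the
        # local linearization over a scale set by the data resolution
        lo, hi = i, j
        if guard > 0:
            if lo > 0:
                lo = min(lo + guard, j)
            if hi < n:
                hi = max(hi - guard, lo)
        if j - i >= min_len and hi - lo >= max(1, min_len // 2):
            name = VARIABLE_NAMES[labels[i]]
            segments.append(Segment(lo, hi, name, REGIME_OF_FAST[name]))
            window.extend(range(i, lo))
            window.extend(range(hi, j))
        else:
            window.extend(range(i, j))
        i = j
    if not segments:
        raise PartitionFailureError(
            f"no stable fast-variable run of length >= {min_len}")
    return Partition(segments, window, n)
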
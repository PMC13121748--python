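"""1:1 Langmuir kinetic fits for biolayer-interferometry sensorgrams.

For analyte concentration C binding an immobilized ligand with rates
k_on and k_off (K_D = k_off/k_on), the sensor response follows

    association:  R(t) = R_eq (1 - exp(-(k_on C + k_off) t)),
                  R_eq = R_max C / (C + K_D)
    dissociation: R(t) = R_0 exp(-k_off (t - t_d))

with continuity at the phase boundary t_d. A single (k_on, k_off,
R_max) triple is fit globally across all concentrations — per-curve fits
of 1:1 kinetics are poorly identifiable, the global fit is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "Sensorgram",
    "BindingFit",
    "equilibrium_response",
    "association_response",
    "dissociation_response",
    "model_1to1",
    "fit_1to1",
    "subtract_baseline",
]


@dataclass
class Sensorgram:
    """One BLI trace: association from t=0, dissociation from t_dissoc."""

    time: np.ndarray  # s, strictly increasing, association starts at 0
    response: np.ndarray  # sensor units
    concentration: float  # M
    t_dissoc: float  # s, start of the dissociation phase

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("analyte concentration must be positive")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not (self.time[0] < self.t_dissoc < self.time[-1]):
            raise ValueError("t_dissoc must lie inside the time range")


@dataclass
class BindingFit:
    k_on: float  # 1/(M·s)
    k_off: float  # 1/s
    R_max: float  # sensor units
    residual_norm: float
    per_curve_residuals: dict[float, float] = field(default_factory=dict)

    @property
    def K_D(self) -> float:
        return self.k_off / self.k_on


def equilibrium_response(C: float, K_D: float, R_max: float) -> float:
    """Langmuir isotherm R_eq = R_max C / (C + K_D)."""
    if C < 0 or K_D <= 0 or R_max <= 0:
        raise ValueError("C must be >= 0; K_D, R_max must be positive")
    return R_max * C / (C + K_D)


def association_response(
    t: np.ndarray, C: float, k_on: float, k_off: float, R_max: float
) -> np.ndarray:
    k_obs = k_on * C + k_off
    r_eq = R_max * C / (C + k_off / k_on)
    return r_eq * (1.0 - np.exp(-k_obs * np.asarray(t, dtype=float)))


def dissociation_response(t: np.ndarray, R0: float, k_off: float) -> np.ndarray:
    return R0 * np.exp(-k_off * np.asarray(t, dtype=float))


def model_1to1(
    time: np.ndarray,
    C: float,
    t_dissoc: float,
    k_on: float,
    k_off: float,
    R_max: float,
) -> np.ndarray:
    """Piecewise 1:1 response, continuous at the phase boundary."""
    time = np.asarray(time, dtype=float)
    assoc = time <= t_dissoc
    out = np.empty_like(time)
    out[assoc] = association_response(time[assoc], C, k_on, k_off, R_max)
    r_end = float(association_response(np.array([t_dissoc]), C, k_on, k_off, R_max)[0])
    out[~assoc] = dissociation_response(time[~assoc] - t_dissoc, r_end, k_off)
    return out


def subtract_baseline(
    time: np.ndarray, response: np.ndarray, t_assoc_start: float
) -> np.ndarray:
    """Subtract the mean response of the pre-association baseline."""
    time = np.asarray(time, dtype=float)
    pre = time < t_assoc_start
    if not pre.any():
        raise ValueError("no baseline samples before t_assoc_start")
    return np.asarray(response, dtype=float) - float(np.mean(response[pre]))


def fit_1to1(
    sensorgrams: Sequence[Sensorgram],
    n_starts: int = 8,
    seed: int = 0,
    bounds_log10: tuple[tuple[float, float], ...] = (
        (0.0, 8.0),  # k_on
        (-6.0, 2.0),  # k_off
        (-3.0, 4.0),  # R_max
    ),
) -> BindingFit:
    """Global 1:1 fit of (k_on, k_off, R_max) across concentrations.

    Parameters are optimized in log10 space (they are positive and span
    orders of magnitude) with multi-start initialization: a deterministic
    latin-hypercube-like draw of ``n_starts`` starting points inside the
    bounds, keeping the best converged solution.
    """
    if len(sensorgrams) < 2:
        raise ValueError("global 1:1 fit needs at least 2 concentrations")

    times = [np.asarray(s.time, dtype=float) for s in sensorgrams]
    resps = [np.asarray(s.response, dtype=float) for s in sensorgrams]

    def residuals(logp: np.ndarray) -> np.ndarray:
        k_on, k_off, r_max = 10.0 ** logp
        parts = [
            model_1to1(t, s.concentration, s.t_dissoc, k_on, k_off, r_max) - r
            for t, r, s in zip(times, resps, sensorgrams)
        ]
        return np.concatenate(parts)

    lo = np.array([b[0] for b in bounds_log10])
    hi = np.array([b[1] for b in bounds_log10])
    rng = np.random.default_rng(seed)
    starts = lo + (hi - lo) * rng.random((n_starts, 3))
    starts[0] = (lo + hi) / 2.0  # one central deterministic start

    best = None
    for p0 in starts:
        try:
            sol = least_squares(residuals, p0, bounds=(lo, hi))
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("1:1 fit failed to converge from all starting points")

    k_on, k_off, r_max = 10.0 ** best.x
    per_curve = {}
    for t, r, s in zip(times, resps, sensorgrams):
        res = model_1to1(t, s.concentration, s.t_dissoc, k_on, k_off, r_max) - r
        per_curve[s.concentration] = float(np.linalg.norm(res))
    return BindingFit(
        k_on=float(k_on),
        k_off=float(k_off),
        R_max=float(r_max),
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        per_curve_residuals=per_curve,
    )
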
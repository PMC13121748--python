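"""Passive microrheology of condensates from embedded-bead trajectories.

Tracer beads diffusing in a viscous condensate perform 2D Brownian
motion. Pooling all trajectories from one condensate gives the ensemble
time-averaged mean-squared displacement (MSD); fitting the 2D anomalous
diffusion model

    MSD(t) = 4 D t^alpha

yields the diffusion coefficient D and exponent alpha. For beads in a
Newtonian fluid (alpha ≈ 1), the Stokes–Einstein–Sutherland relation

    D = k_B T / (6 pi eta r)

converts D to the viscosity eta of the condensate. Per-condensate
viscosities are compared between conditions with Tukey outlier fences
and Wilcoxon rank-sum tests (Benjamini–Hochberg adjusted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BOLTZMANN_J_PER_K",
    "TrajectorySet",
    "MSDCurve",
    "DiffusionFit",
    "ViscosityEstimate",
    "read_trajectories",
    "ensemble_msd",
    "fit_msd",
    "viscosity_from_D",
    "diffusion_from_viscosity",
    "estimate_viscosity",
    "tukey_filter",
    "compare_groups",
]

BOLTZMANN_J_PER_K = 1.380649e-23

# Defaults matching the bead-tracking experiment: ~19 °C ambient
# temperature, 0.2 µm diameter fluorescent microspheres, 150 ms frame
# interval. All overridable at call sites.
DEFAULT_TEMPERATURE_K = 292.15
DEFAULT_BEAD_RADIUS_UM = 0.1
DEFAULT_FRAME_INTERVAL_S = 0.15

#: When |alpha - 1| is below this, the bead is treated as freely
#: diffusing and D is re-fit with alpha fixed to 1 before the viscosity
#: conversion; beyond it the estimate carries an anomalous-diffusion flag.
ALPHA_NEWTONIAN_TOL = 0.15


@dataclass
class TrajectorySet:
    """Bead tracks from one condensate.

    ``tracks`` maps particle id to an (n, 2) array of (x, y) positions in
    µm at the frames given by ``frames`` (strictly increasing ints).
    """

    tracks: dict[str, np.ndarray]
    frames: dict[str, np.ndarray]
    dt: float
    condensate_id: str = ""

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("frame interval dt must be positive")
        for pid, f in self.frames.items():
            if np.any(np.diff(f) <= 0):
                raise ValueError(f"frames not strictly increasing in track {pid!r}")


@dataclass
class MSDCurve:
    lags: np.ndarray  # seconds
    msd: np.ndarray  # µm²
    n_pairs: np.ndarray  # displacement pairs per lag


@dataclass
class DiffusionFit:
    D: float  # µm²/s
    alpha: float
    fit_range: tuple[int, int]  # lag indices used (inclusive, in frames)
    residual_norm: float


@dataclass
class ViscosityEstimate:
    eta: float  # Pa·s
    D: float  # m²/s
    temperature: float  # K
    bead_radius: float  # m
    condensate_id: str = ""
    alpha: float = 1.0
    anomalous: bool = False


def read_trajectories(
    path: str | Path, dt: float | None = None, condensate_id: str = ""
) -> TrajectorySet:
    """Read a tracking export CSV (particle_id, frame, x_um, y_um).

    The frame interval must be supplied explicitly via ``dt`` or a
    ``dt_s`` column; a missing interval is a configuration error, never a
    silent default.
    """
    df = pd.read_csv(path)
    required = {"particle_id", "frame", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing column(s): {sorted(missing)}")
    if dt is None:
        if "dt_s" in df.columns:
            dt = float(df["dt_s"].iloc[0])
        else:
            raise ValueError(
                "frame interval not provided: pass dt= or include a dt_s column"
            )
    dup = df.duplicated(subset=["particle_id", "frame"])
    if dup.any():
        raise ValueError(
            f"duplicate (particle, frame) rows at index {list(df.index[dup])}"
        )
    tracks: dict[str, np.ndarray] = {}
    frames: dict[str, np.ndarray] = {}
    for pid, grp in df.groupby("particle_id", sort=False):
        grp = grp.sort_values("frame")
        tracks[str(pid)] = grp[["x_um", "y_um"]].to_numpy(dtype=float)
        frames[str(pid)] = grp["frame"].to_numpy(dtype=int)
    return TrajectorySet(tracks=tracks, frames=frames, dt=dt, condensate_id=condensate_id)


def ensemble_msd(ts: TrajectorySet, max_lag: int = 10) -> MSDCurve:
    """Ensemble time-averaged MSD: all tracks of the condensate pooled.

    For each lag k·dt the squared displacements over every particle and
    every start time are averaged together (no per-track averaging, no
    time dependence). Tracks with frame gaps contribute only the pairs
    whose frame difference equals the lag.
    """
    if not ts.tracks:
        raise ValueError("empty trajectory set")
    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=int)
    for pid, pos in ts.tracks.items():
        f = ts.frames[pid]
        contiguous = len(f) > 1 and np.all(np.diff(f) == 1)
        for k in range(1, max_lag + 1):
            if contiguous:
                if len(pos) > k:
                    d = pos[k:] - pos[:-k]
                    sums[k - 1] += float(np.sum(d * d))
                    counts[k - 1] += len(d)
            else:
                # gapped track: match frame pairs explicitly
                idx = {fr: i for i, fr in enumerate(f)}
                for i, fr in enumerate(f):
                    j = idx.get(fr + k)
                    if j is not None:
                        d = pos[j] - pos[i]
                        sums[k - 1] += float(d @ d)
                        counts[k - 1] += 1
    if counts[0] == 0:
        raise ValueError("no displacement pair at lag 1")
    keep = counts >= 1
    lags = (np.arange(1, max_lag + 1) * ts.dt)[keep]
    msd = sums[keep] / counts[keep]
    return MSDCurve(lags=lags, msd=msd, n_pairs=counts[keep])


def fit_msd(
    curve: MSDCurve,
    fit_range: tuple[int, int] | None = None,
    method: str = "loglog",
    fix_alpha: float | None = None,
) -> DiffusionFit:
    """Fit MSD(t) = 4 D t^alpha over a lag window.

    Default method is linear regression of log(MSD) on log(t); a direct
    nonlinear least-squares fit is available via ``method='nonlinear'``
    (identical on exact power-law data). ``fix_alpha`` pins the exponent
    (e.g. to 1 for the Newtonian conversion) and fits only D.
    The default window is lags 1..min(10, n_lags): short lags carry the
    smallest statistical error in time-averaged MSD.
    """
    n = len(curve.lags)
    if fit_range is None:
        fit_range = (1, min(10, n))
    lo, hi = fit_range
    sel = slice(lo - 1, hi)
    t = np.asarray(curve.lags[sel], dtype=float)
    m = np.asarray(curve.msd[sel], dtype=float)
    positive = m > 0
    if not np.all(positive):
        warnings.warn(
            f"excluding {np.sum(~positive)} non-positive MSD value(s) from fit",
            stacklevel=2,
        )
        t, m = t[positive], m[positive]
    min_pts = 2 if fix_alpha is not None else 3
    if len(t) < min_pts:
        raise ValueError(f"need at least {min_pts} positive MSD values in fit range")

    if fix_alpha is not None:
        # log(msd) - alpha*log(t) = log(4D)
        log4d = float(np.mean(np.log(m) - fix_alpha * np.log(t)))
        D = np.exp(log4d) / 4.0
        resid = np.log(m) - (log4d + fix_alpha * np.log(t))
        return DiffusionFit(
            D=float(D),
            alpha=float(fix_alpha),
            fit_range=(lo, hi),
            residual_norm=float(np.linalg.norm(resid)),
        )

    if method == "loglog":
        coeffs, res = np.polynomial.polynomial.polyfit(
            np.log(t), np.log(m), 1, full=True
        )
        intercept, alpha = coeffs
        D = np.exp(intercept) / 4.0
        resid = np.log(m) - (intercept + alpha * np.log(t))
        return DiffusionFit(
            D=float(D),
            alpha=float(alpha),
            fit_range=(lo, hi),
            residual_norm=float(np.linalg.norm(resid)),
        )
    if method == "nonlinear":
        from scipy.optimize import curve_fit

        def model(tt, D, alpha):
            return 4.0 * D * tt**alpha

        # seed from the log-log fit
        seed = fit_msd(
            MSDCurve(lags=t, msd=m, n_pairs=np.ones(len(t), dtype=int)),
            fit_range=(1, len(t)),
            method="loglog",
        )
        popt, _ = curve_fit(
            model, t, m, p0=[seed.D, seed.alpha], bounds=([0, 0], [np.inf, 3.0])
        )
        resid = m - model(t, *popt)
        return DiffusionFit(
            D=float(popt[0]),
            alpha=float(popt[1]),
            fit_range=(lo, hi),
            residual_norm=float(np.linalg.norm(resid)),
        )
    raise ValueError(f"unknown fit method {method!r}")


def viscosity_from_D(
    D_um2_s: float,
    bead_radius_um: float = DEFAULT_BEAD_RADIUS_UM,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> float:
    """Viscosity in Pa·s from a diffusion coefficient in µm²/s.

    Stokes–Einstein–Sutherland: eta = k_B T / (6 pi D r), with D and the
    bead radius converted to SI internally.
    """
    if D_um2_s <= 0 or bead_radius_um <= 0 or temperature_K <= 0:
        raise ValueError("D, bead radius and temperature must be positive")
    D_si = D_um2_s * 1e-12
    r_si = bead_radius_um * 1e-6
    return BOLTZMANN_J_PER_K * temperature_K / (6.0 * np.pi * D_si * r_si)


def diffusion_from_viscosity(
    eta_pa_s: float,
    bead_radius_um: float = DEFAULT_BEAD_RADIUS_UM,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> float:
    """Inverse of :func:`viscosity_from_D`: D in µm²/s implied by eta."""
    if eta_pa_s <= 0 or bead_radius_um <= 0 or temperature_K <= 0:
        raise ValueError("eta, bead radius and temperature must be positive")
    r_si = bead_radius_um * 1e-6
    D_si = BOLTZMANN_J_PER_K * temperature_K / (6.0 * np.pi * eta_pa_s * r_si)
    return D_si * 1e12


def estimate_viscosity(
    ts: TrajectorySet,
    max_lag: int = 10,
    fit_range: tuple[int, int] | None = None,
    bead_radius_um: float = DEFAULT_BEAD_RADIUS_UM,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> ViscosityEstimate:
    """Full per-condensate pipeline: MSD → (D, alpha) → viscosity.

    When the fitted exponent is close to 1 (|alpha−1| < 0.15) the
    conversion uses D from a fixed-alpha=1 refit over the same window,
    since the Stokes–Einstein relation presumes free diffusion. Otherwise
    the estimate is flagged anomalous and uses the free-fit D as-is.
    """
    curve = ensemble_msd(ts, max_lag=max_lag)
    free = fit_msd(curve, fit_range=fit_range)
    anomalous = abs(free.alpha - 1.0) >= ALPHA_NEWTONIAN_TOL
    if anomalous:
        warnings.warn(
            f"condensate {ts.condensate_id!r}: alpha={free.alpha:.2f} far from 1; "
            "Stokes-Einstein conversion is approximate",
            stacklevel=2,
        )
        D = free.D
    else:
        D = fit_msd(curve, fit_range=fit_range, fix_alpha=1.0).D
    eta = viscosity_from_D(D, bead_radius_um, temperature_K)
    return ViscosityEstimate(
        eta=eta,
        D=D * 1e-12,
        temperature=temperature_K,
        bead_radius=bead_radius_um * 1e-6,
        condensate_id=ts.condensate_id,
        alpha=free.alpha,
        anomalous=anomalous,
    )


def tukey_filter(values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Split values into (kept, outliers) by the Tukey fences.

    Outliers fall outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR]; quartiles use
    linear interpolation between order statistics. Fewer than 4 values:
    the filter is skipped with a warning and everything is kept.
    """
    arr = np.asarray(values, dtype=float)
    if len(arr) < 4:
        warnings.warn("fewer than 4 values: Tukey filter skipped", stacklevel=2)
        return arr, np.array([])
    q1, q3 = np.quantile(arr, [0.25, 0.75])  # linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    keep = (arr >= lo) & (arr <= hi)
    return arr[keep], arr[~keep]


def compare_groups(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests across groups.

    P-values are Benjamini–Hochberg adjusted across all pairs. Groups
    with fewer than 3 values yield NaN for their pairs.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = np.asarray(groups[names[i]], dtype=float)
            b = np.asarray(groups[names[j]], dtype=float)
            if len(a) < 3 or len(b) < 3:
                p = np.nan
            else:
                p = float(stats.ranksums(a, b).pvalue)
            rows.append({"group_a": names[i], "group_b": names[j], "pvalue": p})
    df = pd.DataFrame(rows)
    valid = df["pvalue"].notna()
    adj = np.full(len(df), np.nan)
    if valid.any():
        adj[valid.to_numpy()] = multipletests(
            df.loc[valid, "pvalue"].to_numpy(), method="fdr_bh"
        )[1]
    df["pvalue_bh"] = adj
    return df
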
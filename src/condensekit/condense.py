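"""Phase-behavior utilities: saturation-concentration regime tests,
pellet fractions, RNA stoichiometry conversion, and phase diagrams.

In a two-phase regime the dilute-phase protein concentration c_dil
equals the saturation concentration c_sat and is *independent of the
input concentration*; in a one-phase regime c_dil tracks the input.
The regime test operationalizes this with two slope hypotheses on the
regression of c_dil against input concentration: two-phase requires the
slope to be statistically indistinguishable from 0 *and* distinguishable
from 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegimeResult",
    "PelletingResult",
    "PhaseDiagramGrid",
    "ps_regime_test",
    "estimate_csat",
    "pellet_fraction",
    "rna_for_stoichiometry",
    "assemble_phase_diagram",
]

#: In-vivo reference point for protein:RNA stoichiometry: cytoplasmic
#: PGL-3 at 0.68 µM coexists with ~50 ng/µl mRNA.
REF_PROTEIN_UM = 0.68
REF_RNA_NG_UL = 50.0


@dataclass
class RegimeResult:
    regime: str  # "two_phase" | "one_phase" | "indeterminate"
    slope: float
    slope_se: float
    p_slope_zero: float  # H0: slope = 0
    p_slope_one: float  # H0: slope = 1
    c_sat: float | None  # pooled mean c_dil when two-phase


@dataclass
class PelletingResult:
    fraction_pellet: float
    normalized_fraction: float | None


@dataclass
class PhaseDiagramGrid:
    """Protein × salt grid of phase states ('two_phase'/'one_phase'/'untested')."""

    states: pd.DataFrame  # index: salt, columns: protein
    turbidity: pd.DataFrame | None = None
    tie_cells: list[tuple[float, float]] | None = None


def ps_regime_test(
    table: pd.DataFrame,
    alpha: float = 0.05,
    input_col: str = "input_uM",
    cdil_col: str = "c_dil_uM",
) -> RegimeResult:
    """Decide two-phase vs one-phase from c_dil measurements.

    Fits c_dil = a + b·input by least squares and tests the slope b
    against 0 and against 1. Two-phase requires failing to reject b = 0
    and rejecting b = 1 at level ``alpha``; anything else is one-phase.
    A single input level leaves the regime indeterminate.
    """
    x = table[input_col].to_numpy(dtype=float)
    y = table[cdil_col].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        return RegimeResult(
            regime="indeterminate",
            slope=np.nan,
            slope_se=np.nan,
            p_slope_zero=np.nan,
            p_slope_one=np.nan,
            c_sat=None,
        )
    fit = stats.linregress(x, y)
    df = len(x) - 2
    if fit.stderr == 0:
        # perfectly flat (or perfectly linear) data: decide by the slope value
        p_zero = 1.0 if fit.slope == 0 else 0.0
        p_one = 1.0 if fit.slope == 1 else 0.0
    else:
        p_zero = 2.0 * stats.t.sf(abs(fit.slope / fit.stderr), df)
        p_one = 2.0 * stats.t.sf(abs((fit.slope - 1.0) / fit.stderr), df)
    two_phase = (p_zero > alpha) and (p_one < alpha)
    regime = "two_phase" if two_phase else "one_phase"
    if regime == "one_phase" and fit.slope < 0.9:
        warnings.warn(
            f"one-phase table with slope {fit.slope:.2f} < 0.9: apparently low "
            "c_dil values may reflect adsorption losses rather than condensation",
            stacklevel=2,
        )
    c_sat = float(np.mean(y)) if two_phase else None
    return RegimeResult(
        regime=regime,
        slope=float(fit.slope),
        slope_se=float(fit.stderr),
        p_slope_zero=float(p_zero),
        p_slope_one=float(p_one),
        c_sat=c_sat,
    )


def estimate_csat(
    c_dil: Sequence[float], confidence: float = 0.95
) -> tuple[float, tuple[float, float] | None]:
    """Pooled saturation concentration: mean c_dil with a t-based CI.

    With a single measurement the mean is reported and the CI is None.
    """
    arr = np.asarray(c_dil, dtype=float)
    if len(arr) == 0:
        raise ValueError("no c_dil values")
    mean = float(np.mean(arr))
    if len(arr) < 2:
        return mean, None
    sem = stats.sem(arr)
    if sem == 0:
        return mean, (mean, mean)
    lo, hi = stats.t.interval(confidence, len(arr) - 1, loc=mean, scale=sem)
    return mean, (float(lo), float(hi))


def pellet_fraction(
    pellet: float, supernatant: float, control_fraction: float | None = None
) -> PelletingResult:
    """Fraction of protein in the pellet: p / (p + s).

    With a buffer-control fraction the result is additionally normalized
    to it, as in pelleting assays comparing added components against
    buffer alone.
    """
    total = pellet + supernatant
    if total <= 0:
        raise ValueError("pellet + supernatant must be positive")
    frac = pellet / total
    norm = frac / control_fraction if control_fraction else None
    return PelletingResult(fraction_pellet=frac, normalized_fraction=norm)


def rna_for_stoichiometry(
    protein_uM: float,
    ref_protein_uM: float = REF_PROTEIN_UM,
    ref_rna_ng_ul: float = REF_RNA_NG_UL,
) -> float:
    """RNA concentration (ng/µl) matching the in-vivo protein:RNA ratio.

    Scales the reference stoichiometry linearly to the working protein
    concentration and reports to one decimal (e.g. 4 µM protein →
    294.1 ng/µl at the default reference point).
    """
    if protein_uM <= 0 or ref_protein_uM <= 0 or ref_rna_ng_ul <= 0:
        raise ValueError("concentrations must be positive")
    return round(ref_rna_ng_ul * protein_uM / ref_protein_uM, 1)


def assemble_phase_diagram(
    points: Sequence[tuple[float, float, str] | tuple[float, float, str, float]],
    merge: str = "error",
) -> PhaseDiagramGrid:
    """Assemble (protein, salt, state [, A330]) points into a grid.

    States must be 'two_phase' or 'one_phase'; cells without data are
    'untested'. Replicated cells need ``merge='majority'``: the majority
    state wins, and ties resolve to 'two_phase' with the cell flagged in
    ``tie_cells``. Turbidity values, when present, are averaged per cell
    and carried as annotation only.
    """
    if len(points) == 0:
        empty = pd.DataFrame()
        return PhaseDiagramGrid(states=empty, turbidity=None, tie_cells=[])
    cells: dict[tuple[float, float], list[str]] = {}
    turb: dict[tuple[float, float], list[float]] = {}
    for p in points:
        protein, salt, state = p[0], p[1], p[2]
        if state not in ("two_phase", "one_phase"):
            raise ValueError(f"unknown phase state {state!r}")
        cells.setdefault((protein, salt), []).append(state)
        if len(p) > 3 and p[3] is not None:
            turb.setdefault((protein, salt), []).append(float(p[3]))

    ties: list[tuple[float, float]] = []
    resolved: dict[tuple[float, float], str] = {}
    for cell, states in cells.items():
        uniq = set(states)
        if len(uniq) == 1:
            resolved[cell] = states[0]
            continue
        if merge != "majority":
            raise ValueError(
                f"conflicting replicate states at protein={cell[0]}, salt={cell[1]} "
                "(pass merge='majority' to resolve)"
            )
        n_two = states.count("two_phase")
        n_one = states.count("one_phase")
        if n_two == n_one:
            resolved[cell] = "two_phase"
            ties.append(cell)
        else:
            resolved[cell] = "two_phase" if n_two > n_one else "one_phase"

    proteins = sorted({c[0] for c in cells})
    salts = sorted({c[1] for c in cells})
    grid = pd.DataFrame("untested", index=salts, columns=proteins)
    for (protein, salt), state in resolved.items():
        grid.loc[salt, protein] = state
    tgrid = None
    if turb:
        tgrid = pd.DataFrame(np.nan, index=salts, columns=proteins)
        for (protein, salt), vals in turb.items():
            tgrid.loc[salt, protein] = float(np.mean(vals))
    return PhaseDiagramGrid(states=grid, turbidity=tgrid, tie_cells=ties)
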
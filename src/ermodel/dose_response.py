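"""Tamoxifen dose-response curves, response surfaces, and agonism metrics.

Steady-state protein expression p as a function of inhibitor dose, either
alone (dose curve with per-complex decomposition) or against a second
swept quantity (receptor level, hormone, promoter sites, or the
tamoxifen-complex transcription rate).  The non-monotonic dependence of p
on receptor level (prozone / combinatorial inhibition: excess receptor
sequesters ligand into transcriptionally weak complexes) is located with
a simple interior-maximum search.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .core import BindingConstants, SolverError, SystemTotals, TranscriptionRates, solve_equilibrium
from .expression import decompose_response, steady_state_expression

__all__ = [
    "DEFAULT_DOSE_GRID",
    "hek293_totals",
    "dose_curve",
    "response_surface",
    "percent_inhibition",
    "find_interior_maximum",
]

# mirrors the sensitivity-analysis dose grid: 138 log-spaced doses, 0.01-3000 nM
DEFAULT_DOSE_GRID = np.geomspace(0.01, 3000.0, 138)


def hek293_totals(H_t: float = 0.0, I_t: float = 0.0) -> SystemTotals:
    """Totals emulating the HEK293/hERalpha reporter cell line.

    ER_t = 20 nM and D_t = 0.1 nM were calibrated once against the
    reported dose-response features of that line (fold tamoxifen
    agonism, position of the ER2ID contribution peak, residual
    expression at high tamoxifen + 0.5 nM estradiol); see the methods
    note for the rationale.
    """
    return SystemTotals(ER_t=20.0, H_t=H_t, I_t=I_t, D_t=0.1)


def dose_curve(K: BindingConstants, rates: TranscriptionRates,
               totals: SystemTotals, I_grid=None) -> pd.DataFrame:
    """Steady-state expression and its decomposition along an I_t grid.

    ``totals`` fixes ER_t, H_t and D_t; its I_t is ignored in favour of
    the grid.  One equilibrium solve per dose.
    """
    I_grid = DEFAULT_DOSE_GRID if I_grid is None else np.asarray(I_grid, dtype=float)
    if I_grid.size > 1 and np.any(np.diff(I_grid) <= 0):
        raise ValueError("I_t grid must be strictly ascending")
    rows = []
    for i_t in I_grid:
        tot = replace(totals, I_t=float(i_t))
        try:
            st = solve_equilibrium(K, tot)
        except SolverError as e:
            raise SolverError(f"dose point I_t={i_t} nM failed: {e}") from e
        expr = steady_state_expression(st, rates)
        dec = decompose_response(st, rates)
        rows.append({"I_t": i_t, "p": expr.p, "r": expr.r,
                     "v_tr": expr.v_tr, **dec.as_dict()})
    return pd.DataFrame(rows)


_AXIS2 = ("ER_t", "H_t", "D_t", "k_sr_i")


def response_surface(K: BindingConstants, rates: TranscriptionRates,
                     totals: SystemTotals, axis2: str, axis2_grid,
                     I_grid=None) -> pd.DataFrame:
    """Matrix of steady-state protein p over (axis2, I_t).

    ``axis2`` is one of ER_t, H_t, D_t (totals) or k_sr_i (the
    transcription rate constant of tamoxifen-dimer complexes).  Returned
    as a DataFrame indexed by the axis2 grid with I_t columns.
    """
    if axis2 not in _AXIS2:
        raise ValueError(f"unknown axis2 {axis2!r}; choose from {_AXIS2}")
    I_grid = DEFAULT_DOSE_GRID if I_grid is None else np.asarray(I_grid, dtype=float)
    axis2_grid = np.asarray(axis2_grid, dtype=float)
    for g, name in ((I_grid, "I_t"), (axis2_grid, axis2)):
        if g.size > 1 and np.any(np.diff(g) <= 0):
            raise ValueError(f"{name} grid must be strictly ascending")
    mat = np.empty((axis2_grid.size, I_grid.size))
    for a, val in enumerate(axis2_grid):
        if axis2 == "k_sr_i":
            r_a, tot_a = replace(rates, k_sr_i=float(val)), totals
        else:
            r_a, tot_a = rates, replace(totals, **{axis2: float(val)})
        for b, i_t in enumerate(I_grid):
            st = solve_equilibrium(K, replace(tot_a, I_t=float(i_t)))
            mat[a, b] = steady_state_expression(st, r_a).p
    out = pd.DataFrame(mat, index=pd.Index(axis2_grid, name=axis2),
                       columns=pd.Index(I_grid, name="I_t"))
    return out


def percent_inhibition(curve: pd.DataFrame) -> pd.DataFrame:
    """Inhibition 100*(1 - p(I_t)/p(0)) relative to the drug-free point.

    Negative values indicate agonism.  The curve must contain an I_t = 0
    row with p > 0.
    """
    ref_rows = curve[curve["I_t"] == 0]
    if ref_rows.empty:
        raise ValueError("curve lacks an I_t = 0 reference point")
    p0 = float(ref_rows["p"].iloc[0])
    if p0 <= 0:
        raise ValueError("inhibition undefined: reference expression is zero")
    return pd.DataFrame({"I_t": curve["I_t"],
                         "inhibition_pct": 100.0 * (1.0 - curve["p"] / p0)})


def find_interior_maximum(x, y) -> tuple[float, float] | None:
    """Grid argmax if strictly interior and above both endpoints, else None."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 grid points")
    k = int(np.argmax(y))
    if k == 0 or k == y.size - 1:
        return None
    if y[k] > y[0] and y[k] > y[-1]:
        return float(x[k]), float(y[k])
    return None
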
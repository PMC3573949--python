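"""Apparent cooperativity of hormone binding, quantified by Hill fits.

The binding model contains no Hill equation: cooperativity emerges
mechanistically from dimerisation (a hormone-laden monomer recruits a
second monomer whose site is then filled at higher affinity).  Fitting
model-generated binding curves with the empirical Hill equation

    B = L^n_H / (K_A^n_H + L^n_H)

measures the apparent cooperativity: n_H rises from ~1 at low receptor
(monomer-dominated, single-site behaviour) toward ~1.4 at 20 nM receptor.
B is the fraction of receptor sites occupied by hormone and L the free
(not total) hormone concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import BindingConstants, SystemTotals, bound_hormone_metrics, solve_equilibrium

__all__ = ["HillFit", "binding_curve", "fit_hill", "hill_profile",
           "hill_function", "occupancy_spanning_grid"]


@dataclass(frozen=True)
class HillFit:
    K_A: float        # half-saturation free-ligand concentration, nM
    n_H: float        # Hill coefficient
    rss: float        # residual sum of squares
    spans_range: bool = True  # data covered B < 0.1 and B > 0.9


def hill_function(L, K_A, n_H):
    L = np.asarray(L, dtype=float)
    return L**n_H / (K_A**n_H + L**n_H)


def binding_curve(K: BindingConstants, ER_t: float, H_t_grid) -> pd.DataFrame:
    """Hormone-only binding curve: (H_t, free H, occupied fraction H_b)."""
    if not (ER_t > 0):
        raise ValueError("ER_t must be > 0 for a binding curve")
    rows = []
    for h_t in np.asarray(H_t_grid, dtype=float):
        st = solve_equilibrium(K, SystemTotals(ER_t=ER_t, H_t=float(h_t)))
        _, h_b = bound_hormone_metrics(st, SystemTotals(ER_t=ER_t, H_t=float(h_t)))
        rows.append({"H_t": h_t, "H_free": st.H, "H_b": h_b})
    return pd.DataFrame(rows)


def occupancy_spanning_grid(K: BindingConstants, ER_t: float,
                            n_points: int = 50,
                            span: tuple[float, float] = (0.02, 0.98),
                            max_expand: int = 60) -> np.ndarray:
    """Log-spaced H_t grid whose occupancies cover the requested B span."""
    lo, hi = 1e-4, 1e3

    def occ(h_t: float) -> float:
        st = solve_equilibrium(K, SystemTotals(ER_t=ER_t, H_t=h_t))
        _, b = bound_hormone_metrics(st, SystemTotals(ER_t=ER_t, H_t=h_t))
        return b

    for _ in range(max_expand):
        if occ(lo) <= span[0]:
            break
        lo /= 4
    for _ in range(max_expand):
        if occ(hi) >= span[1]:
            break
        hi *= 4
    return np.geomspace(lo, hi, n_points)


def fit_hill(L, B) -> HillFit:
    """Least-squares Hill fit of bound fraction vs free ligand.

    Unweighted nonlinear least squares in linear B-space.  Data that do
    not span B from below 0.1 to above 0.9 are still fitted but flagged
    (``spans_range=False``).  Exact Hill input is recovered exactly.
    """
    L = np.asarray(L, dtype=float)
    B = np.asarray(B, dtype=float)
    if L.size != B.size or L.size < 5:
        raise ValueError("need >= 5 (L, B) pairs")
    if np.any(L < 0):
        raise ValueError("free ligand concentrations must be >= 0")
    if np.ptp(B) <= 0:
        raise ValueError("degenerate binding data: constant B")
    spans = bool(B.min() < 0.1 and B.max() > 0.9)
    # initial guess: K_A from interpolated half-occupancy, n_H = 1
    try:
        ka0 = float(np.interp(0.5, B, L))
    except Exception:
        ka0 = float(np.median(L[L > 0]))
    if not (ka0 > 0):
        ka0 = float(np.median(L[L > 0]))
    popt, _ = curve_fit(hill_function, L, B, p0=[ka0, 1.0],
                        bounds=([1e-12, 1e-3], [np.inf, 20.0]),
                        maxfev=20000)
    resid = B - hill_function(L, *popt)
    return HillFit(K_A=float(popt[0]), n_H=float(popt[1]),
                   rss=float(resid @ resid), spans_range=spans)


def hill_profile(K: BindingConstants, ER_t_grid, n_points: int = 50) -> pd.DataFrame:
    """Apparent Hill coefficient and K_A across receptor concentrations.

    For each ER_t, a hormone-only binding curve is generated on a
    log-spaced total-hormone grid spanning occupancy 0.02-0.98 and fitted
    with the Hill equation in (free L, B) coordinates.
    """
    ER_t_grid = np.asarray(ER_t_grid, dtype=float)
    if ER_t_grid.size > 1 and np.any(np.diff(ER_t_grid) <= 0):
        raise ValueError("ER_t grid must be strictly ascending")
    rows = []
    for er_t in ER_t_grid:
        grid = occupancy_spanning_grid(K, float(er_t), n_points=n_points)
        curve = binding_curve(K, float(er_t), grid)
        fit = fit_hill(curve["H_free"], curve["H_b"])
        rows.append({"ER_t": er_t, "n_H": fit.n_H, "K_A": fit.K_A,
                     "rss": fit.rss})
    return pd.DataFrame(rows)
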
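"""Equilibrium model of ER dimerisation and binding with ligands and ERE DNA.

The model tracks 18 species built from four free components: estrogen
receptor monomer (ER), the natural hormone 17beta-estradiol (H), a
competitive inhibitor such as tamoxifen (I), and estrogen-response-element
promoter sites on DNA (D).  ER monomers dimerise; monomers and dimers bind
ligands; liganded and unliganded dimers bind ERE.  Every complex
concentration is a monomial in the four free concentrations divided by a
product of dissociation constants, so the equilibrium state is fully
determined by the four free concentrations and the constants K1..K20.

Thermodynamic cycles force six of the twenty dissociation constants to be
products/ratios of the others (detailed balance); those six are always
derived, never set directly.

All concentrations are nanomolar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SPECIES",
    "COMPLEX_SPECIES",
    "BindingConstants",
    "SystemTotals",
    "TranscriptionRates",
    "EquilibriumState",
    "derive_dependent_constants",
    "complexes_from_free",
    "solve_equilibrium",
    "bound_hormone_metrics",
    "species_distribution_scan",
    "SolverError",
]


class SolverError(RuntimeError):
    """Equilibrium solve failed to converge (reports residuals and inputs)."""


# Complex species: (name, ER stoichiometry, H, I, D, K-denominator factors)
_COMPLEX_DEFS = [
    ("ER2", 2, 0, 0, 0, ("K1",)),
    ("ER2H", 2, 1, 0, 0, ("K1", "K2")),
    ("ER2H2", 2, 2, 0, 0, ("K1", "K2", "K3")),
    ("ERH", 1, 1, 0, 0, ("K4",)),
    ("ER2I", 2, 0, 1, 0, ("K1", "K7")),
    ("ER2I2", 2, 0, 2, 0, ("K1", "K7", "K8")),
    ("ERI", 1, 0, 1, 0, ("K9",)),
    ("ER2HI", 2, 1, 1, 0, ("K1", "K7", "K13")),
    ("ER2D", 2, 0, 0, 1, ("K1", "K15")),
    ("ER2HD", 2, 1, 0, 1, ("K1", "K2", "K16")),
    ("ER2H2D", 2, 2, 0, 1, ("K1", "K2", "K3", "K17")),
    ("ER2ID", 2, 0, 1, 1, ("K1", "K7", "K18")),
    ("ER2I2D", 2, 0, 2, 1, ("K1", "K7", "K8", "K19")),
    ("ER2HID", 2, 1, 1, 1, ("K1", "K7", "K13", "K20")),
]

COMPLEX_SPECIES = tuple(name for name, *_ in _COMPLEX_DEFS)
SPECIES = ("ER", "H", "I", "D") + COMPLEX_SPECIES

# stoichiometry matrix: rows = complexes, cols = (ER, H, I, D)
_STOICH = np.array([[a, h, i, d] for _, a, h, i, d, _ in _COMPLEX_DEFS], dtype=float)

_INDEPENDENT = (
    "K1", "K2", "K3", "K4", "K7", "K8", "K9",
    "K13", "K15", "K16", "K17", "K18", "K19", "K20",
)
_DEPENDENT = ("K5", "K6", "K10", "K11", "K12", "K14")


@dataclass(frozen=True)
class BindingConstants:
    """The 20 dissociation constants of the binding scheme, in nM.

    Fourteen are independent; K5, K6, K10, K11, K12 and K14 follow from
    detailed balance.  Construct through :func:`derive_dependent_constants`
    unless you already have a consistent set.
    """

    K1: float
    K2: float
    K3: float
    K4: float
    K5: float
    K6: float
    K7: float
    K8: float
    K9: float
    K10: float
    K11: float
    K12: float
    K13: float
    K14: float
    K15: float
    K16: float
    K17: float
    K18: float
    K19: float
    K20: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v > 0) or not math.isfinite(v):
                raise ValueError(f"dissociation constant {f.name} must be "
                                 f"finite and > 0, got {v!r}")

    def independent(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in _INDEPENDENT}

    def detailed_balance_residuals(self) -> dict[str, float]:
        """Relative residual of each of the six cycle identities."""
        derived = _dependent_from(self.independent())
        return {k: abs(getattr(self, k) - v) / v for k, v in derived.items()}

    def check_detailed_balance(self, rtol: float = 1e-10) -> None:
        bad = {k: r for k, r in self.detailed_balance_residuals().items() if r > rtol}
        if bad:
            raise ValueError(f"detailed-balance violation in {sorted(bad)}: {bad}")


def _dependent_from(ind: dict[str, float]) -> dict[str, float]:
    K1, K2, K3, K4 = ind["K1"], ind["K2"], ind["K3"], ind["K4"]
    K7, K8, K9, K13 = ind["K7"], ind["K8"], ind["K9"], ind["K13"]
    return {
        "K5": K1 * K2 / K4,
        "K6": K1 * K2 * K3 / K4**2,
        "K10": K1 * K7 / K9,
        "K11": K1 * K7 * K8 / K9**2,
        "K12": K1 * K7 * K13 / (K4 * K9),
        "K14": K7 * K13 / K2,
    }


def derive_dependent_constants(**independent: float) -> BindingConstants:
    """Build a full constant set from the 14 independent constants.

    Parameters are keyword arguments named K1..K4, K7..K9, K13, K15..K20.
    The six dependent constants are derived from the detailed-balance
    relations K5=K1*K2/K4, K6=K1*K2*K3/K4^2, K10=K1*K7/K9,
    K11=K1*K7*K8/K9^2, K12=K1*K7*K13/(K4*K9), K14=K7*K13/K2.
    """
    missing = set(_INDEPENDENT) - set(independent)
    extra = set(independent) - set(_INDEPENDENT)
    if missing or extra:
        raise ValueError(f"expected exactly the 14 independent constants; "
                         f"missing={sorted(missing)} unexpected={sorted(extra)}")
    for name in _INDEPENDENT:
        v = independent[name]
        if not (v > 0) or not math.isfinite(v):
            raise ValueError(f"independent constant {name} must be finite "
                             f"and > 0, got {v!r}")
    return BindingConstants(**independent, **_dependent_from(independent))


@dataclass(frozen=True)
class SystemTotals:
    """Conserved totals: receptor monomer, hormone, inhibitor, ERE sites (nM)."""

    ER_t: float = 0.0
    H_t: float = 0.0
    I_t: float = 0.0
    D_t: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"total {f.name} must be finite and >= 0, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.ER_t, self.H_t, self.I_t, self.D_t])


@dataclass(frozen=True)
class TranscriptionRates:
    """Rate constants of transcription/translation (s^-1), Table-2 style.

    k_sr applies to hormone-bound dimer complexes at ERE (ER2HD, ER2H2D),
    k_sr_i to inhibitor-bound (ER2ID, ER2I2D), k_sr_hi to the mixed
    ER2HID complex, k_sr_b to the unliganded ER2D complex.  kappa is the
    composite k_dp*k_dr/k_sp governing steady-state protein per unit
    transcription rate; it is derived, never set.
    """

    k_sr: float
    k_sr_i: float
    k_sr_hi: float
    k_sr_b: float
    k_dr: float
    k_sp: float
    k_dp: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v > 0) or not math.isfinite(v):
                raise ValueError(f"rate constant {f.name} must be finite "
                                 f"and > 0, got {v!r}")

    @property
    def kappa(self) -> float:
        return self.k_dp * self.k_dr / self.k_sp

    def with_kappa(self, kappa: float) -> "TranscriptionRates":
        """Rescale k_dp so the composite kappa takes the requested value.

        Steady-state protein depends on the three constituent constants
        only through kappa, so which constituent absorbs the change is
        immaterial for steady-state work.
        """
        if not (kappa > 0):
            raise ValueError(f"kappa must be > 0, got {kappa!r}")
        return replace(self, k_dp=kappa * self.k_sp / self.k_dr)


@dataclass(frozen=True)
class EquilibriumState:
    """Concentrations (nM) of the 4 free species and 14 complexes."""

    ER: float
    H: float
    I: float
    D: float
    ER2: float
    ER2H: float
    ER2H2: float
    ERH: float
    ER2I: float
    ER2I2: float
    ERI: float
    ER2HI: float
    ER2D: float
    ER2HD: float
    ER2H2D: float
    ER2ID: float
    ER2I2D: float
    ER2HID: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in SPECIES}

    def complexes(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in COMPLEX_SPECIES])

    def totals(self) -> SystemTotals:
        """Recompute the conserved totals implied by this state."""
        free = np.array([self.ER, self.H, self.I, self.D])
        tot = free + _STOICH.T @ self.complexes()
        return SystemTotals(*tot)

    def mass_action_residuals(self, K: BindingConstants) -> dict[str, float]:
        """Relative deviation of each complex from its mass-action value."""
        ref = complexes_from_free(self.ER, self.H, self.I, self.D, K)
        out = {}
        for name in COMPLEX_SPECIES:
            expect = getattr(ref, name)
            have = getattr(self, name)
            scale = max(abs(expect), abs(have), 1e-300)
            out[name] = abs(have - expect) / scale if scale > 0 else 0.0
        return out


def _denominators(K: BindingConstants) -> np.ndarray:
    return np.array([math.prod(getattr(K, k) for k in ks)
                     for *_, ks in _COMPLEX_DEFS])


def _complex_vector(free: np.ndarray, denom: np.ndarray) -> np.ndarray:
    # monomial per complex; 0**0 == 1 handled by numpy power
    with np.errstate(divide="ignore", invalid="ignore"):
        mono = np.prod(np.power(free[None, :], _STOICH), axis=1)
    return mono / denom


def complexes_from_free(ER: float, H: float, I: float, D: float,
                        K: BindingConstants) -> EquilibriumState:
    """All 14 complex concentrations by direct substitution of mass action.

    Any zero free concentration propagates to zero for every complex
    containing that component.
    """
    free = np.array([ER, H, I, D], dtype=float)
    if np.any(free < 0) or not np.all(np.isfinite(free)):
        raise ValueError(f"free concentrations must be finite and >= 0, got {free}")
    conc = _complex_vector(free, _denominators(K))
    return EquilibriumState(ER, H, I, D, *conc)


def _totals_and_jacobian(logfree: np.ndarray, active: np.ndarray,
                         denom: np.ndarray):
    """Computed totals and d(totals)/d(log free) for the active components."""
    free = np.zeros(4)
    free[active] = np.exp(logfree)
    conc = _complex_vector(free, denom)
    tot = free + _STOICH.T @ conc
    # dT_x/dlog f_y = sum_s coef_x(s) * exp_y(s) * c_s  + delta_xy * f_x
    J = (_STOICH.T * conc) @ _STOICH + np.diag(free)
    return tot[active], J[np.ix_(active, active)], free


def _newton_solve(totals: np.ndarray, active: np.ndarray, denom: np.ndarray,
                  tol: float = 1e-12, max_iter: int = 200):
    T = totals[active]
    # weak-binding initial guess: free a bit below total
    x = np.log(T * 0.5)
    scale = T
    best = None
    for _ in range(max_iter):
        tot, J, free = _totals_and_jacobian(x, active, denom)
        r = (tot - T) / scale
        nrm = float(np.max(np.abs(r)))
        if best is None or nrm < best[0]:
            best = (nrm, x.copy())
        if nrm < tol:
            return free, nrm
        # Newton step in log space; J is d tot/d log free
        try:
            step = np.linalg.solve(J / scale[:, None], r)
        except np.linalg.LinAlgError:
            break
        step = np.clip(step, -5.0, 5.0)
        lam = 1.0
        for _ in range(40):
            xn = x - lam * step
            tot_n, _, _ = _totals_and_jacobian(xn, active, denom)
            if float(np.max(np.abs((tot_n - T) / scale))) < nrm:
                x = xn
                break
            lam *= 0.5
        else:
            break
    tot, _, free = _totals_and_jacobian(best[1], active, denom)
    return None, best[0]


def _bisection_solve(totals: np.ndarray, active: np.ndarray,
                     denom: np.ndarray) -> np.ndarray:
    """Nested 1-D root isolation, outermost D then I, H, innermost ER.

    Each conservation residual is monotone in its own free concentration
    at fixed outer variables, and brackets a sign change on [0, total];
    Brent's method per level makes the nesting affordable.
    """
    ER_t, H_t, I_t, D_t = totals
    xtol = 1e-300

    def er_residual(er, h, i, d):
        free = np.array([er, h, i, d])
        conc = _complex_vector(free, denom)
        return er + float(_STOICH[:, 0] @ conc) - ER_t

    def solve_er(h, i, d):
        if ER_t == 0:
            return 0.0
        if er_residual(ER_t, h, i, d) <= 0:
            return ER_t
        return brentq(er_residual, 0.0, ER_t, args=(h, i, d),
                      xtol=xtol, rtol=8.9e-16, maxiter=300)

    def h_residual(h, i, d):
        er = solve_er(h, i, d)
        free = np.array([er, h, i, d])
        conc = _complex_vector(free, denom)
        return h + float(_STOICH[:, 1] @ conc) - H_t

    def solve_h(i, d):
        if H_t == 0:
            return 0.0
        if h_residual(H_t, i, d) <= 0:
            return H_t
        return brentq(h_residual, 0.0, H_t, args=(i, d),
                      xtol=xtol, rtol=8.9e-16, maxiter=300)

    def i_residual(i, d):
        h = solve_h(i, d)
        er = solve_er(h, i, d)
        free = np.array([er, h, i, d])
        conc = _complex_vector(free, denom)
        return i + float(_STOICH[:, 2] @ conc) - I_t

    def solve_i(d):
        if I_t == 0:
            return 0.0
        if i_residual(I_t, d) <= 0:
            return I_t
        return brentq(i_residual, 0.0, I_t, args=(d,),
                      xtol=xtol, rtol=8.9e-16, maxiter=300)

    def d_residual(d):
        i = solve_i(d)
        h = solve_h(i, d)
        er = solve_er(h, i, d)
        free = np.array([er, h, i, d])
        conc = _complex_vector(free, denom)
        return d + float(_STOICH[:, 3] @ conc) - D_t

    if D_t == 0:
        d = 0.0
    elif d_residual(D_t) <= 0:
        d = D_t
    else:
        d = brentq(d_residual, 0.0, D_t, xtol=xtol, rtol=8.9e-16, maxiter=300)
    i = solve_i(d)
    h = solve_h(i, d)
    er = solve_er(h, i, d)
    return np.array([er, h, i, d])


def solve_equilibrium(K: BindingConstants, totals: SystemTotals,
                      tol: float = 1e-12) -> EquilibriumState:
    """Solve the four conservation equations for the free concentrations.

    A damped Newton iteration on log-transformed free concentrations
    (positivity by construction) is tried first; on failure the solver
    falls back to nested 1-D root isolation, which is slower but
    guaranteed for this monotone mass-action system.  Components whose
    total is zero are eliminated analytically.

    Raises :class:`SolverError` if neither route reaches the requested
    residual tolerance (relative to each nonzero total).
    """
    T = totals.as_array()
    denom = _denominators(K)
    active = T > 0
    if not np.any(active):
        return complexes_from_free(0.0, 0.0, 0.0, 0.0, K)

    free, nrm = _newton_solve(T, active, denom, tol=tol)
    if free is None:
        free_act = _bisection_solve(T, active, denom)
        free = np.where(active, free_act, 0.0)
        conc = _complex_vector(free, denom)
        tot = free + _STOICH.T @ conc
        scale = np.where(active, T, 1.0)
        nrm = float(np.max(np.abs((tot - T) / scale)[active]))
        if nrm > 1e-8:
            raise SolverError(
                f"equilibrium solve failed: residual {nrm:.3e} for totals "
                f"{totals} (Newton and nested bisection both exhausted)")
    return complexes_from_free(*free, K)


def bound_hormone_metrics(state: EquilibriumState,
                          totals: SystemTotals) -> tuple[float, float]:
    """Hormone-occupied receptor binding sites ER_b (nM) and fraction H_b.

    ER_b counts each bound hormone molecule as one occupied site:
    ERH + ER2H + 2*ER2H2 + ER2HI + ER2HD + 2*ER2H2D + ER2HID.
    H_b = ER_b / ER_t, the fraction of receptor sites occupied by hormone.
    """
    er_b = (state.ERH + state.ER2H + 2 * state.ER2H2 + state.ER2HI
            + state.ER2HD + 2 * state.ER2H2D + state.ER2HID)
    if totals.ER_t == 0:
        raise ValueError("H_b undefined for ER_t = 0")
    return er_b, er_b / totals.ER_t


def species_distribution_scan(K: BindingConstants, totals_template: SystemTotals,
                              er_grid) -> "pandas.DataFrame":
    """Equilibrium species table across a grid of total receptor levels.

    One row per ER_t value, holding the free species and every complex,
    at fixed H_t, I_t, D_t from ``totals_template``.  Mirrors the analysis
    of how receptor over-expression redistributes receptor-ligand and
    ERE-bound complexes (prozone / combinatorial inhibition).
    """
    import pandas as pd

    er_grid = np.asarray(er_grid, dtype=float)
    if er_grid.size == 0:
        raise ValueError("ER_t grid must be nonempty")
    if np.any(np.diff(er_grid) <= 0) and er_grid.size > 1:
        raise ValueError("ER_t grid must be strictly ascending")
    rows = []
    for er_t in er_grid:
        tot = replace(totals_template, ER_t=float(er_t))
        try:
            st = solve_equilibrium(K, tot)
        except SolverError as e:
            raise SolverError(f"scan failed at ER_t={er_t}: {e}") from e
        rows.append({"ER_t": er_t, **st.as_dict()})
    return pd.DataFrame(rows)
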
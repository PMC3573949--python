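"""Global sensitivity analysis: LHS sampling and PRCC indices.

Sensitivity of steady-state protein expression p to simultaneous
variation of all independent model parameters is quantified per fixed
inhibitor dose.  Parameter sets are drawn by Latin Hypercube Sampling
(one sample per equal-probability stratum per parameter, on a log or
linear scale), the model is solved for each set, and a partial rank
correlation coefficient is computed per parameter: rank-transform
parameters and readout, regress each out on all *other* ranked
parameters, and correlate the two residual vectors.  The sign convention
is that a positive index marks a parameter whose larger values
associate with larger transcriptional response.

The perturbed set comprises the 14 independent dissociation constants,
the four transcription rate constants, the composite kappa, and the
totals ER_t, H_t and D_t (22 quantities); the inhibitor total I_t is
fixed per run, and dependent dissociation constants are re-derived per
sample so every sampled model obeys detailed balance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import qmc, rankdata

from .core import SolverError, SystemTotals, derive_dependent_constants, solve_equilibrium
from .expression import steady_state_expression
from .params import PUBLISHED_BINDING, PUBLISHED_RATES, default_rates

__all__ = ["ParameterSpace", "PRCCProfile", "default_space",
           "lhs_sample", "evaluate_readout", "prcc", "gsa_scan"]

_RATE_NAMES = ("k_sr", "k_sr_i", "k_sr_hi", "k_sr_b")


@dataclass(frozen=True)
class ParameterSpace:
    """Ordered parameter names with bounds and per-parameter sampling scale."""

    names: tuple
    lower: np.ndarray
    upper: np.ndarray
    log: np.ndarray  # bool per parameter: sample uniformly in log10

    def __post_init__(self) -> None:
        k = len(self.names)
        if "I_t" in self.names:
            raise ValueError("I_t is fixed per GSA run and cannot be perturbed")
        for arr, nm in ((self.lower, "lower"), (self.upper, "upper"), (self.log, "log")):
            if len(arr) != k:
                raise ValueError(f"{nm} must have length {k}")
        if np.any(self.lower >= self.upper):
            bad = [self.names[i] for i in np.nonzero(self.lower >= self.upper)[0]]
            raise ValueError(f"lower >= upper for {bad}")
        if np.any(self.log & (self.lower <= 0)):
            bad = [self.names[i] for i in np.nonzero(self.log & (self.lower <= 0))[0]]
            raise ValueError(f"log-scaled parameters need positive bounds: {bad}")

    @property
    def k(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class PRCCProfile:
    """Per-parameter PRCC indices at one fixed inhibitor dose."""

    dose: float
    indices: dict
    n_samples: int
    n_effective: int
    seed: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dose": self.dose, "parameter": list(self.indices),
             "prcc": list(self.indices.values()),
             "N_effective": self.n_effective})


def default_space(span: float = 10.0, log: bool = False) -> ParameterSpace:
    """Default parameter space for the sensitivity scan.

    Bounds are value/span .. value*span around the published kinetic
    constants and the composite kappa, and the biologically plausible
    ranges for the totals: ER_t 0.001-300 nM, H_t 0.03-3 nM, D_t
    0.01-1 nM.  Sampling is uniform on each range by default (plain
    Latin Hypercube over the hypercube of ranges); pass ``log=True``
    to stratify uniformly in log10 instead.
    """
    names, lo, hi = [], [], []
    for nm, v in PUBLISHED_BINDING.items():
        names.append(nm)
        lo.append(v / span)
        hi.append(v * span)
    for nm in _RATE_NAMES:
        v = PUBLISHED_RATES[nm]
        names.append(nm)
        lo.append(v / span)
        hi.append(v * span)
    names.append("kappa")
    lo.append(5e-5 / span)
    hi.append(5e-5 * span)
    for nm, (a, b) in (("ER_t", (0.001, 300.0)), ("H_t", (0.03, 3.0)),
                       ("D_t", (0.01, 1.0))):
        names.append(nm)
        lo.append(a)
        hi.append(b)
    k = len(names)
    return ParameterSpace(tuple(names), np.array(lo), np.array(hi),
                          np.full(k, bool(log)))


def lhs_sample(space: ParameterSpace, N: int, seed: int) -> np.ndarray:
    """N x k Latin Hypercube sample mapped onto the space's bounds/scales."""
    if N < 2:
        raise ValueError("need N >= 2 samples")
    unit = qmc.LatinHypercube(d=space.k, seed=int(seed)).random(N)
    lo, hi = space.lower.copy(), space.upper.copy()
    out = np.empty_like(unit)
    logm = space.log
    out[:, logm] = 10.0 ** (np.log10(lo[logm]) + unit[:, logm]
                            * (np.log10(hi[logm]) - np.log10(lo[logm])))
    lin = ~logm
    out[:, lin] = lo[lin] + unit[:, lin] * (hi[lin] - lo[lin])
    return out


def evaluate_readout(samples: np.ndarray, space: ParameterSpace,
                     I_t: float, max_failure_rate: float = 0.01):
    """Steady-state protein p per sampled parameter row at fixed I_t.

    Returns (readout array with NaN for failed solves, failure count).
    A failure rate above ``max_failure_rate`` raises, as it indicates
    pathological bounds rather than isolated numerical trouble.
    """
    name_ix = {nm: j for j, nm in enumerate(space.names)}
    base_rates = default_rates()
    out = np.empty(samples.shape[0])
    failures = 0
    for i, row in enumerate(samples):
        vals = {nm: float(row[j]) for nm, j in name_ix.items()}
        try:
            ind = {nm: vals.get(nm, v) for nm, v in PUBLISHED_BINDING.items()}
            K = derive_dependent_constants(**ind)
            rates = base_rates
            for nm in _RATE_NAMES:
                if nm in vals:
                    rates = replace(rates, **{nm: vals[nm]})
            if "kappa" in vals:
                rates = rates.with_kappa(vals["kappa"])
            totals = SystemTotals(ER_t=vals.get("ER_t", 0.0),
                                  H_t=vals.get("H_t", 0.0),
                                  I_t=I_t,
                                  D_t=vals.get("D_t", 0.0))
            st = solve_equilibrium(K, totals)
            out[i] = steady_state_expression(st, rates).p
        except (SolverError, ValueError):
            out[i] = np.nan
            failures += 1
    if failures > max_failure_rate * samples.shape[0]:
        raise SolverError(
            f"{failures}/{samples.shape[0]} solves failed; bounds likely pathological")
    return out, failures


def prcc(samples: np.ndarray, readout: np.ndarray) -> np.ndarray:
    """Partial rank correlation coefficient of each column with the readout.

    Rows with a non-finite readout are dropped pairwise.  Ranks use
    average tie-breaking.  For each parameter j, both its ranks and the
    readout ranks are regressed (least squares, with intercept) on the
    ranks of all other parameters; the PRCC is the Pearson correlation
    of the two residual vectors.
    """
    samples = np.asarray(samples, dtype=float)
    readout = np.asarray(readout, dtype=float)
    keep = np.isfinite(readout)
    samples, readout = samples[keep], readout[keep]
    N, k = samples.shape
    if N <= k + 2:
        raise ValueError(f"need N > k + 2 samples after filtering (N={N}, k={k})")
    if np.ptp(readout) == 0:
        raise ValueError("PRCC undefined for a constant readout")
    R = np.column_stack([rankdata(samples[:, j], method="average")
                         for j in range(k)])
    p_rank = rankdata(readout, method="average")
    Rc = R - R.mean(axis=0)
    pc = p_rank - p_rank.mean()
    out = np.empty(k)
    for j in range(k):
        others = Rc[:, [l for l in range(k) if l != j]]
        # residuals after least-squares projection onto the other ranks
        coef_k, *_ = np.linalg.lstsq(others, Rc[:, j], rcond=None)
        coef_p, *_ = np.linalg.lstsq(others, pc, rcond=None)
        rk = Rc[:, j] - others @ coef_k
        rp = pc - others @ coef_p
        denom = np.sqrt((rk @ rk) * (rp @ rp))
        out[j] = (rk @ rp) / denom if denom > 0 else 0.0
    return np.clip(out, -1.0, 1.0)


def gsa_scan(space: ParameterSpace, doses, N: int, seed: int,
             max_failure_rate: float = 0.01) -> list[PRCCProfile]:
    """One PRCC profile per inhibitor dose.

    Each dose uses a fresh Latin Hypercube derived deterministically
    from (seed, dose index), so profiles are reproducible and doses are
    statistically independent.
    """
    doses = np.asarray(doses, dtype=float)
    profiles = []
    for ix, dose in enumerate(doses):
        sub_seed = (int(seed) + 7919 * ix) % (2**31 - 1)
        X = lhs_sample(space, N, sub_seed)
        y, failures = evaluate_readout(X, space, float(dose),
                                       max_failure_rate=max_failure_rate)
        idx = prcc(X, y)
        profiles.append(PRCCProfile(
            dose=float(dose),
            indices=dict(zip(space.names, idx)),
            n_samples=N, n_effective=N - failures, seed=sub_seed))
    return profiles
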
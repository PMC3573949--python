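"""Block-wise least-squares calibration with a Hooke-Jeeves pattern search.

The model was historically parameterised block by block: binding
constants against saturation and competition curves of purified
receptor, then transcription parameters against reporter-gene
dose-response data, minimising the sum of squared deviations with the
Hooke & Jeeves derivative-free pattern search.  This module reimplements
that strategy.  Fits operate on log10-transformed parameters inside box
bounds (binding constants span orders of magnitude), vary only
independent binding constants (dependent ones are re-derived so detailed
balance is preserved by construction), and use a seeded multi-start to
mitigate pattern-search local minima.  Reporter datasets carry a free
multiplicative scale mapping protein concentration (nM) to assay units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .core import SolverError, SystemTotals, derive_dependent_constants, solve_equilibrium, bound_hormone_metrics
from .datasets import Dataset
from .expression import steady_state_expression
from .params import PUBLISHED_BINDING, PUBLISHED_RATES, ModelParams

__all__ = [
    "FitResult",
    "hooke_jeeves",
    "sse_objective",
    "predict_saturation",
    "predict_competition",
    "predict_reporter",
    "fit_block",
]


@dataclass
class FitResult:
    params: dict
    sse: float
    iterations: int
    converged: bool
    scale: float | None = None
    flat: bool = False
    eval_failures: int = 0
    x: np.ndarray | None = None  # raw optimizer point (log10 space in fit_block)


def hooke_jeeves(objective, x0, step=0.5, shrink=0.5, tol=1e-6,
                 max_iter=10_000, bounds=None) -> FitResult:
    """Derivative-free pattern search (exploratory + pattern moves).

    ``objective`` maps a parameter vector to a scalar; evaluation
    failures count as +inf (rejected move).  ``step`` is the initial
    per-coordinate step (scalar or vector), multiplied by ``shrink``
    whenever no exploratory move improves; terminates when every step
    falls below ``tol`` or the evaluation budget is exhausted.  The
    returned point is never worse than x0.
    """
    x0 = np.asarray(x0, dtype=float)
    n = x0.size
    step = np.full(n, step, dtype=float) if np.ndim(step) == 0 else np.asarray(step, dtype=float)
    lo = np.full(n, -np.inf) if bounds is None else np.asarray([b[0] for b in bounds], dtype=float)
    hi = np.full(n, np.inf) if bounds is None else np.asarray([b[1] for b in bounds], dtype=float)
    failures = 0

    def f(x):
        nonlocal failures
        if np.any(x < lo) or np.any(x > hi):
            return math.inf
        try:
            v = float(objective(x))
        except Exception:
            failures += 1
            return math.inf
        if not math.isfinite(v):
            failures += 1
            return math.inf
        return v

    def explore(x, fx, s):
        x = x.copy()
        for j in range(n):
            for delta in (s[j], -s[j]):
                xt = x.copy()
                xt[j] += delta
                ft = f(xt)
                if ft < fx:
                    x, fx = xt, ft
                    break
        return x, fx

    base = x0.copy()
    fbase = f(base)
    if not math.isfinite(fbase):
        raise ValueError("objective not finite at the starting point")
    evals = 0
    converged = False
    while evals < max_iter:
        evals += 1
        newx, newf = explore(base, fbase, step)
        if newf < fbase:
            # pattern move: extrapolate along the improvement direction
            while evals < max_iter:
                evals += 1
                pattern = newx + (newx - base)
                base, fbase = newx, newf
                px, pf = explore(np.clip(pattern, lo, hi), f(np.clip(pattern, lo, hi)), step)
                if pf < fbase:
                    newx, newf = px, pf
                else:
                    break
        else:
            step = step * shrink
            if np.all(step < tol):
                converged = True
                break
    return FitResult(params={}, sse=fbase, iterations=evals,
                     converged=converged, eval_failures=failures,
                     flat=False, x=base)


def sse_objective(dataset: Dataset, predictor, weighted: bool = False) -> float:
    """Sum of squared deviations between data and model predictions.

    ``predictor`` maps the dataset's x values to model y values.  Solver
    failures propagate as +inf.  With ``weighted`` and a ``y_err``
    column, residuals are inverse-variance weighted.
    """
    try:
        y_model = np.asarray(predictor(dataset.x), dtype=float)
    except (SolverError, FloatingPointError):
        return math.inf
    resid = y_model - dataset.y
    if weighted and "y_err" in dataset.points:
        err = dataset.points["y_err"].to_numpy(dtype=float)
        resid = resid / np.where(err > 0, err, 1.0)
    return float(resid @ resid)


def predict_saturation(K, ER_t: float, H_t_grid) -> np.ndarray:
    """Hormone-occupied receptor sites ER_b (nM) along a total-hormone grid."""
    out = []
    for h_t in np.asarray(H_t_grid, dtype=float):
        tot = SystemTotals(ER_t=ER_t, H_t=float(h_t))
        st = solve_equilibrium(K, tot)
        er_b, _ = bound_hormone_metrics(st, tot)
        out.append(er_b)
    return np.array(out)


def predict_competition(K, ER_t: float, labelled_H: float, competitor_grid,
                        competitor: str) -> np.ndarray:
    """Percent labelled hormone bound vs competitor dose (B/B0 * 100).

    A hormone-like competitor (unlabelled estradiol) is chemically
    identical to the label, so the two are pooled into one hormone total
    and the labelled share of bound sites is the labelled fraction of
    total hormone.  An inhibitor competitor (tamoxifen) enters through
    the inhibitor arm of the binding scheme.  Curves are normalised to
    the competitor-free point.
    """
    if not (labelled_H > 0):
        raise ValueError("labelled hormone concentration must be > 0")
    if competitor not in ("hormone-like", "inhibitor"):
        raise ValueError(f"unknown competitor kind {competitor!r}")
    grid = np.asarray(competitor_grid, dtype=float)

    def labelled_bound(c: float) -> float:
        if competitor == "hormone-like":
            tot = SystemTotals(ER_t=ER_t, H_t=labelled_H + c)
            st = solve_equilibrium(K, tot)
            er_b, _ = bound_hormone_metrics(st, tot)
            return er_b * labelled_H / (labelled_H + c)
        tot = SystemTotals(ER_t=ER_t, H_t=labelled_H, I_t=c)
        st = solve_equilibrium(K, tot)
        er_b, _ = bound_hormone_metrics(st, tot)
        return er_b

    b0 = labelled_bound(0.0)
    if b0 <= 0:
        raise ValueError("no labelled binding at zero competitor")
    return np.array([100.0 * labelled_bound(float(c)) / b0 for c in grid])


def predict_reporter(K, rates, ER_t: float, D_t: float, H_t: float,
                     I_t_grid, scale: float = 1.0) -> np.ndarray:
    """Reporter readout scale * p (arbitrary units) along an I_t grid."""
    out = []
    for i_t in np.asarray(I_t_grid, dtype=float):
        st = solve_equilibrium(K, SystemTotals(ER_t, H_t, float(i_t), D_t))
        out.append(scale * steady_state_expression(st, rates).p)
    return np.array(out)


def _dataset_predictor(ds: Dataset, K, rates, scale: float):
    if ds.kind == "saturation":
        return lambda x: predict_saturation(K, float(ds.meta["ER_t"]), x)
    if ds.kind == "competition":
        return lambda x: predict_competition(
            K, float(ds.meta["ER_t"]), float(ds.meta["labelled_H"]),
            x, str(ds.meta["competitor"]))
    return lambda x: predict_reporter(
        K, rates, float(ds.meta["ER_t"]), float(ds.meta["D_t"]),
        float(ds.meta["H_t"]), x, scale)


def fit_block(datasets, free, base: ModelParams, seed: int = 0,
              bound_factor: float = 100.0, n_starts: int = 5,
              step: float = 0.2, tol: float = 1e-4,
              max_iter: int = 4000, weighted: bool = False) -> FitResult:
    """Fit the named free parameters to one calibration block.

    ``free`` lists independent binding constants (K1, K2, ...), rate
    constants (k_sr, k_sr_i, ...) and/or ``scale`` (reporter unit
    factor).  All are optimised in log10 space within [x0/bound_factor,
    x0*bound_factor].  Multi-start around the base point (seeded); the
    best sum of squares wins, ties going to the earliest start.  With
    ``weighted`` and datasets carrying a ``y_err`` column, residuals are
    inverse-variance weighted, which is essential when curves of very
    different amplitude (and hence very different assay error) are
    fitted jointly.
    """
    free = list(free)
    k_names = [p for p in free if p in PUBLISHED_BINDING]
    r_names = [p for p in free if p in PUBLISHED_RATES]
    unknown = set(free) - set(k_names) - set(r_names) - {"scale"}
    if unknown:
        raise ValueError(f"unknown free parameters: {sorted(unknown)}")
    needs_scale = "scale" in free
    if needs_scale and not any(d.kind == "reporter" for d in datasets):
        raise ValueError("'scale' is only meaningful for reporter datasets")

    ind0 = base.binding.independent()
    x0 = np.array([ind0[p] for p in k_names]
                  + [getattr(base.rates, p) for p in r_names]
                  + ([1.0] if needs_scale else []))

    def unpack(theta: np.ndarray):
        vals = 10.0 ** theta
        ind = dict(ind0)
        ind.update({p: float(v) for p, v in zip(k_names, vals)})
        K = derive_dependent_constants(**ind)
        rates = base.rates
        off = len(k_names)
        for p, v in zip(r_names, vals[off:off + len(r_names)]):
            rates = replace(rates, **{p: float(v)})
        scale = float(vals[-1]) if needs_scale else 1.0
        return K, rates, scale

    def objective(theta: np.ndarray) -> float:
        K, rates, scale = unpack(theta)
        return sum(sse_objective(d, _dataset_predictor(d, K, rates, scale),
                                 weighted=weighted)
                   for d in datasets)

    if not free:
        return FitResult(params={}, sse=objective(np.array([])),
                         iterations=0, converged=True,
                         scale=None, flat=False)

    t0 = np.log10(x0)
    lo, hi = t0 - np.log10(bound_factor), t0 + np.log10(bound_factor)
    bounds = list(zip(lo, hi))
    f0 = objective(t0)
    probes = [objective(np.clip(t0 + step * e, lo, hi))
              for e in np.eye(t0.size)]
    flat = all(abs(p - f0) <= 1e-14 * max(abs(f0), 1.0) for p in probes)

    rng = np.random.default_rng(seed)
    starts = [t0] + [np.clip(t0 + rng.uniform(-0.25, 0.25, t0.size), lo, hi)
                     for _ in range(max(0, n_starts - 1))]
    best: FitResult | None = None
    total_iter = 0
    for s in starts:
        try:
            res = hooke_jeeves(objective, s, step=step, tol=tol,
                               max_iter=max_iter, bounds=bounds)
        except ValueError:
            continue
        total_iter += res.iterations
        if best is None or res.sse < best.sse:
            best = res
    if best is None:
        raise ValueError("objective not finite at any start point")
    names = k_names + r_names + (["scale"] if needs_scale else [])
    fitted = {n: float(v) for n, v in zip(names, 10.0 ** best.x)}
    return FitResult(params=fitted, sse=best.sse, iterations=total_iter,
                     converged=best.converged,
                     scale=fitted.get("scale"), flat=flat,
                     eval_failures=best.eval_failures)
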
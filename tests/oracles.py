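"""Independent oracles used by the test suite.

These re-derive expected values through routes that share no code with
the package implementation: the equilibrium oracle writes out each
mass-action equation explicitly and solves the conservation system by
nested 1-D root bracketing; the PRCC oracle builds the regression normal
equations directly.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.stats import rankdata


def oracle_species(ER, H, I, D, K):
    """Each complex written out explicitly from its defining equation."""
    return {
        "ER2": ER * ER / K.K1,
        "ER2H": ER * ER / K.K1 * H / K.K2,
        "ER2H2": ER * ER / K.K1 * H * H / (K.K2 * K.K3),
        "ERH": ER * H / K.K4,
        "ER2I": ER * ER / K.K1 * I / K.K7,
        "ER2I2": ER * ER / K.K1 * I * I / (K.K7 * K.K8),
        "ERI": ER * I / K.K9,
        "ER2HI": ER * ER / K.K1 * I * H / (K.K7 * K.K13),
        "ER2D": ER * ER / K.K1 * D / K.K15,
        "ER2HD": ER * ER / K.K1 * H / K.K2 * D / K.K16,
        "ER2H2D": ER * ER / K.K1 * H * H / (K.K2 * K.K3) * D / K.K17,
        "ER2ID": ER * ER / K.K1 * I / K.K7 * D / K.K18,
        "ER2I2D": ER * ER / K.K1 * I * I / (K.K7 * K.K8) * D / K.K19,
        "ER2HID": ER * ER / K.K1 * I * H / (K.K7 * K.K13) * D / K.K20,
    }


def _conserved(ER, H, I, D, K):
    s = oracle_species(ER, H, I, D, K)
    er = (ER + s["ERH"] + s["ERI"]
          + 2 * (s["ER2"] + s["ER2H"] + s["ER2H2"] + s["ER2I"] + s["ER2I2"]
                 + s["ER2HI"] + s["ER2D"] + s["ER2HD"] + s["ER2H2D"]
                 + s["ER2ID"] + s["ER2I2D"] + s["ER2HID"]))
    h = (H + s["ERH"] + s["ER2H"] + s["ER2HI"] + s["ER2HID"] + s["ER2HD"]
         + 2 * (s["ER2H2"] + s["ER2H2D"]))
    i = (I + s["ERI"] + s["ER2I"] + s["ER2HI"] + s["ER2HID"] + s["ER2ID"]
         + 2 * (s["ER2I2"] + s["ER2I2D"]))
    d = (D + s["ER2D"] + s["ER2HD"] + s["ER2HID"] + s["ER2ID"]
         + s["ER2H2D"] + s["ER2I2D"])
    return er, h, i, d


def oracle_equilibrium(K, ER_t, H_t, I_t, D_t, rtol=1e-13):
    """Nested bracketing: for each free variable the residual of its own
    conservation equation is monotone at fixed outer variables."""

    def solve_er(h, i, d):
        if ER_t == 0:
            return 0.0
        f = lambda er: _conserved(er, h, i, d, K)[0] - ER_t
        return ER_t if f(ER_t) <= 0 else brentq(f, 0.0, ER_t, rtol=rtol)

    def solve_h(i, d):
        if H_t == 0:
            return 0.0
        f = lambda h: _conserved(solve_er(h, i, d), h, i, d, K)[1] - H_t
        return H_t if f(H_t) <= 0 else brentq(f, 0.0, H_t, rtol=rtol)

    def solve_i(d):
        if I_t == 0:
            return 0.0

        def f(i):
            h = solve_h(i, d)
            return _conserved(solve_er(h, i, d), h, i, d, K)[2] - I_t
        return I_t if f(I_t) <= 0 else brentq(f, 0.0, I_t, rtol=rtol)

    if D_t == 0:
        d = 0.0
    else:
        def f(dd):
            i = solve_i(dd)
            h = solve_h(i, dd)
            return _conserved(solve_er(h, i, dd), h, i, dd, K)[3] - D_t
        d = D_t if f(D_t) <= 0 else brentq(f, 0.0, D_t, rtol=rtol)
    i = solve_i(d)
    h = solve_h(i, d)
    er = solve_er(h, i, d)
    out = {"ER": er, "H": h, "I": i, "D": d}
    out.update(oracle_species(er, h, i, d, K))
    return out


def oracle_prcc(samples: np.ndarray, readout: np.ndarray) -> np.ndarray:
    """PRCC via explicit normal equations on centred ranks."""
    N, k = samples.shape
    R = np.column_stack([rankdata(samples[:, j]) for j in range(k)])
    p = rankdata(readout)
    Rc = R - R.mean(axis=0)
    pc = p - p.mean()
    out = np.empty(k)
    for j in range(k):
        X = np.delete(Rc, j, axis=1)
        G = X.T @ X
        beta_k = np.linalg.solve(G, X.T @ Rc[:, j])
        beta_p = np.linalg.solve(G, X.T @ pc)
        rk = Rc[:, j] - X @ beta_k
        rp = pc - X @ beta_p
        out[j] = (rk @ rp) / np.sqrt((rk @ rk) * (rp @ rp))
    return out
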
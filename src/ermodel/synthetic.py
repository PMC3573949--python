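"""Synthetic calibration datasets with realistic assay noise.

The raw curves the model was originally calibrated on (saturation
binding of purified hERalpha with labelled estradiol, competition
against unlabelled estradiol or tamoxifen, and ALP reporter-gene
dose-response in HEK293/hERalpha cells) are not deposited anywhere, so
this module generates pseudo-datasets with the same structure from the
model itself: the noiseless curves are exactly the corresponding
predictor outputs, which makes parameter-recovery experiments and
round-trip tests possible end to end.

Default noise: additive Gaussian at 2% of the curve maximum for binding
assays (scintillation-counting style error) and multiplicative
log-normal at 5% for reporter expression (plate-reader style error).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import predict_competition, predict_reporter, predict_saturation
from .datasets import Dataset
from .params import ModelParams

__all__ = ["NoiseSpec", "gen_saturation", "gen_competition", "gen_reporter"]

DEFAULT_ER_LEVELS = (0.3, 1.2, 7.0, 13.0)  # nM, saturation-binding assays
DEFAULT_H_GRID = tuple(np.geomspace(0.01, 30.0, 12))


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model: 'additive-gaussian' (sigma = fraction of curve max,
    or absolute if ``absolute``) or 'multiplicative-lognormal' (sigma =
    relative scatter).  Deterministic given seed."""

    model: str = "additive-gaussian"
    magnitude: float = 0.0
    seed: int = 0
    absolute: bool = False

    def __post_init__(self) -> None:
        if self.model not in ("additive-gaussian", "multiplicative-lognormal"):
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.magnitude < 0:
            raise ValueError("noise magnitude must be >= 0")

    def sigma(self, y: np.ndarray) -> np.ndarray:
        """Per-point standard deviation implied by the noise model."""
        y = np.asarray(y, dtype=float)
        if self.model == "additive-gaussian":
            s = self.magnitude if self.absolute else self.magnitude * np.max(np.abs(y))
            return np.full(y.shape, s)
        return np.abs(y) * self.magnitude

    def apply(self, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if self.magnitude == 0:
            return y.copy()
        if self.model == "additive-gaussian":
            out = y + rng.normal(0.0, self.sigma(y)[0], y.shape)
        else:
            out = y * rng.lognormal(0.0, self.magnitude, y.shape)
        return np.maximum(out, 0.0)


def _dataset(kind: str, meta: dict, x: np.ndarray, y: np.ndarray,
             y_err: np.ndarray | None = None) -> Dataset:
    pts = pd.DataFrame({"x": np.asarray(x, dtype=float), "y": y})
    if y_err is not None and np.any(y_err > 0):
        pts["y_err"] = y_err
    return Dataset(kind=kind, meta=meta, points=pts)


def gen_saturation(params: ModelParams, noise: NoiseSpec,
                   ER_levels=DEFAULT_ER_LEVELS, H_grid=DEFAULT_H_GRID) -> list[Dataset]:
    """Saturation-binding curves (ER_b vs labelled H_t), one per receptor level."""
    rng = np.random.default_rng(noise.seed)
    out = []
    for er_t in ER_levels:
        clean = predict_saturation(params.binding, float(er_t), H_grid)
        meta = {"ER_t": float(er_t), "noise_model": noise.model,
                "noise_magnitude": noise.magnitude, "seed": noise.seed}
        out.append(_dataset("saturation", meta, np.asarray(H_grid),
                            noise.apply(clean, rng), noise.sigma(clean)))
    return out


def gen_competition(params: ModelParams, competitor: str, noise: NoiseSpec,
                    ER_t: float = 1.0, labelled_H: float = 1.0,
                    competitor_grid=None) -> Dataset:
    """Competition curve: % labelled estradiol bound vs competitor dose."""
    if competitor_grid is None:
        competitor_grid = np.concatenate([[0.0], np.geomspace(0.1, 3000.0, 12)])
    grid = np.asarray(competitor_grid, dtype=float)
    clean = predict_competition(params.binding, ER_t, labelled_H, grid, competitor)
    rng = np.random.default_rng(noise.seed)
    meta = {"ER_t": ER_t, "labelled_H": labelled_H, "competitor": competitor,
            "noise_model": noise.model, "noise_magnitude": noise.magnitude,
            "seed": noise.seed}
    return _dataset("competition", meta, grid, noise.apply(clean, rng),
                    noise.sigma(clean))


def gen_reporter(params: ModelParams, noise: NoiseSpec,
                 H_levels=(0.0, 0.5), I_grid=None,
                 ER_t: float = 20.0, D_t: float = 0.1,
                 scale: float = 1.0) -> list[Dataset]:
    """Reporter dose-response curves (scale * p vs tamoxifen), per H_t level."""
    if I_grid is None:
        I_grid = np.concatenate([[0.0], np.geomspace(0.01, 3000.0, 20)])
    grid = np.asarray(I_grid, dtype=float)
    rng = np.random.default_rng(noise.seed)
    out = []
    for h_t in H_levels:
        clean = predict_reporter(params.binding, params.rates, ER_t, D_t,
                                 float(h_t), grid, scale)
        meta = {"H_t": float(h_t), "ER_t": ER_t, "D_t": D_t, "scale": scale,
                "noise_model": noise.model, "noise_magnitude": noise.magnitude,
                "seed": noise.seed}
        out.append(_dataset("reporter", meta, grid, noise.apply(clean, rng),
                            noise.sigma(clean)))
    return out
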
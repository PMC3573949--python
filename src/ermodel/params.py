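"""Published parameter set and the key-value parameter file format.

The packaged defaults are the calibrated constants of the hERalpha model:
14 independent dissociation constants (nM) with the six dependent ones
re-derived by detailed balance, and the transcription/translation rate
constants (s^-1).  K20 was published only as the range 10-20 nM; the
packaged default is the midpoint, 15 nM.

Parameter files are INI-style text with sections [binding],
[transcription] and [totals]; unknown sections or keys are rejected so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

import configparser
import importlib.resources
from dataclasses import dataclass
from pathlib import Path

from .core import (BindingConstants, SystemTotals, TranscriptionRates,
                   derive_dependent_constants)

__all__ = [
    "PUBLISHED_BINDING",
    "PUBLISHED_RATES",
    "default_binding_constants",
    "default_rates",
    "ModelParams",
    "default_params",
    "load_params",
    "write_params",
]

# Independent dissociation constants, nM.  K20: midpoint of published 10-20.
PUBLISHED_BINDING: dict[str, float] = {
    "K1": 25.0, "K2": 0.2, "K3": 0.1, "K4": 0.25,
    "K7": 10.0, "K8": 150.0, "K9": 30.0, "K13": 0.8,
    "K15": 8.0, "K16": 2.4, "K17": 1.2, "K18": 50.0,
    "K19": 87.0, "K20": 15.0,
}

# Transcription/translation rate constants, s^-1 (kappa = 5e-5 derived).
PUBLISHED_RATES: dict[str, float] = {
    "k_sr": 0.195, "k_sr_i": 0.02, "k_sr_hi": 0.05, "k_sr_b": 0.001,
    "k_dr": 0.0025, "k_sp": 0.001, "k_dp": 2e-5,
}


def default_binding_constants(**overrides: float) -> BindingConstants:
    """Published constants, optionally overriding independent constants."""
    ind = dict(PUBLISHED_BINDING)
    unknown = set(overrides) - set(ind)
    if unknown:
        raise ValueError(f"not independent constants: {sorted(unknown)}")
    ind.update(overrides)
    return derive_dependent_constants(**ind)


def default_rates(**overrides: float) -> TranscriptionRates:
    vals = dict(PUBLISHED_RATES)
    unknown = set(overrides) - set(vals)
    if unknown:
        raise ValueError(f"unknown rate constants: {sorted(unknown)}")
    vals.update(overrides)
    return TranscriptionRates(**vals)


@dataclass(frozen=True)
class ModelParams:
    """A full model configuration: constants, rates, and totals."""

    binding: BindingConstants
    rates: TranscriptionRates
    totals: SystemTotals


def default_params(totals: SystemTotals | None = None) -> ModelParams:
    return ModelParams(default_binding_constants(), default_rates(),
                       totals or SystemTotals())


_TOTAL_KEYS = ("ER_t", "H_t", "I_t", "D_t")


def load_params(path: str | Path) -> ModelParams:
    """Read a parameter file ([binding]/[transcription]/[totals] sections).

    The [binding] section lists independent constants only; dependent
    constants are derived.  Missing keys take the packaged defaults;
    unknown keys raise.
    """
    cp = configparser.ConfigParser()
    text = Path(path).read_text()
    cp.read_string(text, source=str(path))
    known = {"binding", "transcription", "totals"}
    unknown = set(cp.sections()) - known
    if unknown:
        raise ValueError(f"unknown sections in {path}: {sorted(unknown)}")

    def section(name: str) -> dict[str, float]:
        if not cp.has_section(name):
            return {}
        return {k: float(v) for k, v in cp.items(name)}

    bind_raw = section("binding")
    # configparser lowercases keys
    keymap = {k.lower(): k for k in PUBLISHED_BINDING}
    bad = set(bind_raw) - set(keymap)
    if bad:
        raise ValueError(f"unknown/non-independent [binding] keys: {sorted(bad)}")
    binding = default_binding_constants(
        **{keymap[k]: v for k, v in bind_raw.items()})

    rate_raw = section("transcription")
    ratemap = {k.lower(): k for k in PUBLISHED_RATES}
    bad = set(rate_raw) - set(ratemap)
    if bad:
        raise ValueError(f"unknown [transcription] keys: {sorted(bad)}")
    rates = default_rates(**{ratemap[k]: v for k, v in rate_raw.items()})

    tot_raw = section("totals")
    totmap = {k.lower(): k for k in _TOTAL_KEYS}
    bad = set(tot_raw) - set(totmap)
    if bad:
        raise ValueError(f"unknown [totals] keys: {sorted(bad)}")
    totals = SystemTotals(**{totmap[k]: v for k, v in tot_raw.items()})
    return ModelParams(binding, rates, totals)


def write_params(params: ModelParams, path: str | Path) -> None:
    """Write a parameter file readable by :func:`load_params`."""
    lines = ["[binding]"]
    for k in PUBLISHED_BINDING:
        lines.append(f"{k} = {getattr(params.binding, k)!r}")
    lines.append("")
    lines.append("[transcription]")
    for k in PUBLISHED_RATES:
        lines.append(f"{k} = {getattr(params.rates, k)!r}")
    lines.append("")
    lines.append("[totals]")
    for k in _TOTAL_KEYS:
        lines.append(f"{k} = {getattr(params.totals, k)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def packaged_default_file() -> Path:
    """Path to the packaged default parameter file."""
    return Path(importlib.resources.files("ermodel") / "data" / "default_params.ini")
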
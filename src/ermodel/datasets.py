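"""Tabular calibration datasets and their on-disk text format.

Three dataset kinds mirror the calibration data classes:

* ``saturation`` — hormone-occupied receptor sites ER_b (nM) vs total
  labelled hormone, at a stated receptor concentration;
* ``competition`` — percent labelled hormone bound (normalised to the
  competitor-free point) vs total competitor, competitor being either
  hormone-like (unlabelled estradiol) or an inhibitor (tamoxifen);
* ``reporter`` — reporter expression (arbitrary units) vs total
  inhibitor, at a stated background hormone level.

Files are UTF-8 delimited text: a metadata header of ``# key: value``
lines followed by a comma-separated table with a header row.  Floats are
written in shortest round-trip form so write -> read is bit-exact.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Dataset", "read_dataset", "write_dataset"]

KINDS = ("saturation", "competition", "reporter")

_REQUIRED_META = {
    "saturation": ("ER_t",),
    "competition": ("ER_t", "labelled_H", "competitor"),
    "reporter": ("H_t",),
}


@dataclass
class Dataset:
    """One experimental (or synthetic) curve plus its condition metadata."""

    kind: str
    meta: dict = field(default_factory=dict)
    points: pd.DataFrame = None  # columns x, y[, y_err]

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown dataset kind {self.kind!r}")
        missing = [k for k in _REQUIRED_META[self.kind] if k not in self.meta]
        if missing:
            raise ValueError(f"{self.kind} dataset missing metadata {missing}")
        pts = self.points
        if pts is None or "x" not in pts or "y" not in pts:
            raise ValueError("points must be a DataFrame with columns x, y")
        if (pts["x"] < 0).any():
            raise ValueError("x values must be >= 0")
        if not pts["x"].is_monotonic_increasing:
            raise ValueError("points must be sorted by x")

    @property
    def x(self) -> np.ndarray:
        return self.points["x"].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.points["y"].to_numpy(dtype=float)


def _fmt(v) -> str:
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    return str(v)


def write_dataset(ds: Dataset, path: str | Path) -> None:
    buf = _io.StringIO()
    buf.write(f"# kind: {ds.kind}\n")
    for k, v in ds.meta.items():
        buf.write(f"# {k}: {_fmt(v)}\n")
    cols = list(ds.points.columns)
    buf.write(",".join(cols) + "\n")
    for _, row in ds.points.iterrows():
        buf.write(",".join(_fmt(row[c]) for c in cols) + "\n")
    Path(path).write_text(buf.getvalue())


def _parse_meta_value(s: str):
    s = s.strip()
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            pass
    return s


def read_dataset(path: str | Path) -> Dataset:
    meta: dict = {}
    body: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = _parse_meta_value(val)
        elif line.strip():
            body.append(line)
    if "kind" not in meta:
        raise ValueError(f"{path}: missing '# kind:' metadata line")
    kind = str(meta.pop("kind"))
    pts = pd.read_csv(_io.StringIO("\n".join(body)),
                      float_precision="round_trip")
    return Dataset(kind=kind, meta=meta, points=pts)
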
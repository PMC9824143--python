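"""Generic (x, y[, y_err]) data series and delimited-text IO.

A :class:`Curve` is the common container for every one-dimensional trace the
pipeline touches: scattering intensity vs. q (Å⁻¹), excess heat capacity vs.
temperature (°C), and absorbance vs. wavenumber (cm⁻¹).  The abscissa is kept
strictly increasing; free-form string metadata (units, temperature,
composition) travels in ``meta``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Curve", "CurveParseError", "read_xy_curve", "write_xy_curve"]


class CurveParseError(ValueError):
    """Raised when a delimited-text curve file cannot be parsed."""


@dataclass
class Curve:
    """An ordered data series with optional per-point uncertainty.

    Parameters
    ----------
    x, y
        Abscissa and ordinate arrays of equal length; ``x`` must be strictly
        increasing.
    y_err
        Optional 1-sigma uncertainty per point; must be positive everywhere.
    meta
        Free-form string annotations (e.g. ``{"x_unit": "1/angstrom"}``).
    """

    x: np.ndarray
    y: np.ndarray
    y_err: np.ndarray | None = None
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise ValueError("x and y must be 1-d arrays of equal length")
        if self.x.size >= 2 and not np.all(np.diff(self.x) > 0):
            raise ValueError("curve abscissa must be strictly increasing")
        if self.y_err is not None:
            self.y_err = np.asarray(self.y_err, dtype=float)
            if self.y_err.shape != self.x.shape:
                raise ValueError("y_err must match x in length")
            if not np.all(self.y_err > 0):
                raise ValueError("y_err must be positive everywhere")

    def __len__(self) -> int:
        return int(self.x.size)

    def crop(self, lo: float, hi: float) -> "Curve":
        """Return the sub-curve with ``lo <= x <= hi`` (meta preserved)."""
        m = (self.x >= lo) & (self.x <= hi)
        err = self.y_err[m] if self.y_err is not None else None
        return Curve(self.x[m], self.y[m], err, dict(self.meta))


_DELIMS = re.compile(r"[,\s;]+")


def _parse_row(line: str) -> list[float]:
    parts = [p for p in _DELIMS.split(line.strip()) if p]
    return [float(p) for p in parts]


def read_xy_curve(path, x_unit: str = "", *, min_points: int = 4) -> Curve:
    """Read a two- or three-column delimited text file into a :class:`Curve`.

    Columns may be separated by whitespace, commas or semicolons; lines
    starting with ``#`` are comments.  The result is sorted by x, duplicate
    abscissa values are collapsed by averaging their ordinates, and ``x_unit``
    is recorded in ``meta``.

    Raises
    ------
    CurveParseError
        On a non-numeric row (the message names the 1-based line number) or
        when fewer than ``min_points`` distinct points remain.
    """
    xs: list[float] = []
    ys: list[float] = []
    es: list[float] = []
    meta: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    key, _, val = line.lstrip("#").partition(":")
                    meta.setdefault(key.strip(), val.strip())
                continue
            try:
                vals = _parse_row(line)
            except ValueError:
                raise CurveParseError(
                    f"{path}: non-numeric row at line {lineno}: {line!r}"
                ) from None
            if len(vals) not in (2, 3):
                raise CurveParseError(
                    f"{path}: expected 2 or 3 columns at line {lineno}, "
                    f"got {len(vals)}"
                )
            xs.append(vals[0])
            ys.append(vals[1])
            es.append(vals[2] if len(vals) == 3 else np.nan)

    x = np.asarray(xs)
    y = np.asarray(ys)
    e = np.asarray(es)
    order = np.argsort(x, kind="stable")
    x, y, e = x[order], y[order], e[order]

    # collapse duplicate abscissas by averaging
    ux, inverse, counts = np.unique(x, return_inverse=True, return_counts=True)
    if ux.size != x.size:
        uy = np.zeros_like(ux)
        ue = np.zeros_like(ux)
        np.add.at(uy, inverse, y)
        np.add.at(ue, inverse, e)
        x, y, e = ux, uy / counts, ue / counts

    if x.size < min_points:
        raise CurveParseError(f"{path}: curve too short ({x.size} points)")

    if x_unit:
        meta["x_unit"] = x_unit
    have_err = np.isfinite(e).all() and e.size > 0
    return Curve(x, y, e if have_err else None, meta)


def write_xy_curve(curve: Curve, path) -> None:
    """Write a curve as delimited text (meta as ``# key: value`` comments).

    Values are printed with 9 significant digits so a write/read round trip
    preserves x and y well beyond 6 significant digits.
    """
    with open(path, "w") as fh:
        for key in sorted(curve.meta):
            fh.write(f"# {key}: {curve.meta[key]}\n")
        cols = [curve.x, curve.y]
        if curve.y_err is not None:
            cols.append(curve.y_err)
        for row in zip(*cols):
            fh.write("\t".join(f"{v:.9g}" for v in row) + "\n")
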
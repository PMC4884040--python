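"""Lorenz and concentration curves, and the areas that define Gini and CI.

Both curves plot cumulative resource share against cumulative population
share; they differ only in how units are ordered along the x-axis:

* **Lorenz curve** — units sorted ascending by per-capita resource, i.e.
  starting with those holding the least resource per person.  The curve lies
  on or below the 45° equality diagonal.
* **Concentration curve** — units sorted ascending by living standards
  (``ses``), poorest first.  The curve may lie above the diagonal (resource
  concentrated among the poor) or below it (among the rich).

Curves are stored as exact polygon vertices, never resampled: the trapezoid
rule is exact on polygons, so the area decomposition (Area A between the
diagonal and the curve, Area B under the curve, A + B = ½) is exact up to
floating-point rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .data_model import Distribution, ValidationError, validate

__all__ = [
    "Curve",
    "AreaDecomposition",
    "lorenz_curve",
    "concentration_curve",
    "curve_areas",
    "write_curve_csv",
]


@dataclass(frozen=True)
class Curve:
    """Ordered cumulative-share vertices of a Lorenz or concentration curve.

    ``points`` is an (m, 2) array of (p, L) pairs: cumulative population
    share, cumulative resource share.  Always starts at (0, 0) and ends at
    (1, 1); p and L are nondecreasing.
    """

    points: np.ndarray
    kind: Literal["lorenz", "concentration"]
    ordering_key: Literal["per-capita-resource", "ses"]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValidationError("curve needs an (m>=2, 2) vertex array")
        p, L = pts[:, 0], pts[:, 1]
        tol = 1e-9
        if abs(p[0]) > tol or abs(L[0]) > tol:
            raise ValidationError("curve must start at (0, 0)")
        if abs(p[-1] - 1) > tol or abs(L[-1] - 1) > tol:
            raise ValidationError("curve must end at (1, 1)")
        if np.any(np.diff(p) < -tol) or np.any(np.diff(L) < -tol):
            raise ValidationError("curve vertices must be nondecreasing")
        if self.kind == "lorenz" and np.any(L > p + 1e-9):
            raise ValidationError("Lorenz curve must lie on/below the diagonal")

    @property
    def p(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def L(self) -> np.ndarray:
        return self.points[:, 1]

    def interpolate(self, grid: np.ndarray) -> np.ndarray:
        """Piecewise-linear L(p) evaluated on a grid of p values."""
        return np.interp(grid, self.p, self.L)


@dataclass(frozen=True)
class AreaDecomposition:
    """Area A (between diagonal and curve, signed) and Area B (under the
    curve).  A + B = ½ always; A may be negative for a concentration curve
    above the diagonal."""

    area_A: float
    area_B: float


def _cumulate(order: np.ndarray, dist: Distribution, kind, key) -> Curve:
    pop_share = dist.population_shares[order]
    res_share = dist.resource_shares[order]
    p = np.concatenate([[0.0], np.cumsum(pop_share)])
    L = np.concatenate([[0.0], np.cumsum(res_share)])
    # pin the endpoints exactly: cumsum leaves ~1e-16 residue
    p[-1] = 1.0
    L[-1] = 1.0
    return Curve(np.column_stack([p, L]), kind=kind, ordering_key=key)


def lorenz_curve(dist: Distribution) -> Curve:
    """Lorenz curve: units cumulated in ascending per-capita-resource order.

    Ties are kept in stable id order (tie order cannot change the polygon as
    a function, only its vertex list).  Units with zero population and zero
    resource are dropped; zero-population units that do hold resource sort
    last (infinite per-capita) so the curve still ends at (1, 1).
    """
    validate(dist)
    pc = dist.per_capita
    keep = ~((dist.populations == 0) & (dist.resources == 0))
    idx = np.flatnonzero(keep)
    order = idx[np.argsort(pc[idx], kind="stable")]
    return _cumulate(order, dist, "lorenz", "per-capita-resource")


def concentration_curve(dist: Distribution) -> Curve:
    """Concentration curve: units cumulated in ascending ses order, poorest
    first.  May cross the diagonal.

    Raises
    ------
    ValidationError
        If any populated unit lacks an ses score.
    """
    validate(dist)
    for u in dist.units:
        if u.population > 0 and u.ses is None:
            raise ValidationError(
                f"unit {u.id!r} has population but no ses score; "
                "the concentration curve requires a living-standards ranking"
            )
    keep = dist.populations > 0
    if not keep.all():
        dropped_res = dist.resources[~keep].sum()
        if dropped_res > 0:
            # no rank weight for an empty unit; its resource cannot be placed
            raise ValidationError(
                "zero-population units hold resource; they cannot be ranked "
                "by ses — remove or merge them before the concentration curve"
            )
    idx = np.flatnonzero(keep)
    ses = np.array([dist.units[i].ses for i in idx], dtype=float)
    order = idx[np.argsort(ses, kind="stable")]
    return _cumulate(order, dist, "concentration", "ses")


def curve_areas(curve: Curve) -> AreaDecomposition:
    """Trapezoidal area decomposition of a cumulative-share polygon.

    ``area_B`` is the exact area under the polygon; ``area_A = ½ − area_B``
    is the (signed) area between the equality diagonal and the curve.
    """
    area_B = float(np.trapezoid(curve.L, curve.p))
    return AreaDecomposition(area_A=0.5 - area_B, area_B=area_B)


def write_curve_csv(curve: Curve, path: str | Path) -> None:
    """Export curve vertices as a 2-column CSV including the (0, 0) origin."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cum_pop_share,cum_resource_share\n")
        for p, L in curve.points:
            fh.write(f"{p:.17g},{L:.17g}\n")
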
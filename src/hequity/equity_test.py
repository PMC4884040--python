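"""Chi-square test of observed vs population-proportional resource allocation.

The test follows the classical four-step recipe: state the null hypothesis
(resource allocated proportionally to population), compute the expected
allocation per unit under the null, form the Pearson statistic
``X² = Σ (f_i − f̄_i)² / f̄_i`` over the k units, and compare it with the
chi-square critical value at k − 1 degrees of freedom and significance
level α.  A statistic below the critical value means the allocation is
judged equitable at that level.

Note the statistic is *not* scale-free: halving the unit in which the
resource is measured (doubling all counts) doubles the statistic.  Resource
amounts need not be integers (e.g. per-1000 rates); the formula is applied
as-is with a warning, since it is used here on resource amounts rather than
classical counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data_model import Distribution, DomainError, ValidationError, validate

__all__ = [
    "ChiSquareResult",
    "TrendResult",
    "expected_allocation",
    "chi_square_equity",
    "equity_trend",
]


@dataclass(frozen=True)
class ChiSquareResult:
    """Outcome of the chi-square equity test for one distribution."""

    statistic: float
    df: int
    alpha: float
    critical_value: float
    p_value: float
    verdict: str                       # "equitable" | "inequitable"
    per_unit_terms: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "test": "chi_square_equity",
            "statistic": self.statistic,
            "df": self.df,
            "alpha": self.alpha,
            "critical_value": self.critical_value,
            "p_value": self.p_value,
            "verdict": self.verdict,
            "per_unit_terms": self.per_unit_terms,
            "warnings": self.warnings,
        }


def expected_allocation(
    dist: Distribution, expected_from: Sequence[float] | None = None
) -> np.ndarray:
    """Expected resource per unit under proportional allocation.

    By default f̄_i = (pop_i / Σpop) × Σresource — what each unit would
    receive if the resource followed population exactly.  ``expected_from``
    substitutes another weighting base (e.g. land area, or a custom need
    column) of the same length; expectations always sum to the observed
    total exactly.
    """
    validate(dist)
    if expected_from is None:
        base = dist.populations
    else:
        base = np.asarray(expected_from, dtype=float)
        if base.shape != (len(dist),):
            raise DomainError("expected_from length must match the unit count")
        if np.any(base < 0):
            raise ValidationError("expected_from weights must be nonnegative")
    tot = base.sum()
    if tot <= 0:
        raise ValidationError("weighting base must have a positive total")
    return base / tot * dist.total_resource


def chi_square_equity(
    dist: Distribution,
    alpha: float = 0.05,
    expected_from: Sequence[float] | None = None,
) -> ChiSquareResult:
    """Pearson chi-square test of observed against expected allocation.

    df = k − 1 (the expectations are constrained only by the fixed total).
    Verdict is ``equitable`` iff the statistic is below the critical value
    — equivalently, iff the p-value exceeds α.  A warning is attached when
    any expected value falls below 5 (classical small-expected-count
    caveat) or when resource amounts are non-integer.

    Raises
    ------
    ValidationError
        If any expected value is zero (a zero-population unit).
    DomainError
        If alpha is outside (0, 1) or there are fewer than 2 units.
    """
    if not (0.0 < alpha < 1.0):
        raise DomainError(f"alpha must be in (0, 1), got {alpha}")
    validate(dist)
    k = len(dist)
    if k < 2:
        raise DomainError("chi-square equity test needs >= 2 units")
    observed = dist.resources
    expected = expected_allocation(dist, expected_from)
    zero = np.flatnonzero(expected == 0)
    if zero.size:
        bad = [dist.units[i].id for i in zero]
        raise ValidationError(
            f"expected allocation is 0 for units {bad}; the statistic is "
            "undefined — drop or merge zero-weight units first"
        )
    terms = (observed - expected) ** 2 / expected
    statistic = float(terms.sum())
    df = k - 1
    critical = float(stats.chi2.ppf(1.0 - alpha, df))
    p_value = float(stats.chi2.sf(statistic, df))
    warnings = []
    if np.any(expected < 5):
        warnings.append(
            f"{int((expected < 5).sum())} unit(s) have expected value < 5; "
            "the chi-square approximation may be poor"
        )
    if not np.allclose(observed, np.round(observed)):
        warnings.append(
            "resource amounts are non-integer; statistic computed as-is"
        )
    return ChiSquareResult(
        statistic=statistic,
        df=df,
        alpha=alpha,
        critical_value=critical,
        p_value=p_value,
        verdict="equitable" if statistic < critical else "inequitable",
        per_unit_terms={u.id: float(t) for u, t in zip(dist.units, terms)},
        warnings=warnings,
    )


@dataclass(frozen=True)
class TrendResult:
    """Per-year chi-square results plus a trend annotation: comparing the
    statistic across years indicates whether equity is improving (falling
    statistic), worsening (rising), stable, or mixed."""

    per_year: dict[int, ChiSquareResult]
    trend: str            # "improving" | "worsening" | "stable" | "mixed" | "n/a"


def equity_trend(
    panel: Mapping[int, Distribution], alpha: float = 0.05
) -> TrendResult:
    """Run the chi-square equity test on each year of a panel, in
    chronological order, and annotate the direction of the statistic."""
    if not panel:
        raise DomainError("empty panel")
    years = sorted(panel)
    results = {y: chi_square_equity(panel[y], alpha=alpha) for y in years}
    stats_seq = np.array([results[y].statistic for y in years])
    if len(years) < 2:
        trend = "n/a"
    else:
        diffs = np.diff(stats_seq)
        rel_tol = 1e-9 * max(stats_seq.max(), 1.0)
        if np.all(np.abs(diffs) <= rel_tol):
            trend = "stable"
        elif np.all(diffs < 0):
            trend = "improving"
        elif np.all(diffs > 0):
            trend = "worsening"
        else:
            trend = "mixed"
    return TrendResult(per_year=results, trend=trend)
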
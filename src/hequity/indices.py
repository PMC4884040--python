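"""Inequality indices for health resource allocation.

Implements the five index families used to assess horizontal equity of a
resource distribution across population units, together with the published
interpretation rules:

* ``gini`` — twice the area between the Lorenz curve and the equality
  diagonal, computed by the cumulative-share summation formula
  ``G = Σ P_i·S_{i+1} − Σ P_{i+1}·S_i`` over the Lorenz ordering.
* ``concentration_index`` — ``CI = 2·cov_w(X, H) / mean_w(H)``, the
  covariance form over population-weighted fractional SES ranks X and
  per-capita resource H; negative CI means the resource is concentrated
  among the poor.
* ``theil`` — the mean log deviation form ``T = Σ P_i·ln(P_i / Y_i)`` with
  population shares P and resource shares Y, additively decomposable into
  within- and between-group components.
* ``atkinson`` — welfare-based index with inequality-aversion parameter ε;
  1 − (equally-distributed-equivalent / mean).
* ``dissimilarity_index`` — half the L1 distance between group resource
  shares and group population shares: the fraction of the resource that
  would have to move to reach proportionality.

Conventions: natural logarithms throughout (a log base rescales Theil but
not its zero point); no finite-sample correction unless requested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data_model import (
    Distribution,
    DomainError,
    ValidationError,
    validate,
)

__all__ = [
    "RankedDistribution",
    "TheilDecomposition",
    "gini",
    "classify_gini",
    "fractional_ranks",
    "concentration_index",
    "interpret_ci",
    "theil",
    "theil_offenders",
    "theil_decompose",
    "atkinson",
    "ede_fraction",
    "dissimilarity_index",
]


# ---------------------------------------------------------------------------
# Gini
# ---------------------------------------------------------------------------


def _lorenz_cumshares(dist: Distribution) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative (population, resource) shares along the Lorenz ordering,
    each with a leading 0.  Zero-pop/zero-resource units dropped; zero-pop
    units holding resource sort last (infinite per-capita)."""
    pc = dist.per_capita
    keep = ~((dist.populations == 0) & (dist.resources == 0))
    idx = np.flatnonzero(keep)
    order = idx[np.argsort(pc[idx], kind="stable")]
    P = np.concatenate([[0.0], np.cumsum(dist.population_shares[order])])
    S = np.concatenate([[0.0], np.cumsum(dist.resource_shares[order])])
    P[-1] = 1.0
    S[-1] = 1.0
    return P, S


def gini(dist: Distribution, small_sample_correction: bool = False) -> float:
    """Gini coefficient of the resource distribution, in [0, 1).

    Computed by the cumulative-share summation formula over the Lorenz
    ordering; identical (algebraically, and numerically to ~1e-15) to twice
    Area A of :func:`hequity.curves.lorenz_curve`.  0 means every unit has
    the same per-capita resource.

    Parameters
    ----------
    small_sample_correction
        If True, rescale by n/(n−1) (n = number of units with population).
        Off by default: the plain formula is the published convention.
    """
    validate(dist)
    P, S = _lorenz_cumshares(dist)
    g = float(np.sum(P[:-1] * S[1:]) - np.sum(P[1:] * S[:-1]))
    if small_sample_correction:
        n = int((dist.populations > 0).sum())
        if n < 2:
            raise DomainError("small-sample correction needs >= 2 populated units")
        g *= n / (n - 1)
    # clip the ~1e-16 negative residue the summation can leave at equality
    return max(g, 0.0)


_GINI_BANDS = (
    (0.3, "perfect_equity"),   # [0, 0.3)
    (0.4, "normal"),           # [0.3, 0.4]
    (0.6, "alert"),            # (0.4, 0.6]
    (1.0, "highly_inequitable"),  # (0.6, 1]
)


def classify_gini(g: float) -> str:
    """Equity band for a Gini value, following the published banding rule:
    below 0.3 is a state of equity, 0.3–0.4 normal, above 0.4 an alert
    level, and above 0.6 a highly inequitable ("perilous") condition.

    Intervals: [0, 0.3) → ``perfect_equity``; [0.3, 0.4] → ``normal``;
    (0.4, 0.6] → ``alert``; (0.6, 1] → ``highly_inequitable``.
    """
    if not (0.0 <= g <= 1.0):
        raise DomainError(f"Gini value {g} outside [0, 1]")
    if g < 0.3:
        return "perfect_equity"
    if g <= 0.4:
        return "normal"
    if g <= 0.6:
        return "alert"
    return "highly_inequitable"


# ---------------------------------------------------------------------------
# Concentration index
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RankedDistribution:
    """A Distribution together with population-weighted fractional SES ranks.

    Ranks are midpoint ranks in (0, 1): X_i = (cumulative population share
    of all poorer units) + ½·(unit's own share); SES ties receive the
    midpoint rank of the whole tied block.  The population-weighted mean
    rank is exactly 0.5.  Zero-population units carry no rank (excluded).
    """

    dist: Distribution
    order: np.ndarray          # indices into dist.units, ses-ascending
    ranks: np.ndarray          # fractional rank per ordered unit
    weights: np.ndarray        # population share per ordered unit (sums to 1)


def fractional_ranks(dist: Distribution) -> RankedDistribution:
    """Compute population-weighted fractional SES ranks, poorest first.

    Raises
    ------
    ValidationError
        If a populated unit lacks an ses score.
    """
    validate(dist)
    for u in dist.units:
        if u.population > 0 and u.ses is None:
            raise ValidationError(
                f"unit {u.id!r} has no ses score; rank-based measures "
                "require a living-standards ranking"
            )
    idx = np.flatnonzero(dist.populations > 0)
    ses = np.array([dist.units[i].ses for i in idx], dtype=float)
    order = idx[np.argsort(ses, kind="stable")]
    w = dist.populations[order]
    w = w / w.sum()
    cum = np.concatenate([[0.0], np.cumsum(w)])
    ranks = cum[:-1] + 0.5 * w
    # ses ties: whole tied block gets the block's midpoint rank
    ses_sorted = ses[np.argsort(ses, kind="stable")]
    j = 0
    while j < len(ses_sorted):
        k = j
        while k + 1 < len(ses_sorted) and ses_sorted[k + 1] == ses_sorted[j]:
            k += 1
        if k > j:
            block_w = w[j : k + 1].sum()
            ranks[j : k + 1] = cum[j] + 0.5 * block_w
        j = k + 1
    return RankedDistribution(dist=dist, order=order, ranks=ranks, weights=w)


def concentration_index(
    ranked: RankedDistribution | Distribution,
    small_sample_correction: bool = False,
) -> float:
    """Concentration index CI = 2·cov_w(X, H) / mean_w(H), in (−1, 1).

    X is the fractional SES rank, H the per-capita resource, and both the
    covariance and the mean are population-weighted.  CI < 0: the resource
    is disproportionately concentrated among the poor; CI > 0: among the
    rich; 0: proportionate to population across the SES ranking.

    Accepts a :class:`RankedDistribution` or a Distribution with ses scores.
    """
    if isinstance(ranked, Distribution):
        ranked = fractional_ranks(ranked)
    dist = ranked.dist
    H = dist.per_capita[ranked.order]
    if not np.all(np.isfinite(H)):
        raise ValidationError("per-capita resource must be finite for CI")
    w, X = ranked.weights, ranked.ranks
    mean_H = float(w @ H)
    if mean_H <= 0:
        raise ValidationError("mean per-capita resource must be > 0 for CI")
    cov = float(w @ (X * H)) - float(w @ X) * mean_H
    ci = 2.0 * cov / mean_H
    if small_sample_correction:
        n = len(X)
        if n < 2:
            raise DomainError("small-sample correction needs >= 2 populated units")
        ci *= n / (n - 1)
    return ci


def interpret_ci(ci: float, zero_tol: float = 1e-12) -> str:
    """Concentration label for a CI value: ``concentrated_on_poor`` (CI < 0),
    ``proportionate`` (|CI| below tolerance), ``concentrated_on_rich``."""
    if not (-1.0 <= ci <= 1.0):
        raise DomainError(f"CI value {ci} outside [-1, 1]")
    if abs(ci) < zero_tol:
        return "proportionate"
    return "concentrated_on_poor" if ci < 0 else "concentrated_on_rich"


# ---------------------------------------------------------------------------
# Theil index and decomposition
# ---------------------------------------------------------------------------


def _theil_from_shares(P: np.ndarray, Y: np.ndarray) -> float:
    """T = Σ P_i ln(P_i / Y_i), natural log; +inf if some P_i > 0 has Y_i = 0."""
    pos = P > 0
    if np.any(pos & (Y == 0)):
        return math.inf
    P, Y = P[pos], Y[pos]
    return float(np.sum(P * np.log(P / Y)))


def theil(dist: Distribution) -> float:
    """Theil index T = Σ P_i·ln(P_i/Y_i): the population-share-weighted mean
    log deviation of resource shares (natural log).

    0 means resource shares equal population shares (equity); larger values
    mean more inequality.  If a populated unit holds no resource the index
    diverges and +inf is returned (use :func:`theil_offenders` to list the
    responsible units) — zero-resource units are never silently dropped,
    which would bias the result.
    """
    validate(dist)
    return _theil_from_shares(dist.population_shares, dist.resource_shares)


def theil_offenders(dist: Distribution) -> list[str]:
    """Unit ids with population but zero resource (the divergence sources)."""
    P, Y = dist.population_shares, dist.resource_shares
    return [u.id for u, p, y in zip(dist.units, P, Y) if p > 0 and y == 0]


@dataclass(frozen=True)
class TheilDecomposition:
    """Additive split of the Theil index into within- and between-group
    components, with per-group detail.

    ``per_group`` maps group label → dict with the group's population share
    ``P_g``, resource share ``Y_g``, internal Theil ``T_g`` (computed on
    within-group renormalized shares), and its ``contribution`` P_g·T_g to
    the within component.  ``within + between == total`` is an algebraic
    identity; ``contribution_rates`` are each component's share of the total.
    """

    total: float
    within: float
    between: float
    per_group: dict[str, dict[str, float]]
    contribution_rates: dict[str, float] | None

    def __post_init__(self) -> None:
        if math.isfinite(self.total):
            if abs((self.within + self.between) - self.total) > 1e-10:
                raise ValidationError("Theil decomposition identity violated")


def theil_decompose(dist: Distribution) -> TheilDecomposition:
    """Decompose the Theil index by the units' group labels.

    between = Σ_g P_g·ln(P_g/Y_g) over group aggregates; within = Σ_g P_g·T_g
    with T_g the Theil index of group g's units on shares renormalized within
    the group.  The two sum to the total exactly.

    Raises
    ------
    ValidationError
        If any unit lacks a group label, or the total diverges (a populated
        unit with zero resource).
    """
    validate(dist)
    for u in dist.units:
        if u.group is None:
            raise ValidationError(f"unit {u.id!r} has no group label")
    total = theil(dist)
    if not math.isfinite(total):
        raise ValidationError(
            "Theil index diverges (populated units with zero resource: "
            f"{theil_offenders(dist)}); decomposition undefined"
        )
    P, Y = dist.population_shares, dist.resource_shares
    labels = np.array([u.group for u in dist.units])

    per_group: dict[str, dict[str, float]] = {}
    between = 0.0
    within = 0.0
    for g in dist.groups:
        mask = labels == g
        P_g = float(P[mask].sum())
        Y_g = float(Y[mask].sum())
        if P_g > 0:
            between += P_g * math.log(P_g / Y_g)
        T_g = _theil_from_shares(
            P[mask] / P_g if P_g > 0 else P[mask],
            Y[mask] / Y_g if Y_g > 0 else Y[mask],
        )
        contribution = P_g * T_g if P_g > 0 else 0.0
        within += contribution
        per_group[g] = {
            "population_share": P_g,
            "resource_share": Y_g,
            "theil_within": T_g,
            "contribution": contribution,
        }
    rates = None
    if total > 0:
        # normalize by the components' own sum (== total to 1e-10): keeps
        # the rates summing to 1 even when total is vanishingly small
        s = within + between
        rates = {"within": within / s, "between": between / s}
    return TheilDecomposition(
        total=total,
        within=within,
        between=between,
        per_group=per_group,
        contribution_rates=rates,
    )


# ---------------------------------------------------------------------------
# Atkinson
# ---------------------------------------------------------------------------


def atkinson(dist: Distribution, epsilon: float = 2.0) -> float:
    """Atkinson index with inequality aversion ε > 0, in [0, 1).

    A(ε) = 1 − EDE/Ȳ, where the equally-distributed-equivalent EDE is the
    population-weighted power mean of order 1−ε of per-capita resource
    (the geometric mean when ε = 1) and Ȳ the population-weighted arithmetic
    mean.  Higher ε weights the lower tail more heavily; ε = 2 is the
    default (the convention for revealing moderate imbalance).

    A populated unit with zero resource makes the EDE zero for ε ≥ 1; the
    index is then exactly 1 (the degenerate maximum), returned rather than
    raised so callers can flag it.
    """
    if not (epsilon > 0) or not math.isfinite(epsilon):
        raise DomainError(f"inequality aversion must be > 0, got {epsilon}")
    validate(dist)
    keep = dist.populations > 0
    f = dist.populations[keep]
    f = f / f.sum()
    y = dist.resources[keep] / dist.populations[keep]
    ybar = float(f @ y)
    if ybar <= 0:
        raise ValidationError("mean per-capita resource must be > 0")
    rel = y / ybar
    if epsilon == 1.0:
        if np.any(rel == 0):
            return 1.0
        return 1.0 - float(math.exp(f @ np.log(rel)))
    if epsilon > 1.0 and np.any(rel == 0):
        return 1.0
    power = 1.0 - epsilon
    return 1.0 - float((f @ rel**power) ** (1.0 / power))


def ede_fraction(a: float) -> float:
    """Equally-distributed-equivalent fraction 1 − A: the share of the
    present total that, spread equally, would achieve the same level of
    allocation (A = 0.20 ⇒ 80% of the resource would suffice)."""
    if not (0.0 <= a < 1.0):
        raise DomainError(f"Atkinson value {a} outside [0, 1)")
    return 1.0 - a


# ---------------------------------------------------------------------------
# Index of dissimilarity
# ---------------------------------------------------------------------------


def dissimilarity_index(dist: Distribution) -> float:
    """Index of dissimilarity ID = ½·Σ_j |S_jh − S_jp| over groups, in [0, 1]:
    half the L1 distance between group resource shares S_jh and group
    population shares S_jp — the fraction of the resource that would need to
    be redistributed across groups to reach exact proportionality.

    Raises
    ------
    ValidationError
        If any unit lacks a group label.
    """
    validate(dist)
    for u in dist.units:
        if u.group is None:
            raise ValidationError(f"unit {u.id!r} has no group label")
    labels = np.array([u.group for u in dist.units])
    P, Y = dist.population_shares, dist.resource_shares
    total = 0.0
    for g in dist.groups:
        mask = labels == g
        total += abs(float(Y[mask].sum()) - float(P[mask].sum()))
    return 0.5 * total
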
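"""Direct and indirect need standardization.

Units that serve populations with different need structures (age bands,
morbidity strata) are not directly comparable: a district full of elderly
residents *should* receive more beds per person.  Standardization removes
the need-driven component of the allocation so that the equity measures see
only the non-need (horizontal) variation.

Two classical demographic forms are provided:

* **indirect** — compute each unit's need-expected resource
  ``E_i = Σ_s count_{i,s} × m_s`` from its stratum composition and a set of
  reference per-person means ``m_s``, then replace the need-driven deviation
  by the overall mean:  ``adjusted_i = observed_i − E_i + r̄ × pop_i`` with
  r̄ the overall per-person mean.  The reference means act as *relative*
  need weights: the expectations are rescaled so Σ E_i equals the observed
  total, which also preserves the total exactly.  Needs only stratum
  population counts per unit.
* **direct** — apply each unit's own stratum-specific per-capita rates to
  the pooled population's stratum composition:
  ``rate_i = Σ_s W_s × (resource_{i,s} / count_{i,s})`` with W_s the pooled
  stratum shares; ``adjusted_i = rate_i × pop_i``.  Requires per-unit
  per-stratum resource amounts (unit totals alone cannot yield
  stratum-specific rates).

Standardization is idempotent by construction: the output carries a digest
of the profile and method in its metadata, and re-standardizing such a
distribution with the same profile and method returns it unchanged —
double-adjustment is a pipeline bug, not a meaningful operation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np

from .data_model import Distribution, DomainError, ValidationError, validate

__all__ = ["NeedProfile", "standardize"]

_COUNT_TOL = 1e-6


@dataclass(frozen=True)
class NeedProfile:
    """Need structure of every unit, by stratum.

    Parameters
    ----------
    stratum_counts
        unit id → {stratum → population count}.  Counts must cover every
        unit and sum to the unit's population.
    reference_means
        stratum → reference mean resource per person.  Only the *relative*
        sizes matter for indirect standardization (they are rescaled to the
        observed total); all nonnegative, at least one positive.
    stratum_resource
        Optional unit id → {stratum → resource amount}; required by the
        direct method, which needs stratum-specific rates.
    """

    stratum_counts: Mapping[str, Mapping[str, float]]
    reference_means: Mapping[str, float]
    stratum_resource: Mapping[str, Mapping[str, float]] | None = None

    @property
    def strata(self) -> list[str]:
        return list(self.reference_means)

    def __post_init__(self) -> None:
        if not self.reference_means:
            raise DomainError("need profile has no strata")
        for s, m in self.reference_means.items():
            if m < 0:
                raise DomainError(f"reference mean for stratum {s!r} is negative")
        if all(m == 0 for m in self.reference_means.values()):
            raise DomainError("all reference means are zero")
        strata = set(self.strata)
        for uid, counts in self.stratum_counts.items():
            extra = set(counts) - strata
            if extra:
                raise ValidationError(
                    f"unit {uid!r} has counts for unknown strata {sorted(extra)}"
                )

    def digest(self) -> str:
        h = hashlib.sha256()
        for uid in sorted(self.stratum_counts):
            for s in sorted(self.stratum_counts[uid]):
                h.update(repr((uid, s, self.stratum_counts[uid][s])).encode())
        for s in sorted(self.reference_means):
            h.update(repr((s, self.reference_means[s])).encode())
        if self.stratum_resource is not None:
            for uid in sorted(self.stratum_resource):
                for s in sorted(self.stratum_resource[uid]):
                    h.update(
                        repr((uid, s, self.stratum_resource[uid][s])).encode()
                    )
        return h.hexdigest()


def _check_coverage(dist: Distribution, profile: NeedProfile) -> None:
    for u in dist.units:
        if u.id not in profile.stratum_counts:
            raise ValidationError(f"need profile does not cover unit {u.id!r}")
        total = sum(profile.stratum_counts[u.id].values())
        if abs(total - u.population) > _COUNT_TOL * max(1.0, u.population):
            raise ValidationError(
                f"unit {u.id!r}: stratum counts sum to {total}, "
                f"population is {u.population}"
            )


def standardize(
    dist: Distribution,
    profile: NeedProfile,
    method: Literal["direct", "indirect"] = "indirect",
) -> Distribution:
    """Return a need-standardized copy of ``dist``.

    Indirect standardization preserves the resource total exactly; the
    direct method generally does not (it re-rates every unit at the pooled
    composition).  Adjusted amounts that come out negative (possible under
    the indirect correction for units far below their need expectation) are
    floored at 0 with a warning recorded in ``meta["warnings"]``, because
    downstream indices require nonnegative resources.

    Re-standardizing output of this function with the same profile and
    method is a no-op (see module docstring).
    """
    if method not in ("direct", "indirect"):
        raise DomainError(f"unknown standardization method {method!r}")
    validate(dist)
    mark = {"method": method, "profile_digest": profile.digest()}
    if dist.meta.get("standardized") == mark:
        return dist
    _check_coverage(dist, profile)

    pop = dist.populations
    obs = dist.resources
    warnings: list[str] = []

    if method == "indirect":
        raw_expected = np.array(
            [
                sum(
                    profile.stratum_counts[u.id].get(s, 0.0)
                    * profile.reference_means[s]
                    for s in profile.strata
                )
                for u in dist.units
            ]
        )
        tot_exp = raw_expected.sum()
        if tot_exp <= 0:
            raise ValidationError("need-expected totals are zero")
        expected = raw_expected * (dist.total_resource / tot_exp)
        mean_alloc = dist.total_resource / dist.total_population * pop
        adjusted = obs - expected + mean_alloc
    else:  # direct
        if profile.stratum_resource is None:
            raise ValidationError(
                "direct standardization requires per-unit per-stratum "
                "resource amounts (NeedProfile.stratum_resource)"
            )
        # pooled reference composition W_s from the profile's counts
        pooled = {
            s: sum(
                profile.stratum_counts[u.id].get(s, 0.0) for u in dist.units
            )
            for s in profile.strata
        }
        pooled_total = sum(pooled.values())
        if pooled_total <= 0:
            raise ValidationError("pooled stratum counts are zero")
        W = {s: c / pooled_total for s, c in pooled.items()}
        rates = []
        for u in dist.units:
            res_by_s = profile.stratum_resource.get(u.id)
            if res_by_s is None:
                raise ValidationError(
                    f"stratum_resource does not cover unit {u.id!r}"
                )
            rate = 0.0
            for s in profile.strata:
                c = profile.stratum_counts[u.id].get(s, 0.0)
                r = res_by_s.get(s, 0.0)
                if c > 0:
                    rate += W[s] * (r / c)
                elif r > 0:
                    raise ValidationError(
                        f"unit {u.id!r}: resource in empty stratum {s!r}"
                    )
            rates.append(rate)
        adjusted = np.array(rates) * pop

    negative = adjusted < 0
    if negative.any():
        bad = [u.id for u, n in zip(dist.units, negative) if n]
        warnings.append(
            f"adjusted resource negative for units {bad}; floored at 0"
        )
        adjusted = np.maximum(adjusted, 0.0)

    out = dist.replace_resources(adjusted)
    out.meta["standardized"] = mark
    if warnings:
        out.meta.setdefault("warnings", []).extend(warnings)
    return out
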
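"""Domain types, validation and I/O for health-resource equity analysis.

The central container is :class:`Distribution`: an ordered collection of
population units (regions, facilities, socioeconomic groups), each carrying
a population count and a resource amount (beds, doctors, nurses, spending —
any single resource measured in the same unit across rows), plus an optional
living-standards score (``ses``, higher = richer) used by rank-based measures
and an optional ``group`` label used by decomposable measures.

Grouped data is first-class: individual-level data is simply a distribution
whose units all have population 1.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EquityError",
    "ConfigurationError",
    "ValidationError",
    "DomainError",
    "Unit",
    "Distribution",
    "MeasureResult",
    "EquityReport",
    "read_units_csv",
    "validate",
    "write_report",
    "read_report",
]

#: tolerance for share-vector conservation checks
SHARE_TOL = 1e-12


class EquityError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(EquityError):
    """A problem with the run configuration (e.g. a missing mapped column)."""


class ValidationError(EquityError):
    """Input data violates a domain invariant (names the offending unit/row)."""


class DomainError(EquityError, ValueError):
    """A parameter is outside its mathematical domain (e.g. epsilon <= 0)."""


@dataclass(frozen=True)
class Unit:
    """One population unit.

    Parameters
    ----------
    id : str
        Unique label within a distribution.
    population : float
        Nonnegative person count (or weighting denominator: see the
        area-density mode in :mod:`hequity.cli`).
    resource : float
        Nonnegative resource amount, same physical unit across all rows.
    ses : float, optional
        Living-standards score; higher means richer. Required only by
        rank-based measures (concentration curve/index).
    group : str, optional
        Stratum label for decomposable measures (Theil, dissimilarity).
    """

    id: str
    population: float
    resource: float
    ses: float | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.population) or self.population < 0:
            raise ValidationError(
                f"unit {self.id!r}: population must be finite and >= 0, "
                f"got {self.population}"
            )
        if not math.isfinite(self.resource) or self.resource < 0:
            raise ValidationError(
                f"unit {self.id!r}: resource must be finite and >= 0, "
                f"got {self.resource}"
            )


@dataclass
class Distribution:
    """A validated, ordered collection of :class:`Unit`.

    Every measure in the package consumes this type.  Share vectors
    (``population_shares`` = P_i, ``resource_shares`` = Y_i) are computed
    lazily in double precision and never rounded.
    """

    units: tuple[Unit, ...]
    resource_name: str = "resource"
    meta: dict[str, Any] = field(default_factory=dict)

    def __init__(
        self,
        units: Iterable[Unit],
        resource_name: str = "resource",
        meta: Mapping[str, Any] | None = None,
    ) -> None:
        self.units = tuple(units)
        self.resource_name = resource_name
        self.meta = dict(meta or {})
        validate(self)

    # -- vector views -----------------------------------------------------

    @property
    def ids(self) -> list[str]:
        return [u.id for u in self.units]

    @property
    def populations(self) -> np.ndarray:
        return np.array([u.population for u in self.units], dtype=float)

    @property
    def resources(self) -> np.ndarray:
        return np.array([u.resource for u in self.units], dtype=float)

    @property
    def total_population(self) -> float:
        return float(self.populations.sum())

    @property
    def total_resource(self) -> float:
        return float(self.resources.sum())

    @property
    def population_shares(self) -> np.ndarray:
        """P_i = pop_i / Σ pop."""
        return self.populations / self.total_population

    @property
    def resource_shares(self) -> np.ndarray:
        """Y_i = res_i / Σ res."""
        return self.resources / self.total_resource

    @property
    def per_capita(self) -> np.ndarray:
        """Resource per person; +inf where population is 0 but resource > 0,
        and 0 where both are 0."""
        pop = self.populations
        res = self.resources
        with np.errstate(divide="ignore", invalid="ignore"):
            pc = np.where(pop > 0, res / np.where(pop > 0, pop, 1.0), np.inf)
        return np.where((pop == 0) & (res == 0), 0.0, pc)

    @property
    def has_ses(self) -> bool:
        return all(u.ses is not None for u in self.units if u.population > 0)

    @property
    def has_groups(self) -> bool:
        return all(u.group is not None for u in self.units)

    @property
    def groups(self) -> list[str]:
        """Distinct group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for u in self.units:
            if u.group is not None:
                seen.setdefault(u.group, None)
        return list(seen)

    # -- convenience ------------------------------------------------------

    def replace_resources(self, new_resources: Sequence[float]) -> "Distribution":
        """Return a copy with resource amounts replaced, order preserved."""
        if len(new_resources) != len(self.units):
            raise DomainError("replacement vector length mismatch")
        units = tuple(
            dataclasses.replace(u, resource=float(r))
            for u, r in zip(self.units, new_resources)
        )
        return Distribution(units, self.resource_name, self.meta)

    def digest(self) -> str:
        """SHA-256 over the ordered numeric content; used for provenance."""
        h = hashlib.sha256()
        for u in self.units:
            h.update(
                repr((u.id, u.population, u.resource, u.ses, u.group)).encode()
            )
        return h.hexdigest()

    def __len__(self) -> int:
        return len(self.units)


def validate(dist: Distribution) -> Distribution:
    """Check the Distribution invariants; return the same object if they hold.

    Invariants: unique ids, nonnegative populations/resources (enforced per
    Unit), positive totals, and share vectors summing to 1 within 1e-12.

    Raises
    ------
    ValidationError
        With the first offending unit named.
    """
    if len(dist.units) == 0:
        raise ValidationError("distribution has no units")
    seen: set[str] = set()
    for u in dist.units:
        if u.id in seen:
            raise ValidationError(f"duplicate unit id {u.id!r}")
        seen.add(u.id)
    if dist.total_population <= 0:
        raise ValidationError("total population must be > 0")
    if dist.total_resource <= 0:
        raise ValidationError(
            f"total {dist.resource_name} must be > 0 "
            "(every ratio-based index divides by it)"
        )
    if abs(dist.population_shares.sum() - 1.0) > SHARE_TOL:
        raise ValidationError("population shares do not sum to 1")
    if abs(dist.resource_shares.sum() - 1.0) > SHARE_TOL:
        raise ValidationError("resource shares do not sum to 1")
    return dist


# ---------------------------------------------------------------------------
# CSV input
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = ("id", "population", "resource")
_OPTIONAL_KEYS = ("ses", "group")


def read_units_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    resource_name: str | None = None,
) -> Distribution:
    """Read a units table from a UTF-8, comma-separated, headered CSV.

    Parameters
    ----------
    path
        CSV file with one row per unit.
    column_map
        Maps the roles ``id``, ``population``, ``resource`` (required) and
        ``ses``, ``group`` (optional) to column names in the file.  Roles
        omitted from the map default to their own name; optional roles whose
        column is absent simply become absent fields.
    resource_name
        Label stored on the Distribution; defaults to the mapped resource
        column name.

    Raises
    ------
    ConfigurationError
        If the file or a mapped required column is missing.
    ValidationError
        If a row has a negative or unparseable value (names the row id) or
        the totals are not positive.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    cmap = dict(column_map or {})
    for key in _REQUIRED_KEYS + _OPTIONAL_KEYS:
        cmap.setdefault(key, key)

    df = pd.read_csv(path, encoding="utf-8")
    for key in _REQUIRED_KEYS:
        if cmap[key] not in df.columns:
            raise ConfigurationError(
                f"required column {cmap[key]!r} (role {key!r}) not in {path.name}; "
                f"available: {list(df.columns)}"
            )
    has_ses = cmap["ses"] in df.columns
    has_group = cmap["group"] in df.columns

    units = []
    for idx, row in df.iterrows():
        uid = str(row[cmap["id"]])
        try:
            pop = float(row[cmap["population"]])
            res = float(row[cmap["resource"]])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"row {uid!r}: non-numeric value ({exc})") from exc
        ses = None
        if has_ses and pd.notna(row[cmap["ses"]]):
            ses = float(row[cmap["ses"]])
        group = None
        if has_group and pd.notna(row[cmap["group"]]):
            group = str(row[cmap["group"]])
        try:
            units.append(Unit(uid, pop, res, ses=ses, group=group))
        except ValidationError as exc:
            raise ValidationError(f"row {uid!r}: {exc}") from exc

    return Distribution(
        units,
        resource_name=resource_name or cmap["resource"],
        meta={"source": str(path)},
    )


# ---------------------------------------------------------------------------
# Report types and JSON round-trip
# ---------------------------------------------------------------------------


@dataclass
class MeasureResult:
    """One computed index: value, the parameters used, an interpretation
    label from the published banding rules, and any flags (e.g. a divergent
    Theil with the offending units listed)."""

    measure: str
    value: float
    params: dict[str, Any] = field(default_factory=dict)
    label: str | None = None
    flags: list[str] = field(default_factory=list)
    extra: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "measure": self.measure,
            "value": self.value,
            "params": self.params,
            "label": self.label,
            "flags": self.flags,
            "extra": self.extra,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "MeasureResult":
        return cls(
            measure=d["measure"],
            value=d["value"],
            params=dict(d.get("params", {})),
            label=d.get("label"),
            flags=list(d.get("flags", [])),
            extra=dict(d.get("extra", {})),
        )


@dataclass
class EquityReport:
    """Aggregated results of an equity run: every computed index with its
    interpretation label, test verdicts, exported curve references and
    computation metadata (timestamp, input digest, log-base convention).

    Serializes to JSON with stable key order and round-trips losslessly.
    """

    resource_name: str
    results: list[MeasureResult] = field(default_factory=list)
    tests: list[dict[str, Any]] = field(default_factory=list)
    curves: dict[str, Any] = field(default_factory=dict)
    meta: dict[str, Any] = field(default_factory=dict)

    _RANGES = {
        "gini": (0.0, 1.0),
        "atkinson": (0.0, 1.0),
        "dissimilarity": (0.0, 1.0 + 1e-12),
        "concentration_index": (-1.0, 1.0),
    }

    def check_ranges(self) -> None:
        """Assert every finite index value lies in its documented range."""
        for r in self.results:
            rng = self._RANGES.get(r.measure)
            if rng is None or not math.isfinite(r.value):
                continue
            lo, hi = rng
            if not (lo <= r.value <= hi):
                raise ValidationError(
                    f"{r.measure} = {r.value} outside documented range [{lo}, {hi}]"
                )

    def to_dict(self) -> dict[str, Any]:
        return {
            "resource_name": self.resource_name,
            "results": [r.to_dict() for r in self.results],
            "tests": self.tests,
            "curves": self.curves,
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "EquityReport":
        return cls(
            resource_name=d["resource_name"],
            results=[MeasureResult.from_dict(r) for r in d.get("results", [])],
            tests=list(d.get("tests", [])),
            curves=dict(d.get("curves", {})),
            meta=dict(d.get("meta", {})),
        )


def write_report(report: EquityReport, path: str | Path) -> None:
    """Write an EquityReport as JSON (stable key order, lossless floats).

    Non-finite values (a divergent Theil index) are serialized using the
    JSON extension tokens ``Infinity``/``NaN`` that :mod:`json` reads back.
    """
    path = Path(path)
    try:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=False)
            fh.write("\n")
    except OSError as exc:
        raise EquityError(f"cannot write report to {path}: {exc}") from exc


def read_report(path: str | Path) -> EquityReport:
    """Read back a report written by :func:`write_report`."""
    with open(path, encoding="utf-8") as fh:
        return EquityReport.from_dict(json.load(fh))
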
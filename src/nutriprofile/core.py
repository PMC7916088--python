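"""Domain types for nutrient profiling of packaged foods.

The model works with five nutrients for which population-level intake
goals exist: three *disqualifying* components that should be limited
(saturated fat, total sugars, total sodium) and two *qualifying*
components that should be encouraged (protein, dietary fiber).

Products are assessed per reference unit — 100 g for solids, 100 mL for
liquids (powders are reconstituted to liquids upstream).  All values,
including sodium, are carried internally in grams per reference unit;
milligrams appear only at I/O and in reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "Nutrient",
    "Basis",
    "ClaimLimits",
    "ThresholdSet",
    "NotAssessableError",
    "PROTEIN_NRV_G",
    "DISQUALIFYING",
    "QUALIFYING",
    "NUTRIENT_COLUMNS",
    "complies",
]


class Nutrient(str, Enum):
    """One of the five modelled nutrients."""

    SATURATED_FAT = "saturated_fat"
    TOTAL_SUGARS = "total_sugars"
    TOTAL_SODIUM = "total_sodium"
    PROTEIN = "protein"
    FIBER = "fiber"

    @property
    def disqualifying(self) -> bool:
        """True if the nutrient should be limited (lower is better)."""
        return self in DISQUALIFYING

    @property
    def qualifying(self) -> bool:
        """True if the nutrient should be encouraged (higher is better)."""
        return self in QUALIFYING


DISQUALIFYING: tuple[Nutrient, ...] = (
    Nutrient.SATURATED_FAT,
    Nutrient.TOTAL_SUGARS,
    Nutrient.TOTAL_SODIUM,
)
QUALIFYING: tuple[Nutrient, ...] = (Nutrient.PROTEIN, Nutrient.FIBER)

#: Canonical column order for product tables.
NUTRIENT_COLUMNS: tuple[str, ...] = tuple(n.value for n in Nutrient)

#: Nutrient reference value for protein claims (g/day).
PROTEIN_NRV_G: float = 50.0


class Basis(str, Enum):
    """Declaration basis of a product's nutrient contents.

    Powders are a transient ingest-time basis: a fixed dilution converts
    them to ``LIQUID`` before any analysis, so analysed products carry
    exactly one of ``SOLID`` or ``LIQUID``.
    """

    SOLID = "solid_per_100g"
    LIQUID = "liquid_per_100mL"
    POWDER = "powder_per_100g"

    @property
    def reference_unit(self) -> str:
        return "g/100 mL" if self is Basis.LIQUID else "g/100 g"


# "Low in" limits for disqualifying and "source of" limits for qualifying
# nutrients, in g per reference unit.  Codex limits for saturated fat,
# sodium and protein (protein limit = 10% of the 50 g NRV per 100 g,
# halved for liquids); EU regulation for sugars and fiber, with the
# liquid fiber limit set to half the solid one.
_DEFAULT_LIMITS: dict[tuple[Nutrient, Basis], float] = {
    (Nutrient.SATURATED_FAT, Basis.SOLID): 1.50,
    (Nutrient.TOTAL_SUGARS, Basis.SOLID): 5.0,
    (Nutrient.TOTAL_SODIUM, Basis.SOLID): 0.120,
    (Nutrient.PROTEIN, Basis.SOLID): 5.0,
    (Nutrient.FIBER, Basis.SOLID): 3.0,
    (Nutrient.SATURATED_FAT, Basis.LIQUID): 0.75,
    (Nutrient.TOTAL_SUGARS, Basis.LIQUID): 2.5,
    (Nutrient.TOTAL_SODIUM, Basis.LIQUID): 0.120,
    (Nutrient.PROTEIN, Basis.LIQUID): 2.5,
    (Nutrient.FIBER, Basis.LIQUID): 1.5,
}


@dataclass(frozen=True)
class ClaimLimits:
    """Per-(nutrient, basis) claim limits in g per reference unit.

    For disqualifying nutrients the limit is a "low in" claim cut-point
    (a product at or below it is low in that nutrient); for qualifying
    nutrients it is a "source of" cut-point (at or above it the product
    is a source of that nutrient).
    """

    values: Mapping[tuple[Nutrient, Basis], float] = field(
        default_factory=lambda: dict(_DEFAULT_LIMITS)
    )

    def limit(self, nutrient: Nutrient, basis: Basis) -> float:
        """Return the claim limit for ``nutrient`` on ``basis``."""
        nutrient = Nutrient(nutrient)
        basis = Basis(basis)
        if basis is Basis.POWDER:
            raise ValueError(
                "powders carry no claim limits; reconstitute to liquid first"
            )
        try:
            return self.values[(nutrient, basis)]
        except KeyError:
            raise ValueError(
                f"no claim limit defined for {nutrient.value} on {basis.value}"
            ) from None

    @classmethod
    def default(cls) -> "ClaimLimits":
        return cls()

    @classmethod
    def from_mapping(cls, overrides: Mapping[str, Mapping[str, float]]) -> "ClaimLimits":
        """Build limits from ``{basis: {nutrient: value}}`` overriding defaults."""
        values = dict(_DEFAULT_LIMITS)
        basis_aliases = {"solid": Basis.SOLID, "liquid": Basis.LIQUID}
        for basis_key, per_nutrient in overrides.items():
            basis = basis_aliases.get(str(basis_key).lower(), None) or Basis(basis_key)
            for nut_key, value in per_nutrient.items():
                value = float(value)
                if value < 0:
                    raise ValueError(f"claim limit must be >= 0, got {value}")
                values[(Nutrient(nut_key), basis)] = value
        return cls(values=values)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ClaimLimits":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data.get("limits", data))


def claim_limit(
    nutrient: Nutrient, basis: Basis, limits: ClaimLimits | None = None
) -> float:
    """Claim limit ("low in" / "source of") in g per reference unit."""
    return (limits or ClaimLimits.default()).limit(nutrient, basis)


@dataclass(frozen=True)
class ThresholdSet:
    """Joint nutrient thresholds for a target best-fraction ``x``.

    A product complies when every disqualifying nutrient is at or below
    its threshold and every qualifying nutrient at or above it.  ``p``
    is the common percentile level at which the per-nutrient cuts were
    taken; ``coverage`` is the achieved fraction of products complying
    simultaneously with all cuts.
    """

    x: float
    thresholds: Mapping[Nutrient, float]
    p: float
    coverage: float
    clamped: frozenset[Nutrient] = frozenset()
    all_clamped: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.x <= 100:
            raise ValueError(f"target fraction x must be in (0, 100], got {self.x}")

    @property
    def nutrients(self) -> tuple[Nutrient, ...]:
        return tuple(self.thresholds)

    def to_dict(self) -> dict:
        return {
            "x": self.x,
            "p": self.p,
            "coverage": self.coverage,
            "all_clamped": self.all_clamped,
            "thresholds": {
                n.value: {
                    "threshold": float(t),
                    "direction": "<=" if n.disqualifying else ">=",
                    "clamped": n in self.clamped,
                }
                for n, t in self.thresholds.items()
            },
        }


class NotAssessableError(ValueError):
    """A product misses a declared value for a threshold-relevant nutrient.

    Raised so that "cannot be assessed" is never conflated with
    "does not comply": missingness is informative and preserved.
    """


def complies(
    values: Mapping[Nutrient | str, float | None], thresholds: ThresholdSet
) -> bool:
    """True iff the product meets every threshold in ``thresholds``.

    Compliance is inclusive: a disqualifying value exactly at its
    threshold complies (mirroring the "low in if <= limit" convention),
    as does a qualifying value exactly at its threshold.

    Raises :class:`NotAssessableError` if a relevant nutrient is missing.
    """
    lookup = {Nutrient(k): v for k, v in values.items()}
    for nutrient, threshold in thresholds.thresholds.items():
        value = lookup.get(nutrient)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise NotAssessableError(
                f"product has no declared {nutrient.value}; compliance not assessable"
            )
        if nutrient.disqualifying:
            if value > threshold:
                return False
        else:
            if value < threshold:
                return False
    return True


def ensure_analysis_basis(basis_values: Iterable[str]) -> Basis:
    """Return the single analysis basis of a category, or raise.

    Analysis operates on one (category, basis) cell at a time; mixed or
    powder bases indicate a missing upstream ingest step.
    """
    bases = {Basis(b) for b in basis_values}
    if len(bases) != 1:
        raise ValueError(f"category mixes declaration bases: {sorted(b.value for b in bases)}")
    basis = bases.pop()
    if basis is Basis.POWDER:
        raise ValueError("powder products must be reconstituted before analysis")
    return basis
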
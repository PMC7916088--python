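"""Reading, cleaning and normalising product tables.

Input is a flat CSV with one row per product: ``product_id``,
``category``, ``basis`` and the five nutrient columns in g per declared
reference unit (sodium in g), plus optional ``salt`` and ``rating``
columns.  Missing values stay missing throughout — they are informative
(regional labelling policy, product type) and are never zero-filled or
imputed.

Cleaning removes rows whose declared nutrient values sum to more than
100 g per reference unit, estimates sodium from salt where only salt is
declared, reconstitutes powders to liquids with a fixed dilution, and
splits each category label by declaration basis into *initial
categories*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Basis, Nutrient, NUTRIENT_COLUMNS

__all__ = [
    "SODIUM_MOLAR_MASS",
    "NACL_MOLAR_MASS",
    "NACL_MOLAR_MASS_AS_PRINTED",
    "POWDER_DILUTION",
    "CleaningReport",
    "read_products",
    "clean",
    "salt_to_sodium",
    "apply_salt_conversion",
    "reconstitute_powders",
    "partition_by_basis",
]

SODIUM_MOLAR_MASS = 22.99  # g/mol
NACL_MOLAR_MASS = 58.44  # g/mol
#: Value printed in some sources for the NaCl molar mass; kept available
#: so published numbers derived with it can be mimicked exactly.
NACL_MOLAR_MASS_AS_PRINTED = 55.44

#: 1 g powder per 10 mL water => 100 mL of prepared product holds 10 g powder.
POWDER_DILUTION = 0.1

REQUIRED_COLUMNS = ("product_id", "category", "basis") + NUTRIENT_COLUMNS
OPTIONAL_COLUMNS = ("salt", "rating")


@dataclass
class CleaningReport:
    """Bookkeeping for one cleaning pass over a product table."""

    rows_read: int = 0
    rows_rejected_negative: int = 0
    rows_removed_sum_rule: int = 0
    rows_retained: int = 0
    salt_conversions: int = 0
    salt_conversions_skipped: int = 0
    powders_reconstituted: int = 0
    declaration_rates: dict[str, float] = field(default_factory=dict)
    rejected_rows: list[dict] = field(default_factory=list)

    def validate(self) -> None:
        total = self.rows_rejected_negative + self.rows_removed_sum_rule + self.rows_retained
        if total != self.rows_read:
            raise AssertionError(
                f"cleaning bookkeeping inconsistent: {total} != {self.rows_read}"
            )
        for rate in self.declaration_rates.values():
            if not 0.0 <= rate <= 1.0:
                raise AssertionError("declaration rate outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "rows_read": self.rows_read,
            "rows_rejected_negative": self.rows_rejected_negative,
            "rows_removed_sum_rule": self.rows_removed_sum_rule,
            "rows_retained": self.rows_retained,
            "salt_conversions": self.salt_conversions,
            "salt_conversions_skipped": self.salt_conversions_skipped,
            "powders_reconstituted": self.powders_reconstituted,
            "declaration_rates": self.declaration_rates,
            "rejected_rows": self.rejected_rows,
        }


def read_products(path: str | Path) -> pd.DataFrame:
    """Read a product CSV, enforcing the header contract and dtypes."""
    df = pd.read_csv(path, dtype={"product_id": str, "category": str, "basis": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"product table misses required columns: {missing}")
    for col in NUTRIENT_COLUMNS + ("salt", "rating"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    unknown = set(df["basis"].dropna()) - {b.value for b in Basis}
    if unknown:
        raise ValueError(f"unknown declaration basis values: {sorted(unknown)}")
    return df


def salt_to_sodium(salt_g: float, m_nacl: float = NACL_MOLAR_MASS) -> float:
    """Estimate sodium (g) from salt (g) via the molar-mass ratio Na/NaCl."""
    if salt_g < 0:
        raise ValueError(f"salt content must be >= 0, got {salt_g}")
    return salt_g * (SODIUM_MOLAR_MASS / m_nacl)


def apply_salt_conversion(
    df: pd.DataFrame, m_nacl: float = NACL_MOLAR_MASS, report: CleaningReport | None = None
) -> pd.DataFrame:
    """Fill missing sodium from declared salt; never overwrite declared sodium."""
    df = df.copy()
    if "salt" not in df.columns:
        return df
    sodium = Nutrient.TOTAL_SODIUM.value
    fillable = df[sodium].isna() & df["salt"].notna()
    skipped = df[sodium].notna() & df["salt"].notna()
    df.loc[fillable, sodium] = df.loc[fillable, "salt"] * (SODIUM_MOLAR_MASS / m_nacl)
    if report is not None:
        report.salt_conversions = int(fillable.sum())
        report.salt_conversions_skipped = int(skipped.sum())
    return df


def clean(
    df: pd.DataFrame, report: CleaningReport | None = None
) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the nutrient-sum plausibility rule.

    Rows whose declared nutrient values (the five model nutrients, sodium
    in g, missing values absent from the sum) add up to strictly more
    than 100 g per reference unit are physically impossible and removed.
    Rows with any negative declared value are rejected with a diagnostic
    rather than silently dropped.
    """
    report = report or CleaningReport()
    report.rows_read = len(df)
    nutrient_cols = list(NUTRIENT_COLUMNS)

    negative = (df[nutrient_cols] < 0).any(axis=1)
    if "salt" in df.columns:
        negative |= df["salt"] < 0
    for _, row in df[negative].iterrows():
        bad = {
            c: row[c]
            for c in nutrient_cols + (["salt"] if "salt" in df.columns else [])
            if pd.notna(row[c]) and row[c] < 0
        }
        report.rejected_rows.append(
            {"product_id": row["product_id"], "reason": "negative declared value", "values": bad}
        )
    report.rows_rejected_negative = int(negative.sum())
    df = df[~negative]

    # np.nansum treats all-missing rows as 0, which never exceeds 100.
    sums = df[nutrient_cols].sum(axis=1, skipna=True)
    violates = sums > 100.0
    report.rows_removed_sum_rule = int(violates.sum())
    kept = df[~violates].copy()
    report.rows_retained = len(kept)
    report.declaration_rates = {
        c: (float(kept[c].notna().mean()) if len(kept) else 0.0) for c in nutrient_cols
    }
    report.validate()
    return kept, report


def reconstitute_powders(
    df: pd.DataFrame,
    dilution: float = POWDER_DILUTION,
    report: CleaningReport | None = None,
) -> pd.DataFrame:
    """Convert powder products to their as-prepared liquid basis.

    Every declared value is scaled by the dilution factor (default 10 g
    powder per 100 mL prepared product); missing stays missing.  The
    operation is idempotent: its output contains no powders.
    """
    df = df.copy()
    is_powder = df["basis"] == Basis.POWDER.value
    cols = list(NUTRIENT_COLUMNS) + (["salt"] if "salt" in df.columns else [])
    df.loc[is_powder, cols] = df.loc[is_powder, cols] * dilution
    df.loc[is_powder, "basis"] = Basis.LIQUID.value
    if report is not None:
        report.powders_reconstituted = int(is_powder.sum())
    return df


def reconstitute_powder(record: dict, dilution: float = POWDER_DILUTION) -> dict:
    """Single-product version of :func:`reconstitute_powders`."""
    record = dict(record)
    if Basis(record["basis"]) is not Basis.POWDER:
        warnings.warn("product is not a powder; reconstitution is a no-op", stacklevel=2)
        return record
    for col in NUTRIENT_COLUMNS + ("salt",):
        value = record.get(col)
        if value is not None and not (isinstance(value, float) and np.isnan(value)):
            record[col] = value * dilution
    record["basis"] = Basis.LIQUID.value
    return record


def partition_by_basis(df: pd.DataFrame) -> dict[tuple[str, Basis], pd.DataFrame]:
    """Split each category label by declaration basis into initial categories.

    The same consumer offer can be declared per 100 g in one region and
    per 100 mL in another; such labels become separate initial
    categories.  Product count is conserved.
    """
    if (df["basis"] == Basis.POWDER.value).any():
        raise ValueError("reconstitute powders before partitioning by basis")
    out: dict[tuple[str, Basis], pd.DataFrame] = {}
    for (category, basis), group in df.groupby(["category", "basis"], sort=True):
        out[(category, Basis(basis))] = group
    assert sum(len(g) for g in out.values()) == len(df)
    return out


def initial_category_label(category: str, basis: Basis) -> str:
    return f"{category} [{Basis(basis).value}]"
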
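"""Category-relevant nutrients and the analyzable product subset.

A nutrient matters for a category when the category's products are
typically *not* "low in" it (disqualifying) or typically *are* a
"source of" it (qualifying): concretely, when strictly more than half
of the category's products declare a value strictly above the claim
limit.  Missing declarations count against relevance — the denominator
is the whole category — which is the conservative reading and keeps
poorly-declared nutrients from driving thresholds.
"""

from __future__ import annotations

import pandas as pd

from .core import Basis, ClaimLimits, Nutrient, ensure_analysis_basis

__all__ = ["relevant_nutrients", "relevance_report", "analyzable_subset", "UnratedCategoryError"]


class UnratedCategoryError(ValueError):
    """No nutrient is category-relevant: the category cannot be rated."""


def relevance_report(
    df: pd.DataFrame, limits: ClaimLimits | None = None, basis: Basis | None = None
) -> dict[Nutrient, dict]:
    """Per-nutrient exceedance fractions and relevance decisions.

    A product contributes to a nutrient's exceedance count only if it
    declares a value strictly above the claim limit; a product exactly
    at the "low in" limit is low in the nutrient, hence no evidence of
    relevance.
    """
    if len(df) == 0:
        raise ValueError("cannot assess relevance of an empty category")
    limits = limits or ClaimLimits.default()
    basis = basis or ensure_analysis_basis(df["basis"])
    n = len(df)
    report: dict[Nutrient, dict] = {}
    for nutrient in Nutrient:
        limit = limits.limit(nutrient, basis)
        exceeders = int((df[nutrient.value] > limit).sum())  # NaN compares False
        report[nutrient] = {
            "limit": limit,
            "n_exceeding": exceeders,
            "fraction_exceeding": exceeders / n,
            "relevant": exceeders > 0.5 * n,
        }
    return report


def relevant_nutrients(
    df: pd.DataFrame, limits: ClaimLimits | None = None, basis: Basis | None = None
) -> set[Nutrient]:
    """Nutrients for which strictly more than half the products exceed the claim limit."""
    return {n for n, r in relevance_report(df, limits, basis).items() if r["relevant"]}


def analyzable_subset(df: pd.DataFrame, relevant: set[Nutrient]) -> pd.DataFrame:
    """Products declaring every category-relevant nutrient.

    Missing values of non-relevant nutrients are ignored, so a category
    with two relevant nutrients typically keeps far more products than
    a complete-case analysis over all five would.
    """
    if not relevant:
        raise UnratedCategoryError(
            "no category-relevant nutrient: category is unrated and has no analyzable subset"
        )
    mask = pd.Series(True, index=df.index)
    for nutrient in relevant:
        mask &= df[nutrient.value].notna()
    return df[mask]
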
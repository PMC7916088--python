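"""Per-product 0-100% scores against the category's threshold family.

The threshold search is run once per integer target ``x`` from 1 to
100 on a sub-category; a product's score is then the proportion of the
category it beats: the complement of the smallest ``x`` whose
thresholds it meets.  A product that complies with the 13% thresholds
but fails the 12% thresholds scores 87%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    Basis,
    ClaimLimits,
    NotAssessableError,
    Nutrient,
    ThresholdSet,
    complies,
)
from .thresholds import (
    MIN_PRODUCTS,
    QuantileMethod,
    derive_thresholds,
)

__all__ = ["ScoreResult", "threshold_family", "score_product", "score_category"]

DEFAULT_GRID: tuple[int, ...] = tuple(range(1, 101))


@dataclass(frozen=True)
class ScoreResult:
    """Score of one product within its sub-category.

    ``score = 100 - x_min`` where ``x_min`` is the smallest target
    fraction whose thresholds the product meets; products meeting no
    thresholds at all (possible once clamping tightens a qualifying
    cut) score 0, and products missing a relevant nutrient are not
    assessable rather than scored.
    """

    product_id: str
    category: str
    score: int
    x_min: int | None
    assessable: bool = True

    def __post_init__(self) -> None:
        if self.assessable and self.x_min is not None:
            if self.score != 100 - self.x_min:
                raise ValueError("score must equal 100 - x_min")
        if not 0 <= self.score <= 100:
            raise ValueError("score outside [0, 100]")


def threshold_family(
    df: pd.DataFrame,
    relevant: Iterable[Nutrient],
    xs: Sequence[int] = DEFAULT_GRID,
    *,
    limits: ClaimLimits | None = None,
    basis: Basis | None = None,
    clamp: bool = False,
    qualifying_clamp: Literal["raise", "lower"] = "raise",
    min_products: int = MIN_PRODUCTS,
    quantile_method: QuantileMethod = "nearest_rank",
) -> dict[int, ThresholdSet]:
    """Threshold sets for every target fraction on the integer grid.

    Scoring uses the raw minimal-common-percentile family by default
    (``clamp=False``); clamping exists to publish reformulation targets
    and would discretise scores near the claim limits.
    """
    relevant = list(relevant)
    return {
        int(x): derive_thresholds(
            df,
            relevant,
            float(x),
            limits=limits,
            basis=basis,
            clamp=clamp,
            qualifying_clamp=qualifying_clamp,
            min_products=min_products,
            quantile_method=quantile_method,
        )
        for x in xs
    }


def score_product(
    values: Mapping[Nutrient | str, float | None],
    family: Mapping[int, ThresholdSet],
    *,
    product_id: str = "",
    category: str = "",
) -> ScoreResult:
    """Score one product against a precomputed threshold family.

    ``x_min`` is found by an ascending scan: the thresholds tighten as
    ``x`` shrinks, so the first compliant level is the minimal one.
    """
    try:
        x_min: int | None = None
        for x in sorted(family):
            if complies(values, family[x]):
                x_min = int(x)
                break
        if x_min is None:
            return ScoreResult(product_id=product_id, category=category, score=0, x_min=None)
        return ScoreResult(
            product_id=product_id, category=category, score=100 - x_min, x_min=x_min
        )
    except NotAssessableError:
        return ScoreResult(
            product_id=product_id, category=category, score=0, x_min=None, assessable=False
        )


def score_category(
    df: pd.DataFrame,
    family: Mapping[int, ThresholdSet],
    *,
    category: str = "",
) -> pd.DataFrame:
    """One ScoreResult row per product; deterministic, order-independent.

    Products equal on all relevant nutrients share ``x_min`` and hence
    the score — there is no tie-breaking.
    """
    nutrients = next(iter(family.values())).nutrients if family else ()
    n = len(df)
    x_min = np.full(n, -1, dtype=int)
    assessable = np.ones(n, dtype=bool)
    cols = {nut: df[nut.value].to_numpy(dtype=float) for nut in nutrients}
    for nut in nutrients:
        assessable &= ~np.isnan(cols[nut])
    undecided = assessable.copy()
    for x in sorted(family):
        if not undecided.any():
            break
        ts = family[x]
        ok = undecided.copy()
        for nut, t in ts.thresholds.items():
            v = cols[nut]
            with np.errstate(invalid="ignore"):
                ok &= (v <= t) if nut.disqualifying else (v >= t)
        x_min[ok] = int(x)
        undecided &= ~ok
    score = np.where(x_min > 0, 100 - x_min, 0)
    out = df[["product_id"]].copy()
    out["category"] = category or df.get("category", "")
    out["score"] = score
    out["x_min"] = pd.array(
        [int(v) if v > 0 else None for v in x_min], dtype="Int64"
    )
    out["assessable"] = assessable
    return out
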
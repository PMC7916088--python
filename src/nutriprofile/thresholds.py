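"""Joint nutrient thresholds via the minimal common percentile search.

For a target best-fraction ``x`` (in percent) of a nutritionally
homogeneous sub-category, the method looks for the *smallest* single
percentile level ``p`` such that, cutting every category-relevant
nutrient at its own empirical ``p``-level (the p-th percentile for a
disqualifying nutrient, compliance <=; the mirrored (100-p)-th
percentile for a qualifying nutrient, compliance >=), at least ``x``
percent of the products comply with all cuts *simultaneously*.  Because
nutrients are correlated, ``p`` generally exceeds ``x``: e.g. a 50%
target may land on the 65th percentile of each nutrient.

Joint coverage is a non-decreasing step function of ``p`` that only
changes at the attainable levels ``p = 100 i / n`` (the order
statistics), so a monotone bisection over ``i`` finds the minimal level
exactly.

Thresholds that fall below the "low in" / "source of" claim limit are
clamped up to the limit and the search is rerun with the clamped
nutrients held fixed, so the remaining thresholds still capture the
expected proportion of products.
"""

from __future__ import annotations

import math
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .core import Basis, ClaimLimits, Nutrient, ThresholdSet, ensure_analysis_basis

__all__ = [
    "common_percentile_thresholds",
    "clamp_and_rerun",
    "derive_thresholds",
    "threshold_report",
    "TooFewProductsError",
    "MIN_PRODUCTS",
]

#: Below this many products, order-statistic thresholds are too unstable
#: to publish as reformulation targets.
MIN_PRODUCTS = 20

QuantileMethod = Literal["nearest_rank", "linear"]
_NP_METHOD = {"nearest_rank": "inverted_cdf", "linear": "linear"}


class TooFewProductsError(ValueError):
    """Sub-category too small for stable threshold derivation."""


def _cut(sorted_values: np.ndarray, p: float, disqualifying: bool, method: QuantileMethod) -> float:
    """Per-nutrient cut at common level ``p`` (percent).

    Disqualifying: the empirical p-th percentile (values at or below
    comply).  Qualifying: the mirrored cut — the p-th percentile of the
    reversed distribution, i.e. the (100-p)-th percentile from below —
    so that values at or above comply.

    Nearest-rank cuts are taken by integer order-statistic index (the
    ``ceil(p*n/100)``-th smallest / largest observed value), never via a
    float quantile, so grid levels p = 100*i/n are exact.
    """
    n = len(sorted_values)
    if method == "nearest_rank":
        k = min(max(math.ceil(round(p * n / 100.0, 9)), 1), n)
        idx = k - 1 if disqualifying else n - k
        return float(sorted_values[idx])
    q = min(max(p / 100.0, 0.0), 1.0)
    if disqualifying:
        return float(np.quantile(sorted_values, q, method=_NP_METHOD[method]))
    return float(-np.quantile(-sorted_values, q, method=_NP_METHOD[method]))


def _thresholds_at(
    sorted_cols: Mapping[Nutrient, np.ndarray], p: float, method: QuantileMethod
) -> dict[Nutrient, float]:
    return {
        nut: _cut(vals, p, nut.disqualifying, method) for nut, vals in sorted_cols.items()
    }


def _coverage(
    cols: Mapping[Nutrient, np.ndarray],
    thresholds: Mapping[Nutrient, float],
    fixed: Mapping[Nutrient, float] | None = None,
) -> float:
    """Fraction of products simultaneously compliant with all cuts."""
    n = len(next(iter(cols.values())))
    ok = np.ones(n, dtype=bool)
    merged = dict(fixed or {})
    merged.update(thresholds)
    for nut, t in merged.items():
        v = cols[nut]
        ok &= (v <= t) if nut.disqualifying else (v >= t)
    return float(ok.mean())


def common_percentile_thresholds(
    df: pd.DataFrame,
    relevant: Iterable[Nutrient],
    x: float,
    *,
    min_products: int = MIN_PRODUCTS,
    quantile_method: QuantileMethod = "nearest_rank",
    _fixed: Mapping[Nutrient, float] | None = None,
    _clamped: frozenset[Nutrient] = frozenset(),
) -> ThresholdSet:
    """Minimal-common-percentile thresholds for target top-fraction ``x``.

    Returns the per-nutrient thresholds, the common level ``p`` found,
    and the achieved joint coverage (always >= x/100 unless fixed
    constraints make the target unattainable).

    ``_fixed`` holds clamped nutrients as immovable constraints during a
    rerun; they participate in coverage but not in the search.
    """
    if not 0 < x <= 100:
        raise ValueError(f"target fraction x must be in (0, 100], got {x}")
    free = [n for n in relevant if n not in (_fixed or {})]
    all_nutrients = list(relevant)
    if not all_nutrients:
        raise ValueError("no relevant nutrients to derive thresholds for")
    n = len(df)
    if n < min_products:
        raise TooFewProductsError(
            f"{n} products < required minimum {min_products}; refusing to derive thresholds"
        )
    cols: dict[Nutrient, np.ndarray] = {}
    for nut in all_nutrients:
        v = df[nut.value].to_numpy(dtype=float)
        if np.isnan(v).any():
            raise ValueError(f"undeclared {nut.value}; derive on the analyzable subset")
        cols[nut] = v
    sorted_free = {nut: np.sort(cols[nut]) for nut in free}
    fixed = dict(_fixed or {})

    if not free:
        # everything clamped: coverage is whatever the limits achieve
        cov = _coverage(cols, {}, fixed)
        return ThresholdSet(
            x=x, thresholds=dict(fixed), p=float("nan"), coverage=cov,
            clamped=_clamped, all_clamped=True,
        )

    def cov_at(i: int) -> float:
        p = 100.0 * i / n
        return _coverage(cols, _thresholds_at(sorted_free, p, quantile_method), fixed)

    target = x / 100.0
    lo, hi = 1, n  # search minimal i in [1, n] with coverage >= target
    if cov_at(n) < target:
        i_star = n  # unattainable under the fixed constraints: fully relax
    else:
        while lo < hi:
            mid = (lo + hi) // 2
            if cov_at(mid) >= target:
                hi = mid
            else:
                lo = mid + 1
        i_star = lo
    p_star = 100.0 * i_star / n
    thresholds = _thresholds_at(sorted_free, p_star, quantile_method)
    coverage = _coverage(cols, thresholds, fixed)
    ordered = {nut: fixed.get(nut, thresholds.get(nut)) for nut in all_nutrients}
    return ThresholdSet(
        x=x, thresholds=ordered, p=p_star, coverage=coverage, clamped=_clamped
    )


def clamp_and_rerun(
    df: pd.DataFrame,
    thresholds: ThresholdSet,
    limits: ClaimLimits | None = None,
    *,
    basis: Basis | None = None,
    qualifying_clamp: Literal["raise", "lower"] = "raise",
    min_products: int = MIN_PRODUCTS,
    quantile_method: QuantileMethod = "nearest_rank",
) -> ThresholdSet:
    """Clamp thresholds beyond their claim limits and re-search.

    Default behaviour follows the rule "if the derived threshold is
    below the 'low in' / 'source of' limit, set it to this limit": a
    disqualifying threshold stricter than the low-in claim is relaxed up
    to it (no point demanding less than "low in"), and a qualifying
    threshold weaker than the source-of claim is raised to it (a
    compliant product should support the claim).  With
    ``qualifying_clamp="lower"`` the alternative lenient reading is
    used: qualifying thresholds *above* the source-of limit are lowered
    to it.

    Clamped nutrients become fixed constraints and the minimal common
    percentile is re-searched over the remaining ones, iterating until
    no new clamp appears.  If every nutrient ends up clamped, the
    achieved coverage is reported as-is and flagged.
    """
    limits = limits or ClaimLimits.default()
    basis = basis or ensure_analysis_basis(df["basis"])
    current = thresholds
    fixed: dict[Nutrient, float] = {}
    while True:
        new_clamp = False
        for nut, t in current.thresholds.items():
            if nut in fixed:
                continue
            limit = limits.limit(nut, basis)
            if nut.disqualifying:
                needs = t < limit
            elif qualifying_clamp == "raise":
                needs = t < limit
            else:
                needs = t > limit
            if needs:
                fixed[nut] = limit
                new_clamp = True
        if not new_clamp:
            return current
        current = common_percentile_thresholds(
            df,
            list(thresholds.thresholds),
            current.x,
            min_products=min_products,
            quantile_method=quantile_method,
            _fixed=fixed,
            _clamped=frozenset(fixed),
        )


def derive_thresholds(
    df: pd.DataFrame,
    relevant: Iterable[Nutrient],
    x: float,
    *,
    limits: ClaimLimits | None = None,
    basis: Basis | None = None,
    clamp: bool = True,
    qualifying_clamp: Literal["raise", "lower"] = "raise",
    min_products: int = MIN_PRODUCTS,
    quantile_method: QuantileMethod = "nearest_rank",
) -> ThresholdSet:
    """Search plus (by default) claim-limit clamping, in one call."""
    ts = common_percentile_thresholds(
        df, list(relevant), x, min_products=min_products, quantile_method=quantile_method
    )
    if clamp:
        ts = clamp_and_rerun(
            df,
            ts,
            limits,
            basis=basis,
            qualifying_clamp=qualifying_clamp,
            min_products=min_products,
            quantile_method=quantile_method,
        )
    return ts


def _round_half_away(value: float) -> int:
    return int(math.copysign(math.floor(abs(value) + 0.5), value))


def threshold_report(
    ts_from: ThresholdSet, ts_to: ThresholdSet
) -> dict[Nutrient, dict]:
    """Compare two threshold sets on the same sub-category.

    The relative change per nutrient, (T_to - T_from) / T_from, is
    rendered as a signed integer percent (rounded half away from zero);
    a zero baseline leaves the relative change undefined ("n/a").
    """
    if set(ts_from.thresholds) != set(ts_to.thresholds):
        raise ValueError("threshold sets cover different nutrients")
    out: dict[Nutrient, dict] = {}
    for nut, t0 in ts_from.thresholds.items():
        t1 = ts_to.thresholds[nut]
        if t0 == 0:
            pct: int | None = None
            rendered = "n/a"
        else:
            pct = _round_half_away(100.0 * (t1 - t0) / t0)
            rendered = f"{pct:+d}%" if pct else "0%"
        out[nut] = {
            "from": float(t0),
            "to": float(t1),
            "relative_change_pct": pct,
            "rendered": rendered,
        }
    return out
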
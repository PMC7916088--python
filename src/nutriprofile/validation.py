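"""Convergent validation of scores against an external ordinal rating.

The profiling score is compared with an independent, previously
validated rating (e.g. Health Star Rating stars, declared in half-star
steps) via a weighted Spearman correlation.  Ratings cluster heavily on
a few classes in real data, so each product can be weighted by the
inverse frequency of its rating class to keep dominant classes from
swamping the correlation.  Boxplot-style five-number summaries per
rating class and a list of strongly discordant products complete the
report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "weighted_spearman",
    "class_balance_weights",
    "agreement_summary",
    "AgreementSummary",
    "plot_agreement",
]


def weighted_spearman(
    scores: Sequence[float],
    ratings: Sequence[float],
    weights: Sequence[float] | None = None,
) -> float:
    """Weighted Spearman rank correlation with midranks for ties.

    Both columns are rank-transformed (average ranks on ties) and the
    weighted Pearson correlation of the ranks is returned, so uniform
    weights reduce exactly to the classical Spearman coefficient.
    Returns NaN when either ranking carries no (weighted) variance.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(ratings, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("scores and ratings must be 1-D and the same length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if weights is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != x.shape:
            raise ValueError("weights must match scores in length")
        if (w <= 0).any():
            raise ValueError("weights must be strictly positive")
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    w = w / w.sum()
    mx, my = w @ rx, w @ ry
    cov = w @ ((rx - mx) * (ry - my))
    vx = w @ (rx - mx) ** 2
    vy = w @ (ry - my) ** 2
    if vx <= 0 or vy <= 0:
        return float("nan")
    return float(cov / np.sqrt(vx * vy))


def class_balance_weights(ratings: Sequence[float]) -> np.ndarray:
    """Per-product weights proportional to 1 / frequency of the rating class.

    Normalised to mean 1 (so they sum to n); a uniformly distributed
    rating yields unit weights for everyone.
    """
    r = pd.Series(list(ratings))
    if len(r) == 0:
        raise ValueError("no ratings")
    freq = r.map(r.value_counts(normalize=True))
    w = 1.0 / freq.to_numpy(dtype=float)
    return w * (len(w) / w.sum())


@dataclass(frozen=True)
class AgreementSummary:
    """Per-rating-class score summaries plus flagged discordant products."""

    class_summaries: pd.DataFrame  # index: rating class; columns: n/min/q1/median/q3/max
    discordant: pd.DataFrame  # rows flagged by the discordance cut-offs
    weighted_correlation: float

    def to_dict(self) -> dict:
        return {
            "weighted_spearman": self.weighted_correlation,
            "classes": self.class_summaries.reset_index().to_dict(orient="records"),
            "discordant": self.discordant.to_dict(orient="records"),
        }


def agreement_summary(
    scores: Sequence[float],
    ratings: Sequence[float],
    *,
    product_ids: Sequence[str] | None = None,
    low_rating: float = 1.5,
    high_score: float = 85.0,
    high_rating: float = 4.0,
    low_score: float = 15.0,
    weight_fn: Callable[[Sequence[float]], np.ndarray] | None = class_balance_weights,
) -> AgreementSummary:
    """Summarise score-vs-rating agreement per rating class.

    Discordant products are those rated at or below ``low_rating`` yet
    scoring above ``high_score``, or rated at or above ``high_rating``
    yet scoring below ``low_score``.
    """
    df = pd.DataFrame({"score": np.asarray(scores, float), "rating": np.asarray(ratings, float)})
    df["product_id"] = list(product_ids) if product_ids is not None else df.index.astype(str)
    per_class = (
        df.groupby("rating")["score"]
        .agg(
            n="size",
            min="min",
            q1=lambda s: s.quantile(0.25),
            median="median",
            q3=lambda s: s.quantile(0.75),
            max="max",
        )
    )
    discordant = df[
        ((df["rating"] <= low_rating) & (df["score"] > high_score))
        | ((df["rating"] >= high_rating) & (df["score"] < low_score))
    ][["product_id", "rating", "score"]].reset_index(drop=True)
    weights = weight_fn(df["rating"]) if weight_fn is not None else None
    if df["rating"].nunique() < 2 or df["score"].nunique() < 2 or len(df) < 3:
        r_ws = float("nan")
    else:
        r_ws = weighted_spearman(df["score"], df["rating"], weights)
    return AgreementSummary(
        class_summaries=per_class, discordant=discordant, weighted_correlation=r_ws
    )


def plot_agreement(
    scores: Sequence[float], ratings: Sequence[float], path: str
) -> None:
    """Boxplots of scores per rating class, written to ``path`` (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = pd.DataFrame({"score": scores, "rating": ratings}).dropna()
    classes = sorted(df["rating"].unique())
    data = [df.loc[df["rating"] == c, "score"] for c in classes]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot(data, tick_labels=[f"{c:g}" for c in classes])
    ax.set_xlabel("external rating")
    ax.set_ylabel("score (%)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
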
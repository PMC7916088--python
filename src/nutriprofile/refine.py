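"""Category refinement by histogram-convexity mode detection.

An initial category can group several distinct consumer offers (e.g.
regular vs. intense-sweetener soft drinks); these show up as separate
modes in the univariate distribution of a relevant nutrient.  The
detector is deliberately *less* sensitive than formal modality tests:
it bins the values into a fixed, small number of equal-width bins
(default 12) and calls a bin a potential mode when it is locally convex
— it counts strictly more products than the average of its two
neighbours.  Runs of adjacent potential-mode bins merge into a single
mode at the centre of their combined span.  The category is then split
at the midpoints between consecutive modes, independently per nutrient,
and products are assigned to the Cartesian product of the per-nutrient
intervals.

The bin count is the method's only sensitivity knob: fewer bins mean
fewer, broader modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Nutrient

__all__ = ["ModeDetection", "CategoryPartition", "detect_modes", "split_category"]

DEFAULT_N_BINS = 12


@dataclass(frozen=True)
class ModeDetection:
    """Result of mode detection on one nutrient's declared values."""

    nutrient: Nutrient | None
    bin_edges: np.ndarray  # length n_bins + 1
    counts: np.ndarray  # length n_bins
    potential_mode_bins: tuple[int, ...]
    mode_runs: tuple[tuple[int, int], ...]  # inclusive (first_bin, last_bin)
    modes: tuple[float, ...]  # strictly increasing locations
    cuts: tuple[float, ...]  # midpoints of consecutive modes

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    @property
    def unimodal(self) -> bool:
        return self.n_modes <= 1

    def to_dict(self) -> dict:
        return {
            "nutrient": self.nutrient.value if self.nutrient else None,
            "bin_edges": [float(e) for e in self.bin_edges],
            "counts": [int(c) for c in self.counts],
            "potential_mode_bins": list(self.potential_mode_bins),
            "modes": [float(m) for m in self.modes],
            "cuts": [float(c) for c in self.cuts],
        }


def _potential_mode_bins(counts: np.ndarray) -> list[int]:
    """Bins that are locally convex (strict, ties do not qualify).

    Interior bins compare against the mean of both neighbours; edge bins
    have a single neighbour and qualify when they exceed it.
    """
    n = len(counts)
    if n == 1:
        return [0]
    c = counts.astype(float)
    out = []
    if c[0] > c[1]:
        out.append(0)
    for i in range(1, n - 1):
        if c[i] > (c[i - 1] + c[i + 1]) / 2.0:
            out.append(i)
    if c[n - 1] > c[n - 2]:
        out.append(n - 1)
    return out


def detect_modes(
    values,
    n_bins: int = DEFAULT_N_BINS,
    nutrient: Nutrient | None = None,
    anchor_zero: bool = False,
) -> ModeDetection:
    """Detect modes of a nutrient distribution via the convexity rule.

    Bins are equal-width over ``[min, max]`` of the declared values
    (``[0, max]`` with ``anchor_zero=True``), half-open with the last
    bin closed.  If all values coincide the distribution is unimodal by
    definition: a single mode at the common value, no cuts.
    """
    values = np.asarray(pd.Series(values).dropna(), dtype=float)
    if len(values) == 0:
        raise ValueError("cannot detect modes without declared values")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    lo = 0.0 if anchor_zero else float(values.min())
    hi = float(values.max())
    if hi <= lo:
        edges = np.linspace(lo, hi if hi > lo else lo + 1.0, n_bins + 1)
        counts = np.zeros(n_bins, dtype=int)
        counts[0] = len(values)
        return ModeDetection(
            nutrient=nutrient,
            bin_edges=edges,
            counts=counts,
            potential_mode_bins=(0,),
            mode_runs=((0, 0),),
            modes=(float(values[0]),),
            cuts=(),
        )

    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    potential = _potential_mode_bins(counts)
    if not potential:
        # perfectly flat histogram (every bin ties its neighbours): no
        # evidence of distinct offers — unimodal, mode at the range centre
        return ModeDetection(
            nutrient=nutrient,
            bin_edges=edges,
            counts=counts,
            potential_mode_bins=(),
            mode_runs=(),
            modes=((lo + hi) / 2.0,),
            cuts=(),
        )

    runs: list[tuple[int, int]] = []
    for b in potential:
        if runs and b == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], b)
        else:
            runs.append((b, b))
    # mode of a run = centre of the run's full span (reduces to the bin
    # midpoint for an isolated potential-mode bin)
    modes = tuple((edges[first] + edges[last + 1]) / 2.0 for first, last in runs)
    cuts = tuple((a + b) / 2.0 for a, b in zip(modes, modes[1:]))
    return ModeDetection(
        nutrient=nutrient,
        bin_edges=edges,
        counts=counts,
        potential_mode_bins=tuple(potential),
        mode_runs=tuple(runs),
        modes=modes,
        cuts=cuts,
    )


@dataclass(frozen=True)
class CategoryPartition:
    """Assignment of a category's products to refined sub-categories."""

    category: str
    nutrients: tuple[Nutrient, ...]
    detections: dict[Nutrient, ModeDetection]
    labels: pd.Series  # sub-category label per product (index = input index)
    cell_index: pd.DataFrame  # per-nutrient interval index per product
    n_cells_expected: int  # product of per-nutrient mode counts
    cell_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_cells_nonempty(self) -> int:
        return len(self.cell_counts)

    def to_dict(self) -> dict:
        return {
            "category": self.category,
            "n_cells_expected": self.n_cells_expected,
            "n_cells_nonempty": self.n_cells_nonempty,
            "cell_counts": dict(self.cell_counts),
            "detections": {n.value: d.to_dict() for n, d in self.detections.items()},
        }


def _interval_label(nutrient: Nutrient, idx: int, n_intervals: int) -> str:
    return f"{nutrient.value}:{idx + 1}/{n_intervals}"


def split_category(
    df: pd.DataFrame,
    detections: dict[Nutrient, ModeDetection],
    category: str = "",
) -> CategoryPartition:
    """Split a category along each nutrient's mode cut points.

    Sub-categories are the Cartesian product of per-nutrient intervals;
    membership is left-closed (a product exactly at a cut point belongs
    to the upper interval, so "less than c" is the lower group).  Cells
    with no products are dropped from the output but remain counted in
    ``n_cells_expected``.
    """
    nutrients = tuple(detections)
    cell_index = pd.DataFrame(index=df.index)
    parts: list[pd.Series] = []
    for nutrient in nutrients:
        det = detections[nutrient]
        cuts = np.asarray(det.cuts, dtype=float)
        values = df[nutrient.value].to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValueError(
                f"undeclared {nutrient.value} in analyzable subset; filter upstream"
            )
        idx = np.searchsorted(cuts, values, side="right")
        cell_index[nutrient.value] = idx
        n_int = det.n_modes if det.n_modes else 1
        parts.append(
            pd.Series(
                [_interval_label(nutrient, i, n_int) for i in idx], index=df.index
            )
        )
    n_expected = int(np.prod([max(detections[n].n_modes, 1) for n in nutrients])) if nutrients else 1

    if parts:
        suffix = parts[0].str.cat(parts[1:], sep=",") if len(parts) > 1 else parts[0]
        labels = (category + "|" if category else "") + suffix
    else:
        labels = pd.Series(category, index=df.index)
    counts = labels.value_counts().to_dict()
    return CategoryPartition(
        category=category,
        nutrients=nutrients,
        detections=dict(detections),
        labels=labels,
        cell_index=cell_index,
        n_cells_expected=n_expected,
        cell_counts={str(k): int(v) for k, v in counts.items()},
    )
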
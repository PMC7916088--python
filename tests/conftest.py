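import numpy as np
import pandas as pd
import pytest

from nutriprofile.core import Basis, NUTRIENT_COLUMNS


def make_products(
    category: str = "cat",
    basis: Basis = Basis.SOLID,
    **columns,
) -> pd.DataFrame:
    """Build a product table from per-nutrient value lists (NaN = missing)."""
    n = max((len(v) for v in columns.values()), default=0)
    data = {
        "product_id": [f"{category}-{i:04d}" for i in range(n)],
        "category": category,
        "basis": basis.value,
    }
    for col in NUTRIENT_COLUMNS:
        vals = columns.get(col, [np.nan] * n)
        assert len(vals) == n
        data[col] = [float(v) if v is not None else np.nan for v in vals]
    for extra in ("salt", "rating"):
        if extra in columns:
            data[extra] = [
                float(v) if v is not None else np.nan for v in columns[extra]
            ]
    return pd.DataFrame(data)


@pytest.fixture
def margarine():
    from nutriprofile.synth import margarine_fixture

    df, truth = margarine_fixture()
    return df, truth


def oracle_potential_modes(counts) -> list[int]:
    """Direct, loop-based evaluation of the convexity predicate."""
    counts = list(counts)
    n = len(counts)
    if n == 1:
        return [0]
    out = []
    for i in range(n):
        if i == 0:
            if counts[0] > counts[1]:
                out.append(0)
        elif i == n - 1:
            if counts[-1] > counts[-2]:
                out.append(n - 1)
        elif counts[i] > (counts[i - 1] + counts[i + 1]) / 2:
            out.append(i)
    return out


def oracle_common_percentile(df, relevant, x, fixed=None):
    """Exhaustive linear scan over all joint order-statistic levels.

    Independent of the bisection implementation: walks i = 1..n,
    recomputes per-nutrient cuts from sorted copies and counts joint
    compliance directly, returning the first level reaching x%.
    """
    fixed = dict(fixed or {})
    n = len(df)
    cols = {nut: df[nut.value].to_numpy(dtype=float) for nut in relevant}
    srt = {nut: np.sort(v) for nut, v in cols.items()}
    best = None
    for i in range(1, n + 1):
        thr = {}
        for nut in relevant:
            if nut in fixed:
                thr[nut] = fixed[nut]
            elif nut.disqualifying:
                thr[nut] = srt[nut][i - 1]
            else:
                thr[nut] = srt[nut][n - i]
        ok = np.ones(n, dtype=bool)
        for nut, t in thr.items():
            v = cols[nut]
            ok &= (v <= t) if nut.disqualifying else (v >= t)
        cov = ok.mean()
        if cov >= x / 100.0:
            best = (100.0 * i / n, thr, float(cov))
            break
    if best is None:  # unattainable under the fixed constraints
        best = (100.0, thr, float(cov))
    return best
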
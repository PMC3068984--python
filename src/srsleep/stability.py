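"""Stability-hypothesis testing: does one line's curve lie constantly above another's?

For each quantity of interest (a band's mean relative power within a
vigilance state, or a transition pair's hourly frequency) the group means
across animals form one curve per line over the 23 ZT points.  At each ZT
point the common median across the groups is subtracted, and the signed
excesses of two groups are compared with a Wilcoxon matched-pairs
signed-ranks test over the ZT points (exact null distribution for n <= 25,
normal approximation with tie correction above; zero differences dropped).
A pair is labelled *stable* when the test is significant and the sign of
the excess difference is constant in at least 90% of the points — the
operational reading of "stable and continuously above/below".
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sct

__all__ = [
    "StabilityResult",
    "common_median_excess",
    "stability_test",
    "stability_screen",
]

MIN_PAIRED_POINTS = 10


@dataclass
class StabilityResult:
    group_a: str
    group_b: str
    n_pairs: int
    statistic: float
    p: float
    direction: str          # "A>B", "B>A" or "none"
    stable: bool
    sign_constancy: float   # fraction of non-zero differences sharing the majority sign

    def as_dict(self) -> dict:
        return {
            "group_a": self.group_a, "group_b": self.group_b, "n": self.n_pairs,
            "W": self.statistic, "p": self.p, "direction": self.direction,
            "stable": self.stable, "sign_constancy": self.sign_constancy,
        }


def common_median_excess(series: pd.DataFrame) -> pd.DataFrame:
    """Signed excess of each group over the per-ZT common median.

    ``series`` holds one column per group, indexed by ZT point; the common
    median at each point is the median of the group values there.  Points
    missing for all groups are dropped; points missing for some groups are
    kept (the median uses the available values) with NaN excess for the
    missing groups.
    """
    series = series.dropna(how="all")
    med = series.median(axis=1, skipna=True)
    return series.sub(med, axis=0)


def stability_test(
    excess_a: pd.Series,
    excess_b: pd.Series,
    *,
    alpha: float = 0.05,
    sign_fraction: float = 0.9,
    name_a: str = "A",
    name_b: str = "B",
) -> StabilityResult:
    """Wilcoxon matched-pairs signed-ranks test on two excess series.

    Pairs with a missing value on either side are dropped; at least 10
    paired points are required.  Zero differences are dropped before
    ranking.  The direction is the sign of the median difference when the
    test is significant, otherwise "none".
    """
    a = pd.Series(excess_a)
    b = pd.Series(excess_b)
    df = pd.concat({"a": a, "b": b}, axis=1).dropna()
    n = len(df)
    if n < MIN_PAIRED_POINTS:
        raise ValueError(f"need at least {MIN_PAIRED_POINTS} paired points, got {n}")
    d = (df["a"] - df["b"]).to_numpy()
    nz = d[d != 0.0]
    if nz.size == 0:
        return StabilityResult(name_a, name_b, n, float("nan"), 1.0, "none", False, 0.0)
    method = "exact" if nz.size <= 25 else "approx"
    res = sct.wilcoxon(nz, zero_method="wilcox", alternative="two-sided", method=method)
    p = float(res.pvalue)
    n_pos = int((nz > 0).sum())
    constancy = max(n_pos, nz.size - n_pos) / nz.size
    significant = p < alpha
    if significant:
        direction = f"{name_a}>{name_b}" if np.median(nz) > 0 else f"{name_b}>{name_a}"
    else:
        direction = "none"
    stable = significant and constancy >= sign_fraction
    return StabilityResult(name_a, name_b, n, float(res.statistic), p, direction,
                           stable, float(constancy))


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out


def stability_screen(
    series_map: dict,
    *,
    alpha: float = 0.05,
    sign_fraction: float = 0.9,
) -> pd.DataFrame:
    """Run the stability test for every quantity and every group pair.

    ``series_map`` maps a quantity label (e.g. ``("NREMS", "theta")`` or
    ``"NREMS->REMS"``) to a DataFrame of group-mean values (index = ZT
    points, one column per group).  The full table is emitted — every
    quantity x pair, no selective reporting — with an informational
    Benjamini-Hochberg column alongside the raw p values (the headline
    ``stable`` flag uses the uncorrected level, as in the source analysis
    convention of reporting nominal p < 0.05).
    """
    rows = []
    for quantity, series in series_map.items():
        excess = common_median_excess(series)
        for ga, gb in combinations(series.columns, 2):
            r = stability_test(
                excess[ga], excess[gb],
                alpha=alpha, sign_fraction=sign_fraction, name_a=str(ga), name_b=str(gb),
            )
            row = {"quantity": quantity if isinstance(quantity, str) else "/".join(map(str, quantity))}
            row.update(r.as_dict())
            rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        table["p_bh"] = _benjamini_hochberg(table["p"].to_numpy())
    return table
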
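"""Group statistics: MANOVA (Wilks/Rao), univariate F, LSD contrasts, ANOVA, band AUC.

The battery applied per time interval: a one-way MANOVA over a family of
responses (normed durations, normed transition frequencies, or band-power
AUCs) tests the global breeding-line effect via Wilks' lambda with Rao's F
approximation; only when the global test is significant do univariate F
tests follow (at a Bonferroni-adjusted alpha of 0.05/m for m responses),
and pairwise group contrasts use Fisher's LSD t statistics with the pooled
within-group error, judged at alpha/(number of pairs) ("Bonferroni
modified LSD").  Mean REMS episode length is compared by plain one-way
ANOVA.  Band-power AUCs come from the trapezoid rule over hourly mean
relative powers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sct

from srsleep.metrics import TimeInterval

__all__ = [
    "AnovaResult",
    "MANOVAResult",
    "band_auc",
    "manova",
    "lsd_contrasts",
    "oneway_anova",
]


@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    n_used: int
    n_excluded: int = 0

    def __str__(self) -> str:
        return f"F_({self.df1},{self.df2}) = {self.F:.3f}; p = {self.p:.4g} (N = {self.n_used})"


@dataclass
class MANOVAResult:
    wilks_lambda: float
    F_approx: float
    df1: float
    df2: float
    p: float
    n_used: int
    responses: list
    alpha: float
    significant: bool
    univariate: dict = field(default_factory=dict)   # response -> AnovaResult + flag
    univariate_alpha: float = np.nan
    contrasts: dict | None = None                    # response -> contrast table

    def __str__(self) -> str:
        return (
            f"Wilks lambda = {self.wilks_lambda:.4f}; "
            f"F_({self.df1:g},{self.df2:g}) = {self.F_approx:.3f}; p = {self.p:.4g} "
            f"(N = {self.n_used}, m = {len(self.responses)})"
        )


def band_auc(profile: pd.DataFrame, interval: TimeInterval) -> dict:
    """Trapezoid-rule AUC of each band's hourly profile within an interval.

    ``profile`` is indexed by ZT hour (hour h summarises [h-1, h), as
    produced by :func:`srsleep.features.hourly_band_profile`); the points
    belonging to an interval are the hours whose span lies inside it, at
    unit (1 h) spacing.  Interior missing hours are linearly interpolated;
    missing endpoint hours are dropped with a warning; fewer than two
    non-missing points make the AUC undefined (NaN).
    """
    hours = np.asarray(profile.index, dtype=float)
    sel = interval.contains(hours - 1.0)
    hrs = hours[sel]
    out = {}
    for band in profile.columns:
        y = profile.loc[sel, band].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if ok.sum() < 2:
            out[band] = float("nan")
            continue
        first, last = np.flatnonzero(ok)[[0, -1]]
        if first > 0 or last < y.size - 1:
            warnings.warn(
                f"band {band!r}, interval {interval.name}: missing endpoint hours "
                "dropped from the AUC", stacklevel=2,
            )
        x = hrs[first:last + 1]
        yy = y[first:last + 1]
        bad = ~np.isfinite(yy)
        if bad.any():
            yy[bad] = np.interp(x[bad], x[~bad], yy[~bad])
        out[band] = float(np.trapezoid(yy, x))
    return out


def _group_arrays(values: np.ndarray, groups: np.ndarray):
    labels = pd.unique(pd.Series(groups))
    return labels, [values[groups == g] for g in labels]


def oneway_anova(values, groups, *, alpha: float = 0.05) -> AnovaResult:
    """One-way fixed-effects ANOVA; animals with a missing response are
    excluded listwise for that response."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = np.isfinite(values)
    n_excluded = int((~ok).sum())
    values, groups = values[ok], groups[ok]
    labels, samples = _group_arrays(values, groups)
    samples = [s for s in samples if s.size >= 1]
    if len(samples) < 2 or any(s.size < 2 for s in samples):
        raise ValueError("need at least 2 groups with at least 2 observations each")
    F, p = sct.f_oneway(*samples)
    df1 = len(samples) - 1
    df2 = values.size - len(samples)
    return AnovaResult(F=float(F), df1=df1, df2=df2, p=float(p),
                       n_used=int(values.size), n_excluded=n_excluded)


def lsd_contrasts(values, groups, *, alpha: float = 0.05, n_comparisons: int | None = None) -> pd.DataFrame:
    """Fisher LSD pairwise t tests with a Bonferroni-adjusted decision level.

    The t statistic for groups a, b is (mean_a - mean_b) /
    sqrt(MSE * (1/n_a + 1/n_b)) with the pooled within-group mean square
    error and its df; significance is judged at alpha / n_comparisons
    (default: the number of group pairs).  Raw two-sided p values are
    reported alongside the decision.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = np.isfinite(values)
    values, groups = values[ok], groups[ok]
    labels, samples = _group_arrays(values, groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_err = values.size - len(labels)
    mse = ssw / df_err
    if mse <= 0:
        raise ValueError("zero within-group mean square error (degenerate data)")
    pairs = list(combinations(range(len(labels)), 2))
    m = n_comparisons if n_comparisons is not None else len(pairs)
    adj_alpha = alpha / m
    rows = []
    for i, j in pairs:
        a, b = samples[i], samples[j]
        diff = a.mean() - b.mean()
        se = np.sqrt(mse * (1.0 / a.size + 1.0 / b.size))
        t = diff / se
        p_raw = 2.0 * sct.t.sf(abs(t), df_err)
        rows.append({
            "group_a": labels[i], "group_b": labels[j],
            "mean_diff": diff, "t": t, "df": df_err, "p_raw": p_raw,
            "alpha_adjusted": adj_alpha, "significant": p_raw < adj_alpha,
        })
    return pd.DataFrame(rows)


def _sscp(X: np.ndarray, groups: np.ndarray):
    labels = pd.unique(pd.Series(groups))
    grand = X.mean(axis=0)
    p = X.shape[1]
    B = np.zeros((p, p))
    W = np.zeros((p, p))
    for g in labels:
        Xg = X[groups == g]
        d = Xg.mean(axis=0) - grand
        B += Xg.shape[0] * np.outer(d, d)
        R = Xg - Xg.mean(axis=0)
        W += R.T @ R
    return B, W, len(labels)


def manova(
    responses: pd.DataFrame,
    groups,
    *,
    alpha: float = 0.05,
    univariate_divisor: int | None = None,
) -> MANOVAResult:
    """One-way MANOVA via Wilks' lambda and Rao's F approximation.

    Rows with any missing response are dropped (complete-case); the N used
    is reported so exclusions stay visible.  Univariate follow-up F tests
    are evaluated at alpha/m (m = number of responses, or an explicit
    ``univariate_divisor``), and pairwise LSD contrasts — computed only when
    the global test is significant, the gatekeeping hierarchy — at
    alpha/(number of group pairs).
    """
    responses = pd.DataFrame(responses)
    groups = np.asarray(groups)
    keep = responses.notna().all(axis=1).to_numpy()
    X = responses.to_numpy(dtype=float)[keep]
    g = groups[keep]
    n, p = X.shape
    B, W, k = _sscp(X, g)
    if k < 2:
        raise ValueError("need at least two groups")
    if n - k < p or np.linalg.matrix_rank(W) < p:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.nan_to_num(np.corrcoef(X, rowvar=False))
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise np.linalg.LinAlgError(
            "within-group SSCP is singular; most collinear responses: "
            f"{responses.columns[i]!r} and {responses.columns[j]!r}"
        )
    lam = float(np.linalg.det(W) / np.linalg.det(W + B))
    q = k - 1
    v = n - k
    df1 = p * q
    denom = p * p + q * q - 5
    t = np.sqrt((p * p * q * q - 4.0) / denom) if denom > 0 else 1.0
    df2 = t * (v - (p - q + 1) / 2.0) - (df1 - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    F = (1.0 - lam_t) / lam_t * df2 / df1
    p_val = float(sct.f.sf(F, df1, df2))
    significant = p_val < alpha

    m = univariate_divisor if univariate_divisor is not None else p
    uni_alpha = alpha / m
    univariate = {}
    for col in responses.columns:
        res = oneway_anova(responses[col].to_numpy(dtype=float)[keep], g, alpha=uni_alpha)
        univariate[col] = {"anova": res, "significant": res.p < uni_alpha}

    contrasts = None
    if significant:
        contrasts = {
            col: lsd_contrasts(responses[col].to_numpy(dtype=float)[keep], g, alpha=alpha)
            for col in responses.columns
        }
    return MANOVAResult(
        wilks_lambda=lam, F_approx=float(F), df1=float(df1), df2=float(df2),
        p=p_val, n_used=n, responses=list(responses.columns), alpha=alpha,
        significant=significant, univariate=univariate, univariate_alpha=uni_alpha,
        contrasts=contrasts,
    )
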
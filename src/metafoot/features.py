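"""Untargeted LC-MS feature-table screening and kinetic group comparisons.

Feature tables are pandas DataFrames in the style of an XCMS-online /
CAMERA export, one row per aligned feature with at least::

    id, mz, rt_s, ln_fc, p_value, max_intensity

plus optional per-sample area columns (``area_<time>h_r<rep>``).  The
screening steps are: a three-way significance/intensity filter
(|ln fold change| > 1, P < 0.05, max intensity > 1e7; strict inequalities),
removal of features overlapping already-targeted compounds (inclusive
+/-0.001 m/z and +/-30 s windows), and a split by direction of change.

Group comparisons between decreasing and increasing features use a
pooled-variance two-sample t-test on fitted t50s and a Wilcoxon rank-sum
(Mann-Whitney) test on 90% usage windows; both statistic conventions
(rank-sum W and U) are reported because the literature mixes them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FilterThresholds",
    "filter_features",
    "dedup_targeted",
    "split_directions",
    "compare_t50_groups",
    "compare_window_groups",
    "area_columns",
]


@dataclass(frozen=True)
class FilterThresholds:
    """Strict screening thresholds for untargeted features."""

    ln_fc_min: float = 1.0
    p_max: float = 0.05
    intensity_min: float = 1e7


def filter_features(features: pd.DataFrame,
                    thresholds: FilterThresholds | None = None
                    ) -> pd.DataFrame:
    """Keep features with |ln_fc| > ln_fc_min, p < p_max and
    max_intensity > intensity_min (all strict); order preserved."""
    th = thresholds or FilterThresholds()
    if min(th.ln_fc_min, th.p_max, th.intensity_min) <= 0:
        raise ValueError("thresholds must be positive")
    keep = ((features["ln_fc"].abs() > th.ln_fc_min)
            & (features["p_value"] < th.p_max)
            & (features["max_intensity"] > th.intensity_min))
    return features.loc[keep].copy()


def dedup_targeted(features: pd.DataFrame, targets: pd.DataFrame,
                   mz_tol: float = 0.001, rt_tol_s: float = 30.0
                   ) -> pd.DataFrame:
    """Drop features overlapping any targeted reference within the
    inclusive tolerances |dmz| <= mz_tol AND |drt| <= rt_tol_s."""
    if mz_tol <= 0 or rt_tol_s <= 0:
        raise ValueError("tolerances must be positive")
    if targets.empty:
        return features.copy()
    mz = features["mz"].to_numpy()[:, None]
    rt = features["rt_s"].to_numpy()[:, None]
    tmz = targets["mz"].to_numpy()[None, :]
    trt = targets["rt_s"].to_numpy()[None, :]
    # inclusive bounds; epsilon keeps exact-boundary differences (e.g.
    # 150.001 - 150.0) inside the window despite float representation
    hit = ((np.abs(mz - tmz) <= mz_tol + 1e-12)
           & (np.abs(rt - trt) <= rt_tol_s + 1e-9)).any(axis=1)
    return features.loc[~hit].copy()


def area_columns(features: pd.DataFrame) -> list[str]:
    return [c for c in features.columns if c.startswith("area_")]


def split_directions(features: pd.DataFrame, noise_tol: float = 0.0
                     ) -> pd.DataFrame:
    """Annotate each feature as decreasing or increasing over the course.

    Precomputed ``ln_fc`` takes precedence (the upstream tool defines fold
    change); otherwise the sign of last-to-first mean area change is used.
    Changes with |ln_fc| <= ``noise_tol`` are flagged ``tie``.
    """
    out = features.copy()
    if "ln_fc" in out.columns and out["ln_fc"].notna().all():
        change = out["ln_fc"].to_numpy(dtype=float)
    else:
        cols = area_columns(out)
        if len(cols) < 2:
            raise ValueError("need area columns spanning >= 2 time points")
        first, last = cols[0], cols[-1]
        with np.errstate(divide="ignore"):
            change = np.log(out[last].to_numpy() / out[first].to_numpy())
    out["direction"] = np.where(change < 0, "decreasing", "increasing")
    out.loc[np.abs(change) <= noise_tol, "direction"] = "tie"
    return out


def compare_t50_groups(dec_t50s, inc_t50s) -> dict[str, float]:
    """Pooled-variance two-sample t-test on midpoint times.

    Returns the signed t statistic (decreasing minus increasing), the
    structural degrees of freedom n1 + n2 - 2, the two-sided p-value and
    the mean difference in hours.
    """
    x = np.asarray(dec_t50s, dtype=float)
    y = np.asarray(inc_t50s, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("zero pooled variance")
    res = stats.ttest_ind(x, y, equal_var=True)
    return {
        "t_statistic": float(res.statistic),
        "df": len(x) + len(y) - 2,
        "p_value": float(res.pvalue),
        "mean_difference": float(np.mean(x) - np.mean(y)),
    }


def compare_window_groups(dec_windows, inc_windows,
                          exact_max_n: int = 20) -> dict[str, float]:
    """Wilcoxon rank-sum comparison of 90% usage windows.

    Reports both statistic conventions: the rank-sum W of the first group
    and the Mann-Whitney U (W = U + n1(n1+1)/2).  The p-value is from the
    exact permutation distribution when n1 + n2 <= ``exact_max_n`` and
    there are no ties, else the normal approximation; ties are handled by
    midranks and flagged.
    """
    x = np.asarray(dec_windows, dtype=float)
    y = np.asarray(inc_windows, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    ties = len(np.unique(np.concatenate([x, y]))) < n1 + n2
    method = "exact" if (n1 + n2 <= exact_max_n and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u = float(res.statistic)
    return {
        "U": u,
        "W": u + n1 * (n1 + 1) / 2.0,
        "p_value": float(res.pvalue),
        "median_difference": float(np.median(x) - np.median(y)),
        "ties": ties,
        "method": method,
    }
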
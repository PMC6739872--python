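"""Behavioral-ratings analysis.

Per-subject Pearson correlation of each rating measure with the spatial
scale index, tested against zero across subjects; within-subject
z-transforms (feeding the parametric-modulation regressors); and a
one-way ANOVA across the six scales with Tukey-Kramer post-hoc pairwise
comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class RatingScaleCorrelation:
    """Per-subject correlation of one measure with scale, and the group
    two-tailed one-sample t-test of those r values against zero."""

    measure: str
    per_subject_r: np.ndarray
    mean_r: float
    t: float
    p: float
    df: int
    n_excluded: int


def z_transform_within_subject(values: np.ndarray):
    """Standardise one subject's ratings to mean 0, sd 1 (sample sd).

    A zero-variance vector returns zeros with a flag instead of raising.
    Returns (z, degenerate_flag).
    """
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=1)
    if sd == 0:
        return np.zeros_like(v), True
    return (v - v.mean()) / sd, False


def correlate_with_scale(ratings, measure: str) -> RatingScaleCorrelation:
    """Pearson correlation of a rating measure with scale index (1-6),
    per subject, then a two-tailed one-sample t-test across subjects.

    Location-level measures use the subject's per-scale mean rating.
    Subjects with constant ratings have undefined r and are excluded
    (counted).
    """
    rs = []
    n_excluded = 0
    for subj in ratings.subjects:
        sub = ratings.values_for(subj, measure)
        per_scale = sub.groupby("scale")[measure].mean()
        if len(per_scale) < 2:
            n_excluded += 1
            continue
        x = per_scale.index.to_numpy(float)
        y = per_scale.to_numpy(float)
        if y.std() == 0:
            n_excluded += 1
            continue
        rs.append(stats.pearsonr(x, y).statistic)
    rs = np.asarray(rs)
    if len(rs) < 2:
        raise ValueError("fewer than 2 subjects with defined correlations")
    t, p = stats.ttest_1samp(rs, 0.0)
    return RatingScaleCorrelation(measure=measure, per_subject_r=rs,
                                  mean_r=float(rs.mean()), t=float(t),
                                  p=float(p), df=len(rs) - 1,
                                  n_excluded=n_excluded)


def anova_scales(ratings, measure: str, alpha: float = 0.01):
    """One-way ANOVA of a measure across the six scales with Tukey-Kramer
    post-hoc pairwise comparisons (the Kramer adjustment handles
    unbalanced groups).

    Observations pool subjects; scales with fewer than 2 observations are
    excluded with a warning. Returns a dict with the omnibus F and p and
    a pairwise table (scale_a, scale_b, meandiff, p_adj, reject).
    """
    table = (ratings.location_ratings
             if ratings.is_location_measure(measure)
             else ratings.scale_ratings)
    groups, labels = [], []
    for scale, grp in table.groupby("scale"):
        vals = grp[measure].to_numpy(float)
        if len(vals) < 2:
            warnings.warn(f"scale {scale} has fewer than 2 observations of "
                          f"{measure}; excluded", stacklevel=2)
            continue
        groups.append(vals)
        labels.append(int(scale))
    if len(groups) < 2:
        raise ValueError("need at least 2 scales with >= 2 observations")
    F, p = stats.f_oneway(*groups)
    values = np.concatenate(groups)
    group_ids = np.concatenate([np.full(len(g), lab)
                                for g, lab in zip(groups, labels)])
    tk = pairwise_tukeyhsd(values, group_ids, alpha=alpha)
    pairwise = pd.DataFrame({
        "scale_a": [int(a) for a in tk.groupsunique[
            np.array([g[0] for g in _pair_indices(len(labels))])]],
        "scale_b": [int(b) for b in tk.groupsunique[
            np.array([g[1] for g in _pair_indices(len(labels))])]],
        "meandiff": tk.meandiffs,
        "p_adj": tk.pvalues,
        "reject": tk.reject,
    })
    return {"F": float(F), "p": float(p), "pairwise": pairwise,
            "alpha": alpha, "scales": labels}


def _pair_indices(k: int):
    return [(i, j) for i in range(k) for j in range(i + 1, k)]
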
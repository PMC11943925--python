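"""Per-bucket two-group screening.

Each bucket of the normalized table is tested for a location difference
between the control and study groups.  Family-wise error across the K
buckets is controlled by Bonferroni: a bucket is significant when its
p-value falls below ``alpha_total / K``.  Alongside the p-value the
Mann-Whitney AUC (probability that a random study sample exceeds a random
control sample in that bucket) and the log2 fold change of group means are
reported, mirroring standard NMR biomarker-screening practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CONTROL, STUDY, BucketTable, ValidationError

__all__ = [
    "ComparisonResult",
    "two_group_test",
    "bonferroni_alpha",
    "auc_group_membership",
    "compare_buckets",
]


@dataclass
class ComparisonResult:
    """Per-bucket screening results for one control-vs-study comparison.

    ``per_bucket`` is indexed by bucket id with columns ``p_value``,
    ``auc``, ``log2_fold_change``, ``significant_p`` and ``significant_auc``.
    """

    per_bucket: pd.DataFrame
    alpha_total: float
    alpha_bonferroni: float
    n_buckets_tested: int
    n_significant: int
    auc_threshold: float
    method: str

    def significant_buckets(self) -> list[str]:
        return list(self.per_bucket.index[self.per_bucket["significant_p"]])


def _check_group(x, name):
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValidationError(f"group {name!r} needs >= 2 values, has {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValidationError(f"group {name!r} contains non-finite values")
    return x


def two_group_test(xs, ys, method: str = "welch") -> float:
    """Two-sided p-value for a location difference between two groups.

    ``method='welch'`` (default) is the unequal-variance t-test with
    Welch-Satterthwaite degrees of freedom; ``method='ranksum'`` is the
    two-sided Mann-Whitney U test.  When both groups have zero variance the
    p-value is 1.0 for equal means and 0.0 otherwise.
    """
    xs = _check_group(xs, "xs")
    ys = _check_group(ys, "ys")
    if method == "welch":
        if np.var(xs) == 0.0 and np.var(ys) == 0.0:
            return 1.0 if np.mean(xs) == np.mean(ys) else 0.0
        return float(stats.ttest_ind(xs, ys, equal_var=False).pvalue)
    if method == "ranksum":
        return float(stats.mannwhitneyu(xs, ys, alternative="two-sided").pvalue)
    raise ValueError(f"unknown method {method!r}")


def bonferroni_alpha(n_buckets: int, alpha_total: float = 0.05) -> float:
    """Per-test alpha controlling family-wise error: ``alpha_total / K``."""
    if n_buckets < 1:
        raise ValidationError(f"n_buckets must be >= 1, got {n_buckets}")
    return alpha_total / n_buckets


def auc_group_membership(xs, ys) -> float:
    """Mann-Whitney concordance: fraction of (x, y) pairs with y > x.

    Ties count 0.5.  Equals the area under the ROC curve for classifying
    group membership from the single feature; 0.5 means no discrimination,
    0 or 1 perfect discrimination (in either direction).
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size == 0 or ys.size == 0:
        raise ValidationError("both groups must be non-empty")
    u_y = stats.mannwhitneyu(ys, xs, alternative="two-sided").statistic
    return float(u_y) / (xs.size * ys.size)


def _vector_welch(xc: np.ndarray, xs: np.ndarray) -> np.ndarray:
    """Column-wise Welch p-values with the zero-variance convention."""
    res = stats.ttest_ind(xc, xs, axis=0, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if np.any(degenerate):
        equal = np.isclose(xc.mean(axis=0), xs.mean(axis=0))
        p = np.where(degenerate & equal, 1.0, p)
        p = np.where(degenerate & ~equal, 0.0, p)
    return p


def _vector_ranksum(xc: np.ndarray, xs: np.ndarray) -> np.ndarray:
    res = stats.mannwhitneyu(xc, xs, axis=0, alternative="two-sided")
    return np.asarray(res.pvalue, dtype=float)


def _vector_auc(xc: np.ndarray, xs: np.ndarray) -> np.ndarray:
    """Column-wise AUC via midranks (ties handled exactly)."""
    n_c, n_s = xc.shape[0], xs.shape[0]
    pooled = np.vstack([xc, xs])
    ranks = stats.rankdata(pooled, axis=0)
    u_study = ranks[n_c:].sum(axis=0) - n_s * (n_s + 1) / 2.0
    return u_study / (n_c * n_s)


def compare_buckets(
    table: BucketTable,
    alpha_total: float = 0.05,
    auc_threshold: float = 0.75,
    method: str = "welch",
) -> ComparisonResult:
    """Screen every bucket of a normalized table for a group difference.

    Requires a normalized table (statistics are defined on total-intensity
    normalized data) containing both groups.  A bucket is
    ``significant_p`` when its two-sided p-value is below the Bonferroni
    threshold ``alpha_total / K``, and ``significant_auc`` when its AUC is
    at least ``auc_threshold`` or at most ``1 - auc_threshold``.
    """
    if not table.normalized:
        raise ValidationError(
            "compare_buckets requires a total-intensity normalized table; "
            "apply normalize_total_intensity first"
        )
    mask_c = table.group_mask(CONTROL)
    mask_s = table.group_mask(STUDY)
    if mask_c.sum() < 2 or mask_s.sum() < 2:
        raise ValidationError(
            f"need >= 2 samples per group, found control={int(mask_c.sum())}, "
            f"study={int(mask_s.sum())}"
        )
    xc = table.values[mask_c]
    xs = table.values[mask_s]
    k = table.n_buckets
    alpha_b = bonferroni_alpha(k, alpha_total)

    if method == "welch":
        p = _vector_welch(xc, xs)
    elif method == "ranksum":
        p = _vector_ranksum(xc, xs)
    else:
        raise ValueError(f"unknown method {method!r}")
    auc = _vector_auc(xc, xs)
    mean_c = xc.mean(axis=0)
    mean_s = xs.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(mean_s / mean_c)
    log2fc = np.where(np.isnan(log2fc) & (mean_c == 0) & (mean_s == 0), 0.0, log2fc)

    sig_p = p < alpha_b
    sig_auc = (auc >= auc_threshold) | (auc <= 1.0 - auc_threshold)
    per_bucket = pd.DataFrame(
        {
            "p_value": p,
            "auc": auc,
            "log2_fold_change": log2fc,
            "significant_p": sig_p,
            "significant_auc": sig_auc,
        },
        index=pd.Index(table.bucket_ids, name="bucket_id"),
    )
    return ComparisonResult(
        per_bucket=per_bucket,
        alpha_total=alpha_total,
        alpha_bonferroni=alpha_b,
        n_buckets_tested=k,
        n_significant=int(sig_p.sum()),
        auc_threshold=auc_threshold,
        method=method,
    )
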
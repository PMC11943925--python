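"""Shared constructions used by several test modules."""

import numpy as np

from uromet.io import BucketTable


def shifted_bucket_table(k=114, n_shifted=17, n_per_group=15, shift_sds=10.0):
    """Deterministic two-group table where a chosen subset of buckets is
    shifted by ``shift_sds`` pooled standard deviations.

    Both groups share the same within-group value pattern, so unshifted
    buckets have exactly equal group means (their tests cannot fire), while
    the shifted buckets are low-abundance resonances whose study-group
    values are raised by ``shift_sds`` pooled SDs.  Keeping the shifted
    mass tiny relative to the total means total-intensity normalization
    does not smear the effect into the unshifted buckets.

    Returns ``(table, shifted_bucket_ids)``.
    """
    n = 2 * n_per_group
    # deterministic per-sample, per-bucket variation, repeated identically
    # in the two groups so unshifted buckets have exactly equal group means
    base = np.cos(np.add.outer(7.3 * np.arange(n_per_group),
                               1.7 * np.arange(k)))
    pattern = np.vstack([base, base])  # (n, k), matched between groups
    shifted_cols = np.arange(n_shifted)
    ordinary = np.arange(n_shifted, k)
    bucket_mean = 1.0 + 0.1 * np.cos(np.arange(k))
    values = bucket_mean[None, :] * (1.0 + 0.05 * pattern)
    values[:, shifted_cols] *= 1e-3
    pooled_sd = values[:, shifted_cols].std(axis=0, ddof=1)
    values[n_per_group:, shifted_cols] += shift_sds * pooled_sd
    bucket_ids = [f"b{j}" for j in range(k)]
    table = BucketTable(
        sample_ids=[f"s{i}" for i in range(n)],
        groups=["control"] * n_per_group + ["study"] * n_per_group,
        weeks=[1] * n,
        bucket_ids=bucket_ids,
        values=values,
    )
    return table, [bucket_ids[j] for j in shifted_cols]
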
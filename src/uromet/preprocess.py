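"""Spectrum -> normalized bucket matrix.

Three steps take raw 1D traces to the matrix the statistics operate on:

1. :func:`reference_to_tsp` — shift the ppm axis so the TSP reference
   singlet sits at exactly 0.0 ppm;
2. :func:`integrate_buckets` — trapezoidal integration of intensity over
   each scheme bucket on the native ppm grid;
3. :func:`normalize_total_intensity` — divide every sample row by its own
   total so rows sum to 1, removing dilution differences between urines.
"""

from __future__ import annotations

import warnings

import numpy as np

from .io import BucketScheme, BucketTable, Spectrum, ValidationError

__all__ = [
    "reference_to_tsp",
    "integrate_buckets",
    "normalize_total_intensity",
]


def reference_to_tsp(
    spectrum: Spectrum,
    search_window: tuple[float, float] = (0.3, -0.3),
) -> tuple[Spectrum, float]:
    """Reference the ppm axis to TSP at 0.0 ppm.

    The dominant peak inside ``search_window`` (descending ppm interval,
    default 0.3 to -0.3) is taken to be the TSP singlet and the whole axis
    is shifted so that its intensity argmax lands at exactly 0.000 ppm.

    Returns the shifted spectrum and the applied shift (new = old + shift).
    """
    hi, lo = max(search_window), min(search_window)
    mask = (spectrum.ppm >= lo) & (spectrum.ppm <= hi)
    if not np.any(mask):
        raise ValidationError(
            f"no data points in TSP search window ({hi}, {lo}) ppm"
        )
    idx = np.flatnonzero(mask)
    peak_ppm = spectrum.ppm[idx[np.argmax(spectrum.intensity[idx])]]
    shift = -float(peak_ppm)
    return spectrum.shifted(shift), shift


def _trapezoid_interval(ppm_asc, intensity_asc, lo, hi):
    """Trapezoid integral over [lo, hi] with linearly interpolated endpoints."""
    ilo = np.interp(lo, ppm_asc, intensity_asc)
    ihi = np.interp(hi, ppm_asc, intensity_asc)
    inner = np.searchsorted(ppm_asc, lo, side="right"), \
        np.searchsorted(ppm_asc, hi, side="left")
    xs = np.concatenate(([lo], ppm_asc[inner[0]:inner[1]], [hi]))
    ys = np.concatenate(([ilo], intensity_asc[inner[0]:inner[1]], [ihi]))
    return float(np.trapezoid(ys, xs))


def integrate_buckets(spectrum: Spectrum, scheme: BucketScheme) -> np.ndarray:
    """Integrate intensity over each bucket of ``scheme``.

    Integration is trapezoidal on the native ppm grid, with the bucket
    boundaries entering as linearly interpolated points, which makes the
    integral exactly additive under splitting a bucket in two.  Numerically
    negative integrals (baseline artifacts) are clipped to 0 with a warning.

    Raises if any bucket lies outside the spectral range, naming the bucket.
    """
    ppm_asc = spectrum.ppm[::-1]
    int_asc = spectrum.intensity[::-1]
    lo_edge, hi_edge = float(ppm_asc[0]), float(ppm_asc[-1])
    out = np.empty(len(scheme), dtype=float)
    clipped = []
    for k, b in enumerate(scheme.buckets):
        if b.right < lo_edge or b.left > hi_edge:
            raise ValidationError(
                f"bucket {b.bucket_id!r} ({b.left}, {b.right}) outside the "
                f"spectral range ({hi_edge}, {lo_edge})"
            )
        val = _trapezoid_interval(ppm_asc, int_asc, b.right, b.left)
        if val < 0:
            clipped.append(b.bucket_id)
            val = 0.0
        out[k] = val
    if clipped:
        warnings.warn(
            f"clipped negative integrals to 0 for buckets {clipped}",
            stacklevel=2,
        )
    return out


def normalize_total_intensity(table: BucketTable) -> BucketTable:
    """Divide each sample row by its own total intensity.

    Every row of the returned table sums to 1 and the ``normalized`` flag is
    set.  Idempotent, and invariant to rescaling any row by a positive
    constant.  An all-zero row is an error naming the sample.
    """
    sums = table.values.sum(axis=1)
    bad = np.flatnonzero(sums <= 0)
    if bad.size:
        raise ValidationError(
            f"sample {table.sample_ids[int(bad[0])]!r} has non-positive total "
            "intensity; cannot normalize"
        )
    return BucketTable(
        sample_ids=list(table.sample_ids),
        groups=list(table.groups),
        weeks=list(table.weeks),
        bucket_ids=list(table.bucket_ids),
        values=table.values / sums[:, None],
        normalized=True,
    )
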
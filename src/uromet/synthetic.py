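"""Synthetic urine-NMR cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes: two
groups (sham ``control`` vs orthotopic ``study``) sampled at weeks 1, 3, 5
and 7; ~114 buckets per spectrum of which a curated subset is annotated to
metabolites; log-normal per-metabolite concentrations; a multiplicative
effect applied to the affected metabolites of the study group that rises
through weeks 3-5 and attenuates at week 7; small per-sample chemical-shift
jitter; and additive noise.

Spectra are modelled as sums of Lorentzian singlets.  For speed, cohort
tables are produced directly from the analytic Lorentzian mass inside each
bucket (the exact integral the spectral route converges to), while
:func:`generate_spectrum` renders full traces on a fine ppm grid for
exercising the spectrum-level pipeline.

Every draw flows from one master seed, so a design is fully reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CONTROL, STUDY, Bucket, BucketScheme, BucketTable, Spectrum, \
    ValidationError
from .preprocess import normalize_total_intensity
from .univariate import ComparisonResult, compare_buckets

__all__ = [
    "MetaboliteSpec",
    "SyntheticDesign",
    "CohortTruth",
    "load_metabolite_library",
    "build_scheme",
    "generate_spectrum",
    "generate_cohort",
    "estimate_type1_error",
    "estimate_power",
    "DEFAULT_EXCLUSIONS",
]

#: standard urine-NMR exclusion regions: urea, water, TSP (descending ppm)
DEFAULT_EXCLUSIONS: list[tuple[float, float]] = [
    (6.20, 5.40),
    (5.00, 4.50),
    (0.20, -0.20),
]


@dataclass(frozen=True)
class MetaboliteSpec:
    """One synthetic metabolite: resonance lines and concentration model."""

    name: str
    lines: tuple[tuple[float, float], ...]  # (ppm position, relative intensity)
    baseline_log_mean: float
    baseline_log_sd: float
    affected: bool

    def __post_init__(self):
        if not self.lines:
            raise ValidationError(f"metabolite {self.name!r} has no lines")
        for ppm, rel in self.lines:
            if rel <= 0:
                raise ValidationError(
                    f"metabolite {self.name!r}: relative intensity must be > 0"
                )
            if not 0.5 <= ppm <= 9.5:
                raise ValidationError(
                    f"metabolite {self.name!r}: line at {ppm} ppm outside 0.5-9.5"
                )
        if self.baseline_log_sd <= 0 or not math.isfinite(self.baseline_log_mean):
            raise ValidationError(
                f"metabolite {self.name!r}: invalid baseline parameters"
            )


def load_metabolite_library(source=None) -> list[MetaboliteSpec]:
    """Load a metabolite library TSV (default: the packaged library).

    Columns: name, affected (0/1), log_mean, log_sd, lines as
    ``ppm:rel;ppm:rel``.
    """
    if source is None:
        source = resources.files("uromet.data") / "metabolites.tsv"
    text = source.read_text() if hasattr(source, "read_text") else open(source).read()
    specs = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise ValidationError(
                f"metabolite library line {lineno}: expected 5 tab fields"
            )
        name, affected, log_mean, log_sd, lines_str = fields
        lines = []
        for token in lines_str.split(";"):
            ppm, rel = token.split(":")
            lines.append((float(ppm), float(rel)))
        specs.append(MetaboliteSpec(
            name=name,
            lines=tuple(lines),
            baseline_log_mean=float(log_mean),
            baseline_log_sd=float(log_sd),
            affected=bool(int(affected)),
        ))
    return specs


@dataclass
class SyntheticDesign:
    """Generative description of a cohort.

    The defaults encode the study conditions the pipeline targets: 15
    samples per group at each of weeks 1/3/5/7, 114 buckets, an effect on
    the affected metabolites that peaks in weeks 3-5 (multiplicative folds
    1.2/1.6/1.5/1.1) and ~1 Hz Lorentzian linewidth at 600 MHz
    (0.0017 ppm).
    """

    metabolites: list[MetaboliteSpec] = field(default_factory=load_metabolite_library)
    weeks: tuple[int, ...] = (1, 3, 5, 7)
    effect_trajectory: dict[int, float] = field(
        default_factory=lambda: {1: 1.2, 3: 1.6, 5: 1.5, 7: 1.1}
    )
    n_control: int = 15
    n_study: int = 15
    noise_sd: float = 0.01          # additive noise, fraction of median signal
    shift_jitter_sd: float = 0.002  # ppm
    linewidth: float = 0.0017       # ppm FWHM (~1 Hz at 600 MHz)
    n_buckets: int = 114
    bucket_width: float = 0.03      # ppm
    filler_log_mean: float = math.log(0.5)  # unassigned-resonance baseline
    filler_log_sd: float = 0.25
    ppm_range: tuple[float, float] = (9.5, 0.5)
    n_grid: int = 2**15
    seed: int = 0

    def __post_init__(self):
        if self.n_control < 3 or self.n_study < 3:
            raise ValidationError("group sizes must be >= 3")
        missing = [w for w in self.weeks if w not in self.effect_trajectory]
        if missing:
            raise ValidationError(f"effect_trajectory missing weeks {missing}")
        for w, fold in self.effect_trajectory.items():
            if not (math.isfinite(fold) and fold > 0):
                raise ValidationError(f"fold for week {w} must be positive")
        for name, v in (("noise_sd", self.noise_sd),
                        ("shift_jitter_sd", self.shift_jitter_sd),
                        ("linewidth", self.linewidth),
                        ("bucket_width", self.bucket_width)):
            if not (math.isfinite(v) and v >= 0):
                raise ValidationError(f"{name} must be finite and >= 0")
        if self.linewidth <= 0:
            raise ValidationError("linewidth must be > 0")

    @property
    def affected_metabolites(self) -> list[str]:
        return [m.name for m in self.metabolites if m.affected]

    def is_null(self) -> bool:
        return all(self.effect_trajectory[w] == 1.0 for w in self.weeks)


@dataclass
class CohortTruth:
    """Ground truth behind a generated cohort.

    ``concentrations`` has one row per sample (columns ``sample_id``,
    ``group``, ``week`` then one column per metabolite).
    """

    concentrations: pd.DataFrame
    affected_metabolites: list[str]
    affected_bucket_ids: list[str]
    scheme: BucketScheme
    annotation: dict[str, str]


# ---------------------------------------------------------------------------
# Scheme construction
# ---------------------------------------------------------------------------


def build_scheme(design: SyntheticDesign) -> tuple[BucketScheme, dict[str, str]]:
    """Build the cohort's bucket scheme and bucket -> metabolite annotation.

    One bucket is centered on every metabolite line; the remaining buckets
    (up to ``design.n_buckets``) are unassigned "filler" resonances placed
    deterministically in signal-free regions outside the exclusion windows.
    """
    w = design.bucket_width
    half = w / 2.0
    line_entries = []  # (center, metabolite)
    for m in design.metabolites:
        for ppm, _ in m.lines:
            line_entries.append((ppm, m.name))
    line_entries.sort(key=lambda e: -e[0])
    centers = [c for c, _ in line_entries]
    for a, b in zip(centers, centers[1:]):
        if a - b < w + 1e-9:
            raise ValidationError(
                f"metabolite lines at {a} and {b} ppm closer than one bucket "
                "width; adjust the library or bucket_width"
            )
    buckets = []
    annotation: dict[str, str] = {}
    for c, met in line_entries:
        bid = f"B{c:.3f}"
        buckets.append(Bucket(bid, c + half, c - half))
        annotation[bid] = met

    n_filler = design.n_buckets - len(buckets)
    if n_filler < 0:
        raise ValidationError(
            f"n_buckets={design.n_buckets} smaller than the number of "
            f"metabolite lines ({len(buckets)})"
        )
    if n_filler:
        hi, lo = max(design.ppm_range), min(design.ppm_range)
        blocked = [(b.left + 0.005, b.right - 0.005) for b in buckets]
        blocked += [(a, b) for a, b in DEFAULT_EXCLUSIONS]
        candidates = []
        pos = lo + half  # candidate centers, ascending
        step = w + 0.01
        while pos + half <= hi:
            left, right = pos + half, pos - half
            if not any(right < bl and br < left for bl, br in blocked):
                candidates.append(pos)
            pos += step
        if len(candidates) < n_filler:
            raise ValidationError(
                f"cannot place {n_filler} filler buckets; only "
                f"{len(candidates)} free positions"
            )
        pick = np.unique(np.round(
            np.linspace(0, len(candidates) - 1, n_filler)
        ).astype(int))
        # np.linspace indices are distinct because n_filler <= len(candidates)
        for i in pick:
            c = candidates[int(i)]
            buckets.append(Bucket(f"U{c:.3f}", c + half, c - half))
    buckets.sort(key=lambda b: -b.left)
    scheme = BucketScheme(buckets=buckets, exclusions=list(DEFAULT_EXCLUSIONS))
    if len(scheme) != design.n_buckets:
        raise ValidationError("filler placement failed to reach n_buckets")
    return scheme, annotation


# ---------------------------------------------------------------------------
# Spectrum-level generation
# ---------------------------------------------------------------------------


def generate_spectrum(
    concentrations: Mapping[str, float],
    design: SyntheticDesign,
    rng: np.random.Generator | None = None,
    sample_id: str = "synthetic",
    group: str = CONTROL,
    week: int = 1,
) -> Spectrum:
    """Render one full 1D trace from true metabolite concentrations.

    Intensity is the sum over metabolite lines of
    ``concentration * relative_intensity * Lorentzian(center + jitter)``
    (unit-area Lorentzian of FWHM ``design.linewidth``) plus Gaussian noise
    scaled to ``noise_sd`` times the median line peak height.  All random
    draws (jitter, noise) come from ``rng``; with ``rng=None`` the spectrum
    is noise- and jitter-free.
    """
    hi, lo = max(design.ppm_range), min(design.ppm_range)
    grid_step = (hi - lo) / (design.n_grid - 1)
    if design.linewidth / grid_step < 4:
        raise ValidationError(
            f"grid too coarse: {design.linewidth / grid_step:.2f} points per "
            "linewidth (< 4)"
        )
    ppm = np.linspace(hi, lo, design.n_grid)
    intensity = np.zeros_like(ppm)
    hw = design.linewidth / 2.0
    peak_heights = []
    for m in design.metabolites:
        conc = float(concentrations.get(m.name, 0.0))
        if conc == 0.0:
            continue
        for center, rel in m.lines:
            jitter = (
                float(rng.normal(0.0, design.shift_jitter_sd))
                if rng is not None and design.shift_jitter_sd > 0 else 0.0
            )
            amp = conc * rel
            intensity += amp * (hw / math.pi) / ((ppm - center - jitter) ** 2 + hw**2)
            peak_heights.append(amp / (math.pi * hw))
    if rng is not None and design.noise_sd > 0 and peak_heights:
        sigma = design.noise_sd * float(np.median(peak_heights))
        intensity = intensity + rng.normal(0.0, sigma, size=ppm.size)
    return Spectrum(sample_id=sample_id, group=group, week=week,
                    ppm=ppm, intensity=intensity)


# ---------------------------------------------------------------------------
# Cohort-level generation (analytic bucket masses)
# ---------------------------------------------------------------------------


class _CohortEngine:
    """Precomputed arrays for fast per-week table sampling."""

    def __init__(self, design: SyntheticDesign):
        self.design = design
        self.scheme, self.annotation = build_scheme(design)
        mets = design.metabolites
        self.met_names = [m.name for m in mets]
        self.log_means = np.asarray([m.baseline_log_mean for m in mets])
        self.log_sds = np.asarray([m.baseline_log_sd for m in mets])
        self.affected = np.asarray([m.affected for m in mets])
        centers, rels, met_idx = [], [], []
        for i, m in enumerate(mets):
            for ppm, rel in m.lines:
                centers.append(ppm)
                rels.append(rel)
                met_idx.append(i)
        self.line_centers = np.asarray(centers)
        self.line_rel = np.asarray(rels)
        self.line_met = np.asarray(met_idx)
        self.bucket_ids = self.scheme.bucket_ids
        self.edge_lo = np.asarray([b.right for b in self.scheme.buckets])
        self.edge_hi = np.asarray([b.left for b in self.scheme.buckets])
        self.filler_cols = np.asarray(
            [i for i, bid in enumerate(self.bucket_ids) if bid.startswith("U")],
            dtype=int,
        )
        self.hw = design.linewidth / 2.0

    def sample_concentrations(self, week: int, rng: np.random.Generator):
        d = self.design
        fold = d.effect_trajectory[week]
        conc_c = np.exp(rng.normal(self.log_means, self.log_sds,
                                   size=(d.n_control, len(self.met_names))))
        conc_s = np.exp(rng.normal(self.log_means, self.log_sds,
                                   size=(d.n_study, len(self.met_names))))
        conc_s[:, self.affected] *= fold
        return conc_c, conc_s

    def table_from_concentrations(self, conc, rng: np.random.Generator):
        """Bucket values for (n, M) concentrations via analytic line masses."""
        d = self.design
        n = conc.shape[0]
        jitter = (
            rng.normal(0.0, d.shift_jitter_sd, size=(n, self.line_centers.size))
            if d.shift_jitter_sd > 0 else np.zeros((n, self.line_centers.size))
        )
        pos = self.line_centers[None, :] + jitter          # (n, L)
        upper = np.arctan((self.edge_hi[None, None, :] - pos[:, :, None]) / self.hw)
        lower = np.arctan((self.edge_lo[None, None, :] - pos[:, :, None]) / self.hw)
        mass = (upper - lower) / math.pi                   # (n, L, K)
        amp = conc[:, self.line_met] * self.line_rel[None, :]
        values = np.einsum("nl,nlk->nk", amp, mass)
        if self.filler_cols.size:
            values[:, self.filler_cols] += np.exp(rng.normal(
                d.filler_log_mean, d.filler_log_sd,
                size=(n, self.filler_cols.size),
            ))
        if d.noise_sd > 0:
            sigma = d.noise_sd * float(np.median(values))
            values = values + rng.normal(0.0, sigma, size=values.shape)
        return np.clip(values, 0.0, None)

    def sample_week(self, week: int, rng: np.random.Generator):
        d = self.design
        conc_c, conc_s = self.sample_concentrations(week, rng)
        conc = np.vstack([conc_c, conc_s])
        values = self.table_from_concentrations(conc, rng)
        sample_ids = (
            [f"w{week}_c{i + 1}" for i in range(d.n_control)]
            + [f"w{week}_s{i + 1}" for i in range(d.n_study)]
        )
        groups = [CONTROL] * d.n_control + [STUDY] * d.n_study
        table = BucketTable(
            sample_ids=sample_ids,
            groups=groups,
            weeks=[week] * len(sample_ids),
            bucket_ids=list(self.bucket_ids),
            values=values,
            normalized=False,
        )
        return table, conc

    def affected_bucket_ids(self) -> list[str]:
        affected = set(np.asarray(self.met_names)[self.affected])
        return [bid for bid, met in self.annotation.items() if met in affected]


def generate_cohort(
    design: SyntheticDesign,
) -> tuple[dict[int, BucketTable], CohortTruth]:
    """Generate per-week bucket tables and the matching ground truth.

    Returns ``(tables, truth)`` where ``tables`` maps each week to an
    unnormalized :class:`~uromet.io.BucketTable`.  Identical designs
    (including the seed) generate identical cohorts.
    """
    engine = _CohortEngine(design)
    rng = np.random.default_rng(design.seed)
    tables: dict[int, BucketTable] = {}
    conc_rows = []
    for week in design.weeks:
        table, conc = engine.sample_week(week, rng)
        tables[week] = table
        meta = pd.DataFrame({
            "sample_id": table.sample_ids,
            "group": table.groups,
            "week": table.weeks,
        })
        conc_rows.append(pd.concat(
            [meta, pd.DataFrame(conc, columns=engine.met_names)], axis=1
        ))
    truth = CohortTruth(
        concentrations=pd.concat(conc_rows, ignore_index=True),
        affected_metabolites=design.affected_metabolites,
        affected_bucket_ids=engine.affected_bucket_ids(),
        scheme=engine.scheme,
        annotation=engine.annotation,
    )
    return tables, truth


# ---------------------------------------------------------------------------
# Monte-Carlo calibration
# ---------------------------------------------------------------------------


def _replicate_comparisons(design, n_reps, week, alpha_total, seed):
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    engine = _CohortEngine(design)
    week = design.weeks[0] if week is None else week
    if week not in design.effect_trajectory:
        raise ValidationError(f"week {week} not in the design trajectory")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    for _ in range(n_reps):
        table, _ = engine.sample_week(week, rng)
        yield engine, compare_buckets(
            normalize_total_intensity(table), alpha_total=alpha_total
        )


def estimate_type1_error(
    design: SyntheticDesign,
    n_reps: int,
    week: int | None = None,
    alpha_total: float = 0.05,
    seed: int | None = None,
) -> tuple[float, float]:
    """Family-wise false-positive rate of the Bonferroni screen under the null.

    Requires a null design (all trajectory folds 1.0).  Returns the
    fraction of replicates with at least one significant bucket and its
    binomial Monte-Carlo standard error.
    """
    if not design.is_null():
        raise ValidationError(
            "estimate_type1_error requires a null design (all folds 1.0)"
        )
    hits = 0
    for _, comparison in _replicate_comparisons(design, n_reps, week,
                                                alpha_total, seed):
        hits += comparison.n_significant >= 1
    rate = hits / n_reps
    se = math.sqrt(rate * (1.0 - rate) / n_reps)
    return rate, se


def estimate_power(
    design: SyntheticDesign,
    n_reps: int,
    week: int | None = None,
    alpha_total: float = 0.05,
    seed: int | None = None,
) -> pd.Series:
    """Per-metabolite detection rate of the Bonferroni screen.

    A metabolite counts as detected in a replicate when any of its
    constituent buckets is significant.  ``week`` defaults to the
    trajectory's peak-fold week.  Returns a Series indexed by affected
    metabolite name.
    """
    affected = design.affected_metabolites
    if not affected:
        raise ValidationError("design has no affected metabolites")
    if week is None:
        week = max(design.weeks, key=lambda w: design.effect_trajectory[w])
    counts = {name: 0 for name in affected}
    buckets_of: dict[str, list[str]] | None = None
    for engine, comparison in _replicate_comparisons(design, n_reps, week,
                                                     alpha_total, seed):
        if buckets_of is None:
            buckets_of = {name: [] for name in affected}
            for bid, met in engine.annotation.items():
                if met in buckets_of:
                    buckets_of[met].append(bid)
        sig = set(comparison.significant_buckets())
        for name in affected:
            if sig.intersection(buckets_of[name]):
                counts[name] += 1
    return pd.Series({name: counts[name] / n_reps for name in affected},
                     name="detection_rate")
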
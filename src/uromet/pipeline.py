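"""Per-timepoint orchestration and the longitudinal trend summary.

:func:`run_timepoint` chains the full analysis for one week's comparison:
total-intensity normalization (if needed), Bonferroni-screened univariate
statistics, PLS-DA with cross-validated Q², the cluster-separation F-test,
and bucket -> metabolite mapping of the significant hits.

:func:`build_trend_matrix` assembles the per-week results into a
metabolites x weeks matrix of signed log2 fold changes, masked to 0
wherever the Bonferroni screen did not flag any bucket of the metabolite —
the quantity behind a longitudinal heat map of tumor-progression
biomarkers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BucketTable, ValidationError
from .plsda import PlsdaModel, cross_validate_q2, fit_plsda
from .preprocess import normalize_total_intensity
from .separation import SeparationTest, assess_separation
from .univariate import ComparisonResult, compare_buckets

__all__ = [
    "AnalysisConfig",
    "TimepointResult",
    "LongitudinalSummary",
    "run_timepoint",
    "run_longitudinal",
    "build_trend_matrix",
    "plot_trend_heatmap",
]


@dataclass
class AnalysisConfig:
    """Tunable parameters shared by every per-week comparison."""

    alpha_total: float = 0.05
    auc_threshold: float = 0.75
    test_method: str = "welch"
    n_components: int = 2
    scaling: str = "uv"
    n_folds: int = 7
    convention: str = "paper"


@dataclass
class TimepointResult:
    """Everything computed for one week's control-vs-study comparison.

    ``plsda`` and ``separation`` are ``None`` when the normalized bucket
    matrix is degenerate (e.g. a single-bucket table, which normalization
    maps to a constant column).
    """

    week: int
    comparison: ComparisonResult
    plsda: PlsdaModel | None
    separation: SeparationTest | None
    significant_metabolites: list[str]

    def summary_dict(self) -> dict:
        return {
            "week": self.week,
            "n_buckets_tested": self.comparison.n_buckets_tested,
            "alpha_bonferroni": self.comparison.alpha_bonferroni,
            "n_significant_buckets": self.comparison.n_significant,
            "significant_metabolites": self.significant_metabolites,
            "r2y_cum": None if self.plsda is None else self.plsda.r2y_cum,
            "q2_cum": None if self.plsda is None else self.plsda.q2_cum,
            "separation": None if self.separation is None
            else self.separation.to_dict(),
        }

    def to_json(self, dest=None) -> str:
        text = json.dumps(self.summary_dict(), sort_keys=True)
        if dest is not None:
            with open(dest, "w") as fh:
                fh.write(text)
        return text


@dataclass
class LongitudinalSummary:
    """Metabolites x weeks matrix of Bonferroni-masked signed log2FC.

    ``values`` is indexed by metabolite (ordered by peak absolute log2 fold
    change, descending) with one column per analyzed week.  Entries are 0
    where the metabolite had no significant bucket that week.
    """

    values: pd.DataFrame
    weeks: list[int]

    def to_tsv(self, dest) -> None:
        self.values.to_csv(dest, sep="\t", float_format="%.17g")


def run_timepoint(
    table: BucketTable,
    config: AnalysisConfig | None = None,
    annotation: dict[str, str] | None = None,
) -> TimepointResult:
    """Run the complete single-week analysis on one bucket table.

    The table must contain exactly one week and both groups.  If it is not
    yet normalized, total-intensity normalization is applied first.  A
    metabolite is significant when any of its constituent buckets is;
    significant buckets without an annotation entry are reported by id in a
    warning and excluded from the metabolite list.
    """
    config = config or AnalysisConfig()
    weeks = sorted(set(table.weeks))
    if len(weeks) != 1:
        raise ValidationError(
            f"run_timepoint expects a single-week table, found weeks {weeks}"
        )
    if not table.normalized:
        table = normalize_total_intensity(table)
    comparison = compare_buckets(
        table,
        alpha_total=config.alpha_total,
        auc_threshold=config.auc_threshold,
        method=config.test_method,
    )
    try:
        model = fit_plsda(
            table.values,
            table.groups,
            n_components=config.n_components,
            scaling=config.scaling,
            bucket_ids=table.bucket_ids,
        )
        model.q2_cum = cross_validate_q2(
            table.values,
            table.groups,
            n_components=config.n_components,
            n_folds=config.n_folds,
            scaling=config.scaling,
        )
        separation = assess_separation(
            model, table.groups, alpha=config.alpha_total,
            convention=config.convention,
        )
    except ValidationError as exc:
        warnings.warn(
            f"multivariate stage skipped (degenerate matrix): {exc}",
            stacklevel=2,
        )
        model = None
        separation = None
    annotation = annotation or {}
    sig_buckets = comparison.significant_buckets()
    unannotated = sorted(b for b in sig_buckets if b not in annotation)
    if unannotated:
        warnings.warn(
            f"significant buckets without annotation: {unannotated}",
            stacklevel=2,
        )
    metabolites = sorted({annotation[b] for b in sig_buckets if b in annotation})
    return TimepointResult(
        week=weeks[0],
        comparison=comparison,
        plsda=model,
        separation=separation,
        significant_metabolites=metabolites,
    )


def run_longitudinal(
    tables_by_week: dict[int, BucketTable],
    config: AnalysisConfig | None = None,
    annotation: dict[str, str] | None = None,
) -> tuple[list[TimepointResult], "LongitudinalSummary"]:
    """Run every week's comparison and assemble the trend matrix."""
    results = [
        run_timepoint(tables_by_week[w], config=config, annotation=annotation)
        for w in sorted(tables_by_week)
    ]
    return results, build_trend_matrix(results, annotation or {})


def _metabolite_week_value(comparison: ComparisonResult, buckets: list[str]) -> float:
    """Signed log2FC for one metabolite in one week, 0 if not significant."""
    pb = comparison.per_bucket
    sig = [b for b in buckets if bool(pb.loc[b, "significant_p"])]
    if not sig:
        return 0.0
    fcs = pb.loc[sig, "log2_fold_change"].to_numpy(dtype=float)
    finite = np.isfinite(fcs)
    if not finite.any():
        warnings.warn("non-finite fold change masked to 0", stacklevel=2)
        return 0.0
    fcs = fcs[finite]
    return float(fcs[np.argmax(np.abs(fcs))])


def build_trend_matrix(
    results: list[TimepointResult],
    annotation: dict[str, str],
) -> LongitudinalSummary:
    """Assemble the longitudinal metabolites x weeks trend matrix.

    Each entry is the log2 fold change (study vs control) of the
    metabolite's largest-magnitude significant bucket that week, or 0 when
    no bucket of the metabolite passed the Bonferroni screen.  Metabolites
    are ordered by their peak absolute entry, descending (name as
    tie-break).  All weeks must share the same bucket set.
    """
    if not results:
        raise ValidationError("need at least one timepoint result")
    ref = list(results[0].comparison.per_bucket.index)
    for r in results[1:]:
        other = list(r.comparison.per_bucket.index)
        if other != ref:
            missing = sorted(set(ref).symmetric_difference(other))
            raise ValidationError(
                f"inconsistent bucket sets across weeks; mismatches: {missing}"
            )
    buckets_of: dict[str, list[str]] = {}
    for bid, met in annotation.items():
        if bid in set(ref):
            buckets_of.setdefault(met, []).append(bid)
    weeks = [r.week for r in results]
    data = {
        met: [_metabolite_week_value(r.comparison, buckets) for r in results]
        for met, buckets in sorted(buckets_of.items())
    }
    values = pd.DataFrame.from_dict(data, orient="index", columns=weeks)
    values.index.name = "metabolite"
    peak = values.abs().max(axis=1)
    order = sorted(values.index, key=lambda m: (-peak[m], m))
    values = values.loc[order]
    return LongitudinalSummary(values=values, weeks=weeks)


def plot_trend_heatmap(summary: LongitudinalSummary, dest) -> None:
    """Render the trend matrix as a diverging heat map (warm = elevated in
    study urine, cool = elevated in control)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = summary.values.to_numpy(dtype=float)
    vmax = max(float(np.abs(vals).max()), 1e-12)
    fig, ax = plt.subplots(
        figsize=(2 + 0.6 * len(summary.weeks), 1 + 0.25 * vals.shape[0])
    )
    im = ax.imshow(vals, aspect="auto", cmap="RdYlGn_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(len(summary.weeks)))
    ax.set_xticklabels([f"week {w}" for w in summary.weeks])
    ax.set_yticks(range(vals.shape[0]))
    ax.set_yticklabels(summary.values.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="log2 fold change (study / control)")
    fig.tight_layout()
    fig.savefig(dest, dpi=150)
    plt.close(fig)
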
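#!/usr/bin/env python
"""Soft validation against a deposited binned-NMR dataset.

Given the deposited bucket-table CSVs (one row per sample, metadata columns
then bucket columns), runs the full per-week pipeline and prints the
quantities a reader would compare with the original report: per-week
significant-resonance counts, R²Y(cum), Q²(cum), Mahalanobis D, F-value and
critical F.  Exact reproduction of the original per-week counts is not
guaranteed — it depends on the original software's unstated test and
scaling choices — so this script reports, it does not assert.

Example::

    python scripts/validate_deposit.py week1.csv week3.csv \
        --sample-col Sample --group-col Group --week-col Week \
        --group-map sham=control,orthotopic=study
"""

from __future__ import annotations

import argparse

from uromet.io import read_annotation, read_bucket_table
from uromet.pipeline import AnalysisConfig, run_timepoint


def parse_group_map(text):
    if not text:
        return None
    return dict(item.split("=", 1) for item in text.split(","))


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("tables", nargs="+", help="bucket-table CSV/TSV files")
    parser.add_argument("--sample-col", default="sample_id")
    parser.add_argument("--group-col", default="group")
    parser.add_argument("--week-col", default="week")
    parser.add_argument("--group-map", default=None,
                        help="e.g. 'sham=control,orthotopic=study'")
    parser.add_argument("--annotation", default=None,
                        help="bucket_id -> metabolite TSV")
    parser.add_argument("--alpha", type=float, default=0.05)
    parser.add_argument("--components", type=int, default=2)
    parser.add_argument("--convention", default="paper",
                        choices=["paper", "hotelling"])
    args = parser.parse_args()

    annotation = read_annotation(args.annotation) if args.annotation else {}
    config = AnalysisConfig(alpha_total=args.alpha,
                            n_components=args.components,
                            convention=args.convention)
    for path in args.tables:
        table = read_bucket_table(
            path,
            sample_col=args.sample_col,
            group_col=args.group_col,
            week_col=args.week_col,
            group_labels=parse_group_map(args.group_map),
        )
        for week in sorted(set(table.weeks)):
            res = run_timepoint(table.subset_week(week), config=config,
                                annotation=annotation)
            sep = res.separation
            print(f"week {week}: {res.comparison.n_significant} of "
                  f"{res.comparison.n_buckets_tested} resonances significant "
                  f"(alpha_b = {res.comparison.alpha_bonferroni:.3e})")
            if res.plsda is not None and sep is not None:
                print(f"  R2Y(cum) = {res.plsda.r2y_cum:.3f}   "
                      f"Q2(cum) = {res.plsda.q2_cum:.3f}")
                print(f"  D = {sep.mahalanobis_d:.3f}   F = {sep.f_value:.3f} "
                      f"  F_crit({sep.df1},{sep.df2}) = {sep.critical_f:.3f} "
                      f"  significant = {sep.significant}")
            if res.significant_metabolites:
                print(f"  metabolites: {', '.join(res.significant_metabolites)}")


if __name__ == "__main__":
    main()
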
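"""Hypergeometric over-representation analysis of metabolite sets.

Given the metabolites flagged significant in a comparison and the universe
of all annotated metabolites, each metabolite set (a pathway stand-in) is
tested for over-representation with the upper-tail hypergeometric
probability P(X >= k), where k is the number of significant metabolites in
the set.  P-values are adjusted across sets with the Holm step-down
procedure.  Pathway-topology/impact scoring is deliberately out of scope;
this module ranks affected sets only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import MetaboliteSetLibrary, ValidationError

__all__ = ["EnrichmentResult", "hypergeometric_ora"]


@dataclass
class EnrichmentResult:
    """Per-set enrichment table plus the test's global parameters.

    ``table`` is indexed by set id with columns ``set_name``, ``k`` (hits),
    ``set_size``, ``p_hyper`` and ``holm_adjusted_p``, sorted by raw
    p-value ascending.
    """

    table: pd.DataFrame
    n_significant: int
    universe_size: int


def hypergeometric_ora(
    significant,
    universe,
    library: MetaboliteSetLibrary,
) -> EnrichmentResult:
    """Test each metabolite set for over-representation of hits.

    ``significant`` must be a subset of ``universe``.  Sets are intersected
    with the universe before testing; sets with no overlap are skipped with
    a warning.  For each set, ``p_hyper = P(X >= k)`` with
    X ~ Hypergeometric(N, set_size, n_significant).
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValidationError("universe is empty")
    uni = set(universe)
    sig = set(significant)
    stray = sorted(sig - uni)
    if stray:
        raise ValidationError(
            f"significant metabolites not in universe: {stray}"
        )
    n = len(uni)
    n_sig = len(sig)

    rows = []
    for set_id, (name, members) in library.items():
        members_in = sorted(set(members) & uni)
        if not members_in:
            warnings.warn(
                f"set {set_id!r} has no overlap with the universe; skipped",
                stacklevel=2,
            )
            continue
        k_set = len(members_in)
        k = len(sig & set(members_in))
        p = float(stats.hypergeom.sf(k - 1, n, k_set, n_sig))
        rows.append((set_id, name, k, k_set, p))
    if not rows:
        raise ValidationError("no set overlaps the universe")

    table = pd.DataFrame(
        rows, columns=["set_id", "set_name", "k", "set_size", "p_hyper"]
    ).set_index("set_id")
    table["holm_adjusted_p"] = multipletests(
        table["p_hyper"].to_numpy(), method="holm"
    )[1]
    table = table.sort_values(["p_hyper", "set_name"])
    return EnrichmentResult(table=table, n_significant=n_sig, universe_size=n)
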
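"""Comprehensive (RefFinder-style) ranking: geometric mean of per-method ranks.

Each stability method contributes a rank per gene (ties may yield fractional
ranks); the comprehensive score is the unweighted geometric mean of a gene's
ranks across methods, and the final ordering is ascending in that score. Ties
in the score are broken by mean rank, then lexicographically by gene name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import GeneSetMismatchError

__all__ = ["ComprehensiveRanking", "comprehensive_rank"]


@dataclass
class ComprehensiveRanking:
    method_ranks: pd.DataFrame  # genes x methods
    gm_score: pd.Series  # gene -> geometric mean of ranks
    final_rank: pd.Series  # gene -> 1..k
    order: list[str]  # genes, best first
    n_methods: int
    tie_events: list[str] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        """Tidy output with display rounding (2 decimals) on the score."""
        t = self.method_ranks.copy()
        t["gm_score"] = self.gm_score.round(2)
        t["final_rank"] = self.final_rank
        return t.sort_values("final_rank")


def comprehensive_rank(rank_lists: Mapping[str, Mapping[str, float] | pd.Series]) -> ComprehensiveRanking:
    """Aggregate 2-6 per-method rank mappings over an identical gene set.

    Raises :class:`GeneSetMismatchError` listing the symmetric difference if
    the gene sets disagree. Methods that could not run are simply omitted from
    ``rank_lists``; the geometric mean is over the methods provided and the
    count is recorded in ``n_methods``.
    """
    methods = sorted(rank_lists)  # canonical order => method-order invariance
    if not 2 <= len(methods) <= 6:
        raise ValueError(f"need 2-6 rank lists, got {len(methods)}")
    gene_sets = {m: frozenset(dict(rank_lists[m])) for m in methods}
    ref = gene_sets[methods[0]]
    for m in methods[1:]:
        if gene_sets[m] != ref:
            diff = sorted(ref.symmetric_difference(gene_sets[m]))
            raise GeneSetMismatchError(
                f"gene sets differ between {methods[0]!r} and {m!r}: {diff}"
            )
    genes = sorted(ref)
    mat = pd.DataFrame(
        {m: pd.Series(dict(rank_lists[m])).reindex(genes) for m in methods}, index=genes
    )
    if (mat.to_numpy() <= 0).any() or not np.all(np.isfinite(mat.to_numpy())):
        raise ValueError("ranks must be positive finite numbers")
    gm = pd.Series(
        np.power(mat.to_numpy().prod(axis=1), 1.0 / len(methods)), index=genes, name="gm_score"
    )
    mean_rank = mat.mean(axis=1)
    order_idx = np.lexsort((genes, mean_rank.to_numpy(), gm.to_numpy()))
    order = [genes[i] for i in order_idx]
    tie_events = []
    gm_sorted = gm.to_numpy()[order_idx]
    for i in range(1, len(order)):
        if np.isclose(gm_sorted[i], gm_sorted[i - 1], rtol=0, atol=1e-12):
            tie_events.append(f"gm_score tie between {order[i - 1]!r} and {order[i]!r}")
    final = pd.Series({g: float(i + 1) for i, g in enumerate(order)}, name="final_rank").reindex(genes)
    return ComprehensiveRanking(
        method_ranks=mat,
        gm_score=gm,
        final_rank=final,
        order=order,
        n_methods=len(methods),
        tie_events=tie_events,
    )
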
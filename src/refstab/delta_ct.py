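"""Comparative dCt stability: mean standard deviation of pairwise Cq differences.

For each gene pair (j, k) the SD over samples of (Cq_j - Cq_k) measures how
much the two genes co-vary; a gene's stability is the mean of its pair SDs
against all other candidates, ranked ascending. Computed on raw (replicate
collapsed) Cq: because log2 RQ differs from -Cq only by a per-gene constant,
this equals the geNorm full-set M exactly when all E = 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CqDataset, collapse_replicates
from .errors import InsufficientDataError

__all__ = ["DeltaCtResult", "delta_ct_stability"]


@dataclass
class DeltaCtResult:
    pair_sd: pd.DataFrame  # symmetric gene x gene, SD of Cq differences
    mean_sd: pd.Series  # gene -> mean pair SD ("Std dev"), input gene order
    ranking: pd.Series  # gene -> rank, ascending mean_sd


def delta_ct_stability(ds: CqDataset) -> DeltaCtResult:
    """Pairwise Cq-difference SDs (n-1 denominator, pairwise-complete samples)."""
    if ds.max_replicates > 1:
        ds, _ = collapse_replicates(ds)
    wide = ds.wide()
    genes = list(wide.index)
    if len(genes) < 3:
        raise InsufficientDataError("comparative dCt needs >= 3 genes")
    if wide.shape[1] < 2:
        raise InsufficientDataError("comparative dCt needs >= 2 samples")
    cq = wide.to_numpy(dtype=float)
    k = len(genes)
    pair = np.zeros((k, k))
    for j in range(k):
        for m in range(j + 1, k):
            d = cq[j] - cq[m]
            d = d[np.isfinite(d)]
            if d.size < 2:
                raise InsufficientDataError(
                    f"genes {genes[j]!r} and {genes[m]!r} share {d.size} complete sample(s)"
                )
            pair[j, m] = pair[m, j] = float(np.std(d, ddof=1))
    pair_sd = pd.DataFrame(pair, index=genes, columns=genes)
    mean_sd = pd.Series(pair.sum(axis=1) / (k - 1), index=genes, name="std_dev")
    order = mean_sd.iloc[np.lexsort((mean_sd.index, mean_sd.to_numpy()))]
    ranking = pd.Series(
        {g: float(i + 1) for i, g in enumerate(order.index)}, name="deltact_rank"
    ).reindex(genes)
    return DeltaCtResult(pair_sd=pair_sd, mean_sd=mean_sd, ranking=ranking)
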
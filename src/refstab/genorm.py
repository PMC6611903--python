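"""geNorm expression stability: pairwise variation V, M-values, stepwise ranking,
and the V(n/n+1) criterion for the optimal number of reference genes.

For genes j, k the pairwise variation V_jk is the standard deviation
(n-1 denominator) over samples of log2(RQ_j / RQ_k). A gene's M-value is the
mean of its pairwise variations against all other candidates; lower M = more
stable. True geNorm ranking excludes the worst gene stepwise and recomputes M
on the remainder; the final two genes cannot be ordered and form the most
stable pair. V(n/n+1) compares normalization factors built from the top n and
n+1 genes; V < 0.15 indicates n genes suffice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .data import RQMatrix
from .errors import InsufficientDataError

__all__ = [
    "GenormResult",
    "OptimalN",
    "pairwise_variation_matrix",
    "m_values",
    "genorm_rank",
    "optimal_gene_count",
    "V_CUTOFF",
]

V_CUTOFF = 0.15


def _pair_sd(a: np.ndarray, b: np.ndarray, name_a: str, name_b: str) -> float:
    """SD of (a - b) over pairwise-complete entries; error if < 2 shared samples."""
    d = a - b
    d = d[np.isfinite(d)]
    if d.size < 2:
        raise InsufficientDataError(
            f"genes {name_a!r} and {name_b!r} share {d.size} complete sample(s); need >= 2"
        )
    return float(np.std(d, ddof=1))


def pairwise_variation_matrix(rq: RQMatrix) -> pd.DataFrame:
    """Symmetric gene x gene matrix of V_jk = SD_s[log2(rq_j / rq_k)]."""
    genes = rq.genes
    if len(genes) < 2 or len(rq.samples) < 2:
        raise InsufficientDataError("need >= 2 genes and >= 2 samples")
    log = rq.log2.to_numpy()
    v = np.zeros((len(genes), len(genes)))
    for j in range(len(genes)):
        for k in range(j + 1, len(genes)):
            v[j, k] = v[k, j] = _pair_sd(log[j], log[k], genes[j], genes[k])
    return pd.DataFrame(v, index=genes, columns=genes)


def m_values(rq: RQMatrix, v_matrix: pd.DataFrame | None = None) -> pd.Series:
    """Single-pass M: mean pairwise variation of each gene against all others."""
    if len(rq.genes) < 3:
        raise InsufficientDataError("geNorm M needs >= 3 genes")
    v = v_matrix if v_matrix is not None else pairwise_variation_matrix(rq)
    k = v.shape[0]
    m = v.sum(axis=1) / (k - 1)
    m.name = "M"
    return m


@dataclass
class GenormResult:
    """Stepwise geNorm output.

    ``ranking`` maps gene -> numeric rank for downstream aggregation: the
    unordered most-stable pair both carry ``final_pair_rank`` (1 by default,
    1.5 optionally); the remaining genes carry 3, 4, ... in exclusion order.
    ``ranking_order`` lists genes most-stable first (pair ordered
    lexicographically). ``m_steps`` records M at each exclusion step.
    """

    v_matrix: pd.DataFrame
    m_single_pass: pd.Series
    m_steps: list[pd.Series]
    exclusion_order: list[str]
    most_stable_pair: tuple[str, str]
    ranking: pd.Series
    ranking_order: list[str]
    tie_events: list[str] = field(default_factory=list)


def genorm_rank(rq: RQMatrix, stepwise: bool = True, final_pair_rank: float = 1.0) -> GenormResult:
    """Rank genes by geNorm stability.

    With ``stepwise=True`` (true geNorm behaviour) the gene with the highest M
    is removed and M recomputed on the remainder until two genes are left; with
    ``stepwise=False`` a single-pass M ordering is used. Ties in the maximum M
    are broken lexicographically (the alphabetically first gene is excluded)
    and recorded in ``tie_events``.
    """
    genes = list(rq.genes)
    if len(genes) < 3:
        raise InsufficientDataError("geNorm ranking needs >= 3 genes")
    v_full = pairwise_variation_matrix(rq)
    m_full = m_values(rq, v_full)

    tie_events: list[str] = []
    exclusion: list[str] = []
    m_steps: list[pd.Series] = []

    if stepwise:
        remaining = sorted(genes)  # canonical order => input-order invariance
        while len(remaining) > 2:
            v = v_full.loc[remaining, remaining]
            m = v.sum(axis=1) / (len(remaining) - 1)
            m_steps.append(m.copy())
            worst_m = m.max()
            tied = sorted(m.index[np.isclose(m.to_numpy(), worst_m, rtol=0, atol=0)])
            if len(tied) > 1:
                tie_events.append(f"max-M tie among {tied}; excluded {tied[0]!r}")
            worst = tied[0]
            exclusion.append(worst)
            remaining = [g for g in remaining if g != worst]
        pair = tuple(sorted(remaining))
    else:
        order = m_full.sort_values(ascending=False, kind="stable")
        # break exact ties lexicographically, worst first
        order = order.iloc[np.lexsort((order.index, -order.to_numpy()))]
        exclusion = list(order.index[:-2])
        pair = tuple(sorted(order.index[-2:]))
        m_steps.append(m_full.copy())

    ranking_order = list(pair) + list(reversed(exclusion))
    ranks = {pair[0]: final_pair_rank, pair[1]: final_pair_rank}
    for i, g in enumerate(reversed(exclusion)):
        ranks[g] = float(i + 3)
    ranking = pd.Series({g: ranks[g] for g in genes}, name="genorm_rank")
    return GenormResult(
        v_matrix=v_full,
        m_single_pass=m_full,
        m_steps=m_steps,
        exclusion_order=exclusion,
        most_stable_pair=pair,
        ranking=ranking,
        ranking_order=ranking_order,
        tie_events=tie_events,
    )


@dataclass
class OptimalN:
    """V(n/n+1) series and the smallest n meeting the cutoff."""

    nf_pairwise: pd.Series  # index n, value V(n/n+1)
    optimal_n: int
    cutoff: float
    satisfied: bool  # False if no n met the cutoff (optimal_n = k then)


def optimal_gene_count(rq: RQMatrix, ranking_order: list[str], cutoff: float = V_CUTOFF) -> OptimalN:
    """Pairwise variation V(n/n+1) between successive normalization factors.

    NF_n(s) is the geometric mean RQ of the n top-ranked genes at sample s;
    V(n/n+1) is the SD over samples of log2(NF_n / NF_{n+1}), for n = 2..k-1.
    The optimal gene count is the smallest n with V(n/n+1) < cutoff, or k
    (flagged) if none qualifies.
    """
    k = len(ranking_order)
    if k < 3:
        raise InsufficientDataError("V(n/n+1) needs >= 3 ranked genes")
    log = rq.log2.loc[ranking_order].to_numpy()
    vs = {}
    for n in range(2, k):
        log_nf_n = log[:n].mean(axis=0)  # log of geometric mean
        log_nf_n1 = log[: n + 1].mean(axis=0)
        d = log_nf_n - log_nf_n1
        d = d[np.isfinite(d)]
        vs[n] = float(np.std(d, ddof=1))
    series = pd.Series(vs, name="V")
    series.index.name = "n"
    hits = [n for n, v in vs.items() if v < cutoff]
    if hits:
        return OptimalN(nf_pairwise=series, optimal_n=hits[0], cutoff=cutoff, satisfied=True)
    return OptimalN(nf_pairwise=series, optimal_n=k, cutoff=cutoff, satisfied=False)


def nf_geometric_mean(rq: RQMatrix, genes: list[str]) -> pd.Series:
    """Normalization factor: per-sample geometric mean RQ of ``genes``."""
    sub = rq.rq.loc[genes]
    return pd.Series(gmean(sub.to_numpy(), axis=0), index=sub.columns, name="nf")
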
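"""Normalization factors and target-gene relative expression.

The normalization factor at a sample is the geometric mean of the reference
genes' relative quantities there; a target's relative expression is its own RQ
divided by the factor. Comparing the same target normalized two ways (e.g. the
validated stable pair vs the least-stable candidate) quantifies, in log2 fold
change, how much the choice of reference genes distorts the biology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .data import RQMatrix
from .errors import InsufficientDataError

__all__ = [
    "NormalizedExpression",
    "normalization_factor",
    "relative_expression",
    "group_summaries",
    "compare_normalizations",
]


@dataclass
class NormalizedExpression:
    target: str
    references: list[str]
    nf: pd.Series  # sample -> normalization factor
    rel_expr: pd.Series  # sample -> RQ_target / nf
    log2_rel: pd.Series
    dropped_samples: list[str]


def normalization_factor(rq_refs: RQMatrix | pd.DataFrame, references: list[str] | None = None) -> pd.Series:
    """Per-sample geometric mean RQ over the reference genes.

    Samples missing any reference RQ are dropped with a warning.
    """
    mat = rq_refs.rq if isinstance(rq_refs, RQMatrix) else rq_refs
    refs = references if references is not None else list(mat.index)
    if not refs:
        raise InsufficientDataError("need >= 1 reference gene")
    missing_genes = [g for g in refs if g not in mat.index]
    if missing_genes:
        raise KeyError(f"reference gene(s) not in RQ matrix: {missing_genes}")
    sub = mat.loc[refs]
    complete = sub.notna().all(axis=0)
    dropped = list(sub.columns[~complete])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} sample(s) with missing reference RQ: {dropped}")
    sub = sub.loc[:, complete]
    return pd.Series(gmean(sub.to_numpy(), axis=0), index=sub.columns, name="nf")


def relative_expression(
    target_cq: pd.Series,
    nf: pd.Series,
    e_target: float = 2.0,
    target: str = "target",
    references: list[str] | None = None,
) -> NormalizedExpression:
    """Normalize a target gene's Cq vector by a per-sample normalization factor.

    rel_expr(s) = E_target**(Cqmin - Cq_s) / nf(s), anchored so the target's
    minimum-Cq sample has RQ 1 before normalization.
    """
    common = [s for s in nf.index if s in target_cq.index and np.isfinite(target_cq[s])]
    dropped = [s for s in nf.index if s not in common]
    if len(common) == 0:
        raise InsufficientDataError("target Cq and normalization factor share no samples")
    cq = target_cq[common].astype(float)
    rq = pd.Series(np.power(e_target, cq.min() - cq), index=common)
    rel = rq / nf[common]
    return NormalizedExpression(
        target=target,
        references=list(references or []),
        nf=nf[common],
        rel_expr=rel.rename("rel_expr"),
        log2_rel=np.log2(rel).rename("log2_rel"),
        dropped_samples=dropped,
    )


def group_summaries(
    ne: NormalizedExpression,
    metadata: pd.DataFrame,
    factors: list[str],
    bio_rep: str = "bio_rep",
) -> pd.DataFrame:
    """Mean +/- SD of relative expression per condition, over biological replicates.

    Technical replicates are assumed already collapsed into the Cq values; if a
    ``bio_rep`` factor is present, replicate expression values are first
    averaged within each (condition, bio_rep) cell so that the SD reflects
    biological replication only.
    """
    df = pd.DataFrame({"rel_expr": ne.rel_expr, "log2_rel": ne.log2_rel})
    df = df.join(metadata, how="left")
    group_cols = list(factors)
    if bio_rep in metadata.columns:
        per_rep = df.groupby(group_cols + [bio_rep], sort=True)["rel_expr"].mean().reset_index()
    else:
        per_rep = df.reset_index().rename(columns={"index": bio_rep})
    out = (
        per_rep.groupby(group_cols, sort=True)["rel_expr"]
        .agg(mean="mean", sd="std", n="size")
        .reset_index()
    )
    out["sd"] = out["sd"].fillna(0.0)
    return out


def compare_normalizations(a: NormalizedExpression, b: NormalizedExpression) -> tuple[pd.Series, float]:
    """Per-sample log2 discrepancy between two normalizations of the same target.

    Returns (discrepancy series, max absolute discrepancy). The discrepancy at
    sample s is log2_rel_a(s) - log2_rel_b(s).
    """
    if a.target != b.target:
        raise ValueError(f"targets differ: {a.target!r} vs {b.target!r}")
    if set(a.log2_rel.index) != set(b.log2_rel.index):
        diff = sorted(set(a.log2_rel.index) ^ set(b.log2_rel.index))
        raise ValueError(f"sample sets differ: {diff}")
    d = (a.log2_rel - b.log2_rel.reindex(a.log2_rel.index)).rename("log2_discrepancy")
    return d, float(d.abs().max())
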
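"""NormFinder model-based stability.

Log-scale expression y_igj (gene i, group g, sample j) is modelled as

    y_igj = alpha_ig + beta_gj + eps_igj,   eps ~ N(0, sigma2_ig)

i.e. a gene-in-group effect, a sample-in-group effect (mRNA loading) and
gene-specific noise. A gene's stability combines its estimated intragroup
variance sigma2_ig with the deviation d_ig of its group mean from its grand
mean (net of group-wide shifts):

    rho_i = mean_g( |d_ig| + sqrt(sigma2_ig / n_g) )

and, with a single group, rho_i = sqrt(sigma2_i). Lower rho = more stable.

Variance estimation corrects for the variance absorbed by per-sample centering
across the k genes. For the two-way layout with gene-specific variances the
double-centered residual sum of squares satisfies

    E[ RSS_i / (n_g - 1) ] = sigma2_i (k - 2)/k + S / k^2,   S = sum_i sigma2_i

so with S_hat = k/(k-1) * sum_i s2_i (unbiased for S) the moment estimator

    sigma2_hat_i = ( s2_i - S_hat / k^2 ) * k / (k - 2)

is unbiased; negative estimates are truncated at 0 and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError

__all__ = ["NormfinderResult", "normfinder_stability"]


@dataclass
class NormfinderResult:
    """Per-gene stability rho (ascending = most stable first) and components."""

    stability: pd.Series  # gene -> rho, sorted ascending
    ranking: pd.Series  # gene -> rank (1 = most stable)
    intragroup_var: pd.DataFrame  # genes x groups
    intergroup_dev: pd.DataFrame | None  # genes x groups (unshrunk d); None if 1 group
    grouping: str
    truncated: list[tuple[str, str]] = field(default_factory=list)  # (gene, group) with sigma2<0


def _group_variances(y: np.ndarray, bias_correction: bool) -> tuple[np.ndarray, np.ndarray]:
    """Intragroup variance estimates for one group's k x n matrix.

    Returns (sigma2_hat truncated at 0, raw untruncated estimates).
    """
    k, n = y.shape
    resid = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + y.mean()
    s2 = (resid**2).sum(axis=1) / (n - 1)
    if not bias_correction:
        return s2.copy(), s2
    s_hat = s2.sum() * k / (k - 1)
    raw = (s2 - s_hat / k**2) * k / (k - 2)
    return np.maximum(raw, 0.0), raw


def normfinder_stability(
    logrq: pd.DataFrame,
    groups: pd.Series | dict | None = None,
    min_genes: int = 3,
    bias_correction: bool = True,
    shrinkage: bool = True,
) -> NormfinderResult:
    """Compute NormFinder stability values.

    Parameters
    ----------
    logrq:
        Genes x samples matrix of log2 relative quantities. Because the
        per-gene Cq minimum is a constant, ``-Cq`` columns aligned the same way
        are an equivalent fast path.
    groups:
        Mapping sample -> group label, or None for the single-group
        (intragroup-only) mode used when a subset has no natural grouping.
    bias_correction:
        Apply the sample-centering variance correction (see module docstring).
    shrinkage:
        Shrink the intergroup deviations toward 0 by the empirical-Bayes factor
        gamma2 / (gamma2 + sigma2_ig / n_g), where gamma2 is the between-gene
        variance of the deviations net of their sampling noise.
    """
    genes = list(logrq.index)
    samples = list(logrq.columns)
    k = len(genes)
    if k < min_genes or k < 3:
        raise InsufficientDataError(
            f"NormFinder needs >= {max(min_genes, 3)} genes to separate sample effects; got {k}"
        )
    y_all = logrq.to_numpy(dtype=float)
    if not np.all(np.isfinite(y_all)):
        raise InsufficientDataError("NormFinder requires complete log-RQ data (no missing wells)")

    if groups is None:
        labels = pd.Series("all", index=samples)
        grouping = "none"
    else:
        labels = pd.Series({s: str(groups[s]) for s in samples})
        grouping = "groups"
    group_names = sorted(labels.unique())

    sigma2 = pd.DataFrame(index=genes, columns=group_names, dtype=float)
    truncated: list[tuple[str, str]] = []
    n_g: dict[str, int] = {}
    for g in group_names:
        cols = [s for s in samples if labels[s] == g]
        if len(cols) < 2:
            raise InsufficientDataError(f"group {g!r} has {len(cols)} sample(s); need >= 2")
        n_g[g] = len(cols)
        est, raw = _group_variances(logrq.loc[:, cols].to_numpy(dtype=float), bias_correction)
        sigma2[g] = est
        for i, gene in enumerate(genes):
            if raw[i] < 0:
                truncated.append((gene, g))

    if len(group_names) == 1:
        g = group_names[0]
        rho = np.sqrt(sigma2[g].to_numpy(dtype=float))
        stability = pd.Series(rho, index=genes, name="stability").sort_values(kind="stable")
        ranking = _ranks(stability, genes)
        return NormfinderResult(
            stability=stability,
            ranking=ranking,
            intragroup_var=sigma2,
            intergroup_dev=None,
            grouping=grouping,
            truncated=truncated,
        )

    # intergroup deviations: gene-in-group mean vs gene grand mean, net of the
    # group-wide shift (group grand mean vs overall grand mean). Weighted by
    # group size these sum to 0 per gene.
    grand_gene = y_all.mean(axis=1)  # over all samples
    grand_all = y_all.mean()
    d = pd.DataFrame(index=genes, columns=group_names, dtype=float)
    for g in group_names:
        cols = [s for s in samples if labels[s] == g]
        sub = logrq.loc[:, cols].to_numpy(dtype=float)
        d[g] = (sub.mean(axis=1) - grand_gene) - (sub.mean() - grand_all)

    d_used = d.copy()
    if shrinkage:
        for g in group_names:
            dv = d[g].to_numpy(dtype=float)
            noise = sigma2[g].to_numpy(dtype=float) / n_g[g]
            gamma2 = max(0.0, float((dv**2).sum() / (k - 1) - noise.mean()))
            denom = gamma2 + noise
            factor = np.where(denom > 0, gamma2 / np.where(denom > 0, denom, 1.0), 0.0)
            d_used[g] = dv * factor

    per_group = d_used.abs() + np.sqrt(sigma2.div(pd.Series(n_g)))
    rho = per_group.mean(axis=1)
    stability = pd.Series(rho, index=genes, name="stability").sort_values(kind="stable")
    ranking = _ranks(stability, genes)
    return NormfinderResult(
        stability=stability,
        ranking=ranking,
        intragroup_var=sigma2,
        intergroup_dev=d,
        grouping=grouping,
        truncated=truncated,
    )


def _ranks(sorted_stability: pd.Series, genes: list[str]) -> pd.Series:
    """Average ranks (ties share the mean rank), reported in input gene order."""
    r = sorted_stability.rank(method="average")
    return pd.Series({g: float(r[g]) for g in genes}, name="normfinder_rank")
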
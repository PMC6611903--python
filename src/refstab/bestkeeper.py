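"""BestKeeper descriptive stability on raw Cq values.

Per gene: geometric/arithmetic mean Cq, min, max, dispersion, CV% and the
x-fold dispersion E**sd. Dispersion is computed in BOTH conventions — the
BestKeeper applet's "SD (+/- Cq)", which is the mean absolute deviation from
the arithmetic mean, and the usual sample standard deviation — with the
ranking convention configurable (default: mean absolute deviation). Genes with
dispersion above 1 cycle are flagged "inconsistent" per the BestKeeper rule.

The BestKeeper index is the per-sample geometric mean Cq across included
genes; each gene's Pearson correlation against the index (two-sided t-test
p-value, no multiple-testing correction) measures its agreement with the
consensus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import CqDataset, collapse_replicates
from .errors import InsufficientDataError

__all__ = ["BestkeeperResult", "bestkeeper_descriptives", "bestkeeper_index", "bestkeeper_analysis"]

SD_INCONSISTENT = 1.0  # cycles


@dataclass
class BestkeeperResult:
    """Descriptive table, ranking, index and gene-vs-index correlations."""

    table: pd.DataFrame  # per-gene descriptive statistics
    ranking: pd.Series  # gene -> rank by ascending dispersion (configured convention)
    sd_convention: str  # "mad" or "sample"
    index: pd.Series | None = None  # sample -> geometric mean Cq
    correlations: pd.DataFrame | None = None  # gene -> r, p (NaN if undefined)


def _collapsed_wide(ds: CqDataset) -> pd.DataFrame:
    if ds.max_replicates > 1:
        ds, _ = collapse_replicates(ds)
    return ds.wide()


def bestkeeper_descriptives(ds: CqDataset, sd_convention: str = "mad") -> BestkeeperResult:
    """Per-gene BestKeeper statistics on replicate-collapsed raw Cq.

    ``sd_convention`` chooses the ranking dispersion: ``"mad"`` (applet
    convention, mean absolute deviation from the arithmetic mean) or
    ``"sample"`` (n-1 standard deviation). Both are always reported.
    """
    if sd_convention not in ("mad", "sample"):
        raise ValueError(f"sd_convention must be 'mad' or 'sample', got {sd_convention!r}")
    wide = _collapsed_wide(ds)
    if wide.shape[1] < 2:
        raise InsufficientDataError("BestKeeper needs >= 2 samples")
    rows = []
    for gene, row in wide.iterrows():
        v = row.dropna().to_numpy(dtype=float)
        ar_mean = float(v.mean())
        mad = float(np.abs(v - ar_mean).mean())
        sd = float(np.std(v, ddof=1))
        disp = mad if sd_convention == "mad" else sd
        e = ds.efficiency(gene)
        rows.append(
            {
                "gene": gene,
                "geo_mean": float(stats.gmean(v)),
                "ar_mean": ar_mean,
                "min": float(v.min()),
                "max": float(v.max()),
                "sd_mad": mad,
                "sd_sample": sd,
                "cv_pct": 100.0 * disp / ar_mean,
                "xfold_sd": float(e**disp),
                "zero_variance": bool(np.isclose(sd, 0.0)),
                "inconsistent": disp > SD_INCONSISTENT,
            }
        )
    table = pd.DataFrame(rows).set_index("gene")
    disp_col = "sd_mad" if sd_convention == "mad" else "sd_sample"
    order = table[disp_col].sort_values(kind="stable")
    order = order.iloc[np.lexsort((order.index, order.to_numpy()))]
    ranking = pd.Series(
        {g: float(i + 1) for i, g in enumerate(order.index)}, name="bestkeeper_rank"
    ).reindex(table.index)
    return BestkeeperResult(table=table, ranking=ranking, sd_convention=sd_convention)


def bestkeeper_index(ds: CqDataset, include: list[str] | None = None) -> tuple[pd.Series, pd.DataFrame]:
    """BestKeeper index and per-gene Pearson correlation against it.

    index(s) = geometric mean Cq over included genes at sample s, defined for
    samples with complete data on those genes. Zero-variance genes get an
    undefined (NaN) correlation.
    """
    wide = _collapsed_wide(ds)
    genes = include if include is not None else list(wide.index)
    if len(genes) < 3:
        raise InsufficientDataError("BestKeeper index needs >= 3 genes")
    sub = wide.loc[genes].dropna(axis=1)
    if sub.shape[1] < 3:
        raise InsufficientDataError("BestKeeper correlations need >= 3 complete samples")
    index = pd.Series(stats.gmean(sub.to_numpy(), axis=0), index=sub.columns, name="bk_index")
    rows = []
    for gene in genes:
        v = sub.loc[gene].to_numpy(dtype=float)
        if np.isclose(np.std(v), 0.0) or np.isclose(np.std(index.to_numpy()), 0.0):
            # identical genes make the index equal to each gene up to rounding
            if np.allclose(v - v.mean(), index.to_numpy() - index.to_numpy().mean()):
                rows.append({"gene": gene, "r": 1.0, "p": 0.0})
            else:
                rows.append({"gene": gene, "r": np.nan, "p": np.nan})
            continue
        r, p = stats.pearsonr(v, index.to_numpy())
        r = float(r)
        if 1.0 - abs(r) < 1e-12:  # identical-gene panels: snap rounding dust
            r = 1.0 if r > 0 else -1.0
        rows.append({"gene": gene, "r": r, "p": float(p)})
    return index, pd.DataFrame(rows).set_index("gene")


def bestkeeper_analysis(
    ds: CqDataset, include: list[str] | None = None, sd_convention: str = "mad"
) -> BestkeeperResult:
    """Descriptives, ranking, index and correlations in one result."""
    res = bestkeeper_descriptives(ds, sd_convention=sd_convention)
    index, corr = bestkeeper_index(ds, include=include)
    res.index = index
    res.correlations = corr
    return res
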
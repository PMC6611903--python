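"""Cq data model: parsing, replicate collapsing, subsetting and the RQ transform.

The central container is :class:`CqDataset`, a long-format table of
quantification-cycle (Cq) values — one row per well, i.e. per
(sample, gene, technical replicate) — together with a sample-metadata table of
experimental design factors (altitude, collection month, subsequent fate, ...)
and optional per-gene amplification factors E.

Expression on the relative-quantity scale is held in :class:`RQMatrix`, where
each gene is rescaled so its lowest-Cq (highest-expression) sample equals 1:

    RQ(g, s) = E_g ** (Cqmin_g - Cq_gs)

with E_g = 2 (perfect doubling) unless efficiency correction is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CqValueError, FormatError, InsufficientDataError

CQ_COLUMNS = ("sample", "gene", "replicate", "cq")

__all__ = [
    "CqDataset",
    "RQMatrix",
    "read_cq_table",
    "write_cq_table",
    "collapse_replicates",
    "subset",
    "relative_quantities",
]


@dataclass
class CqDataset:
    """Long-format Cq measurements plus sample metadata.

    Parameters
    ----------
    cq:
        DataFrame with columns ``sample, gene, replicate, cq``; one row per well.
    metadata:
        DataFrame indexed by sample identifier; columns are design factors.
        Factor levels are compared as strings, case-sensitively.
    efficiencies:
        Optional mapping gene -> amplification factor E (per-cycle fold change).
        Genes absent from the mapping default to E = 2.0.
    """

    cq: pd.DataFrame
    metadata: pd.DataFrame
    efficiencies: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CQ_COLUMNS if c not in self.cq.columns]
        if missing:
            raise FormatError(f"Cq table missing column(s): {missing}")
        self.cq = self.cq.loc[:, list(CQ_COLUMNS)].reset_index(drop=True)
        self.cq["sample"] = self.cq["sample"].astype(str)
        self.cq["gene"] = self.cq["gene"].astype(str)
        vals = pd.to_numeric(self.cq["cq"], errors="coerce").to_numpy(dtype=float)
        bad = ~np.isfinite(vals) | (vals <= 0)
        if bad.any():
            row = self.cq.loc[np.flatnonzero(bad)[0]]
            raise CqValueError(
                f"invalid Cq {row['cq']!r} at sample={row['sample']!r} "
                f"gene={row['gene']!r} replicate={row['replicate']!r}"
            )
        self.cq["cq"] = vals
        dup = self.cq.duplicated(subset=["sample", "gene", "replicate"])
        if dup.any():
            row = self.cq.loc[dup.idxmax()]
            raise FormatError(
                f"duplicate well: sample={row['sample']!r} gene={row['gene']!r} "
                f"replicate={row['replicate']!r}"
            )
        if self.metadata.index.name != "sample":
            if "sample" in self.metadata.columns:
                self.metadata = self.metadata.set_index("sample")
            else:
                self.metadata.index.name = "sample"
        self.metadata.index = self.metadata.index.astype(str)
        if self.metadata.index.duplicated().any():
            raise FormatError("duplicate sample identifiers in metadata")
        unknown = set(self.cq["sample"]) - set(self.metadata.index)
        if unknown:
            raise FormatError(f"Cq table references samples absent from metadata: {sorted(unknown)}")
        for e in self.efficiencies.values():
            if not (np.isfinite(e) and e > 1):
                raise CqValueError(f"amplification factor must be > 1, got {e}")

    @property
    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.cq["gene"]))

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.cq["sample"]))

    @property
    def max_replicates(self) -> int:
        return int(self.cq.groupby(["sample", "gene"]).size().max())

    def efficiency(self, gene: str) -> float:
        return float(self.efficiencies.get(gene, 2.0))

    def wide(self) -> pd.DataFrame:
        """Genes x samples matrix of Cq values (requires collapsed replicates)."""
        if self.max_replicates > 1:
            raise InsufficientDataError(
                "dataset has multiple technical replicates; collapse_replicates() first"
            )
        w = self.cq.pivot(index="gene", columns="sample", values="cq")
        return w.reindex(index=self.genes, columns=self.samples)


@dataclass
class RQMatrix:
    """Relative quantities, genes x samples; per-gene max is exactly 1."""

    rq: pd.DataFrame  # index: gene, columns: sample
    missing: list[tuple[str, str]] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return list(self.rq.index)

    @property
    def samples(self) -> list[str]:
        return list(self.rq.columns)

    @property
    def log2(self) -> pd.DataFrame:
        """log2 relative quantities; <= 0 everywhere by construction."""
        return np.log2(self.rq)


def read_cq_table(path, metadata_path, efficiencies: dict[str, float] | None = None) -> CqDataset:
    """Read a long-format Cq CSV (``sample,gene,replicate,cq``) plus metadata CSV.

    The metadata CSV must have a ``sample`` column; remaining columns are design
    factors. Raises :class:`FormatError` for structural problems and
    :class:`CqValueError` for non-numeric/non-positive Cq values (named by well).
    """
    cq = pd.read_csv(path, dtype={"sample": str, "gene": str}, float_precision="round_trip")
    meta = pd.read_csv(metadata_path, dtype=str)
    if "sample" not in meta.columns:
        raise FormatError("metadata CSV must contain a 'sample' column")
    return CqDataset(cq=cq, metadata=meta.set_index("sample"), efficiencies=dict(efficiencies or {}))


def write_cq_table(ds: CqDataset, path, metadata_path) -> None:
    """Write the dataset in the same dialect :func:`read_cq_table` accepts.

    Floats are written with shortest round-trip repr so read(write(ds)) is
    value-identical.
    """
    out = ds.cq.copy()
    out["cq"] = [repr(float(v)) for v in out["cq"]]
    out.to_csv(path, index=False)
    ds.metadata.reset_index().to_csv(metadata_path, index=False)


def collapse_replicates(ds: CqDataset, sd_tol: float = 0.5) -> tuple[CqDataset, pd.DataFrame]:
    """Average technical replicates per (sample, gene).

    Returns the collapsed dataset (replicate index 1 everywhere) and a QC table
    with the replicate standard deviation (n-1 denominator) per well group and a
    flag for SD > ``sd_tol`` cycles. Single-replicate groups get SD 0.
    """
    g = ds.cq.groupby(["sample", "gene"], sort=False)["cq"]
    stats = g.agg(mean="mean", sd="std", n="size").reset_index()
    stats["sd"] = stats["sd"].fillna(0.0)
    stats["flagged"] = stats["sd"] > sd_tol
    collapsed = stats.rename(columns={"mean": "cq"})[["sample", "gene", "cq"]].copy()
    collapsed["replicate"] = 1
    out = CqDataset(cq=collapsed, metadata=ds.metadata.copy(), efficiencies=dict(ds.efficiencies))
    qc = stats[["sample", "gene", "n", "sd", "flagged"]]
    return out, qc


def subset(ds: CqDataset, factor: str, level: str) -> CqDataset:
    """Restrict the dataset to samples whose ``factor`` equals ``level``.

    The gene list is unchanged. Requires the level to occur in at least two
    samples (stability statistics need n >= 2).
    """
    if factor not in ds.metadata.columns:
        raise KeyError(f"unknown design factor {factor!r}; have {list(ds.metadata.columns)}")
    keep = ds.metadata.index[ds.metadata[factor].astype(str) == str(level)]
    if len(keep) == 0:
        raise KeyError(f"level {level!r} not found for factor {factor!r}")
    if len(keep) < 2:
        raise InsufficientDataError(
            f"factor {factor!r} level {level!r} matches {len(keep)} sample(s); need >= 2"
        )
    cq = ds.cq[ds.cq["sample"].isin(set(keep))].reset_index(drop=True)
    return CqDataset(cq=cq, metadata=ds.metadata.loc[keep].copy(), efficiencies=dict(ds.efficiencies))


def relative_quantities(ds: CqDataset, use_efficiency: bool = False) -> RQMatrix:
    """Transform collapsed Cq values to relative quantities.

    RQ(g, s) = E_g ** (Cqmin_g - Cq_gs), where Cqmin_g is the minimum Cq of
    gene g *within this dataset* (i.e. within the analysed subset) and E_g is 2
    unless ``use_efficiency`` and a per-gene amplification factor is available.
    Missing wells propagate as missing RQ and are listed in ``RQMatrix.missing``.
    """
    wide = ds.wide()
    e = np.array([ds.efficiency(g) if use_efficiency else 2.0 for g in wide.index])
    cqmin = wide.min(axis=1)
    rq = pd.DataFrame(
        np.power(e[:, None], cqmin.to_numpy()[:, None] - wide.to_numpy()),
        index=wide.index,
        columns=wide.columns,
    )
    miss = [(g, s) for g, s in zip(*np.nonzero(wide.isna().to_numpy()))]
    missing = [(wide.index[g], wide.columns[s]) for g, s in miss]
    return RQMatrix(rq=rq, missing=missing)
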
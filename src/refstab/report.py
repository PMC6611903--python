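"""Study orchestration: run stability methods over experimental-group subsets
and emit per-subset tables, comprehensive rankings and an optimal-n report.

The report bundle is a pure function of (inputs, config, seed): per subset and
method a stability TSV, per subset a comprehensive-ranking TSV, plus a
machine-readable JSON summary and a plain-text run log recording the
conventions in force (dispersion convention, geNorm tie rule, RQ scope).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .bestkeeper import bestkeeper_analysis
from .data import CqDataset, collapse_replicates, relative_quantities, subset
from .delta_ct import delta_ct_stability
from .genorm import genorm_rank, optimal_gene_count
from .normfinder import normfinder_stability
from .ranking import comprehensive_rank

ALL_METHODS = ("genorm", "normfinder", "bestkeeper", "deltact")


@dataclass
class AnalysisConfig:
    """What to run and how; mirrors the CLI flags."""

    subsets: list[tuple[str, str] | str] = field(default_factory=lambda: ["total"])
    methods: tuple[str, ...] = ALL_METHODS
    v_cutoff: float = 0.15
    use_efficiency: bool = False
    sd_convention: str = "mad"  # BestKeeper dispersion convention
    final_pair_rank: float = 1.0  # geNorm tie rule for the most stable pair
    group_factor: str | None = None  # NormFinder grouping; None = intragroup only
    global_rq: bool = False  # compute Cqmin before subsetting instead of within
    seed: int = 0

    def __post_init__(self):
        if not self.methods:
            raise ValueError("methods must be non-empty")
        bad = [m for m in self.methods if m not in ALL_METHODS]
        if bad:
            raise ValueError(f"unknown method(s) {bad}; choose from {ALL_METHODS}")
        if self.v_cutoff <= 0:
            raise ValueError("v_cutoff must be > 0")


def analyse_subset(ds: CqDataset, cfg: AnalysisConfig, rq_full=None) -> dict:
    """Run the configured methods on one (already subset) dataset."""
    collapsed, rep_qc = collapse_replicates(ds)
    if cfg.global_rq and rq_full is not None:
        rq = type(rq_full)(rq=rq_full.rq.loc[:, collapsed.samples], missing=rq_full.missing)
    else:
        rq = relative_quantities(collapsed, use_efficiency=cfg.use_efficiency)
    out: dict = {"replicate_qc": rep_qc, "methods": {}, "ranks": {}, "errors": {}}
    if "genorm" in cfg.methods:
        try:
            gres = genorm_rank(rq, final_pair_rank=cfg.final_pair_rank)
            opt = optimal_gene_count(rq, gres.ranking_order, cutoff=cfg.v_cutoff)
            out["methods"]["genorm"] = gres
            out["optimal_n"] = opt
            out["ranks"]["genorm"] = gres.ranking
        except Exception as exc:  # keep other methods running
            out["errors"]["genorm"] = str(exc)
    if "normfinder" in cfg.methods:
        try:
            groups = None
            if cfg.group_factor and cfg.group_factor in collapsed.metadata.columns:
                levels = collapsed.metadata[cfg.group_factor].astype(str)
                if levels.nunique() > 1:
                    groups = levels
            nres = normfinder_stability(rq.log2, groups=groups)
            out["methods"]["normfinder"] = nres
            out["ranks"]["normfinder"] = nres.ranking
        except Exception as exc:
            out["errors"]["normfinder"] = str(exc)
    if "bestkeeper" in cfg.methods:
        try:
            bres = bestkeeper_analysis(collapsed, sd_convention=cfg.sd_convention)
            out["methods"]["bestkeeper"] = bres
            out["ranks"]["bestkeeper"] = bres.ranking
        except Exception as exc:
            out["errors"]["bestkeeper"] = str(exc)
    if "deltact" in cfg.methods:
        try:
            dres = delta_ct_stability(collapsed)
            out["methods"]["deltact"] = dres
            out["ranks"]["deltact"] = dres.ranking
        except Exception as exc:
            out["errors"]["deltact"] = str(exc)
    if len(out["ranks"]) >= 2:
        out["comprehensive"] = comprehensive_rank(out["ranks"])
    return out


def run_study(ds: CqDataset, cfg: AnalysisConfig, outdir: str | Path) -> dict:
    """Run every configured subset, write the report bundle, return the results.

    A failure in one subset is recorded in the summary and does not abort the
    others. Files are written with fixed column order and repr floats so the
    bundle is byte-identical across runs with the same inputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rq_full = None
    if cfg.global_rq:
        collapsed_full, _ = collapse_replicates(ds)
        rq_full = relative_quantities(collapsed_full, use_efficiency=cfg.use_efficiency)

    summary: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "conventions": {
            "sd_convention": cfg.sd_convention,
            "final_pair_rank": cfg.final_pair_rank,
            "use_efficiency": cfg.use_efficiency,
            "global_rq": cfg.global_rq,
            "v_cutoff": cfg.v_cutoff,
        },
        "subsets": {},
    }
    results: dict = {}
    log_lines = [
        f"refstab {__version__}",
        f"seed={cfg.seed} methods={list(cfg.methods)}",
        f"sd_convention={cfg.sd_convention} final_pair_rank={cfg.final_pair_rank} "
        f"use_efficiency={cfg.use_efficiency} global_rq={cfg.global_rq} v_cutoff={cfg.v_cutoff}",
    ]
    for spec in cfg.subsets:
        name = "total" if spec == "total" else f"{spec[0]}={spec[1]}"
        tag = name.replace("=", "_")
        entry: dict = {"errors": {}}
        try:
            sub_ds = ds if spec == "total" else subset(ds, spec[0], spec[1])
            res = analyse_subset(sub_ds, cfg, rq_full=rq_full)
            results[name] = res
            entry["n_samples"] = len(sub_ds.samples)
            entry["errors"] = res["errors"]
            _write_subset(res, outdir, tag)
            if "comprehensive" in res:
                comp = res["comprehensive"]
                entry["n_methods"] = comp.n_methods
                entry["order"] = comp.order
            if "optimal_n" in res:
                entry["optimal_n"] = res["optimal_n"].optimal_n
                entry["v_satisfied"] = res["optimal_n"].satisfied
            log_lines.append(f"[{name}] ok; errors={res['errors'] or 'none'}")
        except Exception as exc:
            entry["failed"] = str(exc)
            log_lines.append(f"[{name}] FAILED: {exc}")
        summary["subsets"][name] = entry
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return results


def _tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def _write_subset(res: dict, outdir: Path, tag: str) -> None:
    m = res["methods"]
    if "genorm" in m:
        g = m["genorm"]
        _tsv(
            pd.DataFrame({"M": g.m_single_pass, "rank": res["ranks"]["genorm"]}),
            outdir / f"{tag}_genorm.tsv",
        )
        if "optimal_n" in res:
            _tsv(res["optimal_n"].nf_pairwise.to_frame(), outdir / f"{tag}_genorm_v.tsv")
    if "normfinder" in m:
        n = m["normfinder"]
        _tsv(
            pd.DataFrame({"stability": n.stability.reindex(n.ranking.index), "rank": n.ranking}),
            outdir / f"{tag}_normfinder.tsv",
        )
    if "bestkeeper" in m:
        b = m["bestkeeper"]
        t = b.table.copy()
        if b.correlations is not None:
            t = t.join(b.correlations.rename(columns={"r": "r_vs_index", "p": "p"}))
        t["rank"] = b.ranking
        _tsv(t, outdir / f"{tag}_bestkeeper.tsv")
    if "deltact" in m:
        d = m["deltact"]
        _tsv(
            pd.DataFrame({"std_dev": d.mean_sd, "rank": d.ranking}),
            outdir / f"{tag}_deltact.tsv",
        )
    if "comprehensive" in res:
        _tsv(res["comprehensive"].table(), outdir / f"{tag}_comprehensive.tsv")
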
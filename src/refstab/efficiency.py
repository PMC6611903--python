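"""Amplification-efficiency arithmetic, per-curve estimation and primer QC.

The amplification factor E is the per-cycle fold change of product
(2.0 = perfect doubling); percent efficiency is (E - 1) x 100. Per-curve
estimation follows the window-of-linearity idea: after baseline subtraction,
the contiguous run of cycles where log-fluorescence is most linear in cycle
number gives E = 10**slope of the log10(F) ~ cycle regression.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError, FormatError

__all__ = [
    "EfficiencyRecord",
    "AmplificationCurve",
    "efficiency_percent",
    "amp_factor_from_percent",
    "estimate_efficiency",
    "qc_primer",
    "mean_gene_efficiency",
    "simulate_curve",
    "read_curves",
    "write_efficiency_table",
    "check_consistency",
]

QC_BAND = (90.0, 110.0)
MIN_R2 = 0.99


@dataclass(frozen=True)
class EfficiencyRecord:
    """Per-gene (or per-curve) amplification efficiency and fit quality."""

    gene: str
    amp_factor: float
    efficiency_pct: float
    r_squared: float
    qc_pass: bool | None = None

    @property
    def consistent(self) -> bool:
        """True if amp_factor and efficiency_pct agree by (E-1)x100 within 0.05%."""
        return abs(efficiency_percent(self.amp_factor) - self.efficiency_pct) <= 0.05


@dataclass(frozen=True)
class AmplificationCurve:
    """Raw fluorescence readings for one well, indexed by cycle 1..C."""

    well: str
    gene: str
    sample: str
    fluorescence: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.fluorescence, dtype=float)
        if f.ndim != 1 or f.size < 10:
            raise FormatError(f"curve {self.well!r}: need >= 10 cycles, got {f.size}")
        if not np.all(np.isfinite(f)):
            raise FormatError(f"curve {self.well!r}: non-finite fluorescence")
        object.__setattr__(self, "fluorescence", f)


def efficiency_percent(amp_factor: float) -> float:
    """Convert amplification factor E to percent efficiency, (E - 1) x 100."""
    if not (np.isfinite(amp_factor) and amp_factor > 1):
        raise ValueError(f"amplification factor must be > 1 (no amplification), got {amp_factor}")
    return (amp_factor - 1.0) * 100.0


def amp_factor_from_percent(pct: float) -> float:
    """Inverse of :func:`efficiency_percent`."""
    if not (np.isfinite(pct) and pct > 0):
        raise ValueError(f"percent efficiency must be > 0, got {pct}")
    return 1.0 + pct / 100.0


def estimate_efficiency(
    curve: AmplificationCurve,
    window_size: int = 4,
    baseline_cycles: int = 3,
) -> EfficiencyRecord:
    """Estimate E from one amplification curve.

    Subtracts the mean of the first ``baseline_cycles`` readings, then scans all
    contiguous windows of ``window_size`` cycles with strictly positive corrected
    fluorescence, fits log10(F) against cycle number and keeps the window with
    the highest R^2 among windows showing real amplification (slope implying
    E > 1.1, which excludes flat baseline/plateau stretches). Returns
    E = 10**slope and the window's R^2.
    """
    f = curve.fluorescence
    if f.size < baseline_cycles + window_size:
        raise EstimationError(
            f"curve {curve.well!r}: {f.size} cycles < baseline {baseline_cycles} + window {window_size}"
        )
    baseline = f[:baseline_cycles].mean() if baseline_cycles > 0 else 0.0
    corrected = f - baseline
    cycles = np.arange(1, f.size + 1, dtype=float)
    min_slope = np.log10(1.1)
    best: tuple[float, float] | None = None  # (r2, slope)
    for start in range(f.size - window_size + 1):
        win = corrected[start : start + window_size]
        if np.any(win <= 0):
            continue
        res = stats.linregress(cycles[start : start + window_size], np.log10(win))
        r2 = res.rvalue**2
        if res.slope >= min_slope and (best is None or r2 > best[0]):
            best = (r2, res.slope)
    if best is None:
        raise EstimationError(
            f"curve {curve.well!r}: no window of {window_size} cycles with positive "
            "baseline-corrected fluorescence and measurable amplification"
        )
    r2, slope = best
    e = float(10.0**slope)
    return EfficiencyRecord(
        gene=curve.gene, amp_factor=e, efficiency_pct=efficiency_percent(e), r_squared=float(r2)
    )


def qc_primer(
    rec: EfficiencyRecord,
    band: tuple[float, float] = QC_BAND,
    min_r2: float = MIN_R2,
) -> EfficiencyRecord:
    """Set the QC flag: efficiency within [lo, hi] percent (inclusive) and R^2 >= min_r2."""
    lo, hi = band
    ok = (lo <= rec.efficiency_pct <= hi) and (rec.r_squared >= min_r2)
    return replace(rec, qc_pass=bool(ok))


def mean_gene_efficiency(records: list[EfficiencyRecord]) -> dict[str, float]:
    """Arithmetic mean of per-curve E over each gene's wells (used downstream)."""
    by_gene: dict[str, list[float]] = {}
    for r in records:
        by_gene.setdefault(r.gene, []).append(r.amp_factor)
    return {g: float(np.mean(v)) for g, v in by_gene.items()}


def check_consistency(records: list[EfficiencyRecord]) -> pd.DataFrame:
    """Report stated vs recomputed percent efficiency for externally supplied tables.

    Flags rows where the stated percentage disagrees with (E - 1) x 100 by more
    than 0.05 points; the toolkit reports the conversion rather than reconciling.
    """
    rows = []
    for r in records:
        recomputed = efficiency_percent(r.amp_factor)
        rows.append(
            {
                "gene": r.gene,
                "amp_factor": r.amp_factor,
                "stated_pct": r.efficiency_pct,
                "recomputed_pct": recomputed,
                "consistent": abs(recomputed - r.efficiency_pct) <= 0.05,
            }
        )
    return pd.DataFrame(rows)


def simulate_curve(
    well: str = "w1",
    gene: str = "g",
    sample: str = "s",
    e: float = 2.0,
    f0: float = 1e-3,
    n_cycles: int = 40,
    baseline: float = 0.0,
    plateau: float | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> AmplificationCurve:
    """Generate a simple exponential (optionally saturating, noisy) curve.

    F_c = baseline + min(f0 * E**c, plateau) * (1 + multiplicative noise).
    """
    c = np.arange(1, n_cycles + 1, dtype=float)
    signal = f0 * np.power(e, c)
    if plateau is not None:
        signal = np.minimum(signal, plateau)
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng(0)
        signal = signal * (1.0 + rng.normal(0.0, noise_sd, size=signal.size))
    return AmplificationCurve(well=well, gene=gene, sample=sample, fluorescence=baseline + signal)


def read_curves(path) -> list[AmplificationCurve]:
    """Read curves from CSV with header ``well,gene,sample,cycle,fluorescence``."""
    df = pd.read_csv(path)
    need = {"well", "gene", "sample", "cycle", "fluorescence"}
    if not need.issubset(df.columns):
        raise FormatError(f"curve CSV missing column(s): {sorted(need - set(df.columns))}")
    curves = []
    for (well, gene, samp), grp in df.groupby(["well", "gene", "sample"], sort=False):
        grp = grp.sort_values("cycle")
        curves.append(
            AmplificationCurve(
                well=str(well), gene=str(gene), sample=str(samp),
                fluorescence=grp["fluorescence"].to_numpy(dtype=float),
            )
        )
    return curves


def write_efficiency_table(records: list[EfficiencyRecord], path) -> None:
    """Write ``gene,amp_factor,efficiency_pct,r_squared,qc_pass`` CSV."""
    pd.DataFrame(
        [
            {
                "gene": r.gene,
                "amp_factor": r.amp_factor,
                "efficiency_pct": r.efficiency_pct,
                "r_squared": r.r_squared,
                "qc_pass": r.qc_pass,
            }
            for r in records
        ]
    ).to_csv(path, index=False)
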
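"""Synthetic Cq-data generator emulating a field translocation study.

The generator produces the data structure of an alpine masting-plant
experiment: 8 candidate reference genes measured by RT-qPCR in triplicate over
a factorial design of altitudes x collection months x subsequent fate
(vegetative / flowering) x biological replicates, with one high-abundance,
unstable ribosomal gene (U18S-like, mean Cq ~ 10) and several stable genes
(mean Cq ~ 18-23).

Generative model (log2 expression scale):

    x_gs  = delta_s + sum_f beta_g,f(level_f(s)) + eps_gs
    Cq_gsr = mu_g - x_gs * (log 2 / log E_g) + tau_gsr

where delta_s ~ N(0, sigma_load^2) is a per-sample mRNA-loading effect shared
by all genes, beta are fixed design effects, eps_gs ~ N(0, sigma_g^2) is
gene-specific biological noise and tau ~ N(0, sigma_tech^2) is per-well
technical noise. Efficiency enters as a slope rescaling: a one-log2 change in
template shifts Cq by 1/log2(E_g) cycles.

Ground truth for recovery tests: a gene's non-loading log2 variance is
sigma_g^2 plus the design-induced variance of its summed beta effects over the
realized samples; the true stability ordering sorts this ascending.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data import CqDataset

__all__ = [
    "GeneProfile",
    "SimConfig",
    "SimTruth",
    "simulate_experiment",
    "default_study_config",
    "PANELS",
]

# Published per-gene primer amplification factors for the two study panels,
# used both as simulator defaults and as inputs to efficiency QC.
PANELS: dict[str, dict[str, float]] = {
    "celmisia": {
        "EF": 1.995,
        "eIF": 2.087,
        "GAPDH": 2.055,
        "U18S": 1.954,
        "SAND": 1.972,
        "MTP": 1.977,
        "PGK1": 1.99,
        "PP2A": 2.116,
    },
    "chionochloa": {
        "EF": 2.077,
        "GAPDH": 2.073,
        "U18S": 1.965,
        "NBP": 1.984,
        "ExP": 1.968,
        "THP": 2.045,
        "Actin": 2.003,
        "B-Tubulin": 1.974,
    },
}


@dataclass
class GeneProfile:
    """Generative parameters for one candidate gene.

    ``effects`` maps design factor -> {level -> log2 expression offset}; levels
    absent from the mapping contribute 0.
    """

    name: str
    base_cq: float
    sigma: float  # gene-specific biological noise, log2 units
    amp_factor: float = 2.0
    effects: dict[str, dict[str, float]] = field(default_factory=dict)

    def beta(self, levels: dict[str, str]) -> float:
        return sum(self.effects.get(f, {}).get(lv, 0.0) for f, lv in levels.items())


@dataclass
class SimConfig:
    """Design and noise configuration for :func:`simulate_experiment`."""

    genes: list[GeneProfile]
    factors: dict[str, list[str]]  # ordered factor -> levels (incl. bio_rep)
    tech_reps: int = 3
    sigma_load: float = 0.8  # per-sample mRNA-loading SD, log2 units
    sigma_tech: float = 0.15  # per-well technical SD, cycles
    seed: int = 0
    sample_prefix: str = "S"

    def validate(self) -> None:
        if not self.genes:
            raise ValueError("need >= 1 gene profile")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names")
        for g in self.genes:
            if g.sigma < 0 or g.amp_factor <= 1:
                raise ValueError(f"gene {g.name!r}: sigma >= 0 and E > 1 required")
        if self.sigma_load < 0 or self.sigma_tech < 0 or self.tech_reps < 1:
            raise ValueError("sds must be >= 0 and tech_reps >= 1")
        for f, lv in self.factors.items():
            if not lv:
                raise ValueError(f"factor {f!r} has no levels")

    def design(self) -> pd.DataFrame:
        """Metadata table: one sample per cell of the full factorial design."""
        names = list(self.factors)
        rows = list(itertools.product(*(self.factors[f] for f in names)))
        idx = [f"{self.sample_prefix}{i + 1:03d}" for i in range(len(rows))]
        meta = pd.DataFrame(rows, columns=names, index=idx)
        meta.index.name = "sample"
        return meta


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset."""

    true_log2_variance: dict[str, float]  # sigma_g^2 + design-induced beta variance
    ordering: list[str]  # most stable first
    stable_pair: tuple[str, str]
    least_stable: str
    config: SimConfig

    def to_json(self) -> str:
        d = {
            "true_log2_variance": self.true_log2_variance,
            "ordering": self.ordering,
            "stable_pair": list(self.stable_pair),
            "least_stable": self.least_stable,
            "config": asdict(self.config),
        }
        return json.dumps(d, indent=2)


def simulate_experiment(cfg: SimConfig, seed: int | None = None) -> tuple[CqDataset, SimTruth]:
    """Draw one synthetic experiment; deterministic given the seed.

    RNG streams are split per purpose and per gene index via seed sequences, so
    adding a gene to the panel leaves the other genes' draws untouched.
    """
    cfg.validate()
    s = int(cfg.seed if seed is None else seed)
    meta = cfg.design()
    samples = list(meta.index)
    n = len(samples)
    r = cfg.tech_reps

    load_rng = np.random.default_rng(np.random.SeedSequence([s, 101]))
    delta = load_rng.normal(0.0, cfg.sigma_load, size=n)

    records = []
    truth_var: dict[str, float] = {}
    for gi, gene in enumerate(cfg.genes):
        eps_rng = np.random.default_rng(np.random.SeedSequence([s, 211, gi]))
        tech_rng = np.random.default_rng(np.random.SeedSequence([s, 307, gi]))
        eps = eps_rng.normal(0.0, gene.sigma, size=n)
        tau = tech_rng.normal(0.0, cfg.sigma_tech, size=(n, r))
        beta = np.array([gene.beta(meta.loc[smp].to_dict()) for smp in samples])
        x = delta + beta + eps
        slope = np.log(2.0) / np.log(gene.amp_factor)
        # floor at 1 cycle: a reaction cannot cross threshold before the first
        # cycle; with the default panels this touches < 0.01% of wells
        cq = np.maximum(gene.base_cq - x[:, None] * slope + tau, 1.0)
        for si, smp in enumerate(samples):
            for rep in range(r):
                records.append((smp, gene.name, rep + 1, cq[si, rep]))
        truth_var[gene.name] = gene.sigma**2 + float(np.var(beta))  # population variance
    cq_df = pd.DataFrame(records, columns=["sample", "gene", "replicate", "cq"])
    ds = CqDataset(
        cq=cq_df,
        metadata=meta.copy(),
        efficiencies={g.name: g.amp_factor for g in cfg.genes},
    )
    ordering = sorted(truth_var, key=lambda g: (truth_var[g], g))
    truth = SimTruth(
        true_log2_variance=truth_var,
        ordering=ordering,
        stable_pair=(ordering[0], ordering[1]),
        least_stable=ordering[-1],
        config=cfg,
    )
    return ds, truth


def _panel_profiles(species: str) -> list[GeneProfile]:
    """Default gene profiles for each study panel.

    Two designed-stable genes (the study's validated pair), a third nearly as
    stable (the study found V2/3 ~ 0, i.e. several concordant genes), four
    moderately variable genes with small seasonal/altitudinal responses, and a
    U18S-like gene: high abundance (Cq ~ 10), large noise and a 2-log2 shift
    with subsequent fate.
    """
    e = PANELS[species]
    if species == "celmisia":
        month = {"March": 1.0, "May": -1.0}  # scaled by amplitude below
        return [
            GeneProfile("GAPDH", 18.5, 0.10, e["GAPDH"]),
            GeneProfile("PP2A", 19.5, 0.10, e["PP2A"]),
            GeneProfile("SAND", 21.0, 0.32, e["SAND"]),
            GeneProfile("EF", 20.0, 0.50, e["EF"], {"month": {k: 0.3 * v for k, v in month.items()}}),
            GeneProfile("eIF", 22.0, 0.65, e["eIF"], {"month": {k: 0.4 * v for k, v in month.items()}}),
            GeneProfile("MTP", 21.5, 0.80, e["MTP"], {"altitude": {"1070": 0.5, "1520": -0.5}}),
            GeneProfile("PGK1", 22.5, 0.95, e["PGK1"], {"month": {k: 0.5 * v for k, v in month.items()}}),
            GeneProfile("U18S", 10.0, 1.20, e["U18S"], {"fate": {"flowering": 2.0}}),
        ]
    if species == "chionochloa":
        month = {"March": 1.0, "September": -1.0}
        return [
            GeneProfile("ExP", 19.0, 0.10, e["ExP"]),
            GeneProfile("THP", 20.0, 0.10, e["THP"]),
            GeneProfile("NBP", 21.0, 0.32, e["NBP"]),
            GeneProfile("EF", 20.5, 0.50, e["EF"], {"month": {k: 0.3 * v for k, v in month.items()}}),
            GeneProfile("GAPDH", 18.0, 0.65, e["GAPDH"], {"month": {k: 0.4 * v for k, v in month.items()}}),
            GeneProfile("Actin", 21.5, 0.80, e["Actin"], {"altitude": {"1070": 0.5, "1520": -0.5}}),
            GeneProfile("B-Tubulin", 22.5, 0.95, e["B-Tubulin"], {"month": {k: 0.5 * v for k, v in month.items()}}),
            GeneProfile("U18S", 10.0, 1.20, e["U18S"], {"fate": {"flowering": 2.0}}),
        ]
    raise KeyError(f"unknown species {species!r}; choose 'celmisia' or 'chionochloa'")


def default_study_config(species: str, seed: int = 0) -> SimConfig:
    """Default configurations reaching the study's per-species sample totals.

    Celmisia: 3 altitudes x 4 months x 2 fates x 2 biological replicates = 48
    samples; Chionochloa: 3 altitudes x 3 months x 2 fates x 3 biological
    replicates = 54 samples. Balanced cells approximating the field design.
    """
    species = species.lower()
    profiles = _panel_profiles(species)
    if species == "celmisia":
        factors = {
            "altitude": ["1070", "1350", "1520"],
            "month": ["January", "March", "May", "September"],
            "fate": ["vegetative", "flowering"],
            "bio_rep": ["1", "2"],
        }
        prefix = "CEL"
    else:
        factors = {
            "altitude": ["UC", "1070", "1520"],
            "month": ["January", "March", "September"],
            "fate": ["vegetative", "flowering"],
            "bio_rep": ["1", "2", "3"],
        }
        prefix = "CHI"
    return SimConfig(genes=profiles, factors=factors, seed=seed, sample_prefix=prefix)
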
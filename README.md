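# refstab

Reference-gene stability and normalization toolkit for RT-qPCR.

Quantitative PCR expression estimates are only as good as their normalization:
a target gene's quantification cycle (Cq) is compared against reference
("housekeeping") genes assumed stable across all samples. In field and
environmental experiments — different altitudes, seasons, developmental fates —
that assumption routinely fails, and an unstable normalizer silently rewrites
the biology. `refstab` implements the standard candidate-gene validation
workflow end-to-end for people choosing reference genes from a panel of
candidates:

- **geNorm** — pairwise variation `V_jk = SD_s[log2(RQ_j/RQ_k)]`, stability
  `M_j = mean_k V_jk`, stepwise exclusion ranking, and the `V(n/n+1) < 0.15`
  rule for the number of reference genes needed;
- **NormFinder** — a two-way model `y_igj = α_ig + β_gj + ε_igj` on log
  relative quantities, combining unbiasedly estimated intragroup variances
  `σ̂²_ig` with intergroup deviations `d_ig` into a stability value
  `ρ_i = mean_g(|d_ig| + √(σ̂²_ig/n_g))`;
- **BestKeeper** — raw-Cq descriptive dispersion (both the applet's
  "SD ± Cq" mean absolute deviation and the sample SD), CV%, x-fold
  dispersion `E^SD`, and each gene's Pearson correlation against the
  geometric-mean Cq index;
- **comparative ΔCt** — mean SD of pairwise Cq differences (provably equal to
  geNorm's full-panel M when E = 2);
- **comprehensive ranking** — geometric mean of the per-method ranks;
- **efficiency QC** — amplification factor E per primer pair from
  window-of-linearity fits to raw curves, percent efficiency `(E−1)×100`,
  the 90–110% / R² ≥ 0.99 acceptance band;
- **normalization** — per-sample normalization factors
  `NF(s) = geomean_refs RQ(g,s)`, target-gene relative expression
  `E^(Cqmin−Cq)/NF`, and quantification of the log2 discrepancy between two
  normalization choices;
- **simulation** — a generator emulating a translocation field study
  (altitudes × months × vegetative/flowering fate × biological replicates,
  shared mRNA-loading effects, technical triplicates, one high-abundance
  unstable ribosomal gene) with known ground truth, so every method above is
  testable against designed stability orderings.

Relative quantities use the anchor convention `RQ = E^(Cqmin − Cq)`, so each
gene's lowest-Cq (highest-expression) sample scores 1.

## Worked example

```python
from refstab import (simulate_experiment, default_study_config, collapse_replicates,
                     relative_quantities, genorm_rank, optimal_gene_count)

ds, truth = simulate_experiment(default_study_config("celmisia", seed=1))
collapsed, qc = collapse_replicates(ds)          # triplicates -> means + QC table
rq = relative_quantities(collapsed)              # RQ = 2**(Cqmin - Cq)
res = genorm_rank(rq)                            # stepwise geNorm
opt = optimal_gene_count(rq, res.ranking_order)  # V(n/n+1)
print(res.ranking_order, opt.nf_pairwise[2], opt.optimal_n)
```

prints

```
['GAPDH', 'PP2A', 'SAND', 'EF', 'eIF', 'MTP', 'PGK1', 'U18S'] 0.11488... 2
```

i.e. geNorm recovers the designed stability ordering (`truth.ordering` is the
same list), `V(2/3) = 0.115 < 0.15`, so two reference genes — the designed
stable pair GAPDH/PP2A — suffice for normalization. The scripts in
`examples/` walk through each capability the same way (stability ranking and
aggregation, reference-gene count, efficiency QC, normalization bias); for
instance `examples/05_normalization_bias.py` shows a true +2.0-log2 effect
estimated as +1.98 with the stable pair but −1.02 when normalized by a gene
that itself shifts 3 log2 units between fates.

A thin CLI mirrors the library:

```bash
refstab simulate --species celmisia --seed 1 --out-prefix cel
refstab report --cq cel_cq.csv --metadata cel_meta.csv \
    --subsets total,fate=vegetative,fate=flowering --outdir bundle/
refstab choose-n --cq cel_cq.csv --metadata cel_meta.csv --out v.tsv
```

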
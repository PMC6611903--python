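"""Decide how many reference genes are needed via geNorm's V(n/n+1).

V(n/n+1) is the SD of the log2 ratio between normalization factors built from
the n and n+1 top-ranked genes. If adding gene n+1 barely changes the factor
(V < 0.15 by convention), n genes suffice.
"""

from refstab import (
    collapse_replicates,
    default_study_config,
    genorm_rank,
    optimal_gene_count,
    relative_quantities,
    simulate_experiment,
)

ds, _ = simulate_experiment(default_study_config("celmisia", seed=1))
collapsed, _ = collapse_replicates(ds)
rq = relative_quantities(collapsed)

res = genorm_rank(rq)
opt = optimal_gene_count(rq, res.ranking_order, cutoff=0.15)

print("gene ranking (most stable first):", " > ".join(res.ranking_order))
print("\n  n   V(n/n+1)")
for n, v in opt.nf_pairwise.items():
    marker = " <- first below 0.15" if n == opt.optimal_n else ""
    print(f"  {n}   {v:.4f}{marker}")
print(f"\noptimal number of reference genes: {opt.optimal_n} (cutoff satisfied: {opt.satisfied})")
# V(2/3) under the cutoff means the two top genes alone form a stable factor.
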
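"""Generate a synthetic field translocation study and inspect its ground truth.

The generator emulates an RT-qPCR reference-gene experiment: 8 candidate genes
measured in triplicate across altitudes x months x subsequent fate x biological
replicates, with a shared per-sample mRNA-loading effect, gene-specific noise
and a high-abundance unstable ribosomal gene.
"""

from refstab import collapse_replicates, default_study_config, simulate_experiment

cfg = default_study_config("celmisia", seed=1)
ds, truth = simulate_experiment(cfg)

print(f"samples: {len(ds.samples)}, genes: {len(ds.genes)}, wells: {len(ds.cq)}")
print(f"design factors: {list(ds.metadata.columns)}")

collapsed, qc = collapse_replicates(ds, sd_tol=0.5)
print(f"replicate QC: {int(qc['flagged'].sum())} of {len(qc)} wells flagged (SD > 0.5 cycles)")

print("\ntrue per-gene log2 variance (noise + design effects), most stable first:")
for g in truth.ordering:
    print(f"  {g:10s} {truth.true_log2_variance[g]:.3f}")
print(f"\ndesigned stable pair: {truth.stable_pair}; least stable: {truth.least_stable}")
# The stability methods below should recover this ordering from the Cq data alone.
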
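# Methods

## Data model and the RQ transform

A `CqDataset` holds one Cq value per well — per (sample, gene, technical
replicate) — plus a sample-metadata table of design factors and optional
per-gene amplification factors E. Technical replicates are collapsed to
arithmetic means before any stability statistic; the replicate QC table
reports the per-well-group SD (n−1) and flags groups above a tolerance
(default 0.5 cycles, a common plate-QC convention).

Relative quantities are `RQ(g, s) = E_g^(Cqmin_g − Cq_gs)` with `E_g = 2`
unless efficiency correction is requested, so each gene's lowest-Cq sample is
anchored at exactly 1 and `log2 RQ ≤ 0`. **Cqmin is taken within the analysed
subset, after replicate collapsing** — so subsetting then transforming is not
the same as transforming then subsetting; the pipeline always transforms
after subsetting (a `global_rq` flag exposes the other convention). Because
Cqmin is a per-gene constant, every ratio- or SD-based statistic downstream
is invariant to it; the anchor matters only for the absolute scale of
relative expression (which sample "means 1").

Missing wells are tolerated at parse time; pairwise statistics drop
incomplete sample pairs and report the affected pairs, and any pair sharing
fewer than two complete samples raises an explicit error rather than
producing a silent NaN.

## Stability statistics

**geNorm.** `V_jk` is the sample SD (n−1 everywhere in this package) over
samples of `log2(RQ_j/RQ_k)`; `M_j` is the mean of `V_jk` over partners. The
ranking is the true stepwise procedure: remove the highest-M gene, recompute
M on the remainder, repeat until two genes are left. Those two cannot be
ordered by the method; both are reported at rank 1 (a switch yields 1.5/1.5
for rank aggregation). A single-pass M ranking is available as a flag, and
per-step M values are retained since published M charts may show either.
Exact ties in the maximum M are broken lexicographically and recorded.
`V(n/n+1)` is the SD of `log2(NF_n/NF_{n+1})` where `NF_n` is the per-sample
geometric mean RQ of the top n genes; the optimal count is the smallest
n ≥ 2 with V below the cutoff (default 0.15), flagged if none qualifies.

**NormFinder.** Input is the genes × samples matrix of log2 RQ (equivalently
−Cq up to per-gene constants, offered as a fast path). Within each group the
matrix is double-centered (gene-in-group and sample-in-group means removed);
the residual sum of squares per gene estimates the intragroup variance after
a bias correction for the variance absorbed by sample-centering across k
genes. For a two-way layout with gene-specific variances,

    E[RSS_i/(n−1)] = σ²_i (k−2)/k + S/k²,   S = Σ_i σ²_i,

so with `Ŝ = k/(k−1) · Σ_i s²_i` (unbiased for S) the moment estimator
`σ̂²_i = (s²_i − Ŝ/k²) · k/(k−2)` is exactly unbiased; this is verified by
simulation (mean σ̂² over 500 runs at n = 100, k = 8 within 5% of truth) —
the simulation, not the algebra, is the acceptance arbiter. Negative
estimates are truncated at 0 and flagged; truncation necessarily inflates
the *mean* estimate for genes whose true σ is near zero relative to the
estimator's sampling noise, which is why the unbiasedness check uses
moderate σ (0.3–0.8) where truncation never triggers. Intergroup deviations
`d_ig = (gene-group mean − gene grand mean) − (group grand mean − overall
grand mean)` satisfy `Σ_g n_g d_ig = 0`; an optional (default-on)
empirical-Bayes shrinkage scales d by `γ̂²/(γ̂² + σ̂²_ig/n_g)` with
`γ̂² = max(0, Σ d²/(k−1) − mean(σ̂²/n_g))`. The stability value is
`ρ_i = mean_g(|d_ig| + √(σ̂²_ig/n_g))`, or `√σ̂²_i` with a single group.
Note a structural property of the model: with few genes, one strongly
group-regulated gene moves the group grand mean and thereby injects
±shift/(2k)-scale deviations into *every* gene's d. For pooled analyses with
no canonical grouping the package therefore also supports (and the recovery
benchmark uses) the ungrouped, intragroup-only mode; both modes are
first-class.

**BestKeeper.** Computed on raw collapsed Cq. Dispersion is reported in both
conventions — the applet's "SD ± Cq", i.e. the mean absolute deviation from
the arithmetic mean, and the n−1 sample SD — because published tables say
only "standard deviation"; the ranking convention is configurable (default
MAD) and always stated in outputs. CV% = 100·SD/mean-Cq, x-fold dispersion
= E^SD, and genes with dispersion > 1 cycle are flagged inconsistent per the
BestKeeper rule. The index is the per-sample geometric mean Cq over included
genes; each gene is scored by Pearson r against it (two-sided t-test p, no
multiplicity correction — none is conventional here). Zero-variance genes
get an undefined correlation marker. Correlations within 1e−12 of ±1 are
snapped to exactly ±1 so that identical-gene panels report r = 1.

**Comparative ΔCt.** The mean over partners of `SD_s(Cq_j − Cq_k)`, ranked
ascending. On the Cq scale this is identical to geNorm's full-panel M when
all E = 2 (log2 RQ differs from −Cq by per-gene constants, which SDs
ignore); this equality to 1e−10 on random data is the signature cross-check
of both implementations.

**Comprehensive ranking.** The unweighted geometric mean of per-method ranks
(2–6 methods over an identical gene set; fractional tie ranks allowed),
computed as `(Π ranks)^(1/M)` in plain products for exactness. Ties in the
score break by mean rank, then gene name, and are recorded. A method that
could not run is simply omitted and the method count reported — matching how
aggregate rankings behave when one tool fails. No method weighting is
implemented: the aggregation is the plain GM of raw ranks.

## Efficiency estimation and QC

Percent efficiency is `(E − 1) × 100`. Per-curve estimation subtracts a
baseline (mean of the first 3 cycles), scans every contiguous window of 4
cycles with strictly positive corrected fluorescence, fits
log10(F) ~ cycle, and keeps the window with the highest R² among windows
whose slope implies E > 1.1 — the slope floor rejects flat baseline and
plateau stretches that are locally linear but show no amplification. E is
10^slope; the per-gene E used downstream is the arithmetic mean of per-curve
estimates. The QC band (default 90–110%, inclusive, with R² ≥ 0.99) flags
rather than fails: published panels include primer pairs slightly outside
the band, and the decision belongs to the analyst. Tables supplied with both
E and a stated percentage are checked for consistency with the (E−1)×100
rule and mismatches are reported, not reconciled.

## Normalization

`NF(s)` is the geometric mean RQ of the chosen references at sample s;
relative expression is `E_target^(Cqmin − Cq_s)/NF(s)`. Samples missing any
reference RQ are dropped with a warning. Group summaries (mean ± SD per
condition) aggregate over biological replicates (a `bio_rep` metadata
factor) after technical collapsing. `compare_normalizations` reports the
per-sample log2 discrepancy between two normalizations of the same target
and its maximum magnitude; note the discrepancy series is anchored by which
sample sets each gene's RQ to 1, so the scientifically stable summary is the
discrepancy *range* (max − min), which equals the unstable normalizer's own
expression swing. Significance testing of expression differences is out of
scope by design; a tidy per-sample table is exported for any stats package.

## The synthetic study generator

The generator emulates a field translocation experiment on alpine masting
plants: leaf samples across altitudes and collection months, later labelled
vegetative or flowering, two (or three) biological replicates, technical
triplicates, eight candidate genes per species panel with the published
primer amplification factors as defaults. Latent log2 expression is

    x_gs = δ_s + Σ_f β_g,f(level_f(s)) + ε_gs,
    Cq_gsr = μ_g − x_gs·(log 2 / log E_g) + τ_gsr,

with `δ_s ~ N(0, σ_load²)` a per-sample mRNA-loading effect shared by all
genes (default σ_load = 0.8 log2 units), `ε ~ N(0, σ_g²)` gene noise,
`τ ~ N(0, σ_tech²)` per-well technical noise (default 0.15 cycles), and
efficiency entering as the log2→cycle slope (one log2 of template shifts Cq
by 1/log2(E) cycles). Cq is floored at 1 cycle (a reaction cannot cross
threshold before the first cycle); with the default panels this touches
fewer than 0.01% of wells. RNG streams are split per purpose and per gene
index, so adding a gene never perturbs existing genes' draws and the same
seed reproduces the dataset bit-for-bit.

Default designs use balanced cells reaching the study sample totals:
Celmisia 3 altitudes × 4 months × 2 fates × 2 bio-reps = 48 samples;
Chionochloa 3 altitudes × 3 months × 2 fates × 3 bio-reps = 54. The exact
field design was not fully balanced; these are deliberate approximations
that preserve the totals, the factor structure and the subset sizes that
matter to the statistics.

Default gene profiles follow the study's qualitative structure — several
nearly equally stable genes (the real data showed V(2/3) ≈ 0) plus one
high-abundance (mean Cq ≈ 10), strongly unstable ribosomal gene with a
2-log2 developmental-fate shift. The designed-stable pair has σ = 0.10, the
third gene σ = 0.32, the remaining panel σ = 0.50–0.95 with small seasonal
or altitudinal effects, and the U18S-like gene σ = 1.20. The third gene's σ
was calibrated so the designed ordering is identifiable at the study's
replication level (stable pair recoverable by the ratio-based methods in
≳95% of replicates) while keeping V(2/3) comfortably under the 0.15 rule —
the two constraints pull in opposite directions and 0.32 is the workable
middle. Ground truth (`SimTruth`) records each gene's non-loading log2
variance, σ_g² plus the realized design variance of its summed β effects,
and the implied stability ordering.

**What the generator does not emulate:** Cq-dependent (heteroscedastic)
technical noise, plate/batch effects, amplification failures and missing
wells, inhibitor-driven efficiency variation between samples, and
correlated regulation among candidate genes. Passing recovery tests on this
generator therefore demonstrates the estimators work under idealized
Gaussian field-like variation, not that any real panel is stable.

A documented consequence of the model: BestKeeper ranks raw-Cq dispersion,
which *includes* the shared loading variance σ_load that the ratio-based
methods (geNorm, ΔCt, NormFinder) cancel exactly (exactly when all E are
equal; near-exactly otherwise, since δ enters Cq as δ/log2 E_g). Under
realistic loading (σ_load = 0.8) the dispersion gap between σ = 0.10 and
σ = 0.32 genes is comparable to its own sampling noise at n = 48, so
BestKeeper separates the top of the panel much less reliably than the other
methods (≈94–96% vs ≈97–100% top-2 recovery) while still excluding the
unstable gene essentially always. This reproduces the method disagreement
seen in real validation studies and is asserted as such in the test suite.

## Numerical conventions

- SD uses the n−1 denominator everywhere; BestKeeper's MAD is the mean
  absolute deviation about the arithmetic mean.
- Geometric means of RQ/ranks use plain products (inputs are small and
  positive); the BestKeeper index uses scipy's gmean.
- CSV floats are written with shortest round-trip repr and read with
  pandas' round-trip parser, so write→read is value-exact.
- Deterministic tie-breaks: lexicographic by gene name (geNorm exclusion,
  rank aggregation after mean-rank), always recorded in the result object.
- Report bundles are byte-deterministic functions of (input, config, seed).

## Known limitations

- BestKeeper's pairwise gene-vs-gene regression matrix is not implemented
  (only SD/CV/index ranking is used in the supported workflow).
- NormFinder's combined "best pair" statistic is not implemented; single-gene
  stabilities only.
- No instrument-native file parsing (RDML etc.), melt-curve analysis, or
  Cq-calling from raw curves; Cq values are inputs.
- Efficiency estimation supports the window-of-linearity method only, not
  dilution-series standard curves.
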
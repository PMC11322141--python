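# Methods

This note documents the models, conventions and numerical choices behind
`reservoirnet`, and what the synthetic validation does and does not show.

## Edge calling

Correlation is mid-rank Spearman: values are ranked per variable with ties
averaged, and ρ is the Pearson correlation of the ranks. The raw p-value
uses the t approximation, t = ρ√((n−2)/(1−ρ²)) on n−2 degrees of freedom;
|ρ| = 1 maps to p = 0, and an exact permutation p is available for n ≤ 10.
At least 4 samples are required — below that, p-values are meaningless.
Variables with zero variance are flagged and excluded from edge calling
(ρ = 0, p = 1 against all partners) rather than raising.

Multiple testing is corrected by Benjamini–Hochberg over the V(V−1)/2
unordered pairs only (the diagonal and the lower triangle are not counted
as tests). An edge is called iff |ρ| > 0.6 **and adjusted** p < 0.01, both
strict inequalities.

Two conventions here deserve justification:

- **The threshold applies to |ρ|, not signed ρ.** Signed thresholding at
  ρ > 0.6 could never produce the substantial negative-edge fractions
  (tens of percent) that characterize these networks; magnitude
  thresholding with the sign stored on the edge is the standard
  co-occurrence convention.
- **The significance cut is applied after FDR adjustment.** This is the
  conservative reading when both a p-value cut and FDR correction are in
  play; `use_adjusted_p=False` switches to raw p.

Isolated nodes are retained in the node set by default (`keep_isolated`),
since whether they count toward a network's node total is a reporting
convention, not a property of the data.

Node identity is the OTU, with the genus-bearing lineage string attached as
an attribute; pre-aggregation to genus can be done upstream by summing
counts over a taxonomy map.

## Networks per time point

With one sample per (day, port), a single day provides only n = 7
observations, for which adjusted p < 0.01 at |ρ| > 0.6 is unattainable.
The pipeline's default `day_window` grouping therefore pools, for each
focal day, all samples within ±2 days that belong to the same nutrient
stage (n up to 35). Defaults use four focal days per stage
(high: 16, 20, 24, 39; low: 42, 48, 53, 58). Pooled per-stage and
single-network groupings are available via `group_by`.

## Nutrient–OTU bipartite networks

TS, TN and TP join the abundance matrix as three extra variables, matched
to samples by (day, port); a sample without a nutrient record is an error
listing the missing keys. The network is built exactly as the OTU–OTU
network; afterwards every OTU node with no direct edge to a nutrient node
is removed, keeping OTU–OTU edges among the survivors. One such network is
built per nutrient stage.

## Topology and robustness

Average degree is 2E/N and density 2E/(N(N−1)) for the undirected simple
graph; tables report 3 decimals for both and the negative-edge share as a
percentage with 2 decimals. Betweenness is unnormalized shortest-path
betweenness on the unweighted graph (correlation magnitudes are not used as
distances; no weighting scheme is defined for these networks), endpoints
excluded.

A robustness replicate removes ⌊f·N⌋ nodes uniformly without replacement
and reports the proportion of the *original* N nodes that keep at least one
edge in the induced subgraph. This "node residual ratio" convention makes
an edgeless network maximally fragile (robustness 0) and a complete graph
maximally robust (exactly 1 − f up to rounding). Because the y-axis
definition of such curves is not standardized, the denominator can be
switched to surviving nodes and the measure to the largest connected
component. Defaults: 1000 replicates; the curve grid is 0.05…0.95 in steps
of 0.05, each fraction on an independent child stream spawned from the
seed, so the whole curve is reproducible and fractions are uncorrelated.
The Monte-Carlo loop runs on the boolean adjacency matrix, which keeps
thousand-replicate curves on few-hundred-node networks instantaneous.

One published topology row (day 41: N = 377, E = 1 227, average degree
printed as 8.509) is internally inconsistent — 2E/N = 6.510, although its
density 0.017 does match — and is treated as a typographical artifact: it
is excluded from consistency checks and not "corrected".

## Stage comparison

Diversity is compared per sample, negative-edge fraction and
robustness-at-0.5 per network; this unit-of-replication choice is the
package's own, documented rather than asserted as canonical. The default
test is the two-sided Mann–Whitney U (exact for small untied groups, normal
approximation with tie correction otherwise; Welch's t by flag), with star
labels at p < 0.05/0.01/0.001. Each group needs ≥ 3 values; comparisons are
skipped otherwise.

## Synthetic community generator

One sample per (day, port). A latent vector z follows a factor model: OTU i
in block b has z_i = s_i(√ρ_b·f_b + √(1−ρ_b)·ε_i) with block factor f_b,
so within-block latent correlation is s_i·s_j·ρ_b. "Negative" blocks
alternate s_i = ±1 — an all-negative block of size > 2 is not a valid
correlation matrix — so roughly half (for size 6, 60%) of a negative
block's pairs are negative; the ground truth records each pair's realized
sign. Log abundance is μ_i + σ·z_i with baseline μ_i ~ N(0, 1.25²) drawn
once per scenario and dispersion σ = 1; counts are multinomial at
sequencing depth 41 051 (matching the rarefaction depth of the emulated
workflow), so column sums are exact. Because the marginal transform is
monotone, planted latent correlations are what the Spearman stage of the
pipeline estimates, attenuated only by counting noise.

Stage structure: samples on or after the boundary day (default 40) are
"low". `diversity_shift` compresses the baseline spread μ_i by the factor
(1 − shift) in the low stage, raising evenness and hence Shannon diversity.
The two-regime preset plants 8 blocks of 6 OTUs (ρ = 0.9) in the high
stage and 8 blocks of 8 in the low stage, with 50% vs 12.5% of blocks
negative — fewer negative associations and a denser (hence more robust)
network after the nutrient step-down, the qualitative contrast the study
design asks about. Per-day sample counts beyond the 7 ports are not part of
the emulated design and are a free choice.

Nutrient curves are piecewise: linear ramp to the high plateau (TS over 17
days to 150 mg/L; TN and TP over 8 days, defaults 120 and 30 mg/L — chosen
as plausible assay-scale values, since only the TS plateau is constrained),
then a step down to half the plateau when the boundary passes the port
(the reduced recipe halves the carbon source). Each port lags the injection
front by a fixed integer number of days, default 0…6 — a lag is part of the
emulated design but its magnitude is not, so it is configurable.
Optionally, dedicated OTUs are driven by a nutrient: the standardized
concentration is added to their latent log abundance with a chosen
coupling, planting a monotone nutrient–taxon dependence for validating the
bipartite network (the `nutrient_demo` preset restricts itself to the
ramp-up days, where concentrations actually vary across samples).

### What the generator does not emulate

No hydrodynamics, oil-phase chemistry, or aerobic→anaerobic succession
dynamics; no phylogenetic signal in the taxonomy (lineages are arbitrary
labels); no temporal autocorrelation beyond the stage structure; and
compositional closure is the only source of spurious correlation. Passing
the planted-recovery checks therefore shows the inference chain is
correct and well calibrated under a known copula model — not that real
reservoir networks are recovered at these error rates.

## Problem sizes and numerical conventions

Validation runs use 120 OTUs × 420 samples (two-regime) or × 200 samples
(recovery preset), 100 random instances of ≤ 8 variables × ≤ 12 samples
for oracle equivalence, and 2000 Monte-Carlo replicates against exhaustive
enumeration on 6-node graphs — sizes at which exact oracles are feasible
while the pipeline code paths are identical to production use. Ties in
ranking always use mid-ranks; BH adjusted values are clipped at 1;
proportions must sum to 1 within 1e-9 after normalization; all randomness
flows through `numpy.random.default_rng` seeds (spawned `SeedSequence`
children for independent substreams), and every pipeline run writes a
manifest of SHA-256 output digests to make byte-level reproducibility
checkable.

## Known limitations

- Plain Spearman ignores compositionality; SparCC/SPIEC-EASI-style
  corrections are deliberately out of scope.
- The t approximation to the Spearman null is inaccurate for very small n;
  the exact permutation option covers n ≤ 10 only.
- Rarefaction is a single draw per sample (no averaging over repeated
  rarefactions).
- Per-day networks at the native n = 7 replication cannot reach the default
  significance threshold; the day-window pooling is a pragmatic remedy, not
  a claim about the original sampling design.
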
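# reservoirnet

Co-occurrence network analysis of nutrient-stimulated oil-reservoir
microbial communities.

During indigenous microbial enhanced oil recovery (IMEOR), nutrients
injected into a flooded reservoir stimulate the resident bacteria. A
recurring field question is how the *concentration* of the injected
nutrients shapes the community: does lowering the dose increase bacterial
diversity and make the community's interaction network more stable?
`reservoirnet` implements the full abundance-to-network workflow used to
answer that question from 16S OTU tables sampled along a long-core flooding
device (7 sampling ports, ~60 days, a high-nutrient stage followed by a
reduced-nutrient stage), plus a synthetic community generator with planted
correlation structure so every step can be validated against ground truth.

## Method

Starting from a sample × OTU count table:

1. **Preprocessing** — OTUs with mean relative abundance < 0.01% are
   removed; samples may be rarefied without replacement to a common depth
   (default 41 051 reads); alpha diversity (Shannon in bits, observed OTUs,
   Simpson, Pielou evenness) is computed per sample.
2. **Network inference** — for every OTU pair, the mid-rank Spearman
   correlation ρ and its t-approximation p-value are computed across
   samples; p-values are Benjamini–Hochberg adjusted over the V(V−1)/2
   pairs; an edge is called iff |ρ| > 0.6 and adjusted p < 0.01. Nodes are
   OTUs (with taxonomic lineage attributes); edges carry ρ and sign.
   A bipartite variant adds the nutrient concentrations TS/TN/TP (total
   sugars/nitrogen/phosphorus, mg/L) as extra variables and prunes OTUs
   with no direct nutrient edge.
3. **Topology** — per network: N nodes, E edges, average degree 2E/N,
   density 2E/(N(N−1)), negative-edge fraction, and unnormalized
   betweenness centrality per node.
4. **Robustness** — remaining-node proportion (nodes keeping ≥ 1 edge,
   over the original N) after removing ⌊f·N⌋ random nodes, distributed
   over Monte-Carlo replicates, for one fraction or a whole removal grid.
5. **Stage comparison** — high- vs low-nutrient values of diversity
   (per sample), negative-edge fraction and robustness-at-0.5 (per
   network), tested two-sided by Mann–Whitney U and labelled
   `*`/`**`/`***` at p < 0.05/0.01/0.001.

The synthetic generator draws OTU abundances through a latent-Gaussian
copula with planted correlation blocks, log-normal marginals, and
multinomial sampling at fixed sequencing depth, together with
ramp-then-plateau nutrient curves (TS plateau 150 mg/L, stepping down when
the recipe is halved after day 40, with per-port lags).

## Worked example

Run the packaged two-regime demo scenario (420 samples, 120 OTUs, planted
blocks that are denser and less often negative in the low-nutrient stage):

```bash
reservoirnet run --out demo --seed 1
```

prints the per-day network topology table and the stage comparisons:

```
label  nodes  edges  average_degree  density negative_pct
day16    120    118           1.967    0.017       29.66%
day20    120    114           1.900    0.016       27.19%
day24    120    120           2.000    0.017       30.00%
day39    120    103           1.717    0.014       23.30%
day42    120    225           3.750    0.032        7.11%
day48    120    225           3.750    0.032        7.11%
day53    120    224           3.733    0.031        7.14%
day58    120    224           3.733    0.031        7.14%
alpha_diversity_shannon: p=1.056e-27 ***
negative_edge_fraction: p=0.02843 *
robustness_at_0.5: p=0.02857 *
```

Days 16–39 fall in the high-nutrient stage, days 42–58 in the reduced
stage. The low-stage networks have more edges (≈225 vs ≈114, reflecting the
larger planted blocks), a much smaller share of negative correlations
(≈7% vs ≈28%), and all three stage contrasts — diversity up, negative
fraction down, robustness up after the nutrient step-down — are significant
in the expected direction. `demo/` also receives per-network edge/node
tables and GraphML, robustness and diversity TSVs, and a manifest with
SHA-256 digests: re-running with the same seed reproduces every file byte
for byte.

Other entry points: `reservoirnet simulate` (write a synthetic OTU
table/taxonomy/metadata/nutrient bundle), `preprocess`, `network`
(including `--with-nutrients`), `topology`, `robustness`.

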
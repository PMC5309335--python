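# Methods

## Scope and model

`virhost` computes site-level statistics that link viral sequence pressure
to bacterial community structure in placement-based metagenomics, and the
resampling inference used to interpret them. The observable unit is a
*site*: a set of reads placed onto nodes of a fixed reference phylogeny
(for diversity) and a set of taxon counts labeled by domain (for the
virus-to-bacterium ratio). Placements may sit on internal nodes as well as
leaves; all distances are patristic (path sums of branch lengths).

## Diversity statistics

**node50.** Sort a site's node counts descending; node50 is the minimal k
whose top-k sum reaches ≥ 50 % of the total. The comparison is done in
integer arithmetic (`2·cumsum ≥ total`), so exact-half cases are included
and no floating rounding is involved. Ties between equal counts cannot
change k, so no tie-break rule is needed. node50 is invariant under label
permutation and under scaling all counts by a positive integer.

**MPD.** The mean patristic distance over all unordered pairs of placed
reads, multiplicity-weighted: with node counts `c` and distance matrix `D`
(zero diagonal), `MPD = cᵀDc / (n(n−1))`, `n = Σc`. This equals the
brute-force double loop over reads because same-node pairs contribute
zero. A presence-only variant (mean over pairs of distinct occupied
nodes) is available behind a flag for comparison; the default weights
reads because the hits being compared are placed reads, and dominance is
part of the signal.

**sesMPD.** `(MPD_obs − mean MPD_null) / SD(MPD_null)`, with the null
formed by drawing subsamples of the focal sample's size, without
replacement, from the hits of all sites mixed together (the focal site's
hits included — the pool is the whole survey). The default number of
randomizations is 100. Draws are realized as multivariate hypergeometric
counts over the pooled node-count vector, which is distributionally
identical to sampling reads without replacement and lets each null MPD be
one quadratic form. The null SD uses the sample SD (ddof = 1), matching
the convention of the R `sd()` used by the community-phylogenetics
toolchain this statistic comes from. When the null SD is zero (e.g. the
pool equals the sample at equal size) sesMPD is NA and is excluded
pairwise, with a warning, from downstream correlations. A with-replacement
null is available behind a flag.

Under its own null — a sample that genuinely is a random subsample of the
pool — sesMPD is approximately standard normal; the test suite checks mean
∈ [−0.2, 0.2] and SD ∈ [0.7, 1.3] over 200 replicates. Multiplying all
branch lengths by c > 0 scales MPD, null mean and null SD by c and leaves
sesMPD unchanged; this is asserted in tests.

## Viral metrics

**VBR** is the ratio of viral to bacterial relative abundance at a site;
both share the site total, so it reduces to the raw count ratio. "Viral"
defaults to the `bacteriophage` domain — annotations that imply a
bacterial host — with an option to include `other_virus`. Sites with zero
bacterial counts have no defined VBR (error); zero viral counts give
VBR = 0 with a warning, and such sites carry an NA infection potential so
they drop out of log-scale correlation inputs. If the inputs are size-
fractionated, VBR should be computed on the cellular size class; the
package trusts the counts it is given and documents rather than enforces
this.

**Infection potential** is `VBR / node50`. The pipeline computes all five
per-site statistics for every site present in both input tables, pooling
the sesMPD null over *all* placement sites, and reports skipped sites with
reasons instead of dropping them. Per-site null draws are seeded by
`(seed, site_id)` substreams, so results are independent of column order.

## Correlation inference

Spearman's rho is the Pearson correlation of average-ranked vectors (ties
get average ranks, matching `cor.test`). One-sided p-values use the t
approximation `t = rho·sqrt((n−2)/(1−rho²))` on n−2 degrees of freedom;
for n ≤ 9 an exact permutation p (full enumeration of the n! orderings,
ties handled by ranking first) is available. The caller must state the
alternative direction — it encodes the ecological hypothesis (e.g. `less`
for "infection potential depresses diversity") and has no sensible
default. R² is reported from the least-squares line through the same
pairs; for simple regression it equals the squared Pearson correlation
(asserted to 1e-12), which also makes the axis orientation immaterial.

The bootstrap resamples (x, y) pairs with replacement, 1000 times by
default, recomputing rho per replicate; the interval is the percentile
interval at level 0.90 by default. BCa was not used because a plain
percentile interval is the simplest procedure consistent with "bootstrap
with a 90 % interval", and site counts here (≈ 20) do not support finer
corrections. Replicates with a constant resampled vector are redrawn and
counted; if more than half of all draws are degenerate the procedure
aborts rather than report an interval from heavily tied data.

## Coverage normalization

Per-base depth is the number of alignments overlapping a position
(0-based, half-open intervals; SAM input is converted on read and only
mapped reads are used). The removal threshold `T = mean + k·SD` (k = 2 by
default) is computed **once** from the initial profile and frozen;
recomputing after removals would chase a moving target. Statistics are per
contig by default (`global` pools all positions); the SD is the population
SD over all positions, zeros included. Removal is greedy: the position
with maximal excess over T (ties: leftmost position on the
lexicographically smallest contig) loses one uniformly random covering
read, until no position exceeds T. Each step removes a read, so
termination is guaranteed; the report's removed-read list reproduces the
final profile exactly, and the number of removals is non-increasing in k.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes — a
single latent site-evenness driver that shapes both the placement
distribution and the virus load — at the scale of a ~20-station survey:

| parameter | default | meaning |
|---|---|---|
| `n_leaves` | 64 | reference-tree leaves (pure-birth topology, exp(0.1) branch lengths) |
| `n_sites` | 20 | survey stations |
| `reads_per_site` | 2000 | placed core-gene reads per site |
| `alpha_range` | 0.05–5 | log-uniform Dirichlet concentration bounds (clustered → even) |
| `beta` | 1.5 | coupling of log-VBR to the standardized evenness driver z |
| `sigma` | 0.2 | log-normal noise SD on VBR |
| `mean_log_vbr` | log 0.1 | central virus-to-bacterium ratio |
| `bacteria_per_site` | 10000 | bacterial count pool per site |

Per site: `alpha ~ log-uniform(alpha_range)`; `z = standardized log alpha`;
leaf proportions `~ Dirichlet(alpha)`; reads multinomial;
`log VBR = mean_log_vbr − beta·z + N(0, sigma²)`, phage counts rounded
against the fixed bacterial pool. `beta > 0` produces the negative
association between infection potential and diversity. Counts are plain
multinomial; a Dirichlet-multinomial overdispersion knob exists but is off
by default. Reads are placed on leaves only — internal-node placement adds
realism but no testing power, and the diversity code's internal-node
support is covered by hand fixtures.

**What the generator does not emulate.** Real surveys have uneven
sequencing depth, annotation error in domain labels, spatially structured
(not exchangeable) sites, and — critically — *phylogenetically localized*
dominance: in the generator a low-evenness site concentrates on uniformly
random leaves, which may be mutually distant. Passing tests therefore show
the statistics behave correctly under the stated model, not that real
communities satisfy that model.

**A consequence worth knowing.** Because concentrated sites land on random
leaves, the evenness driver z explains sesMPD only partially
(rank-correlation ≈ 0.45 ± 0.21 across surveys). At 20 sites this caps the
power of the one-sided test on infection potential vs. sesMPD near 70 %
under the default coupling; detecting the association reliably needs more
sites, a stronger coupling, or a generator in which dominance is
phylogenetically clustered. Relatedly, infection potential shares node50
with the diversity axis, so its correlation with sesMPD is not centered at
zero even when `beta = 0`; the calibrated null test of the virus–diversity
coupling is therefore rho(VBR, sesMPD), which attains the nominal 5 %
type-I rate, and that is the statistic the acceptance checks use for the
no-coupling condition.

## Numerical conventions and degenerate inputs

- TSV everywhere: UTF-8, tab-separated, `#` comments, `NA` for undefined
  floats; metrics floats at 6 significant digits, round-tripping at that
  precision.
- Branch lengths must be finite and ≥ 0; unlabeled internal nodes get
  deterministic preorder ids `N<i>`.
- node50 of an all-zero site, MPD of < 2 reads, VBR without bacteria, and
  correlations of constant vectors are errors, not silent NaNs; pipeline-
  level failures become entries in the skipped-sites report.
- One user seed per invocation is expanded into per-stage substreams keyed
  by fixed labels (`tree`, `placements`, `taxa`, `ses:<site>`), so stage
  or site order never perturbs reproducibility; seeded runs are
  byte-identical.
- Problem sizes in the test-suite Monte-Carlo runs (e.g. 200 null
  replicates, 50 + 200 survey replicates, 25-seed coupling sweeps at a
  reduced 12-site configuration) were chosen to keep the whole suite in
  the low minutes on one CPU while leaving the binomial error on each
  estimated rate well inside the asserted bands.

## Known limitations

- Patristic distances are exact path sums; trees up to a few thousand
  nodes are comfortable, but the all-pairs matrix is quadratic in the
  number of occupied nodes.
- The exact Spearman permutation p enumerates n! orderings and is limited
  to n ≤ 9.
- The SAM reader is deliberately minimal: mapped reads' aligned spans
  only; no BAM/CRAM, no CIGAR-aware per-base events beyond the span.
- The pooled-subsampling null conditions on the observed survey; it is not
  a tree-randomization null and does not correct for reference-tree bias.
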
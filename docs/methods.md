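# Methods

This note documents the models behind `wgdkit`, the parameter choices
that matter, what the synthetic data do and do not emulate, and the
numerical decisions a maintainer should know about.  It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The generative model

**Species tree.** All benchmarks use a fully ladderized (caterpillar)
ultrametric species tree — the shape the duplication-mapping stage
requires — with the deepest-diverging tip as outgroup.  `make_ladder_tree`
draws the non-root divergence times uniformly on [0.1, 0.9] × depth from
the given seed, so replicate trees share shape but vary in node ages.
Branch lengths are in arbitrary time units; "MY" is used throughout for
concreteness.

**Gene families.** Each family starts from one gene at the root (a
geometric root-copy prior is available to mirror the inference side) and
evolves by a linear birth–death process: every gene duplicates at rate λ
and dies at rate μ, independently, restarting in both descendant branches
at each speciation.  A WGD event on a branch (position 0.5 = midpoint) is
a single instant at which every lineage alive there duplicates
independently with probability equal to the event's *retention rate*; the
resulting node is tagged with the event id.  No later forced loss is
applied — post-WGD erosion is carried by the background μ.  This is the
simplest generative reading of a single "retention" knob; the alternative
(duplicate always, lose later) is deliberately not implemented, because
with a critical background process the two are nearly indistinguishable
at the family-count level while the chosen form makes the expected
fraction of duplicate-carrying families exactly the retention rate (a
property the acceptance suite checks: 0.20 ± 0.02 at 2,000 families).

**Conditioning.** `simulate_family_set` rejects families with no
surviving outgroup copy, no surviving non-outgroup copy, or more than 100
copies in any taxon — the same filter the likelihood conditions on — and
raises once the estimated acceptance probability drops below 10⁻⁴.

**Sequences.** Codon sequences evolve down the true gene tree with sites
classified synonymous/nonsynonymous by NG86 fractional site counting and
mutations placed by a Poisson process per site class: synonymous events
at `syn_rate` per synonymous site per time unit, nonsynonymous at
`omega × syn_rate` (default ω = 0.2).  Site weights are frozen at the
branch-start sequence, multiple hits apply sequentially, mutations that
would create a stop codon are not proposed, and there are no indels, no
among-site rate variation and no codon-usage bias.  Consequently the
expected pairwise K_S of two genes is 2 × (time to common ancestor) ×
`syn_rate` to first order; the simulation tests verify the estimator mean
stays within 10% of that up to K_S ≈ 1.

**GO tables.** Each gene draws one GO Slim category; genes retained in
duplicate by a named WGD draw the biased categories with probability
multiplied by the enrichment factor (renormalized), background genes draw
uniformly.  Factor 3 with one biased category in ten gives the biased
category frequency 3/12 = 0.25 among paralogs.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: assembly and annotation noise, missing genes,
alignment error, gene conversion, rate heterogeneity among lineages or
sites, allopolyploid subgenomes, and gene-tree estimation error (the
mapping stage sees *true* gene trees; with inferred trees the duplication
background would be inflated by reconstruction artifacts).

## K_S estimation and peak calling

`estimate_ks` implements NG86 counting with Jukes–Cantor correction per
site class, with the conventions of the standard implementation
(mutations to stops count as nonsynonymous sites; 2–3-difference codon
pairs average syn/nonsyn counts over all mutational pathways with equal
weight; a stop-to-stop pathway step counts as synonymous): the test suite
checks exact agreement with Biopython's independent NG86 on random codon
pairs.  K_S is undefined (NaN) when the proportion of synonymous
differences reaches 3/4; such pairs are dropped from distributions and
tallied.  A maximum-likelihood (codeml-style) estimator is deliberately
not used: the counting estimator is dependency-free, deterministic, and
accurate for peak positions in the K_S ≤ 2 range the pipeline interprets.

Paralog distributions take all within-family, within-species pairs inside
the analysis window, default [0.01, 5] on raw K_S.  Optional node
weighting de-duplicates non-independent pairs: the n−1 merge nodes of an
average-linkage dendrogram over the family's genes each distribute total
weight 1 among the pairs first joined there.  It is off by default
(mixtures are fit to unweighted values; both modes are tested).

Mixtures of 1..k_max (default 4) normal components are fit by EM with
restarts (first restart quantile-initialized, the rest from random data
points; SD floor 10⁻³ × range; convergence at relative log-likelihood
change 10⁻⁹).  Model choice uses AIC with a parsimony rule: a larger
model counts as different only if it beats a smaller one by more than 2
AIC units, so the selected k is the smallest within 2 of the minimum.
The same ΔAIC > 2 margin is the "peak evidence" criterion against k = 1.
AIC's well-known occasional overselection on large samples is accepted
and characterized in the tests rather than hidden.  Components with mean
K_S > 2 (strict) are flagged as possible saturation artifacts requiring
corroboration from the mapping stage.

The slope scan evaluates the derivative of a Gaussian-kernel density
estimate on a grid for 11 log-spaced bandwidths on [0.05, 1.0] K_S units,
classifying each (bandwidth, point) as increasing/decreasing when the
pointwise normal CI at level 1 − α (α default 0.05) excludes zero, flat
otherwise, and insufficient-data where the effective sample size is
below 5.  Two boundary guards keep the scan calibrated: points within one
bandwidth of the observed data range are never classified, and neither
are points where the worst-case boundary-truncation bias of the smoothed
derivative exceeds a quarter of a critical standard error — near the
support edge the smoothed density genuinely rises from zero, which is not
a slope feature of the underlying distribution.  Under a flat density the
per-grid-point "increasing" rate stays below 1.5α (measured over 1,000
simulations in the acceptance suite).

Ortholog K_S uses strict one-to-one families (exactly one gene in each
species; no best-hit rescue) and summarizes divergence as the mode of a
Gaussian KDE (median reported alongside).  Rate correction decomposes a
focal/sister/outgroup trio as d_F = (d_FS + d_FO − d_SO)/2 and compares
the paralog peak with 2·d_F, the focal–sister divergence re-expressed on
the focal K_S scale; trios with d_F < 0 are flagged inconsistent and
excluded, and with several outgroups the mean ± SD of 2·d_F is reported.

## Duplication mapping

Gene trees are filtered to ≥ 45% species occupancy and ≥ 1 outgroup gene,
re-rooted on the branch above the LCA of their outgroup genes (largest
outgroup-only clade, with a logged warning, if the outgroup is not
monophyletic), and polytomies are resolved into a left ladder in
sorted-label order so runs are bit-reproducible.  Each internal node maps
to the species-tree LCA of its descendant species; a node is a
duplication iff its map equals a child's map.  The reported statistic
follows the MAPS convention — per species-tree node, the proportion of
*gene trees* with at least one duplication mapping there — while raw
node-level tallies are kept for accounting checks; tip-mapped nodes
(within-species expansions) are tallied separately.

## Birth–death inference and WGD calling

Copy-number transition probabilities along a branch use the classical
Kendall solution (extinction weight α, shifted-geometric growth β, i-fold
convolution for i ancestors; the λ = μ case by its limit), truncated at a
state-space bound of twice the largest observed count (25–200); row-mass
deficits at the default bound are below 10⁻⁸ for benchmark-scale rates.
The family likelihood is computed by pruning, vectorized across families,
with a geometric root-size prior conditioned on at least one surviving
copy in each root-child clade.  The prior mean defaults to the geometric
mean of nonzero per-species counts — per-species counts, not family
totals, proxy the ancestral copy number; using the total-family-size mean
(≈ 6.6 on the benchmark) makes the prior expect several root copies and
visibly biases the rate estimates (both variants are exposed).

Rates are estimated as the mean of per-subset MLEs over 10 random subsets
of 500 families (Nelder–Mead on log rates).  A candidate WGD can be
included in the count model as a binomial copy-doubling step at the event,
with its retention co-estimated on the logit scale; the screen pipeline
uses this because a plain birth–death fit absorbs the WGD's duplicates
into λ (≈ +10% at benchmark conditions), which propagates into the
simulated pools and degrades the verdicts.

The screen then simulates a null pool (1,000 trees at each of 1×, 0.5×
and 3× the estimated rates, no WGD) and a positive pool (3,000 trees
split over the same regimes with the candidate event at 20% retention),
pools them, and applies two-sided Fisher's exact tests at each node
(direction reported; sidedness is consumed by the decision rule; no
multiple-testing correction by default, Benjamini–Hochberg behind a
flag).  Verdicts: *supported* if the empirical proportion significantly
exceeds the null and is not significantly below the positive; *partial*
if it exceeds the null but falls significantly short of the positive;
*unsupported* otherwise.

**Stepwise secondary testing.** A WGD's surviving extra lineages pass
through every descendant branch and inflate duplication proportions below
it.  Testing all nodes against the no-WGD null therefore yields spurious
secondary calls.  Once the primary candidate (the node with the highest
empirical proportion, unless supplied) is established against the null,
the remaining nodes are tested against the null-plus-candidate pool — the
positive pool — and only a node that still shows a significant excess
earns a joint positive simulation (candidate + secondary event) and a
full verdict.  This mirrors testing one candidate branch per analysis
rather than a genome-wide sweep, and generalizes to genuinely multi-WGD
scenarios (the two-event analysis in `analysis/` recovers both).

## Retention and GO bias

Paralog pairs are assigned to a mixture component only if their K_S lies
within 1 SD of the component mean **and** that component holds the
strictly highest posterior responsibility (ties leave the pair
unassigned, conservatively).  Retention is reported as unique genes among
assigned pairs over the predicted gene total; pair counts are emitted
alongside.  GO Slim enrichment compares paralog tallies (one count per
annotation; a unique-gene mode exists) against the full gene set:
expected counts scale the background composition to the paralog total,
standardized Pearson residuals (O − E)/√E are called over/under beyond
±2, and the global statistic is Σ(O−E)²/E on categories−1 degrees of
freedom.  Cross-event matrices order events by ascending component median
K_S; the per-category convergence score is the fraction of event pairs
sharing a call.

## Benchmark scale and numerical choices

The canonical benchmark (used by the acceptance suite and script) is a
6-taxon, 300 MY ladder; λ = μ = 0.002 per gene per MY (critical, so
family sizes stay realistic); 2,000 conditioned families; one WGD at the
midpoint of the branch above N3 with retention 0.2; screens summarized
over 20 replicate seeds.  Sequence-level checks use 2,000-codon genes at
`syn_rate` 0.005/MY (≥ 500 retained pairs per run); the analysis scripts
use 300-codon genes and 600 families so the full narrative chain runs in
about a minute.  These sizes were chosen as the smallest at which the
binomial/Fisher noise floors sit well inside the tolerances being tested.

All stochastic operations require an explicit seed (no silent global
state); identical configs reproduce byte-identical pipeline outputs, and
the run manifest records SHA-256 checksums to prove it.

## Known limitations

- The mapping stage consumes true (or user-supplied) gene trees; gene-tree
  inference error, which inflates empirical duplication backgrounds, is
  out of scope.
- The count likelihood assumes a single (λ, μ) across branches; lineage
  rate heterogeneity enters only through the 0.5×/3× null regimes.
- The K_S estimator shares its site-classification conventions with the
  sequence simulator; on real data, NG86 counting is known to diverge
  from ML estimators at high divergence (hence the K_S > 2 saturation
  flag and the corroboration requirement).
- SiZer classifications within one bandwidth of the data range (and where
  boundary bias dominates) are deliberately withheld, so very young peaks
  pressed against K_S = 0 are detected by the mixture stage, not the
  slope scan.
- The retention statistic inherits the ambiguity of its denominator: with
  simulated data "predicted genes" is the focal taxon's gene count, which
  is itself shaped by the conditioning filter.
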
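# wgdkit

Placing whole-genome duplications (WGDs) on a species phylogeny from
coding-sequence data.

Ancient polyploidy leaves two complementary signatures in a transcriptome:
a cohort of similarly aged paralog pairs (a peak in the distribution of
synonymous divergence, K<sub>S</sub>) and an excess of gene-tree subtrees
duplicated at the corresponding node of the species tree.  `wgdkit`
implements the full inference chain that turns those signatures into
statistically tested WGD placements, together with a generative simulator
so that every stage can be validated on data with known truth:

- **Synthetic data** — gene families evolving by a linear birth–death
  process (per-gene birth rate λ, death rate μ) along a known, ladderized
  species tree, with episodic WGDs planted at branch midpoints (each
  lineage alive at the event keeps the extra copy with a stated retention
  rate, default 20%); in-frame codon sequences whose pairwise
  K<sub>S</sub> tracks divergence time; GO Slim tables with planted
  retention bias.
- **K<sub>S</sub> toolkit** — NG86 (Nei–Gojobori) K<sub>a</sub>/K<sub>S</sub>
  with Jukes–Cantor correction; paralog age distributions with optional
  node-weight de-duplication; normal-mixture fits with AIC model choice;
  SiZer-style significant-slope scans; one-to-one ortholog K<sub>S</sub>;
  relative-rate trio correction (d_F = (d_FS + d_FO − d_SO)/2) to place a
  paralog peak before or after a speciation.
- **Duplication mapping** — LCA (soft-parsimony) reconciliation of rooted
  gene trees onto the species tree and the per-node proportion of gene
  trees duplicated there (the MAPS statistic).
- **Birth–death inference** — Kendall transition probabilities, pruning
  likelihood of family-size matrices with a geometric root prior and
  one-in-both-clades conditioning, λ/μ (and retention) estimation on
  random family subsets, simulated null (3 × 1,000 trees at 1×/0.5×/3×
  the ML rates) and positive (3,000 trees, 20% retention) pools, and
  per-node Fisher's exact verdicts: *supported*, *partial*
  (above the null but below the positive), or *unsupported*.
- **Retention bias** — paralog-to-peak assignment (±1 SD **and**
  max-posterior), percent of predicted genes retained in duplicate, and
  chi-squared GO Slim enrichment with ±2 standardized-residual calls
  compared across events.

It is aimed at phylogenomics researchers who want a tested, reusable and
fully scriptable version of this pipeline — and a sandbox in which its
operating characteristics (sensitivity, specificity, calibration) can be
measured.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data: two WGDs (20% retention) planted above nodes N3 and N5 of a
six-taxon ladder tree, λ = μ = 0.002 per gene per MY, 600 conditioned
families with 300-codon sequences.

```bash
python analysis/01_simulate_benchmark.py
python analysis/02_ks_peaks.py
python analysis/04_maps_profile.py
```

`02_ks_peaks.py` prints the mixture fit of the focal taxon's paralog
K<sub>S</sub> distribution:

```
1046 paralog pairs in window for t6 (0 saturated, 5 outside window)
selected k = 4; peak evidence (AIC beats k=1 by >2): True
  component 0: mean 0.198, sd 0.121, weight 0.15, median 0.211
  component 1: mean 0.647, sd 0.101, weight 0.20, median 0.641
  component 2: mean 1.114, sd 0.390, weight 0.50, median 1.225
  component 3: mean 1.147, sd 0.092, weight 0.14, median 1.151
slope scan: significant rise-then-fall at 7/11 bandwidths
```

The planted events sit at expected K<sub>S</sub> 0.66 (young, above N5)
and 1.15 (old, above N3): component 1 recovers the young peak, components
2–3 the old one, and component 0 absorbs the young background
duplications.  `04_maps_profile.py` shows the same events as elevated
duplication proportions on the species tree:

```
node  n_mapped  n_duplicated  proportion
  N5       420           168    0.400000
  N4       368            47    0.127717
  N3       410           128    0.312195
  N2       388            48    0.123711
  N1       553             0    0.000000
```

N5 and N3 stand out against the ~0.12 birth–death background;
`05_wgd_test.py` then tests them against simulated null and positive
pools, and `06_retention_bias.py` estimates per-event retention and
recovers the planted threefold GO bias (category GO0001 called
over-represented for the WGD peaks, not for the background component).

The same pipeline is scriptable from a single YAML config (only the keys
you want to override; everything else takes the documented defaults):

```yaml
# config.yaml
seed: 1
scenario:
  n_families: 500
  wgds:
    - {branch: N3, retention_rate: 0.2, event_id: WGD1}
```

```bash
wgdkit all --config config.yaml --out results/run
```

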
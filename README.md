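# qtlbridge

Cross-population integration of expression QTL (eQTL) datasets: replication
statistics, trans-band hotspot detection, and marker-based candidate-gene
fine mapping.

## The problem

eQTL studies face a power/resolution trade-off that depends on the mapping
population. Recombinant-inbred panels give strong associations but few
informative markers — a significant locus is a whole linkage block holding
dozens of genes. Diversity panels of classical inbred strains give dense
informative markers and localized signals, but at much lower power.
`qtlbridge` is for analysts who have eQTL score matrices from both kinds of
population and want to (1) quantify how consistent the two datasets are,
(2) find trans-band hotspots that replicate across populations, and
(3) use the high-resolution signals to rank candidate causal genes inside
low-resolution loci.

## The statistics

* **Common eQTL.** Markers from the two maps are paired (*exact*: same
  position ± a few bp; *interval*: every dense marker assigned to its
  nearest low-resolution marker, maxima compared per locus). A gene–locus
  pair is a common eQTL when its score exceeds the genome-wide q-quantile
  threshold in both datasets; peaks of one gene within 5 Mb are counted
  once. The fraction of common signals F_C = N_C/(N_low + N_high) is
  compared against score shuffles that re-assign binned scores to random
  genes, and every record gets an empirical match p-value with add-one
  correction, p = (1 + #{null ≥ obs})/(1 + n_rand).
* **Hotspots.** Distant (trans) common eQTL are counted in 2 Mb genomic
  bins (the common-eQTL frequency, CEF). Marker-position shuffles give
  global max-bin thresholds at chosen α levels; per-locus probeset shuffles
  give per-bin null means controlling for eQTL-dense loci.
* **Fine mapping.** A significant low-resolution marker defines an interval
  between its flanking markers (optionally restricted to ±ΔcM via linear
  interpolation on the genetic map). Candidate genes are ranked by the
  target's high-resolution scores at markers inside each gene, falling back
  to markers within `ext` bp of the gene; the scaled rank R_K ∈ [0, 1]
  (0 = best). Success — judged by pathway co-membership with the target —
  is compared against picking the closest gene (S_C) and a random gene
  (S_R = mean k_i/N_G,i).

A synthetic-data generator plants cis-eQTL, trans-regulators with target
batches (hotspots), a tunable replication probability between the two
panels, pathway co-memberships and a tissue-expression atlas, so the whole
pipeline is testable without any external data. See `docs/methods.md` for
the models, defaults and design decisions.

## Worked example

Simulate a small two-chromosome study (3 planted regulators with 10 targets
each, 30 cis genes, 70% replication) and run every stage:

```
$ cat demo_cfg.yaml
n_chrom: 2
chrom_length_bp: 20000000
n_markers_high: 600
block_length_bp: 2000000
n_genes: 300
n_cis: 30
n_regulators: 3
targets_per_regulator: 10
n_pathways: 15
replication_prob: 0.7
signal_strength: 20.0

$ qtlbridge pipeline --config demo_cfg.yaml --seed 7 \
      --q-common 0.99 --q-finemap 0.99 --outdir demo
simulated dataset written to demo
50 common eQTL -> demo/common_eqtl.tsv
hotspot profile -> demo/hotspots.tsv
38 loci -> demo/finemap_rankings.tsv
 n_loci     s_hr      s_c      s_r  n_top_half  n_bottom_half  n_not_ranked
     38 0.921053 0.052632 0.076967          37              1             0
```

Reading the output: of the 60 planted eQTL, 50 were called common between
the two datasets (the planted replication rate is 0.7, plus interval-scheme
noise hits). Fine mapping selected 38 strong loci; ranking candidates by
the dense-panel scores put a pathway co-member of the target on top in 92%
of them (`s_hr`), against 5% for the closest-gene baseline (`s_c`) and 8%
expected by chance (`s_r`) — the pathway co-member landed in the top half
of the ranking at 37 of 38 loci. The hotspot table flags the planted
trans-bands:

```
chrom  bin_start  bin_end  cef_obs  exceeds_alpha_0.01  null_mean  null_sd
 chr1   10000001 12000000        6                True        1.6 0.966092
 chr2    6000001  8000000        5                True        1.3 1.059350
```

Each stage is also available separately (`simulate`, `compare`, `grid`,
`hotspots`, `finemap`, `evaluate`, `enrich`; see `qtlbridge <cmd> --help`),
and everything can be driven from Python:

```python
import qtlbridge as qb

ds = qb.simulate_dataset(qb.SyntheticConfig(seed=7))
pairing = qb.pair_markers(ds.low_map, ds.high_map, "interval")
common = qb.find_common_eqtl(ds.low_scores, ds.high_scores, pairing,
                             q_low=0.99, q_high=0.99)
print(common.n_common, qb.fraction_common(common.n_common,
                                          common.n_low, common.n_high))
```

Real datasets enter through the same readers the simulator writes with:
score matrices as TSV (or MatrixMarket + id sidecars), marker maps as TSV,
gene annotation as BED/GFF3, pathways as GMT, tissue expression as TSV.

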
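# Methods

`qtlbridge` integrates two eQTL association-score matrices obtained from
genetically different mouse (or other model-organism) populations: a
*low-resolution* panel such as a set of recombinant-inbred strains, where
few markers are informative and signals smear over whole linkage blocks,
and a *high-resolution* panel such as a diversity panel of classical inbred
strains, where many markers are informative but statistical power is lower.
This note records the models, the parameters that matter, and the design
choices made where the procedure was genuinely open.

## Input model

Both datasets enter as dense genes × markers matrices of nonnegative
association scores (LOD scores or −log10 p-values; the two matrices need
not use the same score type because all selection is quantile-based).
Internal genomic coordinates are 1-based closed intervals; BED (0-based
half-open) and GFF3 (1-based closed) are converted at the I/O boundary.
Strand is stored but ignored by positional logic: search regions around a
gene extend symmetrically in both directions. Sparse matrix input is
densified with explicit zeros at load time because quantile thresholds are
defined over the full matrix.

## Comparison schemes and common eQTL

Markers are paired in one of two ways:

* **exact** — a low marker is paired with a high marker at (virtually) the
  same position, within `tol_bp` (default 5 bp); only markers with such a
  partner participate.
* **interval** — every high marker is assigned to its nearest low marker on
  the same chromosome (ties to the lower coordinate), and the maximum high
  score over the assigned group is compared with the low score.

Selection thresholds are empirical quantiles (linear interpolation) of the
full matrices, with the rule *score ≥ threshold* so that degenerate
constant matrices remain well defined. A **common eQTL** is a (gene,
low-marker) pair above threshold on both sides. Multiple common peaks of
one gene within a deduplication window (default 5 Mb) on one chromosome are
counted once; we keep the peak with the strongest low-resolution score,
breaking ties toward the lower coordinate (a greedy strongest-first rule —
the window size is a convention, the keep-rule is ours). Per-dataset counts
are deduplicated the same way and restricted to paired markers so that the
fraction of common signals F_C = N_common/(N_low + N_high) is comparable
across schemes; F_C is bounded by 0.5.

The **match p-value** of one record is empirical: the statistic is the
number of paired markers at which both of the gene's profiles exceed their
thresholds; the null re-pairs the gene's low profile with high profiles of
genes drawn from the same score bin (deciles of the maximum matched high
score), with the add-one correction p = (1 + #{null ≥ obs})/(1 + n_rand) to
avoid zero p-values. This statistic is sharp under the exact scheme; under
the interval scheme the per-locus maximum makes joint exceedance common by
chance and the p-values are correspondingly conservative, so summaries
report it for the exact scheme.

The **threshold grid** computes observed F_C over a grid of quantile pairs
(starting at 0.99) and a shuffled F_C obtained by re-assigning the selected
eQTL's scores to different genes within score-decile bins, independently in
each dataset (10 shuffles by default; mean and sd are reported per cell).

## Hotspots

Common eQTL are classified *local* if the marker lies within
`local_window_bp` of the target gene's transcribed region (distance to the
nearest gene edge, 0 inside; boundary inclusive; default 5 Mb, with 500 kb
used for focused single-region analyses) and *distant* otherwise. Distant
common eQTL are binned by marker position in per-chromosome tiles of
`bin_bp` (default 2 Mb; the last tile of a chromosome may be short — tiles
never span chromosome junctions). Two nulls qualify a bin:

* **marker shuffle** — every common eQTL is re-assigned to a marker drawn
  uniformly with replacement from the low map; the genome-wide maximum bin
  count over `n_perm` permutations gives global thresholds at requested
  alpha levels (the 1−α quantile of the maxima, conservative `higher`
  interpolation).
* **probeset shuffle** — at each locus the gene labels of the
  low-resolution dataset's selected cells are permuted and the common set
  recomputed, yielding per-bin null means and sds; this controls for loci
  that are eQTL-dense in both datasets by chance.

The minimum-count display filter (bins with at least 5 common eQTL) is
presentation only; nulls and thresholds are computed over all bins.

## Fine mapping

A significant low marker defines an interval delimited by its flanking low
markers (chromosome ends for terminal markers). Candidate causal genes are
all genes overlapping the open interval (any overlap; flank positions
themselves excluded). Intervals can be restricted to ±ΔcM around the linked
marker: genetic positions come from linear interpolation between the two
closest cM-bearing markers (nearest-segment extrapolation beyond the ends;
inversion by monotone bisection), and restriction never adds candidates.

Candidates are scored from the target gene's high-resolution profile:
(a) the maximum over markers inside the candidate's transcribed region; or,
if none, (b) the maximum over markers within `ext_bp` of either gene end
(default 100 kb); otherwise (c) the gene is unscored and excluded from the
rank denominator. Scored genes are ranked by descending score with ties
broken by gene-midpoint distance to the linked marker, then gene id — the
tie-break is our convention, required for determinism. The scaled rank is
R_K = (rank − 1)/(#scored − 1) with 0 the best (and R_K = 0 when only one
gene is scored).

Assessment loci are selected by six ordered criteria: low score above the
genome-wide q-quantile (default 0.9999); matched high signal above the same
quantile; more than one candidate gene; at least two high markers above
threshold inside the interval; target annotated in at least one pathway;
and at least one candidate sharing a pathway with the target. Rejected loci
carry the first criterion they failed.

## Evaluation

A locus is a *success* when the top-ranked candidate shares a pathway with
the target gene; a candidate identical to the target (the cis case) counts
as sharing provided the gene is annotated at all. S_HR is the success
fraction. Baselines: S_C picks the candidate whose midpoint is nearest the
linked marker (midpoint rather than edge — our reading; ties to the smaller
gene id); S_R is the analytic expectation of a uniform random pick,
mean_i(k_i/N_G,i), with an optional explicit-sampling mode kept for
cross-checking the expectation. Rank summaries tally loci with the best
pathway co-member in the top half (R_K < 0.5), bottom half (R_K ≥ 0.5 —
the boundary goes to the bottom) or not ranked, and a one-sample one-sided
t-test against 0.5 summarizes top-half enrichment (zero-variance input
short-circuits to 0 or 1 with a warning).

## Hotspot dissection utilities

Tissue specificity is a per-gene Welch t comparing expression in a
designated CNS tissue subset against **all** tissues — overlapping groups,
kept deliberately because that is how atlas-based specificity contrasts
are conventionally quoted; a disjoint-groups variant sits behind a flag.
Duplicate gene rows are averaged first; genes with zero variance in both
groups are reported missing. Group contrasts use two-sided Wilcoxon
rank-sum tests.

The distance-enrichment scan classifies region-mapped genes by whether
their best in-region marker lies within L/2 of a centre gene's midpoint
(the anchor point is our choice) and applies a one-sided (greater) Fisher
exact test for target enrichment inside, for a ladder of interval lengths
L; null curves average n_rand random target sets of the same size drawn
from the mapped universe (the universe is the in-region mapped genes, a
parameter). Per-class marker profiles are means of a gene class's scores at
each region marker, optionally restricted to class members whose best
in-region score passes a bound.

## Synthetic data

The generator emulates the paired-study design; its defaults are the study
conditions under which the test suite's statistical claims hold, and they
describe a scaled-down mouse-like genome:

| parameter | default | meaning |
|---|---|---|
| n_chrom × chrom_length_bp | 5 × 50 Mb | genome |
| n_markers_high | 1,000/chrom | dense panel, one marker per 50 kb |
| block_length_bp | 2.5 Mb | linkage block of the low-resolution panel |
| n_genes | 1,000 | non-overlapping, log-normal lengths (median 50 kb) |
| n_cis / n_regulators × targets | 100 / 10 × 20 | planted architecture |
| replication_prob r | 0.5 | chance a planted eQTL replicates in the dense panel |
| signal_strength s | 20 | score added on top of noise |
| noise_rate λ | 1.0 | background scores ~ Exponential(λ) |
| decay | 0.5 | geometric decay per marker outside the gene |
| cm_per_mb | 1.0 | constant genetic map (piecewise option exists) |
| n_tissues / n_cns / cns_effect | 78 / 11 / 3 | tissue atlas block |

Background scores are i.i.d. Exponential — the right tail shape for
−log10 p under a null, and the only distributional choice the score-free
method actually feels. Each planted eQTL adds `s` in the low matrix at the
single informative marker of the block containing the causal gene, and (if
replicated) in the high matrix at all markers inside the causal gene's
transcribed region, decaying geometrically up to one block away; a causal
gene whose block has no dense marker gets the signal at the nearest marker,
with a warning. Two geometric choices matter and are deliberate: the block
representative is the dense marker nearest the block centre, so that
nearest-marker assignment boundaries coincide with block boundaries (a
randomly placed representative systematically decouples the low signal
from its matched high markers); and genes are placed without overlap,
matching the one-probeset-per-location convention (overlapping genes share
signal markers and produce artificial score ties).

Each regulator and its targets are co-assigned to one pathway — the ground
truth for the evaluation — with remaining pathways filled at random.
Planted cis genes double as the CNS-specific set in the tissue matrix.
All stages draw from independent RNG streams derived from the master seed,
so any stage can be re-run alone and full runs are byte-reproducible.

What the generator does **not** emulate: linkage disequilibrium between
noise cells (background scores are independent, so genome-wide score
quantiles are cleaner than in real data), population structure and its
inflation of trans signals, marker ascertainment bias, probe-level
artefacts, and correlated expression between co-regulated targets. Passing
tests therefore demonstrate the pipeline's statistical correctness and its
behaviour under a controlled replication model — not performance on any
real cross-population dataset.

## Problem sizes and numerical conventions

The test suite and the acceptance script size their simulations to run
comfortably on one CPU: recovery experiments use 2,000 plants in a
2,500-gene × 4,000-marker study; fine-mapping evaluation pools ~500 loci
over replicates of an 800-gene genome with a 30 kb marker grid (dense
enough that nearly every gene's transcribed region contains markers — the
regime in which the causal gene actually carries its own signal); hotspot
detection uses 20 replicates of a 300-gene study with a planted 50-target
band against 100–200 marker permutations. Fisher p-values use scipy's
exact implementation and are verified against exact rational
hypergeometric enumeration for all tables with total ≤ 40; quantiles use
linear interpolation; empirical p-values use add-one correction.

## Known limitations

* The probeset-collapse step that keys both matrices to shared gene ids is
  assumed done upstream.
* The interval scheme's per-locus maximum makes per-record match p-values
  conservative (see above); they remain valid but are best read under the
  exact scheme.
* Greedy strongest-first deduplication is order-dependent in pathological
  equal-score ties; ties are broken deterministically but other keep-rules
  are defensible.
* `restrict_interval` inverts the genetic map by bisection; on segments of
  exactly zero recombination the returned boundary is one point of the
  flat segment, not its extreme.
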
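"""Hotspot-dissection utilities.

Three independent lines of evidence for dissecting a trans-band into its
causal genes:

* CNS-style tissue specificity: per-gene Welch t comparing expression in a
  designated tissue subset against all tissues (overlapping groups, exactly
  as the comparison is usually reported for atlas data), with group-level
  rank-sum comparisons;
* a distance-dependent enrichment scan: Fisher's exact test for target-set
  enrichment inside exploratory intervals of growing length centred on a
  candidate regulator, against randomized target sets;
* per-class marker score profiles: the mean high-resolution score of a gene
  class at each marker of a region.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .model import GeneAnnotation, ScoreMatrix, TissueExpressionMatrix

__all__ = [
    "SpecificityScore", "EnrichmentCurve", "cns_specificity",
    "group_specificity_compare", "distance_enrichment_scan",
    "class_score_profile",
]


@dataclass
class SpecificityScore:
    """Per-gene tissue-specificity t-statistics.

    ``table`` columns: gene_id, t, p. Genes whose two comparison groups
    both have zero variance carry NaN.
    """

    table: pd.DataFrame
    cns_tissues: tuple[str, ...]

    def t_of(self, gene_id: str) -> float:
        hit = self.table[self.table["gene_id"] == gene_id]
        return float(hit["t"].iloc[0]) if len(hit) else float("nan")


def cns_specificity(expr: TissueExpressionMatrix,
                    disjoint: bool = False) -> SpecificityScore:
    """Welch two-sample t per gene: CNS tissues vs all tissues.

    The reference group is *all* tissues (CNS included), mirroring how
    atlas-based specificity is conventionally reported; ``disjoint=True``
    compares CNS against non-CNS tissues instead. Genes measured by
    multiple rows (e.g. several probesets) are averaged first.
    """
    cns_cols = expr.cns_columns()
    if len(cns_cols) < 2 or len(expr.tissue_ids) < 2:
        raise ValueError("need at least two tissues in each comparison group")
    df = pd.DataFrame(expr.expression, index=expr.gene_ids)
    df = df.groupby(level=0, sort=True).mean()
    values = df.to_numpy()
    other = (np.setdiff1d(np.arange(values.shape[1]), cns_cols)
             if disjoint else np.arange(values.shape[1]))
    rows = []
    for gid, v in zip(df.index, values):
        a, b = v[cns_cols], v[other]
        if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
            rows.append((gid, float("nan"), float("nan")))
            continue
        t, p = scipy.stats.ttest_ind(a, b, equal_var=False)
        rows.append((gid, float(t), float(p)))
    return SpecificityScore(pd.DataFrame(rows, columns=["gene_id", "t", "p"]),
                            expr.cns_tissues)


def group_specificity_compare(scores: SpecificityScore,
                              groups: "dict[str, set[str]]"
                              ) -> tuple[dict, pd.DataFrame]:
    """Distributions of specificity t-scores per gene group, with two-sided
    Wilcoxon rank-sum p-values for every group pair. Groups with fewer than
    two scored genes get distributions only, no tests."""
    t_by_gene = dict(zip(scores.table["gene_id"], scores.table["t"]))
    dists = {}
    for name, members in groups.items():
        if not members:
            raise ValueError(f"group {name!r} is empty")
        vals = np.array([t_by_gene[g] for g in sorted(members)
                         if g in t_by_gene], dtype=float)
        dists[name] = vals[~np.isnan(vals)]
    rows = []
    for a, b in itertools.combinations(sorted(groups), 2):
        if len(dists[a]) < 2 or len(dists[b]) < 2:
            rows.append((a, b, float("nan")))
            continue
        stat = scipy.stats.mannwhitneyu(dists[a], dists[b],
                                        alternative="two-sided")
        rows.append((a, b, float(stat.pvalue)))
    return dists, pd.DataFrame(rows, columns=["group_a", "group_b", "p"])


@dataclass
class EnrichmentCurve:
    """Target enrichment as a function of exploratory-interval length.

    ``table`` columns: length_bp, a (targets inside), b (non-targets
    inside), c (targets outside), d (non-targets outside), neglogp,
    null_mean, null_sd. Margins (a+c, b+d) are constant across lengths.
    """

    center_gene: str
    center_pos: float
    table: pd.DataFrame
    n_rand: int


def fisher_enrichment_p(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher exact p for enrichment of targets inside."""
    _, p = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(p)


def distance_enrichment_scan(center_gene: str, genes: GeneAnnotation,
                             mapped_genes: "dict[str, int]",
                             targets: "set[str]",
                             lengths_bp: "list[int]",
                             n_rand: int = 100,
                             seed: int | None = 0) -> EnrichmentCurve:
    """Scan target enrichment in intervals centred on a candidate regulator.

    ``mapped_genes`` maps each gene of the universe (genes with an eQTL in
    the region) to the position of its best in-region marker. For each
    interval length L, genes are classified by whether that marker lies
    within L/2 of the centre gene's midpoint, and a one-sided Fisher exact
    test measures enrichment of ``targets`` inside. Null curves come from
    ``n_rand`` random target sets of the same size drawn from the mapped
    universe.
    """
    rng = np.random.default_rng(seed)
    center_pos = genes.midpoint(center_gene)
    univ = sorted(mapped_genes)
    pos = np.array([mapped_genes[g] for g in univ], dtype=float)
    is_target = np.array([g in targets for g in univ], dtype=bool)
    n_targets = int(is_target.sum())

    rand_sets = np.zeros((n_rand, len(univ)), dtype=bool)
    for t in range(n_rand):
        pick = rng.choice(len(univ), size=n_targets, replace=False) \
            if n_targets else np.empty(0, dtype=int)
        rand_sets[t, pick] = True

    rows = []
    for L in lengths_bp:
        inside = np.abs(pos - center_pos) <= L / 2
        a = int((inside & is_target).sum())
        b = int((inside & ~is_target).sum())
        c = int((~inside & is_target).sum())
        d = int((~inside & ~is_target).sum())
        if n_targets == 0:
            neglogp, null_mean, null_sd = 0.0, 0.0, 0.0
        else:
            neglogp = -np.log10(fisher_enrichment_p(a, b, c, d))
            null_ps = np.empty(n_rand)
            for t in range(n_rand):
                rt = rand_sets[t]
                na = int((inside & rt).sum())
                nb = int((inside & ~rt).sum())
                nc = int((~inside & rt).sum())
                nd = int((~inside & ~rt).sum())
                null_ps[t] = -np.log10(fisher_enrichment_p(na, nb, nc, nd))
            null_mean = float(null_ps.mean())
            null_sd = float(null_ps.std(ddof=1)) if n_rand > 1 else 0.0
        rows.append((L, a, b, c, d, float(neglogp), null_mean, null_sd))
    table = pd.DataFrame(rows, columns=["length_bp", "a", "b", "c", "d",
                                        "neglogp", "null_mean", "null_sd"])
    return EnrichmentCurve(center_gene, center_pos, table, n_rand)


def class_score_profile(high: ScoreMatrix, class_genes: "set[str]",
                        region_markers: "list[str]",
                        min_score: float | None = None) -> pd.Series:
    """Mean high-resolution score of a gene class at each region marker.

    ``min_score`` optionally restricts the class to genes whose maximum
    in-region score meets the bound (the significant-subset variant).
    """
    members = sorted(g for g in class_genes if g in set(high.gene_ids))
    if not members:
        raise ValueError("gene class is empty or absent from the matrix")
    cols = high.marker_indices(region_markers)
    rows = np.array([high.gene_index(g) for g in members], dtype=np.intp)
    sub = high.scores[np.ix_(rows, cols)]
    if min_score is not None:
        keep = sub.max(axis=1) >= min_score
        if not keep.any():
            raise ValueError("no class gene passes the score bound")
        sub = sub[keep]
    return pd.Series(sub.mean(axis=0), index=list(region_markers))
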
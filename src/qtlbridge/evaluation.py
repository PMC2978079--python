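"""Assessment of fine-mapping rankings against pathway co-membership.

A locus prediction is a *success* when the top-ranked candidate shares at
least one pathway with the target gene (the cis case, where the candidate
is the target itself, counts as a success provided the gene is annotated).
The high-resolution success rate S_HR is compared against two baselines:
picking the candidate closest to the linked marker (S_C) and picking a
candidate uniformly at random (S_R, computed analytically as the mean
per-locus frequency of pathway co-members).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .finemap import EqtlInterval, LocusRanking
from .model import GeneAnnotation, GeneSetCollection

__all__ = [
    "EvaluationSummary", "success_rate", "closest_gene_baseline",
    "random_baseline", "rank_half_test",
]


@dataclass
class EvaluationSummary:
    """Per-locus and aggregate fine-mapping performance.

    ``per_locus`` columns: target_gene, marker_id, n_genes, n_scored,
    top_gene, success, best_comember_r_k (NaN when no scored co-member),
    not_ranked. Tallies partition the locus count: top-half (R_K < 0.5),
    bottom-half (R_K >= 0.5) and not-ranked.
    """

    n_loci: int
    n_successes: int
    s_hr: float
    per_locus: pd.DataFrame
    n_top_half: int
    n_bottom_half: int
    n_not_ranked: int


def _comember_r_k(ranking: LocusRanking, target: str,
                  pathways: GeneSetCollection) -> float:
    scored = ranking.table[~ranking.table["unscored"]]
    rks = [row.r_k for row in scored.itertuples(index=False)
           if pathways.share_set(target, row.gene_id)]
    return min(rks) if rks else float("nan")


def success_rate(rankings: "list[LocusRanking]",
                 pathways: GeneSetCollection) -> EvaluationSummary:
    """Fraction of loci whose top-ranked gene shares a pathway with the
    target (S_HR), plus the scaled rank of the best pathway co-member per
    locus and the top-half / bottom-half / not-ranked tallies."""
    rows = []
    for r in rankings:
        target = r.interval.target_gene
        if target is None:
            raise ValueError("ranking has no target gene attached")
        top = r.top_gene()
        success = top is not None and pathways.share_set(target, top)
        rk = _comember_r_k(r, target, pathways)
        rows.append((target, r.interval.marker_id, r.interval.n_genes,
                     r.n_scored, top, success, rk, np.isnan(rk)))
    per_locus = pd.DataFrame(rows, columns=[
        "target_gene", "marker_id", "n_genes", "n_scored", "top_gene",
        "success", "best_comember_r_k", "not_ranked"])
    n = len(per_locus)
    n_succ = int(per_locus["success"].sum())
    rk = per_locus["best_comember_r_k"]
    n_top = int((rk < 0.5).sum())                 # R_K = 0.5 goes bottom-half
    n_not = int(per_locus["not_ranked"].sum())
    n_bottom = n - n_top - n_not
    return EvaluationSummary(n, n_succ, n_succ / n if n else float("nan"),
                             per_locus, n_top, n_bottom, n_not)


def closest_gene_baseline(intervals: "list[EqtlInterval]",
                          genes: GeneAnnotation,
                          pathways: GeneSetCollection) -> float:
    """S_C: per locus, pick the candidate whose midpoint is nearest the
    linked marker (ties to the lexicographically smaller gene id); success
    as in :func:`success_rate`."""
    if not intervals:
        return float("nan")
    succ = 0
    for iv in intervals:
        if iv.target_gene is None:
            raise ValueError("interval has no target gene attached")
        if not iv.candidate_genes:
            continue
        best = min(iv.candidate_genes,
                   key=lambda g: (abs(genes.midpoint(g) - iv.marker_pos), g))
        succ += pathways.share_set(iv.target_gene, best)
    return succ / len(intervals)


def random_baseline(intervals: "list[EqtlInterval]",
                    pathways: GeneSetCollection,
                    sample: int = 0,
                    seed: int | None = 0) -> float:
    """S_R: expected success rate of uniform random candidate selection,
    S_R = mean_i(k_i / N_G,i) with k_i the number of candidates at locus i
    sharing a pathway with the target.

    With ``sample`` > 0 the expectation is replaced by explicit random
    draws (``sample`` picks per locus, averaged) -- a testing aid.
    """
    if not intervals:
        return float("nan")
    rng = np.random.default_rng(seed)
    vals = []
    for iv in intervals:
        if iv.target_gene is None:
            raise ValueError("interval has no target gene attached")
        if iv.n_genes == 0:
            raise ValueError(f"interval at {iv.marker_id} has no candidates")
        share = np.array([pathways.share_set(iv.target_gene, g)
                          for g in iv.candidate_genes], dtype=float)
        if sample > 0:
            picks = rng.integers(iv.n_genes, size=sample)
            vals.append(share[picks].mean())
        else:
            vals.append(share.mean())
    return float(np.mean(vals))


def rank_half_test(summary: EvaluationSummary) -> float:
    """One-sided test that pathway co-members rank in the top half.

    One-sample t-test of the best co-member scaled ranks against 0.5 with
    the smaller-mean alternative. Degenerate zero-variance inputs
    short-circuit to 0.0 or 1.0 with a warning.
    """
    rks = summary.per_locus["best_comember_r_k"].dropna().to_numpy()
    if len(rks) < 2:
        raise ValueError("need at least two ranked loci")
    if np.ptp(rks) == 0.0:
        warnings.warn("zero-variance scaled ranks; returning a degenerate p")
        if rks[0] < 0.5:
            return 0.0
        return 1.0
    res = scipy.stats.ttest_1samp(rks, 0.5, alternative="less")
    return float(res.pvalue)
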
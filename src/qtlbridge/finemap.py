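"""Candidate-gene fine mapping of low-resolution eQTL intervals.

A significant low-resolution marker defines an interval delimited by its
flanking markers; all genes overlapping the interval are candidate causal
genes. The interval can optionally be restricted to a maximal genetic
distance (cM) around the linked marker, with genetic positions obtained by
linear interpolation on the marker map. Candidates are then ranked by the
high-resolution scores of markers inside (or, failing that, near) their
transcribed region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .consistency import (MarkerPairing, _matched_max, _shared_genes,
                          quantile_threshold)
from .model import (GeneAnnotation, GeneSetCollection, GenomeDescription,
                    MarkerMap, ScoreMatrix)

__all__ = [
    "EqtlInterval", "LocusRanking", "define_interval", "interpolate_cm",
    "restrict_interval", "score_candidates", "select_assessment_loci",
]

EXT_BP_DEFAULT = 100_000


@dataclass
class EqtlInterval:
    """A low-resolution eQTL interval delimited by flanking markers.

    Candidate genes are those whose transcribed region overlaps the open
    interval (flank_left, flank_right); genes spanning a flank are included
    (any-overlap rule). ``restricted`` holds optional tighter bp bounds
    from a genetic-distance cut.
    """

    marker_id: str
    chrom: str
    marker_pos: int
    flank_left: float
    flank_right: float
    candidate_genes: list[str]
    target_gene: str | None = None
    restricted: tuple[float, float] | None = None

    @property
    def n_genes(self) -> int:
        return len(self.candidate_genes)

    @property
    def bounds(self) -> tuple[float, float]:
        return self.restricted if self.restricted is not None else (
            self.flank_left, self.flank_right)


def _candidates_in(genes: GeneAnnotation, chrom: str, left: float,
                   right: float) -> list[str]:
    sub = genes.genes_on(chrom)
    hit = sub[(sub["end_bp"] > left) & (sub["start_bp"] < right)]
    return list(hit["gene_id"])


def define_interval(low_map: MarkerMap, marker_id: str,
                    genes: GeneAnnotation,
                    genome: GenomeDescription | None = None,
                    target_gene: str | None = None) -> EqtlInterval:
    """Interval delimited by the neighbouring low-resolution markers.

    The first marker of a chromosome uses position 1 as its left flank; the
    last uses the chromosome end (or an unbounded flank when no genome
    description is supplied).
    """
    if marker_id not in low_map:
        raise KeyError(f"unknown marker {marker_id!r}")
    chrom, pos = low_map.position(marker_id)
    sub = low_map.markers_on(chrom)
    positions = sub["pos_bp"].to_numpy()
    ids = sub["marker_id"].to_numpy()
    i = int(np.flatnonzero(ids == marker_id)[0])
    left = float(positions[i - 1]) if i > 0 else 1.0
    if i < len(positions) - 1:
        right = float(positions[i + 1])
    elif genome is not None:
        right = float(genome.length_of(chrom))
    else:
        right = math.inf
    return EqtlInterval(marker_id, chrom, pos, left, right,
                        _candidates_in(genes, chrom, left, right),
                        target_gene=target_gene)


def interpolate_cm(marker_map: MarkerMap, chrom: str, pos_bp: float) -> float:
    """Genetic position by linear interpolation between the two closest
    markers with known cM; beyond the outermost such markers the nearest
    segment's rate is extrapolated."""
    sub = marker_map.markers_on(chrom)
    known = sub.dropna(subset=["cm"])
    if len(known) < 2:
        raise ValueError(f"need >= 2 markers with cM on {chrom}")
    xp = known["pos_bp"].to_numpy(dtype=float)
    fp = known["cm"].to_numpy(dtype=float)
    if pos_bp < xp[0]:
        rate = (fp[1] - fp[0]) / (xp[1] - xp[0])
        return float(fp[0] + (pos_bp - xp[0]) * rate)
    if pos_bp > xp[-1]:
        rate = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        return float(fp[-1] + (pos_bp - xp[-1]) * rate)
    return float(np.interp(pos_bp, xp, fp))


def _invert_cm(marker_map: MarkerMap, chrom: str, cm: float,
               lo: float, hi: float) -> float:
    """A bp position whose interpolated cM equals ``cm``, found by monotone
    bisection on [lo, hi] (cM is non-decreasing in bp)."""
    f = lambda x: interpolate_cm(marker_map, chrom, x)
    if f(lo) >= cm:
        return lo
    if f(hi) <= cm:
        return hi
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if f(mid) < cm:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def restrict_interval(interval: EqtlInterval, low_map: MarkerMap,
                      delta_cm: float,
                      genes: GeneAnnotation | None = None) -> EqtlInterval:
    """Restrict the interval to positions within +-delta_cm of the linked
    marker, intersected with the flank bounds. Re-filters the candidate
    list when the gene annotation is supplied."""
    if math.isinf(delta_cm):
        return interval
    cm_i = interpolate_cm(low_map, interval.chrom, interval.marker_pos)
    span = interval.flank_right - interval.flank_left
    if not math.isfinite(span) or span <= 0:
        span = 10 * abs(interval.marker_pos) + 1e6
    lo_search = max(interval.flank_left - span, 1.0) \
        if math.isfinite(interval.flank_left) else 1.0
    hi_search = interval.flank_right + span \
        if math.isfinite(interval.flank_right) else interval.marker_pos + span
    left = _invert_cm(low_map, interval.chrom, cm_i - delta_cm,
                      lo_search, float(interval.marker_pos))
    right = _invert_cm(low_map, interval.chrom, cm_i + delta_cm,
                       float(interval.marker_pos), hi_search)
    left = max(left, interval.flank_left)
    right = min(right, interval.flank_right)
    candidates = (_candidates_in(genes, interval.chrom, left, right)
                  if genes is not None else
                  list(interval.candidate_genes))
    return dc_replace(interval, restricted=(left, right),
                      candidate_genes=candidates)


@dataclass
class LocusRanking:
    """Ranked candidate genes at one locus.

    ``table`` columns: gene_id, score, rank (1 = best, NaN for unscored),
    r_k (scaled rank in [0, 1], 0 = best), unscored, dist_to_marker.
    Unscored genes (no high-resolution marker inside the gene or within
    ``ext_bp`` of it) are excluded from the rank denominator.
    """

    interval: EqtlInterval
    table: pd.DataFrame
    ext_bp: int

    @property
    def n_scored(self) -> int:
        return int((~self.table["unscored"]).sum())

    def top_gene(self) -> str | None:
        scored = self.table[~self.table["unscored"]]
        if scored.empty:
            return None
        return scored.loc[scored["rank"].idxmin(), "gene_id"]


def score_candidates(interval: EqtlInterval, high: ScoreMatrix,
                     target_gene: str, high_map: MarkerMap,
                     genes: GeneAnnotation,
                     ext_bp: int = EXT_BP_DEFAULT) -> LocusRanking:
    """Rank the interval's candidate genes by high-resolution scores.

    Per candidate: (a) if markers lie inside the transcribed region, its
    score is the maximum of those markers' scores for the target gene;
    (b) otherwise, markers within ``ext_bp`` of either gene end are used
    (symmetric extension, strand ignored); (c) otherwise the gene is
    unscored. Scored genes are ranked by descending score; ties break by
    distance of the gene midpoint to the linked marker, then by gene id.
    """
    row = high.row(target_gene)
    sub = high_map.markers_on(interval.chrom)
    mpos = sub["pos_bp"].to_numpy()
    mcols = high.marker_indices(sub["marker_id"])

    recs = []
    for gid in interval.candidate_genes:
        g = genes.loc(gid)
        inside = (mpos >= g["start_bp"]) & (mpos <= g["end_bp"])
        if inside.any():
            score, unscored = float(row[mcols[inside]].max()), False
        else:
            near = ((mpos >= g["start_bp"] - ext_bp) &
                    (mpos <= g["end_bp"] + ext_bp))
            if near.any():
                score, unscored = float(row[mcols[near]].max()), False
            else:
                score, unscored = float("nan"), True
        mid = 0.5 * (g["start_bp"] + g["end_bp"])
        recs.append((gid, score, unscored, abs(mid - interval.marker_pos)))
    table = pd.DataFrame(recs, columns=["gene_id", "score", "unscored",
                                        "dist_to_marker"])
    scored = table[~table["unscored"]].sort_values(
        ["score", "dist_to_marker", "gene_id"],
        ascending=[False, True, True], kind="stable")
    table["rank"] = np.nan
    table.loc[scored.index, "rank"] = np.arange(1, len(scored) + 1,
                                                dtype=float)
    ns = len(scored)
    table["r_k"] = np.nan
    if ns == 1:
        table.loc[scored.index, "r_k"] = 0.0
    elif ns > 1:
        table.loc[scored.index, "r_k"] = \
            (table.loc[scored.index, "rank"] - 1) / (ns - 1)
    tgt = interval.target_gene if interval.target_gene is not None else target_gene
    return LocusRanking(dc_replace(interval, target_gene=tgt), table, ext_bp)


def _interval_marker_cols(high: ScoreMatrix, high_map: MarkerMap,
                          interval: EqtlInterval) -> np.ndarray:
    sub = high_map.markers_on(interval.chrom)
    sel = sub[(sub["pos_bp"] > interval.flank_left) &
              (sub["pos_bp"] < interval.flank_right)]
    return high.marker_indices(sel["marker_id"])


def select_assessment_loci(low: ScoreMatrix, high: ScoreMatrix,
                           pairing: MarkerPairing, low_map: MarkerMap,
                           high_map: MarkerMap, genes: GeneAnnotation,
                           pathways: GeneSetCollection,
                           q: float = 0.9999,
                           genome: GenomeDescription | None = None,
                           min_high_signals: int = 2
                           ) -> tuple[list[EqtlInterval], pd.DataFrame]:
    """Select strong, informative loci for the fine-mapping assessment.

    Criteria, applied in order to every (gene, paired low marker) pair:

    1. low-resolution score >= genome-wide q-quantile of the low matrix;
    2. matched high-resolution signal >= genome-wide q-quantile;
    3. more than one candidate gene in the interval;
    4. at least ``min_high_signals`` high-resolution markers inside the
       interval exceed the high threshold (for the target gene);
    5. the target gene belongs to at least one pathway;
    6. at least one interval candidate shares a pathway with the target.

    Returns the surviving intervals (with ``target_gene`` set) and a table
    of rejected loci naming the first criterion each one failed. Criterion 1
    defines the scan, so loci failing it never appear in either output.
    """
    thr_low = quantile_threshold(low, q)
    thr_high = quantile_threshold(high, q)
    shared = _shared_genes(low, high)
    lrows = np.array([low.gene_index(g) for g in shared], dtype=np.intp)
    hrows = np.array([high.gene_index(g) for g in shared], dtype=np.intp)
    lcols = low.marker_indices(pairing.low_ids)
    L = low.scores[np.ix_(lrows, lcols)]
    H = _matched_max(high, pairing, hrows)

    selected: list[EqtlInterval] = []
    rejected: list[tuple[str, str, str]] = []
    interval_cache: dict[str, EqtlInterval] = {}
    cols_cache: dict[str, np.ndarray] = {}

    gi, mj = np.nonzero(L >= thr_low)
    for i, j in zip(gi, mj):
        gene = shared[i]
        marker = pairing.low_ids[j]
        if H[i, j] < thr_high:
            rejected.append((gene, marker, "high signal below threshold"))
            continue
        if marker not in interval_cache:
            interval_cache[marker] = define_interval(low_map, marker, genes,
                                                     genome)
            cols_cache[marker] = _interval_marker_cols(
                high, high_map, interval_cache[marker])
        base = interval_cache[marker]
        if base.n_genes <= 1:
            rejected.append((gene, marker, "N_G <= 1"))
            continue
        row = high.scores[high.gene_index(gene)]
        if int((row[cols_cache[marker]] >= thr_high).sum()) < min_high_signals:
            rejected.append((gene, marker, "high-resolution signals <= 1"))
            continue
        if not pathways.annotated(gene):
            rejected.append((gene, marker, "target not in any pathway"))
            continue
        if not any(pathways.share_set(gene, c)
                   for c in base.candidate_genes):
            rejected.append((gene, marker, "no candidate shares a pathway"))
            continue
        selected.append(dc_replace(base, target_gene=gene,
                                   candidate_genes=list(base.candidate_genes)))
    rej = pd.DataFrame(rejected, columns=["gene_id", "marker_id", "reason"])
    return selected, rej
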
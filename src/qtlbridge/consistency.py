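"""Cross-population eQTL consistency: marker pairing, common-eQTL calling,
empirical match p-values and threshold-grid randomization.

Two comparison schemes are supported. The *exact* scheme pairs markers that
sit at (virtually) identical genomic positions in both panels (within a few
bp). The *interval* scheme assigns every high-resolution marker to its
nearest low-resolution marker and compares the maximum high-resolution
signal in that interval against the low-resolution signal -- trading
specificity for recovery.

A *common eQTL* is a (gene, low marker) pair whose score meets the
per-dataset quantile threshold on both sides; multiple common peaks of the
same gene within a deduplication window (default 5 Mb) on one chromosome
are counted once, keeping the peak with the strongest low-resolution score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import MarkerMap, ScoreMatrix

__all__ = [
    "MarkerPairing", "CommonEqtlSet", "ThresholdGrid",
    "quantile_threshold", "pair_markers", "find_common_eqtl",
    "match_pvalue", "add_match_pvalues", "fraction_common", "threshold_grid",
]

DEDUP_WINDOW_BP = 5_000_000


def quantile_threshold(m: ScoreMatrix, q: float) -> float:
    """Empirical q-quantile of all matrix cells (linear interpolation).

    The downstream selection rule is ``score >= threshold``, so that a
    constant matrix at any q selects every cell.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"quantile must be in (0, 1), got {q}")
    if m.scores.size == 0:
        raise ValueError("empty score matrix")
    return float(np.quantile(m.scores, q))


@dataclass
class MarkerPairing:
    """Assignment of high-resolution markers to low-resolution markers.

    ``low_ids[i]`` (on ``chrom[i]`` at ``pos_bp[i]``) is matched with the
    high markers ``matched[i]`` (a nonempty list). In exact mode each list
    has length one and the two markers are within ``tol_bp`` of each other;
    in interval mode every high marker appears in exactly one list (that of
    its nearest low marker on the same chromosome, ties going to the
    lower-coordinate low marker).
    """

    mode: str
    tol_bp: int
    low_ids: list[str]
    chrom: list[str]
    pos_bp: np.ndarray
    matched: list[list[str]]

    def __len__(self) -> int:
        return len(self.low_ids)


def pair_markers(low: MarkerMap, high: MarkerMap, mode: str,
                 tol_bp: int = 5) -> MarkerPairing:
    """Build the exact or interval marker pairing between two maps."""
    if mode not in ("exact", "interval"):
        raise ValueError(f"unknown pairing mode {mode!r}")
    shared = set(low.df["chrom"]) & set(high.df["chrom"])
    if not shared:
        raise ValueError("marker maps share no chromosomes")
    low_ids: list[str] = []
    chroms: list[str] = []
    poss: list[int] = []
    matched: list[list[str]] = []
    for chrom in sorted(shared):
        lsub = low.markers_on(chrom)
        hsub = high.markers_on(chrom)
        hpos = hsub["pos_bp"].to_numpy()
        hids = hsub["marker_id"].to_numpy()
        lpos = lsub["pos_bp"].to_numpy()
        lids = lsub["marker_id"].to_numpy()
        if mode == "exact":
            for lid, lp in zip(lids, lpos):
                d = np.abs(hpos - lp)
                j = int(np.argmin(d)) if len(d) else -1
                if j >= 0 and d[j] <= tol_bp:
                    # nearest high marker within tolerance; ties at equal
                    # distance resolve to the lower coordinate via argmin
                    low_ids.append(lid)
                    chroms.append(chrom)
                    poss.append(int(lp))
                    matched.append([hids[j]])
        else:
            if len(lpos) == 0 or len(hpos) == 0:
                continue
            # nearest low marker for each high marker; exact midpoint ties
            # go to the lower-coordinate low marker
            idx = np.searchsorted(lpos, hpos)
            idx_left = np.clip(idx - 1, 0, len(lpos) - 1)
            idx_right = np.clip(idx, 0, len(lpos) - 1)
            d_left = np.abs(hpos - lpos[idx_left])
            d_right = np.abs(hpos - lpos[idx_right])
            assign = np.where(d_left <= d_right, idx_left, idx_right)
            groups: dict[int, list[str]] = {}
            for hid, a in zip(hids, assign):
                groups.setdefault(int(a), []).append(hid)
            for a in sorted(groups):
                low_ids.append(lids[a])
                chroms.append(chrom)
                poss.append(int(lpos[a]))
                matched.append(groups[a])
    return MarkerPairing(mode, tol_bp, low_ids, chroms,
                         np.asarray(poss, dtype=np.int64), matched)


@dataclass
class CommonEqtlSet:
    """Matched (gene, marker) signals above paired thresholds.

    ``records`` columns: gene_id, low_marker_id, high_marker_id, chrom,
    pos_bp, low_score, high_score and (after :func:`add_match_pvalues`)
    match_pvalue. Counts are deduplicated per gene and chromosome within
    the window used at construction.
    """

    records: pd.DataFrame
    thr_low: float
    thr_high: float
    q_low: float
    q_high: float
    n_low: int          # selected eQTL in the low-resolution dataset
    n_high: int         # selected eQTL in the high-resolution dataset
    dedup_window_bp: int = DEDUP_WINDOW_BP

    @property
    def n_common(self) -> int:
        return len(self.records)


def _dedup_keep(chroms: np.ndarray, pos: np.ndarray,
                scores: np.ndarray, window: int) -> np.ndarray:
    """Greedy per-gene dedup: keep the strongest peak, suppress weaker
    peaks on the same chromosome within +-window bp. Ties resolve to the
    lower coordinate. Returns indices kept, in input order."""
    order = np.lexsort((pos, -scores))
    kept: list[int] = []
    for i in order:
        ok = True
        for j in kept:
            if chroms[i] == chroms[j] and abs(int(pos[i]) - int(pos[j])) <= window:
                ok = False
                break
        if ok:
            kept.append(int(i))
    return np.array(sorted(kept), dtype=np.intp)


def _matched_max(high: ScoreMatrix, pairing: MarkerPairing,
                 gene_rows: np.ndarray) -> np.ndarray:
    """Per (gene, low marker): max high score over the matched markers."""
    cols = []
    starts = []
    k = 0
    for group in pairing.matched:
        starts.append(k)
        idx = high.marker_indices(group)
        cols.extend(idx)
        k += len(idx)
    sub = high.scores[np.ix_(gene_rows, np.asarray(cols, dtype=np.intp))]
    return np.maximum.reduceat(sub, np.asarray(starts, dtype=np.intp), axis=1)


def _shared_genes(low: ScoreMatrix, high: ScoreMatrix) -> list[str]:
    shared = sorted(set(low.gene_ids) & set(high.gene_ids))
    if not shared:
        raise ValueError("score matrices share no gene ids")
    return shared


def find_common_eqtl(low: ScoreMatrix, high: ScoreMatrix,
                     pairing: MarkerPairing, q_low: float, q_high: float,
                     dedup_window_bp: int = DEDUP_WINDOW_BP,
                     thr_low: float | None = None,
                     thr_high: float | None = None) -> CommonEqtlSet:
    """Call common eQTL between the two datasets at paired markers.

    Thresholds default to genome-wide quantiles of the full matrices; they
    can be passed explicitly to reuse thresholds across calls. Per-dataset
    counts (``n_low``, ``n_high``) tally threshold-exceeding cells at the
    paired markers, deduplicated exactly like the common eQTL so that the
    fraction of common signals is comparable across pairing schemes.
    """
    thr_low = quantile_threshold(low, q_low) if thr_low is None else thr_low
    thr_high = quantile_threshold(high, q_high) if thr_high is None else thr_high
    genes = _shared_genes(low, high)
    lrows = np.array([low.gene_index(g) for g in genes], dtype=np.intp)
    hrows = np.array([high.gene_index(g) for g in genes], dtype=np.intp)
    lcols = low.marker_indices(pairing.low_ids)
    L = low.scores[np.ix_(lrows, lcols)]
    H = _matched_max(high, pairing, hrows)
    low_hit = L >= thr_low
    high_hit = H >= thr_high

    chrom_arr = np.asarray(pairing.chrom, dtype=object)
    pos_arr = pairing.pos_bp

    def dedup_count(hits: np.ndarray, scores: np.ndarray) -> int:
        total = 0
        for i in np.flatnonzero(hits.any(axis=1)):
            js = np.flatnonzero(hits[i])
            kept = _dedup_keep(chrom_arr[js], pos_arr[js], scores[i, js],
                               dedup_window_bp)
            total += len(kept)
        return total

    n_low = dedup_count(low_hit, L)
    n_high = dedup_count(high_hit, H)

    common = low_hit & high_hit
    rows = []
    for i in np.flatnonzero(common.any(axis=1)):
        js = np.flatnonzero(common[i])
        kept = _dedup_keep(chrom_arr[js], pos_arr[js], L[i, js],
                           dedup_window_bp)
        for j in js[kept]:
            group = pairing.matched[j]
            gcols = high.marker_indices(group)
            gi = hrows[i]
            best = int(np.argmax(high.scores[gi, gcols]))
            rows.append((genes[i], pairing.low_ids[j], group[best],
                         chrom_arr[j], int(pos_arr[j]),
                         float(L[i, j]), float(H[i, j])))
    records = pd.DataFrame(rows, columns=[
        "gene_id", "low_marker_id", "high_marker_id", "chrom", "pos_bp",
        "low_score", "high_score"])
    return CommonEqtlSet(records, thr_low, thr_high, q_low, q_high,
                         n_low, n_high, dedup_window_bp)


def match_pvalue(low_profile: np.ndarray, high_profile: np.ndarray,
                 thr_low: float, thr_high: float,
                 pool: np.ndarray, n_rand: int = 10_000,
                 rng: np.random.Generator | int | None = None,
                 observed: int | None = None) -> float:
    """Empirical p-value for the joint exceedance of one gene's profiles.

    The statistic is the number of paired markers at which both the low
    profile and the (matched-max) high profile meet their thresholds. The
    null re-pairs the low profile with the high profiles of randomly drawn
    genes from ``pool`` (genes with comparable scores, i.e. the same score
    bin). Add-one correction: p = (1 + #{randomized >= observed})/(1 + n_rand).
    """
    if n_rand < 100:
        warnings.warn("n_rand < 100 gives a coarse empirical p-value")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    low_hit = low_profile >= thr_low
    if observed is None:
        observed = int(np.count_nonzero(low_hit & (high_profile >= thr_high)))
    if len(pool) == 0:
        raise ValueError("empty randomization pool")
    draws = rng.integers(len(pool), size=n_rand)
    rand_hits = (pool[draws] >= thr_high) & low_hit[None, :]
    stat = rand_hits.sum(axis=1)
    return float((1 + np.count_nonzero(stat >= observed)) / (1 + n_rand))


def add_match_pvalues(common: CommonEqtlSet, low: ScoreMatrix,
                      high: ScoreMatrix, pairing: MarkerPairing,
                      n_rand: int = 10_000, seed: int | None = 0,
                      n_bins: int = 10) -> CommonEqtlSet:
    """Attach an empirical match p-value to every common-eQTL record.

    Genes are binned by the quantile of their maximum matched high-resolution
    score (deciles by default); each record's null draws high profiles from
    genes in the same bin, so that a gene with strong scores is compared
    against equally strong decoys.
    """
    rng = np.random.default_rng(seed)
    genes = _shared_genes(low, high)
    lrows = np.array([low.gene_index(g) for g in genes], dtype=np.intp)
    hrows = np.array([high.gene_index(g) for g in genes], dtype=np.intp)
    lcols = low.marker_indices(pairing.low_ids)
    L = low.scores[np.ix_(lrows, lcols)]
    H = _matched_max(high, pairing, hrows)
    gmax = H.max(axis=1)
    edges = np.quantile(gmax, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(edges, gmax, side="right") - 1, 0, n_bins - 1)
    g_index = {g: i for i, g in enumerate(genes)}
    pvals = []
    for rec in common.records.itertuples(index=False):
        i = g_index[rec.gene_id]
        pool_rows = np.flatnonzero(bins == bins[i])
        pvals.append(match_pvalue(L[i], H[i], common.thr_low, common.thr_high,
                                  H[pool_rows], n_rand=n_rand, rng=rng))
    records = common.records.copy()
    records["match_pvalue"] = pvals
    return CommonEqtlSet(records, common.thr_low, common.thr_high,
                         common.q_low, common.q_high, common.n_low,
                         common.n_high, common.dedup_window_bp)


def fraction_common(n_hits: int, n_low: int, n_high: int) -> float:
    """Fraction of common signals, F_C = n_hits / (n_low + n_high).

    Bounded by 0.5 because each hit consumes one selection from each side.
    Undefined (NaN) when both per-dataset counts are zero.
    """
    if n_low + n_high == 0:
        return float("nan")
    return n_hits / (n_low + n_high)


@dataclass
class ThresholdGrid:
    """Observed and shuffled F_C over a grid of quantile cutoffs."""

    q_low: np.ndarray
    q_high: np.ndarray
    f_obs: np.ndarray          # len(q_low) x len(q_high)
    f_null_mean: np.ndarray
    f_null_sd: np.ndarray
    n_common: np.ndarray
    n_low: np.ndarray
    n_high: np.ndarray
    n_shuffles: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, ql in enumerate(self.q_low):
            for j, qh in enumerate(self.q_high):
                rows.append((ql, qh, self.f_obs[i, j], self.f_null_mean[i, j],
                             self.f_null_sd[i, j], self.n_common[i, j],
                             self.n_low[i, j], self.n_high[i, j]))
        return pd.DataFrame(rows, columns=[
            "q_low", "q_high", "f_c_obs", "f_c_null_mean", "f_c_null_sd",
            "n_common", "n_low", "n_high"])


def _shuffle_hits(g_idx: np.ndarray, scores: np.ndarray, n_bins: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Permute gene labels of selected eQTL within score-decile bins."""
    out = g_idx.copy()
    if len(g_idx) == 0:
        return out
    edges = np.quantile(scores, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(edges, scores, side="right") - 1,
                   0, n_bins - 1)
    for b in np.unique(bins):
        sel = np.flatnonzero(bins == b)
        out[sel] = out[sel][rng.permutation(len(sel))]
    return out


def threshold_grid(low: ScoreMatrix, high: ScoreMatrix,
                   pairing: MarkerPairing,
                   q_grid_low: "list[float]", q_grid_high: "list[float]",
                   n_shuffles: int = 10, seed: int | None = 0,
                   dedup_window_bp: int = DEDUP_WINDOW_BP,
                   n_bins: int = 10) -> ThresholdGrid:
    """Observed vs shuffled fraction of common eQTL over a threshold grid.

    For the null, within each score-decile bin of the selected eQTL the
    scores are re-assigned to different target genes (gene labels permuted
    independently in each dataset), and the common-eQTL fraction is
    recomputed; the grid stores the mean and sd over ``n_shuffles``
    randomizations.
    """
    q_grid_low = list(q_grid_low)
    q_grid_high = list(q_grid_high)
    if min(q_grid_low + q_grid_high) < 0.99:
        raise ValueError("threshold grids start at the 99% quantile")
    rng = np.random.default_rng(seed)
    genes = _shared_genes(low, high)
    lrows = np.array([low.gene_index(g) for g in genes], dtype=np.intp)
    hrows = np.array([high.gene_index(g) for g in genes], dtype=np.intp)
    lcols = low.marker_indices(pairing.low_ids)
    L = low.scores[np.ix_(lrows, lcols)]
    H = _matched_max(high, pairing, hrows)
    chrom_arr = np.asarray(pairing.chrom, dtype=object)
    pos_arr = pairing.pos_bp
    thr_l = {q: quantile_threshold(low, q) for q in q_grid_low}
    thr_h = {q: quantile_threshold(high, q) for q in q_grid_high}

    shape = (len(q_grid_low), len(q_grid_high))
    f_obs = np.full(shape, np.nan)
    f_mean = np.full(shape, np.nan)
    f_sd = np.full(shape, np.nan)
    n_c = np.zeros(shape, dtype=int)
    n_l = np.zeros(shape, dtype=int)
    n_h = np.zeros(shape, dtype=int)

    def dedup_count_pairs(gi: np.ndarray, mj: np.ndarray,
                          scores: np.ndarray) -> int:
        total = 0
        df_order = np.argsort(gi, kind="stable")
        gi, mj, scores = gi[df_order], mj[df_order], scores[df_order]
        bounds = np.flatnonzero(np.r_[True, gi[1:] != gi[:-1], True])
        for a, b in zip(bounds[:-1], bounds[1:]):
            kept = _dedup_keep(chrom_arr[mj[a:b]], pos_arr[mj[a:b]],
                               scores[a:b], dedup_window_bp)
            total += len(kept)
        return total

    for i, ql in enumerate(q_grid_low):
        low_hit = L >= thr_l[ql]
        gl, ml = np.nonzero(low_hit)
        for j, qh in enumerate(q_grid_high):
            high_hit = H >= thr_h[qh]
            gh, mh = np.nonzero(high_hit)
            if len(gl) == 0 and len(gh) == 0:
                continue
            common = low_hit & high_hit
            gc, mc = np.nonzero(common)
            nc = dedup_count_pairs(gc, mc, L[gc, mc])
            nl = dedup_count_pairs(gl, ml, L[gl, ml])
            nh = dedup_count_pairs(gh, mh, H[gh, mh])
            n_c[i, j], n_l[i, j], n_h[i, j] = nc, nl, nh
            f_obs[i, j] = fraction_common(nc, nl, nh)
            if n_shuffles <= 0:
                continue
            null_fs = []
            for _ in range(n_shuffles):
                gl_s = _shuffle_hits(gl, L[gl, ml], n_bins, rng)
                gh_s = _shuffle_hits(gh, H[gh, mh], n_bins, rng)
                set_low = {}
                for g, m, sc in zip(gl_s, ml, L[gl, ml]):
                    set_low[(g, m)] = sc
                rows_g, rows_m, rows_s = [], [], []
                for g, m in zip(gh_s, mh):
                    if (g, m) in set_low:
                        rows_g.append(g)
                        rows_m.append(m)
                        rows_s.append(set_low[(g, m)])
                if rows_g:
                    nc_s = dedup_count_pairs(np.asarray(rows_g),
                                             np.asarray(rows_m),
                                             np.asarray(rows_s))
                else:
                    nc_s = 0
                null_fs.append(fraction_common(nc_s, nl, nh))
            null_fs = np.asarray(null_fs, dtype=float)
            f_mean[i, j] = np.nanmean(null_fs)
            f_sd[i, j] = np.nanstd(null_fs, ddof=1) if n_shuffles > 1 else 0.0
    return ThresholdGrid(np.asarray(q_grid_low), np.asarray(q_grid_high),
                         f_obs, f_mean, f_sd, n_c, n_l, n_h, n_shuffles)
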
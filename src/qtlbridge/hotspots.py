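"""Trans-band hotspot detection on the common-eQTL frequency (CEF) profile.

Common eQTL are classified as *local* (marker within a window of the target
gene, default 5 Mb; inclusive boundary) or *distant*. Distant common eQTL
are binned along the genome (2 Mb bins tiled per chromosome) and the bin
counts are compared against two randomization schemes:

* *marker shuffle*: every common eQTL is re-assigned to a uniformly random
  marker of the low-resolution map, giving a genome-wide null for the
  maximum bin count and hence global significance thresholds;
* *probeset shuffle*: at each locus the gene labels of one dataset's
  selected eQTL are permuted and the common-eQTL set recomputed, which
  controls for loci that carry many eQTL in both datasets purely by chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consistency import (CommonEqtlSet, MarkerPairing, _dedup_keep,
                          _matched_max, _shared_genes, quantile_threshold)
from .model import GeneAnnotation, GenomeDescription, MarkerMap, ScoreMatrix

__all__ = [
    "EqtlClassification", "HotspotProfile", "classify_eqtl",
    "classify_common_set", "cef_profile", "hotspot_null_marker_shuffle",
    "hotspot_null_probeset_shuffle",
]

LOCAL_WINDOW_BP = 5_000_000
FOCUSED_LOCAL_WINDOW_BP = 500_000
BIN_BP = 2_000_000


def classify_eqtl(gene: pd.Series, marker_chrom: str, marker_pos: int,
                  window_bp: int = LOCAL_WINDOW_BP) -> str:
    """Classify one eQTL as ``local`` or ``distant``.

    Local iff the marker is on the gene's chromosome and the distance from
    the marker to the nearest gene edge (0 if inside) is at most
    ``window_bp`` (inclusive boundary).
    """
    if marker_chrom != gene["chrom"]:
        return "distant"
    if gene["start_bp"] <= marker_pos <= gene["end_bp"]:
        return "local"
    d = min(abs(marker_pos - gene["start_bp"]), abs(marker_pos - gene["end_bp"]))
    return "local" if d <= window_bp else "distant"


@dataclass
class EqtlClassification:
    """Common-eQTL records with a local/distant ``kind`` column."""

    records: pd.DataFrame
    local_window_bp: int

    @property
    def distant(self) -> pd.DataFrame:
        return self.records[self.records["kind"] == "distant"]

    @property
    def local(self) -> pd.DataFrame:
        return self.records[self.records["kind"] == "local"]


def classify_common_set(common: CommonEqtlSet, genes: GeneAnnotation,
                        window_bp: int = LOCAL_WINDOW_BP) -> EqtlClassification:
    records = common.records.copy()
    kinds = []
    for rec in records.itertuples(index=False):
        if rec.gene_id not in genes:
            raise KeyError(f"gene {rec.gene_id!r} missing from annotation")
        kinds.append(classify_eqtl(genes.loc(rec.gene_id), rec.chrom,
                                   rec.pos_bp, window_bp))
    records["kind"] = kinds
    return EqtlClassification(records, window_bp)


def _bin_table(genome: GenomeDescription, bin_bp: int) -> pd.DataFrame:
    """Per-chromosome tiling [k*bin+1, (k+1)*bin]; the last bin of each
    chromosome may be short. No bin spans a chromosome junction."""
    rows = []
    for chrom in genome.chroms:
        L = genome.lengths[chrom]
        n_bins = int(np.ceil(L / bin_bp))
        for k in range(n_bins):
            rows.append((chrom, k * bin_bp + 1, min((k + 1) * bin_bp, L)))
    return pd.DataFrame(rows, columns=["chrom", "bin_start", "bin_end"])


def _bin_counts(bins: pd.DataFrame, chroms: np.ndarray, pos: np.ndarray,
                bin_bp: int, genome: GenomeDescription) -> np.ndarray:
    offsets = {}
    k = 0
    for chrom in genome.chroms:
        offsets[chrom] = k
        k += int(np.ceil(genome.lengths[chrom] / bin_bp))
    counts = np.zeros(len(bins), dtype=int)
    for c, p in zip(chroms, pos):
        if c not in offsets:
            raise KeyError(f"marker on unknown chromosome {c!r}")
        if p > genome.lengths[c] or p < 1:
            raise ValueError(f"marker position {p} outside {c}")
        counts[offsets[c] + (int(p) - 1) // bin_bp] += 1
    return counts


@dataclass
class HotspotProfile:
    """Observed CEF per genomic bin, with optional null columns."""

    bins: pd.DataFrame          # chrom, bin_start, bin_end, cef_obs [,nulls]
    bin_bp: int
    n_eqtl: int
    alpha_thresholds: dict[float, float] | None = None

    def display(self, min_count: int = 5) -> pd.DataFrame:
        """Presentation filter: bins holding at least ``min_count`` common
        eQTL. Nulls and thresholds are computed on all bins regardless."""
        return self.bins[self.bins["cef_obs"] >= min_count]


def cef_profile(common: CommonEqtlSet | EqtlClassification,
                genes: GeneAnnotation, genome: GenomeDescription,
                bin_bp: int = BIN_BP, distant_only: bool = True,
                local_window_bp: int = LOCAL_WINDOW_BP) -> HotspotProfile:
    """Common-eQTL frequency per genomic bin (by marker position)."""
    if isinstance(common, CommonEqtlSet):
        classified = classify_common_set(common, genes, local_window_bp)
    else:
        classified = common
    records = classified.distant if distant_only else classified.records
    bins = _bin_table(genome, bin_bp)
    counts = _bin_counts(bins, records["chrom"].to_numpy(),
                         records["pos_bp"].to_numpy(), bin_bp, genome)
    bins = bins.copy()
    bins["cef_obs"] = counts
    return HotspotProfile(bins, bin_bp, len(records))


def hotspot_null_marker_shuffle(profile: HotspotProfile, low_map: MarkerMap,
                                genome: GenomeDescription, n_perm: int = 100,
                                alphas: "tuple[float, ...]" = (0.05, 0.01),
                                seed: int | None = 0) -> HotspotProfile:
    """Global significance thresholds from shuffled marker positions.

    Each permutation re-assigns every common eQTL to a marker drawn
    uniformly (with replacement) from the low-resolution map and records
    the genome-wide maximum bin count; the alpha-level threshold is the
    (1 - alpha) quantile of those maxima.
    """
    rng = np.random.default_rng(seed)
    mdf = low_map.df
    mchrom = mdf["chrom"].to_numpy()
    mpos = mdf["pos_bp"].to_numpy()
    bins = _bin_table(genome, profile.bin_bp)
    maxima = np.empty(n_perm, dtype=int)
    for t in range(n_perm):
        draw = rng.integers(len(mdf), size=profile.n_eqtl)
        counts = _bin_counts(bins, mchrom[draw], mpos[draw], profile.bin_bp,
                             genome)
        maxima[t] = counts.max() if len(counts) else 0
    thresholds = {a: float(np.quantile(maxima, 1 - a, method="higher"))
                  for a in alphas}
    out = profile.bins.copy()
    for a in alphas:
        out[f"exceeds_alpha_{a:g}"] = out["cef_obs"] > thresholds[a]
    return HotspotProfile(out, profile.bin_bp, profile.n_eqtl, thresholds)


def hotspot_null_probeset_shuffle(low: ScoreMatrix, high: ScoreMatrix,
                                  pairing: MarkerPairing,
                                  genes: GeneAnnotation,
                                  genome: GenomeDescription,
                                  q_low: float, q_high: float,
                                  bin_bp: int = BIN_BP,
                                  local_window_bp: int = LOCAL_WINDOW_BP,
                                  distant_only: bool = True,
                                  n_perm: int = 10,
                                  dedup_window_bp: int = 5_000_000,
                                  seed: int | None = 0) -> pd.DataFrame:
    """Per-bin null mean/sd of the CEF after shuffling probeset assignments.

    Each permutation permutes, independently at every locus (paired low
    marker), the gene labels of the low-resolution dataset's cells -- i.e.
    the high-resolution eQTL are compared against random probesets -- and
    the common-eQTL set is recomputed, classified and re-binned.
    """
    rng = np.random.default_rng(seed)
    thr_low = quantile_threshold(low, q_low)
    thr_high = quantile_threshold(high, q_high)
    shared = _shared_genes(low, high)
    lrows = np.array([low.gene_index(g) for g in shared], dtype=np.intp)
    hrows = np.array([high.gene_index(g) for g in shared], dtype=np.intp)
    lcols = low.marker_indices(pairing.low_ids)
    L = low.scores[np.ix_(lrows, lcols)]
    H = _matched_max(high, pairing, hrows)
    low_hit = L >= thr_low
    high_hit = H >= thr_high
    chrom_arr = np.asarray(pairing.chrom, dtype=object)
    pos_arr = pairing.pos_bp
    bins = _bin_table(genome, bin_bp)
    gene_rows = {g: genes.loc(g) for g in shared}

    n_genes = len(shared)
    null_counts = np.zeros((n_perm, len(bins)), dtype=float)
    for t in range(n_perm):
        perm_hit = np.empty_like(low_hit)
        perm_L = np.empty_like(L)
        for j in range(low_hit.shape[1]):
            p = rng.permutation(n_genes)
            perm_hit[:, j] = low_hit[p, j]
            perm_L[:, j] = L[p, j]
        common = perm_hit & high_hit
        rec_chrom, rec_pos = [], []
        for i in np.flatnonzero(common.any(axis=1)):
            js = np.flatnonzero(common[i])
            kept = _dedup_keep(chrom_arr[js], pos_arr[js], perm_L[i, js],
                               dedup_window_bp)
            for j in js[kept]:
                if distant_only:
                    kind = classify_eqtl(gene_rows[shared[i]], chrom_arr[j],
                                         int(pos_arr[j]), local_window_bp)
                    if kind == "local":
                        continue
                rec_chrom.append(chrom_arr[j])
                rec_pos.append(int(pos_arr[j]))
        null_counts[t] = _bin_counts(bins, np.asarray(rec_chrom, dtype=object),
                                     np.asarray(rec_pos, dtype=np.int64),
                                     bin_bp, genome)
    out = bins.copy()
    out["null_mean"] = null_counts.mean(axis=0)
    out["null_sd"] = null_counts.std(axis=0, ddof=1) if n_perm > 1 else 0.0
    return out
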
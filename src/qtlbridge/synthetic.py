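"""Synthetic paired low-/high-resolution eQTL datasets with known truth.

The generator emulates the structure of a two-population eQTL study:

* a *high-resolution* panel (dense informative markers, localized signals),
  standing in for an association study on a diversity panel, and
* a *low-resolution* panel whose informative markers are one representative
  per linkage block, so that signals are smeared over whole blocks --
  standing in for a recombinant-inbred panel where adjacent markers carry
  the same inheritance information.

Planted architecture: a set of cis-eQTL (causal gene == target gene), plus
trans-regulators each controlling a batch of distant target genes (a planted
hotspot). Each planted eQTL replicates in the high-resolution data with a
configurable probability ``replication_prob``; regulators are co-assigned to
one pathway with their targets, which is the ground truth the fine-mapping
evaluation measures against.

All outputs are deterministic functions of (config, seed): every stage
derives its own RNG stream from the master seed so stages can be re-run
independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .model import (GeneAnnotation, GeneSetCollection, GenomeDescription,
                    MarkerMap, ScoreMatrix, TissueExpressionMatrix)

__all__ = [
    "SyntheticConfig", "SyntheticTruth", "SyntheticDataset",
    "generate_maps", "generate_genes", "plant_architecture",
    "simulate_scores", "simulate_tissue_matrix", "simulate_dataset",
]

# stage tags for per-stage RNG streams derived from the master seed
_STAGE_MAPS, _STAGE_GENES, _STAGE_PLANT, _STAGE_SCORES, _STAGE_TISSUE = range(5)


class ConfigError(ValueError):
    """Invalid synthetic-data configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Tunable parameters of the synthetic study.

    Defaults describe a scaled-down mouse-like design: 5 chromosomes of
    50 Mb, 1,000 dense markers per chromosome (one per 50 kb), 2.5 Mb
    linkage blocks (20 informative low-resolution markers per chromosome),
    1,000 genes with log-normal lengths (median 50 kb), 100 cis-eQTL and
    10 trans-regulators with 20 targets each.
    """

    n_chrom: int = 5
    chrom_length_bp: int = 50_000_000
    n_markers_high: int = 1_000          # per chromosome
    block_length_bp: int = 2_500_000     # low-resolution linkage block
    n_genes: int = 1_000
    gene_length_median_bp: int = 50_000
    gene_length_sd_log: float = 0.6
    gene_length_min_bp: int = 5_000
    gene_length_max_bp: int = 300_000
    n_pathways: int = 50
    pathway_size: tuple[int, int] = (5, 30)
    n_cis: int = 100
    n_regulators: int = 10
    targets_per_regulator: int = 20
    replication_prob: float = 0.5
    signal_strength: float = 20.0
    noise_rate: float = 1.0              # Exponential rate of background scores
    decay: float = 0.5                   # geometric decay per marker outside gene
    cm_per_mb: float = 1.0
    cm_map: str = "constant"             # "constant" or "piecewise"
    n_tissues: int = 78
    n_cns: int = 11
    cns_effect: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_chrom, self.chrom_length_bp, self.n_markers_high,
               self.block_length_bp, self.n_genes, self.n_pathways) <= 0:
            raise ConfigError("all counts must be positive")
        if self.n_markers_high < 2:
            raise ConfigError("need at least 2 markers per chromosome")
        if self.block_length_bp > self.chrom_length_bp:
            raise ConfigError("block_length_bp exceeds chromosome length")
        if not 0.0 <= self.replication_prob <= 1.0:
            raise ConfigError("replication_prob must be in [0, 1]")
        if self.signal_strength < 0 or self.noise_rate <= 0:
            raise ConfigError("signal_strength must be >= 0, noise_rate > 0")
        need = self.n_cis + self.n_regulators * (1 + self.targets_per_regulator)
        if need > self.n_genes:
            raise ConfigError(
                f"need {need} genes for the requested architecture, "
                f"have {self.n_genes}")
        if self.n_cns >= self.n_tissues:
            raise ConfigError("n_cns must be smaller than n_tissues")
        if self.cm_map not in ("constant", "piecewise"):
            raise ConfigError("cm_map must be 'constant' or 'piecewise'")
        if not 0.0 <= self.decay <= 1.0:
            raise ConfigError("decay must be in [0, 1]")

    def with_(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)


@dataclass
class SyntheticTruth:
    """Planted ground truth.

    ``plants`` has one row per planted eQTL with columns ``causal_gene``,
    ``target_gene``, ``kind`` (cis/trans), ``replicated_in_high``,
    ``pathway`` and ``low_marker`` (the informative marker of the linkage
    block containing the causal gene -- where the low-resolution signal
    sits).
    """

    plants: pd.DataFrame
    pathways: GeneSetCollection
    hotspot_markers: dict[str, str]      # regulator gene -> low marker id
    cns_specific: frozenset[str]
    gene_ids: tuple[str, ...]

    def regulators(self) -> list[str]:
        return sorted(self.hotspot_markers)


@dataclass
class SyntheticDataset:
    """Everything one simulated study produces."""

    config: SyntheticConfig
    genome: GenomeDescription
    high_map: MarkerMap
    low_map: MarkerMap
    genes: GeneAnnotation
    truth: SyntheticTruth
    low_scores: ScoreMatrix
    high_scores: ScoreMatrix
    tissue: TissueExpressionMatrix


def _rng(cfg: SyntheticConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(
        entropy=cfg.seed, spawn_key=(stage,)))


def _chrom_names(cfg: SyntheticConfig) -> list[str]:
    return [f"chr{i + 1}" for i in range(cfg.n_chrom)]


def _assign_cm(cfg: SyntheticConfig, pos: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
    if cfg.cm_map == "constant":
        return pos * (cfg.cm_per_mb / 1e6)
    # piecewise-linear map: 4 segments with rates drawn around cm_per_mb,
    # used to exercise the interpolation code on non-trivial maps
    n_seg = 4
    bounds = np.linspace(0, cfg.chrom_length_bp, n_seg + 1)
    rates = rng.uniform(0.3, 3.0, size=n_seg) * cfg.cm_per_mb / 1e6
    knot_cm = np.concatenate([[0.0], np.cumsum(np.diff(bounds) * rates)])
    return np.interp(pos, bounds, knot_cm)


def generate_maps(cfg: SyntheticConfig) -> tuple[MarkerMap, MarkerMap,
                                                 GenomeDescription]:
    """Create the dense high-resolution map and its low-resolution subset.

    High markers are evenly spaced along each chromosome. The low map keeps
    exactly one informative marker per linkage block of ``block_length_bp``
    -- the block's representative, taken as the high marker nearest the
    block centre so that nearest-marker assignment boundaries coincide with
    block boundaries -- making the low map a subset of the high map.
    """
    cfg.validate()
    rng = _rng(cfg, _STAGE_MAPS)
    L, n = cfg.chrom_length_bp, cfg.n_markers_high
    genome = GenomeDescription.from_pairs(
        [(c, L) for c in _chrom_names(cfg)])
    high_rows, low_rows = [], []
    for chrom in genome.chroms:
        pos = np.round(np.arange(1, n + 1) * L / (n + 1)).astype(np.int64)
        pos = np.maximum(pos, 1)
        cm = _assign_cm(cfg, pos, rng)
        ids = [f"m_{chrom}_{i:05d}" for i in range(n)]
        for mid, p, c in zip(ids, pos, cm):
            high_rows.append((mid, chrom, int(p), float(c)))
        block = (pos - 1) // cfg.block_length_bp
        for b in np.unique(block):
            idx = np.flatnonzero(block == b)
            center = (b + 0.5) * cfg.block_length_bp
            i = idx[int(np.argmin(np.abs(pos[idx] - center)))]
            low_rows.append((ids[i], chrom, int(pos[i]), float(cm[i])))
    return (MarkerMap.from_records(high_rows),
            MarkerMap.from_records(low_rows), genome)


def generate_genes(cfg: SyntheticConfig,
                   genome: GenomeDescription) -> GeneAnnotation:
    """Place non-overlapping genes with log-normal lengths.

    Genes are laid out along each chromosome with random gaps (lengths drawn
    log-normal, gaps uniform over the remaining free space), so every gene
    occupies a unique locus -- matching the one-probeset-per-location
    convention of the downstream analyses.
    """
    rng = _rng(cfg, _STAGE_GENES)
    per_chrom = np.full(len(genome.chroms), cfg.n_genes // len(genome.chroms))
    per_chrom[: cfg.n_genes % len(genome.chroms)] += 1
    rows = []
    k = 0
    for chrom, n_c in zip(genome.chroms, per_chrom):
        L = genome.lengths[chrom]
        lengths = np.clip(
            rng.lognormal(np.log(cfg.gene_length_median_bp),
                          cfg.gene_length_sd_log, size=n_c),
            cfg.gene_length_min_bp, cfg.gene_length_max_bp).astype(np.int64)
        free = L - 1 - int(lengths.sum())
        if free <= n_c:
            raise ConfigError(
                f"{chrom}: requested genes do not fit without overlap")
        gaps = rng.random(n_c + 1)
        gaps = np.floor(gaps / gaps.sum() * free).astype(np.int64)
        strands = rng.choice(["+", "-"], size=n_c)
        pos = 1
        for i in range(n_c):
            start = pos + int(gaps[i])
            rows.append((f"g{k:05d}", chrom, start,
                         start + int(lengths[i]), strands[i]))
            pos = start + int(lengths[i]) + 1
            k += 1
    return GeneAnnotation.from_records(rows)


def _low_marker_lookup(low_map: MarkerMap, block_bp: int) -> dict:
    """(chrom, block index) -> low marker id; plus per-chrom arrays for
    nearest-marker fallback."""
    table = {}
    for _, row in low_map.df.iterrows():
        b = (int(row["pos_bp"]) - 1) // block_bp
        table[(row["chrom"], b)] = row["marker_id"]
    return table


def low_marker_for(low_map: MarkerMap, block_bp: int, chrom: str,
                   pos: int) -> str:
    """The informative low-resolution marker of the block containing *pos*;
    falls back to the nearest low marker on the chromosome if the block has
    none."""
    b = (int(pos) - 1) // block_bp
    table = _low_marker_lookup(low_map, block_bp)
    if (chrom, b) in table:
        return table[(chrom, b)]
    sub = low_map.markers_on(chrom)
    if sub.empty:
        raise KeyError(f"no low-resolution markers on {chrom}")
    i = (sub["pos_bp"] - pos).abs().idxmin()
    return sub.loc[i, "marker_id"]


def plant_architecture(cfg: SyntheticConfig,
                       maps: tuple[MarkerMap, MarkerMap],
                       genes: GeneAnnotation) -> SyntheticTruth:
    """Choose cis genes, trans-regulators with distant targets, replication
    flags and pathway co-memberships."""
    cfg.validate()
    high_map, low_map = maps
    rng = _rng(cfg, _STAGE_PLANT)
    gene_df = genes.df
    gene_ids = gene_df["gene_id"].to_numpy()
    n = len(gene_ids)
    if cfg.n_cis + cfg.n_regulators * (1 + cfg.targets_per_regulator) > n:
        raise ConfigError("not enough genes for requested architecture")

    perm = rng.permutation(n)
    cis_idx = perm[: cfg.n_cis]
    reg_idx = perm[cfg.n_cis: cfg.n_cis + cfg.n_regulators]
    pool = list(perm[cfg.n_cis + cfg.n_regulators:])

    chrom_of = dict(zip(gene_df["gene_id"], gene_df["chrom"]))
    mid_of = dict(zip(gene_df["gene_id"],
                      0.5 * (gene_df["start_bp"] + gene_df["end_bp"])))

    block_table = _low_marker_lookup(low_map, cfg.block_length_bp)

    def marker_for(gid: str) -> str:
        chrom = chrom_of[gid]
        b = int(mid_of[gid] - 1) // cfg.block_length_bp
        if (chrom, b) in block_table:
            return block_table[(chrom, b)]
        sub = low_map.markers_on(chrom)
        i = (sub["pos_bp"] - mid_of[gid]).abs().idxmin()
        return sub.loc[i, "marker_id"]

    rows = []
    for i in cis_idx:
        g = gene_ids[i]
        rows.append((g, g, "cis", marker_for(g)))

    hotspot_markers: dict[str, str] = {}
    pathway_sets: dict[str, set[str]] = {}
    for j, i in enumerate(reg_idx):
        reg = gene_ids[i]
        hotspot_markers[reg] = marker_for(reg)
        # distant targets: drawn from other chromosomes so every
        # regulator-target pair is unambiguously trans
        eligible = [k for k in pool if chrom_of[gene_ids[k]] != chrom_of[reg]]
        if len(eligible) < cfg.targets_per_regulator:
            raise ConfigError("not enough genes on other chromosomes for "
                              f"regulator {reg}")
        pick = rng.choice(len(eligible), size=cfg.targets_per_regulator,
                          replace=False)
        chosen = [eligible[p] for p in pick]
        pool = [k for k in pool if k not in set(chosen)]
        members = {reg}
        for k in chosen:
            tg = gene_ids[k]
            rows.append((reg, tg, "trans", marker_for(reg)))
            members.add(tg)
        pathway_sets[f"pw_reg{j:03d}"] = members

    plants = pd.DataFrame(rows, columns=["causal_gene", "target_gene", "kind",
                                         "low_marker"])
    plants["replicated_in_high"] = rng.random(len(plants)) < cfg.replication_prob

    # attach the co-membership pathway of each trans plant; cis plants carry
    # no planted pathway (the gene may still land in a random-filled one)
    pw_of_reg = {next(iter(m & set(hotspot_markers))): sid
                 for sid, m in pathway_sets.items()}
    plants["pathway"] = [
        pw_of_reg.get(c, "") if k == "trans" else ""
        for c, k in zip(plants["causal_gene"], plants["kind"])]

    lo, hi = cfg.pathway_size
    for j in range(len(pathway_sets), cfg.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(gene_ids, size=min(size, n), replace=False)
        pathway_sets[f"pw_rand{j:03d}"] = set(members)

    truth = SyntheticTruth(
        plants=plants,
        pathways=GeneSetCollection(pathway_sets),
        hotspot_markers=hotspot_markers,
        cns_specific=frozenset(gene_ids[i] for i in cis_idx),
        gene_ids=tuple(gene_ids),
    )
    return truth


def simulate_scores(cfg: SyntheticConfig, truth: SyntheticTruth,
                    maps: tuple[MarkerMap, MarkerMap],
                    genes: GeneAnnotation) -> tuple[ScoreMatrix, ScoreMatrix]:
    """Draw background noise and superimpose the planted signals.

    Background scores are i.i.d. Exponential with rate ``noise_rate``
    (mean 1/rate), mimicking the tail behaviour of -log10 p under the null.
    Each planted eQTL adds ``signal_strength`` in the low matrix at the
    single informative marker of the causal gene's block; in the high
    matrix (only if replicated) at all markers inside the causal gene's
    transcribed region, decaying geometrically for markers up to one block
    away. Returns (low, high).
    """
    cfg.validate()
    high_map, low_map = maps
    rng = _rng(cfg, _STAGE_SCORES)
    gene_ids = list(truth.gene_ids)
    g_index = {g: i for i, g in enumerate(gene_ids)}

    low_ids = list(low_map.ids())
    high_ids = list(high_map.ids())
    low_col = {m: j for j, m in enumerate(low_ids)}

    scale = 1.0 / cfg.noise_rate
    low = rng.exponential(scale, size=(len(gene_ids), len(low_ids)))
    high = rng.exponential(scale, size=(len(gene_ids), len(high_ids)))

    # per-chromosome high-marker arrays for fast window lookups
    hdf = high_map.df
    by_chrom = {c: (sub["pos_bp"].to_numpy(),
                    sub.index.to_numpy())
                for c, sub in hdf.groupby("chrom", sort=False)}

    s = cfg.signal_strength
    for row in truth.plants.itertuples(index=False):
        ti = g_index[row.target_gene]
        low[ti, low_col[row.low_marker]] += s
        if not row.replicated_in_high:
            continue
        grow = genes.loc(row.causal_gene)
        chrom = grow["chrom"]
        pos, cols = by_chrom[chrom]
        inside = np.flatnonzero((pos >= grow["start_bp"]) &
                                (pos <= grow["end_bp"]))
        if len(inside):
            left, right = inside[0], inside[-1]
            high[ti, cols[inside]] += s
        else:
            mid = 0.5 * (grow["start_bp"] + grow["end_bp"])
            nearest = int(np.argmin(np.abs(pos - mid)))
            block = int(mid - 1) // cfg.block_length_bp
            if (pos[nearest] - 1) // cfg.block_length_bp != block:
                warnings.warn(
                    f"no high-resolution marker within the block of "
                    f"{row.causal_gene}; signal placed at nearest marker")
            left = right = nearest
            high[ti, cols[nearest]] += s
        if cfg.decay > 0:
            reach = grow["end_bp"] + cfg.block_length_bp
            low_reach = grow["start_bp"] - cfg.block_length_bp
            k = 1
            i, j = left - 1, right + 1
            while (i >= 0 and pos[i] >= low_reach) or \
                  (j < len(pos) and pos[j] <= reach):
                bump = s * cfg.decay ** k
                if i >= 0 and pos[i] >= low_reach:
                    high[ti, cols[i]] += bump
                    i -= 1
                if j < len(pos) and pos[j] <= reach:
                    high[ti, cols[j]] += bump
                    j += 1
                k += 1
    return (ScoreMatrix(gene_ids, low_ids, low),
            ScoreMatrix(gene_ids, high_ids, high))


def simulate_tissue_matrix(cfg: SyntheticConfig,
                           truth: SyntheticTruth) -> TissueExpressionMatrix:
    """Standard-normal expression over tissues; CNS-specific genes (here:
    the planted cis genes) get their CNS tissue means shifted by
    ``cns_effect``."""
    cfg.validate()
    rng = _rng(cfg, _STAGE_TISSUE)
    gene_ids = list(truth.gene_ids)
    n_t, n_c = cfg.n_tissues, cfg.n_cns
    tissue_ids = ([f"cns_{i + 1:02d}" for i in range(n_c)] +
                  [f"t_{i + 1:02d}" for i in range(n_t - n_c)])
    expr = rng.normal(0.0, 1.0, size=(len(gene_ids), n_t))
    cns_rows = [i for i, g in enumerate(gene_ids) if g in truth.cns_specific]
    expr[np.ix_(cns_rows, range(n_c))] += cfg.cns_effect
    return TissueExpressionMatrix(gene_ids, tissue_ids, expr,
                                  tissue_ids[:n_c])


def simulate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Run all generator stages in dependency order."""
    high_map, low_map, genome = generate_maps(cfg)
    genes = generate_genes(cfg, genome)
    truth = plant_architecture(cfg, (high_map, low_map), genes)
    low, high = simulate_scores(cfg, truth, (high_map, low_map), genes)
    tissue = simulate_tissue_matrix(cfg, truth)
    return SyntheticDataset(cfg, genome, high_map, low_map, genes, truth,
                            low, high, tissue)
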
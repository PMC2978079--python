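import warnings

import numpy as np
import pytest

import qtlbridge as qb

# the generator warns when a causal gene's block carries no dense marker;
# irrelevant for most tests, which assert on planted structure directly
warnings.filterwarnings("ignore", message="no high-resolution marker")


@pytest.fixture(scope="session")
def small_cfg() -> qb.SyntheticConfig:
    """Compact two-chromosome study used by several module tests."""
    return qb.SyntheticConfig(n_chrom=2, chrom_length_bp=20_000_000,
                              n_markers_high=400, block_length_bp=2_000_000,
                              n_genes=200, n_cis=20, n_regulators=2,
                              targets_per_regulator=10, n_pathways=10,
                              replication_prob=1.0, signal_strength=20.0,
                              seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_cfg) -> qb.SyntheticDataset:
    return qb.simulate_dataset(small_cfg)


@pytest.fixture(scope="session")
def noise_dataset() -> qb.SyntheticDataset:
    """Pure-noise study (no planted signal) for calibration checks."""
    cfg = qb.SyntheticConfig(n_chrom=2, chrom_length_bp=40_000_000,
                             n_markers_high=800, block_length_bp=200_000,
                             n_genes=600, n_cis=1, n_regulators=1,
                             targets_per_regulator=1, n_pathways=5,
                             signal_strength=0.0, seed=7)
    return qb.simulate_dataset(cfg)


def brute_force_common(low, high, pairing, q_low, q_high,
                       window=5_000_000):
    """Independent oracle: exhaustive double loop over genes and paired
    markers with greedy strongest-first deduplication."""
    thr_l = np.quantile(low.scores, q_low)
    thr_h = np.quantile(high.scores, q_high)
    genes = sorted(set(low.gene_ids) & set(high.gene_ids))
    recs = []
    for g in genes:
        cand = []
        for j, lid in enumerate(pairing.low_ids):
            ls = low.scores[low.gene_index(g), low.marker_index(lid)]
            hs = max(high.scores[high.gene_index(g), high.marker_index(h)]
                     for h in pairing.matched[j])
            if ls >= thr_l and hs >= thr_h:
                cand.append((pairing.chrom[j], int(pairing.pos_bp[j]),
                             ls, hs, lid))
        cand.sort(key=lambda r: (-r[2], r[1]))
        kept = []
        for r in cand:
            if all(not (r[0] == k[0] and abs(r[1] - k[1]) <= window)
                   for k in kept):
                kept.append(r)
        recs += [(g, r[4]) for r in kept]
    return sorted(recs)
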
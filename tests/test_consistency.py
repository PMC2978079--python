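"""Marker pairing, common-eQTL calling, match p-values and threshold grid."""

import numpy as np
import pytest

import qtlbridge as qb
from conftest import brute_force_common


class TestQuantileThreshold:
    def test_linear_interpolation_quantile(self):
        m = qb.ScoreMatrix([f"g{i}" for i in range(10)],
                           [f"m{j}" for j in range(10)],
                           np.arange(1.0, 101.0).reshape(10, 10))
        thr = qb.quantile_threshold(m, 0.99)
        assert thr == pytest.approx(99.01)
        assert (m.scores >= thr).sum() == 1      # only the 100 survives

    def test_constant_matrix_selects_everything(self):
        m = qb.ScoreMatrix(["g"], ["m1", "m2"], [[3.0, 3.0]])
        thr = qb.quantile_threshold(m, 0.87)
        assert thr == 3.0 and (m.scores >= thr).all()

    def test_median_of_two(self):
        m = qb.ScoreMatrix(["g"], ["m1", "m2"], [[0.0, 10.0]])
        assert qb.quantile_threshold(m, 0.5) == 5.0

    def test_quantile_bounds(self):
        m = qb.ScoreMatrix(["g"], ["m"], [[1.0]])
        for q in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                qb.quantile_threshold(m, q)


class TestPairMarkers:
    def test_exact_within_tolerance(self):
        low = qb.MarkerMap.from_records([("L", "chr1", 1000, None)])
        high = qb.MarkerMap.from_records([("H", "chr1", 1003, None)])
        p = qb.pair_markers(low, high, "exact", tol_bp=5)
        assert p.low_ids == ["L"] and p.matched == [["H"]]
        p2 = qb.pair_markers(low, high, "exact", tol_bp=2)
        assert len(p2) == 0

    def test_interval_nearest_assignment(self):
        low = qb.MarkerMap.from_records([
            ("L0", "chr1", 1, None), ("L10", "chr1", 10_000_000, None)])
        high = qb.MarkerMap.from_records([
            ("H1", "chr1", 1_000_000, None), ("H2", "chr1", 2_000_000, None),
            ("H9", "chr1", 9_000_000, None)])
        p = qb.pair_markers(low, high, "interval")
        groups = dict(zip(p.low_ids, p.matched))
        assert groups == {"L0": ["H1", "H2"], "L10": ["H9"]}

    def test_interval_tie_goes_to_lower_coordinate(self):
        low = qb.MarkerMap.from_records([
            ("La", "chr1", 1000, None), ("Lb", "chr1", 3000, None)])
        high = qb.MarkerMap.from_records([("H", "chr1", 2000, None)])
        p = qb.pair_markers(low, high, "interval")
        assert dict(zip(p.low_ids, p.matched)) == {"La": ["H"]}

    def test_no_shared_chromosomes(self):
        low = qb.MarkerMap.from_records([("L", "chr1", 1, None)])
        high = qb.MarkerMap.from_records([("H", "chr2", 1, None)])
        with pytest.raises(ValueError, match="chromosome"):
            qb.pair_markers(low, high, "interval")


def _two_sided_fixture():
    """One gene, one low marker matched to two high markers."""
    low = qb.MarkerMap.from_records([("L", "chr1", 1_000_000, None)])
    high = qb.MarkerMap.from_records([
        ("Ha", "chr1", 900_000, None), ("Hb", "chr1", 1_100_000, None)])
    lsm = qb.ScoreMatrix(["g"], ["L"], [[10.0]])
    hsm = qb.ScoreMatrix(["g"], ["Ha", "Hb"], [[1.0, 9.0]])
    pairing = qb.pair_markers(low, high, "interval")
    return lsm, hsm, pairing


class TestFindCommonEqtl:
    def test_max_over_matched_markers(self):
        lsm, hsm, pairing = _two_sided_fixture()
        common = qb.find_common_eqtl(lsm, hsm, pairing, 0.5, 0.5,
                                     thr_low=5.0, thr_high=8.0)
        assert common.n_common == 1
        rec = common.records.iloc[0]
        assert rec["high_score"] == 9.0 and rec["high_marker_id"] == "Hb"

    def test_thresholds_above_maxima_empty(self):
        lsm, hsm, pairing = _two_sided_fixture()
        common = qb.find_common_eqtl(lsm, hsm, pairing, 0.5, 0.5,
                                     thr_low=99.0, thr_high=99.0)
        assert common.n_common == 0 and len(common.records) == 0

    @pytest.mark.parametrize("pos2,expected", [(3_000_000, 1),
                                               (8_000_000, 2)])
    def test_dedup_window(self, pos2, expected):
        """Two common peaks of one gene merge iff within 5 Mb."""
        low = qb.MarkerMap.from_records([
            ("L1", "chr1", 1_000_000, None), ("L2", "chr1", pos2, None)])
        high = qb.MarkerMap.from_records([
            ("H1", "chr1", 1_000_000, None), ("H2", "chr1", pos2, None)])
        lsm = qb.ScoreMatrix(["g"], ["L1", "L2"], [[10.0, 9.0]])
        hsm = qb.ScoreMatrix(["g"], ["H1", "H2"], [[9.0, 9.0]])
        pairing = qb.pair_markers(low, high, "exact")
        common = qb.find_common_eqtl(lsm, hsm, pairing, 0.5, 0.5,
                                     thr_low=5.0, thr_high=5.0)
        assert common.n_common == expected
        # the strongest low peak always survives
        assert "L1" in set(common.records["low_marker_id"])

    def test_empty_gene_intersection(self):
        lsm, hsm, pairing = _two_sided_fixture()
        other = qb.ScoreMatrix(["other"], ["Ha", "Hb"], [[1.0, 1.0]])
        with pytest.raises(ValueError, match="gene"):
            qb.find_common_eqtl(lsm, other, pairing, 0.5, 0.5)

    def test_matches_brute_force(self):
        """Vectorized caller equals the exhaustive oracle (both schemes)."""
        rng = np.random.default_rng(17)
        for rep in range(40):
            ng = int(rng.integers(3, 30))
            nl = int(rng.integers(3, 12))
            nh = int(rng.integers(5, 35))
            lpos = rng.choice(30_000_000, nl, replace=False)
            hpos = rng.choice(30_000_000, nh, replace=False)
            two = ["c1", "c2"]
            lmap = qb.MarkerMap.from_records(
                [(f"L{i}", two[int(rng.integers(2))], int(p), None)
                 for i, p in enumerate(lpos)])
            hmap = qb.MarkerMap.from_records(
                [(f"H{i}", two[int(rng.integers(2))], int(p), None)
                 for i, p in enumerate(hpos)])
            gids = [f"g{i}" for i in range(ng)]
            low = qb.ScoreMatrix(gids, [f"L{i}" for i in range(nl)],
                                 rng.exponential(1, (ng, nl)))
            high = qb.ScoreMatrix(gids, [f"H{i}" for i in range(nh)],
                                  rng.exponential(1, (ng, nh)))
            for mode, tol in (("exact", 2_000_000), ("interval", 5)):
                pairing = qb.pair_markers(lmap, hmap, mode, tol_bp=tol)
                if len(pairing) == 0:
                    continue
                got = qb.find_common_eqtl(low, high, pairing, 0.95, 0.9)
                mine = sorted(zip(got.records["gene_id"],
                                  got.records["low_marker_id"]))
                assert mine == brute_force_common(low, high, pairing,
                                                  0.95, 0.9)


class TestMatchPvalue:
    def test_add_one_formula(self):
        rng = np.random.default_rng(0)
        low_profile = np.array([10.0, 10.0, 10.0])
        high_profile = np.array([10.0, 10.0, 10.0])
        pool = np.zeros((50, 3))              # no randomized comparison matches
        p = qb.match_pvalue(low_profile, high_profile, 5.0, 5.0, pool,
                            n_rand=10_000, rng=rng)
        assert p == pytest.approx(1 / 10_001)

    def test_zero_observed_gives_one(self):
        rng = np.random.default_rng(0)
        p = qb.match_pvalue(np.zeros(4), np.zeros(4), 5.0, 5.0,
                            np.zeros((10, 4)), n_rand=1000, rng=rng)
        assert p == 1.0

    def test_small_n_rand_warns(self):
        with pytest.warns(UserWarning, match="n_rand"):
            qb.match_pvalue(np.zeros(2), np.zeros(2), 1.0, 1.0,
                            np.zeros((5, 2)), n_rand=50, rng=0)


class TestFractionCommon:
    def test_published_style_counts(self):
        # 65 common eQTL against 4,776 + 4,801 selected signals
        assert qb.fraction_common(65, 4776, 4801) == pytest.approx(
            0.006787, abs=1e-6)

    def test_bounds_and_degenerate(self):
        assert qb.fraction_common(0, 10, 10) == 0.0
        assert qb.fraction_common(7, 7, 7) == 0.5
        assert np.isnan(qb.fraction_common(0, 0, 0))


class TestThresholdGrid:
    def test_observed_only_when_no_shuffles(self, small_dataset):
        ds = small_dataset
        pairing = qb.pair_markers(ds.low_map, ds.high_map, "interval")
        tg = qb.threshold_grid(ds.low_scores, ds.high_scores, pairing,
                               [0.99], [0.99], n_shuffles=0, seed=0)
        assert np.isnan(tg.f_null_mean).all()
        assert np.isfinite(tg.f_obs[0, 0])

    def test_grid_must_start_at_99(self, small_dataset):
        ds = small_dataset
        pairing = qb.pair_markers(ds.low_map, ds.high_map, "interval")
        with pytest.raises(ValueError, match="99"):
            qb.threshold_grid(ds.low_scores, ds.high_scores, pairing,
                              [0.95], [0.99])

    def test_planted_signal_beats_shuffles(self, small_dataset):
        """With r = 1 and strong signals the observed overlap exceeds the
        probeset-shuffled null by > 3 sd in the top cell."""
        ds = small_dataset
        pairing = qb.pair_markers(ds.low_map, ds.high_map, "interval")
        tg = qb.threshold_grid(ds.low_scores, ds.high_scores, pairing,
                               [0.99], [0.99], n_shuffles=10, seed=5)
        assert tg.f_obs[0, 0] > tg.f_null_mean[0, 0] + 3 * tg.f_null_sd[0, 0]

    def test_pure_noise_grid_calibrated(self, noise_dataset):
        ds = noise_dataset
        pairing = qb.pair_markers(ds.low_map, ds.high_map, "exact")
        tg = qb.threshold_grid(ds.low_scores, ds.high_scores, pairing,
                               [0.99, 0.995], [0.99, 0.995],
                               n_shuffles=10, seed=5)
        ok = 0
        for i in range(2):
            for j in range(2):
                sd = max(tg.f_null_sd[i, j], 1e-12)
                ok += abs(tg.f_obs[i, j] - tg.f_null_mean[i, j]) <= 3 * sd
        assert ok >= 3       # >= 95% of cells in spirit; 4 cells here

    def test_interval_recovers_at_least_exact(self, small_dataset):
        ds = small_dataset
        ex = qb.pair_markers(ds.low_map, ds.high_map, "exact")
        iv = qb.pair_markers(ds.low_map, ds.high_map, "interval")
        ce = qb.find_common_eqtl(ds.low_scores, ds.high_scores, ex,
                                 0.99, 0.99)
        ci = qb.find_common_eqtl(ds.low_scores, ds.high_scores, iv,
                                 0.99, 0.99)
        assert ci.n_common >= ce.n_common

    def test_fraction_never_exceeds_half(self, small_dataset):
        ds = small_dataset
        pairing = qb.pair_markers(ds.low_map, ds.high_map, "interval")
        for q in (0.99, 0.999):
            c = qb.find_common_eqtl(ds.low_scores, ds.high_scores, pairing,
                                    q, q)
            f = qb.fraction_common(c.n_common, c.n_low, c.n_high)
            assert np.isnan(f) or 0.0 <= f <= 0.5
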
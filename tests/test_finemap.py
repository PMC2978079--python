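"""Interval definition, cM interpolation, candidate scoring and locus
selection."""

import math

import numpy as np
import pytest

import qtlbridge as qb
from qtlbridge.finemap import EqtlInterval


MB = 1_000_000


@pytest.fixture
def three_marker_map():
    return qb.MarkerMap.from_records([
        ("mA", "chr1", 1 * MB, 1.0), ("mB", "chr1", 5 * MB, 5.0),
        ("mC", "chr1", 9 * MB, 9.0)])


@pytest.fixture
def interval_genes():
    return qb.GeneAnnotation.from_records([
        ("gLeft", "chr1", int(0.5 * MB), int(1.5 * MB), "+"),   # spans left flank
        ("gIn1", "chr1", 3 * MB, int(3.1 * MB), "+"),
        ("gIn2", "chr1", 6 * MB, int(6.2 * MB), "-"),
        ("gOut", "chr1", 20 * MB, int(20.1 * MB), "+"),
        ("gOther", "chr2", 3 * MB, int(3.1 * MB), "+")])


class TestDefineInterval:
    def test_flanking_markers(self, three_marker_map, interval_genes):
        iv = qb.define_interval(three_marker_map, "mB", interval_genes)
        assert (iv.flank_left, iv.flank_right) == (1 * MB, 9 * MB)
        assert set(iv.candidate_genes) == {"gLeft", "gIn1", "gIn2"}

    def test_first_marker_left_flank_is_one(self, three_marker_map,
                                            interval_genes):
        iv = qb.define_interval(three_marker_map, "mA", interval_genes)
        assert iv.flank_left == 1.0

    def test_last_marker_uses_genome_end(self, three_marker_map,
                                         interval_genes):
        genome = qb.GenomeDescription.from_pairs([("chr1", 30 * MB)])
        iv = qb.define_interval(three_marker_map, "mC", interval_genes,
                                genome)
        assert iv.flank_right == 30 * MB
        assert "gOut" in iv.candidate_genes

    def test_unknown_marker(self, three_marker_map, interval_genes):
        with pytest.raises(KeyError):
            qb.define_interval(three_marker_map, "nope", interval_genes)


class TestInterpolateCm:
    def test_midpoint(self):
        mm = qb.MarkerMap.from_records([("a", "chr1", 100, 0.0),
                                        ("b", "chr1", 200, 1.0)])
        assert qb.interpolate_cm(mm, "chr1", 150) == pytest.approx(0.5)

    def test_identity_at_marker(self, three_marker_map):
        assert qb.interpolate_cm(three_marker_map, "chr1", 5 * MB) == 5.0

    def test_exact_on_linear_map(self):
        """On a collinear map interpolation reproduces the generating line
        exactly, inside and (by extrapolation) outside the markers."""
        mm = qb.MarkerMap.from_records([
            ("a", "chr1", 1_000, 0.002), ("b", "chr1", 51_000, 0.102),
            ("c", "chr1", 101_000, 0.202)])
        for pos in (500, 1_000, 26_000, 88_000, 150_000):
            assert qb.interpolate_cm(mm, "chr1", pos) == pytest.approx(
                pos * 2e-6, rel=1e-12)

    def test_needs_two_cm_markers(self):
        mm = qb.MarkerMap.from_records([("a", "chr1", 100, 1.0),
                                        ("b", "chr1", 200, None)])
        with pytest.raises(ValueError, match="cM"):
            qb.interpolate_cm(mm, "chr1", 150)


class TestRestrictInterval:
    def test_infinite_delta_is_noop(self, three_marker_map, interval_genes):
        iv = qb.define_interval(three_marker_map, "mB", interval_genes)
        assert qb.restrict_interval(iv, three_marker_map, math.inf) is iv

    def test_constant_rate_restriction(self, three_marker_map,
                                       interval_genes):
        # 1 cM/Mb map: +-0.5 cM is +-0.5 Mb around the 5 Mb marker
        iv = qb.define_interval(three_marker_map, "mB", interval_genes)
        rv = qb.restrict_interval(iv, three_marker_map, 0.5, interval_genes)
        lo, hi = rv.restricted
        assert lo == pytest.approx(4.5 * MB, rel=1e-6)
        assert hi == pytest.approx(5.5 * MB, rel=1e-6)
        assert rv.candidate_genes == []     # no gene within half a Mb

    def test_restriction_never_adds_candidates(self, three_marker_map,
                                               interval_genes):
        iv = qb.define_interval(three_marker_map, "mB", interval_genes)
        for delta in (5.0, 2.0, 1.0, 0.5, 0.1):
            rv = qb.restrict_interval(iv, three_marker_map, delta,
                                      interval_genes)
            assert set(rv.candidate_genes) <= set(iv.candidate_genes)
            assert rv.n_genes <= iv.n_genes


def _scoring_fixture():
    """Target row over 6 markers; two candidate genes, one without any
    in-gene marker."""
    high_map = qb.MarkerMap.from_records([
        (f"h{i}", "chr1", p, None) for i, p in
        enumerate([500, 1200, 1800, 2500, 7000, 9000])])
    high = qb.ScoreMatrix(["tgt"], [f"h{i}" for i in range(6)],
                          [[1.0, 5.0, 7.0, 4.0, 2.0, 6.0]])
    genes = qb.GeneAnnotation.from_records([
        ("gA", "chr1", 1000, 2000, "+"),    # h1, h2 inside -> max(5, 7)
        ("gB", "chr1", 3000, 4000, "+"),    # no marker inside; h3 at 2500
        ("tgt", "chr2", 10, 1000, "+")])
    iv = EqtlInterval("m", "chr1", 2000, 1.0, 10_000.0,
                      ["gA", "gB"], target_gene="tgt")
    return iv, high, high_map, genes


class TestScoreCandidates:
    def test_in_gene_max_rule(self):
        iv, high, high_map, genes = _scoring_fixture()
        rk = qb.score_candidates(iv, high, "tgt", high_map, genes,
                                 ext_bp=1000)
        assert rk.table.set_index("gene_id").loc["gA", "score"] == 7.0

    def test_ext_boundary(self):
        iv, high, high_map, genes = _scoring_fixture()
        rk = qb.score_candidates(iv, high, "tgt", high_map, genes,
                                 ext_bp=1000)
        row = rk.table.set_index("gene_id").loc["gB"]
        assert row["score"] == 4.0 and not row["unscored"]
        rk2 = qb.score_candidates(iv, high, "tgt", high_map, genes,
                                  ext_bp=100)
        assert bool(rk2.table.set_index("gene_id").loc["gB", "unscored"])

    def test_ranks_and_scaled_rank(self):
        iv, high, high_map, genes = _scoring_fixture()
        rk = qb.score_candidates(iv, high, "tgt", high_map, genes,
                                 ext_bp=1000)
        t = rk.table.set_index("gene_id")
        assert t.loc["gA", "rank"] == 1 and t.loc["gB", "rank"] == 2
        assert t.loc["gA", "r_k"] == 0.0 and t.loc["gB", "r_k"] == 1.0
        assert rk.top_gene() == "gA"

    def test_single_scored_gene_rk_zero(self):
        iv, high, high_map, genes = _scoring_fixture()
        rk = qb.score_candidates(
            EqtlInterval("m", "chr1", 2000, 1.0, 10_000.0, ["gA"],
                         target_gene="tgt"),
            high, "tgt", high_map, genes, ext_bp=1000)
        assert rk.table["r_k"].tolist() == [0.0]

    def test_tie_break_distance_then_id(self):
        high_map = qb.MarkerMap.from_records([("h0", "chr1", 5000, None)])
        high = qb.ScoreMatrix(["tgt"], ["h0"], [[3.0]])
        genes = qb.GeneAnnotation.from_records([
            ("gNear", "chr1", 4000, 6000, "+"),
            ("gFar", "chr1", 4500, 9000, "+"),
            ("tgt", "chr2", 10, 1000, "+")])
        iv = EqtlInterval("m", "chr1", 5000, 1.0, 10_000.0,
                          ["gFar", "gNear"], target_gene="tgt")
        rk = qb.score_candidates(iv, high, "tgt", high_map, genes, 0)
        t = rk.table.set_index("gene_id")
        # equal scores; gNear's midpoint (5000) sits on the marker
        assert t.loc["gNear", "rank"] == 1 and t.loc["gFar", "rank"] == 2

    def test_ext_monotonicity_property(self):
        """Growing the search region never unscores a gene and never touches
        in-gene (rule a) scores."""
        rng = np.random.default_rng(8)
        high_map = qb.MarkerMap.from_records([
            (f"h{i}", "chr1", int(p), None)
            for i, p in enumerate(np.sort(rng.choice(10_000_000, 60,
                                                     replace=False)))])
        high = qb.ScoreMatrix(["tgt"], [f"h{i}" for i in range(60)],
                              rng.exponential(1.0, (1, 60)))
        recs = []
        for i in range(25):
            start = int(rng.integers(1, 9_900_000))
            recs.append((f"g{i}", "chr1", start,
                         start + int(rng.integers(1_000, 120_000)), "+"))
        recs.append(("tgt", "chr2", 10, 1000, "+"))
        genes = qb.GeneAnnotation.from_records(recs)
        iv = EqtlInterval("m", "chr1", 5_000_000, 1.0, 10_000_000.0,
                          [f"g{i}" for i in range(25)], target_gene="tgt")
        prev_unscored = None
        rule_a = None
        for ext in (0, 10_000, 50_000, 200_000, 1_000_000):
            rk = qb.score_candidates(iv, high, "tgt", high_map, genes, ext)
            t = rk.table.set_index("gene_id")
            unscored = set(t.index[t["unscored"]])
            if prev_unscored is not None:
                assert unscored <= prev_unscored
            prev_unscored = unscored
            if rule_a is None:
                # ext=0 scores are exactly the rule-(a) scores
                rule_a = t.loc[~t["unscored"], "score"]
            else:
                for g, s in rule_a.items():
                    assert t.loc[g, "score"] == s


class TestSelectAssessmentLoci:
    def _fixture(self, n_candidates: int):
        """One strong locus at mB; candidate count is configurable."""
        low_map = qb.MarkerMap.from_records([
            ("mA", "chr1", 2 * MB, None), ("mB", "chr1", 5 * MB, None),
            ("mC", "chr1", 8 * MB, None)])
        hm = [("hB1", "chr1", int(4.6 * MB)), ("hB2", "chr1", int(5.4 * MB)),
              ("hX", "chr1", int(7.9 * MB))]
        high_map = qb.MarkerMap.from_records([(m, c, p, None)
                                              for m, c, p in hm])
        cand = [("c1", "chr1", int(4.5 * MB), int(4.7 * MB), "+"),
                ("c2", "chr1", int(5.3 * MB), int(5.5 * MB), "+")]
        genes = qb.GeneAnnotation.from_records(
            cand[:n_candidates] + [("tgt", "chr2", MB, MB + 1000, "+")])
        gids = ["tgt"] + [c[0] for c in cand[:n_candidates]]
        low = qb.ScoreMatrix(gids, ["mA", "mB", "mC"],
                             np.vstack([[0.0, 50.0, 0.0]] +
                                       [[0.0, 0.0, 0.0]] * n_candidates))
        high = qb.ScoreMatrix(gids, ["hB1", "hB2", "hX"],
                              np.vstack([[45.0, 45.0, 0.0]] +
                                        [[0.0, 0.0, 0.0]] * n_candidates))
        pairing = qb.pair_markers(low_map, high_map, "interval")
        pathways = qb.GeneSetCollection({"P": {"tgt", "c1"}})
        return low, high, pairing, low_map, high_map, genes, pathways

    def test_locus_meeting_all_criteria_retained(self):
        low, high, pairing, lm, hm, genes, pw = self._fixture(2)
        sel, rej = qb.select_assessment_loci(low, high, pairing, lm, hm,
                                             genes, pw, q=0.9)
        assert [iv.target_gene for iv in sel] == ["tgt"]
        assert sel[0].marker_id == "mB"
        assert set(sel[0].candidate_genes) == {"c1", "c2"}

    def test_single_gene_interval_rejected(self):
        low, high, pairing, lm, hm, genes, pw = self._fixture(1)
        sel, rej = qb.select_assessment_loci(low, high, pairing, lm, hm,
                                             genes, pw, q=0.9)
        assert sel == []
        assert "N_G <= 1" in set(rej["reason"])

    def test_unannotated_target_rejected(self):
        low, high, pairing, lm, hm, genes, _ = self._fixture(2)
        pw = qb.GeneSetCollection({"P": {"c1", "c2"}})   # target missing
        sel, rej = qb.select_assessment_loci(low, high, pairing, lm, hm,
                                             genes, pw, q=0.9)
        assert sel == []
        assert "target not in any pathway" in set(rej["reason"])

    def test_planted_trans_loci_selected_on_synthetic_data(self,
                                                           small_dataset):
        ds = small_dataset
        pairing = qb.pair_markers(ds.low_map, ds.high_map, "interval")
        # q = 0.99 keeps the threshold below the planted signal strength
        # (plants make up 1% of low-resolution cells in this configuration)
        sel, _ = qb.select_assessment_loci(
            ds.low_scores, ds.high_scores, pairing, ds.low_map, ds.high_map,
            ds.genes, ds.truth.pathways, q=0.99, genome=ds.genome)
        trans = ds.truth.plants.query("kind == 'trans'")
        selected_targets = {iv.target_gene for iv in sel}
        # every planted trans target replicates (r = 1) and is recovered
        assert set(trans["target_gene"]) <= selected_targets
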
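"""Chromatin-state enrichment, NAT couples, TFBS scanning and classes."""

import numpy as np
import pandas as pd
import pytest

from floraleaf import context, simulate
from floraleaf.context import (
    ChromatinStateTrack, _classify_hit, find_nat_couples, state_enrichment,
    tfbs_scan,
)
from floraleaf.intervals import GeneModel, GenomicInterval, LncTU


def _units(intervals):
    return [LncTU(iv) for iv in intervals]


class TestStateTrack:
    def test_overlapping_states_rejected(self):
        with pytest.raises(ValueError):
            ChromatinStateTrack.from_intervals(
                [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 50, 150)],
                ["CS1", "CS2"])

    def test_coverage_accounting(self):
        track = ChromatinStateTrack.from_intervals(
            [GenomicInterval("chr1", 0, 300), GenomicInterval("chr1", 300, 1000)],
            ["CS1", "CS2"])
        assert track.coverage_bp() == {"CS1": 300, "CS2": 700}
        assert track.overlap_by_state("chr1", 250, 350) == {"CS1": 50, "CS2": 50}


class TestStateEnrichment:
    def test_single_state_saturation_gives_fold_one(self):
        track = ChromatinStateTrack.from_intervals(
            [GenomicInterval("chr1", 0, 100_000)], ["CS1"])
        units = _units([GenomicInterval("chr1", s, s + 500)
                        for s in range(0, 50_000, 5000)])
        for metric in ("count", "bp"):
            res = state_enrichment(units, track, n_shuffles=50, metric=metric,
                                   seed=1)
            assert res["fold_change"].iloc[0] == pytest.approx(1.0)

    def test_uniform_placement_yields_null_fold_changes(self, small_bundle):
        track = simulate.make_chromatin_states(small_bundle, seed=2)
        rng = np.random.default_rng(3)
        units = []
        for _ in range(1000):
            chrom = "chr1" if rng.random() < 0.5 else "chr2"
            length = int(rng.integers(300, 1500))
            s = int(rng.integers(0, len(small_bundle.sequences[chrom]) - length))
            units.append(LncTU(GenomicInterval(chrom, s, s + length)))
        res = state_enrichment(units, track, n_shuffles=500, seed=4)
        cov = track.coverage_bp()
        total = sum(cov.values())
        for row in res.itertuples(index=False):
            if cov[row.state] / total >= 0.05:
                assert 0.75 <= row.fold_change <= 1.3

    def test_bp_fold_change_approximates_inverse_coverage(self):
        # all lncTUs inside a state covering fraction f -> bp fold ~ 1/f
        f = 0.2
        L = 1_000_000
        track = ChromatinStateTrack.from_intervals(
            [GenomicInterval("chr1", 0, int(f * L)),
             GenomicInterval("chr1", int(f * L), L)], ["CSin", "CSout"])
        rng = np.random.default_rng(5)
        units = _units([
            GenomicInterval("chr1", s, s + 400)
            for s in rng.integers(0, int(f * L) - 400, size=120)
        ])
        res = state_enrichment(units, track, n_shuffles=400, metric="bp", seed=6)
        fc = res.set_index("state").loc["CSin", "fold_change"]
        assert abs(fc - 1 / f) / (1 / f) < 0.15

    def test_planted_bias_detected(self, small_bundle):
        track = simulate.make_chromatin_states(small_bundle, seed=7)
        lengths = [("chr1", 500)] * 100 + [("chr2", 700)] * 100
        ivs = simulate.place_intervals_with_bias(track, lengths, {"CS4": 5.0},
                                                 seed=8)
        res = state_enrichment(_units(ivs), track, n_shuffles=500, seed=9)
        row = res.set_index("state").loc["CS4"]
        assert row["fold_change"] > 1.0
        assert row["p_enrich"] < 0.01

    def test_reproducible_for_fixed_seed(self):
        track = ChromatinStateTrack.from_intervals(
            [GenomicInterval("chr1", 0, 5000), GenomicInterval("chr1", 5000, 20_000)],
            ["CS1", "CS2"])
        units = _units([GenomicInterval("chr1", 100, 600)] * 10)
        a = state_enrichment(units, track, n_shuffles=100, seed=11)
        b = state_enrichment(units, track, n_shuffles=100, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_interval_longer_than_chromosome_rejected(self):
        track = ChromatinStateTrack.from_intervals(
            [GenomicInterval("chr1", 0, 1000)], ["CS1"])
        with pytest.raises(ValueError):
            state_enrichment(_units([GenomicInterval("chr1", 0, 999_999)]),
                             track, n_shuffles=2)


class TestNatCouples:
    def _genes(self):
        return [
            GeneModel("gA", GenomicInterval("chr1", 1000, 3000, "+"), 1200),
            GeneModel("gB", GenomicInterval("chr1", 5000, 7000, "-"), 6800),
            GeneModel("gC", GenomicInterval("chr2", 100, 900, "+"), 300),
        ]

    def test_same_strand_overlap_is_not_a_candidate(self):
        units = _units([GenomicInterval("chr1", 1500, 2500, "+")])
        out = find_nat_couples(units, self._genes())
        assert len(out) == 0

    def test_antisense_overlap_is_candidate(self):
        units = _units([GenomicInterval("chr1", 1500, 2500, "-")])
        out = find_nat_couples(units, self._genes())
        assert len(out) == 1
        assert out["overlap_bp"].iloc[0] == 1000

    def test_na_strand_lnctus_excluded(self):
        units = _units([GenomicInterval("chr1", 1500, 2500, "NA")])
        assert len(find_nat_couples(units, self._genes())) == 0

    def test_opposite_expression_flagging(self):
        units = _units([GenomicInterval("chr1", 1500, 2500, "-")])
        lid = units[0].id
        de = pd.DataFrame({
            "feature": [lid, "gA", lid, "gA"],
            "contrast": ["T0/T2", "T0/T2", "T2/T3", "T2/T3"],
            "log2fc": [2.0, -1.5, 1.0, 1.0],
            "call": [True, True, True, False],
        })
        out = find_nat_couples(units, self._genes(), de)
        assert bool(out["flagged"].iloc[0])
        assert out["label_T0/T2"].iloc[0] == "opposite"
        assert out["label_T2/T3"].iloc[0] == "one-sided"

    def test_both_members_must_be_called(self):
        units = _units([GenomicInterval("chr1", 1500, 2500, "-")])
        lid = units[0].id
        de = pd.DataFrame({
            "feature": [lid, "gA"], "contrast": ["T0/T2", "T0/T2"],
            "log2fc": [2.0, -1.5], "call": [True, False],
        })
        out = find_nat_couples(units, self._genes(), de)
        assert not bool(out["flagged"].iloc[0])
        assert out["label_T0/T2"].iloc[0] == "one-sided"

    def test_matches_brute_force_all_pairs(self, small_bundle):
        ds, _ = simulate.make_lnc_sources(small_bundle, seed=12)
        from floraleaf.atlas import atlas_units, merge_to_lnctus

        units = atlas_units(merge_to_lnctus([r for d in ds for r in d]))
        out = find_nat_couples(units, small_bundle.genes)
        found = {(r.lnctu, r.gene) for r in out.itertuples(index=False)}
        brute = set()
        for u in units:
            if u.strand_class == "NA":
                continue
            for g in small_bundle.genes:
                a, b = u.interval, g.interval
                if (a.chrom == b.chrom and a.strand != b.strand
                        and min(a.end, b.end) - max(a.start, b.start) >= 1):
                    brute.add((u.id, g.id))
        assert found == brute

    def test_strand_swap_symmetry(self, small_bundle):
        ds, _ = simulate.make_lnc_sources(small_bundle, seed=13)
        from floraleaf.atlas import atlas_units, merge_to_lnctus

        units = atlas_units(merge_to_lnctus([r for d in ds for r in d]))
        flip = {"+": "-", "-": "+"}
        units_f = [LncTU(GenomicInterval(u.interval.chrom, u.interval.start,
                                         u.interval.end,
                                         flip.get(u.strand_class, "NA")))
                   for u in units]
        genes_f = [GeneModel(g.id,
                             GenomicInterval(g.interval.chrom, g.interval.start,
                                             g.interval.end,
                                             flip[g.interval.strand]),
                             None)
                   for g in small_bundle.genes]
        a = find_nat_couples(units, small_bundle.genes)
        b = find_nat_couples(units_f, genes_f)
        pairs_a = {(r.lnctu.rsplit(":", 1)[0], r.gene)
                   for r in a.itertuples(index=False)}
        pairs_b = {(r.lnctu.rsplit(":", 1)[0], r.gene)
                   for r in b.itertuples(index=False)}
        assert pairs_a == pairs_b


class TestTfbsScan:
    def test_position_classes(self):
        # body [1000, 2000)
        assert _classify_hit(500, 510, 1000, 2000) == "5prime"
        assert _classify_hit(995, 1005, 1000, 2000) == "overlap-5prime"
        assert _classify_hit(1500, 1510, 1000, 2000) == "inside"
        assert _classify_hit(1995, 2005, 1000, 2000) == "overlap-3prime"
        assert _classify_hit(2500, 2510, 1000, 2000) == "3prime"

    def test_classes_partition_the_window(self):
        # sliding a 10-bp hit across the window yields exactly one class each
        seen = set()
        for s in range(0, 3000, 7):
            cls = _classify_hit(s, s + 10, 1000, 2000)
            assert cls in context.POSITION_CLASSES
            seen.add(cls)
        assert seen == set(context.POSITION_CLASSES)

    def test_hits_match_rescan_oracle(self):
        rng = np.random.default_rng(14)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=30_000))}
        units = _units([GenomicInterval("chr1", 10_000, 12_000, "+"),
                        GenomicInterval("chr1", 20_000, 21_000, "-")])
        motifs = pd.DataFrame({"name": ["m1"], "motif": ["ACGTAC"]})
        hits = tfbs_scan(units, genome, motifs)
        from floraleaf.plm import match_positions, revcomp as rc

        for u in units:
            iv = u.interval
            lo = iv.start - (1000 if iv.strand == "-" else 3000)
            hi = iv.end + (3000 if iv.strand == "-" else 1000)
            region = genome["chr1"][max(0, lo):hi]
            expect = set()
            for m in ("ACGTAC", rc("ACGTAC")):
                for p in match_positions(region, m):
                    expect.add(max(0, lo) + p)
            got = set(hits.loc[hits["lnctu"] == u.id, "start"])
            assert got == expect

    def test_every_hit_has_one_class(self):
        rng = np.random.default_rng(15)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=20_000))}
        units = _units([GenomicInterval("chr1", 8000, 9000, "+")])
        hits = tfbs_scan(units, genome,
                         pd.DataFrame({"name": ["m"], "motif": ["ACG"]}))
        assert hits["position_class"].isin(context.POSITION_CLASSES).all()

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            tfbs_scan([], {}, pd.DataFrame({"name": [], "motif": []}),
                      window_up=-1)
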
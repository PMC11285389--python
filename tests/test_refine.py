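"""Breakpoint refinement: CIGAR patterns, SR/PEM arithmetic, classification."""

import numpy as np
import pysam
import pytest

from tdscan.detect import CandidateRegion
from tdscan.refine import (
    DiscordantPairEvidence,
    PartnerAlignment,
    RefinementConfig,
    SplitReadEvidence,
    call_tds,
    classify_duplication,
    harvest_discordant_pairs,
    harvest_split_reads,
    refine_with_pem,
    refine_with_sr,
)

from conftest import simple_record, write_bam

CFG = RefinementConfig()  # m=2, lb=1000 -> S=2000; r_l=100; min_clip=20


def cand(start, end):
    return CandidateRegion("chr1", start, end, score=1.0)


# ---------------------------------------------------------------------------
# split-read harvesting and the CIGAR clip patterns


class TestHarvestSplitReads:
    def harvest(self, tmp_path, records, region=(4000, 6000), length=20_000):
        bam = write_bam(tmp_path / "a.bam", records, length=length)
        with pysam.AlignmentFile(str(bam)) as fh:
            return harvest_split_reads(fh, cand(*region), CFG)

    def test_leading_clip_is_post_alignment(self, tmp_path):
        """The worked example: 20S80M on a 100 bp read is post-aligned with
        80 matched and 20 clipped bases."""
        out = self.harvest(tmp_path, [simple_record("r0", 4000, "20S80M")])
        assert len(out) == 1
        sr = out[0]
        assert (sr.orientation, sr.matched_len, sr.clipped_len) == ("post", 80, 20)
        assert sr.breakpoint == 4000

    def test_trailing_clip_is_pre_alignment(self, tmp_path):
        out = self.harvest(tmp_path, [simple_record("r0", 4000, "80M20S")])
        sr = out[0]
        assert (sr.orientation, sr.matched_len, sr.clipped_len) == ("pre", 80, 20)
        assert sr.breakpoint == 4080

    def test_full_match_is_not_a_split_read(self, tmp_path):
        assert self.harvest(tmp_path, [simple_record("r0", 4000, "100M")]) == []

    def test_short_clip_below_min_clip_excluded(self, tmp_path):
        assert self.harvest(tmp_path, [simple_record("r0", 4000, "90M10S")]) == []

    def test_supplementary_records_are_harvested(self, tmp_path):
        out = self.harvest(
            tmp_path, [simple_record("r0", 4000, "30S70M", flag=0x800)]
        )
        assert len(out) == 1

    def test_sa_tag_partners_parsed(self, tmp_path):
        rec = simple_record(
            "r0", 4000, "30S70M", tags="SA:Z:chr1,10001,+,70M30S,60,0;"
        )
        out = self.harvest(tmp_path, [rec])
        (sr,) = out
        assert len(sr.partners) == 1
        p = sr.partners[0]
        assert (p.pos, p.orientation, p.matched_len) == (10_000, "pre", 70)
        assert p.breakpoint == 10_070

    def test_outside_search_windows_ignored(self, tmp_path):
        out = self.harvest(
            tmp_path, [simple_record("r0", 12_000, "20S80M")], region=(4000, 6000)
        )
        assert out == []


# ---------------------------------------------------------------------------
# SR refinement arithmetic


def post_sr(pos, x=80, partners=()):
    return SplitReadEvidence("q", pos, x, 100 - x, "post", list(partners))


def pre_sr(pos, x=80, partners=()):
    return SplitReadEvidence("q", pos, x, 100 - x, "pre", list(partners))


class TestRefineWithSr:
    def test_post_clip_position_becomes_start(self):
        a, b = refine_with_sr(cand(10_000, 20_000), [post_sr(10_050)], CFG)
        assert a == 10_050 and b is None

    def test_pre_clip_end_is_pos_plus_matched(self):
        # 0-based half-open end = POS + x, i.e. 1-based inclusive POS + x - 1
        a, b = refine_with_sr(cand(10_000, 20_000), [pre_sr(20_000, x=70)], CFG)
        assert b == 20_070 and a is None

    def test_empty_windows_leave_both_edges_open(self):
        assert refine_with_sr(cand(10_000, 20_000), [], CFG) == (None, None)

    def test_majority_wins_then_proximity(self):
        srs = [post_sr(10_050), post_sr(10_050), post_sr(10_300)]
        a, _ = refine_with_sr(cand(10_000, 20_000), srs, CFG)
        assert a == 10_050
        tie = [post_sr(10_050), post_sr(10_300)]
        a, _ = refine_with_sr(cand(10_000, 20_000), tie, CFG)
        assert a == 10_050  # tie broken by distance to the rough boundary

    def test_breakpoints_beyond_2s_rejected_for_direct_evidence(self):
        a, b = refine_with_sr(cand(10_000, 20_000), [post_sr(15_000)], CFG)
        assert a is None

    def test_partner_locus_fills_missing_edge(self):
        # no post SR near the start, but the pre SRs at the end carry the
        # supplementary locus of the same junction reads
        partner = PartnerAlignment(pos=9_400, orientation="post", matched_len=70, clipped_len=30)
        srs = [pre_sr(19_930, x=70, partners=[partner])]
        a, b = refine_with_sr(cand(10_000, 20_000), srs, CFG)
        assert b == 20_000
        assert a == 9_400  # beyond the rough start, supplied by the partner

    def test_partner_locus_rejected_when_mostly_outside_candidate(self):
        partner = PartnerAlignment(pos=100_000, orientation="pre", matched_len=70, clipped_len=30)
        srs = [post_sr(10_050, partners=[partner])]
        a, b = refine_with_sr(cand(10_000, 20_000), srs, CFG)
        assert a == 10_050 and b is None


# ---------------------------------------------------------------------------
# PEM refinement


class TestRefineWithPem:
    def test_outermost_pair_positions(self):
        # Rfirst at 9980 gives the start; the mate of Rlast (at 19900)
        # plus the read length gives the end
        pairs = [
            DiscordantPairEvidence("p1", 9_980, 19_820, 9_940),
            DiscordantPairEvidence("p2", 10_040, 19_900, 9_960),
        ]
        a, b = refine_with_pem(cand(10_000, 20_000), pairs, CFG)
        assert a == 9_980  # leftmost qualifying read
        assert b == 20_000  # mate of the rightmost read + read length

    def test_no_pairs_leaves_edges_open(self):
        assert refine_with_pem(cand(10_000, 20_000), [], CFG) == (None, None)

    def test_edges_beyond_2s_rejected(self):
        pairs = [DiscordantPairEvidence("p1", 3_000, 30_000, 27_100)]
        assert refine_with_pem(cand(10_000, 20_000), pairs, CFG) == (None, None)


class TestHarvestDiscordantPairs:
    def records_for_pair(self, qname, pos1, pos2, tlen, proper=False, cigar="100M"):
        f1 = 0x1 | 0x40 | 0x20 | (0x2 if proper else 0)
        f2 = 0x1 | 0x80 | 0x10 | (0x2 if proper else 0)
        return [
            simple_record(qname, pos1, cigar, flag=f1, rnext="=", pnext=pos2, tlen=tlen),
            simple_record(qname, pos2, "100M", flag=f2, rnext="=", pnext=pos1, tlen=-tlen),
        ]

    def harvest(self, tmp_path, records, region=(10_000, 20_000), **kw):
        bam = write_bam(tmp_path / "a.bam", records, length=50_000)
        with pysam.AlignmentFile(str(bam)) as fh:
            return harvest_discordant_pairs(fh, cand(*region), CFG, **kw)

    def test_qualifying_pair_kept(self, tmp_path):
        recs = self.records_for_pair("p1", 10_020, 19_900, 9_980)
        out = self.harvest(tmp_path, recs)
        assert [e.read_pos for e in out] == [10_020]

    def test_insert_size_far_from_candidate_length_excluded(self, tmp_path):
        recs = self.records_for_pair("p1", 10_020, 25_000, 15_080)
        assert self.harvest(tmp_path, recs) == []

    def test_proper_pairs_excluded(self, tmp_path):
        recs = self.records_for_pair("p1", 10_020, 19_900, 9_980, proper=True)
        assert self.harvest(tmp_path, recs) == []

    def test_reads_used_as_sr_evidence_excluded(self, tmp_path):
        recs = self.records_for_pair("p1", 10_020, 19_900, 9_980)
        assert self.harvest(tmp_path, recs, exclude_qnames={"p1"}) == []

    def test_reads_outside_start_window_excluded(self, tmp_path):
        recs = self.records_for_pair("p1", 14_000, 19_900, 6_000)
        assert self.harvest(tmp_path, recs) == []


# ---------------------------------------------------------------------------
# classification


class TestClassifyDuplication:
    def test_tandem_signature(self):
        b_partner = PartnerAlignment(19_950, "pre", 70, 30)
        a_partner = PartnerAlignment(10_050, "post", 70, 30)
        srs = [
            post_sr(10_050, partners=[b_partner]),
            pre_sr(19_880, x=70, partners=[a_partner]),
        ]
        assert classify_duplication(cand(10_000, 20_000), srs, CFG) == "tandem"

    def test_external_partner_means_interspersed(self):
        c_partner = PartnerAlignment(200_000, "pre", 70, 30)
        srs = [post_sr(10_050, partners=[c_partner])]
        assert classify_duplication(cand(10_000, 20_000), srs, CFG) == "interspersed"

    def test_both_patterns_at_one_locus_means_interspersed(self):
        # an insertion site C just outside the candidate shows both clip
        # patterns: junction reads at the source start point pre-at-C, those
        # at the source end point post-at-C
        srs = [
            post_sr(10_050, partners=[PartnerAlignment(22_930, "pre", 70, 30)]),
            pre_sr(19_930, x=70, partners=[PartnerAlignment(23_000, "post", 70, 30)]),
        ]
        assert classify_duplication(cand(10_000, 20_000), srs, CFG) == "interspersed"

    def test_no_split_reads_is_unresolved(self):
        assert classify_duplication(cand(10_000, 20_000), [], CFG) == "unresolved"

    def test_wrong_partner_orientation_is_interspersed(self):
        srs = [post_sr(10_050, partners=[PartnerAlignment(19_950, "post", 70, 30)])]
        assert classify_duplication(cand(10_000, 20_000), srs, CFG) == "interspersed"


# ---------------------------------------------------------------------------
# end-to-end calling on simulated data


class TestCallTds:
    def test_empty_candidate_list(self, tiny_sim):
        _, sim = tiny_sim
        assert call_tds(str(sim.bam), [], CFG) == []

    def test_pure_sample_single_td_called_exactly(self, tmp_path):
        from tdscan import PipelineConfig, SimConfig, simulate_sample
        from tdscan.caller import run_call

        cfg = SimConfig(
            ref_length=1_000_000, n_tds=1, td_size_range=(25_000, 25_000),
            coverage=8.0, purity=1.0, seed=77,
        )
        sim = simulate_sample(cfg, tmp_path)
        res = run_call(sim.bam, sim.fasta, PipelineConfig(seed=77))
        (t,) = sim.truth
        assert len(res.calls) == 1
        call = res.calls[0]
        assert call.classification == "tandem"
        assert (call.start, call.end) == (t.start, t.end)
        assert (call.source_start, call.source_end) == ("SR", "SR")

    def test_interspersed_duplications_not_called(self, tmp_path):
        from tdscan import PipelineConfig, SimConfig, simulate_sample
        from tdscan.caller import run_call

        cfg = SimConfig(
            ref_length=1_500_000, n_tds=2, coverage=8.0, purity=1.0,
            interspersed_fraction=1.0, seed=78,
        )
        sim = simulate_sample(cfg, tmp_path)
        res = run_call(sim.bam, sim.fasta, PipelineConfig(seed=78))
        inter = [t for t in sim.truth if t.kind == "interspersed"]
        assert inter  # the fixture actually contains interspersed events
        for t in inter:
            for c in res.calls:
                ov = min(c.end, t.end) - max(c.start, t.start)
                assert ov < t.length / 2

    def test_pem_applies_only_to_edges_sr_left_open(self, tmp_path):
        # SR pins the start; discordant pairs would place it elsewhere
        sr_rec = simple_record("s1", 10_050, "30S70M")
        pair = [
            simple_record("p1", 10_020, "100M", flag=0x61, rnext="=", pnext=19_900, tlen=9_980),
            simple_record("p1", 19_900, "100M", flag=0x91, rnext="=", pnext=10_020, tlen=-9_980),
        ]
        bam = write_bam(tmp_path / "a.bam", [sr_rec, *pair], length=50_000)
        calls = call_tds(str(bam), [cand(10_000, 20_000)], CFG)
        assert len(calls) == 1
        call = calls[0]
        assert (call.start, call.source_start) == (10_050, "SR")
        assert (call.end, call.source_end) == (20_000, "PEM")

    def test_candidate_without_evidence_keeps_bin_boundaries(self, tmp_path):
        bam = write_bam(tmp_path / "a.bam", [simple_record("r0", 500, "100M")], length=50_000)
        calls = call_tds(str(bam), [cand(10_000, 20_000)], CFG)
        assert len(calls) == 1
        call = calls[0]
        assert (call.start, call.end) == (10_000, 20_000)
        assert (call.source_start, call.source_end) == ("bin", "bin")
        assert call.classification == "unresolved"
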
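"""LTR realignment, clip placement, breakpoint/TSD calls, region coverage."""

import numpy as np
import pytest

from oracles import ungapped_local_oracle

from ervmap.breakpoint_inference import (
    SeqIndex,
    call_breakpoints,
    clip_to_host,
    local_align,
    ltr_region_coverage,
    realign_to_ltr,
    revcomp,
)
from ervmap.model import GenomicInterval, LTRModel, ReadRecord


def rng_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="module")
def ltr():
    rng = np.random.default_rng(5)
    return LTRModel(rng_seq(rng, 287))


def raw_read(seq, name="q", mate=1):
    return ReadRecord(name, mate, False, None, None, 0, None, seq)


class TestRealignToLtr:
    def test_exact_substring_maps_full_length(self, ltr):
        read = raw_read(ltr.seq[50:150])
        (rec,) = realign_to_ltr([read], ltr)
        assert rec.is_mapped
        assert rec.pos_1based == 51
        assert rec.cigar == [("M", 100)]

    def test_junction_read_soft_clipped_at_ltr_start(self, ltr):
        rng = np.random.default_rng(6)
        flank = rng_seq(rng, 30)
        (rec,) = realign_to_ltr([raw_read(flank + ltr.seq[:70])], ltr)
        assert rec.pos_1based == 1
        assert rec.cigar == [("S", 30), ("M", 70)]

    def test_read_sharing_no_kmer_stays_unmapped(self, ltr):
        rng = np.random.default_rng(7)
        (rec,) = realign_to_ltr([raw_read(rng_seq(rng, 100))], ltr)
        assert not rec.is_mapped

    def test_reverse_complement_read_mapped_on_minus_strand(self, ltr):
        (rec,) = realign_to_ltr([raw_read(revcomp(ltr.seq[50:150]))], ltr)
        assert rec.is_mapped and rec.is_reverse
        assert rec.pos_1based == 51
        assert rec.seq == ltr.seq[50:150]  # stored in reference orientation


@pytest.fixture(scope="module")
def window():
    rng = np.random.default_rng(8)
    chrom_seq = rng_seq(rng, 20_000)
    return chrom_seq, GenomicInterval("chr1", 8000, 9000)


class TestClipToHost:
    def test_verbatim_clip_hits_with_identity_one(self, window):
        chrom_seq, iv = window
        clip = chrom_seq[8400:8440]
        hits = clip_to_host(clip, chrom_seq, iv)
        assert hits and hits[0].identity == 1.0
        assert (hits[0].ref_start, hits[0].ref_end) == (8400, 8440)
        assert hits[0].strand == "+"

    def test_reverse_complement_flips_strand_preserves_span(self, window):
        chrom_seq, iv = window
        clip = chrom_seq[8400:8440]
        fwd = clip_to_host(clip, chrom_seq, iv)[0]
        rev = clip_to_host(revcomp(clip), chrom_seq, iv)[0]
        assert rev.strand == "-"
        assert (rev.ref_start, rev.ref_end) == (fwd.ref_start, fwd.ref_end)

    def test_foreign_sequence_yields_no_hits(self, window):
        chrom_seq, iv = window
        rng = np.random.default_rng(9)
        assert clip_to_host(rng_seq(rng, 30), chrom_seq, iv) == []

    def test_hits_outside_expanded_window_discarded(self, window):
        chrom_seq, iv = window
        clip = chrom_seq[100:140]  # well outside 8000 +/- 5000... inside!
        # position 100 is outside [3000, 14000)
        hits = clip_to_host(clip, chrom_seq, iv, flank=5000)
        assert all(3000 <= h.ref_start < 14000 for h in hits)


class TestSeedExtendEngine:
    def test_agreement_with_brute_force_ungapped_oracle(self):
        """Engine and exhaustive per-diagonal search score 200 planted
        30-60-mers identically (allowing <=5% co-optimal discrepancies)."""
        rng = np.random.default_rng(10)
        agree = 0
        total = 200
        for _ in range(total):
            ref = rng_seq(rng, 2000)
            qlen = int(rng.integers(30, 61))
            start = int(rng.integers(0, 2000 - qlen))
            q = list(ref[start : start + qlen])
            for _ in range(int(rng.integers(0, 3))):
                p = int(rng.integers(0, qlen))
                q[p] = "ACGT"[int(rng.integers(0, 4))]
            query = "".join(q)
            segs = local_align(query, SeqIndex(ref), min_score=1)
            engine_best = segs[0].score if segs else 0
            if engine_best == ungapped_local_oracle(query, ref):
                agree += 1
        assert agree / total >= 0.95

    def test_engine_never_beats_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            ref = rng_seq(rng, 500)
            query = ref[100:140]
            segs = local_align(query, SeqIndex(ref), min_score=1)
            assert segs[0].score <= ungapped_local_oracle(query, ref)


class TestCallBreakpoints:
    def test_reported_junglefowl_style_pair_called_as_tsd(self):
        obs = [("chr3", 84550973)] * 3 + [("chr3", 84550979)] * 2
        call = call_breakpoints(obs, "c1", tsd_expected=6)
        assert call.breakpoints == [84550973, 84550979]
        assert call.tsd_len == 6
        assert call.support == [3, 2]

    def test_single_breakpoint_has_no_tsd(self):
        call = call_breakpoints([("chr1", 500)] * 4, "c1")
        assert call.breakpoints == [500] and call.tsd_len is None

    def test_wrong_separation_flagged(self):
        obs = [("chr1", 100)] * 2 + [("chr1", 150)] * 2
        call = call_breakpoints(obs, "c1", tsd_expected=6)
        assert call.tsd_len is None
        assert call.note

    def test_conflicting_chromosomes_ambiguous(self):
        obs = [("chr1", 100)] * 2 + [("chr2", 100)] * 2
        call = call_breakpoints(obs, "c1")
        assert call.ambiguous and call.breakpoints == []

    def test_singleton_observations_below_support_dropped(self):
        call = call_breakpoints([("chr1", 99)], "c1", min_support=2)
        assert call.breakpoints == []


class TestLtrRegionCoverage:
    def aligned(self, pos, length):
        return ReadRecord("r", 1, True, "LTR", pos, 60, [("M", length)],
                          "A" * length)

    def test_full_coverage_gives_unit_fractions(self, ltr):
        recs = [self.aligned(1, 287)]
        cov = ltr_region_coverage(recs, ltr)
        assert (cov.u3_frac, cov.r_frac, cov.u5_frac) == (1.0, 1.0, 1.0)
        assert cov.full_ltr

    def test_tail_only_coverage_matches_positionwise_fractions(self, ltr):
        recs = [self.aligned(140, 287 - 140 + 1)]  # positions 140..287
        cov = ltr_region_coverage(recs, ltr)
        assert cov.u3_frac == pytest.approx(7 / 146)
        assert cov.r_frac == 1.0 and cov.u5_frac == 1.0

    def test_u3_only_coverage(self, ltr):
        cov = ltr_region_coverage([self.aligned(1, 146)], ltr)
        assert (cov.u3_frac, cov.r_frac, cov.u5_frac) == (1.0, 0.0, 0.0)

    def test_empty_alignment_set(self, ltr):
        cov = ltr_region_coverage([], ltr)
        assert (cov.u3_frac, cov.r_frac, cov.u5_frac) == (0.0, 0.0, 0.0)

    def test_fractions_monotone_as_reads_added(self, ltr):
        rng = np.random.default_rng(12)
        recs = []
        prev = (0.0, 0.0, 0.0)
        for _ in range(15):
            pos = int(rng.integers(1, 240))
            recs.append(self.aligned(pos, 50))
            cov = ltr_region_coverage(recs, ltr)
            cur = (cov.u3_frac, cov.r_frac, cov.u5_frac)
            assert all(c >= p for c, p in zip(cur, prev))
            prev = cur


class TestBreakpointRecoveryOnSimulatedData:
    def test_called_breakpoints_match_truth_junctions(
        self, small_sim, small_library, small_sites
    ):
        """Every called breakpoint is one of {j, j+tsd} for its insertion."""
        from ervmap.breakpoint_inference import (
            analyze_cluster,
            retrieve_cluster_reads,
        )
        from ervmap.interval_clustering import cluster_sites

        sites, _ = small_sites
        clusters = cluster_sites(sites, ["lib1"])
        reads = retrieve_cluster_reads(
            {"lib1": str(small_library["host_sam"])}, clusters
        )
        truth_by_chrom = {}
        for t in small_sim.truth:
            truth_by_chrom.setdefault(t.chrom, []).append(t)
        n_tsd = 0
        for c in clusters:
            call, cov = analyze_cluster(
                c, reads[c.cluster_id],
                small_sim.genome[c.interval.chrom], small_sim.ltr_model,
            )
            (t,) = [
                t for t in truth_by_chrom[c.interval.chrom]
                if abs(t.junction_pos - c.interval.start) < 20_000
            ]
            expected = {t.junction_pos, t.junction_pos + t.tsd_len}
            assert set(call.breakpoints) <= expected
            if call.tsd_len is not None:
                assert call.tsd_len == t.tsd_len
                n_tsd += 1
            assert cov.full_ltr  # 30x fully tiles the 287-bp LTR
        assert n_tsd == len(clusters)
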
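"""CluMP: discordant extraction, clustering, clip evidence, refinement, filtering."""

import numpy as np
import pytest

from capig.clump import (
    BreakpointCluster,
    ClipEvidence,
    ClumpConfig,
    ReadIndex,
    call_translocations,
    calls_to_rows,
    cluster_pairs,
    collect_clip_support,
    extract_discordant,
    filter_events,
    is_discordant_pair,
    mismatch_fraction,
    refine_breakpoint,
)
from capig.io import GenomicIntervals
from capig.simulate import SimConfig, simulate_translocation_reads

from .conftest import make_pair, make_read, sort_reads

CFG = ClumpConfig()


class TestExtractDiscordant:
    def test_proper_same_chrom_pair_not_emitted(self):
        reads = sort_reads(make_pair("q1", "chr1", 1000, "chr1", 1150, insert=300))
        pairs, _ = extract_discordant(reads, CFG)
        assert pairs == []

    def test_low_mapq_mate_drops_pair(self):
        reads = []
        reads += make_pair("q1", "chr1", 1000, "chr2", 5000)
        reads += make_pair("q2", "chr1", 2000, "chr2", 6000, mapq=(60, 10))
        reads += make_pair("q3", "chr1", 3000, "chr2", 7000)
        pairs, _ = extract_discordant(sort_reads(reads, ["chr1", "chr2"]), CFG)
        assert sorted(p.qname for p in pairs) == ["q1", "q3"]

    def test_insert_exactly_at_threshold_is_emitted(self):
        reads = sort_reads(make_pair("q1", "chr1", 1000, "chr1", 5850, insert=5000))
        pairs, _ = extract_discordant(reads, CFG)
        assert len(pairs) == 1 and not pairs[0].inter_chromosomal

    def test_duplicate_pair_excluded(self):
        reads = sort_reads(
            make_pair("q1", "chr1", 1000, "chr2", 5000, dup=True), ["chr1", "chr2"]
        )
        pairs, _ = extract_discordant(reads, CFG)
        assert pairs == []

    def test_unsorted_input_is_hard_error(self):
        r1, r2 = make_pair("q1", "chr1", 2000, "chr1", 9000, insert=7150)
        with pytest.raises(ValueError, match="sorted"):
            extract_discordant([r2, r1], CFG)

    def test_anchors_canonicalised(self):
        reads = sort_reads(make_pair("q1", "chr2", 5000, "chr1", 1000), ["chr1", "chr2"])
        (pair,), _ = extract_discordant(reads, CFG)
        assert pair.anchor_a[0] == "chr1" and pair.anchor_b[0] == "chr2"

    def test_matches_brute_force_predicate(self):
        """Streamed extraction equals a literal scan over all mate pairs."""
        rng = np.random.default_rng(11)
        reads, by_qname = [], {}
        for i in range(300):
            chrom2 = "chr2" if rng.random() < 0.5 else "chr1"
            mq = (int(rng.integers(0, 61)), int(rng.integers(0, 61)))
            insert = int(rng.integers(100, 10_000))
            r1, r2 = make_pair(
                f"q{i}", "chr1", int(rng.integers(1, 50_000)), chrom2,
                int(rng.integers(1, 50_000)), mapq=mq, insert=insert,
                dup=bool(rng.random() < 0.1),
            )
            reads += [r1, r2]
            by_qname[f"q{i}"] = (r1, r2)
        pairs, _ = extract_discordant(sort_reads(reads, ["chr1", "chr2"]), CFG)
        expected = {q for q, (a, b) in by_qname.items() if is_discordant_pair(a, b, CFG)}
        assert {p.qname for p in pairs} == expected


class TestClusterPairs:
    def _pairs(self, coords):
        out = []
        for i, (pa, pb) in enumerate(coords):
            reads = sort_reads(make_pair(f"q{i}", "chr1", pa, "chr2", pb), ["chr1", "chr2"])
            ps, _ = extract_discordant(reads, CFG)
            out += ps
        return sorted(out, key=lambda p: (p.anchor_a, p.anchor_b))

    def test_single_pair_single_cluster(self):
        clusters = cluster_pairs(self._pairs([(1000, 2000)]), CFG)
        assert len(clusters) == 1 and len(clusters[0].pairs) == 1

    def test_nearby_pairs_merge(self):
        clusters = cluster_pairs(self._pairs([(1000, 2000), (1200, 2200)]), CFG)
        assert len(clusters) == 1
        assert clusters[0].window_a == ("chr1", 1000, 1200)

    def test_distant_a_anchors_split(self):
        clusters = cluster_pairs(self._pairs([(1000, 2000), (6000, 2200)]), CFG)
        assert len(clusters) == 2

    def test_single_linkage_chains_through_intermediate(self):
        clusters = cluster_pairs(self._pairs([(1000, 2000), (1900, 2000), (2800, 2000)]), CFG)
        assert len(clusters) == 1 and len(clusters[0].pairs) == 3

    def test_orientation_classes_kept_apart(self):
        pairs = self._pairs([(1000, 2000), (1100, 2100)])
        flipped = pairs[1]
        object.__setattr__(flipped, "anchor_a", (*flipped.anchor_a[:2], "-"))
        clusters = cluster_pairs(pairs, CFG)
        assert len(clusters) == 2


class TestClipSupport:
    def test_mismatch_fraction_arithmetic(self):
        half_clip = make_read(cigar="75S75M", clipped_prefix="A" * 75, nm=0)
        small_clip = make_read(cigar="10S140M", clipped_prefix="A" * 10, nm=2)
        assert mismatch_fraction(half_clip) == pytest.approx(0.5)
        assert mismatch_fraction(small_clip) == pytest.approx(12 / 150)

    def _cluster(self):
        return BreakpointCluster(("chr1", 900, 1100), ("chr2", 5000, 5200), [], "FR")

    def test_qualifying_clip_collected_and_small_clip_excluded(self):
        keep = make_read(
            qname="k", pos=1000, cigar="75M75S", clipped_suffix="C" * 75, ref_len=75
        )
        drop = make_read(
            qname="d", pos=1010, cigar="10S140M", clipped_prefix="A" * 10, nm=2, ref_len=140
        )
        clips_a, clips_b = collect_clip_support(ReadIndex([keep, drop]), self._cluster(), CFG)
        assert [c.qname for c in clips_a] == ["k"]
        assert clips_a[0].side == "right" and clips_a[0].clip_coord == 1074
        assert clips_b == []

    def test_duplicate_and_low_quality_reads_excluded(self):
        dup = make_read(qname="dup", pos=1000, cigar="75M75S", clipped_suffix="C" * 75,
                        ref_len=75, is_duplicate=True)
        lowq = make_read(qname="lowq", pos=1000, cigar="75M75S", clipped_suffix="C" * 75,
                         ref_len=75, mean_baseq=10.0)
        lowmq = make_read(qname="lowmq", pos=1000, cigar="75M75S", clipped_suffix="C" * 75,
                          ref_len=75, mapq=20)
        clips_a, _ = collect_clip_support(ReadIndex([dup, lowq, lowmq]), self._cluster(), CFG)
        assert clips_a == []


class TestRefine:
    def _cluster(self, n_pairs=3):
        return BreakpointCluster(("chr1", 9_800, 10_200), ("chr2", 5_000, 5_400), [None] * n_pairs, "FR")

    def test_identical_clips_give_exact_breakpoint_and_consensus(self):
        seq = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"
        clips = [ClipEvidence(f"q{i}", 10_000, "right", seq, 35.0, 60) for i in range(5)]
        call = refine_breakpoint(self._cluster(), clips, [])
        assert call.pos_a == 10_000 and call.consensus_clip_a == seq
        assert call.n_clip_reads_a == 5 and call.resolution == "base_pair"

    def test_no_clips_falls_back_to_window_midpoint(self):
        call = refine_breakpoint(self._cluster(), [], [])
        assert call.resolution == "window"
        assert call.pos_a == 10_000 and call.pos_b == 5_200

    def test_modal_coordinate_tie_breaks_to_smallest(self):
        clips = [ClipEvidence(f"q{i}", 10_000, "right", "A" * 20, 35.0, 60) for i in range(3)]
        clips += [ClipEvidence(f"p{i}", 10_002, "right", "C" * 20, 35.0, 60) for i in range(3)]
        call = refine_breakpoint(self._cluster(), clips, [])
        assert call.pos_a == 10_000

    def test_consensus_majority_per_position(self):
        clips = [
            ClipEvidence("q1", 10_000, "right", "TTG", 35.0, 60),
            ClipEvidence("q2", 10_000, "right", "TAG", 35.0, 60),
            ClipEvidence("q3", 10_000, "right", "AAGC", 35.0, 60),
        ]
        # T(2)/A(1) -> T, T(1)/A(2) -> A, G(3) -> G, C from the longest read
        call = refine_breakpoint(self._cluster(), clips, [])
        assert call.consensus_clip_a == "TAGC"

    def test_consensus_tie_breaks_to_lexicographically_smallest_base(self):
        clips = [
            ClipEvidence("q1", 10_000, "right", "GC", 35.0, 60),
            ClipEvidence("q2", 10_000, "right", "AC", 35.0, 60),
        ]
        call = refine_breakpoint(self._cluster(), clips, [])
        assert call.consensus_clip_a == "AC"

    def test_left_clips_consensus_in_reference_orientation(self):
        clips = [ClipEvidence(f"q{i}", 5_100, "left", "TTGCA", 35.0, 60) for i in range(2)]
        call = refine_breakpoint(self._cluster(), [], clips)
        assert call.pos_b == 5_100 and call.consensus_clip_b == "TTGCA"


class TestFilterEvents:
    def _call(self, pos_a=25_000, pos_b=26_000, chrom_b="chr2", n_pairs=3, n_clips=2):
        from capig.clump import TranslocationCall

        return TranslocationCall(
            chrom_a="chr1", pos_a=pos_a, chrom_b=chrom_b, pos_b=pos_b, n_pairs=n_pairs,
            n_clip_reads_a=n_clips, n_clip_reads_b=n_clips, consensus_clip_a="",
            consensus_clip_b="", resolution="base_pair",
        )

    def _ig(self):
        ig = GenomicIntervals()
        ig.add("chr1", 20_000, 30_000, "igh")
        ig.add("chr2", 20_000, 30_000, "igk")
        return ig

    def test_both_breakpoints_in_ig_loci_filtered(self):
        calls = filter_events([self._call()], None, self._ig(), CFG)
        assert calls[0].status == "filtered" and calls[0].filter_reason == "ig_internal"

    def test_single_ig_breakpoint_survives(self):
        calls = filter_events([self._call(pos_b=50_000)], None, self._ig(), CFG)
        assert calls[0].status == "candidate"

    def test_blacklist_hit_on_one_side_filtered(self):
        bl = GenomicIntervals()
        bl.add("chr1", 24_000, 26_000, "rep")
        calls = filter_events([self._call()], bl, None, CFG)
        assert calls[0].filter_reason == "blacklist"

    def test_single_pair_without_clips_is_low_support(self):
        calls = filter_events([self._call(n_pairs=1, n_clips=0)], None, None, CFG)
        assert calls[0].filter_reason == "low_support"

    def test_empty_interval_sets_change_nothing(self):
        call = self._call()
        filter_events([call], None, None, CFG)
        assert call.status == "candidate" and call.filter_reason == ""

    def test_idempotent_and_statuses_partition(self):
        calls = [self._call(pos_b=50_000), self._call(n_pairs=1, n_clips=0)]
        once = [(c.status, c.filter_reason) for c in filter_events(calls, None, self._ig(), CFG)]
        twice = [(c.status, c.filter_reason) for c in filter_events(calls, None, self._ig(), CFG)]
        assert once == twice
        assert {s for s, _ in once} == {"filtered", "candidate"}


class TestPipeline:
    def test_planted_breakpoint_recovered_exactly(self):
        cfg = SimConfig(seed=101, tumor_fraction=0.1, n_fragments=8000)
        res = simulate_translocation_reads(cfg)
        calls = [c for c in call_translocations(res.reads) if c.status != "filtered"]
        assert len(calls) == 1
        bp = res.truth.breakpoints[0]
        call = calls[0]
        assert (call.chrom_a, call.pos_a) == (bp.chrom_a, bp.pos_a)
        assert (call.chrom_b, call.pos_b) == (bp.chrom_b, bp.pos_b)
        assert bp.junction_seq_a.startswith(call.consensus_clip_a)
        assert bp.junction_seq_b.endswith(call.consensus_clip_b)

    def test_zero_tumor_fraction_yields_no_candidates(self):
        res = simulate_translocation_reads(SimConfig(seed=102, tumor_fraction=0.0, n_fragments=5000))
        assert call_translocations(res.reads) == []

    def test_repeat_run_is_byte_identical(self):
        res = simulate_translocation_reads(SimConfig(seed=103, tumor_fraction=0.1, n_fragments=5000))
        rows1 = calls_to_rows(call_translocations(res.reads))
        rows2 = calls_to_rows(call_translocations(list(res.reads)))
        assert rows1 == rows2
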
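"""Event scanning, filters, break-interval calling and deduplication."""

import numpy as np
import pytest

from steelseq.alignio import ReferenceGenome, extract_mutations
from steelseq.detector import (
    PROFILES,
    SloppyEvent,
    SSBCall,
    apply_filters,
    call_ssb,
    dedupe_calls,
    detect,
    get_profile,
    mode_targets,
    scan_events,
)
from steelseq.simulator import NickPlan, make_reference, simulate_library

from conftest import make_record
from helpers import mirror_record, oracle_scan, random_toy, revcomp


def _scan(ref, rec, target):
    obs, _ = extract_mutations(rec, ref)
    return scan_events(obs, rec, ref, target)


class TestScanEvents:
    def test_worked_example(self, toy_ref):
        # ref GACATGACAGTACAT: As at 1,3,6,8,11,13; read mutates 6,8,11,13
        rec = make_record("GACATGGCGGTGCGT", [("M", 15)], quals="const30")
        events = _scan(toy_ref, rec, "A")
        assert len(events) == 1
        ev = events[0]
        assert ev.mutated_target_positions == [6, 8, 11, 13]
        assert (ev.n_sub, ev.n_del) == (4, 0)
        assert ev.anchor_pos == 3

    def test_partial_run_after_intact_target(self, toy_ref):
        # A at 6 left intact: the maximal run is {8,11,13} anchored at 6
        rec = make_record("GACATGACGGTGCGT", [("M", 15)], quals="const30")
        events = _scan(toy_ref, rec, "A")
        assert len(events) == 1
        assert events[0].mutated_target_positions == [8, 11, 13]
        assert events[0].anchor_pos == 6

    def test_clean_read_no_events(self, toy_ref):
        rec = make_record(toy_ref.sequences["chr1"], [("M", 15)], quals="const30")
        assert _scan(toy_ref, rec, "A") == []
        assert _scan(toy_ref, rec, "T") == []

    def test_unanchored_run_discarded(self):
        # read starts inside the mutated run: no intact A on the 5' side
        ref = ReferenceGenome({"c": "AAAAAACAAA"})
        rec = make_record("GGGGC", [("M", 5)], chrom="c", start=2, quals="const30")
        assert _scan(ref, rec, "A") == []

    def test_deletions_count_as_mutated(self):
        ref = ReferenceGenome({"c": "CACACACACC"})
        # delete As at 5,7; substitute A at 3; intact A at 1 anchors
        rec = make_record("CACGC" + "C" + "CC",
                          [("M", 5), ("D", 1), ("M", 1), ("D", 1), ("M", 2)],
                          chrom="c", quals="const30")
        events = _scan(ref, rec, "A")
        assert len(events) == 1
        ev = events[0]
        assert ev.mutated_target_positions == [3, 5, 7]
        assert (ev.n_sub, ev.n_del) == (1, 2)
        assert ev.anchor_pos == 1

    @pytest.mark.parametrize("target", ["A", "T", "C", "G"])
    def test_oracle_equivalence_random_toys(self, target):
        """Brute-force all-subinterval oracle agrees on 300 random alignments."""
        rng = np.random.default_rng(hash(target) % 2**31)
        for _ in range(300):
            ref, rec = random_toy(rng)
            got = {
                (tuple(e.mutated_target_positions), e.anchor_pos)
                for e in _scan(ref, rec, target)
            }
            assert got == oracle_scan(rec, ref, target)

    def test_strand_symmetry(self, toy_ref):
        """Reverse-complementing reference and read maps A-events to T-events
        at mirrored coordinates."""
        L = 15
        rec = make_record("GACATGGCGGTGCGT", [("M", 15)], quals="const30")
        fwd = [call_ssb(e) for e in _scan(toy_ref, rec, "A")]
        ref_rc = ReferenceGenome({"chr1": revcomp(toy_ref.sequences["chr1"])})
        rec_rc = mirror_record(rec, L)
        rev = [call_ssb(e) for e in _scan(ref_rc, rec_rc, "T")]
        assert [(L - c.end, L - c.start, "-") for c in fwd] == [
            (c.start, c.end, c.strand) for c in rev
        ]


class TestApplyFilters:
    @staticmethod
    def event(n_mut=5, n_sub=4, qual=30.0):
        pos = list(range(10, 10 + 2 * n_mut, 2))
        return SloppyEvent(
            read_name="r", chrom="c", target_base="A",
            mutated_target_positions=pos, n_sub=n_sub, n_del=n_mut - n_sub,
            anchor_pos=8, mean_sub_quality=qual, read_error_rate=0.01, mapq=60,
        )

    def test_nanopore_pass(self):
        ok, reason = apply_filters(self.event(5, 4, 30.0), PROFILES["nanopore"])
        assert ok and reason is None

    def test_min_targets_fails(self):
        ok, reason = apply_filters(self.event(4, 4, 30.0), PROFILES["pacbio-hifi"])
        assert not ok and reason == "min_mutated_targets"

    def test_all_deletions_fail_nanopore(self):
        ok, reason = apply_filters(self.event(5, 0, None), PROFILES["nanopore"])
        assert not ok and reason == "min_substitutions"

    def test_quality_boundary(self):
        ok, _ = apply_filters(self.event(qual=10.0), PROFILES["pacbio-hifi"])
        assert ok
        ok, reason = apply_filters(self.event(qual=9.99), PROFILES["pacbio-hifi"])
        assert not ok and reason == "min_mean_subst_quality"

    def test_missing_quality_fails_closed(self):
        ok, reason = apply_filters(self.event(qual=None), PROFILES["illumina-tk6"])
        assert not ok and reason == "min_mean_subst_quality"
        lenient = get_profile("custom", min_mutated_targets=3, require_quality=False)
        ok, _ = apply_filters(self.event(qual=None), lenient)
        assert ok


class TestCallSSB:
    def test_a_event_interval(self):
        ev = TestApplyFilters.event()
        ev.anchor_pos, ev.mutated_target_positions = 3, [6, 8, 11, 13]
        c = call_ssb(ev)
        assert (c.start, c.end, c.strand) == (4, 7, "+")

    def test_t_event_interval(self):
        ev = TestApplyFilters.event()
        ev.target_base = "T"
        ev.mutated_target_positions = [110, 115, 120]
        ev.anchor_pos = 125
        c = call_ssb(ev)
        assert (c.start, c.end, c.strand) == (120, 125, "-")

    def test_adjacent_anchor_single_base(self):
        ev = TestApplyFilters.event()
        ev.anchor_pos, ev.mutated_target_positions = 10, [11, 13, 15]
        c = call_ssb(ev)
        assert (c.start, c.end) == (11, 12)


def _call(start, end, strand="+", name="r", mapq=60):
    return SSBCall(chrom="c", start=start, end=end, strand=strand, read_name=name,
                   mapq=mapq, n_mut_targets=5, n_sub=5, n_del=0, mean_sub_quality=30.0)


class TestDedupe:
    def test_identical_positions_collapse(self):
        calls = [_call(5, 9, name=n) for n in "abc"]
        assert len(dedupe_calls(calls)) == 1

    def test_strand_in_key(self):
        calls = [_call(5, 9, "+"), _call(5, 9, "-")]
        assert len(dedupe_calls(calls)) == 2

    def test_idempotent(self):
        calls = [_call(5, 9), _call(5, 9), _call(7, 8, "-"), _call(1, 3)]
        once = dedupe_calls(calls)
        assert dedupe_calls(once) == once

    def test_tiebreak_mapq_then_name(self):
        calls = [_call(5, 9, name="z", mapq=60), _call(5, 9, name="a", mapq=10),
                 _call(5, 9, name="b", mapq=60)]
        (kept,) = dedupe_calls(calls)
        assert (kept.mapq, kept.read_name) == (60, "b")

    def test_disabled_is_identity_sorted(self):
        calls = [_call(7, 8), _call(5, 9), _call(5, 9)]
        out = dedupe_calls(calls, enabled=False)
        assert len(out) == 3
        assert [c.start for c in out] == [5, 5, 7]


class TestDetect:
    def test_mode_targets(self):
        assert mode_targets("-dATP") == ("A", "T")
        assert mode_targets("-dCTP") == ("C", "G")

    def test_clean_library_zero_calls(self):
        ref, _ = make_reference(20000, seed=3)
        lib = simulate_library(ref, [], tech="perfect", coverage=10, seed=3,
                               read_length=500)
        calls, stats = detect(lib.records(), ref, PROFILES["pacbio-hifi"])
        assert calls == [] and stats["events_scanned"] == 0

    def test_deterministic_bed(self, tmp_path):
        ref, _ = make_reference(30000, seed=9, motif="GTCTC", n_motifs=10)
        from steelseq.simulator import place_nicks

        nicks = place_nicks(ref, motif="GTCTC")
        lib = simulate_library(ref, nicks, tech="pacbio-hifi", coverage=15,
                               seed=9, read_length=1000)
        sam = tmp_path / "lib.sam"
        lib.write_sam(sam)
        beds = []
        for i in (1, 2):
            bed = tmp_path / f"out{i}.bed"
            detect(str(sam), ref, PROFILES["pacbio-hifi"], out_bed=bed)
            beds.append(bed.read_bytes())
        assert beds[0] == beds[1] and beds[0]

    def test_subset_bam_and_log(self, tmp_path):
        ref, _ = make_reference(30000, seed=9, motif="GTCTC", n_motifs=10)
        from steelseq.simulator import place_nicks
        import pysam

        nicks = place_nicks(ref, motif="GTCTC")
        lib = simulate_library(ref, nicks, tech="pacbio-hifi", coverage=15,
                               seed=9, read_length=1000)
        sam = tmp_path / "lib.sam"
        lib.write_sam(sam)
        out_sam, log = tmp_path / "subset.sam", tmp_path / "run.log"
        calls, stats = detect(str(sam), ref, PROFILES["pacbio-hifi"],
                              out_bam=out_sam, log=log)
        with pysam.AlignmentFile(out_sam) as af:
            names = {a.query_name for a in af}
        assert names == {c.read_name for c in calls}
        text = log.read_text()
        assert "usable_reads" in text and "calls_final" in text

    def test_monotone_in_thresholds(self):
        ref, _ = make_reference(30000, seed=9, motif="GTCTC", n_motifs=10)
        from steelseq.simulator import place_nicks

        nicks = place_nicks(ref, motif="GTCTC")
        lib = simulate_library(ref, nicks, tech="pacbio-hifi", coverage=15,
                               seed=9, read_length=1000)
        reads = lib.reads
        counts = []
        for min_mut in (3, 5, 8, 12):
            prof = get_profile("custom", min_mutated_targets=min_mut)
            calls, _ = detect((r.to_record() for r in reads), ref, prof)
            counts.append(len(calls))
        assert counts == sorted(counts, reverse=True)

    def test_soundness_of_calls(self):
        """Every emitted call's source run has all in-between target bases
        mutated and an intact anchor, checked against the raw reference."""
        ref, _ = make_reference(30000, seed=9, motif="GTCTC", n_motifs=10)
        from steelseq.simulator import place_nicks

        nicks = place_nicks(ref, motif="GTCTC")
        lib = simulate_library(ref, nicks, tech="pacbio-hifi", coverage=15,
                               seed=9, read_length=1000)
        calls, _ = detect(lib.records(), ref, PROFILES["pacbio-hifi"])
        assert calls
        seq = ref.sequences["chr1"]
        for c in calls[:500]:
            ev = c.source_event
            lo, hi = ev.first_mut_pos, ev.last_mut_pos
            inside = [p for p in range(lo, hi + 1) if seq[p] == ev.target_base]
            assert inside == ev.mutated_target_positions
            assert seq[ev.anchor_pos] == ev.target_base
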
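"""Aligner correctness, SAM ingestion, and pileup conventions."""

import numpy as np
import pytest

import pyrofrag as pf
from pyrofrag.pileup import (AlignedRead, align_read, build_pileup,
                             from_simulated, read_sam, read_pileup_tsv,
                             write_pileup_tsv)
from pyrofrag.simdata import (apply_ops, decode, encode, ops_read_len,
                              ops_ref_span, revcomp)
from conftest import single_sample_config
from helpers import brute_align_score, sam_from_truth


class TestAlignRead:
    def test_exact_substring_all_match(self):
        ref = "TTTTACGTACGTTTTT"
        aln = align_read("ACGTACGT", ref)
        assert aln.ref_start == 4
        assert aln.ops == ((8, "=", ""),)

    def test_single_mismatch(self):
        aln = align_read("ACGAACGT", "TTTTACGTACGTTTTT")
        assert aln.ref_start == 4
        assert aln.ops == ((3, "=", ""), (1, "X", "A"), (4, "=", ""))

    def test_score_floor_flags_unalignable(self):
        assert align_read("AAAAAAAA", "CCCCCCCCCCCC", score_floor=0) is None

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            align_read("", "ACGT")

    def test_matches_bruteforce_dp_on_random_cases(self):
        rng = np.random.default_rng(41)
        bases = np.array(list("ACGT"))
        for _ in range(120):
            n = int(rng.integers(20, 61))
            m = int(rng.integers(5, 31))
            ref = "".join(rng.choice(bases, n))
            if rng.random() < 0.5:
                s = int(rng.integers(0, max(n - m, 0) + 1))
                read = list(ref[s:s + m])
                for _ in range(int(rng.integers(0, 4))):
                    p = int(rng.integers(0, len(read)))
                    u = rng.random()
                    if u < 0.4:
                        read[p] = str(rng.choice(bases))
                    elif u < 0.7:
                        read.insert(p, str(rng.choice(bases)))
                    elif len(read) > 2:
                        read.pop(p)
                read = "".join(read)
            else:
                read = "".join(rng.choice(bases, m))
            aln = align_read(read, ref)
            assert aln.score == brute_align_score(read, ref)
            # returned ops are a valid alignment of the whole read
            assert ops_read_len(aln.ops) == len(read)
            span = ops_ref_span(aln.ops)
            rebuilt = decode(apply_ops(
                encode(ref[aln.ref_start:aln.ref_start + span]), aln.ops))
            assert rebuilt == read


class TestReadSam:
    def _region(self):
        return pf.ReferenceRegion("r", 0, 40, "ACGTACGTACGTACGTACGT" * 2)

    def _parse(self, tmp_path, body):
        region = self._region()
        sam = tmp_path / "t.sam"
        sam.write_text("@HD\tVN:1.6\n@SQ\tSN:r\tLN:40\n" + body)
        return read_sam(sam, region), region

    def test_matching_m_run_resolves_to_eq(self, tmp_path):
        (aligned, n_unmapped), region = self._parse(
            tmp_path, "r1\t0\tr\t5\t60\t10M\t*\t0\t0\t"
                      + region_seq(4, 14) + "\t*\n")
        assert n_unmapped == 0
        assert aligned[0].ref_start == 4
        assert aligned[0].ops == ((10, "=", ""),)

    def test_deletion_anchored_at_correct_base(self, tmp_path):
        seq = region_seq(4, 8) + region_seq(9, 13)
        (aligned, _), region = self._parse(
            tmp_path, f"r1\t0\tr\t5\t60\t4M1D4M\t*\t0\t0\t{seq}\t*\n")
        ar = aligned[0]
        assert ar.ops == ((4, "=", ""), (1, "D", ""), (4, "=", ""))
        pu = build_pileup([ar], region, normalize_indels=False)
        assert pu.dels[8] == 1 and pu.dels.sum() == 1

    def test_mismatch_resolved_against_reference(self, tmp_path):
        seq = list(region_seq(0, 10))
        seq[3] = "A" if seq[3] != "A" else "C"
        (aligned, _), _ = self._parse(
            tmp_path, f"r1\t0\tr\t1\t60\t10M\t*\t0\t0\t{''.join(seq)}\t*\n")
        ops = aligned[0].ops
        assert ops[0] == (3, "=", "") and ops[1][1] == "X"

    def test_unmapped_record_skipped_and_counted(self, tmp_path):
        (aligned, n_unmapped), _ = self._parse(
            tmp_path, "r1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t*\n")
        assert aligned == [] and n_unmapped == 1

    def test_softclip_consumes_read_only(self, tmp_path):
        seq = "TTT" + region_seq(4, 10)
        (aligned, _), _ = self._parse(
            tmp_path, f"r1\t0\tr\t5\t60\t3S6M\t*\t0\t0\t{seq}\t*\n")
        assert aligned[0].ops == ((6, "=", ""),)


def region_seq(start, end):
    return ("ACGTACGTACGTACGTACGT" * 2)[start:end]


class TestBuildPileup:
    def test_identical_reads_stack_at_one_column(self):
        region = pf.ReferenceRegion("r", 0, 10, "ACGTACGTAC")
        reads = [AlignedRead(f"r{i}", 3, ((1, "=", ""),)) for i in range(30)]
        pu = build_pileup(reads, region)
        col = pu.column(3)
        assert col.depth == 30 and col.base_counts["T"] == 30
        assert pu.depth.sum() == 30

    def test_deletion_counts_at_every_deleted_position(self):
        region = pf.ReferenceRegion("r", 0, 12, "ACGTACGTACGT")
        ar = AlignedRead("r1", 2, ((2, "=", ""), (2, "D", ""), (3, "=", "")))
        pu = build_pileup([ar], region, normalize_indels=False)
        assert pu.dels[4] == 1 and pu.dels[5] == 1
        # deleted bases still contribute to depth
        assert pu.depth[4] == 1 and pu.depth[5] == 1

    def test_insertion_anchors_to_preceding_position_without_depth(self):
        region = pf.ReferenceRegion("r", 0, 12, "ACGTACGTACGT")
        ar = AlignedRead("r1", 2, ((2, "=", ""), (1, "I", "T"), (2, "=", "")))
        pu = build_pileup([ar], region)
        # inserted T abuts the T at position 3: left-normalized anchor is 2
        assert pu.ins[2]["T"] == 1
        assert pu.depth[3] == 1  # insertions do not add depth

    def test_uniform_indels_left_normalize_within_runs(self):
        region = pf.ReferenceRegion("r", 0, 12, "ACAAAAAGTACG")
        d1 = AlignedRead("r1", 0, ((4, "=", ""), (1, "D", ""), (5, "=", "")))
        d2 = AlignedRead("r2", 0, ((6, "=", ""), (1, "D", ""), (3, "=", "")))
        pu = build_pileup([d1, d2], region)
        assert pu.dels[2] == 2  # both shift to the start of the A-run
        i1 = AlignedRead("r3", 0, ((5, "=", ""), (1, "I", "A"), (5, "=", "")))
        i2 = AlignedRead("r4", 0, ((7, "=", ""), (1, "I", "A"), (3, "=", "")))
        pu2 = build_pileup([i1, i2], region)
        assert pu2.ins[1]["A"] == 2  # anchored left of the A-run

    def test_read_outside_region_skipped_and_counted(self):
        region = pf.ReferenceRegion("r", 0, 10, "ACGTACGTAC")
        ar = AlignedRead("r1", 50, ((3, "=", ""),))
        pu = build_pileup([ar], region)
        assert pu.n_skipped == 1 and pu.n_reads == 0

    def test_depth_conservation_over_simulated_run(self, small_panel):
        cfg = single_sample_config(small_panel, molecules_per_amplicon=10,
                                   seed=43, hp_beta=0.03)
        sim = pf.simulate_run(cfg)
        pu = pf.pileup_from_simulated(sim.reads, small_panel.region)
        consumed = sum(ops_ref_span(from_simulated(r).ops) for r in sim.reads)
        assert int(pu.depth.sum()) == consumed


class TestTruthVsAligner:
    def test_error_free_pileups_agree_column_by_column(self):
        region = pf.ReferenceRegion("r", 0, 2000,
                                    pf.synthetic_reference(2000, seed=7))
        panel = pf.AmpliconPanel(region, (pf.Amplicon("A", 0, 2000),))
        cfg = single_sample_config(panel, molecules_per_amplicon=8, seed=5,
                                   sub_rate0=0.0, sub_rate_slope=0.0,
                                   hp_beta=0.0)
        sim = pf.simulate_run(cfg)
        truth_pu = pf.pileup_from_simulated(sim.reads, region)
        aligned = []
        for r in sim.reads:
            fwd = align_read(r.insert_bases, region.sequence)
            rev = align_read(revcomp(r.insert_bases), region.sequence)
            best = fwd if fwd.score >= rev.score else rev
            aligned.append(AlignedRead(r.read_id, best.ref_start, best.ops))
        aln_pu = build_pileup(aligned, region)
        assert (truth_pu.counts == aln_pu.counts).all()
        assert (truth_pu.dels == aln_pu.dels).all()
        assert truth_pu.ins == aln_pu.ins


class TestSamRoundTrip:
    def test_truth_sam_reproduces_truth_pileup(self, small_panel, tmp_path):
        cfg = single_sample_config(small_panel, molecules_per_amplicon=4,
                                   seed=47, hp_beta=0.03)
        sim = pf.simulate_run(cfg)
        sam = tmp_path / "truth.sam"
        sam.write_text(sam_from_truth(sim.reads, small_panel.region))
        aligned, n_unmapped = read_sam(sam, small_panel.region)
        assert n_unmapped == 0
        pu_sam = build_pileup(aligned, small_panel.region)
        pu_truth = pf.pileup_from_simulated(sim.reads, small_panel.region)
        assert (pu_sam.counts == pu_truth.counts).all()
        assert (pu_sam.dels == pu_truth.dels).all()
        assert pu_sam.ins == pu_truth.ins


class TestPileupTsv:
    def test_roundtrip(self, small_panel, tmp_path):
        cfg = single_sample_config(small_panel, molecules_per_amplicon=3,
                                   seed=51, hp_beta=0.05)
        sim = pf.simulate_run(cfg)
        pu = pf.pileup_from_simulated(sim.reads, small_panel.region)
        path = tmp_path / "p.tsv"
        write_pileup_tsv(pu, path)
        back = read_pileup_tsv(path, small_panel.region)
        assert (back.counts == pu.counts).all()
        assert (back.dels == pu.dels).all()
        assert back.ins == pu.ins
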
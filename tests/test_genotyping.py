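"""Homopolymer filtering, genotype calling, pooling, Sanger concordance."""

from collections import Counter

import numpy as np
import pytest

import pyrofrag as pf
from pyrofrag import datasets
from pyrofrag.genotyping import (SangerTruthEntry, call_genotype, call_locus,
                                 concordance, filter_indels,
                                 homopolymer_runs, pool_replicates,
                                 round_half_away)
from pyrofrag.pileup import PileupColumn
from conftest import single_sample_config


def col(pos=0, ref="A", del_count=0, ins=None, **base_counts):
    counts = {b: base_counts.get(b, 0) for b in "ACGTN"}
    return PileupColumn(ref_pos=pos, ref_base=ref, base_counts=counts,
                        del_count=del_count, ins_events=Counter(ins or {}))


class TestHomopolymerRuns:
    @pytest.mark.parametrize("seq,min_len,expected", [
        ("AAAAA", 5, [(0, 5, "A")]),
        ("AAAAATTTTTT", 5, [(0, 5, "A"), (5, 6, "T")]),
        ("ACGT", 5, []),
        ("AATTTTTGG", 4, [(2, 5, "T")]),
    ])
    def test_maximal_runs(self, seq, min_len, expected):
        assert homopolymer_runs(seq, min_len) == expected

    def test_min_len_below_two_rejected(self):
        with pytest.raises(ValueError):
            homopolymer_runs("AAAA", 1)


class TestFilterIndels:
    RUNS = [(10, 6, "A")]  # run covering positions 10..15

    def test_deletions_inside_run_removed_from_calling_view(self):
        c = col(pos=12, del_count=7, A=20)
        f = filter_indels(c, self.RUNS)
        assert f.del_count == 0
        assert f.base_counts == c.base_counts  # base counts untouched

    def test_positions_outside_runs_retained(self):
        c = col(pos=5, del_count=7, A=20)
        assert filter_indels(c, self.RUNS).del_count == 7

    def test_insertion_abutting_run_removed(self):
        # anchor 9 sits immediately left of the run
        c = col(pos=9, A=20, ins={"A": 5})
        assert not filter_indels(c, self.RUNS).ins_events

    def test_filtering_never_adds_alleles(self, small_region):
        pu = pf.Pileup(small_region)
        pu.counts[0, 100] = 30
        pu.dels[100] = 10
        runs = homopolymer_runs(small_region.sequence, 5)
        f = filter_indels(pu, runs)
        assert (f.dels <= pu.dels).all()
        assert sum(len(c) for c in f.ins.values()) <= \
            sum(len(c) for c in pu.ins.values())


class TestCallGenotype:
    def test_even_split_calls_het(self):
        call = call_genotype(col(ref="T", T=384, G=369))  # 51% major
        assert call.alleles == ("T", "G")
        assert call.render() == "T|G"

    def test_pure_column_calls_hom(self):
        call = call_genotype(col(ref="T", T=482))
        assert call.alleles == ("T", "T")
        assert call.major_pct_prefilter == pytest.approx(100.0)

    def test_hom_het_boundary_at_80_percent(self):
        het = call_genotype(col(A=79, G=21))
        hom = call_genotype(col(A=80, G=20))
        assert het.alleles == ("A", "G")
        assert hom.alleles == ("A", "A")

    def test_deletion_allele_rendered_in_brackets(self):
        call = call_genotype(col(ref="A", A=60, del_count=40))
        assert call.alleles == ("A", "-")
        assert call.render() == "A|[]"

    def test_zero_depth_is_no_call(self):
        assert call_genotype(col()).alleles is None

    def test_prefilter_counts_attached_while_call_uses_filtered(self):
        # counts printed before the filter, genotype called after it
        pre = col(pos=12, ref="A", A=70, del_count=30)
        filt = filter_indels(pre, [(10, 6, "A")])
        call = call_genotype(filt, prefilter=pre)
        assert call.alleles == ("A", "A")
        assert call.depth_prefilter == 100
        assert call.major_pct_prefilter == pytest.approx(70.0)
        assert call.filtered_indel


class TestPooling:
    @pytest.mark.parametrize("locus", [
        loc for loc in datasets.VALIDATION_LOCI if loc.consistent])
    def test_replicate_pooling_reproduces_published_row(self, locus):
        depth, pct = pool_replicates(list(zip(locus.depths, locus.major_pct)))
        assert depth == locus.pooled_depth
        assert pct == locus.pooled_major_pct

    def test_single_sample_is_identity(self):
        assert pool_replicates([(44, 59.0)]) == (44, 59)

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(50.5) == 51
        assert round_half_away(50.4) == 50
        assert pool_replicates([(1, 50.0), (1, 51.0)]) == (2, 51)


class TestConcordance:
    def _mini_region(self):
        seq = "ACGTACGTGGTTAAAAAACC"
        return pf.ReferenceRegion("r", 0, len(seq), seq)

    def _pileup(self, region, columns):
        pu = pf.Pileup(region)
        for c in columns:
            for i, b in enumerate("ACGTN"):
                pu.counts[i, c.ref_pos] = c.base_counts.get(b, 0)
            pu.dels[c.ref_pos] = c.del_count
            if c.ins_events:
                pu.ins[c.ref_pos] = Counter(c.ins_events)
        return pu

    def test_matching_calls_are_concordant(self):
        region = self._mini_region()
        truth = [SangerTruthEntry("r", (4,), "A", "het", ("A", "G")),
                 SangerTruthEntry("r", (7,), "T", "hom", ("T",))]
        pu = self._pileup(region, [col(pos=3, ref="A", A=50, G=48),
                                   col(pos=6, ref="T", T=90)])
        records, summary = concordance(truth, {"S1": pu}, region)
        assert all(rec.agreement["S1"] for rec in records)
        assert summary.n_loci_any_discordant == 0

    def test_wrong_zygosity_is_discordant(self):
        region = self._mini_region()
        truth = [SangerTruthEntry("r", (4,), "A", "het", ("A", "G"))]
        pu = self._pileup(region, [col(pos=3, ref="A", A=95, G=5)])
        records, summary = concordance(
            truth, {"S1": pu}, region, methods={"S1": "nebulization"})
        assert records[0].agreement["S1"] is False
        assert summary.discordant_pairs_by_method == {"nebulization": 1}

    def test_zero_coverage_yields_no_call_not_discordance(self):
        region = self._mini_region()
        truth = [SangerTruthEntry("r", (4,), "A", "het", ("A", "G"))]
        records, summary = concordance(truth, {"S1": pf.Pileup(region)}, region)
        assert records[0].agreement["S1"] is None
        assert summary.n_loci_any_discordant == 0

    def test_dinucleotide_locus_compared_jointly(self):
        region = self._mini_region()
        # hom AA truth at positions 13-14 (inside the A-run, 1-based 14-15)
        truth = [SangerTruthEntry("r", (14, 15), "AA", "hom", ("AA",))]
        good = self._pileup(region, [col(pos=13, ref="A", A=90),
                                     col(pos=14, ref="A", A=88)])
        rec, _ = concordance(truth, {"S1": good}, region)
        assert rec[0].agreement["S1"] is True
        assert rec[0].per_sample["S1"].rendered == "AA|AA"
        # second position drops to a deletion-rich call without filtering;
        # with the HP filter active the deletion evidence is discarded
        bad = self._pileup(region, [col(pos=13, ref="A", A=90),
                                    col(pos=14, ref="A", A=60, del_count=40)])
        rec2, _ = concordance(truth, {"S1": bad}, region, hp_min_run=5)
        assert rec2[0].agreement["S1"] is True  # filter removed the indel
        rec3, _ = concordance(truth, {"S1": bad}, region, hp_min_run=8)
        assert rec3[0].agreement["S1"] is False
        assert rec3[0].per_sample["S1"].rendered == "AA|A[]"

    def test_pooled_depth_is_sum_of_replicates(self):
        region = self._mini_region()
        truth = [SangerTruthEntry("r", (4,), "A", "het", ("A", "G"))]
        pus = {f"S{i}": self._pileup(region,
                                     [col(pos=3, ref="A", A=30, G=28)])
               for i in range(3)}
        records, _ = concordance(truth, pus, region)
        assert records[0].pooled.depth == 3 * 58


class TestFilteringDirection:
    def test_filtering_reduces_indel_discordant_calls(self):
        ref = pf.synthetic_reference(4000, seed=21, hp_runs=25, hp_len=(6, 9))
        region = pf.ReferenceRegion("r", 0, 4000, ref)
        panel = pf.AmpliconPanel(region, (pf.Amplicon("A", 0, 4000),))
        cfg = single_sample_config(panel, molecules_per_amplicon=90, seed=3,
                                   hp_beta=0.08)
        pu = pf.pileup_from_simulated(pf.simulate_run(cfg).reads, region)
        runs = homopolymer_runs(ref, 5)
        filt = filter_indels(pu, runs)

        def indel_discordant(p):
            n = 0
            for pos in range(4000):
                call = call_genotype(p.column(pos))
                if call.alleles and set(call.alleles) != {ref[pos]} \
                        and "-" in call.alleles:
                    n += 1
            return n

        before, after = indel_discordant(pu), indel_discordant(filt)
        assert after < before


class TestEndToEndRecovery:
    def test_planted_het_snps_and_hom_background_recovered(self):
        region = pf.ReferenceRegion("r", 0, 4000,
                                    pf.synthetic_reference(4000, seed=33))
        panel = pf.AmpliconPanel(region, (pf.Amplicon("A", 0, 4000),))
        rng = np.random.default_rng(1)
        snp_pos = sorted(int(p) for p in rng.choice(3900, 4, replace=False))
        snps = tuple(
            (p, "A" if region.sequence[p] != "A" else "G") for p in snp_pos)
        mids = tuple(pf.MIDTag(s, b) for s, b in
                     zip(("S1", "S2", "S3"), pf.simdata.DEFAULT_BARCODES))
        cfg = pf.SimulationConfig(
            panel=panel, mids=mids,
            methods={s: pf.NEBULIZATION for s in ("S1", "S2", "S3")},
            molecules_per_amplicon=60, het_snps=snps, seed=77,
            mid_corrupt_prob=0.0)
        sim = pf.simulate_run(cfg)
        pus = {}
        for s in ("S1", "S2", "S3"):
            reads = [r for r in sim.reads if r.sample_id_truth == s]
            pus[s] = pf.pileup_from_simulated(reads, region)

        truth = [SangerTruthEntry("r", (p + 1,), region.sequence[p], "het",
                                  (region.sequence[p], a)) for p, a in snps]
        hom_pos = [p for p in range(50, 3950, 130) if p not in snp_pos]
        truth += [SangerTruthEntry("r", (p + 1,), region.sequence[p], "hom",
                                   (region.sequence[p],)) for p in hom_pos]
        records, summary = concordance(truth, pus, region)
        pooled_ok = sum(rec.pooled_agrees is True for rec in records)
        assert pooled_ok / len(records) >= 0.99
        het_recs = [rec for rec in records if rec.truth.zygosity == "het"]
        assert all(rec.pooled_agrees for rec in het_recs)
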
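"""Mutation characterization: spectrum, ORF annotation, coverage, frequency
and extrapolation arithmetic."""

from __future__ import annotations

import math

import numpy as np
import pytest
from Bio.Seq import Seq

from polymut.align import AlignmentRecord
from polymut.charstats import (alleles_per_unigene, coverage_class_histogram,
                               coverage_depth_summary, depth_class_histogram,
                               extrapolate_effective, longest_orf,
                               mutation_frequency, orf_classify,
                               saturation_curve, spectrum,
                               total_covered_bp,
                               transition_transversion_percent)

RNG = np.random.default_rng(314)


def _rand(n, rng=RNG):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _rec(uid, start, length=64, sample="s1", rid="r"):
    return AlignmentRecord(rid, sample, uid, start, "+", f"{length}=", 0, 60,
                           "A" * length, "I" * length)


class TestSpectrum:
    def test_published_ts_tv_split(self):
        assert transition_transversion_percent(9667, 4245) == (69.5, 30.5)

    def test_single_transition(self):
        df = spectrum([("C", "T")])
        assert df.attrs["transitions_pct"] == 100.0
        assert df.loc["C>T", "count"] == 1

    def test_conservation_and_skip_tally(self):
        snps = [("A", "G")] * 3 + [("G", "C")] * 2
        df = spectrum(snps + [("AT", "A")])
        assert df["count"].sum() == 5 == df.attrs["total"]
        assert df.attrs["skipped"] == 1
        assert df.attrs["transitions"] == 3 and df.attrs["transversions"] == 2

    def test_matches_planted_directed_counts(self, small_truth):
        planted = [(e.ref, e.alt) for e in small_truth.ems_events
                   if e.kind == "snp"]
        df = spectrum(planted)
        for ref, alt in set(planted):
            assert df.loc[f"{ref}>{alt}", "count"] == planted.count((ref, alt))

    def test_percentages_sum_to_100(self, small_truth):
        planted = [(e.ref, e.alt) for e in small_truth.ems_events
                   if e.kind == "snp"]
        df = spectrum(planted)
        assert df["pct_of_total"].sum() == pytest.approx(100.0, abs=0.5)


class TestAllelesPerUnigene:
    def test_published_mean(self):
        events = [(f"u{i % 6961}",) for i in range(13912)]
        assert alleles_per_unigene(events)["mean_per_unigene"] == 2.0

    def test_single_unigene_single_bin(self):
        res = alleles_per_unigene([("u1",)] * 7)
        assert res["n_unigenes"] == 1 and res["bins"]["6-10"]["unigenes"] == 1

    def test_histogram_conserves_totals(self, small_truth):
        events = [(e.unigene,) for e in small_truth.ems_events]
        res = alleles_per_unigene(events)
        assert res["n_events"] == len(events)
        assert sum(b["unigenes"] for b in res["bins"].values()) == \
            res["n_unigenes"]


class TestOrf:
    def test_synonymous_third_position(self):
        # frame 0 is stop-free and longest; GCT -> GCC is Ala -> Ala
        seq = "ATGGCTAAACGTCGCTGGACT"
        orf = longest_orf(seq)
        assert orf.strand == "+" and orf.start == 0
        assert orf_classify(seq, 5, "T", "C", orf) == "synonymous"

    def test_nonsynonymous_met_to_ile(self):
        seq = "ATGGCTAAACGTCGCTGGACT"
        assert orf_classify(seq, 2, "G", "A") == "non-synonymous"

    def test_outside_orf_is_noncoding(self):
        # stops early in frames force the ORF away from the 5' end
        seq = "TAATAGTGA" + "ATGGCAGCTGCAGCAGCTTGA"
        orf = longest_orf(seq)
        assert orf.start >= 9 or orf.strand == "-"

    def test_position_outside_unigene_rejected(self):
        with pytest.raises(ValueError):
            orf_classify("ATG", 7, "A", "G")

    def test_agrees_with_translate_and_compare_oracle(self):
        """Classification equals translating the whole ORF with and without
        the SNP and comparing protein strings."""
        rng = np.random.default_rng(2718)
        n_coding = 0
        for _ in range(400):
            seq = _rand(int(rng.integers(90, 240)), rng)
            pos = int(rng.integers(0, len(seq)))
            ref = seq[pos]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            orf = longest_orf(seq)
            got = orf_classify(seq, pos, ref, alt, orf)
            if pos not in orf:
                assert got == "non-coding"
                continue
            n_coding += 1
            mutated = seq[:pos] + alt + seq[pos + 1:]
            if orf.strand == "+":
                a = seq[orf.start:orf.end]
                b = mutated[orf.start:orf.end]
            else:
                from polymut._seq import revcomp
                a = revcomp(seq)[len(seq) - orf.end:len(seq) - orf.start]
                b = revcomp(mutated)[len(seq) - orf.end:len(seq) - orf.start]
            same = str(Seq(a).translate()) == str(Seq(b).translate())
            assert got == ("synonymous" if same else "non-synonymous")
        assert n_coding > 100

    def test_longest_orf_is_stop_free_and_maximal(self):
        rng = np.random.default_rng(123)
        from polymut._seq import revcomp
        from polymut.charstats import STOPS
        for _ in range(50):
            seq = _rand(int(rng.integers(60, 150)), rng)
            orf = longest_orf(seq)
            s = seq if orf.strand == "+" else revcomp(seq)
            start = orf.start if orf.strand == "+" else len(seq) - orf.end
            length = orf.end - orf.start
            assert length % 3 == 0
            codons = [s[start + i:start + i + 3] for i in range(0, length, 3)]
            assert not set(codons) & STOPS


class TestCoverage:
    def test_percent_covered_simple(self):
        ref = {"u": "A" * 100}
        recs = [_rec("u", 0, 28)]
        summ = coverage_depth_summary(recs, ref, min_depth=1)
        assert summ["u"].percent_covered == 28.0

    def test_unmapped_unigenes_absent(self):
        ref = {"u": "A" * 100, "v": "A" * 100}
        summ = coverage_depth_summary([_rec("u", 0)], ref)
        assert "v" not in summ

    def test_region_math_follows_read_count_rule(self):
        # two disjoint regions: 12 reads and 3 reads; min_depth 10 keeps one
        ref = {"u": "A" * 400}
        recs = sorted([_rec("u", 0, 50, rid=f"a{i}") for i in range(12)] +
                      [_rec("u", 200, 50, rid=f"b{i}") for i in range(3)],
                      key=lambda r: r.start)
        summ = coverage_depth_summary(recs, ref, min_depth=10)
        s = summ["u"]
        assert s.regions == [(0, 50), (200, 250)]
        assert s.reads_per_region == [12, 3]
        assert s.average_depth == 12.0  # 12 reads / 1 retained region
        assert s.percent_covered == 25.0

    def test_summaries_match_per_base_recount(self, small_alignments,
                                              small_reference):
        pooled = sorted((r for recs in small_alignments.values() for r in recs),
                        key=lambda r: (r.unigene, r.start))
        summ = coverage_depth_summary(pooled, small_reference)
        for uid, s in list(summ.items())[:10]:
            mask = np.zeros(len(small_reference[uid]), dtype=bool)
            n_reads = 0
            for r in pooled:
                if r.unigene == uid:
                    mask[r.start:r.start + r.ref_span()] = True
                    n_reads += 1
            pct = math.floor(100.0 * mask.sum() / len(mask) * 10 + 0.5) / 10
            assert s.percent_covered == pct
            assert sum(b - a for a, b in s.regions) == mask.sum()
            assert sum(s.reads_per_region) == n_reads

    def test_histograms_cover_all_unigenes(self, small_alignments,
                                           small_reference):
        pooled = sorted((r for recs in small_alignments.values() for r in recs),
                        key=lambda r: (r.unigene, r.start))
        summ = coverage_depth_summary(pooled, small_reference)
        assert sum(coverage_class_histogram(summ).values()) == len(summ)
        assert sum(depth_class_histogram(summ).values()) == len(summ)


class TestSaturation:
    def test_duplicate_samples_plateau_immediately(self):
        ref = {"u": "A" * 200, "v": "A" * 200}
        recs = [_rec("u", 0), _rec("v", 10)]
        df = saturation_curve({"a": recs, "b": list(recs)}, ref)
        assert list(df["unique_unigenes"]) == [2, 2]

    def test_disjoint_samples_are_additive(self):
        ref = {f"u{i}": "A" * 200 for i in range(4)}
        per = {"a": [_rec("u0", 0)], "b": [_rec("u1", 0), _rec("u2", 0)],
               "c": [_rec("u3", 0)]}
        df = saturation_curve(per, ref)
        assert list(df["unique_unigenes"]) == [1, 2, 4]
        assert df["unique_unigenes"].is_monotonic_increasing

    def test_orders_by_mapped_read_count(self, small_alignments,
                                         small_reference):
        df = saturation_curve(small_alignments, small_reference)
        assert df["mapped_reads_added"].is_monotonic_increasing
        assert df["unique_unigenes"].is_monotonic_increasing

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            saturation_curve({"a": []}, {})


class TestFrequencyAndExtrapolation:
    def test_published_mutation_frequencies(self):
        assert mutation_frequency(72_558_853, 14_130) == 5.1
        assert mutation_frequency(72_558_853, 28_348) == 2.6
        assert mutation_frequency(1000, 1) == 1.0

    def test_zero_mutations_flagged_infinite(self):
        assert mutation_frequency(1000, 0) == math.inf

    def test_published_extrapolation_chain(self):
        res = extrapolate_effective(13_912, 0.63, 0.0133, 0.28,
                                    79_123, 178_494)
        assert res == {"effective": 8_648, "full_coverage": 30_885,
                       "genome_wide": 69_675}

    def test_identity_when_fractions_are_one(self):
        res = extrapolate_effective(1000, 1.0, 0.0, 1.0, 10, 10)
        assert res == {"effective": 1000, "full_coverage": 1000,
                       "genome_wide": 1000}

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            extrapolate_effective(10, 0.5, 0.0, 0.0, 1, 1)
        with pytest.raises(ValueError):
            mutation_frequency(0, 5)

    def test_covered_bp_equals_region_sum(self, small_alignments,
                                          small_reference):
        pooled = sorted((r for recs in small_alignments.values() for r in recs),
                        key=lambda r: (r.unigene, r.start))
        summ = coverage_depth_summary(pooled, small_reference)
        brute = 0
        for uid, s in summ.items():
            mask = np.zeros(len(small_reference[uid]), dtype=bool)
            for r in pooled:
                if r.unigene == uid:
                    mask[r.start:r.start + r.ref_span()] = True
            brute += int(mask.sum())
        assert total_covered_bp(summ) == brute
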
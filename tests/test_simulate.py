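"""Generator correctness: planted variation, digestion, determinism."""

from __future__ import annotations

import math

import numpy as np
import pytest

from polymut._seq import revcomp
from polymut.simulate import (DEFAULT_BARCODES, SimConfig, SimulationError,
                              digest_and_sequence, find_cut_sites,
                              fragments_between_sites, plant_ems,
                              simulate_experiment, simulate_reference)


def _ref(cfg, seed_offset=0):
    return simulate_reference(cfg, np.random.default_rng(cfg.seed + seed_offset))


class TestReference:
    def test_zero_rates_give_identical_copies(self):
        cfg = SimConfig(n_unigenes=10, homoeolog_divergence=0.0,
                        intervarietal_rate=0.0, seed=3)
        ref = _ref(cfg)
        for uid, useq in ref.unigenes.items():
            assert ref.copies[uid] == [useq, useq, useq]
        assert ref.truth.homoeo_sites == []
        assert ref.truth.intervarietal_sites == []

    def test_pairwise_copy_divergence_matches_config(self):
        d = 0.01
        cfg = SimConfig(n_unigenes=50, unigene_len_range=(300, 900),
                        homoeolog_divergence=d, intervarietal_rate=0.0, seed=5)
        ref = _ref(cfg)
        mismatches = total = 0
        for uid in ref.unigenes:
            a, b, c = ref.copies[uid]
            for x, y in ((a, b), (a, c), (b, c)):
                mismatches += sum(1 for p, q in zip(x, y) if p != q)
                total += len(x)
        f = mismatches / total
        sd = math.sqrt(d * (1 - d) / total)
        assert abs(f - d) <= 3 * sd

    def test_every_planted_site_is_on_exactly_one_copy(self):
        ref = _ref(SimConfig(n_unigenes=20, seed=11))
        for s in ref.truth.homoeo_sites:
            hits = [c for c in range(3)
                    if ref.copies[s.unigene][c][s.pos] == s.alt]
            assert hits == list(s.copies)
            assert ref.unigenes[s.unigene][s.pos] == s.ref
        for s in ref.truth.intervarietal_sites:
            assert all(ref.copies[s.unigene][c][s.pos] == s.alt
                       for c in range(3))

    def test_degenerate_config_rejected(self):
        with pytest.raises(SimulationError):
            SimConfig(unigene_len_range=(0, 0)).validate()
        with pytest.raises(SimulationError):
            SimConfig(homoeolog_divergence=1.5).validate()
        with pytest.raises(SimulationError):
            SimConfig(trim_len=101, read_len=100).validate()


class TestEms:
    def test_zero_load_leaves_copies_untouched(self, tmp_path):
        cfg = SimConfig(n_unigenes=8, ems_snps_per_plant=0,
                        ems_indels_per_plant=0, junk_fraction=0.0,
                        base_error_rate=0.0, n_mutant_plants=2,
                        n_wildtype_plants=0, seed=9)
        res = simulate_experiment(cfg, tmp_path / "sim")
        assert res.truth.ems_events == []
        # every read is then a clean substring of an unmutated copy
        copies = {(u, c): res.reference.copies[u][c]
                  for u in res.reference.unigenes for c in range(3)}
        with open(res.paths["fastq"]) as fh:
            lines = fh.read().splitlines()
        for i in range(0, len(lines), 4):
            rid, seq = lines[i][1:], lines[i + 1]
            uid, sample, ch, frag, orient, _n = rid.split("|")
            bc = res.barcodes[sample]
            core = seq[len(bc):]
            copy = copies[(uid, int(ch[1]))]
            assert core in copy or core in revcomp(copy)

    def test_pure_gc_to_at_spectrum(self):
        cfg = SimConfig(n_unigenes=40, ems_gc_to_at_fraction=1.0,
                        ems_snps_per_plant=50, ems_indels_per_plant=0,
                        n_mutant_plants=4, seed=13)
        ref = _ref(cfg)
        events = plant_ems(ref, cfg, np.random.default_rng(1))
        assert len(events) == 200
        assert all((e.ref, e.alt) in {("G", "A"), ("C", "T")} for e in events)

    def test_gc_to_at_fraction_recovered(self):
        frac = 0.43
        cfg = SimConfig(n_unigenes=150, ems_gc_to_at_fraction=frac,
                        ems_snps_per_plant=300, ems_indels_per_plant=0,
                        n_mutant_plants=4, seed=17)
        ref = _ref(cfg)
        events = plant_ems(ref, cfg, np.random.default_rng(2))
        n = len(events)
        got = sum(1 for e in events
                  if (e.ref, e.alt) in {("G", "A"), ("C", "T")}) / n
        assert abs(got - frac) <= 3 * math.sqrt(frac * (1 - frac) / n)

    def test_indel_size_ranges(self):
        cfg = SimConfig(n_unigenes=60, ems_snps_per_plant=0,
                        ems_indels_per_plant=40, n_mutant_plants=3, seed=19)
        ref = _ref(cfg)
        events = plant_ems(ref, cfg, np.random.default_rng(3))
        dels = [len(e.ref) - 1 for e in events if e.kind == "del"]
        inss = [len(e.alt) - 1 for e in events if e.kind == "ins"]
        assert dels and inss
        assert set(dels) <= {1, 2, 3}
        assert set(inss) <= {1, 2, 3, 4}

    def test_no_event_class_collisions(self, small_truth):
        seen = {}
        for s in small_truth.homoeo_sites:
            seen[(s.unigene, s.pos)] = "homoeo"
        for s in small_truth.intervarietal_sites:
            assert (s.unigene, s.pos) not in seen
            seen[(s.unigene, s.pos)] = "inter"
        ems_keys = set()
        for e in small_truth.ems_events:
            span = range(e.pos, e.pos + len(e.ref))
            for p in span:
                assert (e.unigene, p) not in seen
            key = (e.unigene, e.pos)
            assert key not in ems_keys, "EMS events must be plant-unique"
            ems_keys.add(key)

    def test_overfull_request_raises(self):
        cfg = SimConfig(n_unigenes=2, unigene_len_range=(200, 200),
                        ems_snps_per_plant=500, n_mutant_plants=2, seed=23)
        ref = _ref(cfg)
        with pytest.raises(SimulationError, match="eligible positions"):
            plant_ems(ref, cfg, np.random.default_rng(4))


class TestDigest:
    def test_fragments_are_remnant_delimited(self):
        seq = "A" * 40 + "GCAGC" + "T" * 70 + "GCTGC" + "A" * 40
        frags = fragments_between_sites(seq)
        assert frags == [(41, 119)]
        frag = seq[41:119]
        assert frag.startswith("CAGC")
        assert revcomp(frag)[:4] == "CAGC"  # filled-in remnant on the other end

    def test_unigene_without_cut_sites_yields_no_reads(self):
        cfg = SimConfig(n_unigenes=1, unigene_len_range=(140, 140),
                        ems_snps_per_plant=0, ems_indels_per_plant=0,
                        n_mutant_plants=1, n_wildtype_plants=0,
                        junk_fraction=0.0, seed=29)
        ref = _ref(cfg)
        assert all(len(find_cut_sites(s)) <= 1 for s in ref.unigenes.values())
        events = plant_ems(ref, cfg, np.random.default_rng(5))
        reads = digest_and_sequence(ref, events, {"mut01": "CTCC"}, cfg,
                                    np.random.default_rng(6))
        assert reads == []

    def test_empty_barcode_table_rejected(self):
        cfg = SimConfig(n_unigenes=2, ems_snps_per_plant=0,
                        ems_indels_per_plant=0, seed=31)
        ref = _ref(cfg)
        with pytest.raises(SimulationError, match="barcode"):
            digest_and_sequence(ref, [], {}, cfg)

    def test_total_reads_follow_poisson_sum(self):
        # ~one fragment per unigene, single plant: total ~ Poisson(20 x n)
        cfg = SimConfig(n_unigenes=200, unigene_len_range=(250, 250),
                        ems_snps_per_plant=0, ems_indels_per_plant=0,
                        n_mutant_plants=1, n_wildtype_plants=0,
                        junk_fraction=0.0, mean_depth_per_fragment=20.0,
                        homoeolog_divergence=0.0, intervarietal_rate=0.0,
                        seed=37)
        ref = _ref(cfg)
        n_frags = len(ref.truth.fragment_map)
        assert n_frags > 0
        reads = digest_and_sequence(ref, [], {"mut01": "CTCC"}, cfg,
                                    np.random.default_rng(8))
        lam = 20.0 * n_frags
        assert abs(len(reads) - lam) <= 3 * math.sqrt(lam)

    def test_error_free_reads_are_chromatid_substrings(self, tmp_path):
        cfg = SimConfig(n_unigenes=10, base_error_rate=0.0, junk_fraction=0.0,
                        n_mutant_plants=2, n_wildtype_plants=1,
                        ems_snps_per_plant=10, ems_indels_per_plant=2, seed=41)
        res = simulate_experiment(cfg, tmp_path / "sim")
        from polymut.simulate import _apply_events
        with open(res.paths["fastq"]) as fh:
            lines = fh.read().splitlines()
        checked = 0
        for i in range(0, len(lines), 4):
            rid, seq = lines[i][1:], lines[i + 1]
            uid, sample, ch, frag, orient, _n = rid.split("|")
            copy, hap = int(ch[1]), int(ch[3])
            evs = [e for e in res.truth.ems_events
                   if (e.plant, e.unigene, e.copy) == (sample, uid, copy)
                   and (e.zygosity == "hom" or e.chromatid == hap)]
            chromatid = _apply_events(res.reference.copies[uid][copy], evs)
            # first trim_len bases are pure fragment (size selection keeps
            # fragments >= 64 bp); beyond that the raw read may run into
            # the common adapter
            core = seq[len(res.barcodes[sample]):][:cfg.trim_len]
            assert core in chromatid or core in revcomp(chromatid)
            checked += 1
        assert checked > 100


class TestDeterminism:
    def test_same_seed_same_bytes(self, tmp_path):
        cfg = SimConfig(n_unigenes=12, seed=43)
        r1 = simulate_experiment(cfg, tmp_path / "a")
        r2 = simulate_experiment(cfg, tmp_path / "b")
        for key in ("reference", "fastq", "truth_homoeo", "truth_ems",
                    "truth_fragments", "barcodes"):
            assert r1.paths[key].read_bytes() == r2.paths[key].read_bytes()

    def test_barcodes_prefix_free(self):
        for a in DEFAULT_BARCODES:
            for b in DEFAULT_BARCODES:
                assert a == b or not b.startswith(a)
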
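"""Synthetic hexaploid GBS experiment with known ground truth.

Emulates the study design this pipeline targets: a set of unigenes (the
reference transcriptome), three homoeologous genome copies per unigene
diverged from that reference, intervarietal substitutions shared by every
plant, per-plant EMS point mutations and small INDELs with a GC->AT-biased
spectrum, ApeKI (GCWGC) digestion, barcoded single-end reads with the CWGC
cut-site remnant, per-base errors, and a configurable admixture of junk
reads. Every planted feature is recorded in a :class:`GroundTruth` so each
downstream stage can be validated against known answers.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._seq import COMMON_ADAPTER, left_align_indel, phred_char, revcomp

_SITE_RE = re.compile(r"(?=GC[AT]GC)")
BASES = "ACGT"

#: 24 prefix-free GBS barcodes, 4-8 bp, one per multiplexed plant.
DEFAULT_BARCODES = [
    "CTCC", "TGCA", "ACTA", "CAGA", "AACT", "GCGT", "CGAT", "GTAA",
    "AGGC", "GATC", "TCAC", "CCAG",
    "TTGAC", "AGCCC", "GTATT", "CTGTA",
    "ACCGTA", "TAGGAA", "GCTCTA", "ATTGGC",
    "GAACTTC", "CCTTGAC",
    "TTCAGGAC", "AAGGTACG",
]


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Generator settings; defaults define the bundled validation conditions."""

    n_unigenes: int = 200
    unigene_len_range: tuple[int, int] = (300, 900)
    homoeolog_divergence: float = 0.01
    intervarietal_rate: float = 0.0005
    n_mutant_plants: int = 5
    n_wildtype_plants: int = 2
    ems_snps_per_plant: int = 40
    ems_indels_per_plant: int = 5
    ems_gc_to_at_fraction: float = 0.43
    ems_het_fraction: float = 0.89
    read_len: int = 100
    trim_len: int = 64
    mean_depth_per_fragment: float = 20.0
    base_error_rate: float = 0.001
    junk_fraction: float = 0.05
    cut_site_spacing: int = 150
    min_fragment_len: int = 64  # library size selection; keeps adapter out of the trimmed read
    seed: int = 42

    def validate(self) -> None:
        for name in ("homoeolog_divergence", "intervarietal_rate",
                     "ems_gc_to_at_fraction", "ems_het_fraction",
                     "base_error_rate", "junk_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0, 1]")
        if self.n_unigenes < 1:
            raise SimulationError("n_unigenes must be >= 1")
        lo, hi = self.unigene_len_range
        if lo <= 0 or hi < lo:
            raise SimulationError(f"degenerate unigene_len_range {self.unigene_len_range}")
        if self.trim_len > self.read_len:
            raise SimulationError("trim_len must be <= read_len")
        if self.n_mutant_plants + self.n_wildtype_plants < 1:
            raise SimulationError("at least one plant required")
        if self.mean_depth_per_fragment < 0:
            raise SimulationError("mean_depth_per_fragment must be >= 0")


@dataclass
class HomoeoSite:
    unigene: str
    pos: int
    ref: str
    alt: str
    copies: tuple[int, ...]  # which of the 3 homoeologous copies carry alt


@dataclass
class EmsEvent:
    plant: str
    unigene: str
    pos: int          # 0-based position on the reference unigene (left-aligned)
    ref: str
    alt: str
    zygosity: str     # 'het' (one chromatid) or 'hom' (both)
    copy: int         # homoeologous copy 0..2 carrying the event
    chromatid: int    # chromatid mutated for het events
    kind: str         # 'snp' | 'ins' | 'del'


@dataclass
class GroundTruth:
    homoeo_sites: list[HomoeoSite] = field(default_factory=list)
    intervarietal_sites: list[HomoeoSite] = field(default_factory=list)
    ems_events: list[EmsEvent] = field(default_factory=list)
    fragment_map: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass
class Reference:
    unigenes: dict[str, str]
    copies: dict[str, list[str]]
    truth: GroundTruth
    free_positions: dict[str, list[int]]  # positions still open for EMS planting


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def find_cut_sites(seq: str) -> list[int]:
    """0-based starts of every GCWGC occurrence (overlaps included)."""
    return [m.start() for m in _SITE_RE.finditer(seq)]


def fragments_between_sites(seq: str, min_len: int = 0) -> list[tuple[int, int]]:
    """Digestion intervals [a, b) between consecutive GCWGC sites.

    The cut falls between the leading G and the CWGC remnant, and the 3-base
    5' overhangs are filled in, so a fragment runs from site1+1 through
    site2+4: it starts with CWGC and its reverse complement also starts with
    a CWGC-pattern remnant. Fragments shorter than ``min_len`` are dropped,
    emulating library size selection.
    """
    sites = find_cut_sites(seq)
    return [(p + 1, q + 4) for p, q in zip(sites, sites[1:])
            if q + 4 - (p + 1) >= min_len]


def simulate_reference(config: SimConfig, rng: np.random.Generator | None = None,
                       ) -> Reference:
    """Draw the unigene set, its three homoeologous copies, and the shared
    (homoeologous + intervarietal) variant sites.

    ApeKI sites are written into each unigene at ``cut_site_spacing`` so that
    every unigene yields restriction fragments at desk scale; variant sites
    never land inside a cut-site footprint, so the planted fragment layout is
    shared by all copies.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.unigene_len_range
    truth = GroundTruth()
    unigenes: dict[str, str] = {}
    copies: dict[str, list[str]] = {}
    free: dict[str, list[int]] = {}
    width = max(5, len(str(config.n_unigenes)))
    # pairwise copy divergence d: each site sits on exactly one of the three
    # copies, so a random position differs between two given copies iff it is
    # a planted site on either (2/3 of sites) -> plant sites at rate 1.5 d
    site_rate = min(1.0, 1.5 * config.homoeolog_divergence)
    for i in range(config.n_unigenes):
        uid = f"Ta.{i + 1:0{width}d}"
        n = int(rng.integers(lo, hi + 1))
        seq = list(_random_seq(rng, n))
        for p in range(30, n - 35, config.cut_site_spacing):
            w = "A" if rng.random() < 0.5 else "T"
            seq[p:p + 5] = ["G", "C", w, "G", "C"]
        useq = "".join(seq)
        unigenes[uid] = useq
        forbidden = set()
        for p in find_cut_sites(useq):
            forbidden.update(range(p, p + 5))
        eligible = np.array([p for p in range(n) if p not in forbidden])
        rng.shuffle(eligible)
        n_homoeo = rng.binomial(len(eligible), site_rate)
        n_inter = rng.binomial(len(eligible) - n_homoeo, config.intervarietal_rate)
        cseqs = [list(useq) for _ in range(3)]
        for p in eligible[:n_homoeo]:
            p = int(p)
            ref = useq[p]
            alt = _other_base(rng, ref)
            c = int(rng.integers(0, 3))
            cseqs[c][p] = alt
            truth.homoeo_sites.append(HomoeoSite(uid, p, ref, alt, (c,)))
        for p in eligible[n_homoeo:n_homoeo + n_inter]:
            p = int(p)
            ref = useq[p]
            alt = _other_base(rng, ref)
            for c in range(3):
                cseqs[c][p] = alt
            truth.intervarietal_sites.append(HomoeoSite(uid, p, ref, alt, (0, 1, 2)))
        copies[uid] = ["".join(c) for c in cseqs]
        free[uid] = [int(p) for p in eligible[n_homoeo + n_inter:]]
        for a, b in fragments_between_sites(useq, config.min_fragment_len):
            truth.fragment_map.append((uid, a, b))
    truth.homoeo_sites.sort(key=lambda s: (s.unigene, s.pos))
    truth.intervarietal_sites.sort(key=lambda s: (s.unigene, s.pos))
    return Reference(unigenes, copies, truth, free)


def _other_base(rng: np.random.Generator, ref: str) -> str:
    choices = [b for b in BASES if b != ref]
    return choices[int(rng.integers(0, 3))]


def plant_ems(reference: Reference, config: SimConfig,
              rng: np.random.Generator | None = None) -> list[EmsEvent]:
    """Assign per-plant EMS SNPs and INDELs on the simulated copies.

    Each mutant plant receives exactly ``ems_snps_per_plant`` SNPs and
    ``ems_indels_per_plant`` INDELs (1-3 bp deletions, 1-4 bp insertions);
    a fraction ``ems_gc_to_at_fraction`` of the SNPs are G->A or C->T.
    Heterozygous events sit on one of the two chromatids of one homoeologous
    copy; homozygous events on both. Events never collide with homoeologous
    or intervarietal sites, cut sites, or each other, and each belongs to a
    single plant. Wild-type plants receive nothing.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    pool: list[tuple[str, int]] = [
        (uid, p) for uid in sorted(reference.free_positions)
        for p in reference.free_positions[uid]
    ]
    order = rng.permutation(len(pool))
    pool = [pool[i] for i in order]
    # positions already holding homoeologous/intervarietal sites or cut-site
    # bases: indel footprints (after left-alignment) may never touch them
    occupied: dict[str, set[int]] = {}
    for uid, useq in reference.unigenes.items():
        occupied[uid] = set(range(len(useq))) - set(reference.free_positions[uid])
    blocked: dict[str, set[int]] = {uid: set() for uid in reference.unigenes}
    events: list[EmsEvent] = []
    cursor = 0

    def take(candidate, footprint: int):
        """Scan the shuffled pool for a position whose event is admissible.

        ``candidate(uid, p)`` returns the event footprint interval
        (start, end) on the reference — possibly shifted left of p by indel
        normalization — or None to reject. The footprint must not touch
        other planted variation.
        """
        nonlocal cursor
        i = cursor
        while i < len(pool):
            uid, p = pool[i]
            if all(q not in blocked[uid] for q in range(p - 6, p + footprint + 6)):
                span = candidate(uid, p)
                if span is not None:
                    a, b = span
                    guard = range(a - 6, b + 6)
                    if (all(q not in blocked[uid] for q in guard) and
                            all(q not in occupied[uid] for q in range(a, b))):
                        pool[i], pool[cursor] = pool[cursor], pool[i]
                        cursor += 1
                        blocked[uid].update(guard)
                        return uid, p
            i += 1
        raise SimulationError(
            "requested mutation count exceeds available eligible positions")

    plants = [f"mut{i + 1:02d}" for i in range(config.n_mutant_plants)]
    for plant in plants:
        for _ in range(config.ems_snps_per_plant):
            gc2at = rng.random() < config.ems_gc_to_at_fraction
            if gc2at:
                uid, p = take(
                    lambda u, q: (q, q + 1)
                    if reference.unigenes[u][q] in "GC" else None, 1)
                ref = reference.unigenes[uid][p]
                alt = "A" if ref == "G" else "T"
            else:
                uid, p = take(lambda u, q: (q, q + 1), 1)
                ref = reference.unigenes[uid][p]
                # keep the planted spectrum exact: non-spectrum draws never
                # produce the G->A / C->T pairing
                choices = [b for b in BASES if b != ref]
                if ref == "G":
                    choices.remove("A")
                if ref == "C":
                    choices.remove("T")
                alt = choices[int(rng.integers(0, len(choices)))]
            events.append(_zygosed(rng, plant, uid, p, ref, alt, "snp", config))
        for _ in range(config.ems_indels_per_plant):
            is_del = rng.random() < 0.64  # deletions predominate in EMS lines
            picked: dict[tuple[str, int], tuple[int, str, str]] = {}
            if is_del:
                dlen = int(rng.integers(1, 4))

                def cand_del(u, q, L=dlen, picked=picked):
                    useq = reference.unigenes[u]
                    if q + 1 + L > len(useq):
                        return None
                    a, r, alt_ = left_align_indel(useq, q, useq[q:q + 1 + L],
                                                  useq[q])
                    picked[(u, q)] = (a, r, alt_)
                    return a, a + len(r)

                uid, p = take(cand_del, 1 + dlen)
                kind = "del"
            else:
                ilen = int(rng.integers(1, 5))
                ins = _random_seq(rng, ilen)

                def cand_ins(u, q, ins=ins, picked=picked):
                    useq = reference.unigenes[u]
                    a, r, alt_ = left_align_indel(useq, q, useq[q],
                                                  useq[q] + ins)
                    picked[(u, q)] = (a, r, alt_)
                    return a, a + 1

                uid, p = take(cand_ins, 1)
                kind = "ins"
            p, ref, alt = picked[(uid, p)]
            events.append(_zygosed(rng, plant, uid, p, ref, alt, kind, config))
    events.sort(key=lambda e: (e.plant, e.unigene, e.pos))
    reference.truth.ems_events = events
    return events


def _zygosed(rng, plant, uid, pos, ref, alt, kind, config) -> EmsEvent:
    het = rng.random() < config.ems_het_fraction
    copy = int(rng.integers(0, 3))
    chromatid = int(rng.integers(0, 2)) if het else 0
    return EmsEvent(plant, uid, pos, ref, alt, "het" if het else "hom",
                    copy, chromatid, kind)


def _apply_events(seq: str, evs: list[EmsEvent]) -> str:
    s = seq
    for e in sorted(evs, key=lambda e: -e.pos):
        if e.kind == "snp":
            s = s[:e.pos] + e.alt + s[e.pos + 1:]
        elif e.kind == "del":
            s = s[:e.pos + 1] + s[e.pos + len(e.ref):]
        else:
            s = s[:e.pos + 1] + e.alt[1:] + s[e.pos + 1:]
    return s


def plant_names(config: SimConfig) -> tuple[list[str], list[str]]:
    mutants = [f"mut{i + 1:02d}" for i in range(config.n_mutant_plants)]
    wildtypes = [f"wt{i + 1:02d}" for i in range(config.n_wildtype_plants)]
    return mutants, wildtypes


def digest_and_sequence(reference: Reference, events: list[EmsEvent],
                        barcodes: dict[str, str], config: SimConfig,
                        rng: np.random.Generator | None = None,
                        ) -> list[tuple[str, str, str]]:
    """ApeKI-digest every chromatid and emit barcoded single-end reads.

    Each fragment locus of a plant receives a Poisson(mean_depth_per_fragment)
    read count, split as independent Poissons over the 3 copies x 2
    chromatids x 2 read orientations. A read is barcode + CWGC-led fragment
    prefix, padded with common-adapter sequence or truncated to ``read_len``.
    Sequencing errors are substitutions at ``base_error_rate`` anywhere in
    the read (barcode included), with low quality symbols; correct bases are
    Q40. ``junk_fraction`` of the output is unassignable reads exercising
    the read-preparation filters.
    """
    if not barcodes:
        raise SimulationError("empty barcode table")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    lam = config.mean_depth_per_fragment / 12.0
    reads: list[tuple[str, str, str]] = []
    ev_by_key: dict[tuple[str, str, int, int], list[EmsEvent]] = {}
    for e in events:
        ev_by_key.setdefault((e.plant, e.unigene, e.copy, 0), [])
        for ch in range(2):
            if e.zygosity == "hom" or e.chromatid == ch:
                ev_by_key.setdefault((e.plant, e.unigene, e.copy, ch), []).append(e)
    for sample in sorted(barcodes):
        bc = barcodes[sample]
        core_len = config.read_len - len(bc)
        for uid in sorted(reference.unigenes):
            for copy in range(3):
                for ch in range(2):
                    evs = ev_by_key.get((sample, uid, copy, ch), [])
                    seq = _apply_events(reference.copies[uid][copy], evs)
                    for a, b in fragments_between_sites(seq, config.min_fragment_len):
                        frag = seq[a:b]
                        for orient, core_full in (("F", frag), ("R", revcomp(frag))):
                            for i in range(rng.poisson(lam)):
                                core = core_full[:core_len]
                                if len(core) < core_len:
                                    pad = (COMMON_ADAPTER * 4)[:core_len - len(core)]
                                    core += pad
                                rid = (f"{uid}|{sample}|c{copy}h{ch}|"
                                       f"f{a}-{b}|{orient}|{i}")
                                reads.append(_seq_with_errors(rng, rid, bc + core, config))
    n_real = len(reads)
    n_junk = int(round(config.junk_fraction / (1.0 - config.junk_fraction) * n_real)) \
        if config.junk_fraction < 1.0 else 0
    reads.extend(_junk_reads(rng, n_junk, barcodes, config))
    order = rng.permutation(len(reads))
    return [reads[i] for i in order]


def _seq_with_errors(rng, rid, seq, config) -> tuple[str, str, str]:
    qual = ["I"] * len(seq)  # Q40
    if config.base_error_rate > 0:
        err = np.flatnonzero(rng.random(len(seq)) < config.base_error_rate)
        if len(err):
            s = list(seq)
            for p in err:
                s[p] = _other_base(rng, s[p])
                qual[p] = phred_char(int(rng.integers(2, 16)))
            seq = "".join(s)
    return rid, seq, "".join(qual)


def _junk_reads(rng, n, barcodes, config) -> list[tuple[str, str, str]]:
    out = []
    bclist = sorted(barcodes.values())
    kinds = ["no_barcode", "no_barcode", "no_remnant", "no_remnant",
             "with_N", "dimer"]
    for i in range(n):
        kind = kinds[int(rng.integers(0, len(kinds)))]
        bc = bclist[int(rng.integers(0, len(bclist)))]
        w = "A" if rng.random() < 0.5 else "T"
        if kind == "no_barcode":
            while True:
                seq = _random_seq(rng, config.read_len)
                if not any(seq.startswith(b) and seq[len(b):len(b) + 4] ==
                           f"C{x}GC" for b in bclist for x in "AT"):
                    break
            qual = "I" * len(seq)
        elif kind == "no_remnant":
            seq = bc + "CCGC" + _random_seq(rng, config.read_len - len(bc) - 4)
            qual = "I" * len(seq)
        elif kind == "with_N":
            body = list(_random_seq(rng, config.read_len - len(bc) - 4))
            npos = int(rng.integers(0, min(len(body), 72 - len(bc) - 4)))
            body[npos] = "N"
            seq = bc + f"C{w}GC" + "".join(body)
            qual = "I" * len(seq)
            qual = qual[:len(bc) + 4 + npos] + "#" + qual[len(bc) + 5 + npos:]
        else:  # adapter dimer read-through
            seq = (bc + f"C{w}GC" + COMMON_ADAPTER * 4)[:config.read_len]
            qual = "I" * len(seq)
        out.append((f"junk|{kind}|{i}", seq, qual))
    return out


# ---------------------------------------------------------------------------
# file-level interface

@dataclass
class SimResult:
    config: SimConfig
    reference: Reference
    truth: GroundTruth
    barcodes: dict[str, str]
    roles: dict[str, str]
    paths: dict[str, Path]


def simulate_experiment(config: SimConfig, outdir: str | Path) -> SimResult:
    """Run the full generator and write FASTA/FASTQ/TSV/YAML artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    reference = simulate_reference(config, rng)
    events = plant_ems(reference, config, rng)
    mutants, wildtypes = plant_names(config)
    samples = mutants + wildtypes
    if len(samples) > len(DEFAULT_BARCODES):
        raise SimulationError(f"at most {len(DEFAULT_BARCODES)} plants supported")
    barcodes = {s: DEFAULT_BARCODES[i] for i, s in enumerate(samples)}
    roles = {s: ("mutant" if s in mutants else "wildtype") for s in samples}
    reads = digest_and_sequence(reference, events, barcodes, config, rng)

    paths = {
        "reference": outdir / "reference.fa",
        "fastq": outdir / "reads.fastq",
        "barcodes": outdir / "barcodes.tsv",
        "roles": outdir / "roles.tsv",
        "truth_homoeo": outdir / "truth_homoeologous.tsv",
        "truth_intervarietal": outdir / "truth_intervarietal.tsv",
        "truth_ems": outdir / "truth_ems.tsv",
        "truth_fragments": outdir / "truth_fragments.tsv",
        "config": outdir / "sim_config.yaml",
    }
    with open(paths["reference"], "w") as fh:
        for uid in sorted(reference.unigenes):
            fh.write(f">{uid}\n{reference.unigenes[uid]}\n")
    with open(paths["fastq"], "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    with open(paths["barcodes"], "w") as fh:
        fh.write("sample\tbarcode\n")
        for s in samples:
            fh.write(f"{s}\t{barcodes[s]}\n")
    with open(paths["roles"], "w") as fh:
        fh.write("sample\trole\n")
        for s in samples:
            fh.write(f"{s}\t{roles[s]}\n")
    write_truth_tables(reference.truth, paths)
    cfg = dataclasses.asdict(config)
    cfg["unigene_len_range"] = list(config.unigene_len_range)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return SimResult(config, reference, reference.truth, barcodes, roles, paths)


def write_truth_tables(truth: GroundTruth, paths: dict[str, Path]) -> None:
    with open(paths["truth_homoeo"], "w") as fh:
        fh.write("unigene\tpos\tref\talt\tcopies\n")
        for s in truth.homoeo_sites:
            fh.write(f"{s.unigene}\t{s.pos}\t{s.ref}\t{s.alt}\t"
                     f"{','.join(map(str, s.copies))}\n")
    with open(paths["truth_intervarietal"], "w") as fh:
        fh.write("unigene\tpos\tref\talt\tcopies\n")
        for s in truth.intervarietal_sites:
            fh.write(f"{s.unigene}\t{s.pos}\t{s.ref}\t{s.alt}\t"
                     f"{','.join(map(str, s.copies))}\n")
    with open(paths["truth_ems"], "w") as fh:
        fh.write("plant\tunigene\tpos\tref\talt\tzygosity\tcopy\tchromatid\tkind\n")
        for e in truth.ems_events:
            fh.write(f"{e.plant}\t{e.unigene}\t{e.pos}\t{e.ref}\t{e.alt}\t"
                     f"{e.zygosity}\t{e.copy}\t{e.chromatid}\t{e.kind}\n")
    with open(paths["truth_fragments"], "w") as fh:
        fh.write("unigene\tstart\tend\n")
        for uid, a, b in truth.fragment_map:
            fh.write(f"{uid}\t{a}\t{b}\n")


def read_truth_tables(dirpath: str | Path) -> GroundTruth:
    dirpath = Path(dirpath)
    truth = GroundTruth()
    with open(dirpath / "truth_homoeologous.tsv") as fh:
        next(fh)
        for line in fh:
            u, p, r, a, c = line.rstrip("\n").split("\t")
            truth.homoeo_sites.append(
                HomoeoSite(u, int(p), r, a, tuple(map(int, c.split(",")))))
    with open(dirpath / "truth_intervarietal.tsv") as fh:
        next(fh)
        for line in fh:
            u, p, r, a, c = line.rstrip("\n").split("\t")
            truth.intervarietal_sites.append(
                HomoeoSite(u, int(p), r, a, tuple(map(int, c.split(",")))))
    with open(dirpath / "truth_ems.tsv") as fh:
        next(fh)
        for line in fh:
            pl, u, p, r, a, z, c, ch, k = line.rstrip("\n").split("\t")
            truth.ems_events.append(
                EmsEvent(pl, u, int(p), r, a, z, int(c), int(ch), k))
    with open(dirpath / "truth_fragments.tsv") as fh:
        next(fh)
        for line in fh:
            u, a, b = line.rstrip("\n").split("\t")
            truth.fragment_map.append((u, int(a), int(b)))
    return truth
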
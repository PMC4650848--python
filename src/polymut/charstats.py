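"""Downstream characterization of detected mutations.

Transition/transversion spectrum, alleles-per-unigene distribution,
longest-ORF synonymous/non-synonymous annotation, per-unigene coverage and
depth summaries, mutation frequency, sample-saturation curves, and the
effective/extrapolated mutation arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from Bio.Seq import Seq

from ._seq import TRANSITIONS, revcomp
from .align import AlignmentRecord

BASES = "ACGT"
SUBSTITUTIONS = [(a, b) for a in BASES for b in BASES if a != b]


def _round1(x: float) -> float:
    return math.floor(x * 10 + 0.5) / 10 if x >= 0 else -math.floor(-x * 10 + 0.5) / 10


# ---------------------------------------------------------------------------
# substitution spectrum

def spectrum(snps: Iterable[tuple[str, str]]) -> pd.DataFrame:
    """Directed substitution counts on the reference strand as called.

    Input is (REF, ALT) pairs; non-SNV records are skipped and tallied in
    the frame's ``attrs['skipped']``. Columns: count, pct_of_total (the 12
    values sum to 100 within rounding), pct_of_class (percent within the
    transition or transversion class, as mutation spectra are usually
    reported), is_transition.
    """
    counts = {s: 0 for s in SUBSTITUTIONS}
    skipped = 0
    for ref, alt in snps:
        if len(ref) == 1 and len(alt) == 1 and (ref, alt) in counts:
            counts[(ref, alt)] += 1
        else:
            skipped += 1
    total = sum(counts.values())
    ts = sum(c for s, c in counts.items() if s in TRANSITIONS)
    tv = total - ts
    rows = []
    for (ref, alt), c in counts.items():
        is_ts = (ref, alt) in TRANSITIONS
        cls = ts if is_ts else tv
        rows.append({
            "substitution": f"{ref}>{alt}",
            "count": c,
            "pct_of_total": _round1(100.0 * c / total) if total else 0.0,
            "pct_of_class": _round1(100.0 * c / cls) if cls else 0.0,
            "is_transition": is_ts,
        })
    df = pd.DataFrame(rows).set_index("substitution")
    df.attrs["total"] = total
    df.attrs["transitions"] = ts
    df.attrs["transversions"] = tv
    df.attrs["transitions_pct"] = _round1(100.0 * ts / total) if total else 0.0
    df.attrs["transversions_pct"] = _round1(100.0 * tv / total) if total else 0.0
    df.attrs["skipped"] = skipped
    return df


def transition_transversion_percent(n_transitions: int, n_transversions: int,
                                    ) -> tuple[float, float]:
    total = n_transitions + n_transversions
    return (_round1(100.0 * n_transitions / total),
            _round1(100.0 * n_transversions / total))


# ---------------------------------------------------------------------------
# alleles per unigene

ALLELE_BINS = [(1, 1, "1"), (2, 2, "2"), (3, 5, "3-5"), (6, 10, "6-10"),
               (11, None, "11+")]


def alleles_per_unigene(events: Iterable[tuple[str, ...]]) -> dict:
    """Histogram of EMS events per unigene.

    ``events`` yields tuples whose first element is the unigene id. Returns
    per-unigene counts, binned shares (percent of unigenes), and the mean
    (1 decimal) events/unigene.
    """
    per: dict[str, int] = {}
    for ev in events:
        per[ev[0]] = per.get(ev[0], 0) + 1
    n_uni = len(per)
    binned = {}
    for lo, hi, label in ALLELE_BINS:
        k = sum(1 for c in per.values()
                if c >= lo and (hi is None or c <= hi))
        binned[label] = {
            "unigenes": k,
            "pct": _round1(100.0 * k / n_uni) if n_uni else 0.0,
        }
    total = sum(per.values())
    return {
        "per_unigene": per,
        "n_unigenes": n_uni,
        "n_events": total,
        "mean_per_unigene": _round1(total / n_uni) if n_uni else 0.0,
        "max_per_unigene": max(per.values()) if per else 0,
        "bins": binned,
    }


# ---------------------------------------------------------------------------
# longest-ORF synonymous / non-synonymous classification

@dataclass(frozen=True)
class Orf:
    """Longest stop-codon-free codon stretch over all six frames.

    No ATG anchoring is required; ``start``/``end`` delimit the stretch in
    forward unigene coordinates, half-open, and ``strand`` says which strand
    is read. Reported in output metadata so the definition is switchable.
    """

    strand: str  # '+' or '-'
    start: int
    end: int

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos < self.end


STOPS = {"TAA", "TAG", "TGA"}


def longest_orf(seq: str) -> Orf:
    best: tuple[int, int, str, int] | None = None  # (-len, tiebreak, strand, start)
    n = len(seq)
    for order, (strand, s) in enumerate([("+", seq), ("-", revcomp(seq))]):
        for frame in range(3):
            run_start = frame
            for i in list(range(frame, n - 2, 3)) + [None]:
                if i is not None and s[i:i + 3] not in STOPS:
                    continue
                run_end = i if i is not None else frame + 3 * ((n - frame) // 3)
                if run_end > run_start:
                    cand = (-(run_end - run_start), order * 3 + frame,
                            strand, run_start)
                    if best is None or cand < best:
                        best = cand
                if i is not None:
                    run_start = i + 3
    if best is None:
        return Orf("+", 0, 0)
    length, _tb, strand, start = -best[0], best[1], best[2], best[3]
    if strand == "+":
        return Orf("+", start, start + length)
    # map the reverse-strand stretch back to forward coordinates
    return Orf("-", n - (start + length), n - start)


def orf_classify(unigene_seq: str, pos: int, ref: str, alt: str,
                 orf: Orf | None = None) -> str:
    """'synonymous' | 'non-synonymous' | 'non-coding' | 'unclassified'.

    The SNP must lie inside the unigene; it is compared codon-wise inside
    the longest ORF using the standard genetic code.
    """
    if not 0 <= pos < len(unigene_seq):
        raise ValueError(f"SNP position {pos} outside unigene")
    if len(ref) != 1 or len(alt) != 1:
        return "unclassified"
    if orf is None:
        orf = longest_orf(unigene_seq)
    if pos not in orf:
        return "non-coding"
    if orf.strand == "+":
        offset = pos - orf.start
        codon_start = orf.start + (offset // 3) * 3
        codon = unigene_seq[codon_start:codon_start + 3]
        mut = list(codon)
        mut[pos - codon_start] = alt
    else:
        rc = revcomp(unigene_seq)
        rpos = len(unigene_seq) - 1 - pos
        rstart = len(unigene_seq) - orf.end
        offset = rpos - rstart
        codon_start = rstart + (offset // 3) * 3
        codon = rc[codon_start:codon_start + 3]
        mut = list(codon)
        mut[rpos - codon_start] = revcomp(alt)
    if set(codon) - set(BASES) or set(mut) - set(BASES):
        return "unclassified"
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq("".join(mut)).translate())
    return "synonymous" if aa_ref == aa_alt else "non-synonymous"


# ---------------------------------------------------------------------------
# per-unigene coverage and depth

DEPTH_CLASSES = [(1, 10, "<=10"), (11, 50, "11-50"), (51, 100, "51-100"),
                 (101, 500, "101-500"), (501, 1000, "501-1000"),
                 (1001, None, ">1000")]


@dataclass
class CoverageSummary:
    unigene: str
    length: int
    regions: list[tuple[int, int]]      # maximal covered intervals, half-open
    reads_per_region: list[int]
    percent_covered: float              # over the whole unigene
    average_depth: float                # reads in kept regions / kept regions
    retained_min_depth: bool            # any region with >= min_depth reads


def coverage_depth_summary(records: Iterable[AlignmentRecord],
                           reference: dict[str, str],
                           min_depth: int = 10,
                           ) -> dict[str, CoverageSummary]:
    """Per-unigene percent base coverage and region-based average depth.

    Coverage is covered bases / unigene length. Regions are the maximal
    read-covered intervals; a read belongs to the region containing it, and
    average depth divides the reads in all retained regions by the number of
    retained regions. Regions with fewer than ``min_depth`` reads are
    dropped before averaging (mirroring the minimum-10-reads retention
    rule); unigenes with no mapped reads are absent from the result.
    """
    spans: dict[str, list[tuple[int, int]]] = {}
    for r in records:
        if r.mapped:
            spans.setdefault(r.unigene, []).append(
                (r.start, r.start + r.ref_span()))
    out: dict[str, CoverageSummary] = {}
    for uid, sp in spans.items():
        sp.sort()
        regions: list[list[int]] = []
        counts: list[int] = []
        for a, b in sp:
            if regions and a <= regions[-1][1]:
                regions[-1][1] = max(regions[-1][1], b)
                counts[-1] += 1
            else:
                regions.append([a, b])
                counts.append(1)
        covered = sum(b - a for a, b in regions)
        kept = [(tuple(r), c) for r, c in zip(regions, counts) if c >= min_depth]
        avg_depth = (sum(c for _r, c in kept) / len(kept)) if kept else 0.0
        out[uid] = CoverageSummary(
            uid, len(reference[uid]), [tuple(r) for r in regions], counts,
            _round1(100.0 * covered / len(reference[uid])),
            round(avg_depth, 2), bool(kept))
    return out


def coverage_class_histogram(summaries: dict[str, CoverageSummary],
                             ) -> dict[str, int]:
    """Decile bins of percent base coverage (1-10, 11-20, ..., 91-100)."""
    hist = {f"{lo}-{lo + 9}%": 0 for lo in range(1, 100, 10)}
    for s in summaries.values():
        pct = min(max(s.percent_covered, 0.0), 100.0)
        lo = min(int((math.ceil(pct) - 1) // 10) * 10 + 1, 91) if pct > 0 else 1
        hist[f"{lo}-{lo + 9}%"] += 1
    return hist


def depth_class_histogram(summaries: dict[str, CoverageSummary],
                          ) -> dict[str, int]:
    hist = {label: 0 for _lo, _hi, label in DEPTH_CLASSES}
    for s in summaries.values():
        d = sum(s.reads_per_region)
        for lo, hi, label in DEPTH_CLASSES:
            if d >= lo and (hi is None or d <= hi):
                hist[label] += 1
                break
    return hist


def saturation_curve(per_sample: dict[str, list[AlignmentRecord]],
                     reference: dict[str, str], min_depth: int = 0,
                     ) -> pd.DataFrame:
    """Sequential sample-addition saturation analysis.

    Samples are pooled in ascending order of mapped read count (the study's
    least-sequenced plant first); after each addition the pooled unique
    unigene count, mean percent coverage and mean average depth are
    recomputed from scratch.
    """
    if len(per_sample) < 2:
        raise ValueError("saturation analysis needs >= 2 samples")
    sizes = {s: sum(1 for r in recs if r.mapped)
             for s, recs in per_sample.items()}
    order = sorted(per_sample, key=lambda s: (sizes[s], s))
    pooled: list[AlignmentRecord] = []
    rows = []
    for s in order:
        pooled = sorted(pooled + per_sample[s],
                        key=lambda r: (r.unigene is None, r.unigene or "",
                                       r.start))
        summ = coverage_depth_summary(pooled, reference, min_depth)
        rows.append({
            "sample": s,
            "mapped_reads_added": sizes[s],
            "unique_unigenes": len(summ),
            "mean_percent_coverage": round(
                sum(x.percent_covered for x in summ.values()) / len(summ), 2)
            if summ else 0.0,
            "mean_average_depth": round(
                sum(x.average_depth for x in summ.values()) / len(summ), 2)
            if summ else 0.0,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# frequency and extrapolation arithmetic

def mutation_frequency(total_covered_bp: int, n_mutations: int) -> float:
    """Kilobases of covered sequence per mutational change (1 decimal)."""
    if total_covered_bp <= 0:
        raise ValueError("total_covered_bp must be > 0")
    if n_mutations == 0:
        return math.inf
    return _round1(total_covered_bp / n_mutations / 1000.0)


def extrapolate_effective(ems_snps: int, nonsyn_fraction: float,
                          error_rate: float, coverage_fraction: float,
                          n_unigenes_covered: int, n_unigenes_total: int,
                          ) -> dict[str, int]:
    """Effective (non-synonymous, error-corrected) mutation count and its
    extrapolation to full unigene coverage and the whole unigene set.

    The full-coverage value is carried unrounded into the genome-wide
    extrapolation; both extrapolations truncate, matching how such
    projections are conventionally printed.
    """
    if not 0 < coverage_fraction <= 1:
        raise ValueError("coverage_fraction must be in (0, 1]")
    if not 0 < nonsyn_fraction <= 1:
        raise ValueError("nonsyn_fraction must be in (0, 1]")
    effective = round(ems_snps * nonsyn_fraction * (1.0 - error_rate))
    full = effective / coverage_fraction
    genome = full * n_unigenes_total / n_unigenes_covered
    return {
        "effective": int(effective),
        "full_coverage": int(full),
        "genome_wide": int(genome),
    }


def total_covered_bp(summaries: dict[str, CoverageSummary]) -> int:
    return sum(sum(b - a for a, b in s.regions) for s in summaries.values())
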
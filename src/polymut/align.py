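"""Minimal homoeolog-tolerant short-read mapper plus SAM interoperability.

Maps trimmed 64-bp GBS reads to the unigene reference with k-mer seeding and
banded edit-distance extension (edlib). Reads from the three homoeologous
copies of a gene are *expected* to co-map onto the one unigene contig; no
attempt is made to separate homoeologs at alignment time — that signal is
resolved by the variant classifier. SAM read/write keeps the stage swappable
with an external aligner such as BWA.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import edlib
import pysam
from Bio import Align, SeqIO

from ._seq import COMMON_ADAPTER, revcomp

log = logging.getLogger(__name__)

_ADAPTER_PROBE = COMMON_ADAPTER[:10]
_MIN_CLIPPED_LEN = 24


class ReferenceError_(ValueError):
    pass


def read_reference(path: str | Path) -> dict[str, str]:
    ref: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in ref:
            raise ReferenceError_(f"duplicate unigene id {rec.id}")
        ref[rec.id] = str(rec.seq).upper()
    if not ref:
        raise ReferenceError_(f"{path}: empty reference FASTA")
    return ref


@dataclass
class ReferenceIndex:
    k: int
    lengths: dict[str, int]
    seqs: dict[str, str]
    postings: dict[str, list[tuple[str, int]]]  # k-mer -> [(unigene, offset)]


def build_index(reference: dict[str, str] | str | Path, k: int = 16,
                ) -> ReferenceIndex:
    """Exhaustive forward k-mer index of the unigene set."""
    if not isinstance(reference, dict):
        reference = read_reference(reference)
    postings: dict[str, list[tuple[str, int]]] = {}
    lengths: dict[str, int] = {}
    for uid in sorted(reference):
        seq = reference[uid]
        lengths[uid] = len(seq)
        if len(seq) < k:
            log.warning("unigene %s shorter than k=%d; not indexed", uid, k)
            continue
        for off in range(len(seq) - k + 1):
            postings.setdefault(seq[off:off + k], []).append((uid, off))
    return ReferenceIndex(k, lengths, reference, postings)


@dataclass
class AlignmentRecord:
    """One read placed on a unigene, SAM-convention fields.

    ``seq``/``qual`` are stored in reference orientation; ``cigar`` uses
    =/X/I/D (plus terminal S for adapter clips) along the reference.
    """

    read_id: str
    sample: str
    unigene: str | None
    start: int            # 0-based
    strand: str           # '+' or '-'
    cigar: str
    nm: int
    mapq: int
    seq: str
    qual: str

    @property
    def mapped(self) -> bool:
        return self.unigene is not None

    def ref_span(self) -> int:
        span = 0
        for n, op in cigar_ops(self.cigar):
            if op in "=XDM":
                span += n
        return span


def cigar_ops(cigar: str) -> list[tuple[int, str]]:
    ops, n = [], 0
    for c in cigar:
        if c.isdigit():
            n = n * 10 + int(c)
        else:
            ops.append((n, c))
            n = 0
    return ops


_gap_aligner = Align.PairwiseAligner()
_gap_aligner.mode = "global"
_gap_aligner.match_score = 2
_gap_aligner.mismatch_score = -4
_gap_aligner.open_gap_score = -6
_gap_aligner.extend_gap_score = -1


def _affine_cigar(query: str, target: str) -> tuple[str, int]:
    """Re-align with affine gap penalties and rebuild the =/X/I/D CIGAR.

    Plain edit distance scores a contiguous 2-bp deletion and two split
    1-bp deletions identically; the gap-open penalty makes the contiguous
    (biologically canonical) representation win. Used only for
    indel-containing placements. Returns (cigar, NM).
    """
    aln = _gap_aligner.align(target, query)[0]
    t_blocks, q_blocks = aln.aligned
    parts: list[tuple[int, str]] = []

    def push(n: int, op: str) -> None:
        if n <= 0:
            return
        if parts and parts[-1][1] == op:
            parts[-1] = (parts[-1][0] + n, op)
        else:
            parts.append((n, op))

    t_prev = q_prev = 0
    for (t0, t1), (q0, q1) in zip(t_blocks.tolist(), q_blocks.tolist()):
        push(t0 - t_prev, "D")
        push(q0 - q_prev, "I")
        run_op = None
        run = 0
        for a, b in zip(target[t0:t1], query[q0:q1]):
            op = "=" if a == b else "X"
            if op == run_op:
                run += 1
            else:
                push(run, run_op) if run_op else None
                run_op, run = op, 1
        push(run, run_op) if run_op else None
        t_prev, q_prev = t1, q1
    push(len(target) - t_prev, "D")
    push(len(query) - q_prev, "I")
    nm = sum(n for n, op in parts if op in "XID")
    return "".join(f"{n}{op}" for n, op in parts), nm


def _absorb_terminal_insertions(cigar: str, start: int, query: str,
                                ref: str) -> tuple[str, int, int]:
    """Rewrite terminal I ops as substitutions where reference exists.

    An edit at the first/last read base is representable as either a
    mismatch or an insertion at identical edit cost; the unaligned-end
    placement fabricates indels from plain SNVs, so the substitution
    representation is canonical. Returns (cigar, start, NM).
    """
    ops = cigar_ops(cigar)
    if ops and ops[0][1] == "I" and start - ops[0][0] >= 0:
        k = ops[0][0]
        start -= k
        repl = [(1, "=" if query[i] == ref[start + i] else "X")
                for i in range(k)]
        ops = repl + ops[1:]
    if ops and ops[-1][1] == "I":
        k = ops[-1][0]
        span = sum(n for n, op in ops[:-1] if op in "=XDM")
        if start + span + k <= len(ref):
            qoff = sum(n for n, op in ops[:-1] if op in "=XIM")
            repl = [(1, "=" if query[qoff + i] == ref[start + span + i] else "X")
                    for i in range(k)]
            ops = ops[:-1] + repl
    merged: list[tuple[int, str]] = []
    for n, op in ops:
        if merged and merged[-1][1] == op:
            merged[-1] = (merged[-1][0] + n, op)
        else:
            merged.append((n, op))
    nm = sum(n for n, op in merged if op in "XID")
    return "".join(f"{n}{op}" for n, op in merged), start, nm


def _clip_adapter(seq: str) -> tuple[str, int]:
    """Trim 3' common-adapter read-through; returns (core, clipped length)."""
    i = seq.find(_ADAPTER_PROBE)
    if i >= 0:
        return seq[:i], len(seq) - i
    return seq, 0


def map_read(read: tuple[str, str, str], index: ReferenceIndex,
             sample: str = "", max_mismatches: int = 4, max_indel: int = 4,
             ) -> AlignmentRecord:
    """Seed-and-extend placement of one read.

    Seeds are non-overlapping k-mers of the read (both orientations); each
    candidate locus is rescored by banded edit distance over a window padded
    by ``max_indel``. MQ is 0 on a tie for best, 60 for a sole candidate,
    otherwise ``min(60, 20 + 10 * (second_best - best))`` — unique perfect
    hits score >= 30, ambiguous ones < 30, matching the classifier's MQ
    expectations.
    """
    rid, seq, qual = read
    core, _clip = _clip_adapter(seq)
    k = index.k
    unmapped = AlignmentRecord(rid, sample, None, -1, "+", "*", 0, 0, seq, qual)
    if len(core) < k:
        return unmapped
    max_edits = max_mismatches + max_indel
    candidates: dict[tuple[str, int, str], tuple[int, int, str]] = {}
    for strand, query in (("+", core), ("-", revcomp(core))):
        starts: set[tuple[str, int]] = set()
        offs = list(range(0, len(query) - k + 1, k))
        if offs[-1] != len(query) - k:
            offs.append(len(query) - k)
        for off in offs:
            for uid, tpos in index.postings.get(query[off:off + k], ()):
                s = tpos - off
                starts.add((uid, min(max(s, -max_indel),
                                     index.lengths[uid] - 1)))
        for uid, s in starts:
            ref = index.seqs[uid]
            lo = max(0, s - max_indel)
            hi = min(len(ref), s + len(query) + max_indel)
            res = edlib.align(query, ref[lo:hi], mode="HW", task="path",
                              k=max_edits)
            if res["editDistance"] < 0:
                continue
            t0, _t1 = res["locations"][0]
            key = (uid, lo + t0, strand)
            val = (res["editDistance"], lo + t0, res["cigar"])
            prev = candidates.get(key)
            if prev is None or val[0] < prev[0]:
                candidates[key] = val
    if not candidates:
        return unmapped
    ranked = sorted(
        ((dist, uid, start, strand, cig)
         for (uid, _s, strand), (dist, start, cig) in candidates.items()),
        key=lambda t: (t[0], t[1], t[2], t[3]))
    best = ranked[0]
    if len(ranked) == 1:
        mapq = 60
    elif ranked[1][0] == best[0]:
        mapq = 0
    else:
        mapq = min(60, 20 + 10 * (ranked[1][0] - best[0]))
    dist, uid, start, strand, cig = best
    if "I" in cig or "D" in cig:
        span = sum(n for n, op in cigar_ops(cig) if op in "=XD")
        query = core if strand == "+" else revcomp(core)
        # window at least as long as the read, so a terminal edit can be
        # represented as a substitution rather than a forced insertion
        hi = min(index.lengths[uid], start + max(span, len(query)))
        cig, dist = _affine_cigar(query, index.seqs[uid][start:hi])
        ops = cigar_ops(cig)
        if ops and ops[0][1] == "D":  # realignment pushed a gap to the edge
            start += ops[0][0]
            ops = ops[1:]
        if ops and ops[-1][1] == "D":
            ops = ops[:-1]
        cig = "".join(f"{n}{op}" for n, op in ops)
        if "I" in cig:
            cig, start, dist = _absorb_terminal_insertions(
                cig, start, query, index.seqs[uid])
    clip = len(seq) - len(core)
    if strand == "+":
        out_seq, out_qual = seq, qual
        cigar = cig + (f"{clip}S" if clip else "")
    else:
        out_seq, out_qual = revcomp(seq), qual[::-1]
        cigar = (f"{clip}S" if clip else "") + cig
    return AlignmentRecord(rid, sample, uid, start, strand, cigar, dist,
                           mapq, out_seq, out_qual)


def map_reads(reads: Iterable[tuple[str, str, str]], index: ReferenceIndex,
              sample: str = "", max_mismatches: int = 4, max_indel: int = 4,
              ) -> list[AlignmentRecord]:
    recs = [map_read(r, index, sample, max_mismatches, max_indel)
            for r in reads]
    recs.sort(key=lambda a: (a.unigene is None, a.unigene or "", a.start,
                             a.read_id))
    return recs


def flagstat(records: Iterable[AlignmentRecord]) -> dict[str, int | float]:
    total = mapped = 0
    for r in records:
        total += 1
        mapped += r.mapped
    return {"total": total, "mapped": mapped,
            "mapped_fraction": mapped / total if total else math.nan}


# ---------------------------------------------------------------------------
# SAM interoperability (pysam)

def _sam_header(reference: dict[str, str], samples: list[str],
                ) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": uid, "LN": len(reference[uid])}
               for uid in sorted(reference)],
        "RG": [{"ID": s, "SM": s} for s in samples],
    })


def write_sam(records: Iterable[AlignmentRecord], reference: dict[str, str],
              path: str | Path) -> None:
    records = list(records)
    samples = sorted({r.sample for r in records if r.sample})
    header = _sam_header(reference, samples)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in records:
            a = pysam.AlignedSegment(header)
            a.query_name = r.read_id
            a.query_sequence = r.seq
            a.query_qualities = pysam.qualitystring_to_array(r.qual)
            if r.sample:
                a.set_tag("RG", r.sample)
            if not r.mapped:
                a.flag = 4
                a.reference_id = -1
                a.reference_start = -1
                a.mapping_quality = 0
            else:
                a.flag = 16 if r.strand == "-" else 0
                a.reference_id = header.get_tid(r.unigene)
                a.reference_start = r.start
                a.mapping_quality = r.mapq
                a.cigarstring = r.cigar
                a.set_tag("NM", r.nm)
            out.write(a)


def read_sam(path: str | Path, reference: dict[str, str] | None = None,
             ) -> list[AlignmentRecord]:
    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        if reference is not None:
            for sq in fh.header.get("SQ", []):
                if sq["SN"] not in reference:
                    raise ReferenceError_(
                        f"SAM references unknown unigene {sq['SN']}")
        for a in fh:
            sample = a.get_tag("RG") if a.has_tag("RG") else ""
            qual = (pysam.qualities_to_qualitystring(a.query_qualities)
                    if a.query_qualities is not None else "")
            if a.is_unmapped:
                out.append(AlignmentRecord(a.query_name, sample, None, -1,
                                           "+", "*", 0, 0,
                                           a.query_sequence or "", qual))
                continue
            if reference is not None and a.reference_name not in reference:
                raise ReferenceError_(
                    f"SAM references unknown unigene {a.reference_name}")
            nm = a.get_tag("NM") if a.has_tag("NM") else 0
            out.append(AlignmentRecord(
                a.query_name, sample, a.reference_name, a.reference_start,
                "-" if a.is_reverse else "+", a.cigarstring, nm,
                a.mapping_quality, a.query_sequence or "", qual))
    return out
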
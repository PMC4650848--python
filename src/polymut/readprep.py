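"""Demultiplexing, filtering and trimming of raw GBS reads.

A read is kept only if it starts with one of the sample barcodes followed by
the ApeKI cut-site remnant CWGC (exact matches only); the barcode is removed,
reads with N early in the original read or adapter-dimer read-through are
discarded, and survivors are trimmed to a fixed analysis length that includes
the initial CWGC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._seq import COMMON_ADAPTER, is_remnant

#: minimum adapter-prefix match length used to flag adapter/adapter dimers
DIMER_MATCH_LEN = 12

#: N's anywhere in the first this-many bases of the *original* (barcoded)
#: read disqualify it: max barcode (8) + 64 analysed bases
N_SCAN_LEN = 72

Read = tuple[str, str, str]  # (id, sequence, quality)


class BarcodeError(ValueError):
    pass


class FastqParseError(ValueError):
    pass


@dataclass
class BarcodeTable:
    """sample -> barcode (4-8 bp, ACGT, unique, prefix-free)."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        bcs = list(self.entries.values())
        if not bcs:
            raise BarcodeError("barcode table is empty")
        if len(set(bcs)) != len(bcs):
            raise BarcodeError("barcodes are not unique")
        for s, b in self.entries.items():
            if not 4 <= len(b) <= 8 or set(b) - set("ACGT"):
                raise BarcodeError(f"invalid barcode {b!r} for sample {s}")
        for a in bcs:
            for b in bcs:
                if a != b and b.startswith(a):
                    raise BarcodeError(f"barcode {a} is a prefix of {b}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeTable":
        entries = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("sample"):
                raise BarcodeError(f"{path}: expected 'sample\\tbarcode' header")
            for line in fh:
                if line.strip():
                    sample, bc = line.rstrip("\n").split("\t")[:2]
                    entries[sample] = bc
        return cls(entries)

    def items(self):
        return self.entries.items()


@dataclass
class PrepStats:
    total_reads: int = 0
    with_barcode: int = 0
    with_remnant: int = 0
    discarded_N: int = 0
    discarded_dimer: int = 0
    discarded_short: int = 0
    retained_per_sample: dict[str, int] = field(default_factory=dict)

    @property
    def retained(self) -> int:
        return sum(self.retained_per_sample.values())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            for k in ("total_reads", "with_barcode", "with_remnant",
                      "discarded_N", "discarded_dimer", "discarded_short"):
                fh.write(f"{k}\t{getattr(self, k)}\n")
            fh.write(f"retained\t{self.retained}\n")
            for s in sorted(self.retained_per_sample):
                fh.write(f"retained:{s}\t{self.retained_per_sample[s]}\n")


def parse_fastq(path: str | Path) -> Iterator[Read]:
    try:
        with open(path) as fh:
            yield from FastqGeneralIterator(fh)
    except ValueError as exc:
        raise FastqParseError(f"{path}: {exc}") from exc


def demultiplex(reads: Iterable[Read], barcodes: BarcodeTable,
                ) -> tuple[dict[str, list[Read]], PrepStats]:
    """Assign reads to samples by exact barcode + CWGC remnant match.

    Returns per-sample reads with the barcode removed (so each retained read
    starts at the CWGC remnant) and the running :class:`PrepStats`. The
    returned reads still carry their full post-barcode length; trimming and
    the N / dimer filters are :func:`quality_filter_and_trim`'s job.
    """
    stats = PrepStats(retained_per_sample={s: 0 for s in barcodes.entries})
    out: dict[str, list[Read]] = {s: [] for s in barcodes.entries}
    # prefix-freeness guarantees at most one barcode can match
    by_barcode = sorted(barcodes.items(), key=lambda kv: -len(kv[1]))
    for rid, seq, qual in reads:
        stats.total_reads += 1
        if len(seq) != len(qual):
            raise FastqParseError(
                f"record {stats.total_reads} ({rid}): sequence/quality length mismatch")
        hit = None
        for sample, bc in by_barcode:
            if seq.startswith(bc):
                hit = (sample, bc)
                break
        if hit is None:
            continue
        stats.with_barcode += 1
        sample, bc = hit
        rest = seq[len(bc):]
        if not is_remnant(rest):
            continue
        stats.with_remnant += 1
        out[sample].append((rid, rest, qual[len(bc):]))
    return out, stats


def quality_filter_and_trim(per_sample: dict[str, list[Read]],
                            barcodes: BarcodeTable,
                            stats: PrepStats | None = None,
                            trim_len: int = 64,
                            adapter: str = COMMON_ADAPTER,
                            ) -> dict[str, list[Read]]:
    """Drop N-containing and adapter-dimer reads, trim survivors.

    N's are scanned over the first 72 bases of the original read, i.e. the
    first ``72 - len(barcode)`` bases of the demultiplexed read. A read whose
    post-remnant sequence starts with >= 12 bases of the common adapter is an
    adapter/adapter dimer. Survivors are truncated to ``trim_len`` bases
    counted from (and including) the CWGC remnant; shorter reads are dropped
    so the analysis length stays uniform. Idempotent on its own output.
    """
    if stats is None:
        stats = PrepStats(retained_per_sample={s: 0 for s in per_sample})
    dimer_probe = adapter[:DIMER_MATCH_LEN]
    out: dict[str, list[Read]] = {s: [] for s in per_sample}
    for sample, reads in per_sample.items():
        bc_len = len(barcodes.entries[sample])
        n_scan = max(0, N_SCAN_LEN - bc_len)
        for rid, seq, qual in reads:
            if "N" in seq[:n_scan]:
                stats.discarded_N += 1
                continue
            if seq[4:4 + DIMER_MATCH_LEN] == dimer_probe:
                stats.discarded_dimer += 1
                continue
            if len(seq) < trim_len:
                stats.discarded_short += 1
                continue
            out[sample].append((rid, seq[:trim_len], qual[:trim_len]))
            stats.retained_per_sample[sample] = \
                stats.retained_per_sample.get(sample, 0) + 1
    return out


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def demux_fastq(fastq: str | Path, barcodes: BarcodeTable, outdir: str | Path,
                trim_len: int = 64) -> PrepStats:
    """File-level convenience: FASTQ in, one trimmed FASTQ per sample out."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    per_sample, stats = demultiplex(parse_fastq(fastq), barcodes)
    trimmed = quality_filter_and_trim(per_sample, barcodes, stats, trim_len)
    for sample, reads in trimmed.items():
        write_fastq(reads, outdir / f"{sample}.fastq")
    stats.to_tsv(outdir / "prep_stats.tsv")
    return stats
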
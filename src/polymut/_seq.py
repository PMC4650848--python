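"""Small sequence helpers shared across the pipeline."""

from __future__ import annotations

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Illumina universal adapter; the GBS "common adapter" ligated opposite the
#: barcoded adapter. Reads from fragments shorter than the read length run
#: into this sequence.
COMMON_ADAPTER = "AGATCGGAAGAGCGGTTCAGCAGGAATGCCGAGACCG"

#: ApeKI recognition site, W in {A, T}; the enzyme cuts between the leading
#: G and the CWGC remnant that starts every genuine GBS read.
APEKI_SITE_RE = r"GC[AT]GC"

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def is_remnant(s: str) -> bool:
    """True if ``s`` starts with the ApeKI cut-site remnant CWGC."""
    return len(s) >= 4 and s[0] == "C" and s[1] in "AT" and s[2] == "G" and s[3] == "C"


def phred_char(q: int) -> str:
    return chr(33 + q)


def phred_of(c: str) -> int:
    return ord(c) - 33


def left_align_indel(ref_seq: str, pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-align a VCF-style indel against ``ref_seq``.

    ``pos`` is the 0-based anchor; ``ref``/``alt`` both start with the anchor
    base and exactly one of them has length 1. Returns the canonical
    (pos, ref, alt). SNVs are returned unchanged.
    """
    if len(ref) == 1 and len(alt) == 1:
        return pos, ref, alt
    longer, shorter = (ref, alt) if len(ref) > len(alt) else (alt, ref)
    if len(shorter) != 1 or longer[0] != shorter[0]:
        return pos, ref, alt  # not a simple anchored indel; leave as-is
    run = longer[1:]
    # an anchored indel shifts one base left whenever the run's last base
    # equals the anchor base (rotating the run through the anchor)
    while pos > 0 and run[-1] == ref_seq[pos]:
        run = ref_seq[pos] + run[:-1]
        pos -= 1
    anchor = ref_seq[pos]
    longer = anchor + run
    if len(ref) > len(alt):
        return pos, longer, anchor
    return pos, anchor, longer
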
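"""Multi-sample pileup and diploid genotype calling.

Aggregates per-sample allele observations over every covered reference
position, then computes per-sample diploid genotype likelihoods from base
qualities. The diploid model is deliberate despite hexaploidy: reads from
the three homoeologous copies collapse onto one unigene, so a fixed
homoeologous difference looks heterozygous in *every* sample — exactly the
cross-sample signal the downstream classifier uses to separate homoeologous
from induced changes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from ._seq import left_align_indel, phred_of
from .align import AlignmentRecord, cigar_ops

log = logging.getLogger(__name__)

#: bases below this phred quality are excluded from pileup counts
DEFAULT_MIN_BASE_QUAL = 13

#: indel observations anchored closer than this to either read end are
#: ignored — a terminal gap is representationally interchangeable with
#: substitutions and cannot be placed reliably
MIN_INDEL_END_DIST = 5

#: SNVs called within this many bases of an indel call are suppressed
#: (realignment satellites around the gap), as in classic SnpGap filtering
DEFAULT_SNP_GAP = 5

GT_ORDER = ((0, 0), (0, 1), (1, 1))
NO_CALL = (None, None)


class PileupError(ValueError):
    pass


@dataclass
class Observation:
    allele: str   # "A" etc. for SNVs; "+SEQ" insertion; "-SEQ" deletion
    qual: int     # phred base quality (min over involved bases for indels)
    mapq: int


@dataclass
class PileupSite:
    unigene: str
    pos: int                 # 0-based
    ref_base: str
    by_sample: dict[str, list[Observation]] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return sum(len(v) for v in self.by_sample.values())


@dataclass
class SampleCall:
    gt: tuple[int | None, int | None]
    gq: int | None
    dp: int
    ad: tuple[int, int] = (0, 0)  # (REF, ALT) observation counts


@dataclass
class VariantCall:
    unigene: str
    pos: int                 # 0-based
    ref: str
    alt: str
    qual: float              # phred P(every sample is 0/0)
    dp: int
    ns: int
    mq: float                # RMS mapping quality over covering reads
    samples: dict[str, SampleCall]

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


def pileup(per_sample: dict[str, list[AlignmentRecord]],
           reference: dict[str, str],
           min_base_qual: int = DEFAULT_MIN_BASE_QUAL,
           ) -> list[PileupSite]:
    """Stack per-sample alignments into per-position allele observations.

    Insertions are attached to the preceding reference position and
    deletions span their reference bases (both re-left-aligned against the
    reference); bases below ``min_base_qual`` are excluded. Input records
    must be coordinate-sorted per sample.
    """
    sites: dict[tuple[str, int], PileupSite] = {}

    def obs(uid: str, pos: int, sample: str, o: Observation) -> None:
        key = (uid, pos)
        site = sites.get(key)
        if site is None:
            site = PileupSite(uid, pos, reference[uid][pos])
            sites[key] = site
        site.by_sample.setdefault(sample, []).append(o)

    for sample in sorted(per_sample):
        last: dict[str, int] = {}
        for rec in per_sample[sample]:
            if not rec.mapped:
                continue
            if rec.start < last.get(rec.unigene, -1):
                raise PileupError(
                    f"alignments for sample {sample} are not coordinate-sorted; "
                    "sort before pileup")
            last[rec.unigene] = rec.start
            _walk(rec, sample, reference, min_base_qual, obs)
    return [sites[k] for k in sorted(sites)]


def _walk(rec: AlignmentRecord, sample: str, reference: dict[str, str],
          min_q: int, obs) -> None:
    ref = reference[rec.unigene]
    rpos, qpos = rec.start, 0
    for n, op in cigar_ops(rec.cigar):
        if op in "=XM":
            for i in range(n):
                q = phred_of(rec.qual[qpos + i])
                if q >= min_q:
                    obs(rec.unigene, rpos + i, sample,
                        Observation(rec.seq[qpos + i], q, rec.mapq))
            rpos += n
            qpos += n
        elif op == "I":
            ins = rec.seq[qpos:qpos + n]
            q = min(phred_of(c) for c in rec.qual[qpos:qpos + n])
            anchor = rpos - 1
            if (anchor >= 0 and q >= min_q
                    and qpos >= MIN_INDEL_END_DIST
                    and qpos + n <= len(rec.seq) - MIN_INDEL_END_DIST):
                a_pos, _r, a_alt = left_align_indel(
                    ref, anchor, ref[anchor], ref[anchor] + ins)
                obs(rec.unigene, a_pos, sample,
                    Observation("+" + a_alt[1:], q, rec.mapq))
            qpos += n
        elif op == "D":
            anchor = rpos - 1
            if anchor >= 0:
                q = phred_of(rec.qual[qpos - 1]) if qpos > 0 else 40
                if (q >= min_q and qpos >= MIN_INDEL_END_DIST
                        and qpos <= len(rec.seq) - MIN_INDEL_END_DIST):
                    a_pos, a_ref, _a = left_align_indel(
                        ref, anchor, ref[anchor:rpos + n], ref[anchor])
                    obs(rec.unigene, a_pos, sample,
                        Observation("-" + a_ref[1:], q, rec.mapq))
            rpos += n
        elif op == "S":
            qpos += n
        else:
            raise PileupError(f"unsupported CIGAR op {op!r} in {rec.cigar}")


def _allele_strings(site: PileupSite, allele: str) -> tuple[str, str]:
    """VCF REF/ALT for an observation key at this site."""
    if allele.startswith("+"):
        return site.ref_base, site.ref_base + allele[1:]
    if allele.startswith("-"):
        return site.ref_base + allele[1:], site.ref_base
    return site.ref_base, allele


def genotype_likelihoods(observations: Sequence[Observation], ref_key: str,
                         alt_key: str) -> list[float]:
    """log10 L(0/0), L(0/1), L(1/1) for one sample's allele observations.

    Each read is drawn from one of the sample's two chromatids; with
    base-error probability e = 10^(-q/10), an observation b given true
    allele a has probability 1-e if b == a, else e/3.
    """
    loglik = []
    for f in (0.0, 0.5, 1.0):
        ll = 0.0
        for o in observations:
            e = 10.0 ** (-o.qual / 10.0)
            p_ref = (1.0 - e) if o.allele == ref_key else e / 3.0
            p_alt = (1.0 - e) if o.allele == alt_key else e / 3.0
            ll += math.log10((1.0 - f) * p_ref + f * p_alt)
        loglik.append(ll)
    return loglik


def genotype_sample(observations: Sequence[Observation], ref_key: str,
                    alt_key: str) -> tuple[int, int, list[float]]:
    """Maximum-posterior genotype for one sample under a uniform prior.

    Returns (index into GT_ORDER, phred GQ capped at 99, posterior list).
    """
    loglik = genotype_likelihoods(observations, ref_key, alt_key)
    m = max(loglik)
    post = [10.0 ** (l - m) for l in loglik]
    tot = sum(post)
    post = [p / tot for p in post]
    gi = max(range(3), key=lambda i: (post[i], -i))
    p_other = max(1.0 - post[gi], 1e-10)
    gq = min(99, int(round(-10.0 * math.log10(p_other))))
    return gi, gq, post


def genotype_site(site: PileupSite, min_alt_obs: int = 2,
                  ) -> VariantCall | None:
    """Call per-sample diploid genotypes at one pileup site.

    The two most frequent alleles are kept (the reference allele always
    survives; extra alleles are dropped with a logged tally). Per-sample
    likelihoods L(0/0), L(0/1), L(1/1) treat each read as drawn from one of
    two chromatids, with base-quality error probability e and P(b|a) = 1-e
    for b==a else e/3. GT is the maximum-posterior genotype under a uniform
    prior, GQ = -10 log10(posterior of the other genotypes) capped at 99,
    QUAL = -10 log10 P(all covered samples 0/0), MQ the RMS mapping quality.
    Returns None when no sample supports an alternate allele with at least
    ``min_alt_obs`` reads or no non-reference genotype is called.
    """
    counts: dict[str, int] = {}
    for obs_list in site.by_sample.values():
        for o in obs_list:
            counts[o.allele] = counts.get(o.allele, 0) + 1
    alts = {a: c for a, c in counts.items() if a != site.ref_base}
    if not alts:
        return None
    alt_key = max(alts, key=lambda a: (alts[a], a))
    if max(max(sum(1 for o in v if o.allele == alt_key)
               for v in site.by_sample.values()), 0) < min_alt_obs:
        return None
    dropped = sum(c for a, c in alts.items() if a != alt_key)
    if dropped:
        log.debug("site %s:%d: dropped %d reads on minor alleles",
                  site.unigene, site.pos, dropped)
    ref_allele, alt_allele = _allele_strings(site, alt_key)

    samples: dict[str, SampleCall] = {}
    log10_p_all_ref = 0.0
    sq = n = 0
    any_alt_called = False
    for sample, obs_list in site.by_sample.items():
        used = [o for o in obs_list if o.allele in (site.ref_base, alt_key)]
        for o in obs_list:
            sq += o.mapq * o.mapq
            n += 1
        ad = (sum(1 for o in used if o.allele == site.ref_base),
              sum(1 for o in used if o.allele == alt_key))
        if not used:
            samples[sample] = SampleCall(NO_CALL, None, len(obs_list), ad)
            continue
        gi, gq, post = genotype_sample(used, site.ref_base, alt_key)
        samples[sample] = SampleCall(GT_ORDER[gi], gq, len(obs_list), ad)
        log10_p_all_ref += math.log10(max(post[0], 1e-300))
        if gi > 0:
            any_alt_called = True
    if not any_alt_called:
        return None
    qual = round(min(-10.0 * log10_p_all_ref, 9999.0), 1)
    mq = round(math.sqrt(sq / n), 1) if n else 0.0
    ns = sum(1 for s in samples.values() if s.dp > 0)
    dp = site.depth
    return VariantCall(site.unigene, site.pos, ref_allele, alt_allele,
                       qual, dp, ns, mq, samples)


def call_variants(per_sample: dict[str, list[AlignmentRecord]],
                  reference: dict[str, str],
                  min_base_qual: int = DEFAULT_MIN_BASE_QUAL,
                  all_samples: Sequence[str] | None = None,
                  snp_gap: int = DEFAULT_SNP_GAP,
                  ) -> list[VariantCall]:
    """Pileup + genotyping; uncovered samples get GT ./. at each variant.

    SNVs within ``snp_gap`` bases of an indel call on the same unigene are
    suppressed: gap realignment scatters substitution artifacts around true
    indels, so those calls are untrustworthy.
    """
    if all_samples is None:
        all_samples = sorted(per_sample)
    calls = []
    for site in pileup(per_sample, reference, min_base_qual):
        call = genotype_site(site)
        if call is None:
            continue
        for s in all_samples:
            call.samples.setdefault(s, SampleCall(NO_CALL, None, 0))
        calls.append(call)
    if snp_gap > 0:
        shadow: dict[str, set[int]] = {}
        for c in calls:
            if c.is_indel:
                shadow.setdefault(c.unigene, set()).update(
                    range(c.pos - snp_gap, c.pos + len(c.ref) + snp_gap))
        kept = [c for c in calls
                if c.is_indel or c.pos not in shadow.get(c.unigene, ())]
        if len(kept) < len(calls):
            log.info("snp_gap filter removed %d SNV calls near indels",
                     len(calls) - len(kept))
        calls = kept
    return calls


# ---------------------------------------------------------------------------
# VCF 4.x interoperability (pysam)

def write_vcf(calls: Iterable[VariantCall], reference: dict[str, str],
              samples: Sequence[str], path: str | Path) -> None:
    header = pysam.VariantHeader()
    for uid in sorted(reference):
        header.add_line(f"##contig=<ID={uid},length={len(reference[uid])}>")
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,'
                    'Description="Combined depth across samples">')
    header.add_line('##INFO=<ID=NS,Number=1,Type=Integer,'
                    'Description="Number of samples with data">')
    header.add_line('##INFO=<ID=MQ,Number=1,Type=Float,'
                    'Description="RMS mapping quality">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=GQ,Number=1,Type=Integer,'
                    'Description="Genotype quality">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                    'Description="Allele observation counts">')
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in calls:
            rec = out.new_record(contig=c.unigene, start=c.pos,
                                 alleles=(c.ref, c.alt), qual=c.qual)
            rec.info["DP"] = c.dp
            rec.info["NS"] = c.ns
            rec.info["MQ"] = c.mq
            for s in samples:
                sc = c.samples.get(s, SampleCall(NO_CALL, None, 0))
                rec.samples[s]["GT"] = sc.gt
                if sc.gq is not None:
                    rec.samples[s]["GQ"] = sc.gq
                rec.samples[s]["DP"] = sc.dp
                rec.samples[s]["AD"] = sc.ad
            out.write(rec)


def read_vcf(path: str | Path) -> list[VariantCall]:
    calls: list[VariantCall] = []
    try:
        with pysam.VariantFile(str(path)) as fh:
            for i, rec in enumerate(fh):
                if rec.alts is None or len(rec.alts) != 1:
                    raise PileupError(
                        f"{path} record {i + 1}: expected exactly one ALT")
                samples = {}
                for s, v in rec.samples.items():
                    gt = tuple(v["GT"]) if v.get("GT") is not None else NO_CALL
                    if gt == ():
                        gt = NO_CALL
                    ad = v.get("AD")
                    if ad is None or ad == (None,) or None in tuple(ad or ()):
                        ad = (0, 0)
                    samples[s] = SampleCall(gt, v.get("GQ"), v.get("DP") or 0,
                                            tuple(ad))
                calls.append(VariantCall(
                    rec.contig, rec.start, rec.ref, rec.alts[0],
                    round(rec.qual, 1) if rec.qual is not None else 0.0,
                    rec.info.get("DP", 0), rec.info.get("NS", 0),
                    round(float(rec.info.get("MQ", 0.0)), 1), samples))
    except (ValueError, OSError) as exc:
        if isinstance(exc, PileupError):
            raise
        raise PileupError(f"malformed VCF {path}: {exc}") from exc
    return calls
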
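"""Partition variant calls into EMS-induced, homoeologous and intervarietal
classes, and estimate the mutation-calling error rate from wild-type plants.

The discrimination logic is cross-sample: a fixed homoeologous difference is
seen (as an apparent heterozygote) in every plant whose reads cover the
locus; an intervarietal difference between the study cultivar and the
reference unigene is homozygous-alternate in every plant; an EMS-induced
change deviates in exactly one mutant plant against a uniform background.
The same singleton-deviator rule applied to the non-mutagenized plants
yields the empirical error rate of EMS calling, since a "mutation" in a
wild-type plant can only be an artifact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .pileup import VariantCall

CATEGORY_EMS_SNP = "EMS_SNP"
CATEGORY_EMS_INDEL = "EMS_INDEL"
CATEGORY_HOMOEOLOGOUS = "homoeologous"
CATEGORY_INTERVARIETAL = "intervarietal"
CATEGORY_FILTERED = "filtered"


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class CriteriaSet:
    """Site and genotype thresholds for variant retention and EMS calling."""

    name: str
    min_qual: float = 30.0
    min_dp: int = 10
    min_mq: float = 30.0
    min_samples_with_reads: int = 2
    ems_min_gq: int = 30

    def __post_init__(self) -> None:
        for f in ("min_qual", "min_dp", "min_mq", "min_samples_with_reads",
                  "ems_min_gq"):
            if getattr(self, f) < 0:
                raise ClassificationError(f"{f} must be >= 0")


STRINGENT = CriteriaSet("stringent", ems_min_gq=30)
REDEFINED = CriteriaSet("redefined", ems_min_gq=20)

CRITERIA = {"stringent": STRINGENT, "redefined": REDEFINED}


@dataclass
class ClassifiedVariant:
    call: VariantCall
    category: str
    criteria: str
    carrier: str | None = None        # the one mutant plant, EMS only
    zygosity_class: str | None = None  # 'het' (0/1) or 'hom' (1/1 / 0/0 singleton)
    filter_reason: str | None = None


def apply_site_filters(calls: Iterable[VariantCall], criteria: CriteriaSet,
                       ) -> tuple[list[VariantCall], dict[str, int]]:
    """Sequential QUAL / DP / MQ / NS retention filter with a removal tally."""
    tally = {"input": 0, "fail_qual": 0, "fail_dp": 0, "fail_mq": 0,
             "fail_ns": 0, "retained": 0}
    retained = []
    for c in calls:
        tally["input"] += 1
        for name in ("qual", "dp", "mq", "ns"):
            if getattr(c, name) is None:
                raise ClassificationError(f"call at {c.unigene}:{c.pos + 1} "
                                          f"missing required field {name.upper()}")
        if c.qual < criteria.min_qual:
            tally["fail_qual"] += 1
        elif c.dp < criteria.min_dp:
            tally["fail_dp"] += 1
        elif c.mq < criteria.min_mq:
            tally["fail_mq"] += 1
        elif c.ns < criteria.min_samples_with_reads:
            tally["fail_ns"] += 1
        else:
            tally["retained"] += 1
            retained.append(c)
    return retained, tally


def _covered_genotypes(call: VariantCall) -> dict[str, tuple[int, int]]:
    out = {}
    for s, sc in call.samples.items():
        if sc.gt is not None and sc.gt[0] is not None:
            out[s] = tuple(sc.gt)
    return out


def _sole_deviator(gts: dict[str, tuple[int, int]]) -> str | None:
    """Sample whose genotype differs from the uniform genotype of all others.

    Uncovered samples are ignored. Requires >= 2 covered samples so that a
    'background' genotype exists at all.
    """
    if len(gts) < 2:
        return None
    by_gt: dict[tuple[int, int], list[str]] = {}
    for s, g in gts.items():
        by_gt.setdefault(g, []).append(s)
    if len(by_gt) != 2:
        return None
    (g1, s1), (g2, s2) = by_gt.items()
    if len(s1) == 1 and len(s2) > 1:
        return s1[0]
    if len(s2) == 1 and len(s1) > 1:
        return s2[0]
    return None


def find_singleton_candidate(call: VariantCall, criteria: CriteriaSet,
                             ) -> tuple[str | None, str | None, str | None]:
    """Locate a mutation-like singleton deviator at a retained site.

    Returns (deviator sample, zygosity class, rejection reason). A candidate
    requires (a) one covered sample whose genotype deviates from the uniform
    homozygous genotype (0/0 or 1/1) of all other covered samples, (b) the
    allele distinguishing the deviator to be absent from every other
    sample's reads — an induced change is private to one plant at the read
    level, whereas a homoeologous difference undercalled in the other plants
    still leaves tell-tale reads there — and (c) deviator GQ >= the
    criteria's threshold.
    """
    gts = _covered_genotypes(call)
    dev = _sole_deviator(gts)
    if dev is None:
        return None, None, "no_singleton"
    background = next(g for s, g in gts.items() if s != dev)
    if background not in ((0, 0), (1, 1)):
        return None, None, "het_background"
    # allele index carried by the deviator but not the uniform background
    distinguishing = 1 if 1 not in background else 0
    for s, sc in call.samples.items():
        if s != dev and sc.ad[distinguishing] > 0:
            return None, None, "not_private"
    gq = call.samples[dev].gq
    if gq is None or gq < criteria.ems_min_gq:
        return None, None, "low_gq"
    zyg = "het" if gts[dev] == (0, 1) else "hom"
    return dev, zyg, None


def classify(retained: Iterable[VariantCall], roles: dict[str, str],
             criteria: CriteriaSet) -> list[ClassifiedVariant]:
    """Categorize each retained call.

    Precedence: intervarietal (every covered sample 1/1) first; then the
    singleton-deviator rule (EMS when the deviator is a mutant plant with
    GQ >= the criteria's threshold; wild-type deviators are routed to the
    error-rate accounting, never to EMS); then homoeologous (alternate
    allele in two or more samples); anything else is filtered. Exactly one
    category per call, so the classes partition the retained set.
    """
    out: list[ClassifiedVariant] = []
    for call in retained:
        for s in call.samples:
            if s not in roles:
                raise ClassificationError(f"sample {s} has no declared role")
        gts = _covered_genotypes(call)
        alt_samples = [s for s, g in gts.items() if 1 in g]
        cat = ClassifiedVariant(call, CATEGORY_FILTERED, criteria.name)
        dev, zyg, reason = find_singleton_candidate(call, criteria)
        if gts and all(g == (1, 1) for g in gts.values()):
            cat.category = CATEGORY_INTERVARIETAL
        elif dev is not None and roles[dev] == "wildtype":
            cat.filter_reason = "wildtype_deviation"
        elif dev is not None:
            cat.category = (CATEGORY_EMS_INDEL if call.is_indel
                            else CATEGORY_EMS_SNP)
            cat.carrier = dev
            cat.zygosity_class = zyg
        elif len(alt_samples) >= 2:
            cat.category = CATEGORY_HOMOEOLOGOUS
        else:
            cat.filter_reason = reason
        out.append(cat)
    return out


def estimate_error_rate(retained: Iterable[VariantCall], roles: dict[str, str],
                        criteria: CriteriaSet = STRINGENT,
                        ) -> dict[str, float | int | None]:
    """EMS-calling error rate from the non-mutagenized plants.

    Denominator: retained variants at which at least one wild-type plant has
    reads. Numerator: those where a wild-type plant is the sole deviator
    from an otherwise uniform genotype (its GQ passing the same threshold a
    mutant would need). Rate is reported in percent.
    """
    wildtypes = {s for s, r in roles.items() if r == "wildtype"}
    if not wildtypes:
        raise ClassificationError("error-rate estimation needs >= 1 wild-type plant")
    denom = numer = 0
    for call in retained:
        wt_covered = any(call.samples.get(s) is not None and
                         call.samples[s].dp > 0 for s in wildtypes)
        if not wt_covered:
            continue
        denom += 1
        dev, _zyg, _reason = find_singleton_candidate(call, criteria)
        if dev in wildtypes:
            numer += 1
    rate = 100.0 * numer / denom if denom else None
    return {"numerator": numer, "denominator": denom, "rate_percent": rate,
            "undefined": denom == 0}


def error_rate_percent(numerator: int, denominator: int) -> float:
    """Percent error rate, 2 decimals, as reported for wild-type deviators."""
    if denominator == 0:
        raise ClassificationError("zero denominator: error rate undefined")
    return round(100.0 * numerator / denominator, 2)


def summarize_by_plant(classified: Iterable[ClassifiedVariant],
                       mutants: Sequence[str]) -> pd.DataFrame:
    """Per-plant EMS SNP / INDEL counts and distinct unigenes hit."""
    snps = {p: 0 for p in mutants}
    indels = {p: 0 for p in mutants}
    unigenes: dict[str, set[str]] = {p: set() for p in mutants}
    for cv in classified:
        if cv.carrier is None:
            continue
        if cv.category == CATEGORY_EMS_SNP:
            snps[cv.carrier] += 1
        elif cv.category == CATEGORY_EMS_INDEL:
            indels[cv.carrier] += 1
        unigenes[cv.carrier].add(cv.call.unigene)
    df = pd.DataFrame({
        "plant": list(mutants),
        "ems_snps": [snps[p] for p in mutants],
        "ems_indels": [indels[p] for p in mutants],
        "unigenes_hit": [len(unigenes[p]) for p in mutants],
    })
    total = pd.DataFrame({
        "plant": ["total"],
        "ems_snps": [df["ems_snps"].sum()],
        "ems_indels": [df["ems_indels"].sum()],
        "unigenes_hit": [len(set().union(*unigenes.values())) if mutants else 0],
    })
    return pd.concat([df, total], ignore_index=True)


def read_roles(path: str | Path) -> dict[str, str]:
    roles = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sample"):
            raise ClassificationError(f"{path}: expected 'sample\\trole' header")
        for line in fh:
            if line.strip():
                sample, role = line.rstrip("\n").split("\t")[:2]
                if role not in ("mutant", "wildtype"):
                    raise ClassificationError(f"unknown role {role!r} for {sample}")
                roles[sample] = role
    return roles


def classified_to_frame(classified: Iterable[ClassifiedVariant]) -> pd.DataFrame:
    rows = []
    for cv in classified:
        c = cv.call
        rows.append({
            "unigene": c.unigene, "pos": c.pos, "ref": c.ref, "alt": c.alt,
            "qual": c.qual, "dp": c.dp, "ns": c.ns, "mq": c.mq,
            "category": cv.category, "criteria": cv.criteria,
            "carrier": cv.carrier or "", "zygosity": cv.zygosity_class or "",
            "filter_reason": cv.filter_reason or "",
        })
    return pd.DataFrame(rows)
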
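"""Consensus-chromosome physical mapping of mutation-bearing unigenes.

Each arm of the seven wheat consensus chromosomes is split into three
deletion-bin regions — R1 proximal to the centromere, R2 middle, R3 distal —
with a known number of physically mapped ESTs per region. Unigenes carrying
EMS hits are localized by sequence similarity to those anchor ESTs, and
per-region mutation counts are normalized by the region's mapped-EST count
to give comparable regional mutation loads.

The packaged consensus map (``data/wheat_consensus_region_map.tsv``) carries
the 42 regions with their fraction-length intervals, anchor-EST counts and
the observed mutation counts of the bundled regression fixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import Align


class PhysmapError(ValueError):
    pass


def _round2(x: float) -> float:
    return math.floor(x * 100 + 0.5) / 100


def load_region_map(path: str | Path | None = None) -> pd.DataFrame:
    """Region table: group, arm, region, interval, mapped ESTs (+ fixture
    observed mutation counts)."""
    if path is None:
        src = resources.files("polymut.data") / "wheat_consensus_region_map.tsv"
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"group", "arm", "region", "interval_start", "interval_end",
                "mapped_ests"}
    missing = required - set(df.columns)
    if missing:
        raise PhysmapError(f"region map missing columns {sorted(missing)}")
    return df


def region_loads(region_map: pd.DataFrame,
                 observed: dict[tuple[int, str, str], int] | None = None,
                 ) -> pd.DataFrame:
    """Normalized mutation load per region, arm and chromosome.

    ``observed`` maps (group, arm, region) to a mutation count; when None
    the region map's own ``observed_mutations`` column (the bundled
    fixture) is used. The per-region load is observed / mapped ESTs
    rounded to 2 decimals; arm and chromosome sums are computed on the
    *unrounded* loads and then rounded, which is how the printed table
    arithmetic reproduces.
    """
    df = region_map.copy()
    if observed is not None:
        df["observed_mutations"] = [
            observed.get((g, a, r), 0)
            for g, a, r in zip(df["group"], df["arm"], df["region"])]
    elif "observed_mutations" not in df.columns:
        raise PhysmapError("no observed mutation counts supplied")
    bad = df[(df["observed_mutations"] > 0) & (df["mapped_ests"] <= 0)]
    if len(bad):
        raise PhysmapError(
            "regions with observed mutations but zero mapped ESTs: "
            + ", ".join(f"{g}{a}-{r}" for g, a, r in
                        zip(bad["group"], bad["arm"], bad["region"])))
    exact = df["observed_mutations"] / df["mapped_ests"].where(
        df["mapped_ests"] > 0, other=pd.NA).astype(float)
    exact = exact.fillna(0.0)
    df["normalized"] = [_round2(x) for x in exact]
    arm_exact = exact.groupby([df["group"], df["arm"]]).sum()
    df["arm_sum"] = [
        _round2(arm_exact[(g, a)]) for g, a in zip(df["group"], df["arm"])]
    chrom_exact = exact.groupby(df["group"]).sum()
    df["chromosome_sum"] = [_round2(chrom_exact[g]) for g in df["group"]]
    return df


# ---------------------------------------------------------------------------
# unigene -> region assignment by similarity to anchor ESTs

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


@dataclass
class EstHit:
    est: str
    region: tuple[int, str, str]
    identity: float
    aligned_length: int
    score: float


def assign_unigenes(unigene_seqs: dict[str, str],
                    est_seqs: dict[str, str],
                    est_regions: dict[str, tuple[int, str, str]],
                    min_identity: float = 0.95,
                    min_length: int = 200,
                    ) -> dict[str, tuple[int, str, str] | None]:
    """Place each unigene in the region of its best-matching anchor EST.

    Local alignment against every EST; the best-scoring hit assigns its
    region when it reaches ``min_identity`` over ``min_length`` aligned
    bases (an identity/length stand-in for a stringent E-value cutoff).
    Score ties between ESTs from different regions leave the unigene
    unassigned, as do unigenes with no qualifying hit.
    """
    if not est_seqs:
        raise PhysmapError("empty anchor-EST set")
    aligner = _make_aligner()
    out: dict[str, tuple[int, str, str] | None] = {}
    for uid in sorted(unigene_seqs):
        useq = unigene_seqs[uid]
        hits: list[EstHit] = []
        for est in sorted(est_seqs):
            aln = aligner.align(useq, est_seqs[est])
            if len(aln) == 0:
                continue
            best = aln[0]
            matches = aligned = 0
            for (u0, u1), (e0, e1) in zip(*best.aligned):
                aligned += u1 - u0
                matches += sum(a == b for a, b in
                               zip(useq[u0:u1], est_seqs[est][e0:e1]))
            if aligned == 0:
                continue
            hits.append(EstHit(est, est_regions[est], matches / aligned,
                               aligned, best.score))
        qualifying = [h for h in hits
                      if h.identity >= min_identity and
                      h.aligned_length >= min_length]
        if not qualifying:
            out[uid] = None
            continue
        top = max(h.score for h in qualifying)
        top_regions = {h.region for h in qualifying if h.score == top}
        out[uid] = top_regions.pop() if len(top_regions) == 1 else None
    return out


def loads_from_assignments(assignments: dict[str, tuple[int, str, str] | None],
                           ems_counts: dict[str, int],
                           region_map: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-unigene EMS counts into region loads."""
    observed: dict[tuple[int, str, str], int] = {}
    for uid, region in assignments.items():
        if region is not None:
            observed[region] = observed.get(region, 0) + ems_counts.get(uid, 0)
    return region_loads(region_map, observed)
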
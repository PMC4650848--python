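"""End-to-end orchestration: simulate -> demux -> map -> call -> classify ->
report, with plain-file handoff between stages and a JSON run manifest.

Each stage reads and writes ordinary FASTQ/SAM/VCF/TSV files, so any stage
can be swapped for an external tool (e.g. BWA for mapping) without touching
the rest, and a fixed seed reproduces the artifact tree byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import align, charstats, classify, pileup, readprep
from .classify import CRITERIA, ClassifiedVariant
from .simulate import GroundTruth, SimConfig, simulate_experiment

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class RunConfig:
    outdir: Path
    criteria: str = "stringent"
    seed: int = 42
    sim: SimConfig | None = None        # simulate inputs when set ...
    reference: Path | None = None       # ... otherwise start from files
    fastq: Path | None = None
    barcodes: Path | None = None
    roles: Path | None = None
    trim_len: int = 64
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.criteria not in CRITERIA:
            raise PipelineError("config", f"unknown criteria {self.criteria!r}; "
                                f"choose from {sorted(CRITERIA)}")
        if self.sim is None:
            for name in ("reference", "fastq", "barcodes", "roles"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise PipelineError(
                        "config", f"missing input file for {name!r}: {p}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest: dict = {"seed": config.seed, "criteria": config.criteria,
                      "stages": {}, "outputs": {}}
    t0 = time.time()

    def stage(name):
        log.info("stage %s", name)
        manifest["stages"][name] = {"started_s": round(time.time() - t0, 2)}
        return manifest["stages"][name]

    truth = None
    if config.sim is not None:
        st = stage("simulate")
        sim = simulate_experiment(config.sim, out / "sim")
        truth = sim.truth
        reference_path = sim.paths["reference"]
        fastq_path = sim.paths["fastq"]
        barcode_path = sim.paths["barcodes"]
        roles_path = sim.paths["roles"]
        st["reads"] = sum(1 for _ in open(fastq_path)) // 4
        st["ems_events_planted"] = len(truth.ems_events)
    else:
        reference_path = Path(config.reference)
        fastq_path = Path(config.fastq)
        barcode_path = Path(config.barcodes)
        roles_path = Path(config.roles)

    st = stage("demux")
    try:
        barcodes = readprep.BarcodeTable.from_tsv(barcode_path)
        stats = readprep.demux_fastq(fastq_path, barcodes, out / "demux",
                                     config.trim_len)
    except (readprep.BarcodeError, readprep.FastqParseError) as exc:
        raise PipelineError("demux", str(exc)) from exc
    st.update(total_reads=stats.total_reads, with_barcode=stats.with_barcode,
              with_remnant=stats.with_remnant, retained=stats.retained)

    st = stage("map")
    reference = align.read_reference(reference_path)
    index = align.build_index(reference)
    aligned_dir = out / "aligned"
    aligned_dir.mkdir(exist_ok=True)
    per_sample: dict[str, list[align.AlignmentRecord]] = {}
    mapped = total = 0
    for sample in sorted(barcodes.entries):
        reads = list(readprep.parse_fastq(out / "demux" / f"{sample}.fastq"))
        recs = align.map_reads(reads, index, sample)
        align.write_sam(recs, reference, aligned_dir / f"{sample}.sam")
        per_sample[sample] = [r for r in recs if r.mapped]
        mapped += len(per_sample[sample])
        total += len(recs)
    st.update(reads=total, mapped=mapped,
              mapped_fraction=round(mapped / total, 4) if total else None)

    st = stage("call")
    roles = classify.read_roles(roles_path)
    samples = sorted(barcodes.entries)
    calls = pileup.call_variants(per_sample, reference, all_samples=samples)
    vcf_path = out / "calls.vcf"
    pileup.write_vcf(calls, reference, samples, vcf_path)
    st["variant_sites"] = len(calls)

    st = stage("classify")
    criteria = CRITERIA[config.criteria]
    retained, tally = classify.apply_site_filters(calls, criteria)
    classified = classify.classify(retained, roles, criteria)
    err = classify.estimate_error_rate(retained, roles, criteria) \
        if any(r == "wildtype" for r in roles.values()) else None
    classify.classified_to_frame(classified).to_csv(
        out / "classified.tsv", sep="\t", index=False)
    by_cat: dict[str, int] = {}
    for cv in classified:
        by_cat[cv.category] = by_cat.get(cv.category, 0) + 1
    st.update(filter_tally=tally, categories=by_cat,
              error_rate=err)

    st = stage("report")
    mutants = sorted(s for s, r in roles.items() if r == "mutant")
    per_plant = classify.summarize_by_plant(classified, mutants)
    per_plant.to_csv(out / "per_plant.tsv", sep="\t", index=False)
    ems_snp_pairs = [(cv.call.ref, cv.call.alt) for cv in classified
                     if cv.category == classify.CATEGORY_EMS_SNP]
    spec_df = charstats.spectrum(ems_snp_pairs)
    spec_df.to_csv(out / "spectrum.tsv", sep="\t")
    summaries = charstats.coverage_depth_summary(
        [r for recs in per_sample.values() for r in recs], reference)
    covered_bp = charstats.total_covered_bp(summaries)
    n_ems = sum(1 for cv in classified
                if cv.category in (classify.CATEGORY_EMS_SNP,
                                   classify.CATEGORY_EMS_INDEL))
    st.update(ems_total=n_ems,
              transitions_pct=spec_df.attrs["transitions_pct"],
              covered_bp=covered_bp,
              kb_per_mutation=(charstats.mutation_frequency(covered_bp, n_ems)
                               if covered_bp and n_ems else None))

    if truth is not None:
        metrics = compare_to_truth(classified, truth, retained)
        manifest["validation"] = metrics

    manifest["runtime_s"] = round(time.time() - t0, 2)
    manifest["outputs"] = {
        "vcf": str(vcf_path), "classified": str(out / "classified.tsv"),
        "per_plant": str(out / "per_plant.tsv"),
        "spectrum": str(out / "spectrum.tsv"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# validation against simulator ground truth

def _ems_truth_keys(truth: GroundTruth) -> set[tuple]:
    return {(e.plant, e.unigene, e.pos, e.ref, e.alt)
            for e in truth.ems_events}


def compare_to_truth(classified: list[ClassifiedVariant], truth: GroundTruth,
                     retained_calls=None) -> dict:
    """Recall/precision of EMS detection and a per-class confusion table.

    EMS events are keyed by (plant, unigene, position, REF, ALT).
    ``filter_passing`` restricts the recall denominator to planted events
    whose site survived the site filters (detection power at covered,
    well-supported sites); ``overall`` counts every planted event.
    """
    truth_keys = _ems_truth_keys(truth)
    homoeo_pos = {(s.unigene, s.pos) for s in truth.homoeo_sites}
    inter_pos = {(s.unigene, s.pos) for s in truth.intervarietal_sites}
    detected: set[tuple] = set()
    confusion: dict[str, dict[str, int]] = {}
    for cv in classified:
        key = (cv.call.unigene, cv.call.pos)
        if key in homoeo_pos:
            true_cat = "homoeologous"
        elif key in inter_pos:
            true_cat = "intervarietal"
        elif (cv.carrier, cv.call.unigene, cv.call.pos, cv.call.ref,
              cv.call.alt) in truth_keys:
            true_cat = "EMS"
        elif any((p, cv.call.unigene, cv.call.pos, cv.call.ref, cv.call.alt)
                 in truth_keys for p in {e.plant for e in truth.ems_events}):
            true_cat = "EMS"
        else:
            true_cat = "none"
        pred = ("EMS" if cv.category in ("EMS_SNP", "EMS_INDEL")
                else cv.category)
        confusion.setdefault(true_cat, {}).setdefault(pred, 0)
        confusion[true_cat][pred] += 1
        if pred == "EMS":
            detected.add((cv.carrier, cv.call.unigene, cv.call.pos,
                          cv.call.ref, cv.call.alt))
    tp = len(detected & truth_keys)
    fp = len(detected - truth_keys)
    metrics: dict = {
        "ems_planted": len(truth_keys),
        "ems_detected": len(detected),
        "ems_true_positive": tp,
        "ems_false_positive": fp,
        "precision": tp / len(detected) if detected else None,
        "recall_overall": tp / len(truth_keys) if truth_keys else None,
        "homoeologous_classified_ems": confusion.get(
            "homoeologous", {}).get("EMS", 0),
        "confusion": confusion,
    }
    if not truth_keys:
        metrics["recall_undefined"] = True
    if retained_calls is not None:
        retained_pos = {(c.unigene, c.pos, c.ref, c.alt)
                        for c in retained_calls}
        passing = {k for k in truth_keys
                   if (k[1], k[2], k[3], k[4]) in retained_pos}
        metrics["ems_filter_passing"] = len(passing)
        metrics["recall_filter_passing"] = (
            len(detected & passing) / len(passing) if passing else None)
    return metrics


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    sim = None
    if raw.get("sim"):
        s = dict(raw["sim"])
        if "unigene_len_range" in s:
            s["unigene_len_range"] = tuple(s["unigene_len_range"])
        sim = SimConfig(**s)
    kwargs = {k: v for k, v in raw.items() if k != "sim"}
    for k in ("outdir", "reference", "fastq", "barcodes", "roles"):
        if kwargs.get(k) is not None:
            kwargs[k] = Path(kwargs[k])
    return RunConfig(sim=sim, **kwargs)
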
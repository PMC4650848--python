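"""Shared fixtures: one small simulated experiment and one full pipeline
run, computed once per session and reused read-only across test modules."""

from __future__ import annotations

import json
from pathlib import Path

import pytest

from polymut import align, pileup, readprep
from polymut.pipeline import RunConfig, run_pipeline
from polymut.simulate import SimConfig, read_truth_tables

SMALL_SIM = dict(n_unigenes=30, seed=7)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory) -> Path:
    """Full pipeline run on a 30-unigene simulation; returns the output dir."""
    out = tmp_path_factory.mktemp("run") / "small"
    run_pipeline(RunConfig(outdir=out, sim=SimConfig(**SMALL_SIM), seed=7,
                           log_level="ERROR"))
    return out


@pytest.fixture(scope="session")
def small_manifest(small_run) -> dict:
    with open(small_run / "manifest.json") as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def small_truth(small_run):
    return read_truth_tables(small_run / "sim")


@pytest.fixture(scope="session")
def small_reference(small_run) -> dict[str, str]:
    return align.read_reference(small_run / "sim" / "reference.fa")


@pytest.fixture(scope="session")
def small_alignments(small_run, small_reference):
    """Per-sample mapped AlignmentRecords re-read from the run's SAMs."""
    per_sample = {}
    for sam in sorted((small_run / "aligned").glob("*.sam")):
        recs = [r for r in align.read_sam(sam, small_reference) if r.mapped]
        per_sample[sam.stem] = recs
    return per_sample


@pytest.fixture(scope="session")
def small_calls(small_run):
    return pileup.read_vcf(small_run / "calls.vcf")


@pytest.fixture(scope="session")
def small_roles(small_run):
    from polymut.classify import read_roles
    return read_roles(small_run / "sim" / "roles.tsv")


@pytest.fixture(scope="session")
def small_barcodes(small_run):
    return readprep.BarcodeTable.from_tsv(small_run / "sim" / "barcodes.tsv")
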
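"""Shared fixtures: generated references, study run directory, pipeline results.

Everything is generated programmatically at fixed seeds; expensive artefacts
(the full study run, the multi-seed metabarcoding recovery panel) are built
once per session and shared across test modules.
"""

from __future__ import annotations

from pathlib import Path

import pytest

import puerabar as pb
from puerabar.metabar import FilterParams, run_metabarcoding
from puerabar.synthetic_data import SampleSpec, simulate_reads

REF_SEED = 1
STUDY_SEED = 7
RECOVERY_SEEDS = list(range(101, 111))
RECOVERY_COMPOSITION = {"pml": 0.60, "asp": 0.25, "hvu": 0.15}
RECOVERY_READS = 5000


@pytest.fixture(scope="session")
def refs():
    return pb.make_references(REF_SEED)


@pytest.fixture(scope="session")
def ref_dir(tmp_path_factory, refs) -> Path:
    out = tmp_path_factory.mktemp("refs")
    refs.write(out)
    return out


@pytest.fixture(scope="session")
def db(ref_dir) -> pb.ReferenceDB:
    return pb.build_reference_db(ref_dir / "refs.fasta", ref_dir / "taxonomy.tsv")


@pytest.fixture(scope="session")
def sites(db) -> pb.SiteTable:
    return pb.detect_variable_sites(db, "lobata", "thomsonii")


@pytest.fixture(scope="session")
def study_run(tmp_path_factory) -> Path:
    out = tmp_path_factory.mktemp("study")
    pb.make_study_fixtures(STUDY_SEED, out, n_reads=2000)
    return out


@pytest.fixture(scope="session")
def study_db_sites(study_run):
    db, sites, manifest = pb.load_run(study_run)
    return db, sites, manifest


@pytest.fixture(scope="session")
def raw_panel_report(study_run, study_db_sites) -> pb.AuthReport:
    db, sites, _ = study_db_sites
    return pb.authenticate_sanger_panel(study_run, db, sites)


@pytest.fixture(scope="session")
def metabar_panel(study_run, study_db_sites):
    db, sites, _ = study_db_sites
    return pb.authenticate_metabarcoding_panel(study_run, db, sites)


@pytest.fixture(scope="session")
def recovery_runs(refs, db, sites):
    """Per-seed metabarcoding recovery: (truth composition, measured
    proportions by taxon_id) for a mixed herbal-product read set."""
    results = []
    tag = "ACGTACGTAC"
    for seed in RECOVERY_SEEDS:
        spec = SampleSpec(f"MIX{seed}", "pml", RECOVERY_COMPOSITION,
                          RECOVERY_READS, error_rate=0.002,
                          product_type="herbal", tag=tag)
        reads, truth = simulate_reads(spec, refs, seed=seed)
        comp, assignments, _ = run_metabarcoding(
            reads, {spec.sample_id: tag}, db, sites, filters=FilterParams())
        measured: dict[str, float] = {}
        total = sum(c.count for c, _ in assignments[spec.sample_id])
        for cluster, result in assignments[spec.sample_id]:
            measured[result.taxon_id] = (
                measured.get(result.taxon_id, 0.0) + cluster.count / total)
        results.append((truth, measured))
    return results
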
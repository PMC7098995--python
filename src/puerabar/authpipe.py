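"""End-to-end authentication runs and label-consistency reporting.

A run directory (as produced by :func:`puerabar.synthetic_data.make_study_fixtures`,
or assembled by hand in the same layout) holds the reference database, the
per-sample Sanger traces, the pooled metabarcoding reads and a sample
manifest.  The Sanger path calls bases on both trace directions, assembles a
consensus, triages the trace (type A/B/C) and calls the subspecies; type-C
traces yield no reliable barcode and are reported as failed.  The
metabarcoding path runs the full read pipeline and reports the dominant
*Pueraria* subspecies plus any contaminant taxon above a reporting
threshold.  Chemistry (TLC/HPLC) results are never computed — they are
user-supplied pass/fail annotations carried through to the report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import metabar
from .metabar import CompositionTable, FilterParams, read_tag_manifest
from .refdb import (IdentityThresholds, ReferenceDB, SiteTable,
                    build_reference_db, call_subspecies, detect_variable_sites)
from .sanger import Chromatogram, assemble_bidirectional, call_bases, classify_trace

DEFAULT_CONTAMINANT_THRESHOLD = 0.01   # fraction of retained reads
FOCAL_GROUPS = ("lobata", "thomsonii")


@dataclass
class SampleResult:
    sample_id: str
    label_taxon: str
    called_taxon: str
    consistent: bool
    trace_class: str | None = None
    composition_summary: str | None = None
    contaminants: list[str] = field(default_factory=list)
    chemistry_note: str = ""


@dataclass
class AuthReport:
    rows: list[SampleResult]

    @property
    def n_samples(self) -> int:
        return len(self.rows)

    @property
    def n_consistent(self) -> int:
        return sum(1 for r in self.rows if r.consistent)

    @property
    def consistency_pct(self) -> float:
        if not self.rows:
            return 0.0
        return round(100.0 * self.n_consistent / self.n_samples, 1)

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            d = asdict(r)
            d["contaminants"] = ";".join(r.contaminants)
            recs.append(d)
        return pd.DataFrame(recs)

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_samples": self.n_samples,
            "n_consistent": self.n_consistent,
            "consistency_pct": self.consistency_pct,
            "samples": [asdict(r) for r in self.rows],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    def attach_chemistry(self, notes: Mapping[str, str]) -> None:
        for r in self.rows:
            if r.sample_id in notes:
                r.chemistry_note = notes[r.sample_id]


def load_run(run_dir: str | Path) -> tuple[ReferenceDB, SiteTable, pd.DataFrame]:
    """Reference DB, recomputed diagnostic sites and manifest of a run dir."""
    run = Path(run_dir)
    db = build_reference_db(run / "refs" / "refs.fasta",
                            run / "refs" / "taxonomy.tsv")
    sites = detect_variable_sites(db, *FOCAL_GROUPS)
    manifest = pd.read_csv(run / "manifest.tsv", sep="\t", dtype=str)
    return db, sites, manifest


def authenticate_sanger_panel(run_dir: str | Path, db: ReferenceDB,
                              sites: SiteTable,
                              product_types: tuple[str, ...] = ("raw_material",),
                              thresholds: IdentityThresholds = IdentityThresholds()
                              ) -> AuthReport:
    """Sanger path over every manifest sample of the given product types.

    Per sample: call both trace directions, classify the forward trace,
    assemble the bidirectional consensus and call the subspecies; a sample is
    consistent when the called taxon equals the label taxon exactly.  Type-C
    traces and any per-sample error are recorded as "failed" (inconsistent)
    rather than aborting the panel.
    """
    run = Path(run_dir)
    manifest = pd.read_csv(run / "manifest.tsv", sep="\t", dtype=str)
    rows: list[SampleResult] = []
    for rec in manifest.itertuples(index=False):
        if rec.product_type not in product_types:
            continue
        called = "failed"
        trace_label = None
        try:
            fwd_chrom = Chromatogram.from_tsv(
                run / "sanger" / f"{rec.sample_id}_fwd.tsv", rec.sample_id)
            rev_chrom = Chromatogram.from_tsv(
                run / "sanger" / f"{rec.sample_id}_rev.tsv", rec.sample_id,
                direction="reverse")
            fwd = call_bases(fwd_chrom)
            rev = call_bases(rev_chrom)
            trace = classify_trace(fwd, sites)
            trace_label = trace.label
            if trace.label != "C":
                consensus = assemble_bidirectional(fwd, rev)
                call = call_subspecies(consensus, db, sites, thresholds,
                                       query_id=rec.sample_id)
                called = call.called_taxon
        except (ValueError, OSError):
            called = "failed"
        rows.append(SampleResult(
            sample_id=rec.sample_id,
            label_taxon=rec.label_taxon,
            called_taxon=called,
            consistent=called == rec.label_taxon,
            trace_class=trace_label,
        ))
    return AuthReport(rows)


def authenticate_metabarcoding_panel(run_dir: str | Path, db: ReferenceDB,
                                     sites: SiteTable,
                                     filters: FilterParams = FilterParams(),
                                     contaminant_threshold: float =
                                     DEFAULT_CONTAMINANT_THRESHOLD,
                                     thresholds: IdentityThresholds =
                                     IdentityThresholds()
                                     ) -> tuple[AuthReport, CompositionTable]:
    """Metabarcoding path over the pooled reads of a run directory.

    The dominant *Pueraria* subspecies of each sample (largest retained read
    share among focal-group assignments) becomes the called taxon; every
    non-*Pueraria* taxon at or above ``contaminant_threshold`` of the
    sample's retained reads is listed as a contaminant.
    """
    run = Path(run_dir)
    manifest = pd.read_csv(run / "manifest.tsv", sep="\t", dtype=str)
    labels = dict(zip(manifest.sample_id, manifest.label_taxon))
    tag_manifest = read_tag_manifest(run / "metabar" / "tags.tsv")
    comp, assignments, _ = metabar.run_metabarcoding(
        run / "metabar" / "pooled.fastq", tag_manifest, db, sites,
        filters=filters, thresholds=thresholds)

    focal_taxa = {db.group_taxon_id(g) for g in FOCAL_GROUPS}
    rows: list[SampleResult] = []
    for sample_id in tag_manifest:
        pueraria: dict[str, int] = {}
        others: dict[str, tuple[str, int]] = {}
        total = 0
        for cluster, result in assignments.get(sample_id, []):
            total += cluster.count
            if result.taxon_id in focal_taxa:
                pueraria[result.taxon_id] = (
                    pueraria.get(result.taxon_id, 0) + cluster.count)
            else:
                name, n = others.get(result.taxon_id, (result.taxon_name, 0))
                others[result.taxon_id] = (name, n + cluster.count)
        if total == 0:
            called = "failed"
            contaminants: list[str] = []
        else:
            called = (max(sorted(pueraria), key=lambda t: pueraria[t])
                      if pueraria else "failed")
            contaminants = sorted(
                name for name, n in others.values()
                if name != "unassigned" and n / total >= contaminant_threshold)
        rows.append(SampleResult(
            sample_id=sample_id,
            label_taxon=labels.get(sample_id, ""),
            called_taxon=called,
            consistent=called == labels.get(sample_id, ""),
            composition_summary=_summarize(comp, sample_id),
            contaminants=contaminants,
        ))
    return AuthReport(rows), comp


def _summarize(comp: CompositionTable, sample_id: str) -> str:
    parts = [f"{taxon}:{reads}({100.0 * prop:.1f}%)"
             for sid, taxon, reads, prop in comp.rows if sid == sample_id]
    return "; ".join(parts)


def run_cli(argv: list[str] | None = None) -> int:
    """Run the command-line interface; returns the process exit status."""
    from .cli import main as _main
    try:
        _main.main(args=argv, prog_name="puerabar")
    except SystemExit as exc:
        code = exc.code
        return code if isinstance(code, int) else (0 if code is None else 1)
    return 0


def classify_herbal_traces(run_dir: str | Path,
                           sites: SiteTable) -> dict[str, str]:
    """Type A/B/C label per herbal sample, from the forward trace."""
    run = Path(run_dir)
    manifest = pd.read_csv(run / "manifest.tsv", sep="\t", dtype=str)
    out: dict[str, str] = {}
    for rec in manifest.itertuples(index=False):
        if rec.product_type != "herbal":
            continue
        chrom = Chromatogram.from_tsv(
            run / "sanger" / f"{rec.sample_id}_fwd.tsv", rec.sample_id)
        out[rec.sample_id] = classify_trace(call_bases(chrom), sites).label
    return out
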
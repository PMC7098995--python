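"""Amplicon metabarcoding pipeline.

Pooled single-end reads carry a 10-bp sample tag at the 5' end.  The
pipeline demultiplexes by tag, removes low-quality reads (length < 300 or
mean Phred < 30, the conventional amplicon thresholds), trims each read to
its ITS2 region using position-weight-matrix anchors trained on the
conserved 5.8S/28S flanks of the annotated references, collapses identical
trimmed reads, keeps unique sequences seen more than 10 times, assigns each
retained unique sequence by best-identity search of the reference database
(with subspecies resolution through the diagnostic-site caller for
*Pueraria* hits), and tabulates per-sample taxon composition.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .refdb import (IdentityThresholds, ReferenceDB, SiteTable, align_pair,
                    call_subspecies, reverse_complement)

TAG_LENGTH = 10
DEFAULT_MIN_LENGTH = 300
DEFAULT_MIN_AVG_QV = 30.0
DEFAULT_MIN_COPIES = 11          # "more than 10 repetitions" retained


# --------------------------------------------------------------------------
# Reads
# --------------------------------------------------------------------------

@dataclass
class TaggedRead:
    read_id: str
    sequence: str
    quality: list[int]               # Phred scores, one per base
    tag: str = ""
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.quality) != len(self.sequence):
            raise ValueError(f"{self.read_id}: quality/sequence length mismatch")

    @property
    def mean_qv(self) -> float:
        return float(np.mean(self.quality)) if self.quality else 0.0


@dataclass
class ReadBatch:
    sample_id: str
    reads: list[TaggedRead] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)


def read_fastq(path: str | Path) -> list[TaggedRead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(TaggedRead(rec.id, str(rec.seq).upper(),
                                list(rec.letter_annotations["phred_quality"])))
    return reads


def write_fastq(reads: Iterable[TaggedRead], path: str | Path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(r.quality)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_tag_manifest(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["sample_id", "tag"]:
        raise ValueError("tag manifest header must be: sample_id  tag")
    return dict(zip(df.sample_id, df.tag))


# --------------------------------------------------------------------------
# Demultiplexing
# --------------------------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def demultiplex(reads: Iterable[TaggedRead] | str | Path,
                tag_manifest: Mapping[str, str],
                max_mismatch: int = 0) -> tuple[dict[str, ReadBatch], ReadBatch]:
    """Partition reads by their leading 10-bp tag.

    A read goes to the unique sample whose tag is within ``max_mismatch`` of
    its first 10 bases (tag and its quality values are then stripped);
    unmatched or ambiguous reads land in the unassigned bin.  The partition
    is exhaustive and disjoint.
    """
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)
    tags = dict(tag_manifest)
    for sid, tag in tags.items():
        if len(tag) != TAG_LENGTH:
            raise ValueError(f"sample {sid}: tag must be {TAG_LENGTH} bases")
    items = list(tags.items())
    for i, (si, ti) in enumerate(items):
        for sj, tj in items[i + 1:]:
            if _hamming(ti, tj) <= max_mismatch:
                raise ValueError(
                    f"colliding tags: {si} and {sj} are within "
                    f"{max_mismatch} mismatches")
    batches = {sid: ReadBatch(sid) for sid in tags}
    unassigned = ReadBatch("unassigned")
    for read in reads:
        prefix = read.sequence[:TAG_LENGTH]
        hits = [sid for sid, tag in tags.items()
                if len(prefix) == TAG_LENGTH and _hamming(prefix, tag) <= max_mismatch]
        if len(hits) == 1:
            sid = hits[0]
            batches[sid].reads.append(TaggedRead(
                read.read_id,
                read.sequence[TAG_LENGTH:],
                read.quality[TAG_LENGTH:],
                tag=prefix,
                sample_id=sid,
            ))
        else:
            unassigned.reads.append(read)
    return batches, unassigned


# --------------------------------------------------------------------------
# Quality filtering
# --------------------------------------------------------------------------

def quality_filter(batch: ReadBatch,
                   min_length: int = DEFAULT_MIN_LENGTH,
                   min_avg_qv: float = DEFAULT_MIN_AVG_QV) -> ReadBatch:
    """Keep reads with length >= min_length and mean Phred >= min_avg_qv."""
    kept = [r for r in batch.reads
            if len(r.sequence) >= min_length and r.mean_qv >= min_avg_qv]
    return ReadBatch(batch.sample_id, kept)


# --------------------------------------------------------------------------
# ITS2 extraction by flank anchors
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Its2Hit:
    sequence: str
    start: int          # 1-based, on the reported strand
    end: int            # inclusive
    strand: str         # + | -


class AnchorModel:
    """Two PWM anchors bracketing ITS2: end of 5.8S and start of 28S.

    Each anchor is a log-odds position weight matrix (pseudocount-smoothed
    column frequencies against a uniform background).  A window counts as an
    anchor occurrence when it scores at least ``min_score_frac`` of the
    matrix's maximum attainable score, which tolerates a few point errors.
    """

    def __init__(self, left_pwm: np.ndarray, right_pwm: np.ndarray,
                 min_score_frac: float = 0.6) -> None:
        for pwm in (left_pwm, right_pwm):
            if pwm.ndim != 2 or pwm.shape[1] != 5:
                raise ValueError("PWM must have shape (anchor_len, 5)")
        self.left_pwm = left_pwm
        self.right_pwm = right_pwm
        self.min_score_frac = min_score_frac

    @classmethod
    def from_sequences(cls, left_flanks: Sequence[str], right_flanks: Sequence[str],
                       anchor_len: int = 20, pseudocount: float = 0.1,
                       min_score_frac: float = 0.6) -> "AnchorModel":
        left = [f[-anchor_len:] for f in left_flanks]
        right = [f[:anchor_len] for f in right_flanks]
        return cls(_pwm(left), _pwm(right), min_score_frac)

    @classmethod
    def from_reference_db(cls, db: ReferenceDB, anchor_len: int = 20,
                          min_score_frac: float = 0.6) -> "AnchorModel":
        left, right = [], []
        for rec in db.records:
            if rec.region != "full_amplicon":
                continue
            s, e = rec.its2_span
            if s - 1 >= anchor_len and len(rec.sequence) - e >= anchor_len:
                left.append(rec.sequence[:s - 1])
                right.append(rec.sequence[e:])
        if not left:
            raise ValueError(
                "no full_amplicon references with long enough flanks to train anchors")
        return cls.from_sequences(left, right, anchor_len,
                                  min_score_frac=min_score_frac)

    def _threshold(self, pwm: np.ndarray) -> float:
        return self.min_score_frac * float(pwm[:, :4].max(axis=1).sum())

    def _scan(self, enc: np.ndarray, pwm: np.ndarray) -> np.ndarray:
        k = pwm.shape[0]
        if len(enc) < k:
            return np.empty(0)
        windows = np.lib.stride_tricks.sliding_window_view(enc, k)
        return pwm[np.arange(k), windows].sum(axis=1)

    def locate(self, sequence: str) -> Its2Hit | None:
        """Best-scoring non-overlapping anchor pair on either strand."""
        best: tuple[float, Its2Hit] | None = None
        for strand, seq in (("+", sequence), ("-", reverse_complement(sequence))):
            hit = self._locate_one_strand(seq, strand)
            if hit is not None and (best is None or hit[0] > best[0]):
                best = hit
        return best[1] if best else None

    def _locate_one_strand(self, seq: str,
                           strand: str) -> tuple[float, Its2Hit] | None:
        enc = _encode_acgt(seq)
        kl, kr = self.left_pwm.shape[0], self.right_pwm.shape[0]
        ls = self._scan(enc, self.left_pwm)
        rs = self._scan(enc, self.right_pwm)
        if ls.size == 0 or rs.size == 0:
            return None
        ls_ok = np.where(ls >= self._threshold(self.left_pwm), ls, -np.inf)
        rs_ok = np.where(rs >= self._threshold(self.right_pwm), rs, -np.inf)
        # best left-anchor start at or before each position (running max)
        run_best = np.maximum.accumulate(ls_ok)
        run_arg = np.maximum.accumulate(
            np.where(ls_ok == run_best, np.arange(len(ls_ok)), -1))
        best_total = -np.inf
        best_pair = None
        for r in range(len(rs_ok)):
            if not np.isfinite(rs_ok[r]):
                continue
            lmax = r - kl - 1          # leave >= 1 base of ITS2 between anchors
            if lmax < 0 or not np.isfinite(run_best[lmax]):
                continue
            total = run_best[lmax] + rs_ok[r]
            if total > best_total:
                best_total = total
                best_pair = (int(run_arg[lmax]), r)
        if best_pair is None:
            return None
        l, r = best_pair
        start, end = l + kl + 1, r      # 1-based inclusive ITS2 span
        return best_total, Its2Hit(seq[start - 1:end], start, end, strand)


def _encode_acgt(seq: str) -> np.ndarray:
    table = bytes("ACGT".index(chr(i)) if chr(i) in "ACGT" else 4
                  for i in range(256))
    return np.frombuffer(seq.upper().encode().translate(table), dtype=np.uint8)


def _pwm(windows: Sequence[str], pseudocount: float = 0.1) -> np.ndarray:
    k = len(windows[0])
    if any(len(w) != k for w in windows):
        raise ValueError("anchor windows must have equal length")
    counts = np.full((k, 4), pseudocount)
    for w in windows:
        for i, c in enumerate(w.upper()):
            if c in "ACGT":
                counts[i, "ACGT".index(c)] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    logodds = np.log2(freqs / 0.25)
    # column 5: score for N/unknown bases = the column's worst base score
    out = np.hstack([logodds, logodds.min(axis=1, keepdims=True)])
    return out


def extract_its2(sequence: str, model: AnchorModel) -> Its2Hit | None:
    """Trim a read to its ITS2 region; None when either anchor is not found."""
    return model.locate(sequence)


# --------------------------------------------------------------------------
# Dereplication and assignment
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DerepCluster:
    representative: str
    count: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("cluster count must be >= 1")


def dereplicate(batch: ReadBatch,
                min_count: int = DEFAULT_MIN_COPIES) -> list[DerepCluster]:
    """Exact-string collapse; keep clusters with count >= min_count, sorted by
    descending count then sequence."""
    counts = Counter(r.sequence for r in batch.reads)
    clusters = [DerepCluster(seq, n, batch.sample_id)
                for seq, n in counts.items() if n >= min_count]
    clusters.sort(key=lambda c: (-c.count, c.representative))
    return clusters


@dataclass(frozen=True)
class AssignmentResult:
    taxon_id: str            # taxon_id | "unassigned"
    taxon_name: str
    best_seq_id: str
    identity: float
    subspecies_support: float | None = None


def assign_taxon(cluster: DerepCluster, db: ReferenceDB, sites: SiteTable,
                 thresholds: IdentityThresholds = IdentityThresholds()
                 ) -> AssignmentResult:
    """Best-identity search of the reference database.

    *Pueraria* hits (the two focal barcode groups) are resolved to subspecies
    with the diagnostic-site caller; other taxa are reported at the identity
    of their best reference, or "unassigned" below the genus threshold.
    """
    best_id, best_rec = -1.0, None
    for rec in db.records:
        aln = align_pair(cluster.representative, rec.its2)
        if aln.identity > best_id:
            best_id, best_rec = aln.identity, rec
    if best_id < thresholds.genus:
        return AssignmentResult("unassigned", "unassigned",
                                best_rec.seq_id, best_id)
    group = db.taxa[best_rec.taxon_id].group
    if group in (sites.group_a, sites.group_b):
        call = call_subspecies(cluster.representative, db, sites, thresholds)
        if call.called_taxon in ("ambiguous", "not_pueraria"):
            return AssignmentResult("pueraria_sp", "Pueraria sp.",
                                    best_rec.seq_id, best_id, call.support)
        return AssignmentResult(call.called_taxon,
                                db.taxa[call.called_taxon].name,
                                best_rec.seq_id, call.best_identity,
                                call.support)
    return AssignmentResult(best_rec.taxon_id, db.taxa[best_rec.taxon_id].name,
                            best_rec.seq_id, best_id)


# --------------------------------------------------------------------------
# Composition
# --------------------------------------------------------------------------

@dataclass
class CompositionTable:
    """Per-sample taxon read counts and proportions over retained clusters."""
    rows: list[tuple[str, str, int, float]]   # sample_id, taxon, reads, proportion

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows,
                            columns=["sample_id", "taxon", "reads", "proportion"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False,
                                   float_format="%.6f")

    def sample(self, sample_id: str) -> dict[str, tuple[int, float]]:
        return {t: (n, p) for s, t, n, p in self.rows if s == sample_id}


def composition(assignments: Mapping[str, Sequence[tuple[DerepCluster,
                                                         AssignmentResult]]]
                ) -> CompositionTable:
    """Aggregate cluster assignments into a per-sample composition table."""
    rows: list[tuple[str, str, int, float]] = []
    for sample_id in assignments:
        counts: dict[str, int] = {}
        names: dict[str, str] = {}
        for cluster, result in assignments[sample_id]:
            counts[result.taxon_id] = counts.get(result.taxon_id, 0) + cluster.count
            names[result.taxon_id] = result.taxon_name
        total = sum(counts.values())
        for taxon_id in sorted(counts, key=lambda t: (-counts[t], t)):
            rows.append((sample_id, names[taxon_id], counts[taxon_id],
                         counts[taxon_id] / total if total else 0.0))
    return CompositionTable(rows)


# --------------------------------------------------------------------------
# Whole pipeline
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterParams:
    min_length: int = DEFAULT_MIN_LENGTH
    min_avg_qv: float = DEFAULT_MIN_AVG_QV
    min_copies: int = DEFAULT_MIN_COPIES
    max_tag_mismatch: int = 0


def run_metabarcoding(fastq: str | Path | Iterable[TaggedRead],
                      tag_manifest: Mapping[str, str],
                      db: ReferenceDB, sites: SiteTable,
                      filters: FilterParams = FilterParams(),
                      anchors: AnchorModel | None = None,
                      thresholds: IdentityThresholds = IdentityThresholds()):
    """Demultiplex -> filter -> trim -> dereplicate -> assign -> compose.

    Returns (composition_table, per_sample_assignments, stage_counts) where
    stage_counts logs read/cluster counts per pipeline stage per sample.
    """
    if anchors is None:
        anchors = AnchorModel.from_reference_db(db)
    batches, unassigned = demultiplex(fastq, tag_manifest,
                                      filters.max_tag_mismatch)
    stage_counts: dict[str, dict[str, int]] = {
        "unassigned_reads": {"pool": len(unassigned)}}
    assignments: dict[str, list[tuple[DerepCluster, AssignmentResult]]] = {}
    for sample_id, batch in batches.items():
        log = {"demultiplexed": len(batch)}
        batch = quality_filter(batch, filters.min_length, filters.min_avg_qv)
        log["quality_filtered"] = len(batch)
        trimmed = []
        for read in batch.reads:
            hit = extract_its2(read.sequence, anchors)
            if hit is not None:
                trimmed.append(TaggedRead(read.read_id, hit.sequence,
                                          [0] * len(hit.sequence),
                                          sample_id=sample_id))
        log["its2_extracted"] = len(trimmed)
        clusters = dereplicate(ReadBatch(sample_id, trimmed), filters.min_copies)
        log["retained_clusters"] = len(clusters)
        log["retained_reads"] = sum(c.count for c in clusters)
        assignments[sample_id] = [
            (c, assign_taxon(c, db, sites, thresholds)) for c in clusters]
        stage_counts[sample_id] = log
    return composition(assignments), assignments, stage_counts
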
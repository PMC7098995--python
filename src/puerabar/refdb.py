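"""Reference database, pairwise alignment and diagnostic-site subspecies calling.

The ITS2 barcode region separates *Pueraria montana* var. *lobata* from
var. *thomsonii* by a single 1-bp insertion/deletion plus three SNPs.  This
module builds a local taxon-annotated reference database, detects those
variable sites between (and within) barcode groups from group consensus
sequences, and calls the subspecies of a query sequence by a
reliability-weighted vote over the diagnostic sites, backed by a global
sequence-identity screen against the reference consensuses.

Coordinates: all site positions are 1-based columns of the pairwise global
alignment of the two group consensus sequences (the only frame a 246-bp and
a 247-bp sequence share).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

# --------------------------------------------------------------------------
# IUPAC nucleotide code utilities
# --------------------------------------------------------------------------

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}
IUPAC_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}
ALPHABET = "ACGTRYSWKMBDHVN"

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


def iupac_code(bases: Iterable[str]) -> str:
    """Single-letter IUPAC code covering a set of bases."""
    return IUPAC_CODE[frozenset(bases)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def bases_agree(a: str, b: str) -> bool:
    """True when two IUPAC states are compatible ('-' only matches '-')."""
    if a == "-" or b == "-":
        return a == b
    return bool(IUPAC_SETS[a] & IUPAC_SETS[b])


def _sanitize(seq: str) -> str:
    s = seq.upper().replace("U", "T")
    return "".join(c if c in IUPAC_SETS else "N" for c in s)


# --------------------------------------------------------------------------
# Pairwise global alignment
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentScoring:
    """Needleman-Wunsch scoring; gap_open is the cost of the first gap base."""
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -0.5


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    identity: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)


@functools.lru_cache(maxsize=8)
def _make_aligner(scoring: AlignmentScoring) -> PairwiseAligner:
    matrix = substitution_matrices.Array(ALPHABET, dims=2)
    for x in ALPHABET:
        for y in ALPHABET:
            hit = bool(IUPAC_SETS[x] & IUPAC_SETS[y])
            matrix[x, y] = scoring.match if hit else scoring.mismatch
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def align_pair(a: str, b: str,
               scoring: AlignmentScoring = AlignmentScoring()) -> PairwiseAlignment:
    """Optimal global alignment of two nucleotide strings.

    Matching is IUPAC-aware: two states score as a match when their base sets
    intersect, so ambiguity codes produced by heterozygous trace calling align
    cleanly against plain references.  Among co-optimal alignments the first
    traceback is returned, which is deterministic for fixed inputs.

    Identity is matches / aligned columns (dual-gap columns cannot occur in a
    pairwise global alignment).
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(scoring)
    aln = aligner.align(_sanitize(a), _sanitize(b))[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    matches = sum(
        1 for x, y in zip(row_a, row_b)
        if x != "-" and y != "-" and bases_agree(x, y)
    )
    return PairwiseAlignment(row_a, row_b, float(aln.score), matches / len(row_a))


# --------------------------------------------------------------------------
# Reference database
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TaxonRecord:
    taxon_id: str
    name: str
    rank: str          # variety | species | genus
    group: str         # barcode group used for intra/inter partitioning

    def __post_init__(self) -> None:
        if not self.group:
            raise ValueError(f"taxon {self.taxon_id}: group must be non-empty")


@dataclass(frozen=True)
class ReferenceSequence:
    seq_id: str
    taxon_id: str
    sequence: str                       # uppercase, full record as read
    region: str = "its2"                # its2 | full_amplicon
    its2_span: tuple[int, int] | None = None   # 1-based inclusive, full_amplicon only

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.seq_id}: empty sequence")
        if self.region == "full_amplicon":
            if self.its2_span is None:
                raise ValueError(f"{self.seq_id}: full_amplicon requires its2_span")
            s, e = self.its2_span
            if not (1 <= s <= e <= len(self.sequence)):
                raise ValueError(f"{self.seq_id}: its2_span out of bounds")

    @property
    def its2(self) -> str:
        """The ITS2 portion of the record (the whole record when region=its2)."""
        if self.region == "full_amplicon":
            s, e = self.its2_span
            return self.sequence[s - 1:e]
        return self.sequence


class ReferenceDB:
    """Taxon-annotated reference sequences with per-group consensuses."""

    def __init__(self, records: Sequence[ReferenceSequence],
                 taxa: Mapping[str, TaxonRecord]) -> None:
        if not records:
            raise ValueError("reference database is empty")
        seen: set[str] = set()
        for rec in records:
            if rec.seq_id in seen:
                raise ValueError(f"duplicate seq_id {rec.seq_id}")
            seen.add(rec.seq_id)
            if rec.taxon_id not in taxa:
                raise ValueError(f"taxonomy missing for {rec.seq_id}")
        self.records = list(records)
        self.taxa = dict(taxa)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def groups(self) -> list[str]:
        order: list[str] = []
        for rec in self.records:
            g = self.taxa[rec.taxon_id].group
            if g not in order:
                order.append(g)
        return order

    def group_records(self, group: str) -> list[ReferenceSequence]:
        if group not in self.groups:
            raise ValueError(f"unknown group label {group!r}")
        return [r for r in self.records if self.taxa[r.taxon_id].group == group]

    def group_taxon_id(self, group: str) -> str:
        ids = {r.taxon_id for r in self.group_records(group)}
        if len(ids) != 1:
            raise ValueError(f"group {group!r} spans several taxa: {sorted(ids)}")
        return ids.pop()

    def group_consensus(self, group: str) -> str:
        return self._consensus_columns(group)[0]

    def group_column_sets(self, group: str) -> list[frozenset[str]]:
        """Observed base set per consensus column; >1 base = intragroup polymorphism."""
        return self._consensus_columns(group)[1]

    @functools.lru_cache(maxsize=32)
    def _consensus_columns(self, group: str) -> tuple[str, list[frozenset[str]]]:
        seqs = [r.its2 for r in self.group_records(group)]
        if len({len(s) for s in seqs}) == 1:
            stacks = [list(col) for col in zip(*seqs)]
        else:
            # near-identical groups: map every member onto the longest one
            scaffold = max(seqs, key=len)
            stacks = [[c] for c in scaffold]
            for s in seqs:
                if s is scaffold:
                    continue
                aln = align_pair(scaffold, s)
                pos = -1
                for x, y in zip(aln.aligned_a, aln.aligned_b):
                    if x != "-":
                        pos += 1
                        if y != "-":
                            stacks[pos].append(y)
        consensus: list[str] = []
        column_sets: list[frozenset[str]] = []
        for stack in stacks:
            counts: dict[str, int] = {}
            for c in stack:
                counts[c] = counts.get(c, 0) + 1
            top = max(counts.values())
            tied = frozenset(c for c, n in counts.items() if n == top)
            consensus.append(next(iter(tied)) if len(tied) == 1 else iupac_code(tied))
            column_sets.append(frozenset(stack))
        return "".join(consensus), column_sets


def build_reference_db(fasta_path: str | Path, taxonomy_path: str | Path) -> ReferenceDB:
    """Load references from a FASTA plus a taxonomy TSV.

    The TSV carries ``seq_id  taxon_id  name  rank  group``.  A FASTA
    description token ``its2=START..END`` (1-based inclusive) marks a full
    amplicon whose ITS2 region is the given span; records without the token
    are taken to be ITS2-only.
    """
    tax = pd.read_csv(taxonomy_path, sep="\t", dtype=str)
    expected = ["seq_id", "taxon_id", "name", "rank", "group"]
    if list(tax.columns) != expected:
        raise ValueError(f"taxonomy header must be {expected}, got {list(tax.columns)}")
    taxa: dict[str, TaxonRecord] = {}
    seq_to_taxon: dict[str, str] = {}
    for row in tax.itertuples(index=False):
        rec = TaxonRecord(row.taxon_id, row.name, row.rank, row.group)
        if row.taxon_id in taxa and taxa[row.taxon_id] != rec:
            raise ValueError(f"conflicting taxonomy rows for taxon {row.taxon_id}")
        taxa[row.taxon_id] = rec
        seq_to_taxon[row.seq_id] = row.taxon_id

    records: list[ReferenceSequence] = []
    for fasta_rec in SeqIO.parse(str(fasta_path), "fasta"):
        if fasta_rec.id not in seq_to_taxon:
            raise ValueError(f"taxonomy missing for {fasta_rec.id}")
        span = None
        for token in fasta_rec.description.split():
            if token.startswith("its2="):
                s, e = token[5:].split("..")
                span = (int(s), int(e))
        records.append(ReferenceSequence(
            seq_id=fasta_rec.id,
            taxon_id=seq_to_taxon[fasta_rec.id],
            sequence=_sanitize(str(fasta_rec.seq)),
            region="full_amplicon" if span else "its2",
            its2_span=span,
        ))
    if not records:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    return ReferenceDB(records, taxa)


# --------------------------------------------------------------------------
# Variable sites between / within groups
# --------------------------------------------------------------------------

#: weight of a diagnostic site that is also polymorphic within a group —
#: such sites (here the T/G column 244, segregating within lobata) cannot
#: separate the groups on their own and are down-weighted in the vote.
INTRA_POLYMORPHIC_WEIGHT = 0.25


@dataclass(frozen=True)
class Site:
    position: int              # 1-based column of the consensus-pair alignment
    kind: str                  # snp | indel
    state_a: str
    state_b: str
    intra_polymorphic: bool
    reliability_weight: float

    def __post_init__(self) -> None:
        if self.kind not in ("snp", "indel"):
            raise ValueError(f"bad site kind {self.kind!r}")
        if (self.kind == "indel") != ((self.state_a == "-") ^ (self.state_b == "-")):
            raise ValueError("kind=indel iff exactly one state is '-'")
        if not 0 < self.reliability_weight <= 1:
            raise ValueError("reliability_weight must be in (0, 1]")


@dataclass
class SiteTable:
    entries: list[Site]
    coordinate_frame: str
    group_a: str
    group_b: str

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def indel_position(self) -> int | None:
        for site in self.entries:
            if site.kind == "indel":
                return site.position
        return None

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            [(s.position, s.kind, s.state_a, s.state_b,
              int(s.intra_polymorphic), s.reliability_weight)
             for s in self.entries],
            columns=["position", "kind", "state_a", "state_b",
                     "intra_polymorphic", "weight"],
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, coordinate_frame: str = "",
                 group_a: str = "lobata", group_b: str = "thomsonii") -> "SiteTable":
        df = pd.read_csv(path, sep="\t")
        entries = [
            Site(int(r.position), str(r.kind), str(r.state_a), str(r.state_b),
                 bool(r.intra_polymorphic), float(r.weight))
            for r in df.itertuples(index=False)
        ]
        return cls(entries, coordinate_frame, group_a, group_b)


def detect_variable_sites(db: ReferenceDB, group_a: str, group_b: str) -> SiteTable:
    """List alignment columns at which the two group consensuses differ.

    Each differing column becomes a :class:`Site` (kind ``indel`` when one
    consensus has a gap, else ``snp``), flagged ``intra_polymorphic`` when the
    column also varies within either group and down-weighted accordingly.
    """
    cons_a, sets_a = db._consensus_columns(group_a)
    cons_b, sets_b = db._consensus_columns(group_b)
    aln = align_pair(cons_a, cons_b)
    entries: list[Site] = []
    pos_a = pos_b = 0
    for col, (x, y) in enumerate(zip(aln.aligned_a, aln.aligned_b), start=1):
        if x != "-":
            pos_a += 1
        if y != "-":
            pos_b += 1
        if x == y:
            continue
        poly = False
        if x != "-" and len(sets_a[pos_a - 1]) > 1:
            poly = True
        if y != "-" and len(sets_b[pos_b - 1]) > 1:
            poly = True
        entries.append(Site(
            position=col,
            kind="indel" if "-" in (x, y) else "snp",
            state_a=x,
            state_b=y,
            intra_polymorphic=poly,
            reliability_weight=INTRA_POLYMORPHIC_WEIGHT if poly else 1.0,
        ))
    frame = (f"1-based columns of the global alignment of the {group_a} and "
             f"{group_b} ITS2 consensus sequences ({aln.n_columns} columns)")
    return SiteTable(entries, frame, group_a, group_b)


# --------------------------------------------------------------------------
# Subspecies calling
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IdentityThresholds:
    """Identity screens for the similarity search.

    subspecies: minimum best-reference identity to attempt a subspecies-level
    call (the two focal varieties exceed 0.99 mutual identity on the full
    amplicon, well above any outgroup).  genus: minimum identity to accept the
    query as *Pueraria* at all.
    """
    subspecies: float = 0.99
    genus: float = 0.90


@dataclass(frozen=True)
class SubspeciesCall:
    query_id: str
    called_taxon: str                   # taxon_id | "ambiguous" | "not_pueraria"
    site_states: dict[int, str]         # observed query state per site position
    support: float                      # weighted agreement of the winning group
    best_identity: float


def _query_states_vs_consensus(query: str, consensus: str) -> list[str]:
    """Query state aligned to each consensus position (may be '-')."""
    aln = align_pair(query, consensus)
    states: list[str] = []
    for q, c in zip(aln.aligned_a, aln.aligned_b):
        if c != "-":
            states.append(q)
    return states


def call_subspecies(query: str, db: ReferenceDB, sites: SiteTable,
                    thresholds: IdentityThresholds = IdentityThresholds(),
                    min_length: int = 100,
                    query_id: str = "query") -> SubspeciesCall:
    """Call the barcode group of a query from its diagnostic-site states.

    The query is aligned to both group consensuses; when the better identity
    falls below the genus threshold the call is ``not_pueraria``, and between
    the genus and subspecies thresholds it is ``ambiguous``.  Otherwise the
    observed query state at every diagnostic site votes (IUPAC set
    intersection, weighted by site reliability) for group A or B; the call is
    the better-supported group, or ``ambiguous`` on a tied vote or when
    full-weight sites conflict.
    """
    query = _sanitize(query)
    if len(query) < min_length:
        raise ValueError(f"query shorter than minimum length {min_length}")
    cons_a = db.group_consensus(sites.group_a)
    cons_b = db.group_consensus(sites.group_b)
    aln_qa = align_pair(query, cons_a)
    aln_qb = align_pair(query, cons_b)
    best_identity = max(aln_qa.identity, aln_qb.identity)

    # map alignment columns of the A/B consensus pair onto consensus positions
    aln_ab = align_pair(cons_a, cons_b)
    states_via_a = _query_states_vs_consensus(query, cons_a)
    states_via_b = _query_states_vs_consensus(query, cons_b)
    col_to_state: dict[int, str] = {}
    pos_a = pos_b = 0
    for col, (x, y) in enumerate(zip(aln_ab.aligned_a, aln_ab.aligned_b), start=1):
        if x != "-":
            pos_a += 1
        if y != "-":
            pos_b += 1
        if y != "-":
            col_to_state[col] = states_via_b[pos_b - 1]
        else:
            col_to_state[col] = states_via_a[pos_a - 1]

    site_states = {s.position: col_to_state.get(s.position, "-") for s in sites}

    if best_identity < thresholds.genus:
        return SubspeciesCall(query_id, "not_pueraria", site_states, 0.0, best_identity)

    total_w = sum(s.reliability_weight for s in sites) or 1.0
    support_a = support_b = 0.0
    exclusive_high_a = exclusive_high_b = False
    for s in sites:
        obs = site_states[s.position]
        agree_a = bases_agree(obs, s.state_a)
        agree_b = bases_agree(obs, s.state_b)
        if agree_a:
            support_a += s.reliability_weight
        if agree_b:
            support_b += s.reliability_weight
        if s.reliability_weight >= 0.5:
            exclusive_high_a |= agree_a and not agree_b
            exclusive_high_b |= agree_b and not agree_a
    support_a /= total_w
    support_b /= total_w

    if best_identity < thresholds.subspecies:
        return SubspeciesCall(query_id, "ambiguous", site_states,
                              max(support_a, support_b), best_identity)
    if support_a == support_b or (exclusive_high_a and exclusive_high_b):
        return SubspeciesCall(query_id, "ambiguous", site_states,
                              max(support_a, support_b), best_identity)
    if support_a > support_b:
        winner, support = sites.group_a, support_a
    else:
        winner, support = sites.group_b, support_b
    return SubspeciesCall(query_id, db.group_taxon_id(winner), site_states,
                          support, best_identity)
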
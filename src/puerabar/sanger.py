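"""Sanger trace modelling, base calling and type A/B/C triage.

A chromatogram is taken as a per-position table of four channel intensities
(A, C, G, T); electropherogram physics (mobility, peak spacing) is out of
scope.  Base calling emits a two-base IUPAC ambiguity code wherever the
secondary channel reaches a fraction of the primary, which is how
heterozygous positions in mixed-template amplicons present.  Traces are then
triaged the way barcoding labs do:

* type A — clean trace, at most sporadic heterozygous calls; a reliable
  barcode.
* type B — a few isolated heterozygous positions (co-linear template
  mixtures differing at SNPs); usable with minor editing.
* type C — widespread "nested" secondary peaks downstream of an indel
  breakpoint, produced when templates of unequal length phase-shift against
  each other; no reliable barcode can be read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .refdb import IUPAC_SETS, SiteTable, align_pair, iupac_code, reverse_complement

CHANNEL_ORDER = "ACGT"

#: secondary/primary intensity ratio at which a position is called heterozygous
DEFAULT_AMBIGUITY_THRESHOLD = 0.25
#: het fraction at or below which a trace is type A
TYPE_A_MAX_HET_FRACTION = 0.005
#: het fraction at or below which a trace can still be type B
TYPE_B_MAX_HET_FRACTION = 0.05
#: nested score (het fraction downstream of the indel column) forcing type C
TYPE_C_MIN_NESTED_SCORE = 0.3
#: minimum forward/reverse overlap identity for assembly
MIN_ASSEMBLY_IDENTITY = 0.8


@dataclass
class Chromatogram:
    """Four-channel trace: intensities[pos, channel] with channels A,C,G,T."""
    intensities: np.ndarray
    sample_id: str = ""
    direction: str = "forward"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2 or self.intensities.shape[1] != 4:
            raise ValueError("intensities must have shape (positions, 4)")
        if (self.intensities < 0).any():
            raise ValueError("channel intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.intensities)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.intensities, columns=list(CHANNEL_ORDER))
        df.insert(0, "pos", np.arange(1, len(self) + 1))
        df.to_csv(path, sep="\t", index=False, float_format="%.3f")

    @classmethod
    def from_tsv(cls, path: str | Path, sample_id: str = "",
                 direction: str = "forward") -> "Chromatogram":
        df = pd.read_csv(path, sep="\t")
        return cls(df[list(CHANNEL_ORDER)].to_numpy(float), sample_id, direction)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sample_id": self.sample_id,
            "direction": self.direction,
            "channels": CHANNEL_ORDER,
            "intensities": self.intensities.round(3).tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "Chromatogram":
        payload = json.loads(Path(path).read_text())
        return cls(np.asarray(payload["intensities"], dtype=float),
                   payload.get("sample_id", ""), payload.get("direction", "forward"))


@dataclass
class TraceCallResult:
    sequence: str
    het_positions: list[int]          # 1-based
    secondary_ratio: np.ndarray       # per position, in [0, 1]


@dataclass(frozen=True)
class TraceClass:
    label: str              # A | B | C
    het_fraction: float
    nested_score: float


def call_bases(chrom: Chromatogram,
               ambiguity_threshold: float = DEFAULT_AMBIGUITY_THRESHOLD
               ) -> TraceCallResult:
    """Call one base (or a two-base IUPAC code) per trace position.

    The primary base is the strongest channel; when the second-strongest
    channel reaches ``ambiguity_threshold`` times the primary the position is
    recorded as heterozygous and the two-base ambiguity code is emitted.
    """
    if not 0 < ambiguity_threshold < 1:
        raise ValueError("ambiguity_threshold must be in (0, 1)")
    inten = chrom.intensities
    if (inten.sum(axis=1) == 0).any():
        bad = int(np.flatnonzero(inten.sum(axis=1) == 0)[0]) + 1
        raise ValueError(f"all-zero channel intensities at position {bad}")
    order = np.argsort(inten, axis=1)
    primary = order[:, -1]
    secondary = order[:, -2]
    p_int = inten[np.arange(len(inten)), primary]
    s_int = inten[np.arange(len(inten)), secondary]
    ratio = s_int / p_int
    het = ratio >= ambiguity_threshold
    seq = []
    for i in range(len(inten)):
        if het[i]:
            seq.append(iupac_code({CHANNEL_ORDER[primary[i]],
                                   CHANNEL_ORDER[secondary[i]]}))
        else:
            seq.append(CHANNEL_ORDER[primary[i]])
    return TraceCallResult("".join(seq),
                           [int(i) + 1 for i in np.flatnonzero(het)],
                           ratio)


def assemble_bidirectional(fwd: TraceCallResult, rev: TraceCallResult) -> str:
    """Consensus of a forward call and a reverse-direction call.

    The reverse call is reverse-complemented, globally aligned to the forward
    call, and merged column-wise: compatible states resolve to the IUPAC code
    of their base-set intersection, incompatible ones to N, and a gap in one
    read defers to the other.
    """
    rev_rc = reverse_complement(rev.sequence)
    aln = align_pair(fwd.sequence, rev_rc)
    if aln.identity < MIN_ASSEMBLY_IDENTITY:
        raise ValueError(
            f"reads do not assemble: overlap identity "
            f"{aln.identity:.3f} < {MIN_ASSEMBLY_IDENTITY}")
    out = []
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x == "-":
            out.append(y)
        elif y == "-":
            out.append(x)
        else:
            inter = IUPAC_SETS[x] & IUPAC_SETS[y]
            out.append(iupac_code(inter) if inter else "N")
    return "".join(out)


def classify_trace(call: TraceCallResult, sites: SiteTable,
                   f_a: float = TYPE_A_MAX_HET_FRACTION,
                   f_b: float = TYPE_B_MAX_HET_FRACTION,
                   s_c: float = TYPE_C_MIN_NESTED_SCORE) -> TraceClass:
    """Triage a trace call into type A, B or C.

    het_fraction is the fraction of called positions that are heterozygous;
    nested_score is the het fraction restricted to positions strictly
    downstream of the known indel breakpoint (the site table's indel column),
    the signature of phase-shifted mixed templates.
    """
    n = len(call.sequence)
    if n == 0:
        raise ValueError("empty trace call")
    het_fraction = len(call.het_positions) / n
    indel_pos = sites.indel_position
    if indel_pos is None or indel_pos >= n:
        nested_score = 0.0
    else:
        downstream = n - indel_pos
        nested = sum(1 for p in call.het_positions if p > indel_pos)
        nested_score = nested / downstream
    if het_fraction <= f_a:
        label = "A"
    elif het_fraction <= f_b and nested_score < s_c:
        label = "B"
    else:
        label = "C"
    return TraceClass(label, het_fraction, nested_score)
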
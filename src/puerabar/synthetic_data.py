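"""Synthetic study fixtures.

Generates every input the authentication pipeline consumes, as a pure
function of an integer seed (Philox counter-based generator, so outputs are
byte-identical across runs and platforms):

* a reference set with two *P. montana* var. *lobata* ITS2 haplotypes
  (246 bp, differing by one T/G transversion at alignment column 244), two
  identical var. *thomsonii* sequences (247 bp, separated from lobata by the
  1-bp indel at column 29 and SNPs at columns 52, 201 and 244), two
  *Pueraria* outgroups (~5% ITS2 divergence) and three contaminants
  (*Aspergillus* sp., *Hordeum vulgare*, *Rosa* sp., >15% divergence), all
  sharing conserved 5.8S/28S rRNA flanks (lobata full amplicon 477 bp);
* tagged Phred+33 FASTQ read sets with substitution errors and a two-state
  quality model (good ~Q35, bad ~Q12 reads that fail the mean-QV-30 filter);
* four-channel mixture chromatograms in which templates of unequal length
  are laid down without re-alignment, so the 1-bp indel phase-shifts every
  downstream peak of the minor template;
* the three study panels: 30 raw-material samples whose labels and true
  taxa follow the published verification table (21 labelled lobata of which
  2 are really thomsonii, 9 labelled and true thomsonii), 10 food samples
  (5 truly lobata, 5 truly thomsonii) and 12 herbal samples (9 pure, 2
  co-linear 70:30 mixtures, 1 50:50 lobata:thomsonii mixture), plus pooled
  metabarcoding reads for three herbal samples.

Reference backbones are random sequences at ~55% GC rather than GenBank
material, so the package is fully self-contained; user-supplied FASTA
references drop in without code changes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .metabar import TaggedRead, write_fastq
from .refdb import reverse_complement
from .sanger import Chromatogram

ITS2_LEN_LOBATA = 246
FLANK5_LEN = 120          # 5.8S side; lobata amplicon = 120 + 246 + 111 = 477
FLANK3_LEN = 111          # 28S side
INDEL_COLUMN = 29         # 1-based alignment column of the T/- indel
SNP_COLUMNS = (52, 201, 244)
#: lobata/thomsonii states at the SNP columns (column 244 also segregates
#: T/G within lobata: the second haplotype carries the thomsonii state)
SNP_STATES = {52: ("A", "G"), 201: ("C", "T"), 244: ("T", "G")}

OUTGROUP_ITS2_SUBS = 12       # ~5% of 246
CONTAMINANT_ITS2_SUBS = 40    # ~16% of 246

TAXONOMY_ROWS = [
    # seq_id, taxon_id, name, rank, group
    ("LOB001", "pml", "Pueraria montana var. lobata", "variety", "lobata"),
    ("LOB002", "pml", "Pueraria montana var. lobata", "variety", "lobata"),
    ("THO001", "pmt", "Pueraria montana var. thomsonii", "variety", "thomsonii"),
    ("THO002", "pmt", "Pueraria montana var. thomsonii", "variety", "thomsonii"),
    ("OUT_TUB", "ptu", "Pueraria tuberosa", "species", "outgroup"),
    ("OUT_CAN", "pca", "Pueraria candollei", "species", "outgroup"),
    ("CON_ASP", "asp", "Aspergillus sp.", "genus", "contaminant"),
    ("CON_HOR", "hvu", "Hordeum vulgare", "species", "contaminant"),
    ("CON_ROS", "ros", "Rosa sp.", "genus", "contaminant"),
]

#: raw-material verification panel: (sample_id, label taxon, true taxon),
#: 21 labelled lobata (2 of them really thomsonii), 9 labelled thomsonii.
RAW_MATERIAL_PANEL = (
    [(f"HSMS{i:04d}", "pml", "pml") for i in range(1, 20)]
    + [(f"HSMS{i:04d}", "pmt", "pmt") for i in range(20, 29)]
    + [("HSMS0029", "pml", "pmt"), ("HSMS0030", "pml", "pmt")]
)

#: raw lobata samples carrying the minor 244-G haplotype
HAP2_SAMPLES = {"HSMS0005", "HSMS0012"}

HERBAL_SAMPLES = [f"HSZY{1000 + i}" for i in range(1, 13)]
HERBAL_C = {"HSZY1003"}                      # 50:50 indel-shifted mixture
HERBAL_B = {"HSZY1005", "HSZY1009"}          # 70:30 co-linear mixture
HERBAL_TRUE_THOMSONII = {"HSZY1007", "HSZY1011"}
METABARCODED = ["HSZY1006", "HSZY1009", "HSZY1003"]
METABAR_COMPOSITIONS = {
    "HSZY1006": {"pml": 0.92, "asp": 0.08},
    "HSZY1009": {"pml": 0.75, "ros": 0.10, "asp": 0.15},
    "HSZY1003": {"pmt": 0.55, "hvu": 0.30, "asp": 0.15},
}

_BASES = np.array(list("ACGT"))
_GC55 = [0.225, 0.275, 0.275, 0.225]


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31))


def _random_seq(rng: np.random.Generator, length: int) -> list[str]:
    return list(rng.choice(_BASES, size=length, p=_GC55))


def _mutate_positions(rng: np.random.Generator, seq: list[str], n_subs: int,
                      forbidden: set[int]) -> list[str]:
    allowed = [i for i in range(len(seq)) if i not in forbidden]
    out = list(seq)
    for pos in rng.choice(allowed, size=n_subs, replace=False):
        out[pos] = rng.choice([b for b in "ACGT" if b != out[pos]])
    return out


@dataclass
class SampleSpec:
    sample_id: str
    label_taxon: str
    true_composition: dict[str, float]
    n_reads: int
    error_rate: float
    product_type: str                 # raw_material | food | herbal
    tag: str | None = None

    def __post_init__(self) -> None:
        total = sum(self.true_composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.sample_id}: composition sums to {total}")
        if self.n_reads < 0:
            raise ValueError(f"{self.sample_id}: n_reads must be >= 0")
        if self.tag is not None and len(self.tag) != 10:
            raise ValueError(f"{self.sample_id}: tag must be 10 bases")


@dataclass
class StudyDesign:
    samples: list[SampleSpec]
    seed: int

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")

    def sample(self, sample_id: str) -> SampleSpec:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)


@dataclass
class References:
    """Generator truth: sequences, alignment and site table ground truth."""
    seed: int
    flank5: str
    flank3: str
    its2: dict[str, str]              # per seq_id
    aligned_its2: dict[str, str]      # 247-column ITS2 alignment rows
    sites_truth: list[tuple[int, str]]   # (alignment column, kind)

    @property
    def seq_ids(self) -> list[str]:
        return list(self.its2)

    def amplicon(self, seq_id: str) -> str:
        return self.flank5 + self.its2[seq_id] + self.flank3

    def its2_span(self, seq_id: str) -> tuple[int, int]:
        return (FLANK5_LEN + 1, FLANK5_LEN + len(self.its2[seq_id]))

    def amplicon_for_taxon(self, taxon_id: str) -> str:
        for seq_id, tid, *_ in TAXONOMY_ROWS:
            if tid == taxon_id:
                return self.amplicon(seq_id)
        raise ValueError(f"no reference for taxon {taxon_id!r}")

    def template(self, key: str) -> str:
        """ITS2 trace template by mixture key.

        ``thomsonii_colinear`` is the thomsonii haplotype with the column-29
        insertion removed: same length as lobata, so a mixture differs only
        at the SNP columns (substitution-only adulteration, the type-B
        mechanism) instead of phase-shifting downstream peaks.
        """
        mapping = {
            "lobata": "LOB001", "lobata_hap2": "LOB002",
            "thomsonii": "THO001",
            "aspergillus": "CON_ASP", "hordeum": "CON_HOR", "rosa": "CON_ROS",
            "tuberosa": "OUT_TUB", "candollei": "OUT_CAN",
        }
        if key == "thomsonii_colinear":
            t = self.its2["THO001"]
            return t[:INDEL_COLUMN - 1] + t[INDEL_COLUMN:]
        return self.its2[mapping[key]]

    def aligned_amplicons(self) -> dict[str, str]:
        """True full-amplicon alignment (one gap column for the indel)."""
        return {sid: self.flank5 + row + self.flank3
                for sid, row in self.aligned_its2.items()}

    def groups(self) -> dict[str, str]:
        return {seq_id: group for seq_id, _, _, _, group in TAXONOMY_ROWS}

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "refs.fasta", "w") as fh:
            for seq_id in self.seq_ids:
                s, e = self.its2_span(seq_id)
                fh.write(f">{seq_id} its2={s}..{e}\n{self.amplicon(seq_id)}\n")
        with open(out / "taxonomy.tsv", "w") as fh:
            fh.write("seq_id\ttaxon_id\tname\trank\tgroup\n")
            for row in TAXONOMY_ROWS:
                fh.write("\t".join(row) + "\n")
        with open(out / "refs.aln", "w") as fh:
            for seq_id, row in self.aligned_amplicons().items():
                fh.write(f">{seq_id}\n{row}\n")
        with open(out / "groups.tsv", "w") as fh:
            fh.write("seq_id\tgroup\n")
            for seq_id, group in self.groups().items():
                fh.write(f"{seq_id}\t{group}\n")
        with open(out / "sites_truth.tsv", "w") as fh:
            fh.write("position\tkind\n")
            for pos, kind in self.sites_truth:
                fh.write(f"{pos}\t{kind}\n")


def make_references(seed: int) -> References:
    """Build the reference haplotype set for a seed (see module docstring)."""
    rng = np.random.Generator(np.random.Philox(seed))
    lob = _random_seq(rng, ITS2_LEN_LOBATA)
    # pin the insertion neighbourhood (non-T) so the indel column is unique,
    # and the lobata states at the diagnostic columns
    lob[INDEL_COLUMN - 2] = "A"     # alignment column 28
    lob[INDEL_COLUMN - 1] = "C"     # alignment column 30
    for col, (state_l, _) in SNP_STATES.items():
        lob[col - 2] = state_l      # column c maps to lobata index c-2 (c > 29)
    thom = lob[:INDEL_COLUMN - 1] + ["T"] + lob[INDEL_COLUMN - 1:]
    for col, (_, state_t) in SNP_STATES.items():
        thom[col - 1] = state_t
    lob2 = list(lob)
    lob2[244 - 2] = SNP_STATES[244][1]   # minor haplotype: thomsonii state at 244

    # Outgroups and contaminants carry third-party states at the diagnostic
    # columns (neither the lobata nor the thomsonii base), as truly external
    # taxa would: otherwise they would share the lobata states and sit inside
    # the lobata radiation, making the subspecies clades unresolvable.
    diagnostic_lob_idx = {INDEL_COLUMN - 2, INDEL_COLUMN - 1} | {
        c - 2 for c in SNP_COLUMNS}
    external = list(lob)
    for col, (state_l, state_t) in SNP_STATES.items():
        external[col - 2] = next(b for b in "ACGT" if b not in (state_l, state_t))

    out_tub = _mutate_positions(rng, external, OUTGROUP_ITS2_SUBS, diagnostic_lob_idx)
    out_can = _mutate_positions(rng, external, OUTGROUP_ITS2_SUBS, diagnostic_lob_idx)
    con_asp = _mutate_positions(rng, external, CONTAMINANT_ITS2_SUBS, diagnostic_lob_idx)
    con_hor = _mutate_positions(rng, external, CONTAMINANT_ITS2_SUBS, diagnostic_lob_idx)
    con_ros = _mutate_positions(rng, external, CONTAMINANT_ITS2_SUBS, diagnostic_lob_idx)

    flank5 = "".join(_random_seq(rng, FLANK5_LEN))
    flank3 = "".join(_random_seq(rng, FLANK3_LEN))

    its2 = {
        "LOB001": "".join(lob), "LOB002": "".join(lob2),
        "THO001": "".join(thom), "THO002": "".join(thom),
        "OUT_TUB": "".join(out_tub), "OUT_CAN": "".join(out_can),
        "CON_ASP": "".join(con_asp), "CON_HOR": "".join(con_hor),
        "CON_ROS": "".join(con_ros),
    }

    def aligned(seq: str) -> str:
        if len(seq) == ITS2_LEN_LOBATA:       # insert the indel gap column
            return seq[:INDEL_COLUMN - 1] + "-" + seq[INDEL_COLUMN - 1:]
        return seq

    aligned_its2 = {sid: aligned(s) for sid, s in its2.items()}
    sites_truth = [(INDEL_COLUMN, "indel")] + [(c, "snp") for c in SNP_COLUMNS]
    sites_truth.sort()
    return References(seed, flank5, flank3, its2, aligned_its2, sites_truth)


# --------------------------------------------------------------------------
# Reads
# --------------------------------------------------------------------------

GOOD_QV_MEAN, GOOD_QV_SD = 35.0, 3.0
BAD_QV_MEAN, BAD_QV_SD = 12.0, 2.0
DEFAULT_BAD_READ_FRACTION = 0.1


def simulate_reads(spec: SampleSpec, refs: References, seed: int,
                   bad_read_fraction: float = DEFAULT_BAD_READ_FRACTION
                   ) -> tuple[list[TaggedRead], dict]:
    """Simulate one sample's tagged amplicon reads.

    Read counts per taxon are multinomial in the true composition; each read
    is its taxon's full amplicon with independent per-base substitution
    errors at ``spec.error_rate``, a two-state quality string (a
    ``bad_read_fraction`` of reads draw ~Q12 bases and fail the mean-QV-30
    filter, the rest ~Q35), and the sample tag prepended.  Returns the reads
    plus a truth record (per-taxon counts and the planted bad-read count).
    """
    if spec.tag is None:
        raise ValueError(f"{spec.sample_id}: read simulation requires a tag")
    rng = np.random.Generator(np.random.Philox(seed))
    taxa = sorted(spec.true_composition)
    probs = [spec.true_composition[t] for t in taxa]
    counts = rng.multinomial(spec.n_reads, probs)
    templates = {t: refs.amplicon_for_taxon(t) for t in taxa}

    reads: list[TaggedRead] = []
    n_bad = 0
    per_read_taxon: list[str] = []
    for taxon, count in zip(taxa, counts):
        per_read_taxon.extend([taxon] * int(count))
    order = rng.permutation(len(per_read_taxon))
    for i, idx in enumerate(order):
        taxon = per_read_taxon[int(idx)]
        template = templates[taxon]
        seq = np.array(list(template))
        err = rng.random(len(seq)) < spec.error_rate
        for pos in np.flatnonzero(err):
            seq[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
        full = spec.tag + "".join(seq)
        bad = bool(rng.random() < bad_read_fraction)
        n_bad += bad
        mean, sd = (BAD_QV_MEAN, BAD_QV_SD) if bad else (GOOD_QV_MEAN, GOOD_QV_SD)
        quals = np.clip(np.rint(rng.normal(mean, sd, size=len(full))),
                        2, 40).astype(int).tolist()
        reads.append(TaggedRead(f"{spec.sample_id}_r{i:05d}", full, quals))
    truth = {
        "sample_id": spec.sample_id,
        "taxon_counts": {t: int(c) for t, c in zip(taxa, counts)},
        "n_bad_quality": int(n_bad),
        "n_reads": int(spec.n_reads),
    }
    return reads, truth


# --------------------------------------------------------------------------
# Chromatograms
# --------------------------------------------------------------------------

PEAK_SCALE = 100.0
DEFAULT_NOISE_SD = 2.0


def simulate_chromatogram(composition: dict[str, float], refs: References,
                          noise_sd: float = DEFAULT_NOISE_SD, seed: int = 0,
                          direction: str = "forward",
                          sample_id: str = "") -> Chromatogram:
    """Mixture trace over ITS2 templates.

    Each template adds proportion-weighted intensity to its base's channel at
    every position.  Templates of unequal length are laid down from position
    1 without re-alignment, so a 1-bp indel between templates phase-shifts
    every downstream contribution of the shorter one — the mechanism behind
    "nested" type-C traces.  Gaussian noise (sd ``noise_sd``, clipped at 0)
    is added to all channels.
    """
    if abs(sum(composition.values()) - 1.0) > 1e-9:
        raise ValueError("mixture proportions must sum to 1")
    rng = np.random.Generator(np.random.Philox(seed))
    templates = [(refs.template(key), prop)
                 for key, prop in sorted(composition.items())]
    if direction == "reverse":
        templates = [(reverse_complement(t), p) for t, p in templates]
    length = max(len(t) for t, _ in templates)
    inten = np.zeros((length, 4))
    for template, prop in templates:
        for i, base in enumerate(template):
            inten[i, "ACGT".index(base)] += PEAK_SCALE * prop
    if noise_sd > 0:
        inten = inten + rng.normal(0.0, noise_sd, size=inten.shape)
    return Chromatogram(np.clip(inten, 0.0, None), sample_id, direction)


# --------------------------------------------------------------------------
# Whole study
# --------------------------------------------------------------------------

def _herbal_mixture(sample_id: str) -> dict[str, float]:
    if sample_id in HERBAL_C:
        return {"lobata": 0.5, "thomsonii": 0.5}
    if sample_id in HERBAL_B:
        return {"lobata": 0.7, "thomsonii_colinear": 0.3}
    if sample_id in HERBAL_TRUE_THOMSONII:
        return {"thomsonii": 1.0}
    return {"lobata": 1.0}


def _make_tags(rng: np.random.Generator, n: int, min_dist: int = 5) -> list[str]:
    tags: list[str] = []
    while len(tags) < n:
        cand = "".join(rng.choice(_BASES, size=10))
        if all(sum(a != b for a, b in zip(cand, t)) >= min_dist for t in tags):
            tags.append(cand)
    return tags


def make_study_fixtures(seed: int, out_dir: str | Path,
                        n_reads: int = 2000, error_rate: float = 0.002,
                        noise_sd: float = DEFAULT_NOISE_SD) -> StudyDesign:
    """Emit the full study fixture tree under ``out_dir``.

    Layout: ``refs/`` (FASTA, taxonomy, true alignment, site truth),
    ``sanger/<sample>_{fwd,rev}.tsv`` traces for the raw-material, food and
    herbal panels, ``metabar/pooled.fastq`` + ``metabar/tags.tsv`` for the
    three metabarcoded herbal samples, ``manifest.tsv`` and ``truth.json``.
    """
    out = Path(out_dir)
    (out / "sanger").mkdir(parents=True, exist_ok=True)
    (out / "metabar").mkdir(parents=True, exist_ok=True)
    rng = np.random.Generator(np.random.Philox(seed))
    refs = make_references(seed)
    refs.write(out / "refs")

    samples: list[SampleSpec] = []
    truth: dict = {"seed": seed, "samples": {}, "metabar": {}}
    tags = _make_tags(rng, len(METABARCODED))
    tag_of = dict(zip(METABARCODED, tags))

    def emit_traces(sample_id: str, mixture: dict[str, float]) -> None:
        for direction in ("forward", "reverse"):
            chrom = simulate_chromatogram(mixture, refs, noise_sd,
                                          seed=_child_seed(rng),
                                          direction=direction,
                                          sample_id=sample_id)
            suffix = "fwd" if direction == "forward" else "rev"
            chrom.to_tsv(out / "sanger" / f"{sample_id}_{suffix}.tsv")

    # (a) 30 raw-material samples, labels/truth per the verification table
    for sample_id, label, true_taxon in RAW_MATERIAL_PANEL:
        if true_taxon == "pml":
            template = "lobata_hap2" if sample_id in HAP2_SAMPLES else "lobata"
        else:
            template = "thomsonii"
        mixture = {template: 1.0}
        emit_traces(sample_id, mixture)
        samples.append(SampleSpec(sample_id, label, {true_taxon: 1.0}, 0,
                                  error_rate, "raw_material"))
        truth["samples"][sample_id] = {
            "true_taxon": true_taxon, "template": template,
            "label_taxon": label, "product_type": "raw_material"}

    # (b) 10 food samples: 5 truly lobata, 5 truly thomsonii
    for i in range(1, 11):
        sample_id = f"GGFP{i:04d}"
        true_taxon = "pml" if i <= 5 else "pmt"
        template = "lobata" if i <= 5 else "thomsonii"
        emit_traces(sample_id, {template: 1.0})
        samples.append(SampleSpec(sample_id, true_taxon, {true_taxon: 1.0}, 0,
                                  error_rate, "food"))
        truth["samples"][sample_id] = {
            "true_taxon": true_taxon, "template": template,
            "label_taxon": true_taxon, "product_type": "food"}

    # (c) 12 herbal samples: 9 pure (A), 2 co-linear mixtures (B), 1 50:50 (C)
    for sample_id in HERBAL_SAMPLES:
        mixture = _herbal_mixture(sample_id)
        emit_traces(sample_id, mixture)
        if sample_id in HERBAL_C:
            expected = "C"
        elif sample_id in HERBAL_B:
            expected = "B"
        else:
            expected = "A"
        tag = tag_of.get(sample_id)
        comp = METABAR_COMPOSITIONS.get(sample_id, {"pml": 1.0})
        samples.append(SampleSpec(sample_id, "pml", comp,
                                  n_reads if tag else 0, error_rate,
                                  "herbal", tag=tag))
        truth["samples"][sample_id] = {
            "mixture": mixture, "expected_trace_class": expected,
            "label_taxon": "pml", "product_type": "herbal"}

    # pooled metabarcoding reads for the three representative herbal samples
    pooled: list[TaggedRead] = []
    design = StudyDesign(samples, seed)
    for sample_id in METABARCODED:
        spec = design.sample(sample_id)
        reads, read_truth = simulate_reads(spec, refs, seed=_child_seed(rng))
        pooled.extend(reads)
        truth["metabar"][sample_id] = read_truth
        truth["metabar"][sample_id]["true_composition"] = spec.true_composition
    write_fastq(pooled, out / "metabar" / "pooled.fastq")
    with open(out / "metabar" / "tags.tsv", "w") as fh:
        fh.write("sample_id\ttag\n")
        for sample_id in METABARCODED:
            fh.write(f"{sample_id}\t{tag_of[sample_id]}\n")

    with open(out / "manifest.tsv", "w") as fh:
        fh.write("sample_id\tlabel_taxon\tproduct_type\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.label_taxon}\t{s.product_type}\n")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return design
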
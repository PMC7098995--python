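# puerabar

ITS2 DNA barcoding and metabarcoding toolkit for authenticating *Pueraria
montana* raw materials, foods and herbal products at the subspecies level.

## The problem

The roots of *Pueraria montana* var. *lobata* (kudzu; herbal-trade name
**Gegen**) and *P. montana* var. *thomsonii* (**Fenge**) are widely traded
as food and medicine, but only var. *lobata* is the legal raw material for
some herbal products (e.g. Yufeng Ningxin). Once roots are dried, ground or
extracted, morphology is useless and standard chemical quality tests
(TLC/HPLC) cannot tell the two varieties apart. The nuclear ribosomal ITS2
region, however, carries a compact diagnostic signature between the two
varieties:

* a 1-bp insertion/deletion at alignment column **29** (T in *thomsonii*,
  absent in *lobata*, making the ITS2 regions 247 bp vs 246 bp), and
* three SNPs at columns **52** (A/G), **201** (C/T) and **244** (T/G), of
  which column 244 also segregates T/G *within* var. *lobata* and is
  therefore down-weighted when calling.

`puerabar` implements the full authentication workflow around this
signature:

1. **refdb** — a local taxon-annotated ITS2 reference database; IUPAC-aware
   global (Needleman–Wunsch) alignment; detection of between- and
   within-group variable sites from group consensuses; subspecies calling by
   a reliability-weighted diagnostic-site vote behind a sequence-identity
   screen.
2. **phylo** — Kimura 2-parameter distances with pairwise gap deletion,

       d = -½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q),

   where P and Q are the transition and transversion fractions over
   comparable sites; barcoding-gap statistics (max intra- vs min
   inter-group distance); Saitou–Nei neighbor joining with column-resampling
   bootstrap support and Newick output.
3. **sanger** — four-channel chromatogram model, base calling with IUPAC
   ambiguity codes at secondary peaks, bidirectional assembly, and triage of
   traces into type **A** (clean), **B** (isolated heterozygous peaks from
   co-linear template mixtures) or **C** ("nested" peaks downstream of the
   indel, where templates of unequal length phase-shift — no usable
   barcode).
4. **metabar** — single-end amplicon metabarcoding: 10-bp tag
   demultiplexing, length/quality filtering (≥ 300 bp, mean QV ≥ 30),
   PWM-anchor ITS2 trimming, exact dereplication (unique sequences with
   more than 10 copies retained), reference-database assignment and
   per-sample composition tables.
5. **synthetic_data** — a seeded generator for every fixture: reference
   haplotypes embedding the diagnostic sites, tagged FASTQ read sets with a
   two-state quality model, mixture chromatograms, and the three study
   panels (30 raw materials, 10 foods, 12 herbal products).
6. **authpipe / CLI** — end-to-end authentication runs and
   label-consistency reports.

## Worked example

```bash
puerabar simulate --seed 7 --out demo --n-reads 2000
puerabar barcode demo --panel raw_material
puerabar gap --alignment demo/refs/refs.aln --groups demo/refs/groups.tsv \
             --bootstrap 2000 --seed 1 --outgroup OUT_TUB --out-prefix demo/gap
puerabar metabarcode demo/metabar/pooled.fastq --tags demo/metabar/tags.tsv \
             --db-fasta demo/refs/refs.fasta --db-taxonomy demo/refs/taxonomy.tsv \
             --out demo/composition.tsv
```

prints

```
wrote 52 samples under demo
28/30 consistent (93.3%) -> demo/barcode_report.tsv
max intra lobata: 0.0021
max intra thomsonii: 0.0000
min inter: 0.0042 (LOB002, THO001)
barcoding gap present: True
HSZY1006: demultiplexed=2000, quality_filtered=1809, its2_extracted=1809, retained_clusters=2, retained_reads=1115
...
```

and `demo/composition.tsv` ends with

```
HSZY1003  Pueraria montana var. thomsonii  672  0.584856
HSZY1003  Hordeum vulgare                  340  0.295909
HSZY1003  Aspergillus sp.                  137  0.119234
```

Reading: 28 of the 30 raw-material samples match their labels (93.3%) — the
two mismatches are products labelled Gegen that are really var. *thomsonii*.
The largest within-variety distance (0.0021, one transversion across 477
sites between the two lobata haplotypes) is smaller than the smallest
between-variety distance, so a barcoding gap separates the varieties, and
the bootstrapped NJ tree (`demo/gap.nwk`) keeps each variety monophyletic.
In the metabarcoded herbal sample HSZY1003 the dominant *Pueraria* is var.
*thomsonii* (an illegal substitution for this product) with heavy barley
(*Hordeum vulgare*) and fungal (*Aspergillus*) contamination — none of
which chemical testing would flag.

## Scope notes

* The reference database is local files only (FASTA + taxonomy TSV); there
  are no remote queries. User-supplied references (e.g. real GenBank ITS2
  sequences) drop in without code changes.
* Chromatograms are consumed as plain TSV/JSON four-channel tables;
  proprietary AB1/SCF trace parsing is out of scope.
* ITS2 only; no multi-locus barcoding, chimera detection, sub-100%-identity
  OTU clustering, or likelihood-based tree inference.

See `docs/methods.md` for the model details, parameter choices and known
limitations.
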
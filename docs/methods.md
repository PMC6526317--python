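# Methods

This note documents the models, estimators and numerical choices behind
`rdnakit`, what the synthetic-data generator does and does not emulate,
and the limitations a user should know before applying the package to
real data.

## The estimation problem

Ribosomal DNA occurs as tandem arrays: 35S units (18S–ITS1–5.8S–ITS2–26S,
flanked by the intergenic spacer) and 5S units (a 120-bp gene plus a
non-transcribed spacer), either at separate loci (S-type) or as a single
linked unit (L-type). At sequencing depths far below 1× no single-copy
locus is assembled, but a repeat present in thousands of copies is
sampled deeply in aggregate. Every analysis in the package exploits this:
cluster sizes, mapped-read counts and pileup depths all measure aggregate
copy number and diversity rather than any individual locus.

## Read model and quality filter

Reads are Phred+33 paired-end, 90–100 bp, with inserts of 170–300 bp. A
read is removed iff **strictly more than 10 %** of its bases are below
Q20; by default a pair is dropped when either mate fails, so mate pairing
is preserved for the linkage analysis. The boundary is intentionally
strict-greater: a 90-bp read with exactly 9 sub-Q20 bases (10.0 %) is
kept.

## Similarity graph and clustering

Two reads are connected when the best local alignment of one against the
other (either strand) reaches **≥ 90 % identity over ≥ 55 % of the
shorter read's length**. Identity is matches / alignment columns with gap
columns counted; the overlap denominator is configurable ("shorter" by
default, "longer" available) because the classic rule leaves it
ambiguous. Clusters are **connected components** of this graph — a
deliberate simplification of community-detection repeat clustering.
Components are deterministic, order-independent, and sufficient for the
signal this package needs (whether 35S and 5S reads co-cluster);
they do not split chimeric clusters the way modularity-based methods can.
Clusters are ordered by (size desc, smallest read id) for reproducibility.

All-to-all alignment is accelerated by a shared-canonical-13-mer
prefilter. A qualifying pair (≥ 50 aligned columns at ≥ 90 % identity)
virtually always shares an exact 13-mer, and the prefilter is guarded by
an exhaustive all-pairs oracle in the test suite; pairs the prefilter can
miss are far below the edge threshold anyway.

Alignment scoring is BLAST-like: match +1, mismatch −2, gap open −5, gap
extend −2. The penalties matter: with milder penalties (mismatch −1, gap
−2), unrelated 90-mers produce gappy ~60 % "alignments" long enough to
pass the 55 % overlap rule, polluting pair-identity histograms with a
spurious low mode. With the adopted scores, random alignments stay short
and every retained pair reflects genuine homology.

## Genome proportion and copy number

GP = mapped reads / total reads analysed; CN = GP × genome size (bp/1C) /
reference length. The reference is the **trimmed gene region** (120-bp 5S
gene; 18S gene, ~1800 bp at natural scale), not the whole repeat unit,
because spacer regions are too diverged for stable mapping in real data.
Each mate counts independently.

A read counts as mapped when its best local alignment reaches ≥ 90 %
identity over at least a fraction *f* of the read length. The choice of
*f* controls estimator bias for a short reference: a read of length *r*
overlapping a reference of length *L* by at least *o* bases has
*L + r − 2o + 1* qualifying start positions. With *f* = 0.5 (so *o* ≈
*r*/2) the window is *L* + 1 — the estimator is essentially unbiased;
with *f* = 0.8 the window shrinks to ~0.55 *L* for a 90-bp read on a
120-bp reference and CN would be underestimated ~2-fold. The pipeline
therefore uses *f* = 0.5 for GP/CN (`gp_read_fraction`), while the
general-purpose mapper default remains *f* = 0.8 (appropriate when the
reference is a full unit and partial alignments are unwanted). Validated
on a 20-Mb synthetic genome with 1000 planted 700-bp units: CN 990 at
0.05× and 972 at 0.5× (seed 1), against an expectation of ~1008 from the
window arithmetic.

For the 5S family the estimate deliberately counts everything that maps
to the gene reference at ≥ 90 % identity — including diverged or
truncated pseudogene copies. Pseudogene-rich genomes therefore show 5S
copy numbers well above their unit counts, which is the biologically
expected reading (pseudogene copy number is comparable to or higher than
that of functional genes in such genomes), not an artifact.

## Pileup, SNPs and consensus

The pileup is substitution-only: aligned blocks contribute A/C/G/T counts
per reference position; insertions and N bases are ignored. An alternate
allele is reported iff site depth ≥ 200 (100 for low-coverage samples),
allele count ≥ 40 and allele frequency ≥ 20 % — all three exactly at
their boundaries (depth 200 / alt 40 / 20.0 % is called; 200 / 39 is
not). Tri-allelic sites produce one row per qualifying allele. SNP
density is 1000 × count / pooled length per subregion label. The
consensus takes the majority base per position, keeping the reference
base at zero depth and on ties that include it.

The ≥ 20 % frequency threshold has a modelling consequence the simulator
respects: independent per-copy noise can never produce a 20 %-frequency
allele, so called SNPs in real arrays reflect *subfamily structure* —
variant haplotypes amplified across many copies. The simulator's
pseudogene events build **one** diverged haplotype and splice it into the
affected copies (amplified-pseudogene model); per-copy i.i.d. noise is a
separate control (`per_copy_sub_rate`).

## Structural analyses

**Subrepeats.** For every candidate period *p* the boolean self-match
profile `m[i] = (seq[i] == seq[i+p])` is smoothed over a window of *p*
and thresholded at 0.75; candidate runs are boundary-refined on the raw
profile (8-bp edge windows at ≥ 0.8, then single-position trimming) and
accepted when the run is ≥ 16 bp, the exact match fraction is ≥ 0.85 and
the implied copy number is ≥ 1.8. Harmonic periods (2*p*, 3*p*, …) are
collapsed to the smallest period among overlapping spans. Copy number is
span/period to one decimal; with random flanks the span boundary can
legitimately shift a base or two (flank bases may continue the period),
so copy number is exact only to ~0.1. Validated: 50/50 planted periods
(20–100 bp, 2–5 copies, 2 % motif noise) recovered exactly; 0/50 false
reports on random 500-mers.

**5S classification.** Each annotated 5S/5S_pseudo subregion is scored by
local alignment against the canonical 120-bp gene. Functional requires
full length (120 bp), ≥ 90 % identity **and** no 5′ truncation;
truncation outranks identity (a full-length 95 % copy is functional, an
80-bp 99 % copy is a pseudogene). The 5′ deletion is measured as the
unaligned canonical prefix; values under 10 bp are treated as alignment
trimming of terminal mismatches rather than structural truncation —
without this tolerance a single mutated first base would masquerade as a
"deletion". The BamHI flag simply reports a GGATCC match inside the copy
(functional plant 5S genes carry the site; diverged pseudogenes typically
lose it, which is what makes BamHI monomer ladders informative).

**Digestion.** Cut positions are every IUPAC match of the recognition
sequence on either strand; the cut offset is simplified to the site start
(fragment lengths shift by at most the site length — irrelevant at gel
resolution — and the offset is configurable). Linear topology yields
fragments between consecutive cuts; *tandem-circularized* topology joins
the terminal fragments, modelling an effectively infinite array: one site
per unit then gives the monomer ladder of a genomic Southern. Probes hit
a fragment when a local alignment of ≥ 50 columns at ≥ 90 % identity lies
within it.

**Arrangement call.** Three independent channels: (1) co-clustering — a
cluster assigned ≥ 3 reads of both the 35S and the 5S family; (2)
cross-mate fraction — among pairs whose mates both carry a 26S or 5S
label, the fraction with one mate in 26S and the other in 5S (threshold
0.05); (3) digest co-hybridization — any fragment hit by both the 26S and
5S probes for any configured enzyme. The call is L if **any** channel is
positive, S if all available channels are negative and both families were
detected, ambiguous otherwise. Family detection uses both cluster labels
and mapping evidence (≥ 3 labelled mates), since sparse samples can map
unambiguously yet yield too few overlapping reads to cluster.

## The synthetic-data generator

`plant_arrays` builds an i.i.d. background (default GC 0.40) and replaces
segments with tandem arrays built copy-by-copy from a master unit;
`simulate_reads` samples `round(coverage × G / (2 × read length))`
fragments uniformly on either strand with substitution errors at a
uniform rate (default 0.3 %) and constant Q40 qualities (a degraded mode
plants low-quality reads to exercise the filter). Identical seeds yield
byte-identical FASTA/FASTQ output.

What it emulates: tandem architecture, copy-number scale-down,
subfamily/pseudogene structure, S- vs L-type organization, read geometry
of real skim designs. What it does **not** emulate: indels (in copies or
reads), GC-dependent coverage bias, quality-score decay along reads,
adapter contamination, organellar DNA, or dispersed repeat families that
could share k-mers with rDNA. Passing tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
every artifact of real libraries.

The bundled archetypes are length-scaled (genes of 300/60/500 bp; the 5S
gene kept at its natural 120 bp) on 150-kb genomes in which rDNA occupies
10–25 % — far above the ~0.05–0.3 % of real Gb-scale genomes — because
the GP/CN arithmetic is scale-free while clustering and linkage evidence
need on the order of 100 rDNA reads to be informative at desk scale. The
validation experiments use: 20-Mb genomes with 1000 planted 700-bp units
at 0.05× and 0.5× for copy-number recovery; 150-kb archetype genomes at
1.0× (0.5× sparse) with insert 300 bp for arrangement typing; 15–40-copy
arrays for heterogeneity and SNP-direction trials. These sizes keep the
full validation suite within a few minutes on one CPU.

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| `q_min` / `max_low_fraction` | 20 / 0.10 | quality filter: remove read iff > 10 % of bases < Q20 |
| `min_identity` / `min_overlap_fraction` | 90 / 0.55 | similarity-graph edge rule |
| `kmer_size` (cluster prefilter) | 13 | canonical k-mer candidate generation |
| `map min_identity` / `min_read_fraction` | 90 / 0.8 | general mapping acceptance |
| `gp_read_fraction` | 0.5 | mapping fraction for GP/CN (unbiased window) |
| `SnpParams` | 0.20 / 200 / 40 | min frequency / depth / allele count |
| `ref_length` 5S / 18S | 120 / 1800 | trimmed gene references at natural scale |
| `cross_mate_threshold` | 0.05 | L-call threshold on the cross-mate fraction |
| `min_family_reads` | 3 | reads needed to credit a family to a cluster/sample |
| subrepeat `min_period` / `min_copies` | 10 / 1.8 | detection floor |
| enzymes | BamHI GGATCC, EcoRI GAATTC, NcoI CCATGG, StuI AGGCCT, BstNI CCWGG | standard recognition sites |

## Known limitations

* Connected-component clustering cannot separate repeat families joined
  by even a single chimeric or shared-segment read pair; community
  detection would.
* The mapper is a best-hit, k-mer-seeded local aligner intended for short
  reads against references under ~10 kb; it is not a general-purpose
  aligner and multi-mapping within a tandem reference is collapsed by
  best score (leftmost on ties), which is immaterial for GP/CN but makes
  within-array positions meaningless.
* Functionality of 5S copies is judged purely by length, identity and
  truncation against the canonical gene; no secondary-structure or
  promoter-element evidence is considered, so a full-length, high-identity
  copy with a disabling internal mutation would still be called
  functional.
* Consensus reconstruction is reference-anchored; the package does not
  assemble units de novo and cannot recover spacers absent from the
  supplied unit models.
* GP/CN accuracy is limited by binomial sampling of mapped reads: at
  0.05× with ~70 mapped reads the relative standard error is ~12 %, so
  single-run estimates at very low coverage carry that uncertainty
  irrespective of implementation.
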
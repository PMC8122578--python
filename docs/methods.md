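# Methods

## The problem

A *Tnt1* insertional-mutagenesis population is characterized by flanking
sequence tags: TAIL-PCR amplicons sequenced outward from the transposon's
LTR into the host genome. Each genuine FST therefore begins (or, if the
read was reported in the opposite orientation, ends) with a short stretch
of LTR sequence — the *signature* — followed by genomic flank. The
analysis problem has three parts: decide which reads are genuine
junctions, locate each junction on the reference assembly, and summarize
the resulting insertion landscape per chromosome, gene, window and synteny
block. `tnt1map` implements all three plus a generator of ground-truthed
synthetic populations used to validate them.

## Signature QC

A read passes iff

* length ≥ `min_fst_length` (default 50 bp), and
* one of the signature motifs `CCCAACA`, `CATCATCA`, `TGATGATGTCC` —
  or, by default, their reverse complements, since TAIL-PCR read
  orientation is arbitrary — occurs *end-proximally*: the motif's first
  base within the first `end_window` (28) bases ("head"), or its last base
  within the final 28 bases ("tail").

Rejection reasons are assigned with fixed precedence TOO_SHORT >
NO_SIGNATURE > SIGNATURE_INTERNAL so each read gets exactly one, and batch
counts always satisfy `total = passed + Σ reasons`.

The window rule is interpreted inclusively (head iff 0-based start offset
≤ 27) and bounds the motif start at the head but the motif end at the
tail; both are natural readings of "within 28 bp of an end" for the end
the motif is anchored to, and `end_window` is configurable.

Among several end-proximal matches the junction is called from the one
closest to its end, with ties broken toward the **longer** motif. The tie
matters because the motif set is nested: `TGATGATGTCC` begins with the
reverse complement of `CATCATCA`, so a single junction produces two
co-located matches whose implied junctions differ by 3 bp; the longer
motif is the more specific observation.

## Mapping and insertion-site calling

FSTs are near-identical local copies of their source locus, so the aligner
is a classical ungapped seed-and-extend:

* **Index**: every N-free k-mer of the reference (k = `seed_k`, default 15)
  in a hash map.
* **Seeding**: all k-mers of the read, in both orientations; seeds landing
  inside a segment already extended on the same (chromosome, diagonal) are
  skipped.
* **Extension**: ungapped in both directions, +1/−2 match/mismatch scores,
  stopping when the running score drops `xdrop` (20) below the running
  best; the reported segment is the best-scoring one containing the seed.
  `N` never matches anything.
* **Thresholds**: identity = matches / alignment columns ≥ `min_identity`
  (0.90; a strict-inequality mode is a flag, as published descriptions use
  both "at least 90%" and "greater than 90%"), and E-value ≤ `max_evalue`
  (10⁻⁵) with `E = K·m·n·e^(−λS)`, m the read length and n the total
  genome length, no edge correction. λ is solved from
  `Σᵢⱼ pᵢpⱼ e^(λ sᵢⱼ) = 1` by bracketed root finding at uniform base
  frequencies (+1/−2 gives λ ≈ 1.3327); K is a configurable constant
  (default 0.3) rather than the full Karlin–Altschul series — the E-value
  serves only as a generous noise threshold, and its required properties
  (strictly decreasing in S, linear in m and n) are independent of K.
* **Best hit**: maximum score, ties broken by lower E-value, longer
  alignment, lexicographic chromosome, smaller coordinate.

The insertion coordinate is the reference position of the *junction base*
— the read base immediately adjacent to the signature motif — obtained by
projecting the junction through the best hit's diagonal:
`pos = ref_start + (junction − read_start)` on the plus strand, mirrored
on the minus strand, clamped to the chromosome. Projection rather than
"first aligned base" matters: a substitution at the junction gets trimmed
from the maximal-scoring segment, but it does not move the diagonal, so
the call survives sequencing errors at the read end. Site strand is the
hit strand for head signatures and its opposite for tail signatures.

FST-level counting is the default everywhere (each mapped read counts
once); a line-deduplicated table (unique line × coordinate) is written
alongside for downstream use.

## Landscape and assembly statistics

* **Chromosome table**: counts per chromosome-length scaffold with
  percents of the high-confidence total, plus total/unanchored/mean rows.
  All printed percents are round-half-up at the precision of the table (2
  decimals for distribution tables, 1 decimal for gene-class percents,
  integer for the mapped-rate figure); Python's banker's rounding is never
  used for reported numbers.
* **Gene tallies**: a site is assigned to every gene whose full span
  (introns and UTRs included) contains it, inclusive ends, via an interval
  tree; overlapping genes each receive the site (logged). Frequency
  classes count genes at ≥ 1, > 1 and ≥ 4 insertions; because the natural
  denominator of "mean insertions per gene" is ambiguous, both means are
  reported (per inserted gene and per annotated gene). Frequent genes are
  those strictly above the mean.
* **Bins**: fixed-width windows (default 500 kb, terminal bin truncated)
  tile each chromosome exactly once; GC fraction is (G+C)/(A+C+G+T),
  all-N bins flagged.
* **Synteny blocks** are consumed, not computed: a two-column TSV of block
  id → member gene id, tallied into members, members-with-insertion and
  summed insertions per block.
* **Assembly partitions**: scaffolds below 1 kb are excluded, partitions
  are user-supplied labels (no hidden size cutoff is invented), N50 is the
  largest length L with pieces ≥ L covering half the total, and contigs
  are scaffolds split at runs of ≥ `min_n_run` (10) N — the gap-splitting
  convention is a parameter because published contig definitions vary.

## The synthetic population

The generator emulates the structure of a real FST dataset at desk scale.
Defaults (the study conditions of the test suite and acceptance script):

| parameter | default | why |
|---|---|---|
| genome | 8 × 125 kb, i.i.d. bases | 1 Mb total; eight chromosomes like the target taxon |
| GC | 0.34 | legume-like composition |
| genes | 100, non-overlapping, 1–4 kb | ~1 gene / 10 kb, the real annotation's density |
| lines × insertions | 100 × U{10..30} | ~2,000 insertions, ≈ 18 FSTs/line as in the real population |
| read length | Normal(363, 60), floor 50 | 363 bp is the empirical mean FST length |
| class mix | 55% signature / 35% no-signature / 5% too-short / 5% internal | ≈ the real 56% high-confidence fraction |
| substitution rate | 0.01 per base, motif exempt | Sanger/Illumina-era error scale |
| orientation | 50% of reads reverse-complemented | TAIL-PCR orientation is arbitrary |

Insertions are uniform over the genome (chromosome probability ∝ length),
strands uniform, no duplicate coordinate within a line. A signature read
is motif + genomic flank from the insertion point in the strand's
direction (truncated at chromosome ends; reads left shorter than the QC
floor are skipped and logged); an internal-signature read carries its
motif ≥ 28 bp from both ends; a no-signature read is pure flank; a
too-short read is 15–49 bp.

Class labels are **content-enforced**: after substitution noise, any
chance motif occurrence that would contradict the label (a spurious motif
in a contaminant, an end-proximal occurrence in an internal-signature
read) is disrupted by mutating one of its bases. Labels are therefore
exact by construction at any substitution rate, which is what makes
"100% of contaminants rejected with the correct reason" a meaningful
test of the classifier rather than of the noise process.

What the generator does *not* emulate — and what passing tests therefore
do not demonstrate about real data: indel sequencing errors (the aligner
is ungapped; real reads with indels near the junction would shift calls),
repetitive genomes (i.i.d. sequence has no paralogy, so best-hit selection
is never stressed by multi-mapping), chimeric reads, insertion-site
preference (real *Tnt1* is only approximately uniform), and library-level
biases across lines.

## Numerical choices

* Internal coordinates are 1-based inclusive throughout (GFF3
  convention); BED output converts to 0-based half-open at the boundary.
* Identity comparisons allow a 10⁻¹² float tolerance so 90/100 columns
  passes a 0.90 threshold.
* λ is cached per scoring scheme; bracketing doubles the upper bound until
  the defining function changes sign, then Brent's method to 10⁻¹².
* IUPAC ambiguity codes in input sequences collapse to N; N matches
  nothing during alignment and motif search.
* Degenerate inputs: empty batches give all-zero summaries (mapped
  percent reported as 0 with a warning); all-N bins and scaffolds are
  flagged/logged rather than dropped silently.

## Known limitations

* Ungapped alignment only; no gapped or spliced mode.
* E-values are threshold-grade, not calibrated significances (constant K).
* The aligner guarantees the optimal *ungapped* segment only when a seed
  of length k survives inside the optimal segment; with the default
  k = 15 and the ≥ 90% identity regime this is effectively always, and an
  exhaustive all-placement oracle is part of the test suite, but
  adversarial inputs (dense substitutions spaced < k apart) can evade
  seeding.
* Single-threaded; problem sizes are desk-scale (a 1 Mb toy study runs in
  ~15 s; a full 400 Mb genome index would need a different representation).
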
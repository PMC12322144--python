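# Methods

## Signature model

A single-strand break with a 3′-OH end is extended by an error-prone
polymerase whose 5′→3′ exonuclease removes the downstream strand while the
polymerase resynthesizes it from a dNTP pool missing one nucleotide. Within
the resynthesized tract, every template position calling for the omitted
nucleotide receives one of the other three (a transition most often) or is
skipped; the tract therefore contains **zero** copies of the omitted base.
With dATP omitted, the signature on the forward reference strand is a run of
mutated A positions when the forward strand was nicked, and a run of mutated
T positions (the complement, in forward coordinates) when the reverse strand
was nicked. Omitting dCTP instead gives C/G runs; both modes are supported.

## Detection

1. **Usable alignments.** Primary, mapped, non-secondary, non-supplementary
   records whose error rate is at most 10 % (inclusive). The error rate is
   `(substituted + inserted + deleted bases) / reference span`, where the
   reference span counts M/=/X/D CIGAR bases (N skips excluded). This is the
   NM-style edit distance; the bound sits well above platform error rates,
   so it removes only junk alignments while tolerating signature tracts.
2. **Mutation extraction.** One observation per substituted reference
   position, per deleted reference position, and one per insertion run
   (anchored at the following reference position). Reference bases come
   from the FASTA, not MD tags; positions where the reference is N are never
   counted. Soft/hard clips are ignored.
3. **Event scan.** For each target base, all reference target positions
   within the aligned span are flagged mutated (substituted or deleted) or
   intact. Every maximal run of consecutive mutated target positions is an
   event if the neighbouring target position on the anchor side (5′ for A/C,
   3′ for T/G) exists in the same contiguous aligned segment and is intact.
   Runs touching the alignment edge or an N skip on the anchor side are
   discarded: the "last intact target base" cannot be verified there. Both
   A- and T-type events are scanned on every read regardless of the
   alignment's orientation flag, since either physical strand may have been
   sequenced.
4. **Filters.** Per technology profile: minimum mutated targets per event
   (PacBio HiFi 5, Nanopore 5, Illumina/TK6 3, Illumina/HaCaT 4), minimum
   mean quality of substituted bases 10 (deletions carry no quality and are
   excluded from the mean), and for Nanopore at least 3 of the mutations
   must be substitutions. When base qualities are absent the quality filter
   fails closed unless the profile says otherwise. The first failing filter
   is recorded per event.
5. **Break interval.** A 5′-anchored event with intact anchor *a* and first
   mutated target *m* yields `[a+1, m+1)` on the + strand; a 3′-anchored
   event with last mutated target *l* and anchor *a* yields `[l, a)` on the
   − strand. The planted nick always lies inside this interval for a clean
   signature read. "First mutated nucleotide" is read as the first mutated
   *target* base: isolated non-target mismatches are indistinguishable from
   sequencing errors, so using them would corrupt localization.
6. **Dedup and output.** Short-read (PCR-amplified) profiles deduplicate on
   (chrom, start, end, strand), keeping the highest-mapq call (ties:
   lexicographically smallest read name) for determinism; long-read
   profiles do not, as each read is one molecule. The BED is
   coordinate-sorted with byte-identical duplicate lines removed.

## Simulator

The generator emits **pre-aligned** SAM (exact CIGAR/MD/NM constructed from
the known edit script — no aligner runs), FASTQ and a truth BED.

* **Reference:** seeded i.i.d. sequence with configurable GC (default 0.41,
  the human genome-wide value), optionally embedding motif copies in both
  orientations at recorded positions.
* **Nicks:** at motif sites (recognition GTCTC, nick offset 6, i.e.
  GTCTCN^N, mirrored on the reverse strand), at a Poisson per-bp rate, or
  from a BED.
* **Signature spectrum (−dATP default):** A→G 0.55, A→T 0.10, A→C 0.10,
  deletion 0.25, insertion 0.01/position. These are qualitative defaults —
  "mostly the transition partner, deletions frequent" — not published
  numbers (the published percentages are figure-image content); they are
  configurable. Tract length is geometric with mean 50 bp (a hairpin design
  point of 55 modified nucleotides is the only measured anchor; the true
  distribution is unknown) or fixed.
* **Molecule copies:** each library draws reads from `n_copies` (default
  20) independently modified genome copies; every copy redraws tract
  lengths and substitution outcomes. A sequencing library samples each
  locus from many distinct template molecules, so one unlucky short tract
  must not silence a nick in every read — with a single copy, recall
  saturates near the probability that one tract draw contains enough
  target bases (~0.7), which is an artefact, not chemistry.
* **Error layers:** per-technology constant-quality models
  (illumina 1e-3 sub / 1e-4 indel, q35; pacbio-hifi 2e-3 / 1e-3, q30;
  nanopore 2e-2 / 2e-2, q15) — invented, documented, configurable, and all
  far below the 10 % usability bound. Reads are drawn uniformly from both
  duplex strands; reverse-strand reads are emitted flag-16 with SEQ in
  forward orientation, as an aligner would.

What a green simulation test establishes: the scan/filter/interval logic
recovers planted breaks under idealized error models and uniform coverage.
What it does not: robustness to alignment artefacts (the simulator never
misaligns), PCR chimeras, coverage bias, or real platform error profiles
(homopolymer-context errors especially).

## Site coincidence and scoring

Nick points are represented as 1-bp intervals (`site_repr="motif-span"`
exposes the alternative reading). A call coincides with a track under the
`bedtools window -w` rule: the call extended by `w` (default 10 bp) on both
sides overlaps the site, half-open; `w=0` is plain intersection. Recall is
the fraction of truth nicks with a call within tolerance, precision the
fraction of calls within tolerance of some nick; a greedy closest-first
1-to-1 matching (ties by coordinate) supplies the per-nick table. For a
random track of *n* 1-bp sites on a genome of length *L*, a call of length
ℓ coincides with probability `1 − (1 − (ℓ+2w)/L)^n`, the null used by the
random-control check.

## Region annotation

One representative transcript per gene (longest genomic span). Categories,
in increasing priority: distal intergenic < downstream ≤3 kb < other intron
< first intron < exon < 3′UTR < 5′UTR < promoter 2–3 kb < 1–2 kb < 0–1 kb
(painted low-to-high onto per-position label arrays, so the result is an
exact partition of the genome). The promoter is 3 kb upstream of the TSS in
1-kb bins. Calls are assigned by interval midpoint (calls are at most tens
of bp; the midpoint is deterministic). Relative strand is *forward* when
the call strand equals the assigned gene's strand; intergenic calls keep
their absolute strand. Per-category frequency divides by the category's bp
(a `coverage_weight` option rescales denominators by mean coverage; whether
published region frequencies were coverage-normalized is not stated, so
both readings are exposed and neither asserted). Non-canonical chromosomes
are dropped before annotation (configurable regex, default chr1–22/X/Y/M).

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open everywhere; BED output likewise.
* The 10 % error bound is inclusive ("at most").
* Mean substituted-base quality is an arithmetic mean of phred scores;
  missing qualities propagate as "unavailable", failing closed where the
  profile requires quality.
* Empty inputs produce empty, valid outputs; an alignment referencing a
  chromosome absent from the reference is an error naming the chromosome.
* All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds give byte-identical outputs.
* A read may contain several events; all passing events are reported.

## Known limitations

* Supplementary/split alignments are ignored, so breaks detectable only via
  split long reads are missed.
* Breaks are localized between flanking target bases; in target-poor
  sequence the interval is wide, and a sequencing error that restores an
  intact-looking target base inside a long run can split it and shift the
  reported interval (the dominant source of >10 bp misses in simulation,
  well under 1 % of calls).
* The detector is rule-based, not probabilistic: no per-call confidence
  score beyond the annotation columns.
* Paired-end simulation and PCR-duplicate modelling are not implemented;
  dedup behaviour is still exercised through positional duplicates.
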
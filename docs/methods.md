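# Methods

## Scope and model

`aontriage` decides, per neurodevelopmental disorder (NDD) and per
pathogenic variant, which of seven antisense-oligonucleotide strategies is
mechanically plausible. It is a deterministic rule system, not a
statistical model: every decision reduces to arithmetic over one MANE
transcript per gene (exon coding lengths, mod-3 frame classes, distances
to exon–intron boundaries, coding-loss fractions), set operations over an
HPO subgraph, simple threshold gates, and one genuinely statistical step —
the lncRNA co-expression search (Pearson correlation across brain
tissues, Benjamini–Hochberg corrected).

All genomic coordinates are 0-based half-open internally; GTF and
ClinVar-dialect inputs (1-based inclusive) are converted at the I/O
boundary. Exons are stored 5′→3′ in transcript orientation, so every rule
is strand-symmetric by construction; the test suite verifies this by
mirroring transcripts to the opposite strand and asserting identical
results.

## Rules and the parameters that matter

Thresholds live in `aontriage.config`, all config-exposed:

| constant | default | meaning |
|---|---|---|
| `DEEP_INTRONIC_MIN_DISTANCE` | 50 nt | minimum distance from an exon–intron boundary for splice-correction; the intronic base adjacent to an exon has distance 1 (HGVS offset convention), so the rule is distance ≥ 50 |
| `RECURRENT_MIN_SUBMISSIONS` | 3 | submissions for a variant to count as recurrent |
| `SV_MIN_LENGTH` | 50 bp | span at which a variant is classified SV before any other rule |
| `SPLICEAI_THRESHOLD` | 0.2 | strict lower bound on the max of the four SpliceAI deltas for the splice-region disambiguation |
| `MAX_CDS_LOSS` | 0.10 | cap on combined coding loss for both skipping strategies; exactly 10 % is accepted |
| `CANONICAL_SPLICE_WINDOW` | 2 nt | donor/acceptor variants within ±2 nt obligate skipping the adjacent exon |
| `NMD_LAST_JUNCTION_WINDOW` / `NMD_START_PROXIMAL_WINDOW` | 50 / 100 nt | NMD-escape rule set (last exon, near-junction, start-proximal, intronless) |
| `PLI_THRESHOLD` / `LOF_RATIO_THRESHOLD` | 0.9 / 0.2 | strict gates (pLI > 0.9, LoF ratio > 0.2) for wildtype-allele upregulation |
| `MIN_SOURCE_SCORE` | 3 | retention threshold for merged associations |
| `COEXPRESSION_ALPHA` | 0.05 | BH-adjusted significance for lncRNA partners |
| `BRAIN_TISSUE_PREFIX` | `"Brain"` | tissue columns forming the correlation panel |

Design choices where the design was genuinely open:

* **Exon "length" in all mod-3 arithmetic is the coding
  (CDS-overlapping) length**, not the full exon length; UTR-only exons are
  frame-neutral. Reading-frame restoration is only meaningful over coding
  sequence. An exon is "in frame" iff its coding length is a multiple of
  three; no codon-boundary phase condition is imposed (flagged for
  sensitivity analysis).
* **First/last-exon exclusion applies to the transcript's first and last
  exons**, not the first/last coding exons.
* **Splice-site orientation**: a donor variant obligates skipping its
  upstream exon (transcript orientation), an acceptor its downstream exon
  — the disrupted site borders that exon. "Neighboring" means the
  immediately adjacent exon only; one neighbor is skipped per plan, and
  when both neighbors restore the frame both plans are reported.
* **Severity ranking** for ambiguous consequence lists is frozen from the
  Ensembl order into a config table so resolution is reproducible offline.
* **Ties in the most-reported OMIM id** attach the variant to all tied
  associations (logged); downstream union semantics tolerate this.
* **Unresolvable inheritance conflicts** go to a manual-curation queue; an
  unknown-inheritance row joins the unique known inheritance for its
  (gene, OMIM) pair, otherwise it is queued, never guessed.
* **Negative co-expression partners are reported with sign** and count as
  partners: the antisense-lncRNA mechanism predicts negative regulation,
  and the test is a correlation test, not a positivity test.
* **BH family**: all lncRNA–gene pairs evaluated in a run form one family
  (size recorded in the pair table and run summary).
* **LoF-ratio denominator**: all pathogenic variants attached to the
  gene's retained association(s).
* **Retention-exclusion precedence**: an association failing both filters
  reports `no_omim` (a missing OMIM id blocks all downstream annotation).
* **Gene-based strategy flags require ≥ 1 attached LoF variant** in
  addition to the gate, and the phenotype call gates all seven flags.
* **Frameshift PTC placement**: with a CDS sequence available the shifted
  frame is scanned for the first stop; without one, the PTC is assumed at
  the variant position (a documented surrogate that is exact when the
  first shifted-frame stop is nearby). Both modes are tested.

## Numerical choices

Pearson r and p come from `scipy.stats.pearsonr`; BH from
`statsmodels.stats.multitest.multipletests(method="fdr_bh")`. Both are
cross-checked in the tests against independent textbook-formula
implementations (centered-sums r, exact t transform for p, step-up BH) to
1e-10. Zero-variance expression vectors are skipped with an explicit
flag; candidate lncRNAs must have TPM > 0 in at least one brain tissue;
fewer than three brain tissues is an error. Loss fractions are exact
rationals evaluated in floating point; the 10 % comparison uses plain
`>` on the fraction, which is exact for the test fixtures (denominators
are decimal-friendly) and stable in general because inputs are integers.

## The synthetic cohort generator

`aontriage.synthetic` generates every input the pipeline reads, with truth
labels derived constructively at generation time — never by running the
pipeline — so end-to-end recovery is a genuine check:

* **Transcripts**: 6–9 exons per gene, coding exon lengths 60–240 nt,
  introns 400–3000 nt, fixed 120/150 nt UTRs, alternating strands
  (minus-strand genes are exact mirrors, exercising strand symmetry).
  CDS sequences are random sense codons with planted codons at variant
  sites (TAT→TAA stops, GCT→GGT missense, CTA→CTG synonymous, an
  engineered ATA·AAT pair so a 1-bp deletion yields an immediate stop).
* **Planted strategy cases**: each positive case is built to satisfy its
  rule with margin — e.g. an ES-RF case picks exon lengths ≡ 1 and ≡ 2
  (mod 3) and pads another exon until the combined loss is under 10 %; a
  planted upregulation gene draws AD inheritance, pLI 0.92–0.99 and three
  non-escaping stop variants among nine variants (LoF ratio 1/3).
* **Negative controls** pin every inequality: distance 49, submissions 2,
  pLI exactly 0.9, LoF ratio exactly 0.2 (2 LoF of 10), loss exactly 10 %
  (accepted) vs one codon more (rejected; the generator works in whole
  codons, so the 1-nt boundary itself is pinned by direct unit tests),
  first/last-exon variants, a last-exon stop (NMD escape), and a
  seizure-annotated disease voided by neonatal lethality.
* **Expression**: 13 brain-named tissues plus two non-brain. A planted
  lncRNA partner is constructed with *sample* correlation exactly ρ
  (default 0.95) by projecting noise orthogonal to the gene vector, then
  affine-shifted positive (Pearson r is affine-invariant). Decoy lncRNAs
  live in the TADs of filler genes only, so their occasional BH false
  positives can never flip a truth flag.
* **Submission counts** are geometric (mean 1.6, capped at 25), mimicking
  ClinVar's long tail.

Defaults produce ~44 genes + 10 boundary-control genes and ~290 variants;
five such cohorts run end-to-end in a few seconds on one CPU. What the
generator does **not** emulate: real gene nomenclature, population allele
frequencies, mutational signatures, multi-transcript genes, coordinated
multi-OMIM phenotype records, or realistic expression covariance between
genes. Passing the recovery tests therefore demonstrates that the rule
implementations are faithful and internally consistent — not that the
rules themselves capture real-data annotation noise, and absolute
targetability percentages from synthetic cohorts reflect the planted
mixture, not any real database snapshot.

## Problem sizes used in tests and the acceptance script

Ground-truth recovery uses five default cohorts (~290 variants each); the
frame-arithmetic oracle enumerates 1000 random transcripts of ≤ 8 exons;
the statistics oracle checks 100 pairs against textbook formulas and runs
200 BH-calibration simulations (31 pairs each). These sizes keep the full
suite under ten seconds while exercising every rule branch; all are
seed-driven and scale up by changing one constant.

## Known limitations

* The internal positional annotator is deliberately simplified and only
  trusted for synthetic cohorts; real-data runs must supply precomputed
  VEP/SpliceAI annotation columns, which always take precedence.
* Multi-exon ES-RF deletions consider one neighbor per plan; skipping one
  exon on *each* side simultaneously is out of scope.
* ES-VE treats any in-frame internal exon under the loss cap as
  skippable; protein-domain criticality is not modeled, so these calls
  are optimistic by design.
* The NMD-escape rule set is the standard four-criterion approximation;
  tissue-specific NMD efficiency is not modeled.
* Phenotype calls use descendant-closure matching on whatever disease
  annotations are provided; onset/frequency qualifiers are ignored.
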
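# aontriage

Rule-based triage of neurodevelopmental disorders (NDDs) and their
pathogenic variants for seven antisense-oligonucleotide (AON) therapeutic
strategies.

Most monogenic NDDs have no disease-modifying therapy, yet several AON
modalities have reached patients: splice-correcting AONs for deep-intronic
variants (milasen), exon skipping to restore a disrupted reading frame
(the *DMD* eteplirsen family), TANGO-style suppression of non-productive
splicing (*SCN1A*/Dravet), and degradation of cis-acting regulatory
lncRNAs (*UBE3A-ATS*/Angelman). Whether any one disorder — or any one
variant — is a plausible target is decided by a small set of mechanical
rules over transcript structure, variant consequence, phenotype and gene
dosage sensitivity. `aontriage` implements those rules as a tested,
reusable pipeline for clinical geneticists and RNA-therapeutics
researchers, together with a synthetic-cohort generator that emulates
every input (ClinVar-style variant tables, disease-gene associations, HPO,
GTEx-like expression, TAD maps) with planted ground truth.

## The rule set

A disorder must first have a presumably rescuable phenotype: at least one
HPO annotation at or below one of six roots (developmental regression
HP:0002376, mental deterioration HP:0001268, loss of ambulation
HP:0002505, neurodegeneration HP:0007367, seizures HP:0001250,
abnormality of movement HP:0100022) and none under neonatal lethality
(HP:0003811). Per strategy, on the MANE transcript:

| strategy | requirement |
|---|---|
| T1 splice correction | consequence `intron_variant` at distance ≥ 50 nt from the nearest exon–intron boundary (recurrence: ≥ 3 ClinVar submissions) |
| T2 exon skip, reading frame (ES-RF) | whole-exon deletion (or canonical ±2 nt splice variant at an out-of-frame exon) with Σ coding length ≢ 0 (mod 3); a neighboring exon *N* with len(*N*) ≢ 0 and Σ + len(*N*) ≡ 0 (mod 3) |
| T3 exon skip, variant exclusion (ES-VE) | stop-gain/frameshift wholly inside a single internal in-frame exon |
| T4–T7 upregulation (TANGO, uAUG, ARE, lncRNA) | autosomal dominant inheritance, pLI > 0.9, > 20 % of causative variants loss-of-function, plus catalog membership (T4–T6) or a TAD-sharing lncRNA significantly co-expressed across brain tissues (Pearson, Benjamini–Hochberg, α = 0.05) (T7) |

Both skipping strategies spare the first and last exon and cap the
combined coding-sequence loss (variant plus skipped exons) at 10 %.
Loss-of-function means stop-gain, frameshift or canonical splice
donor/acceptor, excluding predicted NMD escapers (PTC in the last exon,
within 50 nt of the last junction, within 100 nt of the start codon, or an
intronless transcript). Ambiguous VEP-style consequence lists in the
splice region resolve to `splice_region_variant` when the maximum SpliceAI
delta exceeds 0.2, otherwise to the most severe consequence; variants of
≥ 50 bp are structural variants. Disease–gene associations are merged from
sysNDD-, DDG2P-, HPO- and panel-style sources, scored for clinical
validity (+1/+2 per source and confidence category) and retained at score
≥ 3 with an OMIM id. Variants attach via their most-reported OMIM disease
id; submission counts proxy the number of affected individuals.

## Worked example

```bash
aontriage simulate --seed 7 -o demo/
aontriage run --bundle demo/ -o demo_out/
```

prints (abridged):

```
bundle written to demo: 291 variants, 54 retained disorders
{
 "n_associations_merged": 56,
 "n_retained": 54,
 "n_excluded": 2,
 "n_variants_attached": 283,
 "n_ndds_targetable": 28,
 "n_submissions_total": 433,
 "n_submissions_targetable": 69,
 ...
}
```

Of 56 merged disease–gene associations, 54 survive the score ≥ 3 + OMIM
filters (one planted low-score and one OMIM-less exclusion). 28 disorders
carry at least one targetable combination of characteristics, covering 69
of 433 submissions (the per-individual view). `demo_out/` then holds the
per-disorder and per-variant seven-flag profiles (`ndd_profiles.tsv`,
`variant_profiles.tsv`), UpSet-style combination tables, and
`economics.tsv` with the AONs-needed arithmetic, e.g.

```
strategy            recurrent_only  amenable_individuals  aons_needed  individuals_per_aon
splice_correction   False           11                    6            1.83
splice_correction   True            4                     1            4.0
```

— one AON per unique deep-intronic variant; restricting to recurrent
variants (≥ 3 submissions) treats fewer individuals but needs far fewer
AONs per individual treated. Gene-based strategies count one AON per gene,
exon-skipping one per unique (gene, exon) pair.

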
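# File dialects

All tables are UTF-8 TSV with a header row unless noted. Coordinates on
disk follow each format's native convention (GTF and the ClinVar dialect
are 1-based inclusive; BED is 0-based half-open); everything is converted
to 0-based half-open at the I/O boundary.

## Association sources (`read_association_source`)

| source | required columns | notes |
|---|---|---|
| `sysndd` | `gene_symbol` or `hgnc_id`; optional `omim_id`, `inheritance`, `category` | categories: limited / moderate / definitive |
| `ddg2p` | `gene_symbol` or `hgnc_id`; optional `disease_mim`, `allelic_requirement`, `confidence_category`, `organ_specificity_list` | only rows whose organ list contains `Brain/Cognition` are kept |
| `hpo` | `gene_symbol` or `hgnc_id`; optional `disease_id` | no confidence category; every entry scores +1 |
| `panel` | `gene_symbol` or `hgnc_id`; optional `omim_id`, `inheritance`, `panel` | every entry scores +2 |

Inheritance strings are normalized to {AD, AR, XL, XLD, XLR, unknown}
(`monoallelic_autosomal` → AD, `biallelic_autosomal` → AR, ...). OMIM ids
are normalized to `OMIM:######`. Rows without any gene identifier are
rejected and counted.

## ClinVar dialect (`read_clinvar_summary`)

Columns (subset of variant_summary): `VariationID`, `Name`, `GeneSymbol`,
`ClinSigSimple`, `Chromosome`, `Start`, `Stop` (1-based inclusive),
`ReferenceAlleleVCF`, `AlternateAlleleVCF`, `PhenotypeIDS`, and a
submission count (`Submissions` preferred, `NumberSubmitters` fallback,
default 1 with a warning). Leading `#` comment lines are allowed; a
`#Assembly: <name>` line is checked against the expected assembly
(default GRCh38) and mismatches are hard errors. Only `ClinSigSimple = 1`
rows are retained. `PhenotypeIDS` holds `|`-separated per-submission
groups of `,`/`;`-separated ids; occurrences of `OMIM:######` are counted
across groups to define the most-reported disease id(s).

## Transcripts (GTF)

`exon` and `CDS` features with `gene_id` and `transcript_id` attributes;
transcripts carrying a `tag` attribute containing `MANE` are used (one
model per gene). An optional FASTA keyed by transcript id supplies
spliced CDS sequences for frameshift PTC scanning.

## Ontology and disease phenotypes

OBO with `[Term]` stanzas (`id`, `name`, `is_a` only; the is_a graph must
be acyclic). Disease annotations in phenotype_to_genes format: columns
`hpo_id` and `disease_id` (other columns ignored).

## Expression, TADs, gene lists, lncRNA catalog, pLI

* GCT-like: `#1.2` line, dimension line, then `Name` (+ optional
  `Description`) and one column per tissue; duplicate gene ids are errors.
* TADs: BED3, 0-based half-open.
* Gene lists: one column whose header names the list (`tango`, `uaug`,
  `are`).
* lncRNA catalog: headerless BED-like TSV `chrom start end id biotype`;
  only `biotype == lncRNA` rows are used.
* pLI: two columns, gene and pLI.

## Bundle layout (`run_pipeline`, `aontriage run --bundle`)

```
transcripts.gtf  cds.fa  sysndd.tsv  ddg2p.tsv  hpo_source.tsv  panel.tsv
clinvar.tsv  annotations.tsv  hp.obo  phenotype_to_genes.tsv  pli.tsv
tango.tsv  uaug.tsv  are.tsv  tads.bed  expression.gct  lncrna.tsv
```

`annotations.tsv` (optional, takes precedence over the internal
annotator): `variant_id`, `consequences` (comma-joined), `DS_AG`,
`DS_AL`, `DS_DG`, `DS_DL`, optional `nmd_escape`.

## Outputs

`retained.tsv`, `excluded.tsv`, `curation_queue.tsv`,
`variant_links.tsv`, `ndd_profiles.tsv`, `variant_profiles.tsv` (seven
boolean strategy columns + `any_strategy` + JSON `evidence`),
`upset_disease.tsv`, `upset_individuals.tsv`, `economics.tsv`,
`run_summary.json`.
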
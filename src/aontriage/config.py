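"""Central rule constants for the AON triage pipeline.

Every threshold that appears in a filtering rule lives here so that the
pipeline is auditable in one place.  All distances are in nucleotides, all
fractions are on [0, 1], and all genomic coordinates elsewhere in the
package are 0-based half-open.
"""

from __future__ import annotations

# --- splice-correction (deep-intronic) rule -------------------------------
# An intron_variant is amenable to splice-correcting AONs only when it is at
# least this far from the nearest exon-intron boundary (the base adjacent to
# an exon has distance 1).
DEEP_INTRONIC_MIN_DISTANCE = 50

# Recurrence: a variant counts as recurrent with this many ClinVar
# submissions or more.
RECURRENT_MIN_SUBMISSIONS = 3

# --- variant classification ------------------------------------------------
# Variants spanning this many base pairs or more are classified as SVs
# before any other consequence rule is applied.
SV_MIN_LENGTH = 50

# Ambiguous consequence lists that include a splice-region call are resolved
# to splice_region_variant when the maximum SpliceAI delta exceeds this.
SPLICEAI_THRESHOLD = 0.2

# --- exon skipping ---------------------------------------------------------
# Maximum tolerated loss of coding sequence (variant plus skipped exons
# combined) for either exon-skipping strategy.  The rule is "at most 10%",
# so exactly 0.10 is accepted.
MAX_CDS_LOSS = 0.10

# Splice donor/acceptor variants within this many bases of the exon edge are
# treated as canonical-site hits that obligate skipping the adjacent exon.
CANONICAL_SPLICE_WINDOW = 2

# --- NMD escape (VEP NMD-plugin rule set) ----------------------------------
# A premature termination codon escapes NMD when it lies in the last exon,
# within this many nt upstream of the last exon-exon junction, within this
# many nt of the start codon, or in an intronless transcript.
NMD_LAST_JUNCTION_WINDOW = 50
NMD_START_PROXIMAL_WINDOW = 100

# --- wildtype-allele upregulation gate -------------------------------------
# Haploinsufficiency gate: pLI strictly greater than 0.9 and strictly more
# than 20% of the gene's causative variants loss-of-function.
PLI_THRESHOLD = 0.9
LOF_RATIO_THRESHOLD = 0.2

# --- dataset construction --------------------------------------------------
# Disease-gene associations are retained when their cumulative source score
# reaches this value (and an OMIM disease id is present).
MIN_SOURCE_SCORE = 3

# --- phenotype targetability ----------------------------------------------
# HPO roots whose descendant closure marks a presumably rescuable phenotype:
# developmental / mental / ambulation deterioration, neurodegeneration,
# seizures, abnormality of movement.
PHENOTYPE_INCLUDE_ROOTS = (
    "HP:0002376",  # developmental regression
    "HP:0001268",  # mental deterioration
    "HP:0002505",  # loss of ambulation
    "HP:0007367",  # neurodegeneration (atrophy/degeneration of CNS)
    "HP:0001250",  # seizure
    "HP:0100022",  # abnormality of movement
)
# Diseases annotated under this root are excluded regardless of the above.
PHENOTYPE_EXCLUDE_ROOT = "HP:0003811"  # neonatal death

# --- lncRNA co-expression search ------------------------------------------
# BH-adjusted significance level for Pearson co-expression partners.
COEXPRESSION_ALPHA = 0.05
# Tissue columns whose name starts with this prefix form the brain panel.
BRAIN_TISSUE_PREFIX = "Brain"

# Expected genome assembly for ClinVar-dialect tables.
EXPECTED_ASSEMBLY = "GRCh38"

STRATEGIES = (
    "splice_correction",
    "es_rf",
    "es_ve",
    "tango",
    "uaug",
    "are",
    "lncrna",
)
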
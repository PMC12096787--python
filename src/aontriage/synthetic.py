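"""Synthetic input bundles with planted ground-truth strategy labels.

The generator emits every file the pipeline reads — transcripts (GTF + CDS
FASTA), association sources, a ClinVar-dialect variant table, HPO ontology
and disease annotations, pLI, gene lists, TADs and a brain expression
matrix — with each targetable characteristic planted by construction: an
exon-skipping case is built by choosing exon coding lengths with the
required mod-3 relations and a combined loss under the 10% cap, a
deep-intronic case places its variant at a chosen distance inside a long
intron, an upregulation case draws AD inheritance, pLI > 0.9 and enough
non-NMD-escaping stop variants to clear the 20% LoF-ratio gate, and a
lncRNA partner is co-located in the gene's TAD with an exactly-ρ sample
correlation across the brain tissues.

Truth labels are derived from these constructions, never by running the
pipeline, so recovering them end-to-end is a genuine check.  All
randomness flows from the config seed; two runs with the same config
produce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Set, Tuple

import numpy as np

from . import config as cfgmod
from .gene_model import TranscriptModel

UTR5 = 120
UTR3 = 150

_BASES = "ACGT"
# sense codons for background sequence (no stops)
_SENSE_CODONS = [
    a + b + c
    for a in _BASES for b in _BASES for c in _BASES
    if a + b + c not in {"TAA", "TAG", "TGA"}
]

BRAIN_TISSUES = [
    "Brain - Amygdala", "Brain - Anterior cingulate cortex",
    "Brain - Caudate", "Brain - Cerebellar Hemisphere", "Brain - Cerebellum",
    "Brain - Cortex", "Brain - Frontal Cortex", "Brain - Hippocampus",
    "Brain - Hypothalamus", "Brain - Nucleus accumbens",
    "Brain - Putamen", "Brain - Spinal cord", "Brain - Substantia nigra",
]
OTHER_TISSUES = ["Liver", "Muscle - Skeletal"]

# small synthetic HPO: child/grandchild chain below every include root
_ROOT_CHILDREN = {
    root: (f"HP:09{idx}0001", f"HP:09{idx}0002")
    for idx, root in enumerate(cfgmod.PHENOTYPE_INCLUDE_ROOTS)
}
_LETHAL_CHILD = "HP:0990001"

SCENARIOS_TARGETING = {
    "deep_intronic": "splice_correction",
    "deep_intronic_recurrent": "splice_correction",
    "es_rf_sv": "es_rf",
    "es_rf_splice": "es_rf",
    "es_ve": "es_ve",
}


class GenerationError(ValueError):
    """The cohort config is infeasible; the message names the constraint."""


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Planted fractions are fractions of ``n_genes`` receiving each planted
    strategy; the remainder are filler genes with non-targetable variants.
    Submission counts are geometric with the given mean, mimicking the
    long-tailed ClinVar submission distribution.
    """

    seed: int = 0
    n_genes: int = 44
    exon_count_range: Tuple[int, int] = (6, 9)
    exon_coding_length_range: Tuple[int, int] = (60, 240)
    n_filler_variants: int = 4
    planted_fractions: Dict[str, float] = field(
        default_factory=lambda: {
            "deep_intronic": 0.12,
            "es_rf_sv": 0.09,
            "es_rf_splice": 0.09,
            "es_ve": 0.12,
            "upregulation": 0.18,
        }
    )
    submissions_mean: float = 1.6
    partner_rho: float = 0.95
    n_decoy_lncrnas: int = 40
    alpha: float = 0.05
    include_negative_controls: bool = True

    def validate(self) -> None:
        lo_n, hi_n = self.exon_count_range
        if lo_n < 6 or hi_n < lo_n:
            raise GenerationError(
                "exon_count_range: planted skip patterns need at least 6 "
                f"exons per transcript and a non-empty range, got ({lo_n}, {hi_n})"
            )
        lo, hi = self.exon_coding_length_range
        if lo < 60 or hi < lo:
            raise GenerationError(
                "exon_coding_length_range: coding exons must be at least "
                f"60 nt and the range non-empty, got ({lo}, {hi})"
            )
        for k, f in self.planted_fractions.items():
            if not 0 <= f <= 1:
                raise GenerationError(f"planted fraction {k} = {f} outside [0, 1]")
        if sum(self.planted_fractions.values()) > 1:
            raise GenerationError("planted fractions sum above 1")


@dataclass
class TruthLabels:
    """Constructive ground truth for one generated bundle."""

    variant_flags: Dict[str, Dict[str, bool]] = field(default_factory=dict)
    ndd_flags: Dict[str, Dict[str, bool]] = field(default_factory=dict)
    variant_classes: Dict[str, str] = field(default_factory=dict)
    phenotype_targetable: Dict[str, bool] = field(default_factory=dict)
    gate_eligible: Dict[str, bool] = field(default_factory=dict)
    lof_ratio: Dict[str, float] = field(default_factory=dict)
    recurrent_variants: Set[str] = field(default_factory=set)
    expected_excluded: Dict[str, str] = field(default_factory=dict)
    planted_partners: Dict[str, str] = field(default_factory=dict)
    variant_gene: Dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["recurrent_variants"] = sorted(self.recurrent_variants)
        return json.dumps(d, indent=1, sort_keys=True)


def mirror_interval(iv: Tuple[int, int], m: int) -> Tuple[int, int]:
    return (m - iv[1], m - iv[0])


def mirror_transcript(t: TranscriptModel, m: int) -> TranscriptModel:
    """Reflect a transcript to the opposite strand around coordinate ``m``.

    The mirrored model has identical exon order in transcript orientation
    and identical coding structure; every derived quantity must be
    unchanged (the strand-symmetry oracle used throughout the tests).
    """
    return TranscriptModel(
        transcript_id=t.transcript_id,
        gene=t.gene,
        chromosome=t.chromosome,
        strand="-" if t.strand == "+" else "+",
        exons=tuple(mirror_interval(iv, m) for iv in t.exons),
        cds_start=m - t.cds_end,
        cds_end=m - t.cds_start,
        mane=t.mane,
        cds_sequence=t.cds_sequence,
    )


# ---------------------------------------------------------------------------
# per-gene plans and construction
# ---------------------------------------------------------------------------


@dataclass
class _GenePlan:
    gene: str
    omim: Optional[str]
    inheritance: str
    scenario: str
    phenotype: str  # targetable | lethal | none
    pli: float
    lists: Set[str] = field(default_factory=set)
    lncrna: Optional[str] = None  # planted | zero_tpm | None
    strand: str = "+"
    score_pattern: int = 0
    retained: bool = True
    exclusion_reason: Optional[str] = None
    n_lof_planted: int = 0
    n_variants_planted: int = 0


@dataclass
class _BuiltGene:
    plan: _GenePlan
    transcript: TranscriptModel
    variants: List[dict]
    annotations: Dict[str, dict] = field(default_factory=dict)


class _CodonAllocator:
    """Hand out non-colliding codon-aligned CDS positions inside exons."""

    def __init__(self, coding_lengths: List[int]):
        self.coding_lengths = coding_lengths
        self.used: Set[int] = set()

    def exon_codon_span(self, exon: int) -> Tuple[int, int]:
        """[first, last] fully-contained 0-based codon indices of an exon."""
        before = sum(self.coding_lengths[: exon - 1])
        first = math.ceil(before / 3)
        last = (before + self.coding_lengths[exon - 1]) // 3 - 1
        return first, last

    def take(self, exon: int, min_codon: int = 1) -> Optional[int]:
        first, last = self.exon_codon_span(exon)
        for ci in range(max(first + 1, min_codon), last):
            if ci not in self.used:
                self.used.add(ci)
                return ci
        return None


def _geometric(rng: np.random.Generator, mean: float) -> int:
    p = min(1.0, 1.0 / max(mean, 1.0))
    return int(min(rng.geometric(p), 25))


def _build_gene(
    plan: _GenePlan,
    cfg: CohortConfig,
    rng: np.random.Generator,
    chrom: str,
    offset: int,
    vid_counter: List[int],
    truth: TruthLabels,
    gate_truth: bool,
) -> _BuiltGene:
    lo_n, hi_n = cfg.exon_count_range
    lo, hi = cfg.exon_coding_length_range
    n = int(rng.integers(lo_n, hi_n + 1))
    c = [int(rng.integers(lo, hi + 1)) for _ in range(n)]
    scen = plan.scenario

    def set_mod(idx: int, mod: int) -> None:
        c[idx - 1] += (mod - c[idx - 1] % 3) % 3

    # --- scenario constraints on exon coding lengths (before layout) -------
    critical: List[int] = []
    planted_exon = planted_nb = None
    splice_site = None
    stop_hosts: List[int] = []

    if scen in {"es_ve", "es_ve_loss_pos", "es_ve_loss_neg"}:
        planted_exon = int(rng.integers(3, n - 1))  # internal and <= n-2
        set_mod(planted_exon, 0)
        critical = [planted_exon]
    elif scen == "es_rf_sv":
        planted_exon = int(rng.integers(2, n - 2))  # deleted whole exon
        planted_nb = planted_exon + 1  # restoring neighbor, internal
        set_mod(planted_exon, 1)
        set_mod(planted_nb, 2)
        critical = [planted_exon, planted_nb]
    elif scen == "es_rf_first_exon_sv":
        set_mod(1, 1)  # frameshifting deletion of the first exon
    elif scen == "es_rf_splice":
        planted_exon = int(rng.integers(3, n - 1))  # obligate skip
        planted_nb = planted_exon - 1  # >= 2, internal
        set_mod(planted_exon, 1)
        set_mod(planted_nb, 2)
        splice_site = "donor" if rng.integers(2) else "acceptor"
        critical = [planted_exon, planted_nb]
    elif scen in {"upregulation", "upreg_pli_boundary"}:
        stop_hosts = [int(rng.integers(3, n - 1)) for _ in range(3)]
        for h in stop_hosts:
            set_mod(h, 1)  # out-of-frame hosts keep ES-VE out of the picture
    elif scen == "upreg_ratio_boundary":
        stop_hosts = [int(rng.integers(3, n - 1)) for _ in range(2)]
        for h in stop_hosts:
            set_mod(h, 1)
    elif scen == "nmd_escape_last_exon":
        stop_hosts = [n]

    flex = next(
        i for i in range(2, n)
        if i not in set(critical) | {planted_exon, planted_nb} | set(stop_hosts)
    )

    if scen in {"es_ve_loss_pos", "es_ve_loss_neg"}:
        # deterministic lengths: planted exon L, CDS exactly 10L (loss = 10%)
        # or 10L - 3 (loss just above 10%); every exon a whole codon count
        L = hi - hi % 3
        lo3 = lo + (-lo) % 3
        target = 10 * L if scen == "es_ve_loss_pos" else 10 * L - 3
        for i in range(1, n + 1):
            c[i - 1] = lo3
        c[planted_exon - 1] = L
        rest = target - sum(c)
        if rest < 0:
            raise GenerationError(
                "exon_coding_length_range: cannot reach a 10% CDS-loss "
                "boundary with these exon lengths"
            )
        c[flex - 1] += rest
    else:
        if critical:
            need = 10 * sum(c[i - 1] for i in critical) + 9
            if sum(c) < need:
                pad = need - sum(c)
                c[flex - 1] += pad + (-pad) % 3
        c[flex - 1] += (3 - sum(c) % 3) % 3  # whole number of codons

    # --- genomic layout (+ strand; mirrored afterwards for '-' genes) ------
    introns = [int(rng.integers(400, 3001)) for _ in range(n - 1)]
    exon_totals = list(c)
    exon_totals[0] += UTR5
    exon_totals[-1] += UTR3
    exons = []
    cur = offset
    for i, length in enumerate(exon_totals):
        exons.append((cur, cur + length))
        cur += length
        if i < n - 1:
            cur += introns[i]
    cds_start = exons[0][0] + UTR5
    cds_end = exons[-1][1] - UTR3

    n_codons = sum(c) // 3
    codons = [
        "ATG",
        *(_SENSE_CODONS[int(k)]
          for k in rng.integers(0, len(_SENSE_CODONS), n_codons - 2)),
        "TAA",
    ]

    def cds_to_genomic(pos: int) -> int:
        remaining = pos - 1
        for (s, e) in exons:
            cs, ce = max(s, cds_start), min(e, cds_end)
            if cs >= ce:
                continue
            if remaining < ce - cs:
                return cs + remaining
            remaining -= ce - cs
        raise AssertionError("CDS position outside transcript")

    alloc = _CodonAllocator(c)
    variants: List[dict] = []
    annotations: Dict[str, dict] = {}
    pheno_ok = plan.phenotype == "targetable"

    def add_variant(start, end, ref, alt, truth_class, flags, lof,
                    submissions=None) -> dict:
        vid_counter[0] += 1
        vid = f"v{vid_counter[0]:05d}"
        subs = submissions if submissions is not None else _geometric(
            rng, cfg.submissions_mean)
        row = {
            "variant_id": vid, "gene": plan.gene, "chromosome": chrom,
            "start": start, "end": end, "ref": ref, "alt": alt,
            "submission_count": subs, "_lof": lof,
        }
        variants.append(row)
        truth.variant_classes[vid] = truth_class
        truth.variant_gene[vid] = plan.gene
        truth.variant_flags[vid] = {s: False for s in cfgmod.STRATEGIES}
        truth.variant_flags[vid].update(flags)
        if subs >= cfgmod.RECURRENT_MIN_SUBMISSIONS:
            truth.recurrent_variants.add(vid)
        return row

    def plant_codon(exon: int, codon_seq: str, min_codon: int = 1,
                    fallback: Optional[List[int]] = None) -> int:
        candidates = [exon] + [i for i in (fallback or []) if i != exon]
        for ex in candidates:
            ci = alloc.take(ex, min_codon=min_codon)
            if ci is not None:
                codons[ci] = codon_seq
                return ci
        raise GenerationError(
            f"exon_coding_length_range: no free codon for planting in "
            f"{plan.gene} exon {exon}"
        )

    def upreg_flags() -> Dict[str, bool]:
        if scen == "upregulation" and gate_truth:
            return {
                "tango": pheno_ok and "tango" in plan.lists,
                "uaug": pheno_ok and "uaug" in plan.lists,
                "are": pheno_ok and "are" in plan.lists,
                "lncrna": pheno_ok and plan.lncrna == "planted",
            }
        return {}

    def plant_stop(exon: int, escape_last_exon: bool = False,
                   flags: Optional[dict] = None) -> None:
        # TAT -> TAA via substitution of the third codon base; min_codon 35
        # keeps the PTC > 100 nt from the start codon (no NMD escape).
        # Fallback hosts stay among the designated out-of-frame stop hosts
        # so the planted NMD fate and ES-VE ineligibility are preserved.
        min_codon = 1 if escape_last_exon else 35
        ci = plant_codon(exon, "TAT", min_codon=min_codon, fallback=stop_hosts)
        pos = cds_to_genomic(3 * ci + 3)
        add_variant(pos, pos + 1, "T", "A", "stop_gained",
                    {**(flags or {}), **upreg_flags()},
                    lof=not escape_last_exon)

    _benign_exons = list(range(2, n))

    def plant_missense(exon: int) -> None:
        ci = plant_codon(exon, "GCT", fallback=_benign_exons)
        pos = cds_to_genomic(3 * ci + 2)  # GCT -> GGT
        add_variant(pos, pos + 1, "C", "G", "missense_variant", {}, lof=False)

    def plant_synonymous(exon: int) -> None:
        ci = plant_codon(exon, "CTA", fallback=_benign_exons)
        pos = cds_to_genomic(3 * ci + 3)  # CTA -> CTG (Leu)
        add_variant(pos, pos + 1, "A", "G", "synonymous_variant", {}, lof=False)

    def plant_utr() -> None:
        pos = exons[0][0] + int(rng.integers(10, UTR5 - 10))
        add_variant(pos, pos + 1, "A", "G", "utr_variant", {}, lof=False)

    def plant_intronic(distance: int, intron_idx: int,
                       submissions: Optional[int] = None) -> None:
        ilen = introns[intron_idx - 1]
        assert 1 <= distance <= ilen - 50, "intron too short for planting"
        pos = exons[intron_idx - 1][1] + distance - 1
        deep = distance >= cfgmod.DEEP_INTRONIC_MIN_DISTANCE
        add_variant(pos, pos + 1, "A", "G", "intron_variant",
                    {"splice_correction": pheno_ok and deep},
                    lof=False, submissions=submissions)

    # --- scenario plantings -------------------------------------------------
    if scen == "deep_intronic":
        idx = int(rng.integers(2, n - 1))
        d = int(rng.integers(50, introns[idx - 1] - 50 + 1))
        plant_intronic(d, idx)
    elif scen == "deep_intronic_recurrent":
        plant_intronic(120, 2, submissions=4)
    elif scen == "deep_intronic_twice_submitted":
        plant_intronic(200, 2, submissions=2)
    elif scen == "intronic_49":
        plant_intronic(49, 2)
    elif scen in {"es_ve", "es_ve_loss_pos"}:
        plant_stop(planted_exon, flags={"es_ve": pheno_ok})
    elif scen == "es_ve_loss_neg":
        plant_stop(planted_exon)  # loss just above 10%: not targetable
    elif scen == "es_rf_sv":
        s = exons[planted_exon - 1][0] - int(rng.integers(10, 60))
        e = exons[planted_exon - 1][1] + int(rng.integers(10, 60))
        add_variant(s, e, "", "", "sv", {"es_rf": pheno_ok}, lof=False)
    elif scen == "es_rf_first_exon_sv":
        add_variant(exons[0][0] - 20, exons[0][1] + 30, "", "", "sv", {},
                    lof=False)
    elif scen == "es_rf_splice":
        d = int(rng.integers(1, cfgmod.CANONICAL_SPLICE_WINDOW + 1))
        if splice_site == "donor":
            pos = exons[planted_exon - 1][1] + d - 1
            klass = "splice_donor_variant"
        else:
            pos = exons[planted_exon - 1][0] - d
            klass = "splice_acceptor_variant"
        add_variant(pos, pos + 1, "G", "T", klass,
                    {"es_rf": pheno_ok}, lof=True)
    elif scen in {"upregulation", "upreg_pli_boundary"}:
        for h in stop_hosts:
            plant_stop(h)
        plant_missense(int(rng.integers(2, n)))
    elif scen == "upreg_ratio_boundary":
        for h in stop_hosts:
            plant_stop(h)
        for _ in range(4):
            plant_missense(int(rng.integers(2, n)))
    elif scen == "nmd_escape_last_exon":
        plant_stop(n, escape_last_exon=True)

    # filler variants (benign classes, never strategy-positive)
    filler_kinds = ["missense", "synonymous", "shallow_intron", "utr"]
    n_filler = 2 if scen == "filler_ambiguous" else cfg.n_filler_variants
    for k in range(n_filler):
        kind = filler_kinds[k % len(filler_kinds)]
        if kind == "missense":
            plant_missense(int(rng.integers(2, n)))
        elif kind == "synonymous":
            plant_synonymous(int(rng.integers(2, n)))
        elif kind == "shallow_intron":
            plant_intronic(int(rng.integers(9, 49)), int(rng.integers(1, n)))
        else:
            plant_utr()

    if scen == "filler_ambiguous":
        # ambiguous external annotations exercising the SpliceAI rule
        for truth_class, ds_ag in (
            ("splice_region_variant", 0.35),
            ("missense_variant", 0.10),
        ):
            ci = plant_codon(int(rng.integers(2, n)), "GCT",
                             fallback=_benign_exons)
            pos = cds_to_genomic(3 * ci + 2)
            row = add_variant(pos, pos + 1, "C", "G", truth_class, {},
                              lof=False)
            annotations[row["variant_id"]] = {
                "consequences": "splice_region_variant,missense_variant",
                "DS_AG": ds_ag, "DS_AL": 0.02, "DS_DG": 0.0, "DS_DL": 0.0,
            }

    transcript = TranscriptModel(
        transcript_id=f"TX_{plan.gene}",
        gene=plan.gene,
        chromosome=chrom,
        strand="+",
        exons=tuple(exons),
        cds_start=cds_start,
        cds_end=cds_end,
        mane=True,
        cds_sequence="".join(codons),
    )
    if plan.strand == "-":
        m = 2 * offset + (exons[-1][1] - exons[0][0])
        transcript = mirror_transcript(transcript, m)
        for row in variants:
            row["start"], row["end"] = mirror_interval(
                (row["start"], row["end"]), m)

    plan.n_lof_planted = sum(r["_lof"] for r in variants)
    plan.n_variants_planted = len(variants)
    return _BuiltGene(plan=plan, transcript=transcript, variants=variants,
                      annotations=annotations)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

_UPREG_LIST_PATTERNS = [
    {"tango"}, {"uaug"}, {"are"}, set(),
    {"tango", "uaug"}, {"tango", "uaug", "are"}, {"uaug", "are"}, {"tango"},
]
# lncRNA plan cycling with the list patterns above
_UPREG_LNCRNA = ["planted", None, "planted", "planted",
                 None, "planted", "zero_tpm", None]

# source-evidence patterns reaching a retention score >= 3
_SCORE_PATTERNS = [
    [("sysndd", "definitive"), ("hpo", None)],                       # 3
    [("sysndd", "moderate"), ("ddg2p", "strong"), ("hpo", None)],    # 3
    [("panel", None), ("sysndd", "limited")],                        # 3
    [("sysndd", "definitive"), ("ddg2p", "definitive"), ("hpo", None)],  # 5
]
_LOW_SCORE_PATTERN = [("ddg2p", "limited"), ("hpo", None)]           # 2


def negative_controls() -> List[dict]:
    """Boundary-probing negative (and matched positive) gene plans.

    Each entry pins one strict/non-strict inequality of the rule set:
    distance 49, submissions 2, pLI exactly 0.9, LoF ratio exactly 0.2,
    CDS loss exactly 10% vs just above, first/last-exon exclusions, NMD
    escape in the last exon, and a seizure phenotype voided by neonatal
    lethality.
    """
    return [
        dict(scenario="intronic_49", inheritance="AR", phenotype="targetable",
             pli=0.3),
        dict(scenario="deep_intronic_twice_submitted", inheritance="AR",
             phenotype="targetable", pli=0.3),
        dict(scenario="deep_intronic", inheritance="AR", phenotype="lethal",
             pli=0.3),
        dict(scenario="upreg_pli_boundary", inheritance="AD",
             phenotype="targetable", pli=0.9),
        dict(scenario="upreg_ratio_boundary", inheritance="AD",
             phenotype="targetable", pli=0.97),
        dict(scenario="es_ve_loss_pos", inheritance="AR",
             phenotype="targetable", pli=0.2),
        dict(scenario="es_ve_loss_neg", inheritance="AR",
             phenotype="targetable", pli=0.2),
        dict(scenario="nmd_escape_last_exon", inheritance="AD",
             phenotype="targetable", pli=0.95, lists={"tango"}),
        dict(scenario="es_rf_first_exon_sv", inheritance="AR",
             phenotype="targetable", pli=0.4),
        dict(scenario="filler", inheritance="AR", phenotype="none", pli=0.1),
    ]


def _schedule(cfg: CohortConfig, rng: np.random.Generator) -> List[_GenePlan]:
    counts = {
        k: int(round(f * cfg.n_genes)) for k, f in cfg.planted_fractions.items()
    }
    scenarios: List[dict] = []
    for _ in range(counts.get("deep_intronic", 0)):
        scenarios.append(dict(scenario="deep_intronic", inheritance="AR",
                              phenotype="targetable", pli=0.3))
    for _ in range(counts.get("es_rf_sv", 0)):
        scenarios.append(dict(scenario="es_rf_sv", inheritance="AR",
                              phenotype="targetable", pli=0.5))
    for _ in range(counts.get("es_rf_splice", 0)):
        scenarios.append(dict(scenario="es_rf_splice", inheritance="AR",
                              phenotype="targetable", pli=0.5))
    for _ in range(counts.get("es_ve", 0)):
        scenarios.append(dict(scenario="es_ve", inheritance="AR",
                              phenotype="targetable", pli=0.4))
    for i in range(counts.get("upregulation", 0)):
        scenarios.append(dict(
            scenario="upregulation", inheritance="AD", phenotype="targetable",
            pli=float(0.92 + 0.01 * (i % 8)),
            lists=set(_UPREG_LIST_PATTERNS[i % 8]),
            lncrna=_UPREG_LNCRNA[i % 8],
        ))
    if scenarios and counts.get("deep_intronic", 0) > 0:
        scenarios[0]["scenario"] = "deep_intronic_recurrent"
    n_filler = cfg.n_genes - len(scenarios)
    if n_filler < 0:
        raise GenerationError("planted fractions exceed n_genes")
    filler_phenos = ["targetable", "none", "targetable", "lethal"]
    for i in range(n_filler):
        scen = "filler_ambiguous" if i == 0 else "filler"
        lists = {"tango", "uaug"} if i % 4 == 1 else set()  # gate-failing members
        scenarios.append(dict(scenario=scen, inheritance="AR",
                              phenotype=filler_phenos[i % 4], pli=0.2,
                              lists=lists))
    if cfg.include_negative_controls:
        scenarios.extend(negative_controls())

    plans: List[_GenePlan] = []
    for i, sc in enumerate(scenarios):
        plans.append(_GenePlan(
            gene=f"GENE{i + 1:03d}",
            omim=f"OMIM:{600001 + i}",
            inheritance=sc["inheritance"],
            scenario=sc["scenario"],
            phenotype=sc["phenotype"],
            pli=sc["pli"],
            lists=set(sc.get("lists", set())),
            lncrna=sc.get("lncrna"),
            strand="+" if i % 2 == 0 else "-",
            score_pattern=i % len(_SCORE_PATTERNS),
        ))
    # two excluded associations: low score and missing OMIM id
    plans.append(_GenePlan(
        gene=f"GENE{len(plans) + 1:03d}", omim=f"OMIM:{600001 + len(plans)}",
        inheritance="AR", scenario="excluded_low_score", phenotype="none",
        pli=0.1, retained=False, exclusion_reason="low_score",
    ))
    plans.append(_GenePlan(
        gene=f"GENE{len(plans) + 1:03d}", omim=None,
        inheritance="AR", scenario="excluded_no_omim", phenotype="none",
        pli=0.1, retained=False, exclusion_reason="no_omim",
    ))
    return plans


def _exact_corr_partner(rng: np.random.Generator, g: np.ndarray,
                        rho: float) -> np.ndarray:
    """A vector whose sample Pearson correlation with ``g`` is exactly ρ."""
    ghat = (g - g.mean()) / g.std()
    e = rng.normal(size=g.size)
    resid = e - (e @ ghat) / (ghat @ ghat) * ghat
    resid = resid / resid.std() if resid.std() > 0 else resid
    l = rho * ghat + math.sqrt(1 - rho ** 2) * resid
    return l - l.min() + 1.0  # affine shift: r preserved, TPM positive


def generate_cohort(cfg: CohortConfig, out_dir) -> TruthLabels:
    """Generate a complete input bundle under ``out_dir``; returns truth.

    The bundle contains: transcripts.gtf, cds.fa, sysndd.tsv, ddg2p.tsv,
    hpo_source.tsv, panel.tsv, clinvar.tsv, annotations.tsv, hp.obo,
    phenotype_to_genes.tsv, pli.tsv, tango.tsv, uaug.tsv, are.tsv,
    tads.bed, expression.gct, lncrna.tsv, truth.json and config.json.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = TruthLabels()

    plans = _schedule(cfg, rng)

    # gate truth is decided by construction before any gene is built
    gate_by_gene: Dict[str, bool] = {}
    for p in plans:
        if p.scenario == "upregulation":
            gate = p.inheritance == "AD" and p.pli > cfgmod.PLI_THRESHOLD
        else:
            gate = False  # every other scenario fails >= 1 gate by design
        gate_by_gene[p.gene] = gate

    built: List[_BuiltGene] = []
    vid_counter = [0]
    chrom_cycle = ["chr1", "chr2", "chr3", "chr4"]
    offsets = {ch: 1_000_000 for ch in chrom_cycle}
    for i, p in enumerate(plans):
        chrom = chrom_cycle[i % len(chrom_cycle)]
        offset = offsets[chrom]
        bg = _build_gene(p, cfg, rng, chrom, offset, vid_counter, truth,
                         gate_by_gene[p.gene])
        span = bg.transcript.span
        offsets[chrom] = max(offsets[chrom], span[1]) + 100_000
        built.append(bg)

    # --- finalize truth -----------------------------------------------------
    for bg in built:
        p = bg.plan
        ratio = (p.n_lof_planted / p.n_variants_planted
                 if p.n_variants_planted else 0.0)
        truth.lof_ratio[p.gene] = ratio
        truth.gate_eligible[p.gene] = (
            p.inheritance == "AD"
            and p.pli > cfgmod.PLI_THRESHOLD
            and ratio > cfgmod.LOF_RATIO_THRESHOLD
        )
        if p.omim is not None:
            truth.phenotype_targetable[p.omim] = p.phenotype == "targetable"
        subject = f"{p.gene}|{p.omim}|{p.inheritance}"
        if not p.retained:
            truth.expected_excluded[subject] = p.exclusion_reason
            continue
        flags = {s: False for s in cfgmod.STRATEGIES}
        for row in bg.variants:
            for s, v in truth.variant_flags[row["variant_id"]].items():
                flags[s] = flags[s] or v
        truth.ndd_flags[subject] = flags
        if p.lncrna == "planted":
            truth.planted_partners[p.gene] = f"LNC_{p.gene}"

    # consistency guard: the upfront gate decision must match the planted
    # variant mix (construction error otherwise)
    for bg in built:
        p = bg.plan
        if p.scenario == "upregulation":
            assert truth.gate_eligible[p.gene] == gate_by_gene[p.gene]

    _write_bundle(cfg, built, rng, out, truth)
    (out / "truth.json").write_text(truth.to_json())
    (out / "config.json").write_text(
        json.dumps(dataclasses.asdict(cfg), indent=1, sort_keys=True))
    return truth


# ---------------------------------------------------------------------------
# bundle writers
# ---------------------------------------------------------------------------


def _write_bundle(cfg: CohortConfig, built: List[_BuiltGene],
                  rng: np.random.Generator, out: Path,
                  truth: TruthLabels) -> None:
    import pandas as pd

    # GTF + CDS FASTA
    gtf_lines = []
    fasta_lines = []
    for bg in built:
        t = bg.transcript
        attrs = (f'gene_id "{t.gene}"; transcript_id "{t.transcript_id}"; '
                 f'tag "MANE_Select";')
        span = t.span
        gtf_lines.append("\t".join([
            t.chromosome, "synthetic", "transcript", str(span[0] + 1),
            str(span[1]), ".", t.strand, ".", attrs]))
        for s, e in sorted(t.exons):
            gtf_lines.append("\t".join([
                t.chromosome, "synthetic", "exon", str(s + 1), str(e), ".",
                t.strand, ".", attrs]))
            cs, ce = max(s, t.cds_start), min(e, t.cds_end)
            if cs < ce:
                gtf_lines.append("\t".join([
                    t.chromosome, "synthetic", "CDS", str(cs + 1), str(ce),
                    ".", t.strand, "0", attrs]))
        fasta_lines.append(f">{t.transcript_id}")
        seq = t.cds_sequence
        fasta_lines.extend(seq[i:i + 60] for i in range(0, len(seq), 60))
    (out / "transcripts.gtf").write_text("\n".join(gtf_lines) + "\n")
    (out / "cds.fa").write_text("\n".join(fasta_lines) + "\n")

    # association sources
    src_rows = {"sysndd": [], "ddg2p": [], "hpo": [], "panel": []}
    for bg in built:
        p = bg.plan
        if p.exclusion_reason == "low_score":
            pattern = _LOW_SCORE_PATTERN
        elif p.exclusion_reason == "no_omim":
            pattern = [("sysndd", "definitive"), ("panel", None)]
        else:
            pattern = _SCORE_PATTERNS[p.score_pattern]
        omim = p.omim or ""
        for source, category in pattern:
            if source == "sysndd":
                src_rows["sysndd"].append({
                    "gene_symbol": p.gene, "hgnc_id": f"HGNC:{p.gene[4:]}",
                    "omim_id": omim, "inheritance": p.inheritance,
                    "category": category})
            elif source == "ddg2p":
                src_rows["ddg2p"].append({
                    "gene_symbol": p.gene, "hgnc_id": f"HGNC:{p.gene[4:]}",
                    "disease_mim": omim, "allelic_requirement": p.inheritance,
                    "confidence_category": category,
                    "organ_specificity_list": "Brain/Cognition"})
            elif source == "hpo":
                src_rows["hpo"].append({
                    "gene_symbol": p.gene, "hgnc_id": f"HGNC:{p.gene[4:]}",
                    "disease_id": omim})
            else:
                src_rows["panel"].append({
                    "gene_symbol": p.gene, "hgnc_id": f"HGNC:{p.gene[4:]}",
                    "omim_id": omim, "inheritance": p.inheritance,
                    "panel": "ID"})
    # DDG2P rows outside the organ filter (dropped at parse time)
    src_rows["ddg2p"].append({
        "gene_symbol": "CARDIAC1", "hgnc_id": "HGNC:99901",
        "disease_mim": "OMIM:699901", "allelic_requirement": "AD",
        "confidence_category": "definitive",
        "organ_specificity_list": "Heart/Cardiovasculature"})
    names = {"sysndd": "sysndd.tsv", "ddg2p": "ddg2p.tsv",
             "hpo": "hpo_source.tsv", "panel": "panel.tsv"}
    for source, rows in src_rows.items():
        pd.DataFrame(rows).to_csv(out / names[source], sep="\t", index=False)

    # ClinVar-dialect table (+ a few non-pathogenic rows dropped at parse)
    cv_rows = []
    for bg in built:
        p = bg.plan
        for row in bg.variants:
            cv_rows.append({
                "VariationID": row["variant_id"],
                "Name": f"{bg.transcript.transcript_id}:g.{row['start'] + 1}",
                "GeneSymbol": p.gene, "ClinSigSimple": 1,
                "Chromosome": row["chromosome"],
                "Start": row["start"] + 1, "Stop": row["end"],
                "ReferenceAlleleVCF": row["ref"],
                "AlternateAlleleVCF": row["alt"],
                "PhenotypeIDS": p.omim or "",
                "Submissions": row["submission_count"],
            })
    for j in range(3):
        bg = built[j % len(built)]
        cv_rows.append({
            "VariationID": f"benign{j}", "Name": "benign",
            "GeneSymbol": bg.plan.gene, "ClinSigSimple": 0,
            "Chromosome": bg.transcript.chromosome,
            "Start": bg.transcript.span[0] + 5, "Stop": bg.transcript.span[0] + 5,
            "ReferenceAlleleVCF": "A", "AlternateAlleleVCF": "C",
            "PhenotypeIDS": bg.plan.omim or "", "Submissions": 1,
        })
    header = "#Assembly: GRCh38\n"
    cv = pd.DataFrame(cv_rows)
    (out / "clinvar.tsv").write_text(
        header + cv.to_csv(sep="\t", index=False))

    # external annotations (ambiguous cases only)
    ann_rows = []
    for bg in built:
        for vid, entry in bg.annotations.items():
            ann_rows.append({"variant_id": vid, **entry})
    pd.DataFrame(
        ann_rows,
        columns=["variant_id", "consequences", "DS_AG", "DS_AL", "DS_DG", "DS_DL"],
    ).to_csv(out / "annotations.tsv", sep="\t", index=False)

    # ontology + disease phenotype annotations
    obo = ["format-version: 1.2", "ontology: hp-synthetic", ""]

    def term(tid, name, parent=None):
        obo.extend(["[Term]", f"id: {tid}", f"name: {name}"])
        if parent:
            obo.append(f"is_a: {parent}")
        obo.append("")

    term("HP:0000001", "All")
    term("HP:0000118", "Phenotypic abnormality", "HP:0000001")
    for root in cfgmod.PHENOTYPE_INCLUDE_ROOTS:
        term(root, f"included root {root}", "HP:0000118")
        child, grandchild = _ROOT_CHILDREN[root]
        term(child, f"child of {root}", root)
        term(grandchild, f"grandchild of {root}", child)
    term(cfgmod.PHENOTYPE_EXCLUDE_ROOT, "Neonatal death", "HP:0000118")
    term(_LETHAL_CHILD, "lethal subterm", cfgmod.PHENOTYPE_EXCLUDE_ROOT)
    term("HP:0880001", "unrelated finding", "HP:0000118")
    (out / "hp.obo").write_text("\n".join(obo))

    p2g_rows = []
    roots = list(cfgmod.PHENOTYPE_INCLUDE_ROOTS)
    for i, bg in enumerate(built):
        p = bg.plan
        if p.omim is None:
            continue
        if p.phenotype == "targetable":
            root = roots[i % len(roots)]
            depth = i % 3  # root, child or grandchild annotation
            tid = ([root] + list(_ROOT_CHILDREN[root]))[depth]
            p2g_rows.append({"hpo_id": tid, "hpo_name": "x",
                             "gene_symbol": p.gene, "disease_id": p.omim})
            if i % 2 == 0:
                p2g_rows.append({"hpo_id": "HP:0880001", "hpo_name": "x",
                                 "gene_symbol": p.gene, "disease_id": p.omim})
        elif p.phenotype == "lethal":
            child, _ = _ROOT_CHILDREN[roots[4]]  # seizures subterm
            p2g_rows.append({"hpo_id": child, "hpo_name": "x",
                             "gene_symbol": p.gene, "disease_id": p.omim})
            p2g_rows.append({"hpo_id": _LETHAL_CHILD, "hpo_name": "x",
                             "gene_symbol": p.gene, "disease_id": p.omim})
        # phenotype == "none": no annotation rows at all
    pd.DataFrame(p2g_rows).to_csv(
        out / "phenotype_to_genes.tsv", sep="\t", index=False)

    # pLI and gene lists
    pd.DataFrame(
        [{"gene": bg.plan.gene, "pLI": bg.plan.pli} for bg in built]
    ).to_csv(out / "pli.tsv", sep="\t", index=False)
    for list_name in ("tango", "uaug", "are"):
        members = [bg.plan.gene for bg in built if list_name in bg.plan.lists]
        pd.DataFrame({list_name: members}).to_csv(
            out / f"{list_name}.tsv", sep="\t", index=False)

    # TADs, lncRNA catalog, expression
    tad_rows, lnc_rows = [], []
    expr: Dict[str, np.ndarray] = {}
    tissues = BRAIN_TISSUES + OTHER_TISSUES
    nb = len(BRAIN_TISSUES)
    decoy_host_genes = {
        bg.plan.gene for bg in built if bg.plan.scenario.startswith("filler")
    }
    decoys_per_host = max(
        1, -(-cfg.n_decoy_lncrnas // max(1, len(decoy_host_genes)))
    )
    n_decoys = 0
    for bg in built:
        p = bg.plan
        t = bg.transcript
        s, e = t.span
        tad_rows.append({"chrom": t.chromosome, "start": s - 5000,
                         "end": e + 5000})
        gvec = np.abs(rng.normal(10, 4, nb)) + 0.5
        full = np.concatenate([gvec, np.abs(rng.normal(5, 2, len(OTHER_TISSUES)))])
        expr[p.gene] = full
        if p.lncrna == "planted":
            lid = f"LNC_{p.gene}"
            lnc_rows.append({"chrom": t.chromosome, "start": e + 1000,
                             "end": e + 2500, "lncrna_id": lid,
                             "biotype": "lncRNA"})
            lvec = _exact_corr_partner(rng, gvec, cfg.partner_rho)
            expr[lid] = np.concatenate(
                [lvec, np.abs(rng.normal(2, 1, len(OTHER_TISSUES)))])
        elif p.lncrna == "zero_tpm":
            lid = f"LNC_{p.gene}"
            lnc_rows.append({"chrom": t.chromosome, "start": e + 1000,
                             "end": e + 2500, "lncrna_id": lid,
                             "biotype": "lncRNA"})
            expr[lid] = np.concatenate(
                [np.zeros(nb), np.abs(rng.normal(2, 1, len(OTHER_TISSUES)))])
        if p.gene in decoy_host_genes and n_decoys < cfg.n_decoy_lncrnas:
            for d in range(decoys_per_host):
                if n_decoys >= cfg.n_decoy_lncrnas:
                    break
                lid = f"LNCD_{p.gene}_{d}"
                # stacked inside the host gene's TAD (overlaps are fine)
                lnc_rows.append({"chrom": t.chromosome,
                                 "start": e + 1000 + 150 * (d % 20),
                                 "end": e + 1600 + 150 * (d % 20),
                                 "lncrna_id": lid, "biotype": "lncRNA"})
                expr[lid] = np.abs(rng.normal(5, 3, len(tissues))) + 0.1
                n_decoys += 1
    # a non-lncRNA biotype row (filtered out by the catalog reader)
    lnc_rows.append({"chrom": "chr1", "start": 100, "end": 200,
                     "lncrna_id": "PSEUDO_1", "biotype": "pseudogene"})
    pd.DataFrame(tad_rows).to_csv(out / "tads.bed", sep="\t", index=False,
                                  header=False)
    pd.DataFrame(lnc_rows).to_csv(out / "lncrna.tsv", sep="\t", index=False,
                                  header=False)

    ids = sorted(expr)
    mat = pd.DataFrame(
        {t: [round(float(expr[g][j]), 4) for g in ids]
         for j, t in enumerate(tissues)},
        index=ids,
    )
    with open(out / "expression.gct", "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{len(ids)}\t{len(tissues)}\n")
        fh.write("Name\tDescription\t" + "\t".join(tissues) + "\n")
        for g in ids:
            fh.write(g + "\tna\t" + "\t".join(str(v) for v in mat.loc[g]) + "\n")
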
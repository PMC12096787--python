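"""Roll per-variant and per-gene evidence into seven-strategy profiles.

A disorder is targetable for a strategy when at least one attached variant
carries the full combination of required characteristics for it; a variant
(weighted by its ClinVar submission count, the occurrence proxy) is
targetable when its own type fits the strategy and its disease and gene
pass the strategy's disease/gene-level requirements.  Phenotype
targetability gates all seven strategies; the four gene-based strategies
additionally require the haploinsufficiency gate and at least one attached
loss-of-function variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd

from . import config
from .dataset_builder import DiseaseGeneAssociation
from .gene_strategies import GeneDossier, UpregulationGate
from .phenotype import PhenotypeCall
from .variant_annotation import AnnotatedVariant, is_lof
from .variant_strategies import SkipPlan

STRATEGIES = config.STRATEGIES


@dataclass
class VariantAssessment:
    """All strategy-relevant facts about one variant on one transcript."""

    variant: AnnotatedVariant
    splice_targetable: bool = False
    splice_distance: Optional[int] = None
    es_ve_plan: Optional[SkipPlan] = None
    es_rf_plans: List[SkipPlan] = field(default_factory=list)

    @property
    def lof(self) -> bool:
        return is_lof(self.variant)

    @property
    def es_ve_accepted(self) -> bool:
        return self.es_ve_plan is not None and self.es_ve_plan.accepted

    @property
    def es_rf_accepted(self) -> bool:
        return any(p.accepted for p in self.es_rf_plans)


@dataclass
class StrategyProfile:
    """Per-subject boolean amenability across the seven AON strategies."""

    subject_type: str  # ndd | variant
    subject_id: str
    gene: str
    flags: Dict[str, bool]
    evidence: Dict[str, object] = field(default_factory=dict)
    submission_count: int = 0

    @property
    def any_strategy(self) -> bool:
        return any(self.flags.values())


def variant_flags(
    va: VariantAssessment,
    phenotype: PhenotypeCall,
    gate: UpregulationGate,
    dossier: GeneDossier,
) -> Dict[str, bool]:
    """Seven-strategy flags for one variant under one association."""
    pheno = phenotype.targetable
    gene_gate = pheno and gate.eligible and va.lof
    return {
        "splice_correction": pheno and va.splice_targetable,
        "es_rf": pheno and va.es_rf_accepted,
        "es_ve": pheno and va.es_ve_accepted,
        "tango": gene_gate and dossier.in_tango_list,
        "uaug": gene_gate and dossier.in_uaug_list,
        "are": gene_gate and dossier.in_are_list,
        "lncrna": gene_gate and bool(dossier.lncrna_partners),
    }


def profile_ndd(
    a: DiseaseGeneAssociation,
    assessments: List[VariantAssessment],
    phenotype: PhenotypeCall,
    gate: UpregulationGate,
    dossier: GeneDossier,
) -> StrategyProfile:
    """Profile one disorder: each flag is the OR over its attached
    variants' flags (phenotype gating applies to all seven)."""
    flags = {s: False for s in STRATEGIES}
    for va in assessments:
        vf = variant_flags(va, phenotype, gate, dossier)
        for s in STRATEGIES:
            flags[s] = flags[s] or vf[s]
    evidence = {
        "phenotype_targetable": phenotype.targetable,
        "matched_hpo_roots": sorted(phenotype.matched_terms),
        "gate_eligible": gate.eligible,
        "gate_reasons": sorted(gate.reasons),
        "n_variants": len(assessments),
        "n_lof_variants": sum(va.lof for va in assessments),
        "lncrna_partners": [p.lncrna_id for p in dossier.lncrna_partners],
    }
    return StrategyProfile(
        subject_type="ndd",
        subject_id=f"{a.gene}|{a.omim_disease_id}|{a.inheritance}",
        gene=a.gene,
        flags=flags,
        evidence=evidence,
        submission_count=sum(va.variant.submission_count for va in assessments),
    )


def profile_submissions(
    links: Dict[Tuple, List[VariantAssessment]],
    phenotypes: Dict[Tuple, PhenotypeCall],
    gates: Dict[Tuple, UpregulationGate],
    dossiers: Dict[str, GeneDossier],
) -> List[StrategyProfile]:
    """Per-variant profiles weighted by submission count.

    ``links`` maps association keys (gene, omim, inheritance) to the
    variant assessments attached to them.  A variant attached to several
    associations gets one profile whose flags are the union over those
    associations, so its submissions are never counted twice.
    """
    by_variant: Dict[str, StrategyProfile] = {}
    for key, assessments in links.items():
        gene = key[0]
        phenotype = phenotypes[key]
        gate = gates[key]
        dossier = dossiers[gene]
        for va in assessments:
            vf = variant_flags(va, phenotype, gate, dossier)
            vid = va.variant.variant_id
            existing = by_variant.get(vid)
            if existing is None:
                by_variant[vid] = StrategyProfile(
                    subject_type="variant",
                    subject_id=vid,
                    gene=gene,
                    flags=vf,
                    evidence={"associations": [key]},
                    submission_count=va.variant.submission_count,
                )
            else:
                for s in STRATEGIES:
                    existing.flags[s] = existing.flags[s] or vf[s]
                existing.evidence["associations"].append(key)
    return list(by_variant.values())


def profiles_frame(profiles: Iterable[StrategyProfile]) -> pd.DataFrame:
    """Tabular view of profiles (one row per subject)."""
    rows = []
    for p in profiles:
        row = {
            "subject_type": p.subject_type,
            "subject_id": p.subject_id,
            "gene": p.gene,
            "submission_count": p.submission_count,
        }
        row.update({s: bool(p.flags[s]) for s in STRATEGIES})
        row["any_strategy"] = p.any_strategy
        row["evidence"] = p.evidence
        rows.append(row)
    cols = (
        ["subject_type", "subject_id", "gene", "submission_count"]
        + list(STRATEGIES)
        + ["any_strategy", "evidence"]
    )
    return pd.DataFrame(rows, columns=cols)


def upset_table(
    profiles: Iterable[StrategyProfile],
    mode: str = "distinct",
    weighted: bool = False,
) -> pd.DataFrame:
    """Combination table over the seven strategy flags.

    ``distinct`` mode partitions subjects by their exact flag combination
    (counts sum to the number of flagged subjects); ``intersect`` mode
    counts, for every observed combination, the subjects satisfying at
    least that combination (overlapping).  A ``union`` row reports the
    number of subjects with any strategy.  With ``weighted=True`` counts
    aggregate submission counts instead of subjects.
    """
    if mode not in {"distinct", "intersect"}:
        raise ValueError(f"mode must be 'distinct' or 'intersect', got {mode!r}")
    profiles = list(profiles)
    weight = (
        (lambda p: p.submission_count) if weighted else (lambda p: 1)
    )
    combos: Dict[frozenset, int] = {}
    observed = set()
    for p in profiles:
        on = frozenset(s for s in STRATEGIES if p.flags[s])
        if on:
            observed.add(on)
    if mode == "distinct":
        for p in profiles:
            on = frozenset(s for s in STRATEGIES if p.flags[s])
            if on:
                combos[on] = combos.get(on, 0) + weight(p)
    else:
        for combo in observed:
            combos[combo] = sum(
                weight(p)
                for p in profiles
                if combo <= frozenset(s for s in STRATEGIES if p.flags[s])
            )
    union = sum(weight(p) for p in profiles if p.any_strategy)
    rows = [
        {
            "combination": "|".join(s for s in STRATEGIES if s in combo),
            "degree": len(combo),
            "count": count,
        }
        for combo, count in combos.items()
    ]
    rows.sort(key=lambda r: (-r["count"], r["combination"]))
    rows.append({"combination": "union", "degree": 0, "count": union})
    return pd.DataFrame(rows, columns=["combination", "degree", "count"])


def aon_economics(
    variant_profiles: List[StrategyProfile],
    assessments: Dict[str, VariantAssessment],
    strategy: str,
    recurrent_only: bool = False,
) -> dict:
    """Amenable individuals and AONs needed for one strategy.

    AONs needed: unique targetable variants (splice correction, optionally
    restricted to recurrent variants with >= 3 submissions), unique
    (gene, exon) pairs over accepted plans (ES-RF/ES-VE), or unique genes
    (the four gene-based strategies).  ``individuals_per_aon`` is reported
    as None when no AON is needed.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    flagged = [p for p in variant_profiles if p.flags[strategy]]
    if strategy == "splice_correction" and recurrent_only:
        flagged = [
            p for p in flagged
            if p.submission_count >= config.RECURRENT_MIN_SUBMISSIONS
        ]
    amenable = sum(p.submission_count for p in flagged)

    if strategy == "splice_correction":
        aons = len({p.subject_id for p in flagged})
    elif strategy in {"es_rf", "es_ve"}:
        pairs = set()
        for p in flagged:
            va = assessments[p.subject_id]
            plans = (
                [va.es_ve_plan] if strategy == "es_ve" else va.es_rf_plans
            )
            for plan in plans:
                if plan is not None and plan.accepted:
                    for exon in plan.exons_to_skip:
                        pairs.add((p.gene, exon))
        aons = len(pairs)
    else:
        aons = len({p.gene for p in flagged})

    return {
        "strategy": strategy,
        "recurrent_only": recurrent_only,
        "amenable_individuals": amenable,
        "aons_needed": aons,
        "individuals_per_aon": (amenable / aons) if aons else None,
    }
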